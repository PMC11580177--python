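import pytest

import fluxdiff as fd
from fluxdiff.synthetic import write_bundle


@pytest.fixture(scope="session")
def toy():
    """Deterministic 2-branch toy model with its planted truth."""
    return fd.make_toy_model(n_branches=2, branch_length=5, seed=1)


@pytest.fixture(scope="session")
def noise_free_bundle(tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    return write_bundle(d / "sigma0", sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def noise_free_report(noise_free_bundle, tmp_path_factory):
    """Full pipeline run on the noise-free bundle (shared across tests)."""
    out = tmp_path_factory.mktemp("run") / "out"
    cfg = _bundle_config(noise_free_bundle, out)
    report = fd.run_pipeline(cfg)
    truth = fd.SyntheticTruth.from_json(noise_free_bundle / "truth.json")
    return report, truth, cfg


def _bundle_config(bundle, outdir):
    return fd.PipelineConfig(
        model_sbml=str(bundle / "model.xml"),
        peptides=str(bundle / "peptides.tsv"),
        design=str(bundle / "design.tsv"),
        id_map=str(bundle / "id_map.tsv"),
        gene_gmt=str(bundle / "gene_sets.gmt"),
        metabolite_gmt=str(bundle / "metabolite_sets.gmt"),
        risk_genes=str(bundle / "risk_genes.txt"),
        outdir=str(outdir),
        biomass_id="R_biomass", ngam_id="R_ngam",
        glucose_uptake_id="EX_glc", oxygen_uptake_id="EX_o2",
    )


@pytest.fixture
def bundle_config():
    return _bundle_config
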