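#!/usr/bin/env python
"""Merge the two regulated-gene/metabolite lists and run enrichment.

Gene and metabolite lists from ΔFBA (03) and the iMAT consensus (04) are
merged with source tags, then tested for over-representation against the
bundle's GMT collections with the hypergeometric test and BH FDR < 0.05
(metabolite sets additionally require >= 4 overlapping members). The
synthetic risk-gene list is cross-referenced against the significant
proteins.
"""

from pathlib import Path

import fluxdiff as fd
from fluxdiff.enrichment import crossref_gene_list
from fluxdiff.model_io import read_id_map
from fluxdiff.proteomics import (filter_peptides, moderated_diff, read_design,
                                 read_peptide_table, rollup_and_normalize)

BUNDLE = Path("results/bundle")
OUT = Path("results")


def _read_list(path: Path) -> set[str]:
    return {l.strip() for l in path.read_text().splitlines() if l.strip()}


def main() -> None:
    dfba_genes = _read_list(OUT / "dfba_genes.txt")
    imat_genes = _read_list(OUT / "imat_genes.txt")
    merged_genes = fd.merge_regulated_lists(dfba_genes, imat_genes)
    merged_genes.to_csv(OUT / "merged_genes.tsv", sep="\t", index=False)
    both = (merged_genes["source"] == "both").sum()
    print(f"merged gene list: {len(merged_genes)} genes "
          f"({len(dfba_genes)} ΔFBA, {len(imat_genes)} iMAT, {both} shared)")

    merged_mets = fd.merge_regulated_lists(
        _read_list(OUT / "dfba_metabolites.txt"),
        _read_list(OUT / "imat_metabolites.txt"))
    merged_mets.to_csv(OUT / "merged_metabolites.tsv", sep="\t", index=False)
    print(f"merged metabolite list: {len(merged_mets)} metabolites")

    model = fd.read_sbml(BUNDLE / "model.xml")
    id_map = read_id_map(BUNDLE / "id_map.tsv")
    design = read_design(BUNDLE / "design.tsv")
    matrix = rollup_and_normalize(
        filter_peptides(read_peptide_table(BUNDLE / "peptides.tsv")), design)
    measured = {id_map[p] for p in matrix.proteins if p in id_map}

    gene_ora = fd.ora(set(merged_genes["id"]),
                      fd.read_gmt(BUNDLE / "gene_sets.gmt"),
                      set(model.genes) & measured, min_overlap=1)
    gene_ora.to_csv(OUT / "gene_enrichment.tsv", sep="\t", index=False)
    sig = gene_ora[gene_ora["significant"]]
    print(f"gene sets enriched at FDR < 0.05: {list(sig['set'])}")

    met_ora = fd.ora(set(merged_mets["id"]),
                     fd.read_gmt(BUNDLE / "metabolite_sets.gmt"),
                     set(model.metabolite_ids), min_overlap=4)
    met_ora.to_csv(OUT / "metabolite_enrichment.tsv", sep="\t", index=False)
    sig_m = met_ora[met_ora["significant"]]
    print(f"metabolite sets enriched at FDR < 0.05 with >= 4 overlaps: "
          f"{list(sig_m['set'])}")

    diff = moderated_diff(matrix)
    risk = crossref_gene_list(diff, _read_list(BUNDLE / "risk_genes.txt"),
                              id_map)
    risk.to_csv(OUT / "risk_gene_overlap.tsv", sep="\t", index=False)
    print(f"significant proteins overlapping the risk-gene list: {len(risk)}")


if __name__ == "__main__":
    main()
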