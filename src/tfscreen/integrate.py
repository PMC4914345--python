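"""Integration of the RNA, DNA and protein screens into a candidate table.

Motif-level hits from the DNA and protein assays are mapped to the TF genes
that recognise them; a gene becomes a candidate when it appears in at least
2 of the 3 assays.
"""

from __future__ import annotations

import warnings

import pandas as pd

ASSAYS = ("rna", "dna", "protein")


def read_motif_gene_map(path) -> dict[str, set[str]]:
    """TSV with columns motif_id, gene_symbol (one pair per row)."""
    table = pd.read_csv(path, sep="\t")
    mapping: dict[str, set[str]] = {}
    for motif, gene in zip(table["motif_id"], table["gene_symbol"]):
        mapping.setdefault(motif, set()).add(gene)
    return mapping


def map_motifs_to_genes(motif_set, mapping: dict[str, set[str]]) -> set[str]:
    """Union of TF genes recognising the given motifs; unmapped motifs warn."""
    unmapped = sorted(m for m in motif_set if m not in mapping)
    if unmapped:
        warnings.warn(f"{len(unmapped)} motifs without gene annotation: "
                      f"{unmapped[:5]}", stacklevel=2)
    out: set[str] = set()
    for m in motif_set:
        out |= mapping.get(m, set())
    return out


def integrate(
    rna_genes,
    dna_genes,
    protein_genes,
    min_assays: int = 2,
) -> pd.DataFrame:
    """Candidate table over the union of the three assay gene sets.

    Returns a DataFrame indexed by gene with boolean columns in_rna, in_dna,
    in_protein, an n_assays count, and candidate = (n_assays >= min_assays),
    sorted by n_assays descending then gene symbol.
    """
    if not 1 <= min_assays <= 3:
        raise ValueError(f"min_assays must be in 1..3, got {min_assays}")
    sets = {"rna": set(rna_genes), "dna": set(dna_genes), "protein": set(protein_genes)}
    union = sorted(sets["rna"] | sets["dna"] | sets["protein"])
    table = pd.DataFrame(
        {f"in_{a}": [g in sets[a] for g in union] for a in ASSAYS},
        index=pd.Index(union, name="gene"),
    )
    table["n_assays"] = table[[f"in_{a}" for a in ASSAYS]].sum(axis=1)
    table["candidate"] = table["n_assays"] >= min_assays
    return table.sort_values(
        ["n_assays", "gene"], ascending=[False, True], kind="mergesort"
    )


def venn_counts(rna_genes, dna_genes, protein_genes) -> dict[str, int]:
    """Sizes of the seven Venn regions of the three assay gene sets."""
    r, d, p = set(rna_genes), set(dna_genes), set(protein_genes)
    return {
        "rna_only": len(r - d - p),
        "dna_only": len(d - r - p),
        "protein_only": len(p - r - d),
        "rna_dna_only": len((r & d) - p),
        "rna_protein_only": len((r & p) - d),
        "dna_protein_only": len((d & p) - r),
        "all_three": len(r & d & p),
    }
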