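"""End-to-end orchestration of the primary and secondary screens.

The primary screen runs the RNA meta-analysis, the promoter-motif
over-representation screen and the protein/DNA array comparison, maps motif
hits to TF genes and integrates the three gene sets with the >=2-of-3 rule.
Every stage writes its intermediate table and the run emits a manifest with
the effective configuration, the seed, per-stage funnel counts and SHA-256
hashes of every output, so identical configurations produce identical runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import dna_screen, growth, protein_screen, rna_screen
from .integrate import integrate as integrate_assays
from .integrate import map_motifs_to_genes, venn_counts
from .simulate import ScreenData, SimConfig, simulate_screen


@dataclass
class RunConfig:
    """Thresholds and inputs of a full screen run; defaults follow the design."""

    seed: int = 0
    alpha_rna: float = 0.05
    alpha_geneset: float = 0.01
    alpha_motif: float = 0.05
    scan_threshold: float = 0.85
    motif_test: str = "binomial"
    fc_min: float = 1.4
    alpha_array: float = 0.05
    min_assays: int = 2
    reduced_max: float = 66.0
    min_lines: int = 2
    min_fraction_measured: float = 0.5
    n_control_genes: int = 1500
    sim: dict = field(default_factory=dict)  # SimConfig overrides, synthetic mode

    def __post_init__(self) -> None:
        for fld in ("alpha_rna", "alpha_geneset", "alpha_motif", "alpha_array"):
            v = getattr(self, fld)
            if not 0 < v <= 1:
                raise ValueError(f"{fld} must be in (0, 1], got {v}")
        if not 1 <= self.min_assays <= 3:
            raise ValueError("min_assays must be in 1..3")
        if not 0 <= self.scan_threshold <= 1:
            raise ValueError("scan_threshold must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PrimaryResult:
    rna_genes: list[str]
    signature_genes: list[str]
    enriched_motifs: list[str]
    dna_genes: list[str]
    bound_motifs: list[str]
    protein_genes: list[str]
    candidates: pd.DataFrame
    funnel: dict[str, int]
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_primary_screen(
    cfg: RunConfig,
    data: ScreenData | None = None,
    outdir=None,
) -> PrimaryResult:
    """Run RNA, DNA and protein stages and integrate the candidate table.

    With no ``data``, a synthetic screen is generated from ``cfg.seed`` and
    ``cfg.sim`` overrides.  When ``outdir`` is given every intermediate is
    written as TSV and a JSON manifest records thresholds, funnel counts and
    output hashes.
    """
    if data is None:
        data = simulate_screen(SimConfig(seed=cfg.seed, **cfg.sim))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # --- RNA: per-cohort one-sided tests, median-rank aggregation ---------
    p_by_cohort = {c.cohort_id: rna_screen.cohort_pvalues(c) for c in data.cohorts}
    meta = rna_screen.median_rank_aggregate(
        p_by_cohort, min_fraction_measured=cfg.min_fraction_measured
    )
    rna_genes = rna_screen.select_candidates(
        meta, data.tf_whitelist, alpha=cfg.alpha_rna
    )

    # --- DNA: signature set, controls, promoter scan, enrichment ----------
    signature = sorted(
        dna_screen.derive_signature_geneset(
            data.signature_cohorts, alpha=cfg.alpha_geneset
        )
    )
    elevated = set().union(
        *(
            set(p.index[p < cfg.alpha_geneset])
            for p in (
                rna_screen.cohort_pvalues(c) for c in data.signature_cohorts
            )
        )
    )
    promoter_universe = set(data.promoters.sequences)
    pool = promoter_universe - elevated - set(signature)
    n_ctrl = min(cfg.n_control_genes, len(pool))
    controls = dna_screen.sample_control_genes(
        pool, excluded=(), n=n_ctrl, rng=cfg.seed
    )
    sig_with_promoters = [g for g in signature if g in promoter_universe]
    records = dna_screen.enrich_all(
        data.pwms,
        data.promoters.subset(sig_with_promoters),
        data.promoters.subset(controls),
        threshold=cfg.scan_threshold,
        alpha=cfg.alpha_motif,
    )
    enriched = dna_screen.select_enriched(
        records, alpha=cfg.alpha_motif, test=cfg.motif_test
    )
    dna_genes = sorted(map_motifs_to_genes(enriched, data.motif_gene_map))

    # --- protein: array normalisation, group comparison, FC+p filter ------
    comparisons, bound = protein_screen.run_protein_screen(
        data.array_intensities,
        data.array_group_map,
        fc_min=cfg.fc_min,
        alpha=cfg.alpha_array,
    )
    protein_genes = sorted(map_motifs_to_genes(bound, data.motif_gene_map))

    # --- integration -------------------------------------------------------
    table = integrate_assays(
        rna_genes, dna_genes, protein_genes, min_assays=cfg.min_assays
    )
    funnel = {
        "tf_whitelist": len(data.tf_whitelist),
        "rna_selected": len(rna_genes),
        "signature_genes": len(signature),
        "control_genes": len(controls),
        "motifs_tested": len(data.pwms),
        "motifs_enriched": len(enriched),
        "dna_genes": len(dna_genes),
        "motifs_bound": len(bound),
        "protein_genes": len(protein_genes),
        "candidates": int(table["candidate"].sum()),
        **{f"venn_{k}": v for k, v in
           venn_counts(rna_genes, dna_genes, protein_genes).items()},
    }

    manifest = {"config": asdict(cfg), "funnel": funnel, "outputs": {}}
    if out is not None:
        meta.to_csv(out / "rna_meta.tsv", sep="\t")
        pd.Series(signature, name="gene").to_csv(
            out / "signature_genes.tsv", sep="\t", index=False
        )
        records.to_csv(out / "motif_enrichment.tsv", sep="\t")
        comparisons.to_csv(out / "array_comparison.tsv", sep="\t")
        table.to_csv(out / "candidates.tsv", sep="\t")
        cfg.to_yaml(out / "effective_config.yaml")
        for f in sorted(out.glob("*.tsv")):
            manifest["outputs"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PrimaryResult(
        rna_genes=rna_genes,
        signature_genes=signature,
        enriched_motifs=enriched,
        dna_genes=dna_genes,
        bound_motifs=bound,
        protein_genes=protein_genes,
        candidates=table,
        funnel=funnel,
        manifest=manifest,
    )


def run_secondary_screen(
    cfg: RunConfig,
    table: pd.DataFrame | None = None,
    group_map: dict[str, str] | None = None,
    outdir=None,
) -> pd.DataFrame:
    """Growth-screen hit calling; defaults to the packaged screen table."""
    if table is None or group_map is None:
        table, group_map = growth.load_sirna_screen()
    calls = growth.classify_all(
        table, group_map, min_lines=cfg.min_lines, reduced_max=cfg.reduced_max
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        calls.to_csv(out / "growth_calls.tsv", sep="\t")
    return calls
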