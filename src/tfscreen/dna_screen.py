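"""DNA screen: signature gene set, control sampling, motif over-representation.

The signature set is the intersection of per-cohort case-elevated gene
selections (one-sided Welch p < 0.01 in each of several subtype-annotated
cohorts).  Motif occurrence is binary per promoter (a promoter either
contains >=1 site at the scan threshold or it does not); over-representation
in the signature promoters relative to a random control promoter set is
tested with an upper-tail exact binomial test (default) and, as a
cross-check, a one-sided Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .promoters import PromoterSet
from .pwm import PWMatrix, has_hit
from .rna_screen import ExpressionCohort, cohort_pvalues


def derive_signature_geneset(
    cohorts: list[ExpressionCohort], alpha: float = 0.01
) -> set[str]:
    """Genes case-elevated at p < alpha in every supplied cohort."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    selections = []
    for cohort in cohorts:
        p = cohort_pvalues(cohort)
        selections.append(set(p.index[p < alpha]))
    out = selections[0]
    for s in selections[1:]:
        out &= s
    return out


def sample_control_genes(
    universe,
    excluded,
    n: int = 1500,
    rng: np.random.Generator | int | None = None,
) -> list[str]:
    """Seeded uniform sample of n genes from universe minus excluded."""
    pool = sorted(set(universe) - set(excluded))
    if len(pool) < n:
        raise ValueError(
            f"control pool has {len(pool)} genes, {n} requested "
            f"(short by {n - len(pool)})"
        )
    rng = np.random.default_rng(rng)
    return sorted(map(str, rng.choice(pool, size=n, replace=False)))


@dataclass
class EnrichmentRecord:
    """Per-motif promoter occurrence counts and over-representation tests."""

    motif_id: str
    k_target: int
    n_target: int
    k_control: int
    n_control: int
    p_binomial: float
    p_fisher: float
    enriched: bool


def _enrichment_pvalues(
    k_target: int, n_target: int, k_control: int, n_control: int
) -> tuple[float, float]:
    """Upper-tail binomial (plug-in control proportion) and one-sided Fisher p."""
    if k_control == 0 and k_target > 0:
        warnings.warn(
            "no control occurrences; binomial null proportion floored at "
            "0.5 / n_control",
            stacklevel=2,
        )
        p0 = 0.5 / n_control
    else:
        p0 = k_control / n_control
    if p0 == 0.0:
        p_binom = 1.0  # k_target == 0 as well
    else:
        p_binom = stats.binomtest(k_target, n_target, p0, alternative="greater").pvalue
    table = [[k_target, n_target - k_target], [k_control, n_control - k_control]]
    p_fisher = stats.fisher_exact(table, alternative="greater")[1]
    return float(p_binom), float(p_fisher)


def count_occurrences(
    pwm: PWMatrix, promoters: PromoterSet, threshold: float = 0.85
) -> int:
    """Number of promoters containing >=1 site at the threshold (both strands)."""
    return sum(has_hit(pwm, seq, threshold) for _, seq in promoters)


def motif_enrichment(
    pwm: PWMatrix,
    targets: PromoterSet,
    controls: PromoterSet,
    threshold: float = 0.85,
    alpha: float = 0.05,
) -> EnrichmentRecord:
    """Test one motif for over-representation in target vs control promoters."""
    if len(targets) == 0 or len(controls) == 0:
        raise ValueError("target and control promoter sets must be non-empty")
    k_t = count_occurrences(pwm, targets, threshold)
    k_c = count_occurrences(pwm, controls, threshold)
    p_binom, p_fisher = _enrichment_pvalues(k_t, len(targets), k_c, len(controls))
    return EnrichmentRecord(
        motif_id=pwm.motif_id,
        k_target=k_t,
        n_target=len(targets),
        k_control=k_c,
        n_control=len(controls),
        p_binomial=p_binom,
        p_fisher=p_fisher,
        enriched=p_binom < alpha,
    )


def enrich_all(
    pwms: list[PWMatrix],
    targets: PromoterSet,
    controls: PromoterSet,
    threshold: float = 0.85,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Enrichment records for a whole motif library as a DataFrame."""
    records = [
        motif_enrichment(pwm, targets, controls, threshold, alpha) for pwm in pwms
    ]
    return pd.DataFrame([vars(r) for r in records]).set_index("motif_id")


def select_enriched(
    records: pd.DataFrame, alpha: float = 0.05, test: str = "binomial"
) -> list[str]:
    """Motifs significant at alpha; no multiplicity correction by default."""
    col = {"binomial": "p_binomial", "fisher": "p_fisher"}[test]
    hits = records[records[col] < alpha]
    return list(hits.sort_values(col).index)
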