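"""RNA screen: per-cohort differential expression and median-rank meta-analysis.

Each cohort is tested gene-by-gene with a one-sided Welch t-test for higher
expression in the case (TNBC-like) group; genes are ranked by p-value within
each cohort, and cohorts are aggregated by the median rank.  The meta p-value
reported for a gene is the actual p-value observed in the cohort that
realises the median rank — not an interpolated quantity — which is what makes
the aggregate robust to a single outlier cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionCohort:
    """One cohort: gene×sample log-expression with a binary group label.

    ``values`` is a DataFrame with gene ids as the index and sample ids as
    columns; ``group`` maps each sample id to 1 (case) or 0 (control).
    """

    cohort_id: str
    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError(f"{self.cohort_id}: duplicated gene ids")
        if not self.values.columns.equals(self.group.index):
            self.group = self.group.reindex(self.values.columns)
            if self.group.isna().any():
                raise ValueError(f"{self.cohort_id}: group labels missing for samples")
        counts = self.group.value_counts()
        if counts.get(0, 0) == 0 or counts.get(1, 0) == 0:
            raise ValueError(f"{self.cohort_id}: both groups must be non-empty")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def case_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == 1].to_numpy()

    def control_matrix(self) -> np.ndarray:
        return self.values.loc[:, self.group == 0].to_numpy()


def _welch_one_sided(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Vectorised one-sided (case > control) Welch t-test over gene rows.

    Degenerate rows (zero variance in both groups and equal means) get
    p = 0.5, the one-sided p of t = 0.
    """
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1) / n1
    v2 = control.var(axis=1, ddof=1) / n2
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(denom)
        df = denom**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = np.where(np.isfinite(t), stats.t.sf(t, np.where(np.isfinite(df), df, 1.0)), np.nan)
    degenerate = denom == 0
    if degenerate.any():
        equal = degenerate & (m1 == m2)
        p = np.where(equal, 0.5, p)
        # zero variance but unequal means: infinitely significant one way
        p = np.where(degenerate & (m1 > m2), np.nextafter(0, 1), p)
        p = np.where(degenerate & (m1 < m2), 1.0, p)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def cohort_pvalues(cohort: ExpressionCohort) -> pd.Series:
    """One-sided Welch p-values for every gene in a cohort."""
    n_case = int((cohort.group == 1).sum())
    n_ctrl = int((cohort.group == 0).sum())
    if n_case < 2 or n_ctrl < 2:
        raise ValueError(f"{cohort.cohort_id}: need >=2 samples per group")
    p = _welch_one_sided(cohort.case_matrix(), cohort.control_matrix())
    return pd.Series(p, index=cohort.gene_ids, name=cohort.cohort_id)


def de_pvalue_one_sided(cohort: ExpressionCohort, gene_id: str) -> float:
    """One-sided Welch p-value that a single gene is higher in the case group."""
    if gene_id not in cohort.values.index:
        raise KeyError(f"gene {gene_id} not in cohort {cohort.cohort_id}")
    row = cohort.values.loc[gene_id]
    case = row[cohort.group == 1].to_numpy(dtype=float)
    control = row[cohort.group == 0].to_numpy(dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("need >=2 samples per group")
    if case.var(ddof=1) == 0 and control.var(ddof=1) == 0 and case.mean() == control.mean():
        warnings.warn(
            f"gene {gene_id}: zero variance in both groups with equal means; p = 0.5",
            stacklevel=2,
        )
        return 0.5
    return float(_welch_one_sided(case[None, :], control[None, :])[0])


def rank_by_significance(p_by_gene: pd.Series) -> pd.Series:
    """Ascending-p ranks 1..G; ties share the average of their positions."""
    if len(p_by_gene) == 0:
        raise ValueError("empty p-value map")
    return pd.Series(
        stats.rankdata(p_by_gene.to_numpy(), method="average"),
        index=p_by_gene.index,
        name="rank",
    )


def median_rank_aggregate(
    p_by_cohort: dict[str, pd.Series],
    min_fraction_measured: float = 0.5,
) -> pd.DataFrame:
    """Aggregate per-cohort significance ranks by the median rank.

    Parameters
    ----------
    p_by_cohort : dict cohort_id -> Series of per-gene one-sided p-values.
        Cohorts may cover different gene subsets (platform differences).
    min_fraction_measured : float
        Genes measured in fewer than this fraction of cohorts are excluded
        (and reported via a warning).

    Returns
    -------
    DataFrame indexed by gene with columns ``median_rank``, ``median_rank_p``
    (the p-value from the cohort realising the median rank),
    ``median_rank_cohort`` and ``n_cohorts_measured``.  For an even number of
    cohorts the less-significant (larger) of the two middle ranks is taken,
    so the reported p always belongs to an actual cohort.
    """
    if not p_by_cohort:
        raise ValueError("need at least one cohort")
    ranks = {cid: rank_by_significance(p) for cid, p in p_by_cohort.items()}
    all_genes = sorted(set().union(*(set(p.index) for p in p_by_cohort.values())))
    n_cohorts = len(p_by_cohort)

    records = []
    dropped = []
    for gene in all_genes:
        triples = [
            (float(ranks[cid][gene]), float(p[gene]), cid)
            for cid, p in p_by_cohort.items()
            if gene in p.index and not np.isnan(p[gene])
        ]
        k = len(triples)
        if k == 0 or k / n_cohorts < min_fraction_measured:
            dropped.append(gene)
            continue
        triples.sort()  # by (rank, p, cohort_id) -- deterministic under ties
        med = triples[k // 2] if k % 2 == 1 else triples[k // 2]  # upper middle
        records.append(
            {
                "gene": gene,
                "median_rank": med[0],
                "median_rank_p": med[1],
                "median_rank_cohort": med[2],
                "n_cohorts_measured": k,
            }
        )
    if dropped:
        warnings.warn(
            f"{len(dropped)} genes measured in < {min_fraction_measured:.0%} "
            f"of cohorts were excluded (e.g. {dropped[:3]})",
            stacklevel=2,
        )
    return pd.DataFrame.from_records(records).set_index("gene")


def select_candidates(
    meta: pd.DataFrame,
    tf_whitelist,
    alpha: float = 0.05,
) -> list[str]:
    """TF-whitelist genes with median-rank p < alpha, sorted by median rank."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    whitelist = set(tf_whitelist)
    if not whitelist:
        raise ValueError("empty TF whitelist")
    hits = meta[(meta.index.isin(whitelist)) & (meta["median_rank_p"] < alpha)]
    return list(hits.sort_values(["median_rank", "median_rank_p"]).index)
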