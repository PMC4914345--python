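"""Protein/DNA-binding array screen: reference normalisation and group filter.

Spot intensities are expressed relative to the TFIID reference spot of the
same membrane, averaged over replicates within each cell line, and then
compared between cell-line groups with a Student's (equal-variance) t-test
on the per-cell-line means — the cell line, not the replicate, is the unit
of replication.  Motifs pass the filter when the fold change exceeds 1.4 AND
the two-sided p-value is below 0.05 (both strict).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

REFERENCE_ID = "TFIID"

INTENSITY_COLUMNS = ["membrane", "cell_line", "replicate", "motif_id", "intensity"]


def normalize_to_reference(
    intensities: pd.DataFrame, reference_id: str = REFERENCE_ID
) -> pd.DataFrame:
    """Divide every spot by its membrane's reference-spot intensity.

    Input and output are long-format tables with columns
    membrane, cell_line, replicate, motif_id, intensity; the output adds
    ``relative`` and the reference spot itself maps to 1.0.
    """
    missing = set(INTENSITY_COLUMNS) - set(intensities.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    ref = (
        intensities[intensities["motif_id"] == reference_id]
        .set_index("membrane")["intensity"]
    )
    bad = ref[ref <= 0]
    if not bad.empty:
        raise ValueError(
            f"non-positive reference intensity on membrane(s) {list(bad.index)}"
        )
    missing_ref = set(intensities["membrane"]) - set(ref.index)
    if missing_ref:
        raise ValueError(f"membranes without a {reference_id} spot: {sorted(missing_ref)}")
    out = intensities.copy()
    out["relative"] = out["intensity"] / out["membrane"].map(ref).to_numpy()
    return out


def summarize_cell_line(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-motif mean relative intensity per cell line (over replicates).

    Returns a DataFrame indexed by motif_id with one column per cell line.
    A motif absent from some replicates is averaged over the replicates that
    carry it, with a warning.
    """
    counts = normalized.groupby(["cell_line", "motif_id"])["relative"].count()
    per_line = normalized.groupby("cell_line")["replicate"].nunique()
    uneven = counts[counts < counts.index.get_level_values(0).map(per_line)]
    if not uneven.empty:
        warnings.warn(
            f"{len(uneven)} (cell line, motif) pairs missing from some replicates; "
            "means taken over present replicates",
            stacklevel=2,
        )
    means = normalized.groupby(["motif_id", "cell_line"])["relative"].mean()
    return means.unstack("cell_line")


def compare_groups(
    line_means: pd.DataFrame,
    group_map: dict[str, str],
    case: str = "BLBC",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Student's t-test of case vs control per-cell-line means, per motif.

    Returns a DataFrame indexed by motif_id with mean_case, mean_control,
    fold_change (case/control on the raw relative-intensity scale),
    t_statistic and two-sided p_value.
    """
    case_lines = [l for l in line_means.columns if group_map.get(l) == case]
    ctrl_lines = [l for l in line_means.columns if l in group_map and group_map[l] != case]
    if len(case_lines) < 2 or len(ctrl_lines) < 2:
        raise ValueError("need >=2 cell lines per group")
    a = line_means[case_lines].to_numpy()
    b = line_means[ctrl_lines].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} motifs with zero variance in both groups; p = 1",
            stacklevel=2,
        )
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, 1.0, p)
    mean_case = a.mean(axis=1)
    mean_ctrl = b.mean(axis=1)
    out = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_ctrl,
            "fold_change": mean_case / mean_ctrl,
            "t_statistic": t,
            "p_value": p,
        },
        index=line_means.index,
    )
    return out


def select_bound_motifs(
    comparisons: pd.DataFrame, fc_min: float = 1.4, alpha: float = 0.05
) -> list[str]:
    """Motifs with fold_change > fc_min AND p < alpha (strict inequalities)."""
    if fc_min <= 0 or alpha <= 0:
        raise ValueError("fc_min and alpha must be positive")
    hits = comparisons[
        (comparisons["fold_change"] > fc_min) & (comparisons["p_value"] < alpha)
    ]
    return list(hits.sort_values("p_value").index)


def run_protein_screen(
    intensities: pd.DataFrame,
    group_map: dict[str, str],
    case: str = "BLBC",
    fc_min: float = 1.4,
    alpha: float = 0.05,
    reference_id: str = REFERENCE_ID,
) -> tuple[pd.DataFrame, list[str]]:
    """Full array screen: normalise, summarise, compare, filter."""
    normalized = normalize_to_reference(intensities, reference_id)
    line_means = summarize_cell_line(normalized)
    comparisons = compare_groups(line_means.drop(index=reference_id), group_map, case)
    return comparisons, select_bound_motifs(comparisons, fc_min, alpha)
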