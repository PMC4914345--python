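"""Secondary siRNA growth screen: hit calling and specificity classification.

Growth values are percentages relative to a non-targeting control siRNA
(siLuc) after six days.  An siRNA is *critical* when its mean relative
growth is at or below 66% (growth suppressed by at least one third) in at
least two of the BLBC cell lines; among critical siRNAs, the number of
non-BLBC lines also reduced determines specificity:

    0 reduced non-BLBC lines -> BLBC-specific
    1                        -> moderately-specific
    >=2                      -> general

The 66% bound is inclusive, matching the screen's reporting bins
(<33%, 33–66%, >66%).  Hit calling uses the reported means only; standard
deviations are carried for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd

GROWTH_COLUMNS = ["siRNA", "cell_line", "mean", "sd"]


def load_sirna_screen() -> tuple[pd.DataFrame, dict[str, str]]:
    """Packaged secondary-screen table (29 siRNAs x 6 breast cancer lines).

    Returns the long-format growth table and the cell-line -> group map
    (three basal-like lines, three luminal lines).
    """
    pkg = resources.files("tfscreen.data")
    table = read_growth_table(pkg / "sirna_growth_screen.tsv")
    groups = read_group_map(pkg / "cell_line_groups.tsv")
    return table, groups


def read_growth_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = set(GROWTH_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    if (table["mean"] < 0).any():
        raise ValueError("negative mean relative growth")
    return table


def read_group_map(path) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    return dict(zip(table["cell_line"], table["group"]))


def bin_growth(value: float) -> str:
    """Reporting bin of a relative-growth percentage: <33, 33-66 or >66."""
    if value < 0:
        raise ValueError(f"negative growth value: {value}")
    if value < 33:
        return "<33"
    if value <= 66:
        return "33-66"
    return ">66"


def _reduced_counts(
    table: pd.DataFrame,
    group_map: dict[str, str],
    blbc_group: str,
    reduced_max: float,
) -> pd.DataFrame:
    t = table.copy()
    unknown = set(t["cell_line"]) - set(group_map)
    if unknown:
        raise ValueError(f"cell lines without a group label: {sorted(unknown)}")
    t["is_blbc"] = t["cell_line"].map(group_map) == blbc_group
    t["reduced"] = t["mean"] <= reduced_max
    out = (
        t.groupby(["siRNA", "is_blbc"])
        .agg(n_reduced=("reduced", "sum"), n_lines=("reduced", "size"))
        .unstack("is_blbc", fill_value=0)
    )
    out.columns = [f"{a}_{'blbc' if b else 'nonblbc'}" for a, b in out.columns]
    for col in ("n_reduced_blbc", "n_lines_blbc", "n_reduced_nonblbc", "n_lines_nonblbc"):
        if col not in out.columns:
            out[col] = 0
    return out


def call_critical(
    table: pd.DataFrame,
    group_map: dict[str, str],
    min_lines: int = 2,
    reduced_max: float = 66.0,
    blbc_group: str = "BLBC",
) -> set[str]:
    """siRNAs with growth <= reduced_max in >= min_lines BLBC lines."""
    counts = _reduced_counts(table, group_map, blbc_group, reduced_max)
    unmeasured = counts[counts["n_lines_blbc"] < min_lines]
    if not unmeasured.empty:
        warnings.warn(
            f"{len(unmeasured)} siRNAs with < {min_lines} BLBC measurements "
            "excluded from hit calling",
            stacklevel=2,
        )
        counts = counts.drop(index=unmeasured.index)
    return set(counts.index[counts["n_reduced_blbc"] >= min_lines])


@dataclass
class GrowthCall:
    """Classification of one siRNA from the secondary screen."""

    siRNA: str
    n_blbc_reduced: int
    n_nonblbc_reduced: int
    bins: dict[str, str]  # cell line -> reporting bin
    label: str  # BLBC-specific | moderately-specific | general | not-critical


def classify_specificity(
    siRNA: str,
    table: pd.DataFrame,
    group_map: dict[str, str],
    min_lines: int = 2,
    reduced_max: float = 66.0,
    blbc_group: str = "BLBC",
) -> GrowthCall:
    """Specificity class of one siRNA per the critical/non-BLBC decision table."""
    rows = table[table["siRNA"] == siRNA]
    if rows.empty:
        raise KeyError(f"siRNA {siRNA} not in growth table")
    counts = _reduced_counts(rows, group_map, blbc_group, reduced_max).loc[siRNA]
    n_blbc = int(counts["n_reduced_blbc"])
    n_non = int(counts["n_reduced_nonblbc"])
    if n_blbc < min_lines:
        label = "not-critical"
    elif n_non == 0:
        label = "BLBC-specific"
    elif n_non == 1:
        label = "moderately-specific"
    else:
        label = "general"
    bins = {r.cell_line: bin_growth(r.mean) for r in rows.itertuples(index=False)}
    return GrowthCall(siRNA, n_blbc, n_non, bins, label)


def classify_all(
    table: pd.DataFrame,
    group_map: dict[str, str],
    min_lines: int = 2,
    reduced_max: float = 66.0,
    blbc_group: str = "BLBC",
) -> pd.DataFrame:
    """GrowthCall for every siRNA in the table, as a DataFrame."""
    calls = [
        classify_specificity(s, table, group_map, min_lines, reduced_max, blbc_group)
        for s in sorted(table["siRNA"].unique())
    ]
    return pd.DataFrame(
        {
            "siRNA": [c.siRNA for c in calls],
            "n_blbc_reduced": [c.n_blbc_reduced for c in calls],
            "n_nonblbc_reduced": [c.n_nonblbc_reduced for c in calls],
            "label": [c.label for c in calls],
        }
    ).set_index("siRNA")
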