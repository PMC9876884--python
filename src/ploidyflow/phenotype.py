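"""Group summaries, phenotype correlations and GC retention indices.

Summaries reproduce the shape of a per-species / half-sib-family genome
table: mean, sample SD, min, max and range for 2C (pg) and GC%.
Correlations are plain Pearson r with pairwise-complete deletion, as used
to relate genome (2C, GC%), epigenome (5-mC%) and essential-oil phenotype
variables.  Retention indices use the van den Dool & Kratz linear
formulation appropriate for temperature-programmed GC runs, anchored on
an n-alkane series.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cytogenomics import GenomeEstimate

__all__ = [
    "COMPOUND_CLASSES",
    "PhenotypeRecord",
    "summarize_groups",
    "group_range",
    "correlate",
    "compound_class_totals",
    "retention_index",
]

COMPOUND_CLASSES = (
    "hydrocarbon monoterpene",
    "oxygenated monoterpene",
    "hydrocarbon sesquiterpene",
    "oxygenated sesquiterpene",
)


@dataclass
class PhenotypeRecord:
    """Essential-oil phenotype of one access."""

    access_id: str
    oil_yield: float | None = None  # percent
    five_mc: float | None = None  # global 5-mC percent
    compounds: dict[str, float] = field(default_factory=dict)  # name -> % of oil
    compound_classes: dict[str, str] = field(default_factory=dict)  # name -> class

    def __post_init__(self) -> None:
        for name, pct in self.compounds.items():
            if pct < 0:
                raise ValueError(f"compound {name!r}: percent must be >= 0")
        for name, cls in self.compound_classes.items():
            if cls not in COMPOUND_CLASSES:
                raise ValueError(
                    f"compound {name!r}: class {cls!r} not in {COMPOUND_CLASSES}"
                )


def group_range(values: Sequence[float]) -> float:
    """max - min of a value set (0 for a singleton)."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("empty value set")
    return float(v.max() - v.min())


def summarize_groups(
    estimates: Sequence[GenomeEstimate],
    groups: Mapping[str, str],
    variables: Sequence[str] = ("c2", "gc_percent"),
) -> pd.DataFrame:
    """Per-group summary table: n, mean, sd, min, max, range per variable.

    ``groups`` maps access_id to a group label (species or half-sib
    family).  Sample SD (ddof=1) is reported as NaN for singleton groups.
    Accesses without a group mapping raise; groups that end up empty are
    simply absent.  Output order follows first appearance.
    """
    rows = []
    for est in estimates:
        if est.access_id not in groups:
            raise KeyError(f"access {est.access_id!r} has no group mapping")
        rows.append(
            {"group": groups[est.access_id], **{v: getattr(est, v) for v in variables}}
        )
    df = pd.DataFrame(rows)
    out = []
    for group, sub in df.groupby("group", sort=False):
        rec: dict = {"group": group, "n": len(sub)}
        for v in variables:
            vals = sub[v].dropna()
            if vals.empty:
                continue
            rec[f"{v}_mean"] = vals.mean()
            rec[f"{v}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
            rec[f"{v}_min"] = vals.min()
            rec[f"{v}_max"] = vals.max()
            rec[f"{v}_range"] = vals.max() - vals.min()
        out.append(rec)
    return pd.DataFrame(out)


def correlate(
    table: pd.DataFrame, min_pairs: int = 3, pvalues: bool = False
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations in long format.

    Returns columns (var1, var2, r, n, defined[, p]).  Pairs with fewer
    than ``min_pairs`` complete observations or with zero variance in
    either variable are reported with r = NaN and defined = False, never
    silently as 0.
    """
    num = table.select_dtypes(include=[np.number])
    rows = []
    for a, b in itertools.combinations(num.columns, 2):
        sub = num[[a, b]].dropna()
        n = len(sub)
        defined = n >= min_pairs and sub[a].nunique() > 1 and sub[b].nunique() > 1
        if defined:
            r, p = stats.pearsonr(sub[a], sub[b])
        else:
            r, p = np.nan, np.nan
        rec = {"var1": a, "var2": b, "r": r, "n": n, "defined": defined}
        if pvalues:
            rec["p"] = p
        rows.append(rec)
    return pd.DataFrame(rows)


def compound_class_totals(record: PhenotypeRecord) -> dict[str, float]:
    """Per-class sums of compound percentages (all four classes present)."""
    totals = {cls: 0.0 for cls in COMPOUND_CLASSES}
    for name, pct in record.compounds.items():
        if name not in record.compound_classes:
            raise ValueError(f"compound {name!r} has no class label")
        totals[record.compound_classes[name]] += pct
    return totals


def retention_index(
    t_compound: float, alkane_times: Mapping[int, float]
) -> float:
    """Linear (van den Dool & Kratz) retention index.

    ``alkane_times`` maps alkane carbon number to retention time under the
    same chromatographic conditions; times must increase strictly with
    carbon number and ``t_compound`` must be bracketed by two adjacent
    alkanes.  For bracketing alkanes with consecutive carbon numbers n
    and n+1, RI = 100 * [n + (t - t_n) / (t_{n+1} - t_n)]; gaps in the
    series interpolate proportionally over the carbon-number difference.
    """
    if len(alkane_times) < 2:
        raise ValueError("need at least two alkane anchors")
    carbons = sorted(alkane_times)
    times = [alkane_times[c] for c in carbons]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("alkane times must increase strictly with carbon number")
    if not times[0] <= t_compound <= times[-1]:
        raise ValueError(
            f"retention time {t_compound:g} outside alkane range "
            f"[{times[0]:g}, {times[-1]:g}]"
        )
    k = int(np.searchsorted(times, t_compound, side="right")) - 1
    k = min(max(k, 0), len(carbons) - 2)
    c0, c1 = carbons[k], carbons[k + 1]
    t0, t1 = times[k], times[k + 1]
    return 100.0 * (c0 + (c1 - c0) * (t_compound - t0) / (t1 - t0))
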