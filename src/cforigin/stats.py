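"""Group-comparison statistics for cfDNA concentrations.

Differences between clinical groups (e.g. megakaryocyte GE/ml in healthy vs
Essential Thrombocythemia plasma) are assessed with the non-parametric
two-tailed Mann-Whitney U test: exact by enumeration of rank splits for small
tie-free samples, tie-corrected normal approximation otherwise. Summaries
follow box-plot conventions: median, quartiles (linear interpolation),
whisker fences at 1.5x the interquartile range, and Tukey-style outlier
flags. Outliers are flagged, never silently excluded; no multiple-testing
correction is applied by default (Holm is available via flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as _sps

_EXACT_MAX_N = 20


@dataclass
class GroupedMeasurements:
    """Named groups of per-sample values sharing one unit (e.g. GE/ml)."""

    groups: dict[str, np.ndarray]
    units: str = ""

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need >= 1 group")
        self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
        for name, vals in self.groups.items():
            if vals.size == 0:
                raise ValueError(f"group {name!r} is empty")
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"group {name!r} contains non-finite values")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, units: str = "") -> "GroupedMeasurements":
        if not {"group", "value"} <= set(df.columns):
            raise ValueError("need columns 'group' and 'value'")
        return cls({g: sub["value"].to_numpy() for g, sub in df.groupby("group")}, units)


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney(
    group_a, group_b, mode: str = "auto"
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U for group_a, p).

    mode "exact" enumerates rank assignments (valid only without ties);
    "normal-approx" uses the tie-corrected normal approximation; "auto"
    (default) picks exact when n_a + n_b <= 20 and the pooled data are
    tie-free, the approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if mode not in ("exact", "normal-approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = (
            "exact"
            if (a.size + b.size <= _EXACT_MAX_N and not _has_ties(a, b))
            else "normal-approx"
        )
    method = "exact" if mode == "exact" else "asymptotic"
    res = _sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_summary(data: GroupedMeasurements) -> pd.DataFrame:
    """Per-group box-plot summary with Tukey outlier flags.

    Quartiles use linear interpolation; whisker fences sit at
    Q1 - 1.5 IQR and Q3 + 1.5 IQR. The ``outliers`` column lists values
    beyond the fences — flagged only, never removed.
    """
    rows = {}
    for name, vals in data.groups.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = vals[(vals < lo_fence) | (vals > hi_fence)]
        rows[name] = {
            "n": vals.size,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(lo_fence),
            "whisker_high": float(hi_fence),
            "n_outliers": int(outliers.size),
            "outliers": list(map(float, outliers)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_groups(
    data: GroupedMeasurements,
    reference_group: str | None = None,
    alpha: float = 0.05,
    mode: str = "auto",
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise Mann-Whitney table with significance flags at ``alpha``.

    With a reference group, every other group is tested against it; without,
    all pairs are tested. Raw p-values are always reported; Holm step-down
    adjustment is applied only when requested. Pairs where either group has
    n < 2 under the normal approximation are warning-flagged.
    """
    names = list(data.groups)
    if reference_group is not None:
        if reference_group not in data.groups:
            raise ValueError(f"unknown reference group {reference_group!r}")
        pairs = [(reference_group, g) for g in names if g != reference_group]
    else:
        pairs = list(combinations(names, 2))

    rows = []
    for ga, gb in pairs:
        a, b = data.groups[ga], data.groups[gb]
        u, p = mann_whitney(a, b, mode=mode)
        warn = mode != "exact" and (a.size < 2 or b.size < 2)
        rows.append(
            {"group_a": ga, "group_b": gb, "n_a": a.size, "n_b": b.size,
             "U": u, "p": p, "small_sample_warning": bool(warn)}
        )
    table = pd.DataFrame(rows)
    if table.empty:
        table["significant"] = []
        return table
    if holm:
        order = np.argsort(table["p"].to_numpy())
        m = len(table)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * table["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table
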