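"""Positive-vs-negative rank statistics over region conservation metrics.

Each metric column is compared between the regions with confirmed
regulatory activity ('+') and those without ('-') using a one-sided
Wilcoxon rank-sum (Mann-Whitney) test.  When the pooled values are
tie-free the p-value is exact, from the full U null distribution
(counting recursion); with ties a normal approximation with mid-ranks,
tie-corrected variance and a 0.5 continuity correction is used, the
convention of standard statistical software at these sample sizes.

The directional hypothesis is that functional regions are the more
conserved set: "positives greater" for the seven similarity metrics and
"positives smaller" for the mismatch metric (a dissimilarity).

Missing values ("nd", or a region shorter than a scoring window) are
deleted per metric, so sample sizes vary across columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .missing import MISSING, ND, is_missing

__all__ = [
    "METRICS",
    "METRIC_DIRECTIONS",
    "MetricTable",
    "ComparisonResult",
    "summarize",
    "rank_sum_one_sided",
    "compare_metrics",
    "relabel_and_recompute",
]

METRICS = (
    "avid",
    "avid_dialign",
    "phastcons_mean",
    "peak100",
    "peak200",
    "peak500",
    "tfbs_presence",
    "tfbs_mismatch",
)

#: alternative hypothesis per metric: the direction meaning "more conserved"
METRIC_DIRECTIONS = {m: "greater" for m in METRICS}
METRIC_DIRECTIONS["tfbs_mismatch"] = "less"


class MetricTable:
    """Region x metric table with activity labels and missing support.

    Backed by a pandas DataFrame indexed by region_id with an ``activity``
    column ('+'/'-') and one column per metric; MISSING is stored as NaN
    and serialized as ``"nd"``.
    """

    def __init__(self, df: pd.DataFrame):
        if "activity" not in df.columns:
            raise ValueError("metric table needs an 'activity' column")
        bad = set(df["activity"]) - {"+", "-"}
        if bad:
            raise ValueError(f"activity labels must be '+'/'-', got {sorted(bad)}")
        if df.index.has_duplicates:
            raise ValueError("duplicate region ids")
        self.df = df.copy()

    @classmethod
    def from_rows(
        cls, rows: Mapping[str, tuple[str, Mapping[str, object]]]
    ) -> "MetricTable":
        """rows: region_id -> (activity, {metric: value-or-MISSING})."""
        data = {}
        for rid, (label, metrics) in rows.items():
            rec = {"activity": label}
            for m in METRICS:
                v = metrics.get(m, MISSING)
                rec[m] = np.nan if is_missing(v) else float(v)
            data[rid] = rec
        return cls(pd.DataFrame.from_dict(data, orient="index"))

    @property
    def region_ids(self) -> list[str]:
        return list(self.df.index)

    def label(self, region_id: str) -> str:
        return self.df.loc[region_id, "activity"]

    def value(self, region_id: str, metric: str):
        v = self.df.loc[region_id, metric]
        return MISSING if is_missing(float(v)) else float(v)

    def column(self, metric: str, label: str) -> list[float]:
        """Values of one metric for one label, missing deleted."""
        sub = self.df[self.df["activity"] == label][metric]
        return [float(v) for v in sub if not is_missing(float(v))]

    def metrics(self) -> list[str]:
        return [c for c in self.df.columns if c != "activity"]

    def with_label(self, region_id: str, new_label: str) -> "MetricTable":
        if region_id not in self.df.index:
            raise KeyError(f"unknown region {region_id!r}")
        out = MetricTable(self.df)
        out.df.loc[region_id, "activity"] = new_label
        return out

    # -- TSV round-trip ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        df = self.df.copy()
        for c in self.metrics():
            df[c] = [ND if is_missing(float(v)) else f"{v:.6g}" for v in df[c]]
        df.index.name = "region_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetricTable":
        df = pd.read_csv(path, sep="\t", index_col="region_id", dtype=str, comment="#")
        for c in df.columns:
            if c == "activity":
                continue
            df[c] = pd.to_numeric(df[c].replace(ND, np.nan), errors="raise")
        return cls(df)


@dataclass(frozen=True)
class ComparisonResult:
    """One metric's positive-vs-negative summary and rank-sum p-value."""

    metric: str
    n_pos: int
    n_neg: int
    mean_pos: object
    mean_neg: object
    sd_pos: object
    sd_neg: object
    p_one_sided: object
    method: str
    alternative: str


def summarize(values: Iterable[object]) -> tuple[float, object]:
    """Mean and sample SD (n-1 denominator) after deleting MISSING.

    SD is MISSING for a single value; an empty collection is an error.
    """
    vals = [float(v) for v in values if not is_missing(v)]
    if not vals:
        raise ValueError("no values left after deleting missing entries")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        return mean, MISSING
    return mean, float(np.std(vals, ddof=1))


# ---------------------------------------------------------------------------
# exact U null distribution


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank configurations with U = u, u = 0..n*m, for sample
    sizes n and m (no ties).  Recursion: c(n, m, u) = c(n-1, m, u-m) +
    c(n, m-1, u)."""
    if n == 0 or m == 0:
        return (1,)
    a = _u_counts(n - 1, m)  # indices shifted by m
    b = _u_counts(n, m - 1)
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def _exact_p_greater(pos: Sequence[float], neg: Sequence[float]) -> float:
    """P(U >= U_obs) under the exact tie-free null, where U counts
    (pos, neg) pairs with pos > neg."""
    n, m = len(pos), len(neg)
    u_obs = sum(1 for x in pos for y in neg if x > y)
    counts = _u_counts(n, m)
    total = math.comb(n + m, n)
    return sum(counts[u_obs:]) / total


def _approx_p_greater(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Normal approximation with mid-ranks, tie-corrected variance and a
    0.5 continuity correction."""
    n1, n2 = len(pos), len(neg)
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    big_n = n1 + n2
    u1 = float(ranks[:n1].sum()) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float((t**3 - t).sum()) / (big_n * (big_n - 1))
    var = n1 * n2 / 12 * ((big_n + 1) - tie_term)
    if var <= 0:
        return 1.0  # all values identical: no evidence in either direction
    z = (u1 - mu - 0.5) / math.sqrt(var)
    return float(norm.sf(z))


def rank_sum_one_sided(
    pos: Iterable[object],
    neg: Iterable[object],
    alternative: str = "greater",
    metric: str = "",
) -> ComparisonResult:
    """One-sided Wilcoxon rank-sum test after per-metric missing deletion.

    ``alternative`` is the direction claimed for the positive set
    ("greater" or "less").  Exact p by full enumeration of the U null when
    the pooled values are tie-free; otherwise the tie-corrected,
    continuity-corrected normal approximation.
    """
    pos_v = [float(v) for v in pos if not is_missing(v)]
    neg_v = [float(v) for v in neg if not is_missing(v)]
    if not pos_v or not neg_v:
        raise ValueError(
            f"metric {metric or '<unnamed>'}: empty sample after missing-value deletion"
        )
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a, b = (pos_v, neg_v) if alternative == "greater" else (neg_v, pos_v)
    ties = len(set(a + b)) < len(a) + len(b)
    if ties:
        p = _approx_p_greater(a, b)
        method = "normal-approx-tie-corrected"
    else:
        p = _exact_p_greater(a, b)
        method = "exact"
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    mean_pos, sd_pos = summarize(pos_v)
    mean_neg, sd_neg = summarize(neg_v)
    return ComparisonResult(
        metric=metric,
        n_pos=len(pos_v),
        n_neg=len(neg_v),
        mean_pos=mean_pos,
        mean_neg=mean_neg,
        sd_pos=sd_pos,
        sd_neg=sd_neg,
        p_one_sided=p,
        method=method,
        alternative=alternative,
    )


def compare_metrics(table: MetricTable) -> list[ComparisonResult]:
    """One ComparisonResult per metric column, with per-metric (pairwise)
    deletion of missing values.  A metric empty on either side yields a
    flagged result (method "insufficient-data") rather than an error."""
    results = []
    for metric in table.metrics():
        pos = table.column(metric, "+")
        neg = table.column(metric, "-")
        alt = METRIC_DIRECTIONS.get(metric, "greater")
        try:
            results.append(rank_sum_one_sided(pos, neg, alternative=alt, metric=metric))
        except ValueError:
            results.append(
                ComparisonResult(
                    metric=metric,
                    n_pos=len(pos),
                    n_neg=len(neg),
                    mean_pos=summarize(pos)[0] if pos else MISSING,
                    mean_neg=summarize(neg)[0] if neg else MISSING,
                    sd_pos=MISSING,
                    sd_neg=MISSING,
                    p_one_sided=MISSING,
                    method="insufficient-data",
                    alternative=alt,
                )
            )
    return results


def relabel_and_recompute(
    table: MetricTable, region_id: str, new_label: str
) -> list[ComparisonResult]:
    """Sensitivity analysis: move one region to the other activity class
    and recompute every comparison.  The input table is left untouched."""
    if region_id not in table.region_ids:
        raise KeyError(f"unknown region {region_id!r}")
    if table.label(region_id) == new_label:
        raise ValueError(f"region {region_id!r} already labeled {new_label!r}")
    return compare_metrics(table.with_label(region_id, new_label))


def results_to_tsv(results: Sequence[ComparisonResult], path: str | Path) -> None:
    """Write comparison results as TSV, p-values to 4 significant figures."""
    rows = []
    for r in results:
        rows.append(
            {
                "metric": r.metric,
                "n_pos": r.n_pos,
                "n_neg": r.n_neg,
                "mean_pos": ND if is_missing(r.mean_pos) else f"{r.mean_pos:.4f}",
                "mean_neg": ND if is_missing(r.mean_neg) else f"{r.mean_neg:.4f}",
                "sd_pos": ND if is_missing(r.sd_pos) else f"{r.sd_pos:.4f}",
                "sd_neg": ND if is_missing(r.sd_neg) else f"{r.sd_neg:.4f}",
                "p_one_sided": ND if is_missing(r.p_one_sided) else f"{r.p_one_sided:.4g}",
                "method": r.method,
                "alternative": r.alternative,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
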