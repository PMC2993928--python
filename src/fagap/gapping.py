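"""Gapping analysis: a Monte-Carlo test for a break in a rank-ordered sample.

Given per-subject region-mean FA values, the procedure rank-orders them,
discards the lowest and highest quarter (floor(trim * n) from each end) to
guard against outliers, computes the successive differences ("gaps") among
the retained middle values, and scales each gap by the mean retained gap.
The statistic is the largest such gap ratio; its null distribution is
obtained by simulating samples of the same size from a single-population
reference family (standard Gaussian, or Student t) and applying the
identical trim-and-ratio rule.  Because the ratio is location- and
scale-invariant, simulating from standard (unit) distributions is valid
for data on any scale.

A large ratio indicates an interval unusually empty for a unimodal sample
— evidence of two underlying subpopulations — and the boundary of the
maximal gap splits the full cohort into below-gap and above-gap subgroups.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GapResult", "gap_statistic", "gap_null_pvalue", "gap_analysis",
           "NULL_FAMILIES"]

NULL_FAMILIES = ("gaussian", "student_t")


@dataclass
class GapResult:
    """Outcome of the gapping analysis on one value set."""

    sorted_values: np.ndarray
    trim_bounds: tuple[int, int]        # retained slice [lo, hi) into sorted order
    gaps: np.ndarray                    # successive differences of retained values
    mean_gap: float
    gap_ratios: np.ndarray
    max_ratio: float
    boundary_index: int                 # gap between sorted[i] and sorted[i+1]
    labels: np.ndarray                  # "below_gap"/"above_gap" per sorted value
    order: np.ndarray                   # argsort mapping input -> sorted
    p_gaussian: float | None = None
    p_t: float | None = None
    df_t: int | None = None
    n_sims: int | None = None
    seed: int | None = None

    @property
    def n_above(self) -> int:
        return int((self.labels == "above_gap").sum())

    @property
    def n_below(self) -> int:
        return int((self.labels == "below_gap").sum())

    def labels_in_input_order(self) -> np.ndarray:
        out = np.empty(len(self.labels), dtype=object)
        out[self.order] = self.labels
        return out

    def to_dict(self) -> dict:
        return {
            "n": len(self.sorted_values),
            "trim_bounds": list(self.trim_bounds),
            "max_ratio": self.max_ratio,
            "mean_gap": self.mean_gap,
            "boundary_index": self.boundary_index,
            "boundary_values": [float(self.sorted_values[self.boundary_index]),
                                float(self.sorted_values[self.boundary_index + 1])],
            "n_below": self.n_below,
            "n_above": self.n_above,
            "gap_ratios": [float(g) for g in self.gap_ratios],
            "p_gaussian": self.p_gaussian,
            "p_t": self.p_t,
            "df_t": self.df_t,
            "n_sims": self.n_sims,
            "seed": self.seed,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def _retained_slice(n: int, trim_fraction: float) -> tuple[int, int]:
    t = math.floor(trim_fraction * n)
    return t, n - t


def gap_statistic(values, trim_fraction: float = 0.25) -> GapResult:
    """Maximal middle-gap ratio of a sample, with subgroup labels.

    The lowest and highest ``floor(trim_fraction * n)`` order statistics are
    excluded; gaps are differences between consecutive retained values; each
    gap is divided by the mean retained gap (so the ratios average to 1) and
    the largest ratio marks the split boundary.  All n subjects — including
    the trimmed ones — are labelled by their side of that boundary.

    Requires at least 8 values and at least 4 retained after trimming.
    Equal adjacent values yield zero gaps; if every retained gap is zero the
    statistic is undefined and a ValueError is raised.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    n = len(values)
    if n < 8:
        raise ValueError(f"gapping needs at least 8 values, got {n}")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must lie in [0, 0.5)")
    lo, hi = _retained_slice(n, trim_fraction)
    if hi - lo < 4:
        raise ValueError(f"fewer than 4 values retained after trimming ({hi - lo})")

    order = np.argsort(values, kind="stable")
    sv = values[order]
    retained = sv[lo:hi]
    gaps = np.diff(retained)
    mean_gap = float(gaps.mean())
    if mean_gap == 0:
        raise ValueError("all retained gaps are zero; gap statistic undefined")
    ratios = gaps / mean_gap
    j = int(np.argmax(ratios))
    boundary = lo + j  # gap between sorted[boundary] and sorted[boundary+1]
    labels = np.where(np.arange(n) <= boundary, "below_gap", "above_gap").astype(object)
    return GapResult(
        sorted_values=sv, trim_bounds=(lo, hi), gaps=gaps, mean_gap=mean_gap,
        gap_ratios=ratios, max_ratio=float(ratios[j]), boundary_index=boundary,
        labels=labels, order=order)


def _simulate_max_ratios(n: int, trim_fraction: float, family: str, df: int,
                         n_sims: int, rng: np.random.Generator,
                         batch: int = 20000) -> np.ndarray:
    lo, hi = _retained_slice(n, trim_fraction)
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(batch, n_sims - done)
        if family == "gaussian":
            s = rng.standard_normal((m, n))
        else:
            s = rng.standard_t(df, (m, n))
        s.sort(axis=1)
        g = np.diff(s[:, lo:hi], axis=1)
        out[done:done + m] = g.max(axis=1) / g.mean(axis=1)
        done += m
    return out


def gap_null_pvalue(max_ratio: float, n: int, null_family: str = "gaussian",
                    df: int = 4, n_sims: int = 10_000, seed: int = 0,
                    trim_fraction: float = 0.25) -> float:
    """Monte-Carlo probability of a maximal middle-gap ratio >= ``max_ratio``
    under a single-population null.

    ``null_family`` is "gaussian" or "student_t" (with ``df`` degrees of
    freedom).  Each of the ``n_sims`` simulated samples of size ``n`` is
    pushed through the same trim-and-ratio rule as the observed statistic;
    p is the plain proportion of simulated maxima at least as large as the
    observed one (>=, no +1 correction).
    """
    if null_family not in NULL_FAMILIES:
        raise ValueError(f"unknown null family {null_family!r}; "
                         f"choose from {NULL_FAMILIES}")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if max_ratio < 0:
        raise ValueError("max_ratio must be non-negative")
    rng = np.random.default_rng(seed)
    sims = _simulate_max_ratios(n, trim_fraction, null_family, df, n_sims, rng)
    return float(np.mean(sims >= max_ratio))


def gap_analysis(values, trim_fraction: float = 0.25, n_sims: int = 10_000,
                 df_t: int = 4, seed: int = 0) -> GapResult:
    """Convenience wrapper: statistic plus Gaussian and Student-t null p's."""
    res = gap_statistic(values, trim_fraction)
    n = len(res.sorted_values)
    res.p_gaussian = gap_null_pvalue(res.max_ratio, n, "gaussian",
                                     n_sims=n_sims, seed=seed,
                                     trim_fraction=trim_fraction)
    res.p_t = gap_null_pvalue(res.max_ratio, n, "student_t", df=df_t,
                              n_sims=n_sims, seed=seed + 1,
                              trim_fraction=trim_fraction)
    res.df_t = df_t
    res.n_sims = n_sims
    res.seed = seed
    return res
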