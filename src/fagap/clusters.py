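"""Cluster detection, tier assignment, tiered Bonferroni correction,
trend classification, permutation validation and laterality indices.

The inference scheme: voxels with uncorrected two-tailed p below the
per-voxel threshold (0.05 by default) are grouped into connected
components separately for positive and negative group differences.  A
cluster is evaluated at the tier of the evaluation area (AOE) holding a
strict majority of its voxels — primary, secondary, or whole-brain — and
is significant when it meets that tier's extent requirement k and its peak
voxel survives a Bonferroni correction over N_search / k effective
comparisons, i.e. peak p < alpha * k / N_search.  A peak within one order
of magnitude of that threshold is a trend.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core import TIERS, AOETier, TierConfig, voxel_to_mm
from .contrast import StatMap

__all__ = [
    "Cluster",
    "CorrectionRule",
    "corrected_threshold",
    "find_clusters",
    "assign_tier",
    "classify_significance",
    "analyze_clusters",
    "cluster_table",
    "permutation_validate",
    "laterality_compare",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),   # faces only
    18: ndimage.generate_binary_structure(3, 2),  # faces + edges, not corners
    26: ndimage.generate_binary_structure(3, 3),  # faces + edges + corners
}


@dataclass
class Cluster:
    """A maximal connected set of same-sign suprathreshold voxels."""

    voxels: np.ndarray          # (m, 3) int indices
    sign: int                   # +1 patients elevated, -1 reduced
    peak_index: tuple[int, int, int]
    peak_t: float
    peak_p: float
    peak_mm: np.ndarray | None = None
    tier: str | None = None
    aoe_name: str | None = None
    status: str = "not_significant"
    k: int | None = None
    n_search: int | None = None
    threshold: float | None = None

    @property
    def size(self) -> int:
        return len(self.voxels)


@dataclass
class CorrectionRule:
    """Bonferroni rule for one tier: threshold = alpha / (N_search / k)."""

    n_search: int
    k: int
    alpha: float = 0.05
    corrected_threshold: float = field(init=False)

    def __post_init__(self) -> None:
        self.corrected_threshold = corrected_threshold(
            self.n_search, self.k, self.alpha)


def corrected_threshold(n_search: int, k: int, alpha: float = 0.05) -> float:
    """Peak-voxel threshold alpha * k / N_search.

    The search volume of N_search voxels is counted as N_search / k
    independent cluster-sized comparisons.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0,1)")
    if k < 1:
        raise ValueError("cluster size k must be >= 1")
    if k > n_search:
        raise ValueError(f"k={k} exceeds search volume N={n_search}")
    return alpha * k / n_search


def find_clusters(statmap: StatMap, config: TierConfig) -> list[Cluster]:
    """Connected components of suprathreshold voxels, split by sign.

    Components are maximal under the configured neighbourhood (default 18:
    voxels sharing a face or an edge, never only a corner).  Components
    smaller than the smallest tier extent are still returned (flagged
    ``not_significant``) so that sub-threshold structure remains visible.
    Clusters are ordered by descending size, ties by peak p.
    """
    structure = _STRUCTURES[config.connectivity]
    supra = (statmap.p_field < config.voxel_p_threshold) & statmap.search_mask
    clusters: list[Cluster] = []
    for sign in (1, -1):
        signed = supra & ((statmap.t_field > 0) if sign > 0 else (statmap.t_field < 0))
        labels, n = ndimage.label(signed, structure=structure)
        for lab in range(1, n + 1):
            vox = np.argwhere(labels == lab)
            pvals = statmap.p_field[tuple(vox.T)]
            tvals = statmap.t_field[tuple(vox.T)]
            # peak = smallest p; break ties on |t|, then index order
            order = np.lexsort((np.arange(len(vox)), -np.abs(tvals), pvals))
            best = order[0]
            peak = tuple(int(i) for i in vox[best])
            clusters.append(Cluster(
                voxels=vox, sign=sign, peak_index=peak,
                peak_t=float(tvals[best]), peak_p=float(pvals[best]),
                peak_mm=voxel_to_mm(np.array(peak), statmap.affine)))
    clusters.sort(key=lambda c: (-c.size, c.peak_p))
    return clusters


def assign_tier(cluster: Cluster, aoes) -> Cluster:
    """Assign a cluster to the AOE holding a strict majority of its voxels.

    A cluster belongs to an AOE iff strictly more than 50% of its voxels
    fall inside that AOE's mask; failing that it is evaluated at the
    whole-brain tier.  If several AOEs qualify (possible only across
    tiers, since same-configuration masks are disjoint), the most lenient
    tier wins (primary over secondary).
    """
    idx = tuple(cluster.voxels.T)
    best_name, best_tier = "whole_brain", "whole_brain"
    best_rank = len(TIERS)
    for aoe in aoes:
        if aoe.tier == "whole_brain":
            continue
        frac = float(aoe.mask[idx].mean())
        if frac > 0.5 and TIERS.index(aoe.tier) < best_rank:
            best_rank = TIERS.index(aoe.tier)
            best_name, best_tier = aoe.name, aoe.tier
    cluster.tier = best_tier
    cluster.aoe_name = best_name
    return cluster


def classify_significance(cluster: Cluster, rule: CorrectionRule,
                          trend_factor: float = 10.0) -> str:
    """Label a tier-assigned cluster significant / trend / not_significant."""
    thr = rule.corrected_threshold
    if cluster.size >= rule.k and cluster.peak_p < thr:
        status = "significant"
    elif cluster.size >= rule.k and cluster.peak_p < trend_factor * thr:
        status = "trend"
    else:
        status = "not_significant"
    cluster.status = status
    cluster.k = rule.k
    cluster.n_search = rule.n_search
    cluster.threshold = thr
    return status


def _tier_n_search(tier: str, aoe_name: str, aoes, statmap: StatMap,
                   config: TierConfig) -> int:
    """Search-volume voxel count for a cluster's tier.

    The correction counts the total evaluated voxels of the area being
    considered: all AOE masks of the cluster's tier combined (not just the
    matched mask), or the whole search mask for the whole-brain tier.
    Config overrides (by AOE name, then by tier) take precedence, e.g. to
    reproduce published search-volume constants.
    """
    if aoe_name in config.n_search:
        return int(config.n_search[aoe_name])
    if tier in config.n_search:
        return int(config.n_search[tier])
    if tier == "whole_brain":
        return statmap.n_search
    total = 0
    matched = False
    for aoe in aoes:
        if aoe.tier == tier:
            total += int((aoe.mask & statmap.search_mask).sum())
            matched = matched or aoe.name == aoe_name
    if not matched:
        raise KeyError(f"no AOE named {aoe_name!r} in tier {tier!r}")
    return total


def analyze_clusters(statmap: StatMap, aoes, config: TierConfig) -> list[Cluster]:
    """Full cluster pipeline: detect, assign tiers, classify significance."""
    clusters = find_clusters(statmap, config)
    for c in clusters:
        assign_tier(c, aoes)
        n_search = _tier_n_search(c.tier, c.aoe_name, aoes, statmap, config)
        k = config.k_cluster[c.tier]
        rule = CorrectionRule(n_search=max(n_search, k), k=k, alpha=config.alpha)
        classify_significance(c, rule, config.trend_factor)
    return clusters


def cluster_table(clusters) -> pd.DataFrame:
    """Tabulate clusters with peak mm coordinates, t, p, size and status."""
    rows = []
    for c in clusters:
        mm = c.peak_mm if c.peak_mm is not None else (np.nan,) * 3
        rows.append({
            "aoe": c.aoe_name, "tier": c.tier,
            "peak_x_mm": round(float(mm[0]), 3),
            "peak_y_mm": round(float(mm[1]), 3),
            "peak_z_mm": round(float(mm[2]), 3),
            "peak_t": c.peak_t, "peak_p": c.peak_p,
            "size_voxels": c.size, "sign": c.sign,
            "status": c.status, "k": c.k, "n_search": c.n_search,
            "corrected_threshold": c.threshold,
        })
    return pd.DataFrame(rows)


def permutation_validate(values, labels, n_perms: int, seed: int) -> float:
    """Label-permutation p for a two-group difference in region means.

    Two-sided via the absolute difference of group means.  When ``n_perms``
    covers all distinct label assignments the test is exhaustive and exact;
    otherwise ``n_perms`` Monte-Carlo assignments are drawn, the first being
    the identity, and p is the plain proportion with absolute mean
    difference at least as large as observed.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("labels must define exactly two groups")
    g1 = labels == groups[0]
    n, n1 = len(values), int(g1.sum())
    if n1 < 2 or n - n1 < 2:
        raise ValueError("need at least two subjects per group")
    obs = abs(values[g1].mean() - values[~g1].mean())

    from math import comb
    total = comb(n, n1)
    if n_perms >= total:
        hits = 0
        for combo in itertools.combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            if abs(values[sel].mean() - values[~sel].mean()) >= obs - 1e-12:
                hits += 1
        return hits / total

    rng = np.random.default_rng(seed)
    hits = 1  # identity permutation
    for _ in range(n_perms - 1):
        sel = np.zeros(n, dtype=bool)
        sel[rng.choice(n, size=n1, replace=False)] = True
        if abs(values[sel].mean() - values[~sel].mean()) >= obs - 1e-12:
            hits += 1
    return hits / n_perms


def _index_test_vs_zero(idx: np.ndarray) -> tuple[float, float]:
    """One-sample two-tailed t of laterality indices against zero."""
    idx = np.asarray(idx, dtype=float)
    sd = idx.std(ddof=1)
    if sd == 0:
        if np.allclose(idx.mean(), 0):
            return 0.0, 1.0
        return np.inf * np.sign(idx.mean()), 0.0
    t, p = stats.ttest_1samp(idx, 0.0)
    return float(t), float(p)


def laterality_compare(group_a, group_b, left: AOETier, right: AOETier) -> dict:
    """Laterality of region-mean FA, per group and between groups.

    Per subject the index is (R - L) / (R + L) over region means; each
    group's indices are tested against zero (one-sample t) and the two
    groups are compared with a pooled two-sample t.  Homologous masks must
    hold the same number of voxels.
    """
    if left.n_voxels == 0 or right.n_voxels == 0:
        raise ValueError("laterality masks must be non-empty")
    if left.n_voxels != right.n_voxels:
        raise ValueError("left/right masks must be homologous (equal voxel counts)")

    def indices(vols):
        out = []
        for v in vols:
            l = float(np.nanmean(v.data[left.mask]))
            r = float(np.nanmean(v.data[right.mask]))
            out.append((r - l) / (r + l))
        return np.array(out)

    ia, ib = indices(group_a), indices(group_b)
    ta, pa = _index_test_vs_zero(ia)
    tb, pb = _index_test_vs_zero(ib)
    if ia.std(ddof=1) == 0 and ib.std(ddof=1) == 0:
        tab, pab = (0.0, 1.0) if np.allclose(ia.mean(), ib.mean()) else (np.inf, 0.0)
    else:
        tab, pab = stats.ttest_ind(ia, ib, equal_var=True)
    return {
        "indices_a": ia, "indices_b": ib,
        "within_a": {"t": float(ta), "p": float(pa)},
        "within_b": {"t": float(tb), "p": float(pb)},
        "between": {"t": float(tab), "p": float(pab)},
    }
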