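"""Per-subject cluster means, subgroup re-contrasts, and symptom comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import SYMPTOM_MEASURES, TierConfig
from .clusters import Cluster, analyze_clusters, cluster_table
from .contrast import contrast

__all__ = [
    "extract_cluster_means",
    "SubgroupDesign",
    "subgroup_contrast",
    "symptom_compare",
]


def extract_cluster_means(cluster: Cluster, volumes) -> pd.Series:
    """Arithmetic mean FA over the cluster's voxels, one value per subject.

    Voxels with missing FA are excluded per subject; a subject with no
    valid voxel in the cluster raises.
    """
    idx = tuple(cluster.voxels.T)
    out = {}
    for v in volumes:
        vals = v.data[idx]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(
                f"cluster empty after missing-data exclusion for {v.subject_id}")
        out[v.subject_id] = float(vals.mean())
    return pd.Series(out, name="cluster_mean_fa")


@dataclass
class SubgroupDesign:
    """Assignment of patients to subgroups plus their matched controls.

    ``labels`` maps patient subject_id -> subgroup name; ``pairs`` maps
    patient subject_id -> matched control subject_id (via pair_id).
    """

    labels: dict
    pairs: dict

    @classmethod
    def from_cohort(cls, cohort: pd.DataFrame, labels: dict) -> "SubgroupDesign":
        pat = cohort[cohort.group == "patient"].set_index("subject_id")
        ctl = cohort[cohort.group == "control"].set_index("pair_id")
        pairs = {}
        for sid in labels:
            if sid not in pat.index:
                raise ValueError(f"labelled subject {sid!r} not in cohort")
            pid = pat.loc[sid, "pair_id"]
            if pid not in ctl.index:
                raise ValueError(f"patient {sid!r} has no matched control")
            pairs[sid] = ctl.loc[pid, "subject_id"]
        return cls(labels=dict(labels), pairs=pairs)

    def members(self, subgroup: str) -> list[str]:
        return [s for s, l in self.labels.items() if l == subgroup]


def subgroup_contrast(design: SubgroupDesign, subgroup: str, patients,
                      controls, aoes, config: TierConfig):
    """Re-run the voxel contrast for one subgroup against its own matched
    controls, under the identical tier/correction configuration.

    Returns (clusters, table, statmap)."""
    members = design.members(subgroup)
    if not members:
        raise ValueError(f"subgroup {subgroup!r} is empty")
    if len(members) < 2:
        raise ValueError(
            f"subgroup {subgroup!r} has {len(members)} member(s); "
            "a t statistic needs at least two per group")
    pat_by_id = {v.subject_id: v for v in patients}
    ctl_by_id = {v.subject_id: v for v in controls}
    try:
        sub_pat = [pat_by_id[s] for s in members]
        sub_ctl = [ctl_by_id[design.pairs[s]] for s in members]
    except KeyError as e:
        raise ValueError(f"volume missing for subject {e}") from e
    statmap = contrast(sub_pat, sub_ctl, variance=config.variance)
    clusters = analyze_clusters(statmap, aoes, config)
    return clusters, cluster_table(clusters), statmap


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        return (0.0, df, 1.0) if a.mean() == b.mean() else (np.inf, df, 0.0)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def symptom_compare(cohort: pd.DataFrame, labels: dict,
                    measures=SYMPTOM_MEASURES, alpha: float = 0.05,
                    n_corrections: int | None = None) -> pd.DataFrame:
    """Two-tailed pooled t-tests of symptom measures between two patient
    subgroups, Bonferroni-corrected across measures.

    ``labels`` maps patient subject_id -> subgroup; exactly two subgroup
    names must occur.  Each measure is analysed on its available cases
    (per-measure n and df).  A measure entirely missing in one subgroup is
    reported as not computable rather than failing the batch.
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise ValueError(f"labels must define exactly two subgroups, got {groups}")
    if n_corrections is None:
        n_corrections = len(measures)
    threshold = alpha / n_corrections
    pat = cohort[cohort.group == "patient"].set_index("subject_id")
    ga = [s for s, l in labels.items() if l == groups[0]]
    gb = [s for s, l in labels.items() if l == groups[1]]

    rows = []
    for m in measures:
        a = pat.loc[ga, m].dropna().to_numpy(dtype=float)
        b = pat.loc[gb, m].dropna().to_numpy(dtype=float)
        row = {
            "measure": m,
            f"mean_{groups[0]}": a.mean() if len(a) else np.nan,
            f"sd_{groups[0]}": a.std(ddof=1) if len(a) > 1 else np.nan,
            f"n_{groups[0]}": len(a),
            f"mean_{groups[1]}": b.mean() if len(b) else np.nan,
            f"sd_{groups[1]}": b.std(ddof=1) if len(b) > 1 else np.nan,
            f"n_{groups[1]}": len(b),
            "bonferroni_threshold": threshold,
        }
        if len(a) < 2 or len(b) < 2:
            row.update(t=np.nan, df=np.nan, p=np.nan,
                       significant=False, computable=False)
        else:
            t, df, p = _pooled_t(a, b)
            row.update(t=t, df=df, p=p,
                       significant=bool(p < threshold), computable=True)
        rows.append(row)
    return pd.DataFrame(rows)
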