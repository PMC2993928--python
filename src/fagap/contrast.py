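"""Mass-univariate two-sample t contrast between patient and control FA maps.

Sign convention throughout: positive t means the patient mean exceeds the
control mean at that voxel.  p values are two-tailed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import FAVolume, check_shared_grid

__all__ = ["StatMap", "contrast"]


@dataclass
class StatMap:
    """Voxel-wise t and two-tailed p fields over a search mask.

    Voxels outside ``search_mask`` (missing FA in any subject, or zero
    pooled variance) carry NaN in both fields and are never evaluated
    downstream.  ``df`` is the scalar pooled-variance df n1+n2-2; under the
    Welch option ``df_field`` holds the per-voxel Welch-Satterthwaite df.
    """

    t_field: np.ndarray
    p_field: np.ndarray
    df: int
    search_mask: np.ndarray
    group_sizes: tuple[int, int]
    affine: np.ndarray
    variance: str = "pooled"
    df_field: np.ndarray | None = None

    @property
    def n_search(self) -> int:
        return int(self.search_mask.sum())


def _stack(volumes) -> np.ndarray:
    return np.stack([v.data for v in volumes], axis=0)


def contrast(patients, controls, mask: np.ndarray | None = None,
             variance: str = "pooled") -> StatMap:
    """Voxel-wise two-tailed two-sample t-test, patients minus controls.

    Parameters
    ----------
    patients, controls
        Sequences of :class:`FAVolume` on one shared grid, at least two per
        group.
    mask
        Optional boolean array restricting the search set (e.g. a brain
        mask); voxels with missing data in any subject or zero variance are
        removed from the search set regardless.
    variance
        "pooled" (classic Student t, df = n1+n2-2; default) or "welch".
    """
    patients, controls = list(patients), list(controls)
    if len(patients) < 2 or len(controls) < 2:
        raise ValueError("need at least two subjects per group")
    shape, affine = check_shared_grid([*patients, *controls])
    x = _stack(patients)
    y = _stack(controls)
    n1, n2 = len(patients), len(controls)

    valid = np.all(np.isfinite(x), axis=0) & np.all(np.isfinite(y), axis=0)
    if mask is not None:
        if mask.shape != shape:
            raise ValueError("mask shape does not match volume grid")
        valid &= mask.astype(bool)

    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1 = x.var(axis=0, ddof=1)
    v2 = y.var(axis=0, ddof=1)

    t_field = np.full(shape, np.nan)
    p_field = np.full(shape, np.nan)
    df_field = None
    df = n1 + n2 - 2

    if variance == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        valid &= se2 > 0
        t = (m1 - m2)[valid] / np.sqrt(se2[valid])
        p = 2.0 * stats.t.sf(np.abs(t), df)
    elif variance == "welch":
        a, b = v1 / n1, v2 / n2
        se2 = a + b
        valid &= se2 > 0
        t = (m1 - m2)[valid] / np.sqrt(se2[valid])
        dfw = se2[valid] ** 2 / (a[valid] ** 2 / (n1 - 1) + b[valid] ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), dfw)
        df_field = np.full(shape, np.nan)
        df_field[valid] = dfw
    else:
        raise ValueError("variance must be 'pooled' or 'welch'")

    t_field[valid] = t
    p_field[valid] = p
    return StatMap(t_field=t_field, p_field=p_field, df=df,
                   search_mask=valid, group_sizes=(n1, n2), affine=affine,
                   variance=variance, df_field=df_field)
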