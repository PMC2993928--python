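"""Shared data model: FA volumes, evaluation-area tiers, cohort tables, tier config.

Fractional anisotropy (FA) is a dimensionless scalar in [0, 1] computed from
the three eigenvalues of the diffusion tensor; 0 means isotropic diffusion,
1 the fully anisotropic limit.  All downstream statistics in this package
operate on registered, resampled FA volumes that share one grid (shape +
voxel-to-mm affine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FAVolume",
    "AOETier",
    "TierConfig",
    "compute_fa",
    "voxel_to_mm",
    "mm_to_voxel",
    "clamp_fa",
    "validate_cohort",
    "COHORT_COLUMNS",
    "SYMPTOM_MEASURES",
]

#: Required columns of a cohort table.  Symptom fields may contain NaN.
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "pair_id",
    "age",
    "education",
    "sex",
    "handedness",
    "IDS_total",
    "IDS_anhedonia",
    "IDS_sadness",
    "IDS_psychomotor",
    "STAI_T",
]

#: The five symptom measures compared across subgroups.
SYMPTOM_MEASURES = [
    "IDS_total",
    "IDS_anhedonia",
    "IDS_sadness",
    "IDS_psychomotor",
    "STAI_T",
]

#: Bound-violation beyond this magnitude is treated as a real error,
#: not floating-point noise.
FA_CLAMP_TOL = 1e-6


class GridMismatchError(ValueError):
    """Raised when volumes that must share a grid do not."""


def compute_fa(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy of a diffusion tensor with eigenvalues ``l1..l3``.

    Uses the standard form

        FA = sqrt(3/2) * sqrt(sum_i (lam_i - lam_bar)^2 / sum_i lam_i^2)

    which is scale-invariant and permutation-invariant in the eigenvalues.
    Accepts scalars or broadcastable arrays.

    Raises
    ------
    ValueError
        if all three eigenvalues are zero (FA undefined), or any is negative.
    """
    lams = np.stack(np.broadcast_arrays(
        np.asarray(l1, dtype=float),
        np.asarray(l2, dtype=float),
        np.asarray(l3, dtype=float)))
    if np.any(lams < 0):
        raise ValueError("diffusion tensor eigenvalues must be non-negative")
    ssq = np.sum(lams ** 2, axis=0)
    if np.any(ssq == 0):
        raise ValueError("FA is undefined for an all-zero eigenvalue triple")
    mean = np.mean(lams, axis=0)
    fa = np.sqrt(1.5 * np.sum((lams - mean) ** 2, axis=0) / ssq)
    fa = np.clip(fa, 0.0, 1.0)  # guard rounding at the anisotropic limit
    if fa.ndim == 0:
        return float(fa)
    return fa


def clamp_fa(data: np.ndarray, tol: float = FA_CLAMP_TOL) -> np.ndarray:
    """Clamp FA values to [0, 1].

    Violations within ``tol`` are treated as numerical noise and clamped with
    a warning; anything larger raises, since it indicates the input is not an
    FA map.
    NaNs (missing voxels) pass through untouched.
    """
    data = np.asarray(data, dtype=float)
    with np.errstate(invalid="ignore"):
        low = np.nanmin(data) if np.any(np.isfinite(data)) else 0.0
        high = np.nanmax(data) if np.any(np.isfinite(data)) else 0.0
    if low < -tol or high > 1.0 + tol:
        raise ValueError(
            f"values outside [0,1] by more than {tol}: range [{low}, {high}]")
    if low < 0.0 or high > 1.0:
        warnings.warn("FA values clamped to [0,1] (numerical noise)", stacklevel=2)
        data = np.clip(data, 0.0, 1.0)
    return data


@dataclass
class FAVolume:
    """A 3-D FA scalar field on a shared grid.

    ``data`` holds FA values (NaN marks missing voxels); ``affine`` maps
    0-based voxel indices to mm coordinates in ``space_label`` space.
    """

    data: np.ndarray
    affine: np.ndarray
    subject_id: str = ""
    space_label: str = "MNI-ICBM152"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"FA volume must be 3-D, got {self.data.ndim}-D data")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        self.data = clamp_fa(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "FAVolume | AOETier") -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine, atol=1e-4))


def check_shared_grid(volumes, reference=None):
    """Assert all volumes share one grid; return (shape, affine)."""
    vols = list(volumes)
    if reference is None:
        reference = vols[0]
    for v in vols:
        if v.data.shape != reference.data.shape or not np.allclose(
                v.affine, reference.affine, atol=1e-4):
            raise GridMismatchError(
                f"volume {getattr(v, 'subject_id', '?')} grid "
                f"{v.data.shape} does not match reference {reference.data.shape}")
    return reference.data.shape, reference.affine


TIERS = ("primary", "secondary", "whole_brain")


@dataclass
class AOETier:
    """A named binary evaluation mask with its hypothesis tier."""

    name: str
    mask: np.ndarray
    tier: str
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise ValueError("AOE mask must be 3-D")
        if self.tier not in TIERS:
            raise ValueError(f"tier must be one of {TIERS}, got {self.tier!r}")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def check_disjoint_aoes(aoes) -> None:
    """Primary/secondary masks within one configuration must not overlap."""
    hyp = [a for a in aoes if a.tier in ("primary", "secondary")]
    for i, a in enumerate(hyp):
        for b in hyp[i + 1:]:
            if np.any(a.mask & b.mask):
                raise ValueError(f"AOE masks {a.name!r} and {b.name!r} overlap")


# Cluster-extent requirements per tier: the least stringent (primary) tier
# demands 9 face/edge-contiguous voxels, tripling per tier.
DEFAULT_K = {"primary": 9, "secondary": 27, "whole_brain": 81}


@dataclass
class TierConfig:
    """Thresholding configuration for tiered cluster inference.

    ``k_cluster`` gives the minimum contiguous-voxel count per tier; the
    peak-voxel Bonferroni threshold is ``alpha / (N_search / k)`` where
    N_search is the tier's search-volume voxel count.  ``n_search`` entries
    override the mask-derived counts (useful for reproducing published
    search volumes); absent entries are computed from the masks at run time.
    ``trend_factor`` widens the corrected threshold by one order of
    magnitude to classify trends.
    """

    alpha: float = 0.05
    voxel_p_threshold: float = 0.05
    trend_factor: float = 10.0
    connectivity: int = 18
    k_cluster: dict = field(default_factory=lambda: dict(DEFAULT_K))
    n_search: dict = field(default_factory=dict)
    variance: str = "pooled"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        for tier in TIERS:
            if tier not in self.k_cluster:
                raise ValueError(f"k_cluster missing tier {tier!r}")
        if self.variance not in ("pooled", "welch"):
            raise ValueError("variance must be 'pooled' or 'welch'")

    def with_overrides(self, **kw) -> "TierConfig":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "TierConfig":
        d = dict(d)
        if "k_cluster" in d:
            d["k_cluster"] = {**DEFAULT_K, **d["k_cluster"]}
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "voxel_p_threshold": self.voxel_p_threshold,
            "trend_factor": self.trend_factor,
            "connectivity": self.connectivity,
            "k_cluster": dict(self.k_cluster),
            "n_search": dict(self.n_search),
            "variance": self.variance,
        }


def voxel_to_mm(index, affine) -> np.ndarray:
    """Map 0-based voxel indices to mm coordinates through a 4x4 affine.

    ``index`` may be one triple or an (m, 3) array.
    """
    affine = np.asarray(affine, dtype=float)
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    mm = idx @ affine[:3, :3].T + affine[:3, 3]
    return mm[0] if np.asarray(index).ndim == 1 else mm


def mm_to_voxel(mm, affine) -> np.ndarray:
    """Inverse of :func:`voxel_to_mm`; raises on a singular affine."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is not invertible")
    inv = np.linalg.inv(affine)
    pts = np.atleast_2d(np.asarray(mm, dtype=float))
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    return vox[0] if np.asarray(mm).ndim == 1 else vox


def validate_cohort(table: pd.DataFrame, matched: bool = True) -> pd.DataFrame:
    """Validate a cohort table: required columns, one-to-one pairing, and
    (optionally) the matched-design constraints on age and education."""
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(table["group"]) - {"patient", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    for grp, sub in table.groupby("group"):
        if sub["pair_id"].duplicated().any():
            raise ValueError(f"duplicate pair_id within group {grp!r}")
    pat = table[table.group == "patient"].set_index("pair_id")
    ctl = table[table.group == "control"].set_index("pair_id")
    if set(pat.index) != set(ctl.index):
        raise ValueError("pair_ids do not match one-to-one across groups")
    if matched:
        for pid in pat.index:
            if abs(pat.loc[pid, "age"] - ctl.loc[pid, "age"]) > 5:
                raise ValueError(f"pair {pid}: age difference exceeds 5 years")
            if abs(pat.loc[pid, "education"] - ctl.loc[pid, "education"]) > 5:
                raise ValueError(f"pair {pid}: education difference exceeds 5 years")
    return table
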