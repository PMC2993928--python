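"""Synthetic matched FA cohorts with planted focal effects.

The generator emulates the statistical structure the pipeline assumes:
registered FA volumes with spatially smooth noise, one-to-one matched
patient/control pairs, focal group differences of configurable sign and
standardized effect size (optionally carried by only a subgroup of
patients, producing a bimodal region-mean distribution), tiered evaluation
masks covering the planted regions, and a symptom table whose trait-anxiety
scores separate by latent subgroup while depression-severity scores share
one distribution.

Noise model: independent Gaussian voxel noise smoothed with an isotropic
Gaussian kernel (default FWHM 2 voxels), the minimal structure mimicking
the spatial correlation of registered FA maps.  Planted shifts are scaled
by the *post-smoothing* voxel standard deviation, computed exactly from the
squared-kernel sum, so that ``effect_size`` is a true Cohen's d at the
voxel level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import AOETier, FAVolume, validate_cohort

__all__ = ["PlantedEffect", "SymptomModel", "SimConfig", "SimulatedCohort",
           "generate_cohort"]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PlantedEffect:
    """A focal FA difference planted in a box-shaped region.

    ``box`` is ((x0, x1), (y0, y1), (z0, z1)) half-open voxel bounds.
    ``effect_size`` shifts every patient; with ``subgroup_fraction`` < 1,
    the ``separation`` (standardized distance between subgroup means) is
    additionally applied to the carrier subgroup only.
    """

    box: tuple
    direction: str = "increase"         # or "decrease"
    effect_size: float = 0.0            # Cohen's d, whole patient group
    subgroup_fraction: float = 1.0
    separation: float = 0.0             # extra d for the carrier subgroup
    name: str = "effect"
    complement_of: str | None = None    # carry in the complement of another
                                        # effect's carrier subgroup

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError("direction must be 'increase' or 'decrease'")
        if not 0 < self.subgroup_fraction <= 1:
            raise ValueError("subgroup_fraction must lie in (0, 1]")
        if self.effect_size < 0 or self.separation < 0:
            raise ValueError("effect sizes must be non-negative")

    @property
    def sign(self) -> int:
        return 1 if self.direction == "increase" else -1

    def region_mask(self, shape) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        (x0, x1), (y0, y1), (z0, z1) = self.box
        if not (0 <= x0 < x1 <= shape[0] and 0 <= y0 < y1 <= shape[1]
                and 0 <= z0 < z1 <= shape[2]):
            raise ValueError(f"planted region {self.box} lies outside grid {shape}")
        mask[x0:x1, y0:y1, z0:z1] = True
        return mask


@dataclass
class SymptomModel:
    """Normal parameters (mean, sd) for symptom generation.

    Trait anxiety (STAI-T) is drawn per latent subgroup; the depression
    measures share one distribution across subgroups, so a correct analysis
    should flag STAI-T and nothing else.
    """

    stai_control: tuple = (35.0, 8.0)
    stai_normal: tuple = (51.3, 8.9)
    stai_abnormal: tuple = (61.8, 7.3)
    ids_total: tuple = (36.0, 9.6)
    ids_anhedonia: tuple = (1.3, 0.8)
    ids_sadness: tuple = (2.1, 0.9)
    ids_psychomotor: tuple = (1.1, 1.0)
    ids_total_control: tuple = (6.0, 4.0)
    ids_item_control: tuple = (0.3, 0.5)


@dataclass
class SimConfig:
    """Full description of one simulated study."""

    shape: tuple = (32, 32, 32)
    spacing_mm: float = 2.0
    n_pairs: int = 22
    baseline_fa: float = 0.45
    noise_sd: float = 0.06
    smooth_fwhm_vox: float = 2.0
    effects: list = field(default_factory=list)
    symptoms: SymptomModel = field(default_factory=SymptomModel)
    seed: int = 0

    def affine(self) -> np.ndarray:
        aff = np.diag([self.spacing_mm] * 3 + [1.0])
        # centre the grid on the origin, mirroring stereotaxic conventions
        aff[:3, 3] = -self.spacing_mm * (np.asarray(self.shape) - 1) / 2.0
        return aff


@dataclass
class SimulatedCohort:
    patients: list
    controls: list
    aoes: list
    cohort: pd.DataFrame
    truth: dict


def smoothed_noise_sd(noise_sd: float, fwhm_vox: float, shape) -> float:
    """Exact post-smoothing sd of iid N(0, noise_sd^2) voxel noise.

    Gaussian filtering with kernel weights w gives output variance
    noise_sd^2 * sum(w^2); the sum is obtained by filtering a unit impulse.
    """
    if fwhm_vox <= 0:
        return noise_sd
    sigma = fwhm_vox * FWHM_TO_SIGMA
    r = int(np.ceil(4 * sigma)) * 2 + 1
    impulse = np.zeros((r, r, r))
    impulse[r // 2, r // 2, r // 2] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma)
    return float(noise_sd * np.sqrt(np.sum(kernel ** 2)))


def _noise_field(rng, cfg: SimConfig) -> np.ndarray:
    f = rng.standard_normal(cfg.shape) * cfg.noise_sd
    if cfg.smooth_fwhm_vox > 0:
        f = ndimage.gaussian_filter(f, cfg.smooth_fwhm_vox * FWHM_TO_SIGMA)
    return f


def _dilate(mask: np.ndarray, it: int = 1) -> np.ndarray:
    return ndimage.binary_dilation(mask, iterations=it)


def generate_cohort(cfg: SimConfig) -> SimulatedCohort:
    """Generate a matched patient/control cohort per ``cfg``.

    Returns volumes, AOE masks (one primary mask per planted region plus a
    disjoint secondary mask and a whole-brain mask), a validated cohort
    table, and a truth record listing each planted region's voxels and each
    patient's latent subgroup.  Bit-reproducible for a fixed seed.
    """
    if cfg.n_pairs < 2:
        raise ValueError("n_pairs must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    affine = cfg.affine()
    n = cfg.n_pairs
    post_sd = smoothed_noise_sd(cfg.noise_sd, cfg.smooth_fwhm_vox, cfg.shape)

    # latent subgroup: carriers of the first subgroup-structured effect
    subgroup = np.array(["normal"] * n, dtype=object)
    carrier_sets = []
    by_name = {}
    for eff in cfg.effects:
        if eff.complement_of is not None:
            if eff.complement_of not in by_name:
                raise ValueError(
                    f"effect {eff.name!r}: complement_of references unknown "
                    f"effect {eff.complement_of!r} (must come earlier)")
            carriers = np.setdiff1d(np.arange(n), by_name[eff.complement_of])
        else:
            n_carriers = int(round(eff.subgroup_fraction * n))
            carriers = np.sort(rng.choice(n, size=n_carriers, replace=False))
        carrier_sets.append(carriers)
        by_name[eff.name] = carriers
        if eff.complement_of is None and eff.subgroup_fraction < 1 \
                and eff.separation > 0:
            subgroup[:] = "normal"
            subgroup[carriers] = "abnormal"

    patients, controls = [], []
    for i in range(n):
        ctl = cfg.baseline_fa + _noise_field(rng, cfg)
        pat = cfg.baseline_fa + _noise_field(rng, cfg)
        for eff, carriers in zip(cfg.effects, carrier_sets):
            region = eff.region_mask(cfg.shape)
            shift = eff.effect_size
            if i in carriers:
                shift += eff.separation
            pat[region] += eff.sign * shift * post_sd
        patients.append(FAVolume(np.clip(pat, 0, 1), affine, f"P{i + 1:02d}"))
        controls.append(FAVolume(np.clip(ctl, 0, 1), affine, f"C{i + 1:02d}"))

    aoes = _build_aoes(cfg)

    cohort = _symptom_table(rng, cfg, subgroup)
    truth = {
        "post_smoothing_sd": post_sd,
        "subgroup": {f"P{i + 1:02d}": str(subgroup[i]) for i in range(n)},
        "effects": [
            {
                "name": eff.name,
                "direction": eff.direction,
                "effect_size": eff.effect_size,
                "separation": eff.separation,
                "carriers": [f"P{i + 1:02d}" for i in carriers],
                "region_voxels": np.argwhere(eff.region_mask(cfg.shape)).tolist(),
            }
            for eff, carriers in zip(cfg.effects, carrier_sets)
        ],
    }
    return SimulatedCohort(patients, controls, aoes, cohort, truth)


def _build_aoes(cfg: SimConfig) -> list:
    """One primary AOE per planted region (slightly dilated), one disjoint
    secondary AOE, and a whole-brain mask."""
    affine = cfg.affine()
    aoes = []
    occupied = np.zeros(cfg.shape, dtype=bool)
    for i, eff in enumerate(cfg.effects):
        m = _dilate(eff.region_mask(cfg.shape), 1)
        aoes.append(AOETier(name=f"primary_{eff.name}", mask=m,
                            tier="primary", affine=affine))
        occupied |= m
    if not cfg.effects:
        m = np.zeros(cfg.shape, dtype=bool)
        c = tuple(s // 2 for s in cfg.shape)
        m[c[0] - 2:c[0] + 3, c[1] - 2:c[1] + 3, c[2] - 2:c[2] + 3] = True
        aoes.append(AOETier(name="primary_central", mask=m,
                            tier="primary", affine=affine))
        occupied |= m
    sec = np.zeros(cfg.shape, dtype=bool)
    sec[1:7, 1:7, 1:7] = True
    sec &= ~_dilate(occupied, 1)
    if sec.any():
        aoes.append(AOETier(name="secondary_box", mask=sec,
                            tier="secondary", affine=affine))
    aoes.append(AOETier(name="whole_brain", mask=np.ones(cfg.shape, bool),
                        tier="whole_brain", affine=affine))
    return aoes


def _draw(rng, params, size):
    return rng.normal(params[0], params[1], size)


def _symptom_table(rng, cfg: SimConfig, subgroup) -> pd.DataFrame:
    n = cfg.n_pairs
    sm = cfg.symptoms
    ages = rng.integers(20, 61, size=n)
    edu = rng.integers(12, 21, size=n)
    sex = rng.choice(["F", "M"], size=n)
    hand = rng.choice(["R", "L"], size=n, p=[0.9, 0.1])
    rows = []
    for grp in ("patient", "control"):
        for i in range(n):
            if grp == "patient":
                stai_par = (sm.stai_abnormal if subgroup[i] == "abnormal"
                            else sm.stai_normal)
                ids_tot, item = sm.ids_total, None
                rows.append({
                    "subject_id": f"P{i + 1:02d}", "group": grp,
                    "pair_id": f"pair{i + 1:02d}",
                    "age": int(ages[i]), "education": int(edu[i]),
                    "sex": sex[i], "handedness": hand[i],
                    "IDS_total": max(0.0, _draw(rng, ids_tot, None)),
                    "IDS_anhedonia": max(0.0, _draw(rng, sm.ids_anhedonia, None)),
                    "IDS_sadness": max(0.0, _draw(rng, sm.ids_sadness, None)),
                    "IDS_psychomotor": max(0.0, _draw(rng, sm.ids_psychomotor, None)),
                    "STAI_T": max(20.0, _draw(rng, stai_par, None)),
                })
            else:
                rows.append({
                    "subject_id": f"C{i + 1:02d}", "group": grp,
                    "pair_id": f"pair{i + 1:02d}",
                    "age": int(ages[i] + rng.integers(-3, 4)),
                    "education": int(np.clip(edu[i] + rng.integers(-3, 4), 10, 22)),
                    "sex": sex[i], "handedness": hand[i],
                    "IDS_total": max(0.0, _draw(rng, sm.ids_total_control, None)),
                    "IDS_anhedonia": max(0.0, _draw(rng, sm.ids_item_control, None)),
                    "IDS_sadness": max(0.0, _draw(rng, sm.ids_item_control, None)),
                    "IDS_psychomotor": max(0.0, _draw(rng, sm.ids_item_control, None)),
                    "STAI_T": max(20.0, _draw(rng, sm.stai_control, None)),
                })
    return validate_cohort(pd.DataFrame(rows))
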