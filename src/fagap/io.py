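"""Readers and writers: NIfTI volumes/masks, cohort TSV, config YAML/JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AOETier, FAVolume, GridMismatchError, TierConfig, validate_cohort

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort",
    "write_cohort",
    "load_tier_config",
    "load_config",
]


def read_volume(path, subject_id: str | None = None,
                reference: FAVolume | None = None) -> FAVolume:
    """Read a 3-D NIfTI FA image.

    If ``reference`` is given, the grid (shape + affine) must match it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D scalar image, got {data.ndim}-D")
    vol = FAVolume(data=data, affine=img.affine,
                   subject_id=subject_id or Path(path).stem.split(".")[0])
    if reference is not None and not vol.same_grid(reference):
        raise GridMismatchError(
            f"{path}: grid {vol.shape} does not match declared reference "
            f"{reference.shape}")
    return vol


def write_volume(volume: FAVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    nib.save(img, str(path))


def read_mask(path, name: str, tier: str) -> AOETier:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    return AOETier(name=name, mask=data > 0, tier=tier, affine=img.affine)


def write_mask(aoe: AOETier, path, affine=None) -> None:
    aff = aoe.affine if aoe.affine is not None else affine
    if aff is None:
        aff = np.eye(4)
    img = nib.Nifti1Image(aoe.mask.astype(np.uint8), aff)
    nib.save(img, str(path))


def read_cohort(path, matched: bool = True) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_cohort(table, matched=matched)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _load_structured(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_tier_config(path) -> TierConfig:
    return TierConfig.from_dict(_load_structured(path))


def load_config(path) -> dict:
    """Load a pipeline config (YAML or JSON) as a plain dict."""
    cfg = _load_structured(path)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg
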