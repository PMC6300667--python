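"""Reading and writing of volumes, masks, tables and configuration.

Volumes and masks are NIfTI (via nibabel); area tables, time series and
timing tables are TSV; results are JSON; configuration is a plain-text
``key = value`` file with unknown keys rejected.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "write_volume", "read_volume", "write_mask", "read_mask",
    "write_table", "read_table", "write_timing_table", "read_timing_table",
    "write_json", "read_config", "write_config",
    "dataset_to_nifti", "PipelineConfig",
]


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a 3-D or 4-D volume as NIfTI."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def write_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def read_mask(path, volume_shape: tuple | None = None) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asarray(img.get_fdata()) > 0
    if volume_shape is not None and mask.shape != tuple(volume_shape[:3]):
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid "
            f"{tuple(volume_shape[:3])}")
    if not mask.any():
        raise ValueError(f"mask {path} contains zero voxels")
    return mask


def dataset_to_nifti(dataset, path) -> None:
    """Write a SubjectDataset's voxel series as a 4-D NIfTI on its lattice."""
    from .preprocess import _lattice_index
    coords = dataset.voxel_coords_mm
    idx, spacing, shape = _lattice_index(coords)
    vol = np.zeros(shape + (dataset.n_timepoints,))
    vol[tuple(idx.T)] = dataset.voxel_series
    origin = coords.min(axis=0)
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    write_volume(vol, affine, path)


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path, required: list | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if required:
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"table {path} missing column(s): {missing}")
    return frame


def write_timing_table(block_table: pd.DataFrame, path) -> None:
    write_table(block_table[["onset", "duration", "condition"]], path)


def read_timing_table(path) -> pd.DataFrame:
    return read_table(path, required=["onset", "duration", "condition"])


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=default))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

#: Defaults follow the analysis parameters: 2.5 SD despike, 0.01-0.1 Hz
#: band, 21.6 s initial drop, 4 mm FWHM smoothing, FDR q = 0.05, 500
#: split-half iterations, 1000 permutations, ISC threshold 0.15.
PIPELINE_DEFAULTS = {
    "simulate": True,
    "output_dir": "results",
    "seed": 0,
    "n_subjects": 13,
    "despike_sd": 2.5,
    "low_hz": 0.01,
    "high_hz": 0.1,
    "drop_seconds": 21.6,
    "smooth_fwhm_mm": 4.0,
    "fdr_q": 0.05,
    "split_half_iterations": 500,
    "n_permutations": 1000,
    "isc_threshold": 0.15,
    "include_self": False,
    "run_isc": True,
    "run_taskglm": True,
    "run_split_half": True,
}

_TYPES = {k: type(v) for k, v in PIPELINE_DEFAULTS.items()}


class PipelineConfig(dict):
    """Validated pipeline configuration (plain key = value file)."""

    def __init__(self, **kwargs):
        unknown = set(kwargs) - set(PIPELINE_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(PIPELINE_DEFAULTS)
        merged.update(kwargs)
        super().__init__(merged)

    def __getattr__(self, key):
        try:
            return self[key]
        except KeyError as exc:
            raise AttributeError(key) from exc


def _parse_value(key: str, raw: str):
    typ = _TYPES[key]
    if typ is bool:
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key!r}: cannot parse bool from {raw!r}")
    return typ(raw)


def read_config(path) -> PipelineConfig:
    """Parse a plain-text ``key = value`` configuration file."""
    values = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in PIPELINE_DEFAULTS:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(key, raw)
    return PipelineConfig(**values)


def write_config(config: PipelineConfig, path) -> None:
    lines = [f"{k} = {config[k]}" for k in sorted(config)]
    Path(path).write_text("\n".join(lines) + "\n")
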