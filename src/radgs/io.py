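"""NIfTI / CSV / YAML input-output.

Parameter maps and ROI masks are stored as single-slice NIfTI files with a
JSON sidecar carrying the metadata NIfTI cannot (map name and units, fit
model, lesion id, inflation level, acquisition axes). Axes are row-major
and 0-based: array index (row, col) maps to voxel (i, j) with pixel units.
Feature tables are plain CSV with the canonical feature names as header.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from radgs.qmaps import ParameterMap
from radgs.roi import ROIMask

__all__ = [
    "save_parameter_map",
    "load_parameter_map",
    "save_mask",
    "load_mask",
    "save_feature_table",
    "load_feature_table",
    "load_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json")


def save_parameter_map(pmap: ParameterMap, path: str | Path, **meta) -> None:
    path = Path(path)
    img = nib.Nifti1Image(pmap.grid.astype(np.float64), affine=np.eye(4))
    nib.save(img, path)
    side = {
        "name": pmap.name,
        "units": pmap.units,
        "valid_mask": pmap.valid_mask.astype(int).tolist(),
        **meta,
    }
    _sidecar(path).write_text(json.dumps(side))


def load_parameter_map(path: str | Path) -> ParameterMap:
    path = Path(path)
    grid = np.asarray(nib.load(path).dataobj, dtype=float)
    side = json.loads(_sidecar(path).read_text())
    return ParameterMap(
        name=side["name"],
        grid=grid,
        units=side["units"],
        valid_mask=np.asarray(side["valid_mask"], dtype=bool),
    )


def save_mask(mask: ROIMask, path: str | Path, **meta) -> None:
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), affine=np.eye(4))
    nib.save(img, path)
    side = {"lesion_id": mask.lesion_id, "dilation_level": mask.dilation_level, **meta}
    _sidecar(path).write_text(json.dumps(side))


def load_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    grid = np.asarray(nib.load(path).dataobj) > 0
    side = json.loads(_sidecar(path).read_text())
    return ROIMask(grid, side["lesion_id"], side["dilation_level"])


def save_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def load_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
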