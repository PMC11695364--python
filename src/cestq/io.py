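"""NIfTI / CSV / JSON-sidecar persistence.

Image stacks, metric maps and masks travel as NIfTI-1 files; the offset
schedule rides in a JSON sidecar next to the stack ({"offsets_ppm": [...],
"reference_index": i}); per-subject histogram features are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import OffsetSchedule, RoiMask

__all__ = [
    "sidecar_path",
    "write_volume",
    "read_volume",
    "write_metric_map",
    "read_mask",
    "write_mask",
    "write_feature_table",
    "read_feature_table",
]


def sidecar_path(path) -> Path:
    p = Path(path)
    name = p.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return p.with_name(name[: -len(suf)] + ".json")
    return p.with_suffix(".json")


def write_volume(data: np.ndarray, path, schedule: OffsetSchedule | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(path))
    if schedule is not None:
        meta = {"offsets_ppm": list(schedule.offsets_ppm),
                "reference_index": schedule.reference_index}
        sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path) -> tuple[np.ndarray, OffsetSchedule | None]:
    """Load a volume and, if a sidecar exists, its offset schedule.

    A sidecar whose schedule length matches neither the full stack depth
    nor the non-reference depth is a hard error.
    """
    data = np.asarray(nib.load(str(path)).get_fdata())
    sc = sidecar_path(path)
    schedule = None
    if sc.exists():
        meta = json.loads(sc.read_text())
        schedule = OffsetSchedule(tuple(meta["offsets_ppm"]),
                                  meta.get("reference_index"))
        depth = data.shape[-1]
        if depth not in (len(schedule), len(schedule.sampled_offsets)):
            raise ValueError(
                f"stack depth {depth} matches neither the {len(schedule)} "
                f"schedule offsets nor the {len(schedule.sampled_offsets)} "
                "non-reference offsets")
    return data, schedule


def write_metric_map(metric_map: np.ndarray, path) -> None:
    write_volume(metric_map, path)


def write_mask(mask: RoiMask, path) -> None:
    write_volume(mask.voxels.astype(np.uint8), path)


def read_mask(path, label: str | None = None,
              image_shape: tuple[int, ...] | None = None) -> RoiMask:
    data, _ = read_volume(path)
    if image_shape is not None and data.shape != tuple(image_shape):
        raise ValueError(f"mask shape {data.shape} does not match image "
                         f"shape {tuple(image_shape)}")
    return RoiMask(label or Path(path).stem.split(".")[0], data > 0.5)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
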