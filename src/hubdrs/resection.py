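"""Label atlas regions as surgically removed or spared.

Two input paths: an explicit list of removed region ids (e.g. transcribed
from a surgery report), or a pair of co-registered volumes — a parcellation
label volume and a binary resection mask.  In the volumetric path a region
counts as removed if *any* of its voxels lies under the mask; there is no
minimum-overlap threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .atlas import RegionAtlas


@dataclass(frozen=True)
class RemovalLabels:
    """Partition of the atlas into removed and spared regions."""

    removed: frozenset[int]
    spared: frozenset[int]

    def __post_init__(self) -> None:
        if self.removed & self.spared:
            raise ValueError("removed and spared sets overlap")


def label_from_volumes(
    labels: np.ndarray,
    mask: np.ndarray,
    atlas: RegionAtlas,
) -> RemovalLabels:
    """Apply the any-overlap rule to a label volume and a resection mask.

    A region is removed iff at least one voxel carries its label and is
    inside the mask (value 1); all other atlas regions are spared.  Voxels
    labelled 0 are background.  Label ids absent from the atlas are an
    error — they indicate a parcellation-scale mismatch, not ignorable
    noise.  An empty removed set is legal here (it only warns); it becomes
    an error downstream where a removed/spared contrast is required.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask)
    if labels.shape != mask.shape:
        raise ValueError(
            f"label volume shape {labels.shape} != mask shape {mask.shape}"
        )
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("resection mask must be binary (values 0/1 only)")
    if np.any(labels < 0):
        raise ValueError("label volume must be nonnegative")
    atlas_ids = set(atlas.region_ids.tolist())
    present = set(np.unique(labels).tolist()) - {0}
    unknown = present - atlas_ids
    if unknown:
        raise ValueError(
            f"label volume contains region ids not in the atlas: {sorted(unknown)}"
        )
    under_mask = set(np.unique(labels[mask == 1]).tolist()) - {0}
    if not under_mask:
        warnings.warn("resection mask overlaps no labelled region; removed set "
                      "is empty", stacklevel=2)
    removed = frozenset(int(r) for r in under_mask)
    return RemovalLabels(removed=removed, spared=frozenset(atlas_ids - removed))


def label_from_list(removed_ids: Iterable[int], atlas: RegionAtlas) -> RemovalLabels:
    """Label regions from an explicit removed-region list."""
    removed = frozenset(int(r) for r in removed_ids)
    if not removed:
        raise ValueError("removed_ids must be nonempty")
    atlas_ids = set(atlas.region_ids.tolist())
    unknown = removed - atlas_ids
    if unknown:
        raise ValueError(f"removed ids not in atlas: {sorted(unknown)}")
    return RemovalLabels(removed=removed, spared=frozenset(atlas_ids - removed))


def load_nifti_volume(path: str | Path) -> np.ndarray:
    """Read a NIfTI volume as an integer array (parcellation or mask)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError(f"{path}: volume does not hold integer labels")
    return rounded.astype(np.int64)


def read_removed_ids(path: str | Path) -> frozenset[int]:
    """Read removed region ids from JSON (list or {'removed': [...]}) or
    plain text (one id per line)."""
    import json

    text = Path(path).read_text()
    try:
        obj = json.loads(text)
    except json.JSONDecodeError:
        ids = [int(line) for line in text.split() if line.strip()]
        return frozenset(ids)
    if isinstance(obj, dict):
        obj = obj["removed"]
    return frozenset(int(r) for r in obj)
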