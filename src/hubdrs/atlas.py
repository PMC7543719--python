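"""Region atlases: ordered cortical parcels with hemisphere labels.

The atlas fixes node identity for the whole pipeline: row/column ``i`` of
every time-series matrix, connectivity matrix and strength vector refers to
``atlas.regions[i]``.  Region ids are positive integers and need not be
contiguous, but the *order* of the atlas is canonical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class Region:
    """One cortical parcel."""

    region_id: int
    name: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.region_id < 1:
            raise ValueError(f"region_id must be >= 1, got {self.region_id}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered collection of regions with at least two per hemisphere."""

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        for hemi in HEMISPHERES:
            n = sum(r.hemisphere == hemi for r in self.regions)
            if n < 2:
                raise ValueError(
                    f"atlas needs at least 2 regions in hemisphere {hemi}, got {n}"
                )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def region_ids(self) -> np.ndarray:
        return np.array([r.region_id for r in self.regions], dtype=int)

    @property
    def hemispheres(self) -> np.ndarray:
        return np.array([r.hemisphere for r in self.regions])

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask (atlas order) of regions in ``hemisphere``."""
        if hemisphere not in HEMISPHERES:
            raise ValueError(f"unknown hemisphere {hemisphere!r}")
        return self.hemispheres == hemisphere

    def index_of(self, region_id: int) -> int:
        """Position of ``region_id`` in atlas order."""
        idx = np.flatnonzero(self.region_ids == region_id)
        if idx.size == 0:
            raise KeyError(f"region id {region_id} not in atlas")
        return int(idx[0])

    def indices_of(self, region_ids: Iterable[int]) -> np.ndarray:
        return np.array(sorted(self.index_of(r) for r in region_ids), dtype=int)

    def hemisphere_of(self, region_id: int) -> str:
        return self.regions[self.index_of(region_id)].hemisphere

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": [r.name for r in self.regions],
                "hemisphere": self.hemispheres,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegionAtlas":
        required = {"region_id", "name", "hemisphere"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        regions = tuple(
            Region(int(row.region_id), str(row.name_), str(row.hemisphere))
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        )
        return cls(regions)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RegionAtlas":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def build_atlas(n_regions: int) -> RegionAtlas:
    """Build a symmetric two-hemisphere atlas with ``n_regions`` parcels.

    The first half of the regions is assigned to the left hemisphere and the
    second half to the right; ids run 1..n_regions.  ``n_regions`` must be
    even and at least 4 so that every hemisphere holds two or more regions
    (intra-hemispheric node strength is undefined otherwise).
    """
    if n_regions < 4:
        raise ValueError(f"n_regions must be >= 4, got {n_regions}")
    if n_regions % 2 != 0:
        raise ValueError(f"n_regions must be even, got {n_regions}")
    half = n_regions // 2
    regions = tuple(
        Region(i + 1, f"{'L' if i < half else 'R'}_region_{i + 1:03d}",
               "L" if i < half else "R")
        for i in range(n_regions)
    )
    return RegionAtlas(regions)
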