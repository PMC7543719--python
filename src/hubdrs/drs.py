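"""Intra-hemispheric node strength and the D_RS distinguishability statistic.

Node strength of region *i* is the mean Pearson correlation between *i* and
every other region of the same hemisphere; inter-hemispheric entries never
enter.  D_RS (Distinguishability of Removed vs Spared node strength) is the
normalized Mann–Whitney U of the spared sample over all removed x spared
strength pairs:

    D_RS = [ #{(r, s) : strength(s) > strength(r)} + 0.5 * #ties ] / (n_r * n_s)

so 0 means every removed node is stronger than every spared node (the
resection took the network hubs), 1 the reverse, and 0.5 that removed and
spared strengths are interleaved.  As a rank statistic it is invariant
under any strictly increasing transform of the strengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .atlas import HEMISPHERES, RegionAtlas
from .connectivity import KIND_EPOCH_MEAN, ConnectivityMatrix
from .resection import RemovalLabels

SPARED_SCOPES = ("both", "ipsilateral")


@dataclass(frozen=True)
class NodeStrengthVector:
    """Per-region intra-hemispheric mean correlation, in atlas order."""

    strength: np.ndarray
    atlas: RegionAtlas

    def __post_init__(self) -> None:
        if self.strength.shape != (self.atlas.n_regions,):
            raise ValueError("strength vector length does not match atlas")
        if np.any(np.abs(self.strength) > 1 + 1e-9):
            raise ValueError("strengths are mean correlations and must lie in [-1, 1]")

    def of(self, region_id: int) -> float:
        return float(self.strength[self.atlas.index_of(region_id)])


@dataclass(frozen=True)
class DrsResult:
    drs: float
    n_removed: int
    n_spared: int
    subject_id: str = ""
    epoch_index: int = 0
    spared_scope: str = "both"

    def __post_init__(self) -> None:
        if not (0.0 <= self.drs <= 1.0):
            raise ValueError("D_RS must lie in [0, 1]")
        if self.n_removed < 1 or self.n_spared < 1:
            raise ValueError("need at least one removed and one spared region")


def intra_hemispheric_strength(
    fc: ConnectivityMatrix, atlas: RegionAtlas | None = None
) -> NodeStrengthVector:
    """Mean within-hemisphere correlation of every region.

    Works on masked or unmasked epoch-mean matrices: only same-hemisphere
    entries are read, which a hemispheric mask leaves untouched.
    """
    atlas = atlas if atlas is not None else fc.atlas
    if atlas != fc.atlas:
        raise ValueError("atlas does not match the connectivity matrix")
    if fc.kind != KIND_EPOCH_MEAN:
        raise ValueError("node strength is defined on epoch-mean matrices")
    strength = np.empty(atlas.n_regions)
    for hemi in HEMISPHERES:
        idx = np.flatnonzero(atlas.hemisphere_mask(hemi))
        if idx.size < 2:
            raise ValueError(
                f"hemisphere {hemi} has {idx.size} region(s); "
                "strength needs at least 2"
            )
        block = fc.values[np.ix_(idx, idx)]
        if not np.all(np.isfinite(block)):
            raise ValueError(f"non-finite within-hemisphere entries ({hemi})")
        strength[idx] = (block.sum(axis=1) - np.diag(block)) / (idx.size - 1)
    return NodeStrengthVector(strength=strength, atlas=atlas)


def rank_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized Mann–Whitney U of sample ``y``:
    P(y > x) + 0.5 * P(y = x) over all cross pairs, via midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = rankdata(np.concatenate([x, y]))
    u_y = ranks[x.size:].sum() - y.size * (y.size + 1) / 2.0
    return float(u_y / (x.size * y.size))


def drs_statistic(
    strength: NodeStrengthVector,
    labels: RemovalLabels,
    subject_id: str = "",
    epoch_index: int = 0,
    spared_scope: str = "both",
) -> DrsResult:
    """D_RS over removed x spared node-strength pairs.

    ``spared_scope`` chooses the comparison set: ``"both"`` compares the
    removed regions against every non-removed region in either hemisphere
    (each node's strength still computed within its own hemisphere);
    ``"ipsilateral"`` restricts the spared set to the resected hemisphere.
    """
    if spared_scope not in SPARED_SCOPES:
        raise ValueError(f"spared_scope must be one of {SPARED_SCOPES}")
    atlas = strength.atlas
    atlas_ids = set(atlas.region_ids.tolist())
    if not labels.removed:
        raise ValueError("D_RS needs at least one removed region")
    if not labels.removed <= atlas_ids:
        raise ValueError("removed regions outside the atlas")
    spared = set(labels.spared) & atlas_ids
    if spared_scope == "ipsilateral":
        hemis = {atlas.hemisphere_of(r) for r in labels.removed}
        if len(hemis) != 1:
            raise ValueError("ipsilateral scope requires a unilateral resection")
        hemi = hemis.pop()
        spared = {r for r in spared if atlas.hemisphere_of(r) == hemi}
    if not spared:
        raise ValueError("D_RS needs at least one spared region")
    removed_s = np.array([strength.of(r) for r in sorted(labels.removed)])
    spared_s = np.array([strength.of(r) for r in sorted(spared)])
    return DrsResult(
        drs=rank_auc(removed_s, spared_s),
        n_removed=removed_s.size,
        n_spared=spared_s.size,
        subject_id=subject_id,
        epoch_index=epoch_index,
        spared_scope=spared_scope,
    )


def drs_from_values(removed_strengths, spared_strengths) -> float:
    """D_RS directly from two strength samples (removed, spared)."""
    return rank_auc(np.asarray(removed_strengths, dtype=float),
                    np.asarray(spared_strengths, dtype=float))
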