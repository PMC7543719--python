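"""Sliding-window amplitude-correlation networks from ROI time series.

One functional network per analysis epoch: the epoch is cut into short
overlapping windows (default 2 s with 50% overlap), one Pearson correlation
matrix is computed per window, and the window matrices are averaged
element-wise into a single epoch matrix.  Inter-hemispheric entries can be
masked afterwards, since unilateral-resection analyses discount them.

Raw correlations are averaged without a variance-stabilizing transform, and
negative correlations are kept as-is.  Trailing samples that do not fill a
complete window are dropped so that every window contributes a correlation
estimate of equal sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .atlas import RegionAtlas

KIND_WINDOW = "window"
KIND_EPOCH_MEAN = "epoch_mean"

Interval = tuple[int, int]  # half-open [start, end) in samples


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry. Lengths are rounded to whole samples."""

    fs: float
    window_seconds: float = 2.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.window_samples < 2:
            raise ValueError("window must span at least 2 samples")
        if self.step_samples < 1:
            raise ValueError("window step must be at least 1 sample")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.fs))

    @property
    def step_samples(self) -> int:
        return int(round(self.window_seconds * self.fs * (1 - self.overlap_fraction)))


@dataclass(frozen=True)
class EpochTimeSeries:
    """One subject-epoch of ROI signals, rows in atlas order."""

    data: np.ndarray  # (n_regions, n_samples)
    fs: float
    atlas: RegionAtlas
    epoch_index: int = 1
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (regions x samples) matrix")
        if self.data.shape[0] != self.atlas.n_regions:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but atlas has "
                f"{self.atlas.n_regions} regions"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region-by-region Pearson correlation matrix.

    ``kind`` distinguishes single-window matrices from epoch averages.
    Masked (inter-hemispheric) entries are NaN; the diagonal is always 1.
    """

    values: np.ndarray
    atlas: RegionAtlas
    kind: str = KIND_WINDOW

    def __post_init__(self) -> None:
        v = self.values
        n = self.atlas.n_regions
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match atlas size {n}")
        if self.kind not in (KIND_WINDOW, KIND_EPOCH_MEAN):
            raise ValueError(f"unknown kind {self.kind!r}")
        finite = np.isfinite(v)
        if not np.array_equal(finite, finite.T):
            raise ValueError("mask must be symmetric")
        if not np.allclose(v[finite & finite.T], v.T[finite & finite.T], atol=1e-10):
            raise ValueError("matrix must be symmetric")
        if np.any(np.abs(v[finite]) > 1 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("diagonal must be 1")

    @property
    def is_masked(self) -> bool:
        return bool(np.isnan(self.values).any())


def select_epochs(
    n_samples: int,
    fs: float,
    n_epochs: int = 3,
    epoch_seconds: float = 60.0,
    min_gap_seconds: float = 300.0,
    seed: int = 0,
) -> list[Interval]:
    """Randomly place up to ``n_epochs`` non-overlapping analysis epochs.

    Consecutive epochs are separated by at least ``min_gap_seconds``.  If the
    recording cannot hold ``n_epochs`` epochs with the required gaps, as many
    as fit are returned (at least one; a recording shorter than one epoch is
    an error).  Placement is uniform over all valid ordered placements: the
    total slack is split by sorted uniform draws, so flush placements are
    admissible.  Deterministic given ``seed``.
    """
    epoch_len = int(round(epoch_seconds * fs))
    gap_len = int(round(min_gap_seconds * fs))
    if epoch_len < 1:
        raise ValueError("epoch length must be at least 1 sample")
    if n_samples < epoch_len:
        raise ValueError(
            f"recording of {n_samples} samples shorter than one epoch "
            f"({epoch_len} samples)"
        )
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    # largest k with k*epoch_len + (k-1)*gap_len <= n_samples
    k_max = (n_samples + gap_len) // (epoch_len + gap_len)
    k = int(min(n_epochs, k_max))
    slack = n_samples - k * epoch_len - (k - 1) * gap_len
    rng = np.random.default_rng(seed)
    offsets = np.sort(rng.integers(0, slack + 1, size=k))
    starts = [int(offsets[i] + i * (epoch_len + gap_len)) for i in range(k)]
    return [(s, s + epoch_len) for s in starts]


def make_windows(n_samples: int, spec: WindowSpec) -> list[Interval]:
    """Full sliding windows covering ``n_samples``; partial tails dropped."""
    win, step = spec.window_samples, spec.step_samples
    if n_samples < win:
        raise ValueError(
            f"{n_samples} samples shorter than one window ({win} samples)"
        )
    n_win = (n_samples - win) // step + 1
    return [(i * step, i * step + win) for i in range(n_win)]


def window_correlation(
    epoch: EpochTimeSeries, window: Interval
) -> ConnectivityMatrix:
    """Pearson correlation matrix over one window of the epoch."""
    start, end = window
    if not (0 <= start < end <= epoch.n_samples):
        raise ValueError(f"window {window} outside epoch of {epoch.n_samples} samples")
    seg = epoch.data[:, start:end]
    sd = seg.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        ids = epoch.atlas.region_ids[flat].tolist()
        raise ValueError(
            f"zero-variance signal in window {window} for region id(s) {ids}"
        )
    r = np.corrcoef(seg)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, atlas=epoch.atlas, kind=KIND_WINDOW)


def average_epoch_fc(windows: Sequence[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of window matrices (raw r, no transform)."""
    if not windows:
        raise ValueError("need at least one window matrix")
    atlas = windows[0].atlas
    for w in windows[1:]:
        if w.atlas is not atlas and w.atlas != atlas:
            raise ValueError("window matrices come from different atlases")
    mean = np.mean([w.values for w in windows], axis=0)
    return ConnectivityMatrix(values=mean, atlas=atlas, kind=KIND_EPOCH_MEAN)


def epoch_connectivity(
    epoch: EpochTimeSeries, spec: WindowSpec
) -> ConnectivityMatrix:
    """Convenience: windows -> per-window correlation -> epoch average."""
    wins = make_windows(epoch.n_samples, spec)
    return average_epoch_fc([window_correlation(epoch, w) for w in wins])


def drop_interhemispheric(
    fc: ConnectivityMatrix, atlas: RegionAtlas | None = None
) -> ConnectivityMatrix:
    """Mask entries between regions of different hemispheres with NaN.

    NaN (not zero) so that downstream means cannot silently include masked
    cells.  Idempotent.
    """
    atlas = atlas if atlas is not None else fc.atlas
    if atlas != fc.atlas:
        raise ValueError("atlas does not match the connectivity matrix")
    hemi = atlas.hemispheres
    same = hemi[:, None] == hemi[None, :]
    masked = np.where(same, fc.values, np.nan)
    return ConnectivityMatrix(values=masked, atlas=fc.atlas, kind=fc.kind)
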