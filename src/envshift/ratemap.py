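"""Occupancy-normalised 2D firing ratemaps.

Position is discretised into 3 cm square bins; the raw rate of a bin is the
number of spikes assigned to it (each spike takes the bin of its temporally
nearest tracking sample) divided by the time the animal spent there.  Bins
the animal never visited are masked out of every computation.  Maps are
smoothed with a Gaussian kernel under masked renormalisation — unvisited
bins contribute neither rate nor kernel weight — and a cell's three
session maps are jointly normalised for display by the 95th percentile of
their pooled visited-bin rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import Arena, PositionTrace, SpikeTrain, nearest_sample_index

BIN_SIZE_CM = 3.0
KERNEL_SPAN_CM = 7.0  # half-width of the truncated Gaussian support


@dataclass
class Ratemap:
    """A firing ratemap and the occupancy that normalises it.

    ``rate`` is NaN on unvisited bins; shape is (nx, ny) with x the first
    axis, edges in cm in the arena frame.
    """

    rate: np.ndarray
    occupancy: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    visited_mask: np.ndarray
    smoothing: Optional[str] = None

    @property
    def n_spikes(self) -> float:
        """Spikes accounted for by the map (rate x occupancy over visited bins)."""
        return float(np.nansum(np.where(self.visited_mask, self.rate * self.occupancy, 0.0)))


def _grid_edges(arena: Arena, bin_size: float) -> tuple[np.ndarray, np.ndarray]:
    w, h = arena.size
    nx = int(np.ceil(w / bin_size))
    ny = int(np.ceil(h / bin_size))
    return np.arange(nx + 1) * bin_size, np.arange(ny + 1) * bin_size


def compute_occupancy(
    trace: PositionTrace, arena: Arena, bin_size: float = BIN_SIZE_CM
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time spent (s) in each spatial bin; returns (occupancy, x_edges, y_edges).

    Each tracking sample contributes one frame interval to its bin, so the
    grid total equals n_samples / frame_rate.  Samples outside the arena
    bounding box are dropped with a warning.
    """
    if len(trace) == 0:
        raise ValueError("empty position trace")
    x_edges, y_edges = _grid_edges(arena, bin_size)
    inside = (
        (trace.x >= x_edges[0])
        & (trace.x <= x_edges[-1])
        & (trace.y >= y_edges[0])
        & (trace.y <= y_edges[-1])
    )
    if not inside.all():
        warnings.warn(f"dropping {np.sum(~inside)} out-of-bounds tracking samples", stacklevel=2)
    counts, _, _ = np.histogram2d(trace.x[inside], trace.y[inside], bins=(x_edges, y_edges))
    return counts / trace.frame_rate, x_edges, y_edges


def compute_ratemap(
    spikes: SpikeTrain,
    trace: PositionTrace,
    arena: Arena,
    bin_size: float = BIN_SIZE_CM,
) -> Ratemap:
    """Raw (unsmoothed) ratemap: per-bin spike count / per-bin occupancy.

    A spike is assigned the spatial bin of its temporally nearest tracking
    sample; spikes outside the trace's time span are dropped with a warning.
    """
    occupancy, x_edges, y_edges = compute_occupancy(trace, arena, bin_size)
    t0, t1 = trace.t[0], trace.t[-1]
    in_span = (spikes.times >= t0) & (spikes.times <= t1 + 1.0 / trace.frame_rate)
    if not in_span.all():
        warnings.warn(
            f"dropping {np.sum(~in_span)} spikes outside the trace time span", stacklevel=2
        )
    times = spikes.times[in_span]
    counts = np.zeros_like(occupancy)
    if len(times):
        idx = nearest_sample_index(trace.t, times)
        ix = np.clip(((trace.x[idx] - x_edges[0]) / bin_size).astype(int), 0, occupancy.shape[0] - 1)
        iy = np.clip(((trace.y[idx] - y_edges[0]) / bin_size).astype(int), 0, occupancy.shape[1] - 1)
        np.add.at(counts, (ix, iy), 1.0)
    visited = occupancy > 0
    rate = np.full_like(occupancy, np.nan)
    rate[visited] = counts[visited] / occupancy[visited]
    return Ratemap(
        rate=rate,
        occupancy=occupancy,
        x_edges=x_edges,
        y_edges=y_edges,
        bin_size=bin_size,
        visited_mask=visited,
        smoothing=None,
    )


def smooth_ratemap(
    raw: Ratemap, kernel_cm: float = KERNEL_SPAN_CM, sigma_cm: Optional[float] = None
) -> Ratemap:
    """Gaussian smoothing with masked renormalisation.

    The kernel has sigma = ``kernel_cm``/3 (override via ``sigma_cm``) and is
    truncated so its support spans +-``kernel_cm``.  Unvisited bins are
    excluded from both the numerator and the kernel-weight normalisation, so
    a constant field stays exactly constant and the visited mask is unchanged.
    """
    if raw.smoothing is not None:
        raise ValueError("ratemap is already smoothed")
    sigma = sigma_cm if sigma_cm is not None else kernel_cm / 3.0
    sigma_bins = sigma / raw.bin_size
    truncate = kernel_cm / sigma
    mask = raw.visited_mask.astype(float)
    num = gaussian_filter(
        np.where(raw.visited_mask, raw.rate, 0.0), sigma_bins, mode="constant", truncate=truncate
    )
    den = gaussian_filter(mask, sigma_bins, mode="constant", truncate=truncate)
    rate = np.full_like(raw.rate, np.nan)
    ok = raw.visited_mask & (den > 0)
    rate[ok] = num[ok] / den[ok]
    desc = f"gaussian sigma={sigma:g}cm support=+-{kernel_cm:g}cm masked"
    return replace(raw, rate=rate, smoothing=desc)


def normalize_for_display(maps: list[Ratemap]) -> list[np.ndarray]:
    """Jointly normalise a cell's three session maps for display.

    All maps are divided by the 95th percentile of the pooled visited-bin
    rates across the three (smoothed) maps; values above that percentile
    exceed 1.  All-zero triplets return zero maps.
    """
    pooled = np.concatenate([m.rate[m.visited_mask] for m in maps])
    pooled = pooled[np.isfinite(pooled)]
    p95 = float(np.percentile(pooled, 95)) if len(pooled) else 0.0
    out = []
    for m in maps:
        grid = np.where(m.visited_mask, m.rate, np.nan)
        out.append(grid / p95 if p95 > 0 else np.where(m.visited_mask, 0.0, np.nan))
    return out
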