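"""Running-speed tuning: curves, the uniform-vs-linear F-test, shapes.

Speed is the finite difference of the tracked position at the video frame
rate (optionally boxcar-smoothed).  A tuning curve bins the session's frames
by speed and divides the spikes landing in each bin's frames by the time
spent there.  Two binnings are used:

* ``analysis``  — 25 bins of 2 cm/s from 5 to 55 cm/s; used for statistics.
* ``display``   — bins of 2.5 cm/s from 0 to 60 cm/s; used for curves shown
  to humans (shape categories, split-half stability).

Speed sensitivity is an F-test comparing the residuals of a uniform
(1-parameter) and a linear (2-parameter) least-squares fit to the analysis
curve; a cell is speed sensitive if p < 0.05 in at least one of its three
sessions.  Shape categories (increasing / preferred / decreasing) are a
qualitative summary of where the merged-session curve peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .core import PositionTrace, SessionTriplet, SpikeTrain, nearest_sample_index

ALPHA = 0.05
SPEED_SMOOTH_FRAMES = 5

ANALYSIS_EDGES = np.arange(5.0, 55.0 + 2.0, 2.0)  # 25 bins of 2 cm/s
DISPLAY_EDGES = np.arange(0.0, 60.0 + 2.5, 2.5)  # 24 bins of 2.5 cm/s


@dataclass
class SpeedSeries:
    """Instantaneous speed aligned to the tracking samples, cm/s."""

    t: np.ndarray
    v: np.ndarray
    smoothing_frames: int = 0  # provenance: boxcar width, 0 = unsmoothed

    def __len__(self) -> int:
        return len(self.t)


def compute_speed(trace: PositionTrace, smooth_frames: int = SPEED_SMOOTH_FRAMES) -> SpeedSeries:
    """Finite-difference speed per frame; v[0] duplicates v[1].

    ``smooth_frames`` > 1 applies a boxcar of that width (set 0 or 1 to
    disable); the width is recorded on the returned series.
    """
    if len(trace) < 2:
        raise ValueError("need at least two samples to compute speed")
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    v = np.hypot(dx, dy) * trace.frame_rate
    v = np.concatenate(([v[0]], v))
    if smooth_frames and smooth_frames > 1:
        v = uniform_filter1d(v, size=int(smooth_frames), mode="nearest")
    return SpeedSeries(t=trace.t.copy(), v=v, smoothing_frames=int(smooth_frames or 0))


@dataclass
class SpeedTuningCurve:
    """Firing rate vs binned running speed; NaN where a bin was never visited."""

    bin_edges: np.ndarray
    rate: np.ndarray  # spikes/s per bin
    occupancy: np.ndarray  # seconds per bin
    flavor: str  # 'analysis' or 'display'

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def defined(self) -> np.ndarray:
        return self.occupancy > 0


def _bin_frames(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Speed-bin index per frame; −1 outside range.  Bins are half-open with
    the top edge closed."""
    idx = np.digitize(v, edges) - 1
    idx[v == edges[-1]] = len(edges) - 2
    idx[(v < edges[0]) | (v > edges[-1])] = -1
    return idx


def _edges(flavor: str) -> np.ndarray:
    if flavor == "analysis":
        return ANALYSIS_EDGES
    if flavor == "display":
        return DISPLAY_EDGES
    raise ValueError(f"unknown flavor {flavor!r}")


def _accumulate(
    spikes: SpikeTrain,
    trace: PositionTrace,
    speed: SpeedSeries,
    edges: np.ndarray,
    frame_mask: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-speed-bin (spike count, occupancy seconds) over masked frames."""
    nb = len(edges) - 1
    idx = _bin_frames(speed.v, edges)
    if frame_mask is not None:
        idx = np.where(frame_mask, idx, -1)
    occ = np.bincount(idx[idx >= 0], minlength=nb)[:nb] / trace.frame_rate
    counts = np.zeros(nb)
    if len(spikes.times):
        sframe = nearest_sample_index(trace.t, spikes.times)
        sbin = idx[sframe]
        ok = sbin >= 0
        counts = np.bincount(sbin[ok], minlength=nb)[:nb].astype(float)
    return counts, occ


def speed_tuning_curve(
    spikes: SpikeTrain,
    trace: PositionTrace,
    speed: Optional[SpeedSeries] = None,
    flavor: str = "analysis",
) -> SpeedTuningCurve:
    """Tuning curve for one session: per-bin spikes / per-bin dwell time.

    Spikes take the speed bin of their temporally nearest frame.  Bins with
    zero occupancy are NaN and excluded from fits; a session whose frames
    never enter the speed range is an error.
    """
    if speed is None:
        speed = compute_speed(trace)
    edges = _edges(flavor)
    counts, occ = _accumulate(spikes, trace, speed, edges)
    if not np.any(occ > 0):
        raise ValueError("no frames fall inside the speed range")
    rate = np.full(len(occ), np.nan)
    rate[occ > 0] = counts[occ > 0] / occ[occ > 0]
    return SpeedTuningCurve(bin_edges=edges, rate=rate, occupancy=occ, flavor=flavor)


@dataclass
class FTestResult:
    F: float
    p: float
    n_bins: int
    perfect_fit: bool = False

    def __iter__(self):  # allows `F, p = linear_vs_uniform_ftest(...)`
        return iter((self.F, self.p))


def linear_vs_uniform_ftest(curve: SpeedTuningCurve) -> FTestResult:
    """F-test of a linear vs a uniform fit to the tuning curve.

    Both fits are unweighted least squares on the defined bins; the uniform
    fit is the mean rate, the linear fit a + b·v.  F = (RSS0 − RSS1) /
    (RSS1/(n − 2)) on (1, n−2) df.  An exactly linear, non-constant curve
    yields p = 0 with a perfect-fit flag; an exactly constant curve yields
    F = 0, p = 1.
    """
    ok = curve.defined & np.isfinite(curve.rate)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >= 3 defined bins, got {n}")
    x = curve.centers[ok]
    y = curve.rate[ok]
    rss0 = float(np.sum((y - y.mean()) ** 2))
    b, a = np.polyfit(x, y, 1)
    rss1 = float(np.sum((y - (a + b * x)) ** 2))
    scale = max(rss0, 1.0)
    if rss0 <= 1e-12 * scale:  # constant curve: the two fits coincide
        return FTestResult(F=0.0, p=1.0, n_bins=n)
    if rss1 <= 1e-12 * scale:  # exactly linear: infinite evidence for slope
        return FTestResult(F=np.inf, p=0.0, n_bins=n, perfect_fit=True)
    F = (rss0 - rss1) / (rss1 / (n - 2))
    return FTestResult(F=float(F), p=float(stats.f.sf(F, 1, n - 2)), n_bins=n)


@dataclass
class SpeedClassification:
    """Speed sensitivity of one cell across its triplet."""

    cell_id: str
    per_session: dict[str, FTestResult]
    speed_sensitive: bool
    category: str  # increasing / preferred / decreasing / unclassified
    merged_curve: SpeedTuningCurve


def categorize_tuning_shape(curve: SpeedTuningCurve, margin: float = 0.10) -> str:
    """Qualitative shape of a (display-flavor) tuning curve.

    The speed range is split into terciles and each tercile's mean rate over
    its defined bins is compared (averaging suppresses single-bin noise, so
    noisy flat curves stay unclassified):

    * lowest-tercile mean highest and > (1+margin) x highest-tercile mean →
      'decreasing' (rate highest at low speed);
    * highest-tercile mean highest and > (1+margin) x lowest-tercile mean →
      'increasing';
    * middle-tercile mean > (1+margin) x both end terciles → 'preferred';
    * otherwise 'unclassified'.
    """
    ok = curve.defined & np.isfinite(curve.rate)
    if not np.any(ok):
        return "unclassified"
    lo, hi = curve.bin_edges[0], curve.bin_edges[-1]
    pos = (curve.centers - lo) / (hi - lo)
    means = []
    for t in range(3):
        sel = ok & (pos >= t / 3.0) & (pos < (t + 1) / 3.0 + (1e-9 if t == 2 else 0))
        means.append(float(np.mean(curve.rate[sel])) if np.any(sel) else -np.inf)
    low, mid, high = means
    top = int(np.argmax(means))
    if top == 0 and low > (1.0 + margin) * high:
        return "decreasing"
    if top == 2 and high > (1.0 + margin) * low:
        return "increasing"
    if top == 1 and mid > (1.0 + margin) * low and mid > (1.0 + margin) * high:
        return "preferred"
    return "unclassified"


def merged_display_curve(
    triplet: SessionTriplet, cell_id: str, smooth_frames: int = SPEED_SMOOTH_FRAMES
) -> SpeedTuningCurve:
    """Display-flavor curve pooling frames and spikes of all three sessions."""
    edges = DISPLAY_EDGES
    counts = np.zeros(len(edges) - 1)
    occ = np.zeros(len(edges) - 1)
    for sess in triplet.sessions:
        speed = compute_speed(sess.trace, smooth_frames)
        c, o = _accumulate(sess.spikes[cell_id], sess.trace, speed, edges)
        counts += c
        occ += o
    rate = np.full(len(occ), np.nan)
    rate[occ > 0] = counts[occ > 0] / occ[occ > 0]
    return SpeedTuningCurve(bin_edges=edges, rate=rate, occupancy=occ, flavor="display")


def classify_speed_cell(
    triplet: SessionTriplet,
    cell_id: str,
    alpha: float = ALPHA,
    smooth_frames: int = SPEED_SMOOTH_FRAMES,
    margin: float = 0.10,
) -> SpeedClassification:
    """Speed sensitivity (any-session rule) and merged-curve shape category.

    A cell is speed sensitive if the uniform-vs-linear F-test gives p < alpha
    in the pre, manipulation, OR post session.
    """
    per_session: dict[str, FTestResult] = {}
    for name, sess in zip(("pre", "manip", "post"), triplet.sessions):
        speed = compute_speed(sess.trace, smooth_frames)
        curve = speed_tuning_curve(sess.spikes[cell_id], sess.trace, speed, flavor="analysis")
        per_session[name] = linear_vs_uniform_ftest(curve)
    sensitive = any(r.p < alpha for r in per_session.values())
    merged = merged_display_curve(triplet, cell_id, smooth_frames)
    category = categorize_tuning_shape(merged, margin=margin)
    return SpeedClassification(
        cell_id=cell_id,
        per_session=per_session,
        speed_sensitive=sensitive,
        category=category,
        merged_curve=merged,
    )


def split_half_curves(
    triplet: SessionTriplet, cell_id: str, smooth_frames: int = SPEED_SMOOTH_FRAMES
) -> tuple[SpeedTuningCurve, SpeedTuningCurve, SpeedTuningCurve]:
    """First-half, second-half and merged display curves.

    The three sessions are concatenated on a common timeline and split at the
    temporal midpoint; each half pools its frames and spikes across session
    boundaries.
    """
    edges = DISPLAY_EDGES
    total = sum(s.duration for s in triplet.sessions)
    mid = total / 2.0
    acc = {
        "first": [np.zeros(len(edges) - 1), np.zeros(len(edges) - 1)],
        "second": [np.zeros(len(edges) - 1), np.zeros(len(edges) - 1)],
    }
    offset = 0.0
    for sess in triplet.sessions:
        speed = compute_speed(sess.trace, smooth_frames)
        global_t = sess.trace.t + offset
        first_mask = global_t < mid
        for half, mask in (("first", first_mask), ("second", ~first_mask)):
            # restrict spikes to frames of this half via the frame mask
            c, o = _accumulate(sess.spikes[cell_id], sess.trace, speed, edges, frame_mask=mask)
            acc[half][0] += c
            acc[half][1] += o
        offset += sess.duration

    def build(counts: np.ndarray, occ: np.ndarray) -> SpeedTuningCurve:
        rate = np.full(len(occ), np.nan)
        rate[occ > 0] = counts[occ > 0] / occ[occ > 0]
        return SpeedTuningCurve(bin_edges=edges, rate=rate, occupancy=occ, flavor="display")

    first = build(*acc["first"])
    second = build(*acc["second"])
    merged = build(acc["first"][0] + acc["second"][0], acc["first"][1] + acc["second"][1])
    return first, second, merged
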