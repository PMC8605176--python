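"""Synthetic foraging trajectories and spike trains with known ground truth.

No recorded dataset ships with this package, so every downstream stage is
exercised against a generative model whose parameters are known exactly:

* **Trajectory** — a smoothed random forage at 30 Hz.  Running speed is an
  Ornstein-Uhlenbeck process mapped through a Gaussian copula onto a broad
  Beta marginal on 0-60 cm/s (mean ~29 cm/s), and heading diffuses slowly,
  which gives persistent, space-filling paths with adequate spatial coverage
  of a 1.25 m arena within 765 s and dwell time in every analysis speed bin.
  Walls reflect the path back into the arena.

* **Spikes** — an inhomogeneous Poisson process simulated by thinning.  The
  rate of a cell is multiplicative:

      lambda(t) = base_rate[session] * g(speed(t)) * s(x(t), y(t)) * d(t)

  with a per-session baseline (spikes/s), a speed gain g normalised to mean
  1 over the session, an optional spatial Gaussian bump s, and an optional
  slow drift ramp d spanning the whole triplet.  The rate is piecewise
  constant per 33.3 ms video frame — far below every analysis bin width.

A "shift" cell changes only its manipulation-session baseline: an increase
cell adds +4.0 spikes/s to its baseline in the middle session, a decrease
cell sits 5.7 spikes/s *below* its flanking sessions (the flankers are
raised so rates stay positive).  Those magnitudes, and the default
11.5% / 7.5% shifted fractions of 200 cells, are the calibration reported
for the object-insertion dataset this generator emulates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import signal, special, stats

from .core import (
    Arena,
    PositionTrace,
    Session,
    SessionTriplet,
    SpikeTrain,
    validate_triplet,
)

SESSION_LABELS = ("pre", "manip", "post")

# trajectory defaults: copula-OU speed process and heading diffusion
SPEED_TAU = 1.5  # s, relaxation time of the speed process
SPEED_MAX = 60.0  # cm/s, upper edge of the stationary speed distribution
SPEED_BETA_A = 1.1  # stationary marginal: SPEED_MAX * Beta(a, b)
SPEED_BETA_B = 1.2
HEADING_DIFFUSION = 1.6  # rad / sqrt(s)

#: per-cell drift-slope sd used when slow representational drift is injected
#: (strong enough that drift, not the shifted subpopulation, dominates the
#: cross-session population-vector correlation gradient)
DRIFT_SD_INJECTED = 1.5


# ---------------------------------------------------------------------------
# ground-truth types
# ---------------------------------------------------------------------------


@dataclass
class SpeedGain:
    """Speed-dependence of a cell's rate; normalised to mean 1 per session.

    shape 'flat' is constant; 'increasing'/'decreasing' interpolate linearly
    between 1-strength at one end of 0-60 cm/s and 1+strength at the other;
    'preferred' is a Gaussian bump at ``center`` cm/s with width ``width``.
    """

    shape: str = "flat"
    center: float = 30.0
    width: float = 8.0
    strength: float = 1.0

    def raw(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.shape == "flat":
            return np.ones_like(v)
        if self.shape == "increasing":
            return np.maximum(0.0, 1.0 + self.strength * (v - 30.0) / 30.0)
        if self.shape == "decreasing":
            return np.maximum(0.0, 1.0 - self.strength * (v - 30.0) / 30.0)
        if self.shape == "preferred":
            return 1.0 + self.strength * 3.0 * np.exp(-0.5 * ((v - self.center) / self.width) ** 2)
        raise ValueError(f"unknown speed gain shape {self.shape!r}")


@dataclass
class CellTruth:
    """Generative parameters of one simulated cell across a triplet."""

    base_rate: dict[str, float]
    speed_gain: SpeedGain = field(default_factory=SpeedGain)
    spatial_field: Optional[tuple[float, float, float, float]] = None  # (cx, cy, sigma, peak)
    drift_slope: float = 0.0  # fractional rate change over the whole triplet

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.base_rate.values()):
            raise ValueError("base rates must be non-negative")

    @property
    def label(self) -> str:
        """Derived shift label: increase / decrease / none."""
        pre, manip, post = (self.base_rate[k] for k in SESSION_LABELS)
        if manip > pre and manip > post:
            return "increase"
        if manip < pre and manip < post:
            return "decrease"
        return "none"

    @property
    def speed_tuned(self) -> bool:
        return self.speed_gain.shape != "flat"


@dataclass
class SimConfig:
    """Study-condition defaults for a simulated manipulation triplet."""

    n_cells: int = 200
    fraction_increase: float = 0.115
    fraction_decrease: float = 0.075
    shift_increase: float = 4.0  # spikes/s added in the manipulation session
    shift_decrease: float = 5.7  # spikes/s removed in the manipulation session
    base_rate_mean: float = 3.0  # spikes/s, mean of the lognormal baseline
    base_rate_sigma: float = 0.5  # lognormal shape parameter
    speed_fractions: dict[str, float] = field(
        default_factory=lambda: {"increasing": 0.25, "decreasing": 0.25, "preferred": 0.10}
    )
    manipulation_type: str = "object"
    arena: Arena = field(default_factory=Arena)
    manip_arena: Optional[Arena] = None  # defaults to `arena`
    duration: float = 800.0  # s, raw session length before truncation
    drift_sd: float = 0.0  # sd of per-cell fractional drift over the triplet
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_increase + self.fraction_decrease <= 1:
            raise ValueError("shift fractions must lie in [0, 1] and sum to <= 1")
        if sum(self.speed_fractions.values()) > 1 + 1e-12:
            raise ValueError("speed-tuned fractions sum to > 1")


@dataclass
class GroundTruth:
    """Per-cell truth plus derived labels for parameter-recovery tests."""

    cells: dict[str, CellTruth]

    @property
    def labels(self) -> dict[str, str]:
        return {cid: ct.label for cid, ct in self.cells.items()}

    @property
    def speed_tuned(self) -> dict[str, bool]:
        return {cid: ct.speed_tuned for cid, ct in self.cells.items()}

    def count(self, label: str) -> int:
        return sum(1 for v in self.labels.values() if v == label)

    def to_json(self) -> dict:
        out = {}
        for cid, ct in self.cells.items():
            d = asdict(ct)
            d["label"] = ct.label
            d["speed_tuned"] = ct.speed_tuned
            out[cid] = d
        return out


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (triangle-wave folding)."""
    span = hi - lo
    v = np.mod(u - lo, 2.0 * span)
    return lo + span - np.abs(v - span)


def simulate_trajectory(
    arena: Arena,
    duration: float,
    seed: int,
    frame_rate: float = 30.0,
    speed_tau: float = SPEED_TAU,
    speed_max: float = SPEED_MAX,
    speed_beta: tuple[float, float] = (SPEED_BETA_A, SPEED_BETA_B),
    heading_diffusion: float = HEADING_DIFFUSION,
) -> PositionTrace:
    """Simulate a foraging path: smoothed speed, diffusing heading, walls reflect.

    Speed is an Ornstein-Uhlenbeck process passed through a Gaussian copula
    onto a ``speed_max * Beta(a, b)`` stationary marginal: temporally smooth
    (relaxation time ``speed_tau``), strictly inside 0-``speed_max`` cm/s,
    and with dwell time spread over the whole range rather than piled at one
    mode.  Deterministic given ``seed``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration * frame_rate))
    dt = 1.0 / frame_rate

    # AR(1) discretisation of a standard-normal OU, mapped through the copula
    phi = np.exp(-dt / speed_tau)
    innov = rng.normal(0.0, np.sqrt(1.0 - phi**2), size=n)
    innov[0] = rng.normal()  # stationary start
    z = signal.lfilter([1.0], [1.0, -phi], innov)
    a, b = speed_beta
    v = speed_max * stats.beta.ppf(special.ndtr(z), a, b)

    heading = np.cumsum(rng.normal(0.0, heading_diffusion * np.sqrt(dt), size=n))
    heading += rng.uniform(0.0, 2.0 * np.pi)
    steps = np.column_stack((np.cos(heading), np.sin(heading))) * (v * dt)[:, None]

    w, h = arena.size
    if arena.shape == "circle":
        x, y = _circle_walk(steps, w / 2.0)
    else:
        start = np.array([w / 2.0, h / 2.0])
        pos = start + np.cumsum(steps, axis=0)
        x = _fold(pos[:, 0], 0.0, w)
        y = _fold(pos[:, 1], 0.0, h)

    t = np.arange(n) / frame_rate
    return PositionTrace(t=t, x=x, y=y, frame_rate=frame_rate)


def _circle_walk(steps: np.ndarray, radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate steps inside a circle of given radius centred at (r, r),
    reflecting radially at the boundary."""
    n = len(steps)
    x = np.empty(n)
    y = np.empty(n)
    px, py = 0.0, 0.0  # centre-relative
    for k in range(n):
        px += steps[k, 0]
        py += steps[k, 1]
        r = np.hypot(px, py)
        if r > radius:
            scale = (2.0 * radius - r) / r  # radial mirror about the boundary
            if scale < 0.0:
                scale = 0.0
            px *= scale
            py *= scale
        x[k] = px + radius
        y[k] = py + radius
    return x, y


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def _frame_speed(trace: PositionTrace) -> np.ndarray:
    """Unsmoothed finite-difference speed per frame, cm/s."""
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    v = np.hypot(dx, dy) * trace.frame_rate
    if len(v) == 0:
        return np.zeros(len(trace))
    return np.concatenate(([v[0]], v))


def cell_rng(seed: int, cell_id: str, session_label: str) -> np.random.Generator:
    """One independent RNG stream per (seed, cell, session).

    Streams are keyed by a CRC of the cell id so adding or removing cells
    never perturbs the spikes of existing ones.
    """
    key = zlib.crc32(cell_id.encode())
    sess = SESSION_LABELS.index(session_label)
    return np.random.default_rng([seed & 0x7FFFFFFF, key, sess])


def rate_per_frame(truth: CellTruth, trace: PositionTrace, session_label: str) -> np.ndarray:
    """The cell's piecewise-constant rate lambda per video frame, spikes/s."""
    base = truth.base_rate[session_label]
    lam = np.full(len(trace), float(base))
    v = _frame_speed(trace)
    g = truth.speed_gain.raw(v)
    mean_g = g.mean()
    if mean_g > 0:
        lam *= g / mean_g  # normalise: mean speed gain over the session is 1
    if truth.spatial_field is not None:
        cx, cy, sigma, peak = truth.spatial_field
        bump = np.exp(-0.5 * (((trace.x - cx) ** 2 + (trace.y - cy) ** 2) / sigma**2))
        lam *= 1.0 + (peak - 1.0) * bump
    if truth.drift_slope != 0.0:
        sess = SESSION_LABELS.index(session_label)
        t_end = trace.t[-1] + 1.0 / trace.frame_rate if len(trace) else 1.0
        phase = (sess + trace.t / t_end) / 3.0  # position within the triplet
        lam *= np.maximum(0.0, 1.0 + truth.drift_slope * (phase - 0.5))
    return lam


def simulate_cell(
    truth: CellTruth,
    trace: PositionTrace,
    session_label: str,
    seed: int,
    cell_id: str = "cell",
) -> SpikeTrain:
    """Inhomogeneous-Poisson spikes for one cell by thinning.

    Candidates are generated at the envelope rate (the maximum of the
    per-frame rate) over the session and accepted with probability
    lambda(t)/envelope; the rate is piecewise constant per frame.
    Deterministic given (seed, cell_id, session_label).
    """
    rng = cell_rng(seed, cell_id, session_label)
    lam = rate_per_frame(truth, trace, session_label)
    t_end = (len(trace)) / trace.frame_rate
    lam_max = float(lam.max()) if len(lam) else 0.0
    if lam_max <= 0.0:
        return SpikeTrain(np.empty(0), cell_id)
    n_cand = rng.poisson(lam_max * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    frames = np.minimum((cand * trace.frame_rate).astype(int), len(lam) - 1)
    lam_at = lam[frames]
    if np.any(lam_at > lam_max + 1e-9):  # envelope must dominate the rate
        raise RuntimeError("thinning envelope below the instantaneous rate")
    accept = rng.uniform(0.0, 1.0, size=n_cand) < lam_at / lam_max
    return SpikeTrain(cand[accept], cell_id)


# ---------------------------------------------------------------------------
# triplet generation
# ---------------------------------------------------------------------------


def _draw_truths(config: SimConfig, rng: np.random.Generator) -> dict[str, CellTruth]:
    n = config.n_cells
    n_inc = int(round(n * config.fraction_increase))
    n_dec = int(round(n * config.fraction_decrease))
    labels = ["increase"] * n_inc + ["decrease"] * n_dec + ["none"] * (n - n_inc - n_dec)

    shapes: list[str] = []
    for shape, frac in config.speed_fractions.items():
        shapes += [shape] * int(round(n * frac))
    shapes += ["flat"] * (n - len(shapes))
    shapes = [str(s) for s in rng.permutation(shapes)]

    # lognormal baselines with the configured mean
    mu = np.log(config.base_rate_mean) - 0.5 * config.base_rate_sigma**2
    cells: dict[str, CellTruth] = {}
    for i in range(n):
        cid = f"cell{i:03d}"
        b = float(rng.lognormal(mu, config.base_rate_sigma))
        lab = labels[i]
        if lab == "increase":
            rates = {"pre": b, "manip": b + config.shift_increase, "post": b}
        elif lab == "decrease":
            # manipulation-session rate ~ baseline distribution; flankers raised
            rates = {"pre": b + config.shift_decrease, "manip": b, "post": b + config.shift_decrease}
        else:
            rates = {"pre": b, "manip": b, "post": b}
        shape = shapes[i]
        gain = SpeedGain(
            shape=shape,
            center=float(rng.uniform(15.0, 45.0)),
            width=float(rng.uniform(6.0, 12.0)),
            strength=1.0 if shape != "flat" else 0.0,
        )
        drift = float(rng.normal(0.0, config.drift_sd)) if config.drift_sd > 0 else 0.0
        cells[cid] = CellTruth(base_rate=rates, speed_gain=gain, drift_slope=drift)
    return cells


def generate_triplet(config: SimConfig) -> tuple[SessionTriplet, GroundTruth]:
    """Simulate a full A-B-A' triplet with the configured study conditions.

    All three sessions share the cell roster and, by default, identical
    trajectory statistics (only the arena of the middle session may differ).
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xC0FFEE])
    truths = _draw_truths(config, rng)
    manip_arena = config.manip_arena if config.manip_arena is not None else config.arena
    arenas = (config.arena, manip_arena, config.arena)
    conditions = ("pre", "manipulation", "post")

    sessions = []
    for i, (label, cond, arena) in enumerate(zip(SESSION_LABELS, conditions, arenas)):
        traj_seed = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x7A37, i]).generate_state(1)[0]
        trace = simulate_trajectory(arena, config.duration, int(traj_seed & 0x7FFFFFFF))
        spikes = {
            cid: simulate_cell(ct, trace, label, config.seed, cid) for cid, ct in truths.items()
        }
        sessions.append(
            Session(
                condition=cond,
                manipulation_type=config.manipulation_type,
                arena=arena,
                trace=trace,
                spikes=spikes,
                duration=config.duration,
            )
        )
    triplet = validate_triplet(*sessions)
    return triplet, GroundTruth(cells=truths)
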