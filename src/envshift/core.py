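"""Domain types and session I/O for A-B-A' open-field recording triplets.

A recording experiment is three consecutive foraging sessions in an open
arena — baseline (pre), manipulation (an object inserted, the arena rotated,
reshaped, expanded, or stripped of its walls), and a return to the baseline
configuration (post).  Animal position is tracked at a nominal 30 Hz and each
sorted unit contributes a list of spike timestamps per session.  All analyses
operate on the first 765 s of each session (the shortest recording in the
source dataset), so every session of a triplet is truncated to a common
window before any statistic is computed.

On disk a session is a directory with three plain-text files::

    tracking.csv   header t,x,y          (seconds, cm, cm)
    spikes.json    {cell_id: [seconds, ...], ...}
    meta.json      {condition, manipulation_type, arena{...}, duration_s}

A triplet manifest is a JSON list of three session paths in A, B, A' order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FRAME_RATE = 30.0
#: common analysis window, seconds: duration of the shortest recording
ANALYSIS_DURATION = 765.0
#: a tracking gap longer than this many nominal frame intervals is flagged
GAP_FACTOR = 5.0

CONDITIONS = ("pre", "manipulation", "post")
MANIPULATION_TYPES = ("object", "rotation", "circle", "expansion", "no_walls", "baseline")


class SessionFormatError(ValueError):
    """A session directory is missing a file or a file cannot be parsed."""


class ValidationError(ValueError):
    """Session content violates an invariant (e.g. spike beyond trace end)."""


class InclusionError(ValueError):
    """Session fails an inclusion rule (e.g. shorter than the analysis window)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PositionTrace:
    """Timestamped 2D position samples, seconds and cm, arena frame."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float = FRAME_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal length")
        if len(self.t) and self.t[0] < 0:
            raise ValidationError("trace starts before time zero")
        if not (np.isfinite(self.t).all() and np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValidationError("trace contains non-finite samples")
        if np.any(np.diff(self.t) < 0):
            raise ValidationError("trace timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.t)

    def gap_indices(self) -> np.ndarray:
        """Indices i where t[i+1]-t[i] exceeds GAP_FACTOR nominal frames."""
        if len(self.t) < 2:
            return np.empty(0, dtype=int)
        dt = np.diff(self.t)
        return np.nonzero(dt > GAP_FACTOR / self.frame_rate)[0]


@dataclass
class SpikeTrain:
    """Sorted spike timestamps (seconds) for one cell in one session."""

    times: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) and self.times.min() < 0:
            raise ValidationError(f"cell {self.cell_id}: negative spike time")
        if np.any(np.diff(self.times) < 0):
            raise ValidationError(f"cell {self.cell_id}: spike times not sorted")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class Arena:
    """Arena geometry.  extent is side (square/none), (w, h) (rectangle) or
    diameter (circle), in cm.  rotation_deg is relative to the room frame and
    is metadata only — positions are always expressed in the arena frame."""

    shape: str = "square"
    extent: float | tuple[float, float] = 125.0
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("square", "rectangle", "circle", "none"):
            raise ValidationError(f"unknown arena shape {self.shape!r}")
        ext = np.atleast_1d(np.asarray(self.extent, dtype=float))
        if np.any(ext <= 0):
            raise ValidationError("arena extent must be positive")

    @property
    def size(self) -> tuple[float, float]:
        """Bounding-box (width, height) in cm."""
        if self.shape == "rectangle":
            w, h = self.extent  # type: ignore[misc]
            return float(w), float(h)
        return float(self.extent), float(self.extent)  # type: ignore[arg-type]

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        w, h = self.size
        if self.shape == "circle":
            r = w / 2.0
            return (x - r) ** 2 + (y - r) ** 2 <= r**2 + 1e-9
        return (x >= -1e-9) & (x <= w + 1e-9) & (y >= -1e-9) & (y <= h + 1e-9)


@dataclass
class Session:
    """One foraging session: behavior plus the spike trains of all cells."""

    condition: str
    manipulation_type: str
    arena: Arena
    trace: PositionTrace
    spikes: dict[str, SpikeTrain]
    duration: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.manipulation_type not in MANIPULATION_TYPES:
            raise ValidationError(f"unknown manipulation_type {self.manipulation_type!r}")

    @property
    def cell_ids(self) -> list[str]:
        return sorted(self.spikes)


@dataclass
class SessionTriplet:
    """Aligned pre / manipulation / post sessions sharing a cell roster.

    ``roster`` holds the cells present in all three sessions — the population
    the change classifier operates on.  Cells recorded in only a subset of
    sessions remain loadable in the member sessions and are listed in
    ``excluded`` with the sessions they are missing from.
    """

    pre: Session
    manip: Session
    post: Session
    roster: list[str]
    excluded: dict[str, str] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def sessions(self) -> tuple[Session, Session, Session]:
        return (self.pre, self.manip, self.post)

    @property
    def manipulation_type(self) -> str:
        return self.manip.manipulation_type


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def nearest_sample_index(t: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Index of the temporally nearest sample in sorted ``t`` for each time."""
    t = np.asarray(t, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = np.searchsorted(t, times)
    idx = np.clip(idx, 1, len(t) - 1)
    left = times - t[idx - 1]
    right = t[idx] - times
    return np.where(left <= right, idx - 1, idx)


def _arena_to_json(a: Arena) -> dict:
    ext = a.extent
    if isinstance(ext, tuple):
        ext = list(ext)
    return {"shape": a.shape, "extent_cm": ext, "rotation_deg": a.rotation_deg}


def _arena_from_json(d: dict) -> Arena:
    ext = d["extent_cm"]
    if isinstance(ext, (list, tuple)):
        ext = tuple(float(v) for v in ext) if len(ext) > 1 else float(ext[0])
    return Arena(shape=d["shape"], extent=ext, rotation_deg=float(d.get("rotation_deg", 0.0)))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session directory (tracking.csv, spikes.json, meta.json)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": session.trace.t, "x": session.trace.x, "y": session.trace.y}).to_csv(
        path / "tracking.csv", index=False, float_format="%.12g"
    )
    with open(path / "spikes.json", "w") as fh:
        json.dump({cid: st.times.tolist() for cid, st in session.spikes.items()}, fh)
    meta = {
        "condition": session.condition,
        "manipulation_type": session.manipulation_type,
        "arena": _arena_to_json(session.arena),
        "duration_s": session.duration,
        "frame_rate_hz": session.trace.frame_rate,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return path


def load_session(path: str | Path) -> Session:
    """Load and validate a session directory.

    Unsorted spike lists are sorted with a warning (flagged); a spike time
    beyond the session end raises :class:`ValidationError`; tracking gaps
    longer than five nominal frame intervals are flagged in ``Session.flags``.
    """
    path = Path(path)
    flags: list[str] = []
    for fname in ("tracking.csv", "spikes.json", "meta.json"):
        if not (path / fname).exists():
            raise SessionFormatError(f"missing {fname} in {path}")
    try:
        track = pd.read_csv(path / "tracking.csv")
    except Exception as exc:  # pragma: no cover - malformed csv
        raise SessionFormatError(f"cannot parse tracking.csv in {path}: {exc}") from exc
    for col in ("t", "x", "y"):
        if col not in track.columns:
            raise SessionFormatError(f"tracking.csv lacks column {col!r}")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    with open(path / "spikes.json") as fh:
        raw_spikes = json.load(fh)

    frame_rate = float(meta.get("frame_rate_hz", FRAME_RATE))
    trace = PositionTrace(track["t"].to_numpy(), track["x"].to_numpy(), track["y"].to_numpy(), frame_rate)
    duration = float(meta["duration_s"])

    spikes: dict[str, SpikeTrain] = {}
    for cid, times in raw_spikes.items():
        arr = np.asarray(times, dtype=float)
        if np.any(np.diff(arr) < 0):
            warnings.warn(f"cell {cid}: spike times unsorted, sorting", stacklevel=2)
            flags.append(f"unsorted_spikes:{cid}")
            arr = np.sort(arr)
        if len(arr) > 1 and np.any(np.diff(arr) == 0):
            flags.append(f"duplicate_spikes:{cid}")
        if len(arr) and arr.max() > duration + 1e-9:
            raise ValidationError(
                f"cell {cid}: spike time {arr.max():g} s exceeds session duration {duration:g} s"
            )
        spikes[cid] = SpikeTrain(arr, cid)

    for i in trace.gap_indices():
        flags.append(f"tracking_gap:{trace.t[i]:.3f}s->{trace.t[i + 1]:.3f}s")

    return Session(
        condition=meta["condition"],
        manipulation_type=meta["manipulation_type"],
        arena=_arena_from_json(meta["arena"]),
        trace=trace,
        spikes=spikes,
        duration=duration,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# truncation and triplet validation
# ---------------------------------------------------------------------------


def truncate_session(session: Session, t_max: float = ANALYSIS_DURATION) -> Session:
    """Restrict a session to the half-open window [0, t_max).

    Trace samples with t < t_max and spikes with time < t_max are retained and
    the duration becomes t_max.  Idempotent.  A session shorter than ``t_max``
    fails the inclusion rule.
    """
    if session.duration < t_max:
        raise InclusionError(
            f"session duration {session.duration:g} s < analysis window {t_max:g} s"
        )
    keep = session.trace.t < t_max
    trace = PositionTrace(
        session.trace.t[keep], session.trace.x[keep], session.trace.y[keep], session.trace.frame_rate
    )
    spikes = {
        cid: SpikeTrain(st.times[st.times < t_max], cid) for cid, st in session.spikes.items()
    }
    return replace(session, trace=trace, spikes=spikes, duration=float(t_max))


def validate_triplet(pre: Session, manip: Session, post: Session) -> SessionTriplet:
    """Assemble a triplet, checking conditions and building the cell roster.

    The roster is the set of cells present in all three sessions (the change
    classifier requires a cell in every session).  Cells missing from one or
    more sessions are excluded with a recorded reason.  An empty roster is a
    warning, not an error.  Flanking sessions must carry the manipulation
    session's type or 'baseline'.
    """
    expected = ("pre", "manipulation", "post")
    for sess, cond in zip((pre, manip, post), expected):
        if sess.condition != cond:
            raise ValidationError(f"expected condition {cond!r}, got {sess.condition!r}")
    fam = manip.manipulation_type
    for sess in (pre, post):
        if sess.manipulation_type not in (fam, "baseline"):
            raise ValidationError(
                f"flanker manipulation_type {sess.manipulation_type!r} does not match {fam!r}"
            )
    sets = [set(s.spikes) for s in (pre, manip, post)]
    roster = sorted(sets[0] & sets[1] & sets[2])
    excluded: dict[str, str] = {}
    names = ("pre", "manip", "post")
    for cid in sorted(sets[0] | sets[1] | sets[2]):
        if cid not in roster:
            missing = [n for n, s in zip(names, sets) if cid not in s]
            excluded[cid] = "missing from " + ", ".join(missing)
    flags: list[str] = []
    if not roster:
        warnings.warn("triplet has an empty cell roster", stacklevel=2)
        flags.append("empty_roster")
    return SessionTriplet(pre=pre, manip=manip, post=post, roster=roster, excluded=excluded, flags=flags)


def truncate_triplet(triplet: SessionTriplet, t_max: float = ANALYSIS_DURATION) -> SessionTriplet:
    """Truncate all three sessions of a triplet to the common window."""
    return replace(
        triplet,
        pre=truncate_session(triplet.pre, t_max),
        manip=truncate_session(triplet.manip, t_max),
        post=truncate_session(triplet.post, t_max),
    )


def load_triplet(manifest: str | Path) -> SessionTriplet:
    """Load a triplet from a JSON manifest listing three session paths (A, B, A')."""
    manifest = Path(manifest)
    with open(manifest) as fh:
        paths = json.load(fh)
    if not (isinstance(paths, list) and len(paths) == 3):
        raise SessionFormatError("triplet manifest must be a JSON list of three session paths")
    base = manifest.parent
    sessions = [load_session(base / p if not Path(p).is_absolute() else p) for p in paths]
    return validate_triplet(*sessions)


def write_triplet(triplet: SessionTriplet, out_dir: str | Path) -> Path:
    """Write the three sessions plus a manifest under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = ("pre", "manip", "post")
    for name, sess in zip(names, triplet.sessions):
        write_session(sess, out_dir / name)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(list(names), fh)
    return out_dir / "manifest.json"
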