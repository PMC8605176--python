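"""Population-vector mean-firing-rate correlation analysis.

For a fixed roster of cells, the whole-session population vector (PV) is the
per-cell MFR over the 765 s window.  Each session is also split into 400 ms
bins — 1912 complete bins per 765 s, the trailing remainder discarded — and
the per-cell MFR inside each bin forms a momentary population vector.  The
whole-session PV of each session type (pre, manipulation, post) is Pearson-
correlated with every 400 ms bin of its own session type and of the other
two, yielding four pooled correlation distributions per triplet:

    same-type, pre x manip, pre x post, manip x post.

A gradient in which same-type correlations are highest and pre x post is the
lowest cross-type pair is the signature of slow representational drift over
the triplet on top of the manipulation-locked rate shifts.  The four
distributions are compared with a Kruskal-Wallis omnibus test and
Scheffé-type pairwise rank comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import ANALYSIS_DURATION, Session, SessionTriplet
from .mfr_change import kruskal_wallis, posthoc_pairwise

PV_BIN_S = 0.4

PAIR_LABELS = ("same_type", "pre_x_manip", "pre_x_post", "manip_x_post")


def whole_session_pv(
    session: Session, roster: Sequence[str], duration: float = ANALYSIS_DURATION
) -> np.ndarray:
    """Whole-session MFR population vector (spikes/s) in roster order."""
    missing = [c for c in roster if c not in session.spikes]
    if missing:
        raise KeyError(f"roster cells missing from session: {missing}")
    return np.array(
        [np.sum(session.spikes[c].times < duration) / duration for c in roster], dtype=float
    )


def binned_pv_matrix(
    session: Session,
    roster: Sequence[str],
    bin_s: float = PV_BIN_S,
    duration: float = ANALYSIS_DURATION,
) -> np.ndarray:
    """(cells x bins) matrix of MFRs in complete half-open time bins.

    The number of bins is floor(duration / bin_s) — 1912 for 765 s at 400 ms
    — and any trailing remainder of the session is discarded.
    """
    missing = [c for c in roster if c not in session.spikes]
    if missing:
        raise KeyError(f"roster cells missing from session: {missing}")
    n_bins = int(np.floor(duration / bin_s + 1e-9))
    t_max = n_bins * bin_s
    mat = np.zeros((len(roster), n_bins))
    for i, cid in enumerate(roster):
        times = session.spikes[cid].times
        times = times[times < t_max]
        idx = np.minimum((times / bin_s).astype(int), n_bins - 1)
        mat[i] = np.bincount(idx, minlength=n_bins) / bin_s
    return mat


def pv_correlations(pv: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson correlation of the whole-session PV with each bin column.

    Returns (correlations over defined bins, number of excluded bins).  A bin
    in which no roster cell fired — or a zero-variance PV — has an undefined
    correlation and is excluded rather than imputed.
    """
    pv = np.asarray(pv, dtype=float)
    if matrix.shape[0] != len(pv):
        raise ValueError("roster size mismatch between PV and matrix")
    p = pv - pv.mean()
    p_norm = np.linalg.norm(p)
    X = matrix - matrix.mean(axis=0, keepdims=True)
    col_norm = np.linalg.norm(X, axis=0)
    ok = (col_norm > 0) & (p_norm > 0)
    r = np.full(matrix.shape[1], np.nan)
    if p_norm > 0:
        r[ok] = (p @ X[:, ok]) / (p_norm * col_norm[ok])
    return r[ok], int(np.sum(~ok))


def triplet_correlation_sets(
    triplet: SessionTriplet,
    bin_s: float = PV_BIN_S,
    duration: float = ANALYSIS_DURATION,
) -> dict[str, np.ndarray]:
    """The four pooled correlation distributions for one (truncated) triplet.

    Every session type's whole-session PV is correlated with the binned
    vectors of every session; both directions of a cross-type pairing pool
    into the same label (pre PV x manip bins and manip PV x pre bins are both
    'pre_x_manip').
    """
    roster = triplet.roster
    names = ("pre", "manip", "post")
    pvs = {n: whole_session_pv(s, roster, duration) for n, s in zip(names, triplet.sessions)}
    mats = {n: binned_pv_matrix(s, roster, bin_s, duration) for n, s in zip(names, triplet.sessions)}
    out: dict[str, list[np.ndarray]] = {lab: [] for lab in PAIR_LABELS}
    for a in names:
        for b in names:
            r, _ = pv_correlations(pvs[a], mats[b])
            if a == b:
                lab = "same_type"
            else:
                pair = tuple(sorted((a, b), key=names.index))
                lab = {
                    ("pre", "manip"): "pre_x_manip",
                    ("pre", "post"): "pre_x_post",
                    ("manip", "post"): "manip_x_post",
                }[pair]
            out[lab].append(r)
    return {lab: np.concatenate(vals) for lab, vals in out.items()}


def pool_correlation_sets(sets: Sequence[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Concatenate per-triplet correlation sets across animals/sessions."""
    return {
        lab: np.concatenate([s[lab] for s in sets if len(s[lab])]) for lab in PAIR_LABELS
    }


@dataclass
class PVComparison:
    """Omnibus and pairwise comparison of the four correlation distributions."""

    H: float
    p_omnibus: float
    pairwise: dict[tuple[str, str], float]
    medians: dict[str, float]
    n: dict[str, int]


def compare_correlation_distributions(sets: dict[str, np.ndarray]) -> PVComparison:
    """Kruskal-Wallis across the labelled distributions plus Scheffé post hoc.

    Effect direction is summarised by the median correlation per group.
    """
    labels = [lab for lab in sets if len(sets[lab])]
    if len(labels) < 2:
        raise ValueError("need at least two nonempty distributions")
    groups = [np.asarray(sets[lab], dtype=float) for lab in labels]
    H, p = kruskal_wallis(groups)
    pw = posthoc_pairwise(groups, labels=labels)
    return PVComparison(
        H=H,
        p_omnibus=p,
        pairwise=pw,
        medians={lab: float(np.median(g)) for lab, g in zip(labels, groups)},
        n={lab: len(g) for lab, g in zip(labels, groups)},
    )
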