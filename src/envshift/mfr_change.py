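"""Classification of systematic mean-firing-rate changes across a triplet.

Each 765 s session is divided into ten equal blocks of 76.5 s and the mean
firing rate (MFR) of each block is computed.  The three sessions' block MFRs
are compared with a Kruskal-Wallis test, followed by Scheffé-type pairwise
comparisons on the pooled ranks (the convention of MATLAB's ``multcompare``
run on ``kruskalwallis`` output, which is how this family of analyses is
conventionally done).  A cell is labelled

* ``increase``  — manipulation vs pre AND manipulation vs post both
  significant, and the manipulation-session MFR is above the flanker mean;
* ``decrease``  — both pairs significant with the manipulation MFR below;
* ``none``      — otherwise.

Pre-vs-post significance never vetoes a label; it is reported as a quality
flag (a cell whose flankers differ has an unstable baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import ANALYSIS_DURATION, SessionTriplet, SpikeTrain

N_BLOCKS = 10
ALPHA = 0.05


@dataclass
class BlockMFR:
    """Per-block mean firing rates of one session."""

    rates: np.ndarray  # spikes/s, one per block
    block_duration: float  # s
    session_mfr: float  # spikes/s, whole-session

    def __len__(self) -> int:
        return len(self.rates)


def block_mfr(
    spikes: SpikeTrain, duration: float = ANALYSIS_DURATION, n_blocks: int = N_BLOCKS
) -> BlockMFR:
    """Mean firing rate per equal time block, half-open [b*T/n, (b+1)*T/n).

    With the 765 s analysis window and ten blocks, blocks last 76.5 s, and
    the mean of the block MFRs equals the whole-session MFR exactly.
    """
    block = duration / n_blocks
    edges = np.arange(n_blocks + 1) * block
    counts, _ = np.histogram(spikes.times[spikes.times < duration], bins=edges)
    rates = counts / block
    return BlockMFR(rates=rates, block_duration=block, session_mfr=len(spikes.times[spikes.times < duration]) / duration)


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate input — every value identical across all groups — returns
    H = 0, p = 1 rather than erroring.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def posthoc_pairwise(
    groups: Sequence[np.ndarray], labels: Optional[Sequence[str]] = None
) -> dict[tuple[str, str], float]:
    """Scheffé-type pairwise comparisons on pooled ranks.

    Mean ranks are compared with the tie-corrected rank variance
    S² = N(N+1)/12 · (1 − Στ(τ³−τ)/(N³−N)); the standardised difference
    d = |R̄_i − R̄_j| / sqrt(S²(1/n_i + 1/n_j)) is referred to the Scheffé
    criterion p = P(χ²_{k−1} ≥ d²), which controls the family-wise error for
    all contrasts simultaneously.  Identical groups give p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if labels is None:
        labels = [str(i) for i in range(k)]
    ns = np.array([len(g) for g in groups])
    N = int(ns.sum())
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    s2 = N * (N + 1) / 12.0 * tie
    out: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if s2 <= 0:
                out[(labels[i], labels[j])] = 1.0
                continue
            se = np.sqrt(s2 * (1.0 / ns[i] + 1.0 / ns[j]))
            d = abs(mean_ranks[i] - mean_ranks[j]) / se
            out[(labels[i], labels[j])] = float(stats.chi2.sf(d**2, k - 1))
    return out


@dataclass
class ChangeClassification:
    """Outcome of the MFR-change test for one cell."""

    cell_id: str
    label: str  # increase / decrease / none
    H: float
    p_omnibus: float
    p_manip_pre: float
    p_manip_post: float
    p_pre_post: float
    delta: float  # manip MFR − mean(pre, post), spikes/s
    session_mfr: dict[str, float]
    block_rates: dict[str, np.ndarray]
    flags: list[str] = field(default_factory=list)


def classify_mfr_change(
    triplet: SessionTriplet,
    cell_id: str,
    alpha: float = ALPHA,
    duration: float = ANALYSIS_DURATION,
    n_blocks: int = N_BLOCKS,
) -> ChangeClassification:
    """Label one cell's manipulation-session MFR shift.

    Sessions must already be truncated to the common window.  ``delta`` is
    the manipulation-session MFR minus the mean of the two flanking-session
    MFRs.  A cell silent in all three sessions is labelled ``none`` and
    flagged.
    """
    if cell_id not in triplet.roster:
        raise KeyError(f"cell {cell_id!r} not in triplet roster")
    blocks = {
        name: block_mfr(sess.spikes[cell_id], duration, n_blocks)
        for name, sess in zip(("pre", "manip", "post"), triplet.sessions)
    }
    flags: list[str] = []
    groups = [blocks[n].rates for n in ("pre", "manip", "post")]
    H, p_omni = kruskal_wallis(groups)
    pw = posthoc_pairwise(groups, labels=["pre", "manip", "post"])
    p_mp = pw[("pre", "manip")]
    p_mq = pw[("manip", "post")]
    p_pp = pw[("pre", "post")]
    mfr = {n: blocks[n].session_mfr for n in ("pre", "manip", "post")}
    delta = mfr["manip"] - 0.5 * (mfr["pre"] + mfr["post"])

    if all(len(triplet.sessions[i].spikes[cell_id]) == 0 for i in range(3)):
        flags.append("silent_cell")
        label = "none"
    elif p_mp < alpha and p_mq < alpha and delta > 0:
        label = "increase"
    elif p_mp < alpha and p_mq < alpha and delta < 0:
        label = "decrease"
    else:
        label = "none"
    if p_pp < alpha:
        flags.append("flankers_differ")  # quality flag, never vetoes the label
    return ChangeClassification(
        cell_id=cell_id,
        label=label,
        H=H,
        p_omnibus=p_omni,
        p_manip_pre=p_mp,
        p_manip_post=p_mq,
        p_pre_post=p_pp,
        delta=delta,
        session_mfr=mfr,
        block_rates={n: blocks[n].rates for n in ("pre", "manip", "post")},
        flags=flags,
    )


def classify_triplet(
    triplet: SessionTriplet, alpha: float = ALPHA, duration: float = ANALYSIS_DURATION
) -> list[ChangeClassification]:
    """Classify every roster cell of a (truncated) triplet."""
    return [classify_mfr_change(triplet, cid, alpha=alpha, duration=duration) for cid in triplet.roster]


@dataclass
class PopulationSummary:
    """Counts and one-decimal percentages of the change classification."""

    manipulation_type: str
    n_total: int
    n_increase: int
    n_decrease: int
    mean_increase: Optional[float] = None  # mean delta among increase cells, spikes/s
    mean_decrease: Optional[float] = None  # mean |delta| among decrease cells, spikes/s

    @property
    def n_significant(self) -> int:
        return self.n_increase + self.n_decrease

    @property
    def n_none(self) -> int:
        return self.n_total - self.n_significant

    @staticmethod
    def _pct(num: int, den: int) -> Optional[float]:
        return round(100.0 * num / den, 1) if den else None

    @property
    def pct_significant(self) -> Optional[float]:
        return self._pct(self.n_significant, self.n_total)

    @property
    def pct_increase(self) -> Optional[float]:
        return self._pct(self.n_increase, self.n_total)

    @property
    def pct_decrease(self) -> Optional[float]:
        return self._pct(self.n_decrease, self.n_total)

    @property
    def pct_none(self) -> Optional[float]:
        return self._pct(self.n_none, self.n_total)

    @property
    def pct_increase_of_significant(self) -> Optional[float]:
        return self._pct(self.n_increase, self.n_significant)

    @property
    def pct_decrease_of_significant(self) -> Optional[float]:
        return self._pct(self.n_decrease, self.n_significant)

    def to_dict(self) -> dict:
        return {
            "manipulation_type": self.manipulation_type,
            "n_total": self.n_total,
            "n_increase": self.n_increase,
            "n_decrease": self.n_decrease,
            "n_significant": self.n_significant,
            "n_none": self.n_none,
            "pct_significant": self.pct_significant,
            "pct_increase": self.pct_increase,
            "pct_decrease": self.pct_decrease,
            "pct_none": self.pct_none,
            "pct_increase_of_significant": self.pct_increase_of_significant,
            "pct_decrease_of_significant": self.pct_decrease_of_significant,
            "mean_increase_spikes_per_s": self.mean_increase,
            "mean_decrease_spikes_per_s": self.mean_decrease,
        }

    @classmethod
    def from_counts(
        cls, n_increase: int, n_decrease: int, n_total: int, manipulation_type: str = "object"
    ) -> "PopulationSummary":
        return cls(
            manipulation_type=manipulation_type,
            n_total=n_total,
            n_increase=n_increase,
            n_decrease=n_decrease,
        )


def summarize_population(
    classifications: Sequence[ChangeClassification], manipulation_type: str = "object"
) -> PopulationSummary:
    """Population breakdown: counts, one-decimal percentages, mean shifts."""
    if not classifications:
        raise ValueError("need at least one classification")
    inc = [c for c in classifications if c.label == "increase"]
    dec = [c for c in classifications if c.label == "decrease"]
    return PopulationSummary(
        manipulation_type=manipulation_type,
        n_total=len(classifications),
        n_increase=len(inc),
        n_decrease=len(dec),
        mean_increase=float(np.mean([c.delta for c in inc])) if inc else None,
        mean_decrease=float(np.mean([abs(c.delta) for c in dec])) if dec else None,
    )
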