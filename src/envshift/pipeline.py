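"""End-to-end orchestration: truncate -> ratemaps -> MFR change -> speed -> PV.

The pipeline is a pure function of (inputs, config, seeds): rerunning with
the same configuration writes byte-identical summary JSON.  Every analysis
parameter is surfaced in :class:`PipelineConfig` with its conventional
default; overrides are recorded in the run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import ANALYSIS_DURATION, SessionTriplet, load_triplet, truncate_triplet
from .mfr_change import ALPHA, N_BLOCKS, classify_triplet, summarize_population
from .popvec import PV_BIN_S, compare_correlation_distributions, triplet_correlation_sets
from .ratemap import BIN_SIZE_CM, KERNEL_SPAN_CM, compute_ratemap, normalize_for_display, smooth_ratemap
from .speed_tuning import SPEED_SMOOTH_FRAMES, classify_speed_cell


@dataclass
class PipelineConfig:
    """All analysis parameters in one place (defaults are the study values)."""

    analysis_duration: float = ANALYSIS_DURATION  # s
    n_blocks: int = N_BLOCKS
    alpha: float = ALPHA
    spatial_bin_cm: float = BIN_SIZE_CM
    smooth_kernel_cm: float = KERNEL_SPAN_CM
    speed_smooth_frames: int = SPEED_SMOOTH_FRAMES
    pv_bin_s: float = PV_BIN_S
    seed: int = 0
    make_ratemaps: bool = True
    make_pngs: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(
    triplet: SessionTriplet | str | Path,
    out_dir: str | Path,
    config: Optional[PipelineConfig] = None,
) -> Path:
    """Run every stage on one triplet and write a run directory.

    ``triplet`` may be an in-memory :class:`SessionTriplet` or a manifest
    path.  Outputs: ``cells.csv`` (per-cell statistics), ``summary.json``
    (population breakdown + PV comparison), ``report.txt`` (human-readable),
    ``run_log.json`` (config, hash, versions).  A stage failure leaves a
    ``FAILED`` marker naming the stage and re-raises.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if not isinstance(triplet, SessionTriplet):
            triplet = load_triplet(triplet)
        stage = "truncate"
        trip = truncate_triplet(triplet, config.analysis_duration)

        if config.make_ratemaps:
            stage = "ratemaps"
            _write_ratemaps(trip, out / "ratemaps", config)

        stage = "mfr_change"
        classifications = classify_triplet(trip, alpha=config.alpha, duration=config.analysis_duration)
        summary = summarize_population(classifications, trip.manipulation_type)

        stage = "speed_tuning"
        speed_rows = []
        for cid in trip.roster:
            sc = classify_speed_cell(trip, cid, alpha=config.alpha, smooth_frames=config.speed_smooth_frames)
            speed_rows.append(
                {
                    "cell_id": cid,
                    "speed_sensitive": sc.speed_sensitive,
                    "category": sc.category,
                    **{f"p_speed_{k}": v.p for k, v in sc.per_session.items()},
                }
            )
        speed_df = pd.DataFrame(speed_rows).set_index("cell_id")

        stage = "popvec"
        sets = triplet_correlation_sets(trip, bin_s=config.pv_bin_s, duration=config.analysis_duration)
        pv_cmp = compare_correlation_distributions(sets)

        stage = "report"
        cell_df = pd.DataFrame(
            [
                {
                    "cell_id": c.cell_id,
                    "label": c.label,
                    "H": c.H,
                    "p_omnibus": c.p_omnibus,
                    "p_manip_pre": c.p_manip_pre,
                    "p_manip_post": c.p_manip_post,
                    "p_pre_post": c.p_pre_post,
                    "delta": c.delta,
                    "mfr_pre": c.session_mfr["pre"],
                    "mfr_manip": c.session_mfr["manip"],
                    "mfr_post": c.session_mfr["post"],
                    "flags": ";".join(c.flags),
                }
                for c in classifications
            ]
        ).set_index("cell_id")
        cell_df = cell_df.join(speed_df)
        cell_df.to_csv(out / "cells.csv", float_format="%.6g")

        n_sig = summary.n_significant
        sig_ids = {c.cell_id for c in classifications if c.label != "none"}
        n_sig_speed = int(speed_df.loc[sorted(sig_ids), "speed_sensitive"].sum()) if sig_ids else 0
        summary_obj = {
            "population": summary.to_dict(),
            "speed": {
                "n_speed_sensitive": int(speed_df["speed_sensitive"].sum()),
                "pct_speed_sensitive": round(100.0 * speed_df["speed_sensitive"].mean(), 1),
                "n_changed_and_speed_sensitive": n_sig_speed,
                "pct_changed_and_speed_sensitive": round(100.0 * n_sig_speed / n_sig, 1) if n_sig else None,
                "categories": {k: int(v) for k, v in speed_df["category"].value_counts().sort_index().items()},
            },
            "popvec": {
                "H": pv_cmp.H,
                "p_omnibus": pv_cmp.p_omnibus,
                "medians": pv_cmp.medians,
                "n": pv_cmp.n,
                "pairwise": {f"{a}|{b}": p for (a, b), p in sorted(pv_cmp.pairwise.items())},
            },
        }
        _json_dump(summary_obj, out / "summary.json")
        _write_report(summary_obj, out / "report.txt")
        _json_dump(
            {"config": asdict(config), "config_hash": config.hash(), "envshift_version": __version__},
            out / "run_log.json",
        )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\n{exc!r}\n")
        raise
    return out


def _write_ratemaps(trip: SessionTriplet, out: Path, config: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    for cid in trip.roster:
        maps = [
            smooth_ratemap(
                compute_ratemap(s.spikes[cid], s.trace, s.arena, config.spatial_bin_cm),
                config.smooth_kernel_cm,
            )
            for s in trip.sessions
        ]
        norm = normalize_for_display(maps)
        for name, m, g in zip(("pre", "manip", "post"), maps, norm):
            np.savetxt(out / f"{cid}_{name}.csv", m.rate, delimiter=",", fmt="%.5g")
        if config.make_pngs:
            _png_preview(cid, maps, norm, out / f"{cid}.png")


def _png_preview(cid: str, maps, norm, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, name, m, g in zip(axes, ("pre", "manip", "post"), maps, norm):
        ax.imshow(np.where(np.isfinite(g), g, np.nan).T, origin="lower", vmin=0, vmax=1)
        peak = np.nanmax(m.rate) if np.any(m.visited_mask) else 0.0
        ax.set_title(f"{name} (peak {peak:.1f} Hz)", fontsize=8)
        ax.set_axis_off()
    fig.suptitle(cid)
    fig.savefig(path, dpi=80)
    plt.close(fig)


def _write_report(summary: dict, path: Path) -> None:
    pop = summary["population"]
    sp = summary["speed"]
    pv = summary["popvec"]
    lines = [
        f"Manipulation: {pop['manipulation_type']}",
        f"Cells in roster: {pop['n_total']}",
        "",
        "Mean firing rate change (manipulation vs both flanking sessions):",
        f"  significant: {pop['n_significant']}/{pop['n_total']} ({pop['pct_significant']}%)",
        f"    increase:  {pop['n_increase']} ({pop['pct_increase']}% of all"
        + (f", {pop['pct_increase_of_significant']}% of significant)" if pop["n_significant"] else ")"),
        f"    decrease:  {pop['n_decrease']} ({pop['pct_decrease']}% of all"
        + (f", {pop['pct_decrease_of_significant']}% of significant)" if pop["n_significant"] else ")"),
        f"  mean increase: {pop['mean_increase_spikes_per_s']} spikes/s",
        f"  mean decrease: {pop['mean_decrease_spikes_per_s']} spikes/s",
        "",
        "Speed tuning:",
        f"  speed sensitive (any session): {sp['n_speed_sensitive']} ({sp['pct_speed_sensitive']}%)",
        f"  MFR-changed cells that are speed sensitive: {sp['n_changed_and_speed_sensitive']}"
        f" ({sp['pct_changed_and_speed_sensitive']}%)",
        f"  shape categories: {sp['categories']}",
        "",
        "Population-vector correlations (medians):",
    ] + [f"  {k}: {v:.4f} (n={pv['n'][k]})" for k, v in pv["medians"].items()] + [
        f"  Kruskal-Wallis H = {pv['H']:.1f}, p = {pv['p_omnibus']:.3g}",
        "",
    ]
    path.write_text("\n".join(lines))
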