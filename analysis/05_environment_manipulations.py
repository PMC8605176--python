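#!/usr/bin/env python
"""Apply the MFR-change classifier to the environmental-manipulation triplets.

The same classifier used for object insertion is run on four further
manipulation families, each simulated at its reported sample size and
shifted-cell composition, with the middle session's arena actually altered
(rotated 45 degrees, circular 1.1 m, expanded to 1.5 m, or wall-less):

    rotation   63 cells (2 increase, 8 decrease)
    circle     23 cells (3 increase, 2 decrease)
    expansion   9 cells (1 increase, 2 decrease)
    no_walls   15 cells (0 increase, 4 decrease)

Writes results/manipulations.json with recovered counts and percentages.
"""

import json
import zlib
from pathlib import Path

from envshift import classify_triplet, summarize_population, truncate_triplet
from envshift.core import Arena
from envshift.synthetic_data import SimConfig, generate_triplet

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1

CONDITIONS = {
    "rotation": dict(
        n_cells=63, n_inc=2, n_dec=8, manip_arena=Arena("square", 125.0, rotation_deg=45.0)
    ),
    "circle": dict(n_cells=23, n_inc=3, n_dec=2, manip_arena=Arena("circle", 110.0)),
    "expansion": dict(n_cells=9, n_inc=1, n_dec=2, manip_arena=Arena("square", 150.0)),
    "no_walls": dict(n_cells=15, n_inc=0, n_dec=4, manip_arena=Arena("none", 125.0)),
}


def main() -> None:
    results = {}
    for mtype, spec in CONDITIONS.items():
        n = spec["n_cells"]
        cfg = SimConfig(
            n_cells=n,
            fraction_increase=spec["n_inc"] / n,
            fraction_decrease=spec["n_dec"] / n,
            manipulation_type=mtype,
            manip_arena=spec["manip_arena"],
            seed=SEED + zlib.crc32(mtype.encode()) % 1000,
        )
        triplet, truth = generate_triplet(cfg)
        triplet = truncate_triplet(triplet)
        cls = classify_triplet(triplet)
        summary = summarize_population(cls, mtype)
        labels = {c.cell_id: c.label for c in cls}
        agree = sum(labels[cid] == truth.labels[cid] for cid in labels) / n
        results[mtype] = {
            "truth": {"increase": spec["n_inc"], "decrease": spec["n_dec"], "n": n},
            "recovered": summary.to_dict(),
            "label_agreement": round(agree, 3),
        }
        print(
            f"{mtype}: {summary.n_significant}/{n} changed ({summary.pct_significant}%), "
            f"{summary.n_increase} increase / {summary.n_decrease} decrease "
            f"(truth {spec['n_inc']}/{spec['n_dec']}), agreement {100 * agree:.0f}%"
        )

    OUT.mkdir(exist_ok=True)
    with open(OUT / "manipulations.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
    print(f"wrote {OUT / 'manipulations.json'}")


if __name__ == "__main__":
    main()
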