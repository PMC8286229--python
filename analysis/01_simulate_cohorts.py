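"""Generate the two synthetic studies all later steps analyze.

Study "edges":    ten weakened + five strengthened connections
                  (|delta z| = 0.4) planted in group B, no coupling change.
Study "coupling": between-module correlation raised by 0.15 in group B,
                  no single-edge effects.

Both use 21 subjects per group, 282 timepoints, and a 40-node
parcellation of four planted systems.  Run from the repository root:

    python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
from pathlib import Path

from conncompare.pipeline import stage_simulate

STUDIES = {
    "edges": {"coupling_delta": 0.0},
    "coupling": {"n_weaker": 0, "n_stronger": 0},
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()
    for study, params in STUDIES.items():
        res = stage_simulate(params, args.out / study / "cohort", args.seed)
        truth = res["truth"]
        print(
            f"[{study}] wrote {2 * truth.n_subjects} subjects x "
            f"{truth.n_timepoints} timepoints, {truth.n_nodes} nodes, "
            f"{len(truth.effect_edges)} planted edge effects, "
            f"coupling_delta={truth.coupling_delta}"
        )


if __name__ == "__main__":
    main()
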