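"""Turn every subject's time series into a Fisher-z connectivity matrix.

Reads the cohorts written by 01_simulate_cohorts.py and writes one
symmetric z-matrix TSV per subject next to them.
"""

import argparse
from pathlib import Path

from conncompare.pipeline import stage_connectivity


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--out", type=Path, default=Path("results/analysis"))
    args = parser.parse_args()
    for study in ("edges", "coupling"):
        cohort = args.out / study / "cohort"
        res = stage_connectivity(cohort, cohort)
        print(f"[{study}] wrote {len(res['outputs'])} connectivity matrices")


if __name__ == "__main__":
    main()
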