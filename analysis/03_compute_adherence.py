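"""Compute PDC adherence measures from the prescription log.

Derives first-year PDC_1 (with the trailing-prescription window rules),
its three-band category, and the interval PDC_k between the LDL-c visits
selected in the trajectory step; applies the cohort exclusions (death
within 90 days, PDC_1 > 200%); writes adherence.csv and exclusions.json.

Usage: python analysis/03_compute_adherence.py --in results/cohort \
           [--visits results/cohort/trajectories_longitudinal.csv] --out results/cohort
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from statin_adherence import apply_cohort_exclusions, build_adherence_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="in_dir", type=Path, required=True)
    ap.add_argument("--visits", type=Path, default=None,
                    help="trajectory table supplying per-patient visit days")
    ap.add_argument("--out", type=Path, default=None)
    args = ap.parse_args()
    out = args.out or args.in_dir
    out.mkdir(parents=True, exist_ok=True)

    rx = pd.read_csv(args.in_dir / "prescriptions.csv")
    events = pd.read_csv(args.in_dir / "events.csv")
    visits_path = args.visits or (args.in_dir / "trajectories_longitudinal.csv")
    visits = pd.read_csv(visits_path)

    adherence = build_adherence_table(rx, visits)
    kept, report = apply_cohort_exclusions(adherence, events)
    kept.to_csv(out / "adherence.csv", index=False)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(report, fh, indent=1)

    valid = kept["pdc1"].dropna()
    print(f"adherence computed for {len(adherence)} patients; "
          f"{report['n_excluded']} excluded {report}")
    print(f"  PDC_1 mean {valid.mean():.1f}%, median {valid.median():.1f}%")
    print("  category shares (%):")
    print((kept["pdc1_category"].value_counts(normalize=True) * 100).round(1).to_string())


if __name__ == "__main__":
    main()
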