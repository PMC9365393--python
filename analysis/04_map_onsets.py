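#!/usr/bin/env python
"""Generate a synthetic onset cohort and map onsets to interfaces.

Builds a 150-subunit cohort under the default study conditions (first
interface 15% larger on average, onset noise 5 residues), maps the
tunnel-adjusted onsets to nearest interface midpoints, and writes
results/cohort.tsv and results/onset_mapping.tsv.
"""

from pathlib import Path

import pandas as pd

from cotasm.onsets import annotate_cohort, map_onsets, recovery_rate
from cotasm.synth import CohortSpec, generate_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 20220728 % 2**20


def main() -> None:
    spec = CohortSpec(n_subunits=150, seed=SEED)
    cohort, onsets, profiles = generate_cohort(spec)
    cohort.to_csv(RESULTS / "cohort.tsv", sep="\t", index=False)

    records = map_onsets(profiles, onsets)
    mapping = pd.DataFrame([{
        "protein_id": r.protein_id, "raw_onset": r.raw_onset,
        "adjusted_onset": r.adjusted_onset,
        "mapped_interface": r.mapped_interface or "",
        "discard_reason": r.discard_reason or "",
    } for r in records])
    mapping.to_csv(RESULTS / "onset_mapping.tsv", sep="\t", index=False)

    annotated = annotate_cohort(profiles, onsets)
    paired = annotated.dropna(subset=["other_mean_bsa"])
    designated = dict(zip(cohort.protein_id, cohort.designated_interface))
    rate, n_mappable = recovery_rate(profiles, onsets, designated)
    print(f"cohort of {len(cohort)} subunits; "
          f"{len(paired)} enter the paired comparison")
    print(f"designated-interface recovery: {100 * rate:.1f}% "
          f"of {n_mappable} mappable onsets")
    print(f"mapped interface mean area {paired.cotranslational_bsa.mean():.0f} "
          f"vs other-interface mean {paired.other_mean_bsa.mean():.0f} "
          f"(Å², per-subunit side)")


if __name__ == "__main__":
    main()
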