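#!/usr/bin/env python
"""Simulate a small demonstration set of reach-to-target trials.

Generates a 2-subject, 2-session, both-arms demo cohort (6 movements per
arm-session), writes the marker trajectories to a long-format CSV and a
per-trial ground-truth/config sidecar JSON under results/data/.  The full
study-sized cohorts used by the statistical drivers are simulated in
memory by those drivers; this script exists to show (and exercise) the
file interfaces.
"""

import json
from dataclasses import asdict
from pathlib import Path

from reachkin.cohort import CohortConfig, iter_cohort_trials
from reachkin.io import write_trials_csv

OUT = Path("results/data")
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = CohortConfig(n_subjects=2, movements_per_session=6)
    trials = list(iter_cohort_trials(cohort, seed=SEED))
    write_trials_csv(trials, OUT / "demo_trials.csv")
    (OUT / "demo_cohort_config.json").write_text(
        json.dumps({"seed": SEED, "cohort": asdict(cohort)}, indent=2)
    )
    n_frames = sum(t.n_frames for t in trials)
    print(f"wrote {len(trials)} trials ({n_frames} frames) "
          f"to {OUT / 'demo_trials.csv'}")
    print(f"subjects: {sorted({t.subject_id for t in trials})}; "
          f"sessions: pre/post; arms: paretic/nonparetic")


if __name__ == "__main__":
    main()
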