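"""Generate a small synthetic cohort and look at its ground truth.

The generator emulates a retrospective smartwatch cohort: heart-rate
sampling every ~5.6 minutes while worn, annual software releases adopted
25-31 days later, occasional hardware purchases, and NB2 daily activity
counts whose mean shifts multiplicatively at each upgrade.
"""

import pandas as pd

from watchdrift import GeneratorConfig, generate_cohort

cfg = GeneratorConfig(n_participants=20, seed=42, end_date="2021-12-31")
cohort = generate_cohort(cfg)

print(f"participants:        {len(cohort.participants)}")
print(f"heart-rate records:  {len(cohort.heart_rate):,}")
print(f"activity days:       {len(cohort.activity):,}")
ups = pd.DataFrame(cohort.ground_truth["upgrades"])
print(f"true upgrades:       {len(ups)} "
      f"({(ups['kind'] == 'software').sum()} software, {(ups['kind'] == 'hardware').sum()} hardware)")
print("\nfirst few true upgrades (the dates the detector must recover):")
print(ups[["participant_id", "kind", "from_version", "to_version", "transition_date"]].head(8).to_string(index=False))
print("\nmean daily exercise minutes:", round(cohort.activity["exercise_minutes"].mean(), 1),
      "- close to the configured baseline of", cfg.baselines["exercise_minutes"]["overall"][0])
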