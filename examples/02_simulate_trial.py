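"""Generate a synthetic trial and inspect its structure.

The generator reproduces the trial's design: a 14-day symptomatic
run-in off antianginal medication, 1:1 block randomization, and an
84-day blinded follow-up with daily diaries, medication uptitration by
patient contact, and rare clinical override events.
"""

from anginatrial import TrialConfig, generate_trial

config = TrialConfig(n_per_arm=150, seed=42)
trial = generate_trial(config)

followup = trial.diary[trial.diary.day >= 1].merge(trial.patients, on="patient_id")
means = followup.groupby("arm")[["episodes", "med_units"]].mean()

print(f"patients randomized : {len(trial.patients)}")
print(f"diary patient-days  : {len(trial.diary)}")
print(f"diary completeness  : {100 * (1 - trial.diary.episodes.isna().mean()):.1f}%")
print("\nfollow-up daily means by arm:")
print(means.round(2))
print("\noverride events:", trial.diary.override.value_counts().drop("none").to_dict())
# PCI cuts the daily episode rate to ~43% of placebo's; medication use
# stays low because uptitration needs a sustained weekly episode burden.
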