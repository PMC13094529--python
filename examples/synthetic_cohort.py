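"""A small synthetic cohort treated at a fixed 50% duty for 28 days.

Each subject draws a log-normal responsiveness; daily dose drives logistic
recovery; the evoked-EMG metric (noisy) and the BBB-like proxy track it.
Prints the weekly snapshot of each subject against the standardized
reference trajectory.
"""

from optocord import physio

cohort = physio.generate_cohort(n_subjects=3, seed=7)
weekly = cohort[cohort.day % 7 == 0]
print(weekly.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

print("\nStandardized reference metric (mV) by day:")
for day in (0, 7, 14, 21, 28):
    print(f"  day {day:2d}: {physio.standard_reference(day):.2f}")
print(
    "\nSubjects whose EMG metric lags the reference are the ones the\n"
    "closed-loop controller escalates; see closed_loop.py."
)
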