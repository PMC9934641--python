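"""Simulate one child's delayed-recognition EEG session.

Builds the trial schedule (3 categories x trials, jittered ITIs, exact
50/50 probe matching), synthesizes the continuous 64-channel recording
(1/f noise + planted category topographies), and prints the session
structure. The events table is what a BIDS-style events.tsv would hold.
"""

import wmdecode as w

cfg = w.SessionConfig(n_trials_per_category=30, fs_raw_hz=250.0)  # reduced size
model = w.SignalModel()
subject = w.SubjectSpec("sub-001", age_months=112, behavioral_accuracy=0.9)

sub = w.synthesize_subject(cfg, model, subject, seed=1)

per_cat = {k: int(v) for k, v in sub.trials.groupby("category").size().items()}
matches = {k: int(v) for k, v in sub.trials.groupby("category")["probe_match"].sum().items()}
print(f"trials: {len(sub.trials)} ({per_cat})")
print(f"probe matches per category: {matches}")
print(f"ITI values used (ms): {sorted(int(v) for v in sub.trials.iti_ms.unique())}")
print(f"continuous record: {sub.data.shape[0]} channels x {sub.data.shape[1]} samples "
      f"at {sub.fs_hz:.0f} Hz ({sub.data.shape[1] / sub.fs_hz:.0f} s)")
print(f"behavioral accuracy this session: {sub.trials.correct.mean():.2f}")
# Counts are exact by design (the scheduler balances categories and probe
# matches); the behavioral accuracy is Bernoulli around the subject's 0.9.
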