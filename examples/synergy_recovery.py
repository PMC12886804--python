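"""Muscle-synergy extraction on synthetic EMG with a known basis.

Generates one trial of 13-channel EMG from the default 3-synergy ground
truth, runs the full preprocessing chain, factorizes the envelopes with
NNMF for k = 1..6, selects the synergy count with the VAF/slope criteria,
and compares the recovered weight vectors against the generating basis.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

from hapticlab import (
    SynergyGroundTruth,
    extract_synergies,
    preprocess_emg,
    select_synergy_count,
    vaf_curve,
)
from hapticlab.cohort import generate_trial

truth = SynergyGroundTruth()
trial = generate_trial("NH", 1, 1, 3000, truth=truth, repetitions=1,
                       with_imu=False)
env = preprocess_emg(trial.emg, 1.0)

curve, _ = vaf_curve(env, 6, n_restarts=5, seed=0, max_iter=1000)
k = select_synergy_count(curve, vaf_threshold=0.90, slope_threshold=0.001)
print("VAF(k):", " ".join(f"{v:.4f}" for v in curve))
print(f"selected synergy count: {k} (generative k = {truth.k})")

best = extract_synergies(env, k, n_restarts=5, seed=100, max_iter=1000)
w_true = truth.W_true / np.linalg.norm(truth.W_true, axis=0)
sim = w_true.T @ best.W
rows, cols = linear_sum_assignment(-sim)
print("matched cosine similarity per synergy:",
      " ".join(f"{sim[r, c]:.3f}" for r, c in zip(rows, cols)))
print(
    "\nThe VAF curve saturates at the generative order; matched cosines"
    "\nabove 0.9 mean the muscle-weight vectors are recovered despite 5%"
    "\nenvelope noise and injected motion artifacts."
)
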