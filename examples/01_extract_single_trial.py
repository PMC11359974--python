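"""Simulate one maximal contraction and extract its outcome measures.

Generates a single MVC trial (quiet baseline, sigmoidal rise to ~142 N,
4.5 s contraction, force-coupled EMG, 1961 Hz) and runs the full
conditioning chain: 15 Hz low-pass, 3-SD onset detection, MVC, RFD200ms,
time to 90% MVC, and the peak EMG RMS within +-1 s of the force peak.
"""

import math

import numpy as np

from dynoreli import TraceParams, extract_trial_outcomes, generate_trial_trace

params = TraceParams()
trial = generate_trial_trace(params, np.random.default_rng(42))
out = extract_trial_outcomes(trial)

print(f"detected onset : {out.onset_s:7.3f} s   (generator truth {params.onset_time} s)")
print(f"MVC            : {out.mvc_n:7.2f} N   (target peak {params.peak_force} N)")
print(f"RFD200ms       : {out.rfd200_n_per_s:7.1f} N/s "
      f"(analytic {params.peak_force * math.tanh(0.1 / params.rise_tau) / 0.2:.1f} N/s)")
print(f"time to 90% MVC: {out.t90_s:7.3f} s   "
      f"(analytic {2 * params.rise_tau * math.atanh(0.9):.3f} s)")
print(f"peak EMG RMS   : {out.peak_emg_rms_v:7.3f} V")
print()
print("Detected onset should sit within ~10 ms of the generator's onset, and")
print("RFD/t90 near their closed forms; small offsets come from the 15 Hz")
print("zero-phase filter and baseline noise, as they would on real traces.")
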