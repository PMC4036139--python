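"""Homogeneous PM 01 chains: stationary probing vs backwards swimming.

Extracts maximal runs of the backward/low-thrust prototype, splits them
at the -2 cm/s mean-thrust threshold, and prints chain statistics plus
an onset-triggered average of the thrust velocity.
"""

import numpy as np

import electrokin as ek

cfg = ek.GeneratorConfig(n_frames_target=20_000)
s = ek.generate_session(cfg, seed=11)
kin = ek.compute_kinematics(s)
labels = s.gt_pm[s.locate(kin.frame_index)]

chains = ek.split_pm01(ek.extract_chains(kin, labels, pm_id=1, min_len=10))
for behavior in ("stationary", "backwards"):
    sub = [c for c in chains if c.behavior == behavior]
    st = ek.chain_statistics(sub)
    print(f"{behavior:<11s} {st['count']:4d} chains, "
          f"length {st['mean_length']:.1f} +/- {st['sd_length']:.1f} frames, "
          f"duration {st['mean_duration_s']:.2f} +/- {st['sd_duration_s']:.2f} s")

onsets = [(0, c.onset_t) for c in chains if c.behavior == "backwards"]
trace = ek.triggered_average([(kin.t, kin.thrust)], onsets, window=(0.6, 1.0))
inside = (trace.t_rel >= 0) & (trace.t_rel <= 0.6) & (trace.n >= 2)
print(f"\nbackwards chains: mean thrust {np.nanmean(trace.mean[inside]):.1f} cm/s "
      f"for 0..0.6 s after onset (negative = reversed swimming)")
before = (trace.t_rel < -0.2) & (trace.n >= 2)
print(f"pre-onset mean thrust {np.nanmean(trace.mean[before]):.1f} cm/s "
      f"(forward swimming before the reversal)")
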