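"""Generate a roving oddball session, its design regressors, and a
simulated detection-threshold staircase.

The session mirrors the tactile study conditions: 158 trains of 3-7
stimuli at 2 s ISI, every first stimulus a deviant and every third
repetition the designated standard.
"""

import numpy as np

import rovingdcm as rd

seq = rd.generate_sequence(n_trains=158, isi=2.0, seed=1)
n_repeated = len(seq.events) - len(seq.deviants)
print(f"session: {len(seq.events)} stimuli = {len(seq.deviants)} deviants "
      f"+ {n_repeated} repeated (of which {len(seq.standards)} standards)")

reg = rd.build_design_regressors(seq, n_volumes=1109, TR=1.54)
print(f"regressors over {len(reg.times)} volumes: all-conditions peak "
      f"{reg.all_conditions.max():.2f}, modulator range "
      f"[{reg.modulator.min():.2f}, {reg.modulator.max():.2f}]")

# threshold staircase against a stochastic observer; the one-up/three-down
# rule homes in on the ~79.4%-detection intensity
observer = rd.LogisticObserver(threshold=12.0, slope=1.5)
result = rd.run_staircase(observer, start_intensity=20.0, seed=3)
print(f"staircase: threshold {result.threshold:.2f} mA from 8 reversals "
      f"({len(result.trial_log)} trials); observer's 79.4% point is "
      f"{observer.intensity_at(rd.ONE_UP_THREE_DOWN_P):.2f} mA")
# stimulation for the main task would then be delivered at twice threshold
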