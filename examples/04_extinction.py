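"""Extinction learning in a T-maze: tabular Dyna-Q vs. DQN.

The agent is rewarded in the right arm for 100 trials, then the reward moves
to the left arm.  The tabular agent unlearns the old response within a few
trials; the DQN, replaying stale experience from its buffer, perseverates
much longer.
"""

import numpy as np

from navrl.experiments import perseveration_trials, run_extinction

for kind in ("dynaq", "dqn"):
    res = run_extinction(kind, n_acq=100, n_ext=100, seed=0)
    acq = res.responses[80:100].mean()
    ext = res.responses[150:200].mean()
    print(f"{kind:6s} right-arm rate, trials 81-100: {acq:.2f}  "
          f"trials 151-200: {ext:.2f}  perseveration trials: "
          f"{perseveration_trials(res)}")
# "Perseveration trials" counts post-switch trials still ending in the old
# (right) arm; the DQN's count is much larger than Dyna-Q's.
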