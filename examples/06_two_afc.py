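"""Two-alternative forced choice with a population of DQN agents.

Each trial presents a rewarded and an unrewarded one-hot stimulus in random
left/right order; the agent picks a side.  Averaging rewards over many
independent agents traces the canonical learning curve from chance (0.5) to
near-perfect choice.
"""

import numpy as np

from navrl.experiments import run_two_afc

rewards = run_two_afc(n_agents=50, n_trials=50, seed=5)
curve = rewards.mean(axis=0)
print("mean reward by trial (every 5th):", np.round(curve[::5], 2))
print(f"trial 1: {curve[0]:.2f} (chance is 0.5)")
print(f"trials 41-50: {rewards[:, 40:].mean():.2f}")
# The first trial sits at chance because the network starts naive; the final
# block approaches the softmax-policy ceiling near 1.0.
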