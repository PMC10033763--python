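"""Learn a successor representation by TD and check it against the closed form.

The SR of a state under a fixed policy is M = (I - gamma * T_pi)^{-1}: the
expected discounted future occupancy of every state.  Here the SR of the
uniform-random policy on a small grid is learned from a sampled random walk.
"""

import numpy as np

from navrl.agents import fit_sr_random_walk, sr_closed_form
from navrl.envs import make_open_field

spec = make_open_field(2, 3)  # no goal: a free-exploration grid
gamma = 0.9
M = sr_closed_form(spec.transitions, None, gamma)
model = fit_sr_random_walk(spec, gamma, n_steps=200_000, seed=1)
psi_bar = model.psi.mean(axis=0)

print("closed-form SR row of state 0:", np.round(M[0], 3))
print("TD-learned  SR row of state 0:", np.round(psi_bar[0], 3))
print(f"L_inf error: {np.abs(psi_bar - M).max():.3f}")
print(f"row sums (should be 1/(1-gamma) = {1/(1-gamma):.1f}):",
      np.round(psi_bar.sum(axis=1), 3))
# Each SR row sums to the discounted-occupancy total 1/(1-gamma); entries say
# how much time the random walk spends in each state, discounted.
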