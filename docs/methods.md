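# Methods

`navrl` simulates the closed-loop interaction of a reinforcement-learning
agent with a navigable environment, organized into trials the way behavioral
experiments are.  This note documents the models implemented, the defaults
chosen where the design was open, what the synthetic inputs do and do not
emulate, and the numerical conventions that make runs reproducible.

## The trial loop

Learning is structured into trials; a trial ends when the environment reports
a terminal state or when the step count reaches the time horizon
(`max_steps`).  Every step yields an experience tuple
(s_t, a_t, r_t, s_{t+1}, terminal) that the agent learns from online and/or
stores for replay.  Callbacks fire in the fixed order `trial_begin`,
(`step_begin`, `step_end`) × steps, `trial_end`; monitors (escape latency,
trial reward, response code, trajectory, unit activity) are pure observers
fed from those calls, so recomputing them offline from a stored `SessionLog`
reproduces the live values exactly.

One master seed is fanned out through `numpy.random.SeedSequence` into
separate environment and agent generators.  Given a configuration and a seed,
`run_session` is bit-reproducible, and every experiment runner inherits that
property.

## Environments

**Gridworlds** are fully tabular: a |S| × |A| × |S| row-stochastic transition
tensor with |A| = 4 (up, down, left, right; "up" decreases the row index;
states are indexed row-major from the top-left), a real reward table and a
binary terminal table of length |S|, a starting set, and per-state grid
coordinates.  Rewards follow reward-on-entry: the reward of a step is
`rewards[next_state]`.  Invalid moves (off-grid, through a wall, against a
one-way door) are self-transitions rather than errors, which is what lets an
action mask be read directly off the diagonal of the transition tensor.
Environments serialize to a versioned JSON schema (portable and diffable;
loading re-runs all invariant checks).

Templates: an open field with an optional single terminal goal; a T-maze
(vertical stem, horizontal crossbar, both arm ends terminal, one rewarded);
and a one-way alley maze for latent-learning studies.  The alley maze is a
serpentine of seven alleys connected at alternating ends by six one-way
doors, with a dead-end stub past each junction; the reverse action at a door
is a self-transition, so the agent cannot retrace its path — the start is
unreachable from any state past the first door.  The layout is a
parameterized abstraction of the classic six-unit alley apparatus, not a
reconstruction of its exact cell geometry.

**Topology graphs** abstract space into nodes and edges: rectangular
lattices (4 headings, 90° apart) and hexagonal lattices (6 headings, 60°
apart; every interior node has six equidistant neighbors).  Translations move
to the neighbor in a compass direction and are no-ops at boundaries.  In
rotation mode the action space doubles: the extra actions turn the agent in
place to face a chosen compass direction, so a hexagonal graph offers twelve
actions (six translations, six rotations).  Heading affects only the
observation, not the transition structure.

**The continuous 2D arena** is an obstacle-free rectangle with two
kinematics: cardinal translation by a fixed step, or a differential-drive
robot with wheel speeds clipped to ±1 unit/s, wheel base b (default 0.1 m)
and integration step dt = 0.1 s.  Linear velocity is (v_l + v_r)/2 and
angular velocity (v_r − v_l)/b; the position advances along the pre-step
heading, so a pure spin leaves the position exactly fixed.  Positions are
clipped to the bounds; entering a reward disc ends the trial with its value,
and wall contact may optionally end the trial.

## Observations

Images are resized and normalized to [0, 1]; integer-factor downscaling uses
exact area (block) averaging and everything else bilinear interpolation —
chosen because block means admit an exact brute-force oracle.  Gaussian noise
is applied after normalization and clipped back to [0, 1] by default, so the
observation contract survives corruption.  Multisensory observations are
keyed dictionaries whose keys route modalities to named network inputs; a
pose observation (x, y, wrapped heading) can stand alongside or instead of
vision.

Where a 3D renderer would normally supply images, a procedural renderer
synthesizes a deterministic texture per (state, heading): a low-resolution
random field upsampled bilinearly plus a heading-dependent bright band.  The
textures are visually distinct and bit-reproducible from the seed, which is
what the learning experiments need, but they carry none of the spatial
correlation structure of real scenes: two adjacent states look unrelated.
Consequently, experiments passing on synthetic textures demonstrate the
machinery (caching, learning dynamics, map analysis), not photometric
realism.

The offline observation cache renders each (state, heading) exactly once and
serves queries from memory; it is semantically transparent, so a session run
with the cache on or off produces identical logs under identical seeds.

## Agents

All agents implement the same small surface (`begin_trial`, `act`, `observe`,
`end_trial`, `predict`), so environments, monitors, and the loop never care
which family they are driving.

**Dyna-Q** holds a |S| × |A| Q table (zero-initialized) updated by
Q-learning: Q(s,a) += α(r + γ(1−T) max_a′ Q(s′,a′) − Q(s,a)).  A tabular
environment-model memory stores the most recent outcome per visited (s,a)
pair — exact for deterministic tasks, a documented limitation for stochastic
ones — and replay draws uniformly among visited pairs after each step, after
each trial, or never.  On deterministic environments exhaustive replay drives
the table to the value-iteration fixed point; `value_iteration` is provided
as the oracle.  Policies are ε-greedy (default) or softmax with temperature
τ; argmax ties break uniformly at random to avoid index bias in symmetric
mazes.  The optional action mask removes guaranteed self-transitions from
selection.

**DQN** keeps online and target networks behind a backend-agnostic contract
(`predict`, `fit`, `clone`, `copy_weights_from`, `activations`).  The bundled
backend is a fully connected ReLU network trained by Adam on squared error;
He-normal initialization from the seed makes agents bit-reproducible.
One-step TD targets use the target network; entries for untaken actions keep
the online predictions so no gradient flows through them.  The target network
syncs every `target_sync` training steps (default 100).  Prioritized replay
follows the proportional scheme: p_i = (|δ_i| + ε_p)^α with sampling ∝ p_i
and importance weights (N·P(i))^(−β) normalized by their maximum (defaults
α = 0.6, β = 0.4, ε_p = 1e−3).  An optional optimistic output-bias
initialization is available for tasks where directed exploration of untried
actions matters.

**Dyna-DSR** learns a per-action successor map ψ and linear reward weights w
directly on observations; with one-hot observations (the default for
discrete environments) ψ is exactly tabular, |A| × |S| × |S|.  The TD update
is ψ(s,a) += α(e_s + γ(1−T)ψ(s′,a*) − ψ(s,a)) with a* the greedy action at
s′, and w[s′] += α_r(r − w[s′]), regressing reward on the *entered* state to
match reward-on-entry.  A terminal successor is absorbing: its SR is its own
one-hot, so the update target gains γ·e_{s′} with no further bootstrap.
Without this term the goal state's occupancy would never enter ψ and terminal
rewards would be invisible to Q = ψ·w.  The closed form under a fixed policy,
M = (I − γT_π)^{-1}, is provided as an oracle; `fit_sr_random_walk` estimates
it by TD along a sampled walk with Robbins–Monro step sizes
α = c/(c + visits), c = 50 — the larger offset keeps step sizes high long
enough for the row-sum contraction (row sums obey their own scalar recursion
toward 1/(1−γ)) to collapse to machine precision while entries converge.

**MFEC** projects observations to low-dimensional keys with a fixed Gaussian
matrix (entries N(0, 1/d), seeded), keeps per-action growing (key, Q_EC)
stores, and updates in one shot: discounted returns are computed backward
over the finished episode and each pair keeps the best return seen so far,
so stored values never decrease.  Value reads are exact-match first, else
the mean over the k nearest keys (Euclidean); stores smaller than k average
over everything.  The KD-tree index is rebuilt lazily once pending
insertions exceed 10% of the indexed size, and queries merge tree hits with
a linear scan of the pending tail, so answers always equal a brute-force
scan — the tree is purely an efficiency device.

## Analysis

Spatial activity maps are built by artificially placing the agent at every
point of a rectangular probe grid (default 25 × 25) spanning the arena and
recording unit activations, separately per heading; for topology graphs the
probe observation is the nearest node's image with the pose channel set to
the probe coordinates, which makes probing independent of the graph's
discreteness.  The heading-averaged map is the arithmetic mean over
headings, and maps are invariant to probe order.

Place-field identification runs on a heading-averaged map.  A unit is
flagged when (i) its peak exceeds an activity floor (default 1e−3), (ii) the
largest 4-connected component of bins at ≥ 50% of peak has an area within
[9, 200] of the 625 bins, (iii) mean activity outside that field is below
30% of peak, and (iv) the field is unique — the second-largest component is
smaller than half the largest, which rejects maps with two equal bumps.
These concrete thresholds are this package's own operating point (the
literature delegates them to experiment-specific choices); all are exposed
in `PlaceFieldParams`.  On the planted-bump fixture (64 units, 7 Gaussian
fields of σ = 2 bins among silent, uniform, noisy, double-bump, over-broad
and speck distractors) the detector is exact by construction of the
defaults.

SR heat maps scatter one row of ψ onto the grid coordinates, using the
greedy action's map at the probed state (the aggregation across actions is
otherwise arbitrary).

## Demonstration experiments

**Extinction** (T-maze, stem 3, arms 2): reward sits in the right arm for
100 trials, then moves to the left arm for 100 more.  Responses code 1 when
the trial ends in the right arm.  The tabular condition runs Dyna-Q
(α = 0.9, γ = 0.9, ε = 0.1, per-step replay of 20, action mask on); the
deep condition runs the DQN on 16 × 16 synthesized per-state images
(lr = 1e−2, buffer 5000, target sync 50).  The tabular agent overwrites its
few Q entries within a couple of post-switch trials; the DQN keeps replaying
stale rewarded tuples from its buffer and perseverates for tens of trials —
the qualitative dissociation the paradigm is designed to show.

**Latent learning** (one-way alley maze): a latent group runs 100 unrewarded
exploration trials before the goal reward is switched on for 100 more; a
direct group has reward from trial 1; curves are aligned at reward
introduction, 30 seeds per group.  Both groups use the Dyna-DSR (α = 0.1,
α_r = 0.9, γ = 0.9, ε = 0.1, per-step replay of 10, mask on).  The split of
learning rates is deliberate: the successor map is the slow, reward-free
part that exploration can pre-train, while the reward weights are fast, so
the latent group converts its pre-built ψ into a policy within a trial or
two of the first reward.  The start state's SR visibly shifts from covering
the start's neighborhood (end of exploration) to covering the path to the
goal (end of run).

**2AFC**: a catalog of four one-hot stimuli and two disjoint choice trials;
each trial presents one randomly drawn pair in randomized left/right order
and rewards the correct side, so a stimulus-blind policy earns 0.5.  One
hundred independent DQNs (γ = 0, softmax policy with τ = 0.2, lr = 3e−2, 16
gradient steps per trial on batches of 32, training from the first
experience) are trained for 50 one-step trials.  The softmax policy is the
load-bearing choice: with ε-greedy, an agent whose untried action drifts
slightly negative can stop sampling it forever, while softmax keeps
exploration pressure proportional to the value gap and self-corrects; its
ceiling at τ = 0.2 is ≈ 0.99.

**Place-field emergence**: a DQN (lr = 2e−3, ε = 0.2, hidden 64 + 64) learns
to reach an unmarked central goal node on a 6 × 5 hexagonal graph with
rotations (12 actions), observing an 8 × 8 per-(node, heading) texture
concatenated with a normalized pose channel (x, y, cos θ, sin θ).  Maps of
all 64 last-hidden-layer units are recorded on a 25 × 25 grid for all six
headings at trials 0, 800, 1600 and after trial 2400, and place-cell-like
units are counted per checkpoint.  The run length of 2,400 trials with
checkpoints every 800 is the package's scaled-down default; longer schedules
are a parameter away.  Node-specific texture tuning plus pose input is what
allows compact fields: a unit keyed to one node's texture is active exactly
on that node's probe-grid cell.

## Known limitations

- The environment-model memory keeps only the latest outcome per (s, a);
  replay on stochastic tasks therefore learns the last-seen, not expected,
  outcome.
- Procedural textures have no inter-state visual correlation, so results
  about representation learning speak to the algorithms, not to natural
  image statistics.
- The alley-maze geometry is an abstraction; quantitative comparisons to the
  historical apparatus are out of scope.
- Only trial-based (episodic) tasks are supported; continuing tasks and
  multi-agent settings are not.
- The DSR agent is tabular-by-one-hot; a learned deep feature front end is
  intentionally not included.
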