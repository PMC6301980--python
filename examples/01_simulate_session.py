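"""Generate a synthetic delayed-grasping session and inspect its structure.

The generator plants known condition-independent, force, grip, and
interaction structure through low-dimensional latents, so the printed
ground-truth variance shares are what downstream analyses should recover.
"""

from graspdyn import TaskConfig
from graspdyn.synthetic import simulate_session

session = simulate_session(TaskConfig(n_trials=120, rng_seed=0), n_units=20)

tt = session.trial_table
print(f"trials: {len(tt)}  successful: {int(tt['success'].sum())}")
print(f"units: {len(session.spikes)}  muscles: {sorted(session.emg)}")
print("planted marginalization variance shares:")
for name, share in session.ground_truth["variance_shares"].items():
    print(f"  {name:22s} {share:.3f}")
# The shares say how much of the planted firing-rate variance is common to
# all conditions (condition-independent) vs. attributable to force, grip,
# or their interaction — the quantities dPCA is meant to recover.
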