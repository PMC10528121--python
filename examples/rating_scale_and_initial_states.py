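"""Map slider ratings onto the discrete reliability scale and build the
initial state vectors both dynamical models start from."""

import numpy as np

from trustwalk import StateSpace, map_rating_to_state, uniform_initial, weighted_initial

space = StateSpace(11)

# A 0-100 reliability rating is binned onto 11 levels (9-point bins,
# everything at or above 90 maps to the top level).
for rating in (48.9, 8.99, 9.0, 90.0, 100.0):
    print(f"rating {rating:6.2f}%  ->  state {map_rating_to_state(rating, space)}")

# The "know nothing" start: every level equally weighted.
phi_u = uniform_initial(space, "markov")
print("\nuniform probabilities:", np.round(phi_u.probs, 4))

# The weighted start centred on a participant's first rating (48.9% -> 5):
# a 7-point stencil, renormalised before use in evolution.
start = map_rating_to_state(48.9, space)
phi_w = weighted_initial(space, start, "markov")
psi_w = weighted_initial(space, start, "quantum")
print("weighted probabilities:", np.round(phi_w.probs, 4))
print("weighted amplitudes:   ", np.round(psi_w.amps.real, 4))

# The peak probability is 0.5/1.015 because the raw stencil sums to 1.015.
print(f"\npeak probability at state {start}: {phi_w.probs[start]:.6f}")
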