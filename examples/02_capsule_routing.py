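"""Dynamic routing between capsules on a toy instance.

Three input capsules vote for two output capsules; routing-by-agreement
(three rounds) concentrates each input's coupling on the output its votes
agree with, and the squash nonlinearity keeps output norms inside [0, 1).
"""

import numpy as np

from gocapgan import CapsuleLayerParams, compute_votes, dynamic_route, capsule_lengths

rng = np.random.default_rng(0)
params = CapsuleLayerParams.init_random(J_in=3, K_out=2, d_in=4, d_out=4,
                                        rng=rng, scale=1.0)
x = rng.normal(size=(3, 4))

votes = compute_votes(x, params)          # vote[j,k] = W[j,k] @ x[j] + B[j,k]
state = dynamic_route(votes, iterations=3)

print("coupling coefficients (rows sum to 1):")
print(np.round(state.coupling, 3))
print("output capsule lengths (existence probabilities, < 1):")
print(np.round(capsule_lengths(state), 4))
# a length near 1 means the routed evidence for that output capsule is strong
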