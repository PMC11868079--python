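"""Learn a spherical boundary model on synthetic ball-vs-shell data and
classify a held-out pattern, printing the full vote trace.

Class 1 occupies a ball of radius 1 over three informative attributes;
class 2 a shell of radius 5-10; fifty standard-normal noise attributes
are appended.  The learner should recover exactly the informative
attributes, place class 1 inside (c1_in = True), and separate the
classes with zero training error.
"""

import numpy as np

import spheremml as sm

data = sm.radial_shells(sm.ShellSpec(seed=7))
held_out, rest = data.values[0], np.arange(1, data.n_patterns)
train = data.subset(rest)

model = sm.learn(train, att=5, bound=3)
print(f"orientation c1_in = {model.c1_in}  (True: class 1 modeled inside)")
print(f"learning attributes (0-based): {[int(a) for a in model.learning_attributes]}")
print(f"spherical boundaries: {np.round(model.boundaries, 4)}")
print(f"training error: {model.training_error}")

predicted, trace = sm.classify(model, held_out)
print(f"\nheld-out pattern true class: {data.labels[0]}")
print(f"progressive norms: {np.round(trace.norms, 4)}")
print(f"votes for class 1: {trace.votes_class1} of {model.bound}")
print(f"predicted class: {predicted}")
# Each progressive attribute set casts one vote: the pattern's radial norm
# over the first k learning attributes is compared with the k-th boundary.
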