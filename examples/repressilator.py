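"""The repressilator: ring of three repressing genes.

With slow promoter kinetics the mixture concentrates on the three
single-gene-high components, and the reduced promoter chain predicts the
cyclic order in which a sample path visits them — stochastic oscillation
even without cooperativity.
"""

import numpy as np

import spkmix as sx

spec = sx.build_fixture("repressilator")  # noncooperative, slow (eps=0.1)
mix = sx.mixture_pmf(spec)
idx, cum = sx.dominant_components(mix, concentration=0.99)
print("dominant components (>= 99% of the weight):")
for i in idx:
    c = mix.components[i]
    print(f"  {c.gene_state.label()}  location={c.location(spec)}  "
          f"weight={mix.weights[i]:.3f}")

gen = mix.generator
dom = {gi: sx.state_index(spec, tuple("0" if i == gi else "1"
                                      for i in range(3)))
       for gi in range(3)}
t = 0.05 / np.abs(gen.matrix.diagonal()).max()
Q = sx.transition_matrix(gen, t)
names = [g.id for g in spec.genes]
print("short-time transition preferences of the reduced chain:")
for gi in range(3):
    others = [h for h in range(3) if h != gi]
    succ = max(others, key=lambda h: Q[dom[h], dom[gi]])
    print(f"  {names[gi]}-high -> {names[succ]}-high next")

traj = sx.ssa_simulate(spec, t_max=120.0, seed=11, record_dt=0.05,
                       burn_in=5.0)
seq = sx.validation.dominant_switch_sequence(traj, ["X", "Y", "Z"])
print("sample-path dominance sequence:",
      " -> ".join(names[i] for i in seq))
print("The path cycles through the modes in the predicted order: the")
print("tri-modal stationary law manifests as sustained oscillation.")
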