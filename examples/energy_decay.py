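"""Demonstrate unconditional free-energy decay of the implicit step.

Without the fidelity term the scheme is a discrete gradient flow: the
Ginzburg-Landau free energy is non-increasing across every time step,
no matter how large the step - the convex-splitting property.
"""

import numpy as np

from chinpaint import (
    PhaseField,
    SolverConfig,
    build_fidelity,
    discrete_free_energy,
    step_full2d,
)

rng = np.random.default_rng(3)
state = PhaseField(rng.uniform(-1, 1, (16, 16)))
fid = build_fidelity(np.zeros((16, 16), bool), 0.0)
cfg = SolverConfig(lam0=0.0)

for dt in (0.1, 1.0, 10.0):
    s = state.copy()
    energies = [discrete_free_energy(s, 1.0)]
    for _ in range(5):
        s, _ = step_full2d(s, state, fid, 1.0, dt, cfg)
        energies.append(discrete_free_energy(s, 1.0))
    trace = " -> ".join(f"{e:.3f}" for e in energies)
    print(f"dt={dt:5.1f}: E = {trace}")

# Each trace is monotonically non-increasing even at dt=10 (100x the
# production step): stability does not rely on a small time step.
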