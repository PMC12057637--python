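# aimpot

A charge-aware message-passing interatomic potential for molecules and
molecular clusters, with everything needed to train and exercise it at
desk scale: the model, the multi-target loss and trainer, a
teacher→student data-distillation loop, geometry optimization, torsion
scans and molecular dynamics, and a synthetic toy reference potential
that provides exactly self-consistent labels in place of quantum
chemistry.

## The model

For a system with coordinates `R`, atomic numbers `Z` (14 elements:
H, B, C, N, O, F, Si, P, S, Cl, As, Se, Br, I) and net charge `Q`,

    U_total = U_local + U_disp + U_coul

* `U_local` — a learned short-range term.  Interatomic distances are
  expanded in 16 Gaussian shells with a cosine cutoff at 5.0 Å; each atom
  carries a 16×16 embedding refined by message passes that combine scalar
  (l = 0) and vector-norm (l = 1) neighbor contractions.  Partial charges
  `q_i` are predicted in the first pass and refined in later passes,
  where the convolutions also run over the current charges; every update
  passes through **Neural Charge Equilibration**

      q_i = q̃_i + f_i (Q − Σ_j q̃_j) / Σ_j f_j,   f_i ≥ 0,

  so Σq equals the exact molecular charge after every pass.  The final
  per-atom representation (AIM vector) feeds a feed-forward energy head
  on top of per-element reference energies.
* `U_coul` — point-charge electrostatics over the predicted charges:
  full direct sum for isolated systems, damped-shifted-force (DSF) with a
  15 Å cutoff under periodic boundaries.
* `U_disp` — two-body dispersion with rational Becke–Johnson damping and
  coordination-number-interpolated C6 coefficients (the shipped reference
  tables are synthetic stand-ins; see `docs/methods.md`).

Forces are exact gradients of the implemented energy — including the
charge-equilibration and coordination-number chains — via a small
built-in reverse-mode autodiff engine that also supports the
second-order gradients needed for force-matching training.

Training minimizes a weighted MSE over energies (scaled by 1/√N per
molecule), force components, charges, and charge-derived dipoles and
quadrupoles, with same-atom-count minibatches, AdamW and a
reduce-on-plateau schedule.  Data distillation grows a compact student
set from a large teacher by selecting samples whose energy or force
error exceeds 3× the current training error, then retrains an ensemble
whose member disagreement is an active-learning uncertainty score.

## Worked example

```python
import numpy as np
from aimpot import (NeuralPotential, ModelConfig, TrainConfig,
                    make_dataset, train, evaluate)

# 1000 toy-labeled conformers of 20 random small molecules
data = make_dataset(n_molecules=20, conformers_per_molecule=50, seed=0)

pot = NeuralPotential(config=ModelConfig(hidden=(96, 48), n_passes=2))
pot, log = train(data, pot, TrainConfig(batch_size=128, lr=3e-3,
                                        max_epochs=60, seed=1,
                                        plateau_patience=4))
table, agg = evaluate(pot, data)
print({k: round(v, 4) for k, v in agg.items()})

mol = data.samples[0].system
b = pot.predict(mol)
print(f"U_total = {b.u_total:.4f} eV "
      f"(local {b.u_local:.4f}, coulomb {b.u_coul:.4f}, "
      f"dispersion {b.u_disp:.4f})")
print("charges:", np.round(b.charges, 3), "sum =", round(b.charges.sum(), 6))
```

prints (seeds fixed; numbers from this run, a few minutes on one CPU):

    {'energy_mae': 0.1203, 'energy_rmse': 0.1762, 'charge_rmse': 0.0681,
     'force_mae': 0.2617, 'force_mae_rms': 0.3404, 'force_rmse': 0.3725}
    U_total = -31.9846 eV (local -31.0508, coulomb -0.2395, dispersion -0.6942)
    charges: [-0.125  0.175  0.035 -0.024 -0.079  0.008  0.019  0.007  0.012 -0.028] sum = -0.0

Energy MAE is per molecule (eV), force MAE per component (eV/Å), charge
RMSE in e; this short demonstration run is far from converged — the
errors keep falling with longer schedules (see ``docs/methods.md``).
Charges sum to the exact net charge by construction.  A command-line interface mirrors the library
(`aimpot synth | train | predict | distill | optimize | md | scan`).

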