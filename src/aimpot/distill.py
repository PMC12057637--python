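"""Teacher→student data distillation and diversity selection.

Distillation grows a small student training set from a large labeled
teacher set: train on an initial random draw, then repeatedly scan the
teacher (molecules sorted smallest to largest) for samples whose energy
*or* force error exceeds ``threshold_factor`` × the corresponding current
training error, add up to ``n_add`` of them, and continue training from
the previous weights.  The loop ends when a full scan selects nothing (or
at ``max_rounds``), after which an ensemble is retrained from scratch on
the student set — its member disagreement is the query-by-committee
uncertainty score.

"Training error" is the per-channel MAE on the current student set:
energy as mean |ΔE|/sqrt(N) (eV), force as the mean per-sample RMS
component error (eV/Å).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .core import init_params
from .system import Dataset
from .training import TrainConfig, evaluate, train


@dataclass
class DistillConfig:
    n_init: int = 1000
    n_add: int = 1000
    threshold_factor: float = 3.0
    max_rounds: int = 20
    ensemble_size: int = 4
    seed: int = 0
    epochs_initial: int | None = None     # default: train config epochs
    epochs_per_round: int | None = None
    epochs_final: int | None = None

    def __post_init__(self):
        if self.n_init < 1 or self.n_add < 1:
            raise ValueError("n_init and n_add must be >= 1")
        if self.threshold_factor <= 0:
            raise ValueError("threshold_factor must be positive")


@dataclass
class DistillState:
    student_ids: list = field(default_factory=list)
    rounds: list = field(default_factory=list)   # append-only per-round log


def _train_errors(potential, student: Dataset, batch_size=256):
    table, _ = evaluate(potential, student, batch_size=batch_size)
    return (float(table["abs_de_scaled"].mean()),
            float(table["force_rms"].mean()))


def distill(teacher: Dataset, potential, config: DistillConfig,
            train_config: TrainConfig | None = None):
    """Run the distillation loop.

    Returns ``(student Dataset, ensemble member potentials, DistillState)``.
    ``potential`` provides the architecture/physics configuration; its
    parameters are (re)initialized for the round-0 fit.
    """
    train_config = train_config or TrainConfig()
    if len(teacher) < config.n_init:
        raise ValueError("teacher smaller than n_init")
    rng = np.random.default_rng(config.seed)
    state = DistillState()

    ids = rng.choice(len(teacher), size=config.n_init, replace=False)
    state.student_ids = sorted(int(i) for i in ids)
    scan_order = np.lexsort((np.arange(len(teacher)), teacher.sizes()))

    def _cfg(epochs, seed_offset):
        cfg = TrainConfig(**{**train_config.__dict__})
        if epochs is not None:
            cfg.max_epochs = epochs
        cfg.seed = train_config.seed + seed_offset
        return cfg

    student = teacher[state.student_ids]
    potential, _ = train(student, potential,
                         _cfg(config.epochs_initial, 0))

    for rnd in range(config.max_rounds):
        e_err, f_err = _train_errors(potential, student)
        e_thr = config.threshold_factor * e_err
        f_thr = config.threshold_factor * f_err
        in_student = np.zeros(len(teacher), dtype=bool)
        in_student[state.student_ids] = True
        candidates = [int(i) for i in scan_order if not in_student[i]]
        selected, scanned = [], 0
        chunk = 4096
        for k in range(0, len(candidates), chunk):
            ids_chunk = candidates[k:k + chunk]
            table, _ = evaluate(potential, teacher[ids_chunk])
            scanned += len(ids_chunk)
            hits = table[(table["abs_de_scaled"] > e_thr)
                         | (table["force_rms"] > f_thr)]
            for local in hits["index"]:
                selected.append(ids_chunk[int(local)])
                if len(selected) >= config.n_add:
                    break
            if len(selected) >= config.n_add:
                break
        state.rounds.append({
            "round": rnd, "energy_err": e_err, "force_err": f_err,
            "scanned": scanned, "selected": len(selected),
            "student_size": len(state.student_ids)})
        if not selected:
            break
        state.student_ids = sorted(state.student_ids + selected)
        student = teacher[state.student_ids]
        potential, _ = train(student, potential,
                             _cfg(config.epochs_per_round, rnd + 1))

    members = []
    for m in range(config.ensemble_size):
        from .potential import NeuralPotential
        cfg_m = potential.config.__class__.from_dict(potential.config.to_dict())
        cfg_m.seed = potential.config.seed + 1000 + m
        member = NeuralPotential(params=init_params(cfg_m), config=cfg_m,
                                 coulomb=potential.coulomb, d3=potential.d3,
                                 long_range_cutoff=potential.long_range_cutoff)
        member, _ = train(student, member,
                          _cfg(config.epochs_final, 100 + m))
        members.append(member)
    return student, members, state


# ---------------------------------------------------------------------------
# atomic-environment hashing and diversity selection
# ---------------------------------------------------------------------------

def _bond_graph(system):
    if system.bonds is not None:
        return system.bonds
    # fall back to covalent-radius bonds
    from .units import COVALENT_RADII
    rc = np.array([COVALENT_RADII[int(z)] for z in system.atomic_numbers])
    d = np.linalg.norm(system.displacements(), axis=-1)
    np.fill_diagonal(d, np.inf)
    thr = 1.25 * (rc[:, None] + rc[None, :])
    ii, jj = np.nonzero((d < thr) & (np.arange(len(rc))[:, None]
                                     < np.arange(len(rc))[None, :]))
    return np.stack([ii, jj], axis=1)


def env_hash(system, bonds=None) -> dict:
    """Stable per-heavy-atom environment hashes.

    The hashed descriptor is (Z, number of attached hydrogens, total
    neighbor count) together with the multiset of the same triple over the
    bonded neighbors.  Identical local environments give identical hashes;
    hashes are deterministic across processes (md5-based, not the salted
    builtin ``hash``).  Returns ``{atom_index: hash_int}``.
    """
    bonds = bonds if bonds is not None else _bond_graph(system)
    n = system.n_atoms
    z = system.atomic_numbers
    adj = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(int(j))
        adj[j].append(int(i))
    triple = []
    for i in range(n):
        nh = sum(1 for j in adj[i] if z[j] == 1)
        triple.append((int(z[i]), nh, len(adj[i])))
    out = {}
    for i in range(n):
        if z[i] == 1:
            continue
        desc = (triple[i], tuple(sorted(triple[j] for j in adj[i])))
        digest = hashlib.md5(repr(desc).encode()).hexdigest()[:16]
        out[i] = int(digest, 16)
    return out


def diversity_select(systems, hashes=None, k: int = 10) -> list:
    """Pick up to ``k`` molecules per element carrying the corpus-rarest
    atomic environments; de-duplicated across elements.

    ``hashes``: optional precomputed ``env_hash`` dicts (one per system).
    Ties break deterministically by (frequency, hash value, molecule id).
    """
    if hashes is None:
        hashes = [env_hash(s) for s in systems]
    freq = {}
    for h in hashes:
        for v in h.values():
            freq[v] = freq.get(v, 0) + 1
    chosen = []
    seen_structures = set()          # uniqueness by environment multiset
    elements = sorted({int(z) for s in systems
                       for z in s.atomic_numbers if z != 1})
    for elem in elements:
        ranked = []
        for mid, (s, h) in enumerate(zip(systems, hashes)):
            vals = [v for i, v in h.items()
                    if int(s.atomic_numbers[i]) == elem]
            if not vals:
                continue
            best = min((freq[v], v) for v in vals)
            ranked.append((best[0], best[1], mid))
        ranked.sort()
        for _, _, mid in ranked[:k]:
            sig = tuple(sorted(hashes[mid].values()))
            if sig not in seen_structures:
                seen_structures.add(sig)
                chosen.append(mid)
    return sorted(chosen)
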