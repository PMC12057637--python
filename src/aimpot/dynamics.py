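"""Simulation drivers: geometry optimization, relaxed torsion scans,
NVT/NVE molecular dynamics and self-diffusion analysis.

All drivers speak to any object exposing
``energy_forces(system) -> (energy eV, forces (N,3) eV/Å)`` — both the
neural potential and the toy reference potential do.

MD integrates velocity Verlet (masses in amu, time in fs); the NVT
thermostat is stochastic velocity rescaling (canonical sampling through
a single global rescaling factor with the exact Ornstein-Uhlenbeck
propagator for the kinetic energy), with the center-of-mass momentum and,
for isolated systems, the net angular momentum zeroed at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import MolecularSystem
from .units import ACC_UNIT, KB


@dataclass
class OptResult:
    system: MolecularSystem
    converged: bool
    n_steps: int
    fmax: float
    energy_history: list = field(default_factory=list)


@dataclass
class Trajectory:
    coords: np.ndarray        # (n_frames, N, 3) unwrapped, Å
    velocities: np.ndarray    # (n_frames, N, 3) Å/fs
    epot: np.ndarray          # (n_frames,) eV
    ekin: np.ndarray          # (n_frames,) eV
    temperature: np.ndarray   # (n_frames,) K
    times: np.ndarray         # (n_frames,) fs
    timestep: float
    thermostat: dict = field(default_factory=dict)

    @property
    def etotal(self) -> np.ndarray:
        return self.epot + self.ekin


# ---------------------------------------------------------------------------
# FIRE
# ---------------------------------------------------------------------------

_FIRE = dict(dt_start=0.1, dt_max=1.0, n_min=5, f_inc=1.1, f_dec=0.5,
             alpha_start=0.1, f_alpha=0.99, max_disp=0.2)


def _fire_single(potential, system, fmax, max_steps, p):
    coords = system.coords.copy()
    work = system.copy()
    v = np.zeros_like(coords)
    dt, alpha, n_pos = p["dt_start"], p["alpha_start"], 0
    history = []
    work.coords = coords
    e, f = potential.energy_forces(work)
    history.append(e)
    fnorm = np.abs(f).max()
    steps = 0
    while fnorm >= fmax and steps < max_steps:
        power = float(np.vdot(f, v))
        if power > 0:
            n_pos += 1
            if n_pos > p["n_min"]:
                dt = min(dt * p["f_inc"], p["dt_max"])
                alpha *= p["f_alpha"]
        else:
            v[:] = 0.0
            dt *= p["f_dec"]
            alpha = p["alpha_start"]
            n_pos = 0
        v = v + dt * f
        vn, fn = np.linalg.norm(v), np.linalg.norm(f)
        if fn > 0:
            v = (1.0 - alpha) * v + alpha * vn * f / fn
        step = dt * v
        slen = np.abs(step).max()
        if slen > p["max_disp"]:
            step *= p["max_disp"] / slen
        coords = coords + step
        work.coords = coords
        e, f = potential.energy_forces(work)
        history.append(e)
        fnorm = np.abs(f).max()
        steps += 1
    return OptResult(system=system.copy(coords=coords),
                     converged=bool(fnorm < fmax), n_steps=steps,
                     fmax=float(fnorm), energy_history=history)


def optimize_fire(potential, systems, fmax: float = 5e-3,
                  max_steps: int = 1000, **overrides):
    """Batched FIRE relaxation.

    Every batch member follows exactly the per-system FIRE update
    sequence (converged members freeze while the rest continue), so the
    batched results are identical to independent runs.  Accepts a single
    system or a list; always returns a list of :class:`OptResult`.
    """
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    single = isinstance(systems, MolecularSystem)
    systems = [systems] if single else list(systems)
    p = {**_FIRE, **overrides}
    return [_fire_single(potential, s, fmax, max_steps, p) for s in systems]


# ---------------------------------------------------------------------------
# L-BFGS
# ---------------------------------------------------------------------------

def optimize_lbfgs(potential, system, fmax: float = 5e-3,
                   max_steps: int = 1000, max_disp: float = 0.02,
                   memory: int = 10, h0: float = 1.0 / 70.0) -> OptResult:
    """Limited-memory BFGS with a hard per-step displacement cap (Å)."""
    if fmax <= 0:
        raise ValueError("fmax must be positive")
    work = system.copy()
    x = work.coords.ravel().copy()
    s_hist, y_hist, rho = [], [], []
    history = []
    work.coords = x.reshape(-1, 3)
    e, f = potential.energy_forces(work)
    g = -f.ravel()
    history.append(e)
    steps = 0
    while np.abs(f).max() >= fmax and steps < max_steps:
        q = g.copy()
        alphas = []
        for s, y, r in zip(reversed(s_hist), reversed(y_hist),
                           reversed(rho)):
            a = r * np.dot(s, q)
            alphas.append(a)
            q -= a * y
        gamma = h0
        if y_hist:
            yy = np.dot(y_hist[-1], y_hist[-1])
            if yy > 1e-12:
                gamma = np.dot(s_hist[-1], y_hist[-1]) / yy
        z = gamma * q
        for (s, y, r), a in zip(zip(s_hist, y_hist, rho),
                                reversed(alphas)):
            b = r * np.dot(y, z)
            z += s * (a - b)
        step = -z
        cap = np.abs(step.reshape(-1, 3)).max()
        if cap > max_disp:
            step *= max_disp / cap
        x_new = x + step
        work.coords = x_new.reshape(-1, 3)
        e, f_new = potential.energy_forces(work)
        g_new = -f_new.ravel()
        s_vec, y_vec = x_new - x, g_new - g
        sy = np.dot(s_vec, y_vec)
        if sy > 1e-10:
            s_hist.append(s_vec)
            y_hist.append(y_vec)
            rho.append(1.0 / sy)
            if len(s_hist) > memory:
                s_hist.pop(0)
                y_hist.pop(0)
                rho.pop(0)
        x, g, f = x_new, g_new, f_new
        history.append(e)
        steps += 1
    return OptResult(system=system.copy(coords=x.reshape(-1, 3)),
                     converged=bool(np.abs(f).max() < fmax),
                     n_steps=steps, fmax=float(np.abs(f).max()),
                     energy_history=history)


# ---------------------------------------------------------------------------
# dihedral tools and relaxed torsion scan
# ---------------------------------------------------------------------------

def dihedral_angle(coords, quad):
    i, j, k, l = quad
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-8 or np.linalg.norm(n2) < 1e-8:
        raise ValueError("collinear atoms: dihedral undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


def _dihedral_gradient(coords, quad, h=1e-6):
    g = np.zeros_like(coords)
    for a in quad:
        for ax in range(3):
            cp = coords.copy()
            cp[a, ax] += h
            cm = coords.copy()
            cm[a, ax] -= h
            dp = dihedral_angle(cp, quad)
            dm = dihedral_angle(cm, quad)
            diff = np.arctan2(np.sin(dp - dm), np.cos(dp - dm))
            g[a, ax] = diff / (2 * h)
    return g


class _ProjectedPotential:
    """Wraps a potential, removing the force component along a dihedral."""

    def __init__(self, potential, quad):
        self.potential = potential
        self.quad = quad

    def energy_forces(self, system):
        e, f = self.potential.energy_forces(system)
        mode = _dihedral_gradient(system.coords, self.quad)
        nrm = np.linalg.norm(mode)
        if nrm > 1e-10:
            mode = mode / nrm
            f = f - np.vdot(f, mode) * mode
        return e, f


def _set_dihedral(system, quad, target):
    """Rotate l's side about the j-k bond so the dihedral equals target."""
    i, j, k, l = quad
    cur = dihedral_angle(system.coords, quad)
    delta = np.arctan2(np.sin(target - cur), np.cos(target - cur))
    side = _side_of_bond(system, j, k)
    axis = system.coords[k] - system.coords[j]
    axis = axis / np.linalg.norm(axis)
    origin = system.coords[k]
    x = system.coords[side] - origin
    cosd, sind = np.cos(delta), np.sin(delta)
    rot = (x * cosd + np.cross(axis, x) * sind
           + np.outer(x @ axis, axis) * (1 - cosd))
    coords = system.coords.copy()
    coords[side] = origin + rot
    return system.copy(coords=coords)


def _side_of_bond(system, j, k):
    if system.bonds is None:
        raise ValueError("torsion scan needs a bond graph")
    n = system.n_atoms
    adj = [[] for _ in range(n)]
    for a, b in system.bonds:
        adj[a].append(int(b))
        adj[b].append(int(a))
    seen = {int(k), int(j)}
    stack = [int(k)]
    out = []
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if nb not in seen:
                seen.add(nb)
                out.append(nb)
                stack.append(nb)
    return sorted(out)


def torsion_scan(potential, system, quad, step_deg: float = 10.0,
                 fmax: float = 5e-3, max_steps: int = 200):
    """Relaxed torsion profile: constrain the dihedral at each increment
    over 360° and relax everything else.

    Returns ``(angles_rad, energies_eV)`` with ``360/step`` points.
    """
    n_pts = int(round(360.0 / step_deg))
    start = dihedral_angle(system.coords, quad)
    proj = _ProjectedPotential(potential, quad)
    angles, energies = [], []
    for p in range(n_pts):
        target = start + np.deg2rad(step_deg) * p
        # each point starts from the input geometry rotated to the target,
        # so the profile is exactly 360°-periodic (no relaxation hysteresis)
        current = _set_dihedral(system.copy(), quad, target)
        for _ in range(4):     # relax / re-impose cycles
            res = optimize_fire(proj, current, fmax=fmax,
                                max_steps=max_steps // 4)[0]
            current = _set_dihedral(res.system, quad, target)
        e, _ = potential.energy_forces(current)
        angles.append(target)
        energies.append(e)
    return np.array(angles), np.array(energies)


# ---------------------------------------------------------------------------
# molecular dynamics
# ---------------------------------------------------------------------------

def _zero_momenta(system, v, masses, angular=True):
    v = v - np.average(v, axis=0, weights=masses)
    if angular and not (system.pbc is not None and system.pbc.any()):
        x = system.coords - system.center_of_mass()
        L = np.sum(masses[:, None] * np.cross(x, v), axis=0)
        inertia = np.zeros((3, 3))
        for m, xi in zip(masses, x):
            inertia += m * ((xi @ xi) * np.eye(3) - np.outer(xi, xi))
        try:
            omega = np.linalg.solve(inertia, L)
            v = v - np.cross(omega, x)
        except np.linalg.LinAlgError:
            pass
    return v


def maxwell_boltzmann_velocities(system, temperature, rng,
                                 zero_angular=True):
    masses = system.masses
    sigma = np.sqrt(KB * temperature / masses) * np.sqrt(ACC_UNIT)
    v = rng.normal(size=(system.n_atoms, 3)) * sigma[:, None]
    return _zero_momenta(system, v, masses, angular=zero_angular)


def _kinetic(masses, v):
    return 0.5 * float(np.sum(masses[:, None] * v * v)) / ACC_UNIT


def _ndof(system):
    n = 3 * system.n_atoms - 3
    if not (system.pbc is not None and system.pbc.any()) \
            and system.n_atoms > 2:
        n -= 3
    return max(n, 1)


def _bussi_factor(kin, kin_target, ndof, c, rng):
    """Squared velocity-rescaling factor of the canonical thermostat."""
    r1 = rng.normal()
    rsum = float(rng.chisquare(ndof - 1)) if ndof > 1 else 0.0
    ratio = kin_target / (ndof * kin)
    a2 = c + (1.0 - c) * ratio * (r1 * r1 + rsum) \
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * ratio)
    return np.sqrt(max(a2, 1e-12))


def _run_md(potential, system, dt, n_steps, temperature=None, tau=100.0,
            seed=0, v0=None, sample_every=1):
    rng = np.random.default_rng(seed)
    masses = system.masses
    work = system.copy()
    x = work.coords.copy()
    if v0 is not None:
        v = np.array(v0, dtype=float)
    elif temperature is not None:
        v = maxwell_boltzmann_velocities(system, temperature, rng)
    else:
        v = np.zeros_like(x)
    work.coords = x
    e, f = potential.energy_forces(work)
    if not np.all(np.isfinite(f)):
        raise FloatingPointError("non-finite forces at frame 0")
    ndof = _ndof(system)
    c = np.exp(-dt / tau) if temperature is not None else None
    frames = {k: [] for k in
              ("coords", "velocities", "epot", "ekin", "temp", "times")}

    def record(step):
        kin = _kinetic(masses, v)
        frames["coords"].append(x.copy())
        frames["velocities"].append(v.copy())
        frames["epot"].append(e)
        frames["ekin"].append(kin)
        frames["temp"].append(2.0 * kin / (ndof * KB))
        frames["times"].append(step * dt)

    record(0)
    a = f / masses[:, None] * ACC_UNIT
    for step in range(1, n_steps + 1):
        if temperature is not None:
            kin = _kinetic(masses, v)
            if kin > 0:
                v *= _bussi_factor(kin, 0.5 * ndof * KB * temperature,
                                   ndof, c, rng)
        v_half = v + 0.5 * dt * a
        x = x + dt * v_half
        work.coords = x
        e, f = potential.energy_forces(work)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite forces at step {step}")
        a = f / masses[:, None] * ACC_UNIT
        v = v_half + 0.5 * dt * a
        if step % sample_every == 0 or step == n_steps:
            record(step)
    return Trajectory(
        coords=np.array(frames["coords"]),
        velocities=np.array(frames["velocities"]),
        epot=np.array(frames["epot"]), ekin=np.array(frames["ekin"]),
        temperature=np.array(frames["temp"]),
        times=np.array(frames["times"]), timestep=dt,
        thermostat=({"kind": "bussi", "T": temperature, "tau": tau,
                     "seed": seed} if temperature is not None
                    else {"kind": "none"}))


def md_nvt(potential, system, temperature: float, dt: float = 0.5,
           tau: float = 100.0, n_steps: int = 1000, seed: int = 0,
           sample_every: int = 1) -> Trajectory:
    """Canonical MD with the stochastic velocity-rescaling thermostat.

    ``dt`` and ``tau`` in fs.  Initial velocities are Maxwell–Boltzmann at
    the set temperature with net linear (and, isolated, angular) momentum
    zeroed; the run is reproducible for a fixed seed.
    """
    if dt <= 0 or tau <= 0:
        raise ValueError("dt and tau must be positive")
    return _run_md(potential, system, dt, n_steps, temperature=temperature,
                   tau=tau, seed=seed, sample_every=sample_every)


def md_nve(potential, system, dt: float = 0.5, n_steps: int = 1000,
           v0=None, temperature: float | None = None, seed: int = 0,
           sample_every: int = 1) -> Trajectory:
    """Microcanonical velocity-Verlet run (no thermostat).

    Initial velocities: ``v0`` if given, else Maxwell–Boltzmann at
    ``temperature`` (seeded), else zero.  Total-energy drift is the
    headline statistic for force correctness.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if v0 is None and temperature is not None:
        rng = np.random.default_rng(seed)
        v0 = maxwell_boltzmann_velocities(system, temperature, rng)
    return _run_md(potential, system, dt, n_steps, temperature=None,
                   v0=v0, sample_every=sample_every)


# ---------------------------------------------------------------------------
# mean-squared displacement / self-diffusion
# ---------------------------------------------------------------------------

def _msd_all_origins(x: np.ndarray) -> np.ndarray:
    """Exact all-time-origin MSD via the FFT autocorrelation identity.

    ``x``: (T, n_particles, 3) unwrapped positions.  Returns msd (T,)
    averaged over particles, summed over Cartesian components.
    """
    T = len(x)
    nfft = 1 << (2 * T - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:T].real
    counts = (T - np.arange(T))[:, None, None]
    acf = acf / counts                                  # <x(t)·x(t+L)>
    sq = np.sum(x * x, axis=-1)                         # (T, W)
    csum = np.cumsum(sq, axis=0)
    total = csum[-1]
    # S1(L) = (1/(T-L)) Σ_t [|x(t)|² + |x(t+L)|²]
    lags = np.arange(T)
    lead = csum[T - 1 - lags]                           # Σ_{t<=T-1-L} sq
    tail = total[None, :] - np.concatenate(
        [np.zeros((1, sq.shape[1])), csum[:-1]])        # Σ_{t>=L} sq
    s1 = (lead + tail) / (T - lags)[:, None]
    out = (s1 - 2.0 * np.sum(acf, axis=-1)).mean(axis=1)
    out[0] = 0.0          # identically zero; clear FFT roundoff
    return out


def self_diffusion(trajectory: Trajectory, fit_window=(0.02, 0.25)):
    """Einstein self-diffusion coefficient from the MSD slope.

    MSD(t) is averaged over particles and *all* time origins (FFT
    algorithm); D = slope/6 from a least-squares fit over the stated
    fractional lag window (short lags, where the origin average is well
    conditioned).  Returns ``(D in m²/s, (lag_times_fs, msd_Å²))``.
    """
    x = trajectory.coords
    n_frames = len(x)
    if n_frames < 8:
        raise ValueError("trajectory too short for an MSD fit")
    msd = _msd_all_origins(np.asarray(x, dtype=np.float64))
    lags = np.arange(n_frames) * (trajectory.times[1] - trajectory.times[0])
    lo = max(1, int(fit_window[0] * n_frames))
    hi = max(int(fit_window[1] * n_frames), lo + 2)
    if hi > n_frames:
        raise ValueError("fit window outside the trajectory")
    slope = np.polyfit(lags[lo:hi], msd[lo:hi], 1)[0]   # Å²/fs
    d_si = slope / 6.0 * 1e-5                            # m²/s
    return d_si, (lags, msd)
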