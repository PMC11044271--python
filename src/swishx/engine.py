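"""Reduced-unit toy particle engine with a lambda-scaled Hamiltonian.

The engine implements the scaled-Hamiltonian idea behind SWISH on small
particle systems: nonbonded energy is decomposed into water-water (ww),
water-solute (ws) and solute-solute (ss) buckets and the ws bucket —
restricted to solvent <-> apolar-solute pairs — is multiplied by a scaling
factor lambda, so that

    U_total(lambda) = U_ww + lambda * U_ws + U_ss .

Units are reduced throughout (epsilon = sigma = k_B = mass = 1).  The pair
potential is a truncated-and-shifted 12-6 Lennard-Jones form with per-role-
pair parameters.  Dynamics is BAOAB Langevin.  Two restraints used by the
simulation protocols are provided: a contact-map upper wall (guards against
"unfolding" at high lambda) and a half-harmonic interprobe repulsion
(prevents probe phase separation).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .switching import rational_switch, rational_switch_deriv

__all__ = [
    "ROLES",
    "ROLE_IDS",
    "PairTable",
    "ParticleSystem",
    "ScaledHamiltonian",
    "ContactWall",
    "InterprobeRepulsion",
    "RestraintSet",
    "GateDoubleWell",
    "Confinement",
    "LangevinParams",
    "LangevinState",
    "OverlapError",
    "compute_scaled_energy",
    "compute_forces",
    "energy_and_forces",
    "langevin_step",
    "contact_map_cv",
    "upper_wall_energy",
    "GatedCavitySpec",
    "build_gated_cavity_system",
]

# particle roles; the ws (scaled) bucket is solvent <-> solute_apolar only
ROLES = ("solvent", "solute_apolar", "solute_polar", "probe")
ROLE_IDS = {name: i for i, name in enumerate(ROLES)}
SOLVENT, SOLUTE_APOLAR, SOLUTE_POLAR, PROBE = range(4)

# pairs closer than this fraction of sigma are treated as unphysical overlap
HARD_CORE_FRACTION = 0.35
# energies beyond this magnitude abort integration
ENERGY_BLOWUP_BOUND = 1.0e10


class OverlapError(RuntimeError):
    """Raised when two particles sit inside the hard-core floor."""


# ---------------------------------------------------------------------------
# pair parameters


@dataclass
class PairTable:
    """Symmetric per-role-pair Lennard-Jones parameters.

    ``eps`` and ``sigma`` are 4x4 symmetric matrices indexed by role id;
    ``cutoff`` defaults to 2.5 * sigma elementwise.
    """

    eps: np.ndarray
    sigma: np.ndarray
    cutoff: np.ndarray

    @classmethod
    def uniform(cls, eps: float = 1.0, sigma: float = 1.0, cutoff_factor: float = 2.5):
        e = np.full((4, 4), float(eps))
        s = np.full((4, 4), float(sigma))
        return cls(eps=e, sigma=s, cutoff=cutoff_factor * s)

    @classmethod
    def from_role_values(
        cls,
        eps: dict[tuple[str, str], float],
        sigma: Optional[dict[tuple[str, str], float]] = None,
        default_eps: float = 1.0,
        default_sigma: float = 1.0,
        cutoff_factor: float = 2.5,
    ):
        t = cls.uniform(default_eps, default_sigma, cutoff_factor)
        for (a, b), v in eps.items():
            i, j = ROLE_IDS[a], ROLE_IDS[b]
            t.eps[i, j] = t.eps[j, i] = v
        if sigma:
            for (a, b), v in sigma.items():
                i, j = ROLE_IDS[a], ROLE_IDS[b]
                t.sigma[i, j] = t.sigma[j, i] = v
        t.cutoff = cutoff_factor * t.sigma
        return t

    def validate(self) -> None:
        for name, m in (("eps", self.eps), ("sigma", self.sigma), ("cutoff", self.cutoff)):
            if m.shape != (4, 4):
                raise ValueError(f"PairTable.{name} must be 4x4")
            if not np.allclose(m, m.T):
                raise ValueError(f"PairTable.{name} must be symmetric under role swap")
        if np.any(self.cutoff <= 0):
            raise ValueError("PairTable cutoff must be positive")

    def shift(self) -> np.ndarray:
        """Potential value at the cutoff, subtracted to make u continuous."""
        sr6 = (self.sigma / self.cutoff) ** 6
        return 4.0 * self.eps * (sr6**2 - sr6)


# ---------------------------------------------------------------------------
# external potential terms used by the gated-cavity toy


@dataclass
class GateDoubleWell:
    """Quartic double well on the x coordinate of one particle.

    U(x) = barrier * (s^2 - 1)^2 with s = (x - x_mid)/half_sep, minima at
    s = +-1 (closed at x_mid - half_sep, open at x_mid + half_sep), barrier
    height `barrier` at s = 0, plus harmonic walls outside s in [s_lo, s_hi].
    The walls default to symmetric about the barrier top so that a
    zero-barrier gate has exactly equal open/closed phase-space volume.
    """

    index: int
    barrier: float
    x_mid: float
    half_sep: float
    wall_k: float = 50.0
    s_lo: float = -2.0
    s_hi: float = 2.0

    def energy_force(self, x: float) -> tuple[float, float]:
        s = (x - self.x_mid) / self.half_sep
        u = self.barrier * (s * s - 1.0) ** 2
        f = -4.0 * self.barrier * s * (s * s - 1.0) / self.half_sep
        if s < self.s_lo:
            d = (s - self.s_lo) * self.half_sep
            u += 0.5 * self.wall_k * d * d
            f += -self.wall_k * d
        elif s > self.s_hi:
            d = (s - self.s_hi) * self.half_sep
            u += 0.5 * self.wall_k * d * d
            f += -self.wall_k * d
        return u, f


@dataclass
class Confinement:
    """Half-harmonic spherical confinement acting on mobile particles."""

    k: float
    radius: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))


# ---------------------------------------------------------------------------
# particle system


@dataclass
class ParticleSystem:
    """A toy system: coordinates, roles, pair parameters and external terms.

    ``box`` is either None (non-periodic) or three box lengths (minimum-image
    periodicity).  ``frozen`` particles are excluded from integration; their
    mutual interactions contribute a constant energy.
    """

    positions: np.ndarray
    roles: np.ndarray
    pair_params: PairTable
    masses: np.ndarray = None
    box: Optional[np.ndarray] = None
    frozen: np.ndarray = None
    tether_k: Optional[np.ndarray] = None  # (N,3) per-coordinate spring constants
    tether_ref: Optional[np.ndarray] = None
    gate: Optional[GateDoubleWell] = None
    confinement: Optional[Confinement] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if isinstance(self.roles, (list, tuple)) and self.roles and isinstance(self.roles[0], str):
            try:
                self.roles = np.array([ROLE_IDS[r] for r in self.roles], dtype=np.int64)
            except KeyError as e:
                raise ValueError(f"unknown particle role: {e.args[0]!r}") from None
        else:
            self.roles = np.asarray(self.roles, dtype=np.int64)
        if np.any((self.roles < 0) | (self.roles > 3)):
            raise ValueError("unknown particle role id")
        n = len(self.positions)
        if len(self.roles) != n:
            raise ValueError("roles length mismatch")
        if self.masses is None:
            self.masses = np.ones(n)
        else:
            self.masses = np.asarray(self.masses, dtype=float)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        self.pair_params.validate()

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def displacement(self, positions: np.ndarray) -> np.ndarray:
        """All-pairs displacement vectors r_i - r_j (minimum image if periodic)."""
        d = positions[:, None, :] - positions[None, :, :]
        if self.box is not None:
            d -= self.box * np.round(d / self.box)
        return d


@dataclass
class ScaledHamiltonian:
    """Energy decomposition of one configuration under scaling factor lambda."""

    lambda_factor: float
    u_ww: float
    u_ws: float
    u_ss: float
    restraint_energy: float = 0.0
    external_energy: float = 0.0

    @property
    def total_nonbonded(self) -> float:
        return self.u_ww + self.lambda_factor * self.u_ws + self.u_ss

    @property
    def total(self) -> float:
        return self.total_nonbonded + self.restraint_energy + self.external_energy


# ---------------------------------------------------------------------------
# restraints


@dataclass
class ContactWall:
    """Upper wall on a contact-map CV: E = 0.5*kappa*(CV - w_max)^2 for CV > w_max."""

    pairs: Sequence[tuple[int, int]]
    r0: float = 0.8
    n_sw: int = 4
    m_sw: int = 8
    w_max: float = np.inf
    kappa: float = 0.0


@dataclass
class InterprobeRepulsion:
    """Half-harmonic probe-probe repulsion: E = k_rep*(d_rep - r)^2 for r < d_rep."""

    d_rep: float = 1.5
    k_rep: float = 10.0


@dataclass
class RestraintSet:
    contact_wall: Optional[ContactWall] = None
    interprobe_repulsion: Optional[InterprobeRepulsion] = None


def contact_map_cv(system: ParticleSystem, wall: ContactWall) -> float:
    """Sum of switching values over the wall's particle pairs."""
    pairs = np.asarray(wall.pairs, dtype=int)
    if pairs.size == 0:
        raise ValueError("contact_map_cv: empty pair list")
    d = system.positions[pairs[:, 0]] - system.positions[pairs[:, 1]]
    if system.box is not None:
        d -= system.box * np.round(d / system.box)
    r = np.linalg.norm(d, axis=1)
    return float(np.sum(rational_switch(r, wall.r0, wall.n_sw, wall.m_sw)))


def upper_wall_energy(cv: float, w_max: float, kappa: float) -> float:
    """Half-harmonic upper wall; zero at or below the wall value."""
    if kappa < 0:
        raise ValueError("upper_wall_energy: kappa must be >= 0")
    if cv <= w_max:
        return 0.0
    return 0.5 * kappa * (cv - w_max) ** 2


# ---------------------------------------------------------------------------
# energies and forces (reference numpy path; the orchestrator uses the
# numba kernels in _kernels.py, which are cross-checked against this one)


def _pair_terms(system: ParticleSystem, positions: np.ndarray):
    """Pairwise LJ energies split by bucket plus force pair list."""
    n = len(positions)
    iu, ju = np.triu_indices(n, k=1)
    d = positions[iu] - positions[ju]
    if system.box is not None:
        d -= system.box * np.round(d / system.box)
    r2 = np.einsum("ij,ij->i", d, d)
    ri, rj = system.roles[iu], system.roles[ju]
    eps = system.pair_params.eps[ri, rj]
    sig = system.pair_params.sigma[ri, rj]
    rc = system.pair_params.cutoff[ri, rj]
    shift = system.pair_params.shift()[ri, rj]

    floor = (HARD_CORE_FRACTION * sig) ** 2
    bad = r2 < floor
    if np.any(bad):
        k = int(np.argmax(bad))
        raise OverlapError(
            f"particles {iu[k]} and {ju[k]} overlap: r = {np.sqrt(r2[k]):.4f} "
            f"< hard-core floor {HARD_CORE_FRACTION:.2f}*sigma = {np.sqrt(floor[k]):.4f}"
        )

    within = r2 < rc * rc
    sr6 = np.where(within, (sig * sig / np.where(within, r2, 1.0)) ** 3, 0.0)
    u = np.where(within, 4.0 * eps * (sr6 * sr6 - sr6) - shift, 0.0)
    # du/dr * (1/r), so that F_i = -du/dr * d_hat = -dudr_over_r * d
    dudr_over_r = np.where(
        within, -24.0 * eps * (2.0 * sr6 * sr6 - sr6) / np.where(within, r2, 1.0), 0.0
    )

    ww = (ri == SOLVENT) & (rj == SOLVENT)
    ws = ((ri == SOLVENT) & (rj == SOLUTE_APOLAR)) | (
        (ri == SOLUTE_APOLAR) & (rj == SOLVENT)
    )
    bucket = np.where(ww, 0, np.where(ws, 1, 2))
    return iu, ju, d, u, dudr_over_r, bucket


def compute_scaled_energy(
    system: ParticleSystem,
    lambda_factor: float,
    restraints: Optional[RestraintSet] = None,
) -> ScaledHamiltonian:
    """Decomposed nonbonded energy with the ws bucket scaled by lambda.

    Only solvent <-> apolar-solute pairs enter the scaled ws bucket; polar
    solute and probe interactions are never scaled.
    """
    if lambda_factor < 0:
        raise ValueError("lambda_factor must be >= 0")
    if not np.all(np.isfinite(system.positions)):
        raise ValueError("non-finite positions")
    _, _, _, u, _, bucket = _pair_terms(system, system.positions)
    u_ww = float(np.sum(u[bucket == 0]))
    u_ws = float(np.sum(u[bucket == 1]))
    u_ss = float(np.sum(u[bucket == 2]))
    restraint_e = 0.0
    if restraints is not None:
        restraint_e = _restraint_energy(system, system.positions, restraints)
    ext = _external_energy(system, system.positions)
    return ScaledHamiltonian(
        lambda_factor=float(lambda_factor),
        u_ww=u_ww,
        u_ws=u_ws,
        u_ss=u_ss,
        restraint_energy=restraint_e,
        external_energy=ext,
    )


def _restraint_energy(system, positions, restraints: RestraintSet) -> float:
    e = 0.0
    wall = restraints.contact_wall
    if wall is not None and len(wall.pairs) > 0 and np.isfinite(wall.w_max):
        tmp = replace_positions(system, positions)
        cv = contact_map_cv(tmp, wall)
        e += upper_wall_energy(cv, wall.w_max, wall.kappa)
    rep = restraints.interprobe_repulsion
    if rep is not None:
        probes = np.flatnonzero(system.roles == PROBE)
        for a in range(len(probes)):
            for b in range(a + 1, len(probes)):
                r = np.linalg.norm(positions[probes[a]] - positions[probes[b]])
                if r < rep.d_rep:
                    e += rep.k_rep * (rep.d_rep - r) ** 2
    return e


def _external_energy(system, positions) -> float:
    e = 0.0
    if system.tether_k is not None:
        d = positions - system.tether_ref
        e += 0.5 * float(np.sum(system.tether_k * d * d))
    if system.gate is not None:
        u, _ = system.gate.energy_force(positions[system.gate.index, 0])
        e += u
    if system.confinement is not None:
        c = system.confinement
        mobile = ~system.frozen
        r = np.linalg.norm(positions[mobile] - c.center, axis=1)
        over = np.maximum(r - c.radius, 0.0)
        e += 0.5 * c.k * float(np.sum(over * over))
    return e


def replace_positions(system: ParticleSystem, positions: np.ndarray) -> ParticleSystem:
    new = replace(system)
    new.positions = np.asarray(positions, dtype=float)
    return new


def energy_and_forces(
    system: ParticleSystem,
    lambda_factor: float,
    restraints: Optional[RestraintSet] = None,
    positions: Optional[np.ndarray] = None,
) -> tuple[ScaledHamiltonian, np.ndarray]:
    """Total energy and analytic forces F = -grad(U_total).

    The gradient covers the lambda-scaled nonbonded terms, both restraints
    and all external terms.
    """
    pos = system.positions if positions is None else np.asarray(positions, dtype=float)
    n = len(pos)
    iu, ju, d, u, dudr_over_r, bucket = _pair_terms(system, pos)
    scale = np.where(bucket == 1, lambda_factor, 1.0)
    fpair = -(scale * dudr_over_r)[:, None] * d  # force on particle iu from ju
    forces = np.zeros((n, 3))
    np.add.at(forces, iu, fpair)
    np.add.at(forces, ju, -fpair)

    u_ww = float(np.sum(u[bucket == 0]))
    u_ws = float(np.sum(u[bucket == 1]))
    u_ss = float(np.sum(u[bucket == 2]))

    restraint_e = 0.0
    if restraints is not None:
        wall = restraints.contact_wall
        if wall is not None and len(wall.pairs) > 0 and np.isfinite(wall.w_max):
            pairs = np.asarray(wall.pairs, dtype=int)
            dv = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            if system.box is not None:
                dv -= system.box * np.round(dv / system.box)
            r = np.linalg.norm(dv, axis=1)
            s = rational_switch(r, wall.r0, wall.n_sw, wall.m_sw)
            cv = float(np.sum(s))
            restraint_e += upper_wall_energy(cv, wall.w_max, wall.kappa)
            if cv > wall.w_max:
                dEdcv = wall.kappa * (cv - wall.w_max)
                dSdr = rational_switch_deriv(r, wall.r0, wall.n_sw, wall.m_sw)
                fw = -(dEdcv * dSdr / np.maximum(r, 1e-12))[:, None] * dv
                np.add.at(forces, pairs[:, 0], fw)
                np.add.at(forces, pairs[:, 1], -fw)
        rep = restraints.interprobe_repulsion
        if rep is not None:
            probes = np.flatnonzero(system.roles == PROBE)
            for a in range(len(probes)):
                for b in range(a + 1, len(probes)):
                    dv = pos[probes[a]] - pos[probes[b]]
                    r = float(np.linalg.norm(dv))
                    if r < rep.d_rep and r > 1e-12:
                        restraint_e += rep.k_rep * (rep.d_rep - r) ** 2
                        # dE/dr = -2 k (d_rep - r); force along +dv on particle a
                        fmag = 2.0 * rep.k_rep * (rep.d_rep - r) / r
                        forces[probes[a]] += fmag * dv
                        forces[probes[b]] -= fmag * dv

    ext = 0.0
    if system.tether_k is not None:
        dt_ = pos - system.tether_ref
        ext += 0.5 * float(np.sum(system.tether_k * dt_ * dt_))
        forces -= system.tether_k * dt_
    if system.gate is not None:
        g = system.gate
        ug, fg = g.energy_force(pos[g.index, 0])
        ext += ug
        forces[g.index, 0] += fg
    if system.confinement is not None:
        c = system.confinement
        mobile = ~system.frozen
        dc = pos[mobile] - c.center
        r = np.linalg.norm(dc, axis=1)
        over = np.maximum(r - c.radius, 0.0)
        ext += 0.5 * c.k * float(np.sum(over * over))
        with np.errstate(invalid="ignore", divide="ignore"):
            fmag = np.where(r > 1e-12, -c.k * over / np.maximum(r, 1e-12), 0.0)
        fc = np.zeros((n, 3))
        fc[mobile] = fmag[:, None] * dc
        forces += fc

    ham = ScaledHamiltonian(
        lambda_factor=float(lambda_factor),
        u_ww=u_ww,
        u_ws=u_ws,
        u_ss=u_ss,
        restraint_energy=restraint_e,
        external_energy=ext,
    )
    return ham, forces


def compute_forces(
    system: ParticleSystem,
    lambda_factor: float,
    restraints: Optional[RestraintSet] = None,
) -> np.ndarray:
    """Analytic forces -grad(total energy including restraints)."""
    _, f = energy_and_forces(system, lambda_factor, restraints)
    return f


# ---------------------------------------------------------------------------
# Langevin dynamics (BAOAB splitting)


@dataclass
class LangevinParams:
    timestep: float
    friction: float
    temperature: float
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class LangevinState:
    positions: np.ndarray
    velocities: np.ndarray
    rng: np.random.Generator
    forces: Optional[np.ndarray] = None
    potential: Optional[float] = None

    @classmethod
    def initialize(
        cls,
        system: ParticleSystem,
        params: LangevinParams,
        resample_velocities: bool = True,
    ) -> "LangevinState":
        rng = np.random.default_rng(params.seed)
        n = system.n_particles
        if resample_velocities:
            v = rng.standard_normal((n, 3)) * np.sqrt(
                params.temperature / system.masses[:, None]
            )
        else:
            v = np.zeros((n, 3))
        v[system.frozen] = 0.0
        return cls(positions=system.positions.copy(), velocities=v, rng=rng)


ForceFn = Callable[[np.ndarray], tuple[float, np.ndarray]]


def langevin_step(
    state: LangevinState,
    params: LangevinParams,
    force_fn: ForceFn,
    system: Optional[ParticleSystem] = None,
) -> LangevinState:
    """One BAOAB update.  ``force_fn(positions) -> (potential, forces)``.

    At zero friction the O-step is the identity and the scheme reduces to
    velocity Verlet.  Frozen particles (if ``system`` is given) do not move.
    Deterministic given the state's RNG stream.
    """
    dt = params.timestep
    masses = np.ones(len(state.positions)) if system is None else system.masses
    frozen = None if system is None else system.frozen
    inv_m = 1.0 / masses[:, None]

    if state.forces is None:
        u0, f0 = force_fn(state.positions)
        state.forces = f0
        state.potential = u0

    v = state.velocities + 0.5 * dt * state.forces * inv_m
    x = state.positions + 0.5 * dt * v
    c1 = np.exp(-params.friction * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    noise = state.rng.standard_normal(x.shape)
    v = c1 * v + c2 * np.sqrt(params.temperature * inv_m) * noise
    x = x + 0.5 * dt * v
    u, f = force_fn(x)
    if not np.isfinite(u) or abs(u) > ENERGY_BLOWUP_BOUND:
        raise RuntimeError(
            f"potential energy blow-up (|U| = {abs(u):.3g}); use a smaller timestep"
        )
    v = v + 0.5 * dt * f * inv_m
    if frozen is not None:
        x[frozen] = state.positions[frozen]
        v[frozen] = 0.0
        f = f.copy()
        f[frozen] = 0.0
    return LangevinState(positions=x, velocities=v, rng=state.rng, forces=f, potential=u)


# ---------------------------------------------------------------------------
# gated-cavity toy builder


@dataclass
class GatedCavitySpec:
    """Construction recipe for the cryptic-pocket toy.

    A frozen spherical shell of apolar particles encloses a cavity; a mobile
    apolar gate particle fills the cavity in the closed state and sits
    solvent-exposed outside the mouth in the open state, with a quartic
    double-well of height ``gate_barrier`` (in k_B T at T = 1) between the
    two.  Solvent (and optionally probe) particles surround the shell at low
    density; raising lambda increases solvent affinity for the apolar gate
    and cavity interior, tilting the system toward open.
    """

    shell_radius: float = 1.8
    n_shell: int = 60
    mouth_half_angle_deg: float = 35.0
    gate_barrier: float = 8.0
    gate_open_x: float = 3.0
    gate_tether_k: float = 20.0
    n_solvent: int = 24
    n_probe: int = 0
    eps_ww: float = 0.6
    eps_ws: float = 1.0
    eps_ss: float = 1.0
    eps_probe_solute: float = 1.2
    probe_sigma: float = 1.4
    confinement_radius: float = 4.0
    confinement_k: float = 10.0
    placement_min_dist: float = 0.95
    placement_retries: int = 4000
    seed: int = 0


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1
    )


def build_gated_cavity_system(spec: GatedCavitySpec) -> ParticleSystem:
    """Deterministically construct the gated-cavity toy from its spec."""
    rng = np.random.default_rng(spec.seed)

    # frozen shell with a mouth opening along +x
    pts = _fibonacci_sphere(spec.n_shell)
    keep = pts[:, 0] < np.cos(np.deg2rad(spec.mouth_half_angle_deg))
    shell = spec.shell_radius * pts[keep]
    n_shell = len(shell)

    gate = np.array([[0.0, 0.0, 0.0]])  # closed position: cavity center

    pair = PairTable.from_role_values(
        eps={
            ("solvent", "solvent"): spec.eps_ww,
            ("solvent", "solute_apolar"): spec.eps_ws,
            ("solute_apolar", "solute_apolar"): spec.eps_ss,
            ("probe", "solute_apolar"): spec.eps_probe_solute,
            ("probe", "solvent"): 0.5,
            ("probe", "probe"): 0.5,
        },
        sigma={
            ("probe", "probe"): spec.probe_sigma,
            ("probe", "solvent"): 0.5 * (1.0 + spec.probe_sigma),
            ("probe", "solute_apolar"): 0.5 * (1.0 + spec.probe_sigma),
        },
    )

    # random solvent/probe placement outside the shell, inside confinement
    n_free = spec.n_solvent + spec.n_probe
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_free:
        if tries > spec.placement_retries:
            raise RuntimeError(
                "build_gated_cavity_system: could not place particles without "
                "overlap within the retry budget"
            )
        tries += 1
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = spec.shell_radius + 1.0 + (spec.confinement_radius - spec.shell_radius - 1.0) * rng.random() ** (1 / 3)
        cand = r * u
        ok = all(np.linalg.norm(cand - p) >= spec.placement_min_dist for p in placed)
        if ok and np.linalg.norm(cand - gate[0]) >= spec.placement_min_dist:
            placed.append(cand)
    free = np.array(placed).reshape(n_free, 3) if n_free else np.zeros((0, 3))

    positions = np.concatenate([shell, gate, free], axis=0)
    roles = np.concatenate(
        [
            np.full(n_shell, SOLUTE_APOLAR),
            [SOLUTE_APOLAR],  # gate
            np.full(spec.n_solvent, SOLVENT),
            np.full(spec.n_probe, PROBE),
        ]
    ).astype(np.int64)
    frozen = np.zeros(len(positions), dtype=bool)
    frozen[:n_shell] = True

    gate_idx = n_shell
    tether_k = np.zeros((len(positions), 3))
    tether_ref = np.zeros((len(positions), 3))
    tether_k[gate_idx] = [0.0, spec.gate_tether_k, spec.gate_tether_k]

    system = ParticleSystem(
        positions=positions,
        roles=roles,
        pair_params=pair,
        frozen=frozen,
        tether_k=tether_k,
        tether_ref=tether_ref,
        gate=GateDoubleWell(
            index=gate_idx,
            barrier=spec.gate_barrier,
            x_mid=0.5 * spec.gate_open_x,
            half_sep=0.5 * spec.gate_open_x,
        )
        if spec.gate_open_x > 0
        else None,
        confinement=Confinement(k=spec.confinement_k, radius=spec.confinement_radius)
        if n_free
        else None,
    )
    return system
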