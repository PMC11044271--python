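"""Simulation strategies on toy systems: unbiased, mixed-solvent, SWISH, SWISH-X.

SWISH runs a ladder of replicas whose solvent<->apolar interactions are
scaled by uniformly spaced lambda factors starting at 1.00 (nonscaled);
SWISH-X adds an OPES MultiThermal bias to every replica.  Replica exchange
uses the standard nearest-neighbor Metropolis criterion with alternating
even/odd pair phases.  Configurations swap on acceptance while lambda and
the bias estimator stay with the replica slot, so recorded series are
lambda-resolved ("demultiplexed by lambda, not by walker").

Seeding: one master seed per run; per-replica noise streams, initial
velocities, the wall-calibration run and the exchange decisions each draw
from children of ``numpy.random.SeedSequence(master_seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from . import _kernels
from .engine import (
    PROBE,
    ContactWall,
    GatedCavitySpec,
    OverlapError,
    ParticleSystem,
    build_gated_cavity_system,
)
from .opes import OpesMultiThermal, make_temperature_grid

__all__ = [
    "STRATEGIES",
    "RunConfig",
    "Replica",
    "ExchangeRecord",
    "ReplicaSeries",
    "RunResult",
    "make_lambda_ladder",
    "attempt_exchange",
    "run_strategy",
    "exchange_statistics",
]

STRATEGIES = ("unbiased", "mixed_solvent", "swish", "swish_x")


def make_lambda_ladder(
    n_replicas: int, lambda_min: float = 1.00, lambda_max: float = 1.35
) -> np.ndarray:
    """Uniformly spaced scaling factors including both endpoints."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    if lambda_min > lambda_max:
        raise ValueError("lambda_min must be <= lambda_max")
    if n_replicas == 1:
        if lambda_min != lambda_max:
            raise ValueError("a single replica needs lambda_min == lambda_max")
        return np.array([float(lambda_min)])
    return np.linspace(lambda_min, lambda_max, n_replicas)


@dataclass
class RunConfig:
    """Run-level knobs shared by all strategies (reduced units)."""

    n_steps: int = 100_000
    dt: float = 0.004
    gamma: float = 1.0
    temperature: float = 1.0
    n_replicas: int = 6
    lambda_min: float = 1.00
    lambda_max: float = 1.35
    exchange_stride: int = 1000
    update_stride: int = 500          # OPES dF refresh = segment length
    sample_stride: int = 10
    frame_stride: int = 500           # must be a multiple of update_stride
    # OPES MultiThermal range (SWISH-X); all replicas share it by default
    T_min: float = 1.0
    T_max: float = 2.0
    n_T: int = 5
    # contact-map upper wall (w_max auto-calibrated: mean + 3 SD unbiased)
    wall_enabled: bool = True
    wall_r0: float = 1.5
    wall_kappa: float = 5.0
    wall_calibration_steps: int = 2000
    unfold_sd_mult: float = 5.0
    unfold_frac: float = 0.10
    # per-replica equilibration with the gate restrained closed (not recorded)
    equilibration_steps: int = 4000
    seed: int = 0


class _SystemContext:
    """Flattened kernel arguments for one ParticleSystem (non-periodic)."""

    def __init__(self, system: ParticleSystem, wall: Optional[ContactWall] = None):
        if system.box is not None:
            raise ValueError("the kernel path supports non-periodic systems only")
        self.system = system
        p = system.pair_params
        self.roles = system.roles.astype(np.int64)
        self.eps = p.eps
        self.sig = p.sigma
        self.rc = p.cutoff
        self.shift = p.shift()
        self.frozen = system.frozen
        self.masses = system.masses
        n = system.n_particles
        self.tether_k = (
            system.tether_k if system.tether_k is not None else np.zeros((n, 3))
        )
        self.tether_ref = (
            system.tether_ref if system.tether_ref is not None else np.zeros((n, 3))
        )
        g = system.gate
        self.gate = (
            (g.index, g.barrier, g.x_mid, g.half_sep, g.wall_k, g.s_lo, g.s_hi)
            if g is not None
            else (-1, 0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
        )
        c = system.confinement
        self.conf = (c.k, c.radius) if c is not None else (0.0, 0.0)
        self.set_wall(wall)
        self.probe_idx = np.flatnonzero(system.roles == PROBE).astype(np.int64)
        self.rep_d = 1.5 * float(p.sigma[PROBE, PROBE])
        self.rep_k = 10.0 if len(self.probe_idx) > 1 else 0.0
        self.u_frozen_const = self._frozen_constant()
        self._fbuf = np.zeros((n, 3))

    def set_wall(self, wall: Optional[ContactWall]) -> None:
        if wall is not None and len(wall.pairs) > 0:
            pairs = np.asarray(wall.pairs, dtype=np.int64)
            self.wall_i = np.ascontiguousarray(pairs[:, 0])
            self.wall_j = np.ascontiguousarray(pairs[:, 1])
            self.wall_par = (
                float(wall.r0),
                float(wall.n_sw),
                float(wall.m_sw),
                float(wall.w_max),
                float(wall.kappa),
            )
        else:
            self.wall_i = np.zeros(0, dtype=np.int64)
            self.wall_j = np.zeros(0, dtype=np.int64)
            self.wall_par = (1.0, 4.0, 8.0, np.inf, 0.0)

    def _frozen_constant(self) -> float:
        """Constant LJ energy of frozen-frozen pairs, skipped in the kernel."""
        idx = np.flatnonzero(self.frozen)
        total = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                d = self.system.positions[i] - self.system.positions[j]
                r2 = float(d @ d)
                ri, rj = self.roles[i], self.roles[j]
                rcut = self.rc[ri, rj]
                if r2 >= rcut * rcut:
                    continue
                sr6 = (self.sig[ri, rj] ** 2 / r2) ** 3
                total += 4.0 * self.eps[ri, rj] * (sr6 * sr6 - sr6) - self.shift[ri, rj]
        return total

    def energy_terms(self, positions: np.ndarray, lam: float):
        res = _kernels.energy_forces_nb(
            positions, self.roles, self.eps, self.sig, self.rc, self.shift,
            lam, self.frozen, self.tether_k, self.tether_ref,
            *self.gate, *self.conf,
            self.wall_i, self.wall_j, *self.wall_par,
            self.probe_idx, self.rep_d, self.rep_k, self._fbuf,
        )
        if res[6] >= 0:
            n = len(positions)
            raise OverlapError(
                f"hard-core overlap between particles {res[6] // n} and {res[6] % n}"
            )
        return res

    def total_energy(self, positions: np.ndarray, lam: float) -> float:
        u_ww, u_ws, u_ss, u_restr, u_ext, _, _ = self.energy_terms(positions, lam)
        return u_ww + lam * u_ws + u_ss + u_restr + u_ext + self.u_frozen_const

    def run_segment(self, rep: "Replica", n_steps: int, dt: float, gamma: float):
        """Advance one replica in place; returns per-step (U, V, cv, gate_x)."""
        noise = rep.rng.standard_normal((n_steps, len(rep.positions), 3))
        u_out = np.empty(n_steps)
        v_out = np.empty(n_steps)
        cv_out = np.empty(n_steps)
        gx_out = np.empty(n_steps)
        if rep.opes is not None:
            bias_on = True
            beta_j = rep.opes.grid.betas
            bj_dF = rep.opes.beta_j_deltaF
        else:
            bias_on = False
            beta_j = np.array([1.0 / rep.temperature])
            bj_dF = np.zeros(1)
        err, err_pair = _kernels.baoab_run(
            rep.positions, rep.velocities, self.masses, self.frozen, self.roles,
            self.eps, self.sig, self.rc, self.shift, rep.lam, self.u_frozen_const,
            self.tether_k, self.tether_ref, *self.gate, *self.conf,
            self.wall_i, self.wall_j, *self.wall_par,
            self.probe_idx, self.rep_d, self.rep_k,
            bias_on, 1.0 / rep.temperature, beta_j, bj_dF,
            dt, gamma, rep.temperature,
            noise, u_out, v_out, cv_out, gx_out,
        )
        if err == 1:
            n = len(rep.positions)
            raise OverlapError(
                f"replica lambda={rep.lam:.3f}: hard-core overlap between "
                f"particles {err_pair // n} and {err_pair % n}"
            )
        if err == 2:
            raise RuntimeError(
                f"replica lambda={rep.lam:.3f}: potential energy blow-up; "
                "use a smaller timestep"
            )
        return u_out, v_out, cv_out, gx_out


@dataclass
class Replica:
    """One ladder slot: a lambda value plus the walker currently holding it."""

    lam: float
    positions: np.ndarray
    velocities: np.ndarray
    temperature: float
    walker_id: int
    opes: Optional[OpesMultiThermal] = None
    rng: Optional[np.random.Generator] = None
    context: Optional[_SystemContext] = None

    def physical_energy(self, positions: Optional[np.ndarray] = None) -> float:
        pos = self.positions if positions is None else positions
        return self.context.total_energy(pos, self.lam)

    def energy_with_bias(self, positions: Optional[np.ndarray] = None) -> float:
        u = self.physical_energy(positions)
        if self.opes is not None:
            u = u + self.opes.bias_energy(u)
        return u


@dataclass
class ExchangeRecord:
    attempt: int
    pair: tuple
    acceptance_probability: float
    accepted: bool
    walker_map: tuple


def attempt_exchange(
    replica_i: Replica,
    replica_j: Replica,
    rng: np.random.Generator,
    attempt: int = 0,
    pair: tuple = (0, 1),
) -> ExchangeRecord:
    """Metropolis Hamiltonian-exchange attempt between two ladder slots.

    acceptance = min(1, exp(-beta*Delta)) with
    Delta = [E_i(R_j) + E_j(R_i)] - [E_i(R_i) + E_j(R_j)], where E_k(R) =
    U_total(R; lambda_k) plus the slot's OPES bias when present.  On
    acceptance the configurations (and velocities) swap; lambda and the bias
    estimator stay with the slot.
    """
    if replica_i.temperature != replica_j.temperature:
        raise ValueError("replica exchange requires a shared thermostat temperature")
    beta = 1.0 / replica_i.temperature
    e_ii = replica_i.energy_with_bias(replica_i.positions)
    e_jj = replica_j.energy_with_bias(replica_j.positions)
    e_ij = replica_i.energy_with_bias(replica_j.positions)
    e_ji = replica_j.energy_with_bias(replica_i.positions)
    delta = (e_ij + e_ji) - (e_ii + e_jj)
    prob = 1.0 if delta <= 0 else float(min(1.0, np.exp(-beta * delta)))
    accepted = bool(rng.random() < prob)
    if accepted:
        replica_i.positions, replica_j.positions = (
            replica_j.positions,
            replica_i.positions,
        )
        replica_i.velocities, replica_j.velocities = (
            replica_j.velocities,
            replica_i.velocities,
        )
        replica_i.walker_id, replica_j.walker_id = (
            replica_j.walker_id,
            replica_i.walker_id,
        )
    return ExchangeRecord(
        attempt=attempt,
        pair=tuple(pair),
        acceptance_probability=prob,
        accepted=accepted,
        walker_map=(replica_i.walker_id, replica_j.walker_id),
    )


@dataclass
class ReplicaSeries:
    """Lambda-resolved time series of one ladder slot."""

    lam: float
    sample_steps: np.ndarray
    U: np.ndarray
    V: np.ndarray
    cv: np.ndarray
    gate_x: np.ndarray
    frame_steps: np.ndarray
    frames: np.ndarray
    excluded: bool = False


@dataclass
class RunResult:
    strategy: str
    lambdas: np.ndarray
    replicas: List[ReplicaSeries]
    exchange_log: List[ExchangeRecord]
    config: RunConfig
    system_spec: Optional[GatedCavitySpec]
    system: ParticleSystem
    wall_w_max: float
    wall_cv_sd: float

    @property
    def active_replicas(self) -> List[ReplicaSeries]:
        return [r for r in self.replicas if not r.excluded]


def _calibrate_wall(
    system: ParticleSystem,
    wall_pairs: np.ndarray,
    config: RunConfig,
    seed_seq: np.random.SeedSequence,
):
    """Short unbiased run at lambda=1; w_max = mean + 3 SD of the wall CV."""
    ctx = _SystemContext(system, None)
    rng = np.random.default_rng(seed_seq)
    rep = Replica(
        lam=1.0,
        positions=system.positions.copy(),
        velocities=_initial_velocities(system, config.temperature, rng),
        temperature=config.temperature,
        walker_id=0,
        rng=rng,
        context=ctx,
    )
    probe_wall = ContactWall(pairs=wall_pairs, r0=config.wall_r0)
    ctx.set_wall(probe_wall)  # records the CV without applying a penalty
    _, _, cv, _ = ctx.run_segment(rep, config.wall_calibration_steps, config.dt, config.gamma)
    burn = len(cv) // 5
    mean, sd = float(np.mean(cv[burn:])), float(np.std(cv[burn:]))
    return mean + 3.0 * sd, sd


def _initial_velocities(
    system: ParticleSystem, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    v = rng.standard_normal((system.n_particles, 3)) * np.sqrt(
        temperature / system.masses[:, None]
    )
    v[system.frozen] = 0.0
    return v


def run_strategy(
    strategy: str,
    spec: Optional[GatedCavitySpec] = None,
    config: Optional[RunConfig] = None,
    system: Optional[ParticleSystem] = None,
) -> RunResult:
    """Run one simulation protocol on the gated-cavity toy.

    unbiased       one replica, lambda = 1, probes stripped;
    mixed_solvent  one replica, lambda = 1, probes + interprobe repulsion;
    swish          lambda ladder + probes + contact-map upper wall;
    swish_x        swish + one OPES MultiThermal bias per replica (shared
                   [T_min, T_max] range by default).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    config = config or RunConfig()
    if config.exchange_stride % config.update_stride:
        raise ValueError("exchange_stride must be a multiple of update_stride")
    if config.frame_stride % config.update_stride:
        raise ValueError("frame_stride must be a multiple of update_stride")

    if system is None:
        spec = spec or GatedCavitySpec()
        if strategy == "unbiased":
            spec = replace(spec, n_probe=0)
        elif strategy in ("mixed_solvent", "swish", "swish_x") and spec.n_probe == 0:
            spec = replace(spec, n_probe=2)
        system = build_gated_cavity_system(spec)

    if strategy in ("unbiased", "mixed_solvent"):
        lambdas = np.array([1.0])
    else:
        if config.n_replicas < 2:
            raise ValueError(f"{strategy} needs n_replicas >= 2")
        lambdas = make_lambda_ladder(
            config.n_replicas, config.lambda_min, config.lambda_max
        )
    n_rep = len(lambdas)

    ss = np.random.SeedSequence(config.seed)
    cal_seed, exch_seed, *rep_seeds = ss.spawn(2 + n_rep)
    exch_rng = np.random.default_rng(exch_seed)

    # contact-map upper wall on gate<->shell contacts
    wall = None
    w_max, cv_sd = np.inf, 0.0
    use_wall = config.wall_enabled and strategy in ("mixed_solvent", "swish", "swish_x")
    gate_idx = system.gate.index if system.gate is not None else None
    if use_wall and gate_idx is not None and np.any(system.frozen):
        shell_idx = np.flatnonzero(system.frozen)
        wall_pairs = np.array([(gate_idx, int(s)) for s in shell_idx], dtype=np.int64)
        w_max, cv_sd = _calibrate_wall(system, wall_pairs, config, cal_seed)
        wall = ContactWall(
            pairs=wall_pairs,
            r0=config.wall_r0,
            w_max=w_max,
            kappa=config.wall_kappa,
        )

    ctx = _SystemContext(system, wall)

    grid = None
    if strategy == "swish_x":
        if config.T_min == config.T_max:
            grid = make_temperature_grid(config.temperature, config.T_min, config.T_max, 1)
        else:
            grid = make_temperature_grid(
                config.temperature, config.T_min, config.T_max, config.n_T
            )

    replicas = []
    for k, lam in enumerate(lambdas):
        rng = np.random.default_rng(rep_seeds[k])
        replicas.append(
            Replica(
                lam=float(lam),
                positions=system.positions.copy(),
                velocities=_initial_velocities(system, config.temperature, rng),
                temperature=config.temperature,
                walker_id=k,
                opes=OpesMultiThermal(grid=grid, update_stride=config.update_stride)
                if grid is not None
                else None,
                rng=rng,
                context=ctx,
            )
        )

    # per-replica equilibration at its own lambda, gate restrained closed
    # (mirrors the per-lambda equilibration of the real protocols); nothing
    # is recorded and the OPES estimator is not updated
    if config.equilibration_steps > 0:
        eq_system = system
        if system.gate is not None:
            eq_tether_k = ctx.tether_k.copy()
            eq_tether_ref = ctx.tether_ref.copy()
            gi = system.gate.index
            x_closed = system.gate.x_mid - system.gate.half_sep
            eq_tether_k[gi] = [100.0, eq_tether_k[gi, 1], eq_tether_k[gi, 2]]
            eq_tether_ref[gi, 0] = x_closed
            eq_ctx = _SystemContext(eq_system, wall)
            eq_ctx.tether_k = eq_tether_k
            eq_ctx.tether_ref = eq_tether_ref
        else:
            eq_ctx = ctx
        for rep in replicas:
            rep_ctx, rep.context = rep.context, eq_ctx
            opes_state, rep.opes = rep.opes, None
            eq_ctx.run_segment(rep, config.equilibration_steps, config.dt, config.gamma)
            rep.context = rep_ctx
            rep.opes = opes_state

    # series buffers, lambda-resolved (slot-resolved)
    buf = {
        k: {"step": [], "U": [], "V": [], "cv": [], "gx": [], "fstep": [], "frames": []}
        for k in range(n_rep)
    }
    exchange_log: List[ExchangeRecord] = []
    seg = config.update_stride
    n_segments = int(np.ceil(config.n_steps / seg))
    attempt = 0
    for s in range(n_segments):
        start = s * seg
        length = min(seg, config.n_steps - start)
        for k, rep in enumerate(replicas):
            u, v, cv, gx = ctx.run_segment(rep, length, config.dt, config.gamma)
            if rep.opes is not None:
                rep.opes.update(u, v)
            idx = np.arange(start, start + length)
            pick = (idx + 1) % config.sample_stride == 0
            b = buf[k]
            b["step"].append(idx[pick] + 1)
            b["U"].append(u[pick])
            b["V"].append(v[pick])
            b["cv"].append(cv[pick])
            b["gx"].append(gx[pick])
            if (start + length) % config.frame_stride == 0:
                b["fstep"].append(start + length)
                b["frames"].append(rep.positions.copy())
        done = start + length
        if n_rep > 1 and done % config.exchange_stride == 0 and done < config.n_steps:
            phase = (done // config.exchange_stride) % 2
            for i in range(phase, n_rep - 1, 2):
                rec = attempt_exchange(
                    replicas[i], replicas[i + 1], exch_rng, attempt=attempt, pair=(i, i + 1)
                )
                rec.walker_map = tuple(r.walker_id for r in replicas)
                exchange_log.append(rec)
                attempt += 1

    series = []
    for k, rep in enumerate(replicas):
        b = buf[k]
        cv_arr = np.concatenate(b["cv"]) if b["cv"] else np.zeros(0)
        excluded = False
        if wall is not None and len(cv_arr):
            over = cv_arr > w_max + config.unfold_sd_mult * cv_sd
            excluded = bool(np.mean(over) > config.unfold_frac)
        series.append(
            ReplicaSeries(
                lam=rep.lam,
                sample_steps=np.concatenate(b["step"]) if b["step"] else np.zeros(0, int),
                U=np.concatenate(b["U"]) if b["U"] else np.zeros(0),
                V=np.concatenate(b["V"]) if b["V"] else np.zeros(0),
                cv=cv_arr,
                gate_x=np.concatenate(b["gx"]) if b["gx"] else np.zeros(0),
                frame_steps=np.array(b["fstep"], dtype=int),
                frames=np.array(b["frames"]) if b["frames"] else np.zeros((0, system.n_particles, 3)),
                excluded=excluded,
            )
        )
    return RunResult(
        strategy=strategy,
        lambdas=lambdas,
        replicas=series,
        exchange_log=exchange_log,
        config=config,
        system_spec=spec,
        system=system,
        wall_w_max=w_max,
        wall_cv_sd=cv_sd,
    )


def exchange_statistics(log: Sequence[ExchangeRecord], n_replicas: Optional[int] = None):
    """Per-pair acceptance rates and walker round-trip counts.

    A round trip counts each time a walker reaches the opposite end of the
    ladder after having visited the other end (two end-to-end legs = one
    round trip).
    """
    if not log:
        raise ValueError("empty exchange log")
    pairs: dict[tuple, tuple[int, int]] = {}
    for rec in log:
        k = tuple(rec.pair)
        att, acc = pairs.get(k, (0, 0))
        pairs[k] = (att + 1, acc + int(rec.accepted))
    rates = {k: acc / att for k, (att, acc) in pairs.items()}

    round_trips = 0
    if n_replicas is not None and n_replicas > 1:
        last_end: dict[int, int] = {}
        legs: dict[int, int] = {}
        for rec in log:
            wm = rec.walker_map
            if len(wm) != n_replicas:
                continue
            for slot in (0, n_replicas - 1):
                w = wm[slot]
                end = 0 if slot == 0 else 1
                prev = last_end.get(w)
                if prev is not None and prev != end:
                    legs[w] = legs.get(w, 0) + 1
                last_end[w] = end
        round_trips = sum(n // 2 for n in legs.values())
    return {"pair_acceptance": rates, "round_trips": round_trips}
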