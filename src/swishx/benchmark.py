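"""Strategy comparison on the gated-cavity toy: first-opening benchmark.

Runs the unbiased, SWISH and SWISH-X protocols on the same cryptic-cavity
toy over several master seeds, measures per-seed first-opening steps through
the pocket-exposure pipeline (grid volume -> exposure % -> opening criteria)
and reports the per-strategy medians.  Runs that never open within the step
budget are right-censored at the budget, which can only make the comparison
conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import GatedCavitySpec, ParticleSystem, build_gated_cavity_system
from .orchestrator import RunConfig, RunResult, run_strategy
from .pocket import OpeningCriteria, PocketDefinition, exposure_series, opening_time

__all__ = [
    "toy_pocket_definition",
    "result_exposure_series",
    "first_opening_step",
    "first_opening_benchmark",
]

# display radius of a toy particle, as a fraction of its LJ sigma
TOY_ATOM_RADIUS_FRACTION = 0.45


def solute_indices(system: ParticleSystem) -> np.ndarray:
    """Solute (shell + gate) atoms: pocket occupancy counts these only.

    As in protein pocket analysis, solvent and probe molecules do not
    occlude the pocket — a water-flooded open cavity is still open.
    """
    return np.flatnonzero((system.roles == 1) | (system.roles == 2))


def toy_pocket_definition(
    system: ParticleSystem,
    spec: GatedCavitySpec,
    grid_spacing: float = 0.15,
    jitter_margin: float = 0.15,
) -> PocketDefinition:
    """Pocket definition for the gated cavity (reduced length units).

    The reference ("holo crystal") is the solute subsystem with the gate at
    its open minimum, i.e. the cavity fully vacated.  The lining selection is
    the frozen shell.  The region radius is derived from the geometry so
    that a closed gate occludes the whole region even under thermal jitter
    of size ``jitter_margin``.
    """
    sol = solute_indices(system)
    ref = system.positions[sol].copy()
    gate_pos = int(np.flatnonzero(sol == system.gate.index)[0])
    ref[gate_pos, 0] = spec.gate_open_x
    sig = system.pair_params.sigma
    radii = TOY_ATOM_RADIUS_FRACTION * sig[system.roles[sol], system.roles[sol]]
    probe_r = TOY_ATOM_RADIUS_FRACTION * 1.0
    gate_exclusion = float(radii[gate_pos] + probe_r)
    region = min(
        spec.shell_radius - radii[0] - probe_r,  # clear of the shell wall
        gate_exclusion - jitter_margin,          # occluded by a jittering gate
    )
    return PocketDefinition(
        reference_coords=ref,
        atom_radii=radii,
        pocket_center=np.zeros(3),
        lining_idx=np.flatnonzero(system.frozen[sol]),
        probe_radius=probe_r,
        region_radius=float(region),
        grid_spacing=grid_spacing,
    )


def result_exposure_series(
    result: RunResult,
    pocket: PocketDefinition,
    include_excluded: bool = False,
) -> pd.DataFrame:
    """Exposure/RMSD series for every (active) replica of a toy run.

    Toy frames live in the frozen-shell reference frame, so no alignment is
    applied before the volume evaluation.
    """
    radii = pocket.atom_radii
    sol = solute_indices(result.system)
    parts = []
    for k, rep in enumerate(result.replicas):
        if rep.excluded and not include_excluded:
            continue
        parts.append(
            exposure_series(
                rep.frames[:, sol, :], rep.frame_steps.astype(float), radii,
                pocket, replica=k, align=False,
            )
        )
    if not parts:
        raise ValueError("all replicas excluded")
    return pd.concat(parts, ignore_index=True)


def first_opening_step(
    result: RunResult,
    pocket: PocketDefinition,
    criteria: Optional[OpeningCriteria] = None,
) -> Optional[float]:
    """Earliest step at which any active replica meets the opening criteria."""
    criteria = criteria or OpeningCriteria(exposure_threshold=60.0, rmsd_ceiling=2.0)
    df = result_exposure_series(result, pocket)
    t, _ = opening_time(df, criteria)
    return t


@dataclass
class BenchmarkResult:
    barrier: float
    n_seeds: int
    n_steps: int
    opening_steps: dict          # strategy -> list (censored at n_steps)
    medians: dict                # strategy -> median opening step
    censored: dict               # strategy -> number of censored seeds


def first_opening_benchmark(
    master_seed: int = 0,
    n_seeds: int = 10,
    barrier: float = 8.0,
    n_steps: int = 100_000,
    strategies: Sequence[str] = ("unbiased", "swish", "swish_x"),
    spec: Optional[GatedCavitySpec] = None,
    config: Optional[RunConfig] = None,
) -> BenchmarkResult:
    """Median first-opening step per strategy over ``n_seeds`` seeds.

    Every strategy sees the same per-seed system construction and the same
    opening pipeline; only the sampling protocol differs.
    """
    base_spec = spec or GatedCavitySpec(gate_barrier=barrier, n_probe=2)
    base_cfg = config or RunConfig(n_steps=n_steps)
    seeds = np.random.SeedSequence(master_seed).generate_state(n_seeds) % (2**31)

    steps: dict[str, list] = {s: [] for s in strategies}
    for seed in seeds:
        for strat in strategies:
            cfg = replace(base_cfg, seed=int(seed))
            run_spec = replace(base_spec, seed=int(seed), gate_barrier=barrier)
            result = run_strategy(strat, spec=run_spec, config=cfg)
            pocket = toy_pocket_definition(result.system, result.system_spec)
            t = first_opening_step(result, pocket)
            steps[strat].append(float(t) if t is not None else float(cfg.n_steps))
    medians = {s: float(np.median(v)) for s, v in steps.items()}
    censored = {
        s: int(np.sum(np.asarray(v) >= base_cfg.n_steps)) for s, v in steps.items()
    }
    return BenchmarkResult(
        barrier=barrier,
        n_seeds=n_seeds,
        n_steps=base_cfg.n_steps,
        opening_steps=steps,
        medians=medians,
        censored=censored,
    )
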