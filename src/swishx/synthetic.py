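"""Synthetic two-state pocket trajectories with ground-truth labels.

The generator stands in for protein trajectories in the analysis pipeline:
pseudo-residues (one COM bead each) arranged on a ring that is tight in the
closed state and dilated in the open state, so the two states differ both in
their pairwise COM-distance contact signature and in the grid volume of the
central cavity.  Frames follow a transition schedule (a single switch frame
or symmetric two-state Markov rates) with isotropic Gaussian coordinate
noise; every frame carries its planted open/closed label.

Coordinates are in Angstrom; contact featurization converts to nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .pocket import PocketDefinition

__all__ = [
    "SyntheticPocketSpec",
    "SyntheticBundle",
    "two_state_templates",
    "generate_two_state_features",
    "synthetic_pocket_definition",
]


def two_state_templates(
    n_residues: int = 8,
    closed_radius: float = 4.0,
    open_radius: float = 7.0,
    z_offset: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed/open residue-COM templates: a ring that dilates on opening.

    Alternating +-z offsets keep the templates genuinely three-dimensional.
    """
    ang = 2.0 * np.pi * np.arange(n_residues) / n_residues
    z = z_offset * np.where(np.arange(n_residues) % 2 == 0, 1.0, -1.0)
    closed = np.stack([closed_radius * np.cos(ang), closed_radius * np.sin(ang), z], axis=1)
    opened = np.stack([open_radius * np.cos(ang), open_radius * np.sin(ang), z], axis=1)
    return closed, opened


@dataclass
class SyntheticPocketSpec:
    """Recipe for a two-state synthetic trajectory set.

    ``switch_frame`` plants a single closed->open transition; alternatively
    ``markov_rates = (k_open, k_close)`` (per frame) draws a two-state jump
    schedule.  ``noise_sigma_nm`` is the isotropic per-coordinate noise.
    """

    n_residues: int = 8
    closed_radius: float = 4.0
    open_radius: float = 7.0
    n_frames: int = 200
    n_replicas: int = 1
    switch_frame: Optional[int] = 100
    markov_rates: Optional[tuple[float, float]] = None
    noise_sigma_nm: float = 0.05
    seed: int = 0
    time_per_frame: float = 1.0

    def __post_init__(self):
        if self.n_frames < 10:
            raise ValueError("need at least 10 frames")
        closed, opened = two_state_templates(
            self.n_residues, self.closed_radius, self.open_radius
        )
        dist = lambda t: np.linalg.norm(
            t[:, None, :] - t[None, :, :], axis=2
        )
        gap = np.max(np.abs(dist(closed) - dist(opened)))
        if gap < 3.0 * self.noise_sigma_nm * 10.0:
            raise ValueError(
                "templates closer than 3 sigma in every pair distance: "
                "unlearnable spec"
            )


@dataclass
class SyntheticBundle:
    """Generated frames plus ground truth and provenance."""

    coords: np.ndarray          # (frames_total, n_residues, 3) in A
    labels: np.ndarray          # 1 = open, 0 = closed (planted truth)
    provenance: pd.DataFrame    # run_type, replica, time, frame
    spec: SyntheticPocketSpec

    @property
    def n_frames(self) -> int:
        return len(self.coords)


def _label_schedule(spec: SyntheticPocketSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.markov_rates is not None:
        k_open, k_close = spec.markov_rates
        lab = np.zeros(spec.n_frames, dtype=int)
        state = 0
        for i in range(spec.n_frames):
            lab[i] = state
            p = k_open if state == 0 else k_close
            if rng.random() < p:
                state = 1 - state
        return lab
    sw = spec.n_frames if spec.switch_frame is None else int(spec.switch_frame)
    lab = np.zeros(spec.n_frames, dtype=int)
    lab[sw:] = 1
    return lab


def generate_two_state_features(
    spec: SyntheticPocketSpec, run_type: str = "apo_unbiased"
) -> SyntheticBundle:
    """Deterministic (seeded) synthetic trajectory with planted labels.

    The label schedule and the coordinate noise use separate RNG streams, so
    two seeds differ in noise but share the schedule whenever the schedule
    itself is deterministic (fixed switch frame).
    """
    ss = np.random.SeedSequence(spec.seed)
    schedule_rng, *noise_rngs = [
        np.random.default_rng(s) for s in ss.spawn(1 + spec.n_replicas)
    ]
    closed, opened = two_state_templates(
        spec.n_residues, spec.closed_radius, spec.open_radius
    )
    sigma_A = spec.noise_sigma_nm * 10.0

    all_coords, all_labels, prov = [], [], []
    for rep in range(spec.n_replicas):
        labels = _label_schedule(spec, schedule_rng)
        base = np.where(labels[:, None, None] == 1, opened, closed)
        noise = noise_rngs[rep].standard_normal(base.shape) * sigma_A
        all_coords.append(base + noise)
        all_labels.append(labels)
        prov.append(
            pd.DataFrame(
                {
                    "run_type": run_type,
                    "replica": rep,
                    "time": spec.time_per_frame * np.arange(spec.n_frames),
                    "frame": np.arange(spec.n_frames),
                }
            )
        )
    return SyntheticBundle(
        coords=np.concatenate(all_coords, axis=0),
        labels=np.concatenate(all_labels),
        provenance=pd.concat(prov, ignore_index=True),
        spec=spec,
    )


def synthetic_pocket_definition(
    spec: SyntheticPocketSpec,
    atom_radius: float = 2.0,
    probe_radius: float = 1.4,
    region_radius: Optional[float] = None,
    grid_spacing: float = 0.5,
) -> PocketDefinition:
    """Pocket definition for the synthetic system (reference = open template).

    The ring encloses a central cavity whose grid volume grows on opening;
    the open template is the "holo crystal" against which exposure is
    measured.
    """
    _, opened = two_state_templates(spec.n_residues, spec.closed_radius, spec.open_radius)
    region = (
        region_radius
        if region_radius is not None
        else spec.open_radius - atom_radius - probe_radius + 0.5
    )
    return PocketDefinition(
        reference_coords=opened,
        atom_radii=np.full(spec.n_residues, atom_radius),
        pocket_center=np.zeros(3),
        lining_idx=np.arange(spec.n_residues),
        probe_radius=probe_radius,
        region_radius=region,
        grid_spacing=grid_spacing,
    )
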