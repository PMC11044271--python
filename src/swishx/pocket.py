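"""Pocket volume, exposure and opening-time analysis.

Pocket volume uses a grid flood fill: grid points inside a spherical region
around the pocket center count as pocket volume when they are farther than
atom_radius + probe_radius from every atom and connected to the seed point
(the empty cell nearest the center) through face-adjacent empty cells, which
drops disconnected bulk-solvent cavities.  Exposure is the volume as a
percentage of the same pocket's volume in the reference (holo) structure and
is reported unclipped (open states larger than the crystal exceed 100%).

All lengths are in Angstrom.  Defaults: probe radius 1.4 A (water-sized),
grid spacing 0.5 A, region radius 8 A, lining shell 7 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "PocketDefinition",
    "OpeningCriteria",
    "grid_pocket_volume",
    "exposure_percent",
    "pocket_rmsd",
    "kabsch_superpose",
    "opening_time",
    "exposure_summary",
    "exposure_series",
    "VDW_RADII",
]

# heavy-atom van der Waals radii (A); fallback for unknown elements
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass
class PocketDefinition:
    """Reference (holo, ligand removed) pocket description.

    ``lining_idx`` are the atom indices used for alignment and RMSD;
    ``reference_volume`` is the grid volume of the pocket in the reference
    coordinates, computed on construction unless provided.
    """

    reference_coords: np.ndarray
    atom_radii: np.ndarray
    pocket_center: np.ndarray
    lining_idx: np.ndarray
    probe_radius: float = 1.4
    region_radius: float = 8.0
    grid_spacing: float = 0.5
    reference_volume: Optional[float] = None

    def __post_init__(self):
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        self.atom_radii = np.asarray(self.atom_radii, dtype=float)
        self.pocket_center = np.asarray(self.pocket_center, dtype=float)
        self.lining_idx = np.asarray(self.lining_idx, dtype=int)
        if not (self.region_radius > self.probe_radius > 0):
            raise ValueError("require region_radius > probe_radius > 0")
        if len(self.lining_idx) == 0:
            raise ValueError("lining selection is empty")
        if self.reference_volume is None:
            self.reference_volume = grid_pocket_volume(
                self.reference_coords, self.atom_radii, self
            )
        if self.reference_volume <= 0:
            raise ValueError("reference pocket volume must be > 0")


@dataclass
class OpeningCriteria:
    """Joint opening criterion: exposure >= threshold AND rmsd < ceiling."""

    exposure_threshold: float = 60.0
    rmsd_ceiling: float = 2.0

    def __post_init__(self):
        if self.exposure_threshold <= 0 or self.rmsd_ceiling <= 0:
            raise ValueError("threshold and ceiling must be > 0")


def grid_pocket_volume(
    coords: np.ndarray,
    radii: Union[float, np.ndarray],
    pocket: PocketDefinition,
) -> float:
    """Flood-fill pocket volume (A^3) of one frame, assumed pre-aligned."""
    coords = np.asarray(coords, dtype=float)
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(coords),))
    c = pocket.pocket_center
    R = pocket.region_radius
    h = pocket.grid_spacing

    ax = np.arange(-R, R + h / 2, h)
    if len(ax) == 0:
        raise ValueError("empty grid region")
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3) + c
    in_region = (np.sum((pts - c) ** 2, axis=1) <= R * R).reshape(gx.shape)

    # occupancy: any atom closer than atom_radius + probe_radius
    near = np.sum((coords - c) ** 2, axis=1) <= (R + np.max(radii) + pocket.probe_radius) ** 2
    occupied = np.zeros(pts.shape[0], dtype=bool)
    if np.any(near):
        sub = coords[near]
        sub_r = radii[near] + pocket.probe_radius
        tree = cKDTree(pts)
        for a, ra in zip(sub, sub_r):
            occupied[tree.query_ball_point(a, ra)] = True
    empty = (~occupied).reshape(gx.shape) & in_region

    if not np.any(empty):
        return 0.0
    # seed: empty cell nearest the pocket center; face-adjacent connectivity
    labels, _ = ndimage.label(empty, structure=ndimage.generate_binary_structure(3, 1))
    d2 = ((gx) ** 2 + (gy) ** 2 + (gz) ** 2)
    d2_masked = np.where(empty, d2, np.inf)
    seed = np.unravel_index(np.argmin(d2_masked), d2.shape)
    pocket_label = labels[seed]
    count = int(np.sum(labels == pocket_label))
    return count * h**3


def exposure_percent(volume: float, reference_volume: float) -> float:
    """100 * v / v_ref, unclipped (values above 100% are reported as-is)."""
    if reference_volume <= 0:
        raise ValueError("reference_volume must be > 0")
    return 100.0 * volume / reference_volume


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation matrix, mobile centroid, target centroid); apply as
    (x - mobile_centroid) @ R.T + target_centroid.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    H = (mobile - mc).T @ (target - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, mc, tc


def pocket_rmsd(
    frame_coords: np.ndarray,
    reference_coords: np.ndarray,
    lining_idx: Optional[np.ndarray] = None,
    align: bool = True,
) -> float:
    """Heavy-atom RMSD (A) over the lining selection after superposition.

    With ``align=False`` the RMSD is computed in the given frame (identity
    alignment), which is occasionally useful against pre-aligned frames.
    """
    frame_coords = np.asarray(frame_coords, float)
    reference_coords = np.asarray(reference_coords, float)
    if frame_coords.shape != reference_coords.shape:
        raise ValueError(
            f"atom-count mismatch: frame has {frame_coords.shape[0]} atoms, "
            f"reference has {reference_coords.shape[0]}"
        )
    sel = slice(None) if lining_idx is None else np.asarray(lining_idx, int)
    a = frame_coords[sel]
    b = reference_coords[sel]
    if align:
        R, mc, tc = kabsch_superpose(a, b)
        a = (a - mc) @ R.T + tc
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def exposure_series(
    frames: np.ndarray,
    times: np.ndarray,
    radii: Union[float, np.ndarray],
    pocket: PocketDefinition,
    replica: int = 0,
    align: bool = True,
) -> pd.DataFrame:
    """Per-frame volume, exposure %, and lining RMSD for one replica.

    Frames are rigid-aligned to the reference on the lining selection before
    the volume evaluation (``align=False`` skips this for frames produced in
    the reference coordinate system, e.g. the frozen-shell toy).
    """
    frames = np.asarray(frames, float)
    rows = []
    ref = pocket.reference_coords
    for t, frame in zip(np.asarray(times), frames):
        coords = frame
        if align:
            R, mc, tc = kabsch_superpose(
                frame[pocket.lining_idx], ref[pocket.lining_idx]
            )
            coords = (frame - mc) @ R.T + tc
            lining_rmsd_now = float(
                np.sqrt(
                    np.mean(
                        np.sum(
                            (coords[pocket.lining_idx] - ref[pocket.lining_idx]) ** 2,
                            axis=1,
                        )
                    )
                )
            )
            if lining_rmsd_now > pocket.region_radius:
                raise ValueError(
                    f"frame at t={t} misaligned: lining RMSD {lining_rmsd_now:.1f} A "
                    f"exceeds the region radius"
                )
        vol = grid_pocket_volume(coords, radii, pocket)
        rmsd = pocket_rmsd(coords, ref, pocket.lining_idx, align=False)
        rows.append(
            {
                "time": float(t),
                "volume": vol,
                "exposure": exposure_percent(vol, pocket.reference_volume),
                "rmsd": rmsd,
                "replica": replica,
            }
        )
    return pd.DataFrame(rows)


def opening_time(
    series: pd.DataFrame, criteria: OpeningCriteria
) -> tuple[Optional[float], Optional[int]]:
    """First time meeting exposure >= threshold AND rmsd < ceiling.

    Accepts a single-replica or multi-replica (column ``replica``) series;
    returns (time, replica id), or (None, None) if the criteria are never
    met ("never").
    """
    if len(series) == 0:
        raise ValueError("empty exposure series")
    df = series.sort_values("time")
    hit = df[
        (df["exposure"] >= criteria.exposure_threshold)
        & (df["rmsd"] < criteria.rmsd_ceiling)
    ]
    if len(hit) == 0:
        return None, None
    first = hit.iloc[0]
    rep = int(first["replica"]) if "replica" in hit.columns else 0
    return float(first["time"]), rep


def exposure_summary(
    series: pd.DataFrame, excluded_replicas: Sequence[int] = ()
) -> dict:
    """Replica-merged exposure statistics (violin-style pooling).

    Frames from all non-excluded replicas are pooled; the pooled median and
    quartiles plus per-replica medians are reported.  The pooled sample is
    returned for violin plotting.
    """
    df = series[~series["replica"].isin(list(excluded_replicas))]
    if len(df) == 0:
        raise ValueError("all replicas excluded")
    pool = df["exposure"].to_numpy()
    per_replica = df.groupby("replica")["exposure"].median().to_dict()
    return {
        "median": float(np.median(pool)),
        "q1": float(np.percentile(pool, 25)),
        "q3": float(np.percentile(pool, 75)),
        "n_frames": int(len(pool)),
        "per_replica_median": per_replica,
        "samples": pool,
    }
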