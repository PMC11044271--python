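"""Structure and trajectory I/O plus run provenance.

PDB structures and XTC/DCD/XYZ trajectories are read through MDAnalysis.
Coordinates follow the MDAnalysis convention (Angstrom); the contact
featurization converts to nm where the switching function applies.  Readers
fail closed: malformed input raises with as much location information as the
parser provides rather than guessing.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

import MDAnalysis as mda

__all__ = [
    "read_structure",
    "read_trajectory",
    "ligand_centroid",
    "residue_coms",
    "TrajectoryBundle",
    "write_xyz",
    "write_pdb_frames",
    "write_colvar_csv",
    "provenance_record",
]

_TRAJ_FORMATS = {".xtc", ".dcd", ".xyz"}


def _validate_pdb(path: Path) -> None:
    """Cheap fail-closed scan: coordinate fields of ATOM/HETATM must parse."""
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except (ValueError, IndexError):
                    raise ValueError(
                        f"{path}: malformed coordinate record at line {ln}"
                    ) from None


def read_structure(path: Union[str, Path]) -> mda.Universe:
    """Read a PDB structure; HETATM (ligand) records stay separable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".pdb":
        _validate_pdb(path)
    u = mda.Universe(str(path))
    if u.atoms.n_atoms == 0:
        raise ValueError(f"{path}: no atoms")
    if not np.all(np.isfinite(u.atoms.positions)):
        raise ValueError(f"{path}: missing or non-finite coordinates")
    return u


def read_trajectory(
    topology: Union[str, Path, mda.Universe], path: Union[str, Path]
) -> mda.Universe:
    """Attach an XTC/DCD/XYZ trajectory to a topology; lazily iterable."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty trajectory file")
    if path.suffix.lower() not in _TRAJ_FORMATS:
        raise ValueError(f"{path}: unsupported trajectory format {path.suffix!r}")
    if isinstance(topology, mda.Universe):
        top = topology.filename
    else:
        top = str(topology)
    try:
        u = mda.Universe(top, str(path))
        n_frames = len(u.trajectory)
    except (OSError, ValueError, EOFError) as e:
        raise ValueError(f"{path}: cannot read trajectory ({e})") from None
    if n_frames == 0:
        raise ValueError(f"{path}: trajectory holds no frames")
    return u


def ligand_centroid(universe: mda.Universe) -> np.ndarray:
    """Heavy-atom centroid of HETATM (ligand) records, for the pocket center."""
    try:
        het = universe.select_atoms("record_type HETATM and not name H*")
        if het.n_atoms == 0:
            het = universe.select_atoms("record_type HETATM")
    except mda.exceptions.SelectionError:
        het = universe.atoms[:0]
    if het.n_atoms == 0:
        raise ValueError(
            "no HETATM ligand records; supply the pocket center explicitly"
        )
    return het.positions.mean(axis=0)


def residue_coms(universe: mda.Universe, selection: str = "not record_type HETATM"):
    """Per-frame residue centers of mass -> (frames, residues, 3) plus resids."""
    try:
        group = universe.select_atoms(selection)
    except mda.exceptions.SelectionError:
        group = universe.atoms
    if group.n_atoms == 0:
        group = universe.atoms
    resids = np.array([r.resid for r in group.residues])
    frames = []
    times = []
    for ts in universe.trajectory:
        frames.append(
            np.array([r.atoms.center_of_mass() for r in group.residues])
        )
        times.append(float(ts.time) if np.isfinite(ts.time) else float(ts.frame))
    return np.array(frames), resids, np.array(times)


@dataclass
class TrajectoryBundle:
    """In-memory frames with provenance (synthetic or toy-engine output)."""

    coords: np.ndarray           # (frames, atoms, 3)
    times: np.ndarray
    run_type: str
    replica: int = 0
    names: Optional[Sequence[str]] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        self.times = np.asarray(self.times, float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be (frames, atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ValueError("times length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing within a replica")


def write_xyz(bundle: TrajectoryBundle, path: Union[str, Path]) -> None:
    """Plain multi-frame XYZ (element column defaults to carbon beads)."""
    path = Path(path)
    n = bundle.coords.shape[1]
    names = bundle.names or ["C"] * n
    with open(path, "w") as fh:
        for t, frame in zip(bundle.times, bundle.coords):
            fh.write(f"{n}\n")
            fh.write(f"t={t:.6f} run={bundle.run_type} replica={bundle.replica}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_pdb_frames(
    coords: np.ndarray,
    path: Union[str, Path],
    names: Optional[Sequence[str]] = None,
    resnames: Optional[Sequence[str]] = None,
) -> None:
    """Minimal PDB writer for exported representative structures."""
    coords = np.atleast_3d(np.asarray(coords, float))
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    names = names or [f"C{i+1}" for i in range(n)]
    resnames = resnames or ["BEA"] * n
    with open(path, "w") as fh:
        for model, frame in enumerate(coords, start=1):
            fh.write(f"MODEL     {model:4d}\n")
            for i, (x, y, z) in enumerate(frame):
                fh.write(
                    f"ATOM  {i+1:5d} {names[i][:4]:<4s} {resnames[i][:3]:<3s} A"
                    f"{i+1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_colvar_csv(df: pd.DataFrame, path: Union[str, Path], units: dict) -> None:
    """CSV time series with a commented header stating column units."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + ", ".join(f"{k} [{v}]" for k, v in units.items()) + "\n")
        df.to_csv(fh, index=False)


def provenance_record(config: dict, seed: int, outputs: Sequence[str] = ()) -> dict:
    """Machine-readable record sufficient to re-run a command bit-identically."""
    import MDAnalysis
    import scipy
    import sklearn

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": int(seed),
        "outputs": list(outputs),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "sklearn": sklearn.__version__,
            "MDAnalysis": MDAnalysis.__version__,
            "pandas": pd.__version__,
        },
    }
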