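"""Contact-map featurization and conformational cluster maps.

Protocol: residues whose center of mass lies within 7 A of the pocket
center in the reference structure define a lining shell; every unordered
pair of shell residues contributes one contact, the COM distance passed
through the rational switch S(r) = (1-(r/r0)^4)/(1-(r/r0)^8) with
r0 = 0.8 nm.  The m-frames x n-contacts matrix is reduced to at most 50
principal components, embedded in 2-D with t-SNE (fitted jointly on
apo-run and holo-like frames so the open state is a landmark in map space),
and the non-holo points are clustered with HDBSCAN.  Holo frames are
embedded but never clustered; their map region is summarized by kernel
density contours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from skimage import measure
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .switching import rational_switch

__all__ = [
    "LINING_SHELL_A",
    "ContactFeatureMatrix",
    "ClusterMap",
    "ClusterSummary",
    "select_pocket_residues",
    "switching_value",
    "featurize_frames",
    "reduce_and_embed",
    "cluster_embedding",
    "holo_density_contour",
    "summarize_clusters",
]

LINING_SHELL_A = 7.0  # residue-COM shell radius around the pocket center (A)
HOLO_LABEL = -2       # labels: >=0 cluster id, -1 noise, -2 holo (never clustered)
NOISE_LABEL = -1


def select_pocket_residues(
    residue_coms: np.ndarray,
    pocket_center: np.ndarray,
    shell_radius: float = LINING_SHELL_A,
    residue_ids: Optional[Sequence] = None,
) -> np.ndarray:
    """Residues whose COM lies within the shell of the pocket center.

    The boundary is inclusive (<= shell_radius, in A).  Returns residue ids
    (or indices when ids are not given), deterministically ordered.
    """
    residue_coms = np.asarray(residue_coms, dtype=float)
    d = np.linalg.norm(residue_coms - np.asarray(pocket_center, float), axis=1)
    idx = np.flatnonzero(d <= shell_radius)
    if len(idx) == 0:
        raise ValueError(
            f"no residue COM within {shell_radius} A of the pocket center; "
            "consider a larger shell"
        )
    if residue_ids is not None:
        return np.asarray(residue_ids)[idx]
    return idx


def switching_value(r_nm, r0: float = 0.8, n_sw: int = 4, m_sw: int = 8):
    """Sigmoid contact value S(r) for COM distances in nm (see module doc)."""
    return rational_switch(r_nm, r0, n_sw, m_sw)


@dataclass
class ContactFeatureMatrix:
    """m frames x n contacts, entries in [0, 1].

    ``pair_index`` lists the unordered residue-pair (i, j) behind each
    column; ``provenance`` carries one label per frame (run type, replica,
    time) for the holo mask and exports.
    """

    values: np.ndarray
    pair_index: np.ndarray
    provenance: pd.DataFrame
    r0: float = 0.8
    n_sw: int = 4
    m_sw: int = 8

    def __post_init__(self):
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("contact features must lie in [0, 1]")
        if len(self.provenance) != len(self.values):
            raise ValueError("provenance length mismatch")


def featurize_frames(
    residue_coms: np.ndarray,
    run_type: str = "apo_unbiased",
    replica: int = 0,
    times: Optional[np.ndarray] = None,
    coords_in_angstrom: bool = True,
    r0: float = 0.8,
    n_sw: int = 4,
    m_sw: int = 8,
) -> ContactFeatureMatrix:
    """Sigmoid-contact featurization of per-frame residue COM coordinates.

    ``residue_coms`` has shape (frames, residues, 3); all unordered residue
    pairs form the contact columns.  Distances are converted to nm before
    the switch when given in A.
    """
    coms = np.asarray(residue_coms, dtype=float)
    if coms.ndim != 3:
        raise ValueError("residue_coms must be (frames, residues, 3)")
    if not np.all(np.isfinite(coms)):
        bad = np.flatnonzero(~np.all(np.isfinite(coms), axis=(1, 2)))[0]
        raise ValueError(f"missing/non-finite residue coordinates in frame {bad}")
    f, nres, _ = coms.shape
    iu, ju = np.triu_indices(nres, k=1)
    d = np.linalg.norm(coms[:, iu, :] - coms[:, ju, :], axis=2)
    if coords_in_angstrom:
        d = d / 10.0
    values = rational_switch(d, r0, n_sw, m_sw)
    times = np.arange(f, dtype=float) if times is None else np.asarray(times, float)
    prov = pd.DataFrame(
        {"run_type": run_type, "replica": replica, "time": times, "frame": np.arange(f)}
    )
    return ContactFeatureMatrix(
        values=values,
        pair_index=np.stack([iu, ju], axis=1),
        provenance=prov,
        r0=r0,
        n_sw=n_sw,
        m_sw=m_sw,
    )


def concat_features(parts: Sequence[ContactFeatureMatrix]) -> ContactFeatureMatrix:
    """Stack featurized runs; all parts must share the same contact columns."""
    first = parts[0]
    for p in parts[1:]:
        if p.values.shape[1] != first.values.shape[1] or not np.array_equal(
            p.pair_index, first.pair_index
        ):
            raise ValueError("contact-column mismatch between featurized runs")
    return ContactFeatureMatrix(
        values=np.concatenate([p.values for p in parts], axis=0),
        pair_index=first.pair_index,
        provenance=pd.concat([p.provenance for p in parts], ignore_index=True),
        r0=first.r0,
        n_sw=first.n_sw,
        m_sw=first.m_sw,
    )


def reduce_and_embed(
    features_apo: ContactFeatureMatrix,
    features_holo: Optional[ContactFeatureMatrix],
    seed: int = 0,
    n_components: int = 50,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """PCA (<= 50 components) then 2-D t-SNE on the combined frames.

    Both transformations are fitted on apo + holo frames together so that
    holo-like structures anchor the open-state region of map space.
    Returns (coords (m, 2), holo_mask (m,)).
    """
    parts = [features_apo] + ([features_holo] if features_holo is not None else [])
    combined = concat_features(parts)
    X = combined.values
    m, n = X.shape
    holo_mask = np.zeros(m, dtype=bool)
    if features_holo is not None:
        holo_mask[len(features_apo.values):] = True

    rank = int(min(n_components, n, m - 1))
    if rank < 1:
        raise ValueError("need at least 2 frames and 1 contact to embed")
    Z = PCA(n_components=rank, random_state=seed).fit_transform(X)
    perp = float(min(perplexity, max(2.0, (m - 1) / 3.0)))
    coords = TSNE(
        n_components=2,
        perplexity=perp,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    ).fit_transform(Z)
    return np.asarray(coords, dtype=float), holo_mask


@dataclass
class ClusterMap:
    """2-D embedding with density-based cluster labels.

    ``labels`` has one entry per embedded frame: cluster ids >= 0, -1 for
    noise ("unclustered"), -2 for holo frames, which are embedded but never
    clustered.
    """

    coords: np.ndarray
    labels: np.ndarray
    holo_mask: np.ndarray
    min_cluster_size: int
    provenance: Optional[pd.DataFrame] = None

    @property
    def cluster_ids(self) -> np.ndarray:
        return np.unique(self.labels[self.labels >= 0])

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def cluster_embedding(
    coords: np.ndarray,
    holo_mask: Optional[np.ndarray] = None,
    min_cluster_size: int = 100,
    min_samples: Optional[int] = None,
    provenance: Optional[pd.DataFrame] = None,
) -> ClusterMap:
    """HDBSCAN on the non-holo embedded points.

    ``min_samples`` defaults to ``min_cluster_size``.  An all-noise result
    is valid (zero clusters).
    """
    coords = np.asarray(coords, dtype=float)
    m = len(coords)
    holo_mask = (
        np.zeros(m, dtype=bool) if holo_mask is None else np.asarray(holo_mask, bool)
    )
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    labels = np.full(m, HOLO_LABEL, dtype=int)
    work = ~holo_mask
    n_work = int(np.sum(work))
    if n_work == 0:
        return ClusterMap(coords, labels, holo_mask, min_cluster_size, provenance)
    if n_work < min_cluster_size:
        labels[work] = NOISE_LABEL
        return ClusterMap(coords, labels, holo_mask, min_cluster_size, provenance)
    clus = HDBSCAN(
        min_cluster_size=int(min_cluster_size),
        min_samples=int(min_samples if min_samples is not None else min_cluster_size),
        copy=True,
    )
    labels[work] = clus.fit_predict(coords[work])
    return ClusterMap(coords, labels, holo_mask, min_cluster_size, provenance)


def holo_density_contour(
    coords: np.ndarray,
    holo_mask: np.ndarray,
    levels: Sequence[float] = (0.1, 0.5),
    grid_size: int = 200,
) -> list[dict]:
    """Kernel-density iso-contours of the holo region of map space.

    Scott's-rule Gaussian KDE over the holo points, evaluated on a regular
    grid; contours at the given fractions of the peak density are returned
    as lists of polylines in embedding coordinates.
    """
    coords = np.asarray(coords, float)
    pts = coords[np.asarray(holo_mask, bool)]
    if len(pts) < 10:
        raise ValueError("need at least 10 holo points for a density contour")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("holo points are degenerate (all identical)")
    kde = gaussian_kde(pts.T)  # Scott's rule bandwidth
    pad = 0.1 * (pts.max(axis=0) - pts.min(axis=0) + 1e-12)
    lo, hi = pts.min(axis=0) - pad, pts.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    dens = kde(np.stack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
    peak = dens.max()
    out = []
    for lev in levels:
        polylines = []
        if 0 < lev < 1:
            for contour in measure.find_contours(dens, lev * peak):
                # grid index -> data coordinates
                px = np.interp(contour[:, 0], np.arange(grid_size), xs)
                py = np.interp(contour[:, 1], np.arange(grid_size), ys)
                polylines.append(np.stack([px, py], axis=1))
        out.append({"level": float(lev), "polylines": polylines})
    return out


@dataclass
class ClusterSummary:
    cluster_id: int
    size: int
    median_exposure: float
    median_rmsd: float
    representative_frames: np.ndarray
    warning: Optional[str] = None


def summarize_clusters(
    cmap: ClusterMap,
    exposure: np.ndarray,
    rmsd: np.ndarray,
    k: int = 10,
) -> list[ClusterSummary]:
    """Per-cluster medians plus the k frames nearest the embedding centroid.

    ``exposure`` and ``rmsd`` are frame-aligned with the embedding.  When a
    cluster holds fewer than k members, all are returned with a warning.
    """
    exposure = np.asarray(exposure, float)
    rmsd = np.asarray(rmsd, float)
    if len(exposure) != len(cmap.coords) or len(rmsd) != len(cmap.coords):
        raise ValueError("metric series must be frame-aligned with the embedding")
    out = []
    for cid in cmap.cluster_ids:
        member = np.flatnonzero(cmap.labels == cid)
        centroid = cmap.coords[member].mean(axis=0)
        d = np.linalg.norm(cmap.coords[member] - centroid, axis=1)
        order = member[np.argsort(d)]
        warn = None
        if len(member) < k:
            warn = f"cluster {cid} has only {len(member)} members (< k={k})"
        out.append(
            ClusterSummary(
                cluster_id=int(cid),
                size=int(len(member)),
                median_exposure=float(np.median(exposure[member])),
                median_rmsd=float(np.median(rmsd[member])),
                representative_frames=order[:k],
                warning=warn,
            )
        )
    return out
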