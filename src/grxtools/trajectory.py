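"""Binding-event analytics for GS- diffusion trajectories.

A glutathionylated glutaredoxin carries a mixed disulfide between the
active-site cysteine sulfur and the sulfur of the covalently bound
glutathione moiety.  Free, deprotonated glutathione (GS-) diffusing in the
solvent is counted as *bound* in a frame when its sulfur atom lies within a
distance cutoff (default 5.5 Angstrom, boundary inclusive) of the center of
the two disulfide sulfurs, implemented as their unweighted midpoint.

On top of this criterion the module provides: per-replication bound-state
fractions with Welch t tests between variants, S-S distance / S-S-S angle
tables with 2D histograms and Pearson correlation, 3D occupancy density
grids of bound GS- sulfur positions, pre-binding path linearization, and
agglomerative clustering of binding poses by superposition RMSD.

Trajectories are assumed unwrapped; no periodic-boundary handling is done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from scipy import ndimage

__all__ = [
    "TrajectoryReplicate",
    "GsTrajectory",
    "BindingEvent",
    "DensityGrid",
    "detect_bound",
    "binding_events",
    "FractionBoundResult",
    "fraction_bound",
    "welch_ttest",
    "SSSGeometry",
    "sss_geometry",
    "occupation_density",
    "linearize_path",
    "kabsch_rmsd",
    "PoseClusters",
    "cluster_poses",
]

DEFAULT_CUTOFF = 5.5  # Angstrom


@dataclass
class TrajectoryReplicate:
    """One simulation replication: GS- sulfurs plus the disulfide sulfur pair.

    ``gs_xyz``        (n_frames, n_gs, 3) coordinates of free GS- sulfurs (A)
    ``disulfide_xyz`` (n_frames, 2, 3); index 0 is the active-site Cys sulfur,
                      index 1 the glutathione-moiety sulfur.
    """

    gs_xyz: np.ndarray
    disulfide_xyz: np.ndarray
    frame_interval_ps: float = 20.0
    replicate: int = 0

    def __post_init__(self) -> None:
        self.gs_xyz = np.asarray(self.gs_xyz, dtype=float)
        self.disulfide_xyz = np.asarray(self.disulfide_xyz, dtype=float)
        if self.gs_xyz.ndim != 3 or self.gs_xyz.shape[2] != 3:
            raise ValueError("gs_xyz must have shape (n_frames, n_gs, 3)")
        if self.gs_xyz.shape[1] < 1:
            raise ValueError("need >= 1 GS- molecule per frame")
        if self.disulfide_xyz.shape != (self.gs_xyz.shape[0], 2, 3):
            raise ValueError("disulfide_xyz must have shape (n_frames, 2, 3)")
        if not (np.isfinite(self.gs_xyz).all()
                and np.isfinite(self.disulfide_xyz).all()):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.gs_xyz.shape[0]

    @property
    def n_gs(self) -> int:
        return self.gs_xyz.shape[1]


@dataclass
class GsTrajectory:
    """A set of independent simulation replications."""

    replicates: list[TrajectoryReplicate]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError("empty trajectory")

    @property
    def n_frames_total(self) -> int:
        return sum(r.n_frames for r in self.replicates)


@dataclass(frozen=True)
class BindingEvent:
    """One (frame, GS- molecule) pair satisfying the distance criterion."""

    replicate: int
    frame: int
    gs_index: int
    s_s_distance: float
    s_s_s_angle: float | None = None


def _midpoints(disulfide_xyz: np.ndarray) -> np.ndarray:
    return disulfide_xyz.mean(axis=-2)


def detect_bound(gs_xyz: np.ndarray, disulfide_xyz: np.ndarray,
                 cutoff: float = DEFAULT_CUTOFF) -> list[BindingEvent]:
    """Binding events in a single frame (boundary inclusive at the cutoff)."""
    gs_xyz = np.asarray(gs_xyz, dtype=float)
    mid = np.asarray(disulfide_xyz, dtype=float).mean(axis=0)
    d = np.linalg.norm(gs_xyz - mid, axis=-1)
    return [
        BindingEvent(replicate=0, frame=0, gs_index=int(i), s_s_distance=float(d[i]))
        for i in np.nonzero(d <= cutoff)[0]
    ]


def _distances(rep: TrajectoryReplicate) -> np.ndarray:
    """(n_frames, n_gs) distances of each GS- sulfur to the disulfide midpoint."""
    mid = _midpoints(rep.disulfide_xyz)  # (n_frames, 3)
    return np.linalg.norm(rep.gs_xyz - mid[:, None, :], axis=-1)


def binding_events(traj: GsTrajectory,
                   cutoff: float = DEFAULT_CUTOFF) -> list[BindingEvent]:
    """All binding events across replications, with distances filled in."""
    events: list[BindingEvent] = []
    for rep in traj.replicates:
        d = _distances(rep)
        frames, gs_idx = np.nonzero(d <= cutoff)
        for f, g in zip(frames, gs_idx):
            events.append(BindingEvent(
                replicate=rep.replicate, frame=int(f), gs_index=int(g),
                s_s_distance=float(d[f, g]),
            ))
    return events


@dataclass
class FractionBoundResult:
    """Per-replication fractions of frames with >= 1 binding event."""

    fractions: np.ndarray
    cutoff: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.fractions))

    @property
    def sem(self) -> float:
        if self.fractions.size < 2:
            return float("nan")
        return float(np.std(self.fractions, ddof=1) / np.sqrt(self.fractions.size))

    def normalized_pct(self, reference: "FractionBoundResult") -> float:
        """This variant's mean as percent of the reference mean (= 100%)."""
        return 100.0 * self.mean / reference.mean

    def summary(self) -> str:
        return (
            f"fraction bound = {self.mean:.4f} +/- {self.sem:.4f} (SEM, "
            f"n={self.fractions.size} replications; cutoff {self.cutoff} A)"
        )


def fraction_bound(traj: GsTrajectory,
                   cutoff: float = DEFAULT_CUTOFF) -> FractionBoundResult:
    """Fraction of frames with a binding event, per replication."""
    fractions = []
    for rep in traj.replicates:
        if rep.n_frames == 0:
            raise ValueError("empty replicate")
        d = _distances(rep)
        bound_frames = np.any(d <= cutoff, axis=1)
        fractions.append(bound_frames.mean())
    return FractionBoundResult(fractions=np.asarray(fractions), cutoff=cutoff)


def welch_ttest(a: FractionBoundResult, b: FractionBoundResult):
    """Two-tailed t test assuming unequal variances on per-replication fractions."""
    t, p = sps.ttest_ind(a.fractions, b.fractions, equal_var=False)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# S-S distance / S-S-S angle geometry
# ---------------------------------------------------------------------------

def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.einsum("...i,...i->...", v1, v2) / (n1 * n2)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


@dataclass
class SSSGeometry:
    table: pd.DataFrame
    hist: np.ndarray
    dist_edges: np.ndarray
    angle_edges: np.ndarray
    r2: float
    pvalue: float
    vertex: str
    correlation_defined: bool = True


def sss_geometry(traj: GsTrajectory, cutoff: float = DEFAULT_CUTOFF,
                 vertex: str = "cys",
                 dist_bin: float = 0.1, angle_bin: float = 2.0) -> SSSGeometry:
    """Per-event S-S distance and S-S-S angle with histogram and correlation.

    The S-S distance is between the GS- sulfur and the disulfide-sulfur
    midpoint.  The angle vertex convention is configurable: ``"cys"``
    (default) puts the vertex at the active-site cysteine sulfur,
    angle(GS-S, Cys-S, moiety-S); ``"gs"`` puts it at the incoming GS-
    sulfur, angle(Cys-S, GS-S, moiety-S).
    """
    if vertex not in ("cys", "gs"):
        raise ValueError("vertex must be 'cys' or 'gs'")
    rows = []
    for rep in traj.replicates:
        d = _distances(rep)
        frames, gs_idx = np.nonzero(d <= cutoff)
        if frames.size == 0:
            continue
        gs = rep.gs_xyz[frames, gs_idx]           # (n_ev, 3)
        cys = rep.disulfide_xyz[frames, 0]
        moi = rep.disulfide_xyz[frames, 1]
        if vertex == "cys":
            ang = _angle_deg(gs - cys, moi - cys)
        else:
            ang = _angle_deg(cys - gs, moi - gs)
        for k in range(frames.size):
            rows.append({
                "replicate": rep.replicate, "frame": int(frames[k]),
                "gs_index": int(gs_idx[k]),
                "s_s_distance": float(d[frames[k], gs_idx[k]]),
                "s_s_s_angle": float(ang[k]),
            })
    if not rows:
        raise ValueError("no binding events at this cutoff")
    table = pd.DataFrame(rows)

    dist = table["s_s_distance"].to_numpy()
    angle = table["s_s_s_angle"].to_numpy()
    dist_edges = np.arange(0.0, cutoff + dist_bin, dist_bin)
    angle_edges = np.arange(0.0, 180.0 + angle_bin, angle_bin)
    hist, _, _ = np.histogram2d(dist, angle, bins=[dist_edges, angle_edges])

    if len(table) >= 3 and np.ptp(dist) > 0 and np.ptp(angle) > 0:
        r, p = sps.pearsonr(dist, angle)
        r2, p, defined = float(r ** 2), float(p), True
    else:
        r2, p, defined = float("nan"), float("nan"), False
    return SSSGeometry(
        table=table, hist=hist, dist_edges=dist_edges, angle_edges=angle_edges,
        r2=r2, pvalue=p, vertex=vertex, correlation_defined=defined,
    )


# ---------------------------------------------------------------------------
# Occupancy density grid
# ---------------------------------------------------------------------------

@dataclass
class DensityGrid:
    """3D occupancy counts of bound-state GS- sulfur positions."""

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_samples: int
    meta: dict = field(default_factory=dict)

    def threshold_mask(self, level: float) -> np.ndarray:
        """Boolean iso-mask at a caller-fixed count level (>= level)."""
        return self.counts >= level

    def components(self, level: float) -> int:
        """Number of connected above-threshold components (26-connectivity)."""
        mask = self.threshold_mask(level)
        structure = np.ones((3, 3, 3), dtype=int)
        _, n = ndimage.label(mask, structure=structure)
        return int(n)


def occupation_density(traj: GsTrajectory, spacing: float,
                       cutoff: float = DEFAULT_CUTOFF) -> DensityGrid:
    """Bin bound-state GS- sulfur positions on a 3D grid.

    Bound states are combined across replications.  The iso-threshold for
    display is chosen by the caller so that different variants are
    comparable at the same level.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    points = []
    for rep in traj.replicates:
        d = _distances(rep)
        frames, gs_idx = np.nonzero(d <= cutoff)
        if frames.size:
            points.append(rep.gs_xyz[frames, gs_idx])
    if not points:
        import warnings
        warnings.warn("no bound states; returning empty density grid")
        return DensityGrid(origin=np.zeros(3), spacing=spacing,
                           counts=np.zeros((1, 1, 1)), n_samples=0)
    pts = np.concatenate(points, axis=0)
    origin = np.floor(pts.min(axis=0) / spacing) * spacing
    idx = np.floor((pts - origin) / spacing).astype(int)
    dims = idx.max(axis=0) + 1
    counts = np.zeros(dims, dtype=float)
    np.add.at(counts, tuple(idx.T), 1.0)
    return DensityGrid(origin=origin, spacing=spacing, counts=counts,
                       n_samples=int(pts.shape[0]))


# ---------------------------------------------------------------------------
# Pre-binding path linearization
# ---------------------------------------------------------------------------

def linearize_path(traj: GsTrajectory, event: BindingEvent,
                   window: int = 25, smooth: int = 5):
    """Smoothed GS- path over the ``window`` frames ending at the bound frame.

    Returns (path, truncated): positions (<= window, 3) smoothed by a
    centered moving average of width ``smooth`` (shrinking symmetrically at
    the ends, so straight-line approaches are preserved exactly), and a flag
    set when the event lies within the first ``window`` frames.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    rep = next(r for r in traj.replicates if r.replicate == event.replicate)
    start = event.frame - window + 1
    truncated = start < 0
    start = max(start, 0)
    raw = rep.gs_xyz[start:event.frame + 1, event.gs_index]
    if smooth <= 1 or raw.shape[0] < 3:
        return raw.copy(), truncated
    half = smooth // 2
    n = raw.shape[0]
    out = np.empty_like(raw)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[i] = raw[i - k:i + k + 1].mean(axis=0)
    return out, truncated


# ---------------------------------------------------------------------------
# Pose clustering
# ---------------------------------------------------------------------------

def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two (n_atoms, 3) poses after optimal rigid
    superposition (translation + proper rotation), via the Kabsch SVD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("poses must share shape (n_atoms, 3)")
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    h = ac.T @ bc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    # reflection correction keeps the rotation proper
    e = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(e) @ u.T
    diff = ac @ rot.T - bc
    return float(np.sqrt((diff ** 2).sum() / a.shape[0]))


@dataclass
class PoseClusters:
    labels: np.ndarray              # cluster index per pose, 0 = most populated
    representatives: np.ndarray     # pose index of each cluster representative
    populations: np.ndarray         # cluster sizes, descending
    rmsd_matrix: np.ndarray


def cluster_poses(poses: np.ndarray, k: int = 2) -> PoseClusters:
    """Agglomerative (average-linkage) clustering of binding poses.

    ``poses`` is (n_poses, n_atoms, 3); distances are pairwise superposition
    RMSDs.  Clusters are cut at a fixed count ``k`` and relabelled by
    population (label 0 = most populated).  The representative of a cluster
    is the member minimizing the mean RMSD to its cluster.
    """
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 3:
        raise ValueError("poses must have shape (n_poses, n_atoms, 3)")
    n = poses.shape[0]
    if n == 1:
        return PoseClusters(
            labels=np.zeros(1, dtype=int), representatives=np.array([0]),
            populations=np.array([1]), rmsd_matrix=np.zeros((1, 1)),
        )
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = kabsch_rmsd(poses[i], poses[j])
    k_eff = min(k, n)
    z = linkage(squareform(dmat, checks=False), method="average")
    raw_labels = fcluster(z, t=k_eff, criterion="maxclust") - 1
    # order clusters by population, descending (ties by first occurrence)
    sizes = np.bincount(raw_labels)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(order.size)
    labels = remap[raw_labels]
    populations = sizes[order]
    reps = []
    for c in range(populations.size):
        members = np.nonzero(labels == c)[0]
        sub = dmat[np.ix_(members, members)]
        reps.append(int(members[np.argmin(sub.mean(axis=1))]))
    return PoseClusters(
        labels=labels, representatives=np.asarray(reps),
        populations=populations, rmsd_matrix=dmat,
    )
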