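"""Discretization of projected trajectories into representative
conformations: k-means (with medoid frame extraction), GROMOS neighbor
clustering, cutoff selection, and cluster populations."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dimred import FeatureMatrix
from .errors import CutoffSelectionError, InvalidArgumentError
from .structures import Trajectory, write_multimodel_pdb

__all__ = [
    "ClusterModel",
    "kmeans_cluster",
    "medoid_frames",
    "gromos_cluster",
    "select_gromos_cutoff",
    "cluster_populations",
    "extract_centroid_ensemble",
    "DEFAULT_GROMOS_CRITERIA",
]


@dataclass
class ClusterModel:
    """Per-frame labels plus medoid frames and populations.

    Cluster 0 is the first/largest cluster (GROMOS emits clusters in
    decreasing size by construction).
    """

    method: str
    labels: np.ndarray
    k: int
    medoid_frames: np.ndarray
    populations: np.ndarray
    centers: np.ndarray | None = None
    cutoff: float | None = None
    seed: int | None = None
    feature_label: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.medoid_frames = np.asarray(self.medoid_frames, dtype=int)
        self.populations = np.asarray(self.populations, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise InvalidArgumentError(
                f"labels must cover exactly 0..{self.k - 1}"
            )
        if self.populations.sum() != self.labels.size:
            raise InvalidArgumentError("populations must sum to frame count")
        for i, f in enumerate(self.medoid_frames):
            if self.labels[f] != i:
                raise InvalidArgumentError(
                    f"medoid frame {f} does not carry label {i}"
                )

    @property
    def n_frames(self) -> int:
        return int(self.labels.size)


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator):
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _assign(X: np.ndarray, centers: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def kmeans_cluster(
    Y,
    k: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    restarts: int = 1,
) -> ClusterModel:
    """Lloyd's k-means with k-means++ initialization.

    Empty clusters are reseeded to the point farthest from its center.  With
    ``restarts`` > 1 the solution with the lowest within-cluster sum of
    squares wins.  Medoid frames are filled in by :func:`medoid_frames`.
    """
    X = Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if n < k:
        raise InvalidArgumentError(f"cannot form {k} clusters from {n} frames")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(restarts, 1)):
        centers = _kmeans_pp_init(X, k, rng)
        history: list[float] = []
        for _ in range(max_iter):
            labels = _assign(X, centers)
            history.append(float(((X - centers[labels]) ** 2).sum()))
            new_centers = centers.copy()
            for j in range(k):
                members = X[labels == j]
                if members.shape[0] == 0:
                    # reseed to the point farthest from its assigned center
                    far = ((X - centers[labels]) ** 2).sum(axis=1).argmax()
                    new_centers[j] = X[far]
                else:
                    new_centers[j] = members.mean(axis=0)
            shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
            centers = new_centers
            if shift < tol:
                break
        labels = _assign(X, centers)
        # guard: reseed any cluster left empty by the final assignment
        while np.bincount(labels, minlength=k).min() == 0:
            j = int(np.bincount(labels, minlength=k).argmin())
            far = ((X - centers[labels]) ** 2).sum(axis=1).argmax()
            centers[j] = X[far]
            labels = _assign(X, centers)
        inertia = ((X - centers[labels]) ** 2).sum()
        if best is None or inertia < best[0]:
            best = (inertia, labels, centers, history)

    _, labels, centers, history = best
    # relabel so that cluster 0 is the largest (ties by original label)
    counts = np.bincount(labels, minlength=k)
    order = np.lexsort((np.arange(k), -counts))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers = centers[order]
    populations = np.bincount(labels, minlength=k)

    model = ClusterModel.__new__(ClusterModel)
    model.method = "kmeans"
    model.labels = labels
    model.k = k
    model.centers = centers
    model.populations = populations
    model.cutoff = None
    model.seed = seed
    model.feature_label = ""
    model.medoid_frames = _medoids(X, labels, centers, k)
    ClusterModel.__post_init__(model)
    model.inertia_history = history  # objective after each Lloyd assignment
    return model


def _medoids(X, labels, centers, k) -> np.ndarray:
    out = np.empty(k, dtype=int)
    for j in range(k):
        members = np.nonzero(labels == j)[0]
        d2 = ((X[members] - centers[j]) ** 2).sum(axis=1)
        out[j] = members[d2.argmin()]  # argmin takes the lowest index on ties
    return out


def medoid_frames(Y, model: ClusterModel) -> np.ndarray:
    """Frame index per cluster minimizing distance to the continuous center
    in the projected space (ties to the lowest frame index)."""
    X = Y.values if isinstance(Y, FeatureMatrix) else np.asarray(Y, float)
    if X.ndim == 1:
        X = X[:, None]
    if model.centers is None:
        raise InvalidArgumentError("model has no continuous centers")
    return _medoids(X, model.labels, model.centers, model.k)


def gromos_cluster(D: np.ndarray, cutoff: float) -> ClusterModel:
    """Daura neighbor-counting clustering on a pairwise RMSD matrix.

    Repeatedly picks the unassigned frame with the most unassigned neighbors
    within ``cutoff`` (inclusive; ties to the lowest frame index) as the next
    cluster center and removes it with its neighbors.  Clusters come out in
    order of decreasing size; each cluster's medoid is its center frame.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise InvalidArgumentError("D must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise InvalidArgumentError("D must be symmetric")
    if np.any(D < 0):
        raise InvalidArgumentError("D must be non-negative")
    if cutoff <= 0:
        raise InvalidArgumentError("cutoff must be positive")

    n = D.shape[0]
    adj = D <= cutoff
    np.fill_diagonal(adj, True)
    unassigned = np.ones(n, dtype=bool)
    labels = np.full(n, -1, dtype=int)
    centers: list[int] = []
    sizes: list[int] = []
    while unassigned.any():
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(counts.argmax())  # argmax ties -> lowest index
        members = np.nonzero(adj[center] & unassigned)[0]
        labels[members] = len(centers)
        centers.append(center)
        sizes.append(members.size)
        unassigned[members] = False

    # order clusters by decreasing size, ties by discovery order
    k = len(centers)
    order = np.lexsort((np.arange(k), -np.asarray(sizes)))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]
    centers_arr = np.asarray(centers)[order]
    populations = np.asarray(sizes)[order]

    model = ClusterModel.__new__(ClusterModel)
    model.method = "gromos"
    model.labels = labels
    model.k = k
    model.centers = None
    model.medoid_frames = centers_arr
    model.populations = populations
    model.cutoff = float(cutoff)
    model.seed = None
    model.feature_label = ""
    ClusterModel.__post_init__(model)
    return model


DEFAULT_GROMOS_CRITERIA = dict(
    max_first_fraction=0.70,   # first cluster holds < 70% of frames
    min_top10_coverage=0.80,   # first 10 clusters hold >= 80% of frames
    min_cluster_frames=20,     # each of the first 10 clusters has >= 20 frames
)


def _criteria_report(model: ClusterModel, criteria: dict) -> dict:
    f = model.populations
    total = f.sum()
    top = f[: min(10, model.k)]
    first_frac = f[0] / total
    coverage = top.sum() / total
    min_frames = int(top.min())
    return {
        "k": model.k,
        "first_fraction": float(first_frac),
        "top10_coverage": float(coverage),
        "min_top10_frames": min_frames,
        "pass_i": bool(first_frac < criteria["max_first_fraction"]),
        "pass_ii": bool(coverage >= criteria["min_top10_coverage"]),
        "pass_iii": bool(min_frames >= criteria["min_cluster_frames"]),
    }


def select_gromos_cutoff(
    D: np.ndarray,
    candidates,
    criteria: dict | None = None,
):
    """First candidate cutoff whose clustering satisfies all three criteria:
    (i) first cluster < 70% of frames, (ii) first 10 clusters >= 80% of
    frames, (iii) each of the first 10 clusters >= 20 frames.

    With fewer than 10 clusters the criteria are evaluated over all existing
    clusters.  Returns (cutoff, per-candidate report list); raises
    CutoffSelectionError carrying the report if nothing passes.
    """
    candidates = list(candidates)
    if not candidates:
        raise InvalidArgumentError("need at least one candidate cutoff")
    crit = dict(DEFAULT_GROMOS_CRITERIA)
    if criteria:
        crit.update(criteria)
    report = []
    chosen = None
    for c in candidates:
        model = gromos_cluster(D, c)
        row = {"cutoff": float(c), **_criteria_report(model, crit)}
        row["pass"] = row["pass_i"] and row["pass_ii"] and row["pass_iii"]
        report.append(row)
        if row["pass"] and chosen is None:
            chosen = float(c)
    if chosen is None:
        raise CutoffSelectionError(
            "no candidate cutoff satisfied the clustering criteria",
            report=report,
        )
    return chosen, report


def cluster_populations(model: ClusterModel) -> np.ndarray:
    """P_i = f_i / f_T, normalized so the populations sum to 1."""
    f = model.populations.astype(float)
    return f / f.sum()


def extract_centroid_ensemble(
    traj: Trajectory,
    model: ClusterModel,
    out_dir: str | Path | None = None,
    name_prefix: str = "cluster",
):
    """Single-frame structures at the medoid frames, coordinates untouched.

    Returns (list of single-frame Trajectories, manifest rows).  If
    ``out_dir`` is given, each centroid is written as
    ``<name_prefix>_c<id>.pdb`` plus a ``<name_prefix>_manifest.csv`` with
    columns cluster, frame_index, f_i, P_i.
    """
    if np.any(model.medoid_frames >= traj.n_frames):
        raise InvalidArgumentError("medoid frame index out of range")
    P = cluster_populations(model)
    structures = [traj.frame(int(f)) for f in model.medoid_frames]
    manifest = [
        {
            "cluster": i,
            "frame_index": int(model.medoid_frames[i]),
            "f_i": int(model.populations[i]),
            "P_i": float(P[i]),
        }
        for i in range(model.k)
    ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(structures):
            write_multimodel_pdb(s, out_dir / f"{name_prefix}_c{i}.pdb")
        with open(out_dir / f"{name_prefix}_manifest.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["cluster", "frame_index", "f_i", "P_i"])
            w.writeheader()
            for row in manifest:
                w.writerow(row)
    return structures, manifest


def write_labels_csv(model: ClusterModel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "cluster"])
        for f, lbl in enumerate(model.labels):
            w.writerow([f, int(lbl)])
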