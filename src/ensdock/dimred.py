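"""PCA and TICA dimensionality reduction with variance cutoffs, and the
cross-validated VAMP2 score used to choose between candidate feature sets.

TICA solves the generalized eigenproblem between the instantaneous
covariance C0 and the symmetrized lagged covariance, yielding the slowest
linear collective coordinates; the retained dimension is chosen by
cumulative kinetic variance (lambda^2) by default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    ShapeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "ReductionModel",
    "fit_pca",
    "fit_tica",
    "project",
    "vamp2_cv_score",
    "choose_feature_set",
]


@dataclass
class FeatureMatrix:
    """F x d real feature matrix with optional labels and time metadata."""

    values: np.ndarray
    feature_labels: list[str] | None = None
    frame_spacing: float = 1.0

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim == 1:
            vals = vals[:, None]
        if vals.ndim != 2:
            raise ShapeError(f"feature matrix must be 2-D, got shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise InvalidArgumentError("feature matrix must be finite")
        self.values = vals

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ReductionModel:
    """Fitted linear reduction (PCA or TICA).

    ``basis`` holds one component per column; ``eigenvalues`` are sorted
    descending.  ``retained_m`` is the smallest m whose cumulative variance
    share reaches ``variance_cutoff`` (kinetic variance, lambda^2, for TICA
    unless ``tica_variance='eigenvalue'`` was requested at fit time).
    """

    kind: str
    mean_vector: np.ndarray
    basis: np.ndarray
    eigenvalues: np.ndarray
    lag: int
    variance_cutoff: float
    retained_m: int
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "mean_vector": self.mean_vector.tolist(),
            "basis": self.basis.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "lag": self.lag,
            "variance_cutoff": self.variance_cutoff,
            "retained_m": self.retained_m,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReductionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            kind=d["kind"],
            mean_vector=np.array(d["mean_vector"]),
            basis=np.array(d["basis"]),
            eigenvalues=np.array(d["eigenvalues"]),
            lag=d["lag"],
            variance_cutoff=d["variance_cutoff"],
            retained_m=d["retained_m"],
        )


def _as_blocks(X) -> list[np.ndarray]:
    """Accept a FeatureMatrix, ndarray, or list thereof (multiple
    trajectories); covariances are accumulated per block so no lagged pair
    straddles a trajectory boundary."""
    if isinstance(X, (list, tuple)):
        return [np.asarray(b.values if isinstance(b, FeatureMatrix) else b, float)
                for b in X]
    if isinstance(X, FeatureMatrix):
        return [X.values]
    return [np.asarray(X, dtype=float)]


def _retained_m(weights: np.ndarray, cutoff: float) -> int:
    total = weights.sum()
    if total <= 0:
        return 1
    frac = np.cumsum(weights) / total
    return int(np.searchsorted(frac, cutoff - 1e-12) + 1)


def fit_pca(X, variance_cutoff: float = 0.95) -> ReductionModel:
    """Eigendecomposition of the sample covariance of mean-free X."""
    if not 0 < variance_cutoff <= 1:
        raise InvalidArgumentError("variance_cutoff must be in (0, 1]")
    blocks = _as_blocks(X)
    data = np.vstack(blocks)
    if data.shape[0] < 2:
        raise InvalidArgumentError("PCA needs at least 2 frames")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if evals[0] <= 1e-14 * max(1.0, np.abs(cov).max(), 1e-300):
        raise DegenerateInputError("input has zero variance; PCA is undefined")
    m = _retained_m(evals, variance_cutoff)
    return ReductionModel(
        kind="pca",
        mean_vector=mean,
        basis=evecs,
        eigenvalues=evals,
        lag=0,
        variance_cutoff=variance_cutoff,
        retained_m=m,
    )


def _lagged_covariances(blocks: list[np.ndarray], lag: int):
    """Mean-free instantaneous and symmetrized lagged covariances, accumulated
    over blocks; the mean is taken over all frames participating in pairs."""
    d = blocks[0].shape[1]
    pairs = [(b[:-lag], b[lag:]) for b in blocks if b.shape[0] > lag]
    if not pairs:
        raise InvalidArgumentError(f"no block has more than lag={lag} frames")
    n = sum(x.shape[0] for x, _ in pairs)
    mean = sum(x.sum(0) + y.sum(0) for x, y in pairs) / (2 * n)
    c0 = np.zeros((d, d))
    ct = np.zeros((d, d))
    for x, y in pairs:
        xc, yc = x - mean, y - mean
        c0 += xc.T @ xc + yc.T @ yc
        ct += xc.T @ yc
    c0 /= 2 * n
    ct /= n
    ct = 0.5 * (ct + ct.T)
    return mean, c0, ct, n


def fit_tica(
    X,
    lag: int,
    variance_cutoff: float = 0.95,
    tica_variance: str = "kinetic",
    ridge: float = 1e-10,
) -> ReductionModel:
    """TICA: generalized eigenproblem C_tau v = lambda C0 v.

    The lagged covariance is symmetrized (reversibility enforced at the
    estimator level) so eigenvalues are real.  ``ridge`` scales a diagonal
    regularizer ridge * trace(C0)/d added to C0.
    """
    if lag < 1:
        raise InvalidArgumentError("lag must be >= 1 frame")
    if not 0 < variance_cutoff <= 1:
        raise InvalidArgumentError("variance_cutoff must be in (0, 1]")
    if tica_variance not in ("kinetic", "eigenvalue"):
        raise InvalidArgumentError("tica_variance must be 'kinetic' or 'eigenvalue'")
    blocks = _as_blocks(X)
    if all(b.shape[0] <= lag for b in blocks):
        raise InvalidArgumentError(f"lag={lag} >= number of frames")
    mean, c0, ct, _ = _lagged_covariances(blocks, lag)
    d = c0.shape[0]
    c0r = c0 + np.eye(d) * (ridge * np.trace(c0) / d)
    try:
        evals, evecs = scipy.linalg.eigh(ct, c0r)
    except scipy.linalg.LinAlgError as exc:
        raise DegenerateInputError(f"C0 numerically singular: {exc}")
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    weights = evals ** 2 if tica_variance == "kinetic" else np.abs(evals)
    m = _retained_m(weights, variance_cutoff)
    return ReductionModel(
        kind="tica",
        mean_vector=mean,
        basis=evecs,
        eigenvalues=evals,
        lag=lag,
        variance_cutoff=variance_cutoff,
        retained_m=m,
        extra={"tica_variance": tica_variance},
    )


def project(X, model: ReductionModel, kinetic_map: bool = False) -> FeatureMatrix:
    """(X - mean) @ basis[:, :retained_m].

    With ``kinetic_map=True`` (TICA only) each retained component is scaled
    by |lambda_i| so that Euclidean distances in the projected space
    approximate kinetic distances; useful before k-means, since raw TICs are
    C0-normalized to unit variance and slow/noise directions would otherwise
    weigh equally.
    """
    fm = X if isinstance(X, FeatureMatrix) else FeatureMatrix(np.asarray(X, float))
    if fm.n_features != model.basis.shape[0]:
        raise ShapeError(
            f"feature dimension {fm.n_features} does not match model "
            f"dimension {model.basis.shape[0]}"
        )
    Y = (fm.values - model.mean_vector) @ model.basis[:, : model.retained_m]
    if kinetic_map:
        if model.kind != "tica":
            raise InvalidArgumentError("kinetic_map scaling applies to TICA only")
        Y = Y * np.abs(model.eigenvalues[: model.retained_m])
    labels = [f"{model.kind}_{i}" for i in range(model.retained_m)]
    return FeatureMatrix(Y, labels, fm.frame_spacing)


# ---------------------------------------------------------------------------
# VAMP2
# ---------------------------------------------------------------------------

def _half_weighted_covariances(x: np.ndarray, y: np.ndarray,
                               mean0: np.ndarray, meant: np.ndarray):
    xc, yc = x - mean0, y - meant
    n = x.shape[0]
    c00 = xc.T @ xc / n
    ctt = yc.T @ yc / n
    c0t = xc.T @ yc / n
    return c00, ctt, c0t


def _inv_sqrt(mat: np.ndarray, rel_eps: float = 1e-10) -> np.ndarray:
    evals, evecs = np.linalg.eigh(mat)
    cut = rel_eps * max(evals.max(), 0.0) + 1e-300
    keep = evals > cut
    inv = np.zeros_like(evals)
    inv[keep] = evals[keep] ** -0.5
    return evecs @ np.diag(inv) @ evecs.T


def _vamp_fit(x: np.ndarray, y: np.ndarray, k: int):
    """Linear VAMP on mean-free pairs; returns singular directions in the
    original feature space plus the training means."""
    mean0 = x.mean(axis=0)
    meant = y.mean(axis=0)
    c00, ctt, c0t = _half_weighted_covariances(x, y, mean0, meant)
    c00_is = _inv_sqrt(c00)
    ctt_is = _inv_sqrt(ctt)
    K = c00_is @ c0t @ ctt_is
    U, s, Vt = np.linalg.svd(K)
    r = min(k - 1, U.shape[1])  # the constant singular function takes one slot
    u = c00_is @ U[:, :r]
    v = ctt_is @ Vt[:r].T
    return mean0, meant, u, v, s[:r]


def _vamp2_in_sample(x, y, k):
    _, _, _, _, s = _vamp_fit(x, y, k)
    return 1.0 + float((s ** 2).sum())


def _vamp2_out_of_sample(fit, x, y, k):
    """Score held-out pairs with the fitted singular functions: VAMP2 of the
    projected test data (constant function contributes 1)."""
    mean0, meant, u, v, _ = fit
    if u.shape[1] == 0:
        return 1.0
    f = (x - mean0) @ u
    g = (y - meant) @ v
    # Center the projections on the test set so the constant direction is
    # factored out, then whiten both sides.
    fm, gm = f.mean(axis=0), g.mean(axis=0)
    fc, gc = f - fm, g - gm
    n = f.shape[0]
    cff = fc.T @ fc / n
    cgg = gc.T @ gc / n
    cfg = fc.T @ gc / n
    M = _inv_sqrt(cff) @ cfg @ _inv_sqrt(cgg)
    s = np.linalg.svd(M, compute_uv=False)
    s = np.clip(s, 0.0, 1.0)
    return 1.0 + float((s ** 2).sum())


def vamp2_cv_score(
    X,
    lag: int,
    k: int,
    folds: int = 10,
    seed: int | None = None,
):
    """Mean k-component VAMP2 score under contiguous-block cross-validation.

    Frame pairs (t, t+lag) are split into ``folds`` contiguous blocks; each
    fold is scored out-of-sample with a linear VAMP model fit on the rest.
    Returns (mean score, per-fold scores).  ``seed`` is accepted for
    interface uniformity; the block split is deterministic.
    """
    if k < 1:
        raise InvalidArgumentError("k must be >= 1")
    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    blocks = _as_blocks(X)
    xs, ys = [], []
    for b in blocks:
        if b.shape[0] > lag:
            xs.append(b[:-lag])
            ys.append(b[lag:])
    if not xs:
        raise InvalidArgumentError(f"lag={lag} >= number of frames")
    x = np.vstack(xs)
    y = np.vstack(ys)
    n = x.shape[0]
    if n // folds < lag + 2:
        raise InvalidArgumentError(
            f"folds of ~{n // folds} pairs are shorter than lag + 2 = {lag + 2}"
        )
    bounds = np.linspace(0, n, folds + 1, dtype=int)
    scores = []
    for f in range(folds):
        lo, hi = bounds[f], bounds[f + 1]
        test = slice(lo, hi)
        train_idx = np.r_[0:lo, hi:n]
        fit = _vamp_fit(x[train_idx], y[train_idx], k)
        scores.append(_vamp2_out_of_sample(fit, x[test], y[test], k))
    scores = np.array(scores)
    return float(scores.mean()), scores


def vamp2_score(X, lag: int, k: int) -> float:
    """In-sample VAMP2 (training score); monotone non-decreasing in k."""
    blocks = _as_blocks(X)
    xs = [b[:-lag] for b in blocks if b.shape[0] > lag]
    ys = [b[lag:] for b in blocks if b.shape[0] > lag]
    if not xs:
        raise InvalidArgumentError(f"lag={lag} >= number of frames")
    return _vamp2_in_sample(np.vstack(xs), np.vstack(ys), k)


def choose_feature_set(
    candidates: dict,
    lag: int,
    k: int,
    folds: int = 10,
    seed: int | None = None,
):
    """Pick the candidate feature set with the largest mean CV VAMP2 score.

    Ties break to the lexicographically first label; candidates with too few
    frames are skipped with a warning.  Returns (label, score table dict).
    """
    if len(candidates) < 2:
        raise InvalidArgumentError("need at least 2 candidate feature sets")
    table: dict[str, float] = {}
    for label in sorted(candidates):
        try:
            mean, _ = vamp2_cv_score(candidates[label], lag, k, folds, seed)
        except InvalidArgumentError as exc:
            logger.warning("skipping feature set %r: %s", label, exc)
            continue
        table[label] = mean
        logger.info("VAMP2[%s] = %.4f", label, mean)
    if not table:
        raise InvalidArgumentError("no candidate feature set could be scored")
    best = max(sorted(table), key=lambda lbl: table[lbl])
    return best, table
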