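"""Score aggregation across a conformational ensemble, rank orderings, and
Kendall-tau evaluation against experiment and a random-permutation null.

Conventions: docking scores are lower = better; pIC50 is higher = better.
Tau is computed between the two best-first rankings so a perfect prediction
gives tau = +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    InvalidArgumentError,
    PairingError,
)

__all__ = [
    "ScoreMatrix",
    "AffinityTable",
    "Ranking",
    "NullDistribution",
    "aggregate_min",
    "aggregate_avg",
    "aggregate_weighted",
    "rank_from_scores",
    "kendall_tau",
    "tau_null_distribution",
    "analytic_tau_sigma",
    "pearson_score_affinity",
    "evaluate_grid",
]

SCHEMES = ("Minimum", "W. Avg.", "Avg.")


@dataclass
class ScoreMatrix:
    """Ligand x conformation docking scores; missing entries are masked.

    ``missing`` is an explicit boolean mask — a missing score is never
    represented by a numeric placeholder.  Ligands with no present score at
    all are flagged in ``unscorable_ligands`` rather than silently dropped.
    """

    ligand_ids: list[str]
    conformation_ids: list[str]
    scores: np.ndarray
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.ligand_ids = list(self.ligand_ids)
        self.conformation_ids = list(self.conformation_ids)
        s = np.asarray(self.scores, dtype=float)
        if s.shape != (len(self.ligand_ids), len(self.conformation_ids)):
            raise InvalidArgumentError(
                f"score shape {s.shape} does not match "
                f"{len(self.ligand_ids)} ligands x "
                f"{len(self.conformation_ids)} conformations"
            )
        if self.missing is None:
            mask = ~np.isfinite(s)
        else:
            mask = np.asarray(self.missing, dtype=bool) | ~np.isfinite(s)
        self.scores = s
        self.missing = mask

    @property
    def unscorable_ligands(self) -> list[str]:
        all_missing = self.missing.all(axis=1)
        return [lid for lid, bad in zip(self.ligand_ids, all_missing) if bad]

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.scores, mask=self.missing)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            np.where(self.missing, np.nan, self.scores),
            index=self.ligand_ids,
            columns=self.conformation_ids,
        )
        df.index.name = "ligand_id"
        df.to_csv(path, float_format="%.6f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col="ligand_id")
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )


@dataclass
class AffinityTable:
    """Experimental affinities: ligand id -> pIC50 (higher = better)."""

    ligand_ids: list[str]
    pic50: np.ndarray

    def __post_init__(self):
        self.ligand_ids = list(self.ligand_ids)
        vals = np.asarray(self.pic50, dtype=float)
        if vals.shape != (len(self.ligand_ids),):
            raise InvalidArgumentError("one pIC50 per ligand id required")
        if not np.all(np.isfinite(vals)):
            raise InvalidArgumentError("pIC50 values must be finite")
        if len(set(self.ligand_ids)) != len(self.ligand_ids):
            raise InvalidArgumentError("ligand ids must be unique")
        self.pic50 = vals

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"ligand_id": self.ligand_ids, "pIC50": self.pic50}).to_csv(
            path, index=False, float_format="%.6f"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "AffinityTable":
        df = pd.read_csv(path)
        return cls([str(i) for i in df["ligand_id"]], df["pIC50"].to_numpy())


@dataclass
class Ranking:
    """Per-ligand aggregate scores and best-first ranks (1 = predicted best)."""

    scheme: str
    ligand_ids: list[str]
    aggregate_scores: np.ndarray
    ranks: np.ndarray
    excluded_ligands: list[str] = field(default_factory=list)
    tie_method: str = "average"


@dataclass
class NullDistribution:
    """Kendall-tau null from random permutations against a fixed reference."""

    n_items: int
    n_samples: int
    tau_samples: np.ndarray
    mean: float
    std: float
    seed: int

    def percentile_of(self, observed_tau: float) -> float:
        return float(100.0 * np.mean(self.tau_samples <= observed_tau))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_items": self.n_items,
                    "n_samples": self.n_samples,
                    "mean": self.mean,
                    "std": self.std,
                    "seed": self.seed,
                },
                indent=1,
            )
        )


def _aggregate(S: ScoreMatrix, scheme: str, P: np.ndarray | None = None) -> Ranking:
    m = S.masked()
    present = ~S.missing
    scorable = present.any(axis=1)
    excluded = [lid for lid, ok in zip(S.ligand_ids, scorable) if not ok]

    if scheme == "Minimum":
        agg = m.min(axis=1)
    elif scheme == "Avg.":
        agg = m.mean(axis=1)
    elif scheme == "W. Avg.":
        if P is None:
            raise InvalidArgumentError("weighted average requires populations P")
        P = np.asarray(P, dtype=float)
        if P.shape != (len(S.conformation_ids),):
            raise InvalidArgumentError("P must align with conformation_ids")
        if np.any(P < 0):
            raise InvalidArgumentError("P entries must be non-negative")
        if abs(P.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError("P must sum to 1")
        # renormalize P over the present entries of each ligand
        w = np.where(present, P[None, :], 0.0)
        wsum = w.sum(axis=1)
        safe = np.where(wsum > 0, wsum, 1.0)
        agg = (np.where(present, S.scores, 0.0) * w).sum(axis=1) / safe
        agg = np.ma.masked_array(agg, mask=~scorable)
    else:
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")

    kept = [lid for lid, ok in zip(S.ligand_ids, scorable) if ok]
    values = np.asarray(agg[scorable])
    ranks = rank_from_scores(values, direction="lower-better")
    return Ranking(scheme, kept, values, ranks, excluded_ligands=excluded)


def aggregate_min(S: ScoreMatrix) -> Ranking:
    """Best (minimum) score per ligand across the ensemble."""
    return _aggregate(S, "Minimum")


def aggregate_avg(S: ScoreMatrix) -> Ranking:
    """Arithmetic mean over the present scores per ligand."""
    return _aggregate(S, "Avg.")


def aggregate_weighted(S: ScoreMatrix, P) -> Ranking:
    """Population-weighted average, sum_i P_i s_{l,i}; P renormalized over
    the present entries of each ligand."""
    return _aggregate(S, "W. Avg.", P=P)


def rank_from_scores(values, direction: str = "lower-better") -> np.ndarray:
    """Best-first ranks (1 = best); ties receive average ranks."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise InvalidArgumentError("scores must be finite to rank")
    if direction == "lower-better":
        key = v
    elif direction == "higher-better":
        key = -v
    else:
        raise InvalidArgumentError(f"unknown direction {direction!r}")
    return stats.rankdata(key, method="average")


def kendall_tau(a, b) -> float:
    """Tie-aware Kendall tau-b between two paired vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise PairingError(
            f"vectors must be paired 1-D arrays, got {a.shape} and {b.shape}"
        )
    if a.size < 2:
        raise PairingError("need at least 2 paired observations")
    tau, _ = stats.kendalltau(a, b)
    return float(tau)


def analytic_tau_sigma(n_items: int) -> float:
    """Large-sample null std of tau: sqrt(2(2n+5) / (9 n (n-1)))."""
    if n_items < 3:
        raise InvalidArgumentError("n_items must be >= 3")
    n = n_items
    return float(np.sqrt(2.0 * (2 * n + 5) / (9.0 * n * (n - 1))))


def tau_null_distribution(
    n_items: int,
    n_samples: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Tau of uniform random permutations against the identity ordering."""
    if n_items < 3:
        raise InvalidArgumentError("n_items must be >= 3")
    if n_samples < 100:
        raise InvalidArgumentError("n_samples must be >= 100")
    rng = np.random.default_rng(seed)
    reference = np.arange(n_items)
    taus = np.empty(n_samples)
    for i in range(n_samples):
        perm = rng.permutation(n_items)
        taus[i] = stats.kendalltau(reference, perm).statistic
    return NullDistribution(
        n_items=n_items,
        n_samples=n_samples,
        tau_samples=taus,
        mean=float(taus.mean()),
        std=float(taus.std(ddof=1)),
        seed=seed,
    )


def pearson_score_affinity(scores, affinities: AffinityTable | np.ndarray) -> float:
    """Sample Pearson correlation between aggregate scores and pIC50s."""
    x = np.asarray(scores, dtype=float)
    y = (
        affinities.pic50
        if isinstance(affinities, AffinityTable)
        else np.asarray(affinities, dtype=float)
    )
    if x.shape != y.shape or x.size < 3:
        raise PairingError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in scores or affinities")
    return float(stats.pearsonr(x, y).statistic)


def _tau_vs_experiment(ranking: Ranking, affinities: AffinityTable) -> float:
    table = dict(zip(affinities.ligand_ids, affinities.pic50))
    unmatched = [lid for lid in ranking.ligand_ids if lid not in table]
    if unmatched:
        raise PairingError(f"ligands without experimental affinity: {unmatched}")
    exp = np.array([table[lid] for lid in ranking.ligand_ids])
    pred_ranks = ranking.ranks
    exp_ranks = rank_from_scores(exp, direction="higher-better")
    # both rankings are best-first, so perfect prediction gives tau = +1
    return kendall_tau(pred_ranks, exp_ranks)


def evaluate_grid(
    score_matrices: dict[str, ScoreMatrix],
    populations: dict[str, np.ndarray],
    affinities: AffinityTable,
    schemes=SCHEMES,
) -> pd.DataFrame:
    """Tau table: rows = scoring scheme, columns = clustering method."""
    if not score_matrices:
        raise InvalidArgumentError("need at least one method's score matrix")
    grid = pd.DataFrame(index=list(schemes), columns=list(score_matrices), dtype=float)
    for method, S in score_matrices.items():
        for scheme in schemes:
            if scheme == "Minimum":
                r = aggregate_min(S)
            elif scheme == "Avg.":
                r = aggregate_avg(S)
            elif scheme == "W. Avg.":
                r = aggregate_weighted(S, populations[method])
            else:
                raise InvalidArgumentError(f"unknown scheme {scheme!r}")
            grid.loc[scheme, method] = _tau_vs_experiment(r, affinities)
    return grid
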