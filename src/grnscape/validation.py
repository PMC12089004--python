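"""Model-vs-experiment comparison of gene coexpression matrices.

The fitted stationary density implies a gene-gene Pearson correlation matrix
``M_m`` (computed from a large sample of concentrations); an experimental
coexpression matrix ``M_e`` comes from expression databases.  The two are
compared by the entrywise Euclidean (Frobenius) distance

    d(M, N) = sqrt( sum_s (m_s - n_s)^2 )

over all t^2 entries (the unit diagonals cancel for genuine correlation
matrices but are kept for fidelity to the definition).  To judge whether the
observed distance is small, it is placed within two empirical null
distributions: distances between pairs of random correlation matrices, and
distances between ``M_e`` and random correlation matrices.  Random
correlation matrices are realised as sample correlations of ``m_eff``
i.i.d. standard-normal vectors, which guarantees symmetry, a unit diagonal
and positive semidefiniteness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "NullDistanceDistribution",
    "ValidationReport",
    "pearson_matrix",
    "euclidean_distance",
    "random_correlation_matrix",
    "null_distributions",
    "validate",
    "read_coexpression_csv",
    "write_coexpression_csv",
]


@dataclass(frozen=True)
class CorrelationMatrix:
    """A labelled symmetric unit-diagonal matrix with entries in [-1, 1]."""

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        t = len(self.labels)
        if v.shape != (t, t):
            raise ValueError(f"values shape {v.shape} does not match {t} labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValueError("correlation matrix must have unit diagonal")
        if (np.abs(v) > 1.0 + 1e-9).any():
            raise ValueError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", v)

    @property
    def t(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class NullDistanceDistribution:
    """Sampled distances under one of the two nulls."""

    kind: str  # "random-vs-random" | "experimental-vs-random"
    samples: np.ndarray = field(repr=False)
    seed: int | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if (s < 0).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "samples", s)

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.samples, q))

    def percentile_of(self, d: float) -> float:
        """Empirical percentile of d with the (r+1)/(n+1) convention."""
        r = int((self.samples < d).sum())
        return (r + 1) / (len(self.samples) + 1)


def pearson_matrix(samples: np.ndarray, labels) -> CorrelationMatrix:
    """Pearson correlation matrix of an (m, t) sample-by-gene data matrix.

    Constant columns carry no correlation information; their off-diagonal
    entries are set to zero with a warning (mirroring missing-data handling).
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need an (m, t) matrix with m >= 3 samples")
    if X.shape[1] != len(labels):
        raise ValueError(f"{X.shape[1]} columns but {len(labels)} labels")
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant column(s) {[labels[i] for i in np.nonzero(const)[0]]}: "
            "correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return CorrelationMatrix(tuple(labels), C)


def euclidean_distance(M: CorrelationMatrix, N: CorrelationMatrix) -> float:
    """Entrywise Euclidean distance over all t^2 entries (Frobenius norm)."""
    if M.labels != N.labels:
        unmatched = set(M.labels).symmetric_difference(N.labels) or {
            "same labels, different order"
        }
        raise ValueError(f"label mismatch between matrices: {sorted(unmatched)}")
    return float(np.sqrt(((M.values - N.values) ** 2).sum()))


def random_correlation_matrix(
    t: int, m_eff: int = 100, seed: int | None = None
) -> CorrelationMatrix:
    """Sample correlation matrix of m_eff i.i.d. standard-normal t-vectors.

    ``m_eff`` tunes the spread: large m_eff concentrates the matrix near the
    identity, small m_eff (>= t+1) produces strongly correlated draws.
    """
    if t < 2:
        raise ValueError("need t >= 2 genes")
    if m_eff < t + 1:
        raise ValueError(f"need m_eff >= t+1 = {t + 1} for a full-rank sample")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((m_eff, t))
    C = np.corrcoef(X, rowvar=False)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(tuple(f"g{i + 1}" for i in range(t)), C)


def null_distributions(
    M_e: CorrelationMatrix,
    n_draws: int = 1000,
    m_eff: int = 100,
    seed: int | None = None,
) -> tuple[NullDistanceDistribution, NullDistanceDistribution]:
    """The two distance nulls: random-vs-random and experimental-vs-random."""
    if n_draws < 100:
        raise ValueError("need at least 100 draws for a usable null")
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(np.random.default_rng(s).integers(2**31 - 1)) for s in ss]
    t = M_e.t

    def draws(seed0, count):
        rng = np.random.default_rng(seed0)
        return [
            random_correlation_matrix(t, m_eff, seed=int(rng.integers(2**31 - 1)))
            for _ in range(count)
        ]

    rr = np.array(
        [
            np.sqrt(((a.values - b.values) ** 2).sum())
            for a, b in zip(draws(seeds[0], n_draws), draws(seeds[1], n_draws))
        ]
    )
    er = np.array(
        [np.sqrt(((M_e.values - c.values) ** 2).sum()) for c in draws(seeds[2], n_draws)]
    )
    return (
        NullDistanceDistribution("random-vs-random", rr, seed=seed),
        NullDistanceDistribution("experimental-vs-random", er, seed=seed),
    )


@dataclass(frozen=True)
class ValidationReport:
    """Distance of the model matrix from the data, placed within the nulls."""

    distance: float
    percentile_random_vs_random: float
    percentile_experimental_vs_random: float
    verdict: str
    q: float
    n_draws: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "distance": self.distance,
            "percentile_random_vs_random": self.percentile_random_vs_random,
            "percentile_experimental_vs_random": self.percentile_experimental_vs_random,
            "verdict": self.verdict,
            "q": self.q,
            "n_draws": self.n_draws,
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def __str__(self) -> str:
        return (
            f"d(M_e, M_m) = {self.distance:.4f}\n"
            f"percentile within random-vs-random null:      "
            f"{self.percentile_random_vs_random:.4f}\n"
            f"percentile within experimental-vs-random null: "
            f"{self.percentile_experimental_vs_random:.4f}\n"
            f"verdict: {self.verdict}"
        )


def validate(
    M_m: CorrelationMatrix,
    M_e: CorrelationMatrix,
    n_draws: int = 1000,
    m_eff: int = 100,
    seed: int | None = None,
    q: float = 0.05,
) -> ValidationReport:
    """Compare the model matrix with the data matrix against both nulls.

    Verdict policy: "discriminated from random" when D falls below the
    q-quantile of the experimental-vs-random null (the model is measurably
    closer to the data than a random matrix would be); "cannot be discarded"
    when D does not exceed that null's (1-q)-quantile; otherwise "discard".
    """
    D = euclidean_distance(M_e, M_m)
    rr, er = null_distributions(M_e, n_draws=n_draws, m_eff=m_eff, seed=seed)
    if D < er.quantile(q):
        verdict = "discriminated from random"
    elif D <= er.quantile(1.0 - q):
        verdict = "cannot be discarded"
    else:
        verdict = "discard"
    return ValidationReport(
        distance=D,
        percentile_random_vs_random=rr.percentile_of(D),
        percentile_experimental_vs_random=er.percentile_of(D),
        verdict=verdict,
        q=q,
        n_draws=n_draws,
        seed=seed,
    )


def read_coexpression_csv(
    path: str | Path, gene_order=None
) -> CorrelationMatrix:
    """Read a labelled square coexpression CSV.

    First row and column are gene labels.  Missing/empty cells become 0,
    asymmetry beyond 1e-6 is averaged away with a warning, and the diagonal
    is forced to 1.  ``gene_order`` reorders rows/columns to a caller-supplied
    gene list.
    """
    df = pd.read_csv(path, index_col=0)
    rows, cols = list(df.index.astype(str)), list(df.columns.astype(str))
    if len(rows) != len(cols):
        raise ValueError(f"non-square table: {len(rows)} rows, {len(cols)} columns")
    if len(set(rows)) != len(rows) or len(set(cols)) != len(cols):
        raise ValueError("duplicate gene labels in coexpression table")
    if set(rows) != set(cols):
        raise ValueError("row and column labels differ")
    df = df.loc[rows, rows]
    V = df.to_numpy(dtype=float)
    V = np.nan_to_num(V, nan=0.0)
    if np.abs(V - V.T).max() > 1e-6:
        warnings.warn(
            f"asymmetry up to {np.abs(V - V.T).max():.3g} symmetrised by averaging",
            stacklevel=2,
        )
    V = (V + V.T) / 2.0
    np.fill_diagonal(V, 1.0)
    M = CorrelationMatrix(tuple(rows), np.clip(V, -1.0, 1.0))
    if gene_order is not None:
        order = [M.labels.index(g) for g in gene_order]
        M = CorrelationMatrix(tuple(gene_order), M.values[np.ix_(order, order)])
    return M


def write_coexpression_csv(M: CorrelationMatrix, path: str | Path) -> None:
    pd.DataFrame(M.values, index=list(M.labels), columns=list(M.labels)).to_csv(
        path, float_format="%.12g"
    )
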