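"""Gamma-mixture ansatz for stationary gene-expression densities.

The trial stationary density over the d protein concentrations is a weighted
sum of n components, each a *product of independent gamma densities*, one per
gene:

    P(p) = sum_i A_i prod_j Gamma(p_j; alpha_ij, beta_ij),
    sum_i A_i = 1, A_i >= 0.

Each component sits at one attractor of the network: its per-gene mode
``(alpha_ij - 1)/beta_ij`` (zero when ``alpha_ij <= 1``) is that attractor's
expression level, so an ON gene has a bumped gamma and an OFF gene an
exponential-like factor peaked at the origin.  The epigenetic landscape is
``U(p) = -ln P(p)``: valleys of U are the attractors.

A diagonal :class:`GaussianMixture` with the same interface serves as the
proxy distribution during fitting (its light tails make Monte Carlo residual
estimates much less noisy than the gamma's).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.spatial.distance import cdist

__all__ = ["GammaMixture", "GaussianMixture", "at_flower_fitted_mixture"]


def _as_points(p, dim: int) -> tuple[np.ndarray, bool]:
    pts = np.asarray(p, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != dim:
        raise ValueError(f"points have dimension {pts.shape[-1]}, mixture has {dim}")
    return pts, single


class _FactorisedMixture:
    """Shared behaviour of the gamma mixture and its Gaussian proxy."""

    weights: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.weights)

    def component_logpdf(self, p) -> np.ndarray:  # (m, n_components)
        raise NotImplementedError

    def logpdf(self, p) -> np.ndarray | float:
        pts, single = _as_points(p, self.dim)
        comp = self.component_logpdf(pts)
        with np.errstate(divide="ignore"):
            out = logsumexp(comp, axis=1, b=self.weights[None, :])
        return out[0] if single else out

    def pdf(self, p) -> np.ndarray | float:
        return np.exp(self.logpdf(p))

    def landscape(self, p) -> np.ndarray | float:
        """Quasi-potential U(p) = -ln P(p); +inf where the density vanishes."""
        return -self.logpdf(p)

    def modes(self) -> np.ndarray:
        raise NotImplementedError

    def landscape_summary(self) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise Manhattan distances between component modes, and U at each mode.

        Well-to-well Manhattan distance is a cheap proxy for how accessible a
        transition between two attractors is; the potential values at the
        modes compare well depths.
        """
        m = self.modes()
        dist = cdist(m, m, metric="cityblock")
        depths = np.array([self.landscape(row) for row in m])
        return dist, depths

    def sample(self, m: int, seed: int | None = None) -> np.ndarray:
        raise NotImplementedError


def _check_weights(weights: np.ndarray) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("mixture weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValueError(f"mixture weights must sum to 1, got {w.sum()!r}")
    return w


@dataclass(frozen=True)
class GammaMixture(_FactorisedMixture):
    """Mixture of products of independent gamma densities.

    ``shapes`` and ``rates`` are (n_components, d) arrays of strictly positive
    gamma shape/rate parameters; ``weights`` lives on the probability simplex.
    """

    weights: np.ndarray = field(repr=False)
    shapes: np.ndarray = field(repr=False)
    rates: np.ndarray = field(repr=False)
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = _check_weights(self.weights)
        a = np.asarray(self.shapes, dtype=float)
        b = np.asarray(self.rates, dtype=float)
        if a.ndim != 2 or a.shape != b.shape or a.shape[0] != len(w):
            raise ValueError(
                f"shapes {a.shape} and rates {b.shape} must both be "
                f"(n_components={len(w)}, d)"
            )
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("gamma shapes and rates must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "shapes", a)
        object.__setattr__(self, "rates", b)
        if self.gene_names:
            object.__setattr__(self, "gene_names", tuple(self.gene_names))
            if len(self.gene_names) != a.shape[1]:
                raise ValueError("gene_names length must equal dimension")

    @property
    def dim(self) -> int:
        return self.shapes.shape[1]

    def component_logpdf(self, p) -> np.ndarray:
        pts, _ = _as_points(p, self.dim)
        a, b = self.shapes, self.rates
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(pts > 0, np.log(pts), -np.inf)  # (m, d)
            terms = (
                a[None] * np.log(b[None])
                - gammaln(a)[None]
                + (a[None] - 1.0) * logp[:, None, :]
                - b[None] * pts[:, None, :]
            )
            # alpha = 1 factors are exponential: finite at the boundary
            terms = np.where(
                (pts[:, None, :] == 0) & (a[None] == 1.0), np.log(b)[None], terms
            )
        return np.nan_to_num(terms, nan=-np.inf, posinf=np.inf, neginf=-np.inf).sum(axis=2)

    def log_derivs(self, p) -> tuple[np.ndarray, np.ndarray]:
        """Per-factor log-density derivatives g = d/dp_j log f_ij and dg = d g/dp_j.

        Shapes (m, n_components, d); requires strictly positive points.
        """
        pts, _ = _as_points(p, self.dim)
        if (pts <= 0).any():
            raise ValueError("log-derivatives require strictly positive points")
        am1 = self.shapes[None] - 1.0
        g = am1 / pts[:, None, :] - self.rates[None]
        dg = -am1 / pts[:, None, :] ** 2
        return g, dg

    def modes(self) -> np.ndarray:
        """Per-component per-gene mode (alpha-1)/beta, clamped to 0 for alpha <= 1."""
        return np.where(self.shapes > 1.0, (self.shapes - 1.0) / self.rates, 0.0)

    def active_gene_summary(self, active_threshold: float = 0.0) -> np.ndarray:
        """Mean mode over each component's active genes (mode > threshold); 0 if none."""
        modes = self.modes()
        out = np.zeros(self.n_components)
        for i in range(self.n_components):
            active = modes[i][modes[i] > active_threshold]
            out[i] = active.mean() if active.size else 0.0
        return out

    def sample(self, m: int, seed: int | None = None) -> np.ndarray:
        """Ancestral sampling: pick a component by weight, then independent gammas."""
        if m < 1:
            raise ValueError(f"sample size must be >= 1, got {m}")
        rng = np.random.default_rng(seed)
        comps = rng.choice(self.n_components, size=m, p=self.weights)
        return rng.gamma(self.shapes[comps], 1.0 / self.rates[comps])

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "shapes": self.shapes.tolist(),
            "rates": self.rates.tolist(),
            "gene_names": list(self.gene_names),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, obj: dict) -> "GammaMixture":
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            shapes=np.asarray(obj["shapes"], dtype=float),
            rates=np.asarray(obj["rates"], dtype=float),
            gene_names=tuple(obj.get("gene_names", ())),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GammaMixture":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class GaussianMixture(_FactorisedMixture):
    """Diagonal-covariance Gaussian mixture (the fitting proxy).

    Mirrors the factorised gamma ansatz: independent coordinates within a
    component, modes = means.
    """

    weights: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)
    variances: np.ndarray = field(repr=False)
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = _check_weights(self.weights)
        mu = np.asarray(self.means, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        if mu.ndim != 2 or mu.shape != var.shape or mu.shape[0] != len(w):
            raise ValueError("means and variances must both be (n_components, d)")
        if (var <= 0).any():
            raise ValueError("variances must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "variances", var)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def component_logpdf(self, p) -> np.ndarray:
        pts, _ = _as_points(p, self.dim)
        z2 = (pts[:, None, :] - self.means[None]) ** 2 / self.variances[None]
        terms = -0.5 * (z2 + np.log(2.0 * np.pi * self.variances)[None])
        return terms.sum(axis=2)

    def log_derivs(self, p) -> tuple[np.ndarray, np.ndarray]:
        pts, _ = _as_points(p, self.dim)
        g = -(pts[:, None, :] - self.means[None]) / self.variances[None]
        dg = np.broadcast_to(-1.0 / self.variances[None], g.shape)
        return g, dg

    def modes(self) -> np.ndarray:
        return self.means.copy()

    def sample(self, m: int, seed: int | None = None) -> np.ndarray:
        if m < 1:
            raise ValueError(f"sample size must be >= 1, got {m}")
        rng = np.random.default_rng(seed)
        comps = rng.choice(self.n_components, size=m, p=self.weights)
        return rng.normal(self.means[comps], np.sqrt(self.variances[comps]))


def at_flower_fitted_mixture() -> GammaMixture:
    """The published four-attractor gamma-mixture fit for the AT flower network.

    Packaged fixture transcribing the printed shape/rate table.  The printed
    table does not report the mixture weights, so the fixture stores uniform
    weights 1/4 — an explicit assumption, documented here and in the fixture
    file itself.
    """
    ref = resources.files("grnscape.data").joinpath("at_flower_fitted_mixture.json")
    return GammaMixture.from_dict(json.loads(ref.read_text()))
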