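"""Brute-force oracles and synthetic data for testing the pipeline.

Three independent routes to ground truth, none sharing derivative or residual
code with the fitting machinery:

* tiny hand-built networks with known Boolean and ODE behaviour;
* a flux-conservative (Chang-Cooper) finite-volume discretisation of the
  stationary Fokker-Planck operator in one or two dimensions, with
  zero-flux (reflecting) boundaries, solved for its near-null eigenvector;
* synthetic coexpression matrices: samples from a known gamma mixture plus
  truncated Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import eigs

from .langevin import FPEModel, diffusion_field, drift_field
from .mixtures import GammaMixture
from .network import GeneNetwork
from .validation import CorrelationMatrix, pearson_matrix

__all__ = [
    "GridSolution",
    "make_toy_network",
    "grid_stationary_density",
    "grid_fpe_stationary",
    "synthetic_coexpression",
    "GradientFlowFPE",
]

_TOYS = {
    # one unregulated gene: dp/dt = alpha0 - delta p
    "single_gene": (["G1"], [[0]], [0]),
    # mutual repression, weak (the published toggle weights)
    "toggle": (["G1", "G2"], [[0, -1], [-1, 0]], [-1, -1]),
    # strong mutual repression; with hill_n=2 and alpha0=0 the continuous
    # model is genuinely bistable (the |w|=1 toggle is not)
    "switch": (["G1", "G2"], [[0, -10], [-10, 0]], [-1, -1]),
    # cooperative self-activation; with hill_n=2 and alpha0=0.05 the 1-D
    # continuous model is bistable and its stationary density bimodal
    "self_activator": (["G1"], [[10]], [1]),
    # self-activator plus an unregulated gene: a 2-gene model with two
    # attractors whose stationary law factorises (product ansatz is exact-
    # family), used for 2-D parameter-recovery checks
    "bistable_pair": (["G1", "G2"], [[10, 0], [0, 0]], [1, 0]),
    # activation chain 1 -> 2 -> 3
    "chain3": (["G1", "G2", "G3"], [[0, 0, 0], [1, 0, 0], [0, 1, 0]], [0, 0, 0]),
}


def make_toy_network(kind: str) -> GeneNetwork:
    """Small benchmark networks: single_gene | toggle | switch | chain3."""
    try:
        genes, W, theta = _TOYS[kind]
    except KeyError:
        raise ValueError(f"unknown toy network {kind!r}; choose from {sorted(_TOYS)}")
    return GeneNetwork(tuple(genes), np.asarray(W, dtype=int), np.asarray(theta, dtype=int))


@dataclass(frozen=True)
class GridSolution:
    """Stationary density on a tensor grid (cell centres per dimension)."""

    grid: tuple[np.ndarray, ...]
    density: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        dens = np.asarray(self.density, dtype=float)
        if (dens < 0).any():
            raise ValueError("density must be non-negative")
        object.__setattr__(self, "grid", tuple(np.asarray(g, float) for g in self.grid))
        object.__setattr__(self, "density", dens)

    @property
    def cell_volume(self) -> float:
        return float(np.prod([g[1] - g[0] for g in self.grid]))

    def mode(self) -> np.ndarray:
        """Grid point of maximal density."""
        idx = np.unravel_index(np.argmax(self.density), self.density.shape)
        return np.array([g[i] for g, i in zip(self.grid, idx)])

    def marginal(self, axis: int) -> np.ndarray:
        other = tuple(i for i in range(self.density.ndim) if i != axis)
        h_other = np.prod([self.grid[i][1] - self.grid[i][0] for i in other]) if other else 1.0
        return self.density.sum(axis=other) * h_other

    def to_csv(self, path: str | Path) -> None:
        mesh = np.meshgrid(*self.grid, indexing="ij")
        cols = {f"p{i + 1}": m.ravel() for i, m in enumerate(mesh)}
        cols["density"] = self.density.ravel()
        pd.DataFrame(cols).to_csv(path, index=False)


def _chang_cooper_face(C: float, D: float, h: float) -> tuple[float, float]:
    """Chang-Cooper flux weights at one face.

    Returns (coef_left, coef_right) so that the face flux is
    J = coef_left * P_left + coef_right * P_right.  The exponentially fitted
    weighting keeps the discrete stationary density positive and exact for
    locally constant coefficients.
    """
    if D <= 0:
        raise ValueError("diffusion must be positive inside the domain")
    w = C * h / D
    if abs(w) < 1e-12:
        delta = 0.5
    else:
        delta = 1.0 / w - 1.0 / np.expm1(w)
    return C * delta + D / h, C * (1.0 - delta) - D / h


def grid_stationary_density(
    drift: Callable[[np.ndarray], np.ndarray],
    diffusion: Callable[[np.ndarray], np.ndarray],
    grid: Sequence[np.ndarray],
    negative_tolerance: float = 1e-8,
) -> GridSolution:
    """Stationary density of a 1-D/2-D FPE with diagonal diffusion on a grid.

    ``drift(p)`` and ``diffusion(p)`` map an (m, d) batch of points to (m, d)
    fields A_j and Gamma_j; the operator discretised is
    ``-sum_j d_j[A_j P] + (1/2) sum_j d_j^2[Gamma_j P]`` with zero-flux
    boundaries at the grid edges.  In advection-diffusion form the effective
    drift is ``A_j - (1/2) d_j Gamma_j`` (evaluated by face differencing, so
    no analytic derivatives are shared with the residual module).  The
    stationary density is the eigenvector of the conservative operator with
    eigenvalue nearest zero, normalised over the grid.
    """
    axes = [np.asarray(g, dtype=float) for g in grid]
    d = len(axes)
    if d not in (1, 2):
        raise ValueError("grid oracle supports 1-D and 2-D only")
    shape = tuple(len(g) for g in axes)
    n_cells = int(np.prod(shape))
    hs = [float(g[1] - g[0]) for g in axes]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)  # (n_cells, d)

    A = np.atleast_2d(drift(pts)).reshape(n_cells, d)
    G = np.atleast_2d(diffusion(pts)).reshape(n_cells, d)
    Ash = A.reshape(*shape, d)
    Gsh = G.reshape(*shape, d)

    rows, cols, vals = [], [], []
    lin = np.arange(n_cells).reshape(shape)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for axis in range(d):
        h = hs[axis]
        n_ax = shape[axis]
        # iterate over interior faces along this axis
        for k in range(n_ax - 1):
            slc_l = [slice(None)] * d
            slc_r = [slice(None)] * d
            slc_l[axis] = k
            slc_r[axis] = k + 1
            il = lin[tuple(slc_l)].ravel()
            ir = lin[tuple(slc_r)].ravel()
            Al = Ash[tuple(slc_l)].reshape(-1, d)[:, axis]
            Ar = Ash[tuple(slc_r)].reshape(-1, d)[:, axis]
            Gl = Gsh[tuple(slc_l)].reshape(-1, d)[:, axis]
            Gr = Gsh[tuple(slc_r)].reshape(-1, d)[:, axis]
            # face values: averaged diffusion, drift corrected by the face
            # difference of Gamma/2 (the d_j Gamma_j term of the operator)
            Dface = 0.25 * (Gl + Gr)          # Gamma/2 at the face
            Cface = 0.5 * (Al + Ar) - (Gr - Gl) / (2.0 * h)
            for jl, jr, Cf, Df in zip(il, ir, Cface, Dface):
                cl, cr = _chang_cooper_face(float(Cf), float(Df), h)
                # flux J = cl P_l + cr P_r leaves cell l and enters cell r
                add(jl, jl, -cl / h)
                add(jl, jr, -cr / h)
                add(jr, jl, +cl / h)
                add(jr, jr, +cr / h)

    M = sparse.csc_matrix(
        (np.array(vals), (np.array(rows), np.array(cols))), shape=(n_cells, n_cells)
    )
    scale = max(1.0, float(np.abs(M.diagonal()).max()))
    val, vec = eigs(M, k=1, sigma=-1e-9 * scale, which="LM")
    dens = np.real(vec[:, 0])
    if dens.sum() < 0:
        dens = -dens
    neg = -dens.min() / max(dens.max(), 1e-300)
    if neg > negative_tolerance:
        raise ValueError(
            f"discrete density has negative mass fraction {neg:.2e}; refine the grid"
        )
    dens = np.clip(dens, 0.0, None).reshape(shape)
    dens /= dens.sum() * np.prod(hs)
    return GridSolution(tuple(axes), dens)


def grid_fpe_stationary(
    fpe: FPEModel, grid: Sequence[np.ndarray], negative_tolerance: float = 1e-8
) -> GridSolution:
    """Grid stationary density of a (1- or 2-gene) FPE model."""
    if fpe.n_genes > 2:
        raise ValueError("grid oracle is limited to 1- and 2-gene models")
    return grid_stationary_density(
        lambda p: drift_field(fpe, p),
        lambda p: diffusion_field(fpe, p),
        grid,
        negative_tolerance=negative_tolerance,
    )


@dataclass(frozen=True)
class GradientFlowFPE:
    """Synthetic FPE whose stationary solution is a *known* mixture.

    With constant diffusion ``sigma2`` and drift ``(sigma2/2) * grad ln P*``,
    the stationary FPE residual of ``P*`` is exactly zero, so refitting from
    this FPE is a parameter-recovery test where the trial family contains the
    truth.  Exposes the ``residual_fields`` interface consumed by the
    residual/fitting machinery.
    """

    target: GammaMixture
    sigma2: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def n_genes(self) -> int:
        return self.target.dim

    @property
    def base(self):  # gene names for fitted mixtures
        class _Names:
            gene_names = self.target.gene_names

        return _Names()

    def residual_fields(self, pts: np.ndarray):
        mix = self.target
        comp = mix.component_logpdf(pts)                       # (m, n)
        g, dg = mix.log_derivs(pts)                            # (m, n, d)
        # responsibilities r_i = w_i P_i / P
        shifted = comp - comp.max(axis=1, keepdims=True)
        r = mix.weights[None, :] * np.exp(shifted)
        r /= r.sum(axis=1, keepdims=True)
        gbar = (r[:, :, None] * g).sum(axis=1)                 # d_j ln P
        # d_j gbar_j = sum_i r_i (dg + g^2) - gbar^2
        dgbar = (r[:, :, None] * (dg + g**2)).sum(axis=1) - gbar**2
        u = 0.5 * self.sigma2 * gbar
        du = 0.5 * self.sigma2 * dgbar
        gam = np.full_like(u, self.sigma2)
        zero = np.zeros_like(u)
        return u, du, gam, zero, zero


def synthetic_coexpression(
    mix: GammaMixture, m: int, noise_sd: float = 0.0, seed: int | None = None
) -> tuple[np.ndarray, CorrelationMatrix]:
    """Samples from a known mixture plus measurement noise, and their Pearson matrix.

    Emulates the statistical structure the validation step assumes: multimodal
    concentration samples blurred by additive Gaussian noise, truncated at
    zero (concentrations cannot be negative).
    """
    if m < 10:
        raise ValueError("need at least 10 samples")
    ss = np.random.SeedSequence(seed).spawn(2)
    sample_seed = int(np.random.default_rng(ss[0]).integers(2**31 - 1))
    X = mix.sample(m, seed=sample_seed)
    if noise_sd > 0:
        rng = np.random.default_rng(ss[1])
        X = np.clip(X + rng.normal(0.0, noise_sd, size=X.shape), 0.0, None)
    labels = mix.gene_names or tuple(f"g{i + 1}" for i in range(mix.dim))
    return X, pearson_matrix(X, labels)
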