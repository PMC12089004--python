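"""Continuous (Hill-type ODE) translation of a Boolean GRN.

Each gene *i* gets one ODE for its protein concentration ``p_i``.  After a
quasi-steady-state elimination of the mRNA stage, production is a saturating
Hill ratio built from the Boolean weights:

    dp_i/dt = N_i(p) / D_i(p) + alpha0_i - delta_i * p_i

where, with ``n`` the Hill exponent,

    D_i(p) = 1 + |theta_i| + sum_{j in regulators(i)} |w_ij| p_j**n
    N_i(p) = sum_{j in activators(i)} |w_ij| p_j**n   [+ (1 + |theta_i|) if theta_i <= 0]

The additive basal numerator term ``1 + |theta_i|`` appears exactly for genes
with non-positive threshold: a negative (or zero) Boolean threshold means the
gene has a basal synthesis route that repressors must actively shut down.
Genes with no regulators reduce to the linear ``dp_i/dt = alpha0_i - delta_i p_i``.
All rate constants not determined by the Boolean model (``alpha0``, ``delta``,
``n``) default to 1 — a deliberately parsimonious translation that adds no
information beyond the signed weights and thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .network import GeneNetwork

__all__ = [
    "GeneRegulationSpec",
    "ContinuousGRNModel",
    "build_continuous_model",
    "drift",
    "ode_fixed_points",
    "boolean_to_concentration",
]


@dataclass(frozen=True)
class GeneRegulationSpec:
    """Drift specification for a single gene.

    ``activators``/``repressors`` are lists of ``(source index, weight)`` with
    strictly positive weights (the absolute Boolean weights); ``basal_numerator``
    marks genes whose Hill numerator carries the additive ``1 + theta_abs`` term.
    """

    activators: tuple[tuple[int, float], ...]
    repressors: tuple[tuple[int, float], ...]
    theta_abs: float
    basal_numerator: bool
    alpha0: float = 1.0
    delta: float = 1.0
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        for _, w in (*self.activators, *self.repressors):
            if w <= 0:
                raise ValueError("interaction weights must be strictly positive")
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.hill_n < 1:
            raise ValueError(f"hill_n must be >= 1, got {self.hill_n}")

    @property
    def regulators(self) -> tuple[tuple[int, float], ...]:
        return self.activators + self.repressors

    @property
    def has_regulators(self) -> bool:
        return bool(self.regulators)


@dataclass(frozen=True)
class ContinuousGRNModel:
    """One :class:`GeneRegulationSpec` per gene, in gene order."""

    specs: tuple[GeneRegulationSpec, ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.specs)
        if len(self.gene_names) != n:
            raise ValueError("one spec per gene name required")
        for spec in self.specs:
            for j, _ in spec.regulators:
                if not 0 <= j < n:
                    raise ValueError(f"regulator index {j} out of range for {n} genes")

    @property
    def n_genes(self) -> int:
        return len(self.specs)

    def saturation_levels(self) -> np.ndarray:
        """Per-gene bound (1 + alpha0_i)/delta_i above which the drift is negative."""
        return np.array([(1.0 + s.alpha0) / s.delta for s in self.specs])


def _per_gene(value, n: int, name: str) -> np.ndarray:
    """Broadcast a scalar / sequence / {gene-index: value} map to length n."""
    if isinstance(value, dict):
        out = np.full(n, value.get("default", 1.0), dtype=float)
        for k, v in value.items():
            if k == "default":
                continue
            out[int(k)] = float(v)
        return out
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"{name} must be scalar or length-{n}")
    return arr


def build_continuous_model(
    net: GeneNetwork,
    alpha0: float | dict | np.ndarray = 1.0,
    delta: float | dict | np.ndarray = 1.0,
    hill_n: float | dict | np.ndarray = 1.0,
) -> ContinuousGRNModel:
    """Translate a Boolean GRN into its continuous Hill-type ODE system.

    ``alpha0``, ``delta`` and ``hill_n`` may each be a scalar, a length-N
    array, or a ``{gene index: value, "default": value}`` mapping.
    """
    n = net.n_genes
    a0 = _per_gene(alpha0, n, "alpha0")
    dl = _per_gene(delta, n, "delta")
    hn = _per_gene(hill_n, n, "hill_n")
    specs = []
    for i in range(n):
        acts, reps = [], []
        for j in range(n):
            w = net.W[i, j]
            if w > 0:
                acts.append((j, float(w)))
            elif w < 0:
                reps.append((j, float(-w)))
        specs.append(
            GeneRegulationSpec(
                activators=tuple(acts),
                repressors=tuple(reps),
                theta_abs=float(abs(net.theta[i])),
                basal_numerator=bool(net.theta[i] <= 0),
                alpha0=float(a0[i]),
                delta=float(dl[i]),
                hill_n=float(hn[i]),
            )
        )
    return ContinuousGRNModel(tuple(specs), net.genes)


# ---------------------------------------------------------------------------
# drift evaluation (vectorised over points)


def _check_points(model: ContinuousGRNModel, p: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    if pts.shape[-1] != model.n_genes:
        raise ValueError(
            f"points have dimension {pts.shape[-1]}, model has {model.n_genes} genes"
        )
    if (pts < 0).any():
        raise ValueError("concentrations must be non-negative (positive orthant)")
    return pts


def hill_terms(model: ContinuousGRNModel, p: np.ndarray) -> np.ndarray:
    """Hill production ratio N_i/D_i per gene (0 for regulator-free genes).

    ``p`` may be a single point or an ``(m, N)`` batch; returns the same
    leading shape.
    """
    pts = _check_points(model, p)
    m = pts.shape[0]
    out = np.zeros((m, model.n_genes))
    for i, spec in enumerate(model.specs):
        if not spec.has_regulators:
            continue
        num = np.zeros(m)
        den = np.full(m, 1.0 + spec.theta_abs)
        if spec.basal_numerator:
            num += 1.0 + spec.theta_abs
        for j, w in spec.activators:
            t = w * pts[:, j] ** spec.hill_n
            num += t
            den += t
        for j, w in spec.repressors:
            den += w * pts[:, j] ** spec.hill_n
        out[:, i] = num / den
    return out.reshape(np.shape(p))


def positive_rate(model: ContinuousGRNModel, p: np.ndarray) -> np.ndarray:
    """Total production rate B_i(p) = Hill_i(p) + alpha0_i (the drift's positive part)."""
    alpha0 = np.array([s.alpha0 for s in model.specs])
    return hill_terms(model, p) + alpha0


def drift(model: ContinuousGRNModel, p: np.ndarray) -> np.ndarray:
    """Deterministic drift dp/dt = B(p) - delta * p, elementwise."""
    deltas = np.array([s.delta for s in model.specs])
    return positive_rate(model, p) - deltas * np.asarray(p, dtype=float)


def production_self_derivatives(
    model: ContinuousGRNModel, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """First and second derivatives dB_i/dp_i and d^2B_i/dp_i^2.

    Only the *diagonal* derivatives are needed by the Fokker-Planck residual
    (the divergence couples coordinate j only to flux component j).  They are
    nonzero only for self-regulating genes; computed analytically from the
    quotient rule on N_i/D_i.
    """
    pts = _check_points(model, p)
    m = pts.shape[0]
    d1 = np.zeros((m, model.n_genes))
    d2 = np.zeros((m, model.n_genes))
    for i, spec in enumerate(model.specs):
        w_act = dict(spec.activators)
        w_all = {j: w for j, w in spec.regulators}
        if i not in w_all:
            continue
        n_exp = spec.hill_n
        x = pts[:, i]
        num = np.zeros(m)
        den = np.full(m, 1.0 + spec.theta_abs)
        if spec.basal_numerator:
            num += 1.0 + spec.theta_abs
        for j, w in spec.activators:
            t = w * pts[:, j] ** n_exp
            num += t
            den += t
        for j, w in spec.repressors:
            den += w * pts[:, j] ** n_exp
        ka = w_act.get(i, 0.0)
        kt = w_all[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            xp1 = np.where(x > 0, x ** (n_exp - 1.0), (1.0 if n_exp == 1 else 0.0))
            xp2 = np.where(
                x > 0, x ** (n_exp - 2.0), (1.0 if n_exp == 2 else 0.0)
            )
        dnum = ka * n_exp * xp1
        dden = kt * n_exp * xp1
        d2num = ka * n_exp * (n_exp - 1.0) * xp2
        d2den = kt * n_exp * (n_exp - 1.0) * xp2
        d1[:, i] = (dnum * den - num * dden) / den**2
        d2[:, i] = (d2num * den - num * d2den) / den**2 - 2.0 * dden * (
            dnum * den - num * dden
        ) / den**3
    shape = np.shape(p)
    return d1.reshape(shape), d2.reshape(shape)


def equation_strings(model: ContinuousGRNModel) -> list[str]:
    """Human-readable per-gene ODEs, mirroring the generated Hill structure."""
    lines = []
    for i, s in enumerate(model.specs):
        name = model.gene_names[i]
        rhs = []
        if s.has_regulators:
            num_terms = []
            if s.basal_numerator:
                num_terms.append(f"{1.0 + s.theta_abs:g}")
            den_terms = [f"{1.0 + s.theta_abs:g}"]
            exp = "" if s.hill_n == 1 else f"^{s.hill_n:g}"
            for j, w in s.activators:
                t = f"{w:g}*p{j + 1}{exp}"
                num_terms.append(t)
                den_terms.append(t)
            for j, w in s.repressors:
                den_terms.append(f"{w:g}*p{j + 1}{exp}")
            rhs.append(f"({' + '.join(num_terms)})/({' + '.join(den_terms)})")
        rhs.append(f"{s.alpha0:g}")
        lines.append(
            f"dp{i + 1}/dt = {' + '.join(rhs)} - {s.delta:g}*p{i + 1}    [{name}]"
        )
    return lines


# ---------------------------------------------------------------------------
# fixed points of the ODE


def boolean_to_concentration(model: ContinuousGRNModel, state: np.ndarray) -> np.ndarray:
    """Map a Boolean state to a concentration point: 0 -> 0, 1 -> (1+alpha0)/delta.

    OFF genes sit at the origin, ON genes at their saturation level; used as
    an initialisation heuristic for root finding and mixture warm starts.
    """
    x = np.asarray(state, dtype=float)
    return x * model.saturation_levels()


def _jacobian_fd(model: ContinuousGRNModel, p: np.ndarray, h: float = 1e-6) -> np.ndarray:
    n = model.n_genes
    J = np.empty((n, n))
    for j in range(n):
        e = np.zeros(n)
        e[j] = h
        lo = np.clip(p - e, 0.0, None)
        hi = p + e
        J[:, j] = (drift(model, hi) - drift(model, lo)) / (hi[j] - lo[j])
    return J


def ode_fixed_points(
    model: ContinuousGRNModel,
    initial_points: np.ndarray,
    tolerance: float = 1e-9,
    dedup_radius: float = 1e-3,
    require_stable: bool = True,
) -> list[np.ndarray]:
    """Locate (stable) fixed points of the drift by root finding.

    Runs ``scipy.optimize.root`` from each start, keeps converged roots in the
    positive orthant with ``||drift|| < tolerance``, deduplicates at
    ``dedup_radius`` (max-norm), and — when ``require_stable`` — keeps only
    roots whose numerical Jacobian has all eigenvalue real parts negative.
    Starts that fail to converge are skipped.
    """
    starts = np.atleast_2d(np.asarray(initial_points, dtype=float))
    found: list[np.ndarray] = []
    for x0 in starts:
        sol = optimize.root(lambda q: drift(model, np.clip(q, 0.0, None)), x0, method="hybr")
        if not sol.success:
            continue
        p = np.clip(sol.x, 0.0, None)
        if np.linalg.norm(drift(model, p)) >= tolerance:
            continue
        if require_stable:
            eig = np.linalg.eigvals(_jacobian_fd(model, p))
            if eig.real.max() >= 0:
                continue
        if any(np.max(np.abs(p - q)) < dedup_radius for q in found):
            continue
        found.append(p)
    found.sort(key=lambda q: tuple(q))
    return found
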