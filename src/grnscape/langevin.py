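"""Chemical Langevin equation and Fokker-Planck fields for a continuous GRN.

Splitting each gene's drift into production ``B_i(p)`` and degradation
``delta_i p_i``, the chemical Langevin approximation at system size Omega is

    dp_i = (B_i(p) - delta_i p_i) dt + sqrt((B_i(p) + delta_i p_i)/Omega) dW_i

(Ito interpretation, independent standard Wiener increments per gene).  The
matching Fokker-Planck equation has drift ``B_j - delta_j p_j`` and diagonal
diffusion ``Gamma_j(p) = (B_j(p) + delta_j p_j)/Omega``: noise variance is the
*sum* of production and degradation propensities, so fluctuations never vanish
at a balance point, and the whole noise scales like 1/Omega (large Omega =
many molecules = near-deterministic).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .continuous import ContinuousGRNModel, drift, positive_rate

__all__ = ["FPEModel", "Trajectory", "drift_field", "diffusion_field", "simulate_langevin"]


@dataclass(frozen=True)
class FPEModel:
    """A continuous GRN equipped with a system size Omega."""

    base: ContinuousGRNModel
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")

    @property
    def n_genes(self) -> int:
        return self.base.n_genes

    @property
    def deltas(self) -> np.ndarray:
        return np.array([s.delta for s in self.base.specs])


def drift_field(fpe: FPEModel, p: np.ndarray) -> np.ndarray:
    """FPE drift B_j(p) - delta_j p_j (identical to the deterministic drift)."""
    return drift(fpe.base, p)


def diffusion_field(fpe: FPEModel, p: np.ndarray) -> np.ndarray:
    """Per-coordinate diffusion Gamma_j(p) = (B_j(p) + delta_j p_j)/Omega."""
    pts = np.asarray(p, dtype=float)
    return (positive_rate(fpe.base, pts) + fpe.deltas * pts) / fpe.omega


@dataclass(frozen=True)
class Trajectory:
    """A sampled Euler-Maruyama path."""

    times: np.ndarray = field(repr=False)
    states: np.ndarray = field(repr=False)
    seed: int | None = None
    gene_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must have equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.states < 0).any():
            raise ValueError("states must be non-negative")

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        cols = list(self.gene_names) or [f"gene{i + 1}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


def simulate_langevin(
    fpe: FPEModel,
    p0: np.ndarray,
    dt: float,
    t_end: float,
    seed: int | None = None,
    store_every: int = 1,
) -> Trajectory:
    """Euler-Maruyama integration of the chemical Langevin equation.

    Negative proposals are reflected at zero (``p -> |p|``), which preserves
    non-negativity without absorbing probability mass at the boundary.
    ``store_every`` thins the stored path (the integration step is always dt).
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt >= t_end:
        raise ValueError(f"need dt < t_end, got dt={dt}, t_end={t_end}")
    p = np.asarray(p0, dtype=float).copy()
    if (p < 0).any():
        raise ValueError("initial state must be non-negative")
    rng = np.random.default_rng(seed)
    n_steps = int(round(t_end / dt))
    sqrt_dt = np.sqrt(dt)
    times = [0.0]
    states = [p.copy()]
    for k in range(1, n_steps + 1):
        a = drift_field(fpe, p)
        g = diffusion_field(fpe, p)
        p = p + a * dt + np.sqrt(g) * rng.standard_normal(p.shape) * sqrt_dt
        p = np.abs(p)  # reflecting boundary at 0
        if k % store_every == 0:
            times.append(k * dt)
            states.append(p.copy())
    return Trajectory(
        times=np.asarray(times),
        states=np.asarray(states),
        seed=seed,
        gene_names=fpe.base.gene_names,
    )
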