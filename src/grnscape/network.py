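"""Boolean gene regulatory networks and their fixed points.

A gene regulatory network (GRN) is given here in its minimal discrete form:
a signed integer weight matrix ``W`` (entry ``w_ij`` is the influence of gene
*j* on gene *i*; positive = activation, negative = repression) and an integer
activation-threshold vector ``theta``.  The synchronous Boolean dynamics are

    x_i(t+1) = H( sum_j w_ij x_j(t) - theta_i ),

with the step function ``H(x) = 1`` for ``x > 0`` and ``0`` otherwise, so a
tie never activates a gene.  Fixed points of this map are the network's
stationary expression patterns (phenotypes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "GeneNetwork",
    "boolean_step",
    "find_fixed_points",
    "load_network",
    "at_flower_network",
]

#: Exhaustive enumeration bound: 2**24 states is the largest search we attempt.
MAX_EXHAUSTIVE_GENES = 24


@dataclass(frozen=True)
class GeneNetwork:
    """A signed-threshold Boolean GRN.

    Parameters
    ----------
    genes
        Unique gene names, one per node.
    W
        Square integer matrix; ``W[i, j]`` is the effect of gene ``j`` on
        gene ``i`` (sign encodes activation/repression, 0 means no edge).
    theta
        Integer activation thresholds, one per gene.
    """

    genes: tuple[str, ...]
    W: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        theta = np.asarray(self.theta)
        object.__setattr__(self, "genes", tuple(str(g) for g in self.genes))
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "theta", theta)
        n = len(self.genes)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if W.shape[0] != n:
            raise ValueError(
                f"W is {W.shape[0]}x{W.shape[1]} but there are {n} gene names"
            )
        if theta.shape != (n,):
            raise ValueError(
                f"theta has length {theta.shape[0] if theta.ndim == 1 else theta.shape}, "
                f"expected {n}"
            )
        if len(set(self.genes)) != n:
            raise ValueError("gene names must be unique")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def boolean_step(state: np.ndarray, net: GeneNetwork) -> np.ndarray:
    """One synchronous update of the Boolean dynamics.

    ``state`` may also be a 2-D array of shape ``(m, N)``; each row is then
    updated independently (used for vectorised enumeration).
    """
    x = np.asarray(state)
    if x.shape[-1] != net.n_genes:
        raise ValueError(
            f"state has length {x.shape[-1]} but network has {net.n_genes} genes"
        )
    if not np.isin(x, (0, 1)).all():
        raise ValueError("Boolean state entries must be 0 or 1")
    # H is strict: the field s - theta must be positive to activate.
    s = x @ net.W.T
    return (s - net.theta > 0).astype(np.int8)


def find_fixed_points(net: GeneNetwork) -> list[np.ndarray]:
    """All fixed points of :func:`boolean_step`, by exhaustive enumeration.

    Returns the states ``x`` with ``boolean_step(x) = x`` in lexicographic
    order.  Raises for networks with more than ``MAX_EXHAUSTIVE_GENES`` genes,
    where 2**N enumeration is no longer reasonable (a sampling-based search
    would be needed; not provided).
    """
    n = net.n_genes
    if n > MAX_EXHAUSTIVE_GENES:
        raise ValueError(
            f"{n} genes means 2**{n} states; exhaustive enumeration is limited to "
            f"{MAX_EXHAUSTIVE_GENES} genes. Consider a sampling-based search "
            "(not implemented)."
        )
    codes = np.arange(2**n, dtype=np.int64)
    # bit i of the code is gene i, so enumeration order is lexicographic in x
    states = (codes[:, None] >> np.arange(n - 1, -1, -1)) & 1
    states = states.astype(np.int8)
    nxt = boolean_step(states, net)
    mask = (nxt == states).all(axis=1)
    return [states[i].copy() for i in np.nonzero(mask)[0]]


def load_network(source: str | Path | dict) -> GeneNetwork:
    """Read a network from a JSON file or an already-parsed mapping.

    The format is ``{"genes": [...], "W": [[...]], "theta": [...]}``; row
    ``i`` of ``W`` belongs to target gene ``i``.  Unknown keys are ignored.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            obj = json.load(fh)
    else:
        obj = source
    try:
        genes, W, theta = obj["genes"], obj["W"], obj["theta"]
    except KeyError as exc:
        raise ValueError(f"network JSON is missing required key {exc}") from exc
    return GeneNetwork(tuple(genes), np.asarray(W, dtype=int), np.asarray(theta, dtype=int))


def at_flower_network() -> GeneNetwork:
    """The 12-gene *Arabidopsis thaliana* flower-morphogenesis GRN.

    Packaged fixture: the published integer weight matrix and threshold
    vector for the EMF1/TFL1/LFY/AP1/CAL/LUG/UFO/BFU/AG/AP3/PI/SUP network,
    whose Boolean dynamics admit (at least) four stationary states matching
    the four floral phenotypic stages.
    """
    ref = resources.files("grnscape.data").joinpath("at_flower_network.json")
    return load_network(json.loads(ref.read_text()))
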