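"""Nodal analysis of the resistive ladder network.

The discretized lumen becomes a ladder: longitudinal saline conductances
chain adjacent lumen nodes, each node has a transverse (cross-wall)
conductance to a single ideal bath/ground node, and the two lumen ends
connect to the bath through the boundary fluid columns.  The bath is one
node at reference potential 0 — the casing ground electrode and all resistor
returns share it, and any bath spreading resistance is considered absorbed
into the transverse values.

Solving G.V = I with the ground row/column eliminated gives the steady-state
(purely resistive) potential at every lumen node for any balanced current
injection.  Electrodes act as ideal point current sources at their nearest
node; no electrode-electrolyte interface element is modelled, which is why
trans-impedances measured *at* a stimulating contact are flagged unreliable
downstream rather than simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import CochleaModel, longitudinal_resistances

__all__ = [
    "Network",
    "CurrentVector",
    "NodeVoltages",
    "FloatingNetworkError",
    "assemble",
    "solve",
    "transfer_resistance",
    "transfer_resistance_matrix",
]


class FloatingNetworkError(RuntimeError):
    """The grounded system is singular: no conductive path to the bath."""


@dataclass(frozen=True)
class CurrentVector:
    """Balanced current injection: one entry per lumen node plus the ground
    return, microampere.  Kirchhoff requires the total (including ground)
    to vanish."""

    node_currents_uA: np.ndarray
    ground_current_uA: float

    def __post_init__(self) -> None:
        i = np.asarray(self.node_currents_uA, dtype=float)
        object.__setattr__(self, "node_currents_uA", i)
        total = float(i.sum()) + float(self.ground_current_uA)
        scale = max(np.abs(i).sum(), abs(self.ground_current_uA), 1.0)
        if abs(total) > 1e-9 * scale:
            raise ValueError(
                f"currents not charge-balanced: net {total:g} uA"
            )


@dataclass(frozen=True)
class NodeVoltages:
    """Potential at each lumen node, millivolt, referenced to the bath (0)."""

    voltages_mV: np.ndarray


@dataclass
class Network:
    """Grounded conductance system of the ladder.

    ``conductance_matrix`` is the full symmetric (N+1)x(N+1) Laplacian in
    siemens with the bath node last; the grounded (bath-eliminated) NxN block
    is Cholesky-factorized lazily and cached for repeated solves.
    """

    conductance_matrix: np.ndarray
    ground_index: int
    _cho: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_lumen_nodes(self) -> int:
        return self.conductance_matrix.shape[0] - 1

    def grounded_matrix(self) -> np.ndarray:
        keep = np.arange(self.conductance_matrix.shape[0]) != self.ground_index
        return self.conductance_matrix[np.ix_(keep, keep)]

    def factorization(self):
        if self._cho is None:
            g = self.grounded_matrix()
            try:
                self._cho = scipy.linalg.cho_factor(g)
            except scipy.linalg.LinAlgError as exc:
                raise FloatingNetworkError(
                    "floating network: no finite path from some node to ground"
                ) from exc
        return self._cho


def assemble(model: CochleaModel) -> Network:
    """Build the ladder's conductance Laplacian from a cochlea model.

    Infinite resistances contribute zero conductance (pathway absent).
    """
    n = model.geometry.n_nodes
    g = np.zeros((n + 1, n + 1))
    ground = n

    r_long = longitudinal_resistances(model.geometry, model.saline_conductivity)
    for k, r in enumerate(r_long):
        _stamp(g, k, k + 1, 1.0 / r)
    for k, r in enumerate(model.transverse_resistances):
        if np.isfinite(r):
            _stamp(g, k, ground, 1.0 / r)
    if np.isfinite(model.basal_boundary_resistance):
        _stamp(g, 0, ground, 1.0 / model.basal_boundary_resistance)
    if np.isfinite(model.apical_boundary_resistance):
        _stamp(g, n - 1, ground, 1.0 / model.apical_boundary_resistance)
    return Network(conductance_matrix=g, ground_index=ground)


def _stamp(g: np.ndarray, a: int, b: int, conductance: float) -> None:
    g[a, a] += conductance
    g[b, b] += conductance
    g[a, b] -= conductance
    g[b, a] -= conductance


def solve(network: Network, currents: CurrentVector) -> NodeVoltages:
    """Solve the grounded system for a balanced injection.

    The residual ||G.V - I|| is checked to 1e-9 relative; a Cholesky failure
    of the grounded matrix is reported as a floating network.
    """
    i_amp = np.asarray(currents.node_currents_uA, dtype=float) * 1e-6
    if i_amp.size != network.n_lumen_nodes:
        raise ValueError("current vector length does not match the network")
    cho = network.factorization()
    v = scipy.linalg.cho_solve(cho, i_amp)
    residual = np.linalg.norm(network.grounded_matrix() @ v - i_amp)
    norm = np.linalg.norm(i_amp)
    if norm > 0 and residual > 1e-9 * norm:
        raise FloatingNetworkError(
            f"solver residual {residual:g} exceeds tolerance for ||I||={norm:g}"
        )
    return NodeVoltages(voltages_mV=v * 1e3)


def transfer_resistance(network: Network, from_node: int, to_node: int) -> float:
    """Voltage at ``to_node`` per unit current injected at ``from_node``
    (return via ground), ohm."""
    n = network.n_lumen_nodes
    if not (0 <= from_node < n and 0 <= to_node < n):
        raise ValueError("node index out of range")
    i = np.zeros(n)
    i[from_node] = 1.0  # uA
    v = solve(network, CurrentVector(node_currents_uA=i, ground_current_uA=-1.0))
    return float(v.voltages_mV[to_node]) * 1e3  # mV/uA -> ohm


def transfer_resistance_matrix(network: Network, nodes: np.ndarray) -> np.ndarray:
    """Trans-resistance matrix (ohm) among a set of lumen nodes."""
    nodes = np.asarray(nodes, dtype=int)
    n = network.n_lumen_nodes
    out = np.empty((nodes.size, nodes.size))
    for row, src in enumerate(nodes):
        i = np.zeros(n)
        i[src] = 1.0
        v = solve(network, CurrentVector(node_currents_uA=i, ground_current_uA=-1.0))
        out[row] = v.voltages_mV[nodes] * 1e3
    return out
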