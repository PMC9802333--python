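"""Directed-graph samples consumed by the interaction models.

Each trajectory time step becomes one directed graph: node feature vectors
``[r, v, (q), m]``, a directed edge list (receiver first, sender second),
optional per-edge minimum-image displacement features for periodic systems,
and the target accelerations.  Small systems use the full graph with
``n (n - 1)`` directed edges; the periodic Lennard-Jones system uses
cutoff-radius connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems import minimum_image

__all__ = [
    "FeatureLayout",
    "GraphSample",
    "build_full_graph",
    "build_cutoff_graph",
    "edge_input",
    "reverse_index",
    "sample_from_state",
    "samples_from_trajectory",
]


@dataclass(frozen=True)
class FeatureLayout:
    """Declares how node and edge input features are laid out.

    The receiver's features lead the edge-input concatenation, the sender's
    follow, and (periodic systems only) the minimum-image displacement from
    receiver to sender is appended.  ``include_charge=False`` reproduces the
    Lennard-Jones configuration where charge is not a particle property.
    """

    d: int
    include_charge: bool = True
    include_displacement: bool = False

    @property
    def node_dim(self):
        return 2 * self.d + (2 if self.include_charge else 1)

    @property
    def edge_dim(self):
        return 2 * self.node_dim + (self.d if self.include_displacement else 0)

    @property
    def receiver_pos(self):
        """Slice of the edge input holding the receiver's position."""
        return slice(0, self.d)

    @property
    def displacement(self):
        """Slice of the edge input holding the displacement feature, or None."""
        if not self.include_displacement:
            return None
        return slice(2 * self.node_dim, 2 * self.node_dim + self.d)

    def to_dict(self):
        return {
            "d": self.d,
            "include_charge": self.include_charge,
            "include_displacement": self.include_displacement,
        }

    @classmethod
    def from_dict(cls, data):
        return cls(**data)


@dataclass
class GraphSample:
    """One trajectory time step as a directed graph."""

    node_features: np.ndarray  # (n, node_dim): [r, v, (q), m]
    edges: np.ndarray  # (E, 2) int: (receiver, sender)
    masses: np.ndarray  # (n,)
    layout: FeatureLayout
    displacements: np.ndarray | None = None  # (E, d)
    targets: np.ndarray | None = None  # (n, d)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64)
        if self.node_features.shape[1] != self.layout.node_dim:
            raise ValueError("node feature length disagrees with layout")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        if self.layout.include_displacement and self.displacements is None:
            raise ValueError("layout declares a displacement feature but none given")

    @property
    def n(self):
        return self.node_features.shape[0]

    @property
    def n_edges(self):
        return self.edges.shape[0]

    @property
    def positions(self):
        return self.node_features[:, : self.layout.d]


def build_full_graph(n):
    """All ordered pairs (receiver, sender), receiver-major order."""
    if n < 2:
        raise ValueError("need at least two particles")
    recv, send = np.mgrid[0:n, 0:n]
    mask = recv != send
    return np.stack([recv[mask], send[mask]], axis=1)


def build_cutoff_graph(positions, box_length, r_cut):
    """Directed edges within the cutoff under the minimum-image convention.

    Returns ``(edges, displacements)`` where each stored displacement is the
    minimum-image vector from receiver to sender.
    """
    if r_cut > box_length / 2 + 1e-12:
        raise ValueError("r_cut must not exceed half the box length")
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    disp = minimum_image(positions[:, None, :], positions[None, :, :], box_length)
    dist = np.linalg.norm(disp, axis=-1)
    idx = np.arange(n)
    dist[idx, idx] = np.inf
    recv, send = np.nonzero(dist <= r_cut)
    edges = np.stack([recv, send], axis=1)
    return edges, disp[recv, send]


def edge_input(sample, edges=None):
    """Edge input features: concat(receiver, sender[, displacement])."""
    if edges is None:
        edges = sample.edges
    parts = [sample.node_features[edges[:, 0]], sample.node_features[edges[:, 1]]]
    if sample.layout.include_displacement:
        parts.append(sample.displacements)
    return np.concatenate(parts, axis=1)


def reverse_index(edges):
    """Position of each directed edge's reverse within the edge list."""
    edges = np.asarray(edges)
    order_fwd = np.lexsort((edges[:, 1], edges[:, 0]))
    order_rev = np.lexsort((edges[:, 0], edges[:, 1]))
    if not np.array_equal(edges[order_fwd], edges[order_rev][:, ::-1]):
        raise ValueError("edge list is not reverse-closed")
    rev = np.empty(len(edges), dtype=np.int64)
    rev[order_fwd] = order_rev
    return rev


def _node_features(state_pos, state_vel, charges, masses, layout):
    parts = [state_pos, state_vel]
    if layout.include_charge:
        parts.append(np.asarray(charges)[:, None])
    parts.append(np.asarray(masses)[:, None])
    return np.concatenate(parts, axis=1)


def sample_from_state(
    positions, velocities, charges, masses, layout, targets=None,
    box_length=None, r_cut=None,
):
    """Build the graph sample for one time step.

    Full connectivity unless the layout declares a displacement feature, in
    which case a periodic cutoff graph is built (``box_length`` and
    ``r_cut`` required).
    """
    feats = _node_features(positions, velocities, charges, masses, layout)
    if layout.include_displacement:
        if box_length is None or r_cut is None:
            raise ValueError("periodic layout needs box_length and r_cut")
        edges, disp = build_cutoff_graph(positions, box_length, r_cut)
    else:
        edges = build_full_graph(len(masses))
        disp = None
    return GraphSample(
        node_features=feats,
        edges=edges,
        masses=np.asarray(masses, dtype=float),
        layout=layout,
        displacements=disp,
        targets=None if targets is None else np.asarray(targets, dtype=float),
    )


def samples_from_trajectory(traj, layout=None, r_cut=None, steps=None):
    """Graph samples (with acceleration targets) for trajectory steps."""
    if layout is None:
        periodic = traj.box_length is not None
        layout = FeatureLayout(
            d=traj.d, include_charge=not periodic, include_displacement=periodic
        )
    if layout.include_displacement and r_cut is None:
        if traj.spec is None:
            raise ValueError("r_cut required for periodic samples")
        r_cut = traj.spec.constants["r_cut"]
    if steps is None:
        steps = range(traj.n_steps)
    return [
        sample_from_state(
            traj.positions[t],
            traj.velocities[t],
            traj.charges,
            traj.masses,
            layout,
            targets=traj.accelerations[t],
            box_length=traj.box_length,
            r_cut=r_cut,
        )
        for t in steps
    ]
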