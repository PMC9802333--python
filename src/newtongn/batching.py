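"""Mini-batch collation: a batch is a set of whole time-step graphs.

Collating concatenates the per-step edge-input matrices and offsets node
indices so scatter-sums over receivers work on the flattened node axis.
``node_orig`` retains each node's index within its own system, which the
GN+ baseline needs to look up its per-node scalars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import edge_input, reverse_index

__all__ = ["Batch", "collate"]


@dataclass
class Batch:
    X: np.ndarray  # (R, edge_dim) stacked edge inputs
    recv: np.ndarray  # (R,) receiver index into flattened nodes
    rev: np.ndarray  # (R,) index of the reverse edge within the batch
    node_features: np.ndarray  # (N, node_dim)
    masses: np.ndarray  # (N,)
    node_orig: np.ndarray  # (N,) node index within its own system
    targets: np.ndarray | None  # (N, d)
    n_steps: int
    n_nodes: int  # N
    n_edges: int  # R
    edges_per_step: np.ndarray  # (n_steps,)

    def cast(self, dtype):
        if self.X.dtype == np.dtype(dtype):
            return self
        return Batch(
            X=self.X.astype(dtype),
            recv=self.recv,
            rev=self.rev,
            node_features=self.node_features.astype(dtype),
            masses=self.masses.astype(dtype),
            node_orig=self.node_orig,
            targets=None if self.targets is None else self.targets.astype(dtype),
            n_steps=self.n_steps,
            n_nodes=self.n_nodes,
            n_edges=self.n_edges,
            edges_per_step=self.edges_per_step,
        )


def _sample_arrays(s, dtype):
    """Edge inputs and reverse index, memoised per dtype.

    Samples are reused across many epochs, so the (large) edge-input cast
    happens once; the small per-node arrays are cast on the fly so that
    in-place edits to targets remain visible.
    """
    cache = getattr(s, "_collate_cache", None)
    if cache is None:
        cache = s._collate_cache = {}
    key = np.dtype(dtype).str if dtype is not None else "native"
    entry = cache.get(key)
    if entry is None:
        X = edge_input(s)
        rev = cache.get("rev")
        if rev is None:
            rev = cache["rev"] = reverse_index(s.edges)
        if dtype is not None:
            X = X.astype(dtype, copy=False)
        entry = cache[key] = (X, rev)
    X, rev = entry
    feats = s.node_features
    masses = s.masses
    targets = s.targets
    if dtype is not None:
        feats = feats.astype(dtype, copy=False)
        masses = masses.astype(dtype, copy=False)
        targets = None if targets is None else targets.astype(dtype, copy=False)
    return X, rev, feats, masses, targets


def collate(samples, with_targets=True, dtype=None):
    """Stack graph samples into one batch with offset node/edge indices."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty batch")
    Xs, recvs, revs, feats, masses, origs, targets = [], [], [], [], [], [], []
    node_off = 0
    edge_off = 0
    eps = []
    for s in samples:
        X, rev, nf, ms, tg = _sample_arrays(s, dtype)
        Xs.append(X)
        recvs.append(s.edges[:, 0] + node_off)
        revs.append(rev + edge_off)
        feats.append(nf)
        masses.append(ms)
        origs.append(np.arange(s.n))
        if with_targets:
            if tg is None:
                raise ValueError("sample has no targets")
            targets.append(tg)
        node_off += s.n
        edge_off += s.n_edges
        eps.append(s.n_edges)
    return Batch(
        X=np.concatenate(Xs),
        recv=np.concatenate(recvs),
        rev=np.concatenate(revs),
        node_features=np.concatenate(feats),
        masses=np.concatenate(masses),
        node_orig=np.concatenate(origs),
        targets=np.concatenate(targets) if with_targets else None,
        n_steps=len(samples),
        n_nodes=node_off,
        n_edges=edge_off,
        edges_per_step=np.asarray(eps),
    )
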