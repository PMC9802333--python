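"""Comparison models: fully learned graph network, GN+ variants, symmetry
regularization.

``gn_baseline`` pairs the edge MLP with a *learned* node MLP mapping
``concat(node features, summed incoming messages)`` to the acceleration —
nothing ties its edge messages to physical forces.  ``gn_symreg`` is the
same architecture trained with an extra L1 penalty on ``M_ij + M_ji``
(action–reaction as a soft constraint, weight ``alpha``; ``alpha=0``
recovers the plain baseline exactly).  ``gn_plus`` divides the aggregated
messages by ``10**w_i`` with one learnable scalar per node;
``gn_plus_uni`` shares a single scalar across nodes.
"""

from __future__ import annotations

import numpy as np

from .batching import Batch, collate
from .mlp import ACTIVATIONS, MLP
from .model import scatter_sum

__all__ = ["BaselineGN", "GNPlus", "build_baseline", "symmetry_penalty"]

LN10 = np.log(10.0)


class _BaseModel:
    def _as_batch(self, sample):
        if isinstance(sample, Batch):
            return sample
        if sample.layout != self.layout:
            raise ValueError("feature layout mismatch")
        return collate(
            [sample], with_targets=sample.targets is not None, dtype=self.edge.dtype
        )

    @property
    def n_params(self):
        return sum(p.size for p in self.params)


class BaselineGN(_BaseModel):
    """Learned edge + node MLPs; optional action–reaction regularization.

    ``mode`` fixes the edge output dimension only (``d`` when competing on
    force inference, 1 on potential inference); the node MLP always outputs
    accelerations and is trained jointly.
    """

    def __init__(
        self,
        layout,
        mode="force",
        hidden_layers=4,
        hidden_units=300,
        activation="silu",
        alpha=0.0,
        seed=0,
        dtype=np.float64,
    ):
        if alpha < 0:
            raise ValueError("alpha must be non-negative")
        act = ACTIVATIONS[activation] if isinstance(activation, str) else activation
        self.layout = layout
        self.mode = mode
        self.alpha = float(alpha)
        self.config = {
            "hidden_layers": hidden_layers,
            "hidden_units": hidden_units,
            "activation": act.name,
            "alpha": float(alpha),
            "seed": seed,
        }
        edge_out = layout.d if mode == "force" else 1
        # seeded sub-networks: edge net then node net from one root seed
        ss = np.random.SeedSequence(seed).spawn(2)
        self.edge = MLP(
            [layout.edge_dim] + [hidden_units] * hidden_layers + [edge_out],
            activation=act,
            rng=ss[0],
            dtype=dtype,
        )
        self.node = MLP(
            [layout.node_dim + edge_out] + [hidden_units] * hidden_layers + [layout.d],
            activation=act,
            rng=ss[1],
            dtype=dtype,
        )

    @property
    def variant(self):
        return "gn_symreg" if self.alpha > 0 else "gn_baseline"

    @property
    def params(self):
        return self.edge.params + self.node.params

    def set_params(self, arrays):
        arrays = list(arrays)
        k = 2 * self.edge.n_layers
        self.edge.set_params(arrays[:k])
        self.node.set_params(arrays[k:])

    def copy_params(self):
        return [p.copy() for p in self.params]

    def edge_messages(self, sample):
        batch = self._as_batch(sample)
        return self.edge.forward(batch.X)

    def extract_interactions(self, sample):
        """Read the edge messages as the baseline's implied interactions."""
        msgs = self.edge_messages(sample)
        if self.mode == "force":
            return msgs, None
        return None, msgs[:, 0]

    def predict(self, sample):
        batch = self._as_batch(sample)
        return self._forward(batch)[0]

    def _forward(self, batch, need_cache=False):
        msgs, ec = self.edge.forward(batch.X, need_cache=True)
        S = scatter_sum(msgs, batch.recv, batch.n_nodes)
        U = np.concatenate([batch.node_features, S], axis=1)
        acc, nc = self.node.forward(U, need_cache=True)
        if need_cache:
            return acc, (msgs, ec, nc)
        return acc, None

    def loss_grads(self, batch):
        batch = batch.cast(self.edge.dtype)
        acc, (msgs, ec, nc) = self._forward(batch, need_cache=True)
        resid = acc - batch.targets
        denom = batch.n_nodes
        loss = float(np.abs(resid).sum()) / denom
        dacc = np.sign(resid) / denom
        node_grads, dU = self.node.backward(nc, dacc, need_dX=True)
        dmsg = dU[:, self.layout.node_dim :][batch.recv]
        if self.alpha > 0:
            pen, dpen = symmetry_penalty(
                msgs, batch.rev, batch.edges_per_step, self.alpha
            )
            loss += pen
            dmsg = dmsg + dpen
        edge_grads = self.edge.backward(ec, dmsg)
        return loss, edge_grads + node_grads


def symmetry_penalty(msgs, rev, edges_per_step, alpha):
    """Mean elementwise |M_ij + M_ji| over directed edges, per step.

    Returns the penalty value (already weighted by ``alpha`` and averaged
    over the steps in the batch) and its gradient w.r.t. the messages.
    """
    n_steps = len(edges_per_step)
    w = np.repeat(alpha / (n_steps * edges_per_step.astype(float)), edges_per_step)
    s = msgs + msgs[rev]
    pen = float((w * np.abs(s).sum(axis=1)).sum())
    # each unordered pair contributes twice; d|M_e + M_rev|/dM_e picks up
    # the sign from its own term and from the reverse edge's term
    grad = (2.0 * w)[:, None] * np.sign(s)
    return pen, grad.astype(msgs.dtype)


class GNPlus(_BaseModel):
    """Edge MLP with aggregated messages divided by ``10**w`` per node.

    ``shared=True`` (the "uni" variant) uses a single scalar for all nodes.
    Per-node scalars are defined for the training system's nodes only; when
    evaluated on a larger system, unseen nodes fall back to the mean trained
    scalar and the model records that it did so.
    """

    def __init__(
        self,
        layout,
        n_nodes,
        shared=False,
        hidden_layers=4,
        hidden_units=300,
        activation="silu",
        seed=0,
        dtype=np.float64,
    ):
        act = ACTIVATIONS[activation] if isinstance(activation, str) else activation
        self.layout = layout
        self.mode = "force"  # GN+ was designed solely for pairwise force
        self.shared = bool(shared)
        self.n_train_nodes = int(n_nodes)
        self.config = {
            "hidden_layers": hidden_layers,
            "hidden_units": hidden_units,
            "activation": act.name,
            "n_nodes": int(n_nodes),
            "shared": bool(shared),
            "seed": seed,
        }
        self.edge = MLP(
            [layout.edge_dim] + [hidden_units] * hidden_layers + [layout.d],
            activation=act,
            rng=seed,
            dtype=dtype,
        )
        n_w = 1 if shared else n_nodes
        self.w = np.zeros(n_w, dtype=dtype)  # zeros: divide by 10**0 = 1
        self.used_fallback_w = False

    @property
    def variant(self):
        return "gn_plus_uni" if self.shared else "gn_plus"

    @property
    def params(self):
        return self.edge.params + [self.w]

    def set_params(self, arrays):
        arrays = list(arrays)
        self.edge.set_params(arrays[:-1])
        self.w[...] = arrays[-1]

    def copy_params(self):
        return [p.copy() for p in self.params]

    def _node_w(self, node_orig):
        if self.shared:
            return np.broadcast_to(self.w, node_orig.shape)
        if np.any(node_orig >= self.n_train_nodes):
            # generalization to a larger system: unseen nodes get the mean
            self.used_fallback_w = True
            w_ext = np.where(
                node_orig < self.n_train_nodes,
                self.w[np.minimum(node_orig, self.n_train_nodes - 1)],
                self.w.mean(),
            )
            return w_ext
        return self.w[node_orig]

    def edge_messages(self, sample):
        batch = self._as_batch(sample)
        return self.edge.forward(batch.X)

    def extract_interactions(self, sample):
        return self.edge_messages(sample), None

    def predict(self, sample):
        batch = self._as_batch(sample)
        return self._forward(batch)[0]

    def _forward(self, batch, need_cache=False):
        msgs, ec = self.edge.forward(batch.X, need_cache=True)
        S = scatter_sum(msgs, batch.recv, batch.n_nodes)
        w = self._node_w(batch.node_orig)
        acc = S / np.power(10.0, w)[:, None]
        if need_cache:
            return acc, (msgs, ec, S, w)
        return acc, None

    def loss_grads(self, batch):
        batch = batch.cast(self.edge.dtype)
        acc, (msgs, ec, S, w) = self._forward(batch, need_cache=True)
        resid = acc - batch.targets
        denom = batch.n_nodes
        loss = float(np.abs(resid).sum()) / denom
        dacc = np.sign(resid) / denom
        dS = dacc / np.power(10.0, w)[:, None]
        edge_grads = self.edge.backward(ec, dS[batch.recv])
        per_node_dw = -(LN10) * (dacc * acc).sum(axis=1)
        if self.shared:
            dw = np.array([per_node_dw.sum()], dtype=self.w.dtype)
        else:
            dw = np.zeros_like(self.w)
            np.add.at(dw, batch.node_orig, per_node_dw.astype(self.w.dtype))
        return loss, edge_grads + [dw]


def build_baseline(variant, layout, mode, cfg, dtype=np.float64):
    """Construct a baseline model from checkpoint metadata."""
    if variant in ("gn_baseline", "gn_symreg"):
        return BaselineGN(
            layout,
            mode=mode,
            hidden_layers=cfg["hidden_layers"],
            hidden_units=cfg["hidden_units"],
            activation=cfg["activation"],
            alpha=cfg.get("alpha", 0.0),
            seed=cfg["seed"],
            dtype=dtype,
        )
    if variant in ("gn_plus", "gn_plus_uni"):
        return GNPlus(
            layout,
            n_nodes=cfg["n_nodes"],
            shared=variant == "gn_plus_uni",
            hidden_layers=cfg["hidden_layers"],
            hidden_units=cfg["hidden_units"],
            activation=cfg["activation"],
            seed=cfg["seed"],
            dtype=dtype,
        )
    raise ValueError(f"unknown baseline variant {variant!r}")
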