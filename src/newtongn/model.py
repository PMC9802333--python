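"""Physics-induced graph network: learned edge messages, Newtonian node update.

The only trainable component is an edge MLP acting on the concatenated
features of a directed pair of particles.  The node update is a fixed
physics operator with zero parameters:

* **force mode** — the edge output (length ``d``) is read as the pairwise
  force, and the node acceleration is the sum of incoming messages divided
  by the receiver's mass (Newton's second law);
* **potential mode** — the edge output (scalar) is read as the pairwise
  potential, and the node acceleration is the negative derivative of the
  summed incoming messages with respect to the receiver's position, divided
  by the mass.  The derivative flows through every input slot that is a
  function of the receiver position: the receiver-position entries of the
  concatenation and, in periodic layouts, the displacement feature (with
  d(disp)/d(r_receiver) = -identity).

Because only the derivative of the potential is constrained by training,
the learned potential carries an arbitrary additive constant: potentials
are identified up to a gauge, increments exactly.
"""

from __future__ import annotations

import io as _io
import json
import zipfile

import numpy as np

from .batching import Batch, collate
from .graphs import FeatureLayout
from .mlp import ACTIVATIONS, MLP

__all__ = [
    "PhysicsGN",
    "node_force_operator",
    "scatter_sum",
    "save_checkpoint",
    "load_checkpoint",
]


def scatter_sum(values, index, n):
    """Sum ``values`` rows into ``n`` bins given by ``index``."""
    values = np.asarray(values)
    out = np.empty((n, values.shape[1]), dtype=values.dtype)
    for k in range(values.shape[1]):  # bincount is much faster than add.at
        out[:, k] = np.bincount(index, weights=values[:, k], minlength=n)
    return out


def node_force_operator(messages, recv, masses):
    """Accelerations = (sum of incoming messages) / mass; no parameters.

    ``messages`` are per-directed-edge force vectors, ``recv`` the receiver
    index of each edge, ``masses`` the per-node masses.
    """
    masses = np.asarray(masses)
    if np.any(masses <= 0):
        raise ValueError("masses must be strictly positive")
    return scatter_sum(messages, recv, len(masses)) / masses[:, None]


class PhysicsGN:
    """Edge MLP + deterministic Newtonian node operator."""

    variant = "physgn"

    def __init__(
        self,
        layout,
        mode="force",
        hidden_layers=4,
        hidden_units=300,
        activation="silu",
        seed=0,
        dtype=np.float64,
    ):
        if mode not in ("force", "potential"):
            raise ValueError("mode must be 'force' or 'potential'")
        act = ACTIVATIONS[activation] if isinstance(activation, str) else activation
        if mode == "potential" and not act.smooth:
            raise ValueError(
                f"activation {act.name!r} has a discontinuous derivative and cannot "
                "be differentiated into smooth forces; use silu or tanh"
            )
        self.layout = layout
        self.mode = mode
        self.config = {
            "hidden_layers": hidden_layers,
            "hidden_units": hidden_units,
            "activation": act.name,
            "seed": seed,
        }
        out_dim = layout.d if mode == "force" else 1
        sizes = [layout.edge_dim] + [hidden_units] * hidden_layers + [out_dim]
        self.mlp = MLP(sizes, activation=act, rng=seed, dtype=dtype)

    # -- plumbing ----------------------------------------------------------

    @property
    def params(self):
        return self.mlp.params

    def set_params(self, arrays):
        self.mlp.set_params(arrays)

    def copy_params(self):
        return self.mlp.copy_params()

    @property
    def n_params(self):
        return sum(p.size for p in self.params)

    def _check_layout(self, sample_or_batch):
        layout = getattr(sample_or_batch, "layout", None)
        if layout is not None and layout != self.layout:
            raise ValueError(
                f"feature layout mismatch: model {self.layout}, data {layout}"
            )

    def _as_batch(self, sample):
        if isinstance(sample, Batch):
            return sample
        self._check_layout(sample)
        return collate(
            [sample], with_targets=sample.targets is not None, dtype=self.mlp.dtype
        )

    # -- forward -----------------------------------------------------------

    def edge_messages(self, sample):
        """Per-directed-edge messages (forces or potentials)."""
        batch = self._as_batch(sample)
        return self.mlp.forward(batch.X)

    def predict(self, sample):
        """Predicted accelerations for one graph sample or a batch."""
        batch = self._as_batch(sample)
        acc, _ = self._forward(batch)
        return acc

    def _forward(self, batch, need_cache=False):
        Y, cache = self.mlp.forward(batch.X, need_cache=True)
        if self.mode == "force":
            acc = node_force_operator(Y, batch.recv, batch.masses)
            extra = {"cache": cache, "Y": Y}
        else:
            g, gcache = self.mlp.input_grad(cache, need_gcache=True)
            F = self._edge_forces_from_gradient(g)
            acc = node_force_operator(F, batch.recv, batch.masses)
            extra = {"cache": cache, "gcache": gcache, "Y": Y, "F": F}
        return acc, (extra if need_cache else None)

    def _edge_forces_from_gradient(self, g):
        """F_ij = -dM_ij/dr_i collected from the relevant input slots."""
        dM = g[:, self.layout.receiver_pos].copy()
        disp = self.layout.displacement
        if disp is not None:
            dM -= g[:, disp]
        return -dM

    def extract_interactions(self, sample):
        """Per-edge forces (both modes) and potentials (potential mode).

        Returns ``(forces, potentials)`` with ``potentials=None`` in force
        mode.  Re-aggregating the forces through the node operator
        reproduces the model's accelerations exactly.
        """
        batch = self._as_batch(sample)
        Y, cache = self.mlp.forward(batch.X, need_cache=True)
        if self.mode == "force":
            return Y, None
        g = self.mlp.input_grad(cache)
        return self._edge_forces_from_gradient(g), Y[:, 0]

    # -- training interface -------------------------------------------------

    def loss_grads(self, batch):
        """Mean-absolute acceleration loss and parameter gradients."""
        batch = batch.cast(self.mlp.dtype)
        acc, extra = self._forward(batch, need_cache=True)
        resid = acc - batch.targets
        denom = batch.n_nodes  # |T|*|V| for equally sized steps
        loss = float(np.abs(resid).sum()) / denom
        dacc = np.sign(resid) / denom / batch.masses[:, None]
        dmsg = dacc[batch.recv]  # adjoint of the per-edge force
        if self.mode == "force":
            grads = self.mlp.backward(extra["cache"], dmsg)
        else:
            Gg = np.zeros_like(batch.X)
            Gg[:, self.layout.receiver_pos] = -dmsg
            disp = self.layout.displacement
            if disp is not None:
                Gg[:, disp] = dmsg
            grads = self.mlp.backward_through_input_grad(
                extra["cache"], extra["gcache"], Gg
            )
        return loss, grads


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model, path, extra_meta=None):
    """Portable checkpoint: config JSON + parameter arrays in one zip."""
    meta = {
        "variant": model.variant,
        "mode": getattr(model, "mode", None),
        "layout": model.layout.to_dict(),
        "config": model.config,
        "dtype": str(model.params[0].dtype),
    }
    if extra_meta:
        meta["extra"] = extra_meta
    buf = _io.BytesIO()
    np.savez(buf, *[p.astype(np.float64) for p in model.params])
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=1))
        zf.writestr("params.npz", buf.getvalue())


def load_checkpoint(path):
    """Rebuild a model from :func:`save_checkpoint` output."""
    from . import baselines  # late import to avoid a cycle

    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with np.load(_io.BytesIO(zf.read("params.npz"))) as npz:
            arrays = [npz[k] for k in npz.files]
    layout = FeatureLayout.from_dict(meta["layout"])
    cfg = meta["config"]
    dtype = np.dtype(meta["dtype"])
    variant = meta["variant"]
    if variant == "physgn":
        model = PhysicsGN(
            layout,
            mode=meta["mode"],
            hidden_layers=cfg["hidden_layers"],
            hidden_units=cfg["hidden_units"],
            activation=cfg["activation"],
            seed=cfg["seed"],
            dtype=dtype,
        )
    else:
        model = baselines.build_baseline(variant, layout, meta["mode"], cfg, dtype)
    model.set_params([a.astype(dtype) for a in arrays])
    return model
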