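"""Feed-forward network toolkit with exact input gradients.

Implements the multilayer perceptron used as the edge network (and the
baselines' node network), together with reverse-mode parameter gradients,
per-sample input gradients for scalar outputs, and the second-order
("double backprop") pass needed when the training loss depends on those
input gradients — the situation that arises when accelerations are the
negative position-derivative of a learned potential. Everything is plain
numpy; correctness is pinned by finite-difference oracle tests.

Shapes follow the row-vector convention: inputs are ``(batch, n_in)``,
weights ``W[l]`` are ``(n_in_l, n_out_l)`` and layers compute
``Z[l] = A[l] @ W[l] + b[l]`` with the activation applied to every layer
except the last.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Activation", "ACTIVATIONS", "MLP", "Adam"]


class Activation:
    """Elementwise activation with first and second derivatives.

    ``smooth`` marks activations whose first derivative is continuous;
    only smooth activations are admissible for a differentiated
    (potential-mode) edge network.

    ``aux(z)`` computes a shared intermediate (the sigmoid for SiLU, the
    tanh for tanh) that forward and backward passes reuse; the derivative
    methods accept it optionally so hot loops pay for it only once.
    """

    def __init__(self, name, aux, f, df, d2f, smooth):
        self.name = name
        self.aux = aux
        self._f = f
        self._df = df
        self._d2f = d2f
        self.smooth = smooth

    def f(self, z, aux=None):
        return self._f(z, self.aux(z) if aux is None else aux)

    def df(self, z, aux=None):
        return self._df(z, self.aux(z) if aux is None else aux)

    def d2f(self, z, aux=None):
        return self._d2f(z, self.aux(z) if aux is None else aux)

    def __repr__(self):  # pragma: no cover
        return f"Activation({self.name!r})"


def _sigmoid(z):
    # overflow in exp(-z) saturates to the correct limit 0
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-z))


ACTIVATIONS = {
    "silu": Activation(
        "silu",
        _sigmoid,
        lambda z, s: z * s,
        lambda z, s: s * (1.0 + z * (1.0 - s)),
        lambda z, s: s * (1.0 - s) * (2.0 + z * (1.0 - 2.0 * s)),
        smooth=True,
    ),
    "tanh": Activation(
        "tanh",
        np.tanh,
        lambda z, t: t,
        lambda z, t: 1.0 - t * t,
        lambda z, t: -2.0 * t * (1.0 - t * t),
        smooth=True,
    ),
    "relu": Activation(
        "relu",
        lambda z: z > 0.0,
        lambda z, p: np.where(p, z, 0.0),
        lambda z, p: p.astype(z.dtype),
        lambda z, p: np.zeros_like(z),
        smooth=False,
    ),
    "leaky_relu": Activation(
        "leaky_relu",
        lambda z: z > 0.0,
        lambda z, p: np.where(p, z, 0.01 * z),
        lambda z, p: np.where(p, 1.0, 0.01).astype(z.dtype),
        lambda z, p: np.zeros_like(z),
        smooth=False,
    ),
}


class MLP:
    """Plain multilayer perceptron with hand-written gradients.

    Parameters are initialised with the standard fan-in-scaled uniform
    scheme ``U(-1/sqrt(fan_in), 1/sqrt(fan_in))`` from a seeded generator.
    """

    def __init__(self, layer_sizes, activation="silu", rng=None, dtype=np.float64):
        if len(layer_sizes) < 2:
            raise ValueError("need at least an input and an output layer")
        if isinstance(activation, str):
            activation = ACTIVATIONS[activation]
        self.activation = activation
        self.layer_sizes = list(layer_sizes)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(rng)
        self.Ws = []
        self.bs = []
        for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
            bound = 1.0 / np.sqrt(n_in)
            self.Ws.append(
                rng.uniform(-bound, bound, size=(n_in, n_out)).astype(self.dtype)
            )
            self.bs.append(rng.uniform(-bound, bound, size=n_out).astype(self.dtype))

    # -- parameter plumbing -------------------------------------------------

    @property
    def n_layers(self):
        return len(self.Ws)

    @property
    def params(self):
        """Flat list of parameter arrays (updated in place by optimizers)."""
        out = []
        for W, b in zip(self.Ws, self.bs):
            out.append(W)
            out.append(b)
        return out

    def set_params(self, arrays):
        arrays = list(arrays)
        if len(arrays) != 2 * self.n_layers:
            raise ValueError("parameter count mismatch")
        for l in range(self.n_layers):
            self.Ws[l][...] = arrays[2 * l]
            self.bs[l][...] = arrays[2 * l + 1]

    def copy_params(self):
        return [p.copy() for p in self.params]

    def astype(self, dtype):
        """Return a copy of this network with parameters cast to ``dtype``."""
        clone = MLP.__new__(MLP)
        clone.activation = self.activation
        clone.layer_sizes = list(self.layer_sizes)
        clone.dtype = np.dtype(dtype)
        clone.Ws = [W.astype(dtype) for W in self.Ws]
        clone.bs = [b.astype(dtype) for b in self.bs]
        return clone

    # -- forward / reverse --------------------------------------------------

    def forward(self, X, need_cache=False):
        """Evaluate the network; optionally keep activations for backprop."""
        X = np.asarray(X, dtype=self.dtype)
        L = self.n_layers
        As = [X]
        Zs = []
        auxs = []
        act = self.activation
        for l in range(L):
            Z = As[-1] @ self.Ws[l] + self.bs[l]
            Zs.append(Z)
            if l < L - 1:
                aux = act.aux(Z)
                auxs.append(aux)
                As.append(act.f(Z, aux))
            else:
                auxs.append(None)
                As.append(Z)
        Y = As[-1]
        if need_cache:
            return Y, {"As": As, "Zs": Zs, "auxs": auxs}
        return Y

    def backward(self, cache, Gy, need_dX=False):
        """Parameter gradients for a loss with output adjoint ``Gy``."""
        As, Zs, auxs = cache["As"], cache["Zs"], cache["auxs"]
        act = self.activation
        L = self.n_layers
        grads = [None] * (2 * L)
        dZ = np.asarray(Gy, dtype=self.dtype)
        dA_prev = None
        for l in range(L - 1, -1, -1):
            grads[2 * l] = As[l].T @ dZ
            grads[2 * l + 1] = dZ.sum(axis=0)
            dA_prev = dZ @ self.Ws[l].T
            if l > 0:
                dZ = dA_prev * act.df(Zs[l - 1], auxs[l - 1])
        if need_dX:
            return grads, dA_prev
        return grads

    def input_grad(self, cache, need_gcache=False):
        """Per-sample gradient of a scalar output w.r.t. the input.

        Only valid for networks whose output dimension is 1. Returns the
        gradient array ``(batch, n_in)``; with ``need_gcache`` also the
        intermediate backward-chain values required by
        :meth:`backward_through_input_grad`.
        """
        if self.layer_sizes[-1] != 1:
            raise ValueError("input_grad requires a scalar-output network")
        As, Zs, auxs = cache["As"], cache["Zs"], cache["auxs"]
        act = self.activation
        L = self.n_layers
        B = As[0].shape[0]
        uz = [None] * L  # dY/dZ[l]
        va = [None] * L  # dY/dA[l]
        uz[L - 1] = np.ones((B, 1), dtype=self.dtype)
        for l in range(L - 1, 0, -1):
            va[l] = uz[l] @ self.Ws[l].T
            uz[l - 1] = va[l] * act.df(Zs[l - 1], auxs[l - 1])
        g = uz[0] @ self.Ws[0].T
        if need_gcache:
            return g, {"uz": uz, "va": va}
        return g

    def backward_through_input_grad(self, cache, gcache, Gg, Gy=None):
        """Double backprop: parameter gradients of a loss on the input gradient.

        ``Gg`` is the adjoint of the per-sample input gradient returned by
        :meth:`input_grad`; ``Gy`` optionally seeds an additional direct
        dependence of the loss on the scalar output. Requires a twice-
        differentiable activation.
        """
        As, Zs, auxs = cache["As"], cache["Zs"], cache["auxs"]
        uz, va = gcache["uz"], gcache["va"]
        act = self.activation
        L = self.n_layers
        grads = [np.zeros_like(p) for p in self.params]
        Ztil = [np.zeros_like(Z) for Z in Zs]

        # reverse sweep over the backward chain:
        #   va[l] = uz[l] @ W[l].T ;  uz[l-1] = va[l] * f'(Z[l-1]) ; g = va[0]
        # where va[0] is the input gradient (adjoint seeded with Gg).
        va_t = np.asarray(Gg, dtype=self.dtype)  # adjoint of va[l], starting l=0
        for l in range(L):
            grads[2 * l] += va_t.T @ uz[l]
            uz_t = va_t @ self.Ws[l]
            if l < L - 1:
                # uz[l] = va[l+1] * f'(Z[l])
                va_t = uz_t * act.df(Zs[l], auxs[l])
                Ztil[l] += uz_t * va[l + 1] * act.d2f(Zs[l], auxs[l])
            # l == L-1: uz[L-1] is constant; its adjoint is discarded.

        if Gy is not None:
            Ztil[L - 1] += np.asarray(Gy, dtype=self.dtype)

        # reverse sweep over the forward chain with accumulated Z adjoints
        for l in range(L - 1, -1, -1):
            grads[2 * l] += As[l].T @ Ztil[l]
            grads[2 * l + 1] += Ztil[l].sum(axis=0)
            if l > 0:
                dA = Ztil[l] @ self.Ws[l].T
                Ztil[l - 1] += dA * act.df(Zs[l - 1], auxs[l - 1])
        return grads


class Adam:
    """Adam optimizer operating in place on a list of parameter arrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
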