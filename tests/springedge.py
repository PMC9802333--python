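"""Closed-form spring potential posing as an edge network (test helper).

Computes M = 0.5 k (r_ij - L)^2 from the receiver/sender position slots of
the edge input, with exact analytic input gradients — an oracle for the
potential-mode node operator that bypasses any learned approximation.
"""

import numpy as np


class AnalyticSpringEdge:
    dtype = np.dtype(np.float64)

    def __init__(self, k=2.0, L=1.0, d=2):
        self.k, self.L, self.d = k, L, d
        self.node_dim = 2 * d + 2

    def _geometry(self, X):
        r_i = X[:, : self.d]
        r_j = X[:, self.node_dim : self.node_dim + self.d]
        diff = r_j - r_i
        dist = np.linalg.norm(diff, axis=1)
        return diff, dist

    def forward(self, X, need_cache=False):
        diff, dist = self._geometry(X)
        Y = (0.5 * self.k * (dist - self.L) ** 2)[:, None]
        return (Y, {"X": X}) if need_cache else Y

    def input_grad(self, cache, need_gcache=False):
        X = cache["X"]
        diff, dist = self._geometry(X)
        n_ij = diff / dist[:, None]
        g = np.zeros_like(X)
        g[:, : self.d] = -self.k * (dist - self.L)[:, None] * n_ij
        g[:, self.node_dim : self.node_dim + self.d] = -g[:, : self.d]
        return (g, None) if need_gcache else g
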