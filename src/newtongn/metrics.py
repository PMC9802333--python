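"""Physics-consistency metrics for learned pairwise interactions.

All metrics are built on the elementwise L1 distance and averaged either
per particle over test steps (``mae_part``, used for accelerations) or per
directed edge over test steps (``mae_inter``, used for pairwise forces and
potential-energy increments).  Action–reaction consistency is measured by
comparing each directed edge with its reverse: forces should negate,
potentials should match.  Potentials are compared as increments relative
to the trajectory's initial configuration because an additive constant in
the potential is unidentifiable from accelerations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "l1",
    "training_loss",
    "mae_part",
    "mae_inter",
    "mae_symm",
    "field_errors",
    "cosine_similarity",
    "MetricsReport",
]


def l1(x, y):
    """Sum of elementwise absolute differences (per spec's l1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.abs(x - y).sum())


def _mean_rowwise_l1(pred, true):
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if pred.ndim == 1:
        return float(np.abs(pred - true).mean())
    flat = pred.reshape(-1, pred.shape[-1])
    return float(np.abs(flat - true.reshape(flat.shape)).sum(axis=1).mean())


def training_loss(pred_acc, true_acc):
    """Mean over steps and particles of l1 between accelerations."""
    return _mean_rowwise_l1(pred_acc, true_acc)


def mae_part(pred, true):
    """Average per-particle l1 over test steps (MAE on node quantities)."""
    return _mean_rowwise_l1(pred, true)


def mae_inter(pred, true):
    """Average per-directed-edge l1 over test steps (MAE on pair quantities)."""
    return _mean_rowwise_l1(pred, true)


def mae_symm(pred, rev, kind):
    """Action–reaction error over directed edges.

    ``kind="force"``: mean l1 between F_ij and -F_ji.
    ``kind="potential"``: mean l1 between P_ij and P_ji.
    ``rev`` maps each directed edge to the position of its reverse.
    """
    pred = np.asarray(pred, dtype=float)
    if kind == "force":
        return _mean_rowwise_l1(pred, -pred[rev])
    if kind == "potential":
        return _mean_rowwise_l1(pred, pred[rev])
    raise ValueError("kind must be 'force' or 'potential'")


def field_errors(pred, true, tol=0.0):
    """Per-edge magnitude and angle errors between force fields.

    Returns ``(mean |  ||F_hat|| - ||F|| |, mean angle in radians,
    n_excluded)``; edges whose true or predicted force norm is ``<= tol``
    are excluded from the angle mean and counted.
    """
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    np_pred = np.linalg.norm(pred, axis=-1)
    np_true = np.linalg.norm(true, axis=-1)
    mag = float(np.abs(np_pred - np_true).mean())
    ok = (np_true > tol) & (np_pred > tol)
    n_excluded = int((~ok).sum())
    if not ok.any():
        return mag, float("nan"), n_excluded
    cosv = (pred[ok] * true[ok]).sum(axis=-1) / (np_pred[ok] * np_true[ok])
    angle = float(np.arccos(np.clip(cosv, -1.0, 1.0)).mean())
    return mag, angle, n_excluded


def cosine_similarity(pred, true, tol=0.0):
    """Mean cosine between predicted and true per-edge forces."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    np_pred = np.linalg.norm(pred, axis=-1)
    np_true = np.linalg.norm(true, axis=-1)
    ok = (np_true > tol) & (np_pred > tol)
    cosv = (pred[ok] * true[ok]).sum(axis=-1) / (np_pred[ok] * np_true[ok])
    return float(np.clip(cosv, -1.0, 1.0).mean())


@dataclass
class MetricsReport:
    """All consistency metrics on a named data split."""

    split: str
    mae_acc: float
    mae_ef: float | None = None
    mae_dep: float | None = None
    mae_symm_f: float | None = None
    mae_symm_p: float | None = None
    magnitude_error: float | None = None
    angle_error: float | None = None
    cosine: float | None = None
    n_nodes: int = 0
    n_edges: int = 0
    n_steps: int = 0
    notes: str = ""

    def __post_init__(self):
        for name in (
            "mae_acc",
            "mae_ef",
            "mae_dep",
            "mae_symm_f",
            "mae_symm_p",
            "magnitude_error",
        ):
            value = getattr(self, name)
            if value is not None and value < -1e-12:
                raise ValueError(f"{name} must be non-negative, got {value}")

    def to_json(self, indent=1):
        return json.dumps(asdict(self), indent=indent)

    @classmethod
    def from_json(cls, text):
        return cls(**json.loads(text))
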