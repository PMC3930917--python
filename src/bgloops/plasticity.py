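"""Dopamine-gated Hebbian plasticity between cortical layers.

Weights grow only when dopamine exceeds a threshold ``zeta``:

    dw_ji = eta * g_j * y_i * (w_max - w_ji) * [d - zeta]^+ * dt

where ``y_i`` is a presynaptic external-layer activation and ``g_j`` a
postsynaptic inner-layer activation.  The rule has no decay term, so weights
are non-decreasing and soft-bounded by ``w_max``.  With the threshold set
above every tonic dopamine excursion, learning happens only inside phasic
burst windows.

The same rule trains both the cortico-cortical forward/inverse models that
link the three loops of the agent and the prefrontal projection onto the
dopamine area's inhibitory interneuron (the agency predictor that cancels
bursts for self-caused outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

__all__ = ["PlasticMatrix", "hebbian_update", "wire_agent_plasticity"]


@dataclass
class PlasticMatrix:
    """A plastic connection ``pre (external layer) -> post (inner layer)``.

    ``w`` has shape (n_pre, n_post); the induced drive on the target layer is
    ``y_pre @ w``.
    """

    pre: str
    post: str
    w: np.ndarray
    eta: float
    w_max: float
    zeta: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.eta < 0 or self.w_max <= 0:
            raise ValueError("eta must be >= 0 and w_max > 0")
        if np.any(self.w < 0) or np.any(self.w > self.w_max):
            raise ValueError("initial weights must lie in [0, w_max]")

    @property
    def shape(self) -> tuple:
        return self.w.shape

    def drive(self, pre_y: np.ndarray) -> np.ndarray:
        """Post-layer input vector induced by presynaptic activations."""
        return np.asarray(pre_y, dtype=float) @ self.w


def hebbian_update(
    m: PlasticMatrix,
    pre_y: np.ndarray,
    post_g: np.ndarray,
    d: float,
    dt: float = 1.0,
) -> PlasticMatrix:
    """Apply one step of the dopamine-gated Hebbian rule in place.

    ``dt`` scales the increment so learning speed does not depend on the
    integration step.  With ``d <= m.zeta`` the update is exactly zero.
    """
    gate = max(d - m.zeta, 0.0)
    if gate > 0.0:
        outer = np.multiply.outer(np.asarray(pre_y, float), np.asarray(post_g, float))
        m.w += m.eta * outer * (m.w_max - m.w) * gate * dt
        # soft ceiling is exact in continuous time; clip Euler overshoot
        np.clip(m.w, 0.0, m.w_max, out=m.w)
    return m


def wire_agent_plasticity(
    agent,
    eta_ctx: float = 2.0,
    w_max_ctx: float = 1.0,
    zeta_ctx: float = 0.2,
    eta_pred: float = 0.00008,
    w_max_pred: float = 18000.0,
    zeta_pred: float | None = None,
    d_baseline: float = 1.0,
    predictor_coeff_role: str = "rate",
) -> Dict[str, PlasticMatrix]:
    """Create the five plastic connections of the three-loop agent.

    Forward models: PMC_ext -> PFC_inner and FEF_ext -> PFC_inner let motor
    and attentional selections anticipate their outcome channel.  Inverse
    models: PFC_ext -> PMC_inner and PFC_ext -> FEF_inner let an active goal
    recall the action/gaze pair that produced it.  The predictor
    PFC_inner -> DA-interneuron cancels bursts for predicted outcomes.

    ``zeta`` values are absolute dopamine thresholds.  The cortico-cortical
    threshold is ``d_baseline + zeta_ctx`` so that only burst-level dopamine
    gates learning.  The predictor coefficient can play two roles
    (``predictor_coeff_role``): as a learning-rate-like coefficient
    (``"rate"``, default, with the same burst-level threshold) or as the
    predictor's own threshold margin (``"threshold"``, with the
    cortico-cortical learning rate).
    """
    n_pmc = agent.loops["manipulation"].n_channels
    n_fef = agent.loops["attention"].n_channels
    n_pfc = agent.loops["goal"].n_channels
    z_ctx_abs = d_baseline + zeta_ctx
    if predictor_coeff_role == "rate":
        z_pred_abs = z_ctx_abs if zeta_pred is None else d_baseline + zeta_pred
        eta_p = eta_pred
    elif predictor_coeff_role == "threshold":
        z_pred_abs = d_baseline + eta_pred
        eta_p = eta_ctx
    else:
        raise ValueError("predictor_coeff_role must be 'rate' or 'threshold'")

    def zeros(a, b):
        return np.zeros((a, b))

    return {
        "pmc_to_pfc": PlasticMatrix("pmc_ext", "pfc_inner", zeros(n_pmc, n_pfc),
                                    eta_ctx, w_max_ctx, z_ctx_abs),
        "fef_to_pfc": PlasticMatrix("fef_ext", "pfc_inner", zeros(n_fef, n_pfc),
                                    eta_ctx, w_max_ctx, z_ctx_abs),
        "pfc_to_pmc": PlasticMatrix("pfc_ext", "pmc_inner", zeros(n_pfc, n_pmc),
                                    eta_ctx, w_max_ctx, z_ctx_abs),
        "pfc_to_fef": PlasticMatrix("pfc_ext", "fef_inner", zeros(n_pfc, n_fef),
                                    eta_ctx, w_max_ctx, z_ctx_abs),
        "predictor": PlasticMatrix("pfc_inner", "da_interneuron", zeros(n_pfc, 1),
                                   eta_p, w_max_pred, z_pred_abs),
    }
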