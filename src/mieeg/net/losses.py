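"""Binary cross-entropy and focal loss.

Focal loss down-weights well-classified examples so that training focuses on
hard ones:

    FL(p_t) = -alpha_t * (1 - p_t)^gamma * log(p_t)

where p_t is the probability assigned to the true class (p if y=1, 1-p
otherwise) and alpha_t = alpha if y=1 else 1-alpha.  With gamma=0 and
alpha=0.5 it reduces to 0.5 * cross-entropy.  Natural logarithm throughout;
probabilities are clipped to [EPS, 1-EPS] before taking logs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigError

EPS = 1e-7


@dataclass
class FocalLossParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.gamma < 0:
            raise ConfigError(f"gamma must be >= 0, got {self.gamma}")


def _check_p(p):
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ConfigError("probability outside [0, 1]")
    return np.clip(p, EPS, 1 - EPS)


def cross_entropy(p, y):
    """-log p if y = 1 else -log(1 - p); elementwise on arrays."""
    p = _check_p(p)
    y = np.asarray(y)
    out = np.where(y == 1, -np.log(p), -np.log(1 - p))
    return float(out) if out.ndim == 0 else out


def pt(p, y):
    """Probability of the true class: p if y = 1 else 1 - p."""
    p = _check_p(p)
    y = np.asarray(y)
    out = np.where(y == 1, p, 1 - p)
    return float(out) if out.ndim == 0 else out


def focal_loss(p, y, params: FocalLossParams | None = None):
    """-alpha_t (1 - p_t)^gamma log p_t, elementwise."""
    params = params or FocalLossParams()
    params.validate()
    p_t = pt(p, y)
    y = np.asarray(y)
    a_t = np.where(y == 1, params.alpha, 1 - params.alpha)
    out = -a_t * (1 - p_t) ** params.gamma * np.log(p_t)
    return float(out) if np.ndim(out) == 0 else out


def focal_loss_from_logits(z, y, params: FocalLossParams):
    """Mean focal loss and its gradient w.r.t. the logits.

    z : (N,) raw scores; p = sigmoid(z).  Returns (loss, dloss/dz) with the
    gradient of the *mean* over the batch.
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y)
    p = 1.0 / (1.0 + np.exp(-z))
    p_t = np.clip(np.where(y == 1, p, 1 - p), EPS, 1 - EPS)
    a_t = np.where(y == 1, params.alpha, 1 - params.alpha)
    g = params.gamma
    one_m = 1 - p_t
    loss = float(np.mean(-a_t * one_m ** g * np.log(p_t)))

    # dFL/dp_t, with the gamma=0 special case avoiding 0^(g-1)
    if g == 0:
        dl_dpt = -a_t / p_t
    else:
        dl_dpt = -a_t * (-g * one_m ** (g - 1) * np.log(p_t) + one_m ** g / p_t)
    sign = np.where(y == 1, 1.0, -1.0)     # dp_t/dz = sign * p_t (1 - p_t)
    dz = dl_dpt * sign * p_t * one_m / z.size
    return loss, dz


__all__ = ["FocalLossParams", "cross_entropy", "pt", "focal_loss",
           "focal_loss_from_logits", "EPS"]
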