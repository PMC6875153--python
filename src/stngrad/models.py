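"""The four spatial negative-binomial GLMs for nucleus-wide immunoreactivity.

Each model describes the expected stained-pixel count of a sector as a
log-linear function of its normalized location ``x = (x1, x2, x3)`` in the
nucleus, with negative-binomial (gamma–Poisson) noise of dispersion ``alpha``
(variance ``mu + mu**2 / alpha``; Poisson limit as ``alpha -> inf``):

* **Model A** — homogeneous field: ``mu = exp(l0)``.
* **Model B** — linear gradient: ``mu = exp(l0 + l1*x1 + l2*x2 + l3*x3)``.
* **Model C** — three discrete subdivisions: locations are projected onto a
  fitted axis ``p = b1*x1 + b2'*x2 + b3'*x3``; sectors left of the boundary
  ``tau1`` (on the min-max normalized projection) get offset ``l1``, sectors
  right of ``tau2`` get ``l2``.
* **Model D** — smooth sigmoidal gradient: the two step offsets of Model C
  are replaced by logistic ramps of smoothness ``kappa``; both sigmoids
  decrease with the projection, so at ``kappa -> inf`` Model D reproduces a
  reparameterized Model C.

The projection weights form a simplex: ``b2' = b2*(1 - b1)`` and
``b3' = 1 - b1 - b2'``, so two free parameters in [0, 1] cover all convex
axis combinations.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from scipy.special import gammaln

MODEL_IDS = ("A", "B", "C", "D")

#: number of free parameters per model (intercept/effects + alpha [+ kappa])
N_PARAMS = {"A": 2, "B": 5, "C": 8, "D": 9}

#: linear predictor clamp before exponentiation (intercept bound is 200)
_ETA_CLAMP = 700.0

#: additive NLL penalty when the middle subdivision spans < 20% of the axis
_TAU_SPAN_MIN = 0.2
_TAU_PENALTY = 1e8


@dataclasses.dataclass
class ModelParams:
    """Parameter vector for one of Models A–D.

    Fields irrelevant to the model (e.g. ``kappa`` for Model B) stay None.
    ``alpha`` is the NB dispersion shared by all models.
    """

    model_id: str
    lambda0: float
    alpha: float
    lambda1: float | None = None
    lambda2: float | None = None
    lambda3: float | None = None
    beta1: float | None = None
    beta2: float | None = None
    tau1: float | None = None
    tau2: float | None = None
    kappa: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ValueError(f"unknown model id {self.model_id!r}")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        need = _FIELDS[self.model_id]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"model {self.model_id} requires {f}")
        # tau1 < tau2 is not enforced here: the optimizer explores unordered
        # boundary proposals, which the likelihood's span penalty rejects.

    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in _FIELDS[self.model_id]], float)

    @classmethod
    def from_vector(cls, model_id: str, vec: Sequence[float]) -> "ModelParams":
        fields = _FIELDS[model_id]
        if len(vec) != len(fields):
            raise ValueError(f"model {model_id} expects {len(fields)} parameters")
        return cls(model_id=model_id, **dict(zip(fields, map(float, vec))))


_FIELDS = {
    "A": ("lambda0", "alpha"),
    "B": ("lambda0", "lambda1", "lambda2", "lambda3", "alpha"),
    "C": ("lambda0", "lambda1", "lambda2", "beta1", "beta2",
          "tau1", "tau2", "alpha"),
    "D": ("lambda0", "lambda1", "lambda2", "beta1", "beta2",
          "tau1", "tau2", "kappa", "alpha"),
}


@dataclasses.dataclass
class ProjectionAxis:
    """Per-sector projection values and their min-max normalization."""

    p: np.ndarray
    p_norm: np.ndarray


def simplex_weights(beta1: float, beta2: float) -> tuple[float, float, float]:
    """Map two free weights in [0,1] to convex axis weights summing to 1."""
    b2p = beta2 * (1.0 - beta1)
    b3p = 1.0 - beta1 - b2p
    return beta1, b2p, b3p


def projection(coords: np.ndarray, beta1: float, beta2: float) -> ProjectionAxis:
    """Project sector coordinates onto the fitted subdivision axis.

    Raises a degenerate-axis error when all projections coincide (the
    boundaries tau1/tau2 would be meaningless).
    """
    coords = np.asarray(coords, float)
    b1, b2p, b3p = simplex_weights(beta1, beta2)
    p = b1 * coords[:, 0] + b2p * coords[:, 1] + b3p * coords[:, 2]
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise ValueError("degenerate projection axis: max(p) == min(p)")
    return ProjectionAxis(p=p, p_norm=(p - lo) / (hi - lo))


def predict_mean(params: ModelParams, coords: np.ndarray) -> np.ndarray:
    """Per-sector expected intensity ``mu > 0`` under the model.

    ``coords`` is (n, 3) normalized locations. The linear predictor is
    clamped to avoid silent overflow of the exponential.
    """
    coords = np.asarray(coords, float)
    m = params.model_id
    if m == "A":
        eta = np.full(len(coords), params.lambda0)
    elif m == "B":
        eta = (params.lambda0
               + params.lambda1 * coords[:, 0]
               + params.lambda2 * coords[:, 1]
               + params.lambda3 * coords[:, 2])
    else:
        axis = projection(coords, params.beta1, params.beta2)
        pn = axis.p_norm
        if m == "C":
            d1 = (pn < params.tau1).astype(float)
            d2 = (pn > params.tau2).astype(float)
            eta = params.lambda0 + params.lambda1 * d1 + params.lambda2 * d2
        else:  # D: both logistic ramps decrease with the projection
            k = params.kappa
            s1 = _expit(np.clip(k * (params.tau1 - pn), -_ETA_CLAMP, _ETA_CLAMP))
            s2 = _expit(np.clip(k * (params.tau2 - pn), -_ETA_CLAMP, _ETA_CLAMP))
            eta = params.lambda0 + params.lambda1 * s1 + params.lambda2 * s2
    return np.exp(np.clip(eta, -_ETA_CLAMP, _ETA_CLAMP))


def _expit(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# negative-binomial likelihood

def nb_logpmf(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Log-density of the gamma–Poisson (NB) count model, shape ``alpha``.

    Uses the continuous gamma-function form so non-integer intensities are
    admitted; for very large ``alpha`` the log-gamma difference is replaced
    by its asymptotic expansion, which keeps the Poisson limit accurate to
    well below 1e-6 instead of being destroyed by cancellation.
    """
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if np.isnan(y).any() or np.isnan(mu).any():
        raise ValueError("NaN in intensities or means")
    if (mu <= 0).any():
        raise ValueError("non-positive mean")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    log_ratio = np.log1p(mu / alpha)  # log((alpha+mu)/alpha)
    if alpha > 1e8:
        # lgamma(y+a) - lgamma(a) ~ y*log(a) + y*(y-1)/(2a)
        lg = y * math.log(alpha) + y * (y - 1.0) / (2.0 * alpha)
    else:
        lg = gammaln(y + alpha) - gammaln(alpha)
    return (lg - gammaln(y + 1.0)
            - alpha * log_ratio
            + y * (np.log(mu) - math.log(alpha) - log_ratio))


def nb_neg_loglik(params: ModelParams, y: np.ndarray, coords: np.ndarray) -> float:
    """Negative log-likelihood over included sectors, with the boundary-span
    penalty for Models C/D (the middle subdivision must cover at least 20%
    of the normalized projection axis)."""
    mu = predict_mean(params, coords)
    nll = -float(nb_logpmf(np.asarray(y, float), mu, params.alpha).sum())
    if params.model_id in "CD" and (params.tau2 - params.tau1) < _TAU_SPAN_MIN:
        nll += _TAU_PENALTY * (_TAU_SPAN_MIN - (params.tau2 - params.tau1))
    return nll


def param_space(model_id: str) -> tuple[list[tuple[float, float]], int]:
    """Box bounds (in the order of :data:`ModelParams.to_vector`) and the
    free-parameter count for a model.

    The intercept and the subdivision offsets range over [-15, 200]; linear
    gradient weights over [-2, 2]; projection weights over [0, 1]; the
    boundaries over [0.2, 0.6] and [0.4, 0.8] (with the additional >=20%
    middle-span constraint enforced as a likelihood penalty); smoothness
    ``kappa`` and dispersion ``alpha`` over [1, 1e20].
    """
    wide = (-15.0, 200.0)
    disp = (1.0, 1e20)
    bounds = {
        "A": [wide, disp],
        "B": [wide, (-2.0, 2.0), (-2.0, 2.0), (-2.0, 2.0), disp],
        "C": [wide, wide, wide, (0.0, 1.0), (0.0, 1.0),
              (0.2, 0.6), (0.4, 0.8), disp],
        "D": [wide, wide, wide, (0.0, 1.0), (0.0, 1.0),
              (0.2, 0.6), (0.4, 0.8), (1.0, 1e20), disp],
    }[model_id]
    return bounds, N_PARAMS[model_id]
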