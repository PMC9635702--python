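"""Length-based age baseline and image/length fusion.

A linear regression of age on fish length with a sex interaction,

    E(Y_i) = b0 + b1 * x_i + b2 * x_i * z_i,   z_i = 1 for males,

where the intercept b0 is shared between sexes (male and female fish have
the same expected length at birth, so the age-at-zero-length extrapolation
coincides).  Its predictions form a second, image-free age estimate that can
be fused with the CNN estimate as a convex combination

    yhat = alpha * yhat_image + (1 - alpha) * yhat_length,

with alpha fitted by least squares under the sum-to-one constraint
(regressing y - yhat_length on yhat_image - yhat_length, no intercept).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class LengthModel:
    """b0: shared intercept (yr); b1: female slope (yr/cm);
    b2: male slope delta (yr/cm) so the male slope is b1 + b2."""

    beta0: float
    beta1: float
    beta2: float

    @property
    def male_slope(self) -> float:
        return self.beta1 + self.beta2

    @property
    def female_slope(self) -> float:
        return self.beta1


def fit_length_model(ages, lengths, sex) -> LengthModel:
    """Least-squares fit of age on (length, length x male) with common intercept.

    Only rows with known sex and finite positive length may be passed.
    """
    ages = np.asarray(ages, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    sex = np.asarray(sex, dtype=object)
    if not (ages.shape == lengths.shape == sex.shape):
        raise ValueError("ages, lengths and sex must be aligned")
    if ages.size < 3:
        raise ValueError("fit requires at least 3 rows")
    bad = set(sex) - {"male", "female"}
    if bad:
        raise ValueError(f"fit requires known sexes only, got {sorted(bad)}")
    if not np.isfinite(lengths).all() or (lengths <= 0).any():
        raise ValueError("lengths must be finite and positive")
    z = (sex == "male").astype(float)
    design = np.column_stack([np.ones_like(lengths), lengths, lengths * z])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("singular design: need both sexes and varying lengths")
    coef, *_ = np.linalg.lstsq(design, ages, rcond=None)
    return LengthModel(beta0=float(coef[0]), beta1=float(coef[1]),
                       beta2=float(coef[2]))


def predict_from_length(model: LengthModel, length, sex):
    """Length-based age estimate (yr), floored at 0; sex must be known."""
    length = np.asarray(length, dtype=float)
    scalar = length.ndim == 0
    length = np.atleast_1d(length)
    sex_arr = np.atleast_1d(np.asarray(sex, dtype=object))
    if sex_arr.size == 1 and length.size > 1:
        sex_arr = np.repeat(sex_arr, length.size)
    bad = set(sex_arr) - {"male", "female"}
    if bad:
        raise ValueError(f"predict_from_length requires known sex, got {sorted(bad)}")
    z = (sex_arr == "male").astype(float)
    pred = np.maximum(model.beta0 + model.beta1 * length + model.beta2 * length * z,
                      0.0)
    return float(pred[0]) if scalar else pred


@dataclasses.dataclass(frozen=True)
class CombinedEstimator:
    """Convex-combination weight on the image-based estimate."""

    alpha: float
    clipped: bool = False


def fit_alpha(y, yhat_image, yhat_length) -> CombinedEstimator:
    """Least-squares alpha for the constrained blend; clipped to [0, 1].

    With d_i = yhat_image_i - yhat_length_i and e_i = y_i - yhat_length_i,
    alpha = sum(d e) / sum(d^2) — ordinary regression through the origin.
    """
    y = np.asarray(y, dtype=float)
    y1 = np.asarray(yhat_image, dtype=float)
    y2 = np.asarray(yhat_length, dtype=float)
    if not (y.shape == y1.shape == y2.shape) or y.size < 2:
        raise ValueError("need aligned vectors of length >= 2")
    d = y1 - y2
    denom = float(np.dot(d, d))
    if denom == 0.0:
        raise ValueError("alpha undefined: image and length estimates coincide")
    alpha = float(np.dot(d, y - y2) / denom)
    clipped = not 0.0 <= alpha <= 1.0
    if clipped:
        logger.info("fit_alpha: raw alpha %.4f clipped into [0, 1]", alpha)
        alpha = float(np.clip(alpha, 0.0, 1.0))
    return CombinedEstimator(alpha=alpha, clipped=clipped)


def combine(est: CombinedEstimator, yhat_image, yhat_length):
    """alpha * yhat_image + (1 - alpha) * yhat_length, elementwise."""
    y1 = np.asarray(yhat_image, dtype=float)
    y2 = np.asarray(yhat_length, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("estimates must be aligned")
    return est.alpha * y1 + (1.0 - est.alpha) * y2
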