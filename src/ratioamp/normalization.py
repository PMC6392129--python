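"""Integrity-based Ct normalization.

Along a degradation gradient the Ct of a transcript rises as its index
falls, and the two are assumed linearly related through the undegraded
reference point t0::

    dCt = alpha * dRamp          (dX = X_at_point - X_at_t0)

alpha is fitted by least squares through the origin — the model has no
intercept, so the corrected Ct is exactly the observed Ct at the
reference — and used to remove the degradation component::

    corrected Ct = Ct - alpha * (Ramp - Ramp_t0)

alpha is transcript- and mechanism-specific; fits are never pooled across
mechanisms unless explicitly requested by the caller, and a positive
fitted alpha (Ct falling as integrity falls) is flagged as anomalous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats as sps

from .errors import DataError, DomainError, NonIdentifiableError

__all__ = [
    "NormalizationFit",
    "CorrectionSummary",
    "fit_alpha",
    "correct_ct",
    "evaluate_correction",
]


@dataclass(frozen=True)
class NormalizationFit:
    """The fitted slope linking dCt to dRamp, with fit diagnostics.

    ``alpha`` is in cycles per unit of index and is expected to be
    negative (Ct rises as integrity falls).  ``r_squared`` and
    ``residual_sd`` are computed about the origin in delta space; ``n``
    counts the non-reference points used.  ``alpha_se`` is NaN when only
    one non-reference point is available (zero residual degrees of
    freedom).
    """

    alpha: float
    ramp_ref: float
    ct_ref: float
    ref_point: str
    r_squared: float
    residual_sd: float
    n: int
    alpha_se: float
    transcript: str = ""
    mechanism_label: str = ""

    @property
    def anomalous_sign(self) -> bool:
        """True when alpha is positive — Ct should not fall as RNA degrades."""
        return self.alpha > 0

    def alpha_ci(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for alpha (dof = n - 1)."""
        dof = self.n - 1
        if dof < 1 or not math.isfinite(self.alpha_se):
            return (-math.inf, math.inf)
        half = float(sps.t.ppf(0.5 + level / 2.0, dof)) * self.alpha_se
        return (self.alpha - half, self.alpha + half)


def fit_alpha(
    series: Mapping[str, tuple[float, float]],
    ref_point: str,
    transcript: str = "",
    mechanism_label: str = "",
) -> NormalizationFit:
    """Fit alpha from ``{point_id: (ramp, ct)}`` against the reference point.

    Deltas are taken against *ref_point* and the slope is the
    through-origin least-squares estimate
    ``alpha = sum(dRamp * dCt) / sum(dRamp**2)``.  All-zero index deltas
    leave the slope non-identifiable.
    """
    if ref_point not in series:
        raise DataError(f"reference point {ref_point!r} not in series")
    ramp_ref, ct_ref = (float(v) for v in series[ref_point])
    others = [(k, float(r), float(c)) for k, (r, c) in series.items() if k != ref_point]
    if not others:
        raise DomainError("need at least one non-reference point")
    d_ramp = np.array([r - ramp_ref for _, r, _ in others])
    d_ct = np.array([c - ct_ref for _, _, c in others])
    if not (np.all(np.isfinite(d_ramp)) and np.all(np.isfinite(d_ct))):
        raise DomainError("series values must be finite")
    ss_x = float(np.sum(d_ramp**2))
    if ss_x == 0.0:
        raise NonIdentifiableError("all index deltas are zero; alpha has no unique value")
    alpha = float(np.sum(d_ramp * d_ct)) / ss_x
    residuals = d_ct - alpha * d_ramp
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum(d_ct**2))
    r_squared = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    n = len(others)
    dof = n - 1
    if dof > 0:
        residual_sd = math.sqrt(ss_res / dof)
        alpha_se = residual_sd / math.sqrt(ss_x)
    else:
        residual_sd = 0.0
        alpha_se = math.nan
    return NormalizationFit(
        alpha=alpha,
        ramp_ref=ramp_ref,
        ct_ref=ct_ref,
        ref_point=ref_point,
        r_squared=r_squared,
        residual_sd=residual_sd,
        n=n,
        alpha_se=alpha_se,
        transcript=transcript,
        mechanism_label=mechanism_label,
    )


def correct_ct(ct: float, ramp: float, fit: NormalizationFit) -> float:
    """Remove the degradation component: ``ct - alpha * (ramp - ramp_ref)``."""
    return ct - fit.alpha * (ramp - fit.ramp_ref)


@dataclass(frozen=True)
class CorrectionSummary:
    """Degradation-attributable Ct error before and after correction.

    RMSE of ``Ct - Ct_ref`` over the non-reference points, raw and
    corrected; ``reduction`` is ``1 - after/before`` (0 when there was no
    error to remove).  Improvement is only guaranteed when the generating
    Ct-index relation is in fact linear.
    """

    rmse_before: float
    rmse_after: float
    reduction: float
    n: int


def evaluate_correction(
    series: Mapping[str, tuple[float, float]],
    fit: NormalizationFit,
) -> CorrectionSummary:
    """Score a fit on a series (the same one, or a held-out one)."""
    deviations_before = []
    deviations_after = []
    for point, (ramp, ct) in series.items():
        if point == fit.ref_point:
            continue
        deviations_before.append(float(ct) - fit.ct_ref)
        deviations_after.append(correct_ct(float(ct), float(ramp), fit) - fit.ct_ref)
    if not deviations_before:
        raise DomainError("series has no non-reference points")
    rmse_before = float(np.sqrt(np.mean(np.square(deviations_before))))
    rmse_after = float(np.sqrt(np.mean(np.square(deviations_after))))
    reduction = 0.0 if rmse_before == 0.0 else 1.0 - rmse_after / rmse_before
    return CorrectionSummary(
        rmse_before=rmse_before,
        rmse_after=rmse_after,
        reduction=reduction,
        n=len(deviations_before),
    )
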