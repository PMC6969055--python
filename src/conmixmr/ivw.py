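"""Inverse-variance weighted (IVW) estimator, fixed- and random-effects.

The IVW estimate is the precision-weighted mean of the variant-specific ratio
estimates, equivalently the slope of the zero-intercept weighted regression of
the outcome associations on the exposure associations with weights
se(beta_Y)^-2.  The random-effects variant multiplies the fixed-effect
standard error by the residual standard error phi of that regression, floored
at one because underdispersion is implausible.  IVW is consistent only when
every variant is a valid instrument; it is the efficiency benchmark the
contamination mixture method is compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import SummarySet
from .exceptions import MRInputError

__all__ = ["IVW", "IVWResults", "ivw_estimate"]

logger = logging.getLogger(__name__)


class IVW:
    """Inverse-variance weighted Mendelian randomization model.

    Parameters
    ----------
    data : SummarySet or DataFrame
    model : {"fixed", "random"}
        Random-effects inflates the standard error by max(1, phi_hat); it
        requires at least 3 variants and otherwise falls back to fixed-effect
        with a warning.
    alpha : float
        Complement of the confidence level for the normal-based interval.
    """

    def __init__(
        self,
        data: SummarySet | pd.DataFrame,
        model: str = "random",
        alpha: float = 0.05,
    ) -> None:
        if isinstance(data, pd.DataFrame):
            data = SummarySet.from_dataframe(data)
        if model not in ("fixed", "random"):
            raise MRInputError("model must be 'fixed' or 'random'")
        if not 0.0 < alpha < 1.0:
            raise MRInputError("alpha must lie in (0, 1)")
        self.data = data
        self.model_type = model
        self.alpha = alpha

    def fit(self) -> "IVWResults":
        data = self.data
        j = data.n_variants
        model = self.model_type
        if model == "random" and j < 3:
            logger.warning(
                "random-effects IVW needs at least 3 variants (got %d); "
                "falling back to fixed-effect",
                j,
            )
            model = "fixed"

        w = 1.0 / data.se_y**2
        # Zero-intercept weighted regression of beta_y on beta_x; the slope is
        # identical to the precision-weighted mean of the ratio estimates with
        # first-order weights.
        wls = sm.WLS(data.beta_y, data.beta_x, weights=w).fit()
        estimate = float(wls.params[0])
        se_fixed = float(np.sqrt(1.0 / np.sum(w * data.beta_x**2)))
        if j >= 2:
            phi_raw = float(np.sqrt(wls.scale))  # weighted RSS / (J - 1)
        else:
            phi_raw = 1.0
        phi = max(1.0, phi_raw)
        se = se_fixed * phi if model == "random" else se_fixed
        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        return IVWResults(
            model=self,
            estimate=estimate,
            se=se,
            ci=(estimate - z * se, estimate + z * se),
            phi_hat=phi if model == "random" else 1.0,
            model_type=model,
            alpha=self.alpha,
            n_variants=j,
        )


@dataclass
class IVWResults:
    """Fit results of :class:`IVW`."""

    model: IVW = field(repr=False)
    estimate: float
    se: float
    ci: tuple[float, float]
    phi_hat: float
    model_type: str
    alpha: float
    n_variants: int

    def covers(self, value: float) -> bool:
        return self.ci[0] <= value <= self.ci[1]

    def rejects_null(self, value: float = 0.0) -> bool:
        return not self.covers(value)

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci),
            "alpha": self.alpha,
            "phi": self.phi_hat,
            "model": self.model_type,
            "n_variants": self.n_variants,
        }

    def summary(self) -> str:
        lo, hi = self.ci
        return "\n".join(
            [
                f"Inverse-variance weighted MR ({self.model_type}-effect)",
                "=" * 46,
                f"Variants:         {self.n_variants}",
                f"Causal estimate:  {self.estimate:.4g} (se {self.se:.4g})",
                f"{100 * (1 - self.alpha):.0f}% CI:           [{lo:.4g}, {hi:.4g}]",
                f"phi:              {self.phi_hat:.4g}",
            ]
        )


def ivw_estimate(
    data: SummarySet | pd.DataFrame, model: str = "random", alpha: float = 0.05
) -> IVWResults:
    """Fit the IVW estimator in one call."""
    return IVW(data, model=model, alpha=alpha).fit()
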