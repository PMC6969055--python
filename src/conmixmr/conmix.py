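"""Contamination mixture estimator for Mendelian randomization.

Each variant-specific causal estimate theta_hat_j is modelled as a draw from a
two-component mixture: if variant j is a valid instrument,

    theta_hat_j ~ N(theta, se_j^2),

and if it is invalid its estimand is itself normal about zero with a wide,
user-chosen standard deviation psi, so marginally

    theta_hat_j ~ N(0, psi^2 + se_j^2).

At each value of theta on a grid, the validity configuration maximising the
likelihood is obtained variant-by-variant (take the larger of the two
component likelihoods), giving a profile log-likelihood that is linear in the
number of variants.  The point estimate is the grid argmax, and the 95%
confidence set is the region where twice the log-likelihood drop from the
maximum stays below chi2(1) at the 95th percentile, inflated by an
overdispersion factor max(1, phi_hat^2) estimated from the valid variants.
The confidence set need not be a single interval: disjoint components signal
distinct groups of variants supporting different causal effects, i.e.
potentially distinct causal mechanisms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal, stats

from .data import RatioEstimates, SummarySet, ratio_estimates
from .exceptions import EstimationError, MRInputError

__all__ = [
    "ConMixConfig",
    "ContaminationMixture",
    "ConMixResults",
    "conmix_estimate",
    "component_logliks",
    "profile_loglik",
    "default_psi",
    "overdispersion_phi",
]

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def component_logliks(
    theta: float, ratios: RatioEstimates, psi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant log-likelihood contributions as a valid and as an invalid IV.

    The valid contribution is the log normal density of theta_hat_j at mean
    ``theta`` and sd se_j; the invalid contribution is the log normal density
    at mean 0 and sd sqrt(psi^2 + se_j^2).
    """
    if not np.isfinite(theta):
        raise MRInputError("theta must be finite")
    if not (np.isfinite(psi) and psi > 0):
        raise MRInputError("psi must be a positive finite number")
    se = ratios.se_theta
    lv = -0.5 * ((theta - ratios.theta_hat) / se) ** 2 - np.log(se) - _LOG_SQRT_2PI
    sf = np.sqrt(psi**2 + se**2)
    lf = -0.5 * (ratios.theta_hat / sf) ** 2 - np.log(sf) - _LOG_SQRT_2PI
    return lv, lf


def profile_loglik(
    theta: float, ratios: RatioEstimates, psi: float
) -> tuple[float, np.ndarray]:
    """Profile log-likelihood at ``theta`` and the maximising validity vector.

    Because the likelihood factorises over variants, the configuration
    maximising it at fixed theta takes each variant's larger component; this
    equals the maximum over all 2^J validity configurations.  Ties are
    classified as valid (deterministic, and ties are measure-zero).
    """
    lv, lf = component_logliks(theta, ratios, psi)
    zeta = (lv >= lf).astype(int)
    return float(np.maximum(lv, lf).sum()), zeta


def default_psi(ratios: RatioEstimates) -> float:
    """Heuristic invalid-estimand spread: 1.5 x sample SD of the ratio estimates.

    The spread of the observed variant-specific estimates bounds how dispersed
    the invalid estimands can plausibly be; the 1.5 inflation accounts for the
    valid instruments clustering more tightly than the full set.  A
    sensitivity analysis over psi is strongly advised: both the estimate and
    the number of detected modes can change with it.
    """
    if ratios.n_variants < 2:
        raise MRInputError("default psi needs at least 2 variants; supply psi")
    sd = float(np.std(ratios.theta_hat, ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise MRInputError(
            "ratio estimates have zero spread; the psi heuristic is degenerate, "
            "supply psi explicitly"
        )
    return 1.5 * sd


def overdispersion_phi(
    data: SummarySet, valid_flags: np.ndarray, floor: bool = True
) -> float:
    """Residual standard error of the valid-instrument IVW regression.

    Weighted zero-intercept regression of beta_y on beta_x with weights
    se_y^-2, restricted to the variants flagged valid.  Values below one
    (underdispersion) are floored to one when ``floor`` is set, as is done
    downstream.  With fewer than 3 valid variants the regression has too few
    residual degrees of freedom and phi is set to 1 with a warning.
    """
    idx = np.asarray(valid_flags, dtype=bool)
    m = int(idx.sum())
    if m < 1:
        raise MRInputError("overdispersion requires at least one valid variant")
    if m < 3:
        logger.warning(
            "only %d valid variant(s): overdispersion regression has "
            "insufficient degrees of freedom, phi set to 1",
            m,
        )
        return 1.0
    w = 1.0 / data.se_y[idx] ** 2
    res = sm.WLS(data.beta_y[idx], data.beta_x[idx], weights=w).fit()
    phi = float(np.sqrt(res.scale))  # weighted RSS / (m - 1)
    return max(1.0, phi) if floor else phi


@dataclass(frozen=True)
class ConMixConfig:
    """Tuning parameters of the contamination mixture estimator.

    psi : float or "auto"
        Standard deviation of the invalid-instrument estimands, in causal
        effect units.  "auto" applies the 1.5 x SD heuristic.
    grid_min, grid_max : float, optional
        Causal-effect grid bounds; by default the grid spans the plausible
        range (theta_hat +/- 3 se) of every variant in the precision core —
        variants whose ratio-estimate SE is within 10x the median SE.
        Near-null exposure associations produce enormous, uninformative
        ratio estimates; letting them stretch the grid destroys the
        resolution where the likelihood mass actually sits.  Confidence-set
        endpoints are reported at grid resolution.
    grid_points : int
        Number of grid points (>= 101; default 5001).
    alpha : float
        Complement of the confidence level (default 0.05 for 95% sets).
    overdispersion : bool
        Inflate the likelihood-ratio cutoff by max(1, phi_hat^2).  The point
        estimate and validity flags are never altered by overdispersion.
    mode_prominence : float, optional
        Log-likelihood prominence required for a local maximum to count as a
        mode, on the 2*delta-log-lik scale.  Defaults to the confidence-set
        cutoff, so reported modes correspond exactly to potential disjoint
        confidence-set components.
    """

    psi: float | str = "auto"
    grid_min: float | None = None
    grid_max: float | None = None
    grid_points: int = 5001
    alpha: float = 0.05
    overdispersion: bool = True
    mode_prominence: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.psi, str):
            if self.psi != "auto":
                raise MRInputError("psi must be a positive number or 'auto'")
        elif not (np.isfinite(self.psi) and self.psi > 0):
            raise MRInputError("psi must be a positive number or 'auto'")
        if (self.grid_min is None) != (self.grid_max is None):
            raise MRInputError("grid_min and grid_max must be given together")
        if self.grid_min is not None and not self.grid_min < self.grid_max:
            raise MRInputError("grid_min must be strictly less than grid_max")
        if int(self.grid_points) < 101:
            raise MRInputError("grid_points must be an integer >= 101")
        if not 0.0 < self.alpha < 1.0:
            raise MRInputError("alpha must lie in (0, 1)")


class ContaminationMixture:
    """Contamination mixture model for two-sample summary-data MR.

    Parameters
    ----------
    data : SummarySet or DataFrame
        Per-variant associations with the risk factor and outcome.
    psi, grid_min, grid_max, grid_points, alpha, overdispersion, mode_prominence
        See :class:`ConMixConfig`.
    se_order : {"first", "second"}
        Standard errors for the variant-specific ratio estimates.

    Examples
    --------
    >>> model = ContaminationMixture(summary_set, psi=1.0)
    >>> res = model.fit()
    >>> res.estimate, res.ci_ranges
    """

    def __init__(
        self,
        data: SummarySet | pd.DataFrame,
        psi: float | str = "auto",
        grid_min: float | None = None,
        grid_max: float | None = None,
        grid_points: int = 5001,
        alpha: float = 0.05,
        overdispersion: bool = True,
        mode_prominence: float | None = None,
        se_order: str = "first",
    ) -> None:
        if isinstance(data, pd.DataFrame):
            data = SummarySet.from_dataframe(data)
        self.data = data
        self.config = ConMixConfig(
            psi=psi,
            grid_min=grid_min,
            grid_max=grid_max,
            grid_points=int(grid_points),
            alpha=alpha,
            overdispersion=overdispersion,
            mode_prominence=mode_prominence,
        )
        self.se_order = se_order
        self.ratios = ratio_estimates(data, se_order=se_order)

    @classmethod
    def from_csv(cls, path, columns=None, sep=None, **kwargs) -> "ContaminationMixture":
        return cls(SummarySet.from_csv(path, columns=columns, sep=sep), **kwargs)

    # internal ---------------------------------------------------------------

    def _grid(self) -> np.ndarray:
        cfg = self.config
        th, se = self.ratios.theta_hat, self.ratios.se_theta
        # precision core: variants whose ratio estimate is precise enough to
        # host a likelihood peak; wildly imprecise estimates (near-null
        # exposure associations) are uninformative and must not be allowed
        # to stretch the grid and destroy its resolution
        core = se <= 10.0 * np.median(se)
        core_lo = float((th[core] - 3.0 * se[core]).min())
        core_hi = float((th[core] + 3.0 * se[core]).max())
        if cfg.grid_min is not None:
            lo, hi = float(cfg.grid_min), float(cfg.grid_max)
            if lo > core_lo or hi < core_hi:
                warnings.warn(
                    "supplied grid does not cover the plausible range of all "
                    "precise variant-specific estimates; the maximum may sit "
                    "at a grid boundary",
                    stacklevel=2,
                )
        else:
            lo, hi = core_lo, core_hi
        return np.linspace(lo, hi, cfg.grid_points)

    def fit(self) -> "ConMixResults":
        cfg = self.config
        ratios = self.ratios
        psi = default_psi(ratios) if cfg.psi == "auto" else float(cfg.psi)

        grid = self._grid()
        th, se = ratios.theta_hat, ratios.se_theta
        # valid-component log density on the full grid (n_grid x J); the
        # invalid component does not depend on theta, so it is a J-vector
        lv = (
            -0.5 * ((grid[:, None] - th[None, :]) / se[None, :]) ** 2
            - np.log(se)[None, :]
            - _LOG_SQRT_2PI
        )
        sf = np.sqrt(psi**2 + se**2)
        lf = -0.5 * (th / sf) ** 2 - np.log(sf) - _LOG_SQRT_2PI
        loglik = np.maximum(lv, lf[None, :]).sum(axis=1)
        if not np.all(np.isfinite(loglik)):
            bad = np.flatnonzero(~np.isfinite(loglik))
            raise EstimationError(
                f"non-finite profile log-likelihood at {bad.size} grid point(s), "
                f"first at theta={grid[bad[0]]:g}; check input scales and psi"
            )

        ll_max = float(loglik.max())
        # argmax with deterministic tie-breaking: most valid-flagged variants,
        # then smallest |theta|
        cand = np.flatnonzero(loglik >= ll_max - 1e-12)
        if cand.size > 1:
            n_valid = (lv[cand] >= lf[None, :]).sum(axis=1)
            cand = cand[n_valid == n_valid.max()]
            cand = cand[np.abs(grid[cand]).argmin()][None] if cand.size > 1 else cand
        imax = int(cand[0])
        if imax in (0, len(grid) - 1) and cfg.grid_min is not None:
            warnings.warn(
                "profile likelihood is maximised at a grid boundary; widen the "
                "grid bounds",
                stacklevel=2,
            )
        estimate = float(grid[imax])
        valid_flags = (lv[imax] >= lf).astype(int)

        if cfg.overdispersion and valid_flags.any():
            phi = overdispersion_phi(self.data, valid_flags.astype(bool))
        else:
            if cfg.overdispersion:
                logger.warning(
                    "no variant is flagged valid at the estimate; "
                    "overdispersion set to 1"
                )
            phi = 1.0

        cutoff = max(1.0, phi) ** 2 * stats.chi2.ppf(1.0 - cfg.alpha, df=1)
        inside = 2.0 * (ll_max - loglik) <= cutoff
        ci_ranges = _runs_to_intervals(grid, inside)

        prominence = cfg.mode_prominence if cfg.mode_prominence is not None else cutoff
        modes = _find_modes(grid, loglik, imax, prominence)

        return ConMixResults(
            model=self,
            estimate=estimate,
            ci_ranges=ci_ranges,
            valid_flags=valid_flags,
            loglik_curve=(grid, loglik),
            phi_hat=max(1.0, phi),
            modes=modes,
            psi_used=psi,
            alpha=cfg.alpha,
            cutoff=cutoff,
        )


def _runs_to_intervals(grid: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    """Maximal runs of consecutive True grid points as [lower, upper] intervals."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return [(float(grid[s]), float(grid[e])) for s, e in zip(starts, ends)]


def _find_modes(
    grid: np.ndarray, loglik: np.ndarray, imax: int, prominence: float
) -> list[float]:
    """Local maxima whose likelihood-ratio dip to the adjacent valley exceeds
    ``prominence`` on the 2*delta-log-lik scale.  The global argmax always
    qualifies."""
    peaks, _ = signal.find_peaks(loglik, prominence=prominence / 2.0)
    peaks = set(int(p) for p in peaks)
    peaks.add(imax)
    return [float(grid[p]) for p in sorted(peaks)]


@dataclass
class ConMixResults:
    """Fit results of :class:`ContaminationMixture`.

    Attributes
    ----------
    estimate : float
        Grid argmax of the profile log-likelihood.
    ci_ranges : list of (lower, upper)
        Disjoint, ordered components of the confidence set.
    valid_flags : ndarray of {0,1}
        Per-variant validity indicator at the point estimate.
    loglik_curve : (grid, loglik)
        The profile log-likelihood evaluated on the grid.
    phi_hat : float
        Overdispersion estimate, floored at 1.
    modes : list of float
        Local maxima of the profile likelihood passing the prominence rule.
    psi_used : float
        The invalid-estimand standard deviation actually applied.
    """

    model: ContaminationMixture = field(repr=False)
    estimate: float
    ci_ranges: list[tuple[float, float]]
    valid_flags: np.ndarray
    loglik_curve: tuple[np.ndarray, np.ndarray] = field(repr=False)
    phi_hat: float
    modes: list[float]
    psi_used: float
    alpha: float
    cutoff: float

    @property
    def conf_set(self) -> list[tuple[float, float]]:
        """Alias for ``ci_ranges``."""
        return self.ci_ranges

    @property
    def n_valid(self) -> int:
        return int(self.valid_flags.sum())

    @property
    def grid_step(self) -> float:
        grid = self.loglik_curve[0]
        return float(grid[1] - grid[0])

    def covers(self, value: float) -> bool:
        """Whether ``value`` lies inside the confidence set.

        Evaluated exactly: the profile log-likelihood is recomputed at
        ``value`` itself, so membership is not quantised to the grid
        (``ci_ranges`` is the grid rendering of the same set).
        """
        ll_v, _ = profile_loglik(float(value), self.model.ratios, self.psi_used)
        ll_max = float(self.loglik_curve[1].max())
        return 2.0 * (ll_max - ll_v) <= self.cutoff

    def rejects_null(self, value: float = 0.0) -> bool:
        """Whether ``value`` lies outside every confidence-set component."""
        return not self.covers(value)

    def variant_table(self) -> pd.DataFrame:
        ratios = self.model.ratios
        return pd.DataFrame(
            {
                "variant": ratios.variant_ids,
                "theta_hat": ratios.theta_hat,
                "se_theta": ratios.se_theta,
                "valid": self.valid_flags,
            }
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_ranges": [list(r) for r in self.ci_ranges],
            "alpha": self.alpha,
            "phi": self.phi_hat,
            "psi_used": self.psi_used,
            "modes": self.modes,
            "n_valid": self.n_valid,
            "valid_flags": self.valid_flags.tolist(),
            "grid_points": len(self.loglik_curve[0]),
            "grid_step": self.grid_step,
        }

    def summary(self) -> str:
        lines = [
            "Contamination mixture Mendelian randomization",
            "=" * 46,
            f"Variants:               {self.model.data.n_variants}"
            f" ({self.n_valid} flagged valid at the estimate)",
            f"psi (invalid spread):   {self.psi_used:.4g}",
            f"Causal estimate:        {self.estimate:.4g}",
            f"{100 * (1 - self.alpha):.0f}% confidence set:    "
            + ", ".join(f"[{lo:.4g}, {hi:.4g}]" for lo, hi in self.ci_ranges),
            f"Overdispersion phi:     {self.phi_hat:.4g}",
            f"Modes:                  {', '.join(f'{m:.4g}' for m in self.modes)}",
            f"Grid resolution:        {self.grid_step:.3g}"
            " (confidence-set endpoints are grid-resolution limited)",
        ]
        if len(self.ci_ranges) > 1:
            lines.append(
                "Note: disjoint confidence set — multiple groups of variants "
                "support different causal effects (possible distinct mechanisms)."
            )
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Plot the profile log-likelihood with the confidence-set cutoff."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        grid, ll = self.loglik_curve
        ax.plot(grid, ll, lw=1.2)
        ax.axhline(ll.max() - self.cutoff / 2.0, ls="--", color="grey", lw=0.8)
        for lo, hi in self.ci_ranges:
            ax.axvspan(lo, hi, color="0.85", zorder=0)
        ax.axvline(self.estimate, color="k", lw=0.8)
        ax.set_xlabel("causal effect")
        ax.set_ylabel("profile log-likelihood")
        return ax


def conmix_estimate(data: SummarySet | pd.DataFrame, **kwargs) -> ConMixResults:
    """Fit the contamination mixture estimator in one call.

    Keyword arguments are passed to :class:`ContaminationMixture`.
    """
    return ContaminationMixture(data, **kwargs).fit()
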