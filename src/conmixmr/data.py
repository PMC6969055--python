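"""Summary-statistic containers and variant-specific (Wald ratio) causal estimates.

Two-sample summary-data Mendelian randomization starts from per-variant
beta-coefficients and standard errors for the genetic association with the
risk factor (exposure) and with the outcome.  ``SummarySet`` holds these with
validation; ``ratio_estimates`` turns them into variant-specific causal
estimates theta_hat_j = beta_Yj / beta_Xj with first- or second-order
(delta-method) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import MRInputError

__all__ = [
    "SummarySet",
    "RatioEstimates",
    "ratio_estimates",
    "read_summary_stats",
    "DEFAULT_COLUMNS",
]

#: canonical column name -> expected header in delimited input files
DEFAULT_COLUMNS: dict[str, str] = {
    "variant": "variant",
    "beta_exposure": "beta_exposure",
    "se_exposure": "se_exposure",
    "beta_outcome": "beta_outcome",
    "se_outcome": "se_outcome",
}


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise MRInputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class SummarySet:
    """Per-variant genetic associations with the risk factor and the outcome.

    Parameters
    ----------
    variant_ids : sequence of str
        Unique variant identifiers (e.g. rsids).
    beta_x, se_x : array-like
        Association with the risk factor (per-allele) and its standard error.
    beta_y, se_y : array-like
        Association with the outcome (per-allele, possibly log odds) and its
        standard error.
    """

    variant_ids: tuple[str, ...]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(v) for v in self.variant_ids)
        object.__setattr__(self, "variant_ids", ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            object.__setattr__(self, name, _as_float_array(getattr(self, name), name))
        j = len(ids)
        if j < 1:
            raise MRInputError("SummarySet requires at least one variant")
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if len(getattr(self, name)) != j:
                raise MRInputError(
                    f"{name} has length {len(getattr(self, name))}, expected {j}"
                )
        if len(set(ids)) != j:
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise MRInputError(f"duplicate variant identifiers: {dupes}")
        for name in ("se_x", "se_y"):
            se = getattr(self, name)
            bad = ~(np.isfinite(se) & (se > 0))
            if bad.any():
                offenders = [ids[i] for i in np.flatnonzero(bad)[:5]]
                raise MRInputError(
                    f"{name} must be strictly positive and finite; "
                    f"offending variants: {offenders}"
                )
        for name in ("beta_x", "beta_y"):
            beta = getattr(self, name)
            if not np.all(np.isfinite(beta)):
                offenders = [ids[i] for i in np.flatnonzero(~np.isfinite(beta))[:5]]
                raise MRInputError(
                    f"{name} must be finite; offending variants: {offenders}"
                )

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return self.n_variants

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, columns: Mapping[str, str] | None = None
    ) -> "SummarySet":
        """Build a SummarySet from a DataFrame.

        ``columns`` maps canonical names (keys of :data:`DEFAULT_COLUMNS`) to
        the DataFrame's column headers; unspecified entries use the defaults.
        """
        mapping = dict(DEFAULT_COLUMNS)
        if columns:
            unknown = set(columns) - set(mapping)
            if unknown:
                raise MRInputError(
                    f"unknown canonical column names in mapping: {sorted(unknown)}"
                )
            mapping.update(columns)
        missing = [col for col in mapping.values() if col not in df.columns]
        if missing:
            raise MRInputError(f"missing required column(s): {missing}")
        return cls(
            variant_ids=tuple(df[mapping["variant"]].astype(str)),
            beta_x=df[mapping["beta_exposure"]].to_numpy(float),
            se_x=df[mapping["se_exposure"]].to_numpy(float),
            beta_y=df[mapping["beta_outcome"]].to_numpy(float),
            se_y=df[mapping["se_outcome"]].to_numpy(float),
        )

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        columns: Mapping[str, str] | None = None,
        sep: str | None = None,
    ) -> "SummarySet":
        """Read a CSV/TSV summary-statistics file (delimiter inferred)."""
        return read_summary_stats(path, columns=columns, sep=sep)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_ids,
                "beta_exposure": self.beta_x,
                "se_exposure": self.se_x,
                "beta_outcome": self.beta_y,
                "se_outcome": self.se_y,
            }
        )


def read_summary_stats(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> SummarySet:
    """Read per-variant summary associations from a delimited text file.

    The delimiter is inferred from the file extension (``.csv`` -> comma,
    otherwise tab) unless ``sep`` is given.  Lines starting with ``#`` are
    treated as comments.
    """
    path = Path(path)
    if not path.exists():
        raise MRInputError(f"summary-statistics file not found: {path}")
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    return SummarySet.from_dataframe(df, columns=columns)


@dataclass(frozen=True)
class RatioEstimates:
    """Variant-specific causal estimates theta_hat_j with standard errors."""

    variant_ids: tuple[str, ...]
    theta_hat: np.ndarray
    se_theta: np.ndarray
    se_order: str = "first"
    source: SummarySet | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta_hat", _as_float_array(self.theta_hat, "theta_hat"))
        object.__setattr__(self, "se_theta", _as_float_array(self.se_theta, "se_theta"))
        if len(self.theta_hat) != len(self.variant_ids) or len(self.se_theta) != len(
            self.variant_ids
        ):
            raise MRInputError("RatioEstimates vectors must share one length")
        if not np.all(np.isfinite(self.se_theta) & (self.se_theta > 0)):
            raise MRInputError("se_theta must be strictly positive and finite")
        if self.se_order not in ("first", "second"):
            raise MRInputError("se_order must be 'first' or 'second'")

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __len__(self) -> int:
        return self.n_variants


def ratio_estimates(
    data: SummarySet,
    se_order: str = "first",
    f_threshold: float | None = None,
) -> RatioEstimates:
    """Variant-specific (Wald ratio) causal estimates.

    theta_hat_j = beta_Yj / beta_Xj.  The first-order standard error,
    se(beta_Yj)/|beta_Xj|, ignores uncertainty in the exposure association;
    the second-order (delta-method) standard error adds it:
    sqrt(se_Yj^2/beta_Xj^2 + beta_Yj^2 se_Xj^2 / beta_Xj^4).

    First-order standard errors are the default: with genome-wide significant
    instruments the exposure association is estimated far more precisely than
    the outcome association, and propagating its uncertainty naively induces a
    correlation between instrument strength and the estimate's standard error.

    Parameters
    ----------
    f_threshold : float, optional
        If given, variants whose exposure F statistic (beta_x/se_x)^2 falls
        below it are flagged with a warning (never dropped).
    """
    if se_order not in ("first", "second"):
        raise MRInputError("se_order must be 'first' or 'second'")
    bad = ~np.isfinite(data.beta_x) | (data.beta_x == 0.0)
    if bad.any():
        offenders = [data.variant_ids[i] for i in np.flatnonzero(bad)[:5]]
        raise MRInputError(
            "beta_exposure must be non-zero and finite to form ratio estimates; "
            f"offending variants: {offenders}"
        )
    theta = data.beta_y / data.beta_x
    if se_order == "first":
        se = data.se_y / np.abs(data.beta_x)
    else:
        se = np.sqrt(
            data.se_y**2 / data.beta_x**2
            + data.beta_y**2 * data.se_x**2 / data.beta_x**4
        )
    if f_threshold is not None:
        f_stat = (data.beta_x / data.se_x) ** 2
        weak = np.flatnonzero(f_stat < f_threshold)
        if weak.size:
            names = [data.variant_ids[i] for i in weak[:10]]
            warnings.warn(
                f"{weak.size} variant(s) have exposure F below {f_threshold:g} "
                f"(weak instruments), e.g. {names}; they are retained",
                stacklevel=2,
            )
    return RatioEstimates(
        variant_ids=data.variant_ids,
        theta_hat=theta,
        se_theta=se,
        se_order=se_order,
        source=data,
    )
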