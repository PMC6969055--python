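"""Posterior instrument-validity probabilities and trait ranking.

At a given causal effect theta, each variant's posterior probability of being
a valid instrument follows from Bayes' rule on the two mixture components:

    pi_1j = pi_0j L_Vj / (pi_0j L_Vj + (1 - pi_0j) L_Fj)

where pi_0j is a per-variant prior.  Unlike the 0/1 validity indicators of
the profile likelihood, the posteriors grade variants by the precision of
their estimates and (through the prior) by their instrument strength.

Given an auxiliary variant x trait association matrix (e.g. a PhenoScanner
extract), traits can be ranked by the mean posterior probability of their
associated variants — a hypothesis-free screen for variables that mark the
subgroup of variants driving a particular causal signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conmix import component_logliks
from .data import RatioEstimates, SummarySet
from .exceptions import MRInputError

__all__ = [
    "PosteriorTable",
    "posterior_validity",
    "default_prior",
    "rank_traits",
    "read_trait_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PosteriorTable:
    """Per-variant prior and posterior validity probabilities at ``theta_ref``."""

    variant_ids: tuple[str, ...]
    prior: np.ndarray
    posterior: np.ndarray
    theta_ref: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior", np.asarray(self.prior, dtype=float))
        object.__setattr__(self, "posterior", np.asarray(self.posterior, dtype=float))
        if len(self.prior) != len(self.variant_ids) or len(self.posterior) != len(
            self.variant_ids
        ):
            raise MRInputError("PosteriorTable vectors must share one length")
        for name in ("prior", "posterior"):
            p = getattr(self, name)
            if np.any((p < 0.0) | (p > 1.0) | ~np.isfinite(p)):
                raise MRInputError(f"{name} probabilities must lie in [0, 1]")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_ids,
                "prior": self.prior,
                "posterior": self.posterior,
                "theta_ref": self.theta_ref,
            }
        )


def posterior_validity(
    ratios: RatioEstimates,
    theta: float,
    psi: float,
    prior: np.ndarray | float,
) -> PosteriorTable:
    """Posterior probability that each variant is a valid instrument at ``theta``.

    ``prior`` may be a scalar or per-variant vector of prior probabilities in
    [0, 1].  Degenerate priors are honoured exactly: prior 0 gives posterior
    0, prior 1 gives posterior 1.
    """
    prior_arr = np.broadcast_to(
        np.asarray(prior, dtype=float), (ratios.n_variants,)
    ).copy()
    if np.any((prior_arr < 0.0) | (prior_arr > 1.0) | ~np.isfinite(prior_arr)):
        raise MRInputError("prior probabilities must lie in [0, 1]")
    lv, lf = component_logliks(theta, ratios, psi)
    # pi1 = p / (p + (1-p) * exp(lf - lv)), computed on the log scale for
    # stability when one component dominates
    ratio = np.exp(np.clip(lf - lv, -745.0, 709.0))
    with np.errstate(invalid="ignore"):
        post = prior_arr / (prior_arr + (1.0 - prior_arr) * ratio)
    post = np.where(prior_arr == 0.0, 0.0, post)
    post = np.where(prior_arr == 1.0, 1.0, post)
    return PosteriorTable(
        variant_ids=ratios.variant_ids,
        prior=prior_arr,
        posterior=post,
        theta_ref=float(theta),
    )


def default_prior(data: SummarySet) -> np.ndarray:
    """Prior validity probability from instrument strength: |beta_exposure|.

    With the exposure in standard-deviation units the absolute per-allele
    association is below one and acts directly as a prior weight, so variants
    strongly associated with the risk factor get higher prior validity.
    Values above one (possible for non-standardized exposures) are clipped to
    one with a warning.
    """
    p = np.abs(data.beta_x)
    clipped = p > 1.0
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} prior(s) |beta_exposure| exceed 1 and were "
            "clipped; consider standardizing the exposure associations",
            stacklevel=2,
        )
    return np.minimum(p, 1.0)


def read_trait_matrix(path: str | Path) -> pd.DataFrame:
    """Read a long-format variant x trait association table.

    Requires columns ``variant``, ``trait`` and ``p`` (association p-value);
    ``beta`` and ``se`` are carried through if present.  Missing
    variant-trait pairs are treated as not associated.
    """
    path = Path(path)
    if not path.exists():
        raise MRInputError(f"trait matrix file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in ("variant", "trait", "p") if c not in df.columns]
    if missing:
        raise MRInputError(f"trait matrix is missing column(s): {missing}")
    return df


def rank_traits(
    posteriors: PosteriorTable,
    traits: pd.DataFrame,
    p_threshold: float = 1e-5,
    min_variants: int = 6,
    exclusions: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Rank auxiliary traits by mean posterior validity of associated variants.

    A variant counts as associated with a trait when its p-value is below
    ``p_threshold``.  Traits with fewer than ``min_variants`` associated
    variants (among the variants in the posterior table) are dropped, as are
    traits named in ``exclusions`` (the place to list duplicates and traits
    closely related to the exposure).  Returns a DataFrame with columns
    ``trait``, ``n_variants``, ``mean_posterior``, ``rank`` sorted by
    descending score.
    """
    missing = [c for c in ("variant", "trait", "p") if c not in traits.columns]
    if missing:
        raise MRInputError(f"trait matrix is missing column(s): {missing}")
    pvals = traits["p"].to_numpy(dtype=float)
    if np.any((pvals <= 0.0) | (pvals > 1.0) | ~np.isfinite(pvals)):
        raise MRInputError("trait association p-values must lie in (0, 1]")

    post = posteriors.to_dataframe()[["variant", "posterior"]]
    assoc = traits.loc[
        (pvals < p_threshold) & ~traits["trait"].isin(set(exclusions)),
        ["variant", "trait"],
    ].drop_duplicates()
    merged = assoc.merge(post, on="variant", how="inner")

    grouped = (
        merged.groupby("trait", sort=True)
        .agg(n_variants=("variant", "size"), mean_posterior=("posterior", "mean"))
        .reset_index()
    )
    grouped = grouped[grouped["n_variants"] >= min_variants]
    if grouped.empty:
        warnings.warn(
            "no trait passes the association filter "
            f"(>= {min_variants} variants at p < {p_threshold:g})",
            stacklevel=2,
        )
        return pd.DataFrame(
            columns=["trait", "n_variants", "mean_posterior", "rank"]
        )
    grouped = grouped.sort_values(
        ["mean_posterior", "trait"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    grouped["rank"] = np.arange(1, len(grouped) + 1)
    return grouped
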