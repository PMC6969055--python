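"""Individual-level data-generating engine for method validation.

Two non-overlapping cohorts are drawn from one data-generating process with a
genetic confounder pathway:

    U_i = sum_j kappa_j G_ij + eps_Ui                (confounder)
    X_i = sum_j gamma_j G_ij + delta_X U_i + eps_Xi  (risk factor)
    Y_i = sum_j alpha_j G_ij + theta X_i + delta_Y U_i + eps_Yi

with G_ij ~ Binomial(2, maf) independently, all eps ~ N(0, 1), and
gamma_j drawn per variant from a uniform or normal effect-size distribution.
Valid instruments have alpha_j = kappa_j = 0.  Invalid instruments carry
either a direct (pleiotropic) effect alpha_j on the outcome — balanced,
U(-0.1, 0.1), or directional, U(0, 0.1) — or an effect kappa_j ~ U(-0.1, 0.1)
on the confounder, which couples pleiotropy to instrument strength and
violates the InSIDE assumption.

Summary statistics come from one-variant-at-a-time simple linear regressions
(with intercept), X on G in cohort 1 and Y on G in cohort 2, matching how
GWAS consortia produce the summary data the estimators consume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .conmix import ContaminationMixture
from .data import SummarySet
from .exceptions import MRInputError
from .ivw import IVW

__all__ = [
    "SimScenario",
    "SimReport",
    "simulate_dataset",
    "run_study",
    "instrument_strength_study",
    "InstrumentStrength",
]

logger = logging.getLogger(__name__)

_PLEIOTROPY_KINDS = ("none", "balanced", "directional", "confounder")


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of the data-generating process.

    Defaults reproduce the standard study conditions: 100 variants, two
    cohorts of 20,000, minor allele frequency 0.3, per-variant instrument
    effects gamma_j ~ U(0.03, 0.1), unit confounder loadings.
    """

    j: int = 100
    n_x: int = 20_000
    n_y: int = 20_000
    maf: float = 0.3
    theta: float = 0.0
    n_invalid: int = 0
    pleiotropy: str = "none"
    gamma_dist: tuple = ("uniform", 0.03, 0.1)
    alpha_range: tuple[float, float] | None = None
    kappa_range: tuple[float, float] = (-0.1, 0.1)
    delta_x: float = 1.0
    delta_y: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.j < 1:
            raise MRInputError("j (number of variants) must be >= 1")
        if self.n_x < 1 or self.n_y < 1:
            raise MRInputError("cohort sizes n_x, n_y must be >= 1")
        if not 0.0 < self.maf <= 0.5:
            raise MRInputError("maf must lie in (0, 0.5]")
        if not 0 <= self.n_invalid <= self.j:
            raise MRInputError("n_invalid must lie in [0, j]")
        if self.pleiotropy not in _PLEIOTROPY_KINDS:
            raise MRInputError(f"pleiotropy must be one of {_PLEIOTROPY_KINDS}")
        if self.pleiotropy == "none" and self.n_invalid != 0:
            raise MRInputError("pleiotropy='none' requires n_invalid == 0")
        kind = self.gamma_dist[0]
        if kind not in ("uniform", "normal") or len(self.gamma_dist) != 3:
            raise MRInputError(
                "gamma_dist must be ('uniform', lo, hi) or ('normal', mean, sd)"
            )

    @classmethod
    def standard(
        cls, scenario: int, theta: float = 0.0, n_invalid: int = 20, **overrides
    ) -> "SimScenario":
        """The four standard scenarios.

        1 — all valid; 2 — balanced pleiotropy; 3 — directional pleiotropy
        (both satisfy InSIDE); 4 — pleiotropy via the confounder (InSIDE
        violated).
        """
        kinds = {1: "none", 2: "balanced", 3: "directional", 4: "confounder"}
        if scenario not in kinds:
            raise MRInputError("scenario must be 1, 2, 3 or 4")
        return cls(
            theta=theta,
            n_invalid=0 if scenario == 1 else n_invalid,
            pleiotropy=kinds[scenario],
            **overrides,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        d = dict(d)
        for key in ("gamma_dist", "alpha_range", "kappa_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise MRInputError(f"unknown scenario field(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def _alpha_range(self) -> tuple[float, float]:
        if self.alpha_range is not None:
            return self.alpha_range
        return {"balanced": (-0.1, 0.1), "directional": (0.0, 0.1)}.get(
            self.pleiotropy, (0.0, 0.0)
        )


class InstrumentStrength(NamedTuple):
    """Joint instrument strength in the exposure cohort."""

    r_squared: float  # proportion of Var(X) explained by all variants jointly
    f_statistic: float  # joint ANOVA F of the all-variant regression


def _draw_gamma(rng: np.random.Generator, dist: tuple, j: int) -> np.ndarray:
    kind, a, b = dist
    if kind == "uniform":
        return rng.uniform(a, b, size=j)
    return rng.normal(a, b, size=j)


def _marginal_regressions(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant simple linear regression (with intercept), vectorised.

    Returns slopes and their standard errors using the usual unbiased
    residual-variance estimator with n - 2 degrees of freedom.
    """
    n = G.shape[0]
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    if np.any(sgg == 0.0):
        raise MRInputError(
            "monomorphic variant in simulated cohort (no genotype variance); "
            "increase the sample size"
        )
    sgy = Gc.T @ yc
    slope = sgy / sgg
    rss = yc @ yc - slope * sgy
    se = np.sqrt(rss / (n - 2) / sgg)
    return slope, se


def _joint_strength(G: np.ndarray, x: np.ndarray) -> InstrumentStrength:
    n, k = G.shape
    Gc = G - G.mean(axis=0)
    xc = x - x.mean()
    gram = Gc.T @ Gc
    gx = Gc.T @ xc
    beta = np.linalg.solve(gram, gx)
    tss = float(xc @ xc)
    rss = tss - float(beta @ gx)
    r2 = 1.0 - rss / tss
    f_stat = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    return InstrumentStrength(r_squared=r2, f_statistic=f_stat)


def _resolve_rng(scenario: SimScenario, seed) -> np.random.Generator:
    if seed is None:
        seed = scenario.seed
    if seed is None:
        raise MRInputError("a seed is required (argument or scenario.seed)")
    return np.random.default_rng(seed)


def simulate_dataset(
    scenario: SimScenario,
    seed: int | np.random.SeedSequence | None = None,
    return_strength: bool = False,
) -> SummarySet | tuple[SummarySet, InstrumentStrength]:
    """Draw one two-sample summary dataset from the scenario's DGP.

    Per-variant parameters (gamma, alpha, kappa and the identity of the
    invalid instruments — a seeded shuffle, first ``n_invalid`` indices) are
    drawn once and shared by both cohorts; genotypes and noise are drawn
    independently per cohort.  With ``return_strength`` the joint R^2 and F
    statistic of the exposure regression on all variants (cohort 1) are also
    returned.
    """
    rng = _resolve_rng(scenario, seed)
    j = scenario.j

    gamma = _draw_gamma(rng, scenario.gamma_dist, j)
    alpha = np.zeros(j)
    kappa = np.zeros(j)
    invalid = rng.permutation(j)[: scenario.n_invalid]
    if scenario.n_invalid and scenario.pleiotropy in ("balanced", "directional"):
        lo, hi = scenario._alpha_range()
        alpha[invalid] = rng.uniform(lo, hi, size=scenario.n_invalid)
    elif scenario.n_invalid and scenario.pleiotropy == "confounder":
        lo, hi = scenario.kappa_range
        kappa[invalid] = rng.uniform(lo, hi, size=scenario.n_invalid)

    def cohort(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        G = rng.binomial(2, scenario.maf, size=(n, j)).astype(np.float64)
        u = G @ kappa + rng.standard_normal(n)
        x = G @ gamma + scenario.delta_x * u + rng.standard_normal(n)
        y = G @ alpha + scenario.theta * x + scenario.delta_y * u + rng.standard_normal(n)
        return G, x, y

    G1, x1, _ = cohort(scenario.n_x)
    beta_x, se_x = _marginal_regressions(G1, x1)
    G2, _, y2 = cohort(scenario.n_y)
    beta_y, se_y = _marginal_regressions(G2, y2)

    data = SummarySet(
        variant_ids=tuple(f"v{i + 1}" for i in range(j)),
        beta_x=beta_x,
        se_x=se_x,
        beta_y=beta_y,
        se_y=se_y,
    )
    if return_strength:
        return data, _joint_strength(G1, x1)
    return data


_METHODS = ("ivw_fixed", "ivw_random", "conmix")


def _replicate_seed(base_seed: int, r: int) -> np.random.SeedSequence:
    """Deterministic, stream-safe per-replicate seed: replicate r uses
    SeedSequence(base_seed, spawn_key=(r,))."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(r,))


@dataclass
class SimReport:
    """Monte-Carlo evaluation of estimators on one scenario.

    ``table`` has one row per method: mean and SD of the estimates, mean
    standard error (where the method reports one), empirical power (% of
    replicates whose 95% confidence set excludes zero), coverage (% covering
    the true effect) and mean squared error.
    """

    table: pd.DataFrame
    scenario: SimScenario
    n_reps: int
    base_seed: int
    psi: float
    estimates: pd.DataFrame | None = field(default=None, repr=False)

    def to_tsv(self, path, include_estimates: bool = False) -> None:
        """Write the report with full provenance in '#' header lines."""
        import json

        with open(path, "w") as fh:
            fh.write("# conmixmr simulation report\n")
            fh.write(f"# scenario: {json.dumps(self.scenario.to_dict())}\n")
            fh.write(
                f"# n_reps: {self.n_reps}\tbase_seed: {self.base_seed}\t"
                f"psi: {self.psi}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        if include_estimates and self.estimates is not None:
            est_path = str(path) + ".estimates.tsv"
            self.estimates.to_csv(est_path, sep="\t", index=False, float_format="%.6g")


def run_study(
    scenario: SimScenario,
    methods: Sequence[str] = ("ivw_random", "conmix"),
    n_reps: int = 1000,
    base_seed: int = 0,
    psi: float = 1.0,
    alpha: float = 0.05,
    keep_estimates: bool = False,
) -> SimReport:
    """Monte-Carlo study of the estimators under one scenario.

    ``psi`` is the invalid-estimand spread handed to the contamination
    mixture method; the study default of 1 avoids extreme values of the
    heuristic in replicates where the ratio estimates happen to be
    wildly dispersed.  A method failure in a replicate is logged and counted,
    not fatal.
    """
    if n_reps < 1:
        raise MRInputError("n_reps must be >= 1")
    bad = set(methods) - set(_METHODS)
    if bad:
        raise MRInputError(f"unknown method(s) {sorted(bad)}; choose from {_METHODS}")

    results: dict[str, dict[str, list]] = {
        m: {"est": [], "se": [], "reject": [], "cover": []} for m in methods
    }
    n_fail = {m: 0 for m in methods}

    for r in range(n_reps):
        data = simulate_dataset(scenario, seed=_replicate_seed(base_seed, r))
        for m in methods:
            try:
                if m == "conmix":
                    res = ContaminationMixture(data, psi=psi, alpha=alpha).fit()
                    se = np.nan  # no single SE: inference is set-based
                else:
                    res = IVW(
                        data, model=m.removeprefix("ivw_"), alpha=alpha
                    ).fit()
                    se = res.se
                results[m]["est"].append(res.estimate)
                results[m]["se"].append(se)
                results[m]["reject"].append(res.rejects_null(0.0))
                results[m]["cover"].append(res.covers(scenario.theta))
            except Exception:  # noqa: BLE001 — tally and continue
                n_fail[m] += 1
                logger.exception("method %s failed on replicate %d", m, r)

    rows = []
    for m in methods:
        est = np.asarray(results[m]["est"], dtype=float)
        if est.size == 0:
            raise MRInputError(f"method {m} failed on every replicate")
        ses = np.asarray(results[m]["se"], dtype=float)
        rows.append(
            {
                "method": m,
                "mean": est.mean(),
                "sd": est.std(ddof=1) if est.size > 1 else np.nan,
                "mean_se": np.nan if np.isnan(ses).all() else np.nanmean(ses),
                "power": 100.0 * np.mean(results[m]["reject"]),
                "coverage": 100.0 * np.mean(results[m]["cover"]),
                "mse": np.mean((est - scenario.theta) ** 2),
                "n_ok": est.size,
                "n_fail": n_fail[m],
            }
        )

    estimates = None
    if keep_estimates:
        estimates = pd.DataFrame(
            {m: pd.Series(results[m]["est"], dtype=float) for m in methods}
        )
    return SimReport(
        table=pd.DataFrame(rows),
        scenario=scenario,
        n_reps=n_reps,
        base_seed=base_seed,
        psi=psi,
        estimates=estimates,
    )


def instrument_strength_study(
    scenario: SimScenario, n_datasets: int = 100, base_seed: int = 0
) -> dict[str, float]:
    """Average joint instrument strength over simulated datasets.

    Returns the mean percentage of exposure variance explained by all
    variants jointly (plain, unadjusted R^2 from the all-variant regression)
    and the mean joint ANOVA F statistic, averaged over datasets.
    """
    if n_datasets < 1:
        raise MRInputError("n_datasets must be >= 1")
    r2, fs = [], []
    for r in range(n_datasets):
        _, strength = simulate_dataset(
            scenario, seed=_replicate_seed(base_seed, r), return_strength=True
        )
        r2.append(strength.r_squared)
        fs.append(strength.f_statistic)
    return {
        "mean_r_squared_pct": 100.0 * float(np.mean(r2)),
        "mean_f_statistic": float(np.mean(fs)),
        "n_datasets": n_datasets,
    }
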