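"""Occupancy, turnover scoring, and binomial mixed models.

For an itinerant colonial breeder, local "extinction" is really cessation
of use: a site occupied in year t−1 that is surveyed but unoccupied in year
t. The denominators matter — an event is only *possible* when both
endpoints' statuses are known, which avoids censoring bias from unmonitored
years. This module scores those events from occupancy series, summarises
per-substrate rates with exact binomial confidence intervals, and fits the
logit-link binomial mixed model (random year intercept) by marginal maximum
likelihood with Gauss–Hermite quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.numdiff import approx_hess1

from .survey_data import OccupancySeries, Status

__all__ = [
    "TransitionTable",
    "SubstrateTurnover",
    "BinaryMixedLogit",
    "BinaryMixedLogitResults",
    "AnovaTable",
    "score_transitions",
    "substrate_turnover_rates",
    "fit_binary_glmm",
    "anova_partition",
    "eta_squared",
    "correlate_occupancy_cessation",
]

DEFAULT_COLONIZATION_START = 2006
REFERENCE_SUBSTRATE = "cattail-marsh"


@dataclass(frozen=True)
class TransitionRow:
    site_id: str
    year: int
    substrate: str
    transition: str  # cessation | persistence | colonization | non-colonization
    possible_cessation: bool
    possible_colonization: bool


@dataclass
class TransitionTable:
    """Scored cessation/colonization events with their denominators."""

    rows: list[TransitionRow] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def counts(self, substrate: str | None = None) -> dict[str, int]:
        rows = self.rows if substrate is None else [
            r for r in self.rows if r.substrate == substrate
        ]
        return {
            "cessations": sum(r.transition == "cessation" for r in rows),
            "possible_cessations": sum(r.possible_cessation for r in rows),
            "colonizations": sum(r.transition == "colonization" for r in rows),
            "possible_colonizations": sum(r.possible_colonization for r in rows),
        }


@dataclass
class SubstrateTurnover:
    """Per-substrate occupancy and turnover rates with exact binomial CIs."""

    substrate: str
    occupancy_mean: float | None = None
    occupancy_ci: tuple[float, float] | None = None
    n_occupancy: int = 0
    cessation_rate: float | None = None
    cessation_ci: tuple[float, float] | None = None
    n_possible_cessations: int = 0
    colonization_rate: float | None = None
    colonization_ci: tuple[float, float] | None = None
    n_possible_colonizations: int = 0


def score_transitions(
    series_set: list[OccupancySeries],
    colonization_start_year: int = DEFAULT_COLONIZATION_START,
) -> TransitionTable:
    """Score year-pair transitions for every occupancy series.

    For each consecutive pair (t−1, t): a site occupied at t−1 and surveyed
    at t is a possible cessation — an actual cessation if unoccupied at t,
    a persistence if still occupied. A site known unoccupied at t−1 and
    surveyed at t is a possible colonization (scored only for
    t ≥ ``colonization_start_year``). Unknown status at either endpoint
    contributes nothing.
    """
    table = TransitionTable()
    for series in series_set:
        st = series.statuses
        for t in sorted(st):
            prev = st.get(t - 1)
            cur = st[t]
            if prev is None or prev is Status.UNKNOWN or cur is Status.UNKNOWN:
                continue
            if prev is Status.OCCUPIED:
                table.rows.append(
                    TransitionRow(
                        site_id=series.site_id,
                        year=t,
                        substrate=series.substrate,
                        transition="cessation" if cur is Status.UNOCCUPIED else "persistence",
                        possible_cessation=True,
                        possible_colonization=False,
                    )
                )
            elif t >= colonization_start_year:
                table.rows.append(
                    TransitionRow(
                        site_id=series.site_id,
                        year=t,
                        substrate=series.substrate,
                        transition="colonization" if cur is Status.OCCUPIED else "non-colonization",
                        possible_cessation=False,
                        possible_colonization=True,
                    )
                )
    return table


def _binom_ci(k: int, n: int, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
    return float(lo), float(hi)


def substrate_turnover_rates(
    table: TransitionTable,
    series_set: list[OccupancySeries],
    min_records: int = 5,
    ci_level: float = 0.95,
) -> list[SubstrateTurnover]:
    """Per-substrate occupancy, cessation, and colonization rates.

    Occupancy is occupied site-years over surveyed site-years; cessation
    and colonization rates use their possible-event denominators. A
    substrate's rate is omitted (left ``None``) when its denominator falls
    below ``min_records`` — small cells give unreliable estimates — and a
    zero denominator is never reported as 0/0. Confidence intervals are
    Clopper–Pearson exact.
    """
    substrates = sorted({s.substrate for s in series_set})
    out = []
    for sub in substrates:
        res = SubstrateTurnover(substrate=sub)
        surveyed = occupied = 0
        for series in series_set:
            if series.substrate != sub:
                continue
            for status in series.statuses.values():
                if status is not Status.UNKNOWN:
                    surveyed += 1
                    occupied += status is Status.OCCUPIED
        res.n_occupancy = surveyed
        if surveyed >= min_records:
            res.occupancy_mean = occupied / surveyed
            res.occupancy_ci = _binom_ci(occupied, surveyed, ci_level)

        c = table.counts(sub)
        res.n_possible_cessations = c["possible_cessations"]
        if c["possible_cessations"] >= min_records:
            res.cessation_rate = c["cessations"] / c["possible_cessations"]
            res.cessation_ci = _binom_ci(c["cessations"], c["possible_cessations"], ci_level)
        res.n_possible_colonizations = c["possible_colonizations"]
        if c["possible_colonizations"] >= min_records:
            res.colonization_rate = c["colonizations"] / c["possible_colonizations"]
            res.colonization_ci = _binom_ci(
                c["colonizations"], c["possible_colonizations"], ci_level
            )
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Binomial GLMM by Gauss–Hermite marginal maximum likelihood


class ConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


class BinaryMixedLogit:
    """Logit-link binomial mixed model with one random intercept.

    The marginal likelihood integrates the random group intercept
    u_g ~ N(0, σ²) out of the Bernoulli likelihood with Gauss–Hermite
    quadrature, so the fit is genuine maximum likelihood (comparable to
    lme4's ``glmer``) rather than a penalised or variational approximation.

    Parameters
    ----------
    endog : array of 0/1 outcomes
    exog : fixed-effect design matrix (first column the intercept)
    groups : group label per observation (the random-intercept factor)
    exog_names : column names for reporting
    n_quad : number of quadrature nodes (default 30; adequate for the
        modest group counts of annual survey data)
    """

    def __init__(self, endog, exog, groups, exog_names=None, n_quad: int = 30):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if set(np.unique(self.endog)) - {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")
        self.groups = np.asarray(groups)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{i}" for i in range(self.exog.shape[1])
        ]
        self.n_quad = n_quad
        self._nodes, self._weights = np.polynomial.hermite.hermgauss(n_quad)
        codes, self._group_labels = pd.factorize(self.groups)
        self._group_codes = codes

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        fixed_factors: list[str],
        group: str,
        reference: dict[str, object] | None = None,
        n_quad: int = 30,
    ) -> "BinaryMixedLogit":
        """Build the model from a tidy frame with treatment coding.

        ``reference`` maps factor name → reference level (e.g. cattails and
        the first study year); other levels appear as difference terms.
        """
        reference = reference or {}
        n = len(data)
        cols = [np.ones(n)]
        names = ["Intercept"]
        for factor in fixed_factors:
            levels = sorted(data[factor].unique(), key=str)
            ref = reference.get(factor, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from factor {factor!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((data[factor] == lev).to_numpy(dtype=float))
                names.append(f"{factor}[{lev}]")
        exog = np.column_stack(cols)
        return cls(
            data[response].to_numpy(dtype=float),
            exog,
            data[group].to_numpy(),
            exog_names=names,
            n_quad=n_quad,
        )

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at (β, log σ)."""
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = self.exog @ beta
        # u = sqrt(2)·σ·node; weights / sqrt(pi)
        u = np.sqrt(2.0) * sigma * self._nodes  # (Q,)
        # log Bernoulli likelihood per obs per node: y*lp + (1-y)*l(1-p)
        lin = eta[:, None] + u[None, :]  # (n, Q)
        # log p = -log1p(exp(-lin)); log(1-p) = -log1p(exp(lin))
        ll_obs = -np.logaddexp(0.0, -lin) * self.endog[:, None] - np.logaddexp(
            0.0, lin
        ) * (1.0 - self.endog[:, None])
        n_groups = len(self._group_labels)
        group_ll = np.zeros((n_groups, self.n_quad))
        np.add.at(group_ll, self._group_codes, ll_obs)
        log_w = np.log(self._weights) - 0.5 * np.log(np.pi)
        return float(special.logsumexp(group_ll + log_w[None, :], axis=1).sum())

    def fit(self, start_params=None, maxiter: int = 500) -> "BinaryMixedLogitResults":
        k = self.exog.shape[1]
        if start_params is None:
            # start from the plain logistic fit with a small random SD
            from statsmodels.api import GLM, families

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                glm = GLM(self.endog, self.exog, family=families.Binomial()).fit()
            start_params = np.r_[glm.params, np.log(0.5)]

        neg = lambda p: -self.loglike(p)
        res = optimize.minimize(
            neg, start_params, method="BFGS", options={"maxiter": maxiter, "gtol": 1e-6}
        )
        if not res.success and np.linalg.norm(res.jac) > 1e-3:
            res = optimize.minimize(neg, res.x, method="Nelder-Mead", options={"maxiter": 5000})
            if not res.success:
                raise ConvergenceError(f"mixed-model fit did not converge: {res.message}")
        params = res.x

        separation = self._separation_flags()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess1(params, neg)
            try:
                cov = np.linalg.inv(hess)
                bse = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            except np.linalg.LinAlgError:
                bse = np.full_like(params, np.nan)
        return BinaryMixedLogitResults(self, params, bse[:k], -res.fun, separation)

    def _separation_flags(self) -> list[str]:
        flags = []
        for j, name in enumerate(self.exog_names):
            if name == "Intercept":
                continue
            mask = self.exog[:, j] == 1.0
            if mask.any():
                ybar = self.endog[mask].mean()
                if ybar in (0.0, 1.0):
                    flags.append(name)
        return flags


class BinaryMixedLogitResults:
    """Fitted binomial mixed model: logit-scale fixed effects, random
    variance, and small-sample-corrected information criterion."""

    def __init__(self, model, params, bse, llf, separation_flags):
        self.model = model
        self.params = params[:-1]
        self.log_sigma = params[-1]
        self.bse = bse
        self.llf = llf
        self.separation_flags = list(separation_flags)
        if self.separation_flags:
            warnings.warn(
                "complete separation for term(s) "
                + ", ".join(self.separation_flags)
                + "; standard errors for these terms are unreliable",
                stacklevel=2,
            )

    @property
    def random_sd(self) -> float:
        return float(np.exp(self.log_sigma))

    @property
    def random_variance(self) -> float:
        return self.random_sd**2

    @property
    def nobs(self) -> int:
        return len(self.model.endog)

    @property
    def n_groups(self) -> int:
        return len(self.model._group_labels)

    @property
    def k_params(self) -> int:
        return len(self.params) + 1

    @property
    def aicc(self) -> float:
        k, n = self.k_params, self.nobs
        aic = -2.0 * self.llf + 2.0 * k
        return aic + 2.0 * k * (k + 1) / max(n - k - 1, 1)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    def fe_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.model.exog_names,
                "estimate": self.params,
                "se": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            }
        )

    def summary(self) -> str:
        lines = [
            "Binomial mixed model (logit link), Gauss-Hermite marginal ML",
            f"n obs = {self.nobs}, n groups = {self.n_groups}, "
            f"logLik = {self.llf:.3f}, AICc = {self.aicc:.2f}",
            f"random intercept variance = {self.random_variance:.5f} "
            f"(sd = {self.random_sd:.5f})",
            "",
            self.fe_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        if self.separation_flags:
            lines.append(
                "WARNING: complete separation for " + ", ".join(self.separation_flags)
            )
        return "\n".join(lines)


def fit_binary_glmm(
    data: pd.DataFrame,
    response: str,
    fixed_factors: list[str],
    group: str = "year",
    reference: dict[str, object] | None = None,
) -> BinaryMixedLogitResults:
    """Fit a binary-outcome mixed model (thin wrapper over
    :class:`BinaryMixedLogit`).

    The occupancy analysis uses year both as a fixed factor and as the
    random intercept; the cessation/colonization analyses use substrate
    alone as fixed with year random.
    """
    model = BinaryMixedLogit.from_dataframe(
        data, response, fixed_factors, group, reference=reference
    )
    return model.fit()


# ---------------------------------------------------------------------------
# ANOVA-style variance partition


@dataclass
class AnovaTable:
    table: pd.DataFrame  # per-effect SS, df, MS, F, p, eta_sq + Error row

    def __str__(self) -> str:
        return self.table.to_string(float_format=lambda v: f"{v:.4g}")


def eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta-squared, SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("eta squared undefined when both sums of squares are zero")
    return ss_effect / (ss_effect + ss_error)


def anova_partition(
    data: pd.DataFrame,
    response: str,
    fixed_factors: list[str],
    reference: dict[str, object] | None = None,
) -> AnovaTable:
    """Sequential sums-of-squares partition over the fixed effects.

    The partition is computed from the ordinary least-squares projection of
    the response onto the fixed-effect design (factors entered in the given
    order), with partial eta-squared per effect against the residual SS.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    reference = reference or {}
    terms = []
    for f in fixed_factors:
        if f in reference:
            terms.append(f"C({f}, Treatment({reference[f]!r}))")
        else:
            terms.append(f"C({f})")
    df = data.rename(columns={response: "_y"})
    formula = "_y ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = ols(formula, data=df).fit()
        aov = anova_lm(fit, typ=1)
    ss_error = float(aov.loc["Residual", "sum_sq"])
    rows = []
    for term, factor in zip(terms, fixed_factors):
        ss = float(aov.loc[term, "sum_sq"])
        dfree = float(aov.loc[term, "df"])
        rows.append(
            {
                "effect": factor,
                "SS": ss,
                "df": dfree,
                "MS": ss / dfree if dfree else np.nan,
                "F": float(aov.loc[term, "F"]),
                "p": float(aov.loc[term, "PR(>F)"]),
                "eta_sq": eta_squared(ss, ss_error),
            }
        )
    rows.append(
        {
            "effect": "Error",
            "SS": ss_error,
            "df": float(aov.loc["Residual", "df"]),
            "MS": ss_error / float(aov.loc["Residual", "df"]),
            "F": np.nan,
            "p": np.nan,
            "eta_sq": np.nan,
        }
    )
    return AnovaTable(pd.DataFrame(rows).set_index("effect"))


def correlate_occupancy_cessation(
    summaries: list[SubstrateTurnover],
) -> tuple[float, float]:
    """Pearson correlation of cessation rate against occupancy across
    substrates, with a one-tailed p-value for negative association."""
    pts = [
        (s.occupancy_mean, s.cessation_rate)
        for s in summaries
        if s.occupancy_mean is not None and s.cessation_rate is not None
    ]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 substrates with both rates, got {len(pts)}")
    occ, cess = zip(*pts)
    res = stats.pearsonr(occ, cess, alternative="less")
    return float(res.statistic), float(res.pvalue)
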