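"""Reproductive-success estimators and the pooled mixed model.

RS is chicks alive per nest at roughly 7-9 days after first hatch,
including the zeros from failed nests; RSS is the same mean restricted to
nests that reared at least one chick. The two are linked through the nest
failure rate by the exact identity RS = RSS * prop_successful. Colony
sizes are recorded in birds, nests in nests; since on average one male
breeds with two females, each two nests have three birds, giving the
conversion factors 2/3 (birds to nests) and 1.5 (nests to birds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy_dynamics import AnovaTable, anova_partition

__all__ = [
    "ReproductionRecord",
    "SubstrateRS",
    "nests_from_birds",
    "birds_from_nests",
    "reproductive_success",
    "success_metrics",
    "substrate_rs_summaries",
    "ReproductiveSuccessLMM",
    "fit_rs_lmm",
]

BIRDS_PER_NEST = 1.5  # each two nests have three birds
NESTS_PER_BIRD = 2.0 / 3.0


def nests_from_birds(n_breeding_birds: float) -> float:
    """Estimated nests constructed from a count of breeding birds (x 2/3)."""
    if n_breeding_birds < 0:
        raise ValueError("bird count must be >= 0")
    return n_breeding_birds * NESTS_PER_BIRD


def birds_from_nests(n_nests: float) -> float:
    """Estimated breeding birds from a nest count (x 1.5); exact inverse of
    :func:`nests_from_birds`."""
    if n_nests < 0:
        raise ValueError("nest count must be >= 0")
    return n_nests * BIRDS_PER_NEST


def reproductive_success(n_breeding_birds: float, n_fledglings: float) -> float:
    """RS: young fledged per nest constructed."""
    if n_breeding_birds <= 0:
        raise ValueError("RS undefined for zero breeding birds")
    if n_fledglings < 0:
        raise ValueError("fledgling count must be >= 0")
    return n_fledglings / nests_from_birds(n_breeding_birds)


def success_metrics(nest_sample: list[int] | np.ndarray) -> tuple[float | None, float, float]:
    """(rss, prop_successful, rs) from per-nest chick counts.

    rss is None when no nest succeeded. The identity
    rs = rss * prop_successful holds exactly by construction.
    """
    counts = np.asarray(nest_sample, dtype=float)
    if counts.size == 0:
        raise ValueError("empty nest sample")
    if (counts < 0).any():
        raise ValueError("chick counts must be >= 0")
    success = counts > 0
    prop = float(success.mean())
    rs = float(counts.mean())
    rss = float(counts[success].mean()) if success.any() else None
    return rss, prop, rs


@dataclass(frozen=True)
class ReproductionRecord:
    """One colony in one year: size, fledglings, and derived rates."""

    colony_id: str
    year: int
    substrate: str
    n_breeding_birds: float
    n_fledglings: float | None = None
    rs: float | None = None
    rss: float | None = None
    prop_successful: float | None = None
    observer: str = "meese"

    def __post_init__(self) -> None:
        if self.n_breeding_birds < 0:
            raise ValueError("n_breeding_birds must be >= 0")
        if self.n_fledglings is not None and self.n_fledglings < 0:
            raise ValueError("n_fledglings must be >= 0")

    def rs_value(self) -> float | None:
        """RS, derived from fledglings and birds when not given directly."""
        if self.rs is not None:
            return self.rs
        if self.n_fledglings is not None and self.n_breeding_birds > 0:
            return reproductive_success(self.n_breeding_birds, self.n_fledglings)
        return None


@dataclass
class SubstrateRS:
    substrate: str
    rs_mean: float
    rs_sd: float
    rs_se: float
    n_records: int
    rss_mean: float | None = None
    rss_se: float | None = None
    prop_successful_mean: float | None = None


def substrate_rs_summaries(
    records: list[ReproductionRecord], min_records: int = 5
) -> list[SubstrateRS]:
    """Raw per-substrate RS/RSS summaries with the minimum-records filter.

    Substrates with fewer than ``min_records`` RS values are dropped: small
    cells give unreliable estimates, mirroring the occupancy analyses.
    """
    rows = [
        (r.substrate, r.rs_value(), r.rss, r.prop_successful)
        for r in records
        if r.rs_value() is not None
    ]
    out = []
    df = pd.DataFrame(rows, columns=["substrate", "rs", "rss", "prop"])
    for sub, grp in df.groupby("substrate"):
        if len(grp) < min_records:
            continue
        rs = grp["rs"].to_numpy(dtype=float)
        rss = grp["rss"].dropna().to_numpy(dtype=float)
        prop = grp["prop"].dropna().to_numpy(dtype=float)
        out.append(
            SubstrateRS(
                substrate=sub,
                rs_mean=float(rs.mean()),
                rs_sd=float(rs.std(ddof=1)) if len(rs) > 1 else 0.0,
                rs_se=float(rs.std(ddof=1) / np.sqrt(len(rs))) if len(rs) > 1 else 0.0,
                n_records=len(rs),
                rss_mean=float(rss.mean()) if rss.size else None,
                rss_se=float(rss.std(ddof=1) / np.sqrt(len(rss))) if rss.size > 1 else None,
                prop_successful_mean=float(prop.mean()) if prop.size else None,
            )
        )
    return out


class ReproductiveSuccessLMM:
    """Linear mixed model for RS or RSS with a colony random intercept.

    Substrate is the fixed factor of interest (treatment coding); observer
    and year are assessed as candidate fixed effects and kept only if they
    lower the small-sample-corrected information criterion, mirroring how
    survey compilations from multiple observers are usually screened before
    pooling. The backend is statsmodels MixedLM fitted by ML.
    """

    def __init__(
        self,
        records: list[ReproductionRecord],
        response: str = "rs",
        min_records: int = 5,
        reference: str | None = None,
    ):
        if response not in ("rs", "rss"):
            raise ValueError("response must be 'rs' or 'rss'")
        rows = []
        for r in records:
            value = r.rs_value() if response == "rs" else r.rss
            if value is None:
                continue
            rows.append(
                {
                    "colony_id": r.colony_id,
                    "year": r.year,
                    "substrate": r.substrate,
                    "observer": r.observer,
                    "value": float(value),
                }
            )
        df = pd.DataFrame(rows)
        if df.empty:
            raise ValueError(f"no usable {response} records")
        keep = df.groupby("substrate")["value"].transform("size") >= min_records
        df = df[keep].reset_index(drop=True)
        if df.empty:
            raise ValueError("no substrate survives the minimum-records filter")
        self.data = df
        # with one substrate the model degenerates to intercept-only
        self.single_substrate = df["substrate"].nunique() < 2
        self.response = response
        self.reference = reference or sorted(df["substrate"].unique())[0]

    def _fit_formula(self, extra_terms: list[str]):
        import statsmodels.formula.api as smf

        terms = (
            [] if self.single_substrate
            else [f"C(substrate, Treatment({self.reference!r}))"]
        ) + extra_terms
        formula = "value ~ " + (" + ".join(terms) if terms else "1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, self.data, groups=self.data["colony_id"])
            fit = model.fit(reml=False)
        return fit

    @staticmethod
    def _aicc(fit) -> float:
        k = fit.params.size
        n = fit.nobs
        return float(-2 * fit.llf + 2 * k + 2 * k * (k + 1) / max(n - k - 1, 1))

    def fit(self) -> "ReproductiveSuccessResults":
        base = self._fit_formula([])
        kept: list[str] = []
        best_aicc = self._aicc(base)
        best = base
        # screen observer and year: keep only if AICc improves
        for term in ("C(observer)", "C(year)"):
            if term == "C(observer)" and self.data["observer"].nunique() < 2:
                continue
            if term == "C(year)" and self.data["year"].nunique() < 2:
                continue
            cand = self._fit_formula(kept + [term])
            if self._aicc(cand) < best_aicc:
                kept.append(term)
                best_aicc = self._aicc(cand)
                best = cand
        return ReproductiveSuccessResults(self, best, kept, best_aicc)


class ReproductiveSuccessResults:
    """Fitted RS/RSS mixed model with its ANOVA-style variance partition."""

    def __init__(self, model: ReproductiveSuccessLMM, fit, kept_terms, aicc):
        self.model = model
        self._fit = fit
        self.kept_terms = kept_terms
        self.aicc = aicc
        self.singular = bool(getattr(fit, "converged", True) is False)

    @property
    def llf(self) -> float:
        return float(self._fit.llf)

    @property
    def random_variance(self) -> float:
        v = float(np.asarray(self._fit.cov_re).ravel()[0])
        return max(v, 0.0)

    def fe_table(self) -> pd.DataFrame:
        fe = self._fit.fe_params
        bse = self._fit.bse_fe
        z = fe / bse
        from scipy import stats as sps

        return pd.DataFrame(
            {
                "term": fe.index,
                "estimate": fe.to_numpy(),
                "se": bse.to_numpy(),
                "z": z.to_numpy(),
                "p": 2 * sps.norm.sf(np.abs(z.to_numpy())),
            }
        )

    def substrate_mean(self, substrate: str) -> float:
        """Model-based mean for a substrate (intercept + difference term)."""
        fe = self._fit.fe_params
        mu = float(fe.iloc[0])
        if substrate == self.model.reference:
            return mu
        key = [i for i in fe.index if f"[T.{substrate}]" in i and "substrate" in i]
        if not key:
            raise KeyError(f"substrate {substrate!r} not in fitted levels")
        return mu + float(fe[key[0]])

    def anova(self) -> AnovaTable:
        factors = ["substrate"]
        if "C(observer)" in self.kept_terms:
            factors.append("observer")
        if "C(year)" in self.kept_terms:
            factors.append("year")
        return anova_partition(
            self.model.data,
            "value",
            factors,
            reference={"substrate": self.model.reference},
        )

    def summary(self) -> str:
        lines = [
            f"Linear mixed model for {self.model.response.upper()} "
            "(colony random intercept, ML)",
            f"n obs = {int(self._fit.nobs)}, n colonies = "
            f"{self.model.data['colony_id'].nunique()}, logLik = {self.llf:.3f}, "
            f"AICc = {self.aicc:.2f}",
            f"colony variance = {self.random_variance:.5f}",
            f"retained screening terms: {self.kept_terms or 'none'}",
            "",
            self.fe_table().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def fit_rs_lmm(
    records: list[ReproductionRecord],
    response: str = "rs",
    min_records: int = 5,
    reference: str | None = None,
) -> ReproductiveSuccessResults:
    """Fit the pooled RS/RSS mixed model (thin functional wrapper)."""
    return ReproductiveSuccessLMM(
        records, response=response, min_records=min_records, reference=reference
    ).fit()
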