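"""Time-averaged reproductive output per habitat substrate.

The habitat-value index combines three independently estimated
ingredients for each nesting substrate:

* mean recent colony size (birds), converted to nests (x 2/3) because
  reproductive success is per nest;
* mean reproductive success RS (chicks per nest);
* mean site occupancy (fraction of surveyed site-years occupied).

Predicted chicks per average colony is x = RS * (2/3) * birds. Its
standard deviation propagates the two proportional SDs (coefficients of
variation) s1 (colony size) and s2 (RS) as x * sqrt(s1^2 + s2^2) — the
first-order delta-method SD of a product of independent estimates. The
occupancy-adjusted output x * occupancy is chicks per site per year
averaged over occupied and vacant years, the quantity that ranks
substrates for conservation value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .occupancy_dynamics import SubstrateTurnover
from .reproduction import SubstrateRS, nests_from_birds

__all__ = [
    "HabitatValue",
    "DecadalSummary",
    "chicks_per_colony",
    "propagate_sd",
    "occupancy_adjusted_output",
    "decadal_summary",
    "habitat_value_table",
]

RECENT_WINDOW = (2000, 2011)
DECADES = (
    ("1980-1989", 1980, 1989),
    ("1990-1999", 1990, 1999),
    ("2000-2009", 2000, 2009),
    ("2010-11", 2010, 2011),
)


def chicks_per_colony(
    rs_mean: float, mean_colony_birds: float, convert_birds_to_nests: bool = True
) -> float:
    """Predicted chicks x for an average-size colony.

    RS is per nest while colony size is in birds, so the bird-to-nest
    factor (2/3) applies by default; ``convert_birds_to_nests=False``
    reports the unconverted product for comparison.
    """
    if rs_mean < 0 or mean_colony_birds < 0:
        raise ValueError("inputs must be >= 0")
    units = nests_from_birds(mean_colony_birds) if convert_birds_to_nests else mean_colony_birds
    return rs_mean * units


def propagate_sd(x: float, s1: float, s2: float) -> float:
    """SD of predicted chick production: x * sqrt(s1^2 + s2^2)."""
    if s1 < 0 or s2 < 0 or x < 0:
        raise ValueError("inputs must be >= 0")
    return x * math.hypot(s1, s2)


def occupancy_adjusted_output(x: float, occupancy: float) -> float:
    """Chicks per site per year: production discounted by occupancy."""
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy must be in [0, 1], got {occupancy}")
    return x * occupancy


@dataclass
class HabitatValue:
    substrate: str
    mean_colony_birds: float
    mean_nests: float
    rs_mean: float
    chicks_per_colony: float
    s1: float
    s2: float
    chicks_sd: float
    occupancy: float
    chicks_per_site_year: float


@dataclass
class DecadalSummary:
    decade: str
    table: pd.DataFrame  # per substrate: proportion, mean_ln_birds, se_ln_birds, n
    n_records: int


def decadal_summary(
    statewide: pd.DataFrame,
    recent_window: tuple[int, int] = RECENT_WINDOW,
) -> tuple[list[DecadalSummary], pd.DataFrame]:
    """Decadal substrate frequencies and log colony sizes, plus recent means.

    ``statewide`` needs columns substrate, year, n_birds. Records with
    n_birds <= 0 are excluded before the log transform (and counted out).
    The recent (2000-2011) per-substrate means are reported both as the
    arithmetic mean of birds and as the back-transformed mean of
    ln(birds) (the geometric mean), clearly labelled, since summaries of
    right-skewed colony sizes differ substantially between the two.
    """
    df = statewide.copy()
    df["n_birds"] = pd.to_numeric(df["n_birds"], errors="coerce")
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df = df.dropna(subset=["n_birds", "year"])
    df = df[df["n_birds"] > 0]
    df["ln_birds"] = np.log(df["n_birds"].astype(float))

    summaries = []
    for label, lo, hi in DECADES:
        dec = df[(df["year"] >= lo) & (df["year"] <= hi)]
        if dec.empty:
            continue
        rows = []
        for sub, grp in dec.groupby("substrate"):
            ln = grp["ln_birds"].to_numpy()
            rows.append(
                {
                    "substrate": sub,
                    "proportion": len(grp) / len(dec),
                    "mean_ln_birds": float(ln.mean()),
                    "se_ln_birds": float(ln.std(ddof=1) / np.sqrt(len(ln)))
                    if len(ln) > 1
                    else 0.0,
                    "n": len(grp),
                }
            )
        summaries.append(
            DecadalSummary(
                decade=label,
                table=pd.DataFrame(rows).set_index("substrate"),
                n_records=len(dec),
            )
        )

    lo, hi = recent_window
    recent = df[(df["year"] >= lo) & (df["year"] <= hi)]
    rec_rows = []
    for sub, grp in recent.groupby("substrate"):
        birds = grp["n_birds"].to_numpy(dtype=float)
        ln = grp["ln_birds"].to_numpy()
        rec_rows.append(
            {
                "substrate": sub,
                "mean_birds": float(birds.mean()),
                "geometric_mean_birds": float(np.exp(ln.mean())),
                "sd_birds": float(birds.std(ddof=1)) if len(birds) > 1 else 0.0,
                "n": len(birds),
            }
        )
    cols = ["substrate", "mean_birds", "geometric_mean_birds", "sd_birds", "n"]
    recent_table = pd.DataFrame(rec_rows, columns=cols).set_index("substrate")
    return summaries, recent_table


def habitat_value_table(
    rs_summaries: list[SubstrateRS],
    size_summaries: pd.DataFrame,
    turnover: list[SubstrateTurnover],
    convert_birds_to_nests: bool = True,
) -> tuple[list[HabitatValue], list[str]]:
    """Compose the habitat-value index per substrate.

    ``size_summaries`` is the recent-size table from
    :func:`decadal_summary` (index substrate, columns mean_birds,
    sd_birds). Substrates missing any of the three ingredients are omitted
    and listed in the returned log. Output order is by substrate label, so
    permuting input rows leaves the table unchanged.
    """
    rs_by_sub = {r.substrate: r for r in rs_summaries}
    occ_by_sub = {
        t.substrate: t.occupancy_mean for t in turnover if t.occupancy_mean is not None
    }
    substrates = (
        set(rs_by_sub) | set(size_summaries.index) | set(occ_by_sub)
    )
    values: list[HabitatValue] = []
    skipped: list[str] = []
    for sub in sorted(substrates):
        missing = []
        if sub not in rs_by_sub:
            missing.append("reproductive success")
        if sub not in size_summaries.index:
            missing.append("colony size")
        if sub not in occ_by_sub:
            missing.append("occupancy")
        if missing:
            skipped.append(f"{sub}: missing {', '.join(missing)}")
            continue
        rs = rs_by_sub[sub]
        birds = float(size_summaries.loc[sub, "mean_birds"])
        sd_birds = float(size_summaries.loc[sub, "sd_birds"])
        x = chicks_per_colony(rs.rs_mean, birds, convert_birds_to_nests)
        s1 = sd_birds / birds if birds > 0 else 0.0
        s2 = rs.rs_sd / rs.rs_mean if rs.rs_mean > 0 else 0.0
        occ = occ_by_sub[sub]
        values.append(
            HabitatValue(
                substrate=sub,
                mean_colony_birds=birds,
                mean_nests=nests_from_birds(birds),
                rs_mean=rs.rs_mean,
                chicks_per_colony=x,
                s1=s1,
                s2=s2,
                chicks_sd=propagate_sd(x, s1, s2),
                occupancy=occ,
                chicks_per_site_year=occupancy_adjusted_output(x, occ),
            )
        )
    if not values:
        raise ValueError("no substrate has all three ingredients: " + "; ".join(skipped))
    return values, skipped


def habitat_value_frame(values: list[HabitatValue]) -> pd.DataFrame:
    """Tabular view of the index, ordered by adjusted output descending."""
    df = pd.DataFrame([vars(v) for v in values])
    return df.sort_values("chicks_per_site_year", ascending=False).reset_index(drop=True)
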