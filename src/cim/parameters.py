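"""Model parameters for the cycle-network investment model.

Holds the three packaged parameter tables — age-band incidence/mortality/
case-fatality probabilities, relative risks (disease given activity and
mortality given disease), and cost/utility values — and derives the
activity-stratified transition inputs that the Markov engine consumes:
incidence split into active/inactive strata via population-attributable
fractions (PAF) and protective relative risks, and state-specific annual
death probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "AgeBandRates",
    "AgeBandTable",
    "RelativeRisk",
    "RelativeRiskSet",
    "CostUtilityParams",
    "PAFSet",
    "ActivityMix",
    "ParameterBundle",
    "ParameterValidationError",
    "load_parameters",
    "derive_activity_mix",
    "incidence_by_activity",
    "mixture_consistency_gap",
    "mortality_in_state",
]

#: Disease states modelled, in canonical order.
DISEASES = ("chd", "stroke", "t2d", "cancer")

#: Lower age bound of each band; ages beyond the last bound use the open band.
BAND_LOWER_BOUNDS = (30, 35, 40, 45, 50, 55, 60, 65, 70)
BAND_LABELS = ("30-34", "35-39", "40-44", "45-49", "50-54",
               "55-59", "60-64", "65-69", "70+")


class ParameterValidationError(ValueError):
    """A parameter table failed validation; the message names the cell."""


@dataclass(frozen=True)
class AgeBandRates:
    """Annual event probabilities for one five-year age band.

    ``inc_*`` are population-level annual incidence probabilities,
    ``mort_cvd``/``mort_allcause`` annual death probabilities, and
    ``cfr_*`` the probability that an incident CHD/stroke event is
    immediately fatal.
    """

    age_band: str
    inc_t2d: float
    inc_cancer: float
    inc_stroke: float
    inc_chd: float
    mort_cvd: float
    mort_allcause: float
    cfr_chd: float
    cfr_stroke: float

    def __post_init__(self) -> None:
        for name in ("inc_t2d", "inc_cancer", "inc_stroke", "inc_chd",
                     "mort_cvd", "mort_allcause", "cfr_chd", "cfr_stroke"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterValidationError(
                    f"{name} for band {self.age_band} is {v}, outside [0, 1]")
        if self.mort_cvd > self.mort_allcause:
            raise ParameterValidationError(
                f"mort_cvd exceeds mort_allcause in band {self.age_band}")

    def incidence(self, disease: str) -> float:
        return getattr(self, f"inc_{disease}")

    @property
    def other_cause_mortality(self) -> float:
        """Annual background mortality net of CVD (all-cause minus CVD)."""
        return self.mort_allcause - self.mort_cvd


class AgeBandTable:
    """Ordered collection of :class:`AgeBandRates` with age lookup."""

    def __init__(self, bands: list[AgeBandRates]):
        if [b.age_band for b in bands] != list(BAND_LABELS):
            raise ParameterValidationError(
                "age-band table must contain exactly the bands "
                + ", ".join(BAND_LABELS) + " in order")
        self.bands = bands
        self._check_monotone()

    def _check_monotone(self) -> None:
        # Incidence/mortality generally rise with age; violations are
        # surfaced as warnings (the packaged data itself has one: T2D
        # incidence dips from 0.0106 at 60-64 to 0.0105 at 65-69).
        cols = ("inc_t2d", "inc_cancer", "inc_stroke", "inc_chd",
                "mort_cvd", "mort_allcause")
        for col in cols:
            vals = [getattr(b, col) for b in self.bands]
            if any(b < a for a, b in zip(vals, vals[1:])):
                warnings.warn(
                    f"column {col} is not non-decreasing across age bands",
                    stacklevel=3)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def band_index_for_age(self, age: float) -> int:
        """Index of the band containing integer ``age``; ages past the last
        bound use the open (70+) band, ages below the first use the first."""
        idx = int(np.searchsorted(BAND_LOWER_BOUNDS, int(age), side="right")) - 1
        return min(max(idx, 0), len(self.bands) - 1)

    def band_for_age(self, age: float) -> AgeBandRates:
        return self.bands[self.band_index_for_age(age)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(b) for b in self.bands]).set_index("age_band")


@dataclass(frozen=True)
class RelativeRisk:
    """A relative risk with its printed 95% CI and PSA distribution family."""

    base: float
    lower: float
    upper: float
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.base > 0:
            raise ParameterValidationError(f"relative risk {self.base} must be > 0")
        if not self.lower <= self.base <= self.upper:
            raise ParameterValidationError(
                f"CI bounds ({self.lower}, {self.upper}) do not bracket "
                f"base value {self.base}")


@dataclass
class RelativeRiskSet:
    """Relative risks per disease.

    ``mortality[d]`` is the mortality RR of individuals in disease state
    ``d`` relative to the reference mortality stream named by
    ``mortality_reference[d]`` ('cvd' or 'all_cause'); ``disease_active[d]``
    is the incidence RR of active vs inactive individuals (< 1, protective).
    """

    mortality: dict[str, RelativeRisk]
    disease_active: dict[str, RelativeRisk]
    mortality_reference: dict[str, str]

    def __post_init__(self) -> None:
        for d in DISEASES:
            if d not in self.mortality or d not in self.disease_active:
                raise ParameterValidationError(f"missing relative risks for {d}")
            if self.disease_active[d].base >= 1.0:
                raise ParameterValidationError(
                    f"disease RR (active vs inactive) for {d} is "
                    f"{self.disease_active[d].base}; protective RRs must be < 1")
            ref = self.mortality_reference.get(d)
            if ref not in ("cvd", "all_cause"):
                raise ParameterValidationError(
                    f"mortality_reference for {d} must be 'cvd' or 'all_cause'")


# Table 3 field names carrying PSA uncertainty, in file order (the PSA
# draw order contract depends on this ordering).
UNCERTAIN_COST_FIELDS = ("invest_per_capita", "maint_per_capita",
                         "cost_chd_first", "cost_chd_post",
                         "cost_stroke_first", "cost_stroke_post",
                         "cost_t2d", "cost_cancer")
UNCERTAIN_UTILITY_FIELDS = ("util_cancer", "util_chd1", "util_chd1plus",
                            "util_stroke1", "util_stroke1plus", "util_t2d",
                            "wellbeing_gain_active")


@dataclass
class CostUtilityParams:
    """Costs (2017 USD) and state utility weights.

    Intervention costs are per-capita *per km* of network built; annual
    disease costs attach to disease states; utilities weight each year of
    state occupancy; ``wellbeing_gain_active`` is the additional utility
    per year from meeting the physical-activity recommendation.
    """

    invest_total: float
    invest_per_capita: float
    maint_total: float
    maint_per_capita: float
    cost_chd_first: float
    cost_chd_post: float
    cost_stroke_first: float
    cost_stroke_post: float
    cost_t2d: float
    cost_cancer: float
    util_healthy: float
    util_cancer: float
    util_chd1: float
    util_chd1plus: float
    util_stroke1: float
    util_stroke1plus: float
    util_t2d: float
    wellbeing_gain_active: float
    #: name -> (sd, distribution family) for parameters varied in PSA
    uncertainty: dict[str, tuple[float, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("invest_total", "invest_per_capita", "maint_total",
                     "maint_per_capita", "cost_chd_first", "cost_chd_post",
                     "cost_stroke_first", "cost_stroke_post", "cost_t2d",
                     "cost_cancer"):
            if getattr(self, name) < 0:
                raise ParameterValidationError(f"{name} must be >= 0")
        for name in ("util_healthy", "util_cancer", "util_chd1",
                     "util_chd1plus", "util_stroke1", "util_stroke1plus",
                     "util_t2d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterValidationError(
                    f"{name} is {v}, outside [0, 1]")
        if self.util_healthy != 1.0:
            raise ParameterValidationError("util_healthy must equal 1")
        if self.wellbeing_gain_active < 0:
            raise ParameterValidationError("wellbeing_gain_active must be >= 0")

    def utility(self, state_field: str) -> float:
        return getattr(self, state_field)


@dataclass
class PAFSet:
    """Population-attributable fractions of incidence due to inactivity.

    CHD 6%, T2D 7% and cancer 10% as reported; stroke is not reported and
    defaults to the CHD value (both are CVD outcomes) but is overridable.
    """

    paf_chd: float = 0.06
    paf_t2d: float = 0.07
    paf_cancer: float = 0.10
    paf_stroke: float = 0.06

    def __post_init__(self) -> None:
        for d in DISEASES:
            v = getattr(self, f"paf_{d}")
            if not 0.0 <= v < 1.0:
                raise ParameterValidationError(
                    f"paf_{d} is {v}, outside [0, 1)")

    def __getitem__(self, disease: str) -> float:
        return getattr(self, f"paf_{disease}")


@dataclass(frozen=True)
class ActivityMix:
    """Initial split of a cohort into cyclist / active / inactive strata.

    All cyclists are physically active; a fraction
    ``p_active_noncyclist`` of non-cyclists meets the activity
    recommendation through other means. The mix is fixed for the whole
    horizon — individuals settle into a stratum and do not move.
    """

    share_cycling: float
    p_active_noncyclist: float = 0.286

    def __post_init__(self) -> None:
        for name in ("share_cycling", "p_active_noncyclist"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterValidationError(f"{name} is {v}, outside [0, 1]")

    @property
    def p_cyclist(self) -> float:
        return self.share_cycling

    @property
    def p_active_nc(self) -> float:
        return (1.0 - self.share_cycling) * self.p_active_noncyclist

    @property
    def p_active(self) -> float:
        """Total physically active fraction (cyclists + active non-cyclists)."""
        return self.share_cycling + (1.0 - self.share_cycling) * self.p_active_noncyclist

    @property
    def p_inactive(self) -> float:
        return 1.0 - self.p_active

    @property
    def stratum_weights(self) -> dict[str, float]:
        return {"cyclist": self.p_cyclist,
                "active": self.p_active_nc,
                "inactive": self.p_inactive}


@dataclass
class ParameterBundle:
    """Everything the Markov engine needs: rates, RRs, costs, PAFs."""

    age_rates: AgeBandTable
    relative_risks: RelativeRiskSet
    costs: CostUtilityParams
    pafs: PAFSet


def _data_dir() -> Path:
    return Path(str(resources.files("cim").joinpath("data")))


def load_parameters(path: str | Path | None = None) -> ParameterBundle:
    """Load the packaged parameter tables (or a directory of overrides).

    Parameters
    ----------
    path
        Directory containing ``table1_age_rates.csv``,
        ``table2_relative_risks.csv`` and ``table3_costs_utilities.csv``.
        ``None`` loads the packaged defaults.

    Returns
    -------
    ParameterBundle
        Fully validated parameter set.
    """
    base = _data_dir() if path is None else Path(path)
    t1 = base / "table1_age_rates.csv"
    t2 = base / "table2_relative_risks.csv"
    t3 = base / "table3_costs_utilities.csv"
    for f in (t1, t2, t3):
        if not f.exists():
            raise FileNotFoundError(f)

    df1 = pd.read_csv(t1)
    required = {"age_band", "inc_t2d", "inc_cancer", "inc_stroke", "inc_chd",
                "mort_cvd", "mort_allcause", "cfr_chd", "cfr_stroke"}
    missing = required - set(df1.columns)
    if missing:
        raise ParameterValidationError(
            f"table1 is missing columns: {sorted(missing)}")
    bands = [AgeBandRates(**{k: (row[k] if k == "age_band" else float(row[k]))
                             for k in required}) for _, row in df1.iterrows()]
    bands.sort(key=lambda b: BAND_LABELS.index(b.age_band))
    table = AgeBandTable(bands)

    df2 = pd.read_csv(t2)
    mortality: dict[str, RelativeRisk] = {}
    disease_active: dict[str, RelativeRisk] = {}
    mort_ref: dict[str, str] = {}
    for _, row in df2.iterrows():
        rr = RelativeRisk(base=float(row["base"]), lower=float(row["lower"]),
                          upper=float(row["upper"]),
                          distribution=str(row["distribution"]).lower())
        d = str(row["disease"]).lower()
        if row["kind"] == "mortality":
            mortality[d] = rr
            mort_ref[d] = str(row["mortality_reference"]).strip()
        elif row["kind"] == "disease_active":
            disease_active[d] = rr
        else:
            raise ParameterValidationError(
                f"unknown relative-risk kind {row['kind']!r} for {d}")
    rrset = RelativeRiskSet(mortality=mortality, disease_active=disease_active,
                            mortality_reference=mort_ref)

    df3 = pd.read_csv(t3).set_index("name")
    fields = {}
    uncertainty = {}
    for name in ("invest_total", "invest_per_capita", "maint_total",
                 "maint_per_capita", "cost_chd_first", "cost_chd_post",
                 "cost_stroke_first", "cost_stroke_post", "cost_t2d",
                 "cost_cancer", "util_healthy", "util_cancer", "util_chd1",
                 "util_chd1plus", "util_stroke1", "util_stroke1plus",
                 "util_t2d", "wellbeing_gain_active"):
        if name not in df3.index:
            raise ParameterValidationError(f"table3 is missing row {name!r}")
        fields[name] = float(df3.loc[name, "value"])
        sd = df3.loc[name, "sd"]
        dist = df3.loc[name, "distribution"]
        if pd.notna(sd) and pd.notna(dist):
            uncertainty[name] = (float(sd), str(dist).lower())
    costs = CostUtilityParams(**fields, uncertainty=uncertainty)

    return ParameterBundle(age_rates=table, relative_risks=rrset,
                           costs=costs, pafs=PAFSet())


def derive_activity_mix(share_cycling: float,
                        p_active_noncyclist: float = 0.286) -> ActivityMix:
    """Split a cohort into activity strata given the cycling mode share.

    ``p_active = share + (1 - share) * p_active_noncyclist``; the remainder
    is inactive (below 150 min/week of moderate activity).
    """
    return ActivityMix(share_cycling=share_cycling,
                       p_active_noncyclist=p_active_noncyclist)


def incidence_by_activity(inc_pop: float, paf: float,
                          rr_active: float) -> tuple[float, float]:
    """Split a population incidence into active and inactive strata.

    The PAF identity gives the counterfactual all-active incidence
    ``inc_pop * (1 - paf)``; dividing by the protective RR (active vs
    inactive, <= 1) recovers the inactive incidence.

    Returns
    -------
    (inc_active, inc_inactive)
        Annual incidence probabilities per stratum. The inactive value is
        clipped to 1 with a warning should the derivation exceed it.
    """
    if not 0.0 <= inc_pop <= 1.0:
        raise ParameterValidationError(f"inc_pop {inc_pop} outside [0, 1]")
    if not 0.0 <= paf < 1.0:
        raise ParameterValidationError(f"paf {paf} outside [0, 1)")
    if not 0.0 < rr_active <= 1.0:
        raise ParameterValidationError(f"rr_active {rr_active} outside (0, 1]")
    inc_active = inc_pop * (1.0 - paf)
    inc_inactive = inc_active / rr_active
    if inc_inactive > 1.0:
        warnings.warn(
            f"derived inactive incidence {inc_inactive:.4g} exceeds 1; clipped",
            stacklevel=2)
        inc_inactive = 1.0
    return inc_active, inc_inactive


def mixture_consistency_gap(inc_pop: float, paf: float, rr_active: float,
                            p_inactive: float) -> float:
    """Diagnostic: mixture-implied incidence minus the population incidence.

    The active/inactive split reproduces ``inc_pop`` exactly only when the
    supplied PAF is internally consistent with the inactive prevalence and
    1/rr_active; the signed gap lets that calibration be audited.
    """
    inc_a, inc_i = incidence_by_activity(inc_pop, paf, rr_active)
    implied = (1.0 - p_inactive) * inc_a + p_inactive * inc_i
    return implied - inc_pop


def mortality_in_state(band: AgeBandRates, disease: str,
                       rrs: RelativeRiskSet) -> float:
    """Annual death probability while in a chronic disease state.

    For CHD/stroke/T2D the mortality RR multiplies the band's CVD
    mortality, with background other-cause mortality (all-cause minus CVD)
    added; for cancer the RR multiplies all-cause mortality directly.
    Capped at 1.
    """
    d = disease.lower().replace("post-", "").replace("post_", "")
    if d not in DISEASES:
        raise ParameterValidationError(f"unknown disease label {disease!r}")
    rr = rrs.mortality[d].base
    if rrs.mortality_reference[d] == "all_cause":
        p = rr * band.mort_allcause
    else:
        p = rr * band.mort_cvd + band.other_cause_mortality
    return min(1.0, p)
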