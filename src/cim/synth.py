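"""Synthetic inputs with the statistical structure the analysis assumes.

The city generator emulates a European city table: populations
log-uniform above 100,000, network densities lognormal, and mode share
following a saturating-exponential (concave, diminishing-returns) curve
with Gaussian noise — giving an analytic ground-truth curve and mean
derivative for regression-recovery tests. The parameter-fixture generator
jitters the packaged model tables within their legal ranges.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    DISEASES,
    AgeBandRates,
    AgeBandTable,
    ParameterBundle,
    RelativeRisk,
    RelativeRiskSet,
    load_parameters,
)

__all__ = ["CityGeneratorSpec", "CityGroundTruth", "generate_city_data",
           "generate_param_fixture"]


@dataclass(frozen=True)
class CityGeneratorSpec:
    """Generating process for a synthetic city table.

    Mode share (%) follows ``s_max * (1 - exp(-k * x))`` in the network
    density ``x`` (km per 100,000 population), plus Gaussian noise,
    truncated to [0, 100].
    """

    n_cities: int = 123
    pop_min: float = 100_000.0
    pop_max: float = 3_000_000.0
    length_median: float = 20.0     # km per 100k, lognormal median
    length_sigma: float = 0.8       # lognormal sigma on the log scale
    s_max: float = 30.0             # saturation share, %
    k: float = 0.012                # curvature per km-per-100k
    noise_sd: float = 3.0           # share noise, percentage points

    def curve(self, x: np.ndarray | float) -> np.ndarray | float:
        """Noise-free generating curve (share % at density x)."""
        return self.s_max * (1.0 - np.exp(-self.k * np.asarray(x, dtype=float)))

    def derivative(self, x: np.ndarray | float) -> np.ndarray | float:
        """Exact derivative s_max * k * exp(-k x) of the generating curve."""
        return self.s_max * self.k * np.exp(-self.k * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class CityGroundTruth:
    """Generating function and its mean derivative over the realized sample."""

    spec: CityGeneratorSpec
    x: np.ndarray
    mean_derivative: float

    def curve(self, x):
        return self.spec.curve(x)

    def derivative(self, x):
        return self.spec.derivative(x)


def generate_city_data(spec: CityGeneratorSpec = CityGeneratorSpec(),
                       seed: int = 0) -> tuple[pd.DataFrame, CityGroundTruth]:
    """Draw a synthetic city table plus its ground truth.

    Returns
    -------
    (cities, truth)
        ``cities`` has the canonical columns (city, country, population,
        network_km, mode_share_pct, network_km_per_100k); ``truth``
        carries the noise-free curve and the mean of its exact derivative
        over the realized densities, the recovery target for the
        average-marginal-effect estimator.
    """
    if spec.n_cities < 1:
        raise ValueError("n_cities must be >= 1")
    rng = np.random.default_rng(seed)
    pop = np.exp(rng.uniform(np.log(spec.pop_min), np.log(spec.pop_max),
                             spec.n_cities))
    x = rng.lognormal(np.log(spec.length_median), spec.length_sigma,
                      spec.n_cities)
    share = spec.curve(x) + rng.normal(0.0, spec.noise_sd, spec.n_cities)
    share = np.clip(share, 0.0, 100.0)
    cities = pd.DataFrame({
        "city": [f"city_{i:03d}" for i in range(spec.n_cities)],
        "country": ["synthetic"] * spec.n_cities,
        "population": np.round(pop).astype(int),
        "network_km": x * pop / 100_000.0,
        "mode_share_pct": share,
    })
    cities["network_km_per_100k"] = (cities.network_km
                                     / (cities.population / 100_000.0))
    truth = CityGroundTruth(spec=spec, x=x,
                            mean_derivative=float(np.mean(spec.derivative(x))))
    return cities, truth


def generate_param_fixture(perturbation_sd: float = 0.1, seed: int = 0,
                           ) -> tuple[ParameterBundle, int]:
    """Packaged parameter tables with multiplicative lognormal jitter.

    Every rate, cost and utility is scaled by exp(sd * z); results are
    clipped back into their legal ranges (probabilities and utilities to
    [0, 1], CVD mortality capped by all-cause, protective RRs kept below
    1) and the number of clipped values is reported. ``sd = 0`` returns
    the packaged values exactly.
    """
    if perturbation_sd < 0:
        raise ValueError("perturbation sd must be >= 0")
    base = load_parameters()
    if perturbation_sd == 0:
        return base, 0
    rng = np.random.default_rng(seed)
    n_clipped = 0

    def jitter(v: float, lo: float = 0.0, hi: float = np.inf) -> float:
        nonlocal n_clipped
        out = v * float(np.exp(rng.normal(0.0, perturbation_sd)))
        if out < lo or out > hi:
            n_clipped += 1
            out = min(max(out, lo), hi)
        return out

    bands = []
    for b in base.age_rates:
        mort_all = jitter(b.mort_allcause, 0.0, 1.0)
        bands.append(AgeBandRates(
            age_band=b.age_band,
            inc_t2d=jitter(b.inc_t2d, 0.0, 1.0),
            inc_cancer=jitter(b.inc_cancer, 0.0, 1.0),
            inc_stroke=jitter(b.inc_stroke, 0.0, 1.0),
            inc_chd=jitter(b.inc_chd, 0.0, 1.0),
            mort_allcause=mort_all,
            mort_cvd=jitter(b.mort_cvd, 0.0, mort_all),
            cfr_chd=jitter(b.cfr_chd, 0.0, 1.0),
            cfr_stroke=jitter(b.cfr_stroke, 0.0, 1.0)))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # jitter breaks age monotonicity
        table = AgeBandTable(bands)

    def jitter_rr(rr: RelativeRisk, hi: float = np.inf) -> RelativeRisk:
        nonlocal n_clipped
        f = float(np.exp(rng.normal(0.0, perturbation_sd)))
        b_ = min(rr.base * f, hi)
        if b_ != rr.base * f:
            n_clipped += 1
        return RelativeRisk(base=b_, lower=min(rr.lower * f, b_),
                            upper=max(rr.upper * f, b_),
                            distribution=rr.distribution)

    rrs = RelativeRiskSet(
        mortality={d: jitter_rr(base.relative_risks.mortality[d])
                   for d in DISEASES},
        disease_active={d: jitter_rr(base.relative_risks.disease_active[d],
                                     hi=1.0 - 1e-9) for d in DISEASES},
        mortality_reference=dict(base.relative_risks.mortality_reference))

    costs = copy.deepcopy(base.costs)
    for name in ("invest_total", "invest_per_capita", "maint_total",
                 "maint_per_capita", "cost_chd_first", "cost_chd_post",
                 "cost_stroke_first", "cost_stroke_post", "cost_t2d",
                 "cost_cancer"):
        setattr(costs, name, jitter(getattr(costs, name)))
    for name in ("util_cancer", "util_chd1", "util_chd1plus",
                 "util_stroke1", "util_stroke1plus", "util_t2d",
                 "wellbeing_gain_active"):
        setattr(costs, name, jitter(getattr(costs, name), 0.0, 1.0))

    return ParameterBundle(age_rates=table, relative_risks=rrs,
                           costs=costs, pafs=copy.deepcopy(base.pafs)), n_clipped
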