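"""Probabilistic sensitivity analysis.

Costs follow gamma distributions, utility weights beta, and relative
risks lognormal (method-of-moments for gamma/beta, CI-based sigma for
lognormal). Each iteration draws one parameter set — shared by both arms,
which differ only in cycling share and intervention cost — runs the full
cohort model, and records the incremental cost and QALY pair. The
cost-effectiveness acceptability curve (CEAC) is the fraction of draws
with positive net monetary benefit across a threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import engine
from .engine import ModelConfig, mix_for_share
from .parameters import (
    DISEASES,
    CostUtilityParams,
    ParameterBundle,
    RelativeRisk,
    RelativeRiskSet,
    UNCERTAIN_COST_FIELDS,
    UNCERTAIN_UTILITY_FIELDS,
)

__all__ = ["UncertainParam", "PSAResult", "natural_params", "sample_param",
           "default_uncertain_set", "run_psa", "ceac"]

#: Table 2 relative risks in file order — the documented PSA draw order
#: starts with these, then the Table 3 costs/utilities in file order.
_RR_ORDER = (("mortality", "chd"), ("mortality", "stroke"),
             ("mortality", "t2d"), ("mortality", "cancer"),
             ("disease_active", "cancer"), ("disease_active", "chd"),
             ("disease_active", "stroke"), ("disease_active", "t2d"))


@dataclass(frozen=True)
class UncertainParam:
    """One uncertain model parameter and its sampling distribution.

    Gamma and beta are parameterized by (mean, sd); lognormal by the
    point estimate with its printed 95% CI.
    """

    name: str
    family: str
    mean: float | None = None
    sd: float | None = None
    base: float | None = None
    lower: float | None = None
    upper: float | None = None


def natural_params(p: UncertainParam) -> dict[str, float]:
    """Natural distribution parameters from the reported moments.

    gamma: shape = mean^2/sd^2, scale = sd^2/mean.
    beta:  alpha = mean * nu, beta = (1-mean) * nu with
           nu = mean(1-mean)/sd^2 - 1.
    lognormal: sigma = (ln upper - ln lower) / (2 * 1.96), mu = ln(base).
    """
    if p.family == "gamma":
        if p.mean is None or p.sd is None or p.mean <= 0 or p.sd <= 0:
            raise ValueError(f"gamma parameter {p.name} needs mean, sd > 0")
        return {"shape": p.mean ** 2 / p.sd ** 2, "scale": p.sd ** 2 / p.mean}
    if p.family == "beta":
        if p.mean is None or p.sd is None or not 0 < p.mean < 1:
            raise ValueError(f"beta parameter {p.name} needs mean in (0,1)")
        if p.sd ** 2 >= p.mean * (1 - p.mean):
            raise ValueError(
                f"beta parameter {p.name}: sd^2 = {p.sd**2:.4g} is not below "
                f"mean(1-mean) = {p.mean * (1 - p.mean):.4g}")
        nu = p.mean * (1 - p.mean) / p.sd ** 2 - 1
        return {"alpha": p.mean * nu, "beta": (1 - p.mean) * nu}
    if p.family == "lognormal":
        if p.base is None or p.lower is None or p.upper is None \
                or not 0 < p.lower <= p.base <= p.upper:
            raise ValueError(
                f"lognormal parameter {p.name} needs 0 < lower <= base <= upper")
        return {"mu": np.log(p.base),
                "sigma": (np.log(p.upper) - np.log(p.lower)) / (2 * 1.96)}
    raise ValueError(f"unknown distribution family {p.family!r}")


def sample_param(p: UncertainParam, rng: np.random.Generator) -> float:
    """One draw; degenerate parameters (sd = 0, collapsed CI) return the
    point estimate so the PSA reduces to the deterministic model."""
    if p.family in ("gamma", "beta") and p.sd == 0:
        return float(p.mean)
    if p.family == "lognormal" and p.lower == p.upper:
        return float(p.base)
    nat = natural_params(p)
    if p.family == "gamma":
        return float(rng.gamma(nat["shape"], nat["scale"]))
    if p.family == "beta":
        return float(rng.beta(nat["alpha"], nat["beta"]))
    return float(rng.lognormal(nat["mu"], nat["sigma"]))


def default_uncertain_set(params: ParameterBundle) -> list[UncertainParam]:
    """Uncertain parameters in the documented draw order.

    Only the relative risks (lognormal, printed CIs) and the costs and
    utilities carrying a printed sd vary; the age-band incidence,
    mortality and case-fatality probabilities are fixed, as no dispersion
    is reported for them.
    """
    out: list[UncertainParam] = []
    for kind, d in _RR_ORDER:
        table = (params.relative_risks.mortality if kind == "mortality"
                 else params.relative_risks.disease_active)
        rr = table[d]
        out.append(UncertainParam(name=f"rr_{kind}_{d}", family="lognormal",
                                  base=rr.base, lower=rr.lower,
                                  upper=rr.upper))
    c = params.costs
    for name in UNCERTAIN_COST_FIELDS + UNCERTAIN_UTILITY_FIELDS:
        if name not in c.uncertainty:
            continue
        sd, family = c.uncertainty[name]
        out.append(UncertainParam(name=name, family=family,
                                  mean=getattr(c, name), sd=sd))
    return out


def _bundle_from_draw(base: ParameterBundle,
                      vals: dict[str, float]) -> tuple[ParameterBundle, int]:
    """Parameter bundle with drawn values substituted; protective disease
    RRs drawn at or above 1 are clipped just below 1 (counted)."""
    n_clipped = 0
    mortality = {}
    disease_active = {}
    for kind, d in _RR_ORDER:
        table = (base.relative_risks.mortality if kind == "mortality"
                 else base.relative_risks.disease_active)
        old = table[d]
        v = vals.get(f"rr_{kind}_{d}", old.base)
        if kind == "disease_active" and v >= 1.0:
            v = 1.0 - 1e-9
            n_clipped += 1
        rr = RelativeRisk(base=v, lower=min(v, old.lower),
                          upper=max(v, old.upper),
                          distribution=old.distribution)
        (mortality if kind == "mortality" else disease_active)[d] = rr
    rrs = RelativeRiskSet(mortality=mortality, disease_active=disease_active,
                          mortality_reference=dict(
                              base.relative_risks.mortality_reference))
    c = base.costs
    fields = {name: vals.get(name, getattr(c, name))
              for name in ("invest_total", "invest_per_capita", "maint_total",
                           "maint_per_capita", "cost_chd_first",
                           "cost_chd_post", "cost_stroke_first",
                           "cost_stroke_post", "cost_t2d", "cost_cancer",
                           "util_healthy", "util_cancer", "util_chd1",
                           "util_chd1plus", "util_stroke1", "util_stroke1plus",
                           "util_t2d", "wellbeing_gain_active")}
    costs = CostUtilityParams(**fields, uncertainty=c.uncertainty)
    return ParameterBundle(age_rates=base.age_rates, relative_risks=rrs,
                           costs=costs, pafs=base.pafs), n_clipped


@dataclass
class PSAResult:
    """Draws, CEAC and summary of one probabilistic sensitivity analysis."""

    draws: pd.DataFrame
    ceac: pd.DataFrame
    p_ce_at_threshold: float
    threshold: float
    seed: int
    n_iterations: int
    n_clipped: int

    @property
    def icer_of_means(self) -> float | None:
        dq = self.draws["d_qaly"].mean()
        return None if dq <= 0 else float(self.draws["d_cost"].mean() / dq)


def ceac(d_cost: np.ndarray, d_qaly: np.ndarray,
         threshold_grid: np.ndarray) -> np.ndarray:
    """P(cost-effective) = fraction of draws with positive NMB per threshold."""
    d_cost = np.asarray(d_cost, dtype=float)
    d_qaly = np.asarray(d_qaly, dtype=float)
    if d_cost.size == 0:
        raise ValueError("ceac needs at least one draw")
    nmb = np.multiply.outer(np.asarray(threshold_grid, dtype=float), d_qaly) \
        - d_cost
    return (nmb > 0).mean(axis=1)


def _arm_totals_from_kind(config: ModelConfig, params: ParameterBundle,
                          ) -> dict[str, tuple[float, float]]:
    """Discounted (cost, qaly) per unit cohort of each risk profile."""
    disc = config.discount_factors
    out = {}
    for kind in ("active", "inactive"):
        occ = engine._unit_trace(engine._kind_matrices(config, params, kind))
        cost_vec, util_vec = engine._reward_vectors(
            params, kind, config.wellbeing_scope)
        cs, qs = engine._unit_streams(occ, cost_vec, util_vec, disc,
                                      config.half_cycle_correction)
        out[kind] = (float(cs.sum()), float(qs.sum()))
    return out


def run_psa(config: ModelConfig, params: ParameterBundle, n: int = 10_000,
            seed: int = 0, uncertain: list[UncertainParam] | None = None,
            threshold_grid: np.ndarray | None = None) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through both arms.

    Each iteration samples every uncertain parameter once (in the
    documented order, from a single seeded generator) and evaluates both
    arms with the shared draw; the arms differ only in cycling share and
    intervention cost. The cohort trace is linear in its initial stratum
    mix, so one active and one inactive unit cohort per draw suffice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if uncertain is None:
        uncertain = default_uncertain_set(params)
    if threshold_grid is None:
        threshold_grid = np.arange(0.0, 150_001.0, 1000.0)

    mix_sq = mix_for_share(config, config.share_cycling_sq)
    mix_int = mix_for_share(config, config.share_cycling_int)
    w_sq = (mix_sq.p_cyclist + mix_sq.p_active_nc, mix_sq.p_inactive)
    w_int = (mix_int.p_cyclist + mix_int.p_active_nc, mix_int.p_inactive)
    disc_sum = config.discount_factors.sum()
    km = config.network_km_built

    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    n_clipped = 0
    for i in range(n):
        vals = {p.name: sample_param(p, rng) for p in uncertain}
        bundle, clipped = _bundle_from_draw(params, vals)
        n_clipped += clipped
        kind = _arm_totals_from_kind(config, bundle)
        (ca, qa), (ci_, qi) = kind["active"], kind["inactive"]
        cost_sq = w_sq[0] * ca + w_sq[1] * ci_
        qaly_sq = w_sq[0] * qa + w_sq[1] * qi
        cost_int = w_int[0] * ca + w_int[1] * ci_
        qaly_int = w_int[0] * qa + w_int[1] * qi
        cost_int += bundle.costs.invest_per_capita * km \
            + bundle.costs.maint_per_capita * km * disc_sum
        d_cost[i] = cost_int - cost_sq
        d_qaly[i] = qaly_int - qaly_sq

    draws = pd.DataFrame({"iteration": np.arange(n), "d_cost": d_cost,
                          "d_qaly": d_qaly})
    probs = ceac(d_cost, d_qaly, threshold_grid)
    ceac_df = pd.DataFrame({"threshold": threshold_grid,
                            "probability": probs})
    thr = config.wtp_threshold
    p_ce = float((thr * d_qaly - d_cost > 0).mean())
    return PSAResult(draws=draws, ceac=ceac_df, p_ce_at_threshold=p_ce,
                     threshold=thr, seed=seed, n_iterations=n,
                     n_clipped=n_clipped)
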