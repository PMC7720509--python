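"""Cost-effectiveness comparison of the two arms, scenario grid and
one-way (tornado) deterministic sensitivity analysis."""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import CohortTrace, ModelConfig, mix_for_share, run_cohort
from .parameters import (
    DISEASES,
    ParameterBundle,
    RelativeRisk,
    UNCERTAIN_COST_FIELDS,
    UNCERTAIN_UTILITY_FIELDS,
)

__all__ = ["CEAResult", "compare_arms", "run_arm", "run_base_case",
           "run_scenarios", "tornado"]


@dataclass(frozen=True)
class CEAResult:
    """Incremental cost-effectiveness of intervention vs status quo.

    ``icer`` is None (with a dominance label) when the incremental QALY
    is non-positive; ``nmb`` is the net monetary benefit
    ``threshold * d_qaly - d_cost``.
    """

    cost_sq: float
    qaly_sq: float
    cost_int: float
    qaly_int: float
    threshold: float

    @property
    def d_cost(self) -> float:
        return self.cost_int - self.cost_sq

    @property
    def d_qaly(self) -> float:
        return self.qaly_int - self.qaly_sq

    @property
    def icer(self) -> float | None:
        if self.d_qaly <= 0:
            return None
        return self.d_cost / self.d_qaly

    @property
    def dominance(self) -> str:
        if self.d_qaly > 0 and self.d_cost <= 0:
            return "dominant"
        if self.d_qaly <= 0 and self.d_cost >= 0 and (self.d_qaly, self.d_cost) != (0.0, 0.0):
            return "dominated"
        return ""

    @property
    def nmb(self) -> float:
        return self.threshold * self.d_qaly - self.d_cost

    def as_dict(self) -> dict[str, float | None]:
        return {"cost_sq": self.cost_sq, "qaly_sq": self.qaly_sq,
                "cost_int": self.cost_int, "qaly_int": self.qaly_int,
                "d_cost": self.d_cost, "d_qaly": self.d_qaly,
                "icer": self.icer, "nmb": self.nmb,
                "threshold": self.threshold}


def compare_arms(trace_sq: CohortTrace, trace_int: CohortTrace,
                 threshold: float) -> CEAResult:
    """Incremental results from two cohort traces."""
    return CEAResult(cost_sq=trace_sq.total_cost, qaly_sq=trace_sq.total_qaly,
                     cost_int=trace_int.total_cost,
                     qaly_int=trace_int.total_qaly, threshold=threshold)


def run_arm(config: ModelConfig, params: ParameterBundle,
            arm: str) -> CohortTrace:
    """Run one arm ('status_quo' or 'intervention') of the model."""
    if arm == "status_quo":
        share, intervention = config.share_cycling_sq, False
    elif arm == "intervention":
        share, intervention = config.share_cycling_int, True
    else:
        raise ValueError(f"unknown arm {arm!r}")
    mix = mix_for_share(config, share)
    return run_cohort(config, mix, params, intervention=intervention)


def run_base_case(config: ModelConfig, params: ParameterBundle) -> CEAResult:
    """Both arms under one configuration, compared at its threshold."""
    return compare_arms(run_arm(config, params, "status_quo"),
                        run_arm(config, params, "intervention"),
                        config.wtp_threshold)


def run_scenarios(config: ModelConfig, params: ParameterBundle,
                  share_grid: tuple[float, ...] = (0.115, 0.15, 0.20, 0.25),
                  horizon_grid: tuple[int, ...] = (20, 30, 35, 40),
                  ) -> pd.DataFrame:
    """Base case plus the share and horizon scenario grid.

    Share scenarios change only the intervention arm's cycling share;
    horizon scenarios re-run both arms over the alternative horizon.
    """
    rows: list[tuple[str, CEAResult]] = [("base_case",
                                          run_base_case(config, params))]
    for s in share_grid:
        rows.append((f"share_{s:g}",
                     run_base_case(replace(config, share_cycling_int=s),
                                   params)))
    for h in horizon_grid:
        rows.append((f"horizon_{h}",
                     run_base_case(replace(config, horizon=h), params)))
    df = pd.DataFrame([r.as_dict() for _, r in rows],
                      index=pd.Index([k for k, _ in rows], name="scenario"))
    return df.drop(columns="threshold")


def _bundle_with_cost(params: ParameterBundle, name: str,
                      value: float) -> ParameterBundle:
    out = copy.deepcopy(params)
    setattr(out.costs, name, value)
    return out


def _bundle_with_rr(params: ParameterBundle, kind: str, disease: str,
                    value: float) -> ParameterBundle:
    out = copy.deepcopy(params)
    table = out.relative_risks.mortality if kind == "mortality" \
        else out.relative_risks.disease_active
    old = table[disease]
    table[disease] = RelativeRisk(base=value, lower=min(value, old.lower),
                                  upper=max(value, old.upper),
                                  distribution=old.distribution)
    return out


def default_tornado_parameters(params: ParameterBundle,
                               share_bounds: tuple[float, float] = (0.07, 0.115),
                               ) -> list[dict]:
    """One-way ranges: printed CIs for RRs, mean +/- 1.96 sd for costs and
    utilities (truncated to their legal range), and explicit bounds for
    the intervention-arm cycling share."""
    entries: list[dict] = [{"name": "share_cycling_int", "kind": "config",
                            "low": share_bounds[0], "high": share_bounds[1]}]
    c = params.costs
    for name in UNCERTAIN_COST_FIELDS + UNCERTAIN_UTILITY_FIELDS:
        if name not in c.uncertainty:
            continue
        sd, _family = c.uncertainty[name]
        mean = getattr(c, name)
        lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
        lo = max(lo, 0.0)
        if name.startswith("util") or name == "wellbeing_gain_active":
            hi = min(hi, 1.0)
        entries.append({"name": name, "kind": "cost", "low": lo, "high": hi})
    for d in DISEASES:
        rr = params.relative_risks.mortality[d]
        entries.append({"name": f"rr_mortality_{d}", "kind": "rr_mortality",
                        "disease": d, "low": rr.lower, "high": rr.upper})
        rr = params.relative_risks.disease_active[d]
        entries.append({"name": f"rr_disease_active_{d}",
                        "kind": "rr_disease", "disease": d,
                        "low": rr.lower, "high": rr.upper})
    return entries


def tornado(config: ModelConfig, params: ParameterBundle,
            parameters: list[dict] | None = None) -> pd.DataFrame:
    """One-way sensitivity of the ICER, sorted by descending range width.

    Each entry sets a single parameter to its low and high bound, holding
    everything else at base values, and records the resulting ICER.
    """
    if parameters is None:
        parameters = default_tornado_parameters(params)
    base = run_base_case(config, params)

    def icer_with(entry: dict, value: float) -> float | None:
        if entry["kind"] == "config":
            return run_base_case(replace(config, **{entry["name"]: value}),
                                 params).icer
        if entry["kind"] == "cost":
            return run_base_case(config,
                                 _bundle_with_cost(params, entry["name"],
                                                   value)).icer
        if entry["kind"] == "rr_mortality":
            return run_base_case(config,
                                 _bundle_with_rr(params, "mortality",
                                                 entry["disease"], value)).icer
        if entry["kind"] == "rr_disease":
            return run_base_case(config,
                                 _bundle_with_rr(params, "disease",
                                                 entry["disease"], value)).icer
        raise ValueError(f"unknown tornado entry kind {entry['kind']!r}")

    records = []
    for entry in parameters:
        lo_icer = icer_with(entry, entry["low"])
        hi_icer = icer_with(entry, entry["high"])
        finite = [v for v in (lo_icer, hi_icer) if v is not None]
        width = (max(finite) - min(finite)) if len(finite) == 2 else np.inf
        records.append({"parameter": entry["name"], "low_value": entry["low"],
                        "high_value": entry["high"], "icer_at_low": lo_icer,
                        "icer_at_high": hi_icer, "range_width": width,
                        "icer_base": base.icer})
    df = pd.DataFrame(records).sort_values("range_width", ascending=False,
                                           kind="stable")
    return df.reset_index(drop=True)
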