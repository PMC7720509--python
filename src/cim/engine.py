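"""Annual-cycle Markov cohort engine.

One cohort arm is a mixture of three activity strata fixed at baseline —
cyclists, active non-cyclists and inactive non-cyclists — each walking the
same eight-state disease process (Well, first-year CHD, post-CHD,
first-year stroke, post-stroke, T2D, cancer, Dead) under stratum-specific
incidence. Cyclists and active non-cyclists share the "active" risk
profile; disease states inherit the stratum they were entered from.
Costs and QALYs accrue per cycle on start-of-cycle occupancy and are
discounted at the configured annual rate with the first cycle undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parameters import (
    DISEASES,
    ActivityMix,
    AgeBandRates,
    ParameterBundle,
    PAFSet,
    RelativeRiskSet,
    incidence_by_activity,
    mortality_in_state,
)

__all__ = [
    "STATES",
    "STRATA",
    "ModelConfig",
    "CohortTrace",
    "MicroSimResult",
    "build_transition_matrix",
    "run_cohort",
    "micro_simulate",
    "mix_for_share",
]

#: Health states of one activity stratum, in matrix order.
STATES = ("well", "chd_first", "chd_post", "stroke_first", "stroke_post",
          "t2d", "cancer", "dead")
WELL, CHD1, CHD2, STR1, STR2, T2D, CANCER, DEAD = range(8)

#: Activity strata tracked in the trace. "active" means active non-cyclist.
STRATA = ("cyclist", "active", "inactive")

# Risk profile of each stratum: cyclists are assumed physically active.
_STRATUM_KIND = {"cyclist": "active", "active": "active",
                 "inactive": "inactive"}


@dataclass
class ModelConfig:
    """Run configuration for one two-arm evaluation.

    Defaults are the Oslo base case: a cohort entering at age 30 followed
    for 25 annual cycles, 4% discounting, a 600,000 NOK (~$72,550) per
    QALY willingness-to-pay threshold, cycling shares of 6% (status quo)
    vs 9% (after building 100 km of network).
    """

    start_age: int = 30
    horizon: int = 25
    cycle_length: float = 1.0
    discount_rate: float = 0.04
    wtp_threshold: float = 72550.0
    share_cycling_sq: float = 0.06
    share_cycling_int: float = 0.09
    p_active_noncyclist: float = 0.286
    network_km_built: float = 100.0
    oslo_population: int = 666_759
    half_cycle_correction: bool = False
    #: 'well' applies the wellbeing gain to active strata in Well only;
    #: 'alive' extends it to their disease states.
    wellbeing_scope: str = "well"
    #: per-cycle multiplicative decline of the T2D mortality RR in the
    #: active strata (1.0 = no decline).
    t2d_mortality_decline_active: float = 1.0
    #: fraction of cyclists assumed to actually be physically active.
    active_cyclist_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")
        for name in ("share_cycling_sq", "share_cycling_int",
                     "p_active_noncyclist", "active_cyclist_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.wellbeing_scope not in ("well", "alive"):
            raise ValueError("wellbeing_scope must be 'well' or 'alive'")

    @property
    def discount_factors(self) -> np.ndarray:
        """Per-cycle discount factors (1+r)^-t, t = 0 for the first cycle."""
        t = np.arange(self.horizon)
        return (1.0 + self.discount_rate) ** (-t)


def mix_for_share(config: ModelConfig, share_cycling: float) -> ActivityMix:
    """Stratum mix for an arm, honouring ``active_cyclist_fraction``.

    When not all cyclists are active, the inactive remainder of the
    cyclist share is pooled with the inactive non-cyclists.
    """
    effective_share = share_cycling * config.active_cyclist_fraction
    mix = ActivityMix(share_cycling=effective_share,
                      p_active_noncyclist=(1.0 - share_cycling)
                      * config.p_active_noncyclist
                      / max(1.0 - effective_share, 1e-15))
    return mix


@dataclass
class CohortTrace:
    """State occupancy and discounted reward streams for one arm.

    ``occupancy`` has one row per cycle boundary (0..horizon) and a
    (stratum, state) column MultiIndex; entries are cohort proportions, so
    every row sums to 1. ``cost_stream``/``qaly_stream`` are per-person
    discounted values accrued in each cycle.
    """

    occupancy: pd.DataFrame
    cost_stream: np.ndarray
    qaly_stream: np.ndarray
    total_cost: float
    total_qaly: float
    config: ModelConfig
    mix: ActivityMix
    intervention: bool

    def validate(self, atol: float = 1e-12) -> None:
        rows = self.occupancy.to_numpy()
        if not np.allclose(rows.sum(axis=1), 1.0, atol=max(atol, 1e-9)):
            raise AssertionError("occupancy rows do not sum to 1")
        if (rows < -atol).any():
            raise AssertionError("negative occupancy")
        dead = self.occupancy.loc[:, pd.IndexSlice[:, "dead"]].sum(axis=1).to_numpy()
        if (np.diff(dead) < -1e-12).any():
            raise AssertionError("Dead occupancy decreased")


def _matrix_from_rates(inc: dict[str, float], cfr_chd: float,
                       cfr_stroke: float, other_cause: float,
                       mort: dict[str, float], *, context: str = "") -> np.ndarray:
    """Assemble one 8x8 row-stochastic annual transition matrix."""
    P = np.zeros((8, 8))
    p_dead_well = (inc["chd"] * cfr_chd + inc["stroke"] * cfr_stroke
                   + other_cause)
    P[WELL, CHD1] = inc["chd"] * (1.0 - cfr_chd)
    P[WELL, STR1] = inc["stroke"] * (1.0 - cfr_stroke)
    P[WELL, T2D] = inc["t2d"]
    P[WELL, CANCER] = inc["cancer"]
    P[WELL, DEAD] = p_dead_well
    P[WELL, WELL] = 1.0 - P[WELL].sum()
    P[CHD1, DEAD] = mort["chd"]
    P[CHD1, CHD2] = 1.0 - mort["chd"]
    P[CHD2, DEAD] = mort["chd"]
    P[CHD2, CHD2] = 1.0 - mort["chd"]
    P[STR1, DEAD] = mort["stroke"]
    P[STR1, STR2] = 1.0 - mort["stroke"]
    P[STR2, DEAD] = mort["stroke"]
    P[STR2, STR2] = 1.0 - mort["stroke"]
    P[T2D, DEAD] = mort["t2d"]
    P[T2D, T2D] = 1.0 - mort["t2d"]
    P[CANCER, DEAD] = mort["cancer"]
    P[CANCER, CANCER] = 1.0 - mort["cancer"]
    P[DEAD, DEAD] = 1.0
    if (P < -1e-15).any() or (P > 1.0 + 1e-12).any():
        raise ValueError(
            f"transition probabilities outside [0, 1] ({context}); "
            "check parameter overrides")
    return np.clip(P, 0.0, 1.0)


def build_transition_matrix(band: AgeBandRates, stratum: str,
                            rrs: RelativeRiskSet, pafs: PAFSet,
                            t2d_mort_factor: float = 1.0) -> np.ndarray:
    """Annual transition matrix for one age band and activity stratum.

    From Well, incident CHD/stroke events are split by case fatality into
    the first-year disease state and Dead; T2D and cancer are entered
    whole; other-cause (all-cause minus CVD) mortality applies. Chronic
    states carry the RR-adjusted state mortality; Dead is absorbing.
    """
    kind = _STRATUM_KIND.get(stratum, stratum)
    if kind not in ("active", "inactive"):
        raise ValueError(f"unknown stratum {stratum!r}")
    inc = {}
    for d in DISEASES:
        a, i = incidence_by_activity(band.incidence(d), pafs[d],
                                     rrs.disease_active[d].base)
        inc[d] = a if kind == "active" else i
    mort = {d: mortality_in_state(band, d, rrs) for d in DISEASES}
    if kind == "active" and t2d_mort_factor != 1.0:
        rr = rrs.mortality["t2d"].base * t2d_mort_factor
        mort["t2d"] = min(1.0, rr * band.mort_cvd + band.other_cause_mortality)
    return _matrix_from_rates(inc, band.cfr_chd, band.cfr_stroke,
                              band.other_cause_mortality, mort,
                              context=f"band {band.age_band}, {stratum}")


def _cycle_band_indices(config: ModelConfig, params: ParameterBundle) -> np.ndarray:
    ages = config.start_age + np.arange(config.horizon)
    return np.array([params.age_rates.band_index_for_age(a) for a in ages])


def _kind_matrices(config: ModelConfig, params: ParameterBundle,
                   kind: str) -> list[np.ndarray]:
    """Per-cycle transition matrices for one risk profile."""
    band_idx = _cycle_band_indices(config, params)
    cache: dict[tuple[int, int], np.ndarray] = {}
    mats = []
    for t, b in enumerate(band_idx):
        decline = config.t2d_mortality_decline_active
        if kind == "active" and decline != 1.0:
            factor = decline ** t
            key = (b, t)
        else:
            factor = 1.0
            key = (b, -1)
        if key not in cache:
            cache[key] = build_transition_matrix(
                params.age_rates.bands[b], kind, params.relative_risks,
                params.pafs, t2d_mort_factor=factor)
        mats.append(cache[key])
    return mats


def _reward_vectors(params: ParameterBundle, kind: str,
                    wellbeing_scope: str) -> tuple[np.ndarray, np.ndarray]:
    c = params.costs
    cost = np.array([0.0, c.cost_chd_first, c.cost_chd_post,
                     c.cost_stroke_first, c.cost_stroke_post,
                     c.cost_t2d, c.cost_cancer, 0.0])
    util = np.array([c.util_healthy, c.util_chd1, c.util_chd1plus,
                     c.util_stroke1, c.util_stroke1plus, c.util_t2d,
                     c.util_cancer, 0.0])
    if kind == "active":
        wb = c.wellbeing_gain_active
        if wellbeing_scope == "well":
            util[WELL] += wb
        else:  # every alive state
            util[:DEAD] += wb
    return cost, util


def _unit_trace(mats: list[np.ndarray]) -> np.ndarray:
    """Occupancy of a unit cohort starting in Well; rows 0..horizon."""
    h = len(mats)
    occ = np.zeros((h + 1, 8))
    occ[0, WELL] = 1.0
    for t in range(h):
        occ[t + 1] = occ[t] @ mats[t]
    return occ


def _unit_streams(occ: np.ndarray, cost_vec: np.ndarray, util_vec: np.ndarray,
                  disc: np.ndarray, half_cycle: bool) -> tuple[np.ndarray, np.ndarray]:
    h = len(disc)
    eff = 0.5 * (occ[:h] + occ[1:h + 1]) if half_cycle else occ[:h]
    return (eff @ cost_vec) * disc, (eff @ util_vec) * disc


def run_cohort(config: ModelConfig, mix: ActivityMix,
               params: ParameterBundle, intervention: bool = False) -> CohortTrace:
    """Run the cohort model for one arm.

    The whole cohort starts disease-free, split across the three Well
    strata according to ``mix``. The intervention arm additionally pays
    the one-time network investment at cycle 0 and per-cycle maintenance,
    both scaled by ``config.network_km_built``.

    Returns
    -------
    CohortTrace
        Occupancy by (stratum, state) and discounted per-person cost and
        QALY streams and totals.
    """
    disc = config.discount_factors
    weights = mix.stratum_weights
    unit: dict[str, np.ndarray] = {}
    streams: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for kind in ("active", "inactive"):
        occ = _unit_trace(_kind_matrices(config, params, kind))
        cost_vec, util_vec = _reward_vectors(params, kind,
                                             config.wellbeing_scope)
        unit[kind] = occ
        streams[kind] = _unit_streams(occ, cost_vec, util_vec, disc,
                                      config.half_cycle_correction)

    cost_stream = np.zeros(config.horizon)
    qaly_stream = np.zeros(config.horizon)
    blocks = {}
    for stratum in STRATA:
        kind = _STRATUM_KIND[stratum]
        w = weights[stratum]
        cost_stream += w * streams[kind][0]
        qaly_stream += w * streams[kind][1]
        blocks[stratum] = w * unit[kind]
    if intervention:
        km = config.network_km_built
        cost_stream = cost_stream + params.costs.maint_per_capita * km * disc
        cost_stream[0] += params.costs.invest_per_capita * km

    occupancy = pd.DataFrame(
        np.hstack([blocks[s] for s in STRATA]),
        columns=pd.MultiIndex.from_product([STRATA, STATES],
                                           names=["stratum", "state"]),
        index=pd.RangeIndex(config.horizon + 1, name="cycle"))
    trace = CohortTrace(occupancy=occupancy, cost_stream=cost_stream,
                        qaly_stream=qaly_stream,
                        total_cost=float(cost_stream.sum()),
                        total_qaly=float(qaly_stream.sum()),
                        config=config, mix=mix, intervention=intervention)
    trace.validate()
    return trace


@dataclass
class MicroSimResult:
    """Individual-level Monte-Carlo counterpart of :class:`CohortTrace`."""

    occupancy: pd.DataFrame
    total_cost: float
    total_qaly: float
    n_individuals: int
    seed: int
    state_paths: np.ndarray | None = None


def micro_simulate(config: ModelConfig, mix: ActivityMix,
                   params: ParameterBundle, n_individuals: int, seed: int,
                   intervention: bool = False,
                   keep_paths: bool = False) -> MicroSimResult:
    """First-order Monte-Carlo walk through the identical transition matrices.

    Serves as the independent validation oracle for :func:`run_cohort`:
    mean occupancy and discounted rewards converge to the cohort trace as
    ``n_individuals`` grows.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    weights = mix.stratum_weights
    counts = rng.multinomial(n_individuals,
                             [weights[s] for s in STRATA])
    disc = config.discount_factors
    h = config.horizon

    occ_blocks = {}
    total_cost = 0.0
    total_qaly = 0.0
    paths = [] if keep_paths else None
    for stratum, m in zip(STRATA, counts):
        kind = _STRATUM_KIND[stratum]
        occ_counts = np.zeros((h + 1, 8))
        if m == 0:
            occ_blocks[stratum] = occ_counts
            continue
        mats = _kind_matrices(config, params, kind)
        cum = [np.cumsum(P, axis=1) for P in mats]
        cost_vec, util_vec = _reward_vectors(params, kind,
                                             config.wellbeing_scope)
        state = np.zeros(m, dtype=np.int64)
        path = np.zeros((h + 1, m), dtype=np.int64) if keep_paths else None
        for t in range(h + 1):
            occ_counts[t] = np.bincount(state, minlength=8)
            if keep_paths:
                path[t] = state
            if t < h:
                total_cost += cost_vec[state].sum() * disc[t]
                total_qaly += util_vec[state].sum() * disc[t]
                u = rng.random(m)
                state = (u[:, None] > cum[t][state]).sum(axis=1)
        occ_blocks[stratum] = occ_counts
        if keep_paths:
            paths.append(path)

    total_cost /= n_individuals
    total_qaly /= n_individuals
    if intervention:
        km = config.network_km_built
        total_cost += params.costs.invest_per_capita * km
        total_cost += params.costs.maint_per_capita * km * disc.sum()

    occupancy = pd.DataFrame(
        np.hstack([occ_blocks[s] for s in STRATA]) / n_individuals,
        columns=pd.MultiIndex.from_product([STRATA, STATES],
                                           names=["stratum", "state"]),
        index=pd.RangeIndex(h + 1, name="cycle"))
    return MicroSimResult(occupancy=occupancy, total_cost=float(total_cost),
                          total_qaly=float(total_qaly),
                          n_individuals=n_individuals, seed=seed,
                          state_paths=(np.hstack(paths) if keep_paths and paths
                                       else None))
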