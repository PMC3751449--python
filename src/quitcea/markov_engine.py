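"""Three-state, six-month-cycle Markov cohort engine.

A cohort of 1,000 enrolled smokers is propagated from its starting age to
the lifetime horizon through three mutually exclusive states -- smoker,
former smoker and dead -- with transitions every 6 months.  The former
state is split internally into ``former_recent`` (quit during the previous
cycle, still exposed to the 6-12 month relapse draw) and ``former_long``
(past the 12-month boundary); both carry former-smoker death and disease
rates.

Within a cycle, events are ordered death -> quit -> relapse: mortality is
resolved on the state at cycle start, surviving smokers may quit into
``former_recent``, and surviving recent quitters face the 21% 6-12 month
relapse followed by a one-off lifetime-relapse draw before entering
``former_long`` (alternatively, the lifetime relapse can be spread as a
constant per-cycle hazard over 10 years; see ``relapse_mode``).

Rewards are credited to the state at cycle start: each alive fraction earns
half a life year; disease events (mutually exclusive within a cycle) earn
the disease utility and half the annual disease cost; the disease-free
remainder earns the smoking-status utility.  No half-cycle correction is
applied, and the discount factor is indexed at cycle start:
``(1 + r) ** (-0.5 * (t - 1))``.  The one-off intervention cost is charged
undiscounted at t = 0 in the intervention arm only; costs common to both
arms cancel in the incremental comparison and are omitted.

The private ``_simulate`` core is written in scalar arithmetic that also
broadcasts over numpy arrays, so a probabilistic sensitivity analysis can
run all iterations simultaneously through the identical code path.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epi_derivation import AgeRates, StatusRates, annual_to_cycle, derive_status_rates
from .params_io import (
    AGE_MIN,
    CostTable,
    EconomicSettings,
    ModelInputs,
    QuitParams,
    UtilityTable,
    ValidationError,
)


class Arm(enum.Enum):
    """Trial arm.  The intervention differs from control only in the
    first-cycle quit probability (the quit relative risk is applied) and in
    the one-off per-smoker intervention cost."""

    CONTROL = "control"
    INTERVENTION = "intervention"

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class CohortState:
    """State occupancy fractions at a cycle boundary."""

    smoker: float
    former_recent: float
    former_long: float
    dead: float

    def __post_init__(self) -> None:
        for name in ("smoker", "former_recent", "former_long", "dead"):
            if getattr(self, name) < -1e-12:
                raise ValidationError(f"negative occupancy in {name}")

    @property
    def former(self) -> float:
        return self.former_recent + self.former_long

    @property
    def alive(self) -> float:
        return self.smoker + self.former

    @property
    def total(self) -> float:
        return self.alive + self.dead


@dataclass(frozen=True)
class Outcomes:
    """Discounted lifetime totals per 1,000 enrollees, with undiscounted
    twins.  ``quitters_6m`` is the former-smoker count at the end of the
    first cycle."""

    total_cost: float
    life_years: float
    qalys: float
    quitters_6m: float
    total_cost_undisc: float
    life_years_undisc: float
    qalys_undisc: float

    def __post_init__(self) -> None:
        if self.qalys > self.life_years + 1e-9:
            raise ValidationError("QALYs cannot exceed life years")
        for name in ("total_cost", "life_years", "qalys", "quitters_6m"):
            if getattr(self, name) < -1e-9:
                raise ValidationError(f"negative outcome {name}")

    @staticmethod
    def weighted(parts: list[tuple[float, "Outcomes"]]) -> "Outcomes":
        def tot(attr: str) -> float:
            return sum(w * getattr(o, attr) for w, o in parts)

        return Outcomes(
            total_cost=tot("total_cost"),
            life_years=tot("life_years"),
            qalys=tot("qalys"),
            quitters_6m=tot("quitters_6m"),
            total_cost_undisc=tot("total_cost_undisc"),
            life_years_undisc=tot("life_years_undisc"),
            qalys_undisc=tot("qalys_undisc"),
        )


@dataclass
class CohortTrajectory:
    """Per-cycle record of one (arm, age, gender) cohort: state at each cycle
    start (plus the final state), deaths per cycle, and expected disease
    events by disease and smoking status."""

    arm: Arm
    start_age: int
    gender: str
    states: list[CohortState]
    deaths: np.ndarray
    disease_events: pd.DataFrame
    quit_6m: float


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def quit_prob_schedule(arm: Arm, cycle_index: int, quit: QuitParams) -> float:
    """Per-cycle quit probability: the trial effect in cycle 1, the
    background quit rate (converted to 6 months) thereafter in both arms."""
    if cycle_index < 1:
        raise ValidationError(f"cycle_index must be >= 1, got {cycle_index}")
    if cycle_index == 1:
        p = quit.control_quit_6m
        if arm is Arm.INTERVENTION:
            p = p * quit.rr_quit
        return p
    return annual_to_cycle(quit.background_quit_annual)


def cycle_transition(
    state: CohortState,
    mortality: tuple[float, float],
    quit_prob: float,
    relapse: tuple[float, float],
) -> CohortState:
    """One 6-month transition: death, then quitting, then relapse.

    ``mortality`` is (smoker, former) per-cycle death probability;
    ``relapse`` is (p_recent, p_long): the 6-12 month relapse probability
    and the one-off lifetime relapse applied to its survivors at the
    12-month boundary.  Occupancy is conserved.
    """
    m_s, m_f = mortality
    p_recent, p_long = relapse
    for name, p in (
        ("m_smoker", m_s),
        ("m_former", m_f),
        ("quit_prob", quit_prob),
        ("p_recent", p_recent),
        ("p_long", p_long),
    ):
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"{name} must lie in [0, 1], got {p!r}")
    dead = state.dead + state.smoker * m_s + state.former * m_f
    s = state.smoker * (1.0 - m_s)
    fr = state.former_recent * (1.0 - m_f)
    fl = state.former_long * (1.0 - m_f)
    moved = s * quit_prob
    s -= moved
    rel1 = fr * p_recent
    rel2 = (fr - rel1) * p_long
    s += rel1 + rel2
    fl += fr - rel1 - rel2
    out = CohortState(smoker=s, former_recent=moved, former_long=fl, dead=dead)
    if min(out.smoker, out.former_recent, out.former_long, out.dead) < -1e-12:
        raise RuntimeError("negative occupancy after transition")
    return out


def cycle_rewards(
    state: CohortState,
    rates: AgeRates,
    utilities: UtilityTable,
    costs: CostTable,
    t: int,
    econ: EconomicSettings,
) -> tuple[float, float, float]:
    """Discounted (cost, life years, QALYs) earned by ``state`` during cycle
    ``t``.  Diseases are mutually exclusive within the cycle; the
    disease-free remainder earns the smoking-status utility."""
    half = econ.cycle_length
    qs_sum = sum(rates.q_smoker.values())
    qf_sum = sum(rates.q_former.values())
    for status, total in (("smoker", qs_sum), ("former", qf_sum)):
        if total > 1.0 + 1e-12:
            raise ValidationError(
                f"disease probabilities for status {status} sum to {total:.4f} > 1"
            )
    disc_c = (1.0 + econ.discount_rate_cost) ** (-half * (t - 1))
    disc_e = (1.0 + econ.discount_rate_effect) ** (-half * (t - 1))
    former = state.former
    cost = half * sum(
        (state.smoker * rates.q_smoker[d] + former * rates.q_former[d])
        * costs.disease_annual_cost[d]
        for d in rates.q_smoker
    )
    qaly = half * (
        state.smoker
        * (
            (1.0 - qs_sum) * utilities.smoker_value
            + sum(rates.q_smoker[d] * utilities.disease_value[d] for d in rates.q_smoker)
        )
        + former
        * (
            (1.0 - qf_sum) * utilities.former_value
            + sum(rates.q_former[d] * utilities.disease_value[d] for d in rates.q_former)
        )
    )
    ly = half * state.alive
    return cost * disc_c, ly * disc_e, qaly * disc_e


# ---------------------------------------------------------------------------
# compiled arrays and the simulation core
# ---------------------------------------------------------------------------


def _compiled_epi(inputs: ModelInputs) -> dict[str, dict]:
    """Per-gender age-indexed arrays of per-cycle status-specific rates."""
    rates = derive_status_rates(inputs.epi)
    comp: dict[str, dict] = {}
    for gender in ("male", "female"):
        sub = rates.cycle.xs(gender, level="gender").sort_index()
        ages = sub.index.to_numpy()
        age0 = int(ages.min())
        full = np.arange(age0, int(ages.max()) + 1)
        sub = sub.reindex(full)
        comp[gender] = {
            "age0": age0,
            "age_max": int(ages.max()),
            "gender": gender,
            "m_s": sub["m_smoker"].to_numpy(),
            "m_f": sub["m_former"].to_numpy(),
            "q_s": sub[[f"q_smoker_{d}" for d in inputs.diseases]].to_numpy(),
            "q_f": sub[[f"q_former_{d}" for d in inputs.diseases]].to_numpy(),
        }
    return comp


def _reward_coeffs(comp_g: dict, u_d, u_smoker, u_former, cost_d, half: float):
    """Per-age cost and utility accrual coefficients for one unit of smoker
    or former-smoker occupancy.  ``u_d``/``cost_d`` may be (n_disease,) for a
    single run or (n_iter, n_disease) for a batch; status utilities scalars
    or (n_iter,)."""
    q_s, q_f = comp_g["q_s"], comp_g["q_f"]
    qs_sum, qf_sum = q_s.sum(axis=1), q_f.sum(axis=1)
    for status, total in (("smoker", qs_sum), ("former", qf_sum)):
        if np.nanmax(total) > 1.0 + 1e-12:
            age = comp_g["age0"] + int(np.nanargmax(total))
            raise ValidationError(
                f"disease probabilities sum above 1 at age={age}, "
                f"gender={comp_g['gender']}, status={status}"
            )
    u_d = np.asarray(u_d, dtype=float)
    cost_d = np.asarray(cost_d, dtype=float)
    if u_d.ndim == 1:
        cost_s = half * (q_s @ cost_d)
        cost_f = half * (q_f @ cost_d)
        qu_s = half * ((1.0 - qs_sum) * u_smoker + q_s @ u_d)
        qu_f = half * ((1.0 - qf_sum) * u_former + q_f @ u_d)
    else:
        u_smoker = np.asarray(u_smoker, dtype=float)
        u_former = np.asarray(u_former, dtype=float)
        cost_s = half * (q_s @ cost_d.T)
        cost_f = half * (q_f @ cost_d.T)
        qu_s = half * ((1.0 - qs_sum)[:, None] * u_smoker[None, :] + q_s @ u_d.T)
        qu_f = half * ((1.0 - qf_sum)[:, None] * u_former[None, :] + q_f @ u_d.T)
    return cost_s, cost_f, qu_s, qu_f


def _simulate(
    comp_g: dict,
    coeffs,
    first_quit,
    bgq,
    p21,
    p30,
    relapse_mode: str,
    econ: EconomicSettings,
    cost0,
    start_age: int,
    record: bool = False,
    arm: Arm | None = None,
):
    """Run one cohort; parameters may be scalars or per-iteration arrays.

    Returns (cost, ly, qaly, quit6, cost_u, ly_u, qaly_u) per person and,
    when ``record`` is true (scalar mode only), a :class:`CohortTrajectory`.
    """
    cost_s, cost_f, qu_s, qu_f = coeffs
    m_s, m_f = comp_g["m_s"], comp_g["m_f"]
    age0 = comp_g["age0"]
    half = econ.cycle_length
    n_cycles = int(round((econ.horizon_age - start_age) / half))
    ia_last = (start_age - age0) + (n_cycles - 1) // 2
    if start_age < age0 or ia_last >= len(m_s) or np.isnan(m_s[start_age - age0:ia_last + 1]).any():
        raise ValidationError(
            f"epidemiological table does not cover ages {start_age}.."
            f"{age0 + ia_last} for gender={comp_g['gender']}"
        )
    step_c = (1.0 + econ.discount_rate_cost) ** (-half)
    step_e = (1.0 + econ.discount_rate_effect) ** (-half)

    s, fr, fl, dead = 1.0, 0.0, 0.0, 0.0
    spread = relapse_mode == "spread"
    if spread:
        n_bins = int(round(10.0 / half))
        haz = 1.0 - (1.0 - p30) ** (1.0 / n_bins)
        bins = [0.0] * n_bins
        safe = 0.0
    cost = cost0 + 0.0
    cost_u = cost0 + 0.0
    ly = qaly = ly_u = qaly_u = 0.0
    disc_c = disc_e = 1.0
    quit6 = 0.0
    states: list[CohortState] = []
    deaths: list = []
    events: list = []

    for t in range(1, n_cycles + 1):
        ia = (start_age - age0) + (t - 1) // 2
        fl_total = (sum(bins) + safe) if spread else fl
        former = fr + fl_total
        if record:
            states.append(CohortState(s, fr, fl_total, dead))
            events.append(
                [s * q for q in comp_g["q_s"][ia]]
                + [former * q for q in comp_g["q_f"][ia]]
            )
        # rewards on the state at cycle start
        c = cost_s[ia] * s + cost_f[ia] * former
        q = qu_s[ia] * s + qu_f[ia] * former
        l = half * (s + former)
        cost = cost + c * disc_c
        cost_u = cost_u + c
        qaly = qaly + q * disc_e
        qaly_u = qaly_u + q
        ly = ly + l * disc_e
        ly_u = ly_u + l
        disc_c = disc_c * step_c
        disc_e = disc_e * step_e
        # transition: death -> quit -> relapse
        ms, mf = m_s[ia], m_f[ia]
        died = s * ms + former * mf
        dead = dead + died
        if record:
            deaths.append(died)
        s = s * (1.0 - ms)
        fr = fr * (1.0 - mf)
        qp = first_quit if t == 1 else bgq
        moved = s * qp
        s = s - moved
        rel1 = fr * p21
        stay = fr - rel1
        if spread:
            surv = 1.0 - mf
            bins = [b * surv for b in bins]
            safe = safe * surv
            rel_bins = [b * haz for b in bins]
            s = s + rel1 + sum(rel_bins)
            shifted = [b - rb for b, rb in zip(bins, rel_bins)]
            safe = safe + shifted[-1]
            bins = [stay] + shifted[:-1]
        else:
            fl = fl * (1.0 - mf)
            rel2 = stay * p30
            s = s + rel1 + rel2
            fl = fl + stay - rel2
        fr = moved
        if t == 1:
            quit6 = fr

    per_person = (cost, ly, qaly, quit6, cost_u, ly_u, qaly_u)
    if not record:
        return per_person, None
    fl_total = (sum(bins) + safe) if spread else fl
    states.append(CohortState(s, fr, fl_total, dead))
    cols = [f"smoker_{d}" for d in _disease_names(comp_g)] + [
        f"former_{d}" for d in _disease_names(comp_g)
    ]
    traj = CohortTrajectory(
        arm=arm if arm is not None else Arm.CONTROL,
        start_age=start_age,
        gender=comp_g["gender"],
        states=states,
        deaths=np.asarray(deaths, dtype=float),
        disease_events=pd.DataFrame(events, columns=cols, index=range(1, n_cycles + 1)),
        quit_6m=float(quit6),
    )
    return per_person, traj


def _disease_names(comp_g: dict) -> tuple[str, ...]:
    return comp_g.get("diseases", ())


# ---------------------------------------------------------------------------
# public runners
# ---------------------------------------------------------------------------


def _outcomes_from_tuple(tup, scale: float = 1000.0) -> Outcomes:
    cost, ly, qaly, quit6, cost_u, ly_u, qaly_u = (float(x) for x in tup)
    return Outcomes(
        total_cost=scale * cost,
        life_years=scale * ly,
        qalys=scale * qaly,
        quitters_6m=scale * quit6,
        total_cost_undisc=scale * cost_u,
        life_years_undisc=scale * ly_u,
        qalys_undisc=scale * qaly_u,
    )


def _arm_params(inputs: ModelInputs, arm: Arm):
    quit = inputs.quit
    first_quit = quit.control_quit_6m
    cost0 = 0.0
    if arm is Arm.INTERVENTION:
        first_quit *= quit.rr_quit
        cost0 = (
            inputs.costs.intervention_cost_per_smoker
            + inputs.costs.royalty_management_per_smoker
        )
    bgq = annual_to_cycle(quit.background_quit_annual)
    return first_quit, bgq, quit.relapse_6_12, quit.relapse_lifetime, cost0


def run_cohort(
    inputs: ModelInputs,
    arm: Arm,
    start_age: int,
    gender: str,
    _comp: dict | None = None,
) -> tuple[CohortTrajectory, Outcomes]:
    """Simulate one (arm, starting age, gender) cohort over the lifetime
    horizon and return its trajectory and discounted outcomes per 1,000
    enrollees."""
    if start_age >= inputs.econ.horizon_age:
        raise ValidationError(
            f"start_age {start_age} must be below horizon_age "
            f"{inputs.econ.horizon_age}"
        )
    comp = _comp if _comp is not None else _compiled_epi(inputs)
    comp_g = dict(comp[gender])
    comp_g["diseases"] = inputs.diseases
    coeffs = _reward_coeffs(
        comp_g,
        [inputs.utilities.disease_value[d] for d in inputs.diseases],
        inputs.utilities.smoker_value,
        inputs.utilities.former_value,
        [inputs.costs.disease_annual_cost[d] for d in inputs.diseases],
        inputs.econ.cycle_length,
    )
    first_quit, bgq, p21, p30, cost0 = _arm_params(inputs, arm)
    tup, traj = _simulate(
        comp_g,
        coeffs,
        first_quit,
        bgq,
        p21,
        p30,
        inputs.relapse_mode,
        inputs.econ,
        cost0,
        start_age,
        record=True,
        arm=arm,
    )
    return traj, _outcomes_from_tuple(tup)


def run_weighted(inputs: ModelInputs, arm: Arm) -> Outcomes:
    """Weighted-average outcomes over the cohort mix (age weights crossed
    with gender weights)."""
    comp = _compiled_epi(inputs)
    parts: list[tuple[float, Outcomes]] = []
    coeffs_by_gender = {}
    for gender in ("male", "female"):
        comp_g = dict(comp[gender])
        comp_g["diseases"] = inputs.diseases
        coeffs_by_gender[gender] = (
            comp_g,
            _reward_coeffs(
                comp_g,
                [inputs.utilities.disease_value[d] for d in inputs.diseases],
                inputs.utilities.smoker_value,
                inputs.utilities.former_value,
                [inputs.costs.disease_annual_cost[d] for d in inputs.diseases],
                inputs.econ.cycle_length,
            ),
        )
    first_quit, bgq, p21, p30, cost0 = _arm_params(inputs, arm)
    for stratum in inputs.mix:
        comp_g, coeffs = coeffs_by_gender[stratum.gender]
        tup, _ = _simulate(
            comp_g,
            coeffs,
            first_quit,
            bgq,
            p21,
            p30,
            inputs.relapse_mode,
            inputs.econ,
            cost0,
            stratum.start_age,
        )
        parts.append((stratum.weight, _outcomes_from_tuple(tup)))
    return Outcomes.weighted(parts)
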