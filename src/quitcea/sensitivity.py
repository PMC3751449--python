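"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full model at the low and high end of a
parameter's range with everything else at base case.  The probabilistic
sensitivity analysis (second-order Monte Carlo) re-runs the model ``n``
times with parameters drawn independently from their distributions:
lognormal for the quit relative risk (fitted to its published 95% CI),
beta for the lifetime relapse rate, the background quit rate and the seven
health-state values, and gamma for the five disease unit costs and the
intervention cost.  Epidemiological tables (mortality, prevalences,
relative risks of death/disease) are not sampled.

Randomness is reproducible: a single seed spawns one counter-indexed
substream per iteration, so results are independent of execution order and
identical whether iterations are run one at a time or as a vectorised
batch.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import markov_engine
from .cea_metrics import IncrementalResult, incremental
from .epi_derivation import (
    DistSpec,
    lognormal_from_ci,
    moments_to_beta,
    moments_to_gamma,
)
from .markov_engine import Arm, run_weighted
from .params_io import ConfigError, ModelInputs, ValidationError

#: Default relative spread (sd as a fraction of the mean) for parameters
#: without a published interval.
DEFAULT_SD_FRAC = 0.10


@dataclass(frozen=True)
class OneWayRange:
    """A low/high range for one scalar parameter."""

    target: str
    low: float
    high: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(
                f"one-way range for {self.target}: low {self.low} > high {self.high}"
            )


def valid_targets(diseases: tuple[str, ...]) -> list[str]:
    """Scalar parameters recognised by the sensitivity machinery."""
    names = [
        "rr_quit",
        "control_quit_6m",
        "relapse_6_12",
        "relapse_lifetime",
        "background_quit_annual",
        "utility_smoker",
        "utility_former",
        "intervention_cost_per_smoker",
        "royalty_management_per_smoker",
    ]
    names += [f"utility_{d}" for d in diseases]
    names += [f"cost_{d}" for d in diseases]
    return names


def set_parameter(inputs: ModelInputs, target: str, value: float) -> ModelInputs:
    """A copy of ``inputs`` with one scalar parameter replaced.

    Setting ``rr_quit`` widens the stored CI if the new value falls outside
    it, so that the parameter block stays internally consistent.
    """
    if target not in valid_targets(inputs.diseases):
        raise ConfigError(
            f"unknown parameter {target!r}; valid targets: "
            + ", ".join(valid_targets(inputs.diseases))
        )
    quit, util, cost = inputs.quit, inputs.utilities, inputs.costs
    if target == "rr_quit":
        quit = dataclasses.replace(
            quit,
            rr_quit=value,
            rr_quit_ci_low=min(quit.rr_quit_ci_low, value),
            rr_quit_ci_high=max(quit.rr_quit_ci_high, value),
        )
    elif target in (
        "control_quit_6m",
        "relapse_6_12",
        "relapse_lifetime",
        "background_quit_annual",
    ):
        quit = dataclasses.replace(quit, **{target: value})
    elif target == "utility_smoker":
        util = dataclasses.replace(util, smoker_value=value)
    elif target == "utility_former":
        util = dataclasses.replace(util, former_value=value)
    elif target.startswith("utility_"):
        d = target.removeprefix("utility_")
        util = dataclasses.replace(
            util, disease_value={**util.disease_value, d: value}
        )
    elif target == "intervention_cost_per_smoker":
        cost = dataclasses.replace(cost, intervention_cost_per_smoker=value)
    elif target == "royalty_management_per_smoker":
        cost = dataclasses.replace(cost, royalty_management_per_smoker=value)
    else:
        d = target.removeprefix("cost_")
        cost = dataclasses.replace(
            cost, disease_annual_cost={**cost.disease_annual_cost, d: value}
        )
    return dataclasses.replace(inputs, quit=quit, utilities=util, costs=cost)


def one_way(
    inputs: ModelInputs, rng: OneWayRange
) -> tuple[IncrementalResult, IncrementalResult]:
    """Full incremental results at the low and high end of one range."""
    out = []
    for value in (rng.low, rng.high):
        varied = set_parameter(inputs, rng.target, value)
        out.append(
            incremental(
                run_weighted(varied, Arm.INTERVENTION),
                run_weighted(varied, Arm.CONTROL),
            )
        )
    return out[0], out[1]


def default_one_way_ranges() -> tuple[OneWayRange, ...]:
    """The base-case one-way analysis grid."""
    return (
        OneWayRange("rr_quit", 1.80, 2.68, "Relative risk of quitting at 6 months"),
        OneWayRange("relapse_lifetime", 0.21, 0.50, "Lifetime relapse rate"),
        OneWayRange("background_quit_annual", 0.012, 0.028, "Background quit rate"),
        OneWayRange(
            "intervention_cost_per_smoker", 6.70, 62.30, "Intervention cost per smoker"
        ),
        OneWayRange(
            "royalty_management_per_smoker",
            1.0,
            35.0,
            "Royalty and management cost per smoker",
        ),
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


def default_psa_dists(
    inputs: ModelInputs, sd_frac: float = DEFAULT_SD_FRAC
) -> list[DistSpec]:
    """The base-case distribution assignments.

    Only the quit relative risk has a published interval; every other
    sampled parameter takes sd = ``sd_frac`` times its base-case mean.
    """
    q, u, c = inputs.quit, inputs.utilities, inputs.costs
    dists = [
        lognormal_from_ci(
            q.rr_quit, q.rr_quit_ci_low, q.rr_quit_ci_high, target="rr_quit"
        ),
        moments_to_beta(
            q.relapse_lifetime, sd_frac * q.relapse_lifetime, target="relapse_lifetime"
        ),
        moments_to_beta(
            q.background_quit_annual,
            sd_frac * q.background_quit_annual,
            target="background_quit_annual",
        ),
        moments_to_beta(u.smoker_value, sd_frac * u.smoker_value, target="utility_smoker"),
        moments_to_beta(u.former_value, sd_frac * u.former_value, target="utility_former"),
    ]
    for d in inputs.diseases:
        v = u.disease_value[d]
        dists.append(moments_to_beta(v, sd_frac * v, target=f"utility_{d}"))
    for d in inputs.diseases:
        v = c.disease_annual_cost[d]
        dists.append(moments_to_gamma(v, sd_frac * v, target=f"cost_{d}"))
    dists.append(
        moments_to_gamma(
            c.intervention_cost_per_smoker,
            sd_frac * c.intervention_cost_per_smoker,
            target="intervention_cost_per_smoker",
        )
    )
    return dists


def _acceptable(target: str, value: float, base: ModelInputs) -> bool:
    if not np.isfinite(value) or value <= 0:
        return False
    if target == "rr_quit":
        return value * base.quit.control_quit_6m <= 1.0
    return True


def _draw_guarded(dist: DistSpec, base: ModelInputs, rng: np.random.Generator) -> float:
    for _ in range(100):
        v = float(dist.sample(rng))
        if _acceptable(dist.target, v, base):
            return v
    raise ValidationError(
        f"could not draw an admissible value for {dist.target} in 100 attempts"
    )


def sample_inputs(
    base: ModelInputs, dists: list[DistSpec], rng: np.random.Generator
) -> ModelInputs:
    """One joint parameter draw: each targeted parameter replaced by an
    independent draw from its distribution, everything else untouched."""
    out = base
    for dist in dists:
        if not dist.target:
            raise ConfigError("DistSpec without a target cannot be sampled")
        out = set_parameter(out, dist.target, _draw_guarded(dist, base, rng))
    return out


@dataclass
class PSAResults:
    """Per-iteration incremental cost/QALY pairs from the second-order
    Monte Carlo, with the sampled parameter vectors."""

    samples: list[dict[str, float]]
    d_cost: np.ndarray
    d_qaly: np.ndarray
    seed: int
    n: int

    def prob_cost_saving(self) -> float:
        return float((self.d_cost < 0).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(1, self.n + 1),
                "d_cost": self.d_cost,
                "d_qaly": self.d_qaly,
            }
        )


def run_psa(
    base: ModelInputs,
    dists: list[DistSpec] | None = None,
    n: int = 1000,
    seed: int = 20120909,
) -> PSAResults:
    """Second-order Monte Carlo: ``n`` model re-runs with sampled parameters.

    Draws for iteration ``i`` come from substream ``i`` of the seed, so the
    vectorised evaluation below reproduces exactly what ``n`` sequential
    :func:`sample_inputs` + :func:`run_weighted` calls would give.
    """
    if n < 1:
        raise ValidationError(f"PSA iteration count must be >= 1, got {n}")
    if dists is None:
        dists = default_psa_dists(base)
    targets = [d.target for d in dists]
    if len(set(targets)) != len(targets):
        raise ConfigError("duplicate PSA targets")
    for t in targets:
        if t not in valid_targets(base.diseases):
            raise ConfigError(f"unknown PSA target {t!r}")

    children = np.random.SeedSequence(seed).spawn(n)
    draws: dict[str, np.ndarray] = {t: np.empty(n) for t in targets}
    samples: list[dict[str, float]] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        row = {d.target: _draw_guarded(d, base, rng) for d in dists}
        samples.append(row)
        for k, v in row.items():
            draws[k][i] = v

    q, u, c = base.quit, base.utilities, base.costs
    nd = len(base.diseases)

    def vec(key: str, default: float) -> np.ndarray:
        return draws.get(key, np.full(n, default))

    u_d = np.tile([u.disease_value[d] for d in base.diseases], (n, 1))
    cost_d = np.tile([c.disease_annual_cost[d] for d in base.diseases], (n, 1))
    for j, d in enumerate(base.diseases):
        if f"utility_{d}" in draws:
            u_d[:, j] = draws[f"utility_{d}"]
        if f"cost_{d}" in draws:
            cost_d[:, j] = draws[f"cost_{d}"]
    u_s = vec("utility_smoker", u.smoker_value)
    u_f = vec("utility_former", u.former_value)
    rr = vec("rr_quit", q.rr_quit)
    ctrl = vec("control_quit_6m", q.control_quit_6m)
    p21 = vec("relapse_6_12", q.relapse_6_12)
    p30 = vec("relapse_lifetime", q.relapse_lifetime)
    bg = vec("background_quit_annual", q.background_quit_annual)
    bgq = 1.0 - np.sqrt(1.0 - bg)
    cost0_int = vec("intervention_cost_per_smoker", c.intervention_cost_per_smoker) + vec(
        "royalty_management_per_smoker", c.royalty_management_per_smoker
    )

    comp = markov_engine._compiled_epi(base)
    coeffs_by_gender = {}
    for gender in ("male", "female"):
        comp_g = dict(comp[gender])
        comp_g["diseases"] = base.diseases
        coeffs_by_gender[gender] = (
            comp_g,
            markov_engine._reward_coeffs(
                comp_g, u_d, u_s, u_f, cost_d, base.econ.cycle_length
            ),
        )

    totals: dict[Arm, dict[str, np.ndarray]] = {}
    for arm in (Arm.INTERVENTION, Arm.CONTROL):
        first = ctrl * rr if arm is Arm.INTERVENTION else ctrl
        cost0 = cost0_int if arm is Arm.INTERVENTION else 0.0
        t_cost = np.zeros(n)
        t_qaly = np.zeros(n)
        for stratum in base.mix:
            comp_g, coeffs = coeffs_by_gender[stratum.gender]
            (cost, _ly, qaly, _q6, *_), _ = markov_engine._simulate(
                comp_g,
                coeffs,
                first,
                bgq,
                p21,
                p30,
                base.relapse_mode,
                base.econ,
                cost0,
                stratum.start_age,
            )
            t_cost += stratum.weight * cost
            t_qaly += stratum.weight * qaly
        totals[arm] = {"cost": 1000.0 * t_cost, "qaly": 1000.0 * t_qaly}

    return PSAResults(
        samples=samples,
        d_cost=totals[Arm.INTERVENTION]["cost"] - totals[Arm.CONTROL]["cost"],
        d_qaly=totals[Arm.INTERVENTION]["qaly"] - totals[Arm.CONTROL]["qaly"],
        seed=seed,
        n=n,
    )
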