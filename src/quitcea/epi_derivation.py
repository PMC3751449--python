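"""Status-specific rates and sensitivity-analysis distributions.

The epidemiological inputs give *general-population* annual mortality and
disease probabilities.  The cohort model needs them split by smoking
status.  Writing the general rate as a prevalence-weighted mix,

    M_gen = M_s * P_s + M_f * P_f + M_n * P_n,

with M_s = RR_s * M_n and M_f = RR_f * M_n, the never-smoker rate is
recovered by inversion:

    M_n = M_gen / (RR_s * P_s + RR_f * P_f + P_n),

and the smoker / former-smoker rates follow by multiplying with their
relative risks.  The same decomposition applies to each disease
probability.  Annual probabilities are converted to 6-month cycle
probabilities under a constant hazard: ``p_cycle = 1 - (1 - p_annual)**0.5``.

The module also fits the parametric distributions used by the
probabilistic sensitivity analysis from summary statistics: a lognormal
from a point estimate with its 95% CI (for relative risks), and beta /
gamma distributions by the method of moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params_io import DISEASES, EpiTables, ValidationError

_Z975 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class AgeRates:
    """Per-cycle probabilities at one (age, gender): death and disease-event
    probabilities for smokers and former smokers."""

    m_smoker: float
    m_former: float
    q_smoker: dict[str, float]
    q_former: dict[str, float]


@dataclass
class StatusRates:
    """Smoking-status-specific rates on the full age-by-gender grid.

    ``annual`` holds annual probabilities (columns ``m_never``, ``m_smoker``,
    ``m_former`` and ``q_<status>_<disease>``); ``cycle`` holds their 6-month
    equivalents.  Both are indexed like the source :class:`EpiTables`.
    """

    annual: pd.DataFrame
    cycle: pd.DataFrame
    diseases: tuple[str, ...] = DISEASES

    def at(self, age: int, gender: str) -> AgeRates:
        row = self.cycle.loc[(age, gender)]
        return AgeRates(
            m_smoker=float(row["m_smoker"]),
            m_former=float(row["m_former"]),
            q_smoker={d: float(row[f"q_smoker_{d}"]) for d in self.diseases},
            q_former={d: float(row[f"q_former_{d}"]) for d in self.diseases},
        )


def annual_to_cycle(p_annual):
    """Convert an annual probability to a 6-month probability under a
    constant hazard: ``1 - (1 - p)**0.5``.  Accepts scalars or arrays."""
    arr = np.asarray(p_annual, dtype=float)
    if np.any((arr < 0.0) | (arr > 1.0)):
        raise ValidationError(f"annual probability outside [0, 1]: {p_annual!r}")
    out = 1.0 - np.sqrt(1.0 - arr)
    if np.isscalar(p_annual) or np.ndim(p_annual) == 0:
        return float(out)
    return out


def _invert_mix(
    general: pd.Series,
    rr_s: pd.Series,
    rr_f: pd.Series,
    p_s: pd.Series,
    p_f: pd.Series,
    p_n: pd.Series,
    label: str,
) -> tuple[pd.Series, pd.Series, pd.Series]:
    denom = rr_s * p_s + rr_f * p_f + p_n
    if (denom <= 0).any():
        raise RuntimeError(f"non-positive mixing denominator for {label}")
    never = general / denom
    smoker = rr_s * never
    former = rr_f * never
    for status, series in (("smoker", smoker), ("former", former), ("never", never)):
        bad = series.index[series > 1.0]
        if len(bad):
            age, gender = bad[0]
            raise ValidationError(
                f"derived {label} probability for {status} exceeds 1 at "
                f"age={age}, gender={gender}"
            )
    return never, smoker, former


def derive_status_rates(epi: EpiTables) -> StatusRates:
    """Split general-population rates by smoking status via the mixing
    inversion, for death and each disease, and convert to 6-month cycles.

    The output satisfies the reconstruction identity: re-mixing the annual
    status-specific rates by prevalence reproduces every general-population
    annual rate to floating-point accuracy.
    """
    t = epi.table
    annual = pd.DataFrame(index=t.index)
    never, smoker, former = _invert_mix(
        t["m_gen"],
        t["rr_death_smoker"],
        t["rr_death_former"],
        t["p_smoker"],
        t["p_former"],
        t["p_never"],
        "mortality",
    )
    annual["m_never"], annual["m_smoker"], annual["m_former"] = never, smoker, former
    for d in epi.diseases:
        never, smoker, former = _invert_mix(
            t[f"prev_{d}"],
            t[f"rr_{d}_smoker"],
            t[f"rr_{d}_former"],
            t["p_smoker"],
            t["p_former"],
            t["p_never"],
            d,
        )
        annual[f"q_never_{d}"] = never
        annual[f"q_smoker_{d}"] = smoker
        annual[f"q_former_{d}"] = former
    cycle = 1.0 - np.sqrt(1.0 - annual)
    return StatusRates(annual=annual, cycle=cycle, diseases=epi.diseases)


# ---------------------------------------------------------------------------
# sensitivity-analysis distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistSpec:
    """A parametric distribution perturbing one model parameter.

    ``lognormal``: param1 = mu, param2 = sigma (of log).
    ``beta``:      param1 = alpha, param2 = beta.
    ``gamma``:     param1 = shape, param2 = scale.
    """

    family: str
    param1: float
    param2: float
    target: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "beta", "gamma"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal":
            if self.param2 <= 0:
                raise ValidationError("lognormal sigma must be > 0")
        elif self.param1 <= 0 or self.param2 <= 0:
            raise ValidationError(
                f"{self.family} parameters must be > 0, got "
                f"({self.param1}, {self.param2})"
            )

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "lognormal":
            return rng.lognormal(mean=self.param1, sigma=self.param2, size=size)
        if self.family == "beta":
            return rng.beta(self.param1, self.param2, size=size)
        return rng.gamma(shape=self.param1, scale=self.param2, size=size)

    @property
    def mean(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.param1 + 0.5 * self.param2**2)
        if self.family == "beta":
            return self.param1 / (self.param1 + self.param2)
        return self.param1 * self.param2


def lognormal_from_ci(point: float, lo: float, hi: float, target: str = "") -> DistSpec:
    """Lognormal whose median is ``point`` and whose (lo, hi) span the
    central 95% interval on the log scale (Wald construction)."""
    if not (0.0 < lo <= point <= hi):
        raise ValidationError(
            f"require 0 < lo <= point <= hi, got ({lo}, {point}, {hi})"
        )
    sigma = (math.log(hi) - math.log(lo)) / (2.0 * _Z975)
    if sigma <= 0.0:
        raise ValidationError("degenerate confidence interval: sigma must be > 0")
    return DistSpec("lognormal", math.log(point), sigma, target)


def moments_to_beta(mean: float, sd: float, target: str = "") -> DistSpec:
    """Beta distribution matching a mean and standard deviation."""
    if not (0.0 < mean < 1.0):
        raise ValidationError(f"beta mean must lie in (0, 1), got {mean!r}")
    if sd <= 0.0:
        raise ValidationError("sd must be > 0")
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise ValidationError(
            f"sd {sd} too large for a beta distribution with mean {mean}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return DistSpec("beta", mean * nu, (1.0 - mean) * nu, target)


def moments_to_gamma(mean: float, sd: float, target: str = "") -> DistSpec:
    """Gamma distribution matching a mean and standard deviation."""
    if mean <= 0.0 or sd <= 0.0:
        raise ValidationError("gamma mean and sd must be > 0")
    return DistSpec("gamma", mean * mean / (sd * sd), sd * sd / mean, target)
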