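"""Synthetic UK-like epidemiological tables.

The cohort model is driven by age-by-gender tables of all-cause mortality,
smoking-status prevalence, disease probabilities and relative risks by
smoking status.  The published sources behind such tables (national health
surveys, long-run cohort studies of smokers) are not redistributable, so
this module generates tables with the same statistical structure:

* Gompertz all-cause annual mortality, ``m(age) = a0 * exp(b * (age - 16))``
  per gender -- monotone increasing in age;
* logistic decline of current-smoker prevalence with age, and a linear ramp
  (capped) of former-smoker prevalence; never-smokers take the remainder;
* exponential growth with age of each disease probability;
* banded relative risks (> 1) for death and each disease, for smokers and
  former smokers versus never-smokers;
* optional multiplicative lognormal jitter so that probabilities stay
  positive and tables resemble the wobble of real survey data.

:func:`default_uk_like` returns the packaged specification used throughout
the test-suite and the acceptance analysis.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params_io import AGE_MAX, AGE_MIN, DISEASES, GENDERS, EpiTables

#: Probabilities are clipped here before renormalisation.
PROB_CAP = 0.9


@dataclass(frozen=True)
class RRBand:
    """Relative risks versus never-smokers, constant within an age band.

    ``death`` and each ``disease`` entry are (smoker, former-smoker) pairs.
    Bands are inclusive on both ends.
    """

    age_lo: int
    age_hi: int
    death: tuple[float, float]
    disease: dict[str, tuple[float, float]]


@dataclass(frozen=True)
class SynthSpec:
    """Generator specification; see the module docstring for the forms."""

    gompertz_a: dict[str, float]
    gompertz_b: dict[str, float]
    smoking_prev_start: float
    smoking_prev_slope: float
    smoking_prev_pivot: float
    former_base: float
    former_slope: float
    former_max: float
    disease_prev_base: dict[str, float]
    disease_prev_growth: dict[str, float]
    gender_factor: dict[str, float]
    rr_bands: tuple[RRBand, ...]
    seed: int = 20120909
    noise_sd: float = 0.0
    diseases: tuple[str, ...] = DISEASES


def default_uk_like() -> SynthSpec:
    """The packaged UK-like specification.

    Constants are chosen for realism of order of magnitude: Gompertz
    mortality close to recent UK life tables, smoker prevalence around a
    quarter of young adults declining into old age, disease probabilities on
    the prevalence scale used by prior cessation models, and smoker
    relative risks of roughly 2 for death in midlife with large excesses for
    lung cancer and COPD.
    """
    return SynthSpec(
        gompertz_a={"male": 4.0e-4, "female": 2.8e-4},
        gompertz_b={"male": 0.080, "female": 0.082},
        smoking_prev_start=0.26,
        smoking_prev_slope=0.08,
        smoking_prev_pivot=62.0,
        former_base=0.05,
        former_slope=0.005,
        former_max=0.40,
        disease_prev_base={
            "lung_cancer": 2.0e-4,
            "stroke": 5.0e-3,
            "mi": 4.0e-3,
            "copd": 7.0e-3,
            "chd": 1.5e-2,
        },
        disease_prev_growth={
            "lung_cancer": 0.050,
            "stroke": 0.040,
            "mi": 0.040,
            "copd": 0.038,
            "chd": 0.035,
        },
        gender_factor={"male": 1.10, "female": 0.90},
        rr_bands=(
            RRBand(
                16,
                34,
                death=(1.6, 1.2),
                disease={
                    "lung_cancer": (10.0, 4.0),
                    "stroke": (1.8, 1.3),
                    "mi": (2.0, 1.4),
                    "copd": (6.0, 3.0),
                    "chd": (2.0, 1.4),
                },
            ),
            RRBand(
                35,
                69,
                death=(2.2, 1.4),
                disease={
                    "lung_cancer": (12.0, 4.0),
                    "stroke": (1.8, 1.3),
                    "mi": (2.0, 1.4),
                    "copd": (6.0, 3.0),
                    "chd": (2.0, 1.4),
                },
            ),
            RRBand(
                70,
                100,
                death=(1.5, 1.2),
                disease={
                    "lung_cancer": (8.0, 3.0),
                    "stroke": (1.4, 1.2),
                    "mi": (1.4, 1.2),
                    "copd": (3.5, 2.2),
                    "chd": (1.4, 1.2),
                },
            ),
        ),
        seed=20120909,
        noise_sd=0.02,
    )


def _band_arrays(
    spec: SynthSpec, ages: np.ndarray
) -> dict[str, np.ndarray]:
    """Expand banded relative risks to per-age arrays."""
    cols: dict[str, np.ndarray] = {
        "rr_death_smoker": np.empty_like(ages, dtype=float),
        "rr_death_former": np.empty_like(ages, dtype=float),
    }
    for d in spec.diseases:
        cols[f"rr_{d}_smoker"] = np.empty_like(ages, dtype=float)
        cols[f"rr_{d}_former"] = np.empty_like(ages, dtype=float)
    covered = np.zeros_like(ages, dtype=bool)
    for band in spec.rr_bands:
        mask = (ages >= band.age_lo) & (ages <= band.age_hi)
        covered |= mask
        cols["rr_death_smoker"][mask] = band.death[0]
        cols["rr_death_former"][mask] = band.death[1]
        for d in spec.diseases:
            s, f = band.disease[d]
            cols[f"rr_{d}_smoker"][mask] = s
            cols[f"rr_{d}_former"][mask] = f
    if not covered.all():
        raise ValueError(
            f"rr_bands leave ages uncovered: {ages[~covered].tolist()}"
        )
    return cols


def _cap(name: str, values: np.ndarray) -> np.ndarray:
    if (values > PROB_CAP).any():
        warnings.warn(
            f"synthetic {name} exceeds {PROB_CAP} before clipping; clipped",
            stacklevel=3,
        )
    return np.clip(values, 0.0, PROB_CAP)


def generate_epi_tables(spec: SynthSpec) -> EpiTables:
    """Generate an :class:`EpiTables` from a :class:`SynthSpec`.

    Deterministic given ``spec.seed``.  With ``noise_sd = 0`` the mortality
    curve is strictly increasing and smoker prevalence strictly decreasing
    in age.
    """
    rng = np.random.default_rng(spec.seed)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    rr_cols = _band_arrays(spec, ages)
    frames = []
    for gender in GENDERS:
        rel = ages - AGE_MIN

        def jitter(x: np.ndarray) -> np.ndarray:
            return x * np.exp(rng.normal(0.0, spec.noise_sd, size=x.shape))

        m_gen = spec.gompertz_a[gender] * np.exp(spec.gompertz_b[gender] * rel)
        m_gen = _cap("m_gen", jitter(m_gen))

        p_smoker = spec.smoking_prev_start / (
            1.0 + np.exp(spec.smoking_prev_slope * (ages - spec.smoking_prev_pivot))
        )
        p_former = np.minimum(
            spec.former_base + spec.former_slope * rel, spec.former_max
        )
        p_never = 1.0 - p_smoker - p_former
        if (p_never < 0).any():
            raise ValueError("smoker + former prevalence exceeds 1 by construction")
        p_smoker, p_former, p_never = (
            jitter(p_smoker),
            jitter(p_former),
            jitter(p_never),
        )
        total = p_smoker + p_former + p_never
        p_smoker, p_former, p_never = p_smoker / total, p_former / total, p_never / total

        cols: dict[str, np.ndarray] = {
            "m_gen": m_gen,
            "p_smoker": p_smoker,
            "p_former": p_former,
            "p_never": p_never,
        }
        for d in spec.diseases:
            prev = (
                spec.disease_prev_base[d]
                * spec.gender_factor[gender]
                * np.exp(spec.disease_prev_growth[d] * rel)
            )
            cols[f"prev_{d}"] = _cap(f"prev_{d}", jitter(prev))
        frame = pd.DataFrame({"age": ages, "gender": gender, **cols, **rr_cols})
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    epi = EpiTables(
        table.set_index(["age", "gender"]).sort_index(), diseases=spec.diseases
    )
    epi.validate()
    return epi


def generate_default(seed: int | None = None, noise_sd: float | None = None) -> EpiTables:
    """Default UK-like tables, optionally re-seeded."""
    spec = default_uk_like()
    updates: dict[str, object] = {}
    if seed is not None:
        updates["seed"] = seed
    if noise_sd is not None:
        updates["noise_sd"] = noise_sd
    if updates:
        spec = dataclasses.replace(spec, **updates)
    return generate_epi_tables(spec)
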