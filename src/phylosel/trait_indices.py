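"""Per-species sex-bias indices and selection effect sizes.

Implements the derived quantities of the comparative analysis:

* opportunity for (sexual) selection ``I`` / ``I_s`` — the standardized
  variance (variance / mean**2) of reproductive or mating success within a
  sex;
* the Bateman gradient ``beta_ss`` — the OLS slope of reproductive success
  on mating success;
* sex-difference effect sizes: ``delta_I`` and ``delta_I_s`` as lnCVR (the
  natural log of the male/female ratio of coefficients of variation) and
  ``delta_beta_ss`` as Hedges' d, all signed so that positive values mean
  stronger selection on males;
* sexual size dimorphism as ``ln(male size / female size)``, with the cubic
  length-to-weight conversion (``weight = c * length**3``; the constant c is
  shared between the sexes and cancels in the ratio);
* the two gametic bias indices of anisogamy, and the five-point male care
  score.

All logarithms are natural.  Variances computed from individuals use the
sample (n-1) convention.  Every function raises on invalid input rather
than returning NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DegenerateInputError",
    "ln_cvr",
    "hedges_d",
    "opportunity_for_selection",
    "bateman_gradient",
    "ssd",
    "gamete_size_bias",
    "gametic_investment_bias",
    "care_score",
    "CareScore",
    "COLUMN_DICTIONARY",
]


class DegenerateInputError(ValueError):
    """Inputs are syntactically valid but make the statistic undefined."""


#: Column dictionary for species trait tables consumed by the pipeline.
COLUMN_DICTIONARY: dict[str, str] = {
    "species": "unique species identifier (matches tree tip labels)",
    "male_mass_g": "adult male body mass, grams",
    "female_mass_g": "adult female body mass, grams",
    "male_gamete_size": "sperm size (volume or length proxy), any unit shared across species",
    "female_gamete_mass_g": "egg / neonate mass, grams",
    "testis_mass_g": "combined testis mass, grams",
    "clutch_size": "number of eggs (offspring) per breeding event",
    "percent_male_care": "percent of parental care provided by males, 0-100",
    "has_care": "boolean; False for species exhibiting no care at all",
    "rs_mean_m / rs_sd_m / rs_n_m": "male reproductive-success mean / SD / sample size",
    "rs_mean_f / rs_sd_f / rs_n_f": "female reproductive-success mean / SD / sample size",
    "ms_mean_m / ms_sd_m / ms_n_m": "male mating-success mean / SD / sample size",
    "ms_mean_f / ms_sd_f / ms_n_f": "female mating-success mean / SD / sample size",
    "bss_mean_m / bss_sd_m / bss_n_m": "male Bateman-gradient mean / SD / n (across studies or bootstrap)",
    "bss_mean_f / bss_sd_f / bss_n_f": "female Bateman-gradient mean / SD / n",
    "delta_I": "lnCVR of reproductive success, male vs female (may be supplied pre-computed)",
    "delta_I_s": "lnCVR of mating success, male vs female",
    "delta_beta_ss": "Hedges' d of the Bateman gradient, male vs female",
}


def ln_cvr(
    mean_m: float,
    sd_m: float,
    n_m: int,
    mean_f: float,
    sd_f: float,
    n_f: int,
    small_sample_correction: bool = True,
) -> float:
    """Log coefficient-of-variation ratio, male relative to female.

    ``ln((sd_m/mean_m) / (sd_f/mean_f))`` plus, when
    ``small_sample_correction`` is on, the additive term
    ``1/(2(n_m-1)) - 1/(2(n_f-1))``.  Positive values indicate greater
    relative variability — here, more intense selection — in males.
    """
    for label, mean, sd, n in (("male", mean_m, sd_m, n_m), ("female", mean_f, sd_f, n_f)):
        if not (mean > 0):
            raise DegenerateInputError(f"{label} mean must be > 0 for a CV (got {mean})")
        if not (sd > 0):
            raise DegenerateInputError(f"{label} SD must be > 0 (got {sd})")
        if n < 2:
            raise DegenerateInputError(f"{label} n must be >= 2 (got {n})")
    value = math.log((sd_m / mean_m) / (sd_f / mean_f))
    if small_sample_correction:
        value += 1.0 / (2 * (n_m - 1)) - 1.0 / (2 * (n_f - 1))
    return value


def hedges_d(
    mean_m: float, sd_m: float, n_m: int, mean_f: float, sd_f: float, n_f: int
) -> float:
    """Hedges' d: bias-corrected standardized mean difference, male minus female.

    ``d = (mean_m - mean_f) / s_pooled * J`` with the pooled SD
    ``s_pooled = sqrt(((n_m-1) sd_m^2 + (n_f-1) sd_f^2) / (n_m+n_f-2))``
    and the small-sample factor ``J = 1 - 3 / (4 (n_m+n_f-2) - 1)``.
    """
    if n_m < 2 or n_f < 2:
        raise DegenerateInputError("need n >= 2 per sex for a pooled SD")
    if sd_m < 0 or sd_f < 0:
        raise DegenerateInputError("SDs must be non-negative")
    if sd_m == 0 and sd_f == 0:
        raise DegenerateInputError("both SDs zero: standardized difference undefined")
    df = n_m + n_f - 2
    s_pooled = math.sqrt(((n_m - 1) * sd_m**2 + (n_f - 1) * sd_f**2) / df)
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return (mean_m - mean_f) / s_pooled * j


def opportunity_for_selection(success: Sequence[float]) -> float:
    """Standardized variance of success: sample variance / mean**2.

    With reproductive success this is the opportunity for selection I;
    with mating success it is the opportunity for sexual selection I_s.
    """
    x = np.asarray(success, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DegenerateInputError("need >= 2 individual success values")
    mean = x.mean()
    if mean <= 0:
        raise DegenerateInputError(f"mean success must be > 0 (got {mean})")
    return float(x.var(ddof=1) / mean**2)


def bateman_gradient(
    mating_success: Sequence[float], reproductive_success: Sequence[float]
) -> float:
    """OLS slope of reproductive success on mating success."""
    ms = np.asarray(mating_success, dtype=float)
    rs = np.asarray(reproductive_success, dtype=float)
    if ms.shape != rs.shape or ms.ndim != 1:
        raise ValueError("mating and reproductive success must be equal-length vectors")
    if ms.size < 3:
        raise DegenerateInputError("need >= 3 individuals for a slope")
    ms_c = ms - ms.mean()
    denom = float(ms_c @ ms_c)
    if denom == 0.0:
        raise DegenerateInputError("mating success is constant: slope undefined")
    return float(ms_c @ (rs - rs.mean()) / denom)


def ssd(male_size: float, female_size: float, dimension: str = "weight") -> float:
    """Sexual size dimorphism: ln(male weight / female weight).

    ``dimension='length'`` applies the cubic conversion
    ``weight = c * length**3`` (c identical in both sexes, so it cancels),
    giving ``3 * ln(male_length / female_length)``.  Positive values mean
    males are larger.
    """
    if male_size <= 0 or female_size <= 0:
        raise ValueError("sizes must be > 0")
    if dimension == "weight":
        return math.log(male_size / female_size)
    if dimension == "length":
        return 3.0 * math.log(male_size / female_size)
    raise ValueError(f"dimension must be 'weight' or 'length', got {dimension!r}")


def gamete_size_bias(
    male_gamete_size: float,
    male_mass: float,
    female_gamete_size: float,
    female_mass: float,
) -> float:
    """Anisogamy index: ln of the ratio of mass-relative gamete sizes.

    ``ln((male_gamete_size / male_mass) / (female_gamete_size / female_mass))``.
    Zero means relative isogamy; the algebra makes positive values a
    male-biased relative gamete size.
    """
    vals = (male_gamete_size, male_mass, female_gamete_size, female_mass)
    if any(v <= 0 for v in vals):
        raise ValueError("all gamete sizes and masses must be > 0")
    return math.log(
        (male_gamete_size / male_mass) / (female_gamete_size / female_mass)
    )


def gametic_investment_bias(
    testis_mass: float,
    male_mass: float,
    female_gamete_mass: float,
    clutch_size: float,
    female_mass: float,
) -> float:
    """Gametic investment index comparing testis mass to per-clutch egg mass.

    ``ln((testis_mass / male_mass) / (female_gamete_mass * clutch_size / female_mass))``.
    """
    vals = (testis_mass, male_mass, female_gamete_mass, clutch_size, female_mass)
    if any(v <= 0 for v in vals):
        raise ValueError("all inputs must be > 0")
    return math.log(
        (testis_mass / male_mass)
        / (female_gamete_mass * clutch_size / female_mass)
    )


@dataclass(frozen=True)
class CareScore:
    """Five-point male parental-care score plus a care/no-care flag."""

    score: int | None
    has_care: bool


# Qualitative labels accepted alongside a numeric percent.
_CARE_LABELS = {
    "female_only": 0.0,
    "biparental": 50.0,
    "male_only": 100.0,
}


def care_score(percent_male_care: float | str | None, has_care: bool = True) -> CareScore:
    """Bin percent male care onto the five-point scale.

    0 — female-only care (exactly 0%); 1 — (0, 33.3]% male care;
    2 — (33.3, 66.7]%; 3 — (66.7, 100)%; 4 — male-only care (exactly 100%).
    Boundary percents fall in the lower bin.  Species with no care at all
    (``has_care=False`` or label ``'none'``) get no score: the care models
    use only species exhibiting some level of care.
    """
    if isinstance(percent_male_care, str):
        label = percent_male_care.strip().lower()
        if label in ("none", "no_care"):
            return CareScore(score=None, has_care=False)
        if label not in _CARE_LABELS:
            raise ValueError(f"unrecognized care label {percent_male_care!r}")
        percent_male_care = _CARE_LABELS[label]
    if not has_care or percent_male_care is None:
        return CareScore(score=None, has_care=False)
    p = float(percent_male_care)
    if not (0.0 <= p <= 100.0):
        raise ValueError(f"percent male care must be in [0, 100], got {p}")
    if p == 0.0:
        score = 0
    elif p == 100.0:
        score = 4
    elif p <= 100.0 / 3.0:
        score = 1
    elif p <= 200.0 / 3.0:
        score = 2
    else:
        score = 3
    return CareScore(score=score, has_care=True)
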