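"""Closed-form expected transcription loss and dose/density/count conversions.

The expected fractional transcription loss after ``M`` lesions placed
uniformly on the diploid double-stranded genome is

    E[w_M] = sum_j alpha_j * (1 - (1 - q_j)^M)

with ``q_j = l_j / (4 L)`` the per-lesion probability of hitting the
transcribed strand of one allele of gene j, and ``alpha_j`` the normalized
nascent-expression weights. Under a constant daily accumulation rate ``r``
(unrepaired lesions/day), ``M = r * (t - t0)`` with age ``t`` in days.

Lesion density is expressed per 100 kb of the *haploid* genome (that is how
the published dose tables count lesions), even though the placement
probability is defined against 4L.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog

#: UV-C conversion: lesions per 100 kb induced per J/m^2. The literature value
#: is approximate; override per call where a different calibration applies.
UV_LESIONS_PER_100KB_PER_JM2 = 0.55

_WINDOW_BP = 100_000.0


def _round_half_away(x: float) -> int:
    """Round half away from zero (lesion counts are event counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_loss(catalog: GeneCatalog, M: int | float) -> float:
    """E[w_M] = sum_j alpha_j (1 - (1-q_j)^M), numerically stable in M.

    (1-q)^M is evaluated as exp(M*log1p(-q)) so tiny q and huge M do not
    underflow; M may be a float when interpolating, but lesions are events
    and integer M is the modeled quantity.
    """
    if M < 0:
        raise ValueError("lesion count M must be non-negative")
    # 1 - (1-q)^M  ==  -expm1(M * log1p(-q))
    per_gene = -np.expm1(M * np.log1p(-catalog.q))
    # rounding in the weighted sum can overshoot 1 by ~1 ulp at saturation
    return float(min(1.0, max(0.0, np.dot(catalog.alpha, per_gene))))


@dataclass
class LossCurve:
    """Expected-loss curve over a grid of lesion counts (or ages in days).

    ``expected`` is the mean across replicate catalogs; ``sd`` and the normal
    95% CI quantify catalog-to-catalog spread (zero for a single catalog).
    """

    grid: np.ndarray
    expected: np.ndarray
    sd: np.ndarray
    ci95_lo: np.ndarray
    ci95_hi: np.ndarray
    grid_is_age: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_value": self.grid,
                "expected_loss": self.expected,
                "sd": self.sd,
                "ci95_lo": self.ci95_lo,
                "ci95_hi": self.ci95_hi,
            }
        )


def loss_curve(
    catalogs: GeneCatalog | Sequence[GeneCatalog],
    grid: Sequence[float],
    rate: float | None = None,
    t0_days: float = 0.0,
    grid_is_age: bool = False,
) -> LossCurve:
    """Evaluate E[w] over a grid of lesion counts M, or ages (days) via M=r*t.

    With several replicate catalogs (e.g., one per sequenced animal) the curve
    reports their per-point mean, SD and normal-approximation 95% CI.
    """
    if isinstance(catalogs, GeneCatalog):
        catalogs = [catalogs]
    grid_arr = np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0:
        raise ValueError("grid is empty")
    if grid_is_age:
        if rate is None:
            raise ValueError("an age grid requires the accumulation rate r")
        Ms = [age_to_count(rate, t, t0_days) for t in grid_arr]
    else:
        Ms = [int(_round_half_away(m)) for m in grid_arr]
    values = np.array([[expected_loss(cat, M) for M in Ms] for cat in catalogs])
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1) if len(catalogs) > 1 else np.zeros_like(mean)
    half = 1.959963984540054 * sd / math.sqrt(len(catalogs))
    return LossCurve(grid_arr, mean, sd, mean - half, mean + half, grid_is_age)


# ---------------------------------------------------------------------------
# Conversions


def uv_dose_to_density(
    dose_J_m2: float, factor: float = UV_LESIONS_PER_100KB_PER_JM2
) -> float:
    """UV-C dose (J/m^2) -> lesion density (TBLs per 100 kb)."""
    if dose_J_m2 < 0:
        raise ValueError("UV dose must be non-negative")
    return factor * dose_J_m2


def density_to_count(density_per_100kb: float, genome_length_L: float) -> int:
    """Lesion density (per 100 kb haploid) -> whole-genome lesion count M."""
    if density_per_100kb < 0:
        raise ValueError("lesion density must be non-negative")
    if genome_length_L <= 0:
        raise ValueError("genome length must be positive")
    return _round_half_away(density_per_100kb * genome_length_L / _WINDOW_BP)


def count_to_density(M: float, genome_length_L: float) -> float:
    """Whole-genome lesion count M -> density per 100 kb (inverse of above)."""
    if M < 0:
        raise ValueError("lesion count must be non-negative")
    if genome_length_L <= 0:
        raise ValueError("genome length must be positive")
    return M * _WINDOW_BP / genome_length_L


def age_to_count(r: float, t_days: float, t0_days: float = 0.0) -> int:
    """M = round(r * (t - t0)): lesions accumulated since the zero-loss age."""
    if r < 0:
        raise ValueError("accumulation rate must be non-negative")
    if t0_days < 0:
        raise ValueError("t0 must be non-negative")
    if t_days < t0_days:
        raise ValueError(f"age {t_days} d precedes the zero-loss age {t0_days} d")
    return _round_half_away(r * (t_days - t0_days))
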