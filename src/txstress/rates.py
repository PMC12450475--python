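"""Calibration of the daily lesion-accumulation rate r and repair arithmetic.

For each genotype the model is calibrated on a single longitudinal time point:
the rate r (unrepaired lesions/day) is the value whose implied lesion count
``M = round(r * (t - t0))`` makes the closed-form expected loss match the
observed loss at that point. Because E[w_M] is monotone in M, the integer M is
found by bisection and r = M / (t - t0). The remaining time points are used
for validation (absolute/relative error). With replicate catalogs (one per
sequenced animal), r is fit per catalog and reported as mean +/- SD.

The default calibration point is the first measurement, with t0 = 0 (lesions
accumulate from birth) — appropriate for repair-deficient genotypes that
already show large loss at their first time point. For slowly accumulating
(wildtype-like) series whose first point is defined as lossless, use
``calibrate_on="last"`` with ``t0_weeks`` set to that first age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .model import expected_loss

DAYS_PER_WEEK = 7.0


@dataclass
class LongitudinalLossSeries:
    """Observed transcription loss (%) of one genotype along age (weeks)."""

    genotype: str
    age_weeks: np.ndarray
    loss_pct: np.ndarray
    sem_pct: np.ndarray
    t0_weeks: float = 0.0

    def __post_init__(self) -> None:
        self.age_weeks = np.asarray(self.age_weeks, dtype=float)
        self.loss_pct = np.asarray(self.loss_pct, dtype=float)
        self.sem_pct = np.asarray(self.sem_pct, dtype=float)
        if np.any(np.diff(self.age_weeks) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any((self.loss_pct < 0) | (self.loss_pct > 100)):
            raise ValueError("losses must lie in [0, 100] percent")
        if self.t0_weeks < 0 or self.t0_weeks > self.age_weeks[0]:
            raise ValueError("t0 must lie in [0, first measured age]")

    def age_days(self) -> np.ndarray:
        return self.age_weeks * DAYS_PER_WEEK

    @property
    def t0_days(self) -> float:
        return self.t0_weeks * DAYS_PER_WEEK

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": self.genotype,
                "age_weeks": self.age_weeks,
                "loss_pct": self.loss_pct,
                "sem_pct": self.sem_pct,
            }
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, genotype: str | None = None, t0_weeks: float = 0.0
    ) -> "LongitudinalLossSeries":
        table = pd.read_csv(path, sep="\t")
        if genotype is not None:
            table = table[table["genotype"] == genotype]
        if table.empty:
            raise ValueError(f"no rows for genotype {genotype!r}")
        table = table.sort_values("age_weeks")
        return cls(
            genotype=str(table["genotype"].iloc[0]),
            age_weeks=table["age_weeks"].to_numpy(),
            loss_pct=table["loss_pct"].to_numpy(),
            sem_pct=table.get("sem_pct", pd.Series(np.zeros(len(table)))).to_numpy(),
            t0_weeks=t0_weeks,
        )


@dataclass
class RateFit:
    """Calibrated daily lesion rate with per-catalog spread."""

    genotype: str
    rate_per_day: float
    rate_sd: float
    per_catalog_rates: np.ndarray
    calibration_index: int
    calibration_age_weeks: float
    t0_weeks: float
    validation: pd.DataFrame | None = field(default=None)

    @property
    def rate_rounded(self) -> int:
        """Rate to the nearest whole lesion per day (reporting convention)."""
        return int(round(self.rate_per_day))


def invert_expected_loss(catalog: GeneCatalog, target_loss: float) -> int:
    """Smallest-error integer M with E[w_M] ~= target_loss (fraction in [0,1)).

    E[w_M] is strictly increasing in M (toward sum(alpha)), so bisect for the
    first M whose expected loss reaches the target, then keep whichever of
    M-1, M lies closer.
    """
    if target_loss < 0:
        raise ValueError("target loss must be non-negative")
    if target_loss == 0:
        return 0
    asymptote = float(catalog.alpha.sum())
    if target_loss >= asymptote:
        raise ValueError(
            f"target loss {target_loss:.4f} is at or above the model asymptote "
            f"sum(alpha) = {asymptote:.4f}; no finite lesion count reaches it"
        )
    hi = 1
    while expected_loss(catalog, hi) < target_loss:
        hi *= 2
    lo = hi // 2 if hi > 1 else 0
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if expected_loss(catalog, mid) < target_loss:
            lo = mid
        else:
            hi = mid
    below = abs(expected_loss(catalog, lo) - target_loss)
    above = abs(expected_loss(catalog, hi) - target_loss)
    return lo if below <= above else hi


def calibrate_rate(
    catalogs: GeneCatalog | Sequence[GeneCatalog],
    series: LongitudinalLossSeries,
    calibrate_on: str | int = "first",
    validate: bool = True,
) -> RateFit:
    """Fit r from one time point of the series; optionally validate the rest."""
    if isinstance(catalogs, GeneCatalog):
        catalogs = [catalogs]
    n_points = len(series.age_weeks)
    if calibrate_on == "first":
        idx = 0
    elif calibrate_on == "last":
        idx = n_points - 1
    else:
        idx = int(calibrate_on)
        if not 0 <= idx < n_points:
            raise ValueError(f"calibration index {idx} out of range")
    delta_days = series.age_days()[idx] - series.t0_days
    if delta_days <= 0:
        raise ValueError(
            "calibration point coincides with the zero-loss age t0; "
            "no accumulation interval to fit over"
        )
    target = series.loss_pct[idx] / 100.0
    rates = np.array(
        [invert_expected_loss(cat, target) / delta_days for cat in catalogs]
    )
    fit = RateFit(
        genotype=series.genotype,
        rate_per_day=float(rates.mean()),
        rate_sd=float(rates.std(ddof=1)) if len(rates) > 1 else 0.0,
        per_catalog_rates=rates,
        calibration_index=idx,
        calibration_age_weeks=float(series.age_weeks[idx]),
        t0_weeks=series.t0_weeks,
    )
    if validate:
        fit.validation = validate_rate(fit, catalogs, series)
    return fit


def validate_rate(
    fit: RateFit,
    catalogs: GeneCatalog | Sequence[GeneCatalog],
    series: LongitudinalLossSeries,
) -> pd.DataFrame:
    """Model-vs-data errors at every non-calibration time point.

    Absolute error is |predicted - observed| loss in percentage points;
    relative error divides by the observed loss (x100). The last row holds
    the across-point averages.
    """
    if isinstance(catalogs, GeneCatalog):
        catalogs = [catalogs]
    rows = []
    for i, (age_w, t_days) in enumerate(zip(series.age_weeks, series.age_days())):
        if i == fit.calibration_index:
            continue
        M = int(round(fit.rate_per_day * (t_days - series.t0_days)))
        predicted = float(
            np.mean([expected_loss(cat, M) for cat in catalogs]) * 100.0
        )
        observed = series.loss_pct[i]
        abs_err = abs(predicted - observed)
        rel_err = abs_err / observed * 100.0 if observed > 0 else np.nan
        rows.append(
            {
                "age_weeks": age_w,
                "M": M,
                "predicted_loss_pct": predicted,
                "observed_loss_pct": observed,
                "abs_error_pct": abs_err,
                "rel_error_pct": rel_err,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        means = table[["abs_error_pct", "rel_error_pct"]].mean(skipna=True)
        avg = {c: np.nan for c in table.columns}
        avg.update({"age_weeks": np.nan, **means.to_dict()})
        table = pd.concat([table, pd.DataFrame([avg])], ignore_index=True)
    return table


def repair_capacity(r_deficient: float, r_reference: float) -> dict:
    """Compare daily lesion rates of a repair-deficient vs a reference line.

    Returns the daily difference (lesions repaired per day by the pathway
    present only in the reference-deficient comparison), that difference as a
    percent of the reference rate (retained repair capacity), the percent of
    lesions persisting, and the percent repaired.
    """
    if r_reference <= 0:
        raise ValueError("reference rate must be positive")
    difference = r_reference - r_deficient
    percent_of_reference = difference / r_reference * 100.0
    percent_persisting = r_deficient / r_reference * 100.0
    return {
        "daily_difference": difference,
        "percent_of_reference": percent_of_reference,
        "percent_persisting": percent_persisting,
        "percent_repaired": 100.0 - percent_persisting,
    }


def residual_activity_projection(r_reference: float, residual_fraction: float) -> int:
    """Projected daily rate if a fraction of repair capacity remains."""
    if not 0.0 <= residual_fraction <= 1.0:
        raise ValueError("residual fraction must lie in [0, 1]")
    return int(round(r_reference * (1.0 - residual_fraction)))
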