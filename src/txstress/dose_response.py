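"""UV dose-response: nascent-RNA intensity to loss, polynomial fits, errors.

Normalized nascent-RNA (EU) intensity is converted to transcription loss as
``loss = 100% - intensity``; replicate experiments are first normalized to
their own untreated (0 J/m^2) control before pooling, and per-dose SEM is
taken across replicates. Linear and third-order-polynomial dose-response
curves are ordinary least squares on the Vandermonde design. The error table
compares model-predicted loss with measured loss per dose: absolute error is
reported as |model - data| in percentage points, relative error as that
difference over the measured loss x 100, each also expressed in multiples of
the experimental SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def intensity_to_loss(
    obs: pd.DataFrame,
    reference_dose: float = 0.0,
    normalize_to_reference: bool = True,
    dose_column: str = "dose",
) -> pd.DataFrame:
    """Per-dose transcription loss (mean %, SEM %) from intensity observations.

    ``obs`` carries one row per replicate x dose with columns ``replicate``,
    ``dose`` (or ``dose_column``) and ``intensity_pct``. Each replicate is
    scaled so its reference-dose intensity is 100 (skip with
    ``normalize_to_reference=False`` if already normalized), then
    loss = 100 - intensity, averaged across replicates with SEM.
    """
    required = {"replicate", dose_column, "intensity_pct"}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = obs.copy()
    if normalize_to_reference:
        pieces = []
        for rep, group in obs.groupby("replicate"):
            ref = group.loc[group[dose_column] == reference_dose, "intensity_pct"]
            if ref.empty:
                raise ValueError(
                    f"replicate {rep!r} lacks the reference dose {reference_dose}"
                )
            scaled = group.copy()
            scaled["intensity_pct"] = group["intensity_pct"] / ref.mean() * 100.0
            pieces.append(scaled)
        obs = pd.concat(pieces, ignore_index=True)
    elif not (obs[dose_column] == reference_dose).any():
        raise ValueError(f"reference dose {reference_dose} absent from observations")
    obs["loss_pct"] = 100.0 - obs["intensity_pct"]
    grouped = obs.groupby(dose_column)["loss_pct"]
    out = grouped.agg(loss_pct="mean", sem_pct="sem", n="count").reset_index()
    out["sem_pct"] = out["sem_pct"].fillna(0.0)
    return out


def loss_to_intensity(loss_pct: np.ndarray | float) -> np.ndarray | float:
    """Inverse of the loss conversion: intensity = 100 - loss."""
    return 100.0 - np.asarray(loss_pct) if np.ndim(loss_pct) else 100.0 - loss_pct


@dataclass
class PolynomialFit:
    """OLS polynomial dose-response fit (coefficients low order -> high)."""

    degree: int
    coefficients: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray

    @property
    def rss(self) -> float:
        return float(np.sum(self.residuals**2))

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(x, self.coefficients)


def fit_polynomial(x, y, degree: int) -> PolynomialFit:
    """Least-squares polynomial of the given degree (1 = linear, 3 = cubic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"degree-{degree} fit needs at least {degree + 1} distinct x values"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, deg=degree)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    return PolynomialFit(degree, coeffs, x, y, fitted, y - fitted)


def per_tbl_slope(fit: PolynomialFit) -> float:
    """Low-dose sensitivity: loss %-points per (lesion per 100 kb).

    For a linear fit this is the slope; for higher degrees, the derivative at
    zero dose (the linear coefficient).
    """
    if fit.degree < 1:
        raise ValueError("fit has no slope")
    return float(fit.coefficients[1])


@dataclass
class ErrorTable:
    """Per-dose model-vs-data discrepancies plus column means.

    Absolute error is |model - data| in loss percentage points; relative
    error is that magnitude over the measured loss x 100; both are also given
    as multiples of the per-dose experimental SEM. Doses with zero measured
    loss have undefined relative error (NaN, excluded from the mean).
    """

    table: pd.DataFrame
    means: pd.Series


def error_table(
    model_losses,
    data_losses,
    sems,
    doses=None,
) -> ErrorTable:
    """Tabulate per-dose model-vs-data errors (percent and SEM multiples)."""
    model = np.asarray(model_losses, dtype=float)
    data = np.asarray(data_losses, dtype=float)
    sem = np.asarray(sems, dtype=float)
    if not (model.shape == data.shape == sem.shape):
        raise ValueError("model, data and SEM grids must match")
    doses = np.arange(1, len(model) + 1) if doses is None else np.asarray(doses)
    abs_err = np.abs(model - data)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(data != 0, abs_err / data * 100.0, np.nan)
        abs_sems = np.where(sem > 0, abs_err / sem, np.nan)
        rel_sems = np.where(sem > 0, rel_err / sem, np.nan)
    table = pd.DataFrame(
        {
            "dose": doses,
            "model_loss_pct": model,
            "data_loss_pct": data,
            "sem_pct": sem,
            "abs_error_pct": abs_err,
            "abs_error_sems": abs_sems,
            "rel_error_pct": rel_err,
            "rel_error_sems": rel_sems,
        }
    )
    means = table[
        ["abs_error_pct", "abs_error_sems", "rel_error_pct", "rel_error_sems"]
    ].mean(skipna=True)
    return ErrorTable(table, means)
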