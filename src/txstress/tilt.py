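"""Gene-body coverage "tilt": 5'->3' redistribution of nascent transcription.

Lesions stall elongating polymerase, so damaged cells over-represent reads
near gene 5' ends. Each gene body is divided into equal-width bins (5'->3',
strand already resolved), an ordinary-least-squares line is fitted to the
per-bin RPKM values, and tilt is the difference of slopes, after minus
before damage. Negative tilt = coverage declining toward the 3' end relative
to baseline, i.e., impaired elongation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Default bin count per gene body; equal-width binning length-normalizes
#: genes so tilts are comparable across genes.
DEFAULT_BINS = 20


@dataclass
class GeneCoverageProfile:
    """Binned coverage (RPKM per equal-width bin, ordered 5'->3')."""

    gene_id: str
    rpkm: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        if self.rpkm.ndim != 1 or len(self.rpkm) < 3:
            raise ValueError(
                f"gene {self.gene_id}: a coverage profile needs >= 3 bins"
            )
        if np.any(self.rpkm < 0):
            raise ValueError(f"gene {self.gene_id}: RPKM must be non-negative")


def body_slope(profile: GeneCoverageProfile) -> float:
    """OLS slope of RPKM against 0-based bin index (RPKM per bin)."""
    n = len(profile.rpkm)
    x = np.arange(n, dtype=float)
    slope, _intercept = np.polynomial.polynomial.polyfit(x, profile.rpkm, 1)[::-1]
    return float(slope)


def tilt(before: GeneCoverageProfile, after: GeneCoverageProfile) -> float:
    """slope(after) - slope(before); negative = 3' loss after damage."""
    if before.gene_id != after.gene_id:
        raise ValueError(
            f"profiles are for different genes: {before.gene_id!r} vs "
            f"{after.gene_id!r}"
        )
    if len(before.rpkm) != len(after.rpkm):
        raise ValueError(
            f"gene {before.gene_id}: bin counts differ "
            f"({len(before.rpkm)} vs {len(after.rpkm)})"
        )
    return body_slope(after) - body_slope(before)


def cohort_tilt(
    profiles_before: Sequence[GeneCoverageProfile],
    profiles_after: Sequence[GeneCoverageProfile],
    weights: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene tilts over the shared gene set, plus cohort summary.

    Summary holds the (optionally expression-weighted) mean, the median and
    the fraction of genes with negative tilt.
    """
    before_by_id = {p.gene_id: p for p in profiles_before}
    after_by_id = {p.gene_id: p for p in profiles_after}
    shared = [g for g in before_by_id if g in after_by_id]
    if not shared:
        raise ValueError("no genes shared between the two conditions")
    tilts = np.array([tilt(before_by_id[g], after_by_id[g]) for g in shared])
    table = pd.DataFrame({"gene_id": shared, "tilt": tilts})
    if weights is not None:
        w = np.array([weights.get(g, 0.0) for g in shared], dtype=float)
        if w.sum() <= 0:
            raise ValueError("weights sum to zero over the shared gene set")
        mean = float(np.average(tilts, weights=w))
    else:
        mean = float(tilts.mean())
    summary = {
        "n_genes": len(shared),
        "mean_tilt": mean,
        "median_tilt": float(np.median(tilts)),
        "fraction_negative": float(np.mean(tilts < 0)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# TSV I/O (columns: gene_id, condition, bin_index, rpkm)


def profiles_to_tsv(
    profiles: Sequence[GeneCoverageProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for i, value in enumerate(p.rpkm):
            rows.append(
                {
                    "gene_id": p.gene_id,
                    "condition": p.condition,
                    "bin_index": i,
                    "rpkm": value,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path: str | Path) -> list[GeneCoverageProfile]:
    table = pd.read_csv(path, sep="\t")
    required = {"gene_id", "bin_index", "rpkm"}
    if not required <= set(table.columns):
        raise ValueError(f"profile table needs columns {sorted(required)}")
    profiles = []
    cond_col = table["condition"] if "condition" in table.columns else ""
    for (gene, cond), group in table.assign(condition=cond_col).groupby(
        ["gene_id", "condition"], sort=False
    ):
        group = group.sort_values("bin_index")
        profiles.append(
            GeneCoverageProfile(str(gene), group["rpkm"].to_numpy(), str(cond))
        )
    return profiles
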