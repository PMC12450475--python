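"""Monte-Carlo lesion placement: the brute-force oracle for the closed form.

Each of M lesions independently lands in one of the 4 strand/allele copies of
each gene (probability ``l_j/(4L)`` per copy) or in the remaining untracked
sequence. Only hits to a *transcribed* strand matter: an allele is silenced as
soon as its transcribed strand carries at least one lesion, and the realized
fractional loss of a cell is

    w = sum_j alpha_j * (hits_allele1_j + hits_allele2_j) / 2

because transcription of a gene is split evenly between its two alleles.
Untranscribed-strand and intergenic hits are drawn but have no effect, and
several lesions may pile onto one strand (independent placement, no
exclusion). Sampling is by category rather than by base-pair coordinate —
equivalent under uniformity, since only hit/no-hit per transcribed strand
enters w.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GeneCatalog
from .model import age_to_count

_CHUNK_CELLS = 8_000_000  # cap on replicates x categories per multinomial block


@dataclass
class LesionPlacementResult:
    """Realized losses per Monte-Carlo replicate at fixed lesion count M.

    ``allele_hits`` holds the (n_genes, 2) silencing indicators of the last
    replicate, for inspection of single draws.
    """

    replicate_losses: np.ndarray
    allele_hits: np.ndarray
    M: int
    seed: int | None

    @property
    def mean(self) -> float:
        return float(self.replicate_losses.mean())

    @property
    def sd(self) -> float:
        if len(self.replicate_losses) < 2:
            return 0.0
        return float(self.replicate_losses.std(ddof=1))

    @property
    def sem(self) -> float:
        n = len(self.replicate_losses)
        return self.sd / np.sqrt(n) if n else 0.0

    def summary(self) -> dict:
        return {
            "M": self.M,
            "replicates": int(len(self.replicate_losses)),
            "mean": self.mean,
            "sd": self.sd,
            "sem": self.sem,
        }


def analytic_loss_sd(catalog: GeneCatalog, M: int) -> float:
    """Exact standard deviation of the realized loss omega at lesion count M.

    Treats allele silencing indicators as independent Bernoulli(p_j) with
    p_j = 1-(1-q_j)^M, giving Var(omega) = sum_j alpha_j^2 p_j (1-p_j) / 2.
    Under multinomial placement distinct strands are weakly negatively
    correlated, so this slightly overestimates the true SD — conservative
    when used as a floor for an empirical SEM whose sample happened to be
    constant (e.g., at full saturation).
    """
    p = -np.expm1(M * np.log1p(-catalog.q))
    var = float(np.sum(catalog.alpha**2 * p * (1.0 - p)) / 2.0)
    return np.sqrt(max(var, 0.0))


def _category_probs(catalog: GeneCatalog) -> np.ndarray:
    """[q_1..q_G (allele 1), q_1..q_G (allele 2), everything else]."""
    q = catalog.q
    rest = 1.0 - 2.0 * q.sum()
    # 4*sum(q) = sum(l)/L <= 1 is enforced by the catalog, so the two
    # transcribed strands alone take 2*sum(q) <= 1/2 of the mass.
    if rest < 0:
        raise ValueError("category probabilities exceed 1; catalog invalid")
    return np.concatenate([q, q, [rest]])


def simulate_loss(
    catalog: GeneCatalog,
    M: int,
    replicates: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> LesionPlacementResult:
    """Place M lesions uniformly, ``replicates`` times; return realized losses."""
    if M < 0 or replicates < 0:
        raise ValueError("M and replicates must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    G = len(catalog)
    probs = _category_probs(catalog)
    half_alpha = catalog.alpha / 2.0
    losses = np.empty(replicates)
    allele_hits = np.zeros((G, 2), dtype=bool)
    chunk = max(1, _CHUNK_CELLS // (2 * G + 1))
    for lo in range(0, replicates, chunk):
        hi = min(lo + chunk, replicates)
        counts = rng.multinomial(M, probs, size=hi - lo)
        hit1 = counts[:, :G] > 0
        hit2 = counts[:, G : 2 * G] > 0
        losses[lo:hi] = hit1 @ half_alpha + hit2 @ half_alpha
        if hi == replicates and hi > lo:
            allele_hits = np.stack([hit1[-1], hit2[-1]], axis=1)
    return LesionPlacementResult(losses, allele_hits, int(M), seed)


def simulate_trajectory(
    catalog: GeneCatalog,
    r: float,
    ages_days: Sequence[float],
    t0_days: float = 0.0,
    replicates: int = 1000,
    seed: int | None = None,
    return_replicate_losses: bool = False,
) -> pd.DataFrame:
    """Cumulative lesion placement along an age grid (lesions persist).

    Within each replicate, the silencing state carries over from one age to
    the next and only the increment ``M(t_k) - M(t_{k-1})`` of new lesions is
    placed, so realized loss is non-decreasing along the trajectory. Returns
    a per-age summary (mean, sd, sem of realized loss).
    """
    ages = list(ages_days)
    if any(b <= a for a, b in zip(ages, ages[1:])):
        raise ValueError("ages must be strictly ascending")
    rng = np.random.default_rng(seed)
    G = len(catalog)
    probs = _category_probs(catalog)
    half_alpha = catalog.alpha / 2.0
    hit = np.zeros((replicates, 2 * G), dtype=bool)
    prev_M = 0
    rows = []
    loss_matrix = []
    for t in ages:
        M = age_to_count(r, t, t0_days)
        delta = M - prev_M
        prev_M = M
        if delta > 0:
            counts = rng.multinomial(delta, probs, size=replicates)
            hit |= counts[:, : 2 * G] > 0
        losses = hit[:, :G] @ half_alpha + hit[:, G:] @ half_alpha
        loss_matrix.append(losses)
        rows.append(
            {
                "age_days": t,
                "M": M,
                "mean_loss": float(losses.mean()),
                "sd": float(losses.std(ddof=1)) if replicates > 1 else 0.0,
                "sem": float(losses.std(ddof=1) / np.sqrt(replicates))
                if replicates > 1
                else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    if return_replicate_losses:
        return summary, np.array(loss_matrix)
    return summary
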