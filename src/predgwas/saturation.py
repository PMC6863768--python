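"""Genome-subsampling saturation analysis and power-law forecasting.

Repeating the association screen on random strain subsets of increasing
size G yields a saturation curve: the number of unique screen-passing genes
falls as more genomes are analysed, because each additional genome can only
remove candidates.  The mean curve is fitted to a power law

    hits(G) = a * G ** b       (b expected negative)

by ordinary least squares of log(hits) on log(G), and inverted to forecast
how many genomes of similar diversity would be needed to shrink the
candidate list to a target size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .binarize import binarize_panel
from .containers import PhenotypePanel, PresenceAbsenceMatrix, align_strains
from .errors import DegenerateDesignError, FitError, NoSolutionError
from .association import ScreenConfig, run_association

logger = logging.getLogger(__name__)


@dataclass
class SaturationCurve:
    """Unique screen-passing gene counts at each subsampled genome count."""

    genome_counts: list[int]
    replicate_hits: dict[int, list[int]]
    mean_hits: list[float]
    n_replicates: int
    seed: int


@dataclass(frozen=True)
class PowerLawFit:
    """hits(G) = coefficient * G**exponent, fitted on the log-log scale."""

    coefficient: float
    exponent: float
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.coefficient > 0:
            raise ValueError("coefficient must be > 0")


def subsample_gene_counts(
    matrix: PresenceAbsenceMatrix,
    panel: PhenotypePanel,
    grid: list[int],
    reps: int = 20,
    seed: int = 0,
    fraction: float = 1 / 3,
    tie_rule: str = "demote",
    screen: ScreenConfig = ScreenConfig(),
) -> SaturationCurve:
    """Rerun the screen on random strain subsets of each size in ``grid``.

    For each genome count G, ``reps`` subsets of size G are drawn uniformly
    without replacement; tertile labels are re-derived within each subset
    (tertiles are defined relative to the analysed strain set); and the
    number of unique genes passing the screen for at least one prey is
    recorded.  A subset in which no prey retains both superior and inferior
    strains yields no count; a G where every replicate is degenerate is
    dropped with a warning.
    """
    align_strains(matrix, panel)
    strains = list(panel.strain_ids)
    grid = sorted(set(int(g) for g in grid))
    if not grid:
        raise ValueError("empty genome-count grid")
    if grid[-1] > len(strains):
        raise ValueError(f"max grid point {grid[-1]} exceeds {len(strains)} strains")
    if reps < 1:
        raise ValueError("reps must be >= 1")

    rng = np.random.default_rng(seed)
    replicate_hits: dict[int, list[int]] = {}
    kept: list[int] = []
    for g in grid:
        counts: list[int] = []
        for _ in range(reps):
            idx = rng.choice(len(strains), size=g, replace=False)
            subset = [strains[i] for i in sorted(idx)]
            sub_matrix = matrix.subset_strains(subset)
            sub_panel = panel.subset_strains(subset)
            try:
                labels = binarize_panel(
                    sub_panel, fraction, tie_rule, skip_insufficient=True
                )
                _, summary = run_association(sub_matrix, labels, screen)
            except DegenerateDesignError:
                continue
            counts.append(summary.total_unique_hits)
        if not counts:
            logger.warning("G=%d skipped: every replicate was degenerate", g)
            continue
        replicate_hits[g] = counts
        kept.append(g)
    if not kept:
        raise DegenerateDesignError("no usable genome count in the grid")
    means = [float(np.mean(replicate_hits[g])) for g in kept]
    return SaturationCurve(kept, replicate_hits, means, reps, seed)


def fit_power_law(curve: SaturationCurve) -> PowerLawFit:
    """OLS of log(mean hits) on log(G); points with zero mean are excluded."""
    g = np.asarray(curve.genome_counts, dtype=float)
    y = np.asarray(curve.mean_hits, dtype=float)
    positive = y > 0
    n_dropped = int((~positive).sum())
    if n_dropped:
        logger.warning("%d zero-mean grid points excluded from the fit", n_dropped)
    if positive.sum() < 2:
        raise FitError("need >= 2 grid points with positive mean hit counts")
    log_g, log_y = np.log(g[positive]), np.log(y[positive])
    slope, intercept = np.polyfit(log_g, log_y, 1)
    fitted = intercept + slope * log_g
    ss_res = float(np.sum((log_y - fitted) ** 2))
    ss_tot = float(np.sum((log_y - log_y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(np.exp(intercept)), float(slope), r2)


def evaluate_power_law(fit: PowerLawFit, genomes: int | float) -> float:
    """Predicted number of screen-passing genes at a given genome count."""
    if genomes < 1:
        raise ValueError("genome count must be >= 1")
    return fit.coefficient * genomes ** fit.exponent


def predict_required_genomes(fit: PowerLawFit, target_hits: float) -> int:
    """Smallest integer G >= 1 with ``coefficient * G**exponent <= target_hits``."""
    if target_hits <= 0:
        raise ValueError("target_hits must be > 0")
    if fit.exponent >= 0:
        raise NoSolutionError(
            "power law does not decay (exponent >= 0); no genome count "
            "reduces the candidate list to the target"
        )
    if fit.coefficient <= target_hits:
        return 1
    guess = (target_hits / fit.coefficient) ** (1.0 / fit.exponent)
    g = max(1, math.ceil(guess))
    while g > 1 and evaluate_power_law(fit, g - 1) <= target_hits:
        g -= 1
    while evaluate_power_law(fit, g) > target_hits:
        g += 1
    return g
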