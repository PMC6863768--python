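"""Gene presence/absence association screen.

Each orthologous cluster is tested, prey by prey, for association between
its presence and the superior/inferior predator labels via a two-sided
Fisher exact test on the 2x2 table

    a = superior strains carrying the gene    b = inferior carriers
    c = superior strains lacking it           d = inferior non-carriers

(moderate and missing strains contribute to no cell).  A cluster passes the
screen for a prey when all of the following hold:

* the association is positive (carriage enriched among superior strains),
* p < 0.05 (raw Fisher p; Benjamini-Hochberg values are reported alongside
  for transparency but are not the screening statistic),
* sensitivity 100*a/(a+c) >= 70%,
* specificity 100*d/(b+d) >= 80%.

With tertiles of nine strains these cutoffs require carriage in at least
7/9 superior predators and absence from at least 8/9 inferior predators —
a deliberately low-stringency screen that tolerates a candidate gene being
absent from one or two superior genomes (draft assemblies) and assumes
several alternative predation mechanisms segregate in the population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import (
    INFERIOR,
    SUPERIOR,
    UNASSIGNED,
    BinaryLabelTable,
    PresenceAbsenceMatrix,
    align_strains,
)
from .errors import DegenerateDesignError, InsufficientAnnotationError

logger = logging.getLogger(__name__)

DIRECTION_POSITIVE = "positive"
DIRECTION_NEGATIVE = "negative"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 counts: carriage (rows) vs superior/inferior label (columns)."""

    a: int  # superior carriers
    b: int  # inferior carriers
    c: int  # superior non-carriers
    d: int  # inferior non-carriers

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def n_superior(self) -> int:
        return self.a + self.c

    @property
    def n_inferior(self) -> int:
        return self.b + self.d


@dataclass(frozen=True)
class ScreenConfig:
    """Cutoffs of the association screen (defaults: p<0.05, sens 70, spec 80)."""

    p_cutoff: float = 0.05
    sensitivity_cutoff_pct: float = 70.0
    specificity_cutoff_pct: float = 80.0

    def __post_init__(self) -> None:
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")
        for name in ("sensitivity_cutoff_pct", "specificity_cutoff_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")


@dataclass
class AssociationRecord:
    """Result of one cluster x prey association test."""

    cluster_id: str
    prey_id: str
    counts: ContingencyCounts
    sensitivity_pct: float
    specificity_pct: float
    p_value: float
    p_value_bh: float
    direction: str
    passes: bool


@dataclass
class HitSummary:
    """Screen-passing genes summarized across the prey panel."""

    per_prey_hits: dict[str, set[str]]
    pairwise_overlap: pd.DataFrame
    genes_by_prey_count: dict[int, int]
    total_unique_hits: int


@lru_cache(maxsize=65536)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
    return min(float(p), 1.0)


def build_contingency(
    presence: pd.Series | np.ndarray,
    labels: pd.Series,
) -> ContingencyCounts:
    """Count carriers/non-carriers among superior and inferior strains.

    ``presence`` and ``labels`` must be aligned on the same strain order.
    Moderate and missing strains are excluded from every cell.
    """
    pres = np.asarray(presence, dtype=bool)
    lab = np.asarray(labels, dtype=object)
    if pres.shape != lab.shape:
        raise ValueError("presence and labels must be aligned vectors")
    sup = lab == SUPERIOR
    inf = lab == INFERIOR
    if not sup.any() or not inf.any():
        raise DegenerateDesignError(
            "need at least one superior and one inferior strain"
        )
    a = int((pres & sup).sum())
    b = int((pres & inf).sum())
    return ContingencyCounts(a, b, int(sup.sum()) - a, int(inf.sum()) - b)


def fisher_two_sided(counts: ContingencyCounts) -> float:
    """Two-sided Fisher exact p: the total hypergeometric probability of all
    tables (margins fixed) no more probable than the observed one."""
    return _fisher_cached(counts.a, counts.b, counts.c, counts.d)


def sensitivity_specificity(counts: ContingencyCounts) -> tuple[float, float]:
    """(sensitivity %, specificity %) of gene carriage as a superior-predator marker."""
    if counts.n_superior == 0 or counts.n_inferior == 0:
        raise DegenerateDesignError("empty superior or inferior margin")
    sens = 100.0 * counts.a / counts.n_superior
    spec = 100.0 * counts.d / counts.n_inferior
    return sens, spec


def _direction(counts: ContingencyCounts) -> str:
    rate_sup = counts.a / counts.n_superior
    rate_inf = counts.b / counts.n_inferior
    if rate_sup > rate_inf:
        return DIRECTION_POSITIVE
    if rate_sup < rate_inf:
        return DIRECTION_NEGATIVE
    return DIRECTION_NONE


def evaluate_gene(
    presence,
    labels,
    screen: ScreenConfig = ScreenConfig(),
    cluster_id: str = "",
    prey_id: str = "",
) -> AssociationRecord:
    """Run the full screen for one cluster against one prey's labels.

    ``p_value_bh`` is filled with NaN here; :func:`run_association` replaces
    it with the within-prey Benjamini-Hochberg adjusted value.
    """
    counts = build_contingency(presence, labels)
    return _evaluate_counts(counts, screen, cluster_id, prey_id)


def _evaluate_counts(
    counts: ContingencyCounts,
    screen: ScreenConfig,
    cluster_id: str,
    prey_id: str,
) -> AssociationRecord:
    sens, spec = sensitivity_specificity(counts)
    p = fisher_two_sided(counts)
    direction = _direction(counts)
    passes = (
        direction == DIRECTION_POSITIVE
        and p < screen.p_cutoff
        and sens >= screen.sensitivity_cutoff_pct
        and spec >= screen.specificity_cutoff_pct
    )
    return AssociationRecord(
        cluster_id=cluster_id,
        prey_id=prey_id,
        counts=counts,
        sensitivity_pct=sens,
        specificity_pct=spec,
        p_value=p,
        p_value_bh=float("nan"),
        direction=direction,
        passes=passes,
    )


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    if len(p_values) == 0:
        return []
    arr = np.asarray(p_values, dtype=float)
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    _, adjusted, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in adjusted]


def run_association(
    matrix: PresenceAbsenceMatrix,
    labels: BinaryLabelTable,
    screen: ScreenConfig = ScreenConfig(),
) -> tuple[list[AssociationRecord], HitSummary]:
    """Screen every cluster against every prey and summarize the hits.

    Per prey, clusters present in all or absent from all informative
    (superior + inferior) strains are uninformative and skipped.  A prey
    with no superior or no inferior strains is skipped with a warning.
    BH adjustment is applied within each prey across its tested clusters.
    """
    align_strains(matrix, labels)
    presence = matrix.presence[labels.strain_ids].to_numpy(dtype=bool)
    cluster_ids = matrix.cluster_ids
    records: list[AssociationRecord] = []
    per_prey_hits: dict[str, set[str]] = {}
    any_informative = False

    for prey in labels.prey_ids:
        lab = labels.label[prey].to_numpy(dtype=object)
        sup = lab == SUPERIOR
        inf = lab == INFERIOR
        n_sup, n_inf = int(sup.sum()), int(inf.sum())
        if n_sup == 0 or n_inf == 0:
            logger.warning(
                "prey %s skipped: %d superior / %d inferior strains",
                prey, n_sup, n_inf,
            )
            continue
        any_informative = True
        a_vec = presence[:, sup].sum(axis=1)
        b_vec = presence[:, inf].sum(axis=1)
        carriers = a_vec + b_vec
        informative = (carriers > 0) & (carriers < n_sup + n_inf)
        n_skipped = int((~informative).sum())
        logger.info(
            "prey %s: %d superior, %d inferior; testing %d clusters "
            "(%d uniform clusters skipped)",
            prey, n_sup, n_inf, int(informative.sum()), n_skipped,
        )
        prey_records: list[AssociationRecord] = []
        for idx in np.nonzero(informative)[0]:
            counts = ContingencyCounts(
                int(a_vec[idx]),
                int(b_vec[idx]),
                n_sup - int(a_vec[idx]),
                n_inf - int(b_vec[idx]),
            )
            prey_records.append(
                _evaluate_counts(counts, screen, cluster_ids[idx], prey)
            )
        if prey_records:
            adjusted = bh_adjust([r.p_value for r in prey_records])
            for rec, q in zip(prey_records, adjusted):
                rec.p_value_bh = q
        per_prey_hits[prey] = {r.cluster_id for r in prey_records if r.passes}
        records.extend(prey_records)

    if not any_informative:
        raise DegenerateDesignError("no prey with both superior and inferior strains")
    return records, summarize_overlaps(per_prey_hits)


def summarize_overlaps(per_prey_hits: dict[str, set[str]]) -> HitSummary:
    """Pairwise hit-set overlaps and the genes-per-prey-count histogram."""
    prey_ids = list(per_prey_hits)
    overlap = pd.DataFrame(
        [
            [len(per_prey_hits[p] & per_prey_hits[q]) for q in prey_ids]
            for p in prey_ids
        ],
        index=prey_ids,
        columns=prey_ids,
        dtype=int,
    )
    gene_counts: dict[str, int] = {}
    for hits in per_prey_hits.values():
        for gene in hits:
            gene_counts[gene] = gene_counts.get(gene, 0) + 1
    histogram: dict[int, int] = {}
    for k in gene_counts.values():
        histogram[k] = histogram.get(k, 0) + 1
    return HitSummary(
        per_prey_hits={p: set(h) for p, h in per_prey_hits.items()},
        pairwise_overlap=overlap,
        genes_by_prey_count=dict(sorted(histogram.items())),
        total_unique_hits=len(gene_counts),
    )


def compare_category_profiles(
    hit_categories: dict[str, str],
    background_frequencies: dict[str, float],
) -> tuple[float, float]:
    """Chi-square goodness of fit of hit COG-category counts vs background.

    A cluster annotated with several category letters contributes one count
    to each letter.  Unassigned clusters are excluded.  Categories whose
    expected count falls below 1 are pooled into ``other``; degrees of
    freedom are (#categories after pooling) - 1.
    """
    total_bg = sum(background_frequencies.values())
    if abs(total_bg - 1.0) > 1e-9:
        raise ValueError(f"background proportions sum to {total_bg}, expected 1")

    observed: dict[str, int] = {}
    n_assigned = 0
    for cats in hit_categories.values():
        if cats == UNASSIGNED:
            continue
        n_assigned += 1
        for letter in cats:
            observed[letter] = observed.get(letter, 0) + 1
    if n_assigned == 0:
        raise InsufficientAnnotationError("every hit is unassigned")

    n_total = sum(observed.values())
    categories = sorted(set(observed) | set(background_frequencies))
    obs, exp, other_obs, other_exp = [], [], 0.0, 0.0
    for cat in categories:
        e = n_total * background_frequencies.get(cat, 0.0)
        o = observed.get(cat, 0)
        if e < 1.0:
            other_obs += o
            other_exp += e
            continue
        obs.append(float(o))
        exp.append(e)
    if other_exp > 0 or other_obs > 0:
        obs.append(float(other_obs))
        exp.append(other_exp)
    if len(obs) < 2:
        raise DegenerateDesignError(
            "fewer than two categories after pooling (zero degrees of freedom)"
        )
    statistic, p_value = stats.chisquare(obs, exp)
    return float(statistic), float(p_value)
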