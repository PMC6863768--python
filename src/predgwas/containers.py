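"""Core in-memory containers shared across the pipeline.

All tabular data is held in pandas objects with explicit, validated axes:
clusters x strains for gene presence/absence, strains x prey for
phenotypes and labels.  Validation happens at construction so downstream
stages can assume aligned, unique identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import DuplicateIdentifierError, PhenotypeDomainError

#: Tertile labels for a strain's predatory performance against one prey.
SUPERIOR = "superior"
INFERIOR = "inferior"
MODERATE = "moderate"

LABELS = (SUPERIOR, INFERIOR, MODERATE)

#: Single-letter COG functional categories (plus the pseudo-category used
#: for clusters the annotation pipeline could not place).
COG_LETTERS = "JAKLBDYVTMNZWUOCGEFHIPQRSX"
UNASSIGNED = "unassigned"


def _check_unique(values, what: str) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise DuplicateIdentifierError(f"duplicate {what}: {v!r}")
        seen.add(v)


@dataclass
class PresenceAbsenceMatrix:
    """Boolean gene presence/absence matrix (orthologous clusters x strains).

    Parameters
    ----------
    presence
        DataFrame indexed by cluster id with one boolean column per strain.
    annotation
        Optional free-text product annotation per cluster id.
    """

    presence: pd.DataFrame
    annotation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.presence.shape[1] == 0:
            raise ValueError("presence/absence matrix needs at least one strain")
        _check_unique(self.presence.index, "cluster id")
        _check_unique(self.presence.columns, "strain id")
        self.presence = self.presence.astype(bool)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def n_strains(self) -> int:
        return self.presence.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.presence.shape[0]

    def subset_strains(self, strains: list[str]) -> "PresenceAbsenceMatrix":
        """Restrict the matrix to the given strains (order preserved)."""
        missing = [s for s in strains if s not in self.presence.columns]
        if missing:
            raise KeyError(f"unknown strains: {missing}")
        return PresenceAbsenceMatrix(self.presence[strains], dict(self.annotation))


@dataclass
class PhenotypePanel:
    """Predation-zone diameters in mm (strains x prey); NaN marks a missing assay."""

    zone_mm: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.zone_mm.index, "strain id")
        _check_unique(self.zone_mm.columns, "prey id")
        self.zone_mm = self.zone_mm.astype(float)
        if (self.zone_mm.to_numpy() < 0).any():
            raise PhenotypeDomainError("zone diameters must be >= 0")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.zone_mm.index)

    @property
    def prey_ids(self) -> list[str]:
        return list(self.zone_mm.columns)

    def subset_strains(self, strains: list[str]) -> "PhenotypePanel":
        missing = [s for s in strains if s not in self.zone_mm.index]
        if missing:
            raise KeyError(f"unknown strains: {missing}")
        return PhenotypePanel(self.zone_mm.loc[strains])


@dataclass
class BinaryLabelTable:
    """Per-prey tertile labels; NaN where the underlying phenotype was missing."""

    label: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.label.index, "strain id")
        _check_unique(self.label.columns, "prey id")
        values = self.label.to_numpy(dtype=object).ravel()
        bad = {v for v in values if isinstance(v, str) and v not in LABELS}
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")

    @property
    def strain_ids(self) -> list[str]:
        return list(self.label.index)

    @property
    def prey_ids(self) -> list[str]:
        return list(self.label.columns)

    def counts(self, prey_id: str) -> dict[str, int]:
        """Label counts for one prey (missing entries excluded)."""
        col = self.label[prey_id].dropna()
        return {lab: int((col == lab).sum()) for lab in LABELS}


def validate_annotation_table(table: dict[str, str]) -> dict[str, str]:
    """Check a cluster -> COG-letter(s) mapping against the COG alphabet."""
    for cluster, cats in table.items():
        if cats == UNASSIGNED:
            continue
        if not cats or any(ch not in COG_LETTERS for ch in cats):
            raise ValueError(
                f"cluster {cluster!r}: categories {cats!r} not in COG alphabet"
            )
    return table


def align_strains(
    matrix: PresenceAbsenceMatrix, panel_or_labels
) -> None:
    """Require identical strain sets between matrix and phenotypes/labels.

    Silent misalignment would corrupt every downstream statistic, so name
    mismatches are a hard error rather than an intersection.
    """
    a = set(matrix.strain_ids)
    b = set(panel_or_labels.strain_ids)
    if a != b:
        only_m = sorted(a - b)
        only_p = sorted(b - a)
        raise KeyError(
            "strain sets differ between matrix and phenotypes: "
            f"matrix-only={only_m}, phenotype-only={only_p}"
        )
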