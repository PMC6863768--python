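"""Readers and writers for the pipeline's file formats.

Supported formats:

* Roary ``gene_presence_absence.csv`` — 14 metadata columns followed by one
  column per strain, RFC-4180 quoting; a strain carries a cluster iff its
  field is non-empty.
* Phenotype TSV — strains x prey, predation-zone diameters in mm, empty
  cells for missing assays.
* Scoary-style traits CSV — ``1`` superior, ``0`` inferior, empty field for
  moderate/unscored strains.
* Association results CSV — one row per cluster x prey test.
"""

from __future__ import annotations

import csv
import math
from typing import Iterable

import numpy as np
import pandas as pd

from .containers import (
    INFERIOR,
    MODERATE,
    SUPERIOR,
    BinaryLabelTable,
    PhenotypePanel,
    PresenceAbsenceMatrix,
)
from .errors import (
    DuplicateIdentifierError,
    MalformedFileError,
    PhenotypeDomainError,
    PhenotypeParseError,
)

#: Roary's fixed metadata columns, in file order.
ROARY_METADATA_COLUMNS = [
    "Gene",
    "Non-unique Gene name",
    "Annotation",
    "No. isolates",
    "No. sequences",
    "Avg sequences per isolate",
    "Genome Fragment",
    "Order within Fragment",
    "Accessory Fragment",
    "Accessory Order with Fragment",
    "QC",
    "Min group size nuc",
    "Max group size nuc",
    "Avg group size nuc",
]

N_ROARY_METADATA = len(ROARY_METADATA_COLUMNS)

ASSOCIATION_COLUMNS = [
    "cluster",
    "prey",
    "a",
    "b",
    "c",
    "d",
    "sensitivity_pct",
    "specificity_pct",
    "p_value",
    "p_value_bh",
    "direction",
    "passes",
]


def read_roary_presence_absence(path) -> PresenceAbsenceMatrix:
    """Read a Roary ``gene_presence_absence.csv`` into a boolean matrix.

    A cell is "present" iff it is non-empty after unquoting; paralogous
    cells listing several locus tags therefore count as present once.
    """
    with open(path, "r", newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise MalformedFileError(f"{path}: empty file") from None
        if len(header) < N_ROARY_METADATA + 1:
            raise MalformedFileError(
                f"{path}: expected >= {N_ROARY_METADATA + 1} columns "
                f"(14 Roary metadata + strains), found {len(header)}"
            )
        strains = header[N_ROARY_METADATA:]
        clusters: list[str] = []
        seen: set[str] = set()
        rows: list[list[bool]] = []
        annotation: dict[str, str] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise MalformedFileError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            gene = row[0]
            if gene in seen:
                raise DuplicateIdentifierError(
                    f"{path}:{lineno}: duplicate cluster name {gene!r}"
                )
            seen.add(gene)
            clusters.append(gene)
            if row[2]:
                annotation[gene] = row[2]
            rows.append([bool(field) for field in row[N_ROARY_METADATA:]])
    presence = pd.DataFrame(rows, index=clusters, columns=strains, dtype=bool)
    return PresenceAbsenceMatrix(presence, annotation)


def write_roary_presence_absence(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write a matrix in the Roary dialect (synthetic locus tags as cells)."""
    presence = matrix.presence
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(ROARY_METADATA_COLUMNS + list(presence.columns))
        for cluster, row in presence.iterrows():
            n_iso = int(row.sum())
            meta = [
                cluster,
                "",
                matrix.annotation.get(cluster, ""),
                str(n_iso),
                str(n_iso),
                "1.0" if n_iso else "0.0",
                "",
                "",
                "",
                "",
                "",
                "",
                "",
                "",
            ]
            cells = [
                f"{cluster}_{strain}" if present else ""
                for strain, present in row.items()
            ]
            writer.writerow(meta + cells)


def read_phenotype_table(path) -> PhenotypePanel:
    """Read a strains x prey TSV of zone diameters (mm); empty cells are missing."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = np.full(raw.shape, np.nan)
    for i, strain in enumerate(raw.index):
        for j, prey in enumerate(raw.columns):
            cell = raw.iat[i, j].strip()
            if cell == "":
                continue
            try:
                value = float(cell)
            except ValueError:
                raise PhenotypeParseError(
                    f"{path}: strain {strain!r}, prey {prey!r}: "
                    f"cannot parse {cell!r} as mm"
                ) from None
            if not math.isfinite(value):
                raise PhenotypeParseError(
                    f"{path}: strain {strain!r}, prey {prey!r}: non-finite value"
                )
            if value < 0:
                raise PhenotypeDomainError(
                    f"{path}: strain {strain!r}, prey {prey!r}: "
                    f"negative zone diameter {value}"
                )
            values[i, j] = value
    frame = pd.DataFrame(values, index=list(raw.index), columns=list(raw.columns))
    return PhenotypePanel(frame)


def write_phenotype_table(panel: PhenotypePanel, path) -> None:
    """Write a phenotype panel as TSV; missing values become empty cells."""
    out = panel.zone_mm.copy()
    out.index.name = "strain"
    out.to_csv(path, sep="\t", na_rep="")


_TRAIT_CODE = {SUPERIOR: "1", INFERIOR: "0"}


def write_traits_table(labels: BinaryLabelTable, path) -> None:
    """Write labels as a Scoary traits CSV (1 superior, 0 inferior, else empty)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow([""] + labels.prey_ids)
        for strain in labels.strain_ids:
            row = [strain]
            for prey in labels.prey_ids:
                value = labels.label.at[strain, prey]
                row.append(_TRAIT_CODE.get(value, ""))
            writer.writerow(row)


def read_traits_table(path) -> BinaryLabelTable:
    """Read a Scoary traits CSV back into labels.

    The traits dialect does not distinguish moderate from missing; both are
    empty fields and both are read back as ``moderate`` (neither takes part
    in any contingency table, so downstream results are unaffected).
    """
    raw = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    decode = {"1": SUPERIOR, "0": INFERIOR, "": MODERATE}
    try:
        label = raw.map(lambda cell: decode[cell.strip()])
    except KeyError as exc:
        raise MalformedFileError(f"{path}: unexpected trait value {exc}") from None
    label.index = [str(i) for i in raw.index]
    return BinaryLabelTable(label)


def write_association_table(records: Iterable, path) -> None:
    """Write association records, sorted by (prey, p ascending, cluster).

    Reals are written with 12 significant digits so that a read-back
    reproduces them to that precision; integers roundtrip exactly.
    """
    rows = sorted(records, key=lambda r: (r.prey_id, r.p_value, r.cluster_id))
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(ASSOCIATION_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.cluster_id,
                    r.prey_id,
                    r.counts.a,
                    r.counts.b,
                    r.counts.c,
                    r.counts.d,
                    f"{r.sensitivity_pct:.12g}",
                    f"{r.specificity_pct:.12g}",
                    f"{r.p_value:.12g}",
                    f"{r.p_value_bh:.12g}",
                    r.direction,
                    "true" if r.passes else "false",
                ]
            )


def read_association_table(path) -> list:
    """Read an association results CSV back into records."""
    from .association import AssociationRecord, ContingencyCounts

    records = []
    with open(path, "r", newline="") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames != ASSOCIATION_COLUMNS:
            raise MalformedFileError(
                f"{path}: unexpected header {reader.fieldnames}"
            )
        for row in reader:
            counts = ContingencyCounts(
                int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"])
            )
            records.append(
                AssociationRecord(
                    cluster_id=row["cluster"],
                    prey_id=row["prey"],
                    counts=counts,
                    sensitivity_pct=float(row["sensitivity_pct"]),
                    specificity_pct=float(row["specificity_pct"]),
                    p_value=float(row["p_value"]),
                    p_value_bh=float(row["p_value_bh"]),
                    direction=row["direction"],
                    passes=row["passes"] == "true",
                )
            )
    return records


def read_annotation_table(path) -> dict[str, str]:
    """Read a cluster -> COG category TSV (columns: cluster, categories)."""
    from .containers import validate_annotation_table

    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise MalformedFileError(f"{path}: expected two columns (cluster, categories)")
    table = dict(zip(raw.iloc[:, 0], raw.iloc[:, 1]))
    return validate_annotation_table(table)


def write_annotation_table(table: dict[str, str], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["cluster", "categories"])
        for cluster, cats in table.items():
            writer.writerow([cluster, cats])
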