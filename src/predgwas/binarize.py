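"""Tertile binarization of graded predation phenotypes.

For each prey, strains are ranked by predation-zone diameter and the top
third labelled superior, the bottom third inferior, the remainder moderate.
With n scored strains and tertile fraction f, group size is k = floor(f*n),
so 29 strains at the default f = 1/3 give 9 superior / 9 inferior / 11
moderate.

Ties at a group boundary admit two policies:

``demote``
    If the boundary value is shared with any excluded strain, the whole
    tied block is demoted to moderate.  Conservative: never fabricates a
    superior/inferior distinction between strains with equal phenotypes.
``expand``
    The group is enlarged to include every strain tied with the boundary
    value.  A strain that would qualify for both groups (possible only
    with extreme ties) is labelled moderate.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .containers import (
    INFERIOR,
    MODERATE,
    SUPERIOR,
    BinaryLabelTable,
    PhenotypePanel,
)
from .errors import InsufficientDataError

TIE_RULES = ("demote", "expand")


def _check_args(fraction: float, tie_rule: str) -> None:
    if not 0 < fraction <= 0.5:
        raise ValueError(f"fraction must be in (0, 1/2], got {fraction}")
    if tie_rule not in TIE_RULES:
        raise ValueError(f"tie_rule must be one of {TIE_RULES}, got {tie_rule!r}")


def binarize_prey(
    values: pd.Series,
    fraction: float = 1 / 3,
    tie_rule: str = "demote",
) -> pd.Series:
    """Label one prey's zone diameters as superior/inferior/moderate.

    Parameters
    ----------
    values
        Zone diameters (mm) indexed by strain; NaN marks missing assays.
    fraction
        Tertile fraction; group size is ``floor(fraction * n_scored)``.
    tie_rule
        Boundary-tie policy, ``demote`` or ``expand`` (see module docs).

    Returns
    -------
    Series of labels aligned to ``values``; missing stays missing (NaN).
    """
    _check_args(fraction, tie_rule)
    scored = values.dropna()
    n = len(scored)
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 non-missing values to binarize, got {n}"
        )
    k = math.floor(fraction * n)
    v = scored.to_numpy(dtype=float)
    labels = pd.Series(np.nan, index=values.index, dtype=object)
    labels[scored.index] = MODERATE
    if k == 0:
        return labels

    desc = np.sort(v)[::-1]
    sup_threshold = desc[k - 1]
    n_ge = int((v >= sup_threshold).sum())
    if tie_rule == "expand" or n_ge == k:
        sup_mask = scored >= sup_threshold
    else:  # demote the tied boundary block
        sup_mask = scored > sup_threshold

    asc = np.sort(v)
    inf_threshold = asc[k - 1]
    n_le = int((v <= inf_threshold).sum())
    if tie_rule == "expand" or n_le == k:
        inf_mask = scored <= inf_threshold
    else:
        inf_mask = scored < inf_threshold

    both = sup_mask & inf_mask  # only possible under expand with heavy ties
    labels[scored.index[(sup_mask & ~both).to_numpy()]] = SUPERIOR
    labels[scored.index[(inf_mask & ~both).to_numpy()]] = INFERIOR
    return labels


def binarize_panel(
    panel: PhenotypePanel,
    fraction: float = 1 / 3,
    tie_rule: str = "demote",
    skip_insufficient: bool = False,
) -> BinaryLabelTable:
    """Apply :func:`binarize_prey` to every prey column independently.

    With ``skip_insufficient`` a prey with fewer than three scored strains
    is left entirely unlabelled (all missing) instead of raising; used by
    the genome-subsampling analysis where small subsets are expected.
    """
    _check_args(fraction, tie_rule)
    columns = {}
    for prey in panel.prey_ids:
        try:
            columns[prey] = binarize_prey(panel.zone_mm[prey], fraction, tie_rule)
        except InsufficientDataError:
            if not skip_insufficient:
                raise
            columns[prey] = pd.Series(
                np.nan, index=panel.zone_mm.index, dtype=object
            )
    label = pd.DataFrame(columns, columns=panel.prey_ids)
    return BinaryLabelTable(label)


def predatory_breadth(labels: BinaryLabelTable) -> pd.DataFrame:
    """Per strain, the number of prey for which it is a superior predator.

    Returns a DataFrame with columns ``strain_id``, ``n_superior``,
    ``n_prey``, sorted by breadth (descending) then strain id.
    """
    n_prey = len(labels.prey_ids)
    n_sup = (labels.label == SUPERIOR).sum(axis=1)
    table = pd.DataFrame(
        {
            "strain_id": labels.strain_ids,
            "n_superior": n_sup.to_numpy(dtype=int),
            "n_prey": n_prey,
        }
    )
    return (
        table.sort_values(["n_superior", "strain_id"], ascending=[False, True])
        .reset_index(drop=True)
    )
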