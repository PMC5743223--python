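"""Bias heritability: ancestor inference, inheritance/switch classification.

A *granddaughter family* is the set of 2-4 second-generation descendants
of one traced ancestor, each cultured and phenotyped separately.  The
ancestor's potency is not observed; it is inferred as the elementwise sum
of its granddaughters' yield vectors.  A granddaughter *inherits* the
ancestral bias when its predominant lineage equals the ancestor's, and
*switches* otherwise.  Families with fewer than two viable granddaughters
are excluded from analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ValidationError
from .lineages import LINEAGES, Subset


@dataclasses.dataclass
class GranddaughterFamily:
    """One ancestor's individually cultured granddaughters.

    ``yields`` is an (n_granddaughters x 6) count matrix in canonical
    lineage order.  ``true_ancestor_bias`` / ``true_inherited`` carry the
    generator's ground truth when the family is synthetic; they are None
    for real data, where the ancestral bias must be inferred from the
    granddaughter sum.
    """

    ancestor_id: str
    subset: Subset
    well_ids: Sequence[str]
    yields: np.ndarray
    true_ancestor_bias: str | None = None
    true_inherited: tuple[bool, ...] | None = None

    def __post_init__(self):
        self.yields = np.asarray(self.yields, dtype=np.int64)
        if self.yields.ndim != 2 or self.yields.shape[1] != 6:
            raise ValidationError(f"family {self.ancestor_id}: yields must be n x 6")
        if not 2 <= self.yields.shape[0] <= 4:
            raise ValidationError(
                f"family {self.ancestor_id}: {self.yields.shape[0]} granddaughters; "
                "only families with 2-4 viable granddaughters are analyzable")
        if len(self.well_ids) != self.yields.shape[0]:
            raise ValidationError(f"family {self.ancestor_id}: well ids misaligned")

    @property
    def n_granddaughters(self) -> int:
        return self.yields.shape[0]


@dataclasses.dataclass
class InheritanceCall:
    """Classification of one family's granddaughters against ancestor bias."""

    ancestor_id: str
    ancestor_bias: str
    well_ids: list[str]
    granddaughter_bias: list[str]
    inherited: list[bool]
    total_yields: list[int]
    fold_changes: list[float]
    excluded_wells: list[str]

    @property
    def n_inherited(self) -> int:
        return int(sum(self.inherited))

    @property
    def n_classified(self) -> int:
        return len(self.inherited)


def infer_ancestor_potency(family: GranddaughterFamily) -> np.ndarray:
    """Ancestor yield vector inferred as the sum of all granddaughters."""
    return family.yields.sum(axis=0)


def _predominant(yields: np.ndarray) -> str:
    """Highest-yield lineage; ties broken by canonical lineage order."""
    return LINEAGES[int(np.argmax(yields))]


def classify_inheritance(
    family: GranddaughterFamily, use_known_ancestor: bool = True
) -> InheritanceCall:
    """Flag each productive granddaughter as bias-inherited or bias-switched.

    The reference ancestral bias is the generator's ground truth when the
    family carries one and ``use_known_ancestor`` is set (synthetic
    parameter-recovery use); otherwise it is the predominant lineage of
    the inferred (summed) ancestor potency, as for real traced families.
    Unproductive (all-zero) granddaughters are excluded with a note.

    Also computes each granddaughter's commitment fold-change relative to
    the inferred ancestor (see :func:`commitment_fold_change`).
    """
    anc = infer_ancestor_potency(family)
    if anc.sum() == 0:
        raise ValidationError(f"family {family.ancestor_id}: no productive granddaughter")
    if use_known_ancestor and family.true_ancestor_bias is not None:
        ancestor_bias = family.true_ancestor_bias
    else:
        ancestor_bias = _predominant(anc)
    wells, gd_bias, inherited, totals, folds, excluded = [], [], [], [], [], []
    for well, y in zip(family.well_ids, family.yields):
        if y.sum() == 0:
            excluded.append(well)
            continue
        b = _predominant(y)
        wells.append(well)
        gd_bias.append(b)
        inherited.append(b == ancestor_bias)
        totals.append(int(y.sum()))
        folds.append(commitment_fold_change(anc, y))
    return InheritanceCall(
        ancestor_id=family.ancestor_id, ancestor_bias=ancestor_bias,
        well_ids=wells, granddaughter_bias=gd_bias, inherited=inherited,
        total_yields=totals, fold_changes=folds, excluded_wells=excluded,
    )


def pooled_inheritance_rate(calls: Sequence[InheritanceCall]) -> tuple[float, float, int]:
    """Pooled inherited fraction, its standard error of proportion, and n."""
    n = sum(c.n_classified for c in calls)
    if n == 0:
        raise InsufficientDataError("no classified granddaughters")
    k = sum(c.n_inherited for c in calls)
    p = k / n
    return p, float(np.sqrt(p * (1 - p) / n)), n


def switch_direction_matrix(calls: Sequence[InheritanceCall]) -> pd.DataFrame:
    """6x6 ancestor-bias x granddaughter-bias counts.

    Off-diagonal entry (a, b) counts granddaughters that switched from
    ancestral bias a to bias b; the diagonal holds inherited counts.
    """
    m = np.zeros((6, 6), dtype=np.int64)
    for c in calls:
        a = LINEAGES.index(c.ancestor_bias)
        for b in c.granddaughter_bias:
            m[a, LINEAGES.index(b)] += 1
    return pd.DataFrame(m, index=list(LINEAGES), columns=list(LINEAGES))


def commitment_fold_change(ancestor: np.ndarray, granddaughter: np.ndarray) -> float:
    """Granddaughter commitment to its own predominant lineage, as a fold
    of the ancestor's commitment to that same lineage.

    Commitment degree is the lineage's share of the clone's total yield.
    For a switched granddaughter the reference lineage is its new
    predominant lineage.  NaN when the ancestor produced none of it.
    """
    ancestor = np.asarray(ancestor, dtype=float)
    granddaughter = np.asarray(granddaughter, dtype=float)
    if granddaughter.sum() == 0 or ancestor.sum() == 0:
        raise ValidationError("fold change requires productive ancestor and granddaughter")
    k = int(np.argmax(granddaughter))
    gd_commit = granddaughter[k] / granddaughter.sum()
    anc_commit = ancestor[k] / ancestor.sum()
    if anc_commit == 0:
        return float("nan")
    return float(gd_commit / anc_commit)


def heritage_summary(calls: Sequence[InheritanceCall]) -> pd.DataFrame:
    """Long-format per-granddaughter call table for export."""
    rows = []
    for c in calls:
        for well, b, inh, tot, fc in zip(
            c.well_ids, c.granddaughter_bias, c.inherited, c.total_yields, c.fold_changes
        ):
            rows.append(dict(ancestor_id=c.ancestor_id, well_id=well,
                             ancestor_bias=c.ancestor_bias, granddaughter_bias=b,
                             inherited=inh, total_yield=tot, fold_change=fc))
    return pd.DataFrame(rows)
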