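"""Canonical lineage and progenitor-subset vocabulary.

Every matrix, statistic and file in this package uses one fixed lineage
order: (G, M, L, DC1, DC2, pDC).  Published figures vary the order; here a
single canonical order is used everywhere so that column permutations of
input files cannot change any downstream statistic.
"""

from __future__ import annotations

from enum import Enum

#: Canonical order of the six core terminal lineages:
#: granulocyte, monocyte, lymphocyte (B/NK), CD141+ cDC1, CD1c+ cDC2,
#: plasmacytoid DC.
LINEAGES: tuple[str, ...] = ("G", "M", "L", "DC1", "DC2", "pDC")

#: Extra lineages produced only in the MS5-stroma (JD) culture arm:
#: erythrocyte and megakaryocyte.  When present they follow the core six.
EXTRA_LINEAGES: tuple[str, ...] = ("Er", "Mk")

N_LINEAGES = len(LINEAGES)


class Subset(str, Enum):
    """Marker-defined CD34+ progenitor subsets of human cord blood."""

    HSC = "HSC"
    MPP = "MPP"
    LMPP = "LMPP"
    MLP = "MLP"
    BNKP = "BNKP"
    CMP = "CMP"
    GMDP = "GMDP"
    MDP = "MDP"
    CDP = "CDP"


class Culture(str, Enum):
    """Single-cell culture system the clone was grown in.

    MPFSG: MS5 stroma + FLT3L/SCF/GM-CSF mix supporting G, M, L and the
    three DC lineages.  JD: MS5 stroma with an extended cytokine mix that
    additionally supports Er and Mk output.
    """

    MPFSG = "MPFSG"
    JD = "JD"


SUBSETS: tuple[str, ...] = tuple(s.value for s in Subset)


def lineage_index(lineage: str) -> int:
    """Position of *lineage* in the canonical order (core + extra)."""
    order = LINEAGES + EXTRA_LINEAGES
    try:
        return order.index(lineage)
    except ValueError:
        raise KeyError(f"unknown lineage {lineage!r}; expected one of {order}") from None
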