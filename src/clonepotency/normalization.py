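"""Geometric-mean (median-of-ratios style) normalization of clonal output.

Two variants are used on clone tables, mirroring the size-factor idea of
DESeq:

* donor factors — within each progenitor subset, per-donor factors that
  equalize the geometric mean of total clonal output across donors (the
  biological assumption being that a given progenitor phenotype should
  behave similarly across cord-blood donors);
* lineage factors — per lineage-column factors that equalize geometric
  means across the six progeny types (the culture system under-produces
  pDCs relative to the others).

Both return multiplicative :class:`SizeFactorSet` objects; dividing by a
factor performs the normalization.  Geometric means are computed over
positive entries (zeros excluded, the DESeq convention), which keeps the
factors finite and makes them exactly equivariant under rescaling; a
pseudocount alternative is available.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .clone_io import CloneTable
from .errors import ValidationError
from .lineages import LINEAGES


@dataclasses.dataclass
class SizeFactorSet:
    """Positive multiplicative factors keyed by group (donor or lineage)."""

    factors: dict
    kind: str  # "donor" or "lineage"
    flagged: list = dataclasses.field(default_factory=list)

    def __post_init__(self):
        for k, f in self.factors.items():
            if not np.isfinite(f) or f <= 0:
                raise ValidationError(f"size factor for {k!r} is {f}; must be positive finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": [_key_str(k) for k in self.factors], "factor": list(self.factors.values())}
        )


def _key_str(k) -> str:
    return "/".join(k) if isinstance(k, tuple) else str(k)


def _geomean_positive(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    pos = x[x > 0]
    if pos.size == 0:
        return float("nan")
    return float(np.exp(np.mean(np.log(pos))))


def donor_size_factors(table: CloneTable) -> SizeFactorSet:
    """Per-(subset, donor) factors equalizing geometric-mean clone totals.

    Within each subset, a donor's factor is the geometric mean of that
    donor's productive-clone totals divided by the geometric mean of all
    donors' per-donor geometric means for the subset.  Dividing totals by
    the factors makes per-donor geometric means agree within each subset.
    Donor groups with only zero-yield clones cannot be scaled; they are
    flagged, given factor 1, and a warning is issued.
    """
    frame = table.frame
    totals = table.yields().sum(axis=1).astype(float)
    factors: dict = {}
    flagged: list = []
    for subset, sub_idx in frame.groupby("subset", sort=False).groups.items():
        sub = frame.loc[sub_idx]
        donor_gms = {}
        for donor, don_idx in sub.groupby("donor_id", sort=False).groups.items():
            gm = _geomean_positive(totals[frame.index.get_indexer_for(don_idx)])
            donor_gms[donor] = gm
        valid = {d: g for d, g in donor_gms.items() if np.isfinite(g)}
        grand = np.exp(np.mean(np.log(list(valid.values())))) if valid else float("nan")
        for donor, gm in donor_gms.items():
            key = (str(subset), str(donor))
            if np.isfinite(gm):
                factors[key] = gm / grand
            else:
                flagged.append(key)
                factors[key] = 1.0
    if flagged:
        warnings.warn(f"{len(flagged)} donor group(s) had no productive clone; left unscaled",
                      stacklevel=2)
    return SizeFactorSet(factors=factors, kind="donor", flagged=flagged)


def apply_donor_factors(table: CloneTable, factors: SizeFactorSet) -> np.ndarray:
    """Clone-by-lineage matrix with each clone divided by its donor factor.

    Returns a float matrix; the clone table itself is left untouched.
    """
    frame = table.frame
    y = table.yields().astype(float)
    f = np.array([factors.factors[(s, d)] for s, d in zip(frame["subset"], frame["donor_id"])])
    return y / f[:, None]


def lineage_size_factors(matrix: np.ndarray, pseudocount: float = 0.0):
    """Per-lineage-column factors equalizing column geometric means.

    With ``pseudocount=0`` the geometric mean of each column is taken
    over its positive entries only, making factors exactly equivariant
    under column rescaling; with a positive pseudocount it is taken over
    all entries of (column + pseudocount), an approximation useful when
    columns are nearly all zero.  Factors are scaled to have geometric
    mean 1.  Returns ``(SizeFactorSet, scaled_matrix)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("need a clones x lineages matrix with >= 2 columns")
    names = list(LINEAGES[: X.shape[1]]) if X.shape[1] <= 6 else [f"col{j}" for j in range(X.shape[1])]
    gms = np.empty(X.shape[1])
    flagged = []
    for j in range(X.shape[1]):
        col = X[:, j] + pseudocount
        gms[j] = _geomean_positive(col)
        if not np.isfinite(gms[j]):
            flagged.append(names[j])
    if flagged:
        warnings.warn(f"all-zero lineage column(s) {flagged}; left unscaled", stacklevel=2)
        gms[~np.isfinite(gms)] = np.nan
    grand = np.exp(np.nanmean(np.log(gms)))
    factors = {}
    scaled = X.copy()
    for j, name in enumerate(names):
        f = gms[j] / grand if np.isfinite(gms[j]) else 1.0
        factors[name] = f
        scaled[:, j] = X[:, j] / f
    return SizeFactorSet(factors=factors, kind="lineage", flagged=flagged), scaled


def log10_transform(matrix: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Elementwise log10(x + pseudocount).

    A positive pseudocount is required whenever zeros are present.
    """
    X = np.asarray(matrix, dtype=float)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (X <= 0).any():
        raise ValidationError("zeros present; a positive pseudocount is required")
    return np.log10(X + pseudocount)
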