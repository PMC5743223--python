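"""Clone data model and delimited-table I/O.

A *clone* is the full progeny of one single sorted progenitor cultured in
one well, summarised by its per-lineage terminal cell counts.  Tables are
plain CSV/TSV with one row per clone and the header

    clone_id, donor_id, subset, culture, division, G, M, L, DC1, DC2, pDC[, Er, Mk]

Counts are non-negative integers (flow-cytometry event counts); fractional
values are rejected rather than rounded.  ``division`` (CFSE division
generation) may be empty — most clones were not division-tracked.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .lineages import EXTRA_LINEAGES, LINEAGES, Culture, Subset

META_COLUMNS: tuple[str, ...] = ("clone_id", "donor_id", "subset", "culture", "division")
MANDATORY_COLUMNS: tuple[str, ...] = META_COLUMNS[:4] + LINEAGES


@dataclasses.dataclass(frozen=True)
class CloneRecord:
    """One clone: identity plus its terminal lineage-yield vector."""

    clone_id: str
    donor_id: str
    subset: Subset
    culture: Culture
    yields: np.ndarray  # int64, canonical lineage order
    division: int | None = None

    def __post_init__(self):
        y = np.asarray(self.yields, dtype=np.int64)
        if y.ndim != 1 or y.size not in (len(LINEAGES), len(LINEAGES) + len(EXTRA_LINEAGES)):
            raise ValidationError(f"clone {self.clone_id}: yield vector has shape {y.shape}")
        if (y < 0).any():
            raise ValidationError(f"clone {self.clone_id}: negative yield")
        object.__setattr__(self, "yields", y)

    @property
    def total_yield(self) -> int:
        return int(self.yields[: len(LINEAGES)].sum())


class CloneTable:
    """An ordered, validated collection of clones backed by a DataFrame.

    Columns are always in canonical order; lineage counts are int64.
    ``provenance`` records where the table came from and what was applied
    to it (source path, thresholds), for the run manifest.
    """

    def __init__(self, frame: pd.DataFrame, provenance: Mapping | None = None):
        self._frame = _canonicalize(frame)
        self.provenance: dict = dict(provenance or {})
        _validate(self._frame)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(cls, records: list[CloneRecord], provenance: Mapping | None = None) -> "CloneTable":
        if not records:
            raise ValidationError("empty clone table")
        extra = any(r.yields.size > len(LINEAGES) for r in records)
        lin_cols = LINEAGES + (EXTRA_LINEAGES if extra else ())
        rows = []
        for r in records:
            y = np.zeros(len(lin_cols), dtype=np.int64)
            y[: r.yields.size] = r.yields
            rows.append(
                dict(
                    clone_id=r.clone_id,
                    donor_id=r.donor_id,
                    subset=r.subset.value,
                    culture=r.culture.value,
                    division=r.division,
                    **dict(zip(lin_cols, y.tolist())),
                )
            )
        return cls(pd.DataFrame(rows), provenance)

    # -- container protocol -----------------------------------------------

    def __len__(self) -> int:
        return len(self._frame)

    def __iter__(self) -> Iterator[CloneRecord]:
        lin = self.lineage_columns
        for _, row in self._frame.iterrows():
            div = row["division"]
            yield CloneRecord(
                clone_id=row["clone_id"],
                donor_id=row["donor_id"],
                subset=Subset(row["subset"]),
                culture=Culture(row["culture"]),
                division=None if pd.isna(div) else int(div),
                yields=row[list(lin)].to_numpy(dtype=np.int64),
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneTable):
            return NotImplemented
        a, b = self._frame, other._frame
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        return a.reset_index(drop=True).equals(b.reset_index(drop=True))

    # -- views -------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying DataFrame (canonical column order); do not mutate."""
        return self._frame

    @property
    def lineage_columns(self) -> tuple[str, ...]:
        cols = LINEAGES
        if all(c in self._frame.columns for c in EXTRA_LINEAGES):
            cols = LINEAGES + EXTRA_LINEAGES
        return cols

    def yields(self, core_only: bool = True) -> np.ndarray:
        """Clones x lineages count matrix (canonical order)."""
        cols = LINEAGES if core_only else self.lineage_columns
        return self._frame[list(cols)].to_numpy(dtype=np.int64)

    def clone_ids(self) -> np.ndarray:
        return self._frame["clone_id"].to_numpy()

    def select(self, mask: np.ndarray, note: str | None = None) -> "CloneTable":
        prov = dict(self.provenance)
        if note:
            prov.setdefault("filters", []).append(note)
        return CloneTable(self._frame.loc[np.asarray(mask)], prov)


def _canonicalize(frame: pd.DataFrame) -> pd.DataFrame:
    """Re-order columns to the canonical layout, dropping nothing."""
    cols = list(META_COLUMNS) if "division" in frame.columns else [c for c in META_COLUMNS if c != "division"]
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    lin = list(LINEAGES) + [c for c in EXTRA_LINEAGES if c in frame.columns]
    out = frame.loc[:, cols[:4] + (["division"] if "division" in frame.columns else []) + lin].copy()
    if "division" not in out.columns:
        out["division"] = pd.array([pd.NA] * len(out), dtype="Int64")
        out = out[list(META_COLUMNS) + lin]
    else:
        out["division"] = pd.array(out["division"], dtype="Int64")
    return out.reset_index(drop=True)


def _validate(frame: pd.DataFrame) -> None:
    if len(frame) == 0:
        raise ValidationError("empty clone table")
    dup = frame["clone_id"].duplicated()
    if dup.any():
        rows = list(np.flatnonzero(dup.to_numpy()))
        raise ValidationError(f"duplicate clone_id(s) at row(s) {rows}", rows=rows)
    for col in ("subset", "culture"):
        enum = Subset if col == "subset" else Culture
        ok = frame[col].isin([e.value for e in enum])
        if not ok.all():
            rows = list(np.flatnonzero(~ok.to_numpy()))
            bad = frame[col].iloc[rows[0]]
            raise ValidationError(f"invalid {col} {bad!r} at row(s) {rows}", rows=rows)
    lin = [c for c in list(LINEAGES) + list(EXTRA_LINEAGES) if c in frame.columns]
    for col in lin:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            rows = list(np.flatnonzero(bad.to_numpy()))
            raise ValidationError(
                f"column {col}: non-integer or negative count at row(s) {rows}", rows=rows
            )
        frame[col] = vals.astype(np.int64)
    div = frame["division"]
    neg = div.notna() & (div < 0)
    if neg.any():
        rows = list(np.flatnonzero(neg.to_numpy()))
        raise ValidationError(f"negative division generation at row(s) {rows}", rows=rows)


def read_clone_table(
    path: str | Path,
    dialect: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> CloneTable:
    """Read and validate a delimited clone table.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    dialect
        "csv" or "tsv"; inferred from the file extension when omitted.
    column_map
        Optional mapping from the file's column names to the canonical
        schema, for importing tables with a foreign layout
        (e.g. ``{"well": "clone_id", "CD66b": "G"}``).
    """
    path = Path(path)
    sep = _sep(dialect, path)
    frame = pd.read_csv(path, sep=sep, dtype={"clone_id": str, "donor_id": str})
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    table = CloneTable(frame, provenance={"source": str(path)})
    return table


def write_clone_table(table: CloneTable, path: str | Path, dialect: str | None = None) -> None:
    """Write a clone table losslessly (round-trips bit-for-bit).

    Missing divisions become empty cells, never the string "None".
    """
    path = Path(path)
    sep = _sep(dialect, path)
    table.frame.to_csv(path, sep=sep, index=False, na_rep="")


def _sep(dialect: str | None, path: Path) -> str:
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".tab", ".txt") else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    return "\t" if dialect == "tsv" else ","
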