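"""Lineage tracks: backbones of highly committed clones, distances, assignment.

In the 2-D map, each lineage's *backbone* is the set of clones with at
least 70% commitment degree to that lineage.  Every clone's distance to a
track is its Euclidean distance to the nearest backbone member, and each
clone is assigned to its closest track.  A threshold above 0.5 guarantees
a clone can belong to at most one backbone.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ValidationError
from .lineages import LINEAGES

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class TrackBackbones:
    """Per-lineage backbone membership over an embedded clone set."""

    members: dict  # lineage -> integer index array
    coords: np.ndarray  # N x 2 embedding, aligned with the commitment matrix
    threshold: float

    @property
    def empty_lineages(self) -> list[str]:
        return [l for l in LINEAGES if len(self.members[l]) == 0]


@dataclasses.dataclass
class TrackAssignment:
    distances: np.ndarray  # N x 6, +inf for empty backbones
    assigned: list  # lineage label per clone
    ties: list  # clone indices where the argmin was tied (broken canonically)


def build_backbones(commitments: np.ndarray, coords: np.ndarray,
                    threshold: float = 0.7) -> TrackBackbones:
    """Backbone_k = clones with commitment degree >= threshold to lineage k.

    The boundary is inclusive ("70% commitment" read as at-least).
    Unipotent clones (commitment 1) participate.  Empty backbones are
    reported, not an error — small tables may lack committed clones for
    a lineage.
    """
    C = np.asarray(commitments, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if not 0.5 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0.5, 1] so backbones are disjoint")
    if C.ndim != 2 or C.shape[1] != 6:
        raise ValidationError("commitments must be N x 6")
    if not np.allclose(C.sum(axis=1), 1.0, atol=1e-6):
        raise ValidationError("commitment rows must sum to 1")
    if coords.shape[0] != C.shape[0]:
        raise ValidationError("coords misaligned with commitments")
    members = {l: np.flatnonzero(C[:, k] >= threshold) for k, l in enumerate(LINEAGES)}
    empties = [l for l in LINEAGES if members[l].size == 0]
    if empties:
        logger.info("empty backbone(s): %s", ", ".join(empties))
    return TrackBackbones(members=members, coords=coords, threshold=threshold)


def distance_to_tracks(coords: np.ndarray, backbones: TrackBackbones) -> np.ndarray:
    """N x 6 matrix of distances to the nearest member of each backbone.

    Empty backbones yield +inf so they can never win an assignment.
    """
    coords = np.asarray(coords, dtype=float)
    if all(backbones.members[l].size == 0 for l in LINEAGES):
        raise ValidationError("every backbone is empty; nothing to assign to")
    out = np.full((coords.shape[0], 6), np.inf)
    for k, l in enumerate(LINEAGES):
        idx = backbones.members[l]
        if idx.size:
            out[:, k] = cdist(coords, backbones.coords[idx]).min(axis=1)
    return out


def assign_tracks(distances: np.ndarray) -> TrackAssignment:
    """Assign each clone to its nearest track (argmin per row).

    Exact ties are broken by canonical lineage order and logged.  A row
    with no finite distance is an error naming the clone indices.
    """
    D = np.asarray(distances, dtype=float)
    bad = np.flatnonzero(~np.isfinite(D).any(axis=1))
    if bad.size:
        raise ValidationError(f"clone(s) {list(bad)} have no finite track distance")
    ties = []
    labels = []
    for i, row in enumerate(D):
        k = int(np.argmin(row))
        if (row == row[k]).sum() > 1:
            ties.append(i)
        labels.append(LINEAGES[k])
    if ties:
        logger.info("tie-broken track assignment for %d clone(s)", len(ties))
    return TrackAssignment(distances=D, assigned=labels, ties=ties)


def assignment_frame(clone_ids, assignment: TrackAssignment) -> pd.DataFrame:
    cols = {f"d_{l}": assignment.distances[:, k] for k, l in enumerate(LINEAGES)}
    return pd.DataFrame({"clone_id": list(clone_ids),
                         "assigned_track": assignment.assigned, **cols})
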