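"""Correlate IRF8/PU.1 gate occupancy with lineage-bias composition.

Mature blood lineages occupy characteristic IRF8/PU.1 expression gates.
Given, per progenitor subset, (a) the percentage of cells falling in each
of the six dosage gates and (b) the percentage of clones biased to each
lineage, a gate-by-lineage Pearson correlation matrix across subsets
quantifies how well a dosage state predicts a lineage propensity.

Significance uses the t-test for a correlation coefficient,
t = r sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom, which is exact
under bivariate normality; a Fisher-z variant (atanh(r) sqrt(n-3)
against the standard normal) is available.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError


@dataclasses.dataclass
class DosageCompositionTables:
    """Aligned per-subset percentage tables (gates and lineage biases).

    Rows are progenitor subsets (shared ordering); each row sums to at
    most 100 (an ungated remainder is allowed).  ``correspondence`` maps
    gate name to generating lineage when known (synthetic tables).
    """

    gate_percent: pd.DataFrame
    bias_percent: pd.DataFrame
    correspondence: dict | None = None

    def __post_init__(self):
        if list(self.gate_percent.index) != list(self.bias_percent.index):
            raise ValidationError("gate and bias tables must share subset ordering")
        for df, name in ((self.gate_percent, "gate"), (self.bias_percent, "bias")):
            if (df.to_numpy() < -1e-9).any():
                raise ValidationError(f"negative percentages in {name} table")
            if (df.sum(axis=1) > 100.0 + 1e-6).any():
                raise ValidationError(f"{name} percentages exceed 100 for some subset")

    @property
    def n_subsets(self) -> int:
        return len(self.gate_percent)


def correlate_compositions(tables: DosageCompositionTables) -> pd.DataFrame:
    """Gate x lineage Pearson r across subsets.

    Entries for constant vectors (zero variance) are NaN and reported via
    the returned frame.
    """
    if tables.n_subsets < 3:
        raise InsufficientDataError("need >= 3 subsets to correlate")
    G = tables.gate_percent.to_numpy(dtype=float)
    B = tables.bias_percent.to_numpy(dtype=float)
    out = np.full((G.shape[1], B.shape[1]), np.nan)
    for i in range(G.shape[1]):
        if np.ptp(G[:, i]) == 0:
            continue
        for j in range(B.shape[1]):
            if np.ptp(B[:, j]) == 0:
                continue
            out[i, j] = np.corrcoef(G[:, i], B[:, j])[0, 1]
    return pd.DataFrame(out, index=tables.gate_percent.columns,
                        columns=tables.bias_percent.columns)


def correlation_significance(r: float, n: int, method: str = "t") -> tuple[float, float]:
    """Two-sided test of H0: rho = 0 for an observed Pearson r at size n.

    method="t": classical t-test on r (exact under the null).
    method="fisher": Fisher z-transform referred to the standard normal.
    |r| = 1 is capped just inside the open interval before transforming.
    Returns ``(statistic, p_value)``.
    """
    if n < 4:
        raise InsufficientDataError("need n >= 4 for a correlation test")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValidationError(f"invalid correlation {r}")
    capped = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    if method == "t":
        stat = capped * np.sqrt((n - 2) / (1.0 - capped**2))
        p = 2.0 * stats.t.sf(abs(stat), df=n - 2)
    elif method == "fisher":
        stat = np.arctanh(capped) * np.sqrt(n - 3)
        p = 2.0 * stats.norm.sf(abs(stat))
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(stat), float(min(max(p, np.nextafter(0, 1)), 1.0))


def significance_matrix(r_matrix: pd.DataFrame, n: int, method: str = "t") -> pd.DataFrame:
    """Elementwise p-values for a correlation matrix at sample size n."""
    out = r_matrix.copy()
    for i in r_matrix.index:
        for j in r_matrix.columns:
            r = r_matrix.loc[i, j]
            out.loc[i, j] = np.nan if np.isnan(r) else correlation_significance(r, n, method)[1]
    return out


def clustered_order(r_matrix: pd.DataFrame):
    """Row/column orderings of the r matrix by complete-linkage clustering,
    for heat-map style reporting.  NaNs are imputed at 0 for ordering only."""
    from .cluster_order import hcluster, optimal_leaf_order, similarity_from_points

    M = r_matrix.to_numpy(dtype=float)
    M = np.where(np.isfinite(M), M, 0.0)
    orders = []
    for axis_matrix in (M, M.T):
        tree = hcluster(axis_matrix)
        perm, _ = optimal_leaf_order(tree, similarity_from_points(axis_matrix))
        orders.append(perm)
    return orders[0], orders[1]
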