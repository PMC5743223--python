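"""Per-clone lineage positivity and bias statistics; subset summaries.

Definitions (all on the six core lineage yields of one clone):

* a lineage is *positive* when its event count reaches the subset's
  detection threshold (7 events; 2 for CDPs, whose clones are small);
  a clone is *productive* when at least one lineage is positive;
* *commitment degree* of lineage k: yield_k / total yield (sums to 1);
* *equipotency ratio*: smallest / largest yield among positive lineages
  of a non-unipotent clone (1 = truly equipotent);
* *bias ratio*: second-largest / largest of the six yields of a
  non-unipotent clone (0 = wholly biased);
* *predominant lineage*: the argmax yield, ties broken by canonical
  lineage order.

The equipotency ratio is restricted to positive lineages because
structural zeros would pin it at 0 for every clone short of six
lineages; a switch computes it over all six instead.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clone_io import CloneRecord, CloneTable
from .errors import InsufficientDataError, ValidationError
from .lineages import LINEAGES, Subset

DEFAULT_THRESHOLD = 7
CDP_THRESHOLD = 2


@dataclasses.dataclass(frozen=True)
class PositivityThresholds:
    """Minimum event count per lineage gate, by subset."""

    default: int = DEFAULT_THRESHOLD
    per_subset: dict = dataclasses.field(default_factory=lambda: {"CDP": CDP_THRESHOLD})

    def __post_init__(self):
        if self.default < 1 or any(v < 1 for v in self.per_subset.values()):
            raise ValidationError("positivity thresholds must be >= 1")

    def for_subset(self, subset: str | Subset) -> int:
        s = subset.value if isinstance(subset, Subset) else subset
        return int(self.per_subset.get(s, self.default))


@dataclasses.dataclass
class CloneBiasProfile:
    clone_id: str
    subset: str
    positive_lineages: np.ndarray  # boolean 6-vector
    n_lineages: int
    commitment_degree: np.ndarray  # 6-vector summing to 1
    equipotency_ratio: float  # NaN for unipotent clones
    bias_ratio: float  # NaN for unipotent clones
    predominant_lineage: str
    total_yield: int

    @property
    def unipotent(self) -> bool:
        return self.n_lineages == 1


def call_positivity(record: CloneRecord, thresholds: PositivityThresholds | None = None):
    """Boolean lineage-positivity 6-vector and productive flag."""
    thresholds = thresholds or PositivityThresholds()
    t = thresholds.for_subset(record.subset)
    positive = record.yields[:6] >= t
    return positive, bool(positive.any())


def bias_profile(record: CloneRecord, thresholds: PositivityThresholds | None = None,
                 equipotency_over_positive: bool = True) -> CloneBiasProfile:
    """Full bias profile of one productive clone.

    Raises for unproductive clones (no positive lineage); equipotency and
    bias ratios are NaN for unipotent clones, for which they are not
    defined.
    """
    positive, productive = call_positivity(record, thresholds)
    if not productive:
        raise ValidationError(f"clone {record.clone_id} is unproductive; profile undefined")
    y = record.yields[:6].astype(float)
    total = y.sum()
    commitment = y / total
    n_lin = int(positive.sum())
    if n_lin >= 2:
        dom = y[positive] if equipotency_over_positive else y
        equi = float(dom.min() / dom.max())
        srt = np.sort(y)
        biasr = float(srt[-2] / srt[-1])
    else:
        equi = float("nan")
        biasr = float("nan")
    return CloneBiasProfile(
        clone_id=record.clone_id,
        subset=record.subset.value,
        positive_lineages=positive,
        n_lineages=n_lin,
        commitment_degree=commitment,
        equipotency_ratio=equi,
        bias_ratio=biasr,
        predominant_lineage=LINEAGES[int(np.argmax(y))],
        total_yield=int(total),
    )


def profile_table(table: CloneTable, thresholds: PositivityThresholds | None = None) -> pd.DataFrame:
    """Per-clone profile frame; unproductive clones get productive=False rows."""
    thresholds = thresholds or PositivityThresholds()
    rows = []
    for rec in table:
        positive, productive = call_positivity(rec, thresholds)
        if not productive:
            rows.append(dict(clone_id=rec.clone_id, subset=rec.subset.value,
                             donor_id=rec.donor_id, productive=False, n_lineages=0,
                             equipotency_ratio=np.nan, bias_ratio=np.nan,
                             predominant_lineage="", total_yield=int(rec.yields[:6].sum()),
                             **{f"commit_{l}": np.nan for l in LINEAGES}))
            continue
        p = bias_profile(rec, thresholds)
        rows.append(dict(clone_id=p.clone_id, subset=p.subset, donor_id=rec.donor_id,
                         productive=True, n_lineages=p.n_lineages,
                         equipotency_ratio=p.equipotency_ratio, bias_ratio=p.bias_ratio,
                         predominant_lineage=p.predominant_lineage, total_yield=p.total_yield,
                         **{f"commit_{l}": c for l, c in zip(LINEAGES, p.commitment_degree)}))
    return pd.DataFrame(rows)


def potency_composition(table: CloneTable, thresholds: PositivityThresholds | None = None) -> pd.DataFrame:
    """Per-subset clonal efficiency, lineage-number distribution and bias
    composition (% of productive clones predominant to each lineage, with
    standard errors of proportion)."""
    prof = profile_table(table, thresholds)
    rows = []
    for subset, sub in prof.groupby("subset", sort=False):
        n_seeded = len(sub)
        prod = sub[sub["productive"]]
        n_prod = len(prod)
        eff = n_prod / n_seeded
        row = dict(subset=subset, n_seeded=n_seeded, n_productive=n_prod,
                   clonal_efficiency=eff,
                   efficiency_se=float(np.sqrt(eff * (1 - eff) / n_seeded)))
        for k in range(7):
            row[f"n_lineages_{k}"] = int((sub["n_lineages"] == k).sum())
        for lin in LINEAGES:
            p = (prod["predominant_lineage"] == lin).mean() if n_prod else np.nan
            row[f"pct_bias_{lin}"] = 100.0 * p if n_prod else np.nan
            row[f"se_bias_{lin}"] = (100.0 * np.sqrt(p * (1 - p) / n_prod)) if n_prod else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class BiasYieldAssociation:
    equipotency_hist: pd.DataFrame
    bias_hist: pd.DataFrame
    equipotency_pct_below_half: float
    equipotency_pct_above_half: float
    bias_pct_below_half: float
    bias_pct_above_half: float
    spearman_equipotency_vs_log_yield: float
    spearman_bias_vs_log_yield: float
    n_non_unipotent: int
    degenerate_yield: bool = False


def _hist(values: np.ndarray) -> pd.DataFrame:
    edges = np.arange(0.0, 1.1, 0.1)
    counts, _ = np.histogram(values, bins=edges)  # last bin [0.9, 1.0] closed, so 1.0 counted
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})


def bias_yield_association(profiles: Sequence[CloneBiasProfile]) -> BiasYieldAssociation:
    """Distribution of equipotency/bias ratios and their association with
    clonal yield, over non-unipotent clones.

    Histograms use bins of width 0.1; the cumulative percentages below and
    above 0.5 summarize how biased the population is.  Association is
    Spearman's rank correlation of each ratio against log10 total yield.
    """
    non_uni = [p for p in profiles if not p.unipotent]
    if len(non_uni) < 3:
        raise InsufficientDataError(
            f"need >= 3 non-unipotent profiles, have {len(non_uni)}")
    equi = np.array([p.equipotency_ratio for p in non_uni])
    biasr = np.array([p.bias_ratio for p in non_uni])
    log_yield = np.log10([p.total_yield for p in non_uni])
    degenerate = bool(np.ptp(log_yield) == 0)
    if degenerate:
        s_eq = s_bi = 0.0
    else:
        s_eq = float(stats.spearmanr(equi, log_yield).statistic)
        s_bi = float(stats.spearmanr(biasr, log_yield).statistic)
    return BiasYieldAssociation(
        equipotency_hist=_hist(equi),
        bias_hist=_hist(biasr),
        equipotency_pct_below_half=100.0 * float((equi < 0.5).mean()),
        equipotency_pct_above_half=100.0 * float((equi > 0.5).mean()),
        bias_pct_below_half=100.0 * float((biasr < 0.5).mean()),
        bias_pct_above_half=100.0 * float((biasr > 0.5).mean()),
        spearman_equipotency_vs_log_yield=s_eq,
        spearman_bias_vs_log_yield=s_bi,
        n_non_unipotent=len(non_uni),
        degenerate_yield=degenerate,
    )
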