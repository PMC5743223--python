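"""Synthetic clone tables, granddaughter families and dosage tables.

The generator emulates the statistical structure of single-cell clonal
fate-mapping of human cord-blood progenitors, so that every downstream
stage is testable without the original flow-cytometry data:

* ~5,000 seeded clones from 9 subsets across 17 donors, with roughly half
  unproductive;
* per-clone lineage composition drawn from subset-specific mixtures of
  seven archetypes — six lineage-biased (one dominant lineage each) and
  one equipotent — via a Dirichlet-multinomial model;
* clone totals log-normal (orders-of-magnitude spread), with biased
  clones yielding more than equipotent ones (positive bias-yield
  coupling) and a multiplicative per-donor effect;
* granddaughter quartets whose members inherit the ancestral bias
  archetype with a tunable probability, switching granddaughters drawing
  lower yields and shallower commitment;
* per-subset IRF8/PU.1 gate-occupancy tables generated as noisy images of
  the subsets' lineage-bias composition with a known gate-to-lineage
  correspondence.

All randomness flows from one seed; independent substreams are derived
per product (clone table / families / dosage) so that, e.g., requesting
more clones never perturbs the granddaughter draws.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clone_io import CloneRecord, CloneTable
from .errors import ValidationError
from .heritage import GranddaughterFamily
from .lineages import LINEAGES, SUBSETS, Culture, Subset

ARCHETYPES: tuple[str, ...] = LINEAGES + ("EQ",)

_DEFAULT_N_CLONES = {
    "HSC": 700, "MPP": 700, "LMPP": 600, "MLP": 500, "BNKP": 450,
    "CMP": 600, "GMDP": 600, "MDP": 450, "CDP": 400,
}
_DEFAULT_UNPRODUCTIVE = {
    "HSC": 0.52, "MPP": 0.52, "LMPP": 0.55, "MLP": 0.60, "BNKP": 0.60,
    "CMP": 0.50, "GMDP": 0.50, "MDP": 0.55, "CDP": 0.65,
}
# Mixture weights over (G, M, L, DC1, DC2, pDC, EQ).  Myeloid-path subsets
# (CMP/GMDP/MDP) weight G and M together; lymphoid-path subsets
# (LMPP/MLP/BNKP) weight L with DC1 and pDC; CDP is DC/pDC-dominated; the
# stem compartments carry the largest equipotent fraction.
_DEFAULT_MIXTURE = {
    "HSC":  (0.18, 0.14, 0.14, 0.08, 0.10, 0.06, 0.30),
    "MPP":  (0.18, 0.16, 0.13, 0.08, 0.11, 0.06, 0.28),
    "LMPP": (0.10, 0.08, 0.30, 0.16, 0.08, 0.18, 0.10),
    "MLP":  (0.06, 0.08, 0.34, 0.16, 0.06, 0.20, 0.10),
    "BNKP": (0.05, 0.05, 0.42, 0.14, 0.04, 0.22, 0.08),
    "CMP":  (0.30, 0.26, 0.06, 0.06, 0.18, 0.04, 0.10),
    "GMDP": (0.30, 0.28, 0.04, 0.08, 0.20, 0.04, 0.06),
    "MDP":  (0.10, 0.36, 0.03, 0.12, 0.26, 0.07, 0.06),
    "CDP":  (0.04, 0.08, 0.02, 0.24, 0.28, 0.30, 0.04),
}


@dataclasses.dataclass
class SimulationParams:
    """Tunable generator parameters; defaults mirror the study conditions.

    bias_concentration sets how dominant each biased archetype's mean
    composition is (dominant share = e^c / (e^c + 5); c=3 gives ~0.80),
    so raising it lowers the typical bias ratio.  dirichlet_precision is
    the total Dirichlet concentration (sampling noise around the mean).
    bias_yield_coupling adds that many log10 units to the expected total
    of a wholly biased clone relative to an equipotent one.
    """

    n_clones: Mapping[str, int] = dataclasses.field(default_factory=lambda: dict(_DEFAULT_N_CLONES))
    n_donors: int = 17
    unproductive_fraction: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_UNPRODUCTIVE))
    archetype_mixture: Mapping[str, Sequence[float]] = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_MIXTURE.items()})
    bias_concentration: float = 3.0
    dirichlet_precision: float = 30.0
    yield_log10_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {a: (3.5 if a == "EQ" else 2.5) for a in ARCHETYPES})
    yield_log10_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {a: (0.6 if a == "EQ" else 0.8) for a in ARCHETYPES})
    bias_yield_coupling: float = 0.8
    donor_log10_effect_sd: float = 0.15
    inheritance_probability: float = 0.8
    switch_yield_penalty_log10: float = 0.5
    inherited_amplification: float = 2.0
    switch_matrix: np.ndarray | None = None  # 6x6 row-stochastic switch kernel; uniform if None
    # optional 6x6 cross-lineage priming: row k sets the relative background
    # composition of archetype k's non-dominant lineages (uniform if None),
    # letting chosen lineage pairs share ancestry by construction
    lineage_background: np.ndarray | None = None
    division_fraction: float = 0.0
    division_levels: tuple[int, ...] = (0, 3, 6)
    division_yield_decay_log10: float = 0.35
    culture: Culture = Culture.MPFSG
    seed: int = 0

    def __post_init__(self):
        for s, f in self.unproductive_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"unproductive_fraction[{s}]={f} outside [0, 1]")
        if not 0.0 <= self.inheritance_probability <= 1.0:
            raise ValidationError("inheritance_probability outside [0, 1]")
        if not 0.0 <= self.division_fraction <= 1.0:
            raise ValidationError("division_fraction outside [0, 1]")
        for s, w in self.archetype_mixture.items():
            w = np.asarray(w, dtype=float)
            if w.size != len(ARCHETYPES) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-8:
                raise ValidationError(f"archetype_mixture[{s}] must be {len(ARCHETYPES)} "
                                      "non-negative weights summing to 1")
        for a in ARCHETYPES:
            if self.yield_log10_sd[a] <= 0:
                raise ValidationError("yield_log10_sd must be positive")
        if self.dirichlet_precision <= 0 or self.bias_concentration <= 0:
            raise ValidationError("concentrations must be positive")
        if self.switch_matrix is not None:
            m = np.asarray(self.switch_matrix, dtype=float)
            if m.shape != (6, 6) or (m < 0).any() or (np.abs(np.diag(m)) > 1e-12).any():
                raise ValidationError("switch_matrix must be 6x6, non-negative, zero diagonal")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent generator for substream *stream* of this seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def archetype_mean(archetype: str, bias_concentration: float,
                   lineage_background: np.ndarray | None = None) -> np.ndarray:
    """Mean lineage composition of an archetype.

    The dominant lineage carries weight e^c against a background of total
    weight 5 spread over the other lineages — uniformly, or proportionally
    to the archetype's row of ``lineage_background`` (cross-lineage
    priming).  The equipotent archetype is uniform regardless.
    """
    if archetype == "EQ":
        return np.full(6, 1.0 / 6.0)
    k = LINEAGES.index(archetype)
    off = np.ones(6)
    if lineage_background is not None:
        off = np.asarray(lineage_background, dtype=float)[k].copy()
        if (off < 0).any() or off[np.arange(6) != k].sum() <= 0:
            raise ValidationError("lineage_background rows must be non-negative with "
                                  "positive off-dominant mass")
    w = off.copy()
    w[k] = 0.0
    w = 5.0 * w / w.sum()
    w[k] = np.exp(bias_concentration)
    return w / w.sum()


def _draw_clone(rng, params: SimulationParams, archetype: str, extra_log10: float = 0.0) -> np.ndarray:
    """One productive clone's count vector under *archetype*."""
    mean = archetype_mean(archetype, params.bias_concentration, params.lineage_background)
    comp = rng.dirichlet(params.dirichlet_precision * mean)
    srt = np.sort(comp)
    bias_ratio = srt[-2] / srt[-1]
    mu = (params.yield_log10_mean[archetype]
          + params.bias_yield_coupling * (1.0 - bias_ratio)
          + extra_log10)
    total = max(1, int(round(10.0 ** rng.normal(mu, params.yield_log10_sd[archetype]))))
    return rng.multinomial(total, comp)


def simulate_clone_table(params: SimulationParams) -> CloneTable:
    """Draw a full clone table; seeded and reproducible.

    Unproductive clones (a per-subset Bernoulli fraction) emit all-zero
    yield vectors.  Productive clones follow archetype -> Dirichlet
    composition -> log-normal total (shifted up with bias degree and by a
    per-donor effect) -> multinomial allocation.
    """
    if sum(params.n_clones.values()) == 0:
        raise ValidationError("zero clones requested")
    rng = params.rng(0)
    donor_ids = [f"D{d + 1:02d}" for d in range(params.n_donors)]
    donor_effect = rng.normal(0.0, params.donor_log10_effect_sd, size=params.n_donors)
    records: list[CloneRecord] = []
    arch_labels: list[str] = []
    for subset in SUBSETS:
        n = int(params.n_clones.get(subset, 0))
        if n == 0:
            continue
        weights = np.asarray(params.archetype_mixture[subset], dtype=float)
        for i in range(n):
            d = int(rng.integers(params.n_donors))
            division = None
            extra = donor_effect[d]
            if params.division_fraction > 0 and rng.random() < params.division_fraction:
                division = int(rng.choice(params.division_levels))
                extra -= params.division_yield_decay_log10 * division
            if rng.random() < params.unproductive_fraction.get(subset, 0.0):
                counts = np.zeros(6, dtype=np.int64)
                arch = "none"
            else:
                arch = ARCHETYPES[int(rng.choice(len(ARCHETYPES), p=weights))]
                counts = _draw_clone(rng, params, arch, extra)
            arch_labels.append(arch)
            records.append(CloneRecord(
                clone_id=f"{subset}_{i + 1:05d}",
                donor_id=donor_ids[d],
                subset=Subset(subset),
                culture=params.culture,
                division=division,
                yields=counts,
            ))
    table = CloneTable.from_records(records, provenance={
        "generator": "clonepotency.synthetic_data", "seed": params.seed,
    })
    table.provenance["true_archetype"] = arch_labels
    return table


def _switch_target(rng, params: SimulationParams, ancestor_idx: int) -> int:
    if params.switch_matrix is None:
        choices = [k for k in range(6) if k != ancestor_idx]
        return int(rng.choice(choices))
    row = np.asarray(params.switch_matrix, dtype=float)[ancestor_idx]
    row = row / row.sum()
    return int(rng.choice(6, p=row))


def simulate_granddaughter_families(
    params: SimulationParams, n_families: int, subset: str | Subset = "HSC"
) -> list[GranddaughterFamily]:
    """Families of 2-4 individually cultured granddaughters of one ancestor.

    Each family has a latent ancestral composition drawn around a biased
    archetype.  A granddaughter inherits the ancestral archetype with
    probability ``inheritance_probability`` — its composition is the
    family composition sharpened toward the dominant lineage (powered by
    ``inherited_amplification``, emulating amplification of inherited
    bias) — otherwise it switches: its dominant and the switch-target
    lineage shares are exchanged and its expected yield drops by
    ``switch_yield_penalty_log10`` decades.  The generator's true
    ancestor bias is stored on each family for parameter-recovery use.
    """
    if n_families < 1:
        raise ValidationError("n_families must be >= 1")
    subset = Subset(subset)
    rng = params.rng(1)
    weights = np.asarray(params.archetype_mixture[subset.value], dtype=float)[:6]
    weights = weights / weights.sum()
    families: list[GranddaughterFamily] = []
    for f in range(n_families):
        a_idx = int(rng.choice(6, p=weights))
        arch = LINEAGES[a_idx]
        base = archetype_mean(arch, params.bias_concentration, params.lineage_background)
        family_comp = rng.dirichlet(params.dirichlet_precision * base)
        n_gd = int(rng.choice([2, 3, 4], p=[0.25, 0.25, 0.50]))
        yields, wells, inherited = [], [], []
        for g in range(n_gd):
            if rng.random() < params.inheritance_probability:
                comp = family_comp ** params.inherited_amplification
                comp = comp / comp.sum()
                mu = params.yield_log10_mean[arch]
                inherited.append(True)
            else:
                b_idx = _switch_target(rng, params, a_idx)
                comp = family_comp.copy()
                comp[[a_idx, b_idx]] = comp[[b_idx, a_idx]]
                mu = params.yield_log10_mean[arch] - params.switch_yield_penalty_log10
                inherited.append(False)
            total = max(1, int(round(10.0 ** rng.normal(mu, params.yield_log10_sd[arch]))))
            yields.append(rng.multinomial(total, comp))
            wells.append(f"F{f + 1:04d}_w{g + 1}")
        families.append(GranddaughterFamily(
            ancestor_id=f"F{f + 1:04d}",
            subset=subset,
            well_ids=wells,
            yields=np.asarray(yields, dtype=np.int64),
            true_ancestor_bias=arch,
            true_inherited=tuple(inherited),
        ))
    return families


#: Paper-style IRF8/PU.1 gate names, in one-to-one correspondence with the
#: canonical lineage order (G, M, L, DC1, DC2, pDC).
GATES: tuple[str, ...] = (
    "IRF8neg_PU1lo", "IRF8loint_PU1hi", "IRF8int_PU1lo",
    "IRF8hi_PU1hi", "IRF8int_PU1hi", "IRF8hi_PU1lo",
)


def expected_bias_composition(params: SimulationParams) -> pd.DataFrame:
    """Expected % of productive clones predominant to each lineage, by subset.

    Biased archetypes are predominant to their own lineage; the equipotent
    archetype contributes uniformly.
    """
    rows = {}
    for subset in SUBSETS:
        w = np.asarray(params.archetype_mixture[subset], dtype=float)
        comp = w[:6] + w[6] / 6.0
        rows[subset] = 100.0 * comp / comp.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(LINEAGES))


def simulate_dosage_tables(params: SimulationParams, noise_sd: float = 3.0,
                           correspondence: Mapping[str, str] | None = None):
    """Per-subset gate-occupancy and bias-composition percentage tables.

    Gate percentages are a (possibly permuted) noisy image of the
    lineage-bias composition, renormalized to sum to 100 per subset; the
    generating gate-to-lineage correspondence is returned on the result
    for recovery tests.
    """
    from .dosage_correlation import DosageCompositionTables

    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = params.rng(2)
    bias = expected_bias_composition(params)
    corr = dict(correspondence) if correspondence else dict(zip(GATES, LINEAGES))
    gate = np.empty((len(SUBSETS), 6))
    for gi, gname in enumerate(GATES):
        gate[:, gi] = bias[corr[gname]].to_numpy()
    gate = np.clip(gate + rng.normal(0.0, noise_sd, size=gate.shape), 0.0, None)
    gate = 100.0 * gate / gate.sum(axis=1, keepdims=True)
    gate_df = pd.DataFrame(gate, index=list(SUBSETS), columns=list(GATES))
    return DosageCompositionTables(gate_percent=gate_df, bias_percent=bias, correspondence=corr)
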