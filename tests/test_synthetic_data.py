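"""Generator contracts: determinism, degenerate limits, parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from clonepotency.errors import ValidationError
from clonepotency.heritage import classify_inheritance, pooled_inheritance_rate
from clonepotency.lineages import LINEAGES, SUBSETS
from clonepotency.potency_metrics import PositivityThresholds, potency_composition, profile_table
from clonepotency.synthetic_data import (ARCHETYPES, SimulationParams,
                                         archetype_mean, expected_bias_composition,
                                         simulate_clone_table,
                                         simulate_dosage_tables,
                                         simulate_granddaughter_families)


def _params(**kw):
    params = SimulationParams(**kw)
    params.n_clones = {s: 60 for s in SUBSETS}
    return params


def test_same_seed_gives_identical_tables():
    a = simulate_clone_table(_params(seed=5))
    b = simulate_clone_table(_params(seed=5))
    assert a == b
    assert simulate_clone_table(_params(seed=6)) != a


def test_all_unproductive_limit():
    params = _params(seed=1)
    params.unproductive_fraction = {s: 1.0 for s in SUBSETS}
    table = simulate_clone_table(params)
    assert table.yields().sum() == 0


def test_zero_clones_requested_is_an_error():
    params = SimulationParams(seed=0)
    params.n_clones = {s: 0 for s in SUBSETS}
    with pytest.raises(ValidationError, match="zero clones"):
        simulate_clone_table(params)


def test_unproductive_share_within_three_binomial_ses():
    params = SimulationParams(seed=2)
    params.n_clones = {"HSC": 2000}
    params.unproductive_fraction = {"HSC": 0.5}
    table = simulate_clone_table(params)
    share = (table.yields().sum(axis=1) == 0).mean()
    se = np.sqrt(0.25 / 2000)
    assert abs(share - 0.5) < 3 * se


def test_invalid_parameters_rejected():
    with pytest.raises(ValidationError):
        SimulationParams(unproductive_fraction={"HSC": 1.5})
    with pytest.raises(ValidationError):
        SimulationParams(inheritance_probability=-0.1)
    bad = {s: tuple(np.full(7, 1 / 7)) for s in SUBSETS}
    bad["HSC"] = tuple([0.5] * 7)  # does not sum to 1
    with pytest.raises(ValidationError):
        SimulationParams(archetype_mixture=bad)


def test_archetype_mean_dominant_share_grows_with_concentration():
    shares = [archetype_mean("G", c)[0] for c in (1.0, 3.0, 5.0)]
    assert shares == sorted(shares)
    assert np.allclose(archetype_mean("EQ", 3.0), 1 / 6)


def test_higher_bias_concentration_lowers_median_bias_ratio():
    medians = []
    for c in (1.5, 3.0, 6.0):
        params = _params(seed=3, bias_concentration=c)
        prof = profile_table(simulate_clone_table(params))
        medians.append(prof["bias_ratio"].median())
    assert medians[0] > medians[1] > medians[2]


def test_composition_recovers_archetype_mixture_within_three_ses():
    """% of productive clones predominant per lineage matches the mixture."""
    params = SimulationParams(seed=8)
    params.n_clones = {"GMDP": 3000}
    params.unproductive_fraction = {"GMDP": 0.0}
    comp = potency_composition(simulate_clone_table(params))
    expected = expected_bias_composition(params).loc["GMDP"]
    row = comp[comp["subset"] == "GMDP"].iloc[0]
    for lin in LINEAGES:
        se = max(row[f"se_bias_{lin}"], 1e-6)
        # archetype -> predominant-lineage mapping is itself slightly noisy;
        # allow 3 SEs plus one percentage point of model slack
        assert abs(row[f"pct_bias_{lin}"] - expected[lin]) < 3 * se + 1.0


def test_dominant_archetype_recovered_as_dominant_bias_group():
    """A subset generated almost purely from the G archetype profiles as G-biased."""
    params = SimulationParams(seed=9)
    params.n_clones = {"CMP": 400}
    params.unproductive_fraction = {"CMP": 0.1}
    mix = dict(params.archetype_mixture)
    mix["CMP"] = (0.9, 0.02, 0.02, 0.02, 0.02, 0.01, 0.01)
    params.archetype_mixture = mix
    comp = potency_composition(simulate_clone_table(params))
    row = comp[comp["subset"] == "CMP"].iloc[0]
    assert row["pct_bias_G"] > max(row[f"pct_bias_{l}"] for l in LINEAGES[1:])


@pytest.mark.parametrize("p,expected", [(1.0, 1.0), (0.0, 0.0)])
def test_inheritance_probability_degenerate_limits(p, expected):
    params = SimulationParams(seed=4, inheritance_probability=p)
    fams = simulate_granddaughter_families(params, 60)
    calls = [classify_inheritance(f) for f in fams]
    rate, _, _ = pooled_inheritance_rate(calls)
    assert rate == pytest.approx(expected, abs=1e-12)


def test_inheritance_rate_recovery_at_p08():
    params = SimulationParams(seed=13, inheritance_probability=0.8)
    fams = simulate_granddaughter_families(params, 500)
    calls = [classify_inheritance(f) for f in fams]
    rate, se, n = pooled_inheritance_rate(calls)
    assert n >= 1000
    assert abs(rate - 0.8) < 3 * np.sqrt(0.8 * 0.2 / n)


def test_families_have_two_to_four_members_and_consistent_subset():
    fams = simulate_granddaughter_families(SimulationParams(seed=0), 50, subset="GMDP")
    assert {f.n_granddaughters for f in fams} <= {2, 3, 4}
    assert all(f.subset.value == "GMDP" for f in fams)


def test_dosage_percentages_sum_to_100_and_noiseless_identity():
    tables = simulate_dosage_tables(SimulationParams(seed=0), noise_sd=0.0)
    np.testing.assert_allclose(tables.gate_percent.sum(axis=1), 100.0, atol=1e-9)
    np.testing.assert_allclose(tables.bias_percent.sum(axis=1), 100.0, atol=1e-9)
    from clonepotency.dosage_correlation import correlate_compositions
    r = correlate_compositions(tables)
    for gate, lineage in tables.correspondence.items():
        assert r.loc[gate, lineage] == pytest.approx(1.0, abs=1e-12)


def test_shuffled_correspondence_matched_pairs_near_zero_in_expectation():
    """With gates mapped to the wrong lineages, the identity-matched pairs
    should average far below the matched-construction value of ~1."""
    shuffled = dict(zip(
        ("IRF8neg_PU1lo", "IRF8loint_PU1hi", "IRF8int_PU1lo",
         "IRF8hi_PU1hi", "IRF8int_PU1hi", "IRF8hi_PU1lo"),
        ("L", "DC1", "G", "pDC", "M", "DC2")))
    vals = []
    for seed in range(10):
        tables = simulate_dosage_tables(SimulationParams(seed=seed), noise_sd=1.0,
                                        correspondence=shuffled)
        from clonepotency.dosage_correlation import correlate_compositions
        r = correlate_compositions(tables)
        vals.extend(float(r.loc[g, l]) for g, l in zip(r.index, r.columns))
    assert abs(np.mean(vals)) < 0.45


def test_substreams_are_independent_of_clone_count():
    """Asking for more clones must not perturb granddaughter draws."""
    small = SimulationParams(seed=21)
    small.n_clones = {"HSC": 10}
    big = SimulationParams(seed=21)
    f1 = simulate_granddaughter_families(small, 20)
    f2 = simulate_granddaughter_families(big, 20)
    for a, b in zip(f1, f2):
        assert np.array_equal(a.yields, b.yields)


def test_division_tracked_yields_decay_with_division():
    params = SimulationParams(seed=6, division_fraction=1.0)
    params.n_clones = {"HSC": 1200}
    params.unproductive_fraction = {"HSC": 0.0}
    table = simulate_clone_table(params)
    frame = table.frame
    totals = table.yields().sum(axis=1)
    means = [np.log10(totals[(frame["division"] == d).to_numpy()] + 1).mean()
             for d in (0, 3, 6)]
    assert means[0] > means[1] > means[2]
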