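import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from epimsap import (
    PairedBandMatrix,
    PopulationMap,
    anova_duncan,
    classify_methylation,
    locus_accounting,
    methylation_levels,
    mixed_score,
)
from epimsap.scoring import duncan_critical_range


@pytest.mark.parametrize(
    "h,m,label,deg",
    [(1, 1, "I", 0), (0, 1, "II", 1), (1, 0, "III", 1), (0, 0, "IV", 2)],
)
def test_type_mapping(h, m, label, deg):
    pbm = PairedBandMatrix(["x"], ["E1/M1_50"], [[h]], [[m]])
    types = classify_methylation(pbm)
    assert types.types[0, 0] == label
    assert types.degree[0, 0] == deg


def _random_bands(seed, n=7, L=11):
    rng = np.random.default_rng(seed)
    return PairedBandMatrix(
        [f"i{k}" for k in range(n)],
        [f"E1/M1_{50 + j}" for j in range(L)],
        rng.integers(0, 2, (n, L)),
        rng.integers(0, 2, (n, L)),
    )


@given(seed=st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_mixed_score_one_hot_and_invertible(seed):
    """Each locus block is one-hot and reconstructs the (H, M) pair."""
    bands = _random_bands(seed)
    types = classify_methylation(bands)
    sub = mixed_score(types)
    assert sub.n_subepiloci == 4 * bands.n_loci
    blocks = sub.B.reshape(bands.n_individuals, bands.n_loci, 4)
    assert (blocks.sum(axis=2) == 1).all()
    back = types.to_bands()
    np.testing.assert_array_equal(back.H, bands.H)
    np.testing.assert_array_equal(back.M, bands.M)


def test_drop_type_columns():
    bands = _random_bands(3)
    sub = mixed_score(classify_methylation(bands))
    reduced = sub.drop_type_columns("I")
    assert reduced.n_subepiloci == 3 * bands.n_loci
    assert all(not s.endswith(":I") for s in reduced.subepilocus_ids)


@given(seed=st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_level_identities_and_order_invariance(seed):
    """Type %s sum to 100; full+hemi=total; total+non=100; order-invariant."""
    rng = np.random.default_rng(seed)
    bands = _random_bands(seed, n=8, L=9)
    pops = PopulationMap(
        assignments={f"i{k}": ("G1" if k < 4 else "G2") for k in range(8)}
    )
    types = classify_methylation(bands)
    summ = methylation_levels(types, pops)
    pct = summ.type_pct
    assert np.allclose(pct.sum(axis=1), 100.0, atol=1e-9)
    lv = summ.levels
    assert np.allclose(lv["full"] + lv["hemi"], lv["total"], atol=1e-9)
    assert np.allclose(lv["total"] + lv["non"], 100.0, atol=1e-9)

    perm = rng.permutation(8)
    shuffled = PairedBandMatrix(
        [bands.individual_ids[p] for p in perm],
        list(bands.locus_ids),
        bands.H[perm],
        bands.M[perm],
    )
    summ2 = methylation_levels(classify_methylation(shuffled), pops)
    assert np.allclose(summ2.levels.to_numpy(), lv.to_numpy(), atol=1e-9)


def test_footnote_convention_swaps_full_hemi():
    bands = _random_bands(5)
    pops = PopulationMap(assignments={f"i{k}": ("G1" if k < 4 else "G2") for k in range(7)})
    types = classify_methylation(bands)
    printed = methylation_levels(types, pops, convention="printed")
    foot = methylation_levels(types, pops, convention="footnote")
    pct = printed.type_pct
    assert np.allclose(printed.levels["full"], pct["II"] + pct["IV"])
    assert np.allclose(printed.levels["hemi"], pct["III"])
    assert np.allclose(foot.levels["full"], pct["III"] + pct["IV"])
    assert np.allclose(foot.levels["hemi"], pct["II"])
    assert np.allclose(foot.levels["total"], printed.levels["total"])


def test_all_type_I_gives_zero_methylation():
    pbm = PairedBandMatrix(
        [f"i{k}" for k in range(4)],
        ["E1/M1_50", "E1/M1_60"],
        np.ones((4, 2)),
        np.ones((4, 2)),
    )
    pops = PopulationMap(assignments={f"i{k}": ("A" if k < 2 else "B") for k in range(4)})
    for conv in ("printed", "footnote"):
        lv = methylation_levels(classify_methylation(pbm), pops, convention=conv).levels
        assert np.allclose(lv["total"], 0) and np.allclose(lv["non"], 100)
        assert np.allclose(lv["full"], 0) and np.allclose(lv["hemi"], 0)


# ---------------------------------------------------------------------------
# ANOVA + Duncan
# ---------------------------------------------------------------------------


def test_duncan_separated_means_distinct_letters():
    rng = np.random.default_rng(0)
    vals, labs = [], []
    for g in range(5):
        vals.append(rng.normal(5.0 * g, 1.0, size=10))  # means 5 SDs apart
        labs += [f"G{g}"] * 10
    res = anova_duncan(np.concatenate(vals), np.array(labs))
    letters = [res["letters"][f"G{g}"] for g in range(5)]
    assert len(set(letters)) == 5 and res["p_value"] < 1e-6
    # brute-force check: every pairwise gap exceeds its Duncan critical range
    means = sorted(np.concatenate(vals).reshape(5, 10).mean(axis=1))
    groups = np.concatenate(vals).reshape(5, 10)
    ms_err = groups.var(axis=1, ddof=1).mean()
    for i in range(5):
        for j in range(i + 1, 5):
            rng_crit = duncan_critical_range(j - i + 1, 45, ms_err, 10, 0.05)
            assert means[j] - means[i] > rng_crit


def test_duncan_tiny_jitter_two_groups():
    vals = np.array([0.0, 1e-6, -1e-6, 0.0, 10.0, 10.0 + 1e-6, 10.0 - 1e-6, 10.0])
    labs = np.array(["A"] * 4 + ["B"] * 4)
    res = anova_duncan(vals, labs)
    assert res["letters"]["A"] != res["letters"]["B"]


def test_duncan_degenerate_equal_constant_groups():
    vals = np.array([3.0] * 4 + [3.0] * 4)
    labs = np.array(["A"] * 4 + ["B"] * 4)
    res = anova_duncan(vals, labs)
    assert res["letters"] == {"A": "a", "B": "a"}


def test_duncan_requires_two_groups():
    with pytest.raises(ValueError):
        anova_duncan(np.arange(4.0), np.array(["A"] * 4))


def test_duncan_null_type_I_error_rate():
    """Two groups from the same distribution share letters ~95% of runs."""
    rng = np.random.default_rng(12)
    same = 0
    n_rep = 1000
    for _ in range(n_rep):
        vals = rng.normal(size=20)
        labs = np.array(["A"] * 10 + ["B"] * 10)
        res = anova_duncan(vals, labs)
        same += res["letters"]["A"] == res["letters"]["B"]
    assert same / n_rep >= 0.94


# ---------------------------------------------------------------------------
# Locus accounting
# ---------------------------------------------------------------------------


def test_locus_accounting_counts(toy_bands):
    acct = locus_accounting(toy_bands)
    tab = acct.table.set_index("primer_pair")
    # E1/M1: locus 100 monomorphic type I; locus 150 polymorphic, methylated
    assert tab.loc["E1/M1", "n_amplified"] == 2
    assert tab.loc["E1/M1", "n_polymorphic"] == 1
    assert tab.loc["E1/M1", "n_methylation"] == 1
    # E2/M2: locus 200 varies (III/II/III) and locus 250 all IV (monomorphic, methylated)
    assert tab.loc["E2/M2", "n_polymorphic"] == 1
    assert tab.loc["E2/M2", "n_methylation"] == 2
    tot = acct.totals
    assert tot["n_methylation"] + tot["n_nonmethylation"] == tot["n_amplified"] == 4
    assert tot["pct_polymorphic"] == pytest.approx(50.0)
    assert tab.loc["E1/M1", "length_min"] == 100
    assert tab.loc["E2/M2", "length_max"] == 250


def test_all_type_I_locus_is_nonmethylated_monomorphic():
    pbm = PairedBandMatrix(
        [f"i{k}" for k in range(5)], ["E1/M1_80"], np.ones((5, 1)), np.ones((5, 1))
    )
    tab = locus_accounting(pbm).table
    assert tab.iloc[0]["n_polymorphic"] == 0
    assert tab.iloc[0]["n_methylation"] == 0
    assert tab.iloc[0]["n_nonmethylation"] == 1
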