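"""Overlap statistics: Jaccard, Fisher, bootstrap machinery, off-target filter."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paraloverlap.decontrast import DEGSet
from paraloverlap.overlapstats import (
    BootstrapConfig,
    basic_bootstrap_ci,
    bootstrap_deg_sets,
    bootstrap_resample_indices,
    cross_pairwise_jaccard,
    fisher_overlap,
    jaccard,
    oe_ratio,
    offtarget_filter,
    pairwise_jaccard,
    z_test_overlap,
    zscore_correlation,
)
from paraloverlap.synth import SimConfig, simulate_counts
from paraloverlap.decontrast import filter_low_counts


# ---------------------------------------------------------------------------
# jaccard
# ---------------------------------------------------------------------------


def test_jaccard_basic_identities():
    assert jaccard({"a", "b"}, {"a", "b"}) == 1.0
    assert jaccard({"a"}, {"b"}) == 0.0
    assert jaccard(set(), set()) == 0.0


def test_jaccard_paper_scale_sets():
    """Sets of 155 and 54 genes sharing 14 members: J = 14/195 ≈ 0.072."""
    A = {f"a{i}" for i in range(141)} | {f"s{i}" for i in range(14)}
    B = {f"b{i}" for i in range(40)} | {f"s{i}" for i in range(14)}
    assert jaccard(A, B) == pytest.approx(14 / 195)
    assert round(jaccard(A, B), 3) == 0.072


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.sets(st.integers(0, 30), max_size=20),
    st.sets(st.integers(0, 30), max_size=20),
)
def test_jaccard_matches_brute_force(A, B):
    inter = sum(1 for x in A if x in B)
    union = len(A) + len(B) - inter
    expected = inter / union if union else 0.0
    assert jaccard(A, B) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# fisher overlap
# ---------------------------------------------------------------------------


def test_fisher_overlap_upregulated_sets():
    t = fisher_overlap(155, 54, 14, 19689)
    assert t.sample_odds_ratio == pytest.approx(14 * 19494 / (141 * 40), rel=1e-12)
    assert t.sample_odds_ratio == pytest.approx(48.39, abs=0.01)
    assert t.odds_ratio == pytest.approx(48.3, abs=0.5)
    assert t.pvalue < 1e-10
    assert t.jaccard == pytest.approx(14 / 195)


def test_fisher_overlap_downregulated_sets():
    t = fisher_overlap(34, 65, 11, 19689)
    assert t.sample_odds_ratio == pytest.approx(173.6, abs=0.5)
    assert t.pvalue < 1e-10


def test_fisher_overlap_zero_intersection():
    t = fisher_overlap(20, 30, 0, 1000)
    assert t.sample_odds_ratio == 0.0
    assert t.jaccard == 0.0


def test_fisher_overlap_validates_inputs():
    with pytest.raises(ValueError):
        fisher_overlap(5, 5, 6, 100)
    with pytest.raises(ValueError):
        fisher_overlap(60, 60, 0, 100)


def _hypergeom_two_sided_p(nA, nB, k, N):
    """Brute-force two-sided Fisher p: sum of hypergeometric probabilities
    not exceeding that of the observed table."""
    rv = stats.hypergeom(N, nA, nB)
    pk = rv.pmf(k)
    ks = np.arange(0, min(nA, nB) + 1)
    return float(rv.pmf(ks)[rv.pmf(ks) <= pk * (1 + 1e-9)].sum())


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.data())
def test_fisher_pvalue_matches_hypergeometric_enumeration(data):
    N = data.draw(st.integers(20, 200))
    nA = data.draw(st.integers(1, N // 2))
    nB = data.draw(st.integers(1, N // 2))
    k = data.draw(st.integers(max(0, nA + nB - N), min(nA, nB)))
    t = fisher_overlap(nA, nB, k, N)
    assert t.pvalue == pytest.approx(_hypergeom_two_sided_p(nA, nB, k, N), rel=1e-6)


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------


def test_resample_constraint_enforced():
    cfg = BootstrapConfig(min_unique=3)
    rng = np.random.default_rng(0)
    sizes = {"c": 6}
    for _ in range(2000):
        idx, _ = bootstrap_resample_indices(sizes, cfg, rng)
        assert len(np.unique(idx["c"])) >= 3


def test_resample_min_unique_one_never_rejects():
    cfg = BootstrapConfig(min_unique=1)
    rng = np.random.default_rng(1)
    total_rej = 0
    for _ in range(200):
        _, rej = bootstrap_resample_indices({"c": 6}, cfg, rng)
        total_rej += rej
    assert total_rej == 0


def test_resample_deterministic_under_seed():
    cfg = BootstrapConfig(min_unique=3)
    out = []
    for _ in range(2):
        rng = np.random.default_rng(99)
        idx, _ = bootstrap_resample_indices({"a": 6, "b": 6}, cfg, rng)
        out.append({k: v.tolist() for k, v in idx.items()})
    assert out[0] == out[1]


def test_resample_min_unique_too_large_errors():
    cfg = BootstrapConfig(min_unique=7)
    with pytest.raises(ValueError, match="min_unique"):
        bootstrap_resample_indices({"c": 6}, cfg, np.random.default_rng(0))


def test_bootstrap_deg_sets_deterministic(small_sim):
    _, cm, _ = small_sim
    cm_f = filter_low_counts(cm, 10)
    cfg = BootstrapConfig(n_boot=2, seed=5)
    b1 = bootstrap_deg_sets(cm_f, "TF1", cfg)
    b2 = bootstrap_deg_sets(cm_f, "TF1", cfg)
    assert [s.up for s in b1.sets] == [s.up for s in b2.sets]
    assert [s.down for s in b1.sets] == [s.down for s in b2.sets]


def test_bootstrap_null_simulation_no_targets():
    """With no targets at all, the main analysis calls nothing and bootstrap
    DEG sets are nearly empty (replicates with few distinct samples produce a
    handful of false calls; the median stays within ~1–2% of the universe)."""
    from paraloverlap.decontrast import call_degs, run_de

    cfg = SimConfig(n_genes=400, n_targets_tf1=0, n_targets_tf2=0,
                    tf_oe_log2fc=(0.0, 0.0), tf_ko_fraction_remaining=(1.0, 1.0),
                    seed=17)
    cm, _ = simulate_counts(cfg)
    cm_f = filter_low_counts(cm, 10)
    main = call_degs(run_de(cm_f, "TF1", min_total=0), "TF1")
    assert len(main.all) == 0
    boots = bootstrap_deg_sets(cm_f, "TF1", BootstrapConfig(n_boot=10, seed=3))
    sizes = [len(s.all) for s in boots.sets]
    assert np.median(sizes) <= 0.02 * main.universe_size


# ---------------------------------------------------------------------------
# pairwise jaccard
# ---------------------------------------------------------------------------


def _degset(up, down=frozenset()):
    return DEGSet("TF1", set(up), set(down), universe_size=1000)


def test_pairwise_identical_sets_all_one():
    sets = [_degset({"a", "b"})] * 4
    assert np.allclose(pairwise_jaccard(sets, "up"), 1.0)


def test_pairwise_matches_hand_computation():
    sets = [_degset({"a", "b"}), _degset({"b", "c"}), _degset({"d"})]
    j = pairwise_jaccard(sets, "up")
    # pairs (0,1), (0,2), (1,2)
    assert np.allclose(sorted(j), sorted([1 / 3, 0.0, 0.0]))


def test_cross_pairwise_covers_all_ordered_pairs():
    a = [_degset({"a"}), _degset({"b"})]
    b = [_degset({"a"}), _degset({"a", "b"}), _degset({"c"})]
    j = cross_pairwise_jaccard(a, b, "up")
    assert len(j) == 6
    expected = [jaccard(x.up, y.up) for x, y in itertools.product(a, b)]
    assert np.allclose(sorted(j), sorted(expected))


def test_pairwise_max_pairs_cap_is_seeded():
    rng = np.random.default_rng(0)
    sets = [_degset({f"g{i}" for i in rng.integers(0, 50, 10)}) for _ in range(30)]
    j1 = pairwise_jaccard(sets, "up", max_pairs=50, seed=7)
    j2 = pairwise_jaccard(sets, "up", max_pairs=50, seed=7)
    assert len(j1) == 50 and np.allclose(j1, j2)


# ---------------------------------------------------------------------------
# basic bootstrap CI
# ---------------------------------------------------------------------------


def test_basic_ci_constant_vector():
    assert basic_bootstrap_ci([0.4] * 10) == (0.4, 0.4)


def test_basic_ci_decile_hand_computation():
    values = np.arange(0.1, 1.05, 0.1)
    lo, hi = basic_bootstrap_ci(values, alpha=0.05, center=0.55, clip=None)
    qlo, qhi = np.quantile(values, [0.025, 0.975])
    assert lo == pytest.approx(2 * 0.55 - qhi)
    assert hi == pytest.approx(2 * 0.55 - qlo)


def test_basic_ci_symmetric_equals_percentile():
    """For values symmetric about their mean, reflection maps the interval
    onto the percentile interval."""
    values = np.concatenate([0.5 - np.linspace(0, 0.3, 50), 0.5 + np.linspace(0, 0.3, 50)])
    lo, hi = basic_bootstrap_ci(values, clip=None)
    qlo, qhi = np.quantile(values, [0.025, 0.975])
    assert lo == pytest.approx(qlo, abs=1e-9)
    assert hi == pytest.approx(qhi, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=50),
    st.floats(0.01, 0.2),
)
def test_basic_ci_matches_definition(values, alpha):
    lo, hi = basic_bootstrap_ci(values, alpha=alpha, clip=None)
    theta = np.mean(values)
    qlo, qhi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    assert lo == pytest.approx(2 * theta - qhi, abs=1e-12)
    assert hi == pytest.approx(2 * theta - qlo, abs=1e-12)
    assert lo <= hi


# ---------------------------------------------------------------------------
# z test / O:E ratio
# ---------------------------------------------------------------------------


def test_z_test_at_bootstrap_mean_is_null():
    vals = [0.4, 0.5, 0.6]
    z, p = z_test_overlap(0.5, vals)
    assert z == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_z_test_normal_arithmetic():
    rng = np.random.default_rng(0)
    vals = rng.normal(0.5, 0.1, 100000)
    z, p = z_test_overlap(0.072, vals)
    assert z == pytest.approx(4.28, abs=0.03)
    assert p == pytest.approx(2 * stats.norm.sf(z), rel=1e-9)
    assert p == pytest.approx(1.87e-5, rel=0.1)


def test_z_test_one_sided_halves_p():
    vals = [0.3, 0.5, 0.7, 0.6, 0.4]
    z2, p2 = z_test_overlap(0.1, vals, "two-sided")
    zg, pg = z_test_overlap(0.1, vals, "greater")
    assert zg == z2
    assert pg == pytest.approx(p2 / 2)


def test_oe_ratio_trivial_and_degenerate():
    assert oe_ratio(0.3, 0.3, 0.3) == 100.0
    assert np.isnan(oe_ratio(0.3, 0.0, 0.0))


# ---------------------------------------------------------------------------
# z-score correlation
# ---------------------------------------------------------------------------


def _fake_de(z, genes=None):
    genes = genes or [f"g{i}" for i in range(len(z))]
    return pd.DataFrame(
        {"wald_z": z, "tested": True, "log2fc": 0.0, "padj": 1.0}, index=genes
    )


def test_zscore_correlation_self_and_negation():
    rng = np.random.default_rng(5)
    z = rng.normal(size=200)
    de = _fake_de(z)
    r = zscore_correlation(de, de)
    assert r.pearson_r == pytest.approx(1.0)
    assert r.r_squared == pytest.approx(1.0)
    rneg = zscore_correlation(de, _fake_de(-z))
    assert rneg.pearson_r == pytest.approx(-1.0)


def test_zscore_correlation_independent_is_near_zero():
    rng = np.random.default_rng(6)
    hits = 0
    for rep in range(5):
        r = zscore_correlation(
            _fake_de(rng.normal(size=5000)), _fake_de(rng.normal(size=5000))
        )
        hits += abs(r.pearson_r) < 0.05
        assert r.ci[0] <= r.pearson_r <= r.ci[1]
    assert hits >= 4


def test_zscore_correlation_too_few_genes():
    with pytest.raises(ValueError, match="3"):
        zscore_correlation(_fake_de([1.0, 2.0]), _fake_de([1.0, 2.0]))


# ---------------------------------------------------------------------------
# off-target filter
# ---------------------------------------------------------------------------


def _candidates(rows):
    return pd.DataFrame(rows, columns=["gene_id", "guide_id", "cfd", "context"])


def test_offtarget_filter_thresholds_and_verdicts():
    deg1 = DEGSet("TF1", {"shared", "only1"}, set(), 1000)
    deg2 = DEGSet("TF2", {"shared"}, set(), 1000)
    cands = _candidates(
        [
            ("lowcfd", "g1", 0.05, "intron"),  # dropped: CFD below strict cutoff
            ("atcut", "g1", 0.1, "intron"),  # dropped: threshold is strict
            ("wrongctx", "g1", 0.2, "intergenic"),  # dropped: context
            ("shared", "g1", 0.2, "intron"),
            ("only1", "g1", 0.3, "exon"),
            ("quiet", "g1", 0.5, "exon"),
        ]
    )
    out = offtarget_filter(cands, deg1, deg2)
    assert set(out["gene_id"]) == {"shared", "only1", "quiet"}
    v = out.set_index("gene_id")["verdict"]
    assert v["shared"] == "shared_effect_not_offtarget"
    assert v["only1"] == "possible_guide_specific_offtarget"
    assert v["quiet"] == "no_expression_effect"


def test_offtarget_filter_unknown_context_errors():
    cands = _candidates([("g", "x", 0.5, "utr")])
    deg = DEGSet("TF1", set(), set(), 10)
    with pytest.raises(ValueError, match="context"):
        offtarget_filter(cands, deg, deg)
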