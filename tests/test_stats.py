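"""Size factors, gene statistic, empirical null, BH, NB fits, ranking."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from isletscreen import (
    ConfigError,
    DataValidationError,
    StatisticalError,
    analyze_screen,
    bh_adjust,
    build_empirical_null,
    control_size_factors,
    drop_silent_guides,
    fit_guide_nb,
    gene_log2fc,
    gene_log2fc_all,
    gene_pvalue,
    rank_genes,
)
from isletscreen.stats import NullDistribution

from conftest import make_library, make_table
from oracles import brute_bh, brute_empirical_p, brute_gene_log2fc


# ---------------------------------------------------------------------------
# control_size_factors


def test_size_factors_identity_for_identical_samples(tiny_library):
    ids = list(tiny_library.guide_ids)
    table = make_table({"control_1": [10] * 8, "hPi_1": [10] * 8}, ids)
    f = control_size_factors(table, tiny_library.control_ids)
    assert np.allclose(f, [1.0, 1.0])


def test_size_factors_hand_computed_doubling(tiny_library):
    """Sample B = 2 x sample A over controls -> factors (1/sqrt2, sqrt2)."""
    ids = ["NT_1", "NT_2", "NT_3"]
    table = make_table({"control_1": [10, 20, 30], "hPi_1": [20, 40, 60]}, ids)
    f = control_size_factors(table, pd.Index(ids))
    assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)], atol=1e-12)
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)


def test_size_factors_row_permutation_invariant(tiny_library):
    ids = ["NT_1", "NT_2", "NT_3", "IG_1"]
    cols = {"control_1": [5, 11, 30, 7], "hPi_1": [9, 40, 31, 12]}
    t1 = make_table(cols, ids)
    perm = [2, 0, 3, 1]
    t2 = make_table({k: [v[i] for i in perm] for k, v in cols.items()},
                    [ids[i] for i in perm])
    f1 = control_size_factors(t1, pd.Index(ids))
    f2 = control_size_factors(t2, pd.Index(ids))
    assert np.allclose(f1, f2)


def test_size_factors_zero_fallback_and_error(tiny_library, caplog):
    ids = ["NT_1", "NT_2", "NT_3"]
    table = make_table({"control_1": [0, 4, 0], "hPi_1": [2, 0, 2]}, ids)
    with caplog.at_level(logging.WARNING, logger="isletscreen.stats"):
        f = control_size_factors(table, pd.Index(ids))
    assert "falling back" in caplog.text
    assert np.allclose(np.exp(np.mean(np.log(f))), 1.0)
    table0 = make_table({"control_1": [0, 0, 0], "hPi_1": [2, 1, 2]}, ids)
    with pytest.raises(StatisticalError, match="zero total control"):
        control_size_factors(table0, pd.Index(ids))


# ---------------------------------------------------------------------------
# gene_log2fc


def _two_gene_table(tiny_library, gene_h, gene_c, nt_h, nt_c):
    """GENE1 gets the given pooled sums split over guides; NT likewise."""
    ids = list(tiny_library.guide_ids)
    cols = {
        "control_1": [gene_c // 2, gene_c - gene_c // 2, 0, 0,
                      nt_c // 3, nt_c // 3, nt_c - 2 * (nt_c // 3), 0],
        "hPi_1": [gene_h // 2, gene_h - gene_h // 2, 0, 0,
                  nt_h // 3, nt_h // 3, nt_h - 2 * (nt_h // 3), 0],
    }
    return make_table(cols, ids)


def test_gene_log2fc_null_case(tiny_library):
    table = _two_gene_table(tiny_library, gene_h=40, gene_c=80, nt_h=400, nt_c=800)
    assert gene_log2fc(table, tiny_library, "GENE1", pseudocount=0) == pytest.approx(0.0)


def test_gene_log2fc_enrichment_case(tiny_library):
    table = _two_gene_table(tiny_library, gene_h=160, gene_c=80, nt_h=400, nt_c=800)
    L = gene_log2fc(table, tiny_library, "GENE1", pseudocount=0)
    assert L == pytest.approx(np.log2((160 / 400) / (80 / 800)))  # == 2


def test_gene_log2fc_scale_invariance(tiny_library):
    t1 = _two_gene_table(tiny_library, 60, 45, 300, 500)
    doubled = make_table(
        {s: (2 * t1.counts[s]).tolist() for s in t1.sample_ids},
        list(t1.counts.index),
    )
    L1 = gene_log2fc(t1, tiny_library, "GENE1", pseudocount=0)
    L2 = gene_log2fc(doubled, tiny_library, "GENE1", pseudocount=0)
    assert L1 == pytest.approx(L2, abs=1e-12)


def test_gene_log2fc_matches_brute_force_random_tables(tiny_library):
    """Vector and scalar paths agree with literal-arithmetic sums to 1e-12."""
    rng = np.random.default_rng(0)
    ids = list(tiny_library.guide_ids)
    nt = list(tiny_library.nt_ids)
    for trial in range(50):
        n_samples = rng.integers(2, 5)
        cols = {}
        conditions = {}
        for i in range(n_samples):
            cond = "hPi" if i % 2 else "control"
            name = f"{cond}_{i}"
            cols[name] = rng.integers(0, 50, len(ids)).tolist()
            conditions[name] = cond
        table = make_table(cols, ids)
        counts_dict = {s: dict(zip(ids, cols[s])) for s in cols}
        for gene in ("GENE1", "GENE2"):
            guides = list(tiny_library.guides_for_gene(gene))
            expected = brute_gene_log2fc(counts_dict, conditions, guides, nt, 1.0)
            got = gene_log2fc(table, tiny_library, gene, pseudocount=1.0)
            assert got == pytest.approx(expected, abs=1e-12)
            vect = gene_log2fc_all(table, tiny_library)["log2fc"][gene]
            assert vect == pytest.approx(expected, abs=1e-12)


def test_gene_log2fc_median_method(tiny_library):
    table = _two_gene_table(tiny_library, 160, 80, 400, 800)
    Ls = gene_log2fc(table, tiny_library, "GENE1", pseudocount=1, method="median")
    Lsum = gene_log2fc(table, tiny_library, "GENE1", pseudocount=1, method="sum")
    assert np.isfinite(Ls) and Ls != Lsum
    with pytest.raises(ConfigError):
        gene_log2fc(table, tiny_library, "GENE1", method="mean")


# ---------------------------------------------------------------------------
# empirical null + p-values


def test_empirical_null_deterministic_and_boundary(null_screen):
    table, lib = null_screen.counts, null_screen.library
    a = build_empirical_null(table, lib, set_size=4, n_draws=200, seed=5)
    b = build_empirical_null(table, lib, set_size=4, n_draws=200, seed=5)
    assert np.array_equal(a.stats, b.stats)
    n_ctrl = len(lib.control_ids)
    with pytest.raises(StatisticalError, match="remainder"):
        build_empirical_null(table, lib, set_size=n_ctrl, n_draws=200, seed=0)
    with pytest.raises(ConfigError):
        build_empirical_null(table, lib, set_size=4, n_draws=10, seed=0)


def test_empirical_null_centered_on_null_screen(null_screen):
    null = build_empirical_null(
        null_screen.counts, null_screen.library, set_size=4, n_draws=1000, seed=1
    )
    assert abs(null.median) < 0.05


def test_nt_pseudo_genes_match_null_distribution(null_screen):
    """Disjoint NT 4-subsets scored as genes look like the sampled null."""
    table, lib = null_screen.counts, null_screen.library
    controls = list(lib.control_ids)
    hpi = table.counts[table.samples_for("hPi")].sum(axis=1)
    ctrl = table.counts[table.samples_for("control")].sum(axis=1)
    stats = []
    for i in range(0, len(controls) - 3, 4):
        subset = controls[i : i + 4]
        rest = [g for g in controls if g not in subset]
        g_h, g_c = hpi[subset].sum(), ctrl[subset].sum()
        r_h, r_c = hpi[rest].sum(), ctrl[rest].sum()
        stats.append(np.log2((g_h + 1) / (r_h + 1)) - np.log2((g_c + 1) / (r_c + 1)))
    null = build_empirical_null(table, lib, set_size=4, n_draws=1000, seed=2)
    _, p = sps.ks_2samp(stats, null.stats)
    assert p > 0.001


def test_gene_pvalue_counting_cases():
    null = NullDistribution(stats=np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                            set_size=4, n_draws=5, seed=0)
    assert gene_pvalue(0.0, null) == pytest.approx(1.0)  # at the center
    assert gene_pvalue(1.5, null) == pytest.approx((2 + 1) / 6)
    assert gene_pvalue(5.0, null) == pytest.approx(1 / 6)  # beyond all draws
    assert gene_pvalue(-5.0, null) == pytest.approx(1 / 6)


def test_gene_pvalue_matches_brute_force_and_vectorizes():
    rng = np.random.default_rng(7)
    stats = rng.normal(0.3, 1.2, size=501)
    null = NullDistribution(stats=stats, set_size=4, n_draws=501, seed=0)
    Ls = rng.normal(0, 2, size=40)
    vect = gene_pvalue(Ls, null)
    for L, p in zip(Ls, vect):
        assert p == pytest.approx(brute_empirical_p(L, list(stats)), abs=1e-12)
        assert p == pytest.approx(gene_pvalue(float(L), null))


def test_gene_pvalue_one_sided():
    null = NullDistribution(stats=np.array([-2.0, -1.0, 0.0, 1.0, 2.0]),
                            set_size=4, n_draws=5, seed=0)
    assert gene_pvalue(1.5, null, alternative="greater") == pytest.approx((1 + 1) / 6)
    assert gene_pvalue(1.5, null, alternative="less") == pytest.approx((4 + 1) / 6)


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_example_and_degenerate_cases():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2] * 3)
    assert np.allclose(bh_adjust([0.07]), [0.07])


def test_bh_matches_reference_implementations():
    rng = np.random.default_rng(11)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(1e-9, 1.0, size=m)
        q = bh_adjust(p)
        assert np.allclose(q, brute_bh(list(p)), atol=1e-12)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)


@given(
    st.lists(
        st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
        min_size=1,
        max_size=50,
    )
)
@settings(deadline=None, derandomize=True)
def test_bh_invariants(p):
    """q in (0,1]; order-preserving; never below the raw p / m inflation."""
    q = bh_adjust(p)
    assert np.all((q > 0) & (q <= 1))
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(q >= np.asarray(p) - 1e-12)


def test_bh_rejects_out_of_range():
    for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.5]):
        with pytest.raises(StatisticalError):
            bh_adjust(bad)


# ---------------------------------------------------------------------------
# per-guide NB model


def _replicate_table(tiny_library, ctrl_counts, hpi_counts):
    ids = list(tiny_library.guide_ids)
    cols = {}
    for i, v in enumerate(ctrl_counts):
        cols[f"control_{i}"] = [v] * len(ids)
    for i, v in enumerate(hpi_counts):
        cols[f"hPi_{i}"] = [v] * len(ids)
    return make_table(cols, ids)


def test_guide_nb_constant_counts(tiny_library):
    table = _replicate_table(tiny_library, [50, 50, 50], [50, 50, 50])
    f = pd.Series(1.0, index=table.sample_ids)
    fit = fit_guide_nb(table, f, "GENE1_sg1")
    assert fit.converged
    assert fit.beta_cond == pytest.approx(0.0, abs=1e-6)
    assert np.allclose(fit.fitted, 50.0, atol=1e-4)


def test_guide_nb_fourfold_condition_effect(tiny_library):
    """hPi counts exactly 4x control: condition effect = 2 on log2 scale."""
    table = _replicate_table(tiny_library, [30, 30, 30], [120, 120, 120])
    f = pd.Series(1.0, index=table.sample_ids)
    fit = fit_guide_nb(table, f, "GENE1_sg1")
    assert fit.converged
    assert fit.beta_cond == pytest.approx(2.0, abs=1e-5)
    assert fit.beta0 == pytest.approx(np.log(30), abs=1e-5)


def test_guide_nb_offset_invariance(tiny_library):
    table = _replicate_table(tiny_library, [40, 44, 36], [90, 110, 100])
    f1 = pd.Series(1.0, index=table.sample_ids)
    f3 = pd.Series(3.0, index=table.sample_ids)
    fit1 = fit_guide_nb(table, f1, "GENE2_sg1")
    fit3 = fit_guide_nb(table, f3, "GENE2_sg1")
    assert fit1.beta_cond == pytest.approx(fit3.beta_cond, abs=1e-6)
    assert fit3.beta0 == pytest.approx(fit1.beta0 - np.log(3), abs=1e-5)


def test_guide_nb_preconditions(tiny_library):
    table = make_table({"control_1": [1] * 8, "hPi_1": [1] * 8},
                       list(tiny_library.guide_ids))
    f = pd.Series(1.0, index=table.sample_ids)
    with pytest.raises(StatisticalError, match=">= 2 samples"):
        fit_guide_nb(table, f, "GENE1_sg1")
    table2 = _replicate_table(tiny_library, [5, 5], [9, 9])
    with pytest.raises(DataValidationError, match="not in count table"):
        fit_guide_nb(table2, pd.Series(1.0, index=table2.sample_ids), "nope")


def test_guide_nb_all_zero_counts_flagged_not_raised(tiny_library):
    table = _replicate_table(tiny_library, [0, 0], [0, 0])
    f = pd.Series(1.0, index=table.sample_ids)
    fit = fit_guide_nb(table, f, "GENE1_sg1")
    assert not fit.converged or np.all(np.isfinite(fit.fitted))


# ---------------------------------------------------------------------------
# ranking and the full pass


def test_rank_genes_order_filter_and_ties():
    results = pd.DataFrame(
        {"gene": ["A", "B", "C"], "log2fc": [2.0, 0.0, -1.0]}
    )
    ranked = rank_genes(results)
    assert ranked["gene"].tolist() == ["A", "B", "C"]
    assert ranked["rank"].tolist() == [1, 2, 3]

    promoted = rank_genes(results, expressed_genes=["B", "C"])
    assert promoted["gene"].tolist() == ["B", "C"]
    assert promoted["rank"].tolist() == [1, 2]

    tied = pd.DataFrame({"gene": ["ZZZ", "AAA", "MMM"], "log2fc": [1.0, 1.0, 1.0]})
    assert rank_genes(tied)["gene"].tolist() == ["AAA", "MMM", "ZZZ"]

    with pytest.raises(StatisticalError):
        rank_genes(results, expressed_genes=["NOPE"])


def test_drop_silent_guides_keeps_partial_genes(tiny_library):
    ids = list(tiny_library.guide_ids)
    cols = {"control_1": [5, 0, 3, 2, 9, 9, 9, 9], "hPi_1": [4, 0, 1, 3, 9, 9, 9, 9]}
    table = drop_silent_guides(make_table(cols, ids))
    assert "GENE1_sg2" not in table.counts.index
    per_gene = gene_log2fc_all(table, tiny_library)
    assert per_gene.loc["GENE1", "n_guides"] == 1
    assert per_gene.loc["GENE2", "n_guides"] == 2


def test_analyze_screen_full_pass(null_screen):
    ranked, null = analyze_screen(
        null_screen.counts, null_screen.library, n_draws=500, seed=3
    )
    assert set(ranked.columns) == {"gene", "n_guides", "log2fc", "p", "q", "rank"}
    assert sorted(ranked["rank"]) == list(range(1, len(ranked) + 1))
    assert ((ranked["p"] > 0) & (ranked["p"] <= 1)).all()
    assert ((ranked["q"] > 0) & (ranked["q"] <= 1)).all()
    # ranked descending
    assert ranked["log2fc"].is_monotonic_decreasing


def test_analyze_screen_expressed_filter_and_validation(null_screen):
    lib = null_screen.library
    keep = list(lib.genes[:50])
    ranked, _ = analyze_screen(
        null_screen.counts, lib, n_draws=200, seed=0, expressed_genes=keep
    )
    assert set(ranked["gene"]) <= set(keep)
    extra = null_screen.counts.counts.copy()
    extra.loc["ROGUE_GUIDE"] = 1
    from isletscreen import GuideCountTable

    rogue = GuideCountTable(extra, null_screen.counts.samples)
    with pytest.raises(DataValidationError, match="not in library"):
        analyze_screen(rogue, lib, n_draws=200)
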