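import numpy as np
import pandas as pd
import pytest
from scipy import stats

from edanet.diffexpr import build_design
from edanet.diffsplice import (
    aggregate_gene_p,
    exon_usage_stats,
    fit_exon_glm,
    run_differential_splicing,
    simes,
)
from edanet.io import ExonCountMatrix


@pytest.fixture(scope="module")
def design36(sample_table_36):
    return build_design(sample_table_36)


def _ec(counts, gene_of, order, samples):
    exon_ids = list(gene_of)
    return ExonCountMatrix(
        exon_ids, dict(gene_of), dict(order), samples, np.asarray(counts, dtype=np.int64)
    )


# ---------------------------------------------------------------- Simes


def test_simes_equal_pvalues_return_that_value():
    assert simes(np.full(7, 0.2)) == pytest.approx(0.2)


def test_simes_worked_example():
    # ordered (0.01, 0.04, 0.90): min(3*0.01/1, 3*0.04/2, 3*0.90/3) = 0.03
    assert simes(np.array([0.90, 0.01, 0.04])) == pytest.approx(0.03)


def test_simes_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(6)
    for _ in range(1000):
        m = rng.integers(1, 9)
        p = rng.uniform(size=m)
        q = np.sort(p)
        expected = min(1.0, min(m * q[j] / (j + 1) for j in range(m)))
        assert simes(p) == pytest.approx(expected, rel=1e-12)


def test_simes_never_below_min_p_times_one_and_capped():
    assert simes(np.array([0.9, 0.95])) <= 1.0
    assert simes(np.array([])) != simes(np.array([]))  # NaN for empty


# ---------------------------------------------------------------- usage stats


def test_constant_proportional_exons_have_zero_usage(sample_table_36, design36):
    # every exon identical across samples: no usage change at all
    counts = np.vstack(
        [np.full(36, 100), np.full(36, 200), np.full(36, 400)]
    )
    ec = _ec(
        counts,
        {"e1": "g", "e2": "g", "e3": "g"},
        {"e1": 1, "e2": 2, "e3": 3},
        list(sample_table_36.frame.index),
    )
    tab = exon_usage_stats(ec, design36, ("LL", "CC"), offsets=np.zeros(36))
    np.testing.assert_allclose(tab["usage"], 0.0, atol=1e-6)
    np.testing.assert_allclose(tab["p"], 1.0, atol=1e-6)


def test_two_exon_gene_usage_is_antisymmetric(sample_table_36, design36):
    rng = np.random.default_rng(13)
    counts = rng.poisson(300, size=(2, 36))
    gt = sample_table_36.frame["genotype"].to_numpy()
    counts[0, gt == "LL"] += 150  # shift usage toward exon 1 in LL
    ec = _ec(
        counts,
        {"e1": "g", "e2": "g"},
        {"e1": 1, "e2": 2},
        list(sample_table_36.frame.index),
    )
    tab = exon_usage_stats(ec, design36, ("LL", "CC"), offsets=np.zeros(36))
    u = tab.set_index("exon_id")
    assert u.loc["e1", "usage"] == pytest.approx(-u.loc["e2", "usage"], rel=1e-8)
    assert u.loc["e1", "se"] == pytest.approx(u.loc["e2", "se"], rel=1e-8)
    assert u.loc["e1", "p"] == pytest.approx(u.loc["e2", "p"], rel=1e-8)
    assert u.loc["e1", "usage"] > 0


def test_single_exon_gene_gets_reason_code(sample_table_36, design36):
    counts = np.vstack([np.full(36, 50), np.full(36, 60), np.full(36, 70)])
    ec = _ec(
        counts,
        {"a1": "gA", "b1": "gB", "b2": "gB"},
        {"a1": 1, "b1": 1, "b2": 2},
        list(sample_table_36.frame.index),
    )
    tab = exon_usage_stats(ec, design36, ("LL", "CC"), offsets=np.zeros(36))
    row = tab[tab["exon_id"] == "a1"].iloc[0]
    assert row["reason"] == "single_exon"
    assert np.isnan(row["p"])
    assert (tab[tab["gene_id"] == "gB"]["reason"] == "").all()


def test_gene_wide_expression_shift_cancels_in_usage(sample_table_36, design36):
    # whole gene up 4x in LL, composition unchanged -> usage ~ 0 for all exons
    gt = sample_table_36.frame["genotype"].to_numpy()
    base = np.vstack([np.full(36, 100), np.full(36, 300), np.full(36, 600)])
    counts = base.copy()
    counts[:, gt == "LL"] *= 4
    ec = _ec(
        counts,
        {"e1": "g", "e2": "g", "e3": "g"},
        {"e1": 1, "e2": 2, "e3": 3},
        list(sample_table_36.frame.index),
    )
    tab = exon_usage_stats(ec, design36, ("LL", "CC"), offsets=np.zeros(36))
    np.testing.assert_allclose(tab["usage"], 0.0, atol=1e-6)


# ---------------------------------------------------------------- aggregation


def test_gene_level_statistic_matches_closed_form():
    tab = pd.DataFrame(
        {
            "exon_id": ["e1", "e2", "e3"],
            "gene_id": ["g", "g", "g"],
            "t": [1.0, -2.0, 0.5],
            "p": [0.3, 0.05, 0.6],
        }
    )
    tab.attrs["residual_df"] = 30
    z = stats.norm.ppf(stats.t.cdf(np.array([1.0, -2.0, 0.5]), 30))
    s = (2 / 3) * np.sum(z**2)
    expected = stats.chi2.sf(s, 2)
    got = aggregate_gene_p(tab, "gene_level")["g"]
    assert got == pytest.approx(expected, rel=1e-12)


def test_gene_level_null_is_calibrated_under_its_own_law():
    # z ~ N(0,1) exons: S = ((m-1)/m) sum z^2 with the leave-one-out
    # correlation structure has exactly the chi2(m-1) law; check the
    # implementation is uniform-ish on raw normal scores (t with huge df)
    rng = np.random.default_rng(17)
    m = 4
    ps = []
    for _ in range(2000):
        raw = rng.normal(size=m)
        # impose the leave-one-out structure: t_e = z_e - mean(others)
        t = raw - (raw.sum() - raw) / (m - 1)
        t /= np.sqrt(1 + 1 / (m - 1))  # unit variance
        tab = pd.DataFrame(
            {"exon_id": range(m), "gene_id": ["g"] * m, "t": t, "p": np.nan}
        )
        tab.attrs["residual_df"] = 1e9
        ps.append(aggregate_gene_p(tab, "gene_level")["g"])
    ps = np.array(ps)
    # KS against uniform: generous 1% level
    d, pval = stats.kstest(ps, "uniform")
    assert pval > 0.01


def test_aggregate_rejects_unknown_method():
    tab = pd.DataFrame({"exon_id": [], "gene_id": [], "t": [], "p": []})
    with pytest.raises(ValueError):
        aggregate_gene_p(tab, "fisher")


def test_fewer_than_two_testable_exons_gives_nan():
    tab = pd.DataFrame(
        {
            "exon_id": ["e1", "e2"],
            "gene_id": ["g", "g"],
            "t": [1.0, np.nan],
            "p": [0.3, np.nan],
        }
    )
    tab.attrs["residual_df"] = 10
    assert np.isnan(aggregate_gene_p(tab, "simes")["g"])
    assert np.isnan(aggregate_gene_p(tab, "gene_level")["g"])


# ---------------------------------------------------------------- end to end


@pytest.fixture(scope="module")
def small_ds_run(small_dataset):
    cm, ec, samples, ann, truth = small_dataset
    design = build_design(samples)
    fit = fit_exon_glm(ec, design)
    res = run_differential_splicing(ec, design, ("LL", "CC"), fit=fit)
    return ec, truth, res, design, fit


def test_union_rule_contains_each_route(small_ds_run):
    _, _, res, *_ = small_ds_run
    gt = res.gene_table
    assert (gt["dsg"] >= gt["dsg_gene_level"]).all()
    assert (gt["dsg"] >= gt["dsg_simes"]).all()
    assert gt["dsg"].equals(gt["dsg_gene_level"] | gt["dsg_simes"])


def test_planted_target_exon_is_typically_the_top_exon(small_ds_run):
    ec, truth, res, *_ = small_ds_run
    tab = res.exon_table
    hits = 0
    total = 0
    for g in truth.dsg_ids:
        grp = tab[(tab["gene_id"] == g) & np.isfinite(tab["p"])]
        if len(grp) < 2:
            continue
        total += 1
        if grp.loc[grp["p"].idxmin(), "exon_id"] == truth.dsg_target_exon[g]:
            hits += 1
    assert total > 0
    assert hits / total >= 0.5


def test_reusing_the_exon_fit_reproduces_results(small_ds_run):
    ec, truth, res, design, fit = small_ds_run
    res2 = run_differential_splicing(ec, design, ("LL", "CC"), fit=fit)
    pd.testing.assert_frame_equal(res.gene_table, res2.gene_table)


def test_cl_vs_cc_is_quiet_under_the_recessive_model(small_ds_run):
    ec, truth, res, design, fit = small_ds_run
    quiet = run_differential_splicing(ec, design, ("CL", "CC"), fit=fit)
    assert len(quiet.dsgs()) <= max(2, len(res.dsgs()) // 5)
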