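import warnings

import numpy as np
import pandas as pd
import pytest

from edanet.network import (
    NetworkConfig,
    adjacency,
    atomize_gene,
    bicor_matrix,
    build_network,
    connectivity,
    detect_modules,
    extract_subnetwork,
    kme,
    pick_soft_threshold,
    tom,
)


# ---------------------------------------------------------------- bicor


def test_bicor_perfect_linear_relations():
    rng = np.random.default_rng(1)
    x = rng.normal(size=24)
    expr = np.vstack([x, 2 * x + 3, -x + 1])
    c = bicor_matrix(expr)
    assert c[0, 1] == pytest.approx(1.0, abs=1e-10)
    assert c[0, 2] == pytest.approx(-1.0, abs=1e-10)
    np.testing.assert_allclose(np.diag(c), 1.0)


def test_bicor_close_to_pearson_on_clean_gaussian_data():
    rng = np.random.default_rng(2)
    expr = rng.normal(size=(15, 40))
    c = bicor_matrix(expr)
    p = np.corrcoef(expr)
    assert np.max(np.abs(c - p)) < 0.25
    assert np.mean(np.abs(c - p)) < 0.06


def _bicor_oracle_pair(x, y):
    """Literal biweight midcorrelation of two vectors, no outlier capping."""

    def transform(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        t = (v - med) * w
        return t / np.sqrt(np.sum(t**2))

    return float(np.dot(transform(x), transform(y)))


def test_bicor_matches_literal_oracle_without_capping():
    rng = np.random.default_rng(3)
    expr = rng.normal(size=(6, 30))
    expr[0, 0] += 8.0  # a genuine outlier the weights must downweight
    c = bicor_matrix(expr, max_p_outliers=0.5)  # 0.5 disables side capping
    for i in range(6):
        for j in range(6):
            if i != j:
                assert c[i, j] == pytest.approx(
                    _bicor_oracle_pair(expr[i], expr[j]), abs=1e-12
                )


def test_bicor_zero_mad_row_warns_and_stays_symmetric():
    rng = np.random.default_rng(4)
    expr = rng.normal(size=(3, 20))
    expr[1] = 0.0
    expr[1, :5] = 1.0  # majority-tied: zero MAD but not constant
    with pytest.warns(UserWarning, match="zero MAD"):
        c = bicor_matrix(expr)
    assert np.isfinite(c).all()
    np.testing.assert_allclose(c, c.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(c), 1.0)


def test_bicor_requires_four_samples():
    with pytest.raises(ValueError, match="4 samples"):
        bicor_matrix(np.ones((3, 3)))


# ---------------------------------------------------------------- adjacency / TOM


def test_signed_adjacency_anchor_values():
    cor = np.array([[1.0, 1.0, -1.0, 0.0]] * 4)
    a = adjacency(cor, beta=14)
    assert a[0, 1] == pytest.approx(1.0)
    assert a[0, 2] == pytest.approx(0.0)
    assert a[0, 3] == pytest.approx(0.5**14)
    assert a[0, 0] == 0.0  # diagonal zeroed


def test_connectivity_small_example_and_row_sum_oracle():
    a = np.array([[0.0, 0.5, 0.25], [0.5, 0.0, 1.0], [0.25, 1.0, 0.0]])
    np.testing.assert_allclose(connectivity(a), [0.75, 1.5, 1.25])
    rng = np.random.default_rng(5)
    m = rng.uniform(size=(8, 8))
    m = (m + m.T) / 2
    k = connectivity(m)
    mm = m.copy()
    np.fill_diagonal(mm, 0.0)
    np.testing.assert_allclose(k, mm.sum(axis=1))


def test_tom_two_nodes():
    # no third parties: TOM = a / (a + 1 - a) = a
    a = np.array([[0.0, 0.3], [0.3, 0.0]])
    t = tom(a)
    assert t[0, 1] == pytest.approx(0.3)
    np.testing.assert_allclose(np.diag(t), 1.0)


def test_tom_complete_equal_weight_graph_closed_form():
    n, w = 5, 0.4
    a = np.full((n, n), w)
    np.fill_diagonal(a, 0.0)
    t = tom(a)
    # shared = (n-2) w^2, k = (n-1) w
    expected = ((n - 2) * w**2 + w) / ((n - 1) * w + 1 - w)
    off = t[~np.eye(n, dtype=bool)]
    np.testing.assert_allclose(off, expected, rtol=1e-12)


def test_tom_matches_triple_loop_oracle():
    rng = np.random.default_rng(6)
    a = rng.uniform(0, 1, size=(6, 6))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    t = tom(a)
    k = a.sum(axis=1)
    for i in range(6):
        for j in range(6):
            if i == j:
                assert t[i, j] == 1.0
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(6) if u not in (i, j))
            expected = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
            assert t[i, j] == pytest.approx(expected, rel=1e-12)


def test_tom_rejects_asymmetric_input():
    a = np.zeros((3, 3))
    a[0, 1] = 0.5
    with pytest.raises(ValueError, match="symmetric"):
        tom(a)


# ---------------------------------------------------------------- soft threshold


def _modular_expression(n_modules=3, per_module=40, n_noise=20, n_samples=30, seed=7):
    rng = np.random.default_rng(seed)
    drivers = rng.normal(size=(n_modules, n_samples))
    rows = []
    for m in range(n_modules):
        load = rng.uniform(0.6, 0.9, size=per_module)
        noise = rng.normal(scale=0.4, size=(per_module, n_samples))
        rows.append(load[:, None] * drivers[m][None, :] + noise)
    rows.append(rng.normal(size=(n_noise, n_samples)))
    expr = np.vstack(rows)
    genes = [f"g{i:03d}" for i in range(expr.shape[0])]
    return expr, genes, n_modules, per_module


def test_pick_soft_threshold_returns_smallest_passing_candidate():
    expr, *_ = _modular_expression()
    # first pass just to learn the diagnostic curve, then set the cut at a
    # value some (but not all) candidates reach and check the selection rule
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, table = pick_soft_threshold(expr, r2_cut=2.0)  # unreachable: table only
    cut = float(np.median(table["signed_r2"]))
    beta, table2 = pick_soft_threshold(expr, r2_cut=cut)
    passing = table2[table2["signed_r2"] >= cut]
    assert len(passing) and beta == int(passing["beta"].iloc[0])
    assert not table2["fallback"].any()


def test_pick_soft_threshold_needs_thirty_genes():
    rng = np.random.default_rng(8)
    with pytest.raises(ValueError, match="30 genes"):
        pick_soft_threshold(rng.normal(size=(10, 20)))


def test_pick_soft_threshold_falls_back_on_structureless_data():
    rng = np.random.default_rng(9)
    expr = rng.normal(size=(60, 12))
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        beta, table = pick_soft_threshold(expr, r2_cut=0.999)
    assert table["fallback"].all()
    assert any("argmax" in str(w.message) for w in rec)
    assert beta in set(table["beta"])


# ---------------------------------------------------------------- modules


@pytest.fixture(scope="module")
def block_network():
    expr, genes, n_mod, per_mod = _modular_expression()
    cfg = NetworkConfig(beta=14, cut_height=0.97, min_module_size=10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_network(pd.DataFrame(expr, index=genes), cfg)
    return net, expr, genes, n_mod, per_mod


def test_detect_modules_recovers_planted_blocks(block_network):
    net, expr, genes, n_mod, per_mod = block_network
    found = {m for m in net.labels.values() if m != "M0"}
    assert len(found) == n_mod
    # each planted block maps to exactly one found module
    for m in range(n_mod):
        block = genes[m * per_mod : (m + 1) * per_mod]
        lbls = pd.Series([net.labels[g] for g in block])
        top = lbls.value_counts()
        assert top.iloc[0] / per_mod >= 0.9
        assert top.index[0] != "M0"


def test_module_labels_are_ordered_by_size(block_network):
    net, *_ = block_network
    sizes = net.module_sizes().drop("M0", errors="ignore")
    nums = sorted(sizes.index, key=lambda m: int(m[1:]))
    vals = [sizes[m] for m in nums]
    assert vals == sorted(vals, reverse=True)


def test_detect_modules_is_invariant_to_gene_order():
    expr, genes, *_ = _modular_expression(seed=11)
    cfg_kwargs = dict(cut_height=0.97, min_size=10, merge_cor=0.75)
    from edanet.network import _correlate

    cfg = NetworkConfig(beta=14)
    a = adjacency(_correlate(expr, cfg), 14)
    labels1, _ = detect_modules(tom(a), expr, genes, **cfg_kwargs)

    rng = np.random.default_rng(0)
    perm = rng.permutation(len(genes))
    expr2 = expr[perm]
    genes2 = [genes[i] for i in perm]
    a2 = adjacency(_correlate(expr2, cfg), 14)
    labels2, _ = detect_modules(tom(a2), expr2, genes2, **cfg_kwargs)
    # same partition of gene ids (labels themselves must match because the
    # relabelling rule is order-free)
    assert labels1 == labels2


def test_small_clusters_go_to_m0(block_network):
    net, expr, genes, n_mod, per_mod = block_network
    noise = genes[n_mod * per_mod :]
    m0_frac = np.mean([net.labels[g] == "M0" for g in noise])
    assert m0_frac >= 0.8


def test_highly_correlated_modules_are_merged():
    rng = np.random.default_rng(12)
    driver = rng.normal(size=25)
    a = driver[None, :] + rng.normal(scale=0.2, size=(30, 25))
    b = driver[None, :] + rng.normal(scale=0.2, size=(30, 25))
    expr = np.vstack([a, b])
    genes = [f"g{i}" for i in range(60)]
    adj = adjacency(np.corrcoef(expr), 6)
    labels, eig = detect_modules(tom(adj), expr, genes, min_size=10, merge_cor=0.75)
    mods = {m for m in labels.values() if m != "M0"}
    assert len(mods) == 1


# ---------------------------------------------------------------- kME / atomize


def test_kme_of_eigengene_with_itself_is_one(block_network):
    net, *_ = block_network
    e = net.eigengenes["M1"].to_numpy()
    tab = kme(e[None, :], net.eigengenes, ["self"], correlation="pearson")
    assert tab.loc["self", "M1"] == pytest.approx(1.0, abs=1e-10)


def test_kme_shape_and_sample_mismatch(block_network):
    net, *_ = block_network
    with pytest.raises(ValueError, match="samples"):
        kme(np.ones((1, 5)), net.eigengenes, ["x"])


def test_atomize_places_module_tracking_exon_and_noise_exon(block_network):
    net, expr, genes, *_ = block_network
    rng = np.random.default_rng(13)
    e1 = net.eigengenes["M2"].to_numpy() + rng.normal(scale=0.05, size=net.eigengenes.shape[0])
    e2 = rng.normal(size=net.eigengenes.shape[0])
    profiles = pd.DataFrame([e1, e2], index=["gX:e1", "gX:e2"])
    tab = atomize_gene("gX", profiles, net)
    assert tab.loc["gX:e1", "assigned"] == "M2"
    assert tab.loc["gX:e2", "assigned"] == "M0"
    assert tab.loc["gX:e1", "best_kme"] >= 0.5


def test_atomize_rejects_empty_profiles(block_network):
    net, *_ = block_network
    with pytest.raises(ValueError, match="no exon"):
        atomize_gene("gX", pd.DataFrame(np.empty((0, 5))), net)


# ---------------------------------------------------------------- subnetworks


def test_extract_subnetwork_gene_mode_picks_strongest_neighbours(block_network):
    net, *_ = block_network
    focal = net.module_members("M1")[0]
    edges = extract_subnetwork(net, focal, n=5, mode="gene")
    nodes = set(edges["source"]) | set(edges["target"])
    assert focal in nodes and len(nodes) == 6
    gi = {g: i for i, g in enumerate(net.gene_ids)}
    row = net.adjacency_matrix[gi[focal]].copy()
    row[gi[focal]] = -np.inf
    top5 = {net.gene_ids[i] for i in np.argsort(row)[::-1][:5]}
    assert nodes - {focal} == top5
    assert len(edges) == 6 * 5 // 2


def test_extract_subnetwork_module_mode_returns_hubs(block_network):
    net, *_ = block_network
    edges = extract_subnetwork(net, "M1", n=4)
    nodes = sorted(set(edges["source"]) | set(edges["target"]))
    members = net.module_members("M1")
    hubs = sorted(sorted(members, key=lambda g: (-net.k_total[g], g))[:4])
    assert nodes == hubs


def test_extract_subnetwork_warns_on_small_module(block_network):
    net, *_ = block_network
    size = len(net.module_members("M1"))
    with pytest.warns(UserWarning, match="only"):
        extract_subnetwork(net, "M1", n=size + 5)


def test_extract_subnetwork_unknown_gene_raises(block_network):
    net, *_ = block_network
    with pytest.raises(KeyError):
        extract_subnetwork(net, "no_such_gene", mode="gene")


# ---------------------------------------------------------------- build guards


def test_build_network_rejects_oversized_input():
    frame = pd.DataFrame(np.zeros((6001, 4)))
    with pytest.raises(ValueError, match="6000"):
        build_network(frame)


def test_build_network_excludes_constant_genes():
    expr, genes, *_ = _modular_expression(seed=14)
    expr[0] = 3.14  # constant gene
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        net = build_network(pd.DataFrame(expr, index=genes), NetworkConfig(beta=6))
    assert genes[0] not in net.gene_ids
    assert any("constant" in str(w.message) for w in rec)


def test_network_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(max_p_outliers=0.7).validate()
    with pytest.raises(ValueError):
        NetworkConfig(beta=0).validate()
    with pytest.raises(ValueError):
        NetworkConfig(correlation="kendall").validate()
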