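import numpy as np
import pytest

from n2vhc.graph import write_edge_list
from n2vhc.integrate import bh_fdr
from n2vhc.simulate import (LFRParams, PlantedDiseaseConfig,
                            generate_lfr_like, generate_planted_disease_data)


@pytest.fixture(scope="module")
def lfr100():
    return generate_lfr_like(LFRParams(n=100, k=10, maxk=30, muw=0.5, seed=1))


def test_lfr_node_and_degree_contract(lfr100):
    net, labels = lfr100
    assert net.n_nodes == 100
    degrees = [net.degree(x) for x in net.nodes()]
    assert abs(np.mean(degrees) - 10) / 10 < 0.15
    assert max(degrees) <= 30
    # labels form a true partition covering every node
    assert set(labels) == set(net.nodes())
    assert min(labels.values()) == 1


def test_lfr_regime_matches_small_benchmark(lfr100):
    """LFR(100, 10, 30) sits in the published small-benchmark regime:
    a handful of communities (~7) at muw = 0.5."""
    _, labels = lfr100
    n_comm = len(set(labels.values()))
    assert 4 <= n_comm <= 12


def test_lfr_weight_mixing_tracks_muw():
    for muw in (0.0, 0.5):
        net, labels = generate_lfr_like(
            LFRParams(n=120, k=8, maxk=25, muw=muw, mut=0.5, seed=3))
        ext = sum(w for u, v, w in net.edges() if labels[u] != labels[v])
        tot = sum(w for *_, w in net.edges())
        if muw == 0.0:
            assert ext / tot < 1e-9
        else:
            assert ext / tot == pytest.approx(muw, abs=0.08)


def test_lfr_connected_and_deterministic(tmp_path):
    import networkx as nx
    p = LFRParams(n=80, k=6, maxk=20, muw=0.4, seed=9)
    net1, lab1 = generate_lfr_like(p)
    net2, lab2 = generate_lfr_like(p)
    assert nx.is_connected(net1.g)
    assert lab1 == lab2
    f1, f2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_edge_list(net1, f1)
    write_edge_list(net2, f2)
    assert f1.read_text() == f2.read_text()  # bit-identical under one seed


def test_lfr_directed_variant():
    net, labels = generate_lfr_like(
        LFRParams(n=80, k=6, maxk=20, muw=0.4, seed=9, directed=True))
    assert net.directed
    assert net.n_nodes == 80
    assert set(labels) == set(net.nodes())


def test_lfr_invalid_params():
    with pytest.raises(ValueError):
        LFRParams(n=10, k=20, maxk=30)
    with pytest.raises(ValueError):
        LFRParams(n=100, k=5, maxk=10, muw=1.5)


def test_lfr_community_sizes_powerlaw_sanity():
    """Community sizes at N=1000 skew small, as a t2=1 power law should."""
    _, labels = generate_lfr_like(
        LFRParams(n=1000, k=20, maxk=100, muw=0.5, seed=2))
    sizes = np.array(sorted(
        np.unique(list(labels.values()), return_counts=True)[1]))
    assert np.median(sizes) < np.mean(sizes)  # right-skewed


# -- planted disease triplets -----------------------------------------

def test_planted_disease_bookkeeping(tmp_path):
    cfg = PlantedDiseaseConfig(module_sizes=(20, 20, 30), n_disease_modules=2,
                               egenes_per_module=5, seed=4,
                               low_expression_fraction=0.2)
    data = generate_planted_disease_data(cfg)
    assert len(data.egenes) == 10
    assert set(data.disease_modules) == {1, 2}
    assert data.interactome.n_nodes == 70
    # egenes live inside disease modules
    planted = set().union(*data.disease_modules.values())
    assert data.egenes <= planted
    # proxy map is chain-free: every image is a fixed point
    assert all(data.proxy_map[v] == v for v in set(data.proxy_map.values()))
    # disease genes are never marked low-expressed
    assert all(data.expression[g] > 0 for g in planted)
    paths = data.write(tmp_path)
    assert all(p.exists() for p in paths.values())


def test_noise_eqtl_controlled_by_bh():
    """Uniform-null eQTL records rarely survive the BH filter."""
    bad_runs = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=1000)
        n_sig = int((bh_fdr(p) <= 0.05).sum())
        if n_sig > 5:
            bad_runs += 1
    assert bad_runs / 40 < 0.05


def test_planted_egenes_survive_integration():
    from n2vhc.integrate import (build_integrated_network,
                                 filter_significant_eqtl, replace_proxies)
    cfg = PlantedDiseaseConfig(seed=8)
    data = generate_planted_disease_data(cfg)
    rec = replace_proxies(data.eqtl, data.proxy_map)
    rec, _ = filter_significant_eqtl(rec, 0.05)
    inet = build_integrated_network(data.interactome, rec)
    assert data.egenes <= inet.egenes
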