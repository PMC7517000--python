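"""Growth-engine unit and property tests."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpanet import generator as gen
from fpanet.generator import (
    CandidatePool,
    GrowthConfig,
    attach_node,
    build_pool,
    generate,
    init_state,
    pool_parent_fraction,
    pool_size,
    rank_nodes,
    resolve_endpoint,
    sample_candidate,
    state_from_parents,
)


# ---------------------------------------------------------------------------
# seed graph and config validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m", [1, 3])
def test_init_state_is_star(m):
    cfg = GrowthConfig(n=100, m=m)
    state = init_state(cfg)
    assert state.num_nodes == m + 1
    assert state.num_edges == m
    assert state.degree[0] == m                   # centre
    assert all(state.degree[v] == 1 for v in range(1, m + 1))
    assert sum(state.degree) == 2 * m             # handshake
    assert state.parent[0] == -1 and state.depth[0] == 0
    assert all(state.parent[v] == 0 and state.depth[v] == 1
               for v in range(1, m + 1))


@pytest.mark.parametrize("kwargs", [
    dict(n=10, m=0),
    dict(n=10, f=0.0),
    dict(n=10, f=1.5),
    dict(n=2, m=1),            # n must exceed m0 = 2
    dict(n=10, m0=1),
])
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        GrowthConfig(**kwargs)


# ---------------------------------------------------------------------------
# pool construction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("existing,f,expected", [
    (10, 0.3, 3),
    (10, 0.25, 3),     # ceil(2.5)
    (1, 0.1, 1),       # floor of one candidate
    (10, 1.0, 10),
    (7, 0.999999, 7),
])
def test_pool_size(existing, f, expected):
    assert pool_size(existing, f) == expected


def test_pool_size_rejects_bad_fraction():
    with pytest.raises(ValueError):
        pool_size(10, 0.0)
    with pytest.raises(ValueError):
        pool_size(10, 1.0001)


def test_rank_nodes_degree_then_depth(rng):
    # degrees [5,3,3,1,...], depths [0,1,2,...]: the degree-5 root first,
    # then the depth-1 degree-3 node before the depth-2 degree-3 node
    state = state_from_parents([-1, 0, 1, 1, 2, 2, 0, 0, 0, 0])
    assert state.degree[:3] == [5, 3, 3]
    assert state.depth[:3] == [0, 1, 2]
    order = rank_nodes(state, rng)
    assert list(order[:3]) == [0, 1, 2]


def test_rank_nodes_ties_are_random_but_reproducible():
    # star: all leaves tie exactly (same degree, same depth)
    state = init_state(GrowthConfig(n=100, m=5))
    orders = {tuple(rank_nodes(state, np.random.default_rng(s)))
              for s in range(20)}
    assert len(orders) > 1                        # ties really permuted
    assert all(o[0] == 0 for o in orders)         # hub always first
    a = rank_nodes(state, np.random.default_rng(3))
    b = rank_nodes(state, np.random.default_rng(3))
    assert np.array_equal(a, b)                   # determinism contract


def test_sample_candidate_probabilities(rng):
    pool = CandidatePool(members=np.array([7, 8, 9]),
                         degrees=np.array([4, 2, 2]), total_degree=8)
    draws = np.array([sample_candidate(pool, rng) for _ in range(100_000)])
    freq = np.array([(draws == v).mean() for v in (7, 8, 9)])
    expect = np.array([0.5, 0.25, 0.25])
    sigma = np.sqrt(expect * (1 - expect) / draws.size)
    assert np.all(np.abs(freq - expect) < 3 * sigma)


def test_sample_candidate_empty_pool_fails(rng):
    pool = CandidatePool(members=np.array([], dtype=int),
                         degrees=np.array([], dtype=int), total_degree=0)
    with pytest.raises(RuntimeError):
        sample_candidate(pool, rng)


# ---------------------------------------------------------------------------
# redirection rule
# ---------------------------------------------------------------------------

def test_resolve_endpoint_branches():
    # path 0-1-2: degrees [1,2,1]
    state = state_from_parents([-1, 0, 1])
    assert resolve_endpoint(state, 2) == 2    # k=1 <= parent's 2: keep
    assert resolve_endpoint(state, 1) == 0    # k=2 > parent's 1: redirect
    assert resolve_endpoint(state, 0) == 0    # root always accepts


def test_resolve_endpoint_equal_degrees_keep_candidate():
    # 0-1, 0-2, 1-3: node 1 has k=2 == k of its parent 0
    state = state_from_parents([-1, 0, 0, 1])
    assert state.degree[1] == state.degree[0] == 2
    assert resolve_endpoint(state, 1) == 1


def test_attach_collapses_colliding_redirections(rng):
    # degrees [1,3,1,1]: pool of size 2 is {node1 (deg 3), node0 (root)}.
    # node1 redirects to 0 (3 > 1) and node0 resolves to itself, so both
    # m=2 draws land on node 0: the new node gets ONE edge, parent 0.
    state = state_from_parents([-1, 0, 1, 1])
    cfg = GrowthConfig(n=10, m=2, f=0.5)
    attach_node(state, cfg, rng)
    v = state.num_nodes - 1
    assert state.degree[v] == 1
    assert state.parent[v] == 0
    assert state.depth[v] == 1


# ---------------------------------------------------------------------------
# full growth invariants
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("f", [0.1, 0.5, 1.0])
def test_generate_m1_is_tree(f):
    state = generate(GrowthConfig(n=100, m=1, f=f, seed=42))
    assert state.num_nodes == 100
    assert state.num_edges == 99
    g = state.to_networkx()
    assert nx.is_connected(g)
    assert nx.is_tree(g)


def test_generate_determinism():
    cfg = GrowthConfig(n=500, m=2, f=0.4, seed=11)
    a = generate(cfg)
    b = generate(cfg)
    assert a.edges == b.edges
    assert a.parent == b.parent
    c = generate(GrowthConfig(n=500, m=2, f=0.4, seed=12))
    assert c.edges != a.edges


@given(
    n=st.integers(6, 60),
    m=st.integers(1, 3),
    f=st.floats(0.05, 1.0),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=40)
def test_growth_invariants(n, m, f, seed):
    state = generate(GrowthConfig(n=n, m=m, f=f, seed=seed))
    assert state.num_nodes == n
    # handshake identity
    assert sum(state.degree) == 2 * state.num_edges
    # parent consistency: parents arrive earlier, depths chain by one
    for v in range(1, n):
        p = state.parent[v]
        assert 0 <= p < v
        assert state.depth[v] == state.depth[p] + 1
    assert state.parent[0] == -1 and state.depth[0] == 0
    # simple graph: no duplicate edges, no self-loops
    edges = {tuple(sorted(e)) for e in state.edges}
    assert len(edges) == state.num_edges
    assert all(u != v for u, v in edges)
    if m == 1:
        assert state.num_edges == n - 1
        assert nx.is_tree(state.to_networkx())


def test_internal_degree_index_matches_degrees():
    state = generate(GrowthConfig(n=300, m=2, f=0.3, seed=9))
    deg = state.degrees_array()
    order = np.asarray(state._order)
    assert sorted(order.tolist()) == list(range(300))
    assert np.all(np.diff(deg[order]) <= 0)       # descending order kept
    for d, start in state._start.items():
        size = state._csize[d]
        assert np.all(deg[order[start:start + size]] == d)


def test_fast_sampler_matches_literal_pool_distribution():
    """The O(1) rejection sampler must reproduce the literal pool law.

    The marginal attachment probability has a closed form: with S the
    (fixed) total pool degree, certain members have k/S and each member
    of the randomly tied boundary group has (s/g) * k/S.  The expected
    values here are recomputed from scratch by sorting degrees/depths,
    independently of the generator's incremental index.
    """
    f = 0.37
    state = generate(GrowthConfig(n=40, m=1, f=f, seed=5))
    j = state.num_nodes
    deg = np.array(state.degree)
    dep = np.array(state.depth)

    # --- independent derivation of the marginal --------------------
    n_pool = int(np.ceil(f * j))
    by_rank = sorted(range(j), key=lambda v: (-deg[v], dep[v]))
    dstar = deg[by_rank[n_pool - 1]]
    certain = [v for v in range(j) if deg[v] > dstar]
    t = n_pool - len(certain)
    boundary = sorted((v for v in range(j) if deg[v] == dstar),
                      key=lambda v: dep[v])
    probs = np.zeros(j)
    depths = sorted({dep[v] for v in boundary})
    taken = 0
    S = float(sum(deg[v] for v in certain) + t * dstar)
    for v in certain:
        probs[v] = deg[v] / S
    for d in depths:
        group = [v for v in boundary if dep[v] == d]
        if taken + len(group) <= t:
            for v in group:
                probs[v] = dstar / S
            taken += len(group)
        else:
            frac = (t - taken) / len(group)
            for v in group:
                probs[v] = frac * dstar / S
            break

    # --- empirical marginal of the fast path -----------------------
    rng = np.random.default_rng(77)
    info = gen._step_pool_info(state, f)
    counts = np.zeros(j)
    ndraw = 60_000
    for _ in range(ndraw):
        v = gen._draw_candidates(state, 1, *info[1:], rng)[0]
        counts[v] += 1
    assert 0.5 * np.abs(counts / ndraw - probs).sum() < 0.02  # TV distance

    # --- and of the literal reference path -------------------------
    counts_lit = np.zeros(j)
    nlit = 30_000
    for _ in range(nlit):
        pool = build_pool(state, f, rng)
        counts_lit[sample_candidate(pool, rng)] += 1
    assert 0.5 * np.abs(counts_lit / nlit - probs).sum() < 0.03


def test_drawn_candidates_stay_inside_ranked_pool():
    """Every drawn candidate ranks at least as high as the pool cut.

    Recomputes the cut independently each step: candidates must have
    degree above the boundary degree, or sit in the boundary class no
    deeper than the depth where the ranked pool is completed.
    """
    cfg = GrowthConfig(n=120, m=2, f=0.3, seed=21)
    rng = np.random.default_rng(cfg.seed)
    state = init_state(cfg)
    while state.num_nodes < cfg.n:
        deg = list(state.degree)
        dep = list(state.depth)
        n_pool = pool_size(state.num_nodes, cfg.f)
        ranked = sorted(range(state.num_nodes),
                        key=lambda v: (-deg[v], dep[v]))
        cut_deg = deg[ranked[n_pool - 1]]
        n_above = sum(1 for d in deg if d > cut_deg)
        class_depths = sorted(dep[v] for v in range(state.num_nodes)
                              if deg[v] == cut_deg)
        cut_depth = class_depths[n_pool - n_above - 1]
        attach_node(state, cfg, rng)
        for c in state.last_drawn:
            assert deg[c] >= cut_deg
            if deg[c] == cut_deg:
                assert dep[c] <= cut_depth


def test_pool_parent_closure(rng):
    """If a node is in the candidate set, so is its parent (closure ~ 1)."""
    for f in (0.3, 0.6, 0.9):
        state = generate(GrowthConfig(n=2000, m=1, f=f, seed=31))
        assert pool_parent_fraction(state, f, rng) >= 0.99


def test_state_from_parents_validates():
    with pytest.raises(ValueError):
        state_from_parents([0, 1])
    with pytest.raises(ValueError):
        state_from_parents([-1, 2])
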