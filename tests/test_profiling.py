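import math

import networkx as nx
import numpy as np
import pytest
from scipy.optimize import linprog

from metaeval.cami_io import ProfileEntry, TaxonProfile
from metaeval.errors import UndefinedMetricError
from metaeval.profiling import (
    bray_curtis,
    diversity_error,
    l1_norm,
    presence_metrics,
    shannon_equitability,
    weighted_unifrac,
)
from metaeval.taxonomy import TaxNode, TaxonomyDB

from conftest import make_profile


def lp_transport_unifrac(db: TaxonomyDB, mass_a: dict, mass_b: dict) -> float:
    """Independent earth-mover's oracle: LP over pairwise tree distances."""
    g = nx.Graph()
    for t, n in db.nodes.items():
        if n.parent != t:
            g.add_edge(t, n.parent, weight=1.0)
        else:
            g.add_node(t)
    sources = sorted(mass_a)
    sinks = sorted(mass_b)
    dist = dict(nx.all_pairs_dijkstra_path_length(g))
    costs = np.array([[dist[s][t] for t in sinks] for s in sources]).ravel()
    n_s, n_t = len(sources), len(sinks)
    a_eq = []
    b_eq = []
    for i in range(n_s):
        row = np.zeros(n_s * n_t)
        row[i * n_t : (i + 1) * n_t] = 1
        a_eq.append(row)
        b_eq.append(mass_a[sources[i]])
    for j in range(n_t):
        row = np.zeros(n_s * n_t)
        row[j::n_t] = 1
        a_eq.append(row)
        b_eq.append(mass_b[sinks[j]])
    res = linprog(costs, A_eq=np.array(a_eq), b_eq=np.array(b_eq), method="highs")
    assert res.success
    return float(res.fun)


def random_tree(rng, n_nodes):
    db = TaxonomyDB()
    db.nodes[1] = TaxNode(1, 1, "no rank")
    for t in range(2, n_nodes + 1):
        parent = int(rng.integers(1, t))
        db.nodes[t] = TaxNode(t, parent, "clade")
    return db


def profile_from_masses(db, masses):
    return TaxonProfile(
        "s", [ProfileEntry(t, db.nodes[t].rank, "", m) for t, m in masses.items()]
    )


class TestPresence:
    def test_partial_overlap(self):
        gold = make_profile({1: 0.4, 2: 0.4, 3: 0.2})
        pred = make_profile({1: 0.5, 2: 0.3, 4: 0.2})
        purity, completeness, f1 = presence_metrics(gold, pred, "species")
        assert purity == pytest.approx(2 / 3)
        assert completeness == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 / 3)

    def test_identity_and_disjoint(self):
        gold = make_profile({1: 0.5, 2: 0.5})
        assert presence_metrics(gold, gold, "species") == pytest.approx((1, 1, 1))
        pred = make_profile({3: 0.5, 4: 0.5})
        assert presence_metrics(gold, pred, "species") == pytest.approx((0, 0, 0))

    def test_empty_gold_rank_undefined(self):
        with pytest.raises(UndefinedMetricError):
            presence_metrics(make_profile({}), make_profile({1: 1.0}), "species")


class TestAbundanceError:
    def test_l1_worked(self):
        gold = make_profile({1: 0.7, 2: 0.3})
        pred = make_profile({1: 0.5, 2: 0.5})
        assert l1_norm(gold, pred, "species") == pytest.approx(0.4)
        assert l1_norm(gold, gold, "species") == 0.0

    def test_l1_upper_bound_on_disjoint_profiles(self):
        gold = make_profile({1: 0.6, 2: 0.4})
        pred = make_profile({3: 0.5, 4: 0.5})
        assert l1_norm(gold, pred, "species") == pytest.approx(2.0)
        assert bray_curtis(gold, pred, "species") == pytest.approx(1.0)

    def test_bray_curtis_half_l1_for_complete_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = rng.dirichlet(np.ones(5))
            b = rng.dirichlet(np.ones(5))
            gold = make_profile(dict(enumerate(a)))
            pred = make_profile(dict(enumerate(b)))
            assert bray_curtis(gold, pred, "species") == pytest.approx(
                l1_norm(gold, pred, "species") / 2
            )

    def test_bray_curtis_exceeds_half_l1_for_incomplete_prediction(self):
        gold = make_profile({1: 0.5, 2: 0.5})
        pred = make_profile({1: 0.25, 2: 0.25})  # same composition, half the data
        assert l1_norm(gold, pred, "species") == pytest.approx(0.5)
        assert bray_curtis(gold, pred, "species") == pytest.approx(0.5 / 1.5)

    def test_entry_order_invariance(self):
        e = [ProfileEntry(1, "species", "", 0.3), ProfileEntry(2, "species", "", 0.7)]
        a = TaxonProfile("s", e)
        b = TaxonProfile("s", e[::-1])
        gold = make_profile({1: 0.5, 2: 0.5})
        assert l1_norm(gold, a, "species") == l1_norm(gold, b, "species")


class TestShannon:
    def test_uniform_is_one(self):
        prof = make_profile({i: 0.1 for i in range(10)})
        assert shannon_equitability(prof, "species") == pytest.approx(1.0)

    def test_single_taxon_is_zero(self):
        assert shannon_equitability(make_profile({1: 1.0}), "species") == 0.0

    def test_worked_value(self):
        prof = make_profile({1: 0.5, 2: 0.25, 3: 0.25})
        expected = (1.5 * math.log(2)) / math.log(3)
        assert shannon_equitability(prof, "species") == pytest.approx(expected)
        assert expected == pytest.approx(0.9464, abs=1e-4)

    def test_diversity_error(self):
        gold = make_profile({1: 0.5, 2: 0.25, 3: 0.25})
        uniform = make_profile({1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
        assert diversity_error(gold, gold, "species") == 0.0
        assert diversity_error(gold, uniform, "species") == pytest.approx(0.0536, abs=1e-4)
        single = make_profile({1: 1.0})
        assert diversity_error(uniform, single, "species") == pytest.approx(1.0)


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self, two_lineages):
        db, sp_a, _ = two_lineages
        p = profile_from_masses(db, {sp_a: 1.0})
        assert weighted_unifrac(p, p, db) == 0.0

    def test_worst_case_sixteen(self, two_lineages):
        """All mass at species depth in two superkingdoms: 8 edges up + 8 down."""
        db, sp_a, sp_b = two_lineages
        pa = profile_from_masses(db, {sp_a: 1.0})
        pb = profile_from_masses(db, {sp_b: 1.0})
        assert weighted_unifrac(pa, pb, db) == pytest.approx(16.0)

    def test_sibling_phyla_distance_two(self):
        """Two phyla under one superkingdom are two unit edges apart."""
        db = TaxonomyDB()
        db.nodes[1] = TaxNode(1, 1, "no rank")
        db.nodes[2] = TaxNode(2, 1, "superkingdom")
        db.nodes[10] = TaxNode(10, 2, "phylum")
        db.nodes[11] = TaxNode(11, 2, "phylum")
        pa = profile_from_masses(db, {10: 1.0})
        pb = profile_from_masses(db, {11: 1.0})
        assert weighted_unifrac(pa, pb, db) == pytest.approx(2.0)
        assert weighted_unifrac(pa, pb, db) == pytest.approx(
            lp_transport_unifrac(db, {10: 1.0}, {11: 1.0})
        )

    def test_mass_sits_at_most_specific_node(self, two_lineages):
        """A profile repeating its mass at every rank scores like its species entry."""
        db, sp_a, sp_b = two_lineages
        full_a = TaxonProfile(
            "s",
            [
                ProfileEntry(t, db.nodes[t].rank, "", 1.0)
                for t in db.lineage(sp_a)[1:]
            ],
        )
        pb = profile_from_masses(db, {sp_b: 1.0})
        assert weighted_unifrac(full_a, pb, db) == pytest.approx(16.0)

    def test_symmetry_zero_iff_equal_and_triangle(self):
        """Metric axioms on random mass-assignment triples on random trees."""
        rng = np.random.default_rng(17)
        for _ in range(25):
            db = random_tree(rng, int(rng.integers(5, 20)))
            nodes = sorted(db.nodes)
            profs = []
            for _ in range(3):
                chosen = rng.choice(nodes, size=min(4, len(nodes)), replace=False)
                w = rng.dirichlet(np.ones(len(chosen)))
                profs.append(profile_from_masses(db, dict(zip((int(c) for c in chosen), w))))
            a, b, c = profs
            dab = weighted_unifrac(a, b, db)
            assert dab == pytest.approx(weighted_unifrac(b, a, db))
            assert weighted_unifrac(a, a, db) == pytest.approx(0.0, abs=1e-12)
            assert dab <= weighted_unifrac(a, c, db) + weighted_unifrac(c, b, db) + 1e-9

    def test_matches_lp_transport_oracle(self):
        """Tree accumulation equals the LP transport optimum on 100 random trees."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            db = random_tree(rng, int(rng.integers(4, 31)))
            # mass on leaves only, so the profile-placement rule is the identity
            # and the LP sees the same distributions as the implementation
            parents = {n.parent for t, n in db.nodes.items() if n.parent != t}
            leaves = sorted(set(db.nodes) - parents)
            k = min(5, len(leaves))
            na = rng.choice(leaves, size=k, replace=False)
            nb = rng.choice(leaves, size=k, replace=False)
            ma = dict(zip((int(x) for x in na), rng.dirichlet(np.ones(k))))
            mb = dict(zip((int(x) for x in nb), rng.dirichlet(np.ones(k))))
            got = weighted_unifrac(profile_from_masses(db, ma), profile_from_masses(db, mb), db)
            want = lp_transport_unifrac(db, ma, mb)
            assert got == pytest.approx(want, abs=1e-6)

    def test_zero_mass_profile_undefined(self, two_lineages):
        db, sp_a, _ = two_lineages
        with pytest.raises(UndefinedMetricError):
            weighted_unifrac(profile_from_masses(db, {}), profile_from_masses(db, {sp_a: 1.0}), db)
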