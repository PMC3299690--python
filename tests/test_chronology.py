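import numpy as np
import pandas as pd
import pytest

import ribophylo as rp
from ribophylo.chronology import rescale_unit, yule_tree
from ribophylo.errors import AnnotationError, DomainError, FitError, InputError

from conftest import rooted_tree


class TestNodeDistance:
    def test_caterpillar_hand_counts(self):
        chron = rp.node_distance(rooted_tree("(((A,B),C),D);"))
        assert chron.nd == {"A": 1.0, "B": 1.0, "C": 0.5, "D": 0.0}

    def test_endpoints_on_random_yule_trees(self):
        import random

        for seed in range(5):
            t = yule_tree(15, random.Random(seed))
            chron = rp.node_distance(t)
            if chron.degenerate:
                continue
            vals = list(chron.nd.values())
            assert max(vals) == 1.0
            assert min(vals) >= 0.0

    def test_basal_leaf_is_zero(self):
        chron = rp.node_distance(rooted_tree("(((A,B),(C,E)),D);"))
        assert chron.nd["D"] == 0.0

    def test_equidistant_leaves_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate|equidistant"):
            chron = rp.node_distance(rooted_tree("((A,B),(C,D));"))
        assert chron.degenerate
        assert set(chron.nd.values()) == {0.0}

    def test_scale_free_under_uniform_deepening(self):
        """Grafting a cherry below every leaf preserves relative order."""
        base = rooted_tree("(((A,B),C),D);")
        deep = rooted_tree("((((A1,A2),(B1,B2)),(C1,C2)),(D1,D2));")
        nd1 = rp.node_distance(base).nd
        nd2 = rp.node_distance(deep).nd
        order1 = sorted("ABCD", key=lambda k: nd1[k])
        order2 = sorted("ABCD", key=lambda k: nd2[k + "1"])
        assert order1 == order2


class TestImbalance:
    def test_balanced_four_leaf(self):
        nbar, cherries = rp.imbalance_stats(rooted_tree("((A,B),(C,D));"))
        assert (nbar, cherries) == (2.0, 2)

    def test_caterpillar_has_one_cherry(self):
        t = rooted_tree("(((((A,B),C),D),E),F);")
        _, cherries = rp.imbalance_stats(t)
        assert cherries == 1

    def test_two_leaf_tree(self):
        assert rp.imbalance_stats(rooted_tree("(A,B);")) == (1.0, 1)


class TestNullEnsembles:
    def test_yule_cherry_expectation(self):
        ens = rp.null_tree_ensemble(30, model="yule", reps=1500, seed=1)
        assert ens["cherries"].mean() == pytest.approx(10.0, abs=0.35)

    def test_caterpillar_rejected_by_yule(self):
        leaves = [chr(ord("a") + i) for i in range(20)]
        newick = f"({leaves[0]},{leaves[1]})"
        for c in leaves[2:]:
            newick = f"({newick},{c})"
        t = rooted_tree(newick + ";")
        ens = rp.null_tree_ensemble(
            20, model="yule", reps=2000, seed=2, observed_tree=t
        )
        assert ens["p_cherries"] < 0.01
        assert ens["p_nbar"] < 0.01

    def test_uniform_and_yule_cherry_means_differ(self):
        yule = rp.null_tree_ensemble(30, model="yule", reps=400, seed=3)
        unif = rp.null_tree_ensemble(30, model="uniform_random", reps=400, seed=3)
        assert unif["cherries"].mean() < yule["cherries"].mean() - 1.0

    def test_self_consistency_envelope(self):
        """A Yule draw falls inside its own model's 99% envelope."""
        import random

        obs = yule_tree(25, random.Random(7))
        ens = rp.null_tree_ensemble(
            25, model="yule", reps=800, seed=8, observed_tree=obs
        )
        assert ens["p_cherries"] > 0.01

    def test_minimum_reps_enforced(self):
        with pytest.raises(InputError):
            rp.null_tree_ensemble(10, reps=10)


class TestTimeline:
    @pytest.fixture
    def chron(self):
        return rp.Chronology({"h44": 0.0, "H71": 0.4, "h10": 0.8})

    def test_bridge_acceptor_rule(self, chron):
        bridges = pd.DataFrame(
            [("B1", "h44", "H71")], columns=["bridge", "acceptor", "donor"]
        )
        tl = rp.assemble_timeline(chron, bridges=bridges, bridge_rule="acceptor")
        event = next(e for e in tl if e.event_class == "bridge")
        assert event.nd == 0.0

    def test_bridge_max_rule(self, chron):
        bridges = pd.DataFrame(
            [("B1", "h44", "H71")], columns=["bridge", "acceptor", "donor"]
        )
        tl = rp.assemble_timeline(chron, bridges=bridges, bridge_rule="max")
        event = next(e for e in tl if e.event_class == "bridge")
        assert event.nd == 0.4

    def test_empty_annotations_only_helices(self, chron):
        tl = rp.assemble_timeline(chron)
        assert [e.event_class for e in tl] == ["helix"] * 3

    def test_unknown_helix_listed(self, chron):
        contacts = pd.DataFrame(
            [("c1", "trna", "h99")], columns=["contact", "class", "helix"]
        )
        with pytest.raises(AnnotationError, match="h99"):
            rp.assemble_timeline(chron, contacts=contacts)

    def test_events_sorted_and_complete(self, chron):
        bridges = pd.DataFrame(
            [("B2", "h10", "h44"), ("B1", "h44", "H71")],
            columns=["bridge", "acceptor", "donor"],
        )
        contacts = pd.DataFrame(
            [("c1", "trna", "H71")], columns=["contact", "class", "helix"]
        )
        tl = rp.assemble_timeline(chron, bridges=bridges, contacts=contacts)
        nds = [e.nd for e in tl]
        assert nds == sorted(nds)
        assert len(tl) == 3 + 2 + 1  # permutation of inputs: no loss, no gain
        assert {e.entity for e in tl} == {"h44", "H71", "h10", "B1", "B2", "c1"}


class TestProteinAge:
    def test_two_domain_protein_takes_younger_domain(self):
        # the ribosomal protein L2 case: N-terminal domain much older
        age, flagged = rp.protein_age([0.037, 0.347], combination_age=0.306)
        assert age == 0.347
        assert not flagged

    def test_single_domain_identity(self):
        assert rp.protein_age([0.25]) == (0.25, False)

    def test_combination_postdating_all_domains_is_flagged(self):
        age, flagged = rp.protein_age([0.1, 0.2], combination_age=0.5)
        assert age == 0.2
        assert flagged

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rp.protein_age([])


class TestInterpolation:
    def test_exact_line(self):
        pairs = [(0, 0), (1, 2), (2, 4), (3, 6)]
        fit = rp.interpolate_protein_age(pairs, query=1.5)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["interpolated"] == pytest.approx(3.0)

    def test_hand_ols_zero_r_squared(self):
        fit = rp.interpolate_protein_age([(0, 0), (1, 1), (2, 0)])
        assert fit["slope"] == pytest.approx(0.0)
        assert fit["r_squared"] == pytest.approx(0.0)

    def test_closed_form_f_statistic(self):
        rng = np.random.default_rng(5)
        x = rng.random(12)
        y = 0.5 * x + 0.05 * rng.standard_normal(12)
        fit = rp.interpolate_protein_age(list(zip(x, y)))
        r2, n = fit["r_squared"], fit["n"]
        assert fit["f_statistic"] == pytest.approx((n - 2) * r2 / (1 - r2))

    def test_inverse_interpolation(self):
        fit = rp.interpolate_protein_age(
            [(0, 0), (1, 2), (2, 4)], query=2.0, on="nd_P"
        )
        assert fit["interpolated"] == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(FitError):
            rp.interpolate_protein_age([(0, 0), (1, 1)])

    def test_zero_variance_predictor(self):
        with pytest.raises(FitError):
            rp.interpolate_protein_age([(1, 0), (1, 1), (1, 2)])


class TestHeatmapColors:
    def test_endpoint_bins(self):
        df = rp.heatmap_colors({"a": 0.0, "b": 1.0})
        assert df.loc[df["id"] == "a", "bin"].item() == 0.0
        assert df.loc[df["id"] == "b", "bin"].item() == 1.0

    def test_rescaled_ndp_range_hits_endpoints(self):
        # observed nd_P ranges like 0.018-0.534 must span the color scale
        scaled = rescale_unit({"p1": 0.018, "p2": 0.25, "p3": 0.534})
        assert scaled["p1"] == 0.0 and scaled["p3"] == 1.0
        df = rp.heatmap_colors(scaled)
        assert len(df) == 3

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            rp.heatmap_colors({"a": 1.2})

    def test_deterministic_101_bins(self):
        df1 = rp.heatmap_colors({f"x{i}": i / 100 for i in range(101)})
        df2 = rp.heatmap_colors({f"x{i}": i / 100 for i in range(101)})
        assert df1.equals(df2)
        assert df1["bin"].nunique() == 101
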