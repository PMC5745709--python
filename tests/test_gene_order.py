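import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodrl.gene_order import (
    DRLScenario,
    GeneOrder,
    canonicalize,
    depth_ratio,
    extract_gene_order,
    infer_single_drl,
    orders_equivalent,
    replay_scenario,
)
from mitodrl.genome_io import DepthTrack, FeatureAnnotation
from mitodrl.drl_simulator import random_drl_order_scenario

from tests.oracles import exhaustive_drl_spans


def order_of(labels, circular=True, strands=None):
    strands = strands or [1] * len(labels)
    return GeneOrder(tuple(zip(labels, strands)), circular=circular)


class TestCanonicalize:
    def test_idempotent(self):
        o = canonicalize(order_of(["trnF", "a", "b"]))
        assert canonicalize(o) == o

    def test_all_rotations_share_canonical_form(self):
        o = order_of(["c", "trnF", "a", "b"])
        forms = {canonicalize(o.rotated(k)) for k in range(len(o))}
        assert len(forms) == 1
        assert forms.pop().elements[0][0] == "trnF"

    def test_linear_unchanged(self):
        o = order_of(["c", "a", "b"], circular=False)
        assert canonicalize(o) is o

    def test_fallback_smallest_label_without_anchor(self):
        o = order_of(["m", "b", "z"])
        assert canonicalize(o).elements[0][0] == "b"


class TestOrdersEquivalent:
    def test_rotation_is_equivalent(self):
        o = order_of(["a", "b", "c", "d"])
        assert orders_equivalent(o, o.rotated(2))

    def test_strand_flip_differs(self):
        a = order_of(["a", "b", "c"])
        b = order_of(["a", "b", "c"], strands=[1, -1, 1])
        assert not orders_equivalent(a, b)

    def test_matches_brute_force_rotation_comparison(self, rng):
        labels = ["a", "b", "c", "d", "e"]
        for _ in range(50):
            x = list(labels)
            y = list(labels)
            rng.shuffle(x)
            rng.shuffle(y)
            a, b = order_of(x), order_of(y)
            brute = any(
                a.elements == b.rotated(k).elements for k in range(len(b))
            )
            assert orders_equivalent(a, b) == brute

    def test_equivalence_relation(self, rng):
        orders = []
        for _ in range(8):
            labs = ["a", "b", "c", "d"]
            rng.shuffle(labs)
            orders.append(order_of(labs).rotated(int(rng.integers(0, 4))))
        for x in orders:
            assert orders_equivalent(x, x)
        for x, y in itertools.combinations(orders, 2):
            assert orders_equivalent(x, y) == orders_equivalent(y, x)
        for x, y, z in itertools.permutations(orders, 3):
            if orders_equivalent(x, y) and orders_equivalent(y, z):
                assert orders_equivalent(x, z)


@settings(derandomize=True, max_examples=60)
@given(
    labels=st.lists(
        st.sampled_from("abcdefgh"), min_size=1, max_size=8, unique=True
    ),
    k=st.integers(),
)
def test_rotation_never_changes_a_circular_order(labels, k):
    order = order_of(labels)
    assert orders_equivalent(order, order.rotated(k % len(order)))
    assert canonicalize(order) == canonicalize(order.rotated(k % len(order)))


class TestExtractGeneOrder:
    def test_single_feature(self):
        f = FeatureAnnotation("g", "trnF", "tRNA", 0, 70, 1)
        order = extract_gene_order([f], 70)
        assert order.elements == (("trnF", 1),)

    def test_wrapping_feature_same_canonical_order(self):
        # same three genes, one annotation wrapping the origin
        flat = [
            FeatureAnnotation("g", "trnF", "tRNA", 0, 100, 1),
            FeatureAnnotation("g", "a", "tRNA", 100, 200, 1),
            FeatureAnnotation("g", "b", "tRNA", 200, 300, 1),
        ]
        wrapped = [
            FeatureAnnotation("g", "b", "tRNA", 250, 350, 1),  # wraps 300
            FeatureAnnotation("g", "trnF", "tRNA", 50, 150, 1),
            FeatureAnnotation("g", "a", "tRNA", 150, 250, 1),
        ]
        assert orders_equivalent(
            extract_gene_order(flat, 300), extract_gene_order(wrapped, 300)
        )

    def test_large_gene_overlap_rejected(self):
        feats = [
            FeatureAnnotation("g", "x", "protein", 0, 100, 1),
            FeatureAnnotation("g", "y", "protein", 50, 150, 1),
        ]
        with pytest.raises(ValueError, match="overlap"):
            extract_gene_order(feats, 150)

    def test_small_overlap_tolerated(self):
        feats = [
            FeatureAnnotation("g", "x", "protein", 0, 100, 1),
            FeatureAnnotation("g", "y", "protein", 93, 200, 1),
        ]
        order = extract_gene_order(feats, 200)
        assert order.labels() == ("x", "y")

    def test_derived_order_swaps_cytb_before_nd6(self, aneides_sim):
        """After the basal duplication-loss event CYTB precedes ND6,
        unlike the typical vertebrate arrangement."""
        order = extract_gene_order(
            aneides_sim.after_event1_features, len(aneides_sim.after_event1)
        )
        labels = list(order.labels())
        assert labels.index("CYTB") < labels.index("ND6")
        # whereas the ancestral order has ND6 before CYTB
        anc = extract_gene_order(
            aneides_sim.reference_features, len(aneides_sim.reference)
        )
        anc_labels = list(anc.labels())
        assert anc_labels.index("ND6") < anc_labels.index("CYTB")


class TestInferSingleDRL:
    def test_worked_six_gene_example_linear(self):
        anc = order_of(
            ["ND6", "trnE", "CYTB", "trnT", "IGS", "trnP"], circular=False
        )
        der = order_of(
            ["CYTB", "trnT", "IGS", "psi_trnP", "ND6", "trnE", "IGS", "trnP"],
            circular=False,
        )
        (scen,) = infer_single_drl(anc, der)
        assert scen.span == (0, 6)
        assert scen.retention == (
            "second", "second", "first", "first", "both", "remnant"
        )
        assert scen.pseudogene_copy == ((5, 1),)

    def test_worked_example_circular_contains_planted_span(self):
        anc = order_of(["ND6", "trnE", "CYTB", "trnT", "IGS", "trnP"])
        der = order_of(
            ["CYTB", "trnT", "IGS", "psi_trnP", "ND6", "trnE", "IGS", "trnP"]
        )
        spans = {s.span for s in infer_single_drl(anc, der)}
        assert spans == exhaustive_drl_spans(anc, der)

    def test_identity_scenarios_flagged_and_nonempty(self):
        x = order_of(["a", "b", "c", "d"])
        scens = infer_single_drl(x, x)
        assert scens
        assert all(s.identity_consistent for s in scens)

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="not ancestral"):
            infer_single_drl(order_of(["a", "b"]), order_of(["a", "z"]))

    def test_strand_difference_rejected(self):
        anc = order_of(["a", "b", "c"])
        der = order_of(["a", "b", "c"], strands=[1, -1, 1])
        assert infer_single_drl(anc, der) == []

    def test_abcde_transposition_and_impossible_case(self):
        A = order_of(list("ABCDE"))
        spans = {s.span for s in infer_single_drl(A, order_of(list("ACDBE")))}
        assert spans == exhaustive_drl_spans(A, order_of(list("ACDBE")))
        assert (1, 3) in spans  # the (B, C, D) span
        assert infer_single_drl(A, order_of(list("ADCBE"))) == []

    def test_every_scenario_replays_to_derived(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 8))
            anc, _, der = random_drl_order_scenario(n, rng)
            for scen in infer_single_drl(anc, der):
                assert orders_equivalent(replay_scenario(anc, scen), der)

    def test_matches_exhaustive_oracle_battery(self, rng):
        """Inference equals span-by-span exhaustive enumeration on random
        single-DRL derivates and on perturbed (often non-DRL) orders."""
        cases = []
        for _ in range(12):
            n = int(rng.integers(3, 7))
            anc, _, der = random_drl_order_scenario(n, rng)
            cases.append((anc, der))
        # one length-7 case
        anc, _, der = random_drl_order_scenario(7, rng)
        cases.append((anc, der))
        # permuted orders that need not be single-DRL reachable
        for _ in range(6):
            n = int(rng.integers(4, 6))
            labels = [f"g{i}" for i in range(n)]
            shuffled = list(labels)
            rng.shuffle(shuffled)
            cases.append((order_of(labels), order_of(shuffled)))
        for anc, der in cases:
            got = {s.span for s in infer_single_drl(anc, der)}
            assert got == exhaustive_drl_spans(anc, der)


class TestDepthRatio:
    def test_uniform_depth(self):
        track = DepthTrack("g", (100,) * 1000)
        ratio, flag = depth_ratio(track, (100, 200))
        assert ratio == pytest.approx(1.0)
        assert not flag

    def test_doubled_region_flags_two_copies(self):
        depths = [100] * 1000
        depths[300:400] = [200] * 100
        ratio, flag = depth_ratio(DepthTrack("g", tuple(depths)), (300, 400))
        assert ratio == pytest.approx(2.0)
        assert flag

    def test_matches_arithmetic_oracle(self, rng):
        depths = tuple(int(d) for d in rng.integers(50, 150, size=500))
        region = (100, 160)
        ratio, _ = depth_ratio(DepthTrack("g", depths), region, trim=0.0)
        inside = depths[100:160]
        outside = depths[:100] + depths[160:]
        expected = (sum(inside) / len(inside)) / (sum(outside) / len(outside))
        assert ratio == pytest.approx(expected)

    def test_zero_background_is_error(self):
        track = DepthTrack("g", (0, 0, 0, 5, 5))
        with pytest.raises(ValueError, match="zero"):
            depth_ratio(track, (3, 5), trim=0.0)
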