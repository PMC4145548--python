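"""LC-weighted agreement table, kappa, Fleiss standard error, Z score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.inter_rater import cohens_kappa

from fsim import agreement_table, fsim_score, kappa, kappa_se
from fsim.annotation import AnnotationClass
from fsim.baselines import david_kappa
from fsim.core import AgreementTable, SimilarityError, score_table

from conftest import naive_kappa


def make_class(bits, universe, name="x"):
    return AnnotationClass(
        gene_id=name, bits=np.asarray(bits, bool), universe=universe
    )


class TestAgreementTable:
    def test_toy_g1_g2(self, dag, classes):
        t = agreement_table(classes["g1"], classes["g2"], dag)
        assert (t.p11, t.p12, t.p21, t.p22) == (1.5, 0.0, 1.0, 1.5)
        assert t.total == pytest.approx(4.0)

    def test_toy_g1_g3_disjoint_leaves(self, dag, classes):
        t = agreement_table(classes["g1"], classes["g3"], dag)
        assert (t.p11, t.p12, t.p21, t.p22) == (0.5, 1.0, 1.5, 1.0)

    def test_identical_classes_have_no_off_diagonal(self, dag, classes):
        t = agreement_table(classes["g2"], classes["g2"], dag)
        assert t.p12 == t.p21 == 0.0

    def test_cells_sum_to_lc_mass(self, dag, classes):
        t = agreement_table(classes["g1"], classes["g3"], dag)
        assert t.total == pytest.approx(sum(dag.lc.values()), abs=1e-9)

    def test_universe_mismatch_rejected(self, dag, classes):
        other = make_class([1, 0], ["A", "B"])
        with pytest.raises(SimilarityError, match="universe"):
            agreement_table(classes["g1"], other, dag)


class TestKappa:
    def test_toy_hand_value(self):
        t = AgreementTable(1.5, 0.0, 1.0, 1.5)
        # Po = 0.75, Pe = 0.46875 -> kappa = 0.28125/0.53125
        assert kappa(t) == pytest.approx(0.28125 / 0.53125, abs=1e-12)

    def test_perfect_agreement(self):
        assert kappa(AgreementTable(2.0, 0.0, 0.0, 3.0)) == pytest.approx(1.0)

    def test_degenerate_single_cell_is_nan(self):
        assert math.isnan(kappa(AgreementTable(4.0, 0.0, 0.0, 0.0)))

    def test_zero_total_rejected(self):
        with pytest.raises(SimilarityError):
            kappa(AgreementTable(0.0, 0.0, 0.0, 0.0))

    def test_range_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            t = AgreementTable(*rng.uniform(0.01, 5.0, size=4))
            assert -1.0 <= kappa(t) <= 1.0


class TestKappaSE:
    def test_positive(self):
        assert kappa_se(AgreementTable(1.5, 0.0, 1.0, 1.5)) > 0

    def test_matches_independent_fleiss_implementation(self):
        # statsmodels implements the same Fleiss-Cohen-Everitt variance
        rng = np.random.default_rng(5)
        for _ in range(50):
            cells = rng.integers(1, 60, size=4).astype(float)
            t = AgreementTable(*cells)
            ref = cohens_kappa(np.array([[t.p11, t.p12], [t.p21, t.p22]]))
            assert kappa(t) == pytest.approx(ref.kappa, abs=1e-9)
            assert kappa_se(t) == pytest.approx(math.sqrt(ref.var_kappa), abs=1e-9)

    def test_cell_scaling_leaves_kappa_scales_se(self):
        t = AgreementTable(1.5, 0.2, 1.0, 1.5)
        c = 4.0
        assert kappa(t.scaled(c)) == pytest.approx(kappa(t), abs=1e-12)
        assert kappa_se(t.scaled(c)) == pytest.approx(
            kappa_se(t) / math.sqrt(c), abs=1e-12
        )

    def test_effective_n_override(self):
        t = AgreementTable(1.5, 0.2, 1.0, 1.5)
        assert kappa_se(t, effective_n=6) == pytest.approx(
            kappa_se(t) * math.sqrt(t.total / 6), abs=1e-12
        )


class TestFsimScore:
    def test_toy_g1_g2_composition(self, dag, classes):
        s = fsim_score(classes["g1"], classes["g2"], dag)
        t = AgreementTable(1.5, 0.0, 1.0, 1.5)
        assert s.kappa == pytest.approx(kappa(t), abs=1e-12)
        assert s.z == pytest.approx(kappa(t) / kappa_se(t), abs=1e-12)

    def test_self_similarity(self, dag, classes):
        s = fsim_score(classes["g1"], classes["g1"], dag)
        assert s.kappa == pytest.approx(1.0)
        assert s.z > 0

    def test_symmetry(self, dag, classes):
        ab = fsim_score(classes["g1"], classes["g3"], dag)
        ba = fsim_score(classes["g3"], classes["g1"], dag)
        assert (ab.kappa, ab.se, ab.z) == (ba.kappa, ba.se, ba.z)

    def test_root_bit_never_affects_score(self, dag, classes):
        a, b = classes["g1"], classes["g3"]
        stripped = make_class(a.bits.copy(), a.universe)
        stripped.bits[a.universe.index("R")] = False
        with_root = fsim_score(a, b, dag)
        without = fsim_score(stripped, b, dag)
        assert with_root.kappa == pytest.approx(without.kappa, abs=1e-12)
        assert with_root.z == pytest.approx(without.z, abs=1e-12)

    def test_per_namespace_mode(self, dag, classes):
        s = fsim_score(classes["g1"], classes["g2"], dag, combine="per_namespace")
        assert set(s.per_namespace) == {"custom"}
        sub = s.per_namespace["custom"]
        assert sub.kappa == pytest.approx(s.kappa, abs=1e-12)

    def test_unknown_combine_mode(self, dag, classes):
        with pytest.raises(SimilarityError):
            fsim_score(classes["g1"], classes["g2"], dag, combine="bogus")


class TestUnweightedEquivalence:
    def test_lc_forced_to_one_equals_david_kappa(self, dag):
        """With unit weights the LC-weighted kappa is Cohen's kappa on raw bits."""
        rng = np.random.default_rng(42)
        universe = list("abcdefghijkl")
        ones = np.ones(len(universe))
        for _ in range(100):
            x = make_class(rng.integers(0, 2, len(universe)), universe)
            y = make_class(rng.integers(0, 2, len(universe)), universe)
            t = agreement_table(x, y, dag, weights=ones)
            expected = naive_kappa(x.bits, y.bits)
            got = kappa(t)
            david = david_kappa(x, y)
            if math.isnan(expected):
                assert math.isnan(got) and math.isnan(david)
            else:
                assert got == pytest.approx(expected, abs=1e-12)
                assert david == pytest.approx(expected, abs=1e-12)

    def test_toy_unweighted_hand_value(self, classes):
        # g1 vs g2 raw counts: 3 shared, 1 g2-only, 2 neither -> kappa = 2/3
        assert david_kappa(classes["g1"], classes["g2"]) == pytest.approx(
            2 / 3, abs=1e-12
        )


@settings(max_examples=60, derandomize=True)
@given(
    bits=st.lists(st.tuples(st.booleans(), st.booleans()), min_size=2, max_size=24),
    weights=st.lists(st.floats(0.0, 1.0), min_size=24, max_size=24),
)
def test_weighted_table_partitions_mass_and_is_symmetric(dag, bits, weights):
    """Cells always partition the weight mass; swapping args swaps p12/p21."""
    universe = [f"t{i}" for i in range(len(bits))]
    w = np.asarray(weights[: len(bits)])
    x = make_class([a for a, _ in bits], universe)
    y = make_class([b for _, b in bits], universe)
    t = agreement_table(x, y, dag, weights=w)
    assert t.total == pytest.approx(w.sum(), abs=1e-9)
    swapped = agreement_table(y, x, dag, weights=w)
    assert (t.p11, t.p22) == (swapped.p11, swapped.p22)
    assert (t.p12, t.p21) == (swapped.p21, swapped.p12)


def test_score_table_degenerate_propagates_nan():
    s = score_table(AgreementTable(4.0, 0.0, 0.0, 0.0))
    assert math.isnan(s.kappa) and math.isnan(s.se) and math.isnan(s.z)
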