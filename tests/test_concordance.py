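"""Cohen's kappa, subtype-specific kappa, bands and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcsubtype.concordance import (
    ComparisonDesign,
    ComparisonGroup,
    ContingencyTable,
    aggregate_concordance,
    cohens_kappa,
    kappa_band,
    subtype_kappa,
)
from bcsubtype.core import Subtype, SubtypeAssignment

from conftest import random_assignment


def brute_force_kappa(a_labels, b_labels):
    """Independent oracle: kappa from raw label counting (no tables)."""
    n = len(a_labels)
    p_o = sum(x == y for x, y in zip(a_labels, b_labels)) / n
    labels = sorted({*a_labels, *b_labels})
    p_e = 0.0
    for l in labels:
        p_e += (sum(x == l for x in a_labels) / n) * (
            sum(y == l for y in b_labels) / n
        )
    if p_e >= 1.0 - 1e-15:
        return None
    return (p_o - p_e) / (1 - p_e)


def _assign(labels, ids=None, pid="p"):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return SubtypeAssignment(sample_ids=tuple(ids), labels=tuple(labels), predictor_id=pid)


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = _assign([Subtype.BASAL, Subtype.LUMA, Subtype.LUMB, Subtype.BASAL])
        res = cohens_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)
        assert res.cc == pytest.approx(100.0)
        assert not res.degenerate

    def test_worked_2x2_table(self):
        # counts [[20, 5], [10, 15]]: p_o = 0.7, p_e = 0.5, kappa = 0.4
        a_labels = [Subtype.BASAL] * 25 + [Subtype.LUMA] * 25
        b_labels = (
            [Subtype.BASAL] * 20 + [Subtype.LUMA] * 5
            + [Subtype.BASAL] * 10 + [Subtype.LUMA] * 15
        )
        res = cohens_kappa(_assign(a_labels), _assign(b_labels))
        assert res.kappa == pytest.approx(0.4, abs=1e-12)
        assert res.cc == pytest.approx(70.0)
        np.testing.assert_array_equal(res.table.counts, [[20, 5], [10, 15]])

    def test_degenerate_constant_equal_assignments_flagged(self):
        a = _assign([Subtype.LUMA] * 5)
        res = cohens_kappa(a, a)
        assert res.degenerate
        assert np.isnan(res.kappa)
        assert res.cc == pytest.approx(100.0)
        assert res.band is None

    def test_sample_mismatch_errors(self):
        a = _assign([Subtype.BASAL], ids=["s1"])
        b = _assign([Subtype.BASAL], ids=["s2"])
        with pytest.raises(ValueError, match="universes differ"):
            cohens_kappa(a, b)

    def test_order_of_samples_does_not_matter(self):
        rng = np.random.default_rng(61)
        ids = [f"s{i}" for i in range(100)]
        a = random_assignment(rng, ids)
        b = random_assignment(rng, ids)
        perm = list(rng.permutation(ids))
        b_perm = b.reindex(perm)
        assert cohens_kappa(a, b).kappa == pytest.approx(cohens_kappa(a, b_perm).kappa)

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(62)
        for _ in range(200):
            n = int(rng.integers(2, 120))
            k = int(rng.integers(2, 5))
            labels = list(Subtype)[:k]
            ids = [f"s{i}" for i in range(n)]
            a = random_assignment(rng, ids, labels)
            b = random_assignment(rng, ids, labels)
            res = cohens_kappa(a, b)
            oracle = brute_force_kappa(list(a.labels), list(b.labels))
            if oracle is None:
                assert res.degenerate
            else:
                assert res.kappa == pytest.approx(oracle, abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_symmetry_and_permutation_invariance(self, data):
        n = data.draw(st.integers(min_value=2, max_value=60))
        labs = list(Subtype)
        a_lab = data.draw(st.lists(st.sampled_from(labs), min_size=n, max_size=n))
        b_lab = data.draw(st.lists(st.sampled_from(labs), min_size=n, max_size=n))
        a, b = _assign(a_lab), _assign(b_lab)
        r_ab, r_ba = cohens_kappa(a, b), cohens_kappa(b, a)
        if not r_ab.degenerate:
            assert r_ab.kappa == pytest.approx(r_ba.kappa, abs=1e-12)
            assert r_ab.kappa <= 1.0
            # joint relabeling of subtype names leaves kappa unchanged
            perm = {
                Subtype.BASAL: Subtype.LUMB, Subtype.LUMB: Subtype.BASAL,
                Subtype.HER2: Subtype.LUMA, Subtype.LUMA: Subtype.HER2,
            }
            r_perm = cohens_kappa(
                _assign([perm[l] for l in a_lab]), _assign([perm[l] for l in b_lab])
            )
            assert r_perm.kappa == pytest.approx(r_ab.kappa, abs=1e-12)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(63)
        ids = [f"s{i}" for i in range(250)]
        a = random_assignment(rng, ids)
        b = random_assignment(rng, ids)
        res = cohens_kappa(a, b)
        expected = cohen_kappa_score(
            [l.value for l in a.labels], [l.value for l in b.labels]
        )
        assert res.kappa == pytest.approx(expected, abs=1e-12)


class TestSubtypeKappa:
    def test_binarized_identical_assignments(self):
        a = _assign([Subtype.BASAL, Subtype.LUMA, Subtype.LUMB])
        assert subtype_kappa(a, a, Subtype.BASAL).kappa == pytest.approx(1.0)

    def test_absent_subtype_is_degenerate(self):
        a = _assign([Subtype.LUMA, Subtype.LUMB])
        res = subtype_kappa(a, a, Subtype.HER2)
        assert res.degenerate

    def test_matches_explicit_2x2_oracle(self):
        rng = np.random.default_rng(64)
        ids = [f"s{i}" for i in range(200)]
        a = random_assignment(rng, ids)
        b = random_assignment(rng, ids)
        for s in Subtype:
            res = subtype_kappa(a, b, s)
            bin_a = [l == s for l in a.labels]
            bin_b = [l == s for l in b.labels]
            oracle = brute_force_kappa(bin_a, bin_b)
            if oracle is None:
                assert res.degenerate
            else:
                assert res.kappa == pytest.approx(oracle, abs=1e-12)


class TestBands:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (-0.3, "slight"), (0.0, "slight"), (0.2, "slight"),
            (0.21, "fair"), (0.4, "fair"),
            (0.467, "moderate"), (0.6, "moderate"),
            (0.61, "substantial"), (0.8, "substantial"),
            (0.81, "almost_perfect"), (1.0, "almost_perfect"),
        ],
    )
    def test_band_boundaries(self, kappa, band):
        assert kappa_band(kappa) == band


class TestAggregation:
    def _design(self, group_kind, vset="V1"):
        kw = dict(type_a="SSP", type_b="SSP", gene_list_a="A", gene_list_b="A",
                  cs_a="T1", cs_b="T1", validation_dataset=vset)
        if group_kind in ("gl", "both"):
            kw["gene_list_b"] = "B"
        if group_kind in ("cs", "both"):
            kw["cs_b"] = "T2"
        if group_kind == "inter":
            kw["type_b"] = "SCM"
        return ComparisonDesign(**kw)

    def _result(self, kappa):
        a = _assign([Subtype.BASAL, Subtype.LUMA] * 10)
        res = cohens_kappa(a, a)
        return type(res)(
            kappa=kappa, cc=100 * kappa, n=res.n, band=kappa_band(kappa),
            table=res.table, per_subtype_kappa={}, degenerate=False,
        )

    def test_group_assignment(self):
        assert self._design("gl").group == ComparisonGroup.GENE_LIST_DIFFERS
        assert self._design("cs").group == ComparisonGroup.CS_DIFFERS
        assert self._design("both").group == ComparisonGroup.BOTH_DIFFER
        assert self._design("inter").group == ComparisonGroup.INTER_TYPE

    def test_single_result_median(self):
        agg = aggregate_concordance([(self._design("gl"), self._result(0.7))])
        assert agg["groups"]["gene_list_differs"]["kappa"]["median"] == pytest.approx(0.7)

    def test_odd_count_median(self):
        results = [(self._design("gl"), self._result(k)) for k in (0.2, 0.9, 0.5)]
        agg = aggregate_concordance(results)
        assert agg["groups"]["gene_list_differs"]["kappa"]["median"] == pytest.approx(0.5)

    def test_train_validation_overlap_excluded(self):
        overlapping = ComparisonDesign(
            type_a="SSP", type_b="SSP", gene_list_a="A", gene_list_b="B",
            cs_a="T1", cs_b="T2", validation_dataset="T1",
        )
        results = [
            (overlapping, self._result(0.1)),
            (self._design("gl"), self._result(0.9)),
        ]
        agg = aggregate_concordance(results)
        assert agg["n_excluded_overlap"] == 1
        assert agg["groups"]["gene_list_differs"]["kappa"]["median"] == pytest.approx(0.9)

    def test_degenerate_excluded_with_count(self):
        a = _assign([Subtype.LUMA] * 4)
        degen = cohens_kappa(a, a)
        agg = aggregate_concordance(
            [(self._design("gl"), degen), (self._design("gl"), self._result(0.6))]
        )
        assert agg["n_excluded_degenerate"] == 1
        assert agg["groups"]["gene_list_differs"]["kappa"]["n"] == 1

    def test_all_excluded_errors(self):
        a = _assign([Subtype.LUMA] * 4)
        with pytest.raises(ValueError, match="excluded"):
            aggregate_concordance([(self._design("gl"), cohens_kappa(a, a))])


class TestContingencyTable:
    def test_canonical_label_order_and_zero_padding(self):
        t = ContingencyTable.from_labels(
            [Subtype.LUMB, Subtype.BASAL], [Subtype.LUMB, Subtype.HER2]
        )
        assert t.labels == ("BASAL", "HER2", "LUMB")
        assert t.n == 2
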