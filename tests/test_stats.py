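"""Resampling statistics: frequencies, sKL, bootstrap, Dunn correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicepairs.dataset import IntronRecord, junction_positions
from splicepairs.stats import (CLASS_ORDER, adjusted_m, bootstrap_differences,
                               build_correction_plan, class_matrix,
                               default_subsites, dunn_threshold,
                               nucleotide_bootstrap, position_frequencies,
                               skl_control_experiment, skl_divergence)


def _records(minus1_bases, start="GTAAGTACGT"):
    """Records whose junctions differ only at exon -1."""
    out = []
    for i, b in enumerate(minus1_bases):
        junction = "ACUUCCA" + b + "GUA"
        out.append(IntronRecord(gene_id="g", transcript_id=f"t{i}",
                                intron_index=1, junction11=junction,
                                intron_start10=start,
                                intron_end60="T" * 57 + "CAG",
                                spliceosome_class="major"))
    return out


class TestFrequencies:
    def test_all_G_at_minus1_gives_wc_probability_one(self, u5):
        dist = position_frequencies(_records("GG"), u5)
        j = dist.positions.index("exon:-1")
        assert dist.probs[j, CLASS_ORDER.index("watson_crick")] == 1.0

    def test_mixed_bases_counted_by_table_lookup(self, u5):
        """exon -1 = G,G,A,U against C39: WC 0.5, isosteric (A:C, U:C) 0.5."""
        dist = position_frequencies(_records("GGAU"), u5)
        j = dist.positions.index("exon:-1")
        assert dist.probs[j, 0] == pytest.approx(0.5)
        assert dist.probs[j, 1] == pytest.approx(0.5)
        assert dist.probs[j, 2] == 0.0

    def test_uridine_partner_positions_have_two_defined_classes(self, u5):
        dist = position_frequencies(_records("G"), u5)
        j = dist.positions.index("exon:-4")
        assert list(dist.defined[j]) == [True, True, False]

    def test_probabilities_sum_to_one_per_position(self, small_dataset, u5):
        dist = position_frequencies(small_dataset.records, u5)
        np.testing.assert_allclose(dist.probs.sum(axis=1), 1.0)

    def test_empty_set_rejected(self, u5):
        with pytest.raises(ValueError, match="empty"):
            position_frequencies([], u5)


class TestSKL:
    def test_identical_distributions_give_zero(self):
        p = np.array([0.3, 0.5, 0.2])
        assert skl_divergence(p, p) == pytest.approx(0.0)

    def test_frozen_hand_computed_value(self):
        """P=(1,0), Q=(.5,.5) with the 0.0001 increment: 6.6439 bits."""
        val = skl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert val == pytest.approx(6.643928320920272, rel=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6),
           st.lists(st.floats(0, 1), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=100)
    def test_symmetric_and_non_negative(self, p, q):
        p, q = np.array(p), np.array(q)
        v1, v2 = skl_divergence(p, q), skl_divergence(q, p)
        assert v1 == pytest.approx(v2, rel=1e-9, abs=1e-12)
        assert v1 >= -1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            skl_divergence(np.zeros(3), np.zeros(4))


class TestSKLControl:
    def test_null_case_mean_ratio_near_one(self, u5):
        """Case sets drawn from the reference population give phi ~ 1.

        A single case realization carries a chi-square-like sampling error
        that dominates phi, so the check averages over 30 independent case
        draws: the grand mean must sit in [0.8, 1.2] and every per-subsite
        mean within 3 SD of 1 for the observed spread.
        """
        from splicepairs.simulate import SiteFrequencyModel, generate_dataset
        model = SiteFrequencyModel()
        ratios: dict[str, list[float]] = {}
        for rep in range(30):
            ds = generate_dataset(model, 700, seed=4000 + rep)
            ref = class_matrix(ds.records[:500], u5)
            case = class_matrix(ds.records[500:], u5)
            res = skl_control_experiment(ref, case, iterations=300, seed=rep)
            for name, r in res.items():
                ratios.setdefault(name, []).append(r.mean_ratio)
        means = {k: np.mean(v) for k, v in ratios.items()}
        assert 0.8 < np.mean(list(means.values())) < 1.2
        for k, v in ratios.items():
            assert abs(means[k] - 1.0) < 3 * np.std(v) / np.sqrt(len(v)) + 0.05

    def test_injected_shift_raises_ratio_at_target_subsite(self, u5):
        """A frequency shift at exon -1 inflates phi at its subsite only."""
        from splicepairs.simulate import SiteFrequencyModel, generate_dataset
        ds = generate_dataset(SiteFrequencyModel(), 700, seed=43)
        ref = class_matrix(ds.records[:500], u5)
        # case: same population but exon -1 forced to A (breaks the G=C pair)
        import dataclasses
        case_records = [
            dataclasses.replace(r, junction11=r.junction11[:7] + "A"
                                + r.junction11[8:])
            for r in ds.records[500:]]
        cm = class_matrix(case_records, u5)
        res = skl_control_experiment(ref, cm, iterations=300, seed=7)
        shifted = res["exon_-2..-1"].mean_ratio
        untouched = [res[k].mean_ratio for k in res if k != "exon_-2..-1"]
        assert all(shifted > u for u in untouched)
        assert shifted > 5

    def test_determinism_and_length(self, u5, small_dataset):
        recs = small_dataset.records
        ref = class_matrix(recs[:150], u5)
        case = class_matrix(recs[150:200], u5)
        r1 = skl_control_experiment(ref, case, iterations=3, seed=9)
        r2 = skl_control_experiment(ref, case, iterations=3, seed=9)
        for name in r1:
            assert len(r1[name].case_values) == 3
            np.testing.assert_array_equal(r1[name].case_values,
                                          r2[name].case_values)
            np.testing.assert_array_equal(r1[name].control_values,
                                          r2[name].control_values)

    def test_reference_too_small_rejected(self, u5, small_dataset):
        recs = small_dataset.records
        ref = class_matrix(recs[:50], u5)
        case = class_matrix(recs[50:100], u5)
        with pytest.raises(ValueError, match="need >= 100"):
            skl_control_experiment(ref, case, iterations=2, seed=0)

    def test_default_subsites_u5_u6(self):
        names = [s.name for s in default_subsites("U5_loop1")]
        assert names == ["exon_-8..-6", "exon_-5..-3", "exon_-2..-1",
                         "exon_+1..+3"]
        assert len(default_subsites("U6_acagaga")) == 3


class TestBootstrap:
    def test_identical_groups_centre_at_zero(self, u5, small_dataset):
        recs = small_dataset.records[:100]
        res = bootstrap_differences(recs, recs, model=u5, iterations=400,
                                    seed=5)
        ph0 = res.p_h0
        defined = res.defined
        assert np.nanmax(np.abs(res.bd.mean(axis=0)[defined])) < 0.05
        # smaller-tail probability concentrates near its 0.5 maximum
        assert np.nanmedian(ph0[defined]) > 0.3

    def test_constant_difference_has_zero_p(self, u5):
        a = _records("G" * 30)
        b = _records("A" * 30)
        res = bootstrap_differences(a, b, model=u5, iterations=200, seed=1)
        bd = res.cell("exon:-1", "watson_crick")
        assert np.all(bd == 1.0)
        j = res.positions.index("exon:-1")
        assert res.p_h0[j, CLASS_ORDER.index("watson_crick")] == 0.0

    def test_resampled_frequencies_conserved(self, u5, small_dataset):
        """Class frequencies sum to 1 at every position in every resample."""
        a = small_dataset.records[:80]
        b = small_dataset.records[80:160]
        res = bootstrap_differences(a, b, model=u5, iterations=50, seed=2)
        assert np.allclose(res.bd.sum(axis=2), 0.0, atol=1e-12)

    def test_determinism(self, u5, small_dataset):
        a = small_dataset.records[:60]
        b = small_dataset.records[60:160]
        r1 = bootstrap_differences(a, b, model=u5, iterations=25, seed=77)
        r2 = bootstrap_differences(a, b, model=u5, iterations=25, seed=77)
        np.testing.assert_array_equal(r1.bd, r2.bd)

    def test_empty_group_rejected(self, u5, small_dataset):
        with pytest.raises(ValueError):
            bootstrap_differences([], small_dataset.records[:5], model=u5)

    def test_undefined_cell_masked(self, u5, small_dataset):
        res = bootstrap_differences(small_dataset.records[:50],
                                    small_dataset.records[50:100],
                                    model=u5, iterations=10, seed=0)
        j = res.positions.index("exon:-4")
        assert np.isnan(res.p_h0[j, CLASS_ORDER.index("non_isosteric")])
        with pytest.raises(ValueError, match="undefined"):
            res.cell("exon:-4", "non_isosteric")


class TestNucleotideBootstrap:
    def test_disjoint_compositions_give_extreme_bd(self, u5):
        a = _records("G" * 20)  # all G at -1; we test at exon:-1
        b = _records("C" * 20)
        res = nucleotide_bootstrap("exon:-1", a, b, model=u5,
                                   iterations=100, seed=3)
        g = res.bd[:, 2]  # A,C,G,U order
        c = res.bd[:, 1]
        assert np.all(g == 1.0) and np.all(c == -1.0)
        assert res.p_h0["G"] == 0.0 and res.p_h0["C"] == 0.0

    def test_identical_groups_near_half(self, u5, small_dataset):
        recs = small_dataset.records[:100]
        res = nucleotide_bootstrap("exon:-3", recs, recs, model=u5,
                                   iterations=400, seed=4)
        assert all(p > 0.2 for p in res.p_h0.values())

    def test_frequencies_sum_to_one_per_resample(self, u5, small_dataset):
        a = small_dataset.records[:50]
        b = small_dataset.records[50:100]
        res = nucleotide_bootstrap("exon:-3", a, b, model=u5,
                                   iterations=30, seed=6)
        assert np.allclose(res.bd.sum(axis=1), 0.0, atol=1e-12)

    def test_unknown_position_rejected(self, u5, small_dataset):
        with pytest.raises(ValueError, match="not covered"):
            nucleotide_bootstrap("exon:-99", small_dataset.records[:5],
                                 small_dataset.records[5:10], model=u5)


class TestDunnCorrection:
    @pytest.mark.parametrize("m, expected", [
        (28, 0.0018), (76, 0.0007), (31, 0.0016), (17, 0.0029),
        (20, 0.0025), (11, 0.0045), (1, 0.05),
    ])
    def test_alpha_prime_rounding(self, m, expected):
        assert dunn_threshold(m)[1] == expected

    def test_m_below_one_rejected(self):
        with pytest.raises(ValueError):
            dunn_threshold(0)

    @pytest.mark.parametrize("groups, expected", [
        ([(2, 1.0)], 1),                       # two perfectly correlated tests
        ([(3, 0.5)], 2),                       # (3+1)-[1+2*0.5] = 2
        ([(3, 0.5)] * 5 + [(2, 1.0)], 11),     # exon-end G experiment
        ([(3, 0.5)] * 6 + [(2, 1.0)] * 5, 17),  # intron -3C experiment
    ])
    def test_adjusted_m(self, groups, expected):
        assert adjusted_m(groups) == expected

    def test_invalid_R_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            adjusted_m([(3, 1.5)])

    def test_u6_plan_counts_17_tests(self, u6):
        plan = build_correction_plan(u6)
        assert plan.m == 17
        assert plan.m_prime == 11
        assert plan.alpha_prime == 0.0029
        assert plan.alpha_prime_adjusted == 0.0045

    def test_u5_plan_counts_28_tests(self, u5):
        plan = build_correction_plan(u5)
        assert plan.m == 28
        assert plan.m_prime == 17

    def test_u5_plan_with_nucleotide_tests(self, u5):
        plan = build_correction_plan(u5, extra_tests=[(4, 0.33)])
        assert plan.m == 32
        assert plan.m_prime == 20
        assert plan.alpha_prime_adjusted == 0.0025
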