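import itertools
import math

import numpy as np
import pytest

from karyoinfer import (ChromosomeProfile, ComputationError, KaryotypeProfile,
                        NoiseModel, RearrangementEvent, ValidationError,
                        apply_event, detect_fission_candidates,
                        detect_fusion_candidates, make_karyotype_from_table,
                        match_homologs, predict_hybrid, sample_plates,
                        score_mechanisms, segregation_expectation,
                        summarize_karyotype)
from karyoinfer.rearrangement import matching_cost


def make_profile(kid, rows, n=20):
    """rows: (label, rl_mean, rl_sd, ci_mean, ci_sd)."""
    from karyoinfer.morphometrics import classify_centromere
    chroms = tuple(
        ChromosomeProfile(label=lab, rl_mean=rl, rl_sd=rs, ci_mean=ci, ci_sd=cs,
                          n_metaphases=n,
                          centromere_class=classify_centromere(ci))
        for lab, rl, rs, ci, cs in rows)
    return KaryotypeProfile(karyotype_id=kid, chromosomes=chroms)


def random_profile(rng, kid, n_chrom):
    rl = rng.dirichlet(np.ones(n_chrom) * 5) * 100.0
    rows = [(str(i + 1), float(rl[i]), float(rng.uniform(0.3, 2.0)),
             float(rng.uniform(0, 50)), float(rng.uniform(0.3, 2.0)))
            for i in range(n_chrom)]
    return make_profile(kid, rows)


def brute_force_match(a, b, threshold):
    """Exhaustive-search oracle: minimum total capped cost over all
    one-to-one assignments, then dissolve over-threshold pairs."""
    cap = threshold * (1.0 + 1e-9)
    small, big, flip = (a, b, False) if len(a.chromosomes) <= len(b.chromosomes) \
        else (b, a, True)
    best, best_cost = None, math.inf
    for perm in itertools.permutations(range(len(big.chromosomes)),
                                       len(small.chromosomes)):
        cost = 0.0
        for i, j in enumerate(perm):
            ca, cb = small.chromosomes[i], big.chromosomes[j]
            cost += min(matching_cost(ca, cb) if not flip
                        else matching_cost(cb, ca), cap)
        if cost < best_cost - 1e-12:
            best_cost, best = cost, perm
    pairs = set()
    for i, j in enumerate(best):
        ca, cb = small.chromosomes[i], big.chromosomes[j]
        d = matching_cost(ca, cb) if not flip else matching_cost(cb, ca)
        if d <= threshold:
            pairs.add((cb.label, ca.label) if flip else (ca.label, cb.label))
    return pairs, best_cost


class TestMatchHomologs:
    def test_published_profiles_share_four_pairs(self, n5, n6, reference_matching):
        m = reference_matching
        assert {(pa, pb) for pa, pb, _ in m.pairs} == {
            ("4", "4"), ("5", "5"), ("6", "6"), ("7", "7")}
        assert m.unmatched_a == ("1",)
        assert set(m.unmatched_b) == {"2", "3"}
        assert all(d <= 3.0 for _, _, d in m.pairs)

    def test_identical_profiles_identity_matching(self, n6):
        m = match_homologs(n6, n6)
        assert all(pa == pb for pa, pb, _ in m.pairs)
        assert not m.unmatched_a and not m.unmatched_b
        assert all(d == 0.0 for _, _, d in m.pairs)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(20190611)
        for trial in range(100):
            na, nb = rng.integers(3, 7), rng.integers(3, 7)
            a = random_profile(rng, "a", int(na))
            b = random_profile(rng, "b", int(nb))
            threshold = float(rng.uniform(1.0, 6.0))
            m = match_homologs(a, b, threshold)
            got = {(pa, pb) for pa, pb, _ in m.pairs}
            expected, _ = brute_force_match(a, b, threshold)
            assert got == expected, f"trial {trial}"

    def test_labels_partition(self, n5, n6, reference_matching):
        m = reference_matching
        covered_a = {pa for pa, _, _ in m.pairs} | set(m.unmatched_a)
        covered_b = {pb for _, pb, _ in m.pairs} | set(m.unmatched_b)
        assert covered_a == set(n5.labels)
        assert covered_b == set(n6.labels)


class TestFusionDetection:
    def test_published_single_candidate(self, n5, n6, reference_matching):
        cands = detect_fusion_candidates(n5, n6, reference_matching, alpha=0.05)
        assert len(cands) == 1
        c = cands[0]
        assert c.component_labels == ("2", "3")
        assert c.product_label == "1"
        assert c.summed_rl == pytest.approx(29.54)
        assert c.product_rl == pytest.approx(29.48)
        assert c.p_value >= 0.05  # RL-sum equality not rejected
        assert abs(c.z_statistic) < 0.5

    def test_unrelated_profiles_no_candidate(self):
        a = make_profile("a", [("1", 60, 1, 45, 1), ("2", 40, 1, 40, 1)])
        b = make_profile("b", [("1", 80, 1, 45, 1), ("2", 15, 1, 10, 1),
                               ("3", 5, 1, 0, 1)])
        m = match_homologs(a, b, threshold=3.0)
        cands = detect_fusion_candidates(a, b, m, alpha=0.05)
        assert cands == []

    def test_equal_haploid_numbers_refused(self, n6):
        m = match_homologs(n6, n6)
        with pytest.raises(ValidationError, match="equal haploid"):
            detect_fusion_candidates(n6, n6, m)

    def test_needs_sample_sds(self, n5, n6, reference_matching):
        a1 = make_profile("n5", [(c.label, c.rl_mean, c.rl_sd, c.ci_mean, c.ci_sd)
                                 for c in n5.chromosomes], n=1)
        with pytest.raises(ComputationError, match="N < 2"):
            detect_fusion_candidates(a1, n6, reference_matching)

    def test_true_fused_pair_ranked_first_under_noise(self, n6):
        """Simulation with known truth: fusion applied, table-like noise."""
        truth6 = make_karyotype_from_table(n6)
        inv = RearrangementEvent("pericentric_inversion", ("2",),
                                 breakpoints=(0.95, 0.02))
        fus = RearrangementEvent("centric_fusion", ("2", "3"))
        truth5 = apply_event(apply_event(truth6, inv), fus, new_id="derived")
        p6 = summarize_karyotype(
            sample_plates(truth6, NoiseModel(seed=101)), "k6")
        p5 = summarize_karyotype(
            sample_plates(truth5, NoiseModel(seed=202)), "k5")
        m = match_homologs(p5, p6)
        cands = detect_fusion_candidates(p5, p6, m)
        assert cands and set(cands[0].component_labels) == {"2", "3"}
        assert cands[0].product_label == "2+3"


class TestFissionDetection:
    def _fission_pair(self, n6, extra=None):
        truth6 = make_karyotype_from_table(n6)
        ev = RearrangementEvent("fission", ("3",), split_fraction=0.55)
        truth7 = apply_event(truth6, ev, new_id="aberrant")
        if extra is not None:
            from karyoinfer.synthetic import TrueChromosome, TrueKaryotype
            chroms = tuple(c for c in truth7.chromosomes if c.label != "3b") + (
                TrueChromosome("x", 0.0, extra),)
            truth7 = TrueKaryotype("aberrant", chroms)
        return truth6, truth7

    def test_noise_free_split_recovered_exactly(self, n6):
        truth6, truth7 = self._fission_pair(n6)
        ref = summarize_karyotype(sample_plates(
            truth6, NoiseModel(rl_cv=0, arm_cv=0, n_metaphases=2)), "ref")
        ab = summarize_karyotype(sample_plates(
            truth7, NoiseModel(rl_cv=0, arm_cv=0, n_metaphases=2)), "ab")
        m = match_homologs(ab, ref)
        cands = detect_fission_candidates(ab, ref, m)
        assert cands
        top = cands[0]
        assert set(top.component_labels) == {"3a", "3b"}
        assert top.product_label == "3"
        assert top.z_statistic == pytest.approx(0.0, abs=1e-9)
        assert top.event_type == "fission"
        assert top.mechanism_scores == ()

    def test_noisy_split_ranked_first(self, n6):
        truth6, truth7 = self._fission_pair(n6)
        ref = summarize_karyotype(sample_plates(truth6, NoiseModel(seed=7)), "ref")
        ab = summarize_karyotype(sample_plates(truth7, NoiseModel(seed=8)), "ab")
        m = match_homologs(ab, ref)
        cands = detect_fission_candidates(ab, ref, m)
        assert cands and set(cands[0].component_labels) == {"3a", "3b"}

    def test_unrelated_extra_chromosome_yields_nothing(self, n6):
        # replace the small fragment by an element of unrelated size: the
        # remaining unmatched pair cannot reconstitute the acrocentric
        truth6, truth7 = self._fission_pair(n6, extra=1.0)
        # renormalise: RL sums must stay near 100 for profile validity
        from karyoinfer.synthetic import TrueChromosome, TrueKaryotype
        scale = truth6.total_length / truth7.total_length
        truth7 = TrueKaryotype("aberrant", tuple(
            TrueChromosome(c.label, c.short_arm * scale, c.long_arm * scale)
            for c in truth7.chromosomes))
        ref = summarize_karyotype(sample_plates(
            truth6, NoiseModel(rl_cv=0, arm_cv=0, n_metaphases=2)), "ref")
        ab = summarize_karyotype(sample_plates(
            truth7, NoiseModel(rl_cv=0, arm_cv=0, n_metaphases=2)), "ab")
        m = match_homologs(ab, ref)
        assert detect_fission_candidates(ab, ref, m, alpha=0.05) == []


class TestScoreMechanisms:
    def test_published_components_prefer_centric_fusion(self, n5, n6):
        comp2, comp3 = n6.chromosome("2"), n6.chromosome("3")
        product = n5.chromosome("1")
        scores = score_mechanisms(comp2, comp3, product)
        by_name = {s.mechanism: s for s in scores}
        assert by_name["centric_fusion_with_pericentric_inversion"].predicted_ci == \
            pytest.approx(100 * 12.86 / 29.54, abs=0.01)
        assert by_name["tandem_fusion_onto_long_arm"].predicted_ci == \
            pytest.approx(25.66, abs=0.01)
        assert by_name["tandem_fusion_onto_short_arm"].predicted_ci == \
            pytest.approx(30.80, abs=0.01)
        assert scores[0].mechanism == "centric_fusion_with_pericentric_inversion"

    def test_equal_acrocentrics_fuse_to_metacentric(self):
        acro = ChromosomeProfile("a", 25.0, 1.0, 0.0, 0.0, 20, "acrocentric")
        acro2 = ChromosomeProfile("b", 25.0, 1.0, 0.0, 0.0, 20, "acrocentric")
        prod = ChromosomeProfile("p", 50.0, 1.0, 50.0, 1.0, 20, "metacentric")
        scores = score_mechanisms(acro, acro2, prod)
        centric = scores[0]
        assert centric.mechanism == "centric_fusion_with_pericentric_inversion"
        assert centric.predicted_ci == pytest.approx(50.0)
        # tandem attachments onto a telocentric degenerate to one entry
        assert len(scores) == 2

    def test_zero_deviation_ranks_first(self, n6):
        comp2, comp3 = n6.chromosome("2"), n6.chromosome("3")
        ci = 100 * 12.86 / (16.68 + 12.86)
        prod = ChromosomeProfile("p", 29.54, 1.0, ci, 1.0, 20, "metacentric")
        scores = score_mechanisms(comp2, comp3, prod)
        assert scores[0].abs_deviation == pytest.approx(0.0, abs=1e-9)
        assert scores[0].mechanism == "centric_fusion_with_pericentric_inversion"

    def test_invariant_to_component_order(self, n5, n6):
        comp2, comp3 = n6.chromosome("2"), n6.chromosome("3")
        product = n5.chromosome("1")
        s1 = score_mechanisms(comp2, comp3, product)
        s2 = score_mechanisms(comp3, comp2, product)
        assert s1 == s2


class TestHybrid:
    def test_published_hybrid_has_eleven_chromosomes(self, n5, n6, reference_matching):
        h = predict_hybrid(n5, n6, reference_matching)
        assert h.total_count == 11
        assert len(h.paired) == 4
        assert len(h.singletons) == 3

    def test_identical_parents_fully_paired(self, n6):
        m = match_homologs(n6, n6)
        h = predict_hybrid(n6, n6, m)
        assert h.total_count == 12
        assert len(h.paired) == 6
        assert h.singletons == ()

    def test_disjoint_parents_all_singletons(self):
        a = make_profile("a", [("1", 70, 1, 45, 1), ("2", 30, 1, 5, 1)])
        b = make_profile("b", [("1", 55, 1, 20, 1), ("2", 25, 1, 49, 1),
                               ("3", 20, 1, 35, 1)])
        m = match_homologs(a, b, threshold=0.5)
        h = predict_hybrid(a, b, m)
        assert len(h.paired) == 0
        assert h.total_count == 5 == len(h.singletons)

    def test_conserves_chromosome_number(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_profile(rng, "a", int(rng.integers(2, 8)))
            b = random_profile(rng, "b", int(rng.integers(2, 8)))
            m = match_homologs(a, b, threshold=float(rng.uniform(0.5, 5)))
            h = predict_hybrid(a, b, m)
            assert h.total_count == a.haploid_number + b.haploid_number


class TestSegregation:
    def test_expected_equal_classes(self, n5, n6, reference_matching):
        h = predict_hybrid(n5, n6, reference_matching)
        res = segregation_expectation(h, 46, seed=1)
        assert res["classes"]["n=5"]["expected"] == 23.0
        assert res["classes"]["n=6"]["expected"] == 23.0
        sim = [v["simulated"] for v in res["classes"].values()]
        assert sum(sim) == 46

    def test_zero_offspring(self, n5, n6, reference_matching):
        h = predict_hybrid(n5, n6, reference_matching)
        res = segregation_expectation(h, 0, seed=1)
        assert sum(v["simulated"] for v in res["classes"].values()) == 0

    def test_large_sample_close_to_half(self, n5, n6, reference_matching):
        h = predict_hybrid(n5, n6, reference_matching)
        res = segregation_expectation(h, 10000, seed=3)
        frac = res["classes"]["n=5"]["simulated"] / 10000
        assert abs(frac - 0.5) <= 3 * math.sqrt(0.25 / 10000)

    def test_requires_fusion_trio(self, n6):
        m = match_homologs(n6, n6)
        h = predict_hybrid(n6, n6, m)
        with pytest.raises(ComputationError, match="fusion trio"):
            segregation_expectation(h, 10, seed=1)
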