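import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyaslide.sliding_sim import (
    MrnaTemplate,
    RibosomeState,
    SlidingParams,
    allowed_slide_offsets,
    encoded_lysine_count,
    exact_category_probabilities,
    exact_distribution,
    find_a_runs,
    simulate_ensemble,
    simulate_ribosome,
    step_rates,
)
from polyaslide.synthetic_data import build_reporter_mrna

MK_A2 = build_reporter_mrna(codons=("AAA", "AAA"), flank_style="minimal")


def elongating_state(a_site_nt, last_lys=False, start=0):
    return RibosomeState(
        a_site_nt=a_site_nt, peptide=["M"], last_aa_lysine=last_lys,
        start_index=start,
    )


class TestFindARuns:
    def test_minimal_message(self):
        runs = find_a_runs("ATGTTCTAA")
        assert runs[0] == (0, 1)  # the A of ATG; caller filters by min_A_run

    def test_a12_insert(self):
        assert (3, 12) in find_a_runs("ATG" + "A" * 12 + "TAA")

    @settings(max_examples=150, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=60))
    def test_matches_regex_oracle(self, seq):
        expected = [(m.start(), len(m.group())) for m in re.finditer("A+", seq)]
        assert find_a_runs(seq) == expected


class TestAllowedSlideOffsets:
    def test_run_start_geometry(self):
        # A site on the first codon of a 6-A run: forward placements only
        mrna = MrnaTemplate("ATG" + "A" * 6 + "TAA")
        params = SlidingParams()
        assert allowed_slide_offsets(elongating_state(3), mrna, params) == [1, 2, 3]

    def test_below_threshold_empty(self):
        mrna = MrnaTemplate("ATG" + "A" * 6 + "TAA")
        params = SlidingParams(min_A_run=7)
        assert allowed_slide_offsets(elongating_state(3), mrna, params) == []

    def test_p_site_contact_allows_backward_slide(self):
        # paused at the stop of the MK_A2 message: P-site codon is in the run
        offsets = allowed_slide_offsets(elongating_state(9), MK_A2, SlidingParams())
        assert offsets == [-6, -5, -4, -3]

    def test_enumeration_matches_brute_force(self, rng):
        params = SlidingParams()
        for _ in range(50):
            seq = "ATG" + "".join(rng.choice(list("ACGT"), size=30)) + "TAATAA"
            try:
                mrna = MrnaTemplate(seq)
            except ValueError:
                continue
            for a in range(3, len(seq) - 3, 1):
                got = allowed_slide_offsets(elongating_state(a), mrna, params)
                runs = [
                    (m.start(), m.end()) for m in re.finditer("A+", seq)
                    if m.end() - m.start() >= params.min_A_run
                ]
                touching = [
                    (s, e) for s, e in runs
                    if s < a + 3 and e > max(a - 3, 0)
                ]
                expected = sorted(
                    {
                        p - a
                        for s, e in touching
                        for p in range(s, e - 2)
                        if p != a
                    }
                )
                assert got == expected


class TestStepRates:
    def test_fast_codon(self):
        mrna = MrnaTemplate("ATGTTCTAA")
        rates = step_rates(elongating_state(3), mrna, SlidingParams())
        assert rates == {"ELONGATE": 12.0}

    def test_stop_without_release_factors_is_frozen(self):
        mrna = MrnaTemplate("ATGTTCTAA")
        rates = step_rates(elongating_state(6), mrna, SlidingParams(k_term=0.0))
        assert rates == {}

    def test_slow_gate_needs_long_lysine_run_and_lysyl_peptide(self):
        mrna = MrnaTemplate("ATG" + "AAA" * 5 + "TAA")  # MK_A5
        params = SlidingParams()
        slow = step_rates(elongating_state(6, last_lys=True), mrna, params)
        assert slow["ELONGATE"] == params.k_slow_AAA
        # first lysine after a non-lysine is fast even in the long run
        fast = step_rates(elongating_state(6, last_lys=False), mrna, params)
        assert fast["ELONGATE"] == params.k_fast
        # di-lysine context stays fast regardless of peptide state
        rates2 = step_rates(elongating_state(6, last_lys=True), MK_A2, params)
        assert rates2["ELONGATE"] == params.k_fast

    def test_aag_slow_rate_on_iterated_aag(self):
        mrna = MrnaTemplate("ATG" + "AAG" * 5 + "TAA")
        params = SlidingParams()
        rates = step_rates(elongating_state(6, last_lys=True), mrna, params)
        assert rates["ELONGATE"] == params.k_slow_AAG

    def test_slide_rate_scales_with_offset_count(self):
        mrna = MrnaTemplate("ATG" + "A" * 12 + "TAA")
        params = SlidingParams()
        state = elongating_state(6, last_lys=True)
        offsets = allowed_slide_offsets(state, mrna, params)
        rates = step_rates(state, mrna, params)
        assert rates["SLIDE"] == pytest.approx(params.k_slide_unit * len(offsets))

    def test_k_next_override_blocks_post_run_codon(self):
        mrna = MrnaTemplate("ATG" + "AAA" * 2 + "TTCTAA")  # MK_A2F
        params = SlidingParams(k_next=0.0)
        rates = step_rates(elongating_state(9, last_lys=True), mrna, params)
        assert "ELONGATE" not in rates


class TestSimulateRibosome:
    def test_plain_elongation_without_a_runs(self):
        mrna = MrnaTemplate("ATGTTCGGTGAATAA")
        params = SlidingParams(k_term=10.0, seed=4)
        res = simulate_ribosome(mrna, params)
        assert res.state.status == "released"
        assert res.state.a_site_nt == mrna.annotated_stop_index
        assert res.state.frame_offset == 0
        assert "".join(res.state.peptide) == "MFGE"

    def test_k_slide_zero_reproduces_deterministic_elongation(self):
        mrna = build_reporter_mrna(poly_a=12, flank_style="mcherry_like")
        params = SlidingParams(k_slide_unit=0.0, k_term=5.0, t_max=1e7, seed=0)
        res = simulate_ribosome(mrna, params)
        assert res.n_slides == 0
        assert res.state.frame_offset == 0
        assert res.state.status == "released"
        assert res.state.lysines_added == encoded_lysine_count(mrna)

    def test_frame_offset_invariant_over_event_log(self):
        params = SlidingParams(k_term=1.0, seed=11, t_max=300.0)
        for i in range(20):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=3, spawn_key=(i,))
            )
            res = simulate_ribosome(MK_A2, params, rng=rng)
            for _t, _event, a, frame in res.events:
                assert frame == (a - MK_A2.start_index) % 3

    def test_majority_extended_on_mk_a2_lys_only(self):
        # iterated-AAA di-lysine message, lysine-only conditions: most
        # trajectories gain at least four lysines by sliding backwards
        params = SlidingParams(k_term=0.0, k_next=0.0, seed=5)
        n = 300
        n4 = 0
        for i in range(n):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=5, spawn_key=(i,))
            )
            res = simulate_ribosome(MK_A2, params, rng=rng)
            if res.state.lysines_added >= 4:
                n4 += 1
        assert n4 / n > 0.5


class TestSimulateEnsemble:
    def test_no_qualifying_run_all_full_length(self):
        mrna = MrnaTemplate("ATGTTCGGTGAATAA")
        summ = simulate_ensemble(mrna, SlidingParams(k_term=10.0, seed=0), 500)
        assert summ.fraction_full_length == 1.0
        assert summ.fraction_extended == 0.0

    def test_same_seed_reproducible(self):
        params = SlidingParams(k_term=0.05, k_next=0.0, seed=9, t_max=300.0)
        a = simulate_ensemble(MK_A2, params, 200)
        b = simulate_ensemble(MK_A2, params, 200)
        assert a == b

    def test_category_fractions_sum_to_one(self):
        params = SlidingParams(k_term=0.05, k_next=0.0, seed=9, t_max=300.0)
        s = simulate_ensemble(MK_A2, params, 300)
        assert (
            s.fraction_full_length + s.fraction_truncated_oof + s.fraction_stalled
        ) == pytest.approx(1.0, abs=1e-12)

    def test_competition_suppresses_extension(self):
        # downstream factors at normal-elongation scale collapse the
        # extended population (release wins over sliding at the stop)
        lys_only = SlidingParams(k_term=0.0, k_next=0.0, seed=2)
        with_rf = SlidingParams(k_term=12.0, k_next=0.0, seed=2)
        n = 400
        ext0 = simulate_ensemble(MK_A2, lys_only, n).fraction_extended
        ext1 = simulate_ensemble(MK_A2, with_rf, n).fraction_extended
        se = 3 * np.sqrt(0.25 / n)
        assert ext1 <= ext0 - 0.4  # a collapse, not a nudge
        assert ext1 <= 0.05 + se

    def test_truncation_nondecreasing_in_run_length(self):
        params = lambda: SlidingParams(k_term=12.0, seed=6)
        n = 2000
        fracs = []
        for L in (9, 10, 11, 13):
            rep = build_reporter_mrna(poly_a=L, flank_style="mcherry_like")
            fracs.append(simulate_ensemble(rep, params(), n).fraction_truncated_oof)
        for lo, hi in zip(fracs, fracs[1:]):
            se = np.sqrt(max(lo * (1 - lo), hi * (1 - hi), 1e-4) / n)
            assert hi >= lo - 3 * se


class TestExactDistribution:
    def test_t_zero_unit_mass(self):
        dist = exact_distribution(MK_A2, SlidingParams(seed=0), t=0.0)
        assert dist == {(3, False, 0, "elongating"): 1.0}

    def test_single_event_closed_form(self):
        # ATG then immediate in-frame stop: release is one exponential event
        mrna = MrnaTemplate("ATGTAA")
        k = 0.7
        t = 1.3
        probs = exact_category_probabilities(
            mrna, SlidingParams(k_term=k, seed=0), t=t
        )
        assert probs["full_length"] == pytest.approx(1 - np.exp(-k * t), abs=1e-8)

    def test_probabilities_sum_to_one(self):
        params = SlidingParams(k_term=0.01, k_next=0.0, seed=0, t_max=600.0)
        dist = exact_distribution(MK_A2, params)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_gillespie_matches_exact_ctmc(self):
        params = SlidingParams(
            k_term=0.01, k_next=0.0, k_slide_unit=0.002, seed=7, t_max=600.0
        )
        exact = exact_category_probabilities(MK_A2, params)
        n = 4000
        summ = simulate_ensemble(MK_A2, params, n)
        for key, sim in [
            ("full_length", summ.fraction_full_length),
            ("truncated_oof", summ.fraction_truncated_oof),
            ("stalled", summ.fraction_stalled),
            ("extended", summ.fraction_extended),
        ]:
            p = exact[key]
            se = max(np.sqrt(p * (1 - p) / n), 1.0 / n)
            assert abs(sim - p) <= 3 * se

    def test_state_space_cap(self):
        big = build_reporter_mrna(poly_a=13, flank_style="mcherry_like")
        with pytest.raises(ValueError, match="cap"):
            exact_distribution(big, SlidingParams(seed=0), max_states=10)


class TestTemplateValidation:
    def test_requires_atg_and_stop(self):
        with pytest.raises(ValueError):
            MrnaTemplate("TTGAAATAA")
        with pytest.raises(ValueError):
            MrnaTemplate("ATGAAATAA", annotated_stop_index=3)

    def test_out_of_frame_stop_index_rejected(self):
        with pytest.raises(ValueError):
            MrnaTemplate("ATGCTAAGGTAA", annotated_stop_index=4)

    def test_encoded_lysines(self):
        assert encoded_lysine_count(MK_A2) == 2
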