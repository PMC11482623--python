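"""Stochastic library-prep model: overhangs, pairing, switching, concatemers."""

import numpy as np
import pytest
from scipy import stats

from rtswitch.switchsim import (
    TSO,
    SwitchParams,
    cross_hybridization_check,
    emit_fasta,
    library_efficiency,
    pairing_score,
    parse_truth_header,
    sample_concatemers,
    sample_nta_overhang,
    simulate_library,
    switch_probability,
)


def _overhang_sample(params, n, seed=0):
    rng = np.random.Generator(np.random.Philox(seed))
    from rtswitch.switchsim import _sample_overhangs

    return _sample_overhangs(params, n, rng)


class TestOverhangSampling:
    def test_pure_datp_gives_poly_a(self, default_params):
        params = default_params.model_copy(update={
            "incorporation_rate": {"A": 0.19, "G": 0.0, "C": 0.0, "T": 0.0}})
        draws = _overhang_sample(params, 2000, seed=1)
        assert all(set(o) <= {"A"} for o in draws)

    def test_triple_a_is_modal_trimer_under_biased_mix(self, default_params):
        """With measured rates and the biased mix, AAA dominates 3-mers."""
        draws = _overhang_sample(default_params, 100_000, seed=2)
        trimers = [o for o in draws if len(o) == 3]
        values, counts = np.unique(trimers, return_counts=True)
        assert values[counts.argmax()] == "AAA"

    def test_first_position_frequencies_match_competition_formula(
            self, default_params):
        """Empirical base frequencies agree with rate x conc competition."""
        n = 1_000_000
        draws = _overhang_sample(default_params, n, seed=3)
        nonempty = [o for o in draws if o]
        probs, bases = default_params.base_probabilities()
        first = np.array([o[0] for o in nonempty])
        m = len(nonempty)
        for p, b in zip(probs, bases):
            obs = (first == b).mean()
            sigma = np.sqrt(p * (1 - p) / m)
            assert abs(obs - p) < 3 * sigma + 1e-9

    def test_all_rates_zero_rejected(self, default_params):
        params = default_params.model_copy(update={
            "incorporation_rate": {b: 0.0 for b in "ACGT"}})
        with pytest.raises(ValueError):
            sample_nta_overhang(params, 0)

    def test_seeded_reproducibility(self, default_params):
        assert sample_nta_overhang(default_params, 42) == sample_nta_overhang(
            default_params, 42)


class TestPairingScore:
    def test_perfect_watson_crick_triple(self, default_params):
        assert pairing_score("AAA", "UUU", default_params) == 1.0

    def test_non_pairing_tso_scores_zero(self, default_params):
        assert pairing_score("AAA", "CAC", default_params) == 0.0

    def test_single_wobble_equals_weight(self, default_params):
        assert pairing_score("G", "U", default_params) == pytest.approx(
            default_params.pair_weight["GU_wobble"])

    def test_empty_overhang_cannot_anneal(self, default_params):
        assert pairing_score("", "UUU", default_params) == 0.0

    def test_invalid_characters_rejected(self, default_params):
        with pytest.raises(ValueError):
            pairing_score("AXA", "UUU", default_params)


class TestSwitchProbability:
    def test_hydroxyl_reference(self, default_params, blocked_tso):
        assert switch_probability("AAA", blocked_tso, "hydroxyl",
                                  default_params) == pytest.approx(0.35)

    def test_cap_penalty(self, default_params, blocked_tso):
        assert switch_probability("AAA", blocked_tso, "m7G",
                                  default_params) == pytest.approx(0.10)

    def test_mismatch_gates_to_zero(self, default_params, blocked_tso):
        assert switch_probability("CCC", blocked_tso, "hydroxyl",
                                  default_params) == 0.0

    def test_unknown_modification_rejected(self, default_params, blocked_tso):
        with pytest.raises(ValueError):
            switch_probability("AAA", blocked_tso, "capped", default_params)

    def test_modification_ordering_over_random_parameterizations(self):
        """hydroxyl >= triphosphate >= m7G for any pairing and base level."""
        rng = np.random.default_rng(99)
        tso = TSO("CCCUUU", "RNA")
        for _ in range(20):
            tri = rng.uniform(0.2, 1.0)
            cap = rng.uniform(0.05, tri)
            params = SwitchParams(
                base_switch_eff=rng.uniform(0.05, 0.9),
                mod_penalty={"hydroxyl": 1.0, "triphosphate": tri, "m7G": cap},
                pair_weight={"AT_AU": 1.0, "GC": 1.0,
                             "GU_wobble": rng.uniform(0.0, 0.5),
                             "mismatch": 0.0},
            )
            for overhang in ("AAA", "AA", "G"):
                p_oh = switch_probability(overhang, tso, "hydroxyl", params)
                p_tp = switch_probability(overhang, tso, "triphosphate", params)
                p_cap = switch_probability(overhang, tso, "m7G", params)
                assert p_oh >= p_tp >= p_cap


class TestConcatemers:
    def test_blocked_tso_always_single_copy(self, default_params, blocked_tso):
        assert all(sample_concatemers(default_params, blocked_tso, s) == 1
                   for s in range(50))

    def test_no_reswitching(self, unblocked_tso, default_params):
        params = default_params.model_copy(update={"reswitch_prob": 0.0})
        assert all(sample_concatemers(params, unblocked_tso, s) == 1
                   for s in range(50))

    def test_geometric_mean(self, unblocked_tso, default_params):
        params = default_params.model_copy(update={"reswitch_prob": 0.5})
        rng = np.random.Generator(np.random.Philox(7))
        draws = rng.geometric(1 - params.reswitch_prob, size=100_000)
        # sanity of the law the simulator uses: mean 1/(1-p) = 2
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.0) < 3 * se

    def test_geometric_goodness_of_fit(self, unblocked_tso, default_params):
        """Concatemer counts follow the geometric law (chi-square, alpha=0.01)."""
        p = 0.4
        params = default_params.model_copy(update={"reswitch_prob": p})
        counts = np.array([sample_concatemers(params, unblocked_tso, s)
                           for s in range(20_000)])
        kmax = 8
        observed = np.array([(counts == k).sum() for k in range(1, kmax)]
                            + [(counts >= kmax).sum()])
        probs = np.array([(1 - p) * p ** (k - 1) for k in range(1, kmax)]
                         + [p ** (kmax - 1)])
        chi2 = ((observed - counts.size * probs) ** 2
                / (counts.size * probs)).sum()
        crit = stats.chi2.ppf(0.99, df=len(observed) - 1)
        assert chi2 < crit


class TestSimulateLibrary:
    def test_forced_switch_blocked_tso(self, small_ladder, blocked_tso):
        params = SwitchParams(
            base_switch_eff=1.0,
            step_continuation=(1.0, 1.0, 1.0),
            incorporation_rate={"A": 1.0, "G": 0.0, "C": 0.0, "T": 0.0},
        )
        reads = simulate_library(small_ladder, params, blocked_tso, 2000,
                                 seed=4)
        assert all(r.n_tso_copies == 1 for r in reads)

    def test_draw_proportions_follow_concentrations(self, default_params,
                                                    blocked_tso):
        from rtswitch.quantify import TranscriptLadder

        ladder = TranscriptLadder(["hi", "lo"], [1000, 1000], [9.0, 1.0],
                                  ["ercc_like"] * 2)
        n = 100_000
        reads = simulate_library(ladder, default_params, blocked_tso, n, seed=5)
        n_hi = sum(r.transcript_id == "hi" for r in reads)
        sigma = np.sqrt(0.9 * 0.1 * n)
        assert abs(n_hi - 0.9 * n) < 3 * sigma

    def test_non_pairing_tso_yields_zero_efficiency(self, small_ladder,
                                                    default_params):
        # pure-dATP overhangs against a 3'-CAC end: every register mismatches
        params = default_params.model_copy(update={
            "incorporation_rate": {"A": 0.19, "G": 0.0, "C": 0.0, "T": 0.0}})
        tso = TSO("UUUCAC", "RNA")
        reads = simulate_library(small_ladder, params, tso, 20_000,
                                 seed=6)
        assert all(r.n_tso_copies == 0 for r in reads)
        assert library_efficiency(reads) == 0.0

    def test_identical_seed_identical_library(self, small_ladder,
                                              default_params, blocked_tso):
        a = simulate_library(small_ladder, default_params, blocked_tso, 5000,
                             seed=8)
        b = simulate_library(small_ladder, default_params, blocked_tso, 5000,
                             seed=8)
        assert a == b

    def test_realized_efficiency_converges_to_mean_probability(
            self, small_ladder, default_params, blocked_tso):
        """Library efficiency concentrates around E[switch probability]."""
        n = 200_000
        reads = simulate_library(small_ladder, default_params, blocked_tso, n,
                                 seed=9)
        # analytic mean switch probability under the default params
        probs, bases = default_params.base_probabilities()
        cont = default_params.step_continuation
        len_probs = {0: 1 - cont[0], 1: cont[0] * (1 - cont[1]),
                     2: cont[0] * cont[1] * (1 - cont[2]),
                     3: cont[0] * cont[1] * cont[2]}
        # per-position expected pair weight: A pairs fully with the TSO's
        # 3' T, G makes a wobble, C/T mismatch; positions are independent
        p = dict(zip(bases, probs))
        w = p["A"] * 1.0 + p["G"] * default_params.pair_weight["GU_wobble"]
        expected = 0.35 * sum(len_probs[m] * w ** m for m in (1, 2, 3))
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(library_efficiency(reads) - expected) < 4 * sigma

    def test_efficiency_monotone_in_datp_concentration(self, small_ladder,
                                                       blocked_tso):
        effs = []
        for datp in (0.1, 0.5, 2.0):
            params = SwitchParams(dntp_conc={"A": datp, "G": 0.4, "C": 0.4,
                                             "T": 0.4})
            reads = simulate_library(small_ladder, params, blocked_tso,
                                     50_000, seed=10)
            effs.append(library_efficiency(reads))
        assert effs[0] < effs[1] < effs[2]

    def test_five_prime_mod_ordering(self, small_ladder, default_params,
                                     blocked_tso):
        effs = [library_efficiency(simulate_library(
            small_ladder, default_params, blocked_tso, 50_000, seed=11,
            template_5mod=mod)) for mod in ("hydroxyl", "triphosphate", "m7G")]
        assert effs[0] > effs[1] > effs[2]

    def test_empty_ladder_rejected(self, default_params, blocked_tso):
        from rtswitch.quantify import TranscriptLadder

        with pytest.raises(ValueError):
            ladder = TranscriptLadder([], [], [], [])
            simulate_library(ladder, default_params, blocked_tso, 10, seed=0)


class TestCrossHybridization:
    def test_ct_only_design_cannot_pair(self):
        tso = TSO("CTCCTCTTCCTCCTCTTT", "DNA")
        assert cross_hybridization_check("TTCTCCTCTT", tso) == 0

    def test_oligo_dt_against_poly_a_tail(self):
        tso = TSO("CCC" + "A" * 10, "DNA")
        assert cross_hybridization_check("T" * 18, tso) == 10

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_scan(self, seed):
        """DP result equals the exhaustive all-offsets complementary scan."""
        rng = np.random.default_rng(seed)
        bases = np.array(list("ACGT"))
        primer = "".join(rng.choice(bases, 30))
        tso_seq = "".join(rng.choice(bases, 30))
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp[b] for b in reversed(tso_seq))
        best = 0
        for i in range(len(primer)):
            for j in range(len(rc)):
                run = 0
                while (i + run < len(primer) and j + run < len(rc)
                       and primer[i + run] == rc[j + run]):
                    run += 1
                best = max(best, run)
        assert cross_hybridization_check(primer, TSO(tso_seq, "DNA")) == best


class TestFastaEmission:
    def test_empty_read_list(self, small_ladder, blocked_tso):
        assert emit_fasta([], small_ladder, blocked_tso, "T" * 18) == ""

    def test_blocked_tso_single_occurrence(self, small_ladder, blocked_tso):
        from rtswitch.switchsim import ReadRecord

        reads = [ReadRecord("tx1", 500, "AAA", 1, "hydroxyl")]
        fasta = emit_fasta(reads, small_ladder, blocked_tso, "T" * 18)
        seq = "".join(fasta.splitlines()[1:])
        rc_tso = "AAAGAGGAGGAAGAGGAG"
        assert seq.count(rc_tso) == 1

    def test_truth_table_round_trip(self, small_ladder, default_params,
                                    blocked_tso, tmp_path):
        from rtswitch.io import read_fasta

        reads = simulate_library(small_ladder, default_params, blocked_tso,
                                 100, seed=12)
        path = tmp_path / "lib.fa"
        path.write_text(emit_fasta(reads, small_ladder, blocked_tso, "T" * 18))
        parsed = [parse_truth_header(h) for h, _ in read_fasta(path)]
        assert parsed == [(r.transcript_id, r.n_tso_copies, r.template_5mod)
                          for r in reads]

    def test_unresolvable_id_rejected(self, small_ladder, blocked_tso):
        from rtswitch.switchsim import ReadRecord

        reads = [ReadRecord("nope", 500, "AAA", 1, "hydroxyl")]
        with pytest.raises(KeyError):
            emit_fasta(reads, small_ladder, blocked_tso, "T" * 18)
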