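"""Expectation scoring, site scanning vs the exhaustive oracle, and UPE."""

import numpy as np
import pytest

from hairpinhunter.core_io import reverse_complement_rna
from hairpinhunter.folding import EnergyModel
from hairpinhunter.targets import (
    DEFAULT_SCHEME,
    ExpectationScheme,
    compute_upe,
    find_target_sites,
    score_duplex,
    score_expectation,
)

COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
MATURE = "UGGAGCUCCCUUCAUUCCAAU"  # 21 nt


def perfect_site(mature):
    return reverse_complement_rna(mature)


def non_pairing_base(partner):
    """A base that neither pairs nor wobbles with *partner*."""
    return next(
        b for b in "ACGU" if b != COMP[partner] and {b, partner} != {"G", "U"}
    )


def mutate_site(mature, positions_1based, wobble=()):
    """Site with mismatches (or wobbles) facing the given mature positions."""
    site = list(perfect_site(mature))
    L = len(mature)
    for pos in positions_1based:
        idx = L - pos  # site index facing mature position pos
        m = mature[pos - 1]
        if pos in wobble:
            site[idx] = "U" if m == "G" else "G"
        else:
            site[idx] = non_pairing_base(m)
    return "".join(site)


class TestExpectationScoring:
    def test_perfect_complement_scores_zero(self):
        assert score_expectation(MATURE, perfect_site(MATURE)) == 0.0

    def test_core_wobble_counts_double(self):
        # G:U at mature position 5 (inside the 2-13 core): 0.5 * 2
        assert MATURE[4] == "G"
        site = mutate_site(MATURE, [5], wobble=[5])
        assert score_expectation(MATURE, site) == pytest.approx(1.0)

    def test_non_core_mismatch_single_weight(self):
        site = mutate_site(MATURE, [20])
        assert score_expectation(MATURE, site) == pytest.approx(1.0)

    def test_core_mismatch_double_weight(self):
        site = mutate_site(MATURE, [7])
        assert score_expectation(MATURE, site) == pytest.approx(2.0)

    def test_bulged_site_costs_gap_penalty(self):
        site = perfect_site(MATURE)
        # insert a bulged nucleotide mid-site (non-core side of the duplex)
        bulged = site[:3] + "A" + site[3:]
        exp = score_expectation(MATURE, bulged)
        assert exp >= DEFAULT_SCHEME.gap
        d = score_duplex(MATURE, bulged)
        assert d.gap_mature_pos is not None
        assert "-" in d.mature_aln

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            score_expectation("", "ACGU")

    def test_incompatible_lengths_rejected(self):
        with pytest.raises(ValueError):
            score_expectation(MATURE, perfect_site(MATURE)[:-3])

    def test_core_rescaling_for_short_matures(self):
        # 15-nt mature: core 2-13 rescales to round(2*15/21)..round(13*15/21)
        scheme = DEFAULT_SCHEME
        assert scheme.core_range(21) == (2, 13)
        assert scheme.core_range(15) == (1, 9)
        assert scheme.central_range(21) == (9, 11)
        assert scheme.central_range(15) == (6, 8)

    def test_reversal_invariance(self):
        # scoring is invariant under reversing both strands when the
        # position-weight map is reversed too (ungapped alignments)
        rng = np.random.default_rng(8)
        L = 21
        lo, hi = DEFAULT_SCHEME.core_range(L)
        rev_scheme = ExpectationScheme(core_span=(L + 1 - hi, L + 1 - lo), ref_len=L)
        for _ in range(25):
            m = "".join(rng.choice(list("ACGU"), size=L))
            s = "".join(rng.choice(list("ACGU"), size=L))
            fwd = score_expectation(m, s)
            rev = score_expectation(m[::-1], s[::-1], rev_scheme)
            assert fwd == pytest.approx(rev)


def exhaustive_site_oracle(mature, transcript, cutoff, scheme=DEFAULT_SCHEME):
    """Score every window of every permitted length; no collapsing."""
    L, n = len(mature), len(transcript)
    out = {}
    for o in range(n):
        for Ls in (L - 1, L, L + 1):
            if Ls >= 1 and o + Ls <= n:
                d = score_duplex(mature, transcript[o : o + Ls], scheme)
                if d.expectation <= cutoff:
                    out[(o, o + Ls)] = d.expectation
    return out


class TestFindTargetSites:
    def test_planted_perfect_site(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=300))
        site = perfect_site(MATURE)
        t = t[:100] + site + t[121:]
        (found,) = find_target_sites(MATURE, t)
        assert (found.start, found.end) == (100, 121)
        assert found.expectation == 0.0
        assert found.mode == "cleavage"

    def test_three_core_mismatches_rejected_at_cutoff(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=200))
        bad = mutate_site(MATURE, [5, 7, 9])  # penalty 6 in the core
        t = t[:50] + bad + t[71:]
        assert find_target_sites(MATURE, t) == []

    def test_central_mismatch_switches_mode_to_translation(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=120))
        site = mutate_site(MATURE, [10])  # central 9-11, penalty 2.0
        t = t[:40] + site + t[61:]
        sites = find_target_sites(MATURE, t)
        assert len(sites) == 1
        assert sites[0].mode == "translation"

    def test_agreement_with_exhaustive_oracle(self):
        rng = np.random.default_rng(77)
        for trial in range(12):
            t = list(rng.choice(list("ACGU"), size=400))
            # plant a mix of perfect, mutated and bulged sites
            for pos, site in (
                (30, perfect_site(MATURE)),
                (90, mutate_site(MATURE, [20])),
                (150, perfect_site(MATURE)[:5] + "A" + perfect_site(MATURE)[5:]),
                (220, mutate_site(MATURE, [5, 7])),
            ):
                t[pos : pos + len(site)] = list(site)
            t = "".join(t)
            found = {(s.start, s.end): s.expectation for s in find_target_sites(MATURE, t)}
            oracle = exhaustive_site_oracle(MATURE, t, 2.0)
            # every reported site must be in the oracle with the same score
            for key, exp in found.items():
                assert oracle[key] == pytest.approx(exp)
            # every oracle site must be reported or overlap a reported
            # site with an expectation at least as good (collapsing rule)
            for (s0, e0), exp in oracle.items():
                covered = any(
                    s.start < e0 and s0 < s.end and s.expectation <= exp + 1e-12
                    for s in find_target_sites(MATURE, t)
                )
                assert covered

    def test_threshold_monotonicity(self, rng):
        t = "".join(rng.choice(list("ACGU"), size=500))
        t = t[:60] + mutate_site(MATURE, [20]) + t[81:]
        for e1, e2 in [(0.5, 1.0), (1.0, 2.0), (2.0, 4.0)]:
            s1 = {(s.start, s.end) for s in find_target_sites(MATURE, t, e1)}
            s2 = {(s.start, s.end) for s in find_target_sites(MATURE, t, e2)}
            assert s1 <= s2

    def test_transcript_shorter_than_mature(self):
        assert find_target_sites(MATURE, "ACGUACGU") == []


class TestUpe:
    def test_unstructured_context_zero_upe(self):
        t = "A" * 100
        assert compute_upe(40, 61, t) == 0.0

    def test_planted_stem_has_known_unpairing_cost(self):
        # 17 upstream Gs pair the first 17 site Cs; opening the site costs
        # exactly the stem energy, 17 * 3 kcal/mol
        t = "A" * 20 + "G" * 17 + "C" * 21 + "A" * 20
        upe = compute_upe(37, 58, t)
        assert upe == pytest.approx(51.0)

    def test_upe_never_negative(self, rng):
        for _ in range(15):
            t = "".join(rng.choice(list("ACGU"), size=120))
            assert compute_upe(40, 61, t) >= -1e-9

    def test_more_flank_can_only_deepen_unconstrained_fold(self):
        # UPE is monotone in the amount of pairing context removed
        t = "A" * 20 + "G" * 17 + "C" * 21 + "A" * 20
        assert compute_upe(37, 58, t, flank_up=0) == 0.0

    def test_out_of_bounds_site(self):
        with pytest.raises(IndexError):
            compute_upe(90, 130, "A" * 100)


class TestPredictTargets:
    def test_upe_cutoff_excludes_inaccessible_site(self):
        from hairpinhunter.core_io import SequenceRecord
        from hairpinhunter.targets import predict_targets

        mature = SequenceRecord(id="m", sequence="G" * 21, alphabet="rna")
        # perfect site (C21) locked in a 17-pair stem: UPE = 51 > 25
        locked = SequenceRecord(
            id="locked", sequence="A" * 20 + "G" * 17 + "C" * 21 + "A" * 20,
            alphabet="rna",
        )
        open_site = SequenceRecord(id="open", sequence="A" * 40 + "C" * 21 + "A" * 40,
                                   alphabet="rna")
        coding, _, graph = predict_targets([mature], [locked, open_site])
        assert set(coding["transcript"]) == {"open"}
        assert graph.degree("m") == 1

    def test_empty_catalogs_give_empty_tables(self):
        from hairpinhunter.targets import predict_targets

        coding, lnc, graph = predict_targets([], [])
        assert coding.empty and lnc.empty and graph.number_of_edges() == 0

    def test_planted_edges_recovered_and_negatives_excluded(self, target_bench):
        assert target_bench["positive_recovery"] == 1.0
        assert target_bench["negatives_excluded"] == 1.0

    def test_degree_matches_planted_truth(self, target_bench):
        graph = target_bench["graph"]
        truth = target_bench["truth"]
        positives = [e for e in truth.target_edges if not e.is_negative]
        for e in positives:
            assert graph.has_edge(e.mature_id, e.transcript_id)
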