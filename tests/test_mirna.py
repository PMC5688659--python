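"""Homology scan completeness, window policy, cascade and naming rules."""

import numpy as np
import pytest

from hairpinhunter.core_io import GenomicInterval, SequenceRecord, reverse_complement
from hairpinhunter.mirna import (
    FilterThresholds,
    HomologyHit,
    PrecursorCandidate,
    WindowPolicy,
    apply_filter_cascade,
    assign_family_and_name,
    exclude_coding,
    extract_windows,
    family_of,
    scan_homology,
    select_best_candidate,
)
from hairpinhunter.synthetic import make_genome, make_hairpin, make_mature_library


def _rec(seq, rid="chr1"):
    return SequenceRecord(id=rid, sequence=seq, alphabet="dna")


def _mature(seq, mid="ath-miR171a"):
    return SequenceRecord(id=mid, sequence=seq, alphabet="dna")


class TestFamilyParsing:
    @pytest.mark.parametrize(
        "mid,family",
        [
            ("ath-miR171a", "miR171"),
            ("cca-miR171b-5p", "miR171"),
            ("gma-MIR398c", "miR398"),
            ("xxx-miR101a", "miR101"),
        ],
    )
    def test_mirbase_style_ids(self, mid, family):
        assert family_of(mid) == family


class TestScanHomology:
    MATURE = "TGGAGCTCCCTTCATTCCAAT"

    def test_planted_verbatim_hit(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=400))
        genome = [_rec(bg[:100] + self.MATURE + bg[121:])]
        hits = scan_homology(genome, [_mature(self.MATURE)])
        exact = [h for h in hits if h.mismatches == 0 and h.interval.strand == "+"]
        assert any(h.interval.start == 100 for h in exact)

    def test_four_mismatches_not_reported(self):
        mutated = list(self.MATURE)
        for i in (2, 6, 10, 14):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        genome = [_rec("".join(mutated) + "A" * 50)]
        assert scan_homology(genome, [_mature(self.MATURE)]) == []

    def test_three_mismatches_reported(self):
        mutated = list(self.MATURE)
        for i in (2, 6, 10):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        genome = [_rec("".join(mutated) + "A" * 50)]
        (hit,) = [h for h in scan_homology(genome, [_mature(self.MATURE)])
                  if h.interval.strand == "+"]
        assert hit.mismatches == 3

    def test_minus_strand_hit_found(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=200))
        genome = [_rec(bg[:60] + reverse_complement(self.MATURE) + bg[81:])]
        hits = scan_homology(genome, [_mature(self.MATURE)])
        minus = [h for h in hits if h.interval.strand == "-" and h.mismatches == 0]
        assert len(minus) == 1
        assert minus[0].interval.start == 60
        assert minus[0].matched_seq == self.MATURE

    def test_completeness_vs_naive_hamming_oracle(self):
        rng = np.random.default_rng(55)
        genome_seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.3, 0.2, 0.2, 0.3]))
        mature = "".join(rng.choice(list("ACGT"), size=16))
        genome = [_rec(genome_seq)]
        hits = scan_homology(genome, [_mature(mature, "x-miR1a")])
        got = {(h.interval.start, h.interval.strand, h.mismatches) for h in hits}

        expect = set()
        L = len(mature)
        rc = reverse_complement(mature)
        for s in range(len(genome_seq) - L + 1):
            win = genome_seq[s : s + L]
            for pattern, strand in ((mature, "+"), (rc, "-")):
                mm = sum(1 for a, b in zip(win, pattern) if a != b)
                if mm <= 3:
                    expect.add((s, strand, mm))
        assert got == expect

    def test_mature_with_n_skipped(self):
        genome = [_rec("ACGT" * 30)]
        assert scan_homology(genome, [_mature("ACGTNACGTACGTACGTACGT")]) == []

    def test_identical_coordinates_collapse_to_lowest_mismatch(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=200))
        genome = [_rec(bg[:50] + self.MATURE + bg[71:])]
        variant = list(self.MATURE)
        variant[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[3]]
        hits = scan_homology(
            genome,
            [_mature("".join(variant), "v-miR9a"), _mature(self.MATURE, "e-miR8a")],
        )
        at_50 = [h for h in hits if h.interval.start == 50 and h.interval.strand == "+"]
        assert len(at_50) == 1 and at_50[0].mature_id == "e-miR8a"


class TestExtractWindows:
    def _hit(self, start, end, strand="+", chrom="chr1"):
        L = end - start
        return HomologyHit("m-miR1a", "miR1", GenomicInterval(chrom, start, end, strand),
                           0, "A" * L)

    def test_flank_split_arithmetic(self, rng):
        genome = {"chr1": _rec("".join(rng.choice(list("ACGT"), size=1000)))}
        hit = self._hit(500, 521)
        policy = WindowPolicy(lengths=(100,), arms=("5p",))
        (cand,) = extract_windows(hit, genome, policy)
        # 5' arm placement: 0 upstream, 79 downstream
        assert (cand.window.start, cand.window.end) == (500, 600)
        assert cand.mature_offset == 0

    def test_three_prime_arm_placement(self, rng):
        genome = {"chr1": _rec("".join(rng.choice(list("ACGT"), size=1000)))}
        hit = self._hit(500, 521)
        (cand,) = extract_windows(hit, genome, WindowPolicy(lengths=(100,), arms=("3p",)))
        assert (cand.window.start, cand.window.end) == (421, 521)
        assert cand.mature_offset == 79

    def test_chromosome_start_clips_windows(self, rng):
        genome = {"chr1": _rec("".join(rng.choice(list("ACGT"), size=500)))}
        hit = self._hit(0, 21)
        cands = extract_windows(hit, genome, WindowPolicy(lengths=(100,), arms=("3p",)))
        (cand,) = cands
        assert cand.window.start == 0  # 5'-clipped
        assert cand.window.end == 21

    def test_minus_strand_window_is_reverse_complement(self, rng):
        bg = "".join(rng.choice(list("ACGT"), size=400))
        genome = {"chr1": _rec(bg)}
        hit = self._hit(200, 221, strand="-")
        (cand,) = extract_windows(hit, genome, WindowPolicy(lengths=(60,), arms=("5p",)))
        # mature 5' end is at the genomic right; window extends left
        assert (cand.window.start, cand.window.end) == (161, 221)
        expect = reverse_complement(bg[161:221]).replace("T", "U")
        assert cand.sequence == expect
        assert cand.mature_offset == 0

    def test_n_window_discarded(self):
        genome = {"chr1": _rec("N" * 10 + "ACGT" * 30)}
        hit = self._hit(12, 33)
        cands = extract_windows(hit, genome, WindowPolicy(lengths=(60,), arms=("3p",)))
        assert all("N" not in c.sequence for c in cands)


class TestExcludeCoding:
    def _window_candidates(self, seqs):
        out = []
        for i, s in enumerate(seqs):
            hit = HomologyHit("m-miR1a", "miR1", GenomicInterval("c", 0, 21), 0, "A" * 21)
            out.append(
                PrecursorCandidate(hit=hit, window=GenomicInterval("c", 0, len(s)),
                                   sequence=s.replace("T", "U"), mature_offset=0, arm="5p")
            )
        return out

    def test_planted_orf_matching_db_removed(self, rng):
        from hairpinhunter.synthetic import make_transcriptome

        tx, truth, proteins = make_transcriptome(2, 0, orf_aa_range=(60, 70),
                                                 utr_range=(10, 30), rng=rng)
        cands = self._window_candidates([t.sequence for t in tx])
        assert exclude_coding(cands, proteins) == []

    def test_random_noncoding_windows_mostly_retained(self):
        from hairpinhunter.synthetic import make_transcriptome

        rng = np.random.default_rng(21)
        _, _, proteins = make_transcriptome(5, 0, rng=rng)
        windows = ["".join(rng.choice(list("ACGT"), size=150)) for _ in range(40)]
        cands = self._window_candidates(windows)
        kept = exclude_coding(cands, proteins)
        fpr = 1.0 - len(kept) / len(cands)
        assert fpr < 0.05

    def test_empty_db_retains_everything(self):
        cands = self._window_candidates(["ACGT" * 30])
        assert exclude_coding(cands, proteins=[]) == cands

    def test_orf_heuristic_fallback(self):
        coding_like = "ATG" + "GCT" * 100 + "TAA"
        cands = self._window_candidates([coding_like, "ACGTTGCA" * 20])
        kept = exclude_coding(cands, proteins=None, orf_min_aa=80)
        assert len(kept) == 1 and "AUG" + "GCU" * 100 not in kept[0].sequence

    def test_heuristic_disabled_without_db_raises(self):
        with pytest.raises(ValueError):
            exclude_coding([], proteins=None, use_orf_heuristic=False)


def _candidate_with(mfei_val=2.0, r_val=0.0, length=60, start=0):
    from hairpinhunter.features import HairpinFeatures

    hit = HomologyHit("m-miR1a", "miR1", GenomicInterval("c", start, start + 21), 0,
                      "A" * 21)
    cand = PrecursorCandidate(
        hit=hit, window=GenomicInterval("c", start, start + length),
        sequence="A" * length, mature_offset=0, arm="5p",
    )
    cand.features = HairpinFeatures(
        length=length, frac_a=0.25, frac_c=0.25, frac_g=0.25, frac_u=0.25,
        gc_percent=50.0, mfe=-30.0, amfe=50.0, mfei=mfei_val, nq=0.1, nd=0.02,
        npb=0.4, r=r_val,
    )
    cand.verdicts = {"all": True}
    return cand


class TestCascadeAndSelection:
    def test_single_filter_failure_flagged(self, rng):
        mature = "UGGAGCUCCCUUCAUUCCAAU"
        pre, _ = make_hairpin(mature, loop_len=8, rng=rng)
        hit = HomologyHit("m-miR1a", "miR1", GenomicInterval("c", 0, 21), 0,
                          mature.replace("U", "T"))
        cand = PrecursorCandidate(hit=hit, window=GenomicInterval("c", 0, len(pre)),
                                  sequence=pre, mature_offset=0, arm="5p")
        strict = FilterThresholds(min_mfei=99.0)  # only MFEI can fail
        verdicts = apply_filter_cascade(cand, strict)
        assert verdicts["mfei"] is False
        assert not cand.passed
        others = {k: v for k, v in verdicts.items() if k != "mfei"}
        assert all(others.values())

    def test_permissive_thresholds_pass_everything(self, rng):
        seq = "".join(rng.choice(list("ACGU"), size=80))
        hit = HomologyHit("m-miR1a", "miR1", GenomicInterval("c", 0, 21), 0, "A" * 21)
        cand = PrecursorCandidate(hit=hit, window=GenomicInterval("c", 0, 80),
                                  sequence=seq, mature_offset=0, arm="5p")
        apply_filter_cascade(cand, FilterThresholds.permissive())
        assert cand.passed

    def test_max_mfei_wins(self):
        a, b = _candidate_with(mfei_val=0.9), _candidate_with(mfei_val=1.1)
        assert select_best_candidate([a, b]) is b

    def test_mfei_tie_broken_by_r(self):
        a, b = _candidate_with(r_val=0.0), _candidate_with(r_val=2.5)
        assert select_best_candidate([a, b]) is b

    def test_remaining_tie_shortest_then_leftmost(self):
        a, b = _candidate_with(length=100), _candidate_with(length=60)
        assert select_best_candidate([a, b]) is b
        c, d = _candidate_with(start=50), _candidate_with(start=10)
        assert select_best_candidate([c, d]) is d

    def test_single_candidate_selected(self):
        a = _candidate_with()
        assert select_best_candidate([a]) is a

    def test_no_passing_candidate_returns_none(self):
        a = _candidate_with()
        a.verdicts = {"mfei": False}
        assert select_best_candidate([a]) is None


class TestNaming:
    def test_genomic_order_suffixes_and_novelty(self):
        c1 = _candidate_with(start=500)
        c2 = _candidate_with(start=100)
        c2.hit = HomologyHit("m-miR1b", "miR1", GenomicInterval("c", 100, 121), 2,
                             "A" * 21)
        catalog = assign_family_and_name([c1, c2], prefix="syn")
        assert list(catalog["name"]) == ["syn-miR1a", "syn-miR1b"]
        assert list(catalog["start"]) == [100, 500]
        # 2-mismatch-only locus is novel; 0-mismatch locus is not
        assert list(catalog["novel"]) == [True, False]


class TestCascadeBenchmark:
    def test_sensitivity_and_specificity_on_planted_vs_shuffled(self):
        from hairpinhunter.synthetic import mononucleotide_shuffle

        rng = np.random.default_rng(71)
        matures = make_mature_library(10, rng=rng)
        thresholds = FilterThresholds()
        passed_true = passed_decoy = 0
        for m in matures:
            pre, _ = make_hairpin(m.as_rna(), loop_len=9, rng=rng)
            flank = "".join(rng.choice(list("ACGU"), size=60 - len(pre)))
            hit = HomologyHit(m.id, family_of(m.id),
                              GenomicInterval("c", 0, len(m)), 0, m.as_dna())
            true_cand = PrecursorCandidate(
                hit=hit, window=GenomicInterval("c", 0, 60), sequence=pre + flank,
                mature_offset=0, arm="5p")
            apply_filter_cascade(true_cand, thresholds)
            passed_true += true_cand.passed
            decoy_seq = mononucleotide_shuffle(pre + flank, rng)
            decoy = PrecursorCandidate(
                hit=hit, window=GenomicInterval("c", 0, 60), sequence=decoy_seq,
                mature_offset=0, arm="5p")
            apply_filter_cascade(decoy, thresholds)
            passed_decoy += decoy.passed
        assert passed_true / len(matures) >= 0.9
        assert 1 - passed_decoy / len(matures) >= 0.9
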