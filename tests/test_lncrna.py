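"""ORF scanning, coding-potential cascade and protein-similarity filter."""

import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from hairpinhunter.core_io import SequenceRecord
from hairpinhunter.lncrna import (
    CodingPotentialScorer,
    classify_coding_potential,
    find_orfs,
    length_filter,
    longest_orf_aa,
    orf_filter,
    protein_similarity_filter,
)
from hairpinhunter.synthetic import dinucleotide_shuffle, make_transcriptome

STOPS = {"TAA", "TAG", "TGA"}


def naive_orf_oracle(seq):
    """Independent six-frame scanner: (frame, start, end, has_stop) tuples."""
    out = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            start = None
            pos = off
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon in STOPS and start is not None:
                    out.append((f"{strand}{off + 1}", start, pos + 3, True))
                    start = None
                elif codon == "ATG" and start is None:
                    start = pos
                pos += 3
            if start is not None and pos > start:
                out.append((f"{strand}{off + 1}", start, pos, False))
    return sorted(out)


class TestFindOrfs:
    def test_hand_translated_minimal_orf(self):
        orfs = find_orfs("ATGAAATAA")
        assert len(orfs) == 1
        assert orfs[0].length_aa == 2  # MK, stop excluded
        assert orfs[0].has_stop

    def test_no_start_codon_no_orfs(self):
        assert find_orfs("TTTCCCGGGTTTCCC") == []

    def test_open_ended_orf_optional(self):
        seq = "ATGAAAAAA"  # start, no stop
        assert find_orfs(seq, include_open_ended=False) == []
        (orf,) = [o for o in find_orfs(seq) if o.frame == "+1"]
        assert not orf.has_stop and orf.length_aa == 3

    def test_matches_naive_scanner_on_random_transcripts(self):
        rng = np.random.default_rng(19)
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=300))
            mine = sorted((o.frame, o.start, o.end, o.has_stop) for o in find_orfs(seq))
            assert mine == naive_orf_oracle(seq)


def _tx(seq, tid="t1"):
    return SequenceRecord(id=tid, sequence=seq, alphabet="dna")


class TestBoundaryFilters:
    def test_length_filter_is_strict(self):
        at_200 = _tx("A" * 200, "a")
        at_201 = _tx("A" * 201, "b")
        assert length_filter([at_200, at_201]) == [at_201]
        assert length_filter([]) == []

    @pytest.mark.parametrize("aa,kept", [(119, True), (120, False)])
    def test_orf_filter_boundary(self, aa, kept):
        # ORF with `aa` amino acids: ATG + (aa-1) codons + stop
        seq = "ATG" + "GCT" * (aa - 1) + "TAA"
        t = _tx(seq)
        assert longest_orf_aa(seq) == aa
        assert (t in orf_filter([t])) is kept

    def test_transcript_without_orf_retained(self):
        t = _tx("TTTCCCGGG" * 30)
        assert orf_filter([t]) == [t]


@dataclasses.dataclass
class StubScorer:
    s: float
    sec: float = 0.0

    def primary_score(self, seq):
        return self.s

    def secondary_score(self, seq):
        return self.sec


class TestClassificationThresholds:
    @pytest.mark.parametrize(
        "s,sec,label",
        [
            (-0.6, None, "noncoding"),
            (-0.5, None, "noncoding"),  # boundary: <= -0.5 is noncoding
            (-0.49, 0.1, "ncRNA-by-secondary"),
            (0.3, 0.1, "ncRNA-by-secondary"),
            (0.3, 0.19, "ncRNA-by-secondary"),
            (0.3, 0.2, "neutral"),  # boundary: secondary must be < 0.2
            (0.99, 0.5, "neutral"),
            (1.0, None, "coding"),  # boundary: >= 1.0 is coding
            (1.5, None, "coding"),
        ],
    )
    def test_threshold_semantics(self, s, sec, label):
        res = classify_coding_potential("ACGT", StubScorer(s, sec or 0.0))
        assert res.label == label
        if label in ("noncoding", "coding"):
            assert res.secondary is None  # secondary only evaluated for neutral


@pytest.fixture(scope="module")
def corpus():
    rng = np.random.default_rng(101)
    tx, truth, _ = make_transcriptome(70, 70, rng=rng)
    coding = [t.sequence for t in tx if truth.transcript_labels[t.id] == "coding"]
    noncoding = [t.sequence for t in tx if truth.transcript_labels[t.id] == "noncoding"]
    return coding, noncoding


@pytest.fixture(scope="module")
def scorer(corpus):
    coding, noncoding = corpus
    return CodingPotentialScorer().fit(coding[:50], noncoding[:50])


class TestBuiltinScorer:

    def test_training_calibration(self, corpus, scorer):
        coding, noncoding = corpus
        c_scores = [scorer.primary_score(s) for s in coding[:50]]
        n_scores = [scorer.primary_score(s) for s in noncoding[:50]]
        assert np.mean([s >= 1.0 for s in c_scores]) >= 0.9
        assert np.mean([s <= -0.5 for s in n_scores]) >= 0.9

    def test_held_out_separation(self, corpus, scorer):
        coding, noncoding = corpus
        held_c = [scorer.primary_score(s) for s in coding[50:]]
        held_n = [scorer.primary_score(s) for s in noncoding[50:]]
        correct = sum(1 for s in held_c if s > 0) + sum(1 for s in held_n if s < 0)
        assert correct / (len(held_c) + len(held_n)) >= 0.9

    def test_planted_orf_vs_its_shuffle(self, corpus, scorer):
        # destroying the reading frame of a confidently coding transcript
        # must drop it out of the coding class
        coding, _ = corpus
        rng = np.random.default_rng(5)
        seq = next(s for s in coding if scorer.primary_score(s) >= 1.0)
        assert classify_coding_potential(seq, scorer).label == "coding"
        shuffled = dinucleotide_shuffle(seq, rng)
        res = classify_coding_potential(shuffled, scorer)
        assert res.label != "coding"
        assert res.s < scorer.primary_score(seq)

    def test_secondary_score_in_unit_interval(self, corpus, scorer):
        coding, noncoding = corpus
        for s in (coding[60], noncoding[60]):
            assert 0.0 <= scorer.secondary_score(s) <= 1.0

    def test_insufficient_training_data_raises(self):
        with pytest.raises(ValueError, match="external"):
            CodingPotentialScorer().fit(["ATG" * 50] * 10, ["AAA" * 50] * 10)


class TestProteinSimilarityFilter:
    def test_planted_protein_removed_shuffle_retained(self):
        rng = np.random.default_rng(3)
        tx, truth, proteins = make_transcriptome(3, 3, rng=rng)
        coding = [t for t in tx if truth.transcript_labels[t.id] == "coding"]
        noncoding = [t for t in tx if truth.transcript_labels[t.id] == "noncoding"]
        kept = protein_similarity_filter(coding + noncoding, proteins)
        kept_ids = {t.id for t in kept}
        assert all(t.id not in kept_ids for t in coding)
        assert all(t.id in kept_ids for t in noncoding)

    def test_no_database_skips_stage(self):
        t = _tx("ATG" + "GCA" * 80 + "TAA")
        assert protein_similarity_filter([t], None) == [t]
        assert protein_similarity_filter([t], []) == [t]

    @pytest.mark.parametrize("identity,kept", [(40.0, True), (40.5, False)])
    def test_identity_cutoff_is_strict(self, monkeypatch, identity, kept):
        import hairpinhunter.lncrna as mod

        monkeypatch.setattr(
            mod, "best_protein_hit", lambda *a, **k: (identity, 1e-6)
        )
        t = _tx("ATG" + "GCA" * 80 + "TAA")
        prot = SequenceRecord(id="p", sequence="M" + "A" * 80, alphabet="protein")
        result = mod.protein_similarity_filter([t], [prot])
        assert (t in result) is kept

    @pytest.mark.parametrize("ev,kept", [(1e-3, False), (2e-3, True)])
    def test_evalue_cutoff(self, monkeypatch, ev, kept):
        import hairpinhunter.lncrna as mod

        monkeypatch.setattr(mod, "best_protein_hit", lambda *a, **k: (95.0, ev))
        t = _tx("ATG" + "GCA" * 80 + "TAA")
        prot = SequenceRecord(id="p", sequence="M" + "A" * 80, alphabet="protein")
        assert (t in mod.protein_similarity_filter([t], [prot])) is kept
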