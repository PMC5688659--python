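"""Long non-coding RNA discovery.

The pipeline runs transcripts through five stages, in order, each strictly
non-increasing in count:

1. length filter — keep transcripts strictly longer than 200 nt;
2. ORF filter — keep transcripts whose longest ORF is strictly shorter
   than 120 amino acids;
3. primary coding-potential score S — keep non-coding (S <= -0.5), pass
   neutral (-0.5 < S < 1.0) on to stage 4, discard coding (S >= 1.0);
4. secondary score — neutral transcripts with a secondary score < 0.2 are
   classified non-coding, the rest discarded;
5. protein-similarity filter — discard transcripts with a significant
   (e <= 1e-3) translated hit of more than 40 % identity to a protein
   database; the survivors are the lncRNA catalog.

The built-in scorer is a calibrated stand-in for external coding-potential
classifiers: a logistic model over ORF coverage, a Fickett-style
position/composition statistic and a hexamer log-likelihood ratio, fitted
on labelled training transcripts and affinely mapped onto the primary
score scale so that its class thresholds (-0.5 / 1.0) are meaningful.
External programs can be plugged in through two-column id->score tables
instead (:class:`TableScorer`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .core_io import SequenceRecord

logger = logging.getLogger("hairpinhunter")

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclasses.dataclass(frozen=True)
class ORF:
    """An open reading frame: first in-frame start codon to the next stop.

    Coordinates are 0-based half-open on the *given* strand (for minus
    frames, on the reverse complement).  ``end`` includes the stop codon
    when one is present; ``length_aa`` never counts the stop.
    """

    frame: str  # one of +1 +2 +3 -1 -2 -3
    start: int
    end: int
    has_stop: bool

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")

    @property
    def length_aa(self) -> int:
        codons = (self.end - self.start) // 3
        return codons - 1 if self.has_stop else codons


def find_orfs(
    transcript: str,
    min_aa: int = 0,
    include_open_ended: bool = True,
) -> list[ORF]:
    """All ORFs in six frames, sorted by amino-acid length descending.

    Default definition: from the first in-frame ATG after the previous
    stop to the next in-frame stop (one ORF per stop segment).  An ORF
    still open at the sequence end is included unless
    *include_open_ended* is false.
    """
    seq = transcript.upper().replace("U", "T")
    orfs: list[ORF] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for off in range(3):
            frame = f"{strand}{off + 1}"
            start: int | None = None
            pos = off
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        orfs.append(ORF(frame, start, pos + 3, has_stop=True))
                        start = None
                elif codon == START_CODON and start is None:
                    start = pos
                pos += 3
            if start is not None and include_open_ended and pos > start:
                orfs.append(ORF(frame, start, pos, has_stop=False))
    orfs = [o for o in orfs if o.length_aa >= min_aa]
    orfs.sort(key=lambda o: (-o.length_aa, o.frame, o.start))
    return orfs


def longest_orf_aa(transcript: str) -> int:
    """Amino-acid length of the longest six-frame ORF (0 if none)."""
    orfs = find_orfs(transcript)
    return orfs[0].length_aa if orfs else 0


def length_filter(
    transcripts: Sequence[SequenceRecord], min_len: int = 200
) -> list[SequenceRecord]:
    """Keep transcripts strictly longer than *min_len* nucleotides."""
    return [t for t in transcripts if len(t) > min_len]


def orf_filter(
    transcripts: Sequence[SequenceRecord], max_aa: int = 120
) -> list[SequenceRecord]:
    """Keep transcripts whose longest ORF is strictly shorter than *max_aa*."""
    return [t for t in transcripts if longest_orf_aa(t.sequence) < max_aa]


@dataclasses.dataclass
class CodingPotentialResult:
    s: float  # primary score
    secondary: float | None  # [0, 1], evaluated only for neutral transcripts
    label: str  # noncoding | neutral | coding | ncRNA-by-secondary

    @property
    def is_noncoding(self) -> bool:
        return self.label in ("noncoding", "ncRNA-by-secondary")


class CodingScorer(Protocol):
    def primary_score(self, seq: str) -> float: ...

    def secondary_score(self, seq: str) -> float: ...


def classify_coding_potential(
    transcript: str,
    scorer: CodingScorer,
    s_noncoding: float = -0.5,
    s_coding: float = 1.0,
    secondary_cutoff: float = 0.2,
) -> CodingPotentialResult:
    """Two-stage classification on the primary/secondary score scales.

    S <= -0.5 -> noncoding; S >= 1.0 -> coding; neutral transcripts fall
    through to the secondary score, where < 0.2 rescues them as ncRNA.
    """
    s = scorer.primary_score(transcript)
    if s <= s_noncoding:
        return CodingPotentialResult(s, None, "noncoding")
    if s >= s_coding:
        return CodingPotentialResult(s, None, "coding")
    sec = scorer.secondary_score(transcript)
    label = "ncRNA-by-secondary" if sec < secondary_cutoff else "neutral"
    return CodingPotentialResult(s, sec, label)


# ---------------------------------------------------------------------------
# Built-in coding-potential scorer
# ---------------------------------------------------------------------------


def _fickett_statistic(seq: str) -> float:
    """Fickett-style position/composition statistic.

    For each base, the positional asymmetry max(c1,c2,c3)/(min(c1,c2,c3)+1)
    over the three codon positions, summed, plus the spread of the base
    composition.  Coding sequences read in frame show strong periodicity,
    non-coding sequences do not.  The raw statistic is consumed by the
    logistic model, which learns its weight, so no lookup tables are used.
    """
    s = seq.upper().replace("U", "T")
    total = max(len(s), 1)
    asym = 0.0
    for base in "ACGT":
        counts = [s[off::3].count(base) for off in range(3)]
        asym += max(counts) / (min(counts) + 1.0)
    comp = [s.count(b) / total for b in "ACGT"]
    spread = max(comp) - min(comp)
    return asym + 10.0 * spread


def _hexamer_counts(seq: str, counts: dict[str, int]) -> None:
    s = seq.upper().replace("U", "T")
    for i in range(0, len(s) - 5, 3):
        counts[s[i : i + 6]] = counts.get(s[i : i + 6], 0) + 1


class CodingPotentialScorer:
    """Trainable stand-in for external coding-potential classifiers.

    sklearn-style estimator: :meth:`fit` on labelled training transcripts,
    then :meth:`primary_score` (open scale, calibrated so that the fitted
    coding class scores >= 1.0 and the noncoding class <= -0.5 at >= 90 %
    training rate) and :meth:`secondary_score` (logistic probability of
    coding in [0, 1]).

    Parameters
    ----------
    pseudocount : float
        Added to hexamer counts before forming the log-likelihood ratio.
    min_train : int
        Minimum training sequences per class.
    """

    def __init__(self, pseudocount: float = 0.5, min_train: int = 50):
        self.pseudocount = pseudocount
        self.min_train = min_train

    # -- features ----------------------------------------------------------
    def _features(self, seq: str) -> np.ndarray:
        orfs = find_orfs(seq)
        if orfs:
            top = orfs[0]
            cov = 3.0 * (top.length_aa + 1) / max(len(seq), 1)
            orf_nt = self._orf_nt(seq, top)
        else:
            cov, orf_nt = 0.0, seq
        return np.array(
            [cov, _fickett_statistic(seq), self._hexamer_llr(orf_nt)]
        )

    @staticmethod
    def _orf_nt(seq: str, orf: ORF) -> str:
        s = seq.upper().replace("U", "T")
        if orf.frame.startswith("-"):
            s = str(Seq(s).reverse_complement())
        return s[orf.start : orf.end]

    def _hexamer_llr(self, seq: str) -> float:
        s = seq.upper().replace("U", "T")
        terms = []
        for i in range(0, len(s) - 5, 3):
            hexamer = s[i : i + 6]
            terms.append(
                math.log(self.hex_coding_.get(hexamer, self._bg_c))
                - math.log(self.hex_noncoding_.get(hexamer, self._bg_n))
            )
        return float(np.mean(terms)) if terms else 0.0

    # -- estimator surface -------------------------------------------------
    def fit(
        self,
        coding: Sequence[str],
        noncoding: Sequence[str],
    ) -> "CodingPotentialScorer":
        if len(coding) < self.min_train or len(noncoding) < self.min_train:
            raise ValueError(
                f"need >= {self.min_train} training sequences per class "
                f"(got {len(coding)} coding, {len(noncoding)} noncoding); "
                "use an external coding-potential adapter instead"
            )
        from sklearn.linear_model import LogisticRegression

        c_counts: dict[str, int] = {}
        n_counts: dict[str, int] = {}
        for s in coding:
            orfs = find_orfs(s)
            _hexamer_counts(self._orf_nt(s, orfs[0]) if orfs else s, c_counts)
        for s in noncoding:
            _hexamer_counts(s, n_counts)
        vocab = set(c_counts) | set(n_counts)
        tot_c = sum(c_counts.values()) + self.pseudocount * (len(vocab) + 1)
        tot_n = sum(n_counts.values()) + self.pseudocount * (len(vocab) + 1)
        self.hex_coding_ = {
            h: (c_counts.get(h, 0) + self.pseudocount) / tot_c for h in vocab
        }
        self.hex_noncoding_ = {
            h: (n_counts.get(h, 0) + self.pseudocount) / tot_n for h in vocab
        }
        self._bg_c = self.pseudocount / tot_c
        self._bg_n = self.pseudocount / tot_n

        X = np.vstack([self._features(s) for s in list(coding) + list(noncoding)])
        y = np.array([1] * len(coding) + [0] * len(noncoding))
        self.model_ = LogisticRegression(max_iter=2000)
        self.model_.fit(X, y)
        z = self.model_.decision_function(X)
        # affine map of the logit onto the primary-score scale: the 10th
        # percentile of coding logits lands on +1.0 and the 90th percentile
        # of noncoding logits on -0.5
        q_c = float(np.percentile(z[y == 1], 10))
        q_n = float(np.percentile(z[y == 0], 90))
        if q_c <= q_n:
            logger.warning(
                "coding/noncoding training logits overlap heavily "
                "(q_c=%.3f <= q_n=%.3f); primary-score calibration is weak",
                q_c,
                q_n,
            )
            q_c = q_n + 1e-6
        self.scale_ = 1.5 / (q_c - q_n)
        self.offset_ = 1.0 - self.scale_ * q_c
        return self

    def primary_score(self, seq: str) -> float:
        z = float(self.model_.decision_function(self._features(seq)[None, :])[0])
        return self.scale_ * z + self.offset_

    def secondary_score(self, seq: str) -> float:
        return float(self.model_.predict_proba(self._features(seq)[None, :])[0, 1])


def builtin_coding_scorer(
    train_coding: Sequence[str], train_noncoding: Sequence[str], **kwargs
) -> CodingPotentialScorer:
    """Fit the built-in coding-potential scorer on labelled transcripts."""
    return CodingPotentialScorer(**kwargs).fit(train_coding, train_noncoding)


@dataclasses.dataclass
class TableScorer:
    """Adapter: id-keyed primary/secondary scores from external programs.

    Built from two-column (id, score) TSVs so that real coding-potential
    classifier output can replace the built-in scorer.
    """

    primary: dict[str, float]
    secondary: dict[str, float]
    _current_id: str | None = None

    @classmethod
    def from_tsv(cls, primary_path: str | Path, secondary_path: str | Path) -> "TableScorer":
        def load(path):
            out = {}
            with open(path) as fh:
                for line in fh:
                    if line.strip():
                        k, v = line.split("\t")[:2]
                        out[k] = float(v)
            return out

        return cls(load(primary_path), load(secondary_path))

    def for_id(self, seq_id: str) -> "TableScorer":
        return dataclasses.replace(self, _current_id=seq_id)

    def primary_score(self, seq: str) -> float:
        return self.primary[self._current_id]

    def secondary_score(self, seq: str) -> float:
        return self.secondary[self._current_id]


# ---------------------------------------------------------------------------
# Translated protein-similarity filter
# ---------------------------------------------------------------------------


def _frame_peptides(seq: str, min_aa: int = 15) -> list[str]:
    """Stop-delimited peptides from all six translation frames."""
    s = seq.upper().replace("U", "T")
    peptides = []
    for strand_seq in (s, str(Seq(s).reverse_complement())):
        for off in range(3):
            trimmed = strand_seq[off : off + 3 * ((len(strand_seq) - off) // 3)]
            if len(trimmed) < 3:
                continue
            aa = str(Seq(trimmed).translate())
            peptides.extend(p for p in aa.split("*") if len(p) >= min_aa)
    return peptides


def _has_seed(a: str, b_kmers: set[str], k: int = 4) -> bool:
    return any(a[i : i + k] in b_kmers for i in range(len(a) - k + 1))


def evalue(raw_score: float, query_len: int, db_residues: int) -> float:
    """Karlin-Altschul expect value for a gapped BLOSUM62 local alignment."""
    return _KA_K * query_len * db_residues * math.exp(-_KA_LAMBDA * raw_score)


def best_protein_hit(
    transcript: str,
    proteins: Sequence[SequenceRecord],
    db_residues: int | None = None,
) -> tuple[float, float] | None:
    """(identity %, e-value) of the best-scoring translated local alignment.

    Translated stop-free peptides of the transcript are aligned locally
    (BLOSUM62, gap open -11 / extend -1) against every database protein
    sharing a 4-mer seed; the best raw score wins.  Returns ``None`` when
    nothing aligns.
    """
    peptides = _frame_peptides(transcript)
    if not peptides or not proteins:
        return None
    if db_residues is None:
        db_residues = sum(len(p.sequence) for p in proteins)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    prot_kmers = [
        {p.sequence[i : i + 4] for i in range(len(p.sequence) - 3)} for p in proteins
    ]
    best: tuple[float, float, float] | None = None  # (raw, identity, qlen)
    for pep in peptides:
        for prot, kmers in zip(proteins, prot_kmers):
            if not _has_seed(pep, kmers):
                continue
            aln = aligner.align(pep, prot.sequence)
            if len(aln) == 0:
                continue
            top = aln[0]
            raw = top.score
            if best is not None and raw <= best[0]:
                continue
            a, b = top[0], top[1]
            matched = sum(1 for x, y in zip(a, b) if x == y and x != "-")
            identity = 100.0 * matched / max(len(a), 1)
            best = (raw, identity, len(pep))
    if best is None:
        return None
    raw, identity, qlen = best
    return identity, evalue(raw, int(qlen), db_residues)


def protein_similarity_filter(
    transcripts: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord] | None,
    max_identity: float = 40.0,
    e_cutoff: float = 1e-3,
) -> list[SequenceRecord]:
    """Remove transcripts with a significant high-identity translated hit.

    A transcript is removed iff its best translated local alignment has
    e-value <= *e_cutoff* AND identity strictly greater than
    *max_identity* percent.  With no protein database the stage is skipped
    with a prominent warning and the catalog is returned unfiltered.
    """
    if not proteins:
        logger.warning(
            "protein similarity filter SKIPPED (no protein database); "
            "lncRNA catalog is unfiltered against proteins"
        )
        return list(transcripts)
    db_residues = sum(len(p.sequence) for p in proteins)
    kept = []
    for t in transcripts:
        hit = best_protein_hit(t.sequence, proteins, db_residues)
        if hit is not None:
            identity, ev = hit
            if ev <= e_cutoff and identity > max_identity:
                continue
        kept.append(t)
    return kept
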