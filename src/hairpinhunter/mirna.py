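"""Homology-based miRNA precursor discovery.

The pipeline maps a library of known mature miRNAs onto a genome and
decides, locus by locus, whether the surrounding sequence folds into a
credible precursor hairpin:

1. homology scan — every ungapped occurrence of a known mature on either
   strand with at most 3 mismatches (an exhaustive Hamming scan, complete
   at this scale, with an adapter for external tabular hit lists);
2. window extraction — a ladder of candidate precursor windows around
   each hit (default total lengths 60-300 nt in steps of 20, mature
   placed on the 5' or 3' arm), minus-strand hits reverse-complemented
   so the mature reads in sense;
3. coding exclusion — windows whose translation matches a protein
   database (or, without one, windows containing a long ORF) are dropped;
4. feature computation and the threshold cascade over composition, MFEI,
   NQ, ND, Npb, SSR signature density R and hairpin placement;
5. per-hit best-candidate retention — maximum MFEI, ties broken by
   maximum R, then shortest window, then leftmost start;
6. family assignment and naming in genomic order.

Default cascade thresholds are calibrated on the packaged synthetic
corpus under the built-in energy model — they are NOT literature values,
and should be recalibrated whenever the folding engine is swapped.
"""

from __future__ import annotations

import dataclasses
import logging
import re
import string
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, SequenceRecord, reverse_complement
from .features import DegenerateCandidateError, HairpinFeatures, compute_features
from .folding import DEFAULT_MODEL, EnergyModel, SecondaryStructure
from .lncrna import best_protein_hit, longest_orf_aa
from .ssr import SignatureTable, UnknownFamilyError, signature_density_r

logger = logging.getLogger("hairpinhunter")

_FAMILY_RE = re.compile(r"(?:^|[-_])((?:miR|MIR|let)-?\d+)", re.IGNORECASE)


def family_of(mature_id: str) -> str:
    """miRBase-style family from a mature id (``ath-miR171a-5p`` -> ``miR171``)."""
    m = _FAMILY_RE.search(mature_id)
    if m is None:
        return mature_id
    fam = m.group(1)
    return "miR" + re.sub(r"^(miR|MIR|let)-?", "", fam, flags=re.IGNORECASE)


@dataclasses.dataclass(frozen=True)
class HomologyHit:
    """One ungapped genome occurrence of a known mature miRNA."""

    mature_id: str
    family: str
    interval: GenomicInterval
    mismatches: int
    matched_seq: str  # genome subsequence in the sense of the mature (DNA)

    def __post_init__(self) -> None:
        if self.mismatches > 3:
            raise ValueError("a homology hit permits at most 3 mismatches")
        if len(self.matched_seq) != len(self.interval):
            raise ValueError("hit length must equal the interval length")


def _mismatch_positions(genome_codes: np.ndarray, pattern: np.ndarray, max_mm: int) -> np.ndarray:
    """Start positions where *pattern* matches with <= max_mm mismatches.

    An N in the genome (code 4) never matches.
    """
    L = len(pattern)
    if len(genome_codes) < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(genome_codes, L)
    mm = (windows != pattern[None, :]).sum(axis=1)
    return np.nonzero(mm <= max_mm)[0]


_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode_dna(seq: str) -> np.ndarray:
    return np.array([_DNA_CODE[c] for c in seq], dtype=np.int8)


def scan_homology(
    genome: Sequence[SequenceRecord],
    matures: Sequence[SequenceRecord],
    max_mismatch: int = 3,
) -> list[HomologyHit]:
    """Exhaustive both-strand Hamming scan of *matures* against *genome*.

    Complete (no heuristic loss): every ungapped occurrence with Hamming
    distance <= *max_mismatch* is returned.  Matures containing N, or
    outside 15-30 nt, are skipped with a warning.  Multiple matures
    hitting identical coordinates collapse to the lowest-mismatch query.
    """
    hits: dict[tuple[str, int, int, str], HomologyHit] = {}
    chrom_codes = {rec.id: _encode_dna(rec.sequence) for rec in genome}
    for mat in matures:
        mseq = mat.as_dna()
        if "N" in mseq:
            logger.warning("mature %s contains N; skipped", mat.id)
            continue
        if not (15 <= len(mseq) <= 30):
            logger.warning("mature %s length %d outside 15-30 nt; skipped", mat.id, len(mseq))
            continue
        fwd = _encode_dna(mseq)
        rev = _encode_dna(reverse_complement(mseq))
        L = len(mseq)
        for rec in genome:
            codes = chrom_codes[rec.id]
            for strand, pattern in (("+", fwd), ("-", rev)):
                for start in _mismatch_positions(codes, pattern, max_mismatch):
                    start = int(start)
                    sub = rec.sequence[start : start + L]
                    if "N" in sub:
                        continue
                    matched = sub if strand == "+" else reverse_complement(sub)
                    mm = sum(1 for a, b in zip(matched, mseq) if a != b)
                    key = (rec.id, start, start + L, strand)
                    prev = hits.get(key)
                    if prev is None or mm < prev.mismatches:
                        hits[key] = HomologyHit(
                            mature_id=mat.id,
                            family=family_of(mat.id),
                            interval=GenomicInterval(rec.id, start, start + L, strand),
                            mismatches=mm,
                            matched_seq=matched,
                        )
    return sorted(
        hits.values(), key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand)
    )


def read_tabular_hits(
    path, matures: Sequence[SequenceRecord], genome: Sequence[SequenceRecord],
    max_mismatch: int = 3,
) -> list[HomologyHit]:
    """Adapter: ingest an external 12-column tabular hit list.

    Columns follow the standard tabular alignment layout (query, subject,
    identity, length, mismatches, gapopen, qstart, qend, sstart, send,
    evalue, bitscore; subject coordinates 1-based inclusive, reversed on
    the minus strand).  Only full-length ungapped hits within the mismatch
    budget are kept.
    """
    genome_by_id = {g.id: g for g in genome}
    mat_by_id = {m.id: m for m in matures}
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            qid, sid = f[0], f[1]
            length, mism, gaps = int(f[3]), int(f[4]), int(f[5])
            sstart, send = int(f[8]), int(f[9])
            mat = mat_by_id.get(qid)
            if mat is None or sid not in genome_by_id:
                continue
            if gaps > 0 or length != len(mat) or mism > max_mismatch:
                continue
            if sstart <= send:
                iv = GenomicInterval(sid, sstart - 1, send, "+")
            else:
                iv = GenomicInterval(sid, send - 1, sstart, "-")
            sub = genome_by_id[sid].sequence[iv.start : iv.end]
            matched = sub if iv.strand == "+" else reverse_complement(sub)
            hits.append(HomologyHit(qid, family_of(qid), iv, mism, matched))
    return hits


@dataclasses.dataclass
class WindowPolicy:
    """Precursor-window ladder: total lengths and mature arm placements."""

    lengths: tuple = tuple(range(60, 301, 20))
    arms: tuple = ("5p", "3p")


@dataclasses.dataclass
class PrecursorCandidate:
    """One candidate precursor window around a homology hit."""

    hit: HomologyHit
    window: GenomicInterval
    sequence: str  # RNA, in the sense of the mature
    mature_offset: int  # 0-based start of the mature within the window
    arm: str
    features: HairpinFeatures | None = None
    structure: SecondaryStructure | None = None
    verdicts: dict = dataclasses.field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())

    @property
    def mature_interval(self) -> GenomicInterval:
        return self.hit.interval


def extract_windows(
    hit: HomologyHit,
    genome_by_id: Mapping[str, SequenceRecord],
    policy: WindowPolicy = WindowPolicy(),
) -> list[PrecursorCandidate]:
    """The window ladder for one hit, clipped at chromosome ends.

    For a plus-strand hit, 5p placement puts the mature at the window's
    5' end (0 upstream / rest downstream); 3p at the 3' end.  Minus-strand
    windows are reverse-complemented so the mature appears in sense.
    Windows containing N are discarded; duplicate post-clipping coordinates
    collapse.
    """
    chrom = genome_by_id[hit.interval.chrom]
    clen = len(chrom)
    hlen = len(hit.interval)
    out: dict[tuple[int, int, str], PrecursorCandidate] = {}
    for total in policy.lengths:
        flank = max(total - hlen, 0)
        for arm in policy.arms:
            # flank split in mature coordinates: 5p = all flank 3' of mature
            if arm == "5p":
                up, down = 0, flank
            else:
                up, down = flank, 0
            if hit.interval.strand == "+":
                gstart = hit.interval.start - up
                gend = hit.interval.end + down
            else:  # mature 5' end is at the genomic right
                gstart = hit.interval.start - down
                gend = hit.interval.end + up
            gstart_c, gend_c = max(0, gstart), min(clen, gend)
            if gend_c - gstart_c < hlen:
                logger.warning("window for hit at %s:%d dropped (off both ends)",
                               hit.interval.chrom, hit.interval.start)
                continue
            key = (gstart_c, gend_c, arm)
            if key in out:
                continue
            sub = chrom.sequence[gstart_c:gend_c]
            if "N" in sub:
                continue
            if hit.interval.strand == "+":
                seq_dna = sub
                mat_off = hit.interval.start - gstart_c
            else:
                seq_dna = reverse_complement(sub)
                mat_off = gend_c - hit.interval.end
            out[key] = PrecursorCandidate(
                hit=hit,
                window=GenomicInterval(chrom.id, gstart_c, gend_c, hit.interval.strand),
                sequence=seq_dna.replace("T", "U"),
                mature_offset=mat_off,
                arm=arm,
            )
    return list(out.values())


def exclude_coding(
    candidates: Sequence[PrecursorCandidate],
    proteins: Sequence[SequenceRecord] | None = None,
    orf_min_aa: int = 80,
    e_cutoff: float = 1e-3,
    min_identity: float = 50.0,
    use_orf_heuristic: bool = True,
) -> list[PrecursorCandidate]:
    """Drop candidate windows that look protein-coding.

    With a protein database, a window is removed when a translated local
    alignment reaches e-value <= *e_cutoff* and identity >= *min_identity*
    percent.  Without one, the fallback heuristic removes windows whose
    longest ORF reaches *orf_min_aa* amino acids.  With neither available
    a configuration error is raised.
    """
    if proteins is not None and len(proteins) == 0:
        logger.warning("empty protein database: no windows excluded as coding")
        return list(candidates)
    if proteins:
        db_res = sum(len(p.sequence) for p in proteins)
        kept = []
        for c in candidates:
            hit = best_protein_hit(c.sequence.replace("U", "T"), proteins, db_res)
            if hit is not None:
                identity, ev = hit
                if ev <= e_cutoff and identity >= min_identity:
                    continue
            kept.append(c)
        return kept
    if not use_orf_heuristic:
        raise ValueError(
            "coding exclusion needs a protein database or the ORF heuristic enabled"
        )
    return [c for c in candidates if longest_orf_aa(c.sequence.replace("U", "T")) < orf_min_aa]


@dataclasses.dataclass
class FilterThresholds:
    """Cascade cut-offs.

    Defaults are calibrated on the packaged synthetic corpus under the
    built-in additive energy model (calibrated, not literature values);
    every field is finite and configurable.
    """

    min_mfei: float = 1.3
    max_nq: float = 0.45
    max_nd: float = 0.14
    npb_range: tuple[float, float] = (0.2, 0.5)
    min_r: float = 0.0
    composition: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: {
            "A": (0.03, 0.6), "C": (0.03, 0.6), "G": (0.03, 0.6), "U": (0.03, 0.6),
        }
    )
    length_range: tuple[int, int] = (50, 320)
    require_hairpin_placement: bool = True

    @classmethod
    def permissive(cls) -> "FilterThresholds":
        """Everything passes (no-op cascade)."""
        inf = float("inf")
        return cls(
            min_mfei=-inf, max_nq=inf, max_nd=inf, npb_range=(0.0, 1.0),
            min_r=-inf,
            composition={b: (0.0, 1.0) for b in "ACGU"},
            length_range=(1, 10**9), require_hairpin_placement=False,
        )


def mature_within_one_arm(
    structure: SecondaryStructure, mature_start: int, mature_end: int,
    min_paired_fraction: float = 0.5,
) -> bool:
    """True when the mature sits on a single helical arm of the structure.

    Two requirements: no base of the mature pairs with another mature base
    (a mature straddling the hairpin loop pairs with itself), and at least
    *min_paired_fraction* of the mature's bases are paired outward (an arm
    is duplexed; a mature drifting in unstructured sequence is not on an
    arm at all).
    """
    outward = 0
    for i, j in structure.pairs:
        i_in = mature_start <= i < mature_end
        j_in = mature_start <= j < mature_end
        if i_in and j_in:
            return False
        if i_in or j_in:
            outward += 1
    return outward >= min_paired_fraction * (mature_end - mature_start)


def apply_filter_cascade(
    candidate: PrecursorCandidate,
    thresholds: FilterThresholds,
    signature_table: SignatureTable | None = None,
    model: EnergyModel = DEFAULT_MODEL,
) -> dict[str, bool]:
    """Score *candidate* against every cascade filter.

    Fills ``candidate.features`` / ``candidate.structure`` if absent and
    records a verdict per filter; the candidate passes overall iff every
    verdict is true.  A GC-free window fails the MFEI filter by definition.
    """
    from .folding import partition_function

    seq = candidate.sequence
    verdicts: dict[str, bool] = {}
    try:
        if candidate.features is None:
            folding = partition_function(seq, model)
            candidate.structure = folding.mfe_structure
            candidate.features = compute_features(seq, model, folding)
        feats = candidate.features
    except DegenerateCandidateError:
        candidate.verdicts = {"mfei": False}
        return candidate.verdicts

    if signature_table is not None:
        try:
            feats.r = signature_density_r(seq, candidate.hit.family, signature_table)
        except UnknownFamilyError:
            feats.r = 0.0

    comp_ok = all(
        lo <= getattr(feats, f"frac_{b.lower()}") <= hi
        for b, (lo, hi) in thresholds.composition.items()
    )
    verdicts["composition"] = comp_ok
    verdicts["length"] = thresholds.length_range[0] <= feats.length <= thresholds.length_range[1]
    verdicts["mfei"] = feats.mfei >= thresholds.min_mfei
    verdicts["nq"] = feats.nq <= thresholds.max_nq
    verdicts["nd"] = feats.nd <= thresholds.max_nd
    verdicts["npb"] = thresholds.npb_range[0] <= feats.npb <= thresholds.npb_range[1]
    verdicts["r"] = feats.r >= thresholds.min_r
    if thresholds.require_hairpin_placement:
        mlen = len(candidate.hit.interval)
        verdicts["hairpin_placement"] = mature_within_one_arm(
            candidate.structure, candidate.mature_offset, candidate.mature_offset + mlen
        )
    else:
        verdicts["hairpin_placement"] = True
    candidate.verdicts = verdicts
    return verdicts


def select_best_candidate(
    candidates: Sequence[PrecursorCandidate],
) -> PrecursorCandidate | None:
    """Best passing window for one hit: max MFEI, then max R, then the
    shortest window, then the leftmost start.  None if nothing passed."""
    passing = [c for c in candidates if c.passed]
    if not passing:
        return None
    return min(
        passing,
        key=lambda c: (
            -c.features.mfei,
            -c.features.r,
            len(c.window),
            c.window.start,
        ),
    )


def _suffix(index: int) -> str:
    """0 -> a, 1 -> b, ..., 25 -> z, 26 -> aa, ..."""
    letters = string.ascii_lowercase
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = letters[rem] + out
    return out


def assign_family_and_name(
    accepted: Sequence[PrecursorCandidate], prefix: str = "syn"
) -> pd.DataFrame:
    """Catalog of accepted loci: names, families, coordinates, novelty.

    Family is inherited from the best-matching known mature; within-family
    letter suffixes run in genomic order; a locus is novel when its hit
    has at least one mismatch to every known mature.
    """
    ordered = sorted(
        accepted, key=lambda c: (c.window.chrom, c.window.start, c.window.strand)
    )
    per_family: dict[str, int] = {}
    rows = []
    for cand in ordered:
        fam = cand.hit.family
        idx = per_family.get(fam, 0)
        per_family[fam] = idx + 1
        fam_num = re.sub(r"^miR", "", fam)
        rows.append(
            {
                "name": f"{prefix}-miR{fam_num}{_suffix(idx)}",
                "family": fam,
                "chrom": cand.window.chrom,
                "start": cand.window.start,
                "end": cand.window.end,
                "strand": cand.window.strand,
                "mature_start": cand.mature_interval.start,
                "mature_end": cand.mature_interval.end,
                "source_mature": cand.hit.mature_id,
                "mismatches": cand.hit.mismatches,
                "novel": cand.hit.mismatches > 0,
                "mature_seq": cand.hit.matched_seq,
                "precursor_seq": cand.sequence,
                **(cand.features.as_row() if cand.features else {}),
            }
        )
    return pd.DataFrame(rows)
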