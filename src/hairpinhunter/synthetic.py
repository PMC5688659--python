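"""Seeded synthetic inputs with ground truth.

Everything the discovery pipelines consume can be generated here with the
statistical structure each stage assumes, plus a complete truth ledger so
runs can be scored without any external downloads:

* :func:`make_hairpin` — a precursor with a known mature on the 5' arm, a
  loop (optionally carrying a trinucleotide SSR signature tract) and a
  near-reverse-complement 3' arm with a chosen number of stem mismatches;
* :func:`make_genome` — i.i.d. background at a requested GC with planted
  precursors on random strands and three decoy classes: matures mutated
  to 4-6 substitutions (straddling the <= 3 homology boundary), shuffled
  whole precursors, and intact matures in shuffled context (hits that
  must die in the filter cascade);
* :func:`make_transcriptome` — codon-biased coding transcripts (UTRs
  around an ORF) with their translated proteins, and dinucleotide-shuffled
  non-coding counterparts (exact-count shuffle, composition-matched);
* :func:`plant_target_sites` — reverse-complement target sites mutated to
  a designed expectation penalty (0, 1, or >2 for designed negatives).

All randomness flows from one explicitly passed ``numpy.random.Generator``;
identical seed and arguments give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, SequenceRecord, reverse_complement
from .lncrna import longest_orf_aa
from .targets import DEFAULT_SCHEME, ExpectationScheme

logger = logging.getLogger("hairpinhunter")

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


# ---------------------------------------------------------------------------
# truth ledger
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PlantedPrecursor:
    locus: GenomicInterval
    mature: GenomicInterval  # genomic coordinates of the mature arm
    mature_id: str
    family: str
    precursor_rna: str  # sense of the mature
    mature_offset: int
    ssr_motif: str | None


@dataclasses.dataclass(frozen=True)
class PlantedDecoy:
    kind: str  # mutated_mature | shuffled_precursor | cascade_decoy
    locus: GenomicInterval
    mature_id: str
    mismatches: int  # vs the source mature (0 for intact-mature decoys)


@dataclasses.dataclass(frozen=True)
class TargetEdge:
    mature_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    designed_expectation: float

    @property
    def is_negative(self) -> bool:
        return self.designed_expectation > 2.0


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth ledger for one synthetic dataset."""

    planted: list = dataclasses.field(default_factory=list)
    decoys: list = dataclasses.field(default_factory=list)
    transcript_labels: dict = dataclasses.field(default_factory=dict)
    target_edges: list = dataclasses.field(default_factory=list)

    def verify_genome(self, genome: Sequence[SequenceRecord]) -> None:
        """Check every planted precursor's coordinates against the FASTA."""
        by_id = {g.id: g for g in genome}
        for p in self.planted:
            seg = by_id[p.locus.chrom].sequence[p.locus.start : p.locus.end]
            expect = p.precursor_rna.replace("U", "T")
            if p.locus.strand == "-":
                seg = reverse_complement(seg)
            if seg != expect:
                raise AssertionError(
                    f"truth ledger mismatch at {p.locus.chrom}:{p.locus.start}"
                )

    def verify_transcripts(self, transcripts: Sequence[SequenceRecord]) -> None:
        by_id = {t.id: t for t in transcripts}
        for e in self.target_edges:
            if e.transcript_id not in by_id:
                raise AssertionError(f"target edge names unknown transcript {e.transcript_id}")
            t = by_id[e.transcript_id]
            if not (0 <= e.start < e.end <= len(t)):
                raise AssertionError("target edge out of transcript bounds")

    def write_tsvs(self, out_dir) -> None:
        import pandas as pd
        from pathlib import Path

        out = Path(out_dir)
        pd.DataFrame(
            [
                {
                    "chrom": p.locus.chrom, "start": p.locus.start, "end": p.locus.end,
                    "strand": p.locus.strand, "mature_start": p.mature.start,
                    "mature_end": p.mature.end, "mature_id": p.mature_id,
                    "family": p.family, "ssr_motif": p.ssr_motif or "",
                }
                for p in self.planted
            ]
        ).to_csv(out / "truth_precursors.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"kind": d.kind, "chrom": d.locus.chrom, "start": d.locus.start,
                 "end": d.locus.end, "strand": d.locus.strand,
                 "mature_id": d.mature_id, "mismatches": d.mismatches}
                for d in self.decoys
            ]
        ).to_csv(out / "truth_decoys.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"transcript": k, "label": v} for k, v in self.transcript_labels.items()]
        ).to_csv(out / "truth_transcript_labels.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"mirna": e.mature_id, "transcript": e.transcript_id,
                 "start": e.start, "end": e.end,
                 "designed_expectation": e.designed_expectation}
                for e in self.target_edges
            ]
        ).to_csv(out / "truth_target_edges.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# shuffles
# ---------------------------------------------------------------------------


def mononucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator, max_tries: int = 200) -> str:
    """Exact-count dinucleotide shuffle (Altschul-Erickson construction).

    Builds the dinucleotide multigraph, draws a random last-edge tree
    rooted at the final character (rejection-sampled for connectivity),
    shuffles the remaining out-edges and walks the Eulerian path.  The
    result has exactly the dinucleotide (hence mononucleotide) counts of
    the input.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = sorted(edges.keys() | {last})

    for _ in range(max_tries):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last or not edges.get(v):
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # connectivity: following last-edges from every vertex must reach `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if not ok:
            continue
        # arrange each vertex's out-edges: random order, its last-edge final
        arranged: dict[str, list[str]] = {}
        for v, out in edges.items():
            rest = list(out)
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            arranged[v] = rest
        # walk
        result = [first]
        ptr = {v: 0 for v in arranged}
        cur = first
        for _ in range(len(seq) - 1):
            nxt = arranged[cur][ptr[cur]]
            ptr[cur] += 1
            result.append(nxt)
            cur = nxt
        return "".join(result)
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian arrangement")


# ---------------------------------------------------------------------------
# hairpins and genomes
# ---------------------------------------------------------------------------


def _mutate_to_nonpairing(base_to_change: str, partner: str, rng: np.random.Generator,
                          alphabet: str = "ACGU") -> str:
    """A replacement for *base_to_change* that neither pairs nor wobbles with *partner*."""
    comp = _RNA_COMP[partner]
    options = [
        b for b in alphabet
        if b != base_to_change and b != comp and _WOBBLE_PARTNER.get(partner) != b
    ]
    return options[rng.integers(len(options))]


def make_hairpin(
    mature: str,
    loop_len: int = 8,
    stem_mismatches: int = 0,
    rng: np.random.Generator | None = None,
    loop_motif: str | None = None,
    min_loop: int = 3,
) -> tuple[str, int]:
    """Precursor RNA = mature + loop + near-reverse-complement, mature at offset 0.

    *loop_motif* (a trinucleotide) tiles the loop so the precursor carries
    an SSR signature tract; *stem_mismatches* bases of the 3' arm are
    mutated so they cannot pair with their mature partner.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    mature = mature.upper().replace("T", "U")
    if not (15 <= len(mature) <= 24):
        raise ValueError(f"mature length {len(mature)} outside 15-24 nt")
    if loop_len < min_loop:
        raise ValueError(f"loop_len {loop_len} below the minimum loop size {min_loop}")
    if stem_mismatches > len(mature):
        raise ValueError("more stem mismatches than stem positions")
    if loop_motif is not None:
        if len(loop_motif) != 3:
            raise ValueError("loop_motif must be a trinucleotide")
        loop = (loop_motif * ((loop_len + 2) // 3))[:loop_len]
    else:
        loop = "".join(rng.choice(list("ACGU"), size=loop_len))
    arm = list("".join(_RNA_COMP[b] for b in reversed(mature)))
    L = len(mature)
    if stem_mismatches:
        positions = rng.choice(L, size=stem_mismatches, replace=False)
        for p in positions:
            partner = mature[L - 1 - p]
            arm[p] = _mutate_to_nonpairing(arm[p], partner, rng)
    return mature + loop + "".join(arm), 0


def _random_background(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _place(
    occupied: dict[str, list[tuple[int, int]]],
    chroms: list[str],
    chrom_len: int,
    span: int,
    rng: np.random.Generator,
    pad: int = 30,
    max_tries: int = 200,
) -> tuple[str, int]:
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        pos = int(rng.integers(0, chrom_len - span))
        if all(
            pos + span + pad <= s or e + pad <= pos for s, e in occupied[chrom]
        ):
            occupied[chrom].append((pos, pos + span))
            return chrom, pos
    raise RuntimeError("genome overcrowded: could not place element without overlap")


def make_genome(
    matures: Sequence[SequenceRecord],
    n_chroms: int = 2,
    chrom_len: int = 10_000,
    gc: float = 0.5,
    n_planted: int = 10,
    n_mutated_decoys: int = 5,
    n_shuffled_decoys: int = 5,
    n_cascade_decoys: int = 5,
    loop_len: int = 9,
    rng: np.random.Generator | None = None,
    signature_motifs: Mapping[str, str] | None = None,
    stem_mismatches: int = 0,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Synthetic genome with planted precursors, decoys and a truth ledger.

    Planted matures cycle through the library; each precursor goes onto a
    random strand of a random chromosome without overlap.  Mutated-mature
    decoys carry 4-6 substitutions (just beyond the homology boundary);
    shuffled-precursor decoys destroy the hairpin and the mature alike;
    cascade decoys keep the mature intact in shuffled context so they
    produce homology hits that the filter cascade must reject.
    """
    from .mirna import family_of

    rng = np.random.default_rng(0) if rng is None else rng
    if not matures:
        raise ValueError("at least one mature required")
    chrom_seqs = {
        f"chr{i + 1}": list(_random_background(chrom_len, gc, rng))
        for i in range(n_chroms)
    }
    chroms = list(chrom_seqs)
    occupied = {c: [] for c in chroms}
    truth = SyntheticTruth()

    def insert(chrom: str, pos: int, dna: str) -> None:
        chrom_seqs[chrom][pos : pos + len(dna)] = list(dna)

    for k in range(n_planted):
        mat = matures[k % len(matures)]
        fam = family_of(mat.id)
        motif = signature_motifs.get(fam) if signature_motifs else None
        pre_rna, offset = make_hairpin(
            mat.as_rna(), loop_len=loop_len, stem_mismatches=stem_mismatches,
            rng=rng, loop_motif=motif,
        )
        pre_dna = pre_rna.replace("U", "T")
        strand = "+" if rng.random() < 0.5 else "-"
        chrom, pos = _place(occupied, chroms, chrom_len, len(pre_dna), rng)
        seg = pre_dna if strand == "+" else reverse_complement(pre_dna)
        insert(chrom, pos, seg)
        L = len(mat)
        if strand == "+":
            m_start = pos + offset
        else:
            m_start = pos + len(pre_dna) - offset - L
        truth.planted.append(
            PlantedPrecursor(
                locus=GenomicInterval(chrom, pos, pos + len(pre_dna), strand),
                mature=GenomicInterval(chrom, m_start, m_start + L, strand),
                mature_id=mat.id,
                family=fam,
                precursor_rna=pre_rna,
                mature_offset=offset,
                ssr_motif=motif,
            )
        )

    for k in range(n_mutated_decoys):
        mat = matures[k % len(matures)]
        dna = list(mat.as_dna())
        n_mut = int(rng.integers(4, 7))
        for p in rng.choice(len(dna), size=n_mut, replace=False):
            choices = [b for b in "ACGT" if b != dna[p]]
            dna[p] = choices[rng.integers(3)]
        dna = "".join(dna)
        chrom, pos = _place(occupied, chroms, chrom_len, len(dna), rng)
        insert(chrom, pos, dna)
        truth.decoys.append(
            PlantedDecoy("mutated_mature", GenomicInterval(chrom, pos, pos + len(dna), "+"),
                         mat.id, n_mut)
        )

    for k in range(n_shuffled_decoys):
        mat = matures[(k + 1) % len(matures)]
        pre_rna, _ = make_hairpin(mat.as_rna(), loop_len=loop_len, rng=rng)
        dna = mononucleotide_shuffle(pre_rna.replace("U", "T"), rng)
        chrom, pos = _place(occupied, chroms, chrom_len, len(dna), rng)
        insert(chrom, pos, dna)
        truth.decoys.append(
            PlantedDecoy("shuffled_precursor", GenomicInterval(chrom, pos, pos + len(dna), "+"),
                         mat.id, 0)
        )

    for k in range(n_cascade_decoys):
        mat = matures[(k + 2) % len(matures)]
        mature_dna = mat.as_dna()
        tail = mononucleotide_shuffle(
            _random_background(loop_len, 0.5, rng) + reverse_complement(mature_dna), rng
        )
        dna = mature_dna + tail
        chrom, pos = _place(occupied, chroms, chrom_len, len(dna), rng)
        insert(chrom, pos, dna)
        truth.decoys.append(
            PlantedDecoy("cascade_decoy", GenomicInterval(chrom, pos, pos + len(dna), "+"),
                         mat.id, 0)
        )

    genome = [
        SequenceRecord(id=c, sequence="".join(chrom_seqs[c]), alphabet="dna")
        for c in chroms
    ]
    truth.verify_genome(genome)
    return genome, truth


# ---------------------------------------------------------------------------
# transcriptomes
# ---------------------------------------------------------------------------

_CODON_TABLE = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "C": ["TGT", "TGC"], "W": ["TGG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"], "G": ["GGT", "GGC", "GGA", "GGG"],
}
_AMINO_ACIDS = sorted(_CODON_TABLE)


def _biased_codon(aa: str, rng: np.random.Generator, bias: float) -> str:
    codons = _CODON_TABLE[aa]
    if len(codons) == 1 or rng.random() < bias:
        return codons[0]  # preferred codon
    return codons[1 + int(rng.integers(len(codons) - 1))]


def _coding_transcript(
    orf_aa: int, utr_range: tuple[int, int], gc: float, bias: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """(transcript DNA, protein) with a codon-biased ORF flanked by UTRs."""
    protein = "".join(rng.choice(_AMINO_ACIDS, size=orf_aa - 1))
    cds = "ATG" + "".join(_biased_codon(aa, rng, bias) for aa in protein)
    stop = ["TAA", "TGA", "TAG"][int(rng.integers(3))]
    utr5 = _random_background(int(rng.integers(*utr_range)), gc, rng)
    utr3 = _random_background(int(rng.integers(*utr_range)), gc, rng)
    transcript = utr5 + cds + stop + utr3
    return transcript, "M" + protein


def make_transcriptome(
    n_coding: int,
    n_noncoding: int,
    orf_aa_range: tuple[int, int] = (150, 250),
    utr_range: tuple[int, int] = (30, 150),
    gc: float = 0.45,
    codon_bias: float = 0.6,
    rng: np.random.Generator | None = None,
    id_prefix: str = "tx",
    max_noncoding_orf_aa: int = 120,
) -> tuple[list[SequenceRecord], SyntheticTruth, list[SequenceRecord]]:
    """Coding + non-coding transcripts, truth labels, and the protein FASTA.

    Coding transcripts place a codon-biased ORF between random UTRs;
    non-coding ones are dinucleotide shuffles of fresh coding templates
    (composition-matched, ORFs destroyed; reshuffled until the longest
    remaining ORF is below *max_noncoding_orf_aa*).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    transcripts: list[SequenceRecord] = []
    proteins: list[SequenceRecord] = []
    truth = SyntheticTruth()
    for i in range(n_coding):
        orf_aa = int(rng.integers(*orf_aa_range))
        t, prot = _coding_transcript(orf_aa, utr_range, gc, codon_bias, rng)
        tid = f"{id_prefix}_cod{i + 1:03d}"
        transcripts.append(SequenceRecord(id=tid, sequence=t, alphabet="dna"))
        proteins.append(
            SequenceRecord(id=f"{tid}_prot", sequence=prot, alphabet="protein")
        )
        truth.transcript_labels[tid] = "coding"
    for i in range(n_noncoding):
        orf_aa = int(rng.integers(*orf_aa_range))
        template, _ = _coding_transcript(orf_aa, utr_range, gc, codon_bias, rng)
        for _ in range(100):
            shuffled = dinucleotide_shuffle(template, rng)
            if longest_orf_aa(shuffled) < max_noncoding_orf_aa:
                break
        else:
            raise RuntimeError("could not shuffle away all long ORFs")
        tid = f"{id_prefix}_nc{i + 1:03d}"
        transcripts.append(SequenceRecord(id=tid, sequence=shuffled, alphabet="dna"))
        truth.transcript_labels[tid] = "noncoding"
    return transcripts, truth, proteins


# ---------------------------------------------------------------------------
# target sites
# ---------------------------------------------------------------------------


def plant_target_sites(
    matures: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    truth: SyntheticTruth,
    n_perfect: int = 5,
    n_penalty1: int = 5,
    n_negative: int = 5,
    rng: np.random.Generator | None = None,
    scheme: ExpectationScheme = DEFAULT_SCHEME,
    max_tries: int = 100,
) -> list[SequenceRecord]:
    """Insert designed target sites into transcripts; returns edited copies.

    Designs: expectation 0 (perfect complement), 1.0 (one mismatch outside
    the core region) and 4.0 (two core mismatches — a designed negative
    that must stay below the reporting cutoff of 2).  Edited positions are
    recorded as truth edges; collisions with earlier plants re-draw the
    position.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    seqs = {t.id: list(t.sequence) for t in transcripts}
    occupied: dict[str, list[tuple[int, int]]] = {t.id: [] for t in transcripts}
    designs = (
        [0.0] * n_perfect + [1.0] * n_penalty1 + [4.0] * n_negative
    )
    t_ids = [t.id for t in transcripts]
    for d_idx, design in enumerate(designs):
        mat = matures[d_idx % len(matures)]
        m_rna = mat.as_rna()
        L = len(m_rna)
        site_rna = "".join(_RNA_COMP[b] for b in reversed(m_rna))  # perfect site
        site = list(site_rna)
        if design == 1.0:
            # mismatch at mature position L (1-based, outside the core):
            # mature position L pairs site index 0
            site[0] = _mutate_to_nonpairing(site[0], m_rna[L - 1], rng)
        elif design > 2.0:
            core_lo, core_hi = scheme.core_range(L)
            for pos in (core_lo, core_lo + 2):  # two core mismatches -> 2 * 2.0
                idx = L - pos  # site index pairing mature position `pos` (1-based)
                site[idx] = _mutate_to_nonpairing(site[idx], m_rna[pos - 1], rng)
        site_dna = "".join(site).replace("U", "T")
        for _ in range(max_tries):
            tid = t_ids[int(rng.integers(len(t_ids)))]
            n = len(seqs[tid])
            if n <= L + 2:
                continue
            pos = int(rng.integers(1, n - L - 1))
            if all(pos + L <= s or e <= pos for s, e in occupied[tid]):
                break
        else:
            raise RuntimeError("could not place target site without collision")
        seqs[tid][pos : pos + L] = list(site_dna)
        occupied[tid].append((pos, pos + L))
        truth.target_edges.append(
            TargetEdge(mat.id, tid, pos, pos + L, design)
        )
    edited = [
        SequenceRecord(id=t.id, sequence="".join(seqs[t.id]), alphabet=t.alphabet,
                       description=t.description)
        for t in transcripts
    ]
    truth.verify_transcripts(edited)
    return edited


def make_mature_library(
    n: int = 12,
    length_range: tuple[int, int] = (19, 23),
    rng: np.random.Generator | None = None,
    species: str = "xxx",
    gc: float = 0.5,
) -> list[SequenceRecord]:
    """A miRBase-style mature library with family labels miR101, miR102, ..."""
    rng = np.random.default_rng(0) if rng is None else rng
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _random_background(L, gc, rng)
        out.append(
            SequenceRecord(
                id=f"{species}-miR{101 + i}a", sequence=seq, alphabet="dna",
                description=f"synthetic mature miRNA family miR{101 + i}",
            )
        )
    return out
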