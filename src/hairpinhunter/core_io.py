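"""Sequence records, genomic intervals, FASTA/GFF3/TSV I/O and run configuration.

Internal coordinates are 0-based half-open throughout the package; every
emitted annotation (GFF3) is 1-based inclusive, converted at the boundary.
Genomic sequences are handled as DNA; anything that enters the folding
engine is converted to the RNA alphabet first.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("hairpinhunter")

DNA_BASES = frozenset("ACGTN")
RNA_BASES = frozenset("ACGUN")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYBZXU*")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_RNA_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class ParseError(ValueError):
    """Raised on malformed input files."""


class AlphabetError(ValueError):
    """Raised when a sequence contains characters outside its declared alphabet."""


@dataclasses.dataclass
class SequenceRecord:
    """An identified nucleotide sequence.

    Parameters
    ----------
    id : str
        Identifier (first whitespace-delimited token of the FASTA header).
    sequence : str
        Upper-case sequence over ``{A,C,G,T,N}`` (dna) or ``{A,C,G,U,N}`` (rna).
    alphabet : {"dna", "rna"}
    description : str
        Remainder of the FASTA header, may be empty.
    """

    id: str
    sequence: str
    alphabet: str = "dna"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        allowed = {"dna": DNA_BASES, "rna": RNA_BASES, "protein": PROTEIN_CHARS}[
            self.alphabet
        ]
        bad = set(self.sequence) - allowed
        if bad:
            raise AlphabetError(
                f"record {self.id!r}: characters {sorted(bad)} not in {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def as_rna(self) -> str:
        """Sequence with T replaced by U."""
        return self.sequence.replace("T", "U")

    def as_dna(self) -> str:
        """Sequence with U replaced by T."""
        return self.sequence.replace("U", "T")


@dataclasses.dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def normalize_sequence(raw: str, alphabet: str) -> str:
    """Upper-case *raw* and fold T/U to the declared alphabet."""
    seq = raw.upper().replace(" ", "")
    if alphabet == "dna":
        seq = seq.replace("U", "T")
    elif alphabet == "rna":
        seq = seq.replace("T", "U")
    elif alphabet != "protein":
        raise ValueError(f"unknown alphabet {alphabet!r}")
    return seq


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[SequenceRecord]:
    """Read a (multi-record, wrapped or unwrapped) FASTA file.

    Records come back in file order; lowercase is upfolded and T/U is
    normalized to *alphabet*. A header with no sequence line, or sequence
    data before any header, is a :class:`ParseError` naming the line.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = normalize_sequence("".join(chunks), alphabet)
        if not seq:
            raise ParseError(f"{path}:{header_line}: header {header!r} has no sequence")
        fields = header.split(None, 1)
        rec_id = fields[0]
        if rec_id in seen:
            raise ParseError(f"{path}:{header_line}: duplicate id {rec_id!r}")
        seen.add(rec_id)
        records.append(
            SequenceRecord(
                id=rec_id,
                sequence=seq,
                alphabet=alphabet,
                description=fields[1] if len(fields) > 1 else "",
            )
        )
        header, chunks = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise ParseError(f"{path}:{line_no}: empty FASTA header")
            else:
                if header is None:
                    raise ParseError(f"{path}:{line_no}: sequence data before any header")
                chunks.append(line.strip())
        flush(line_no=-1)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    bad = set(seq) - DNA_BASES
    if bad:
        raise AlphabetError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    bad = set(seq) - RNA_BASES
    if bad:
        raise AlphabetError(f"non-RNA characters in sequence: {sorted(bad)}")
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def write_gff3(
    features: Sequence[tuple[GenomicInterval, dict]],
    path: str | Path,
    chrom_lengths: dict[str, int] | None = None,
    source: str = "hairpinhunter",
    feature_type: str = "ncRNA",
) -> None:
    """Write intervals as GFF3 (columns 4/5 are 1-based inclusive: start+1, end).

    *features* is a sequence of ``(interval, attributes)`` pairs; attribute
    dicts become the column-9 ``key=value`` list. If *chrom_lengths* is given,
    intervals beyond the end of their chromosome raise ``ValueError``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv, attrs in features:
            if chrom_lengths is not None:
                clen = chrom_lengths.get(iv.chrom)
                if clen is not None and iv.end > clen:
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length {clen}"
                    )
            ftype = attrs.get("type", feature_type)
            attr_str = ";".join(
                f"{k}={v}" for k, v in attrs.items() if k != "type"
            ) or "."
            fh.write(
                f"{iv.chrom}\t{source}\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attr_str}\n"
            )


def read_gff3(path: str | Path) -> list[tuple[GenomicInterval, dict]]:
    """Inverse of :func:`write_gff3` (columns 4/5 converted back to 0-based half-open)."""
    out: list[tuple[GenomicInterval, dict]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: expected 9 GFF3 columns, got {len(cols)}")
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if item:
                        k, _, v = item.partition("=")
                        attrs[k] = v
            attrs["type"] = cols[2]
            out.append(
                (
                    GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6]),
                    attrs,
                )
            )
    return out


@dataclasses.dataclass
class RunConfig:
    """Run configuration: thresholds, energy model parameters, seed, paths.

    Loaded from / saved to YAML; the effective config is echoed into every
    output directory so each catalog is reproducible from its own record.
    """

    seed: int = 0
    params: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        seed = int(data.pop("seed", 0))
        return cls(seed=seed, params=data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump({"seed": self.seed, **self.params}, fh, sort_keys=True)

    def get(self, key: str, default=None):
        return self.params.get(key, default)
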