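"""Simple-sequence-repeat detection and family signature densities.

SSRs are tandem repeats of 1–6 nt motifs.  Trinucleotide SSR "signatures"
are characteristic of individual miRNA families; the density statistic

    R = 100 * (# signature SSR tracts in the candidate) / L

(count per 100 nt) feeds the precursor filter cascade and its tie-break.

An occurrence is a *maximal* tandem tract (not extendable by even one
position in either direction at its period) of a *primitive* motif (one
that is not itself a repeat of a shorter motif), reported at its leftmost
phase.  Minimum repeat counts per period default to conventional
microsatellite minima (mono >= 5, di >= 3, tri..hexa >= 2) and are
configurable.

Motifs are canonicalized to their lexicographically smallest rotation on
the forward strand only when *matching* against a signature set, so that
an AUA-starting and a UAA-starting rendering of the same tract count as
one signature.  Tabulation of signatures keys on the motif as written at
the leftmost maximal tract.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("hairpinhunter")

DEFAULT_MIN_REPEATS = {1: 5, 2: 3, 3: 2, 4: 2, 5: 2, 6: 2}


class UnknownFamilyError(KeyError):
    """The requested family is absent from the signature table entirely
    (as opposed to present with no matching signatures)."""


@dataclasses.dataclass(frozen=True)
class SSROccurrence:
    """One maximal primitive tandem repeat tract."""

    motif: str
    start: int  # 0-based, leftmost phase
    repeat_count: int

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def span(self) -> int:
        return self.period * self.repeat_count

    @property
    def end(self) -> int:
        return self.start + self.span


def is_primitive(motif: str) -> bool:
    """True unless *motif* is an integer repeat of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return False
    return True


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation of *motif* (forward strand only)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def find_ssrs(
    seq: str,
    min_repeats: Mapping[int, int] | None = None,
    periods: Iterable[int] = (1, 2, 3, 4, 5, 6),
) -> list[SSROccurrence]:
    """All maximal primitive tandem repeats in *seq*, sorted by start.

    For each period p, maximal runs of the self-comparison ``seq[x] ==
    seq[x+p]`` delimit periodic tracts; a tract of total length t yields
    ``t // p`` full repeats reported at the leftmost phase.
    """
    if min_repeats is None:
        min_repeats = DEFAULT_MIN_REPEATS
    n = len(seq)
    out: list[SSROccurrence] = []
    for p in sorted(set(periods)):
        need = min_repeats.get(p)
        if need is None or n < p * need:
            continue
        x = 0
        while x < n - p:
            if seq[x] == seq[x + p]:
                run_start = x
                while x < n - p and seq[x] == seq[x + p]:
                    x += 1
                tract_len = (x - run_start) + p  # periodic interval length
                count = tract_len // p
                motif = seq[run_start : run_start + p]
                if count >= need and is_primitive(motif):
                    out.append(SSROccurrence(motif=motif, start=run_start, repeat_count=count))
            else:
                x += 1
    out.sort(key=lambda o: (o.start, o.period))
    return out


@dataclasses.dataclass
class SignatureTable:
    """Mapping family name -> set of trinucleotide signature motifs."""

    families: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for fam, motifs in self.families.items():
            for m in motifs:
                if len(m) != 3 or set(m) - set("ACGU"):
                    raise ValueError(
                        f"family {fam!r}: signature {m!r} is not a trinucleotide RNA motif"
                    )

    def canonical_set(self, family: str) -> frozenset[str]:
        if family not in self.families:
            raise UnknownFamilyError(
                f"family {family!r} not present in signature table "
                f"({len(self.families)} families known)"
            )
        return frozenset(canonical_rotation(m) for m in self.families[family])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"family", "motif"} <= set(df.columns):
            raise ValueError(f"{path}: signature TSV needs columns 'family' and 'motif'")
        fams: dict[str, set[str]] = {}
        for fam, motif in zip(df["family"], df["motif"]):
            fams.setdefault(fam, set()).add(motif.upper().replace("T", "U"))
        return cls({f: frozenset(m) for f, m in fams.items()})

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"family": fam, "motif": m}
            for fam in sorted(self.families)
            for m in sorted(self.families[fam])
        ]
        pd.DataFrame(rows, columns=["family", "motif"]).to_csv(path, sep="\t", index=False)


def signature_density_r(
    seq: str,
    family: str,
    table: SignatureTable,
    min_repeats: Mapping[int, int] | None = None,
) -> float:
    """Signature SSR density R: matching tracts per 100 nt.

    A tract matches when its motif, reduced to the canonical rotation, is in
    the family's (canonicalized) signature set.  Only trinucleotide tracts
    are considered, signatures being defined at window size three.
    """
    sig = table.canonical_set(family)  # raises UnknownFamilyError if absent
    if not seq:
        return 0.0
    hits = [
        occ
        for occ in find_ssrs(seq, min_repeats=min_repeats, periods=(3,))
        if canonical_rotation(occ.motif) in sig
    ]
    return 100.0 * len(hits) / len(seq)


def tabulate_family_signatures(
    families: Mapping[str, Sequence[str]],
    min_repeats: Mapping[int, int] | None = None,
    min_members_with_motif: int = 1,
) -> tuple[SignatureTable, pd.DataFrame]:
    """Derive per-family trinucleotide signatures from pre-miR corpora.

    A motif is a signature of a family when it occurs as an SSR tract in at
    least *min_members_with_motif* of the family's precursors.  The summary
    frame reports, per motif, the percentage of families carrying it.
    Empty families are excluded with a warning.
    """
    if not families:
        raise ValueError("at least one family required")
    fam_motifs: dict[str, frozenset[str]] = {}
    for fam, seqs in families.items():
        seqs = [s for s in seqs if s]
        if not seqs:
            logger.warning("family %r has no precursors; excluded from signature table", fam)
            continue
        counts: dict[str, int] = {}
        for s in seqs:
            motifs_here = {
                occ.motif for occ in find_ssrs(s, min_repeats=min_repeats, periods=(3,))
            }
            for m in motifs_here:
                counts[m] = counts.get(m, 0) + 1
        fam_motifs[fam] = frozenset(
            m for m, c in counts.items() if c >= min_members_with_motif
        )
    n_fam = len(fam_motifs)
    if n_fam == 0:
        raise ValueError("all families empty")
    motif_fams: dict[str, int] = {}
    for motifs in fam_motifs.values():
        for m in motifs:
            motif_fams[m] = motif_fams.get(m, 0) + 1
    summary = pd.DataFrame(
        [
            {"motif": m, "n_families": c, "percent_of_families": 100.0 * c / n_fam}
            for m, c in sorted(motif_fams.items())
        ],
        columns=["motif", "n_families", "percent_of_families"],
    )
    return SignatureTable(fam_motifs), summary
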