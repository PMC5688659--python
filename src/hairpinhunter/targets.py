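"""miRNA target prediction on coding transcripts and lncRNAs.

Complementarity between a mature miRNA (5'->3') and a candidate target
site is scored with an additive *expectation* penalty: each aligned
position contributes 0 for a Watson-Crick pair, 0.5 for a G:U wobble and
1.0 for any other mismatch; a bulged nucleotide (at most one per duplex)
costs 2.0.  Penalties are doubled inside the core region of the miRNA
(positions 2-13 on the canonical 21-nt scale, rescaled proportionally for
other mature lengths), where plant target recognition is most sensitive.
A perfect complement scores 0 and lower is better; sites above the
expectation cutoff (default 2.0) are rejected.

A site is called *cleavage* when the central positions (9-11 on the 21-nt
scale, rescaled) carry no mismatch or gap (wobbles allowed), otherwise
*translation* (inhibition without slicing).

Accepted sites are then checked for accessibility: the target-site
unpairing energy UPE is the energy cost of opening every base of the site
in the local secondary structure (site plus 17 nt upstream and 13 nt
downstream of transcript context), computed as constrained minus
unconstrained MFE.  Sites with UPE above the cutoff (default 25 kcal/mol)
are discarded.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from .core_io import SequenceRecord
from .folding import DEFAULT_MODEL, EnergyModel, constrained_mfe, encode_rna, fold_mfe

logger = logging.getLogger("hairpinhunter")

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclasses.dataclass(frozen=True)
class ExpectationScheme:
    """Penalty constants and position maps of the expectation score."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 2.0
    core_factor: float = 2.0
    core_span: tuple[int, int] = (2, 13)  # 1-based, on the reference length
    central_span: tuple[int, int] = (9, 11)
    ref_len: int = 21
    max_gaps: int = 1

    def core_range(self, length: int) -> tuple[int, int]:
        """1-based inclusive core positions rescaled to *length*."""
        lo = max(1, _round_half_up(self.core_span[0] * length / self.ref_len))
        hi = min(length, _round_half_up(self.core_span[1] * length / self.ref_len))
        return lo, hi

    def central_range(self, length: int) -> tuple[int, int]:
        lo = max(1, _round_half_up(self.central_span[0] * length / self.ref_len))
        hi = min(length, _round_half_up(self.central_span[1] * length / self.ref_len))
        return lo, hi

    def position_weights(self, length: int) -> np.ndarray:
        """Per-position multiplier (1-based core positions doubled)."""
        lo, hi = self.core_range(length)
        w = np.ones(length)
        w[lo - 1 : hi] = self.core_factor
        return w


DEFAULT_SCHEME = ExpectationScheme()


def _pair_penalty(m: str, t: str, scheme: ExpectationScheme) -> float:
    if (m, t) in _WC:
        return 0.0
    if (m, t) in _WOBBLE:
        return scheme.wobble
    return scheme.mismatch


@dataclasses.dataclass
class ScoredDuplex:
    """Best alignment of one mature against one site (both 5'->3' RNA)."""

    expectation: float
    mature_aln: str  # mature 5'->3', '-' at a mature gap
    site_aln: str  # site 3'->5' under the mature, '-' at a site gap
    position_penalties: tuple  # per mature position (gap positions get the gap cost)
    gap_mature_pos: int | None  # 1-based mature position of the bulge, if any

    def central_clean(self, scheme: ExpectationScheme) -> bool:
        """True when no mismatch or gap falls in the central positions."""
        length = len(self.position_penalties)
        lo, hi = scheme.central_range(length)
        for pos in range(lo, hi + 1):
            pen = self.position_penalties[pos - 1]
            if pen >= scheme.mismatch:  # mismatch or gap; wobble is below
                return False
        if self.gap_mature_pos is not None and lo <= self.gap_mature_pos <= hi:
            return False
        return True


def score_duplex(
    mature: str, site: str, scheme: ExpectationScheme = DEFAULT_SCHEME
) -> ScoredDuplex:
    """Best (lowest-expectation) alignment of *mature* against *site*.

    The site is given 5'->3' on the transcript; the duplex is antiparallel,
    so mature position i pairs site position ``len(site)-1-i`` (up to the
    single permitted bulge).  ``len(site)`` must be within one of
    ``len(mature)``.
    """
    if not mature or not site:
        raise ValueError("mature and site must be non-empty")
    L, Ls = len(mature), len(site)
    if abs(Ls - L) > scheme.max_gaps:
        raise ValueError(
            f"site length {Ls} incompatible with mature length {L} at <= "
            f"{scheme.max_gaps} gap(s)"
        )
    sr = site[::-1]  # sr[i] faces mature[i]
    w = scheme.position_weights(L)

    def base_pen(i: int, j: int) -> float:
        return _pair_penalty(mature[i], sr[j], scheme) * w[i]

    best: ScoredDuplex | None = None

    if Ls == L:
        pens = tuple(base_pen(i, i) for i in range(L))
        best = ScoredDuplex(float(sum(pens)), mature, sr, pens, None)
    elif Ls == L + 1:
        # one bulged site nucleotide between mature positions j and j+1
        for j in range(1, L):
            pens = [base_pen(i, i) for i in range(j)]
            gap_cost = scheme.gap * w[j]
            pens.append(gap_cost)  # bookkeeping: charge at position j+1 (1-based)
            pens_tail = [base_pen(i, i + 1) for i in range(j, L)]
            # position j's own pairing penalty still applies
            total = sum(pens[:-1]) + gap_cost + sum(pens_tail)
            per_pos = tuple(
                list(pens[:-1]) + [gap_cost + pens_tail[0]] + pens_tail[1:]
            )
            if best is None or total < best.expectation:
                m_aln = mature[:j] + "-" + mature[j:]
                s_aln = sr
                best = ScoredDuplex(float(total), m_aln, s_aln, per_pos, j + 1)
    else:  # Ls == L - 1: one bulged (unpaired) mature nucleotide
        for j in range(1, L - 1):
            head = [base_pen(i, i) for i in range(j)]
            gap_cost = scheme.gap * w[j]
            tail = [base_pen(i, i - 1) for i in range(j + 1, L)]
            total = sum(head) + gap_cost + sum(tail)
            per_pos = tuple(head + [gap_cost] + tail)
            if best is None or total < best.expectation:
                m_aln = mature
                s_aln = sr[:j] + "-" + sr[j:]
                best = ScoredDuplex(float(total), m_aln, s_aln, per_pos, j + 1)
    assert best is not None
    return best


def score_expectation(
    mature: str, site: str, scheme: ExpectationScheme = DEFAULT_SCHEME
) -> float:
    """Expectation penalty of the best mature/site alignment (0 = perfect)."""
    return score_duplex(mature, site, scheme).expectation


@dataclasses.dataclass
class TargetSite:
    """One predicted miRNA:transcript interaction."""

    mature_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    expectation: float
    duplex: ScoredDuplex
    mode: str  # cleavage | translation
    upe: float | None = None


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _penalty_table(scheme: ExpectationScheme) -> np.ndarray:
    tab = np.empty((4, 4))
    for m, mi in _CODE.items():
        for t, ti in _CODE.items():
            tab[mi, ti] = _pair_penalty(m, t, scheme)
    return tab


def find_target_sites(
    mature: SequenceRecord | str,
    transcript: SequenceRecord | str,
    max_expectation: float = 2.0,
    scheme: ExpectationScheme = DEFAULT_SCHEME,
    mature_id: str = "mature",
    transcript_id: str = "transcript",
) -> list[TargetSite]:
    """Every site on *transcript* whose best alignment scores <= the cutoff.

    A vectorized screen computes exact ungapped scores for every offset and
    a lower bound for every single-bulge alignment; surviving candidates
    are re-scored exactly with :func:`score_duplex`.  Overlapping candidate
    sites are collapsed to the local expectation minimum (ties: leftmost,
    then shorter).
    """
    if isinstance(mature, SequenceRecord):
        mature_id, m_seq = mature.id, mature.as_rna()
    else:
        m_seq = mature.upper().replace("T", "U")
    if isinstance(transcript, SequenceRecord):
        transcript_id, t_seq = transcript.id, transcript.as_rna()
    else:
        t_seq = transcript.upper().replace("T", "U")
    L, n = len(m_seq), len(t_seq)
    if n < L:
        return []
    try:
        t = encode_rna(t_seq)
        m = encode_rna(m_seq)
    except Exception:
        logger.warning("skipping %s/%s: ambiguous bases", mature_id, transcript_id)
        return []

    tab = _penalty_table(scheme)
    w = scheme.position_weights(L)
    wr = w[::-1]
    mr = m[::-1]
    n_off = n - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(t, L)  # (n_off, L)
    P = tab[mr[None, :], windows] * wr[None, :]
    E0 = P.sum(axis=1)
    # cumulative sums for the bulge screens
    C = np.concatenate([np.zeros((n_off, 1)), np.cumsum(P, axis=1)], axis=1)

    candidates: dict[tuple[int, int], TargetSite] = {}

    def consider(start: int, end: int) -> None:
        key = (start, end)
        if key in candidates:
            return
        duplex = score_duplex(m_seq, t_seq[start:end], scheme)
        if duplex.expectation <= max_expectation:
            mode = "cleavage" if duplex.central_clean(scheme) else "translation"
            candidates[key] = TargetSite(
                mature_id, transcript_id, start, end, duplex.expectation, duplex, mode
            )

    for o in np.nonzero(E0 <= max_expectation)[0]:
        consider(int(o), int(o) + L)

    if scheme.max_gaps >= 1 and n_off >= 2:
        # site bulge (site length L+1): rows o and o+1, split at j=1..L-1
        j = np.arange(1, L)
        bulge_t = C[:-1, :][:, j] + (E0[1:, None] - C[1:, :][:, j]) + scheme.gap
        for o in np.nonzero(bulge_t.min(axis=1) <= max_expectation)[0]:
            consider(int(o), int(o) + L + 1)
        # mature bulge (site length L-1): prefix row o (k<j), suffix row o-1 (k>j)
        if L >= 3:
            j = np.arange(1, L - 1)
            bulge_m = C[1:, :][:, j] + (E0[:-1, None] - C[:-1, :][:, j + 1]) + scheme.gap
            for o_idx in np.nonzero(bulge_m.min(axis=1) <= max_expectation)[0]:
                o = int(o_idx) + 1
                if o + L - 1 <= n:
                    consider(o, o + L - 1)

    sites = sorted(candidates.values(), key=lambda s: (s.start, s.end))
    # collapse overlapping sites to the local expectation minimum
    collapsed: list[TargetSite] = []
    cluster: list[TargetSite] = []
    for s in sites:
        if cluster and s.start < max(c.end for c in cluster):
            cluster.append(s)
        else:
            if cluster:
                collapsed.append(
                    min(cluster, key=lambda c: (c.expectation, c.start, c.end - c.start))
                )
            cluster = [s]
    if cluster:
        collapsed.append(
            min(cluster, key=lambda c: (c.expectation, c.start, c.end - c.start))
        )
    return collapsed


def compute_upe(
    site_start: int,
    site_end: int,
    transcript: str,
    model: EnergyModel = DEFAULT_MODEL,
    flank_up: int = 17,
    flank_down: int = 13,
) -> float:
    """Target-site unpairing energy (kcal/mol, >= 0).

    The transcript subsequence spanning the site plus *flank_up* upstream
    and *flank_down* downstream nucleotides (clipped at the transcript
    ends) is folded twice: unconstrained and with every site base forced
    unpaired.  UPE is the energy difference.
    """
    t = transcript.upper().replace("T", "U")
    n = len(t)
    if not (0 <= site_start < site_end <= n):
        raise IndexError(f"site ({site_start},{site_end}) out of bounds for length {n}")
    lo = max(0, site_start - flank_up)
    hi = min(n, site_end + flank_down)
    sub = t[lo:hi]
    region = (site_start - lo, site_end - lo)
    e_free = fold_mfe(sub, model).energy
    e_con = constrained_mfe(sub, model, unpaired_region=region).energy
    return float(e_con - e_free)


def predict_targets(
    matures: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    lncrnas: Sequence[SequenceRecord] = (),
    max_expectation: float = 2.0,
    max_upe: float = 25.0,
    scheme: ExpectationScheme = DEFAULT_SCHEME,
    model: EnergyModel = DEFAULT_MODEL,
    flank_up: int = 17,
    flank_down: int = 13,
):
    """Run target prediction for coding transcripts and lncRNAs.

    Returns ``(coding_df, lncrna_df, graph)``: one table per subject
    class (identical scoring configuration for both) and a bipartite
    networkx graph with expectation edge attributes.
    """
    import networkx as nx
    import pandas as pd

    if not matures or (not transcripts and not lncrnas):
        logger.warning("empty catalog(s): target prediction produces empty output")

    def run(subjects: Sequence[SequenceRecord], subject_class: str) -> list[dict]:
        rows = []
        for subj in subjects:
            subj_rna = subj.as_rna()
            for mat in matures:
                for site in find_target_sites(
                    mat, subj, max_expectation=max_expectation, scheme=scheme
                ):
                    upe = compute_upe(
                        site.start, site.end, subj_rna, model, flank_up, flank_down
                    )
                    if upe > max_upe:
                        continue
                    rows.append(
                        {
                            "mirna": mat.id,
                            "transcript": subj.id,
                            "subject_class": subject_class,
                            "start": site.start + 1,  # 1-based inclusive in output
                            "end": site.end,
                            "expectation": site.expectation,
                            "upe": upe,
                            "mode": site.mode,
                            "duplex_mirna": site.duplex.mature_aln,
                            "duplex_site": site.duplex.site_aln,
                        }
                    )
        return rows

    cols = [
        "mirna", "transcript", "subject_class", "start", "end",
        "expectation", "upe", "mode", "duplex_mirna", "duplex_site",
    ]
    coding_df = pd.DataFrame(run(transcripts, "coding"), columns=cols)
    lnc_df = pd.DataFrame(run(lncrnas, "lncRNA"), columns=cols)

    graph = nx.Graph()
    for df in (coding_df, lnc_df):
        for _, row in df.iterrows():
            graph.add_node(row["mirna"], kind="miRNA")
            graph.add_node(row["transcript"], kind=row["subject_class"])
            graph.add_edge(
                row["mirna"], row["transcript"], expectation=float(row["expectation"])
            )
    return coding_df, lnc_df, graph


def export_network(graph, sif_path, graphml_path=None) -> None:
    """Write the interaction network as SIF (``miRNA targets transcript``)
    and optionally GraphML with expectation edge attributes."""
    import networkx as nx

    with open(sif_path, "w") as fh:
        for u, v, data in graph.edges(data=True):
            a, b = (u, v) if graph.nodes[u].get("kind") == "miRNA" else (v, u)
            fh.write(f"{a}\ttargets\t{b}\n")
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
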