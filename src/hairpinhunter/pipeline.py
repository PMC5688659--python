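"""End-to-end workflows with per-stage audit trails.

Three orchestrators wire the library modules into the two discovery
pipelines and the target-prediction run, recording an
:class:`AuditRecord` per stage (input/output counts, rejection reasons,
thresholds in force, seed) so every catalog is inspectable, and a
packaged synthetic benchmark that scores each pipeline against the truth
ledger of the generator.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import GenomicInterval, SequenceRecord, write_fasta, write_gff3
from .folding import DEFAULT_MODEL, EnergyModel
from .lncrna import (
    CodingPotentialScorer,
    classify_coding_potential,
    length_filter,
    orf_filter,
    protein_similarity_filter,
)
from .mirna import (
    FilterThresholds,
    WindowPolicy,
    apply_filter_cascade,
    assign_family_and_name,
    exclude_coding,
    extract_windows,
    scan_homology,
    select_best_candidate,
)
from .ssr import SignatureTable, tabulate_family_signatures
from .synthetic import (
    make_genome,
    make_mature_library,
    make_transcriptome,
    plant_target_sites,
)
from .targets import predict_targets

logger = logging.getLogger("hairpinhunter")


@dataclasses.dataclass
class AuditRecord:
    """One pipeline stage: counts in/out and why items were rejected."""

    stage: str
    n_in: int
    n_out: int
    rejection_reasons: dict = dataclasses.field(default_factory=dict)
    thresholds: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_in < 0 or self.n_out < 0:
            raise ValueError("audit counts must be non-negative")
        if self.n_out > self.n_in:
            raise ValueError(
                f"stage {self.stage!r}: output ({self.n_out}) exceeds input ({self.n_in})"
            )


def audit_frame(audits: Sequence[AuditRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stage": a.stage, "n_in": a.n_in, "n_out": a.n_out,
                "rejections": ";".join(f"{k}={v}" for k, v in sorted(a.rejection_reasons.items())),
            }
            for a in audits
        ]
    )


# ---------------------------------------------------------------------------
# miRNA pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MirnaResult:
    catalog: pd.DataFrame
    audits: list
    accepted: list  # PrecursorCandidate
    rejected_hits: list  # (HomologyHit, reason)


def run_mirna_pipeline(
    genome: Sequence[SequenceRecord],
    matures: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord] | None = None,
    thresholds: FilterThresholds | None = None,
    policy: WindowPolicy | None = None,
    signature_table: SignatureTable | None = None,
    model: EnergyModel = DEFAULT_MODEL,
    name_prefix: str = "syn",
    seed: int | None = None,
    orf_min_aa: int = 80,
    out_dir: str | Path | None = None,
) -> MirnaResult:
    """Homology scan -> windows -> coding exclusion -> cascade -> catalog.

    Every homology hit appears exactly once in the result: either as an
    accepted locus or in ``rejected_hits`` with its reason.
    """
    thresholds = thresholds or FilterThresholds()
    policy = policy or WindowPolicy()
    audits: list[AuditRecord] = []
    genome_by_id = {g.id: g for g in genome}

    hits = scan_homology(genome, matures)
    # the scan maps queries to an open-ended number of hits; record the hit
    # count in the reasons histogram rather than as a filtered output count
    audits.append(AuditRecord("homology_scan", len(matures), len(matures),
                              {"hits_found": len(hits)}, seed=seed))

    accepted = []
    rejected = []
    reasons: dict[str, int] = {}
    n_windows_total = 0
    for hit in hits:
        windows = extract_windows(hit, genome_by_id, policy)
        n_windows_total += len(windows)
        if not windows:
            rejected.append((hit, "no_window"))
            reasons["no_window"] = reasons.get("no_window", 0) + 1
            continue
        noncoding = exclude_coding(windows, proteins, orf_min_aa=orf_min_aa)
        if not noncoding:
            rejected.append((hit, "coding"))
            reasons["coding"] = reasons.get("coding", 0) + 1
            continue
        for cand in noncoding:
            apply_filter_cascade(cand, thresholds, signature_table, model)
        best = select_best_candidate(noncoding)
        if best is None:
            # most frequent failing filter across this hit's windows
            fails: dict[str, int] = {}
            for cand in noncoding:
                for name, ok in cand.verdicts.items():
                    if not ok:
                        fails[name] = fails.get(name, 0) + 1
            reason = "cascade:" + (max(fails, key=fails.get) if fails else "unknown")
            rejected.append((hit, reason))
            reasons[reason] = reasons.get(reason, 0) + 1
        else:
            accepted.append(best)
    audits.append(
        AuditRecord(
            "cascade", len(hits), len(accepted), reasons,
            thresholds=dataclasses.asdict(thresholds), seed=seed,
        )
    )

    # one precursor per locus: a hairpin is hit once per arm (the star arm
    # is near-complementary to the mature).  Two accepted candidates are the
    # same hairpin when each one's mature interval lies inside the other's
    # precursor window; such pairs collapse to the best-supported candidate.
    # Mutual containment keeps adjacent but distinct loci apart.
    accepted.sort(key=lambda c: (c.window.chrom, c.window.start))

    def same_locus(a, b) -> bool:
        return (
            a.window.chrom == b.window.chrom
            and a.window.start <= b.mature_interval.start
            and b.mature_interval.end <= a.window.end
            and b.window.start <= a.mature_interval.start
            and a.mature_interval.end <= b.window.end
        )

    deduped = []
    n_dup = 0
    for cand in accepted:
        merged = False
        for i, prev in enumerate(deduped):
            if same_locus(prev, cand):
                keep = min(
                    (prev, cand),
                    key=lambda c: (c.hit.mismatches, -c.features.mfei,
                                   -c.features.r, c.window.start),
                )
                drop = cand if keep is prev else prev
                deduped[i] = keep
                rejected.append((drop.hit, "duplicate_locus"))
                n_dup += 1
                merged = True
                break
        if not merged:
            deduped.append(cand)
    accepted = deduped
    audits.append(AuditRecord("locus_dedup", len(accepted) + n_dup, len(accepted),
                              {"duplicate_locus": n_dup}, seed=seed))
    catalog = assign_family_and_name(accepted, prefix=name_prefix)
    audits.append(AuditRecord("catalog", len(accepted), len(accepted), seed=seed))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        catalog.to_csv(out / "mirna_catalog.tsv", sep="\t", index=False)
        audit_frame(audits).to_csv(out / "mirna_audit.tsv", sep="\t", index=False)
        if len(catalog):
            write_gff3(
                [
                    (GenomicInterval(r.chrom, r.start, r.end, r.strand),
                     {"ID": r.name, "type": "miRNA_primary_transcript", "family": r.family})
                    for r in catalog.itertuples()
                ],
                out / "mirna_precursors.gff3",
                chrom_lengths={g.id: len(g) for g in genome},
            )
            write_fasta(
                [SequenceRecord(id=r.name, sequence=r.precursor_seq, alphabet="rna")
                 for r in catalog.itertuples()],
                out / "mirna_precursors.fa",
            )
    return MirnaResult(catalog, audits, accepted, rejected)


# ---------------------------------------------------------------------------
# lncRNA pipeline
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LncrnaResult:
    lncrnas: list  # SequenceRecord
    audits: list
    classifications: pd.DataFrame  # per-transcript stage outcomes


def run_lncrna_pipeline(
    transcripts: Sequence[SequenceRecord],
    scorer,
    proteins: Sequence[SequenceRecord] | None = None,
    min_len: int = 200,
    max_orf_aa: int = 120,
    s_noncoding: float = -0.5,
    s_coding: float = 1.0,
    secondary_cutoff: float = 0.2,
    max_identity: float = 40.0,
    e_cutoff: float = 1e-3,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> LncrnaResult:
    """Length -> ORF -> primary score -> secondary score -> similarity.

    Stage order is fixed; each stage's input/output counts are audited and
    monotonically non-increasing.  *scorer* provides ``primary_score`` and
    ``secondary_score`` (built-in or external adapter); transcripts the
    scorer fails on are flagged unresolved and excluded.
    """
    audits: list[AuditRecord] = []
    outcome: dict[str, str] = {}

    stage1 = length_filter(transcripts, min_len)
    for t in transcripts:
        if t not in stage1:
            outcome[t.id] = "too_short"
    audits.append(AuditRecord("length_filter", len(transcripts), len(stage1),
                              {"too_short": len(transcripts) - len(stage1)},
                              {"min_len": min_len}, seed))

    stage2 = orf_filter(stage1, max_orf_aa)
    for t in stage1:
        if t not in stage2:
            outcome[t.id] = "long_orf"
    audits.append(AuditRecord("orf_filter", len(stage1), len(stage2),
                              {"long_orf": len(stage1) - len(stage2)},
                              {"max_orf_aa": max_orf_aa}, seed))

    stage3: list[SequenceRecord] = []
    reasons: dict[str, int] = {}
    for t in stage2:
        sc = scorer.for_id(t.id) if hasattr(scorer, "for_id") else scorer
        try:
            res = classify_coding_potential(
                t.sequence, sc, s_noncoding, s_coding, secondary_cutoff
            )
        except Exception:
            logger.warning("scorer failed on %s; excluded as unresolved", t.id)
            outcome[t.id] = "unresolved"
            reasons["unresolved"] = reasons.get("unresolved", 0) + 1
            continue
        if res.is_noncoding:
            stage3.append(t)
            outcome[t.id] = res.label
        else:
            outcome[t.id] = res.label  # coding | neutral (discarded)
            reasons[res.label] = reasons.get(res.label, 0) + 1
    audits.append(AuditRecord("coding_potential", len(stage2), len(stage3), reasons,
                              {"s_noncoding": s_noncoding, "s_coding": s_coding,
                               "secondary_cutoff": secondary_cutoff}, seed))

    stage4 = protein_similarity_filter(stage3, proteins, max_identity, e_cutoff)
    for t in stage3:
        if t not in stage4:
            outcome[t.id] = "protein_similarity"
    audits.append(AuditRecord("protein_similarity", len(stage3), len(stage4),
                              {"similar_to_protein": len(stage3) - len(stage4)},
                              {"max_identity": max_identity, "e_cutoff": e_cutoff}, seed))

    for t in stage4:
        outcome[t.id] = outcome.get(t.id, "noncoding") + "+lncRNA"
    classifications = pd.DataFrame(
        [{"transcript": t.id, "outcome": outcome.get(t.id, ""),
          "is_lncrna": t in stage4} for t in transcripts]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if stage4:
            write_fasta(stage4, out / "lncrnas.fa")
        audit_frame(audits).to_csv(out / "lncrna_audit.tsv", sep="\t", index=False)
        classifications.to_csv(out / "lncrna_classifications.tsv", sep="\t", index=False)
    return LncrnaResult(stage4, audits, classifications)


# ---------------------------------------------------------------------------
# target pipeline
# ---------------------------------------------------------------------------


def run_target_pipeline(
    matures: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    lncrnas: Sequence[SequenceRecord] = (),
    max_expectation: float = 2.0,
    max_upe: float = 25.0,
    model: EnergyModel = DEFAULT_MODEL,
    out_dir: str | Path | None = None,
):
    """Target prediction on coding transcripts and lncRNAs with one config."""
    coding_df, lnc_df, graph = predict_targets(
        matures, transcripts, lncrnas,
        max_expectation=max_expectation, max_upe=max_upe, model=model,
    )
    if out_dir is not None:
        from .targets import export_network

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        coding_df.to_csv(out / "targets_coding.tsv", sep="\t", index=False)
        lnc_df.to_csv(out / "targets_lncrna.tsv", sep="\t", index=False)
        export_network(graph, out / "targets.sif", out / "targets.graphml")
    return coding_df, lnc_df, graph


# ---------------------------------------------------------------------------
# packaged synthetic benchmark
# ---------------------------------------------------------------------------

#: trinucleotide signature motifs cycled across synthetic miRNA families
SIGNATURE_MOTIF_CYCLE = ("AAU", "AGA", "UGU", "CUC", "AAG", "UAU")


def benchmark_conditions(seed: int = 42) -> dict:
    """The packaged study conditions: generator inputs for the benchmark."""
    return {
        "seed": seed,
        "n_matures": 12,
        "n_chroms": 2,
        "chrom_len": 10_000,
        "gc": 0.5,
        "n_planted": 10,
        "n_mutated_decoys": 5,
        "n_shuffled_decoys": 5,
        "n_cascade_decoys": 5,
        "n_train_coding": 60,
        "n_train_noncoding": 60,
        "n_test_coding_long": 15,
        "n_test_coding_short": 10,
        "n_test_noncoding": 25,
        "n_perfect_sites": 5,
        "n_penalty1_sites": 5,
        "n_negative_sites": 5,
    }


def run_mirna_benchmark(seed: int = 42, conditions: Mapping | None = None) -> dict:
    """Generate the seeded genome, run the miRNA pipeline, score recovery.

    Returns sensitivity (planted precursors recovered with the mature
    within +/- 5 nt), FDR, and the underlying result objects.
    """
    cond = dict(conditions or benchmark_conditions(seed))
    rng = np.random.default_rng(cond["seed"])
    matures = make_mature_library(cond["n_matures"], rng=rng)
    from .mirna import family_of

    motifs = {
        family_of(m.id): SIGNATURE_MOTIF_CYCLE[i % len(SIGNATURE_MOTIF_CYCLE)]
        for i, m in enumerate(matures)
    }
    genome, truth = make_genome(
        matures,
        n_chroms=cond["n_chroms"], chrom_len=cond["chrom_len"], gc=cond["gc"],
        n_planted=cond["n_planted"], n_mutated_decoys=cond["n_mutated_decoys"],
        n_shuffled_decoys=cond["n_shuffled_decoys"],
        n_cascade_decoys=cond["n_cascade_decoys"],
        rng=rng, signature_motifs=motifs,
    )
    fam_seqs: dict[str, list[str]] = {}
    for p in truth.planted:
        fam_seqs.setdefault(p.family, []).append(p.precursor_rna)
    table, _ = tabulate_family_signatures(fam_seqs)
    result = run_mirna_pipeline(
        genome, matures, signature_table=table, seed=cond["seed"],
    )
    recovered = 0
    matched_loci: set[int] = set()
    for p in truth.planted:
        # a hairpin can be recovered through either helical arm; the star
        # arm occupies the far end of the precursor
        Lm, Lp = len(p.mature), len(p.precursor_rna)
        if p.locus.strand == "+":
            star_start = p.locus.start + Lp - Lm
        else:
            star_start = p.locus.start
        arms = [(p.mature.start, p.mature.end), (star_start, star_start + Lm)]
        for idx, row in result.catalog.iterrows():
            if row["chrom"] != p.mature.chrom:
                continue
            if any(
                abs(row["mature_start"] - a) <= 5 and abs(row["mature_end"] - b) <= 5
                for a, b in arms
            ):
                recovered += 1
                matched_loci.add(idx)
                break
    n_accepted = len(result.catalog)
    false_discoveries = n_accepted - len(matched_loci)
    return {
        "sensitivity": recovered / max(len(truth.planted), 1),
        "fdr": false_discoveries / n_accepted if n_accepted else 0.0,
        "n_planted": len(truth.planted),
        "n_accepted": n_accepted,
        "result": result,
        "truth": truth,
        "genome": genome,
        "matures": matures,
    }


def run_lncrna_benchmark(seed: int = 42, conditions: Mapping | None = None) -> dict:
    """Train the coding scorer, classify a held-out transcript set, score it.

    The held-out set mixes easy coding transcripts (long ORFs, removed by
    the ORF filter), hard coding transcripts (80-115 aa ORFs that only the
    coding-potential stages can catch) and dinucleotide-shuffled
    non-coding transcripts.
    """
    cond = dict(conditions or benchmark_conditions(seed))
    rng = np.random.default_rng(cond["seed"] + 1)
    # training corpus spans the ORF-length range the scorer will face:
    # half long ORFs, half short (ORF-filter-passing) ones
    half_c = cond["n_train_coding"] // 2
    half_n = cond["n_train_noncoding"] // 2
    train_long, truth_tl, _ = make_transcriptome(
        half_c, half_n, rng=rng, id_prefix="trainL"
    )
    train_short, truth_ts, _ = make_transcriptome(
        cond["n_train_coding"] - half_c, cond["n_train_noncoding"] - half_n,
        orf_aa_range=(80, 115), rng=rng, id_prefix="trainS",
    )
    train_tx = train_long + train_short
    train_labels = {**truth_tl.transcript_labels, **truth_ts.transcript_labels}
    coding_train = [t.sequence for t in train_tx if train_labels[t.id] == "coding"]
    noncoding_train = [t.sequence for t in train_tx if train_labels[t.id] == "noncoding"]
    scorer = CodingPotentialScorer().fit(coding_train, noncoding_train)

    test_long, truth_long, proteins = make_transcriptome(
        cond["n_test_coding_long"], 0, rng=rng, id_prefix="testL"
    )
    test_short, truth_short, _ = make_transcriptome(
        cond["n_test_coding_short"], cond["n_test_noncoding"],
        orf_aa_range=(80, 115), rng=rng, id_prefix="testS",
    )
    transcripts = test_long + test_short
    labels = {**truth_long.transcript_labels, **truth_short.transcript_labels}

    result = run_lncrna_pipeline(transcripts, scorer, proteins=proteins, seed=cond["seed"])
    lnc_ids = {t.id for t in result.lncrnas}
    correct = sum(
        1
        for t in transcripts
        if (labels[t.id] == "noncoding") == (t.id in lnc_ids)
    )
    return {
        "accuracy": correct / len(transcripts),
        "n_transcripts": len(transcripts),
        "scorer": scorer,
        "result": result,
        "labels": labels,
    }


def run_target_benchmark(seed: int = 42, conditions: Mapping | None = None) -> dict:
    """Plant designed target sites, run prediction, score edge recovery."""
    cond = dict(conditions or benchmark_conditions(seed))
    rng = np.random.default_rng(cond["seed"] + 2)
    matures = make_mature_library(cond["n_matures"], rng=rng)
    transcripts, truth, _ = make_transcriptome(10, 5, rng=rng, id_prefix="tgt")
    edited = plant_target_sites(
        matures, transcripts, truth,
        n_perfect=cond["n_perfect_sites"], n_penalty1=cond["n_penalty1_sites"],
        n_negative=cond["n_negative_sites"], rng=rng,
    )
    coding_df, _, graph = run_target_pipeline(matures, edited)
    predicted = {
        (r.mirna, r.transcript, r.start - 1, r.end) for r in coding_df.itertuples()
    }
    positives = [e for e in truth.target_edges if not e.is_negative]
    negatives = [e for e in truth.target_edges if e.is_negative]
    recovered = sum(
        1 for e in positives
        if (e.mature_id, e.transcript_id, e.start, e.end) in predicted
    )
    false_neg_edges = sum(
        1 for e in negatives
        if (e.mature_id, e.transcript_id, e.start, e.end) in predicted
    )
    return {
        "positive_recovery": recovered / max(len(positives), 1),
        "negatives_excluded": 1.0 - false_neg_edges / max(len(negatives), 1),
        "n_predicted": len(coding_df),
        "coding_df": coding_df,
        "graph": graph,
        "truth": truth,
    }
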