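# Methods

`hairpinhunter` annotates three classes of plant non-coding RNA from
sequence alone: miRNA precursor hairpins found by homology to known
mature miRNAs, long non-coding RNAs found by a coding-potential cascade,
and miRNA target sites found by complementarity and accessibility
scoring.  This note records the models behind each stage, the parameters
that matter, what the synthetic benchmark does and does not show, and the
design choices made where the design was genuinely open.

## The folding engine

All structure statistics derive from one thermodynamic model: a
pseudoknot-free secondary-structure ensemble with **additive per-pair
energies** — GC −3.0, AU −2.0, GU −1.0 kcal/mol, minimum hairpin loop 3
unpaired bases, RT = 0.6163 kcal/mol (310.15 K).  Under this model the
Boltzmann probability of a structure S with pair set P(S) is

    P(S) = exp(-E_S / RT) / Z,     E_S = Σ_{(i,j) ∈ P(S)} e(i,j),

and the base-pair probability matrix is `p_ij = Σ_S P(S)·[i pairs j]`.

Three dynamic programs operate over an unambiguous decomposition of
half-open intervals (condition on the fate of the left end):

* **MFE** — a Nussinov-style recursion minimizing `(energy, n_pairs)`
  lexicographically, with a deterministic traceback (pair the left end
  with its smallest admissible partner first).  Ties therefore resolve to
  the minimum-energy structure with the fewest pairs, reproducibly.
* **Partition function** — inside recursion
  `Z[i,j] = σ·Z[i+1,j] + Σ_k q(i,k)·σ²·Z[i+1,k]·Z[k+1,j]` and the
  matching outside recursion, giving every `p_ij` in O(n³).  The
  per-nucleotide rescaling factor `σ = exp(MFE/(n·RT))` pins the MFE
  structure's scaled weight at 1 so sequences of several hundred
  nucleotides stay inside double precision; `log Z` is always finite even
  when `Z` itself overflows a float (only possible for extreme sequences
  well past the hairpin length range).
* **Constrained MFE** — the same recursion with a set of positions
  forbidden to pair, used for target-site unpairing energies.

An exhaustive enumerator (guarded to length ≤ 25) is the independent
oracle: the test suite checks `Z`, the MFE and every `p_ij` against direct
Boltzmann summation to 1e-9 relative error, and checks the low-RT limit
(`p_ij` → indicator of the unique MFE structure).

Why an additive model rather than nearest-neighbour parameters: every
statistic the pipeline uses (MFE, MFEI, NQ, ND, Npb, UPE) is defined *on
top of* the ensemble, not on a particular parameterization, and the
additive model keeps the enumeration oracle exact.  Absolute feature
values are therefore model-dependent; the `FoldingEngine` protocol
accepts an external folder for users who want nearest-neighbour energies,
in which case the cascade thresholds must be recalibrated.

## Hairpin statistics

Per candidate window of length L:

* `AMFE = -MFE/L × 100` (kcal/mol per 100 nt);
* `MFEI = AMFE / GC%`, GC on the 0–100 scale, undefined (candidate
  rejected) at GC = 0;
* `NQ = -(1/L) Σ_{i<j} p_ij log₂ p_ij` — ensemble entropy per nucleotide;
* `ND = (1/L) Σ_{i<j} p_ij (1 - p_ij)` — expected base-pair distance per
  nucleotide;
* `Npb = |pairs(MFE)| / L ∈ [0, 0.5]`;
* `R` — SSR signature tracts per 100 nt (below).

NQ and ND sum over i < j only and normalize by sequence length; both are
zero exactly when the ensemble is deterministic.  Npb is computed on the
MFE structure, the one singular structure the pipeline produces.

## SSR signatures

An SSR occurrence is a maximal tandem tract of a primitive 1–6 nt motif,
reported at its leftmost phase; per-period minimum repeat counts default
to conventional microsatellite minima (mono ≥ 5, di ≥ 3, tri–hexa ≥ 2)
and are configuration.  Signatures are trinucleotide motifs per family
("window size three"); matching canonicalizes motifs to the
lexicographically smallest rotation on the forward strand, while
tabulation keys on the motif as written, so rotation-distinct renderings
are distinguishable in summaries but count as one signature in R.  No
published per-family signature table is bundled; the packaged default is
derived from the synthetic corpus (`tabulate_family_signatures`), and a
user TSV overrides it.

## miRNA discovery cascade

1. **Homology scan**: exhaustive both-strand Hamming scan of every
   15–30 nt mature against the genome, complete for ≤ 3 mismatches.  An
   adapter ingests external 12-column tabular hit lists for larger
   genomes.
2. **Window ladder**: total lengths 60–300 nt in steps of 20, mature on
   the 5′ or 3′ arm (asymmetric flanks), clipped at chromosome ends,
   minus-strand windows reverse-complemented into mature sense; windows
   containing N are discarded because the folding statistics are
   undefined for ambiguous bases.
3. **Coding exclusion**: translated local alignment against a protein
   database (seeded, BLOSUM62, gapped Karlin–Altschul e-values; removal
   at e ≤ 1e-3 and identity ≥ 50 %), or without a database an ORF
   heuristic (drop windows with an ORF ≥ 80 aa).
4. **Filter cascade** with per-filter verdicts recorded for audit:
   composition windows, MFEI ≥ 1.3, NQ ≤ 0.45, ND ≤ 0.14,
   Npb ∈ [0.2, 0.5], R ≥ 0, and hairpin placement — no mature base pairs
   another mature base, and ≥ 50 % of mature bases pair outward (a mature
   on a helical arm is duplexed).
5. **Best candidate per hit**: maximum MFEI, ties by maximum R, then the
   shortest window, then the leftmost start.
6. **Locus dedup**: a hairpin is hit once per arm (the star arm is
   near-complementary to the mature), so accepted candidates merge when
   each one's mature lies inside the other's window; the
   lowest-mismatch / highest-MFEI candidate represents the locus.
7. **Naming**: family inherited from the best-matching known mature,
   letter suffixes in genomic order, novelty = no 0-mismatch match.

The cascade thresholds are **calibrated on the synthetic corpus under the
built-in model and are not literature values**.  Under additive energies
MFEI separates weakly (random sequences fold promiscuously when every
pair is worth the same everywhere), so the discriminative load falls on
the ensemble statistics: intact planted hairpins show NQ ≤ ~0.35 while
shuffled/random 60-mers show NQ ≥ ~0.5.  Because the pipeline takes the
best of ~26 windows per hit, a selection effect occasionally pushes a
random-context window below the thresholds; the measured false-discovery
rate on the packaged benchmark is 0 at the packaged seed and stays ≤ ~0.17
across other seeds tested.

## lncRNA cascade

Stage order is fixed and each stage's input/output counts are audited:
length > 200 nt (strict) → longest ORF < 120 aa (strict) → primary score
S → secondary score → protein similarity.  Classification rules:
S ≤ −0.5 non-coding, S ≥ 1.0 coding (discard), neutral otherwise;
neutral transcripts with secondary score < 0.2 are rescued as ncRNA.
The final stage removes transcripts with a translated hit at e ≤ 1e-3
and identity strictly above 40 %; without a protein database the stage is
skipped with a prominent warning.

The built-in scorer is a **calibrated stand-in** for external
coding-potential classifiers, not a reimplementation: a logistic model
over three features (longest-ORF coverage, a Fickett-style
position/composition statistic, and an in-frame hexamer log-likelihood
ratio trained on the labelled corpus), with the logit mapped affinely
onto the primary-score scale so that the 10th percentile of coding
training logits lands at +1.0 and the 90th percentile of non-coding
logits at −0.5.  Training requires ≥ 50 sequences per class; external
classifier outputs plug in as two-column id→score TSVs.  ORFs follow the
start-to-stop definition (first in-frame ATG after the previous stop),
configurable, with open-ended ORFs at the sequence edge included.

## Target prediction

The expectation penalty sums per-position costs over the antiparallel
duplex: Watson–Crick 0, G:U wobble 0.5, other mismatch 1.0, a single
permitted bulge 2.0, all doubled inside the core region (positions 2–13
of a 21-nt mature, rescaled as `round(p·L/21)` for other lengths).  Sites
score ≤ 2.0 by default; overlapping candidate sites collapse to the local
expectation minimum.  A site is a cleavage site when the central
positions (9–11, rescaled) carry no mismatch or gap; wobbles do not block
cleavage.  The exhaustive all-windows scorer is the test oracle; the
production scanner uses a vectorized exact ungapped score plus a
lower-bound bulge screen, then re-scores candidates exactly, so it can
never miss a site the oracle reports.

Accessibility: UPE = constrained-minus-unconstrained MFE of the site plus
17 nt upstream and 13 nt downstream of context, with the site forced
single-stranded; sites with UPE > 25 kcal/mol are discarded.  The 25 is
the conventional cutoff but, like all absolute energies, is
engine-dependent and lives in configuration.

## Synthetic data and the benchmark

The generator emulates the statistical structure each stage assumes — it
does **not** emulate real genomes.  Background is i.i.d. at a requested
GC; planted precursors are mature + loop + near-reverse-complement with
optional loop SSR tracts; decoys straddle the decision boundaries
(matures at 4–6 mismatches for the homology cutoff, shuffled precursors
and intact-mature-in-shuffled-context for the cascade).  Transcriptomes
place codon-biased ORFs between random UTRs; non-coding negatives are
Altschul–Erickson exact-count dinucleotide shuffles (composition-matched,
the minimum honest difficulty for a composition-based scorer).  Planted
target sites realize designed penalties of 0, 1 (one non-core mismatch)
and 4 (two core mismatches, a designed negative).  All randomness flows
from one passed `numpy.random.Generator`; identical seeds give
byte-identical outputs, verified by re-extraction of every ledger entry.

Packaged benchmark conditions (seed 42): 2 × 10 kb chromosomes at GC 0.5,
a 12-mature library, 10 planted precursors, 5 decoys of each class; a
transcript set of 120 training and 50 held-out transcripts mixing long
(150–250 aa) and short (80–115 aa) ORFs with shuffled negatives; 15
planted target sites (5 perfect, 5 penalty-1, 5 designed-negative) over
15 transcripts.  These sizes keep the full benchmark under ~1 minute on
one CPU while leaving each stage a non-trivial decision.  Measured at the
packaged seed: miRNA sensitivity 1.0 at FDR 0.0, lncRNA classification
accuracy 0.98, all designed-positive target edges recovered, all designed
negatives excluded.

What passing does and does not show: recovery on i.i.d. background with
planted truth demonstrates the machinery is correct and the thresholds
coherent under the built-in model; it says nothing about repeat-rich real
genomes, about expression support, or about nearest-neighbour energetics.
At other seeds the metrics fluctuate (a perfect target site planted into
a structured context can honestly fail the accessibility cutoff; an
occasional random window folds hairpin-like and survives the cascade).

## Numerical and degenerate-input choices

* Internal coordinates 0-based half-open; GFF3 output 1-based inclusive.
* Genomes are DNA; anything entering the folding engine becomes RNA.
* GC-free windows have undefined MFEI and are rejected, not scored.
* Rounding of scaled positions uses round-half-up for determinism.
* The partition function is exact up to rescaling round-off; the oracle
  agreement tolerance (1e-9 relative) is far above observed error
  (~1e-14).
* Seeds are recorded in every audit record and echoed into output
  configuration files.

## Known limitations

Additive energies (no stacking, loop-size or dangle terms); no
pseudoknots; no small-RNA-seq validation or star-sequence annotation; no
compound SSRs; the protein-similarity e-value uses fixed gapped BLOSUM62
Karlin–Altschul constants rather than per-alignment estimation; linear
scans assume desk-scale genomes (tens of Mb, not Gb).
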