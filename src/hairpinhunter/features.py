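"""Per-candidate hairpin statistics.

The discovery cascade scores every precursor candidate with a small vector
of sequence and folding statistics:

* ``AMFE = -MFE/L * 100`` — folding energy magnitude per 100 nt (positive
  for any sequence that folds at all);
* ``MFEI = AMFE / (G+C)%`` — AMFE per GC percentage point, with GC on the
  0–100 scale, the index that separates miRNA hairpins from other RNAs;
* ``NQ = -(1/L) sum_{i<j} p_ij log2 p_ij`` — Shannon entropy of the
  base-pair probability distribution per nucleotide (bits/nt);
* ``ND = (1/L) sum_{i<j} p_ij (1 - p_ij)`` — expected base-pair distance
  between two ensemble draws per nucleotide, an ensemble-diversity measure;
* ``Npb = |pairs|/L`` — base pairs of the MFE structure per nucleotide,
  bounded by 0.5 (an L/2-pair structure);
* nucleotide composition and GC%.

NQ and ND vanish together exactly when the ensemble is deterministic
(every p_ij is 0 or 1).  Both sums run over i < j only and are normalized
by sequence length.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import AlphabetError
from .folding import (
    DEFAULT_MODEL,
    EnergyModel,
    FoldingResult,
    SecondaryStructure,
    partition_function,
)


class DegenerateCandidateError(ValueError):
    """Raised when a statistic is undefined (zero length or zero GC)."""


def composition(seq: str) -> dict[str, float]:
    """Base fractions and gc_percent (0-100 scale) of an RNA sequence."""
    if not seq:
        raise DegenerateCandidateError("empty sequence")
    bad = set(seq) - set("ACGU")
    if bad:
        raise AlphabetError(f"ambiguous/non-RNA characters: {sorted(bad)}")
    L = len(seq)
    frac = {b: seq.count(b) / L for b in "ACGU"}
    frac["gc_percent"] = 100.0 * (seq.count("G") + seq.count("C")) / L
    return frac


def amfe(mfe: float, length: int) -> float:
    """Adjusted MFE: ``-MFE/L * 100`` (kcal/mol per 100 nt)."""
    if length < 1:
        raise DegenerateCandidateError("length must be >= 1")
    return -mfe / length * 100.0


def mfei(amfe_value: float, gc_percent: float) -> float:
    """Minimal folding energy index: AMFE / GC%, GC on the 0-100 scale."""
    if gc_percent <= 0:
        raise DegenerateCandidateError("MFEI undefined for GC = 0 (candidate rejected)")
    return amfe_value / gc_percent


def nq(pair_probs: np.ndarray, length: int) -> float:
    """Normalized Shannon entropy of the pair-probability distribution (bits/nt).

    Terms with ``p_ij = 0`` contribute nothing (0·log 0 := 0), as do exact
    ``p_ij = 1`` terms.
    """
    iu = np.triu_indices(pair_probs.shape[0], k=1)
    p = pair_probs[iu]
    p = p[p > 0.0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum() / length)


def nd(pair_probs: np.ndarray, length: int) -> float:
    """Normalized base-pair distance ``(1/L) sum_{i<j} p_ij (1 - p_ij)``."""
    iu = np.triu_indices(pair_probs.shape[0], k=1)
    p = pair_probs[iu]
    return float((p * (1.0 - p)).sum() / length)


def npb(structure: SecondaryStructure, length: int | None = None) -> float:
    """Base-pairing propensity: pairs of the (MFE) structure per nucleotide.

    Ranges from 0.0 (no pairs) to 0.5 (an L/2-pair structure).
    """
    L = structure.length if length is None else length
    return structure.n_pairs / L


FEATURE_COLUMNS = [
    "length", "frac_a", "frac_c", "frac_g", "frac_u", "gc_percent",
    "mfe", "amfe", "mfei", "nq", "nd", "npb", "r",
]


@dataclasses.dataclass
class HairpinFeatures:
    """The full per-candidate feature vector consumed by the filter cascade.

    ``r`` (SSR signature density per 100 nt) is computed by the SSR module
    and defaults to 0 until filled in.
    """

    length: int
    frac_a: float
    frac_c: float
    frac_g: float
    frac_u: float
    gc_percent: float
    mfe: float
    amfe: float
    mfei: float
    nq: float
    nd: float
    npb: float
    r: float = 0.0

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in FEATURE_COLUMNS}


def compute_features(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    folding: FoldingResult | None = None,
) -> HairpinFeatures:
    """Fold *seq* (RNA) and assemble its :class:`HairpinFeatures`.

    Raises :class:`DegenerateCandidateError` for GC-free sequences, whose
    MFEI is undefined; the cascade treats that as a rejection.
    """
    comp = composition(seq)
    L = len(seq)
    if folding is None:
        folding = partition_function(seq, model)
    a = amfe(folding.mfe, L)
    return HairpinFeatures(
        length=L,
        frac_a=comp["A"],
        frac_c=comp["C"],
        frac_g=comp["G"],
        frac_u=comp["U"],
        gc_percent=comp["gc_percent"],
        mfe=folding.mfe,
        amfe=a,
        mfei=mfei(a, comp["gc_percent"]),
        nq=nq(folding.pair_probs, L),
        nd=nd(folding.pair_probs, L),
        npb=npb(folding.mfe_structure),
    )
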