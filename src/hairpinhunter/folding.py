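"""RNA secondary-structure thermodynamics.

A transparent additive pair-energy model (per-pair stacking-free energies,
no loop terms) drives four computations:

* :func:`fold_mfe` — minimum-free-energy structure by dynamic programming,
  with deterministic tie-breaking (fewest pairs, then a fixed traceback
  order preferring the earliest, smallest-partner pair);
* :func:`partition_function` — Boltzmann partition function and the full
  base-pair probability matrix ``p_ij`` by an inside–outside recursion over
  an unambiguous decomposition (each structure weighted exactly once);
* :func:`constrained_mfe` — minimum-energy structure with a region forced
  single-stranded (the primitive behind target-site unpairing energies);
* :func:`enumerate_structures` — exhaustive enumeration for short
  sequences, the independent oracle for everything above.

Energies are additive over pairs, so the ensemble probability of structure
``S`` is ``P(S) = exp(-E_S/RT) / Z`` with ``E_S`` the sum of its pair
energies, and ``p_ij = sum_S P(S) [i pairs j in S]``.  Pseudoknots are
excluded and hairpin loops must contain at least ``min_loop`` unpaired
bases.  The inside recursion is rescaled per nucleotide so hairpins several
hundred nucleotides long stay within double-precision range; ``log_z`` is
always finite even when ``Z`` itself overflows a float.

The default parameters (GC −3.0, AU −2.0, GU −1.0 kcal/mol, min loop 3,
RT = 0.6163 kcal/mol at 310.15 K) keep the enumeration oracle exact while
preserving the structure of every downstream statistic; all of them are
configurable, and an external nearest-neighbour engine can be plugged in
through the :class:`FoldingEngine` protocol.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache
from typing import Protocol, runtime_checkable

import numpy as np
from numba import njit

from .core_io import AlphabetError

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}

DEFAULT_PAIR_ENERGIES = {
    ("G", "C"): -3.0,
    ("A", "U"): -2.0,
    ("G", "U"): -1.0,
}


def encode_rna(seq: str) -> np.ndarray:
    """Encode an unambiguous RNA string as int8 codes (A=0,C=1,G=2,U=3)."""
    try:
        return np.array([_BASE_CODE[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(
            f"cannot fold sequence containing {exc.args[0]!r}; unambiguous RNA required"
        ) from None


@dataclasses.dataclass(frozen=True)
class EnergyModel:
    """Additive per-pair energy model.

    Parameters
    ----------
    pair_energies : dict
        kcal/mol per closed pair, keyed by ordered base tuples; both
        orientations of each pair type are filled in automatically.
    min_loop : int
        Minimum number of unpaired bases enclosed by a hairpin-closing pair.
    rt : float
        kcal/mol; 0.6163 corresponds to 310.15 K.
    """

    pair_energies: tuple = tuple(sorted(DEFAULT_PAIR_ENERGIES.items()))
    min_loop: int = 3
    rt: float = 0.6163

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("min_loop must be >= 3")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        if any(e >= 0 for _, e in self.pair_energies):
            raise ValueError("pair energies must be negative")

    @classmethod
    def from_dict(cls, pair_energies: dict, min_loop: int = 3, rt: float = 0.6163) -> "EnergyModel":
        return cls(tuple(sorted(pair_energies.items())), min_loop, rt)

    @property
    def energy_matrix(self) -> np.ndarray:
        """4x4 matrix of pair energies; +inf marks a disallowed pair."""
        mat = np.full((4, 4), np.inf)
        for (a, b), e in self.pair_energies:
            mat[_BASE_CODE[a], _BASE_CODE[b]] = e
            mat[_BASE_CODE[b], _BASE_CODE[a]] = e
        return mat

    def pair_energy(self, a: str, b: str) -> float:
        e = self.energy_matrix[_BASE_CODE[a], _BASE_CODE[b]]
        return float(e)

    def can_pair(self, a: str, b: str) -> bool:
        return math.isfinite(self.pair_energy(a, b))


DEFAULT_MODEL = EnergyModel()


@dataclasses.dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free set of base pairs with its additive energy."""

    length: int
    pairs: tuple  # sorted tuple of (i, j), i < j, 0-based
    energy: float

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"index in pair ({i},{j}) participates in two pairs")
            seen.update((i, j))
        for (i, j) in self.pairs:
            for (k, l) in self.pairs:
                if i < k < j < l:
                    raise ValueError(f"pseudoknot: ({i},{j}) crosses ({k},{l})")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    def partner_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclasses.dataclass
class FoldingResult:
    """MFE structure plus Boltzmann-ensemble quantities for one RNA."""

    sequence: str
    mfe: float
    mfe_structure: SecondaryStructure
    log_z: float
    pair_probs: np.ndarray  # (L, L) symmetric

    @property
    def z(self) -> float:
        try:
            return math.exp(self.log_z)
        except OverflowError:
            return math.inf


@runtime_checkable
class FoldingEngine(Protocol):
    """Adapter protocol for an external folding engine.

    Any object with this surface (e.g. a wrapper around a nearest-neighbour
    folder) can replace the built-in model in the discovery pipelines.
    """

    def fold(self, seq: str) -> FoldingResult: ...

    def constrained_mfe_energy(self, seq: str, unpaired_start: int, unpaired_end: int) -> float: ...


# ---------------------------------------------------------------------------
# numba kernels (half-open interval DP tables of shape (n+1, n+1))
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_mfe(codes, pair_e, min_loop, blocked):  # pragma: no cover - numba
    n = codes.shape[0]
    W = np.zeros((n + 1, n + 1))
    NP = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # interval [i, j)
            best_e = W[i + 1, j]
            best_n = NP[i + 1, j]
            if not blocked[i]:
                for k in range(i + min_loop + 1, j):
                    if blocked[k]:
                        continue
                    pe = pair_e[codes[i], codes[k]]
                    if np.isfinite(pe):
                        e2 = pe + W[i + 1, k] + W[k + 1, j]
                        n2 = 1 + NP[i + 1, k] + NP[k + 1, j]
                        if e2 < best_e - 1e-12 or (
                            abs(e2 - best_e) <= 1e-12 and n2 < best_n
                        ):
                            best_e = e2
                            best_n = n2
            W[i, j] = best_e
            NP[i, j] = best_n
    return W, NP


@njit(cache=True)
def _fill_inside(codes, q, min_loop, sigma, blocked):  # pragma: no cover - numba
    n = codes.shape[0]
    Z = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        Z[i, i] = 1.0
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            acc = sigma * Z[i + 1, j]
            if not blocked[i]:
                for k in range(i + min_loop + 1, j):
                    if blocked[k]:
                        continue
                    w = q[codes[i], codes[k]]
                    if w > 0.0:
                        acc += w * sigma * sigma * Z[i + 1, k] * Z[k + 1, j]
            Z[i, j] = acc
    return Z


@njit(cache=True)
def _fill_outside(Z, codes, q, min_loop, sigma, blocked):  # pragma: no cover - numba
    n = codes.shape[0]
    O = np.zeros((n + 1, n + 1))
    O[0, n] = 1.0
    for i in range(1, n + 1):
        for j in range(i, n + 1):
            acc = sigma * O[i - 1, j]  # base i-1 unpaired in context [i-1, j)
            # Z[i, j] is the inner part of pair (i-1, j)
            if j < n and not blocked[i - 1] and not blocked[j]:
                if j - (i - 1) > min_loop:
                    w = q[codes[i - 1], codes[j]]
                    if w > 0.0:
                        s = 0.0
                        for b in range(j + 1, n + 1):
                            s += O[i - 1, b] * Z[j + 1, b]
                        acc += w * sigma * sigma * s
            # Z[i, j] is the right remainder after pair (a, i-1)
            if i >= 2 and not blocked[i - 1]:
                for a in range(0, i - 1):
                    if blocked[a]:
                        continue
                    if (i - 1) - a > min_loop:
                        w = q[codes[a], codes[i - 1]]
                        if w > 0.0:
                            acc += O[a, j] * w * sigma * sigma * Z[a + 1, i - 1]
            O[i, j] = acc
    return O


@njit(cache=True)
def _pair_probs(Z, O, codes, q, min_loop, sigma, blocked):  # pragma: no cover - numba
    n = codes.shape[0]
    P = np.zeros((n, n))
    z_tot = Z[0, n]
    for i in range(n):
        if blocked[i]:
            continue
        for k in range(i + min_loop + 1, n):
            if blocked[k]:
                continue
            w = q[codes[i], codes[k]]
            if w > 0.0:
                s = 0.0
                for b in range(k + 1, n + 1):
                    s += O[i, b] * Z[k + 1, b]
                p = w * sigma * sigma * Z[i + 1, k] * s / z_tot
                P[i, k] = p
                P[k, i] = p
    return P


_NO_BLOCK = np.zeros(0, dtype=np.bool_)


def _blocked_array(n: int, region: tuple[int, int] | None) -> np.ndarray:
    blocked = np.zeros(n, dtype=np.bool_)
    if region is not None:
        s, e = region
        if not (0 <= s <= e <= n):
            raise IndexError(f"constraint region ({s},{e}) out of bounds for length {n}")
        blocked[s:e] = True
    return blocked


def _traceback(codes, W, NP, pair_e, min_loop, blocked) -> list[tuple[int, int]]:
    """Deterministic traceback: among (energy, n_pairs)-optimal options prefer
    pairing the left end with the smallest partner, else leave it unpaired."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, codes.shape[0])]
    while stack:
        i, j = stack.pop()
        while j - i >= min_loop + 2:
            target_e, target_n = W[i, j], NP[i, j]
            chosen = -1
            if not blocked[i]:
                for k in range(i + min_loop + 1, j):
                    if blocked[k]:
                        continue
                    pe = pair_e[codes[i], codes[k]]
                    if np.isfinite(pe):
                        e2 = pe + W[i + 1, k] + W[k + 1, j]
                        n2 = 1 + NP[i + 1, k] + NP[k + 1, j]
                        if abs(e2 - target_e) <= 1e-9 and n2 == target_n:
                            chosen = k
                            break
            if chosen >= 0:
                pairs.append((i, chosen))
                stack.append((chosen + 1, j))
                i, j = i + 1, chosen
            else:
                i += 1
    return sorted(pairs)


def fold_mfe(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    unpaired_region: tuple[int, int] | None = None,
) -> SecondaryStructure:
    """Minimum-free-energy structure of *seq* under the additive model.

    Ties are broken deterministically: minimum energy, then fewest pairs,
    then a fixed traceback order (earliest pair, smallest partner).
    """
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    codes = encode_rna(seq)
    n = len(codes)
    blocked = _blocked_array(n, unpaired_region)
    pair_e = model.energy_matrix
    W, NP = _fill_mfe(codes, pair_e, model.min_loop, blocked)
    pairs = _traceback(codes, W, NP, pair_e, model.min_loop, blocked)
    energy = float(sum(pair_e[codes[i], codes[j]] for i, j in pairs))
    return SecondaryStructure(length=n, pairs=tuple(pairs), energy=energy)


def constrained_mfe(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    unpaired_region: tuple[int, int] = (0, 0),
) -> SecondaryStructure:
    """MFE structure among structures leaving ``unpaired_region`` single-stranded.

    The constrained optimum can never beat the unconstrained one, so its
    energy is always >= the plain MFE.
    """
    return fold_mfe(seq, model, unpaired_region=unpaired_region)


def partition_function(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    unpaired_region: tuple[int, int] | None = None,
) -> FoldingResult:
    """Partition function and base-pair probability matrix for *seq*.

    ``Z = sum_S exp(-E_S/RT)`` over every pseudoknot-free structure (the
    open chain contributes 1), and ``p_ij`` is the Boltzmann probability
    that bases i and j pair.  Computed with per-nucleotide rescaling keyed
    to the MFE so that sequences up to several hundred nt stay finite.
    """
    mfe_struct = fold_mfe(seq, model, unpaired_region)
    codes = encode_rna(seq)
    n = len(codes)
    blocked = _blocked_array(n, unpaired_region)
    energy_mat = model.energy_matrix
    q = np.where(np.isfinite(energy_mat), np.exp(-np.where(np.isfinite(energy_mat), energy_mat, 0.0) / model.rt), 0.0)
    sigma = math.exp(mfe_struct.energy / (n * model.rt))
    Z = _fill_inside(codes, q, model.min_loop, sigma, blocked)
    O = _fill_outside(Z, codes, q, model.min_loop, sigma, blocked)
    P = _pair_probs(Z, O, codes, q, model.min_loop, sigma, blocked)
    log_z = math.log(Z[0, n]) - n * math.log(sigma)
    return FoldingResult(
        sequence=seq,
        mfe=mfe_struct.energy,
        mfe_structure=mfe_struct,
        log_z=log_z,
        pair_probs=P,
    )


MAX_ENUM_LENGTH = 25


def enumerate_structures(
    seq: str,
    model: EnergyModel = DEFAULT_MODEL,
    unpaired_region: tuple[int, int] | None = None,
) -> list[SecondaryStructure]:
    """Every valid structure of *seq*, exactly once (including the open chain).

    Guarded to ``len(seq) <= 25``; this is the brute-force oracle for the
    dynamic programs, not a production code path.
    """
    if len(seq) > MAX_ENUM_LENGTH:
        raise ValueError(
            f"enumeration refused for length {len(seq)} > {MAX_ENUM_LENGTH}"
        )
    codes = encode_rna(seq)
    n = len(codes)
    blocked = _blocked_array(n, unpaired_region)
    pair_e = model.energy_matrix
    min_loop = model.min_loop

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple:
        # all pair-sets of the half-open interval [i, j)
        if j - i <= min_loop + 1:
            return ((),)
        out = list(enum(i + 1, j))  # base i unpaired
        if not blocked[i]:
            for k in range(i + min_loop + 1, j):
                if blocked[k]:
                    continue
                if np.isfinite(pair_e[codes[i], codes[k]]):
                    for left in enum(i + 1, k):
                        for right in enum(k + 1, j):
                            out.append(((i, k),) + left + right)
        return tuple(out)

    structures = []
    for pairs in enum(0, n):
        pairs = tuple(sorted(pairs))
        energy = float(sum(pair_e[codes[a], codes[b]] for a, b in pairs))
        structures.append(SecondaryStructure(length=n, pairs=pairs, energy=energy))
    return structures


def ensemble_from_enumeration(
    seq: str, model: EnergyModel = DEFAULT_MODEL
) -> tuple[float, np.ndarray]:
    """(Z, p_ij) by direct Boltzmann summation over all structures.

    Independent oracle for :func:`partition_function` on short sequences.
    """
    structs = enumerate_structures(seq, model)
    n = len(seq)
    weights = np.array([math.exp(-s.energy / model.rt) for s in structs])
    z = float(weights.sum())
    P = np.zeros((n, n))
    for s, w in zip(structs, weights):
        for i, j in s.pairs:
            P[i, j] += w
            P[j, i] += w
    P /= z
    return z, P
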