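"""Peptide and MHC pseudo-sequence encoding.

Variable-length peptides are represented through a fixed-length *binding
core* of ``core_len`` residues.  Peptides longer than the core are mapped
onto it by deleting a contiguous stretch of residues; shorter peptides by
inserting a stretch of wildcard symbols.  The core, the MHC pseudo-sequence
(fixed-length string of binding-groove contact residues) and a small block
of auxiliary features (peptide length one-hot, insertion/deletion size and
gross position) are encoded residue-by-residue with a scaled substitution
matrix and concatenated into one numeric input vector.

The vector layout is ``[peptide-side | allele-side]`` where the
peptide-side block holds the core encoding plus auxiliary features and the
allele-side block holds the pseudo-sequence encoding.  Downstream code
relies on this split to cache per-allele contributions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard residues, alphabetical by one-letter code.  This ordering
#: defines the column order of every encoding and frequency matrix in the
#: package.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Wildcard/unknown residue; encodes to the zero vector.
WILDCARD: str = "X"

_EXTENDED = ALPHABET + WILDCARD
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(_EXTENDED)}

N_RESIDUES = 20


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 21-letter alphabet."""


class LengthBoundError(ValueError):
    """A peptide falls outside the configured length bounds."""


class ConfigurationError(ValueError):
    """Mismatched encoding/pseudo-sequence dimensions."""


def validate_sequence(seq: str) -> None:
    for ch in seq:
        if ch not in AA_INDEX:
            raise AlphabetError(f"illegal residue {ch!r} in sequence {seq!r}")


# ---------------------------------------------------------------------------
# Substitution matrices and the residue encoding matrix
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=8)
def load_substitution_matrix(name: str = "BLOSUM50"):
    """Load a named substitution matrix (NCBI set shipped with Biopython)."""
    return substitution_matrices.load(name)


def read_substitution_matrix(path):
    """Read a substitution matrix from a standard NCBI-format text file."""
    return substitution_matrices.read(str(path))


@dataclass(frozen=True)
class EncodingMatrix:
    """A 21 x 20 residue encoding table.

    Row ``i`` is the encoding of residue ``_EXTENDED[i]``; the last row
    (wildcard) is all zeros.  Columns follow :data:`ALPHABET`.
    """

    name: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_RESIDUES + 1, N_RESIDUES):
            raise ConfigurationError(
                f"encoding matrix must be 21 x 20, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("encoding matrix has non-finite entries")
        if np.any(v[N_RESIDUES] != 0.0):
            raise ConfigurationError("wildcard row must be zero")
        object.__setattr__(self, "values", v)

    def row(self, residue: str) -> np.ndarray:
        return self.values[AA_INDEX[residue]]


@functools.lru_cache(maxsize=4)
def blosum_encoding(name: str = "BLOSUM50", scale: float = 5.0) -> EncodingMatrix:
    """Residue encoding from a substitution matrix divided by ``scale``.

    The conventional input encoding for binding-core alignment networks.
    """
    mat = load_substitution_matrix(name)
    values = np.zeros((N_RESIDUES + 1, N_RESIDUES))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            values[i, j] = mat[a, b] / scale
    return EncodingMatrix(name=f"{name.lower()}/{scale:g}", values=values)


# ---------------------------------------------------------------------------
# Pseudo-sequences
# ---------------------------------------------------------------------------

CLASS_I_PSEUDO_LEN = 34


@dataclass(frozen=True)
class AllelePseudoSequence:
    """An allele name plus its fixed-length groove contact residue string."""

    allele: str
    residues: str

    def __post_init__(self):
        validate_sequence(self.residues)


def read_pseudo_table(path) -> dict[str, AllelePseudoSequence]:
    """Read a two-column whitespace-separated ``ALLELE PSEUDOSEQ`` table.

    All pseudo-sequences must share one length; duplicated allele names keep
    the first occurrence.
    """
    table: dict[str, AllelePseudoSequence] = {}
    length = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 'ALLELE PSEUDOSEQ', got {line!r}")
            allele, residues = parts
            if length is None:
                length = len(residues)
            elif len(residues) != length:
                raise ConfigurationError(
                    f"{path}:{lineno}: pseudo-sequence length {len(residues)} "
                    f"differs from {length}")
            table.setdefault(allele, AllelePseudoSequence(allele, residues))
    if not table:
        raise ConfigurationError(f"{path}: empty pseudo-sequence table")
    return table


def write_pseudo_table(table: dict[str, AllelePseudoSequence], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(table):
            fh.write(f"{name} {table[name].residues}\n")


# ---------------------------------------------------------------------------
# Binding cores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingCore:
    """A fixed-length core plus the insertion/deletion that produced it.

    At most one of ``deletion_length``/``insertion_length`` is positive.  In
    windowed (class II) mode ``deletion_start`` holds the window offset and
    ``deletion_length`` the total number of flanking residues outside the
    window.
    """

    core: str
    deletion_length: int = 0
    deletion_start: int = 0
    insertion_length: int = 0
    insertion_start: int = 0

    def __post_init__(self):
        if self.deletion_length > 0 and self.insertion_length > 0:
            raise ValueError("core cannot have both an insertion and a deletion")
        validate_sequence(self.core)


def enumerate_cores(peptide: str, core_len: int = 9,
                    length_bounds: tuple[int, int] = (8, 14),
                    mode: str = "indel") -> list[BindingCore]:
    """Enumerate candidate binding cores of a peptide.

    ``indel`` mode (class I): a peptide of length L > core_len yields one
    core per contiguous deletion of L - core_len residues, the deleted
    stretch placed at every start position including the termini
    (core_len + 1 candidates before deduplication).  L < core_len yields one
    core per insertion of a wildcard stretch at each interior junction
    (L - 1 candidates).  L == core_len yields the peptide itself.

    ``window`` mode (class II): every contiguous core_len window.

    The returned list is deterministic and deduplicated on the core string
    (first occurrence kept).
    """
    lo, hi = length_bounds
    L = len(peptide)
    if not lo <= L <= hi:
        raise LengthBoundError(
            f"peptide length {L} outside bounds [{lo}, {hi}]: {peptide!r}")
    validate_sequence(peptide)

    cores: list[BindingCore] = []
    seen: set[str] = set()

    def _push(bc: BindingCore) -> None:
        if bc.core not in seen:
            seen.add(bc.core)
            cores.append(bc)

    if mode == "window":
        if L < core_len:
            raise LengthBoundError(
                f"peptide shorter than core in window mode: {peptide!r}")
        for start in range(L - core_len + 1):
            _push(BindingCore(core=peptide[start:start + core_len],
                              deletion_length=L - core_len,
                              deletion_start=start))
        return cores

    if mode != "indel":
        raise ConfigurationError(f"unknown core mode {mode!r}")

    if L == core_len:
        _push(BindingCore(core=peptide))
    elif L > core_len:
        d = L - core_len
        for start in range(L - d + 1):  # == core_len + 1 positions
            core = peptide[:start] + peptide[start + d:]
            _push(BindingCore(core=core, deletion_length=d,
                              deletion_start=start))
    else:
        ins = core_len - L
        for pos in range(1, L):  # interior junctions only
            core = peptide[:pos] + WILDCARD * ins + peptide[pos:]
            _push(BindingCore(core=core, insertion_length=ins,
                              insertion_start=pos))
    return cores


# ---------------------------------------------------------------------------
# Feature layout and example encoding
# ---------------------------------------------------------------------------

_INDEL_CAP = 4.0  # insertion/deletion lengths are scaled by this cap
_PFR_LEN = 3      # flanking residues averaged on each side (class II)


@dataclass(frozen=True)
class FeatureLayout:
    """Dimensions of the encoded input for one prediction task."""

    core_len: int = 9
    length_bounds: tuple[int, int] = (8, 14)
    pseudo_len: int = CLASS_I_PSEUDO_LEN
    class2: bool = False

    @property
    def n_lengths(self) -> int:
        return self.length_bounds[1] - self.length_bounds[0] + 1

    @property
    def n_aux(self) -> int:
        # length one-hot + ins/del scaled lengths + 3 gross-position flags
        n = self.n_lengths + 2 + 3
        if self.class2:
            n += 2 * N_RESIDUES + 2  # mean-encoded PFRs + flank length feats
        return n

    @property
    def dim_peptide(self) -> int:
        return self.core_len * N_RESIDUES + self.n_aux

    @property
    def dim_allele(self) -> int:
        return self.pseudo_len * N_RESIDUES

    @property
    def dim(self) -> int:
        return self.dim_peptide + self.dim_allele


def encode_sequence(seq: str, enc: EncodingMatrix) -> np.ndarray:
    """Flat per-position encoding of a sequence (len(seq) * 20 values)."""
    idx = [AA_INDEX[ch] for ch in seq]
    return enc.values[idx].ravel()


def _gross_position_flags(start: int, length: int, total: int) -> tuple[float, float, float]:
    if length <= 0:
        return 0.0, 0.0, 0.0
    if start == 0:
        return 1.0, 0.0, 0.0
    if start + length >= total:
        return 0.0, 0.0, 1.0
    return 0.0, 1.0, 0.0


def encode_peptide_features(core: BindingCore, peptide: str,
                            layout: FeatureLayout,
                            enc: EncodingMatrix) -> np.ndarray:
    """Peptide-side block: core encoding followed by auxiliary features."""
    if len(core.core) != layout.core_len:
        raise ConfigurationError(
            f"core length {len(core.core)} != configured {layout.core_len}")
    lo, hi = layout.length_bounds
    L = len(peptide)
    out = np.zeros(layout.dim_peptide)
    nc = layout.core_len * N_RESIDUES
    out[:nc] = encode_sequence(core.core, enc)
    aux = out[nc:]
    aux[L - lo] = 1.0  # length one-hot
    k = layout.n_lengths
    aux[k] = min(core.insertion_length, _INDEL_CAP) / _INDEL_CAP
    aux[k + 1] = min(core.deletion_length, _INDEL_CAP) / _INDEL_CAP
    if core.insertion_length > 0:
        flags = _gross_position_flags(core.insertion_start,
                                      core.insertion_length, layout.core_len)
    elif core.deletion_length > 0 and not layout.class2:
        flags = _gross_position_flags(core.deletion_start,
                                      core.deletion_length, L)
    else:
        flags = (0.0, 0.0, 0.0)
    aux[k + 2:k + 5] = flags
    if layout.class2:
        # peptide flanking regions relative to the core window
        start = core.deletion_start
        nfl = peptide[max(0, start - _PFR_LEN):start]
        cfl = peptide[start + layout.core_len:start + layout.core_len + _PFR_LEN]
        base = k + 5
        for s, seq in ((base, nfl), (base + N_RESIDUES, cfl)):
            if seq:
                rows = enc.values[[AA_INDEX[ch] for ch in seq]]
                aux[s:s + N_RESIDUES] = rows.mean(axis=0)
        aux[base + 2 * N_RESIDUES] = min(len(nfl), _PFR_LEN) / _PFR_LEN
        aux[base + 2 * N_RESIDUES + 1] = min(len(cfl), _PFR_LEN) / _PFR_LEN
    return out


def encode_pseudo(pseudo: AllelePseudoSequence, layout: FeatureLayout,
                  enc: EncodingMatrix) -> np.ndarray:
    """Allele-side block: flat encoding of the pseudo-sequence."""
    if len(pseudo.residues) != layout.pseudo_len:
        raise ConfigurationError(
            f"pseudo-sequence length {len(pseudo.residues)} != configured "
            f"{layout.pseudo_len} for allele {pseudo.allele}")
    return encode_sequence(pseudo.residues, enc)


def encode_example(core: BindingCore, peptide: str,
                   pseudo: AllelePseudoSequence, layout: FeatureLayout,
                   enc: EncodingMatrix) -> np.ndarray:
    """Full input vector ``[peptide-side | allele-side]`` for one example."""
    return np.concatenate([
        encode_peptide_features(core, peptide, layout, enc),
        encode_pseudo(pseudo, layout, enc),
    ])


# ---------------------------------------------------------------------------
# Distances between MHC molecules
# ---------------------------------------------------------------------------

def _similarity(a: str, b: str, matrix) -> float:
    return float(sum(matrix[x, y] for x, y in zip(a, b)))


def allele_distance(a: AllelePseudoSequence, b: AllelePseudoSequence,
                    matrix=None) -> float:
    """Pseudo-sequence distance ``1 - s(a,b) / sqrt(s(a,a) * s(b,b))``.

    ``s`` is the summed substitution-matrix similarity over aligned
    positions (BLOSUM50 by default).  Symmetric, zero for identical
    pseudo-sequences.
    """
    if len(a.residues) != len(b.residues):
        raise ConfigurationError(
            f"pseudo-sequence lengths differ: {a.allele} vs {b.allele}")
    if matrix is None:
        matrix = load_substitution_matrix("BLOSUM50")
    sab = _similarity(a.residues, b.residues, matrix)
    saa = _similarity(a.residues, a.residues, matrix)
    sbb = _similarity(b.residues, b.residues, matrix)
    if saa <= 0 or sbb <= 0:
        raise ConfigurationError("non-positive self-similarity")
    return 1.0 - sab / np.sqrt(saa * sbb)


def distance_to_training_set(a: AllelePseudoSequence,
                             training: "list[AllelePseudoSequence] | set",
                             matrix=None) -> float:
    """Closest pseudo-sequence distance from ``a`` to any training allele."""
    training = list(training)
    if not training:
        raise ValueError("empty training set")
    return min(allele_distance(a, t, matrix=matrix) for t in training)
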