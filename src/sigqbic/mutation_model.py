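"""Strand-collapsed algebra of single-base substitutions in sequence context.

Mutational-signature analysis describes single-base substitutions together
with their immediate 5' and 3' neighbours, collapsed onto the pyrimidine
strand: when the mutated base is a purine (A or G), both the trinucleotide
and the alternate base are reverse complemented, so e.g. AGC>ATC is grouped
with GCT>GAT.  This yields 4 x 2 x 3 x 4 = 96 mutation classes.

Binding-change score tables extend the same convention to wider windows: a
single-nucleotide change at the centre of an odd-length k-mer (the canonical
scale is 11-mers, i.e. 4 flanking bases beyond the central trinucleotide on
each side, giving 4**8 = 65,536 k-mers per class and 96 * 65,536 = 6,291,456
canonical changes in total).  Reduced flank widths share the same 96-class
partition structure and are used for fast synthetic tables.

All vectors and files in this package use the conventional COSMIC ordering of
the 96 classes: substitution types C>A, C>G, C>T, T>A, T>C, T>G, then 5'
context A,C,G,T, then 3' context A,C,G,T.  Classes are written "TCA>TTA".
Ambiguity codes (N etc.) are rejected here; callers filter upstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
PURINES = "AG"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: The six pyrimidine substitution types, in canonical (COSMIC) order.
SUBSTITUTION_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Default flank width (bases beyond the central trinucleotide, per side).
FULL_FLANK = 4


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def _check_dna(seq: str, what: str = "sequence") -> None:
    if not seq or any(c not in _BASE_INDEX for c in seq):
        raise ValueError(f"invalid {what} {seq!r}: must be a non-empty A/C/G/T string")


@dataclass(frozen=True, order=True)
class MutationClass:
    """One of the 96 strand-collapsed trinucleotide mutation classes.

    ``ref_tri`` is the reference trinucleotide with a pyrimidine (C or T)
    centre; ``alt`` is the central base after mutation.  Use
    :func:`canonical_class` to build one from an arbitrary-strand observation.
    """

    ref_tri: str
    alt: str

    def __post_init__(self) -> None:
        _check_dna(self.ref_tri, "trinucleotide")
        if len(self.ref_tri) != 3:
            raise ValueError(f"trinucleotide must have length 3, got {self.ref_tri!r}")
        if self.ref_tri[1] not in PYRIMIDINES:
            raise ValueError(
                f"canonical class requires a pyrimidine centre, got {self.ref_tri!r}; "
                "use canonical_class() to strand-collapse"
            )
        _check_dna(self.alt, "alternate base")
        if len(self.alt) != 1 or self.alt == self.ref_tri[1]:
            raise ValueError(
                f"alternate base must be a single base != {self.ref_tri[1]!r}, got {self.alt!r}"
            )

    @property
    def alt_tri(self) -> str:
        return self.ref_tri[0] + self.alt + self.ref_tri[2]

    @property
    def substitution_type(self) -> str:
        """The central change, e.g. 'C>T'."""
        return f"{self.ref_tri[1]}>{self.alt}"

    @property
    def label(self) -> str:
        """String form used in all files and logs, e.g. 'TCA>TTA'."""
        return f"{self.ref_tri}>{self.alt_tri}"

    @property
    def cosmic_label(self) -> str:
        """COSMIC-style bracket label, e.g. 'T[C>T]A'."""
        return f"{self.ref_tri[0]}[{self.substitution_type}]{self.ref_tri[2]}"

    @property
    def index(self) -> int:
        """Position in the canonical COSMIC ordering (0..95)."""
        return class_index(self)

    @classmethod
    def from_label(cls, label: str) -> "MutationClass":
        """Parse either 'TCA>TTA' or COSMIC 'T[C>T]A' labels."""
        label = label.strip()
        if "[" in label:
            # A[C>T]G dialect
            try:
                five, rest = label.split("[")
                sub, three = rest.split("]")
                ref_c, alt_c = sub.split(">")
            except ValueError as exc:
                raise ValueError(f"unparseable mutation-class label {label!r}") from exc
            return canonical_class(five + ref_c + three, alt_c)
        if ">" in label:
            ref_tri, alt_tri = label.split(">")
            if len(ref_tri) != 3 or len(alt_tri) != 3:
                raise ValueError(f"unparseable mutation-class label {label!r}")
            if ref_tri[0] != alt_tri[0] or ref_tri[2] != alt_tri[2]:
                raise ValueError(f"flanks differ in mutation-class label {label!r}")
            return canonical_class(ref_tri, alt_tri[1])
        raise ValueError(f"unparseable mutation-class label {label!r}")

    def __str__(self) -> str:
        return self.label


def canonical_class(ref_tri: str, alt: str) -> MutationClass:
    """Strand-collapse a trinucleotide substitution onto the pyrimidine strand.

    If the central base is a purine, both the trinucleotide and the alternate
    base are reverse complemented, so e.g. ``canonical_class("AGC", "T")``
    (AGC>ATC) returns the class GCT>GAT.
    """
    _check_dna(ref_tri, "trinucleotide")
    if len(ref_tri) != 3:
        raise ValueError(f"trinucleotide must have length 3, got {ref_tri!r}")
    _check_dna(alt, "alternate base")
    if len(alt) != 1:
        raise ValueError(f"alternate base must be a single base, got {alt!r}")
    if alt == ref_tri[1]:
        raise ValueError(f"alternate base equals the reference centre in {ref_tri!r}>{alt!r}")
    if ref_tri[1] in PURINES:
        ref_tri = reverse_complement(ref_tri)
        alt = complement(alt)
    return MutationClass(ref_tri, alt)


def class_index(mc: MutationClass) -> int:
    sub = SUBSTITUTION_TYPES.index(mc.substitution_type)
    return sub * 16 + _BASE_INDEX[mc.ref_tri[0]] * 4 + _BASE_INDEX[mc.ref_tri[2]]


def _build_classes() -> tuple[MutationClass, ...]:
    out = []
    for sub in SUBSTITUTION_TYPES:
        ref_c, alt_c = sub.split(">")
        for five in BASES:
            for three in BASES:
                out.append(MutationClass(five + ref_c + three, alt_c))
    return tuple(out)


#: The 96 mutation classes in canonical COSMIC order.
CLASSES: tuple[MutationClass, ...] = _build_classes()
CLASS_LABELS: tuple[str, ...] = tuple(mc.label for mc in CLASSES)
COSMIC_LABELS: tuple[str, ...] = tuple(mc.cosmic_label for mc in CLASSES)
N_CLASSES = len(CLASSES)


@dataclass(frozen=True)
class KmerChange:
    """A single-nucleotide change at the centre of an odd-length k-mer.

    At the canonical scale ``ref`` has length 11 (flank 4).  The canonical
    form has a pyrimidine centre; :func:`canonical_change` strand-collapses.
    """

    ref: str
    alt: str

    def __post_init__(self) -> None:
        _check_dna(self.ref, "k-mer")
        if len(self.ref) < 3 or len(self.ref) % 2 == 0:
            raise ValueError(f"k-mer must have odd length >= 3, got {self.ref!r}")
        _check_dna(self.alt, "alternate base")
        if len(self.alt) != 1 or self.alt == self.center:
            raise ValueError(
                f"alternate base must be a single base != centre {self.center!r}, got {self.alt!r}"
            )

    @property
    def flank(self) -> int:
        """Bases beyond the central trinucleotide, per side."""
        return (len(self.ref) - 3) // 2

    @property
    def center(self) -> str:
        return self.ref[len(self.ref) // 2]

    @property
    def mutated(self) -> str:
        mid = len(self.ref) // 2
        return self.ref[:mid] + self.alt + self.ref[mid + 1 :]

    @property
    def is_canonical(self) -> bool:
        return self.center in PYRIMIDINES

    @property
    def mutation_class(self) -> MutationClass:
        """The (canonical) mutation class of the central trinucleotide change."""
        mid = len(self.ref) // 2
        return canonical_class(self.ref[mid - 1 : mid + 2], self.alt)

    def canonical(self) -> "KmerChange":
        if self.is_canonical:
            return self
        return KmerChange(reverse_complement(self.ref), complement(self.alt))

    @property
    def label(self) -> str:
        return f"{self.ref}>{self.mutated}"

    def __str__(self) -> str:
        return self.label


def canonical_change(ref_kmer: str, alt: str) -> KmerChange:
    """Strand-collapse a k-mer change so its centre is a pyrimidine."""
    return KmerChange(ref_kmer, alt).canonical()


def count_changes(flank: int = FULL_FLANK) -> int:
    """Number of canonical k-mer changes per mutation class at a flank width."""
    return 4 ** (2 * flank)


def iter_changes(mc: MutationClass, flank: int = FULL_FLANK) -> Iterator[KmerChange]:
    """Yield the canonical k-mer changes of class ``mc`` in flank-index order."""
    for digits in itertools.product(BASES, repeat=2 * flank):
        left = "".join(digits[:flank])
        right = "".join(digits[flank:])
        yield KmerChange(left + mc.ref_tri + right, mc.alt)


def enumerate_changes(mc: MutationClass, flank: int = FULL_FLANK) -> list[KmerChange]:
    """All canonical k-mer changes whose central trinucleotide change is ``mc``.

    At flank 4 the result has exactly 4**8 = 65,536 elements; the 96 sets
    partition the 6,291,456 canonical 11-mer changes.
    """
    return list(iter_changes(mc, flank))


def flank_index(change: KmerChange) -> int:
    """Base-4 rank of the concatenated flanks (left then right, MSB first).

    This is the position of the change inside ``enumerate_changes`` of its
    class, and the column index used by score tables.
    """
    c = change if change.is_canonical else change.canonical()
    f = c.flank
    idx = 0
    for b in c.ref[:f] + c.ref[f + 3 :]:
        idx = idx * 4 + _BASE_INDEX[b]
    return idx


def change_location(ref_kmer: str, alt: str) -> tuple[int, int]:
    """(class index, flank index) of a k-mer change, canonicalizing strands."""
    c = canonical_change(ref_kmer, alt)
    return class_index(c.mutation_class), flank_index(c)


# ---------------------------------------------------------------------------
# Vectorized helpers (used by table readers and the synthetic generator).

#: substitution-type index by (centre digit, alt digit); -1 marks invalid.
_SUB_LUT = np.full((4, 4), -1, dtype=np.int64)
for _i, _sub in enumerate(SUBSTITUTION_TYPES):
    _SUB_LUT[_BASE_INDEX[_sub[0]], _BASE_INDEX[_sub[2]]] = _i

_DECODE = np.full(256, -1, dtype=np.int8)
for _b, _d in _BASE_INDEX.items():
    _DECODE[ord(_b)] = _d
    _DECODE[ord(_b.lower())] = _d


def seqs_to_digits(seqs: "np.ndarray | list[str]") -> np.ndarray:
    """Encode equal-length DNA strings as an (n, L) array of 0..3 digits."""
    arr = np.asarray(seqs, dtype=str)
    if arr.size == 0:
        return np.empty((0, 0), dtype=np.int8)
    joined = "".join(arr.tolist())
    flat = _DECODE[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    if (flat < 0).any():
        raise ValueError("non-ACGT character in sequence array")
    return flat.reshape(arr.size, -1)


def digit_locations(digits: np.ndarray, alt_digits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`change_location` on digit-encoded k-mers.

    ``digits`` is (n, 2*flank+3); ``alt_digits`` is (n,).  Purine-centred rows
    are reverse complemented in place of the string round trip.
    """
    digits = np.asarray(digits, dtype=np.int64)
    alt_digits = np.asarray(alt_digits, dtype=np.int64)
    n, length = digits.shape
    mid = length // 2
    purine = (digits[:, mid] == 0) | (digits[:, mid] == 2)  # A or G
    if purine.any():
        digits = digits.copy()
        alt_digits = alt_digits.copy()
        digits[purine] = 3 - digits[purine, ::-1]
        alt_digits[purine] = 3 - alt_digits[purine]
    if (alt_digits == digits[:, mid]).any():
        raise ValueError("alternate base equals reference centre")
    sub = _SUB_LUT[digits[:, mid], alt_digits]
    if (sub < 0).any():
        raise ValueError("invalid substitution encoding")
    class_idx = sub * 16 + digits[:, mid - 1] * 4 + digits[:, mid + 1]
    flank_cols = np.concatenate([digits[:, : mid - 1], digits[:, mid + 2 :]], axis=1)
    powers = 4 ** np.arange(flank_cols.shape[1] - 1, -1, -1, dtype=np.int64)
    return class_idx, flank_cols @ powers


def flank_digit_matrix(flank: int) -> np.ndarray:
    """(4**(2*flank), 2*flank) digit matrix of all flank combinations, in index order."""
    n = 4 ** (2 * flank)
    cols = []
    for pos in range(2 * flank):
        reps = 4 ** (2 * flank - 1 - pos)
        cols.append(np.tile(np.repeat(np.arange(4), reps), n // (reps * 4)))
    return np.stack(cols, axis=1).astype(np.int8) if cols else np.empty((1, 0), dtype=np.int8)
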