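"""Position-specific nucleotide preference model for the PPARα/RXRα DR1 site.

The PPARα/RXRα heterodimer binds a composite element: five recognized bases of
5' extension, the PPARα hexad, a one-base spacer, and the RXRα hexad (18 bp of
matched sequence in total; the −6 extension position is not recognized and is
excluded from matching).  Competitive-inhibition experiments place each
nucleotide at each position into a stringency tier — above 80% inhibition,
60–80%, 50–60%, or non-preferred — and the degenerate consensus at any tier is
the per-position IUPAC union of nucleotides at or above it:

    >80%    WAWVT-RGGBBA-H-RGKTYA
    60–80%  DAWVT-RGGBBA-N-RGKTBA
    50–60%  NAWVT-RGGBBA-N-RGKTBR

This module encodes that tiered model, derives consensus motifs at a chosen
stringency, builds consensus strings from aligned sites, and classifies DR1
elements as PPRE, RXRE, or dual elements from the 5' hexad and spacer.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "NUCLEOTIDES",
    "IUPAC_SETS",
    "set_from_iupac",
    "iupac_from_set",
    "complement_code",
    "Segment",
    "PositionLabel",
    "MATRIX_POSITIONS",
    "MOTIF_POSITIONS",
    "PreferenceTier",
    "PreferenceMatrix",
    "CompositeMotif",
    "DR1Class",
    "encode_reference_model",
    "consensus_at_threshold",
    "consensus_from_alignment",
    "classify_dr1",
]

# ---------------------------------------------------------------------------
# Nucleotides and IUPAC degeneracy codes
# ---------------------------------------------------------------------------

NUCLEOTIDES: tuple[str, ...] = ("A", "C", "G", "T")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: The 15 non-empty IUPAC codes, each naming a subset of {A,C,G,T}.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {s: c for c, s in IUPAC_SETS.items()}


def set_from_iupac(code: str) -> frozenset[str]:
    """Return the nucleotide subset named by a single IUPAC letter.

    Case-insensitive.  Raises ``ValueError`` naming the letter if it is not
    one of the 15 non-empty codes.
    """
    letter = code.upper()
    try:
        return IUPAC_SETS[letter]
    except KeyError:
        raise ValueError(f"unknown IUPAC code: {code!r}") from None


def iupac_from_set(s: Iterable[str]) -> str:
    """Return the IUPAC letter for a non-empty nucleotide subset.

    Inverse of :func:`set_from_iupac`; raises ``ValueError`` on an empty set
    or on symbols outside A/C/G/T.
    """
    fs = frozenset(x.upper() for x in s)
    if not fs:
        raise ValueError("empty nucleotide set has no IUPAC code")
    if not fs <= IUPAC_SETS["N"]:
        raise ValueError(f"non-nucleotide symbols in set: {sorted(fs)}")
    return _SET_TO_CODE[fs]


def complement_code(code: str) -> str:
    """Complement a single IUPAC code (the code of the complemented set)."""
    return iupac_from_set(_COMPLEMENT[b] for b in set_from_iupac(code))


# ---------------------------------------------------------------------------
# Position labels over the composite site
# ---------------------------------------------------------------------------


class Segment(enum.Enum):
    """The four segments of the composite DR1 site, in 5'→3' order."""

    EXT5 = "ext5"  # 5' extension, positions −6..−1 (−6 not recognized)
    HEXAD5 = "hexad5"  # PPARα core hexad, +1..+6
    SPACER = "spacer"  # single spacer base
    HEXAD3 = "hexad3"  # RXRα core hexad, R+1..R+6


_SEGMENT_ORDER = {Segment.EXT5: 0, Segment.HEXAD5: 1, Segment.SPACER: 2, Segment.HEXAD3: 3}


@dataclass(frozen=True, order=False)
class PositionLabel:
    """A position within the composite site, e.g. EXT5 −5 or HEXAD3 R+3."""

    segment: Segment
    index: int

    def sort_key(self) -> tuple[int, int]:
        return (_SEGMENT_ORDER[self.segment], self.index)

    def __str__(self) -> str:
        if self.segment is Segment.EXT5:
            return str(self.index)
        if self.segment is Segment.HEXAD5:
            return f"+{self.index}"
        if self.segment is Segment.SPACER:
            return "S"
        return f"R+{self.index}"

    @classmethod
    def parse(cls, text: str) -> "PositionLabel":
        t = text.strip()
        if t == "S":
            return cls(Segment.SPACER, 0)
        if t.startswith("R+"):
            return cls(Segment.HEXAD3, int(t[2:]))
        if t.startswith("+"):
            return cls(Segment.HEXAD5, int(t[1:]))
        if t.startswith("-"):
            return cls(Segment.EXT5, int(t))
        raise ValueError(f"unparseable position label: {text!r}")


def _build_positions() -> tuple[PositionLabel, ...]:
    labels = [PositionLabel(Segment.EXT5, i) for i in range(-6, 0)]
    labels += [PositionLabel(Segment.HEXAD5, i) for i in range(1, 7)]
    labels.append(PositionLabel(Segment.SPACER, 0))
    labels += [PositionLabel(Segment.HEXAD3, i) for i in range(1, 7)]
    return tuple(labels)


#: All 19 modelled positions (EXT5 −6 … HEXAD3 R+6).
MATRIX_POSITIONS: tuple[PositionLabel, ...] = _build_positions()

#: The 18 positions that participate in matching (EXT5 −6 excluded:
#: the nucleotide there does not affect PPARα binding).
MOTIF_POSITIONS: tuple[PositionLabel, ...] = MATRIX_POSITIONS[1:]


# ---------------------------------------------------------------------------
# Preference tiers and the tier matrix
# ---------------------------------------------------------------------------


class PreferenceTier(enum.IntEnum):
    """Stringency tier of a nucleotide at a position, by competitive inhibition.

    Ordered: OPTIMAL_GT80 > ALLOWED_60_80 > ALLOWED_50_60 > NONPREFERRED.
    """

    NONPREFERRED = 0
    ALLOWED_50_60 = 1
    ALLOWED_60_80 = 2
    OPTIMAL_GT80 = 3


#: Tiers usable as inclusion thresholds for consensus derivation.
THRESHOLD_TIERS = (
    PreferenceTier.OPTIMAL_GT80,
    PreferenceTier.ALLOWED_60_80,
    PreferenceTier.ALLOWED_50_60,
)

_TSV_HEADER = ["segment", "index", "A", "C", "G", "T"]


@dataclass(frozen=True)
class PreferenceMatrix:
    """Per-position, per-nucleotide preference tiers for the composite site."""

    entries: Mapping[tuple[PositionLabel, str], PreferenceTier]
    provenance: Mapping[PositionLabel, str]

    def __post_init__(self) -> None:
        for pos in MATRIX_POSITIONS:
            for nuc in NUCLEOTIDES:
                if (pos, nuc) not in self.entries:
                    raise ValueError(f"matrix missing entry ({pos}, {nuc})")

    def tier(self, pos: PositionLabel, nuc: str) -> PreferenceTier:
        return self.entries[(pos, nuc.upper())]

    def allowed_at(self, pos: PositionLabel, threshold: PreferenceTier) -> frozenset[str]:
        """Nucleotides whose tier at ``pos`` is at or above ``threshold``."""
        return frozenset(n for n in NUCLEOTIDES if self.entries[(pos, n)] >= threshold)

    # -- TSV round-trip ----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        lines = ["\t".join(_TSV_HEADER)]
        for pos in MATRIX_POSITIONS:
            cells = [pos.segment.value, str(pos.index)]
            cells += [self.entries[(pos, n)].name for n in NUCLEOTIDES]
            lines.append("\t".join(cells))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PreferenceMatrix":
        lines = Path(path).read_text().splitlines()
        if not lines or lines[0].split("\t") != _TSV_HEADER:
            raise ValueError(f"bad preference-matrix header in {path}")
        entries: dict[tuple[PositionLabel, str], PreferenceTier] = {}
        for ln in lines[1:]:
            if not ln.strip():
                continue
            seg, idx, *tiers = ln.split("\t")
            pos = PositionLabel(Segment(seg), int(idx))
            for nuc, name in zip(NUCLEOTIDES, tiers):
                entries[(pos, nuc)] = PreferenceTier[name]
        return cls(entries=entries, provenance={})


# ---------------------------------------------------------------------------
# Composite degenerate motifs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositeMotif:
    """Four-segment degenerate motif: 5' extension (5), PPARα hexad (6),
    spacer (1), RXRα hexad (6) — 18 IUPAC codes in matching order."""

    ext5: str
    hexad5: str
    spacer: str
    hexad3: str

    def __post_init__(self) -> None:
        for name, seg, n in (
            ("ext5", self.ext5, 5),
            ("hexad5", self.hexad5, 6),
            ("spacer", self.spacer, 1),
            ("hexad3", self.hexad3, 6),
        ):
            if len(seg) != n:
                raise ValueError(f"{name} must be {n} codes, got {seg!r}")
            for c in seg:
                set_from_iupac(c)  # validates

    @property
    def codes(self) -> str:
        """The 18 IUPAC codes as one string, 5'→3'."""
        return self.ext5 + self.hexad5 + self.spacer + self.hexad3

    def allowed_sets(self) -> tuple[frozenset[str], ...]:
        return tuple(set_from_iupac(c) for c in self.codes)

    def to_string(self) -> str:
        """Hyphen-delimited dialect, e.g. ``WAWVT-RGGBBA-H-RGKTYA``."""
        return "-".join([self.ext5, self.hexad5, self.spacer, self.hexad3])

    @classmethod
    def from_string(cls, text: str) -> "CompositeMotif":
        parts = text.strip().upper().split("-")
        if len(parts) != 4:
            raise ValueError(f"expected 4 hyphen-separated segments: {text!r}")
        return cls(ext5=parts[0], hexad5=parts[1], spacer=parts[2], hexad3=parts[3])

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "CompositeMotif":
        s = "".join(codes).upper()
        if len(s) != 18:
            raise ValueError(f"composite motif needs 18 codes, got {len(s)}")
        return cls(ext5=s[:5], hexad5=s[5:11], spacer=s[11], hexad3=s[12:])


# ---------------------------------------------------------------------------
# The reference preference model
# ---------------------------------------------------------------------------

# Consensus strings at the three competitive-inhibition thresholds, over the
# 18 matched positions.  The printed 50–60% extension has four letters; the
# model treats position −5 as fully unconstrained (N) at that tier,
# consistent with progressive relaxation of the extension.
_CONSENSUS_GT80 = "WAWVT" + "RGGBBA" + "H" + "RGKTYA"
_CONSENSUS_60_80 = "DAWVT" + "RGGBBA" + "N" + "RGKTBA"
_CONSENSUS_50_60 = "NAWVT" + "RGGBBA" + "N" + "RGKTBR"


def encode_reference_model() -> PreferenceMatrix:
    """Build the reference tier matrix from the three consensus strings.

    Per matched position: nucleotides in the >80% code get OPTIMAL_GT80;
    nucleotides newly admitted by the 60–80% code get ALLOWED_60_80; those
    newly admitted by the 50–60% code get ALLOWED_50_60; the rest are
    NONPREFERRED.  EXT5 −6 is uniformly unconstrained (the nucleotide there
    does not affect PPARα binding).
    """
    entries: dict[tuple[PositionLabel, str], PreferenceTier] = {}
    provenance: dict[PositionLabel, str] = {}

    pos_m6 = MATRIX_POSITIONS[0]
    for nuc in NUCLEOTIDES:
        entries[(pos_m6, nuc)] = PreferenceTier.OPTIMAL_GT80
    provenance[pos_m6] = "position -6 not recognized; uniformly unconstrained"

    for pos, c80, c60, c50 in zip(
        MOTIF_POSITIONS, _CONSENSUS_GT80, _CONSENSUS_60_80, _CONSENSUS_50_60
    ):
        s80 = set_from_iupac(c80)
        s60 = set_from_iupac(c60)
        s50 = set_from_iupac(c50)
        if not (s80 <= s60 <= s50):
            raise AssertionError(f"non-nested consensus codes at {pos}")
        for nuc in NUCLEOTIDES:
            if nuc in s80:
                tier = PreferenceTier.OPTIMAL_GT80
            elif nuc in s60:
                tier = PreferenceTier.ALLOWED_60_80
            elif nuc in s50:
                tier = PreferenceTier.ALLOWED_50_60
            else:
                tier = PreferenceTier.NONPREFERRED
            entries[(pos, nuc)] = tier
        provenance[pos] = f"consensus codes {c80}/{c60}/{c50} (>80 / 60-80 / 50-60)"

    return PreferenceMatrix(entries=entries, provenance=provenance)


def consensus_at_threshold(
    matrix: PreferenceMatrix, threshold: PreferenceTier
) -> CompositeMotif:
    """Degenerate consensus motif at an inclusion threshold.

    Each of the 18 matched positions emits the IUPAC code of the union of
    nucleotides at or above ``threshold``; an all-nucleotide union emits N.
    """
    if threshold not in THRESHOLD_TIERS:
        raise ValueError(f"threshold must be one of {[t.name for t in THRESHOLD_TIERS]}")
    codes = []
    for pos in MOTIF_POSITIONS:
        allowed = matrix.allowed_at(pos, threshold)
        if not allowed:
            raise ValueError(f"malformed matrix: empty allowed set at {pos}")
        codes.append(iupac_from_set(allowed))
    return CompositeMotif.from_codes(codes)


# ---------------------------------------------------------------------------
# Consensus from aligned sites
# ---------------------------------------------------------------------------


def consensus_from_alignment(seqs: Sequence[str]) -> str:
    """Per-column majority consensus of equal-length A/C/G/T sequences.

    A tied column emits the IUPAC code of the tied set (lossless and
    deterministic, unlike picking an arbitrary winner).
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    length = len(seqs[0])
    upper = [s.upper() for s in seqs]
    for s in upper:
        if len(s) != length:
            raise ValueError("sequences must have equal lengths")
        if not set(s) <= set(NUCLEOTIDES):
            raise ValueError(f"non-ACGT characters in sequence {s!r}")
    out = []
    for col in range(length):
        counts = Counter(s[col] for s in upper)
        top = max(counts.values())
        tied = frozenset(n for n, c in counts.items() if c == top)
        out.append(iupac_from_set(tied))
    return "".join(out)


# ---------------------------------------------------------------------------
# DR1 classification: PPRE vs RXRE vs dual
# ---------------------------------------------------------------------------


class DR1Class(enum.Enum):
    """Functional classification of a DR1 element from its 5' hexad + spacer."""

    PPRE_ONLY = "PPRE_ONLY"
    DUAL = "DUAL"
    RXRE_LEANING = "RXRE_LEANING"
    NEITHER = "NEITHER"


_PPAR_HEXAD = "RGGBBA"
# RXRα-compatible hexads: the optimal code plus the two relaxed-tier codes.
_RXR_HEXADS = ("RGKTYA", "RGKTBA", "RGKTBR")


def _matches_code_string(word: str, codes: str) -> bool:
    return len(word) == len(codes) and all(
        b in set_from_iupac(c) for b, c in zip(word, codes)
    )


def classify_dr1(hexad5: str, spacer: str) -> DR1Class:
    """Classify a DR1 element from its concrete 5' hexad and spacer base.

    A hexad matching the PPARα preference (RGGBBA) but not any RXRα code is a
    PPRE; a hexad in both sets is a dual PPRE/RXRE only when the spacer is A
    (RXRα homodimer binding requires the A spacer), otherwise still a PPRE;
    a hexad matching only an RXRα code leans RXRE; anything else is neither.
    """
    h = hexad5.upper()
    s = spacer.upper()
    if len(h) != 6 or not set(h) <= set(NUCLEOTIDES):
        raise ValueError(f"hexad5 must be a 6-mer over ACGT: {hexad5!r}")
    if len(s) != 1 or s not in NUCLEOTIDES:
        raise ValueError(f"spacer must be one of A/C/G/T: {spacer!r}")

    in_ppar = _matches_code_string(h, _PPAR_HEXAD)
    in_rxr = any(_matches_code_string(h, codes) for codes in _RXR_HEXADS)

    if in_ppar and not in_rxr:
        return DR1Class.PPRE_ONLY
    if in_ppar and in_rxr:
        return DR1Class.DUAL if s == "A" else DR1Class.PPRE_ONLY
    if in_rxr:
        return DR1Class.RXRE_LEANING
    return DR1Class.NEITHER
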