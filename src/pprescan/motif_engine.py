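"""Degenerate-motif matching with a position-restricted mismatch budget.

The published genome screen matched the 60–80% consensus DAWVT-RGGBBA-N-RGKTBA
while allowing one non-preferred nucleotide, but only in the last three bases
of the PPARα hexad or the spacer.  This module implements that matching model
generally: a :class:`~pprescan.preference_model.CompositeMotif` plus a
:class:`MatchPolicy` (mismatch budget, the positions where it may be spent,
and strand handling), with window matching, whole-sequence scanning, exact
enumeration, and an analytic per-window match probability for use as oracles.

The core matcher works on plain IUPAC code strings of any length (budget
positions given as 0-based indices); the composite API translates the
18-position labels onto it.  Coordinates are 0-based half-open throughout;
minus-strand hits are reported in plus-strand coordinates with the matched
word given in motif orientation (the reverse complement of the plus-strand
substring).
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

from .preference_model import (
    NUCLEOTIDES,
    CompositeMotif,
    MOTIF_POSITIONS,
    PositionLabel,
    Segment,
    complement_code,
    set_from_iupac,
)

__all__ = [
    "Strand",
    "MatchPolicy",
    "MatchResult",
    "MotifHit",
    "DEFAULT_BUDGET_POSITIONS",
    "default_scan_policy",
    "reverse_complement",
    "match_at",
    "scan_sequence",
    "scan_iupac",
    "motif_cardinality",
    "match_probability",
    "enumerate_words",
]


class Strand(enum.Enum):
    PLUS = "+"
    MINUS = "-"
    BOTH = "both"


#: Positions where the published screen lets the budget be spent: the last
#: three bases of the PPARα hexad and the spacer.  With the scan motif's
#: spacer already N the spacer can never consume budget; it is kept in the
#: set for fidelity to the stated rule.
DEFAULT_BUDGET_POSITIONS: frozenset[PositionLabel] = frozenset(
    [
        PositionLabel(Segment.HEXAD5, 4),
        PositionLabel(Segment.HEXAD5, 5),
        PositionLabel(Segment.HEXAD5, 6),
        PositionLabel(Segment.SPACER, 0),
    ]
)

_MOTIF_INDEX = {lab: i for i, lab in enumerate(MOTIF_POSITIONS)}


@dataclass(frozen=True)
class MatchPolicy:
    """Mismatch budget, where it may be spent, and which strands to scan."""

    budget: int = 0
    budget_positions: frozenset[PositionLabel] = frozenset()
    strands: Strand = Strand.BOTH

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be non-negative")
        extra = self.budget_positions - set(MOTIF_POSITIONS)
        if extra:
            raise ValueError(
                f"budget positions outside the motif: {sorted(map(str, extra))}"
            )

    def budget_indices(self) -> tuple[int, ...]:
        return tuple(sorted(_MOTIF_INDEX[lab] for lab in self.budget_positions))


def default_scan_policy(budget: int = 1, strands: Strand = Strand.BOTH) -> MatchPolicy:
    """The published screen's policy: ``budget`` mismatches over hexad-5
    positions +4..+6 and the spacer, both strands."""
    return MatchPolicy(
        budget=budget, budget_positions=DEFAULT_BUDGET_POSITIONS, strands=strands
    )


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    mismatch_positions: tuple[PositionLabel, ...]
    segments: Mapping[str, str]  # aligned window split as ext5/hexad5/spacer/hexad3


@dataclass(frozen=True)
class MotifHit:
    """A located match; ``word`` is in motif orientation (minus-strand hits
    carry the reverse complement of the plus-strand substring)."""

    seq_id: str
    start: int
    end: int
    strand: str
    word: str
    mismatch_positions: tuple[PositionLabel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("hit interval must be non-empty with start >= 0")
        if self.end - self.start != len(self.word):
            raise ValueError("hit interval length disagrees with matched word")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# Reverse complement over the IUPAC alphabet
# ---------------------------------------------------------------------------

_CODE_COMPLEMENT = {c: complement_code(c) for c in "ACGTRYSWKMBDHVN"}
_RC_TABLE = str.maketrans(_CODE_COMPLEMENT | {c.lower(): _CODE_COMPLEMENT[c].lower() for c in _CODE_COMPLEMENT})
_BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    """Reverse-complement an IUPAC string (set-wise complement per code).

    An involution; case is preserved.  Rejects non-IUPAC characters.
    """
    for ch in seq:
        if ch.upper() not in _CODE_COMPLEMENT:
            raise ValueError(f"non-IUPAC character: {ch!r}")
    return seq.translate(_RC_TABLE)[::-1]


# ---------------------------------------------------------------------------
# Core matcher (plain IUPAC code strings, budget positions as indices)
# ---------------------------------------------------------------------------


def _complement_sets(sets: Sequence[frozenset[str]]) -> list[frozenset[str]]:
    return [frozenset(_BASE_COMPLEMENT[b] for b in s) for s in sets]


def _core_scan(
    seq_upper: str,
    sets: Sequence[frozenset[str]],
    in_budget: Sequence[bool],
    budget: int,
) -> list[tuple[int, tuple[int, ...]]]:
    """All (offset, mismatch-index) pairs where the window is accepted.

    A window is accepted iff every position whose base falls outside the
    allowed set is flagged budget-eligible and the total mismatch count does
    not exceed ``budget``.  Bases outside A/C/G/T (e.g. N) never match.
    """
    n = len(sets)
    out: list[tuple[int, tuple[int, ...]]] = []
    for i in range(len(seq_upper) - n + 1):
        mm: list[int] = []
        ok = True
        for j in range(n):
            if seq_upper[i + j] not in sets[j]:
                if not in_budget[j] or len(mm) >= budget:
                    ok = False
                    break
                mm.append(j)
        if ok:
            out.append((i, tuple(mm)))
    return out


def scan_iupac(
    seq: str,
    codes: str,
    budget: int = 0,
    budget_indices: Sequence[int] = (),
    strands: Strand = Strand.BOTH,
    seq_id: str = "seq",
    mask_lowercase: bool = False,
) -> list[MotifHit]:
    """Scan a sequence for an arbitrary-length IUPAC motif string.

    Generic entry point behind :func:`scan_sequence`; mismatch positions on
    hits are reported through ``MotifHit.mismatch_positions`` only when the
    motif is the full 18-position composite (other lengths report none).
    """
    sets = [set_from_iupac(c) for c in codes]
    n = len(sets)
    if n == 0 or len(seq) < n:
        return []
    flags = [i in set(budget_indices) for i in range(n)]
    upper = seq.upper()
    soft = [c.islower() for c in seq] if mask_lowercase else None

    wanted: list[str] = []
    if strands in (Strand.PLUS, Strand.BOTH):
        wanted.append("+")
    if strands in (Strand.MINUS, Strand.BOTH):
        wanted.append("-")

    hits: list[MotifHit] = []
    for strand in wanted:
        if strand == "+":
            s_sets, s_flags = sets, flags
        else:
            s_sets = _complement_sets(sets)[::-1]
            s_flags = flags[::-1]
        for i, mm in _core_scan(upper, s_sets, s_flags, budget):
            if soft is not None and any(soft[i : i + n]):
                continue
            # map window indices back to motif indices on the minus strand
            motif_idx = tuple(sorted(j if strand == "+" else n - 1 - j for j in mm))
            labels = (
                tuple(MOTIF_POSITIONS[j] for j in motif_idx) if n == 18 else ()
            )
            word = upper[i : i + n]
            if strand == "-":
                word = reverse_complement(word)
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=i,
                    end=i + n,
                    strand=strand,
                    word=word,
                    mismatch_positions=labels,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Composite-motif API
# ---------------------------------------------------------------------------


def match_at(
    seq: str, offset: int, motif: CompositeMotif, policy: MatchPolicy
) -> MatchResult:
    """Test the 18-mer window of ``seq`` at ``offset`` against the motif.

    Case-insensitive; any base outside A/C/G/T (e.g. N) is a mismatch at its
    position.  The window matches iff every mismatching position is in the
    policy's budget set and their count is within budget.
    """
    n = 18
    if offset < 0 or offset + n > len(seq):
        raise ValueError(
            f"window [{offset}, {offset + n}) exceeds sequence of length {len(seq)}"
        )
    window = seq[offset : offset + n].upper()
    sets = [set_from_iupac(c) for c in motif.codes]
    in_budget = {lab for lab in policy.budget_positions}
    mismatches: list[PositionLabel] = []
    ok = True
    for j, (allowed, base) in enumerate(zip(sets, window)):
        if base not in allowed:
            label = MOTIF_POSITIONS[j]
            mismatches.append(label)
            if label not in in_budget:
                ok = False
    matched = ok and len(mismatches) <= policy.budget
    segments = {
        "ext5": window[:5],
        "hexad5": window[5:11],
        "spacer": window[11],
        "hexad3": window[12:],
    }
    return MatchResult(
        matched=matched, mismatch_positions=tuple(mismatches), segments=segments
    )


def scan_sequence(
    seq: str,
    motif: CompositeMotif,
    policy: MatchPolicy,
    seq_id: str = "seq",
    mask_lowercase: bool = False,
) -> list[MotifHit]:
    """All composite-motif hits in a sequence, honouring the strand policy.

    Every offset is tested; overlapping hits are all reported, ordered by
    (start, strand).  ``mask_lowercase`` drops hits whose window overlaps any
    soft-masked (lowercase) base; otherwise matching is case-insensitive.
    """
    return scan_iupac(
        seq,
        motif.codes,
        budget=policy.budget,
        budget_indices=policy.budget_indices(),
        strands=policy.strands,
        seq_id=seq_id,
        mask_lowercase=mask_lowercase,
    )


# ---------------------------------------------------------------------------
# Enumeration and probability oracles
# ---------------------------------------------------------------------------


def _codes_of(motif: CompositeMotif | str) -> str:
    return motif.codes if isinstance(motif, CompositeMotif) else str(motif).upper()


def _budget_spec(
    motif: CompositeMotif | str, policy: MatchPolicy | None
) -> tuple[int, tuple[int, ...]]:
    if policy is None:
        return 0, ()
    return policy.budget, policy.budget_indices()


def motif_cardinality(
    motif: CompositeMotif | str, policy: MatchPolicy | None = None
) -> int:
    """Number of distinct A/C/G/T words the motif accepts under the policy.

    With budget 0 this is the product of per-position allowed-set sizes; a
    positive budget adds, for each admissible mismatch pattern, the words
    that miss exactly at those positions (disallowed-set sizes there).
    """
    codes = _codes_of(motif)
    budget, budget_idx = _budget_spec(motif, policy)
    sets = [set_from_iupac(c) for c in codes]
    total = 0
    for k in range(min(budget, len(budget_idx)) + 1):
        for combo in itertools.combinations(budget_idx, k):
            prod = 1
            for i, s in enumerate(sets):
                prod *= (4 - len(s)) if i in combo else len(s)
            total += prod
    return total


def match_probability(
    motif: CompositeMotif | str,
    policy: MatchPolicy | None = None,
    base_freqs: Mapping[str, float] | None = None,
) -> float:
    """Probability that one i.i.d. random window matches under the policy.

    ``base_freqs`` maps A/C/G/T to frequencies summing to 1 (uniform by
    default).  Computed as the per-position product of allowed-set masses,
    summed over admissible mismatch patterns (disallowed mass at the
    mismatching positions).
    """
    if base_freqs is None:
        base_freqs = {n: 0.25 for n in NUCLEOTIDES}
    freqs = {n: float(base_freqs.get(n, 0.0)) for n in NUCLEOTIDES}
    if any(v < 0 for v in freqs.values()) or abs(sum(freqs.values()) - 1.0) > 1e-9:
        raise ValueError(
            f"base frequencies must be non-negative and sum to 1: {base_freqs}"
        )
    codes = _codes_of(motif)
    budget, budget_idx = _budget_spec(motif, policy)
    sets = [set_from_iupac(c) for c in codes]
    p_in = [sum(freqs[n] for n in s) for s in sets]
    p_out = [1.0 - p for p in p_in]
    total = 0.0
    for k in range(min(budget, len(budget_idx)) + 1):
        for combo in itertools.combinations(budget_idx, k):
            prod = 1.0
            for i in range(len(sets)):
                prod *= p_out[i] if i in combo else p_in[i]
            total += prod
    return total


def enumerate_words(
    motif: CompositeMotif | str, policy: MatchPolicy | None = None
) -> Iterator[str]:
    """Yield every accepted A/C/G/T word (oracle; exponential in degeneracy)."""
    codes = _codes_of(motif)
    budget, budget_idx = _budget_spec(motif, policy)
    sets = [set_from_iupac(c) for c in codes]
    seen: set[str] = set()
    for k in range(min(budget, len(budget_idx)) + 1):
        for combo in itertools.combinations(budget_idx, k):
            choices = [
                sorted(set(NUCLEOTIDES) - sets[i]) if i in combo else sorted(sets[i])
                for i in range(len(sets))
            ]
            for letters in itertools.product(*choices):
                word = "".join(letters)
                if word not in seen:
                    seen.add(word)
                    yield word
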