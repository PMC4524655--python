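"""Synthetic promoter windows with planted DR1 sites and ground truth.

The generator emulates the scan's real inputs — promoter windows around a
TSS — as i.i.d. background of configurable GC content, with DR1-like sites
planted at known offsets and strands, sampled from a degenerate motif and
optionally mutated at chosen positions to a non-preferred base.  Every stage
of the pipeline (scanning, annotation, classification, recovery metrics) is
thereby testable end to end without any genome download.

The whole generator is a pure function of its dataset specification,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .preference_model import (
    NUCLEOTIDES,
    CompositeMotif,
    MOTIF_POSITIONS,
    PositionLabel,
    PreferenceMatrix,
    PreferenceTier,
    Segment,
    encode_reference_model,
    set_from_iupac,
)
from .motif_engine import reverse_complement

__all__ = [
    "PlantSpec",
    "SyntheticDatasetSpec",
    "TruthRecord",
    "RecoveryMetrics",
    "generate_background",
    "sample_site",
    "mutate_site",
    "plant_sites",
    "generate_dataset",
    "build_random_plan",
    "evaluate_recovery",
    "write_fasta",
    "write_truth_bed",
    "read_truth_bed",
]

SITE_LEN = 18

#: Positions where the default plan places mutations: the last three bases of
#: the PPARα hexad, where a non-preferred base is countable under the scan
#: policy's budget.
DEFAULT_MUTABLE_POSITIONS: tuple[PositionLabel, ...] = (
    PositionLabel(Segment.HEXAD5, 4),
    PositionLabel(Segment.HEXAD5, 5),
    PositionLabel(Segment.HEXAD5, 6),
)

_MOTIF_INDEX = {lab: i for i, lab in enumerate(MOTIF_POSITIONS)}


@dataclass(frozen=True)
class PlantSpec:
    """One planted site: where, which strand, from what, mutated how."""

    seq_index: int
    offset: int
    strand: str
    motif: CompositeMotif | None = None
    word: str | None = None
    mutation_positions: tuple[PositionLabel, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if (self.motif is None) == (self.word is None):
            raise ValueError("exactly one of motif/word must be given")
        if self.word is not None and len(self.word) != SITE_LEN:
            raise ValueError(f"explicit word must be {SITE_LEN} bp")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Parameters of a synthetic promoter set.

    Defaults mirror the real scan's window geometry: 50 windows of
    2·2000 + 1 = 4001 bp at promoter-like 42% GC.
    """

    n_sequences: int = 50
    length: int = 4001
    gc: float = 0.42
    seed: int = 0
    plan: tuple[PlantSpec, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"GC fraction must be within [0, 1], got {self.gc}")
        if self.n_sequences < 0 or self.length < 0:
            raise ValueError("n_sequences and length must be non-negative")
        by_seq: dict[int, list[tuple[int, int]]] = {}
        for p in self.plan:
            if not 0 <= p.seq_index < self.n_sequences:
                raise ValueError(f"plant sequence index {p.seq_index} out of range")
            if p.offset < 0 or p.offset + SITE_LEN > self.length:
                raise ValueError(f"plant at offset {p.offset} leaves the sequence")
            for s, e in by_seq.get(p.seq_index, []):
                if p.offset < e and s < p.offset + SITE_LEN:
                    raise ValueError(
                        f"overlapping plants in sequence {p.seq_index} at {p.offset}"
                    )
            by_seq.setdefault(p.seq_index, []).append((p.offset, p.offset + SITE_LEN))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted site (word in motif orientation)."""

    seq_id: str
    start: int
    end: int
    strand: str
    word: str
    n_mutations: int

    def __post_init__(self) -> None:
        if self.end - self.start != SITE_LEN:
            raise ValueError("truth interval must span 18 bp")


def _seq_id(i: int) -> str:
    return f"synthetic_promoter_{i:03d}"


# ---------------------------------------------------------------------------
# Background, site sampling, mutation
# ---------------------------------------------------------------------------


def generate_background(spec: SyntheticDatasetSpec) -> list[tuple[str, str]]:
    """I.i.d. background sequences with freq(G)=freq(C)=GC/2.

    Identical spec (including seed) ⇒ identical output.
    """
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc / 2.0
    p_at = (1.0 - spec.gc) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    alphabet = np.array(list("ACGT"))
    records = []
    for i in range(spec.n_sequences):
        draws = rng.choice(4, size=spec.length, p=probs)
        records.append((_seq_id(i), "".join(alphabet[draws])))
    return records


def sample_site(
    motif: CompositeMotif, rng: np.random.Generator | int | None = None
) -> str:
    """Draw a concrete 18-mer uniformly from the motif's accepted words
    (budget 0): independent uniform choice within each position's set."""
    r = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = []
    for code in motif.codes:
        allowed = sorted(set_from_iupac(code))
        out.append(allowed[r.integers(len(allowed))])
    return "".join(out)


def mutate_site(
    site: str,
    positions: Iterable[PositionLabel],
    rng: np.random.Generator | int | None = None,
    matrix: PreferenceMatrix | None = None,
) -> str:
    """Replace the base at each listed position with a non-preferred one.

    The replacement is drawn uniformly from the bases outside the
    reference-model optimal (>80%) set at that position, guaranteeing a
    countable mismatch against any tier-80-containing motif code there.
    """
    if len(site) != SITE_LEN:
        raise ValueError(f"site must be {SITE_LEN} bp")
    if matrix is None:
        matrix = encode_reference_model()
    r = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    bases = list(site.upper())
    for pos in positions:
        idx = _MOTIF_INDEX[pos]
        optimal = matrix.allowed_at(pos, PreferenceTier.OPTIMAL_GT80)
        complement = sorted(set(NUCLEOTIDES) - optimal)
        if not complement:
            raise ValueError(f"no non-preferred base exists at position {pos}")
        bases[idx] = complement[r.integers(len(complement))]
    return "".join(bases)


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def plant_sites(
    records: Sequence[tuple[str, str]],
    spec: SyntheticDatasetSpec,
    matrix: PreferenceMatrix | None = None,
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Insert the planned sites into background records; return ground truth.

    Minus-strand plants insert the reverse complement of the (motif-oriented)
    word; truth records always carry the motif-oriented word.  Site sampling
    and mutation draw from a generator seeded by ``spec.seed``, independent
    of the background stream.
    """
    if matrix is None:
        matrix = encode_reference_model()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    seqs = [list(seq) for _id, seq in records]
    truth: list[TruthRecord] = []
    for plant in spec.plan:
        word = plant.word.upper() if plant.word else sample_site(plant.motif, rng)
        if plant.mutation_positions:
            word = mutate_site(word, plant.mutation_positions, rng, matrix)
        inserted = word if plant.strand == "+" else reverse_complement(word)
        i, off = plant.seq_index, plant.offset
        seqs[i][off : off + SITE_LEN] = inserted
        truth.append(
            TruthRecord(
                seq_id=records[i][0],
                start=off,
                end=off + SITE_LEN,
                strand=plant.strand,
                word=word,
                n_mutations=len(plant.mutation_positions),
            )
        )
    out = [(rec_id, "".join(s)) for (rec_id, _), s in zip(records, seqs)]
    return out, truth


def generate_dataset(
    spec: SyntheticDatasetSpec, matrix: PreferenceMatrix | None = None
) -> tuple[list[tuple[str, str]], list[TruthRecord]]:
    """Background + planting in one step (pure function of the spec)."""
    return plant_sites(generate_background(spec), spec, matrix)


def build_random_plan(
    spec: SyntheticDatasetSpec,
    n_plants: int,
    motifs: Sequence[CompositeMotif],
    mutation_loads: Sequence[int] = (0,),
    mutable_positions: Sequence[PositionLabel] = DEFAULT_MUTABLE_POSITIONS,
    seed: int | None = None,
) -> SyntheticDatasetSpec:
    """Attach a randomized non-overlapping planting plan to a dataset spec.

    Plants cycle through ``motifs`` and ``mutation_loads``, alternate
    strands, and are placed at uniform offsets rejected on overlap.  The
    plan's randomness is seeded separately (``seed``, defaulting to
    ``spec.seed + 1``) so the background stream is unchanged.
    """
    if spec.n_sequences == 0 or spec.length < SITE_LEN:
        raise ValueError("spec cannot host any plants")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    occupied: dict[int, list[tuple[int, int]]] = {}
    plan: list[PlantSpec] = []
    for k in range(n_plants):
        seq_index = k % spec.n_sequences
        load = mutation_loads[k % len(mutation_loads)]
        motif = motifs[k % len(motifs)]
        strand = "+" if k % 2 == 0 else "-"
        for _attempt in range(1000):
            offset = int(rng.integers(spec.length - SITE_LEN + 1))
            if all(
                not (offset < e and s < offset + SITE_LEN)
                for s, e in occupied.get(seq_index, [])
            ):
                break
        else:
            raise RuntimeError(f"could not place plant {k} without overlap")
        occupied.setdefault(seq_index, []).append((offset, offset + SITE_LEN))
        positions = tuple(
            sorted(
                (
                    mutable_positions[j]
                    for j in rng.choice(
                        len(mutable_positions), size=load, replace=False
                    )
                ),
                key=PositionLabel.sort_key,
            )
        )
        plan.append(
            PlantSpec(
                seq_index=seq_index,
                offset=offset,
                strand=strand,
                motif=motif,
                mutation_positions=positions,
            )
        )
    return replace(spec, plan=tuple(plan))


# ---------------------------------------------------------------------------
# Recovery metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryMetrics:
    """Sensitivity/precision of a hit list against planted ground truth.

    A hit matches a truth record iff (sequence id, start, strand) agree.
    Undefined ratios (zero denominators) are None, not 0.
    """

    n_truth: int
    n_hits: int
    n_matched_truth: int
    n_matched_hits: int
    sensitivity: float | None
    precision: float | None
    per_class: dict[str, dict[str, float | int | None]]

    def to_dict(self) -> dict:
        return {
            "n_truth": self.n_truth,
            "n_hits": self.n_hits,
            "n_matched_truth": self.n_matched_truth,
            "n_matched_hits": self.n_matched_hits,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "per_class": self.per_class,
        }


def _hit_key(hit) -> tuple[str, int, str]:
    seq_id = getattr(hit, "seq_id", None) or getattr(hit, "contig", None)
    if seq_id is None:
        seq_id, start, strand = hit  # tuple-like
        return str(seq_id), int(start), str(strand)
    return str(seq_id), int(hit.start), str(hit.strand)


def evaluate_recovery(hits: Sequence, truth: Sequence[TruthRecord]) -> RecoveryMetrics:
    """Compare scan hits with planted truth, overall and per class.

    Classes break truth down by mutation load (``mut0``, ``mut1``, …) and by
    strand (``strand+``, ``strand-``); each reports its plant count, the
    number recovered, and sensitivity (None when the class is empty).
    """
    hit_keys = {_hit_key(h) for h in hits}
    truth_keys = [(t.seq_id, t.start, t.strand) for t in truth]
    matched = [k in hit_keys for k in truth_keys]
    n_truth = len(truth)
    n_matched_truth = sum(matched)
    truth_key_set = set(truth_keys)
    n_matched_hits = sum(1 for h in hits if _hit_key(h) in truth_key_set)
    n_hits = len(hits)

    def _ratio(num: int, den: int) -> float | None:
        return None if den == 0 else num / den

    per_class: dict[str, dict[str, float | int | None]] = {}
    labels = sorted({f"mut{t.n_mutations}" for t in truth}) + ["strand+", "strand-"]
    for label in labels:
        if label.startswith("mut"):
            idx = [i for i, t in enumerate(truth) if f"mut{t.n_mutations}" == label]
        else:
            idx = [i for i, t in enumerate(truth) if t.strand == label[-1]]
        rec = sum(matched[i] for i in idx)
        per_class[label] = {
            "n": len(idx),
            "recovered": rec,
            "sensitivity": _ratio(rec, len(idx)),
        }

    return RecoveryMetrics(
        n_truth=n_truth,
        n_hits=n_hits,
        n_matched_truth=n_matched_truth,
        n_matched_hits=n_matched_hits,
        sensitivity=_ratio(n_matched_truth, n_truth),
        precision=_ratio(n_matched_hits, n_hits),
        per_class=per_class,
    )


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_bed(truth: Sequence[TruthRecord], path: str | Path) -> None:
    """Truth as BED6: name = planted word, score = mutation count."""
    lines = [
        "\t".join([t.seq_id, str(t.start), str(t.end), t.word, str(t.n_mutations), t.strand])
        for t in truth
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_truth_bed(path: str | Path) -> list[TruthRecord]:
    truth = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        contig, start, end, word, score, strand = line.split("\t")
        truth.append(
            TruthRecord(
                seq_id=contig,
                start=int(start),
                end=int(end),
                strand=strand,
                word=word,
                n_mutations=int(score),
            )
        )
    return truth
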