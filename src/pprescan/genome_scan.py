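"""Promoter-window extraction around TSSs and DR1 scanning with gene-relative
annotation.

The published screen searched ±2 kb around transcription start sites for the
relaxed DR1 consensus.  This module reads TSSs from GTF transcript records or
BED6 intervals, slices promoter windows out of a FASTA genome, scans them on
both strands, and writes a tab-separated report: each hit is annotated
upstream/downstream of its TSS and
forward/backward relative to the gene body, with a gene-oriented signed
distance and the stringency tier of the matched word.

Coordinates are 0-based half-open internally and in BED output; the TSV
report prints 1-based inclusive intervals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyfaidx import Fasta

from .preference_model import (
    CompositeMotif,
    PreferenceMatrix,
    PositionLabel,
    PreferenceTier,
    consensus_at_threshold,
    encode_reference_model,
)
from .motif_engine import MatchPolicy, MotifHit, scan_sequence

__all__ = [
    "TSSRecord",
    "PromoterWindow",
    "ScanReportRow",
    "read_tss",
    "extract_windows",
    "windows_from_records",
    "scan_promoters",
    "write_report",
    "read_report",
    "REPORT_COLUMNS",
]


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: gene, contig, 0-based position, gene strand."""

    gene: str
    contig: str
    tss: int
    strand: str
    transcript: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PromoterWindow:
    """A plus-strand promoter slice [start, end) around a TSS, clipped to the
    contig."""

    record: TSSRecord
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start:
            raise ValueError("window sequence length disagrees with interval")


@dataclass(frozen=True)
class ScanReportRow:
    """One reported hit with gene-relative annotations.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``region``
    is ups/dns by the hit's gene-oriented 5'-most base relative to the TSS;
    ``direction`` is forward when the hit strand equals the gene strand;
    ``distance`` is the gene-oriented signed offset of that 5'-most base from
    the TSS (negative upstream); ``tier`` is the highest consensus threshold
    the matched word satisfies with no mismatch (gt80 / 60-80 / 50-60 /
    below50).
    """

    gene: str
    contig: str
    start: int
    end: int
    strand: str
    region: str
    direction: str
    distance: int
    sequence: str
    mismatch_positions: tuple[PositionLabel, ...]
    tier: str

    def __post_init__(self) -> None:
        if self.region not in ("ups", "dns"):
            raise ValueError(f"region must be ups or dns, got {self.region!r}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"direction must be forward or backward: {self.direction!r}")


# ---------------------------------------------------------------------------
# TSS input
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_attributes(field: str) -> dict[str, str]:
    return dict(_GTF_ATTR.findall(field))


def read_tss(path: str | Path, fmt: str | None = None) -> list[TSSRecord]:
    """Read TSSs from a GTF (transcript features) or BED6 file.

    GTF: the TSS is the 1-based feature start on + genes and the feature end
    on − genes, converted to 0-based.  BED: chromStart on +, chromEnd−1 on −.
    Duplicate (gene, tss, strand) combinations are collapsed.  Format is
    inferred from the extension when ``fmt`` is None.
    """
    p = Path(path)
    if fmt is None:
        suffix = p.suffix.lower()
        fmt = "bed" if suffix == ".bed" else "gtf"
    fmt = fmt.lower()
    if fmt not in ("gtf", "gff", "bed"):
        raise ValueError(f"unsupported annotation format: {fmt!r}")

    records: list[TSSRecord] = []
    seen: set[tuple[str, int, str]] = set()
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 6:
                        raise ValueError("BED needs >= 6 columns")
                    contig, start, end, name, _score, strand = fields[:6]
                    start_i, end_i = int(start), int(end)
                    if strand not in "+-":
                        raise ValueError(f"missing or bad strand {strand!r}")
                    tss = start_i if strand == "+" else end_i - 1
                    rec = TSSRecord(gene=name, contig=contig, tss=tss, strand=strand)
                else:
                    if len(fields) < 9:
                        raise ValueError("GTF needs 9 columns")
                    contig, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
                    if feature not in ("transcript", "mRNA"):
                        continue
                    if strand not in "+-":
                        raise ValueError(f"missing or bad strand {strand!r}")
                    attrd = _parse_gtf_attributes(attrs)
                    gene = attrd.get("gene_id") or attrd.get("gene_name")
                    if not gene:
                        raise ValueError("no gene_id attribute")
                    start_i, end_i = int(start), int(end)
                    tss = start_i - 1 if strand == "+" else end_i - 1
                    rec = TSSRecord(
                        gene=gene,
                        contig=contig,
                        tss=tss,
                        strand=strand,
                        transcript=attrd.get("transcript_id"),
                    )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{p}:{lineno}: unparseable annotation line ({exc})") from None
            key = (rec.gene, rec.tss, rec.strand)
            if key in seen:
                continue
            seen.add(key)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------


def extract_windows(
    genome: str | Path | Fasta,
    records: Iterable[TSSRecord],
    flank: int = 2000,
) -> list[PromoterWindow]:
    """Slice [tss − flank, tss + flank + 1) plus-strand windows from a FASTA.

    The window spans ``flank`` bases on each side of the TSS base (length
    2·flank + 1), clipped to contig bounds.  Raises ``KeyError`` naming any
    contig absent from the FASTA.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    windows: list[PromoterWindow] = []
    for rec in records:
        if rec.contig not in fasta:
            raise KeyError(f"contig {rec.contig!r} absent from genome FASTA")
        contig_len = len(fasta[rec.contig])
        start = max(0, rec.tss - flank)
        end = min(contig_len, rec.tss + flank + 1)
        seq = str(fasta[rec.contig][start:end])
        windows.append(PromoterWindow(record=rec, start=start, end=end, seq=seq))
    return windows


def windows_from_records(
    records: Iterable[tuple[str, str]]
) -> list[PromoterWindow]:
    """Treat whole sequence records as windows (no annotation available).

    Each (id, sequence) record becomes one window on a pseudo-contig of the
    same name, with a + strand pseudo-TSS at the midpoint — useful for
    scanning synthetic promoter sets where the truth is positional rather
    than gene-anchored.
    """
    windows = []
    for seq_id, seq in records:
        tss = len(seq) // 2
        rec = TSSRecord(gene=seq_id, contig=seq_id, tss=tss, strand="+")
        windows.append(PromoterWindow(record=rec, start=0, end=len(seq), seq=seq))
    return windows


# ---------------------------------------------------------------------------
# Scanning and gene-relative annotation
# ---------------------------------------------------------------------------


def _tier_ladder(matrix: PreferenceMatrix) -> list[tuple[str, tuple[frozenset[str], ...]]]:
    ladder = []
    for tier, label in (
        (PreferenceTier.OPTIMAL_GT80, "gt80"),
        (PreferenceTier.ALLOWED_60_80, "60-80"),
        (PreferenceTier.ALLOWED_50_60, "50-60"),
    ):
        ladder.append((label, consensus_at_threshold(matrix, tier).allowed_sets()))
    return ladder


def _word_tier(word: str, ladder) -> str:
    """Highest stringency threshold the 18-mer satisfies exactly."""
    for label, sets in ladder:
        if all(b in s for b, s in zip(word, sets)):
            return label
    return "below50"


def scan_promoters(
    windows: Sequence[PromoterWindow],
    motif: CompositeMotif,
    policy: MatchPolicy,
    matrix: PreferenceMatrix | None = None,
    mask_lowercase: bool = False,
) -> list[ScanReportRow]:
    """Scan promoter windows and annotate hits relative to their genes.

    region: ups when the hit's gene-oriented 5'-most base precedes the TSS in
    gene orientation (ties at the TSS base are dns), else dns.  direction:
    forward when hit strand equals gene strand.  Rows are sorted by
    (contig, start, strand, gene).
    """
    if matrix is None:
        matrix = encode_reference_model()
    ladder = _tier_ladder(matrix)
    rows: list[ScanReportRow] = []
    for win in windows:
        gene = win.record
        hits = scan_sequence(
            win.seq, motif, policy, seq_id=gene.contig, mask_lowercase=mask_lowercase
        )
        for hit in hits:
            g_start = win.start + hit.start
            g_end = win.start + hit.end
            if gene.strand == "+":
                lead = g_start  # gene-oriented 5'-most base
                distance = lead - gene.tss
            else:
                lead = g_end - 1
                distance = gene.tss - lead
            region = "ups" if distance < 0 else "dns"
            direction = "forward" if hit.strand == gene.strand else "backward"
            rows.append(
                ScanReportRow(
                    gene=gene.gene,
                    contig=gene.contig,
                    start=g_start,
                    end=g_end,
                    strand=hit.strand,
                    region=region,
                    direction=direction,
                    distance=distance,
                    sequence=hit.word,
                    mismatch_positions=hit.mismatch_positions,
                    tier=_word_tier(hit.word, ladder),
                )
            )
    rows.sort(key=lambda r: (r.contig, r.start, r.strand, r.gene))
    return rows


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "gene",
    "contig",
    "start_1based",
    "end_1based",
    "strand",
    "region",
    "direction",
    "distance",
    "sequence",
    "mismatches",
    "tier",
]

# Legacy spellings of the direction labels, accepted on read.
_DIRECTION_ALIASES = {"fowrd": "forward", "bckwd": "backward"}


def write_report(
    rows: Sequence[ScanReportRow], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write report rows as TSV (1-based inclusive) or BED6 (0-based half-open).

    Output is byte-stable for identical input: fixed column order, no floats,
    newline-terminated lines.
    """
    fmt = fmt.lower()
    p = Path(path)
    if fmt == "tsv":
        lines = ["\t".join(REPORT_COLUMNS)]
        for r in rows:
            mism = ",".join(str(x) for x in r.mismatch_positions)
            lines.append(
                "\t".join(
                    [
                        r.gene,
                        r.contig,
                        str(r.start + 1),
                        str(r.end),
                        r.strand,
                        r.region,
                        r.direction,
                        str(r.distance),
                        r.sequence,
                        mism,
                        r.tier,
                    ]
                )
            )
        p.write_text("\n".join(lines) + "\n")
    elif fmt == "bed":
        lines = []
        for r in rows:
            name = f"{r.gene}|{r.region}|{r.direction}"
            lines.append(
                "\t".join([r.contig, str(r.start), str(r.end), name, "0", r.strand])
            )
        p.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unsupported report format: {fmt!r}")


def read_report(path: str | Path) -> list[ScanReportRow]:
    """Parse a TSV report back into rows (lossless round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != REPORT_COLUMNS:
        raise ValueError(f"unexpected report columns in {path}: {list(df.columns)}")
    rows = []
    for rec in df.itertuples(index=False):
        mism = tuple(
            PositionLabel.parse(tok) for tok in rec.mismatches.split(",") if tok
        )
        rows.append(
            ScanReportRow(
                gene=rec.gene,
                contig=rec.contig,
                start=int(rec.start_1based) - 1,
                end=int(rec.end_1based),
                strand=rec.strand,
                region=rec.region,
                direction=_DIRECTION_ALIASES.get(rec.direction, rec.direction),
                distance=int(rec.distance),
                sequence=rec.sequence,
                mismatch_positions=mism,
                tier=rec.tier,
            )
        )
    return rows
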