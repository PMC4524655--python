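#!/usr/bin/env python
"""Optional: run the published promoter screen on a real genome.

Scans ±2 kb around every annotated TSS for the relaxed DR1 consensus
DAWVT-RGGBBA-N-RGKTBA, allowing one non-preferred base in the last three
positions of the PPARα hexad or the spacer — the settings of the original
mouse (mm9) screen.  You must supply the genome FASTA and a TSS annotation
yourself; nothing is downloaded.  Note that the original screen's exact hit
list depends on the TSS annotation version used, which is not part of this
package, so differing row counts against any published table are expected.

Example:
    python scripts/mm9_scan.py --genome mm9.fa --annotation refGene.gtf \
        --out mm9_ppre_report.tsv

Equivalent to:
    pprescan scan --genome mm9.fa --annotation refGene.gtf \
        --flank 2000 --tier 60 --budget 1 --out mm9_ppre_report.tsv
"""

import argparse

from pprescan import (
    PreferenceTier,
    consensus_at_threshold,
    default_scan_policy,
    encode_reference_model,
    extract_windows,
    read_tss,
    scan_promoters,
    write_report,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--genome", required=True, help="Genome FASTA (e.g. mm9)")
    parser.add_argument("--annotation", required=True, help="GTF transcripts or BED6 TSSs")
    parser.add_argument("--flank", type=int, default=2000)
    parser.add_argument("--budget", type=int, default=1)
    parser.add_argument("--out", required=True, help="Report TSV path")
    args = parser.parse_args()

    matrix = encode_reference_model()
    motif = consensus_at_threshold(matrix, PreferenceTier.ALLOWED_60_80)
    policy = default_scan_policy(budget=args.budget)
    tss = read_tss(args.annotation)
    print(f"{len(tss)} distinct TSSs")
    windows = extract_windows(args.genome, tss, flank=args.flank)
    rows = scan_promoters(windows, motif, policy, matrix=matrix)
    write_report(rows, args.out)
    print(f"{len(rows)} candidate PPREs -> {args.out}")


if __name__ == "__main__":
    main()
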