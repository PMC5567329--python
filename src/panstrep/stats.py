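"""Per-genome feature statistics: GC content, gene/intergenic/repeat
fractions, and average gene length.

Gene and repeat intervals follow the GFF3 convention (1-based, closed).
Overlapping gene intervals are merged before length accounting so that gene
and intergenic lengths partition the genome exactly; the gene *count* is the
number of annotated genes, not of merged blocks, which is how a genome table
can report both 8,888 genes and a union length that divides to a 904-bp
average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

from Bio.Seq import Seq

__all__ = [
    "FeatureSummary",
    "gc_content",
    "feature_summary",
    "summary_from_lengths",
    "merge_intervals",
    "read_gff3_intervals",
]

Interval = Tuple[int, int]  # 1-based, closed


@dataclass
class FeatureSummary:
    genome_bp: int
    gc_pct: Optional[float]
    gene_count: int
    gene_total_bp: int
    gene_avg_bp: Optional[int]
    gene_pct_of_genome: float
    gc_gene_region_pct: Optional[float]
    intergenic_bp: int
    intergenic_pct: float
    gc_intergenic_pct: Optional[float]
    repeat_total_bp: int
    repeat_pct: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @staticmethod
    def tsv_header() -> str:
        return (
            "genome_bp\tgc_pct\tgene_count\tgene_total_bp\tgene_avg_bp\t"
            "gene_pct_of_genome\tgc_gene_region_pct\tintergenic_bp\t"
            "intergenic_pct\tgc_intergenic_pct\trepeat_total_bp\trepeat_pct"
        )

    def tsv_row(self) -> str:
        vals = [
            self.genome_bp, self.gc_pct, self.gene_count, self.gene_total_bp,
            self.gene_avg_bp, self.gene_pct_of_genome, self.gc_gene_region_pct,
            self.intergenic_bp, self.intergenic_pct, self.gc_intergenic_pct,
            self.repeat_total_bp, self.repeat_pct,
        ]
        return "\t".join("NA" if v is None else str(v) for v in vals)


def gc_content(seq: str) -> float:
    """GC fraction: (G+C) / (A+C+G+T), case-insensitive; ambiguity codes are
    excluded from the denominator.  Raises on empty or all-ambiguous input."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    denom = gc + at
    if denom == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return gc / denom


def merge_intervals(intervals: Sequence[Interval]) -> List[Interval]:
    """Union of 1-based closed intervals, sorted and merged."""
    if not intervals:
        return []
    merged: List[Interval] = []
    for start, end in sorted(intervals):
        if start > end:
            raise ValueError(f"interval start > end: ({start}, {end})")
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _total_length(intervals: Sequence[Interval]) -> int:
    return sum(end - start + 1 for start, end in intervals)


def summary_from_lengths(
    genome_bp: int,
    gene_total_bp: int,
    gene_count: int,
    repeat_total_bp: int = 0,
) -> FeatureSummary:
    """Feature arithmetic from pre-computed totals (no sequence available).

    Percentages are reported to 2 decimals (repeats to 4, matching the extra
    precision genome tables give the small repeat fraction); the average gene
    length is rounded to the nearest bp.
    """
    if genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    intergenic_bp = genome_bp - gene_total_bp
    gene_avg = round(gene_total_bp / gene_count) if gene_count > 0 else None
    return FeatureSummary(
        genome_bp=genome_bp,
        gc_pct=None,
        gene_count=gene_count,
        gene_total_bp=gene_total_bp,
        gene_avg_bp=gene_avg,
        gene_pct_of_genome=round(100.0 * gene_total_bp / genome_bp, 2),
        gc_gene_region_pct=None,
        intergenic_bp=intergenic_bp,
        intergenic_pct=round(100.0 * intergenic_bp / genome_bp, 2),
        gc_intergenic_pct=None,
        repeat_total_bp=repeat_total_bp,
        repeat_pct=round(100.0 * repeat_total_bp / genome_bp, 4),
    )


def feature_summary(
    genome: str,
    genes: Sequence[Interval],
    repeats: Sequence[Interval] = (),
) -> FeatureSummary:
    """Full feature summary from a genome sequence plus gene/repeat intervals.

    Gene intervals are merged (union semantics) for length accounting;
    ``gene_count`` is the number of input intervals.  Repeat intervals are
    consumed as given (annotation input), also merged for length.
    """
    if not genome:
        raise ValueError("empty genome sequence")
    genome_bp = len(genome)
    for start, end in list(genes) + list(repeats):
        if not (1 <= start <= end <= genome_bp):
            raise ValueError(f"interval ({start}, {end}) out of genome bounds [1, {genome_bp}]")
    merged_genes = merge_intervals(genes)
    merged_repeats = merge_intervals(repeats)
    gene_total = _total_length(merged_genes)
    repeat_total = _total_length(merged_repeats)
    summary = summary_from_lengths(genome_bp, gene_total, len(genes), repeat_total)
    summary.gc_pct = round(100.0 * gc_content(genome), 2)
    gene_seq = "".join(genome[s - 1 : e] for s, e in merged_genes)
    intergenic_seq = _complement_sequence(genome, merged_genes)
    summary.gc_gene_region_pct = _safe_gc_pct(gene_seq)
    summary.gc_intergenic_pct = _safe_gc_pct(intergenic_seq)
    return summary


def _safe_gc_pct(seq: str) -> Optional[float]:
    try:
        return round(100.0 * gc_content(seq), 2)
    except ValueError:
        return None


def _complement_sequence(genome: str, merged: Sequence[Interval]) -> str:
    parts = []
    pos = 1
    for start, end in merged:
        if start > pos:
            parts.append(genome[pos - 1 : start - 1])
        pos = end + 1
    if pos <= len(genome):
        parts.append(genome[pos - 1 :])
    return "".join(parts)


def read_gff3_intervals(path, feature_type: str = "gene") -> List[Interval]:
    """Intervals of one feature type from a GFF3 file (1-based, closed)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    return [(f.start, f.end) for f in db.features_of_type(feature_type)]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
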