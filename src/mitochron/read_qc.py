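"""Low-quality read filtering.

A base is low-quality when its Phred score is at or below a threshold
(default Q7); a read is discarded when more than a maximum fraction
(default 10%) of its bases are low-quality.  Both boundaries are inclusive
on the base side and strict on the fraction side: a 100 bp read with
exactly 10 bases at Q<=7 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seq_io import QualityRead

__all__ = ["FilterStats", "is_low_quality_base", "filter_reads"]


@dataclass
class FilterStats:
    total: int = 0
    kept: int = 0
    discarded: int = 0
    empty: int = 0           # zero-length reads, discarded and counted apart
    bases_kept: int = 0
    bases_total: int = 0

    def to_tsv(self) -> str:
        rows = [("total_reads", self.total), ("kept_reads", self.kept),
                ("discarded_reads", self.discarded), ("empty_reads", self.empty),
                ("bases_kept", self.bases_kept), ("bases_total", self.bases_total)]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


def is_low_quality_base(q: int, threshold: int = 7) -> bool:
    """True iff the Phred score is at or below the threshold."""
    if q < 0:
        raise ValueError(f"negative Phred score {q}")
    return q <= threshold


def filter_reads(reads: list[QualityRead], base_threshold: int = 7,
                 max_low_fraction: float = 0.10
                 ) -> tuple[list[QualityRead], FilterStats]:
    """Drop reads whose low-quality-base fraction exceeds ``max_low_fraction``.

    Returns the kept reads in input order and counting statistics.  The
    fraction test is strict (> keeps the boundary read); zero-length reads
    are discarded and tallied separately.
    """
    if not 0 <= max_low_fraction <= 1:
        raise ValueError(f"max_low_fraction {max_low_fraction} outside [0, 1]")
    if base_threshold < 0:
        raise ValueError(f"base_threshold {base_threshold} negative")
    stats = FilterStats()
    kept: list[QualityRead] = []
    for read in reads:
        stats.total += 1
        stats.bases_total += len(read)
        if len(read) == 0:
            stats.empty += 1
            stats.discarded += 1
            continue
        n_low = sum(1 for q in read.quals if q <= base_threshold)
        if n_low > max_low_fraction * len(read):
            stats.discarded += 1
        else:
            kept.append(read)
            stats.kept += 1
            stats.bases_kept += len(read)
    return kept, stats
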