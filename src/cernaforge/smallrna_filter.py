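"""Small-RNA clean-tag filter cascade and exact-match miRNA quantification.

Reads pass through the cascade in a fixed order, and each removed read is
attributed to the first rule it fails, so the report's counts sum exactly to
the input count:

1. low quality      -- more than 50% of bases with Phred quality <= 20;
2. 3' adapter       -- located by the longest prefix match (>= ``min_overlap``
   bases, no mismatches) and trimmed; reads without one are removed, as are
   reads whose remaining insert contains the 5' adapter;
3. length window    -- inserts shorter than 18 nt or longer than 30 nt
   (applied after trimming);
4. polyA            -- inserts with a run of >= 8 consecutive A.

Quantification assigns a clean read to a catalog miRNA only on an exact
sequence match (T/U-insensitive); everything else counts as unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io_formats import SeqRecord, logger


@dataclass(frozen=True)
class SmallRead:
    """A small-RNA read: DNA-alphabet sequence plus Phred+33 qualities."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.id}: sequence and quality lengths differ"
            )


@dataclass
class FilterReport:
    input_count: int = 0
    low_quality: int = 0
    no_3prime_adapter: int = 0
    has_5prime_adapter: int = 0
    short: int = 0
    too_long: int = 0
    polya: int = 0
    output_count: int = 0

    @property
    def removed(self) -> int:
        return (
            self.low_quality + self.no_3prime_adapter + self.has_5prime_adapter
            + self.short + self.too_long + self.polya
        )

    def conserved(self) -> bool:
        return self.input_count == self.output_count + self.removed

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input_count,
            "low_quality": self.low_quality,
            "no_3prime_adapter": self.no_3prime_adapter,
            "has_5prime_adapter": self.has_5prime_adapter,
            "short": self.short,
            "too_long": self.too_long,
            "polya": self.polya,
            "output": self.output_count,
        }


@dataclass(frozen=True)
class FilterConfig:
    min_len: int = 18
    max_len: int = 30
    min_overlap: int = 6
    quality_cutoff: int = 20
    quality_fraction: float = 0.5
    polya_min: int = 8
    # Clean tags are already trimmed; with this off, reads lacking a 3'
    # adapter are kept untrimmed instead of removed, which makes the cascade
    # idempotent on its own output.
    require_3prime_adapter: bool = True


def _low_quality(read: SmallRead, cutoff: int, fraction: float) -> bool:
    n_bad = sum(1 for c in read.quality if ord(c) - 33 <= cutoff)
    return n_bad > fraction * len(read.quality)


def locate_3prime_adapter(
    sequence: str, adapter3: str, min_overlap: int = 6
) -> int | None:
    """Leftmost start of the 3' adapter within the read, or None.

    The adapter may run off the 3' end of the read, so a prefix of the
    adapter of at least ``min_overlap`` bases suffices (exact match).
    """
    n = len(sequence)
    for i in range(n - min_overlap + 1):
        k = min(len(adapter3), n - i)
        if k >= min_overlap and sequence[i : i + k] == adapter3[:k]:
            return i
    return None


def filter_reads(
    reads: Iterable[SmallRead],
    adapter3: str,
    adapter5: str = "",
    config: FilterConfig | None = None,
) -> tuple[list[SmallRead], FilterReport]:
    """Run the clean-tag cascade; returns surviving reads and the report.

    Survivors carry the trimmed insert.  An empty input yields an empty
    output with a zeroed report.
    """
    cfg = config or FilterConfig()
    if not adapter3:
        raise ValueError("3' adapter sequence must be non-empty")
    report = FilterReport()
    clean: list[SmallRead] = []
    for read in reads:
        report.input_count += 1
        if _low_quality(read, cfg.quality_cutoff, cfg.quality_fraction):
            report.low_quality += 1
            continue
        pos = locate_3prime_adapter(read.sequence, adapter3, cfg.min_overlap)
        if pos is None:
            if cfg.require_3prime_adapter:
                report.no_3prime_adapter += 1
                continue
            pos = len(read.sequence)
        insert = read.sequence[:pos]
        if adapter5 and adapter5 in insert:
            report.has_5prime_adapter += 1
            continue
        if len(insert) < cfg.min_len:
            report.short += 1
            continue
        if len(insert) > cfg.max_len:
            report.too_long += 1
            continue
        if "A" * cfg.polya_min in insert:
            report.polya += 1
            continue
        clean.append(
            SmallRead(id=read.id, sequence=insert, quality=read.quality[:pos])
        )
    report.output_count = len(clean)
    logger.info("filter_reads: %s", report.as_dict())
    return clean, report


def quantify_mirna(
    clean_reads_by_sample: Mapping[str, Sequence[SmallRead]],
    catalog: Sequence[SeqRecord],
) -> pd.DataFrame:
    """Exact-match counts per catalog miRNA per sample.

    Returns a DataFrame (rows = miRNA ids plus ``unassigned``, columns =
    samples).  Duplicate catalog sequences are rejected because exact-match
    assignment would be ambiguous.
    """
    lookup: dict[str, str] = {}
    for rec in catalog:
        key = rec.sequence.replace("U", "T").upper()
        if key in lookup:
            raise ValueError(
                f"duplicate catalog sequence for {lookup[key]!r} and {rec.id!r}"
            )
        lookup[key] = rec.id
    index = [rec.id for rec in catalog] + ["unassigned"]
    counts = pd.DataFrame(
        0, index=index, columns=list(clean_reads_by_sample), dtype=int
    )
    for sample, reads in clean_reads_by_sample.items():
        for read in reads:
            target = lookup.get(read.sequence.replace("U", "T").upper(), "unassigned")
            counts.loc[target, sample] += 1
    return counts
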