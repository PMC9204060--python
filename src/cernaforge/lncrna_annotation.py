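"""lncRNA candidate screening, positional classification, and cis-neighbors.

Candidates shorter than 200 nt (spliced) are removed.  Survivors are placed
into exactly one of five positional classes relative to protein-coding genes,
applying the precedence sense_overlapping > antisense > intronic >
bidirectional > intergenic:

* ``sense_overlapping`` -- exon-level overlap with a coding gene, same strand;
* ``antisense``         -- exon-level overlap, opposite strand;
* ``intronic``          -- fully contained in one coding intron, no exon
  overlap, either strand;
* ``bidirectional``     -- no overlap, opposite strand, transcription start
  sites head-to-head within 1 kb;
* ``intergenic``        -- none of the above.

The class names are the standard lncRNA taxonomy; the exact geometric
definitions and the 1 kb bidirectional window are package conventions and are
configurable.  Cis-neighbor search returns coding genes within 10 kb up- or
downstream of the lncRNA span.
"""

from __future__ import annotations

import pandas as pd

from .io_formats import AnnotationSet, TranscriptRecord, logger

LNC_CLASSES = (
    "intergenic",
    "bidirectional",
    "intronic",
    "antisense",
    "sense_overlapping",
)


def screen_candidates(
    transcripts: AnnotationSet, min_length: int = 200
) -> AnnotationSet:
    """Retain lncRNA candidates with spliced length >= min_length (inclusive)."""
    kept = [t for t in transcripts if t.spliced_length >= min_length]
    logger.info(
        "screen_candidates: kept %d of %d (removed %d shorter than %d nt)",
        len(kept), len(transcripts), len(transcripts) - len(kept), min_length,
    )
    return AnnotationSet(features=kept)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _exon_overlap(lnc: TranscriptRecord, gene: TranscriptRecord) -> bool:
    lnc_exons = lnc.exons or ((lnc.start, lnc.end),)
    gene_exons = gene.exons or ((gene.start, gene.end),)
    return any(_overlap(le, ge) for le in lnc_exons for ge in gene_exons)


def _tss(t: TranscriptRecord) -> int:
    return t.start if t.strand == "+" else t.end


def classify(
    lncrna: TranscriptRecord,
    coding: AnnotationSet,
    bidir_window: int = 1000,
) -> str:
    """Assign one of the five positional classes to a lncRNA."""
    genes = [g for g in coding.by_biotype("coding") if g.chrom == lncrna.chrom]
    span = (lncrna.start, lncrna.end)

    overlapping = [g for g in genes if _overlap(span, (g.start, g.end))]
    if any(g.strand == lncrna.strand and _exon_overlap(lncrna, g) for g in overlapping):
        return "sense_overlapping"
    if any(g.strand != lncrna.strand and _exon_overlap(lncrna, g) for g in overlapping):
        return "antisense"
    for g in overlapping:
        if any(
            intron[0] <= lncrna.start and lncrna.end <= intron[1]
            for intron in g.introns
        ):
            return "intronic"
    if not overlapping:
        for g in genes:
            if g.strand == lncrna.strand:
                continue
            # head-to-head: the two TSSs face away from each other within the
            # window, i.e. divergent transcription from a shared promoter.
            if abs(_tss(lncrna) - _tss(g)) <= bidir_window:
                if (lncrna.strand == "+" and _tss(g) <= _tss(lncrna)) or (
                    lncrna.strand == "-" and _tss(g) >= _tss(lncrna)
                ):
                    return "bidirectional"
    return "intergenic"


def classify_all(
    lncrnas: AnnotationSet, coding: AnnotationSet, bidir_window: int = 1000
) -> pd.DataFrame:
    """Classify every lncRNA; returns id, class, spliced length."""
    rows = [
        {
            "lncrna": t.id,
            "lnc_class": classify(t, coding, bidir_window),
            "spliced_length": t.spliced_length,
        }
        for t in lncrnas
    ]
    table = pd.DataFrame(rows, columns=["lncrna", "lnc_class", "spliced_length"])
    if len(table):
        logger.info(
            "classify_all: %s", table["lnc_class"].value_counts().to_dict()
        )
    return table


def cis_targets(
    lncrna: TranscriptRecord, coding: AnnotationSet, window: int = 10_000
) -> list[str]:
    """Coding genes whose span intersects the lncRNA span widened by ``window``.

    The widened interval is [start - window, end + window); both strands
    qualify.  Monotone in ``window``.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    lo = lncrna.start - window
    hi = lncrna.end + window
    return sorted(
        g.id
        for g in coding.by_biotype("coding")
        if g.chrom == lncrna.chrom and _overlap((lo, hi), (g.start, g.end))
    )
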