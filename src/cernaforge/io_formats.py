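"""Readers and writers for the formats the pipeline touches, plus configuration.

All genomic intervals are held internally as 0-based half-open ``[start, end)``
on the forward strand; GFF3 I/O converts to/from the 1-based inclusive
convention at the boundary, so interval arithmetic elsewhere in the package
never has to special-case coordinate systems.

Sequences are stored uppercase.  RNA-facing operations (duplex alignment,
target scanning) expect the RNA alphabet; ``read_fasta(..., rna=True)``
normalizes T to U on input while FASTA output preserves whatever alphabet the
records carry.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
import gffutils

logger = logging.getLogger("cernaforge")

VALID_ALPHABET = set("ACGUTN")


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence (transcript or miRNA).

    ``sequence`` is uppercase over {A, C, G, U, T, N}.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for record {self.id!r} is empty")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def as_rna(self) -> "SeqRecord":
        return replace(self, sequence=self.sequence.replace("T", "U"))

    def as_dna(self) -> "SeqRecord":
        return replace(self, sequence=self.sequence.replace("U", "T"))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptRecord:
    """A genomic feature with strand, exon structure and biotype.

    Coordinates are 0-based half-open.  ``exons`` are disjoint, sorted and lie
    within ``[start, end)``; introns are the gaps between consecutive exons.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: unknown strand symbol {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.id}: malformed span [{self.start}, {self.end})")
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(
                    f"{self.id}: exon [{s}, {e}) outside transcript span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def spliced_length(self) -> int:
        if self.exons:
            return sum(e - s for s, e in self.exons)
        return self.end - self.start

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)


@dataclass
class AnnotationSet:
    """A collection of transcript features sharing one coordinate convention."""

    features: list[TranscriptRecord] = field(default_factory=list)
    coordinate_system: str = "0-based half-open"

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def by_biotype(self, biotype: str) -> list[TranscriptRecord]:
        return [f for f in self.features if f.biotype == biotype]

    def get(self, feature_id: str) -> TranscriptRecord:
        for f in self.features:
            if f.id == feature_id:
                return f
        raise KeyError(feature_id)


@dataclass
class PipelineConfig:
    """Thresholds and parameters for every stage, with legal-range validation.

    Defaults are the published analysis constants: DE at FDR < 0.05 with
    |log2FC| >= 1, miRNA DE on raw p-values (0.05 default, 0.07 preset),
    Spearman < -0.7 for miRNA-target pairs, Pearson > 0.9 for lncRNA-mRNA
    pairs, soft-threshold power 8 with unsigned TOM, module merge cut 0.85,
    minimum module size 50, and duplex MFE ratios 0.74 (ruleset A) / 0.60
    (ruleset B).
    """

    fdr_alpha: float = 0.05
    log2fc_min: float = 1.0
    p_mirna: float = 0.05
    scc_threshold: float = -0.7
    pcc_threshold: float = 0.9
    ruleset: str = "A"
    mfe_ratio_a: float = 0.74
    mfe_ratio_b: float = 0.60
    beta: float = 8.0
    min_module_size: int = 50
    merge_cut: float = 0.85
    drop_fraction: float = 0.45
    min_lnc_length: int = 200
    cis_window: int = 10_000
    bidir_window: int = 1_000
    pseudocount: float = 1.0
    # which contrasts gate "all RNAs differentially expressed" for the ceRNA
    # step: "any" = DE in >= 1 of the nine design contrasts,
    # "between_genotype" = only the three wild-vs-mutant contrasts
    de_gate: str = "any"
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("fdr_alpha", 0.0 < self.fdr_alpha < 1.0),
            ("log2fc_min", self.log2fc_min >= 0.0),
            ("p_mirna", 0.0 < self.p_mirna < 1.0),
            ("scc_threshold", -1.0 <= self.scc_threshold <= 0.0),
            ("pcc_threshold", 0.0 <= self.pcc_threshold <= 1.0),
            ("ruleset", self.ruleset in ("A", "B")),
            ("mfe_ratio_a", 0.0 <= self.mfe_ratio_a <= 1.0),
            ("mfe_ratio_b", 0.0 <= self.mfe_ratio_b <= 1.0),
            ("beta", self.beta >= 1.0),
            ("min_module_size", self.min_module_size >= 1),
            ("merge_cut", 0.0 <= self.merge_cut <= 2.0),
            ("drop_fraction", 0.0 <= self.drop_fraction < 1.0),
            ("min_lnc_length", self.min_lnc_length >= 0),
            ("cis_window", self.cis_window >= 0),
            ("bidir_window", self.bidir_window >= 0),
            ("pseudocount", self.pseudocount > 0),
            ("de_gate", self.de_gate in ("any", "between_genotype")),
            ("seed", isinstance(self.seed, int)),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(
                    f"config parameter {name}={getattr(self, name)!r} outside "
                    "its legal range"
                )

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a TOML document; sections are flattened."""
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        flat: dict = {}
        for key, value in doc.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {k: v for k, v in flat.items() if k in cls.__dataclass_fields__}
        unknown = set(flat) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, rna: bool = False) -> list[SeqRecord]:
    """Read a FASTA file into a list of records.

    Sequences are uppercased; with ``rna=True`` every T is normalized to U.
    Duplicate ids and empty files are errors.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if rna:
            seq = seq.replace("T", "U")
        desc = rec.description[len(rec.id) :].strip()
        records.append(SeqRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ValueError(f"FASTA file {path} contains no records")
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> AnnotationSet:
    """Read gene/transcript/exon rows from GFF3 into an :class:`AnnotationSet`.

    GFF3 carries 1-based inclusive coordinates; internal records are 0-based
    half-open (start-1, end).  Transcript-level features (mRNA, transcript,
    lnc_RNA) become :class:`TranscriptRecord` with their child exons; a
    ``biotype`` attribute is honored, otherwise coding is assumed for mRNA
    and lncRNA_candidate for lnc_RNA.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="error", keep_order=True
    )
    transcript_types = ("mRNA", "transcript", "lnc_RNA")
    features: list[TranscriptRecord] = []
    for ftype in transcript_types:
        for tr in db.features_of_type(ftype):
            if tr.strand not in ("+", "-"):
                raise ValueError(f"{tr.id}: unknown strand symbol {tr.strand!r}")
            exons = sorted(
                (child.start - 1, child.end)
                for child in db.children(tr.id, featuretype="exon")
            )
            span = (tr.start - 1, tr.end)
            for s, e in exons:
                if not (span[0] <= s < e <= span[1]):
                    raise ValueError(
                        f"{tr.id}: exon [{s + 1}, {e}] outside transcript span"
                    )
            biotype = tr.attributes.get(
                "biotype", ["lncRNA_candidate" if ftype == "lnc_RNA" else "coding"]
            )[0]
            features.append(
                TranscriptRecord(
                    id=tr.id,
                    chrom=tr.seqid,
                    strand=tr.strand,
                    start=span[0],
                    end=span[1],
                    exons=tuple(exons),
                    biotype=biotype,
                )
            )
    features.sort(key=lambda f: (f.chrom, f.start, f.id))
    logger.info("read_gff3: %d transcripts from %s", len(features), path)
    return AnnotationSet(features=features)


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write an annotation back to GFF3 (gene + transcript + exon rows)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for tr in sorted(
            annotation.features, key=lambda f: (f.chrom, f.start, f.id)
        ):
            ftype = "lnc_RNA" if tr.biotype == "lncRNA_candidate" else "mRNA"
            gene_id = f"{tr.id}.gene"
            start1, end1 = tr.start + 1, tr.end
            fh.write(
                f"{tr.chrom}\tcernaforge\tgene\t{start1}\t{end1}\t.\t{tr.strand}"
                f"\t.\tID={gene_id};biotype={tr.biotype}\n"
            )
            fh.write(
                f"{tr.chrom}\tcernaforge\t{ftype}\t{start1}\t{end1}\t.\t"
                f"{tr.strand}\t.\tID={tr.id};Parent={gene_id};biotype={tr.biotype}\n"
            )
            for i, (s, e) in enumerate(tr.exons, start=1):
                fh.write(
                    f"{tr.chrom}\tcernaforge\texon\t{s + 1}\t{e}\t.\t{tr.strand}"
                    f"\t.\tID={tr.id}.exon{i};Parent={tr.id}\n"
                )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_matrix(path: str | Path, metadata_path: str | Path, unit: str = "FPKM"):
    """Read a gene x sample TSV plus its sample-metadata sidecar.

    The sidecar maps sample id -> (genotype, leaf, replicate).  Samples in the
    matrix without metadata are rejected; negative or non-numeric cells raise
    with the offending row/column named.
    """
    from .expression_de import ExpressionMatrix

    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any():
            row = raw.index[coerced.isna()][0]
            raise ValueError(f"non-numeric cell at row {row!r}, column {col!r}")
        raw[col] = coerced
    neg = raw < 0
    if neg.to_numpy().any():
        row = raw.index[neg.any(axis=1)][0]
        col = raw.columns[neg.loc[row].to_numpy()][0]
        raise ValueError(f"negative value at row {row!r}, column {col!r}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    missing = [s for s in raw.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    matrix = ExpressionMatrix(values=raw, metadata=meta.loc[list(raw.columns)], unit=unit)
    logger.info(
        "read_matrix: %d features x %d samples from %s", *raw.shape, path
    )
    return matrix


def write_matrix(matrix, path: str | Path, metadata_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t")
    if metadata_path is not None:
        matrix.metadata.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# FASTQ (small-RNA reads)
# ---------------------------------------------------------------------------


def read_fastq(path: str | Path):
    """Read FASTQ into :class:`~cernaforge.smallrna_filter.SmallRead` records."""
    from .smallrna_filter import SmallRead

    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(SmallRead(id=rec.id, sequence=str(rec.seq).upper(), quality=qual))
    return reads


def write_fastq(reads, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
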