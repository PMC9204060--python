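"""Synthetic study generator with a machine-readable truth table.

Emulates the design the pipeline targets: 2 genotypes (wild ZJ22-like,
mutant zj-es-like) x 3 leaf positions (flag, second, third) x 3 biological
replicates = 18 libraries, with

* an annotation whose lncRNAs cover all five positional classes;
* planted differentially expressed genes (genotype main effect, default
  |log2FC| = 2, comfortably above the calling threshold of 1);
* two planted co-expression blocks (within-block correlation ~0.9);
* planted ceRNA triplets driven by a shared latent senescence score that
  rises along the leaf axis and is strongly elevated in the mutant, giving
  miRNA-target anticorrelation and lncRNA-mRNA correlation far beyond the
  -0.7 / 0.9 thresholds;
* miRNA binding sites obeying the duplex rule set, plus decoy near-sites
  violating exactly one named rule each, and correlation decoys carrying a
  valid site but a null expression profile;
* small-RNA read sets with exactly specified contaminant counts.

Expression is log-normal around group means (log2 noise sd 0.15 by
default); a count mode (Poisson around the same means) exists for testing
the operating characteristics of the differential-expression surrogate.
All randomness flows from one integer seed through ``numpy``'s PCG64
generator, so equal seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .expression_de import ExpressionMatrix
from .io_formats import (
    AnnotationSet,
    SeqRecord,
    TranscriptRecord,
    logger,
    write_fasta,
    write_fastq,
    write_gff3,
)
from .smallrna_filter import SmallRead
from .target_rules import duplex_align, evaluate_rules, reverse_complement

MIRNA_LEN = 21
# latent senescence score per (genotype, leaf): a mild natural gradient in
# the wild type, strongly amplified in the mutant's older leaves
LATENT_Z = {
    ("wild", "flag"): 0.0,
    ("wild", "second"): 0.5,
    ("wild", "third"): 1.0,
    ("mutant", "flag"): 0.5,
    ("mutant", "second"): 2.5,
    ("mutant", "third"): 3.5,
}
LEAF_LETTER = {"flag": "a", "second": "b", "third": "c"}


@dataclass(frozen=True)
class ContaminantSpec:
    """Counts of each contaminant read class per library."""

    short: int = 10
    low_quality: int = 5
    no_3prime_adapter: int = 7
    has_5prime_adapter: int = 3
    polya: int = 5


@dataclass(frozen=True)
class GeneratorParams:
    n_mrna: int = 2000
    n_lncrna: int = 300
    n_mirna: int = 100
    n_replicates: int = 3
    noise_sd: float = 0.15          # log2-scale sd of multiplicative noise
    latent_jitter_sd: float = 0.10  # member-specific wobble around the latent score
    planted_log2fc: float = 2.0
    n_de_mrna: int = 100
    n_de_lncrna: int = 20
    n_de_mirna: int = 10
    module_sizes: tuple[int, ...] = (60, 60)
    module_loading: float = 0.5     # within-block correlation ~ l^2/(l^2+sd^2)
    n_triplets: int = 3
    base_log2_range: tuple[float, float] = (4.0, 9.0)
    # count mode emulates deep bulk libraries (tens of millions of reads),
    # so baseline counts for expressed features sit well above the FPKM scale
    count_base_log2_range: tuple[float, float] = (6.0, 11.0)
    transcript_len: int = 500       # spliced length of generated transcripts
    count_mode: bool = False
    ruleset: str = "A"
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    contaminants: ContaminantSpec = field(default_factory=ContaminantSpec)

    def __post_init__(self) -> None:
        if self.planted_log2fc < 1.5:
            raise ValueError("planted |log2FC| must be >= 1.5 (margin above 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per group for DE testing")
        if self.n_lncrna < 5:
            raise ValueError("need >= 5 lncRNAs to cover the positional classes")
        need_mrna = 10 + 3 * self.n_triplets + self.n_de_mrna + sum(self.module_sizes)
        if self.n_mrna < need_mrna:
            raise ValueError(f"n_mrna must be >= {need_mrna} for this configuration")
        if self.n_lncrna < 5 + 2 * self.n_triplets + self.n_de_lncrna:
            raise ValueError("n_lncrna too small for triplets + DE + archetypes")
        if self.n_mirna < self.n_triplets + self.n_de_mirna:
            raise ValueError("n_mirna too small for triplets + DE")
        if self.n_triplets > 8:
            raise ValueError(
                "at most 8 planted triplet miRNAs can be mutually orthogonal"
            )

    @classmethod
    def full_scale(cls) -> "GeneratorParams":
        """The full-scale study configuration (2000/300/100, 18 libraries)."""
        return cls()

    @classmethod
    def small(cls) -> "GeneratorParams":
        """A scaled-down configuration for fast unit testing.

        Keeps the full design's key proportions: most genes unstructured, so
        the ~45% variance pre-filter removes background rather than planted
        module members.
        """
        return cls(
            n_mrna=400, n_lncrna=35, n_mirna=15,
            n_de_mrna=20, n_de_lncrna=6, n_de_mirna=4,
        )


@dataclass
class TruthTable:
    """Ground truth for every planted structure, keyed by feature id."""

    seed: int
    params: GeneratorParams
    de: pd.DataFrame        # feature, feature_class, log2fc (genotype effect)
    modules: dict[str, tuple[str, ...]]
    triplets: pd.DataFrame  # lncrna, mirna, mrna
    sites: pd.DataFrame     # mirna, transcript, position, kind, violated_rule

    def validate(self, transcript_ids: set[str], mirna_ids: set[str]) -> None:
        for row in self.triplets.itertuples(index=False):
            for member, pool in (
                (row.lncrna, transcript_ids),
                (row.mrna, transcript_ids),
                (row.mirna, mirna_ids),
            ):
                if member not in pool:
                    raise AssertionError(f"planted member {member} missing")
        decoys = self.sites[self.sites["kind"] == "decoy"]
        if decoys["violated_rule"].isna().any():
            raise AssertionError("decoy without a named violated rule")


# ---------------------------------------------------------------------------
# Sample design
# ---------------------------------------------------------------------------


def design_metadata(n_replicates: int = 3) -> pd.DataFrame:
    """Sample sheet of the 2 x 3 x n design (18 libraries by default)."""
    rows = []
    for genotype, prefix in (("wild", "ZJ22"), ("mutant", "zjes")):
        for leaf, letter in LEAF_LETTER.items():
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": f"{prefix}{letter}_{rep}",
                        "genotype": genotype,
                        "leaf": leaf,
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows).set_index("sample")


def latent_scores(metadata: pd.DataFrame) -> np.ndarray:
    return np.array(
        [LATENT_Z[(g, l)] for g, l in zip(metadata["genotype"], metadata["leaf"])]
    )


# ---------------------------------------------------------------------------
# Annotation + transcript sequences
# ---------------------------------------------------------------------------

_GENE_SPACING = 12_000
_GENE_OFFSET = 5_000


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_annotation(
    n_genes: int, n_lncrna: int, seed: int, transcript_len: int = 500
) -> tuple[AnnotationSet, list[SeqRecord]]:
    """Coding genes plus lncRNAs covering all five positional classes.

    Genes sit every 12 kb on one chromosome with two exons (250 nt each,
    spliced length 500) separated by a 2,250 nt intron, alternating strands.
    The first five lncRNAs are archetypes of sense_overlapping, antisense,
    intronic, bidirectional and intergenic placement; the rest go to the
    middles of intergenic gaps.  Returns the annotation and random (seeded)
    spliced transcript sequences for every feature.
    """
    if n_lncrna < 5:
        raise ValueError("n_lncrna must be >= 5 to cover the five classes")
    if n_genes < 6:
        raise ValueError("n_genes must be >= 6")
    rng = np.random.default_rng(seed)
    features: list[TranscriptRecord] = []
    gene_spans: list[tuple[int, int, str]] = []
    for i in range(n_genes):
        start = _GENE_OFFSET + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        exons = ((start, start + 250), (start + 2500, start + 2750))
        features.append(
            TranscriptRecord(
                id=f"G{i + 1:04d}", chrom="chr1", strand=strand,
                start=start, end=start + 2750, exons=exons, biotype="coding",
            )
        )
        gene_spans.append((start, start + 2750, strand))

    def flip(s: str) -> str:
        return "-" if s == "+" else "+"

    lnc: list[TranscriptRecord] = []
    g = gene_spans
    # archetypes anchored on the first five genes
    lnc.append(  # sense overlapping: covers part of gene 1 exon 1, same strand
        TranscriptRecord(
            id="L0001", chrom="chr1", strand=g[0][2],
            start=g[0][0] + 100, end=g[0][0] + 500,
            exons=((g[0][0] + 100, g[0][0] + 500),), biotype="lncRNA_candidate",
        )
    )
    lnc.append(  # antisense: exon overlap on the opposite strand of gene 2
        TranscriptRecord(
            id="L0002", chrom="chr1", strand=flip(g[1][2]),
            start=g[1][0] + 50, end=g[1][0] + 450,
            exons=((g[1][0] + 50, g[1][0] + 450),), biotype="lncRNA_candidate",
        )
    )
    lnc.append(  # intronic: inside gene 3's intron (250..2500 within the gene)
        TranscriptRecord(
            id="L0003", chrom="chr1", strand=g[2][2],
            start=g[2][0] + 1200, end=g[2][0] + 1600,
            exons=((g[2][0] + 1200, g[2][0] + 1600),), biotype="lncRNA_candidate",
        )
    )
    # bidirectional: head-to-head with gene 4's TSS, opposite strand, <1 kb
    g3_start, g3_end, g3_strand = g[3]
    if g3_strand == "+":
        b_start, b_end, b_strand = g3_start - 900, g3_start - 400, "-"
    else:
        b_start, b_end, b_strand = g3_end + 400, g3_end + 900, "+"
    lnc.append(
        TranscriptRecord(
            id="L0004", chrom="chr1", strand=b_strand,
            start=b_start, end=b_end, exons=((b_start, b_end),),
            biotype="lncRNA_candidate",
        )
    )
    lnc.append(  # intergenic: middle of the gap after gene 5
        TranscriptRecord(
            id="L0005", chrom="chr1", strand="+",
            start=g[4][1] + 4000, end=g[4][1] + 4400,
            exons=((g[4][1] + 4000, g[4][1] + 4400),), biotype="lncRNA_candidate",
        )
    )
    # remaining lncRNAs: intergenic, one per gap starting after gene 6
    for j in range(5, n_lncrna):
        anchor = g[(j) % (n_genes - 1)]
        offset = 4000 + 500 * ((j - 5) // (n_genes - 1))
        start = anchor[1] + offset
        lnc.append(
            TranscriptRecord(
                id=f"L{j + 1:04d}", chrom="chr1", strand="+",
                start=start, end=start + 400,
                exons=((start, start + 400),), biotype="lncRNA_candidate",
            )
        )
    features.extend(lnc)
    annotation = AnnotationSet(features=sorted(
        features, key=lambda f: (f.chrom, f.start, f.id)
    ))
    sequences = [
        SeqRecord(
            id=f.id,
            sequence=_random_seq(
                rng, transcript_len if f.biotype == "coding" else f.spliced_length
            ),
            description=f.biotype,
        )
        for f in sorted(features, key=lambda f: f.id)
    ]
    logger.info(
        "generate_annotation: %d coding genes, %d lncRNAs", n_genes, n_lncrna
    )
    return annotation, sequences


# ---------------------------------------------------------------------------
# miRNAs, binding sites, decoys
# ---------------------------------------------------------------------------

# Scaffolded miRNA layout (1-based positions, length 21): G at 1,5,9,13,17,21
# and U at 4,8,12,16,20 make wobble arithmetic deterministic; of the ten free
# positions, five carry C and five carry A, fixing the perfect-complement
# energy at 11*(-3) + 10*(-2) = -53 under the default model.
_SCAFFOLD_G = (1, 5, 9, 13, 17, 21)
_SCAFFOLD_U = (4, 8, 12, 16, 20)
_SCAFFOLD_FREE = (2, 3, 6, 7, 10, 11, 14, 15, 18, 19)

# decoy mutation plans: rule -> list of (1-based miRNA position, kind)
_DECOY_PLANS_A = {
    "r1": [(p, "GU") for p in (1, 4, 8, 12, 13, 16, 17, 20, 21)],
    "r2": [(14, "MM"), (15, "MM"), (16, "MM")],
    "r3": [(5, "MM"), (6, "MM")],
    "r4": [(10, "MM")],
    "r5": [(2, "MM"), (6, "MM"), (12, "MM")],
    "r6": [(p, "GU") for p in (1, 5, 9, 13, 17, 21)],  # + one MM at an A, below
}
_DECOY_PLANS_B = {
    "r1": [(p, "MM") for p in (1, 13, 15, 17, 19, 21)],
    "r2": [(14, "MM"), (15, "MM")],
    "r3": [(12, "GU")],
}
DECOY_RULES = {"A": tuple(_DECOY_PLANS_A), "B": tuple(_DECOY_PLANS_B)}


# Orthogonality codes for co-planted miRNAs: any two codes differ at
# position 10 or 11 (their cross-duplex then fails rule 4) or at both 6 and
# 7 (an adjacent mismatch pair inside 2-12, failing rule 3), so one planted
# miRNA can never pass the rules on another's site.  Eight codes exist.
_ORTHO_1011 = (("C", "C"), ("C", "A"), ("A", "C"), ("A", "A"))
MAX_COPLANTED_MIRNAS = 8


def make_scaffold_mirna(
    rng: np.random.Generator, mirna_id: str, ortho_index: int = 0
) -> SeqRecord:
    """A 21-nt miRNA on the fixed wobble scaffold (RNA alphabet).

    ``ortho_index`` (0..7) selects mutually orthogonal free-position codes
    for miRNAs planted in the same study.
    """
    if not 0 <= ortho_index < MAX_COPLANTED_MIRNAS:
        raise ValueError(f"ortho_index must be in [0, {MAX_COPLANTED_MIRNAS})")
    bases = [""] * MIRNA_LEN
    for p in _SCAFFOLD_G:
        bases[p - 1] = "G"
    for p in _SCAFFOLD_U:
        bases[p - 1] = "U"
    bases[9], bases[10] = _ORTHO_1011[ortho_index % 4]
    bases[5] = bases[6] = "C" if ortho_index < 4 else "A"
    n_strong = sum(bases[p - 1] == "C" for p in (6, 7, 10, 11))
    rest = [2, 3, 14, 15, 18, 19]
    strong = rng.choice(len(rest), size=5 - n_strong, replace=False)
    for i, p in enumerate(rest):
        bases[p - 1] = "C" if i in strong else "A"
    return SeqRecord(id=mirna_id, sequence="".join(bases))


def _mutate_window(mirna_rna: str, mutations) -> str:
    """Apply (position, kind) mutations to the perfect-complement window."""
    L = len(mirna_rna)
    window = list(reverse_complement(mirna_rna))
    gu_partner = {"G": "U", "U": "G"}
    mm_partner = {"A": "C", "C": "A", "G": "A", "U": "C"}
    for pos, kind in mutations:
        base = mirna_rna[pos - 1]
        if kind == "GU":
            if base not in gu_partner:
                raise ValueError(f"position {pos} ({base}) cannot form a wobble")
            window[L - pos] = gu_partner[base]
        else:
            window[L - pos] = mm_partner[base]
    return "".join(window)


def _decoy_window(mirna_rna: str, rule: str, ruleset: str) -> str:
    """A window violating exactly ``rule`` of the given ruleset."""
    plans = _DECOY_PLANS_A if ruleset == "A" else _DECOY_PLANS_B
    if rule not in plans:
        raise ValueError(
            f"no single-rule decoy for {rule} under ruleset {ruleset}; "
            f"feasible: {sorted(plans)}"
        )
    mutations = list(plans[rule])
    if ruleset == "A" and rule == "r6":
        # one extra mismatch at an A position drags the energy ratio under
        # 0.74 without tripping the score or adjacency rules
        candidates = [
            p for p in (14, 15, 18, 19) if mirna_rna[p - 1] == "A"
        ] or [p for p in (2, 3, 7) if mirna_rna[p - 1] == "A"]
        mutations.append((candidates[0], "MM"))
    window = _mutate_window(mirna_rna, mutations)
    verdict = evaluate_rules(duplex_align(mirna_rna, window), ruleset=ruleset)
    if verdict.violated() != (rule,):
        raise AssertionError(
            f"decoy construction for {rule}/{ruleset} violates {verdict.violated()}"
        )
    return window


def plant_binding_sites(
    mirnas: list[SeqRecord],
    transcripts: list[SeqRecord],
    plan: list[tuple[str, str, str | None]],
    ruleset: str = "A",
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Embed binding sites (or single-rule decoy near-sites) into transcripts.

    ``plan`` rows are (mirna_id, transcript_id, violated_rule) with
    violated_rule None for a genuine site.  Genuine sites are the reverse
    complement of the miRNA, alternately perfect or carrying one G-U wobble
    at position 16 (half a mismatch).  Site positions are drawn uniformly;
    the site replaces the transcript subsequence in place.  Returns the
    edited transcripts and a truth site table.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.id: t.sequence for t in transcripts}
    mirna_by_id = {m.id: m.sequence.replace("T", "U") for m in mirnas}
    rows = []
    for i, (mirna_id, transcript_id, rule) in enumerate(plan):
        mi_rna = mirna_by_id[mirna_id]
        seq = by_id[transcript_id]
        if len(seq) < len(mi_rna) + 10:
            raise ValueError(
                f"transcript {transcript_id} too short for a planted site"
            )
        is_rna = "U" in seq and "T" not in seq
        if rule is None:
            mutations = [] if i % 2 == 0 else [(16, "GU")]
            window = _mutate_window(mi_rna, mutations)
            verdict = evaluate_rules(duplex_align(mi_rna, window), ruleset=ruleset)
            if not verdict.passed:
                raise AssertionError("planted site fails the rule set")
        else:
            window = _decoy_window(mi_rna, rule, ruleset)
        insert = window if is_rna else window.replace("U", "T")
        pos = int(rng.integers(0, len(seq) - len(insert) + 1))
        by_id[transcript_id] = seq[:pos] + insert + seq[pos + len(insert) :]
        rows.append(
            {
                "mirna": mirna_id,
                "transcript": transcript_id,
                "position": pos,
                "kind": "planted" if rule is None else "decoy",
                "violated_rule": rule,
                "ruleset": ruleset,
            }
        )
    edited = [replace(t, sequence=by_id[t.id]) for t in transcripts]
    sites = pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "position", "kind", "violated_rule", "ruleset"],
    )
    return edited, sites


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def _role_ids(params: GeneratorParams) -> dict[str, list[str]]:
    """Deterministic feature-id allocation for every planted role."""
    p = params
    mrna = [f"G{i + 1:04d}" for i in range(p.n_mrna)]
    lnc = [f"L{i + 1:04d}" for i in range(p.n_lncrna)]
    mir = [f"miR{i + 1:03d}" for i in range(p.n_mirna)]
    k = p.n_triplets
    roles = {
        "triplet_mrna": mrna[10 : 10 + k],
        "decoy_site_mrna": mrna[10 + k : 10 + 2 * k],
        "nullexpr_site_mrna": mrna[10 + 2 * k : 10 + 3 * k],
        "de_mrna": mrna[10 + 3 * k : 10 + 3 * k + p.n_de_mrna],
        "triplet_lnc": lnc[5 : 5 + k],
        "decoy_site_lnc": lnc[5 + k : 5 + 2 * k],
        "de_lnc": lnc[5 + 2 * k : 5 + 2 * k + p.n_de_lncrna],
        "triplet_mirna": mir[:k],
        "de_mirna": mir[k : k + p.n_de_mirna],
        "all_mrna": mrna,
        "all_lnc": lnc,
        "all_mirna": mir,
    }
    offset = 10 + 3 * k + p.n_de_mrna
    for m, size in enumerate(p.module_sizes, start=1):
        roles[f"block{m}"] = mrna[offset : offset + size]
        offset += size
    return roles


def generate_expression(
    params: GeneratorParams, seed: int
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Expression matrices (mRNA, lncRNA, miRNA) with planted structure.

    Log2 abundance = base + effect + noise; effects encode planted DE
    (genotype main effect), module factors (block 1 follows the latent
    senescence score, further blocks are orthogonalized random factors), and
    the ceRNA triplet geometry (targets follow +z, miRNAs follow -z, each
    with small member-specific jitter).  ``count_mode`` replaces the
    log-normal observation with Poisson counts around the same means.
    """
    p = params
    rng = np.random.default_rng(seed)
    meta = design_metadata(p.n_replicates)
    z = latent_scores(meta)
    n_s = len(meta)
    mutant = (meta["genotype"] == "mutant").to_numpy().astype(float)
    roles = _role_ids(p)

    factors = [(z - z.mean()) / z.std(ddof=0)]
    for _ in range(len(p.module_sizes) - 1):
        f = rng.normal(size=n_s)
        for prev in factors:
            f -= f @ prev / (prev @ prev) * prev
        factors.append(f / f.std(ddof=0))

    def build(ids: list[str]) -> tuple[pd.DataFrame, dict[str, float]]:
        base_range = p.count_base_log2_range if p.count_mode else p.base_log2_range
        base = rng.uniform(*base_range, size=len(ids))
        effect = np.zeros((len(ids), n_s))
        de_lfc: dict[str, float] = {}
        index = {g: i for i, g in enumerate(ids)}

        def jitter() -> np.ndarray:
            return rng.normal(0, p.latent_jitter_sd, n_s)

        for role, sign in (("triplet_mrna", +1), ("triplet_lnc", +1),
                           ("decoy_site_mrna", +1), ("decoy_site_lnc", +1),
                           ("triplet_mirna", -1)):
            for fid in roles.get(role, []):
                if fid in index:
                    effect[index[fid]] += sign * (z + jitter())
        for role in ("de_mrna", "de_lnc", "de_mirna"):
            for j, fid in enumerate(roles.get(role, [])):
                if fid in index:
                    lfc = p.planted_log2fc * (1 if j % 2 == 0 else -1)
                    effect[index[fid]] += lfc * mutant
                    de_lfc[fid] = lfc
        for m in range(1, len(p.module_sizes) + 1):
            for fid in roles.get(f"block{m}", []):
                if fid in index:
                    effect[index[fid]] += p.module_loading * factors[m - 1]

        log2mean = base[:, None] + effect
        if p.count_mode:
            values = rng.poisson(2.0 ** log2mean).astype(float)
        else:
            values = 2.0 ** (log2mean + rng.normal(0, p.noise_sd, log2mean.shape))
        return (
            pd.DataFrame(values, index=ids, columns=list(meta.index)),
            de_lfc,
        )

    mrna_vals, mrna_lfc = build(roles["all_mrna"])
    lnc_vals, lnc_lfc = build(roles["all_lnc"])
    mir_vals, mir_lfc = build(roles["all_mirna"])

    unit = "count" if p.count_mode else "FPKM"
    mrna_expr = ExpressionMatrix(values=mrna_vals, metadata=meta, unit=unit)
    lnc_expr = ExpressionMatrix(values=lnc_vals, metadata=meta, unit=unit)
    mir_expr = ExpressionMatrix(
        values=mir_vals, metadata=meta, unit="count" if p.count_mode else "TPM"
    )

    de_rows = (
        [{"feature": f, "feature_class": "mRNA", "log2fc": v} for f, v in mrna_lfc.items()]
        + [{"feature": f, "feature_class": "lncRNA", "log2fc": v} for f, v in lnc_lfc.items()]
        + [{"feature": f, "feature_class": "miRNA", "log2fc": v} for f, v in mir_lfc.items()]
    )
    truth = TruthTable(
        seed=seed,
        params=p,
        de=pd.DataFrame(de_rows, columns=["feature", "feature_class", "log2fc"]),
        modules={
            f"block{m}": tuple(roles[f"block{m}"])
            for m in range(1, len(p.module_sizes) + 1)
        },
        triplets=pd.DataFrame(
            {
                "lncrna": roles["triplet_lnc"],
                "mirna": roles["triplet_mirna"],
                "mrna": roles["triplet_mrna"],
            }
        ),
        sites=pd.DataFrame(
            columns=["mirna", "transcript", "position", "kind", "violated_rule", "ruleset"]
        ),
    )
    return mrna_expr, lnc_expr, mir_expr, truth


# ---------------------------------------------------------------------------
# Small-RNA reads
# ---------------------------------------------------------------------------


def generate_smallrna_reads(
    mirnas: list[SeqRecord],
    copies: pd.DataFrame,
    contaminants: ContaminantSpec,
    adapter3: str,
    adapter5: str,
    seed: int,
) -> dict[str, list[SmallRead]]:
    """Per-library read sets: clean tags plus exactly counted contaminants.

    A clean read is the miRNA sequence (DNA alphabet) followed by the 3'
    adapter, at the planted copy number for its library.  Contaminant counts
    per class follow the requested counts exactly so filter reports are
    checkable.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[SmallRead]] = {}
    mirna_dna = {m.id: m.sequence.replace("U", "T") for m in mirnas}
    for sample in copies.columns:
        reads: list[SmallRead] = []
        i = 0
        for mirna_id in copies.index:
            seq = mirna_dna[mirna_id] + adapter3
            qual = "I" * len(seq)
            for _ in range(int(copies.loc[mirna_id, sample])):
                reads.append(SmallRead(f"{sample}_r{i}", seq, qual))
                i += 1
        for _ in range(contaminants.short):
            seq = _random_seq(rng, 10) + adapter3
            reads.append(SmallRead(f"{sample}_r{i}", seq, "I" * len(seq)))
            i += 1
        for _ in range(contaminants.low_quality):
            seq = _random_seq(rng, 22) + adapter3
            reads.append(SmallRead(f"{sample}_r{i}", seq, "#" * len(seq)))
            i += 1
        for _ in range(contaminants.no_3prime_adapter):
            while True:
                seq = _random_seq(rng, 25, alphabet="ACG")  # cannot hold the T-led adapter
                from .smallrna_filter import locate_3prime_adapter

                if locate_3prime_adapter(seq, adapter3) is None:
                    break
            reads.append(SmallRead(f"{sample}_r{i}", seq, "I" * len(seq)))
            i += 1
        for _ in range(contaminants.has_5prime_adapter):
            seq = adapter5 + _random_seq(rng, 20) + adapter3
            reads.append(SmallRead(f"{sample}_r{i}", seq, "I" * len(seq)))
            i += 1
        for _ in range(contaminants.polya):
            seq = "A" * 20 + adapter3
            reads.append(SmallRead(f"{sample}_r{i}", seq, "I" * len(seq)))
            i += 1
        out[sample] = reads
    return out


def _sanitize_background_hits(
    mirnas: list[SeqRecord],
    transcripts: list[SeqRecord],
    sites: pd.DataFrame,
    roles: dict[str, list[str]],
    ruleset: str,
) -> list[SeqRecord] | None:
    """Remove chance hits so planted miRNAs find exactly the planted sites.

    A stray qualifying window away from any planted or decoy site gets two
    bases replaced so duplex positions 10-11 mismatch.  Returns the cleaned
    transcripts, or None when a stray hit overlaps a planted site (the
    caller then redraws sequences).
    """
    from .target_rules import scan_many

    planted_ids = set(roles["triplet_mirna"])
    scaffolds = {m.id: m.sequence for m in mirnas if m.id in planted_ids}
    expected = {
        (r.mirna, r.transcript, r.position)
        for r in sites.itertuples(index=False)
        if r.kind == "planted"
    }
    site_spans: dict[str, list[int]] = {}
    for r in sites.itertuples(index=False):
        site_spans.setdefault(r.transcript, []).append(r.position)
    by_id = {t.id: t.sequence for t in transcripts}

    for _ in range(10):
        hits = scan_many(
            [SeqRecord(i, s).as_rna() for i, s in scaffolds.items()],
            [SeqRecord(i, s).as_rna() for i, s in by_id.items()],
            ruleset=ruleset,
        )
        found = {
            (r.mirna, r.transcript, r.position) for r in hits.itertuples(index=False)
        }
        if found - expected == set() and expected - found == set():
            return [replace(t, sequence=by_id[t.id]) for t in transcripts]
        if expected - found:
            return None  # a planted site was destroyed; redraw
        for mirna_id, tr_id, pos in found - expected:
            if any(abs(pos - s) < MIRNA_LEN for s in site_spans.get(tr_id, [])):
                return None  # overlaps a planted/decoy site; redraw
            mi = scaffolds[mirna_id]
            seq = list(by_id[tr_id])
            is_rna = "U" in by_id[tr_id] and "T" not in by_id[tr_id]
            for mi_pos in (10, 11):  # window index pairing miRNA position
                base = mi[mi_pos - 1]
                seq[pos + MIRNA_LEN - mi_pos] = base if is_rna else base.replace("U", "T")
            by_id[tr_id] = "".join(seq)
    return None


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    params: GeneratorParams
    seed: int
    annotation: AnnotationSet
    transcripts: list[SeqRecord]   # mRNA + lncRNA spliced sequences (DNA)
    mirnas: list[SeqRecord]        # DNA alphabet
    mrna_expr: ExpressionMatrix
    lnc_expr: ExpressionMatrix
    mirna_expr: ExpressionMatrix
    smallrna_reads: dict[str, list[SmallRead]]
    mirna_copies: pd.DataFrame
    truth: TruthTable


def simulate(params: GeneratorParams | None = None, seed: int = 0) -> SimulatedStudy:
    """Generate a complete synthetic study: annotation, sequences, sites,
    expression, and small-RNA reads, with the truth table tying it together.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    roles = _role_ids(p)

    annotation, transcripts = generate_annotation(
        p.n_mrna, p.n_lncrna, seed=int(rng.integers(2**31)),
        transcript_len=p.transcript_len,
    )

    decoy_rules = list(DECOY_RULES[p.ruleset])
    plan: list[tuple[str, str, str | None]] = []
    for i in range(p.n_triplets):
        m = roles["triplet_mirna"][i]
        plan.append((m, roles["triplet_mrna"][i], None))
        plan.append((m, roles["triplet_lnc"][i], None))
        plan.append((m, roles["nullexpr_site_mrna"][i], None))
        plan.append((m, roles["decoy_site_mrna"][i], decoy_rules[(2 * i) % len(decoy_rules)]))
        plan.append((m, roles["decoy_site_lnc"][i], decoy_rules[(2 * i + 1) % len(decoy_rules)]))

    # The truth table must be exact: scanning a planted miRNA over the study
    # transcripts may yield only the planted sites.  Two rare accidents can
    # break that -- a background window that qualifies by chance, and a
    # shifted window over one planted site re-aligning against another
    # scaffolded miRNA's skeleton.  Chance background windows are sanitized
    # in place (two mismatches forced at duplex positions 10-11, which fails
    # the rules under both variants); overlap accidents trigger a bounded,
    # seeded redraw of the miRNA sequences and site positions.
    for attempt in range(20):
        sub = np.random.default_rng([int(rng.integers(2**31)), attempt])
        mirnas = []
        seen: set[str] = set()
        for mirna_id in roles["all_mirna"]:
            while True:
                if mirna_id in roles["triplet_mirna"]:
                    rec = make_scaffold_mirna(
                        sub, mirna_id,
                        ortho_index=roles["triplet_mirna"].index(mirna_id),
                    )
                else:
                    rec = SeqRecord(
                        id=mirna_id, sequence=_random_seq(sub, MIRNA_LEN, "ACGU")
                    )
                if rec.sequence not in seen:
                    seen.add(rec.sequence)
                    break
            mirnas.append(rec)
        edited, sites = plant_binding_sites(
            mirnas, transcripts, plan, ruleset=p.ruleset,
            seed=int(sub.integers(2**31)),
        )
        edited = _sanitize_background_hits(mirnas, edited, sites, roles, p.ruleset)
        if edited is not None:
            transcripts = edited
            break
    else:
        raise RuntimeError("could not realize the planted site plan exactly")

    mrna_expr, lnc_expr, mirna_expr, truth = generate_expression(
        p, seed=int(rng.integers(2**31))
    )
    truth.sites = sites
    truth.seed = seed

    copies = mirna_expr.values.round().astype(int).clip(lower=0)
    reads = generate_smallrna_reads(
        mirnas, copies, p.contaminants, p.adapter3, p.adapter5,
        seed=int(rng.integers(2**31)),
    )

    truth.validate(
        transcript_ids={t.id for t in transcripts},
        mirna_ids={m.id for m in mirnas},
    )
    return SimulatedStudy(
        params=p, seed=seed, annotation=annotation, transcripts=transcripts,
        mirnas=mirnas, mrna_expr=mrna_expr, lnc_expr=lnc_expr,
        mirna_expr=mirna_expr, smallrna_reads=reads, mirna_copies=copies,
        truth=truth,
    )


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Dump a simulated study to plain-text files (FASTA/GFF3/TSV/FASTQ)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_gff3(study.annotation, out / "annotation.gff3")
    write_fasta(study.transcripts, out / "transcripts.fasta")
    write_fasta(study.mirnas, out / "mirnas.fasta")
    study.mrna_expr.metadata.to_csv(out / "samples.tsv", sep="\t")
    study.mrna_expr.values.to_csv(out / "mrna_expression.tsv", sep="\t")
    study.lnc_expr.values.to_csv(out / "lncrna_expression.tsv", sep="\t")
    study.mirna_expr.values.to_csv(out / "mirna_expression.tsv", sep="\t")
    for sample, reads in study.smallrna_reads.items():
        write_fastq(reads, out / f"smallrna_{sample}.fastq")
    study.truth.de.to_csv(out / "truth_de.tsv", sep="\t", index=False)
    study.truth.sites.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    study.truth.triplets.to_csv(out / "truth_triplets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"gene": gene, "module": label}
            for label, genes in study.truth.modules.items()
            for gene in genes
        ]
    ).to_csv(out / "truth_modules.tsv", sep="\t", index=False)
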