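# Methods

This note documents the models and procedures implemented in `cernaforge`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic data do and do not establish.

## Study design and data model

The pipeline targets a 2-genotype (wild / early-senescence mutant) ×
3-leaf-position (flag, second, third) × 3-replicate design, 18 libraries in
total. Expression lives in `ExpressionMatrix` (features × samples, with
sample metadata and a unit tag: count, FPKM, TPM or log2). Genomic features
are 0-based half-open internally; GFF3 I/O converts from the 1-based
inclusive convention at the boundary. Sequences are uppercased; duplex
operations run on the RNA alphabet (T→U at the call boundary).

## Normalization and differential expression

FPKM_i = count_i / ((L_i/10³)·(total/10⁶)); small-RNA TPM_i =
count_i·10⁶/total. Both satisfy exact conservation identities
(Σ FPKM·L_kb·total_M = total; TPM columns sum to 10⁶) that the test suite
asserts.

Differential expression uses a deliberate surrogate rather than a
negative-binomial count model: Welch's two-sample *t* on log₂(x + c)
(pseudocount c = 1 on the normalized scale), Benjamini–Hochberg adjustment
within each contrast, and class-specific calls — mRNA/lncRNA at
q < 0.05 ∧ |log₂FC| ≥ 1, miRNA at raw p < p₀ ∧ |log₂FC| ≥ 1 with
p₀ = 0.05 by default and a 0.07 preset (both cutoffs are attested
conventions for small-RNA DE; the default follows the stricter one).
"Fold change ≥ 2" and "|log₂FC| > 1" are treated as the same rule, applied
boundary-inclusive as |log₂FC| ≥ 1. The surrogate's operating
characteristics, not any particular gene list, are the contract: on
count-mode synthetic data (Poisson observation) the null positive rate at
α = 0.05 sits near 0.035 (Welch with n = 3 is mildly conservative —
its Satterthwaite df can drop toward 2) and sensitivity for |log₂FC| = 2
exceeds 0.95 at BH FDR 0.05.

Nine contrasts are enumerated from the metadata: three between-genotype
(per leaf) and three within-genotype leaf pairs per genotype. For the ceRNA
gate, "all members differentially expressed" means DE in at least one of
the nine contrasts (configurable to between-genotype only); pooling
contrasts is both the conventional usage for this design and markedly more
robust at n = 3, where a single unlucky within-group variance draw can push
one contrast's q just past the cutoff.

## lncRNA classification

Candidates shorter than 200 nt (spliced) are screened out, boundary
inclusive. Five positional classes are assigned with the precedence
sense_overlapping > antisense > intronic > bidirectional > intergenic:
exon-level overlap same/opposite strand; full containment in an intron
without exon overlap; divergent (head-to-head) transcription start sites on
opposite strands within 1 kb; everything else intergenic. The geometric
definitions and the 1 kb window are package conventions (the class *names*
are standard; their formalizations vary across the literature) and are
configurable. Cis-neighbors are coding genes whose span intersects the
lncRNA span widened by 10 kb on each side, either strand.

## miRNA target rules

A miRNA of length L is scanned gaplessly against every transcript window of
length L, miRNA position i (5′→3′) pairing window position L+1−i. States
are Watson–Crick, G-U wobble, or mismatch; the mismatch score counts a
wobble as 0.5. Ruleset A: total score ≤ 4; no run of three adjacent
mismatches; no adjacent mismatch pair entirely inside positions 2–12; no
mismatch at positions 10–11; score over positions 1–12 ≤ 2.5; duplex
energy ≥ 74% of the perfect-complement energy. Ruleset B tightens adjacency
(none), forbids any mismatch at 2–12, and relaxes the energy ratio to 60%.
Both variants are implemented because both parameterizations are in use;
neither is claimed canonical. Whether a wobble counts as a positional
mismatch *event* (rules 2–4) is a switch, default on; it always carries its
0.5 weight in the scored rules.

No thermodynamic model is specified by the rule sets themselves, so the
energy ratio uses a simple additive per-pair model (GC −3, AU −2, GU −1,
mismatch 0, arbitrary units) applied identically to the duplex and the
perfect complement; the ratio — the actual decision quantity — is therefore
model-consistent, and a nearest-neighbor model can be plugged in behind the
same contract. The scanner prescreens windows on the rule-1 score bound
(vectorized), then applies the full rule set to survivors; tests verify
exact agreement with an exhaustive per-window reference implementation
under both rulesets.

## Small-RNA filter cascade

Reads pass quality (removed if > 50% of bases have Phred ≤ 20, mirroring
the long-read quality rule of the same form), 3′-adapter location by
longest exact prefix match (≥ 6 nt) with trimming, 5′-adapter screening of
the insert, the 18–30 nt length window applied *after* trimming (an
ambiguity resolved here as a decision), and a polyA rule (≥ 8 consecutive
A). Removals are attributed to the first failing rule, so the report's bins
sum exactly to the input. Because clean tags are trimmed, strict
re-application of the 3′-adapter requirement would empty them; the
`require_3prime_adapter` flag exists so the cascade is idempotent on its own
output. Quantification is exact-match (T/U-insensitive) against a
unique-sequence catalog — the strictest reproducible policy absent a stated
mismatch tolerance.

## Co-expression modules

The module stage operates on log₂(x+1) expression — on the linear scale the
exponential's curvature injects a shared skew component that spuriously
correlates eigengenes of orthogonal factors. About 45% of genes are removed
by lowest log-scale variance (deterministic tie-break by id). Adjacency is
unsigned |cor|^β with β = 8 (a β = 7 convention also circulates; β is
config). TOM is the standard unsigned topological overlap; modules come
from average-linkage clustering of 1−TOM with a static cut at height 0.98 —
a deterministic substitute for dynamic tree cutting, placed so that real
modules (whose merges sit far below) separate from unrelated genes
(pairwise overlap ≈ 0, dissimilarity ≈ 1). Clusters below 50 genes fall to
`grey`; module pairs with eigengene dissimilarity 1−cor < 0.85 are merged
iteratively, closest first. Eigengenes are the first principal component of
standardized member expression, sign-fixed against the mean member profile.

A caution on the literal 0.85 merge cut: it merges any module pair whose
eigengene correlation exceeds 0.15, and with 18 samples the correlation of
genuinely unrelated eigengenes fluctuates with sd ≈ 0.24 — so in rich data
(many latent factors) chain merges can fuse unrelated modules at some
seeds. The community default for this parameter is 0.25. The package keeps
the literal value as default and exposes it; module–trait association and
the ceRNA module intersection are robust to over-merging because they only
require the senescence-driven genes to end up inside the chosen module.

## ceRNA assembly

Pairs (miRNA, target) survive iff the target engine predicts a site, both
members are DE, and Spearman ρ < −0.7 (strict; ties mid-ranked; undefined
correlations fail). Triplets join the mRNA- and lncRNA-pair lists on shared
miRNAs and keep those with Pearson r > 0.9 (strict), optionally restricted
to mRNAs in a chosen module (lncRNA membership is a separate switch,
default off — the looser reading of module intersection). Every emitted
triplet is re-audited against its constraints before return. Output is
deduplicated, deterministically sorted, and exportable as SIF and GraphML.

## Synthetic data: what it emulates, and what it does not

The generator realizes the full design with one latent "senescence score"
per sample — 0/0.5/1.0 across wild leaves, 0.5/2.5/3.5 in the mutant — so
senescence rises along leaf age and is strongly amplified in the mutant
(whose flag leaf stays nearly normal). Log₂ abundance = baseline
(U(4, 9)) + effects + N(0, 0.15) noise; count mode replaces the log-normal
observation with Poisson counts around the same means at a deeper baseline
(U(6, 11), matching tens of millions of reads per library, where
down-shifted features remain measurable).

Planted structure: DE genes carry a ±2 log₂FC genotype effect (margin of 1
over the calling threshold); two 60-gene blocks load 0.5× on module
factors — block 1 on the standardized senescence score, later blocks on
factors orthogonalized against it; triplet members follow ±(z + jitter)
with member jitter sd 0.10, which realizes Spearman < −0.7 and
Pearson > 0.9 for planted pairs in ≳99% of runs at default noise while
unplanted pairs center on zero. Binding sites are embedded as reverse
complements (perfect, or one wobble at position 16); decoy near-sites
violate exactly one named rule each, constructed on a fixed miRNA scaffold
(G at 1,5,9,13,17,21; U at 4,8,12,16,20; 5 C + 5 A on the free positions,
pinning the perfect-complement energy at −53) and verified at build time.
Under ruleset A all six single-rule decoys are constructible; under ruleset
B only rules 1–3 can be violated in isolation (any mismatch in 2–12 trips
rule 3 first, and the 60% energy bound cannot be crossed within the other
constraints), so B decoy sets cover those three. Co-planted miRNAs use
mutually orthogonal scaffold codes (differing at duplex positions 10/11 or
jointly at 6/7), capping planted triplets at eight per study and
guaranteeing no cross-recognition of one another's sites. Chance background
windows that qualify for a planted miRNA are sanitized (two mismatches
forced at positions 10–11) so the truth table is exact; a bounded seeded
redraw handles the rare overlap case. Small-RNA libraries carry exactly
counted contaminants per class, so filter reports are checkable to the
read.

What passing these tests shows: the thresholds, rules and recovery logic
behave as specified under the stated noise model. What it does not show:
performance on real data with overdispersed counts, isoform ambiguity,
imperfect annotation, adapter errors, miRNA families with near-identical
sequences, or ceRNA signals far weaker than the planted margins. The
generator makes no attempt to simulate read-level long-RNA sequencing or
splice isoforms.

## Numerical and determinism choices

All randomness flows from one integer seed through PCG64; identical seeds
give byte-identical outputs. Tie-breaks are deterministic everywhere
(variance ranking by gene id; module ordering by size then label; triplet
sort by (lncRNA, miRNA, mRNA)). Hypergeometric tails are computed in log
space; constant-vector correlations return NaN and fail thresholds rather
than fabricate ±1. Rule-boundary comparisons use a 1e-12 guard so exact
half-integer scores land on the inclusive side. Default problem sizes: the
full-scale preset is 2,000 mRNAs / 300 lncRNAs / 100 miRNAs over 18
libraries; the small preset (400/35/15) preserves the full design's key
proportions — in particular most genes unstructured, so the ~45% variance
prefilter removes background rather than planted module members — while
keeping unit tests fast.
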