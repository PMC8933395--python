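# Methods

## Cleavage scoring and site calling

The treated/untreated contrast assumes both libraries come from the same
demethylase-treated RNA pool, differing only in the reduction/aniline
cleavage step. The per-position statistic is the log2 ratio of pseudocounted
5′-end read-start frequencies,

    score(i) = log2( (t_i + c) / (T + c·L) · (U + c·L) / (u_i + c) ),

with t, u the treated/untreated counts at position i, T, U the library-wide
read-start totals, L the tRNA length and c the pseudocount (default 0.5 per
position). The form is antisymmetric under swapping the libraries and
invariant to scaling both libraries (with c scaled along), so thresholds
transfer across sequencing depths. The published description of the assay
defers the numeric score definition to its protocol reference; the formula
above is this package's own reimplementation choice and is recorded in every
run manifest.

Cleavage chemistry places new 5′ ends one nucleotide 3′ of the methylated G,
so scoring and coverage are read at G+1 (`cleavage_offset`, configurable).
Candidate positions are anchored-G hits of the `ABGWY` motif inside the
variable loop; a match may overhang the loop's 3′ end as long as the G itself
is inside, since the modification, not the motif tail, is loop-anchored.
Calling gates: score ≥ 1.0 (two-fold) and treated coverage ≥ 10 — both
unpublished in the source analysis, both exposed as flags. High-scoring
non-motif loop positions are reported unclassified (`motif_ok = false`) so
off-motif signal stays visible without affecting calls.

The variable loop is located from a dot-bracket structure when one is
supplied: the unpaired run between the 3′ side of the helix closing the
anticodon hairpin and the next paired base (the T-stem). Without structure a
positional heuristic window [len−27, len−12) is used, which brackets
canonical positions 44–48 on a 76-nt tRNA; it is overridable per gene and a
trailing CCA can be excluded from the length. This heuristic is the weakest
assumption in the module and is deliberately loose: the motif gate, not the
window boundary, carries the specificity.

## Wobble decoding

Codon positions 1–2 are the Watson–Crick complement of anticodon positions
36–35 in every mode. The third position follows the anticodon position-34
base: `strict_wc` takes the complement only; `crick_wobble` adds G34→{C,T},
U34→{A,G}; `crick_wobble_inosine` additionally lets A34 (normally edited to
inosine in eukaryotes) read U, C and A. The default is
`crick_wobble_inosine` because eukaryotic A34 tRNAs are inosine-modified and
multi-codon decoding by e.g. Val-AAC is what makes single-tRNA rescue
experiments interpretable. Which codons the original analysis counted as
"m⁷G tRNA-decoded" — in particular whether wobble codons were included — is
not recoverable from the publication, so the policy is a config knob and
every downstream output records which policy produced it.

## Expression comparison

Counts are aggregated isodecoder→isotype (the unit displayed in the source
heatmap), CPM-normalised, then expressed per isotype as log2 relative to the
isotype's mean over all samples of both groups. Zeros would map to −∞, so a
floor at half the smallest nonzero value (configurable, disableable) is
applied first. Replicates are averaged per condition before the class
comparison by default; averaging before vs after the log transform is not
specified in the source, so both orders exist (`average_replicates`), with
means-of-logs the default. The class test is the package's own Mann–Whitney
U: U = #{a_i > b_j} + ½·ties; the p-value is exact via the standard counting
recurrence for the tie-free null distribution when min(n,m) ≤ 8, otherwise a
normal approximation with tie and continuity corrections. Exactness where
enumeration is feasible, the standard approximation elsewhere.

## Translation efficiency

FPKM = count / (length_kb · total_Mreads). TE = translated/input FPKM;
undefined (and filtered) when input FPKM is zero. Polysome-seq and Ribo-seq
TE share one code path: footprint FPKM uses CDS length, input mRNA FPKM uses
transcript length by default (whether the original polysome TE used CDS or
transcript length for the input is unstated; `input_length="cds"` switches).
Classification thresholds |log2 ratio| ≥ 1 and input FPKM ≥ 1 are defaults
surfaced in config; the source states none.

## Pausing

The A-site offset rule (+15 nt for 28–31-nt footprints, others discarded) is
the conventional mammalian choice; harringtonine pretreatment affects
initiation sites, which this codon-level statistic does not use. Pause score
= codon count / gene mean count, genes below 0.5 mean counts/codon excluded,
so every included gene contributes mean 1. Codon-type aggregation uses the
mean (median by flag) and the m⁷G-vs-other comparison is on per-type
knockdown-minus-control deltas over the 61 sense codon types; stop codons
are excluded.

Mean-normalising within a gene redistributes any extra dwell time at m⁷G
codons across the whole gene, deflating raw KD/control pause ratios in both
codon classes by the same per-gene factor. The recovered multiplier is
therefore the within-gene double ratio (m⁷G class over other class, KD over
control) averaged over genes, in which that factor cancels exactly.

## Synthetic data

The generators produce the minimal statistical structure each stage assumes,
with standard noise models that are this package's choice, not the source's:
multinomial read starts over per-position weights (uniform background 5×10⁻³
per position; +0.15 at each true site+1 in the treated library; 2×10⁵ read
starts/library), gamma-Poisson (negative binomial) counts for tRNA and mRNA
libraries, Poisson codon occupancy, lognormal abundances. Defaults encode
the emulated study conditions: 50 isotypes × 2 isodecoders, 40% of isotypes
m⁷G-modified (20 types; the source study called 19), knockdown depletion
factor 0.6 on m⁷G isotypes with 2 replicates per arm, 2000 genes of 100–500
codons with m⁷G-codon propensity uniform on [0, 0.5], TE–codon coupling
te_beta = 0.01 (log2 TE loss per m⁷G codon in knockdown), and ribosome
occupancy of 50 mean counts/codon over 200 genes with a 2× pause multiplier
at m⁷G codons under knockdown.

Two noise choices deserve note. First, TE carries per-condition lognormal
biological noise (σ = 0.25) on top of the deterministic
TE_KD = TE_control · 2^(−β·count) relation; without it no gene would ever
classify "up" and the three-class comparison would be degenerate — it models
culture-to-culture TE variability. Second, footprint records are emitted
already consistent with the default offset rule (ramp codons before the
A-site window and the terminal stop receive no reads), so codon assignment
inverts the generator exactly; fragment-length biology is not modelled.

What the generator does **not** emulate: sequence-dependent fragmentation
and ligation bias, isodecoder-specific modification stoichiometry, multi-
isoform genes, uORFs and initiation heterogeneity, tRNA charging, and any
count correlation structure beyond the implanted effects. Passing tests
therefore demonstrate that each statistic recovers the structure it targets
at realistic depths and noise — not that the pipeline is robust to every
artefact of real libraries.

One global seed fans out into named `numpy` SeedSequence substreams
(reference, treated/control pileups, expression, transcriptome, mRNA, ribo)
so stages regenerate independently and byte-identically.

## Problem sizes and numerics

Simulation-based checks use the condition sizes stated above (50 seeds for
site-calling accuracy; 100 power / 200 null seeds for the expression test;
2000 genes with 200 null seeds for the TE–codon comparison; 20 seeds per
multiplier for pause recovery); the whole suite runs in well under a minute
per stage on one CPU. Degenerate inputs (zero library sizes, all-zero
columns, empty classes, disjoint site sets) raise typed errors rather than
propagating NaNs; p-values are clamped to (0, 1]; coordinates are 0-based
half-open internally with 1-based printing only in human-readable reports.

## Known limitations

The cleavage-score formula and all calling thresholds are reimplementation
decisions (the original defers to its protocol reference), so absolute score
values are not comparable to the source's figures — directions, rankings and
class statistics are. The variable-loop heuristic can mis-window unusually
long variable arms (e.g. class II Ser/Leu tRNAs) when no structure is given.
The published 19-type benchmark requires the deposited raw libraries from
NCBI GEO (GSE169590) processed into 5′-end pileups; the corresponding check
runs only when such a local copy exists.
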