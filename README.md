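# m7gflow

Analysis pipeline linking METTL1/WDR4-dependent N⁷-methylguanosine (m⁷G) tRNA
modification to selective mRNA translation. It is aimed at groups studying
codon-usage-dependent translational control who have (or simulate)
chemical-cleavage tRNA sequencing, tRNA quantification, polysome/Ribo-seq
counts and CDS sequences, and want the full chain from m⁷G site calling to
codon-level ribosome pausing as tested, scriptable components.

## What it computes

**m⁷G site calling (TRAC-seq).** NaBH₄ reduction plus aniline treatment
cleaves tRNAs at m⁷G, so new read 5′ ends accumulate one nucleotide 3′ of the
modified G. With pseudocounted 5′-end start frequencies f at position *i*,

    cleavage score(i) = log2( f_treated(i) / f_untreated(i) )

A site is called m⁷G when it is the anchored G of an `ABGWY` motif
(IUPAC: A, [CGT], G, [AT], [CT]) inside the tRNA variable loop, its score
clears a threshold (default 1.0, i.e. two-fold) and the treated coverage
clears a minimum (default 10). A tRNA is m⁷G-modified iff it has ≥ 1 called
site; results are reported at both isodecoder and isotype granularity.

**tRNA expression.** Isodecoder counts are summed to isotypes (amino acid +
anticodon), depth-normalised (CPM), and each isotype is expressed as
log2(value / its mean over all samples of both groups). The knockdown-minus-
control shifts of m⁷G vs non-m⁷G isotypes are compared with a two-sided
Mann–Whitney U test (own implementation: exact by enumeration for small
tie-free samples, tie/continuity-corrected normal approximation otherwise).

**Translation efficiency.** TE = translated FPKM / input mRNA FPKM, where the
translated library is polysome-bound mRNA (transcript length) or ribosome
footprints over the CDS (CDS length). Genes are classified up / down / non at
|log2 ratio| ≥ 1 with an input-FPKM floor, or filtered.

**Codon statistics.** Anticodons map to decoded codons under configurable
wobble rules (strict Watson–Crick; Crick wobble; Crick wobble with A34 read
as inosine, the default). m⁷G-decoded codons are counted over each CDS in
frame 0 and compared between TE classes and gene sets (GMT) with
Mann–Whitney tests; raw counts and CDS-length-normalised densities are both
reported.

**Ribosome pausing.** Footprints are assigned to codons via an A-site offset
rule (+15 nt for 28–31-nt reads by default), per-gene occupancy is
mean-normalised into pause scores, and the knockdown-minus-control shift per
codon type is tested for m⁷G-decoded vs other sense codons.

**Synthetic data.** A seeded generator emulates every input with the
structure above implanted (motifs in loops, cleavage pileups, isotype
depletion, TE–codon coupling, codon-specific pausing) plus ground truth, so
each stage is testable without downloads.

## Worked example

```
m7gflow simulate --seed 7 --out run1
m7gflow call-sites --reference run1/inputs/trna_reference.fasta \
    --treated run1/inputs/trac_treated_control-cond.tsv \
    --control run1/inputs/trac_untreated_control-cond.tsv \
    --out run1/call_sites
# 40 called sites on 40 tRNA genes (20 isotypes)
```

All 40 implanted sites (2 isodecoders for each of 20 m⁷G isotypes) are
recovered with no false positives. Continuing through the stages:

```
m7gflow trna-expression --counts run1/inputs/trna_counts.tsv \
    --reference run1/inputs/trna_reference.fasta \
    --m7g-isotypes run1/call_sites/m7g_isotypes.txt --out run1/trna_expression
# m7G median shift -0.542 vs non +0.222, p = 2.11e-06

m7gflow te --cds run1/inputs/cds.fasta \
    --input-control run1/inputs/input_control.tsv --input-kd run1/inputs/input_kd.tsv \
    --translated-control run1/inputs/polysome_control.tsv \
    --translated-kd run1/inputs/polysome_kd.tsv --out run1/te
# TE classes: up=342, down=280, non=1378, filtered=0

m7gflow pausing --cds run1/inputs/cds.fasta \
    --footprints-control run1/inputs/footprints_control.tsv \
    --footprints-kd run1/inputs/footprints_kd.tsv \
    --reference run1/inputs/trna_reference.fasta \
    --m7g-isotypes run1/call_sites/m7g_isotypes.txt --out run1/pausing
# m7G codon pause shift: median delta +0.508 (other -0.171), p = 2.07e-11
```

The expression test detects the simulated 40% depletion of m⁷G isotypes
(negative m⁷G-class shift, non-m⁷G barely affected); the TE-down class is
enriched for m⁷G-decoded codons; and knockdown pausing rises specifically at
m⁷G codons (the 2× implanted multiplier is recovered as the codon-level
pause ratio). `m7gflow report --run run1` collects everything into one
summary table plus figures (cleavage scores, expression heatmap, class
boxplots). Every command writes a `manifest.json` with parameters, input
digests and seed.

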