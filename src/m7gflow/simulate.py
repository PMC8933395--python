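"""Synthetic data with the statistical structure the pipeline assumes.

Every generator is a pure function of (config, seed): a tRNA reference with
ABGWY motifs implanted in (and rejection-sampled out of) variable loops;
treated/untreated cleavage pileups over fragmentation background; knockdown
tRNA count matrices with multiplicative depletion of m7G isotypes; CDS sets
with a per-gene gradient of m7G-decoded codon content; mRNA libraries whose
knockdown TE loss grows with m7G codon count; and ribosome footprints with a
pause multiplier at m7G codons under knockdown.  Ground truth accompanies
every dataset so each downstream stage can be scored (site recall, depletion
recovery, TE-class confusion, pause-ratio recovery).

Noise models are the standard minimal ones: multinomial read starts,
negative-binomial counts (gamma-Poisson), Poisson codon occupancy, lognormal
abundances.  One global seed fans out into named substreams so stages can be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .errors import ConfigError
from .reference import (
    Interval,
    IUPAC,
    MotifPattern,
    TRNAGene,
    revcomp,
    scan_motif,
)
from .tracseq import EndCountProfile
from .expression import CountMatrix
from .translation import GeneModel, LibraryCounts, STOP_CODONS

import pandas as pd


@dataclass
class TracConfig:
    """Cleavage-sequencing simulation: reads and per-position rates."""

    library_reads: int = 200_000
    cleavage_rate: float = 0.15
    background_rate: float = 5e-3


@dataclass
class ExprConfig:
    """tRNA count simulation: knockdown depletion of m7G isotypes."""

    depletion_factor: float = 0.6
    dispersion: float = 0.1
    replicates: int = 2
    base_mean: float = 500.0
    mean_sigma: float = 0.7  # lognormal spread of isodecoder baselines


@dataclass
class MrnaConfig:
    """Transcriptome + mRNA library simulation."""

    n_genes: int = 2000
    min_codons: int = 100
    max_codons: int = 500
    max_propensity: float = 0.5  # per-gene m7G codon propensity ~ U(0, max)
    te_beta: float = 0.01  # log2 TE loss in knockdown per m7G codon
    te_sigma: float = 0.4  # lognormal spread of baseline TE across genes
    te_condition_sigma: float = 0.25  # per-condition biological TE noise
    abundance_sigma: float = 1.0
    library_total: int = 20_000_000
    dispersion: float = 0.05


@dataclass
class RiboConfig:
    """Ribosome footprint simulation."""

    n_genes: int = 200
    mean_counts_per_codon: float = 50.0
    pause_multiplier: float = 2.0
    footprint_lengths: tuple[int, ...] = (28, 29, 30, 31)
    a_site_offset: int = 15
    skip_start_codons: int = 5  # initiation ramp left unread


@dataclass
class SimulationConfig:
    """Master configuration; ``seed`` fixes every stream."""

    seed: int = 0
    n_isotypes: int = 50
    n_isodecoders_per_isotype: int = 2
    fraction_m7g: float = 0.4
    trna_length_range: tuple[int, int] = (74, 82)
    trac: TracConfig = field(default_factory=TracConfig)
    expr: ExprConfig = field(default_factory=ExprConfig)
    mrna: MrnaConfig = field(default_factory=MrnaConfig)
    ribo: RiboConfig = field(default_factory=RiboConfig)

    def validate(self) -> None:
        if not (0 < self.fraction_m7g < 1):
            raise ConfigError("fraction_m7g must lie strictly in (0, 1)")
        if self.n_isotypes < 2 or self.n_isotypes > 61:
            raise ConfigError("n_isotypes must be in [2, 61]")
        if self.n_isodecoders_per_isotype < 1:
            raise ConfigError("need at least one isodecoder per isotype")
        if self.trna_length_range[0] < 60:
            raise ConfigError(
                "tRNA lengths below 60 nt cannot host the fallback loop window"
            )
        for rate in (self.trac.cleavage_rate, self.trac.background_rate):
            if not (0 <= rate <= 1):
                raise ConfigError("TRAC rates must lie in [0, 1]")
        if self.expr.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.expr.depletion_factor <= 0:
            raise ConfigError("depletion_factor must be > 0")
        if self.ribo.pause_multiplier <= 0:
            raise ConfigError("pause_multiplier must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


_STREAMS = (
    "reference", "trac_treated", "trac_control", "expr",
    "transcriptome", "mrna", "ribo",
)


def stream_rng(config: SimulationConfig, name: str) -> np.random.Generator:
    """Independent, reproducible substream for one generator stage."""
    if name not in _STREAMS:
        raise ConfigError(f"unknown stream {name!r}")
    ss = np.random.SeedSequence(
        entropy=config.seed, spawn_key=(_STREAMS.index(name),)
    )
    return np.random.default_rng(ss)


@dataclass
class ReferenceTruth:
    """Simulated tRNA reference with its implanted-site ground truth."""

    genes: list[TRNAGene]
    sites: list[tuple[str, int]]  # (gene id, modified-G position)
    m7g_isotypes: set[str]

    def m7g_genes(self) -> list[TRNAGene]:
        return [g for g in self.genes if g.isotype_key in self.m7g_isotypes]


_AA3 = {codon: seq3(aa) for codon, aa in standard_dna_table.forward_table.items()}


def _sample_motif_literal(rng: np.random.Generator,
                          pattern: MotifPattern) -> str:
    return "".join(
        rng.choice(sorted(IUPAC[ch])) for ch in pattern.iupac
    )


def simulate_trna_reference(
    config: SimulationConfig,
    pattern: MotifPattern = MotifPattern(),
) -> ReferenceTruth:
    """Simulate a tRNA gene set with motif-bearing variable loops.

    Isotypes are drawn without replacement from the 61 sense anticodons; a
    ``fraction_m7g`` subset carries exactly one ABGWY instance (its anchored G
    being the true site) inside the variable loop of every isodecoder, while
    the remaining genes are rejection-sampled to be motif-free in the loop.
    The variable loop is placed at the fallback window [len-27, len-12) so
    structure-free pipelines locate it exactly.
    """
    config.validate()
    rng = stream_rng(config, "reference")
    codons = sorted(_AA3)
    chosen = list(rng.choice(codons, size=config.n_isotypes, replace=False))
    n_m7g = int(round(config.fraction_m7g * config.n_isotypes))
    if n_m7g == 0 or n_m7g == config.n_isotypes:
        raise ConfigError("fraction_m7g leaves one of the classes empty")
    m7g_codon_keys = set(chosen[:n_m7g])

    genes: list[TRNAGene] = []
    sites: list[tuple[str, int]] = []
    m7g_isotypes: set[str] = set()
    lo, hi = config.trna_length_range
    bases = np.array(list("ACGT"))
    for codon in chosen:
        aa = _AA3[codon]
        anticodon = revcomp(codon)
        is_m7g = codon in m7g_codon_keys
        if is_m7g:
            m7g_isotypes.add(f"{aa}-{anticodon}")
        for j in range(config.n_isodecoders_per_isotype):
            length = int(rng.integers(lo, hi + 1))
            loop = Interval(length - 27, length - 12)
            seq = rng.choice(bases, size=length)
            seq[34:37] = list(anticodon)
            start = g_pos = None
            if is_m7g:
                start = int(
                    rng.integers(loop.start, loop.end - pattern.modified_offset)
                )
                g_pos = start + pattern.modified_offset
            seq = _resample_loop(rng, seq, loop, pattern, start)
            gene_id = f"Syn_tRNA-{aa}-{anticodon}-{j + 1}-1"
            gene = TRNAGene(
                id=gene_id, amino_acid=aa, anticodon=anticodon,
                sequence="".join(seq), variable_loop=loop,
            )
            genes.append(gene)
            if g_pos is not None:
                sites.append((gene_id, g_pos))
    return ReferenceTruth(genes=genes, sites=sites, m7g_isotypes=m7g_isotypes)


def _resample_loop(
    rng: np.random.Generator,
    seq: np.ndarray,
    loop: Interval,
    pattern: MotifPattern,
    implant_start: int | None,
    max_tries: int = 2000,
) -> np.ndarray:
    """Redraw loop-region bases until the motif scan matches the ground truth.

    With an implant, the scan over the loop must report exactly the implanted
    G; without, it must be empty.  The redraw region extends past the loop end
    by the motif overhang so accidental boundary matches are controlled too.
    """
    k = len(pattern.iupac)
    region_end = min(len(seq), loop.end + k - 1)
    implant_pos = (
        set(range(implant_start, implant_start + k))
        if implant_start is not None else set()
    )
    free = [p for p in range(loop.start, region_end) if p not in implant_pos]
    expected = (
        [implant_start + pattern.modified_offset]
        if implant_start is not None else []
    )
    bases = np.array(list("ACGT"))
    if implant_start is not None:
        lit = _sample_motif_literal(rng, pattern)
        seq[implant_start:implant_start + k] = list(lit)
    for _ in range(max_tries):
        hits = scan_motif("".join(seq), loop, pattern)
        if hits == expected:
            return seq
        seq[free] = rng.choice(bases, size=len(free))
    raise ConfigError("could not satisfy motif constraints in variable loop")


def simulate_trac_libraries(
    reference: ReferenceTruth,
    config: SimulationConfig,
    cleavage_rate: float | None = None,
) -> tuple[dict[str, EndCountProfile], dict[str, EndCountProfile]]:
    """Simulate (treated, control) 5'-end pileup libraries.

    Read starts are multinomial over all positions of all tRNAs: the control
    library carries uniform fragmentation background, the treated library adds
    ``cleavage_rate`` weight one nucleotide 3' of each true m7G site (the
    reduction/aniline chemistry offset).  ``cleavage_rate`` may be overridden,
    e.g. to emulate a knockdown condition with reduced modification.
    """
    config.validate()
    rate = config.trac.cleavage_rate if cleavage_rate is None else cleavage_rate
    bg = config.trac.background_rate
    reads = config.trac.library_reads
    site_by_gene: dict[str, list[int]] = {}
    for gid, pos in reference.sites:
        site_by_gene.setdefault(gid, []).append(pos)

    lengths = [len(g.sequence) for g in reference.genes]
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    n_pos = offsets[-1]

    w_control = np.full(n_pos, bg)
    w_treated = w_control.copy()
    for i, gene in enumerate(reference.genes):
        for pos in site_by_gene.get(gene.id, []):
            read_pos = pos + 1
            if read_pos < lengths[i]:
                w_treated[offsets[i] + read_pos] += rate

    out = []
    for name, weights in (("trac_treated", w_treated),
                          ("trac_control", w_control)):
        rng = stream_rng(config, name)
        counts = rng.multinomial(reads, weights / weights.sum())
        lib = {
            gene.id: EndCountProfile(
                trna_id=gene.id,
                counts=counts[offsets[i]:offsets[i + 1]],
                library_size=reads,
            )
            for i, gene in enumerate(reference.genes)
        }
        out.append(lib)
    return out[0], out[1]


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws; Poisson when dispersion is 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_trna_counts(
    reference: ReferenceTruth, config: SimulationConfig
) -> CountMatrix:
    """Simulate an isodecoder count matrix with m7G-isotype knockdown depletion.

    Each isodecoder gets a lognormal baseline mean shared by both conditions;
    knockdown multiplies the means of m7G-isotype isodecoders by the
    depletion factor.  Counts are negative binomial, ``replicates`` columns
    per condition.
    """
    config.validate()
    rng = stream_rng(config, "expr")
    ec = config.expr
    n = len(reference.genes)
    base = rng.lognormal(np.log(ec.base_mean), ec.mean_sigma, size=n)
    is_m7g = np.array(
        [g.isotype_key in reference.m7g_isotypes for g in reference.genes]
    )
    kd_mean = np.where(is_m7g, base * ec.depletion_factor, base)

    data = {}
    conditions = {}
    for r in range(ec.replicates):
        col = f"control_{r + 1}"
        data[col] = _nb_counts(rng, base, ec.dispersion)
        conditions[col] = "control"
    for r in range(ec.replicates):
        col = f"KD_{r + 1}"
        data[col] = _nb_counts(rng, kd_mean, ec.dispersion)
        conditions[col] = "KD"
    df = pd.DataFrame(data, index=[g.id for g in reference.genes])
    df.index.name = "isodecoder"
    return CountMatrix(data=df, conditions=conditions)


@dataclass
class TranscriptomeTruth:
    """Simulated CDS set with per-gene m7G codon propensities and counts."""

    genes: list[GeneModel]
    propensities: np.ndarray
    m7g_counts: np.ndarray  # true per-gene m7G-decoded codon count


def simulate_transcriptome(
    config: SimulationConfig,
    m7g_codons: set[str],
    propensities: np.ndarray | None = None,
) -> TranscriptomeTruth:
    """Simulate CDSs with a controlled gradient of m7G-decoded codon content.

    Per-gene propensity (probability that a sense codon is drawn from the m7G
    set) is uniform on [0, max_propensity] unless given explicitly.  Internal
    codons are sense codons only; each CDS ends in a single terminal stop.
    """
    config.validate()
    if not m7g_codons:
        raise ConfigError("empty m7G codon set")
    rng = stream_rng(config, "transcriptome")
    mc = config.mrna
    m7g_list = sorted(set(m7g_codons) - STOP_CODONS)
    other_list = sorted(
        set(c for c in _AA3) - set(m7g_list)
    )
    if propensities is None:
        propensities = rng.uniform(0, mc.max_propensity, size=mc.n_genes)
    propensities = np.asarray(propensities, dtype=float)
    n_genes = len(propensities)

    genes: list[GeneModel] = []
    m7g_counts = np.zeros(n_genes, dtype=np.int64)
    lengths = rng.integers(mc.min_codons, mc.max_codons + 1, size=n_genes)
    for i in range(n_genes):
        n_sense = int(lengths[i]) - 1
        from_m7g = rng.random(n_sense) < propensities[i]
        picks = np.where(
            from_m7g,
            rng.choice(m7g_list, size=n_sense),
            rng.choice(other_list, size=n_sense),
        )
        m7g_counts[i] = int(from_m7g.sum())
        cds = "".join(picks) + "TAA"
        genes.append(
            GeneModel(gene_id=f"SYNG{i + 1:05d}", cds=cds)
        )
    return TranscriptomeTruth(
        genes=genes, propensities=propensities, m7g_counts=m7g_counts
    )


@dataclass
class MrnaLibraries:
    """Input and polysome libraries for both conditions, plus TE ground truth."""

    input_control: LibraryCounts
    input_kd: LibraryCounts
    polysome_control: LibraryCounts
    polysome_kd: LibraryCounts
    true_te_control: np.ndarray
    true_te_kd: np.ndarray


def simulate_mrna_libraries(
    transcriptome: TranscriptomeTruth, config: SimulationConfig
) -> MrnaLibraries:
    """Simulate input/polysome counts whose knockdown TE loss tracks codon content.

    Input abundances are lognormal and shared across conditions; polysome
    means are input times TE.  The knockdown TE is the control TE times
    ``2**(-te_beta * m7g_codon_count)``; on top sits per-condition lognormal
    biological noise (``te_condition_sigma``) and negative-binomial sampling.
    """
    config.validate()
    rng = stream_rng(config, "mrna")
    mc = config.mrna
    genes = transcriptome.genes
    n = len(genes)
    lengths_kb = np.array([g.transcript_length for g in genes]) / 1000.0
    abundance = rng.lognormal(0.0, mc.abundance_sigma, size=n)
    te_base = rng.lognormal(0.0, mc.te_sigma, size=n)
    te_control = te_base * rng.lognormal(0.0, mc.te_condition_sigma, size=n)
    te_kd = (
        te_base
        * np.exp2(-mc.te_beta * transcriptome.m7g_counts)
        * rng.lognormal(0.0, mc.te_condition_sigma, size=n)
    )

    def library(lib_id, lib_type, condition, weights):
        p = weights / weights.sum()
        counts = _nb_counts(rng, mc.library_total * p, mc.dispersion)
        total = int(counts.sum())
        return LibraryCounts(
            library_id=lib_id,
            library_type=lib_type,
            condition=condition,
            counts={g.gene_id: int(c) for g, c in zip(genes, counts)},
            library_total=max(total, 1),
        )

    w_in = abundance * lengths_kb
    return MrnaLibraries(
        input_control=library("input_control", "input_rna", "control", w_in),
        input_kd=library("input_KD", "input_rna", "KD", w_in),
        polysome_control=library(
            "polysome_control", "polysome", "control", w_in * te_control
        ),
        polysome_kd=library("polysome_KD", "polysome", "KD", w_in * te_kd),
        true_te_control=te_control,
        true_te_kd=te_kd,
    )


FootprintSet = dict[str, tuple[np.ndarray, np.ndarray]]


def simulate_footprints(
    genes: Sequence[GeneModel],
    m7g_codons: set[str],
    config: SimulationConfig,
) -> tuple[FootprintSet, FootprintSet]:
    """Simulate (control, KD) footprint records with m7G-codon pausing.

    Per-codon occupancy is Poisson with a flat mean; under knockdown the mean
    at m7G-decoded codons is multiplied by ``pause_multiplier``.  Records are
    (5' position, length) pairs consistent with the default A-site offset
    rule, so codon assignment inverts them exactly.  The first few codons
    (initiation ramp) and the terminal stop receive no footprints.
    """
    config.validate()
    rng = stream_rng(config, "ribo")
    rc = config.ribo
    lengths = np.array(rc.footprint_lengths)
    out: list[FootprintSet] = [{}, {}]
    for gene in genes:
        codons = np.array(gene.codons())
        j0 = rc.skip_start_codons
        j0 = max(j0, int(np.ceil(rc.a_site_offset / 3)))
        idx = np.arange(j0, gene.n_codons - 1)  # skip ramp and terminal stop
        is_m7g = np.isin(codons[idx], sorted(m7g_codons))
        lam = np.full(idx.size, rc.mean_counts_per_codon)
        for cond_i, mult in enumerate((1.0, rc.pause_multiplier)):
            counts = rng.poisson(np.where(is_m7g, lam * mult, lam))
            positions = np.repeat(
                gene.cds_start + 3 * idx - rc.a_site_offset, counts
            )
            read_lengths = rng.choice(lengths, size=positions.size)
            out[cond_i][gene.gene_id] = (positions, read_lengths)
    return out[0], out[1]
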