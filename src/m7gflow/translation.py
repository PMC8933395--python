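"""Translation efficiency and codon-level ribosome occupancy.

Translation efficiency (TE) is the ratio of ribosome-associated FPKM
(polysome-bound mRNA or ribosome footprints over the CDS) to input mRNA FPKM.
Knockdown-vs-control TE ratios classify genes into up/down/non (or filtered
when expression is too low to trust the ratio).  Ribosome footprints are
assigned to codons via an A-site offset rule, per-gene occupancy is mean-
normalised into pause scores, and pausing shifts are aggregated by codon type
to ask whether knockdown slows ribosomes specifically at codons decoded by
m7G-modified tRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .reference import DNA

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

SENSE_CODONS = tuple(
    sorted(
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in STOP_CODONS
    )
)

#: footprint length -> A-site offset in nt ("discard" drops the read)
DEFAULT_OFFSET_RULE: dict[int, int] = {28: 15, 29: 15, 30: 15, 31: 15}

LIBRARY_TYPES = ("input_rna", "polysome", "ribo_footprint")


@dataclass
class GeneModel:
    """One mRNA: its CDS and the transcript length used for input FPKM."""

    gene_id: str
    cds: str
    transcript_length: int | None = None
    cds_start: int = 0  # 0-based transcript coordinate of the CDS start

    def __post_init__(self) -> None:
        self.cds = self.cds.upper().replace("U", "T")
        if len(self.cds) % 3 != 0:
            raise InputError(
                f"{self.gene_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        if not set(self.cds) <= DNA:
            raise InputError(f"{self.gene_id}: non-DNA characters in CDS")
        if self.transcript_length is None:
            self.transcript_length = len(self.cds)
        if self.transcript_length < len(self.cds):
            raise InputError(
                f"{self.gene_id}: transcript shorter than its CDS"
            )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def codons(self) -> list[str]:
        return [self.cds[i : i + 3] for i in range(0, len(self.cds), 3)]


@dataclass
class LibraryCounts:
    """Per-gene counts for one sequencing library."""

    library_id: str
    library_type: str
    condition: str
    counts: dict[str, int]
    library_total: int

    def __post_init__(self) -> None:
        if self.library_type not in LIBRARY_TYPES:
            raise InputError(f"unknown library type {self.library_type!r}")
        if any(c < 0 for c in self.counts.values()):
            raise InputError(f"{self.library_id}: negative counts")
        if self.library_total <= 0:
            raise InputError(f"{self.library_id}: library_total must be > 0")
        if sum(self.counts.values()) > self.library_total:
            raise InputError(
                f"{self.library_id}: counts exceed library_total"
            )


def fpkm(count: float, length_nt: float, library_total: float) -> float:
    """Fragments per kilobase of feature per million library reads."""
    if length_nt <= 0:
        raise InputError("feature length must be > 0")
    if library_total <= 0:
        raise InputError("library total must be > 0")
    return count / ((length_nt / 1000.0) * (library_total / 1e6))


def translation_efficiency(
    fpkm_translated: float, fpkm_input: float
) -> float | None:
    """Translated-over-input FPKM ratio; None (undefined) when input is 0."""
    if fpkm_input < 0 or fpkm_translated < 0:
        raise InputError("FPKM values must be non-negative")
    if fpkm_input == 0:
        return None
    return fpkm_translated / fpkm_input


TE_CLASSES = ("up", "down", "non", "filtered")


def classify_te(
    te_control: float | None,
    te_kd: float | None,
    lfc_threshold: float = 1.0,
    min_input_fpkm: float = 1.0,
    input_fpkm_control: float | None = None,
    input_fpkm_kd: float | None = None,
) -> str:
    """Classify a gene's TE change as up / down / non / filtered.

    Filtered when either TE is undefined or zero, or when an input FPKM is
    supplied and falls below the expression floor.  Otherwise the log2 of the
    knockdown-over-control TE ratio is thresholded symmetrically.
    """
    if lfc_threshold <= 0 or min_input_fpkm <= 0:
        raise InputError("thresholds must be > 0")
    for f in (input_fpkm_control, input_fpkm_kd):
        if f is not None and f < min_input_fpkm:
            return "filtered"
    if te_control is None or te_kd is None or te_control == 0 or te_kd == 0:
        return "filtered"
    lfc = math.log2(te_kd / te_control)
    if lfc <= -lfc_threshold:
        return "down"
    if lfc >= lfc_threshold:
        return "up"
    return "non"


@dataclass
class TEResult:
    """Per-gene TE in both conditions with its classification."""

    gene_id: str
    te_control: float | None
    te_kd: float | None
    te_class: str

    @property
    def log2_ratio(self) -> float | None:
        if self.te_control and self.te_kd:
            return math.log2(self.te_kd / self.te_control)
        return None


def te_analysis(
    genes: Sequence[GeneModel],
    input_control: LibraryCounts,
    input_kd: LibraryCounts,
    translated_control: LibraryCounts,
    translated_kd: LibraryCounts,
    lfc_threshold: float = 1.0,
    min_input_fpkm: float = 1.0,
    input_length: str = "transcript",
) -> list[TEResult]:
    """Compute and classify per-gene TE changes from four count libraries.

    The translated libraries may be polysome-bound mRNA or ribosome
    footprints; footprint FPKM always uses the CDS length, while the input
    mRNA FPKM uses the transcript length by default (``input_length="cds"``
    switches it).
    """
    if translated_control.library_type == "input_rna":
        raise InputError("translated library has type input_rna")
    if input_length not in ("transcript", "cds"):
        raise InputError(f"unknown input_length {input_length!r}")
    results = []
    for gene in genes:
        in_len = (
            gene.transcript_length if input_length == "transcript"
            else len(gene.cds)
        )
        tr_len = (
            len(gene.cds)
            if translated_control.library_type == "ribo_footprint"
            else gene.transcript_length
        )
        fin_c = fpkm(input_control.counts.get(gene.gene_id, 0), in_len,
                     input_control.library_total)
        fin_k = fpkm(input_kd.counts.get(gene.gene_id, 0), in_len,
                     input_kd.library_total)
        ftr_c = fpkm(translated_control.counts.get(gene.gene_id, 0), tr_len,
                     translated_control.library_total)
        ftr_k = fpkm(translated_kd.counts.get(gene.gene_id, 0), tr_len,
                     translated_kd.library_total)
        te_c = translation_efficiency(ftr_c, fin_c)
        te_k = translation_efficiency(ftr_k, fin_k)
        cls = classify_te(
            te_c, te_k, lfc_threshold, min_input_fpkm,
            input_fpkm_control=fin_c, input_fpkm_kd=fin_k,
        )
        results.append(TEResult(gene.gene_id, te_c, te_k, cls))
    return results


def te_results_frame(results: Sequence[TEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.te_control, r.te_kd, r.log2_ratio, r.te_class)
            for r in results
        ],
        columns=["gene_id", "te_control", "te_kd", "log2_ratio", "te_class"],
    )


@dataclass
class CodonOccupancy:
    """Per-codon footprint counts over one gene's CDS in one condition."""

    gene_id: str
    condition: str
    counts: np.ndarray
    discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise InputError(f"{self.gene_id}: negative occupancy")


def assign_codon_occupancy(
    footprints: Iterable[tuple[int, int]],
    gene: GeneModel,
    offset_rule: Mapping[int, int] = DEFAULT_OFFSET_RULE,
    condition: str = "",
) -> CodonOccupancy:
    """Map footprints (5' transcript position, length) onto CDS codons.

    The A-site nucleotide is the 5' end plus the length-specific offset;
    footprints with lengths absent from the rule, or whose A-site lands
    outside the CDS, are discarded and tallied.  ``footprints`` may be an
    iterable of (position, length) pairs or a pair of parallel arrays.
    """
    if (
        isinstance(footprints, tuple)
        and len(footprints) == 2
        and isinstance(footprints[0], np.ndarray)
    ):
        positions = np.asarray(footprints[0], dtype=np.int64)
        lengths = np.asarray(footprints[1], dtype=np.int64)
    else:
        arr = np.array(list(footprints), dtype=np.int64).reshape(-1, 2)
        positions, lengths = arr[:, 0], arr[:, 1]
    if positions.size and positions.min() < 0:
        raise InputError(f"{gene.gene_id}: negative footprint position")

    max_len = max(list(offset_rule) + [0]) + 1
    offset_lut = np.full(max_len, -1, dtype=np.int64)
    for ln, off in offset_rule.items():
        offset_lut[ln] = off
    known = (lengths < max_len) & (offset_lut[np.minimum(lengths, max_len - 1)] >= 0)
    a_sites = positions[known] + offset_lut[lengths[known]]
    cds_end = gene.cds_start + len(gene.cds)
    in_cds = (a_sites >= gene.cds_start) & (a_sites < cds_end)
    codon_idx = (a_sites[in_cds] - gene.cds_start) // 3
    counts = np.bincount(codon_idx, minlength=gene.n_codons)
    discarded = int(positions.size - in_cds.sum())
    return CodonOccupancy(gene.gene_id, condition, counts, discarded)


def pause_scores(
    occ: CodonOccupancy, min_mean: float = 0.5
) -> np.ndarray | None:
    """Within-gene mean-normalised occupancy; None when coverage is too low.

    Included genes have score mean exactly 1, so pause scores are comparable
    across genes regardless of expression level.
    """
    if occ.counts.size == 0:
        raise InputError(f"{occ.gene_id}: empty occupancy vector")
    mean = occ.counts.mean()
    if mean < min_mean:
        return None
    return occ.counts / mean


@dataclass
class PauseShiftReport:
    """Codon-type pausing shift between conditions with an m7G class test."""

    per_codon: pd.DataFrame  # codon, is_m7g, n, mean_control, mean_kd, delta
    u_statistic: float
    p_value: float
    median_delta_m7g: float
    median_delta_other: float
    mean_ratio_m7g: float  # mean over m7G codon types of KD/control pause
    mean_ratio_other: float  # same over non-m7G sense codon types
    pause_multiplier_estimate: float
    n_genes_included: int
    n_genes_excluded: int


def m7g_pause_shift(
    occ_control: Mapping[str, CodonOccupancy],
    occ_kd: Mapping[str, CodonOccupancy],
    genes: Sequence[GeneModel],
    m7g_codons: set[str],
    min_mean: float = 0.5,
    aggregate: str = "mean",
) -> PauseShiftReport:
    """Compare per-codon-type pause scores between control and knockdown.

    For each of the 61 sense codon types, pause scores from every included
    gene's codon positions of that type are aggregated (mean by default,
    median via ``aggregate="median"``) within each condition; the per-type
    delta is knockdown minus control.  The summary statistic is a two-sided
    Mann-Whitney U test of the deltas of m7G-decoded codon types against all
    other sense codon types.  Stop codons are excluded.  Genes must have
    occupancy in both conditions and clear the coverage floor in both to be
    included.
    """
    if not m7g_codons:
        raise InputError("empty m7G codon set")
    if aggregate not in ("mean", "median"):
        raise InputError(f"unknown aggregate {aggregate!r}")

    pooled: dict[str, tuple[list[np.ndarray], list[np.ndarray]]] = {
        c: ([], []) for c in SENSE_CODONS
    }
    # Within-gene double ratios (m7G vs other, KD vs control): the per-gene
    # mean-normalisation factor cancels exactly, giving an unbiased estimate
    # of the underlying occupancy multiplier at m7G codons.
    gene_ratios: list[float] = []
    n_inc = n_exc = 0
    for gene in genes:
        oc = occ_control.get(gene.gene_id)
        ok = occ_kd.get(gene.gene_id)
        if oc is None or ok is None:
            n_exc += 1
            continue
        if len(oc.counts) != gene.n_codons or len(ok.counts) != gene.n_codons:
            raise InputError(
                f"{gene.gene_id}: occupancy length does not match CDS"
            )
        sc = pause_scores(oc, min_mean)
        sk = pause_scores(ok, min_mean)
        if sc is None or sk is None:
            n_exc += 1
            continue
        n_inc += 1
        codons = np.array(gene.codons())
        for codon in np.unique(codons):
            if codon in STOP_CODONS:
                continue
            mask = codons == codon
            pooled[codon][0].append(sc[mask])
            pooled[codon][1].append(sk[mask])
        sense = ~np.isin(codons, sorted(STOP_CODONS))
        m7g_mask = np.isin(codons, sorted(m7g_codons)) & sense
        other_mask = sense & ~m7g_mask
        if m7g_mask.any() and other_mask.any():
            num_c, num_k = sc[m7g_mask].mean(), sk[m7g_mask].mean()
            den_c, den_k = sc[other_mask].mean(), sk[other_mask].mean()
            if num_c > 0 and den_c > 0 and den_k > 0:
                gene_ratios.append((num_k / num_c) / (den_k / den_c))

    agg = np.mean if aggregate == "mean" else np.median
    rows = []
    for codon in SENSE_CODONS:
        ctrl_parts, kd_parts = pooled[codon]
        if not ctrl_parts:
            continue
        ctrl = np.concatenate(ctrl_parts)
        kd = np.concatenate(kd_parts)
        rows.append(
            (codon, codon in m7g_codons, len(ctrl),
             float(agg(ctrl)), float(agg(kd)))
        )
    per_codon = pd.DataFrame(
        rows, columns=["codon", "is_m7g", "n", "mean_control", "mean_kd"]
    )
    per_codon["delta"] = per_codon["mean_kd"] - per_codon["mean_control"]

    from .expression import mann_whitney_u

    d_m7g = per_codon.loc[per_codon["is_m7g"], "delta"].to_numpy()
    d_other = per_codon.loc[~per_codon["is_m7g"], "delta"].to_numpy()
    if d_m7g.size == 0 or d_other.size == 0:
        raise InputError("need both m7G and non-m7G codon types with data")
    u, p = mann_whitney_u(d_m7g, d_other)

    m7g_rows = per_codon[per_codon["is_m7g"]]
    other_rows = per_codon[~per_codon["is_m7g"]]
    ratio_m7g = float((m7g_rows["mean_kd"] / m7g_rows["mean_control"]).mean())
    ratio_other = float(
        (other_rows["mean_kd"] / other_rows["mean_control"]).mean()
    )
    return PauseShiftReport(
        per_codon=per_codon,
        u_statistic=u,
        p_value=p,
        median_delta_m7g=float(np.median(d_m7g)),
        median_delta_other=float(np.median(d_other)),
        mean_ratio_m7g=ratio_m7g,
        mean_ratio_other=ratio_other,
        pause_multiplier_estimate=(
            float(np.mean(gene_ratios)) if gene_ratios else float("nan")
        ),
        n_genes_included=n_inc,
        n_genes_excluded=n_exc,
    )
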