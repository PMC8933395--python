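"""m7G-tRNA-decoded codon counts per mRNA and their class comparisons.

If knockdown of the m7G methyltransferase starves translation specifically of
m7G-modified tRNAs, mRNAs rich in codons decoded by those tRNAs should be
over-represented among TE-down genes.  This module counts m7G-decoded codons
over each CDS (frame 0, stop codons never counted), compares counts between
TE classes, and compares counts of a gene set's members (restricted to
TE-down genes) against all other detected mRNAs.  Raw counts are the primary
statistic; codon density (count over CDS codons) is reported alongside
because CDS length is a real confounder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .expression import mann_whitney_u
from .translation import GeneModel, STOP_CODONS, TEResult


@dataclass(frozen=True)
class CodonCountRecord:
    """Per-gene m7G-decoded codon count and density."""

    gene_id: str
    m7g_codon_count: int
    cds_codons: int

    @property
    def density(self) -> float:
        return self.m7g_codon_count / self.cds_codons


@dataclass(frozen=True)
class GeneSet:
    """Named gene set (e.g. one GMT line)."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise InputError(f"gene set {self.name!r} is empty")


def count_m7g_codons(gene: GeneModel, m7g_codons: set[str]) -> CodonCountRecord:
    """Count frame-0 CDS codons belonging to the m7G-decoded set."""
    if not m7g_codons:
        raise InputError("empty m7G codon set")
    effective = set(m7g_codons) - STOP_CODONS
    codons = gene.codons()
    count = sum(1 for c in codons if c in effective)
    return CodonCountRecord(gene.gene_id, count, len(codons))


@dataclass
class PairwiseTestReport:
    """Mann-Whitney comparisons of codon counts between TE classes."""

    comparisons: pd.DataFrame  # class_a, class_b, u, p, and the same for density
    class_summary: pd.DataFrame  # te_class, n, median_count, median_density


def compare_counts_by_te_class(
    records: Sequence[CodonCountRecord],
    te_results: Sequence[TEResult],
    pairs: Sequence[tuple[str, str]] = (
        ("down", "non"), ("up", "non"), ("down", "up"),
    ),
) -> PairwiseTestReport:
    """Compare m7G codon counts between TE classes pairwise.

    Each requested pair is tested two-sided on raw counts and, alongside, on
    codon density.  Every record's gene must carry a TE class; each class in
    a requested pair must be non-empty.
    """
    cls_by_gene = {r.gene_id: r.te_class for r in te_results}
    missing = [r.gene_id for r in records if r.gene_id not in cls_by_gene]
    if missing:
        raise InputError(f"records without a TE class: {missing[:5]}")

    by_class: dict[str, list[CodonCountRecord]] = {}
    for rec in records:
        by_class.setdefault(cls_by_gene[rec.gene_id], []).append(rec)

    summary_rows = [
        (cls, len(recs),
         float(np.median([r.m7g_codon_count for r in recs])),
         float(np.median([r.density for r in recs])))
        for cls, recs in sorted(by_class.items())
    ]
    comp_rows = []
    for cls_a, cls_b in pairs:
        for cls in (cls_a, cls_b):
            if not by_class.get(cls):
                raise InputError(f"TE class {cls!r} is empty")
        ca = np.array([r.m7g_codon_count for r in by_class[cls_a]])
        cb = np.array([r.m7g_codon_count for r in by_class[cls_b]])
        da = np.array([r.density for r in by_class[cls_a]])
        db = np.array([r.density for r in by_class[cls_b]])
        u_c, p_c = mann_whitney_u(ca, cb)
        u_d, p_d = mann_whitney_u(da, db)
        comp_rows.append(
            (cls_a, cls_b, len(ca), len(cb),
             float(np.median(ca)), float(np.median(cb)), u_c, p_c,
             u_d, p_d)
        )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["class_a", "class_b", "n_a", "n_b", "median_a", "median_b",
                 "u_count", "p_count", "u_density", "p_density"],
    )
    class_summary = pd.DataFrame(
        summary_rows,
        columns=["te_class", "n", "median_count", "median_density"],
    )
    return PairwiseTestReport(comparisons=comparisons,
                              class_summary=class_summary)


@dataclass
class GeneSetComparisonReport:
    """Gene-set members (within TE-down genes) vs all other detected mRNAs."""

    geneset_name: str
    n_members: int
    n_others: int
    median_members: float
    median_others: float
    u_statistic: float
    p_value: float


def geneset_codon_comparison(
    records: Sequence[CodonCountRecord],
    te_down_genes: Iterable[str],
    geneset: GeneSet,
    universe: Iterable[str] | None = None,
) -> GeneSetComparisonReport:
    """Compare codon counts of TE-down gene-set members vs other mRNAs.

    Members are the gene set intersected with the TE-down genes; the
    comparison group is every other gene of the universe (default: all genes
    with a codon-count record).  Both groups must be non-empty.
    """
    by_gene = {r.gene_id: r for r in records}
    universe_set = set(universe) if universe is not None else set(by_gene)
    universe_set &= set(by_gene)
    down = set(te_down_genes)
    members = geneset.members & down & universe_set
    others = universe_set - members
    if not members:
        raise InputError(
            f"gene set {geneset.name!r} has no TE-down members in the universe"
        )
    if not others:
        raise InputError("comparison group is empty (gene set covers universe)")
    cm = np.array([by_gene[g].m7g_codon_count for g in sorted(members)])
    co = np.array([by_gene[g].m7g_codon_count for g in sorted(others)])
    u, p = mann_whitney_u(cm, co)
    return GeneSetComparisonReport(
        geneset_name=geneset.name,
        n_members=len(cm),
        n_others=len(co),
        median_members=float(np.median(cm)),
        median_others=float(np.median(co)),
        u_statistic=u,
        p_value=p,
    )
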