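"""Cleavage-score computation and m7G site calling from 5'-end pileups.

Chemical reduction (NaBH4) followed by aniline treatment cleaves tRNAs at m7G,
so in the treated library new read 5' ends accumulate one nucleotide 3' of the
modified G; the untreated library carries only fragmentation background.  The
cleavage score at a position is the log2 ratio of pseudocounted 5'-end
read-start frequencies, treated over untreated.  A site is called m7G when it
sits at the anchored G of a variable-loop ABGWY motif, its score clears the
threshold and the treated coverage clears the minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InputError
from .reference import Interval, MotifPattern, TRNAGene, scan_motif


@dataclass
class EndCountProfile:
    """Per-position 5'-end read-start counts for one tRNA in one library.

    ``library_size`` is the total number of read starts in the library across
    all tRNAs, the denominator for start frequencies.
    """

    trna_id: str
    counts: np.ndarray
    library_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise InputError(f"{self.trna_id}: negative counts")
        if self.library_size <= 0:
            raise InputError(f"{self.trna_id}: library_size must be positive")
        if int(self.counts.sum()) > self.library_size:
            raise InputError(
                f"{self.trna_id}: profile counts exceed library_size"
            )


@dataclass(frozen=True)
class CleavageCall:
    """One scored candidate position on one tRNA.

    ``position`` is the 0-based coordinate of the candidate modified G;
    ``score`` is in log2 units at the cleavage read-start position (G +
    chemistry offset); ``coverage`` is the treated read-start count there.
    ``called`` requires ``motif_ok`` plus the score and coverage gates.
    """

    trna_id: str
    position: int
    score: float
    coverage: int
    motif_ok: bool
    called: bool


def position_frequency(
    profile: EndCountProfile, position: int, pseudocount: float = 0.0
) -> float:
    """Pseudocounted read-start frequency at one position.

    ``(count + pc) / (library_size + pc * len(counts))``; lies in [0, 1] for
    pseudocount 0.
    """
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    if not (0 <= position < len(profile.counts)):
        raise InputError(
            f"{profile.trna_id}: position {position} out of bounds"
        )
    denom = profile.library_size + pseudocount * len(profile.counts)
    if denom == 0:
        raise DegenerateInputError("zero library size with zero pseudocount")
    return (float(profile.counts[position]) + pseudocount) / denom


def cleavage_score(
    treated: EndCountProfile,
    control: EndCountProfile,
    position: int,
    pseudocount: float = 0.5,
) -> float:
    """log2 of treated over untreated start frequency at one position.

    Antisymmetric under swapping the two libraries (shared pseudocount).
    """
    if len(treated.counts) != len(control.counts):
        raise InputError(
            f"{treated.trna_id}: treated/control profile length mismatch"
        )
    ft = position_frequency(treated, position, pseudocount)
    fc = position_frequency(control, position, pseudocount)
    return math.log2(ft / fc)


@dataclass
class SiteCallResult:
    """Calls plus bookkeeping from one site-calling run."""

    calls: list[CleavageCall]
    uncovered: list[str]
    params: dict

    def called_sites(self) -> list[CleavageCall]:
        return [c for c in self.calls if c.called]

    def m7g_trna_ids(self) -> set[str]:
        """tRNA genes (isodecoders) with at least one called site."""
        return {c.trna_id for c in self.calls if c.called}

    def m7g_isotypes(self, genes: Iterable[TRNAGene]) -> set[str]:
        """Isotype keys (amino acid + anticodon) with at least one called site."""
        by_id = {g.id: g for g in genes}
        return {
            by_id[c.trna_id].isotype_key
            for c in self.calls
            if c.called and c.trna_id in by_id
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (c.trna_id, c.position, c.position + 1, c.score, c.coverage,
                 c.motif_ok, c.called)
                for c in self.calls
            ],
            columns=["trna_id", "start", "end", "score", "coverage",
                     "motif_ok", "called"],
        )


def call_m7g_sites(
    treated_lib: Mapping[str, EndCountProfile],
    control_lib: Mapping[str, EndCountProfile],
    genes: Sequence[TRNAGene],
    pattern: MotifPattern = MotifPattern(),
    min_score: float = 1.0,
    min_coverage: int = 10,
    pseudocount: float = 0.5,
    cleavage_offset: int = 1,
) -> SiteCallResult:
    """Score variable-loop positions and call m7G sites gated by the motif.

    Candidate m7G positions are the motif's anchored-G hits inside each gene's
    variable loop; scoring and coverage are read at the cleavage read-start
    position (G + ``cleavage_offset``, default +1 for the reduction/aniline
    chemistry).  Every variable-loop position is scored so that high-scoring
    non-motif positions surface with ``motif_ok=False``; only motif positions
    passing both gates are ``called``.  Genes lacking a profile in either
    library are reported in ``uncovered``; profiles without a gene are an
    error.
    """
    by_id = {g.id: g for g in genes}
    for lib_name, lib in (("treated", treated_lib), ("control", control_lib)):
        orphans = sorted(set(lib) - set(by_id))
        if orphans:
            raise InputError(
                f"{lib_name} profiles without reference gene: {orphans}"
            )

    calls: list[CleavageCall] = []
    uncovered: list[str] = []
    for gene in genes:
        if gene.flag is not None:
            continue
        t = treated_lib.get(gene.id)
        c = control_lib.get(gene.id)
        if t is None or c is None:
            uncovered.append(gene.id)
            continue
        if gene.variable_loop is None:
            raise InputError(f"{gene.id}: variable loop not located")
        loop = gene.variable_loop
        motif_hits = set(scan_motif(gene.sequence, loop, pattern))
        for pos in range(loop.start, loop.end):
            read_pos = pos + cleavage_offset
            if not (0 <= read_pos < len(t.counts)):
                continue
            score = cleavage_score(t, c, read_pos, pseudocount)
            coverage = int(t.counts[read_pos])
            motif_ok = pos in motif_hits
            passed = score >= min_score and coverage >= min_coverage
            if not (motif_ok or passed):
                continue
            calls.append(
                CleavageCall(
                    trna_id=gene.id,
                    position=pos,
                    score=score,
                    coverage=coverage,
                    motif_ok=motif_ok,
                    called=motif_ok and passed,
                )
            )
    params = {
        "pattern": pattern.iupac,
        "modified_offset": pattern.modified_offset,
        "min_score": min_score,
        "min_coverage": min_coverage,
        "pseudocount": pseudocount,
        "cleavage_offset": cleavage_offset,
    }
    return SiteCallResult(calls=calls, uncovered=uncovered, params=params)


@dataclass
class LevelChangeReport:
    """Per-site score differences between two conditions plus a group test."""

    per_site: pd.DataFrame  # trna_id, position, score_a, score_b, delta
    unpaired_a: list[tuple[str, int]]
    unpaired_b: list[tuple[str, int]]
    per_trna: pd.DataFrame  # trna_id, n_sites, mean_delta, median_delta
    u_statistic: float
    p_value: float
    median_delta: float


def m7g_level_change(
    calls_a: Sequence[CleavageCall], calls_b: Sequence[CleavageCall]
) -> LevelChangeReport:
    """Compare cleavage scores between two conditions at shared sites.

    Sites are paired by (trna_id, position); the per-site delta is
    ``score_b - score_a`` (condition B minus A, e.g. knockdown minus control).
    The group-level comparison is a two-sided Mann-Whitney U test of the
    per-site scores in A vs B.  Sites present in only one condition are
    reported unpaired.  Both call sets must come from identically
    parameterised runs.
    """
    from .expression import mann_whitney_u

    a_map = {(c.trna_id, c.position): c for c in calls_a}
    b_map = {(c.trna_id, c.position): c for c in calls_b}
    shared = sorted(set(a_map) & set(b_map))
    if not shared:
        raise DegenerateInputError("no sites shared between the two conditions")
    rows = [
        (tid, pos, a_map[(tid, pos)].score, b_map[(tid, pos)].score,
         b_map[(tid, pos)].score - a_map[(tid, pos)].score)
        for tid, pos in shared
    ]
    per_site = pd.DataFrame(
        rows, columns=["trna_id", "position", "score_a", "score_b", "delta"]
    )
    per_trna = (
        per_site.groupby("trna_id")["delta"]
        .agg(n_sites="count", mean_delta="mean", median_delta="median")
        .reset_index()
    )
    u, p = mann_whitney_u(
        per_site["score_a"].to_numpy(), per_site["score_b"].to_numpy()
    )
    return LevelChangeReport(
        per_site=per_site,
        unpaired_a=sorted(set(a_map) - set(b_map)),
        unpaired_b=sorted(set(b_map) - set(a_map)),
        per_trna=per_trna,
        u_statistic=u,
        p_value=p,
        median_delta=float(per_site["delta"].median()),
    )
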