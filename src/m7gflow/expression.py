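"""tRNA expression statistics: isotype aggregation, normalization, group tests.

The comparison of interest is whether methyltransferase knockdown depresses
the expression of m7G-modified tRNA types while leaving non-m7G types alone.
Counts are aggregated from isodecoders to isotypes (amino acid + anticodon),
depth-normalised (CPM), expressed as log2 relative to each isotype's overall
mean across every sample of both groups, and the per-isotype knockdown-minus-
control shifts of the two classes are compared with a Mann-Whitney U test.

The Mann-Whitney implementation here is the package's own: exact p by
enumeration for small tie-free samples, normal approximation with tie and
continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .errors import DegenerateInputError, EmptyInputError, InputError
from .reference import TRNAGene


@dataclass
class CountMatrix:
    """Row-by-sample matrix with a condition label per sample column.

    Raw and depth-normalised counts must be non-negative; matrices holding
    log-transformed values set ``allow_negative``.
    """

    data: pd.DataFrame
    conditions: dict[str, str]
    allow_negative: bool = False

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise InputError(f"duplicate row ids: {dupes}")
        if self.data.columns.duplicated().any():
            raise InputError("duplicate sample ids")
        missing = [c for c in self.data.columns if c not in self.conditions]
        if missing:
            raise InputError(f"samples without condition label: {missing}")
        if not self.allow_negative and (self.data.to_numpy() < 0).any():
            raise InputError("negative counts")

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.data.columns if self.conditions[s] == condition]


def aggregate_isotypes(
    matrix: CountMatrix, genes: Sequence[TRNAGene]
) -> CountMatrix:
    """Sum isodecoder rows into isotype rows; column sums are preserved."""
    key_by_id = {g.id: g.isotype_key for g in genes if g.flag is None}
    unmapped = [rid for rid in matrix.data.index if rid not in key_by_id]
    if unmapped:
        raise InputError(f"rows without a reference isotype: {unmapped}")
    grouped = matrix.data.groupby(
        [key_by_id[rid] for rid in matrix.data.index]
    ).sum()
    grouped.index.name = "isotype"
    return CountMatrix(data=grouped, conditions=dict(matrix.conditions))


def cpm_normalize(matrix: CountMatrix) -> CountMatrix:
    """Counts-per-million depth normalization; every column sums to 1e6."""
    sums = matrix.data.sum(axis=0)
    zero = sums[sums == 0].index.tolist()
    if zero:
        raise DegenerateInputError(f"all-zero sample columns: {zero}")
    cpm = matrix.data / sums * 1e6
    return CountMatrix(data=cpm, conditions=dict(matrix.conditions))


def log2_relative_to_mean(
    values: np.ndarray | Sequence[float], floor: float | str | None = "auto"
) -> np.ndarray:
    """log2 of each value relative to the vector's mean.

    This is the per-isotype transform applied across all samples of both
    groups before plotting or testing.  Zero entries would map to -inf, so a
    configurable floor is applied first: ``"auto"`` (default) uses half the
    smallest nonzero value, a number is used as given, ``None`` disables
    flooring.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise EmptyInputError("empty value vector")
    if (v < 0).any():
        raise InputError("negative values")
    mean = v.mean()
    if mean == 0:
        raise DegenerateInputError("zero mean")
    if floor == "auto":
        nonzero = v[v > 0]
        floor_val = nonzero.min() / 2
    elif floor is None:
        floor_val = None
    else:
        floor_val = float(floor)
    if floor_val is not None:
        v = np.maximum(v, floor_val)
    return np.log2(v / mean)


def _u_null_distribution(n: int, m: int) -> np.ndarray:
    """Exact tie-free null counts of U over 0..n*m.

    Standard recurrence N(u; n, m) = N(u - m; n - 1, m) + N(u; n, m - 1):
    the largest a-observation either exceeds all m b's (contributing m to U)
    or is the overall maximum of the remaining pool.
    """
    prev = [np.ones(1) for _ in range(m + 1)]  # zero a-observations: U = 0
    for i in range(1, n + 1):
        cur: list[np.ndarray] = [np.ones(1)]  # zero b-observations: U = 0
        for j in range(1, m + 1):
            arr = np.zeros(i * j + 1)
            arr[j : j + len(prev[j])] += prev[j]
            arr[: len(cur[j - 1])] += cur[j - 1]
            cur.append(arr)
        prev = cur
    return prev[m]


def _exact_mwu_p(n: int, m: int, u: float) -> float:
    """Two-sided exact p from the tie-free null distribution of U."""
    dist = _u_null_distribution(n, m)
    total = dist.sum()
    k = int(round(u))
    p_le = dist[: k + 1].sum() / total
    p_ge = dist[k:].sum() / total
    return float(min(1.0, 2 * min(p_le, p_ge)))


def mann_whitney_u(
    a: Sequence[float] | np.ndarray,
    b: Sequence[float] | np.ndarray,
    alternative: str = "two-sided",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U, p) with U counted for sample ``a``.

    U = #{(i, j): a_i > b_j} + half the number of ties.  The p-value is exact
    (full enumeration of labelings) when min(n, m) <= ``exact_max_n`` and
    there are no ties across the pooled sample; otherwise the normal
    approximation with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise InputError(f"unknown alternative {alternative!r}")

    n, m = len(a), len(b)
    gt = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    u = float(gt) + 0.5 * float(ties)

    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)

    if alternative == "two-sided" and not has_ties and min(n, m) <= exact_max_n:
        return u, _exact_mwu_p(n, m, u)

    mu = n * m / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    total = n + m
    sigma2 = n * m / 12.0 * (total + 1 - tie_term / (total * (total - 1)))
    if sigma2 <= 0:
        return u, 1.0  # all values identical; no evidence either way
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = (abs(u - mu) - 0.5) / sigma
        p = 2 * (1 - ndtr(max(z, 0.0)))
    elif alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = 1 - ndtr(z)
    else:
        z = (u - mu + 0.5) / sigma
        p = float(ndtr(z))
    return u, float(min(max(p, np.nextafter(0, 1)), 1.0))


def normalize_expression(
    matrix: CountMatrix,
    genes: Sequence[TRNAGene] | None = None,
    floor: float | str | None = "auto",
) -> CountMatrix:
    """Full normalisation chain for isotype expression comparison.

    Optionally aggregates isodecoder counts to isotypes, depth-normalises
    (CPM), then expresses each isotype log2-relative to its own mean across
    every sample of both groups.
    """
    if genes is not None:
        matrix = aggregate_isotypes(matrix, genes)
    cpm = cpm_normalize(matrix)
    logged = cpm.data.apply(
        lambda row: pd.Series(
            log2_relative_to_mean(row.to_numpy(), floor=floor),
            index=row.index,
        ),
        axis=1,
    )
    return CountMatrix(
        data=logged, conditions=dict(matrix.conditions), allow_negative=True
    )


@dataclass
class ClassComparisonReport:
    """Mann-Whitney comparison of per-isotype expression shifts by m7G class."""

    per_isotype: pd.DataFrame  # isotype, is_m7g, mean per condition, delta
    u_statistic: float
    p_value: float
    median_delta_m7g: float
    median_delta_non: float
    n_m7g: int
    n_non: int

    @property
    def direction(self) -> str:
        if self.median_delta_m7g < self.median_delta_non:
            return "m7g_down"
        if self.median_delta_m7g > self.median_delta_non:
            return "m7g_up"
        return "none"


def compare_m7g_vs_non(
    normalized: CountMatrix,
    m7g_membership: Mapping[str, bool],
    condition_pair: tuple[str, str] = ("control", "KD"),
    average_replicates: bool = True,
) -> ClassComparisonReport:
    """Test whether m7G-class isotypes shift differently from non-m7G ones.

    ``normalized`` holds log2-relative expression (rows = isotypes); for each
    isotype the knockdown-minus-control difference of replicate means is
    computed, and the two classes' difference distributions are compared with
    a two-sided Mann-Whitney U test.  With ``average_replicates=False`` the
    per-replicate pairwise differences enter the test instead of their means.
    """
    missing = [r for r in normalized.data.index if r not in m7g_membership]
    if missing:
        raise InputError(f"isotypes without m7G membership: {missing}")
    ref_cond, kd_cond = condition_pair
    ref_samples = normalized.samples_for(ref_cond)
    kd_samples = normalized.samples_for(kd_cond)
    if not ref_samples or not kd_samples:
        raise InputError(f"missing samples for condition pair {condition_pair}")

    ref_mean = normalized.data[ref_samples].mean(axis=1)
    kd_mean = normalized.data[kd_samples].mean(axis=1)
    delta = kd_mean - ref_mean
    is_m7g = pd.Series(
        [bool(m7g_membership[r]) for r in normalized.data.index],
        index=normalized.data.index,
    )
    if is_m7g.all() or not is_m7g.any():
        raise InputError("both m7G and non-m7G classes must be non-empty")

    per_isotype = pd.DataFrame(
        {
            "is_m7g": is_m7g,
            f"mean_{ref_cond}": ref_mean,
            f"mean_{kd_cond}": kd_mean,
            "delta": delta,
        }
    )
    if average_replicates:
        d_m7g = delta[is_m7g].to_numpy()
        d_non = delta[~is_m7g].to_numpy()
    else:
        diffs = {
            r: [
                normalized.data.loc[r, k] - normalized.data.loc[r, c]
                for k in kd_samples
                for c in ref_samples
            ]
            for r in normalized.data.index
        }
        d_m7g = np.concatenate([diffs[r] for r in delta.index[is_m7g]])
        d_non = np.concatenate([diffs[r] for r in delta.index[~is_m7g]])

    u, p = mann_whitney_u(d_m7g, d_non)
    return ClassComparisonReport(
        per_isotype=per_isotype,
        u_statistic=u,
        p_value=p,
        median_delta_m7g=float(np.median(d_m7g)),
        median_delta_non=float(np.median(d_non)),
        n_m7g=int(is_m7g.sum()),
        n_non=int((~is_m7g).sum()),
    )


def lcms_m7g_level(
    table: Mapping[str, float], m7g_key: str = "m7G"
) -> float:
    """m7G fraction of total nucleoside signal from an LC-MS peak table.

    Ratio of the m7G normalized peak area to the sum of normalized peak areas
    over all detected nucleosides; 0.0 when m7G was not detected.
    """
    if not table:
        raise EmptyInputError("empty nucleoside peak table")
    if any(v < 0 for v in table.values()):
        raise InputError("negative peak area")
    total = float(sum(table.values()))
    if total == 0:
        raise DegenerateInputError("zero total peak area")
    return float(table.get(m7g_key, 0.0)) / total
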