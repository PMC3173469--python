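"""T-RFLP profile processing and community statistics.

Terminal restriction fragments are predicted from the 5'-labeled strand
(AluI AG^CT, HhaI GCG^C).  Empirical profiles are filtered to fragments
between 50 bp and the product length with peak area > 500, normalized to
relative abundance, and compared by Bray-Curtis dissimilarity, rank-based
ANOSIM with permutation p-values, and correspondence analysis.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._common import ConfigurationError, InputError
from .otu_cluster import DistanceMatrix

#: recognition sequence and cut offset on the labeled (forward) strand
ENZYMES = {
    "AluI": ("AGCT", 2),
    "HhaI": ("GCGC", 3),
}


@dataclass
class TrflpProfile:
    """Per-sample fragment-size -> peak-area map for one enzyme."""

    sample: str
    enzyme: str
    peaks: dict[float, float] = field(default_factory=dict)
    amplicon_len: int = 0


def insilico_digest(amplicon_nt: str, enzymes: Sequence[str] = ("AluI", "HhaI")
                    ) -> dict[str, int]:
    """Terminal fragment length per enzyme for a 5'-labeled amplicon.

    The TRF is the distance from the labeled 5' end to the first cut on
    the labeled strand; with no recognition site the full amplicon length
    is returned.
    """
    seq = amplicon_nt.upper()
    out = {}
    for name in enzymes:
        if name not in ENZYMES:
            raise ConfigurationError(f"unknown enzyme {name!r}")
        site, offset = ENZYMES[name]
        pos = seq.find(site)
        out[name] = len(seq) if pos < 0 else pos + offset
    return out


def filter_normalize(profile: TrflpProfile, min_size: float = 50.0,
                     min_area: float = 500.0) -> pd.Series:
    """Apply the size window and area threshold, then normalize.

    Peaks with size < `min_size`, size > product length, or area <=
    `min_area` (strict) are dropped; survivors are divided by their total
    area.  When nothing survives, a flagged all-zero row is returned.
    """
    if profile.amplicon_len <= 0:
        raise InputError(f"profile {profile.sample}: unknown amplicon length")
    kept = {size: area for size, area in profile.peaks.items()
            if min_size <= size <= profile.amplicon_len and area > min_area}
    if not kept:
        warnings.warn(f"sample {profile.sample}: all peaks filtered out",
                      stacklevel=2)
        return pd.Series(dtype=float, name=profile.sample)
    total = sum(kept.values())
    return pd.Series({size: area / total for size, area in sorted(kept.items())},
                     name=profile.sample)


def profiles_to_matrix(profiles: Sequence[TrflpProfile], min_size: float = 50.0,
                       min_area: float = 500.0, bin_tolerance: float = 0.0
                       ) -> pd.DataFrame:
    """Stack filtered profiles into a samples x fragment-size matrix.

    With a positive `bin_tolerance` fragment sizes within that many bp are
    merged onto a common bin (nearest-size greedy merge).
    """
    rows = [filter_normalize(p, min_size=min_size, min_area=min_area)
            for p in profiles]
    matrix = pd.DataFrame(rows).fillna(0.0)
    matrix.index = [p.sample for p in profiles]
    if bin_tolerance > 0 and len(matrix.columns) > 1:
        sizes = sorted(matrix.columns)
        groups: list[list[float]] = [[sizes[0]]]
        for size in sizes[1:]:
            if size - groups[-1][-1] <= bin_tolerance:
                groups[-1].append(size)
            else:
                groups.append([size])
        merged = {}
        for group in groups:
            merged[float(np.mean(group))] = matrix[group].sum(axis=1)
        matrix = pd.DataFrame(merged)
    return matrix.sort_index(axis=1)


def bray_curtis(matrix: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between the rows of `matrix`.

    ``d(i, j) = sum|x - y| / sum(x + y)``; a pair of all-zero rows gets
    distance 0 with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    if (values < 0).any():
        raise InputError("Bray-Curtis needs non-negative abundances")
    n = len(values)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (values[i] + values[j]).sum()
            if denom == 0:
                warnings.warn("two empty samples: Bray-Curtis set to 0",
                              stacklevel=2)
                continue
            d[i, j] = d[j, i] = np.abs(values[i] - values[j]).sum() / denom
    return DistanceMatrix(labels=tuple(str(i) for i in matrix.index), values=d)


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def _anosim_r(ranks: np.ndarray, same_group: np.ndarray, n: int) -> float:
    mean_between = ranks[~same_group].mean()
    mean_within = ranks[same_group].mean()
    return (mean_between - mean_within) / (n * (n - 1) / 4.0)


def anosim(dm: DistanceMatrix, groups: Sequence[str], n_perm: int = 999,
           seed: int | None = None, one_sided: bool = True) -> AnosimResult:
    """Rank-based ANOSIM with a permutation p-value.

    ``R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)``
    over the ranked condensed distances; ``p = (#(R_perm >= R_obs) + 1) /
    (n_perm + 1)``.
    """
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(dm.labels):
        raise InputError("group labels do not match the distance matrix")
    uniques, counts = np.unique(labels, return_counts=True)
    if len(uniques) < 2:
        raise InputError("ANOSIM needs at least two groups")
    if (counts < 2).any():
        singles = [str(u) for u, c in zip(uniques, counts) if c < 2]
        raise InputError(f"singleton groups not allowed: {singles}")
    ranks = rankdata(dm.condensed())
    pair_i, pair_j = np.triu_indices(n, k=1)
    same = labels[pair_i] == labels[pair_j]
    observed = _anosim_r(ranks, same, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        perm_same = perm[pair_i] == perm[pair_j]
        r_perm = _anosim_r(ranks, perm_same, n)
        stat = r_perm if one_sided else abs(r_perm)
        ref = observed if one_sided else abs(observed)
        if stat >= ref - 1e-12:
            exceed += 1
    return AnosimResult(r=float(observed),
                        p_value=(exceed + 1) / (n_perm + 1),
                        n_permutations=n_perm)


@dataclass(frozen=True)
class CAResult:
    row_scores: pd.DataFrame
    col_scores: pd.DataFrame
    inertia: tuple[float, ...]

    @property
    def total_inertia(self) -> float:
        return float(sum(self.inertia))

    @property
    def inertia_percent(self) -> tuple[float, ...]:
        total = self.total_inertia
        if total < 1e-12:
            return tuple(0.0 for _ in self.inertia)
        return tuple(100.0 * v / total for v in self.inertia)


def correspondence_analysis(matrix: pd.DataFrame) -> CAResult:
    """Correspondence analysis via SVD of chi-square standardized residuals.

    Total inertia equals the chi-square statistic of the table divided by
    its grand total; axis percentages are each singular value squared over
    the total.  All-zero rows/columns are dropped with a warning.
    """
    work = matrix.astype(float)
    if (work.to_numpy() < 0).any():
        raise InputError("correspondence analysis needs a non-negative table")
    empty_rows = work.index[work.sum(axis=1) == 0]
    empty_cols = work.columns[work.sum(axis=0) == 0]
    if len(empty_rows) or len(empty_cols):
        warnings.warn(f"dropping empty rows {list(empty_rows)} and columns "
                      f"{list(empty_cols)}", stacklevel=2)
        work = work.drop(index=empty_rows, columns=empty_cols)
    total = work.to_numpy().sum()
    if total <= 0:
        raise InputError("table has a zero grand total")
    p = work.to_numpy() / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    residuals = (p - expected) / np.sqrt(expected)
    u, s, vt = np.linalg.svd(residuals, full_matrices=False)
    keep = min(len(s), min(work.shape) - 1) if min(work.shape) > 1 else len(s)
    u, s, vt = u[:, :keep], s[:keep], vt[:keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        row_coords = (u * s) / np.sqrt(r)[:, None]
        col_coords = (vt.T * s) / np.sqrt(c)[:, None]
    axes = [f"CA{i + 1}" for i in range(keep)]
    return CAResult(
        row_scores=pd.DataFrame(row_coords, index=work.index, columns=axes),
        col_scores=pd.DataFrame(col_coords, index=work.columns, columns=axes),
        inertia=tuple(float(v) for v in s**2))


def exhaustive_anosim_p(dm: DistanceMatrix, groups: Sequence[str]) -> float:
    """Exact one-sided p over all distinct relabelings (small n only)."""
    labels = np.asarray(groups)
    n = len(labels)
    ranks = rankdata(dm.condensed())
    pair_i, pair_j = np.triu_indices(n, k=1)
    observed = _anosim_r(ranks, labels[pair_i] == labels[pair_j], n)
    stats = []
    for perm in set(itertools.permutations(labels)):
        perm = np.asarray(perm)
        stats.append(_anosim_r(ranks, perm[pair_i] == perm[pair_j], n))
    stats = np.asarray(stats)
    return float((stats >= observed - 1e-12).sum() / len(stats))
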