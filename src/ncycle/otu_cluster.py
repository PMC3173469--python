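"""Dereplication, pairwise distances, OTU clustering and rarefaction.

Distances are ``1 - identity`` from pairwise global alignment with terminal
gaps excluded and each internal gap run counted as one difference (the
classic distance-matrix convention of hierarchical OTU assignment tools).
Clustering is furthest-neighbor (complete-linkage) agglomeration, so the
maximum intra-OTU distance never exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

from ._common import InputError, ParameterError

MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_SCORE = -1


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise InputError("distance matrix must be symmetric, zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(np.asarray(self.values, dtype=float), checks=False)


@dataclass
class UniqueSeq:
    """One dereplicated sequence with per-sample multiplicities."""

    rep_id: str
    seq: str
    counts: dict[str, int] = field(default_factory=dict)
    members: tuple[str, ...] = ()

    @property
    def multiplicity(self) -> int:
        return sum(self.counts.values())


@dataclass
class OtuTable:
    """OTU x sample count matrix with representative sequence ids."""

    counts: pd.DataFrame          # index: otu ids; columns: samples
    representatives: dict[str, str]
    cutoff: float
    space: str = "amino_acid"
    members: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    def sample_depth(self, sample: str) -> int:
        return int(self.counts[sample].sum())


def dereplicate(records: Sequence[tuple[str, str, str]]
                ) -> tuple[list[UniqueSeq], dict[str, str]]:
    """Collapse identical and exact-prefix duplicates.

    `records` are ``(seq_id, sample, seq)`` triples.  The representative of
    each unique is its longest member (ties: lexicographically smallest
    id); multiplicities are kept per sample.  Returns the unique records
    and a member-id -> representative-id map.
    """
    by_seq: dict[str, list[tuple[str, str]]] = {}
    for seq_id, sample, seq in records:
        by_seq.setdefault(seq, []).append((seq_id, sample))

    uniques: list[UniqueSeq] = []
    # longest first so shorter sequences can fold into existing prefixes
    for seq in sorted(by_seq, key=lambda s: (-len(s), s)):
        target = None
        for unique in uniques:
            if unique.seq.startswith(seq):
                target = unique
                break
        if target is None:
            target = UniqueSeq(rep_id="", seq=seq)
            uniques.append(target)
        for seq_id, sample in by_seq[seq]:
            target.counts[sample] = target.counts.get(sample, 0) + 1
            target.members = target.members + (seq_id,)

    mapping: dict[str, str] = {}
    for unique in uniques:
        unique.rep_id = min(sid for sid, _ in by_seq[unique.seq])
        for member in unique.members:
            mapping[member] = unique.rep_id
    uniques.sort(key=lambda u: u.rep_id)
    return uniques, mapping


def _align_global(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch with linear gaps; traceback prefers diag > up > left."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP_SCORE * np.arange(n + 1)
    score[0, :] = GAP_SCORE * np.arange(m + 1)
    for i in range(1, n + 1):
        row_prev = score[i - 1]
        row = score[i]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = row_prev[j - 1] + (MATCH_SCORE if ai == b[j - 1]
                                      else MISMATCH_SCORE)
            up = row_prev[j] + GAP_SCORE
            left = row[j - 1] + GAP_SCORE
            row[j] = max(diag, up, left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = MATCH_SCORE if a[i - 1] == b[j - 1] else MISMATCH_SCORE
            if score[i, j] == score[i - 1, j - 1] + sub:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + GAP_SCORE:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def distance_from_alignment(aligned_a: str, aligned_b: str) -> float:
    """1 - identity; terminal gaps excluded, internal gap run = 1 difference."""
    start = 0
    end = len(aligned_a)
    while start < end and (aligned_a[start] == "-" or aligned_b[start] == "-"):
        start += 1
    while end > start and (aligned_a[end - 1] == "-" or aligned_b[end - 1] == "-"):
        end -= 1
    matches = mismatches = gap_runs = 0
    in_gap = False
    for ca, cb in zip(aligned_a[start:end], aligned_b[start:end]):
        if ca == "-" or cb == "-":
            if not in_gap:
                gap_runs += 1
                in_gap = True
            continue
        in_gap = False
        if ca == cb:
            matches += 1
        else:
            mismatches += 1
    positions = matches + mismatches + gap_runs
    if positions == 0:
        return 0.0
    return 1.0 - matches / positions


def pairwise_distance(a: str, b: str) -> float:
    if not a or not b:
        raise InputError("cannot align an empty sequence")
    if a == b:
        return 0.0
    return distance_from_alignment(*_align_global(a, b))


def pairwise_distances(seqs: Sequence[str], labels: Sequence[str] | None = None
                       ) -> DistanceMatrix:
    """All-vs-all alignment distances for the given sequences."""
    if len(seqs) < 2:
        raise InputError("need at least two sequences")
    if labels is None:
        labels = [f"seq{i:04d}" for i in range(len(seqs))]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pairwise_distance(seqs[i], seqs[j])
    return DistanceMatrix(labels=tuple(labels), values=d)


def cluster_otus(dm: DistanceMatrix, cutoff: float,
                 counts: Mapping[str, Mapping[str, int]] | None = None,
                 space: str = "amino_acid", method: str = "complete"
                 ) -> OtuTable:
    """Agglomerate sequences into OTUs at a distance cutoff.

    Default linkage is furthest-neighbor, so every OTU's maximum
    intra-cluster distance is <= `cutoff`.  At cutoff 0 every sequence is
    its own OTU.  `counts` maps sequence label -> per-sample counts (one
    read each when omitted).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError("cutoff must lie in [0, 1]")
    labels = dm.labels
    n = len(labels)
    if cutoff == 0.0 or n == 1:
        assignment = list(range(n))
    else:
        tree = linkage(dm.condensed(), method=method)
        flat = fcluster(tree, t=cutoff, criterion="distance")
        assignment = [int(c) - 1 for c in flat]

    clusters: dict[int, list[str]] = {}
    for label, cl in zip(labels, assignment):
        clusters.setdefault(cl, []).append(label)
    ordered = sorted(clusters.values(), key=lambda ms: min(ms))

    if counts is None:
        counts = {label: {"all": 1} for label in labels}
    samples = sorted({s for per in counts.values() for s in per})

    rows = []
    reps: dict[str, str] = {}
    members_map: dict[str, tuple[str, ...]] = {}
    for idx, members in enumerate(ordered):
        otu_id = f"OTU_{idx + 1:04d}"
        per_sample = {s: 0 for s in samples}
        for label in members:
            for sample, c in counts.get(label, {}).items():
                per_sample[sample] += c
        totals = {label: sum(counts.get(label, {}).values()) for label in members}
        reps[otu_id] = min(members, key=lambda l: (-totals[l], l))
        members_map[otu_id] = tuple(sorted(members))
        rows.append(pd.Series(per_sample, name=otu_id))
    table = pd.DataFrame(rows)
    table.index.name = "otu_id"
    return OtuTable(counts=table, representatives=reps, cutoff=cutoff,
                    space=space, members=members_map)


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def expected_richness(counts: Sequence[int], m: int) -> float:
    """Analytic rarefaction: E[S_m] = S - sum_i C(N-N_i, m) / C(N, m)."""
    counts = np.asarray([c for c in counts if c > 0], dtype=float)
    total = counts.sum()
    if m > total:
        raise InputError("subsample size exceeds the sample depth")
    if m == 0:
        return 0.0
    feasible = (total - counts) >= m
    terms = np.zeros(len(counts))
    if feasible.any():
        reduced = total - counts[feasible]
        terms[feasible] = np.exp(_log_comb(reduced, m) - _log_comb(total, m))
    return float(len(counts) - terms.sum())


def rarefaction_curve(otu_table: OtuTable, sample: str,
                      grid: Sequence[int]) -> pd.DataFrame:
    """Expected OTU richness at each subsample size of `grid`."""
    counts = otu_table.counts[sample].to_numpy()
    depth = int(counts.sum())
    for m in grid:
        if m > depth:
            raise InputError(
                f"grid point {m} exceeds depth {depth} of sample {sample}")
    rows = [{"subsample_size": int(m),
             "expected_otus": expected_richness(counts, int(m))}
            for m in grid]
    return pd.DataFrame(rows)


def resample_to_depth(otu_table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to `depth` reads without replacement."""
    rng = np.random.default_rng(seed)
    new = {}
    for sample in otu_table.counts.columns:
        col = otu_table.counts[sample].to_numpy(dtype=np.int64)
        total = int(col.sum())
        if depth > total:
            raise InputError(
                f"depth {depth} exceeds total {total} of sample {sample}")
        new[sample] = rng.multivariate_hypergeometric(col, depth)
    table = pd.DataFrame(new, index=otu_table.counts.index)
    return OtuTable(counts=table, representatives=dict(otu_table.representatives),
                    cutoff=otu_table.cutoff, space=otu_table.space,
                    members=dict(otu_table.members))
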