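"""Six-frame translated search and frameshift/chimera screening.

Each read is aligned locally (Smith-Waterman, BLOSUM62) in all six frames
against every reference protein.  E-values use the Karlin-Altschul form
``E = K * m * n * exp(-lambda * S)`` with gapped BLOSUM62 constants.
Verdicts follow the frame-consistency rules: two largely disjoint regions
of one read hitting the same reference in different frames indicate a
frameshift; disjoint regions hitting different references indicate a
chimera.

Default gap penalties are open 16 / extend 4, stiffer than the BLAST
11/1 pair.  Exhaustive Smith-Waterman keeps any net-positive tail, so at
11/1 alignments creep across chimera breakpoints through cheap gap
bridges, blurring the disjoint-region signal that the verdict rules need;
the stiffer penalties stand in for the X-drop termination a seeded search
applies.  Both are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._common import ConfigurationError, InputError

#: gapped BLOSUM62-11-1 Karlin-Altschul constants
LAMBDA = 0.267
KAPPA = 0.041

FRAMES = (1, 2, 3, -1, -2, -3)

VERDICTS = ("valid", "frameshift", "chimera", "no_hit")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class LocalHit:
    """One local translated alignment of a read region to a reference."""

    subject_id: str
    query_start: int    # nt coordinates on the forward read, half-open
    query_end: int
    frame: int
    score: float
    evalue: float
    aa_start: int       # aa coordinates within the frame translation
    aa_end: int

    def overlap_fraction(self, other: "LocalHit") -> float:
        """Overlap of the two query intervals relative to the shorter one."""
        overlap = min(self.query_end, other.query_end) - max(
            self.query_start, other.query_start)
        shorter = min(self.query_end - self.query_start,
                      other.query_end - other.query_start)
        if shorter <= 0:
            return 0.0
        return max(0.0, overlap) / shorter


@dataclass(frozen=True)
class HitSet:
    read_id: str
    hits: tuple[LocalHit, ...]


@dataclass(frozen=True)
class ReadVerdict:
    read_id: str
    verdict: str
    supporting: tuple[int, ...] = ()


#: default local-alignment gap penalties (see module docstring)
GAP_OPEN = 16.0
GAP_EXTEND = 4.0


def _make_aligner(gap_open: float = GAP_OPEN,
                  gap_extend: float = GAP_EXTEND) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def six_frame_translations(seq: str) -> dict[int, str]:
    """Standard-table translations of all six frames (with '*' for stops)."""
    seq = seq.upper()
    rc = str(Seq(seq).reverse_complement())
    out = {}
    for frame in FRAMES:
        src = seq if frame > 0 else rc
        offset = abs(frame) - 1
        usable = len(src) - offset
        sub = src[offset:offset + usable - usable % 3]
        out[frame] = str(Seq(sub).translate())
    return out


def _nt_interval(frame: int, aa_start: int, aa_end: int, read_len: int
                 ) -> tuple[int, int]:
    offset = abs(frame) - 1
    if frame > 0:
        return offset + 3 * aa_start, offset + 3 * aa_end
    return read_len - (offset + 3 * aa_end), read_len - (offset + 3 * aa_start)


def translated_search(read_seq: str, refs: Sequence, k: int = 10,
                      evalue_cutoff: float = 1e-3, read_id: str = "",
                      aligner: Align.PairwiseAligner | None = None) -> HitSet:
    """Align all six frames against every reference; keep the top `k` hits.

    One hit is retained per (reference, frame) pair: its best local
    alignment.  Hits are ordered by descending score, ties broken by
    subject id then query start, and filtered at `evalue_cutoff`.
    """
    if not refs:
        raise ConfigurationError("reference set is empty")
    if aligner is None:
        aligner = _make_aligner()
    n_db = sum(len(r.aa_seq) for r in refs)
    translations = six_frame_translations(read_seq)
    read_len = len(read_seq)
    hits: list[LocalHit] = []
    for frame, query_aa in translations.items():
        m = len(query_aa)
        if m == 0:
            continue
        # minimum score that can clear the E-value cutoff in this frame
        min_score = math.log(KAPPA * m * n_db / evalue_cutoff) / LAMBDA
        for ref in refs:
            score = aligner.score(ref.aa_seq, query_aa)
            if score < min_score or score <= 0:
                continue
            evalue = KAPPA * m * n_db * math.exp(-LAMBDA * score)
            alignment = aligner.align(ref.aa_seq, query_aa)[0]
            segments = alignment.aligned[1]   # query-side aligned blocks
            aa_start = int(segments[0][0])
            aa_end = int(segments[-1][1])
            q_start, q_end = _nt_interval(frame, aa_start, aa_end, read_len)
            hits.append(LocalHit(
                subject_id=ref.id, query_start=q_start, query_end=q_end,
                frame=frame, score=float(score), evalue=evalue,
                aa_start=aa_start, aa_end=aa_end))
    hits.sort(key=lambda h: (-h.score, h.subject_id, h.query_start))
    return HitSet(read_id=read_id, hits=tuple(hits[:k]))


def classify_read(hitset: HitSet, max_region_overlap: float = 0.2,
                  min_hits: int = 1, chimera_mode: str = "disjoint"
                  ) -> ReadVerdict:
    """Apply the frame-consistency rules to a hit set.

    Frameshift: some reference is hit >= twice, in different frames, on
    query regions overlapping by less than `max_region_overlap` of the
    shorter region.  Chimera: the best hits of two different references
    occupy such disjoint regions (``chimera_mode='distinct_subjects'``
    relaxes this to any two distinct references).  Exactly one verdict per
    read.
    """
    hits = hitset.hits
    if len(hits) < min_hits:
        return ReadVerdict(hitset.read_id, "no_hit")

    by_subject: dict[str, list[int]] = {}
    for idx, hit in enumerate(hits):
        by_subject.setdefault(hit.subject_id, []).append(idx)

    for subject, indices in sorted(by_subject.items()):
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                ha, hb = hits[indices[a]], hits[indices[b]]
                if ha.frame != hb.frame and \
                        ha.overlap_fraction(hb) < max_region_overlap:
                    return ReadVerdict(hitset.read_id, "frameshift",
                                       (indices[a], indices[b]))

    best_per_subject = {
        subject: min(indices, key=lambda i: (-hits[i].score, hits[i].query_start))
        for subject, indices in by_subject.items()}
    subjects = sorted(best_per_subject)
    if chimera_mode == "distinct_subjects" and len(subjects) >= 2:
        return ReadVerdict(hitset.read_id, "chimera",
                           tuple(best_per_subject[s] for s in subjects[:2]))
    for a in range(len(subjects)):
        for b in range(a + 1, len(subjects)):
            ia, ib = best_per_subject[subjects[a]], best_per_subject[subjects[b]]
            if hits[ia].overlap_fraction(hits[ib]) < max_region_overlap:
                return ReadVerdict(hitset.read_id, "chimera", (ia, ib))
    return ReadVerdict(hitset.read_id, "valid", (0,))


def translate_valid(read_seq: str, best_hit: LocalHit) -> tuple[str, bool]:
    """Translate the hit's query region in the hit's frame.

    Returns the amino-acid string and a flag marking internal stop codons
    (translation is truncated at the first stop when one occurs).
    """
    translations = six_frame_translations(read_seq)
    frame_aa = translations[best_hit.frame]
    if not 0 <= best_hit.aa_start < best_hit.aa_end <= len(frame_aa):
        raise InputError("hit interval inconsistent with the frame translation")
    region = frame_aa[best_hit.aa_start:best_hit.aa_end]
    if "*" in region:
        return region.split("*", 1)[0], True
    return region, False


def screen_reads(reads, refs, k: int = 10, evalue_cutoff: float = 1e-3,
                 max_region_overlap: float = 0.2,
                 chimera_mode: str = "disjoint", gap_open: float = GAP_OPEN,
                 gap_extend: float = GAP_EXTEND, ledger=None):
    """Run search + classification over reads; translate the valid ones.

    `reads` are demultiplexed :class:`~ncycle.demux_qc.AmpliconRead`
    records.  Returns ``(verdicts, translations)`` where `translations`
    maps read ids of valid reads to (aa_seq, stop_flag).
    """
    aligner = _make_aligner(gap_open, gap_extend)
    verdicts: dict[str, ReadVerdict] = {}
    translations: dict[str, tuple[str, bool]] = {}
    for read in reads:
        hitset = translated_search(read.seq, refs, k=k,
                                   evalue_cutoff=evalue_cutoff,
                                   read_id=read.read_id, aligner=aligner)
        verdict = classify_read(hitset, max_region_overlap=max_region_overlap,
                                chimera_mode=chimera_mode)
        verdicts[read.read_id] = verdict
        if verdict.verdict == "valid":
            translations[read.read_id] = translate_valid(
                read.seq, hitset.hits[verdict.supporting[0]])
    if ledger is not None:
        ledger.record("frame_valid",
                      sum(v.verdict == "valid" for v in verdicts.values()))
    return verdicts, translations
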