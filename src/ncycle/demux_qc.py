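"""Demultiplexing and read screening.

Implements the survey's screening cascade: raw-quality screen (length >= 50,
no ambiguous bases, mean Phred >= 20), exact-barcode demultiplexing with
barcode removal, degenerate-primer matching with re-orientation of
reverse-primer reads, and the post-trim length filter.  A
:class:`FilterLedger` carries the per-stage accounting that feeds the
summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from ._common import ConfigurationError, InputError, percent_of

IUPAC_SETS = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

STAGES = ("raw", "quality_pass", "barcode_matched", "primer_matched",
          "length_pass", "frame_valid")


@dataclass
class AmpliconRead:
    """One sequencing read, annotated as it moves through the pipeline."""

    read_id: str
    seq: str
    qual: list[int] | None = None
    sample: str | None = None
    gene: str | None = None
    oriented_forward: bool = True
    trimmed: bool = False

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise InputError(
                f"read {self.read_id}: quality length != sequence length")

    def mean_quality(self) -> float | None:
        if not self.qual:
            return None
        return sum(self.qual) / len(self.qual)


@dataclass
class FilterLedger:
    """Per-stage read counts; non-increasing along the stage order."""

    counts: dict[str, int] = field(default_factory=dict)
    per_sample: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def record(self, stage: str, count: int) -> None:
        if stage not in STAGES:
            raise ConfigurationError(f"unknown ledger stage {stage!r}")
        self.counts[stage] = int(count)

    def note(self, message: str) -> None:
        self.notes.append(message)


def reads_from_simulated(sim_reads) -> list[AmpliconRead]:
    """Adapt :class:`~ncycle.synthetic_community.SimulatedRead` records."""
    return [AmpliconRead(read_id=r.read_id, seq=r.seq, qual=list(r.qual))
            for r in sim_reads]


def read_fastq(path) -> list[AmpliconRead]:
    from Bio import SeqIO

    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        reads.append(AmpliconRead(
            read_id=record.id, seq=str(record.seq),
            qual=list(record.letter_annotations["phred_quality"])))
    return reads


def quality_screen(reads: Sequence[AmpliconRead], min_len: int = 50,
                   min_mean_qual: float = 20.0,
                   ledger: FilterLedger | None = None,
                   ) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Drop reads shorter than `min_len`, containing 'N', or low quality.

    Reads without quality strings skip the mean-quality criterion (recorded
    in the ledger).  Order-preserving.
    """
    kept: list[AmpliconRead] = []
    removed: list[AmpliconRead] = []
    saw_no_qual = False
    for read in reads:
        if len(read.seq) < min_len or "N" in read.seq.upper():
            removed.append(read)
            continue
        mean_q = read.mean_quality()
        if mean_q is None:
            saw_no_qual = True
        elif mean_q < min_mean_qual:
            removed.append(read)
            continue
        kept.append(read)
    if ledger is not None:
        ledger.record("raw", len(reads))
        ledger.record("quality_pass", len(kept))
        if saw_no_qual:
            ledger.note("some reads lacked qualities; quality criterion skipped")
    return kept, removed


def check_barcode_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    required = {"sample", "gene", "barcode"}
    if not required.issubset(sheet.columns):
        raise ConfigurationError(
            f"barcode sheet needs columns {sorted(required)}")
    barcodes = sheet["barcode"].str.upper()
    if barcodes.duplicated().any():
        dupes = sorted(barcodes[barcodes.duplicated()].unique())
        raise ConfigurationError(f"duplicate barcodes in sheet: {dupes}")
    if barcodes.str.len().nunique() > 1:
        raise ConfigurationError("all barcodes must have the same length")
    return sheet.assign(barcode=barcodes)


def demultiplex(reads: Sequence[AmpliconRead], sheet: pd.DataFrame,
                ledger: FilterLedger | None = None,
                ) -> tuple[list[AmpliconRead], list[AmpliconRead]]:
    """Assign reads to samples by exact barcode prefix; trim the barcode."""
    sheet = check_barcode_sheet(sheet)
    lookup = {row.barcode: (row.sample, row.gene)
              for row in sheet.itertuples()}
    bc_len = len(next(iter(lookup)))
    assigned: list[AmpliconRead] = []
    unassigned: list[AmpliconRead] = []
    for read in reads:
        prefix = read.seq[:bc_len].upper()
        hit = lookup.get(prefix)
        if hit is None:
            unassigned.append(read)
            continue
        sample, gene = hit
        assigned.append(AmpliconRead(
            read_id=read.read_id, seq=read.seq[bc_len:],
            qual=None if read.qual is None else read.qual[bc_len:],
            sample=sample, gene=gene))
    if ledger is not None:
        ledger.record("barcode_matched", len(assigned))
        counts: dict[str, int] = {}
        for read in assigned:
            counts[read.sample] = counts.get(read.sample, 0) + 1
        ledger.per_sample.update(counts)
    return assigned, unassigned


def _validate_primer(primer: str) -> str:
    primer = primer.replace(" ", "").upper()
    bad = sorted({c for c in primer if c not in IUPAC_SETS})
    if bad:
        raise ConfigurationError(f"non-IUPAC characters in primer: {bad}")
    return primer


def primer_matches(primer: str, seq: str, max_mismatch: int = 0) -> bool:
    """Does `seq` start with a realization of the degenerate `primer`?"""
    if len(seq) < len(primer):
        return False
    mismatches = 0
    for code, base in zip(primer, seq.upper()):
        if base not in IUPAC_SETS[code]:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def primer_screen_and_orient(reads: Sequence[AmpliconRead], fwd_primer: str,
                             rev_primer: str, min_len: int = 350,
                             max_mismatch: int = 0,
                             ledger: FilterLedger | None = None,
                             ) -> list[AmpliconRead]:
    """Keep primer-bearing reads, trim the primer, re-orient reverse reads.

    Reads matching the forward primer at the start are kept as-is; reads
    matching the reverse primer are reverse-complemented so every survivor
    is forward-oriented.  Reads shorter than `min_len` after trimming are
    dropped.  Already-trimmed reads pass through untouched (idempotence).
    """
    fwd = _validate_primer(fwd_primer)
    rev = _validate_primer(rev_primer)
    primer_ok: list[AmpliconRead] = []
    for read in reads:
        if read.trimmed:
            primer_ok.append(read)
            continue
        if primer_matches(fwd, read.seq, max_mismatch):
            seq = read.seq[len(fwd):]
            qual = None if read.qual is None else read.qual[len(fwd):]
            oriented = True
        elif primer_matches(rev, read.seq, max_mismatch):
            seq = str(Seq(read.seq[len(rev):]).reverse_complement())
            qual = None if read.qual is None else read.qual[len(rev):][::-1]
            oriented = True
        else:
            continue
        primer_ok.append(AmpliconRead(
            read_id=read.read_id, seq=seq, qual=qual, sample=read.sample,
            gene=read.gene, oriented_forward=oriented, trimmed=True))
    kept = [r for r in primer_ok if len(r.seq) >= min_len]
    if ledger is not None:
        ledger.record("primer_matched", len(primer_ok))
        ledger.record("length_pass", len(kept))
    return kept


def summarize_filtering(ledger: FilterLedger) -> pd.DataFrame:
    """Stage counts as a table with percentages of the raw total.

    Percentages are ``100 * count / raw`` to one decimal, ties away from
    zero (so 137,891 of 143,487 prints as 96.1).
    """
    raw = ledger.counts.get("raw", 0)
    if raw == 0:
        raise InputError("ledger has no raw reads; nothing to summarize")
    rows = []
    for stage in STAGES:
        if stage not in ledger.counts:
            continue
        count = ledger.counts[stage]
        rows.append({"stage": stage, "count": count,
                     "percent_of_raw": percent_of(count, raw)})
    return pd.DataFrame(rows)


def write_per_sample_fasta(reads: Iterable[AmpliconRead], out_dir) -> dict[str, str]:
    """Distribute reads to one FASTA per sample; returns sample -> path."""
    import os

    groups: dict[str, list[AmpliconRead]] = {}
    for read in reads:
        groups.setdefault(read.sample or "unassigned", []).append(read)
    paths = {}
    os.makedirs(out_dir, exist_ok=True)
    for sample, members in sorted(groups.items()):
        path = os.path.join(out_dir, f"{sample}.fasta")
        with open(path, "w") as handle:
            for read in members:
                handle.write(f">{read.read_id}\n{read.seq}\n")
        paths[sample] = path
    return paths


def ledger_to_frame(ledger: FilterLedger) -> pd.DataFrame:
    return summarize_filtering(ledger)
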