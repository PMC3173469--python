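"""Generators for synthetic functional-gene amplicon surveys with known truth.

Everything the downstream pipeline consumes can be produced here: reference
protein sets, barcoded reads with planted chimeras and frameshifts, qPCR
dilution series and T-RFLP peak tables.  All generators are deterministic
given their seed, and every emitted read carries a ground-truth record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from ._common import ConfigurationError, ParameterError

GENE_FAMILIES = ("nifH", "amoA_archaea", "amoA_bacteria", "nosZ", "16S")

#: default amplicon lengths (nt) per gene family; configurable, not asserted
DEFAULT_AMPLICON_NT = {
    "nifH": 360,
    "amoA_archaea": 635,
    "amoA_bacteria": 491,
    "nosZ": 453,
}

TREND_CLASSES = ("increase", "decrease", "appear", "disappear", "stable")

#: per-timepoint multipliers applied to the baseline relative abundance
_TREND_MULTIPLIERS = {
    "stable": (1.0, 1.0, 1.0),
    "increase": (1.0, 2.0, 4.0),
    "decrease": (1.0, 0.5, 0.25),
    "appear": (0.0, 1.0, 1.0),
    "disappear": (1.0, 0.0, 0.0),
}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in _STANDARD_TABLE.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _codons in _CODONS_BY_AA.values():
    _codons.sort()

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ReferenceProtein:
    """One entry of the reference protein set used by the translated search."""

    id: str
    family: str
    aa_seq: str
    nt_seq: str

    def __post_init__(self) -> None:
        if len(self.nt_seq) != 3 * len(self.aa_seq):
            raise ParameterError("nt_seq length must be 3x aa_seq length")


@dataclass(frozen=True)
class TaxonSpec:
    """A community member: per-crop trend class and baseline abundance."""

    taxon_id: str
    trends: Mapping[str, str]
    baseline: float


@dataclass
class CommunityDesign:
    """Full experimental design of a simulated survey.

    Samples are the cross product of `crops` and `timepoints` (t0 acts as
    the pre-planting baseline of each crop).
    """

    crops: Sequence[str]
    timepoints: Sequence[str]
    taxa: Sequence[TaxonSpec]
    read_depth: int
    chimera_rate: float = 0.0
    frameshift_rate: float = 0.0
    reverse_fraction: float = 0.3
    low_quality_fraction: float = 0.0
    #: "any" draws chimera partners uniformly; "cross_family" restricts them
    #: to taxa whose reference family differs (the detectable minimal case)
    chimera_partner: str = "any"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chimera_partner not in ("any", "cross_family"):
            raise ParameterError("chimera_partner must be any|cross_family")
        if len(self.timepoints) != 3:
            raise ParameterError("designs use exactly three ordered timepoints")
        for rate in (self.chimera_rate, self.frameshift_rate,
                     self.reverse_fraction, self.low_quality_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ParameterError("rates must lie in [0, 1]")
        if self.chimera_rate + self.frameshift_rate > 1.0:
            raise ParameterError("chimera_rate + frameshift_rate must be <= 1")
        for taxon in self.taxa:
            for crop, cls in taxon.trends.items():
                if cls not in TREND_CLASSES:
                    raise ParameterError(f"unknown trend class {cls!r}")

    def sample_id(self, crop: str, timepoint: str) -> str:
        return f"{crop}-{timepoint}"

    def samples(self) -> list[tuple[str, str, str]]:
        """(sample_id, crop, timepoint) for every cell of the design."""
        return [(self.sample_id(c, t), c, t)
                for c in self.crops for t in self.timepoints]

    def abundances(self, crop: str, timepoint: str) -> np.ndarray:
        """Ground-truth relative abundances of all taxa in one sample."""
        ti = list(self.timepoints).index(timepoint)
        raw = np.array(
            [t.baseline * _TREND_MULTIPLIERS[t.trends.get(crop, "stable")][ti]
             for t in self.taxa])
        total = raw.sum()
        if total <= 0:
            raise ParameterError(f"empty community for {crop}/{timepoint}")
        return raw / total


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample: str
    taxon: str
    is_chimera: bool = False
    parent_ids: tuple[str, str] | None = None
    breakpoint: int | None = None
    is_frameshift: bool = False
    indel_pos: int | None = None
    indel_type: str | None = None
    reverse: bool = False


@dataclass
class GroundTruth:
    """Ground truth for one simulated read set."""

    reads: dict[str, ReadTruth] = field(default_factory=dict)
    taxon_trends: dict[tuple[str, str], str] = field(default_factory=dict)

    def flagged(self, kind: str) -> list[str]:
        if kind == "chimera":
            return [r for r, t in self.reads.items() if t.is_chimera]
        if kind == "frameshift":
            return [r for r, t in self.reads.items() if t.is_frameshift]
        raise ParameterError(f"unknown flag kind {kind!r}")


@dataclass(frozen=True)
class SimulatedRead:
    read_id: str
    seq: str
    qual: tuple[int, ...]


def make_reference_set(family: str, n_refs: int, mean_aa_len: int,
                       divergence: float, seed: int) -> list[ReferenceProtein]:
    """Derive `n_refs` proteins from one random ancestor.

    Each site of the ancestor is substituted with probability `divergence`
    independently per reference; codons are drawn uniformly per residue, so
    nucleotide sequences always translate back to the amino-acid sequence.
    """
    if n_refs < 1:
        raise ParameterError("n_refs must be >= 1")
    if not 0.0 < divergence < 0.5:
        raise ParameterError("divergence must lie in (0, 0.5)")
    if mean_aa_len < 50:
        raise ParameterError("mean_aa_len must be >= 50")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(_AA_ALPHABET))
    ancestor = rng.choice(alphabet, size=mean_aa_len)
    refs = []
    for i in range(n_refs):
        aa = ancestor.copy()
        mask = rng.random(mean_aa_len) < divergence
        for pos in np.flatnonzero(mask):
            choices = [a for a in _AA_ALPHABET if a != aa[pos]]
            aa[pos] = choices[rng.integers(len(choices))]
        aa_seq = "".join(aa)
        nt_seq = "".join(
            _CODONS_BY_AA[res][rng.integers(len(_CODONS_BY_AA[res]))]
            for res in aa_seq)
        refs.append(ReferenceProtein(id=f"{family}_ref{i:03d}", family=family,
                                     aa_seq=aa_seq, nt_seq=nt_seq))
    return refs


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    out = []
    for code in primer.replace(" ", "").upper():
        try:
            options = _IUPAC[code]
        except KeyError:
            raise ConfigurationError(f"non-IUPAC character {code!r} in primer")
        out.append(options[rng.integers(len(options))])
    return "".join(out)


def _draw_quals(length: int, mean: float, rng: np.random.Generator) -> tuple[int, ...]:
    q = np.clip(np.rint(rng.normal(mean, 5.0, size=length)), 2, 40)
    return tuple(int(v) for v in q)


def simulate_reads(design: CommunityDesign, refs: Sequence[ReferenceProtein],
                   barcodes: Mapping[str, str],
                   primers: tuple[str, str]) -> tuple[list[SimulatedRead], GroundTruth]:
    """Emit barcoded reads for every sample of the design, plus ground truth.

    Read layout is ``barcode + primer realization + amplicon`` (reverse
    orientation reads carry the reverse primer followed by the reverse
    complement of the amplicon).  Chimeras splice two parents at a single
    breakpoint in the middle 50% of the amplicon; frameshifts carry one 1-bp
    indel at least 60 bp from either end.
    """
    ref_by_id = {r.id: r for r in refs}
    missing = [t.taxon_id for t in design.taxa if t.taxon_id not in ref_by_id]
    if missing:
        raise ConfigurationError(f"taxa without reference sequence: {missing}")
    if len(set(barcodes.values())) != len(barcodes):
        raise ConfigurationError("barcode collision in barcode map")
    for sample_id, _, _ in design.samples():
        if sample_id not in barcodes:
            raise ConfigurationError(f"no barcode for sample {sample_id}")

    fwd_primer, rev_primer = primers
    rng = np.random.default_rng(design.seed)
    taxon_ids = [t.taxon_id for t in design.taxa]
    reads: list[SimulatedRead] = []
    truth = GroundTruth()
    for taxon in design.taxa:
        for crop in design.crops:
            truth.taxon_trends[(taxon.taxon_id, crop)] = taxon.trends.get(
                crop, "stable")

    for sample_id, crop, timepoint in design.samples():
        probs = design.abundances(crop, timepoint)
        counts = rng.multinomial(design.read_depth, probs)
        read_no = 0
        for taxon_idx, n_reads in enumerate(counts):
            source = ref_by_id[taxon_ids[taxon_idx]]
            for _ in range(n_reads):
                read_id = f"{sample_id}_r{read_no:06d}"
                read_no += 1
                amplicon = source.nt_seq
                is_chimera = is_frameshift = False
                parents = None
                breakpoint = indel_pos = None
                indel_type = None
                u = rng.random()
                if u < design.chimera_rate and len(taxon_ids) > 1:
                    is_chimera = True
                    others = [t for t in taxon_ids if t != source.id]
                    if design.chimera_partner == "cross_family":
                        cross = [t for t in others
                                 if ref_by_id[t].family != source.family]
                        others = cross or others
                    partner = ref_by_id[others[rng.integers(len(others))]]
                    lo = min(len(source.nt_seq), len(partner.nt_seq))
                    breakpoint = int(rng.integers(lo // 4, 3 * lo // 4 + 1))
                    amplicon = source.nt_seq[:breakpoint] + partner.nt_seq[breakpoint:]
                    parents = (source.id, partner.id)
                elif u < design.chimera_rate + design.frameshift_rate:
                    is_frameshift = True
                    hi = len(amplicon) - 60
                    if hi <= 60:
                        raise ParameterError(
                            "amplicon too short for a flank-safe indel")
                    indel_pos = int(rng.integers(60, hi + 1))
                    if rng.random() < 0.5:
                        indel_type = "insertion"
                        base = "ACGT"[rng.integers(4)]
                        amplicon = amplicon[:indel_pos] + base + amplicon[indel_pos:]
                    else:
                        indel_type = "deletion"
                        amplicon = amplicon[:indel_pos] + amplicon[indel_pos + 1:]
                reverse = bool(rng.random() < design.reverse_fraction)
                if reverse:
                    insert = _realize_primer(rev_primer, rng) + str(
                        Seq(amplicon).reverse_complement())
                else:
                    insert = _realize_primer(fwd_primer, rng) + amplicon
                seq = barcodes[sample_id] + insert
                mean_q = 15.0 if rng.random() < design.low_quality_fraction else 30.0
                reads.append(SimulatedRead(
                    read_id=read_id, seq=seq,
                    qual=_draw_quals(len(seq), mean_q, rng)))
                truth.reads[read_id] = ReadTruth(
                    read_id=read_id, sample=sample_id, taxon=source.id,
                    is_chimera=is_chimera, parent_ids=parents,
                    breakpoint=breakpoint, is_frameshift=is_frameshift,
                    indel_pos=indel_pos, indel_type=indel_type,
                    reverse=reverse)
    return reads, truth


def write_fastq(reads: Iterable[SimulatedRead], path) -> None:
    """Write simulated reads as Sanger Phred+33 FASTQ."""
    with open(path, "w") as handle:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qual)
            handle.write(f"@{read.read_id}\n{read.seq}\n+\n{quals}\n")


def write_reference_fasta(refs: Iterable[ReferenceProtein], path,
                          space: str = "aa") -> None:
    with open(path, "w") as handle:
        for ref in refs:
            seq = ref.aa_seq if space == "aa" else ref.nt_seq
            handle.write(f">{ref.id} family={ref.family}\n{seq}\n")


def simulate_qpcr(true_efficiency: float, intercept: float,
                  dilution_factors: Sequence[float], noise_sd: float,
                  seed: int, replicates: int = 1) -> pd.DataFrame:
    """Emit a (dilution, replicate, cq) table for a serial dilution.

    `dilution_factors` are relative template inputs (e.g. 1, 0.5, 0.25 for a
    two-fold series), strictly descending.  Cq follows
    ``intercept - log10(input) / log10(E)`` plus Gaussian noise.
    """
    if not 1.0 < true_efficiency <= 2.2:
        raise ParameterError("efficiency must lie in (1, 2.2]")
    factors = np.asarray(dilution_factors, dtype=float)
    if factors.ndim != 1 or len(factors) < 2:
        raise ParameterError("need at least two dilution points")
    if np.any(factors <= 0) or np.any(np.diff(factors) >= 0):
        raise ParameterError("dilution factors must be positive and descending")
    rng = np.random.default_rng(seed)
    rows = []
    for d in factors:
        clean = intercept - np.log10(d) / np.log10(true_efficiency)
        for rep in range(replicates):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append({"input": d, "replicate": rep, "cq": clean + noise})
    return pd.DataFrame(rows)


def simulate_trflp(profiles_truth: Mapping[str, Mapping[float, float]],
                   peak_noise: int, seed: int,
                   amplicon_len: int = 500, enzyme: str = "AluI") -> list:
    """Wrap true size->area maps into profiles, adding spurious peaks.

    `peak_noise` spurious peaks per sample are planted: small areas (<= 500)
    and/or out-of-range sizes, so downstream size/area filters have work to
    do.  Returns a list of :class:`~ncycle.trflp_ordination.TrflpProfile`.
    """
    from .trflp_ordination import TrflpProfile

    rng = np.random.default_rng(seed)
    profiles = []
    for sample in sorted(profiles_truth):
        peaks = dict(profiles_truth[sample])
        for _ in range(peak_noise):
            kind = rng.integers(3)
            if kind == 0:       # sub-threshold area, in-range size
                size = float(rng.integers(50, amplicon_len + 1))
                area = float(rng.integers(50, 501))
            elif kind == 1:     # too small a fragment
                size = float(rng.integers(20, 50))
                area = float(rng.integers(600, 5000))
            else:               # beyond the product length
                size = float(rng.integers(amplicon_len + 1, amplicon_len + 200))
                area = float(rng.integers(600, 5000))
            while size in peaks:
                size += 0.1
            peaks[size] = area
        profiles.append(TrflpProfile(sample=sample, enzyme=enzyme,
                                     peaks=peaks, amplicon_len=amplicon_len))
    return profiles


def design_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth read records as a tidy frame (one row per read)."""
    return pd.DataFrame([dataclasses.asdict(t) for t in truth.reads.values()])
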