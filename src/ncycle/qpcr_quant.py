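"""qPCR standard curves and absolute quantification.

Standard curves are ordinary least squares of mean Cq on log10 input;
amplification efficiency is ``E = 10**(-1/slope)``.  Sample-derived
standards convert a mass concentration to copies via the mean amplicon
molecular weight (660 g/mol per double-stranded bp by default), and
per-gram abundances apply the DNA yield and extraction-efficiency
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._common import DegenerateCurveError, InputError, ParameterError

AVOGADRO = 6.022e23
DS_DNA_MW_PER_BP = 660.0   # g/mol per double-stranded base pair
DETECTION_LIMIT_COPIES_PER_UL = 10.0


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    log_inputs: tuple[float, ...]
    mean_cqs: tuple[float, ...]
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope)

    def copies_at(self, cq: float) -> float:
        """Invert the curve: input quantity for an observed Cq."""
        return 10.0 ** ((cq - self.intercept) / self.slope)

    @property
    def cq_range(self) -> tuple[float, float]:
        return min(self.mean_cqs), max(self.mean_cqs)


@dataclass(frozen=True)
class CopyQuant:
    sample: str
    gene: str
    copies_per_ng_dna: float
    copies_per_g_soil: float
    replicate_cqs: tuple[float, ...]
    below_detection: bool = False
    extrapolated: bool = False


def fit_standard_curve(dilution_table: pd.DataFrame, gene: str = ""
                       ) -> StandardCurve:
    """OLS fit of mean Cq per dilution point on log10 input.

    `dilution_table` needs columns ``input`` (relative or absolute
    quantity) and ``cq``; replicate rows per input are averaged first.
    """
    if not {"input", "cq"}.issubset(dilution_table.columns):
        raise InputError("dilution table needs 'input' and 'cq' columns")
    grouped = dilution_table.groupby("input")["cq"].mean()
    if len(grouped) < 3:
        raise InputError("need at least three dilution points")
    if not np.isfinite(grouped.to_numpy()).all():
        raise InputError("non-finite Cq values in the dilution table")
    log_inputs = np.log10(grouped.index.to_numpy(dtype=float))
    cqs = grouped.to_numpy(dtype=float)
    fit = stats.linregress(log_inputs, cqs)
    if not fit.slope < 0:
        raise DegenerateCurveError(
            f"standard curve slope {fit.slope:.4g} is not negative")
    return StandardCurve(gene=gene, log_inputs=tuple(log_inputs),
                         mean_cqs=tuple(cqs), slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r_squared=float(fit.rvalue**2))


def standard_copies(conc_ng_per_ul: float, mean_len_bp: float,
                    bp_mw: float = DS_DNA_MW_PER_BP) -> float:
    """Copies per microliter of a sample-derived standard.

    ``copies = conc[g/uL] / (mean_len_bp * bp_mw) * Avogadro``.
    """
    if conc_ng_per_ul <= 0 or mean_len_bp <= 0:
        raise InputError("concentration and amplicon length must be positive")
    mw = mean_len_bp * bp_mw
    return conc_ng_per_ul * 1e-9 / mw * AVOGADRO


def quantify_sample(curve: StandardCurve, sample_cqs: Sequence[float],
                    dna_ng_per_g: float, extraction_eff: float = 0.30,
                    sample: str = "", detection_limit: float =
                    DETECTION_LIMIT_COPIES_PER_UL) -> CopyQuant:
    """Convert replicate Cqs to copies per ng DNA and per gram dry soil.

    ``copies_per_g = copies_per_ng * dna_ng_per_g / extraction_eff``.
    Quantities below the assay detection limit are flagged (censored), not
    zeroed; Cqs outside the calibrated range raise an extrapolation
    warning only.
    """
    if not sample_cqs:
        raise InputError("need at least one replicate Cq")
    if not 0 < extraction_eff <= 1:
        raise ParameterError("extraction efficiency must lie in (0, 1]")
    mean_cq = float(np.mean(sample_cqs))
    lo, hi = curve.cq_range
    extrapolated = not lo <= mean_cq <= hi
    if extrapolated:
        warnings.warn(f"mean Cq {mean_cq:.2f} outside calibrated range "
                      f"[{lo:.2f}, {hi:.2f}]; extrapolating", stacklevel=2)
    copies_per_ng = curve.copies_at(mean_cq)
    copies_per_g = copies_per_ng * dna_ng_per_g / extraction_eff
    return CopyQuant(sample=sample, gene=curve.gene,
                     copies_per_ng_dna=copies_per_ng,
                     copies_per_g_soil=copies_per_g,
                     replicate_cqs=tuple(float(c) for c in sample_cqs),
                     below_detection=copies_per_ng < detection_limit,
                     extrapolated=extrapolated)


def compare_groups(quants: Mapping[str, Sequence[float]], alpha: float = 0.05,
                   log_transform: bool = True) -> dict:
    """One-way ANOVA plus Tukey HSD letter display on (log) copy numbers.

    Groups sharing a letter are not separated at `alpha`.  Tukey HSD
    stands in for the Tukey-B procedure; at small balanced designs the
    difference is negligible.
    """
    if len(quants) < 2:
        raise InputError("need at least two groups")
    for name, values in quants.items():
        if len(values) < 2:
            raise InputError(f"group {name} has fewer than two replicates")
    names = sorted(quants)
    data = {name: np.log10(np.asarray(quants[name], dtype=float))
            if log_transform else np.asarray(quants[name], dtype=float)
            for name in names}
    arrays = [data[name] for name in names]
    pooled = np.concatenate(arrays)
    if np.allclose(pooled, pooled[0]):
        f_stat, p_value = 0.0, 1.0
        not_separated = {(a, b) for a in names for b in names}
    else:
        f_stat, p_value = stats.f_oneway(*arrays)
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        labels = np.concatenate([[name] * len(data[name]) for name in names])
        tukey = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
        groups = [str(g) for g in tukey.groupsunique]
        i_idx, j_idx = tukey._multicomp.pairindices
        not_separated = {(a, a) for a in names}
        for i, j, reject in zip(i_idx, j_idx, tukey.reject):
            if not reject:
                not_separated.add((groups[i], groups[j]))
                not_separated.add((groups[j], groups[i]))
    letters = _letter_display(names, data, not_separated)
    return {"f_statistic": float(f_stat), "p_value": float(p_value),
            "letters": letters, "alpha": alpha}


def _letter_display(names, data, not_separated) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not separated."""
    order = sorted(names, key=lambda n: -float(np.mean(data[n])))
    columns: list[set[str]] = []
    for name in order:
        placed = False
        for col in columns:
            if all((name, other) in not_separated for other in col):
                col.add(name)
                placed = True
        if not placed:
            columns.append({name})
    columns = [col for i, col in enumerate(columns)
               if not any(i != j and col < other
                          for j, other in enumerate(columns))]
    letters = {name: "" for name in names}
    for letter, col in zip("abcdefghijklmnopqrstuvwxyz", columns):
        for name in col:
            letters[name] += letter
    return {name: "".join(sorted(letters[name])) for name in names}


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regress_rate_on_logcopies(rates: Sequence[float],
                              copies: Sequence[float]) -> RegressionResult:
    """OLS of a process rate on log10 gene copies per gram."""
    rates = np.asarray(rates, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if len(rates) != len(copies) or len(rates) < 3:
        raise InputError("need >= 3 paired observations")
    x = np.log10(copies)
    if np.allclose(x, x[0]):
        raise DegenerateCurveError("zero variance in log copies")
    fit = stats.linregress(x, rates)
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=float(fit.rvalue**2),
                            p_value=float(fit.pvalue), n=len(rates))
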