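"""Monotonic abundance-trend calls across three ordered timepoints.

A taxon "appears" when absent at baseline and detected at both later
timepoints, "disappears" in the mirror case, and is called increasing or
decreasing only on strictly monotone counts (a flat step breaks the
trend).  Summaries count, per gene, the unique taxa changed in at least
one crop as a percentage of the gene's total phylotype richness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._common import InputError, round_half_away

TREND_SYMBOLS = {"increase": "+", "decrease": "-",
                 "appear": "++", "disappear": "--", "none": "none"}


@dataclass(frozen=True)
class TrendCall:
    taxon: str
    crop: str
    trend: str

    @property
    def changed(self) -> bool:
        return self.trend != "none"


def call_trend(counts: Sequence[float], taxon: str = "", crop: str = "",
               strict: bool = True) -> TrendCall:
    """Classify one (taxon, crop) series of depth-normalized counts.

    Appearance/disappearance is keyed on detection (exact zeros), not on
    ordering, so (0, 7, 7) is an appearance.  Increase/decrease require
    strictly monotone counts unless ``strict=False``.
    """
    if len(counts) != 3:
        raise InputError("trend calls need exactly three timepoints")
    c0, c1, c2 = counts
    if min(counts) < 0:
        raise InputError("counts must be non-negative")
    if c0 == 0 and c1 > 0 and c2 > 0:
        trend = "appear"
    elif c0 > 0 and c1 == 0 and c2 == 0:
        trend = "disappear"
    elif (c0 < c1 < c2) if strict else (c0 <= c1 <= c2 and c0 < c2):
        trend = "increase"
    elif (c0 > c1 > c2) if strict else (c0 >= c1 >= c2 and c0 > c2):
        trend = "decrease"
    else:
        trend = "none"
    return TrendCall(taxon=taxon, crop=crop, trend=trend)


def call_table(counts: pd.DataFrame,
               sample_map: Mapping[str, tuple[str, str]],
               timepoints: Sequence[str], normalize_depth: bool = True,
               strict: bool = True) -> pd.DataFrame:
    """Call trends for every (taxon, crop) of an OTU/genus count table.

    `counts` has taxa as rows and samples as columns; `sample_map` maps
    sample -> (crop, timepoint).  With ``normalize_depth`` the columns are
    rescaled to the smallest sample depth before comparison (zero counts
    stay exactly zero, so detection-based classes are unaffected).
    """
    for sample in counts.columns:
        if sample not in sample_map:
            raise InputError(f"sample {sample} missing from the sample map")
    work = counts.astype(float)
    if normalize_depth:
        depths = work.sum(axis=0)
        if (depths <= 0).any():
            raise InputError("cannot depth-normalize an empty sample")
        work = work * (depths.min() / depths)
    crops = sorted({crop for crop, _ in sample_map.values()})
    rows = []
    for crop in crops:
        series_cols = []
        for tp in timepoints:
            matches = [s for s, (c, t) in sample_map.items()
                       if c == crop and t == tp and s in work.columns]
            if len(matches) != 1:
                raise InputError(
                    f"expected one sample for ({crop}, {tp}), got {matches}")
            series_cols.append(matches[0])
        sub = work[series_cols]
        for taxon, series in sub.iterrows():
            call = call_trend(tuple(series), taxon=str(taxon), crop=crop,
                              strict=strict)
            rows.append({"taxon": call.taxon, "crop": call.crop,
                         "trend": call.trend,
                         "symbol": TREND_SYMBOLS[call.trend]})
    return pd.DataFrame(rows)


def summarize_changed(calls: pd.DataFrame,
                      totals_per_gene: Mapping[str, int]) -> pd.DataFrame:
    """Per-gene changed-phylotype accounting.

    `calls` needs columns taxon/crop/trend and a `gene` column (a single
    unnamed gene is assumed when absent).  Per crop, the number of
    changed (non-none) calls; per gene, the number of unique taxa changed
    in at least one crop, its exact fraction of the gene's phylotype
    total, and that fraction rounded to one decimal.
    """
    if calls.empty and not totals_per_gene:
        raise InputError("no calls and no totals to summarize")
    work = calls.copy()
    if "gene" not in work.columns:
        if len(totals_per_gene) != 1:
            raise InputError("calls lack a gene column; totals are ambiguous")
        work["gene"] = next(iter(totals_per_gene))
    rows = []
    for gene, total in totals_per_gene.items():
        if total <= 0:
            raise InputError(f"gene {gene} has a non-positive phylotype total")
        sub = work[(work["gene"] == gene) & (work["trend"] != "none")]
        per_crop = sub.groupby("crop")["taxon"].nunique().to_dict()
        unique_changed = sub["taxon"].nunique()
        exact = 100.0 * unique_changed / total
        rows.append({"gene": gene, "total_phylotypes": int(total),
                     "unique_changed": int(unique_changed),
                     "per_crop_changed": per_crop,
                     "percent_changed_exact": exact,
                     "percent_changed": round_half_away(exact, 1)})
    return pd.DataFrame(rows)
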