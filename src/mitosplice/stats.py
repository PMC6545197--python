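"""Splicing-efficiency and abundance statistics from junction-read counts.

An unspliced precursor molecule presents two countable junctions (the 5'SS
and the 3'SS flanks) while each spliced molecule presents a single
exon-ligation junction, so the default summary of the unspliced evidence is
the *mean* of the two flank counts; the *sum* is offered as the conservative
alternative since the original counting arithmetic is not fully specified.
Intervals are Wilson score intervals (well-behaved at the small counts
junction counting yields); abundances are normalized as reads per kilobase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .classify import ClassificationCounts
from .genome import InputError
from .splice import JunctionCategory

__all__ = [
    "EfficiencyEstimate",
    "RatioEstimate",
    "splicing_efficiency",
    "compare_introns",
    "reads_per_kb",
    "splicing_report",
]


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Point estimate and 95% Wilson interval of the spliced fraction."""

    n_spliced: int
    n_unspliced_5ss: int
    n_unspliced_3ss: int
    formula: str
    unspliced_summary: float
    spliced_fraction: float
    ci_low: float
    ci_high: float

    @property
    def unspliced_fraction(self) -> float:
        return 1.0 - self.spliced_fraction

    def covers(self, truth: float) -> bool:
        return self.ci_low <= truth <= self.ci_high


def splicing_efficiency(
    n_spliced: int,
    n_unspliced_5ss: int,
    n_unspliced_3ss: int,
    unspliced_formula: str = "mean",
    conf: float = 0.95,
) -> EfficiencyEstimate | None:
    """Spliced fraction from junction-spanning read counts.

    Returns ``None`` when every count is zero (the fraction is undefined).
    """
    if unspliced_formula not in {"mean", "sum"}:
        raise InputError("unspliced_formula must be 'mean' or 'sum'")
    if min(n_spliced, n_unspliced_5ss, n_unspliced_3ss) < 0:
        raise InputError("counts must be non-negative")
    if unspliced_formula == "mean":
        unspliced = (n_unspliced_5ss + n_unspliced_3ss) / 2
    else:
        unspliced = float(n_unspliced_5ss + n_unspliced_3ss)
    denom = n_spliced + unspliced
    if denom == 0:
        return None
    fraction = n_spliced / denom
    nobs = n_spliced + int(round(unspliced))
    if nobs == 0:
        lo, hi = 0.0, 1.0
    else:
        lo, hi = proportion_confint(n_spliced, nobs, alpha=1 - conf, method="wilson")
    return EfficiencyEstimate(
        n_spliced=n_spliced,
        n_unspliced_5ss=n_unspliced_5ss,
        n_unspliced_3ss=n_unspliced_3ss,
        formula=unspliced_formula,
        unspliced_summary=unspliced,
        spliced_fraction=fraction,
        ci_low=float(lo),
        ci_high=float(hi),
    )


@dataclass(frozen=True)
class RatioEstimate:
    ratio: float
    ci_low: float
    ci_high: float
    infinite: bool = False


def compare_introns(
    n_spliced_a: int, n_spliced_b: int, conf: float = 0.95
) -> RatioEstimate:
    """Ratio of spliced-read counts with a log-normal interval.

    Treats each count as Poisson; the interval is a normal approximation on
    the log ratio with variance 1/a + 1/b.
    """
    if n_spliced_a < 0 or n_spliced_b < 0:
        raise InputError("counts must be non-negative")
    if n_spliced_b == 0:
        return RatioEstimate(math.inf, math.nan, math.nan, infinite=True)
    if n_spliced_a == 0:
        return RatioEstimate(0.0, math.nan, math.nan)
    ratio = n_spliced_a / n_spliced_b
    z = norm.ppf(0.5 + conf / 2)
    se = math.sqrt(1 / n_spliced_a + 1 / n_spliced_b)
    return RatioEstimate(
        ratio=ratio,
        ci_low=ratio * math.exp(-z * se),
        ci_high=ratio * math.exp(z * se),
    )


def reads_per_kb(
    counts: Mapping[str, int], lengths: Mapping[str, int]
) -> pd.DataFrame:
    """Per-feature read counts normalized to feature size in kilobases."""
    rows = []
    for fid in lengths:
        length = lengths[fid]
        if length <= 0:
            raise InputError(f"feature {fid} has non-positive length")
        n = counts.get(fid, 0)
        rows.append(
            {"feature": fid, "reads": n, "length_kb": length / 1000,
             "reads_per_kb": n / (length / 1000)}
        )
    return pd.DataFrame(rows, columns=["feature", "reads", "length_kb", "reads_per_kb"])


def splicing_report(
    counts: ClassificationCounts,
    intron_ids: Sequence[str],
    feature_lengths: Mapping[str, int] | None = None,
    unspliced_formula: str = "mean",
    n_backsplice_support: Mapping[str, int] | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the per-intron efficiency table and the abundance table."""
    rows = []
    for iid in intron_ids:
        n_spliced = counts.junction_count(iid, JunctionCategory.E1E2_LIGATION)
        n5 = counts.junction_count(iid, JunctionCategory.UNSPLICED_5SS)
        n3 = counts.junction_count(iid, JunctionCategory.UNSPLICED_3SS)
        n_circle = counts.junction_count(iid, JunctionCategory.INTRON_CIRCLE)
        est = splicing_efficiency(n_spliced, n5, n3, unspliced_formula)
        rows.append(
            {
                "intron": iid,
                "n_spliced": n_spliced,
                "n_unspliced_5ss": n5,
                "n_unspliced_3ss": n3,
                "unspliced_summary": est.unspliced_summary if est else math.nan,
                "spliced_fraction": est.spliced_fraction if est else math.nan,
                "ci_low": est.ci_low if est else math.nan,
                "ci_high": est.ci_high if est else math.nan,
                "n_circle": n_circle,
                "n_backsplice_support": (n_backsplice_support or {}).get(iid, 0),
            }
        )
    report = {"introns": pd.DataFrame(rows)}
    if feature_lengths:
        report["features"] = reads_per_kb(counts.feature_counts, feature_lengths)
    return report
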