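"""Variant classification and per-sample summaries.

Each annotated call is assigned exactly one of three classes:

* ``APPARENTLY_TRUE`` — the allele is absent from the cohort of normals
  (frequency <= ``pop_absent_max``, default 0) and the pool complement shows
  essentially no support (defined PC-AF < 0.01);
* ``SUSPECTED_CONTAMINANT`` — the allele is common in the cohort
  (frequency >= 5%) and the complement shows considerable support
  (PC-AF >= 0.2), the signature of a hop-derived germline artefact;
* ``AMBIGUOUS`` — everything else, including every call whose PC-AF is
  undefined: absence of evidence about the complement must not certify a call.

Both the 0.2 and 5% bounds are inclusive; the 0.01 bound is strict. A sample
is flagged high-contamination when its estimated contaminant read fraction is
>= 0.5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from scipy import stats

from .datamodel import HopauditError, Thresholds
from .pcaf import PCAFRecord


class ClassLabel(Enum):
    APPARENTLY_TRUE = "apparently_true"
    SUSPECTED_CONTAMINANT = "suspected_contaminant"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample class tallies plus the contamination flag."""

    sample_id: str
    n_true: int
    n_contam: int
    n_ambiguous: int
    contamination_estimate: float
    high_contamination: bool


def classify(record: PCAFRecord, pop_freq: float,
             thresholds: Thresholds = Thresholds()) -> ClassLabel:
    """Assign the call's class from its cohort frequency and PC-AF.

    Total function: every (pop_freq, pcaf) pair, including undefined PC-AF,
    maps to exactly one label.
    """
    if not 0.0 <= pop_freq <= 1.0:
        raise HopauditError(f"pop_freq {pop_freq} outside [0, 1]")
    pcaf = record.pcaf
    if pcaf is None:
        return ClassLabel.AMBIGUOUS
    if pop_freq <= thresholds.pop_absent_max and pcaf < thresholds.pcaf_true_max:
        return ClassLabel.APPARENTLY_TRUE
    if pop_freq >= thresholds.pop_common_min and pcaf >= thresholds.pcaf_contam_min:
        return ClassLabel.SUSPECTED_CONTAMINANT
    return ClassLabel.AMBIGUOUS


def summarize_sample(
    sample_id: str,
    labels: Sequence[ClassLabel],
    contamination_estimate: float,
    thresholds: Thresholds = Thresholds(),
) -> SampleSummary:
    """Tally class labels and flag the sample's contamination level."""
    if not 0.0 <= contamination_estimate <= 1.0:
        raise HopauditError(
            f"contamination_estimate {contamination_estimate} outside [0, 1]")
    return SampleSummary(
        sample_id=sample_id,
        n_true=sum(1 for l in labels if l is ClassLabel.APPARENTLY_TRUE),
        n_contam=sum(1 for l in labels if l is ClassLabel.SUSPECTED_CONTAMINANT),
        n_ambiguous=sum(1 for l in labels if l is ClassLabel.AMBIGUOUS),
        contamination_estimate=contamination_estimate,
        high_contamination=contamination_estimate
        >= thresholds.contamination_high_min,
    )


def rank_correlation(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman rank correlation between per-sample suspected-contaminant
    counts and contamination estimates.

    Ties get midranks; the p-value is two-sided and is reported descriptively,
    never used as a filter. Requires at least 3 pairs.
    """
    if len(pairs) < 3:
        raise HopauditError(f"need >= 3 pairs, got {len(pairs)}")
    x, y = zip(*pairs)
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def write_summary_table(summaries: Sequence[SampleSummary],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_true\tn_contam\tn_ambiguous\t"
                 "contamination_estimate\thigh_contamination\n")
        for s in summaries:
            fh.write(f"{s.sample_id}\t{s.n_true}\t{s.n_contam}\t"
                     f"{s.n_ambiguous}\t{s.contamination_estimate:.6g}\t"
                     f"{str(s.high_contamination).lower()}\n")
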