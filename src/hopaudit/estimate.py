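"""Marker-based contamination estimation.

Estimates the fraction ``c`` of a sample's reads that originate from other
individuals, using allele counts at population marker sites where the host is
homozygous. At a host hom-ref marker with population alt frequency ``p``,
foreign reads carry the alt allele with probability ~``p``, so the observed
alt-read fraction has expectation ``c * p`` plus sequencing error; at a
hom-alt marker the foreign allele is the reference, with weight ``1 - p``.

The estimator is method-of-moments: with foreign-allele count ``x_i``, depth
``d_i`` and weight ``q_i`` (``p_i`` at hom-ref, ``1 - p_i`` at hom-alt)
summed over markers,

    c_hat = sum_i (x_i - d_i * e / 3) / sum_i (d_i * q_i),  clipped to [0, 1]

where ``e`` is the uniform miscall rate (each specific wrong base appears
with probability ``e/3``). A percentile bootstrap over markers gives an
optional 95% interval. Host genotypes come from simulation truth or a
supplied matched-normal genotype table; genotype calling from reads is out
of scope. This is a deliberately transparent single-parameter estimator, not
a reimplementation of likelihood-based tools; its expectation does not
depend on how ``c`` is split among contaminant sources.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    BASE_INDEX,
    GenomicSite,
    HopauditError,
    PileupCounts,
    PopulationFrequencyTable,
)

#: Marker sites must be common enough to be informative on both alleles.
MARKER_FREQ_MIN = 0.05
MARKER_FREQ_MAX = 0.95


@dataclass(frozen=True)
class MarkerSite:
    """A population marker where the host sample is homozygous."""

    site: GenomicSite
    pop_freq: float
    host_dosage: int  # 0 (hom-ref) or 2 (hom-alt)

    def __post_init__(self) -> None:
        if not MARKER_FREQ_MIN <= self.pop_freq <= MARKER_FREQ_MAX:
            raise HopauditError(
                f"marker frequency {self.pop_freq} outside "
                f"[{MARKER_FREQ_MIN}, {MARKER_FREQ_MAX}]")
        if self.host_dosage not in (0, 2):
            raise HopauditError("host must be homozygous at a marker")

    @property
    def foreign_base(self) -> str:
        """The base diagnostic of foreign reads at this marker."""
        return self.site.alt if self.host_dosage == 0 else self.site.ref

    @property
    def foreign_weight(self) -> float:
        """Population probability that a foreign read carries foreign_base."""
        return self.pop_freq if self.host_dosage == 0 else 1.0 - self.pop_freq


@dataclass(frozen=True)
class ContaminationEstimate:
    c_hat: float
    n_markers: int
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not self.ci_low <= self.c_hat <= self.ci_high:
                raise HopauditError("bootstrap interval must contain c_hat")


def select_markers(
    freq_table: PopulationFrequencyTable,
    host_genotypes: Mapping[GenomicSite, int],
) -> list[MarkerSite]:
    """Markers with 0.05 <= p <= 0.95 where the host is homozygous.

    ``host_genotypes`` maps sites to alt dosages (0/1/2); heterozygous sites
    are excluded because host alleles there are indistinguishable from
    foreign ones. Deterministic (sorted) order.
    """
    markers: list[MarkerSite] = []
    for site in freq_table.sites():
        p = freq_table.freqs[site]
        if not MARKER_FREQ_MIN <= p <= MARKER_FREQ_MAX:
            continue
        dosage = host_genotypes.get(site)
        if dosage in (0, 2):
            markers.append(MarkerSite(site, p, int(dosage)))
    if not markers:
        raise HopauditError("no qualifying marker sites")
    return markers


def estimate_contamination(
    pileup: PileupCounts,
    markers: Sequence[MarkerSite],
    error_rate: float = 0.001,
    bootstrap: int = 0,
    seed: int = 0,
    min_markers: int = 100,
) -> ContaminationEstimate:
    """Method-of-moments contaminant read fraction from marker allele counts.

    Requires coverage of at least ``min_markers`` marker sites. With
    ``bootstrap`` > 0, a seeded percentile bootstrap over markers yields a
    95% interval.
    """
    x = np.empty(len(markers))
    d = np.empty(len(markers))
    q = np.empty(len(markers))
    covered = 0
    for i, m in enumerate(markers):
        counts = pileup.base_counts(m.site.chrom, m.site.pos)
        d[i] = counts.sum()
        x[i] = counts[BASE_INDEX[m.foreign_base]]
        q[i] = m.foreign_weight
        if d[i] > 0:
            covered += 1
    if covered < min_markers:
        raise HopauditError(
            f"pileup covers only {covered} marker site(s); need >= {min_markers}")

    def moments(idx: np.ndarray) -> float:
        denom = float((d[idx] * q[idx]).sum())
        if denom == 0:
            raise HopauditError("zero total marker information (sum d_i q_i = 0)")
        num = float((x[idx] - d[idx] * error_rate / 3.0).sum())
        return float(np.clip(num / denom, 0.0, 1.0))

    all_idx = np.arange(len(markers))
    c_hat = moments(all_idx)
    ci_low = ci_high = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        reps = np.array([
            moments(rng.choice(all_idx, size=len(all_idx), replace=True))
            for _ in range(bootstrap)
        ])
        ci_low = float(min(np.quantile(reps, 0.025), c_hat))
        ci_high = float(max(np.quantile(reps, 0.975), c_hat))
    return ContaminationEstimate(c_hat, len(markers), ci_low, ci_high)


def write_host_genotypes(genotypes: Mapping[GenomicSite, int],
                         path: str | Path) -> None:
    """Host genotype TSV: chrom, pos, ref, alt, dosage (alt allele count)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tdosage\n")
        for site in sorted(genotypes):
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t"
                     f"{genotypes[site]}\n")


def read_host_genotypes(path: str | Path) -> dict[GenomicSite, int]:
    out: dict[GenomicSite, int] = {}
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            dosage = int(row["dosage"])
            if dosage not in (0, 1, 2):
                raise HopauditError(f"dosage {dosage} outside {{0, 1, 2}}")
            out[GenomicSite(row["chrom"], int(row["pos"]),
                            row["ref"], row["alt"])] = dosage
    return out


def write_estimates(
    estimates: Mapping[str, ContaminationEstimate], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tc_hat\tn_markers\tci_low\tci_high\n")
        for sid in sorted(estimates):
            est = estimates[sid]
            lo = f"{est.ci_low:.6g}" if est.ci_low is not None else ""
            hi = f"{est.ci_high:.6g}" if est.ci_high is not None else ""
            fh.write(f"{sid}\t{est.c_hat:.6g}\t{est.n_markers}\t{lo}\t{hi}\n")
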