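"""Synthetic multiplexed pools with index hopping, plus explicit admixtures.

The generator works at pileup level: it draws per-site base counts, not read
sequences, because PC-AF computation, classification and contamination
estimation consume counts only. Every simulated read keeps an *origin tag* —
the library it truly came from — which provides ground truth for hop-rate
recovery, admixture validation by library-specific depth, and end-to-end
classifier checks.

Model
-----
Each library emits a fixed number of reads per site (defaults 300 for tumour
and 150 for normal libraries, echoing deep-exome coverage). A read's base is
drawn from its source genotype — alt with probability dosage/2 for germline
sites, or with the cellular alt fraction at a tumour's somatic sites — then
miscalled to a uniformly chosen other base with probability ``error_rate``.
With probability ``hop_rate`` the read is then reassigned to another member
of the pool, by default proportionally to library pool fractions (free
indexed molecules are more abundant for larger libraries); a uniform mode
exists for sensitivity checks. Hopping is symmetric and memoryless per read
and conserves the total read count exactly.

Admixtures reproduce deliberate in-silico mixing: reads at each site are
drawn from the target library with weight 1 - c and from each contaminant
library with its specified fraction, emulating contamination by 1, 2, 4 or 7
libraries at ~2% or ~8% total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .datamodel import (
    BASES,
    BASE_INDEX,
    GenomicSite,
    HopauditError,
    PileupCounts,
    PoolLayout,
    PopulationFrequencyTable,
    Role,
    VariantCall,
)


# ---------------------------------------------------------------------------
# Truth layer
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTruth:
    """Ground-truth genotypes for the simulated individuals.

    ``dosages[ind][i]`` is the germline alt dosage (0/1/2) of individual
    ``ind`` at ``sites[i]``; ``somatic[ind]`` maps site indices to cellular
    alt fractions of that individual's tumour. Somatic sites are placed at
    cohort-absent loci, so they are disjoint from germline variation within
    the individual.
    """

    sites: list[GenomicSite]
    freqs: np.ndarray
    dosages: dict[str, np.ndarray]
    somatic: dict[str, dict[int, float]] = field(default_factory=dict)

    def alt_probs(self, individual_id: str, tumour: bool) -> np.ndarray:
        """Per-site probability that a read from this library carries alt."""
        q = self.dosages[individual_id].astype(float) / 2.0
        if tumour:
            for i, af in self.somatic.get(individual_id, {}).items():
                q[i] = af
        return q


@dataclass(frozen=True)
class HopConfig:
    """Index-hopping simulation parameters."""

    hop_rate: float = 0.01
    depth_tumour: int = 300
    depth_normal: int = 150
    error_rate: float = 0.001
    seed: int = 0
    mode: str = "proportional"  # or "uniform"

    def __post_init__(self) -> None:
        if not 0.0 <= self.hop_rate < 0.5:
            raise HopauditError(f"hop_rate {self.hop_rate} outside [0, 0.5)")
        if not 0.0 <= self.error_rate <= 0.01:
            raise HopauditError(f"error_rate {self.error_rate} outside [0, 0.01]")
        if self.mode not in ("proportional", "uniform"):
            raise HopauditError(f"unknown reassignment mode {self.mode!r}")
        if self.depth_tumour <= 0 or self.depth_normal <= 0:
            raise HopauditError("depths must be positive")


@dataclass(frozen=True)
class MixtureSpec:
    """An explicit read admixture: target plus (contaminant, fraction) pairs."""

    target: str
    contaminants: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        for sid, f in self.contaminants:
            if f <= 0:
                raise HopauditError(f"contaminant fraction {f} for {sid!r} <= 0")
            if sid == self.target:
                raise HopauditError("a contaminant cannot equal the target")
        if not 0.0 <= self.total < 1.0:
            raise HopauditError(
                f"total contamination {self.total} outside [0, 1)")

    @property
    def total(self) -> float:
        return float(sum(f for _s, f in self.contaminants))


def synthetic_frequency_table(
    n_common: int,
    n_absent: int = 0,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.05, 0.95),
    chrom: str = "1",
    start: int = 10_000,
    spacing: int = 1_000,
) -> PopulationFrequencyTable:
    """A synthetic cohort frequency table on one contig.

    ``n_common`` sites get frequencies uniform in ``freq_range``;
    ``n_absent`` additional sites are stored with frequency 0 and serve as
    candidate somatic loci.
    """
    rng = np.random.default_rng(seed)
    n = n_common + n_absent
    freqs = np.concatenate([
        rng.uniform(*freq_range, size=n_common), np.zeros(n_absent)])
    table: dict[GenomicSite, float] = {}
    for i in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        site = GenomicSite(chrom, start + i * spacing, BASES[ref], BASES[alt])
        table[site] = float(freqs[i])
    return PopulationFrequencyTable(table)


def draw_genotypes(
    freq_table: PopulationFrequencyTable,
    individuals: Sequence[str],
    n_somatic_per_tumour: int = 0,
    somatic_af_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
) -> GenotypeTruth:
    """Draw germline genotypes under Hardy-Weinberg and plant somatic sites.

    Germline dosages are Binomial(2, p) per individual and site. Each
    individual's tumour gets ``n_somatic_per_tumour`` somatic sites drawn
    without replacement from the cohort-absent loci (frequency 0), with
    cellular alt fractions uniform in ``somatic_af_range``.
    """
    if len(freq_table) == 0:
        raise HopauditError("frequency table is empty")
    rng = np.random.default_rng(seed)
    sites = freq_table.sites()
    freqs = np.array([freq_table.freqs[s] for s in sites])
    dosages = {
        ind: rng.binomial(2, freqs) for ind in individuals
    }
    somatic: dict[str, dict[int, float]] = {}
    if n_somatic_per_tumour > 0:
        candidates = np.flatnonzero(freqs == 0.0)
        if len(candidates) < n_somatic_per_tumour:
            raise HopauditError(
                f"only {len(candidates)} cohort-absent site(s) available for "
                f"{n_somatic_per_tumour} somatic site(s) per tumour")
        for ind in individuals:
            chosen = rng.choice(candidates, size=n_somatic_per_tumour,
                                replace=False)
            afs = rng.uniform(*somatic_af_range, size=n_somatic_per_tumour)
            somatic[ind] = {int(i): float(a) for i, a in zip(chosen, afs)}
    return GenotypeTruth(sites, freqs, dosages, somatic)


# ---------------------------------------------------------------------------
# Read-count sampling
# ---------------------------------------------------------------------------

def _base_probs(q: np.ndarray, ref_idx: np.ndarray, alt_idx: np.ndarray,
                e: float) -> np.ndarray:
    """Per-site base-call probabilities given per-read alt probability q and
    a uniform miscall rate e (each wrong base with probability e/3)."""
    n = len(q)
    p = np.full((n, 4), e / 3.0)
    rows = np.arange(n)
    p[rows, ref_idx] = (1.0 - q) * (1.0 - e) + q * e / 3.0
    p[rows, alt_idx] = q * (1.0 - e) + (1.0 - q) * e / 3.0
    return p


def _site_arrays(truth: GenotypeTruth) -> tuple[list, np.ndarray, np.ndarray]:
    sites = [(s.chrom, s.pos, s.ref) for s in truth.sites]
    ref_idx = np.array([BASE_INDEX[s.ref] for s in truth.sites])
    alt_idx = np.array([BASE_INDEX[s.alt] for s in truth.sites])
    return sites, ref_idx, alt_idx


def simulate_pool(
    truth: GenotypeTruth,
    layout: PoolLayout,
    config: HopConfig = HopConfig(),
) -> dict[str, PileupCounts]:
    """Simulate every library in the layout, with hopping inside each pool.

    Returns one origin-tagged :class:`PileupCounts` per sample. Solo-lane
    samples are simulated without hopping. A pool with a single member and a
    positive hop rate is an error (there is no hop destination).
    """
    for s in layout:
        if s.individual_id not in truth.dosages:
            raise HopauditError(f"no genotypes for individual {s.individual_id!r}")
    rng = np.random.default_rng(config.seed)
    sites, ref_idx, alt_idx = _site_arrays(truth)
    n = len(sites)
    out: dict[str, PileupCounts] = {}

    def library_counts(meta) -> np.ndarray:
        q = truth.alt_probs(meta.individual_id, meta.role is Role.TUMOUR)
        p = _base_probs(q, ref_idx, alt_idx, config.error_rate)
        depth = (config.depth_tumour if meta.role is Role.TUMOUR
                 else config.depth_normal)
        return rng.multinomial(depth, p)

    # solo-lane samples: no pool, no hopping
    for meta in layout:
        if meta.pool_id is None:
            counts = library_counts(meta)
            out[meta.sample_id] = PileupCounts(
                meta.sample_id, list(sites), counts,
                {meta.sample_id: counts.copy()})

    for pool_id, members in sorted(layout.pools().items()):
        if len(members) == 1 and config.hop_rate > 0:
            raise HopauditError(
                f"pool {pool_id!r} has a single member but hop_rate > 0: "
                "no hop destination exists")
        members = sorted(members, key=lambda m: m.sample_id)
        assigned = {
            m.sample_id: {o.sample_id: np.zeros((n, 4), dtype=np.int64)
                          for o in members}
            for m in members
        }
        for origin in members:
            counts = library_counts(origin)
            if config.hop_rate > 0 and len(members) > 1:
                hopped = rng.binomial(counts, config.hop_rate)
            else:
                hopped = np.zeros_like(counts)
            assigned[origin.sample_id][origin.sample_id] += counts - hopped
            if hopped.sum() == 0:
                continue
            others = [m for m in members if m.sample_id != origin.sample_id]
            if config.mode == "proportional":
                w = np.array([m.pool_fraction for m in others], dtype=float)
            else:
                w = np.ones(len(others))
            w /= w.sum()
            for b in range(4):
                dest_counts = rng.multinomial(hopped[:, b], w)  # (n, D)
                for d, m in enumerate(others):
                    assigned[m.sample_id][origin.sample_id][:, b] += \
                        dest_counts[:, d]
        for m in members:
            origin_counts = assigned[m.sample_id]
            total = sum(origin_counts.values())
            out[m.sample_id] = PileupCounts(
                m.sample_id, list(sites), total, origin_counts)
    return out


def build_admixture(
    spec: MixtureSpec,
    truth: GenotypeTruth,
    depth: int = 300,
    seed: int = 0,
    error_rate: float = 0.001,
    layout: PoolLayout | None = None,
) -> PileupCounts:
    """Mix reads from contaminant libraries into the target at known fractions.

    At every site, ``depth`` reads are drawn with origin probabilities
    (1 - c, f_1, ..., f_k); each origin's reads are then sampled from that
    library's genotype with the uniform miscall rate. Without a layout, the
    sample ids in the spec are taken to be individual ids with tumour role.
    """
    rng = np.random.default_rng(seed)
    sites, ref_idx, alt_idx = _site_arrays(truth)
    n = len(sites)

    def resolve(sample_id: str) -> tuple[str, bool]:
        if layout is not None:
            meta = layout.sample(sample_id)
            return meta.individual_id, meta.role is Role.TUMOUR
        return sample_id, True

    origins = [spec.target] + [sid for sid, _f in spec.contaminants]
    weights = np.array([1.0 - spec.total]
                       + [f for _s, f in spec.contaminants])
    origin_reads = rng.multinomial(depth, weights / weights.sum(), size=n)
    origin_counts: dict[str, np.ndarray] = {}
    for k, sid in enumerate(origins):
        ind, tumour = resolve(sid)
        if ind not in truth.dosages:
            raise HopauditError(f"no genotypes for individual {ind!r}")
        q = truth.alt_probs(ind, tumour)
        p = _base_probs(q, ref_idx, alt_idx, error_rate)
        origin_counts[sid] = rng.multinomial(origin_reads[:, k], p)
    total = sum(origin_counts.values())
    return PileupCounts(spec.target, sites, total, origin_counts)


def verify_mixture(pileup: PileupCounts) -> dict[str, float]:
    """Each origin library's share of total reads (library-specific depth).

    Shares sum to 1. Requires an origin-tagged pileup.
    """
    if not pileup.tagged:
        raise HopauditError("pileup carries no origin tags")
    totals = {o: int(arr.sum()) for o, arr in pileup.origin_counts.items()}
    grand = sum(totals.values())
    if grand == 0:
        raise HopauditError("pileup holds no reads")
    return {o: t / grand for o, t in sorted(totals.items())}


# ---------------------------------------------------------------------------
# Truth export and naive candidate calling (for end-to-end checks)
# ---------------------------------------------------------------------------

def truth_class(
    truth: GenotypeTruth,
    layout: PoolLayout,
    sample_id: str,
    site_index: int,
) -> str | None:
    """True variant class of a locus in one sample.

    ``germline`` — the sample's individual carries the allele;
    ``somatic`` — the site is a planted somatic site of this tumour;
    ``hop-contaminant`` — the sample's individual lacks the allele but a
    co-pooled library from another individual carries it (germline or
    somatic); ``None`` — nobody in the pool carries the allele.
    """
    meta = layout.sample(sample_id)
    if meta.role is Role.TUMOUR and site_index in truth.somatic.get(
            meta.individual_id, {}):
        return "somatic"
    if truth.dosages[meta.individual_id][site_index] >= 1:
        return "germline"
    if meta.pool_id is not None:
        for other in layout.pools()[meta.pool_id]:
            if other.individual_id == meta.individual_id:
                continue
            if truth.dosages[other.individual_id][site_index] >= 1:
                return "hop-contaminant"
            if other.role is Role.TUMOUR and site_index in truth.somatic.get(
                    other.individual_id, {}):
                return "hop-contaminant"
    return None


def write_truth(truth: GenotypeTruth, layout: PoolLayout,
                path: str | Path, seed: int | None = None) -> None:
    """Truth TSV: one row per (sample, site) with a non-None true class."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("chrom\tpos\tref\talt\tsample_id\tclass\n")
        for meta in layout:
            for i, site in enumerate(truth.sites):
                cls = truth_class(truth, layout, meta.sample_id, i)
                if cls is not None:
                    fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t"
                             f"{site.alt}\t{meta.sample_id}\t{cls}\n")


def candidate_calls(
    pileup: PileupCounts,
    truth: GenotypeTruth,
    min_alt_reads: int = 3,
    individual_id: str | None = None,
) -> list[VariantCall]:
    """Naive candidate caller over a simulated pileup.

    Emits a call at every truth locus where the sample's own pileup shows at
    least ``min_alt_reads`` reads of the alt base — a permissive stand-in for
    a somatic caller, so that hop-derived artefacts surface as candidates.
    With ``individual_id``, loci where that individual truly carries a
    germline variant are suppressed, emulating a matched-normal somatic
    caller that rejects the host's own germline variation.
    """
    dosages = truth.dosages[individual_id] if individual_id else None
    calls: list[VariantCall] = []
    for i, site in enumerate(truth.sites):
        if dosages is not None and dosages[i] >= 1:
            continue
        counts = pileup.counts[i]
        alt = int(counts[BASE_INDEX[site.alt]])
        depth = int(counts.sum())
        if alt >= min_alt_reads and depth > 0:
            calls.append(VariantCall(site, pileup.sample_id, alt, depth))
    return calls
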