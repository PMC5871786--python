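"""Core domain types and file IO for pool-complement contamination auditing.

The types here model the minimal facts the method needs about a multiplexed
sequencing experiment: which somatic SNVs were called in which tumour sample
(:class:`VariantCall`), which libraries shared a pool and in what proportions
(:class:`PoolLayout`), per-sample base counts at the variant loci
(:class:`PileupCounts`), and how common each variant allele is in a reference
cohort of normals (:class:`PopulationFrequencyTable`).

All coordinates are 1-based inclusive (VCF convention), including the internal
pileup TSV. Only single-nucleotide variants are modelled; indels are rejected
at ingest.

File formats
------------
* calls: VCF 4.2 with per-sample ``AD`` (allelic depths);
* pileup: TSV ``chrom pos ref sample_id nA nC nG nT [origin_sample]`` —
  the optional ``origin_sample`` column carries per-read source truth for
  simulated data (one row per site and origin library);
* layout: TSV or YAML with ``sample_id individual_id pool_id role
  pool_fraction``;
* cohort frequencies: TSV ``chrom pos ref alt frequency`` or a sites-only VCF
  with an ``AF`` INFO field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

logger = logging.getLogger("hopaudit")

#: Canonical base order used by every count array in the package.
BASES: tuple[str, str, str, str] = ("A", "C", "G", "T")
BASE_INDEX: dict[str, int] = {b: i for i, b in enumerate(BASES)}

_FRACTION_TOL = 1e-9


class HopauditError(ValueError):
    """Raised for malformed inputs or contract violations."""


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A biallelic SNV locus: 1-based position with single-base ref and alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise HopauditError(f"position must be >= 1, got {self.pos}")
        if self.ref not in BASE_INDEX or self.alt not in BASE_INDEX:
            raise HopauditError(
                f"alleles must be single bases in {BASES}, got {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise HopauditError(f"ref and alt must differ at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV call in one tumour sample.

    ``af`` is always derived from the stored counts, so the identity
    ``af == alt_count / depth`` holds exactly.
    """

    site: GenomicSite
    sample_id: str
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise HopauditError(
                f"call at {self.site.chrom}:{self.site.pos} has depth {self.depth}"
            )
        if not 0 <= self.alt_count <= self.depth:
            raise HopauditError(
                f"alt_count {self.alt_count} outside [0, depth={self.depth}]"
            )

    @property
    def af(self) -> float:
        """Sample allelic fraction, alt_count / depth."""
        return self.alt_count / self.depth


class Role(str, Enum):
    TUMOUR = "tumour"
    NORMAL = "normal"


@dataclass(frozen=True)
class SampleMeta:
    """One library in the multiplexing design.

    ``pool_id`` is ``None`` for libraries sequenced alone on a lane.
    ``pool_fraction`` is this library's share of its pool (1.0 for solo lanes).
    """

    sample_id: str
    individual_id: str
    pool_id: str | None
    role: Role
    pool_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pool_fraction <= 1.0:
            raise HopauditError(
                f"pool_fraction {self.pool_fraction} for {self.sample_id} "
                "outside [0, 1]"
            )


@dataclass
class PoolLayout:
    """The full multiplexing layout: which samples shared which pool."""

    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise HopauditError(f"duplicate sample_id(s) in layout: {sorted(dupes)}")
        self._by_id = {s.sample_id: s for s in self.samples}
        for pool_id, members in self.pools().items():
            total = sum(m.pool_fraction for m in members)
            if abs(total - 1.0) > _FRACTION_TOL:
                raise HopauditError(
                    f"pool {pool_id!r}: fractions sum to {total}, expected 1"
                )

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def sample(self, sample_id: str) -> SampleMeta:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise HopauditError(
                f"unknown sample {sample_id!r}; layout has "
                f"{sorted(self._by_id)}"
            ) from None

    def pools(self) -> dict[str, list[SampleMeta]]:
        """Pooled samples grouped by pool_id (solo-lane samples excluded)."""
        out: dict[str, list[SampleMeta]] = {}
        for s in self.samples:
            if s.pool_id is not None:
                out.setdefault(s.pool_id, []).append(s)
        return out


@dataclass
class PileupCounts:
    """Per-sample base counts at a fixed panel of sites.

    ``counts[i]`` holds the (A, C, G, T) read counts of ``sample_id`` at
    ``sites[i] = (chrom, pos, ref)``. ``origin_counts`` — present only for
    simulated data — stratifies the same counts by the true source library;
    per site, the origin-stratified counts sum to ``counts``.
    """

    sample_id: str
    sites: list[tuple[str, int, str]]
    counts: np.ndarray
    origin_counts: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.sites), 4):
            raise HopauditError(
                f"counts shape {self.counts.shape} != ({len(self.sites)}, 4)"
            )
        if (self.counts < 0).any():
            raise HopauditError("negative base counts")
        if self.origin_counts is not None:
            total = np.zeros_like(self.counts)
            for origin, arr in self.origin_counts.items():
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != self.counts.shape or (arr < 0).any():
                    raise HopauditError(f"bad origin counts for {origin!r}")
                self.origin_counts[origin] = arr
                total += arr
            if not np.array_equal(total, self.counts):
                raise HopauditError("origin-stratified counts do not sum to totals")
        self._index = {(c, p): i for i, (c, p, _r) in enumerate(self.sites)}

    @property
    def tagged(self) -> bool:
        return self.origin_counts is not None

    def base_counts(self, chrom: str, pos: int) -> np.ndarray:
        """(A, C, G, T) counts at a locus; zeros when the locus is uncovered."""
        i = self._index.get((chrom, pos))
        if i is None:
            return np.zeros(4, dtype=np.int64)
        return self.counts[i]

    def depth(self, chrom: str, pos: int) -> int:
        return int(self.base_counts(chrom, pos).sum())


@dataclass
class PopulationFrequencyTable:
    """Cohort alternate-allele frequencies; absent sites mean frequency 0."""

    freqs: dict[GenomicSite, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, f in self.freqs.items():
            if not 0.0 <= f <= 1.0:
                raise HopauditError(
                    f"frequency {f} at {site.chrom}:{site.pos} outside [0, 1]"
                )

    def lookup(self, site: GenomicSite) -> float:
        return self.freqs.get(site, 0.0)

    def sites(self) -> list[GenomicSite]:
        return sorted(self.freqs)

    def __len__(self) -> int:
        return len(self.freqs)


@dataclass(frozen=True)
class Thresholds:
    """Classification and flagging thresholds.

    Defaults follow the published filter: a call is *apparently true* when the
    allele is absent from the cohort and PC-AF < 0.01; *suspected contaminant*
    when cohort frequency >= 5% and PC-AF >= 0.2; a sample is
    *high-contamination* at an estimate >= 0.5%. ``min_pc_depth`` guards the
    PC-AF denominator: below it the PC-AF is reported as undefined.
    """

    pcaf_true_max: float = 0.01
    pcaf_contam_min: float = 0.2
    pop_common_min: float = 0.05
    pop_absent_max: float = 0.0
    contamination_high_min: float = 0.005
    min_pc_depth: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.pcaf_true_max < self.pcaf_contam_min <= 1.0:
            raise HopauditError("require 0 <= pcaf_true_max < pcaf_contam_min <= 1")
        if not 0.0 <= self.pop_absent_max < self.pop_common_min <= 1.0:
            raise HopauditError("require 0 <= pop_absent_max < pop_common_min <= 1")


# ---------------------------------------------------------------------------
# VCF calls
# ---------------------------------------------------------------------------

def read_vcf_calls(path: str | Path, sample_id: str) -> list[VariantCall]:
    """Read biallelic SNV calls for one sample from a VCF.

    Multiallelic records are split per alternate allele; non-SNV alleles and
    records where the sample carries no allelic-depth data are skipped (and
    counted in the log). Depth is taken as the sum of the AD field, so AD=10,5
    yields depth 15 and AF 1/3.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample_id not in samples:
            raise HopauditError(
                f"sample {sample_id!r} not in {path.name}; available: {samples}"
            )
        if "AD" not in vcf.header.formats:
            raise HopauditError(f"{path.name} lacks the AD FORMAT field")
        for rec in vcf:
            if rec.alts is None:
                n_skipped += 1
                continue
            ad = rec.samples[sample_id].get("AD")
            if ad is None or all(x is None for x in ad):
                n_skipped += 1
                continue
            depth = int(sum(x for x in ad if x is not None))
            for j, alt in enumerate(rec.alts):
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref == alt \
                        or rec.ref not in BASE_INDEX or alt not in BASE_INDEX:
                    n_skipped += 1
                    continue
                if j + 1 >= len(ad) or ad[j + 1] is None:
                    raise HopauditError(
                        f"missing AD for allele {alt} at {rec.chrom}:{rec.pos} "
                        f"in sample {sample_id!r}"
                    )
                if depth == 0:
                    n_skipped += 1
                    continue
                site = GenomicSite(rec.chrom, rec.pos, rec.ref, alt)
                calls.append(VariantCall(site, sample_id, int(ad[j + 1]), depth))
    logger.info(
        "read %d SNV call(s) for %s from %s (%d record/allele(s) skipped)",
        len(calls), sample_id, path.name, n_skipped,
    )
    return calls


def write_annotated_vcf(
    calls: Sequence[VariantCall],
    pcaf_records: Sequence,
    labels: Sequence,
    path: str | Path,
    pop_freq: PopulationFrequencyTable | None = None,
) -> None:
    """Write calls with PC-AF annotations and class labels to a VCF.

    INFO carries PCAF (omitted when undefined), PCDP (pool-complement depth),
    POPAF (cohort frequency) and CLASS; suspected-contaminant calls get FILTER
    ``suspected_contaminant``, all others PASS. ``pcaf_records`` and ``labels``
    must align one-to-one with ``calls``.
    """
    if not (len(calls) == len(pcaf_records) == len(labels)):
        raise HopauditError("calls, pcaf_records and labels must align one-to-one")
    header = pysam.VariantHeader()
    header.add_line('##source=hopaudit')
    for chrom in sorted({c.site.chrom for c in calls}):
        header.contigs.add(chrom)
    header.info.add("PCAF", 1, "Float", "Pool-complement allelic fraction")
    header.info.add("PCDP", 1, "Integer", "Pool-complement depth at the site")
    header.info.add("POPAF", 1, "Float", "Cohort alternate-allele frequency")
    header.info.add("CLASS", 1, "String",
                    "apparently_true, suspected_contaminant or ambiguous")
    header.filters.add("suspected_contaminant", None, None,
                       "Cohort-common allele with strong pool-complement support")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth")
    for sid in sorted({c.sample_id for c in calls}):
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call, rec_pcaf, label in zip(calls, pcaf_records, labels):
            rec = out.new_record(
                contig=call.site.chrom,
                start=call.site.pos - 1,
                alleles=(call.site.ref, call.site.alt),
            )
            label_name = getattr(label, "name", str(label)).lower()
            if label_name == "suspected_contaminant":
                rec.filter.add("suspected_contaminant")
            else:
                rec.filter.add("PASS")
            if rec_pcaf.pcaf is not None:
                rec.info["PCAF"] = float(rec_pcaf.pcaf)
            rec.info["PCDP"] = int(rec_pcaf.pc_depth)
            rec.info["POPAF"] = float(
                pop_freq.lookup(call.site)) if pop_freq is not None else 0.0
            rec.info["CLASS"] = label_name
            rec.samples[call.sample_id]["AD"] = (
                call.depth - call.alt_count, call.alt_count)
            rec.samples[call.sample_id]["DP"] = call.depth
            out.write(rec)


# ---------------------------------------------------------------------------
# Pool layout
# ---------------------------------------------------------------------------

def _layout_from_rows(rows: list[dict]) -> PoolLayout:
    seen: set[str] = set()
    parsed: list[dict] = []
    for row in rows:
        sid = str(row["sample_id"])
        if sid in seen:
            raise HopauditError(f"duplicate sample_id {sid!r} in layout")
        seen.add(sid)
        pool = row.get("pool_id")
        if pool in (None, "", "-", "NA") or (isinstance(pool, float) and np.isnan(pool)):
            pool = None
        else:
            pool = str(pool)
        frac = row.get("pool_fraction")
        if frac in (None, "", "NA") or (isinstance(frac, float) and np.isnan(frac)):
            frac = None
        else:
            frac = float(frac)
            if frac < 0:
                raise HopauditError(f"negative pool_fraction for {sid!r}")
        role = str(row["role"]).lower().replace("tumor", "tumour")
        parsed.append(dict(sample_id=sid, individual_id=str(row["individual_id"]),
                           pool_id=pool, role=Role(role), fraction=frac))
    # normalise fractions within each pool; absent fractions mean equal shares
    by_pool: dict[str | None, list[dict]] = {}
    for p in parsed:
        by_pool.setdefault(p["pool_id"], []).append(p)
    metas: list[SampleMeta] = []
    for pool_id, members in by_pool.items():
        if pool_id is None:
            for m in members:
                metas.append(SampleMeta(m["sample_id"], m["individual_id"],
                                        None, m["role"], 1.0))
            continue
        fracs = [m["fraction"] for m in members]
        if any(f is None for f in fracs):
            fracs = [1.0] * len(members)
        total = sum(fracs)
        if total <= 0:
            raise HopauditError(f"pool {pool_id!r} has zero total fraction")
        for m, f in zip(members, fracs):
            metas.append(SampleMeta(m["sample_id"], m["individual_id"],
                                    pool_id, m["role"], f / total))
    order = {p["sample_id"]: i for i, p in enumerate(parsed)}
    metas.sort(key=lambda s: order[s.sample_id])
    return PoolLayout(metas)


def read_pool_layout(path: str | Path) -> PoolLayout:
    """Read a pool layout from TSV or YAML; fractions are normalised per pool."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text())
        rows = data["samples"] if isinstance(data, dict) else data
    else:
        df = pd.read_csv(path, sep="\t", comment="#",
                         dtype={"sample_id": str, "individual_id": str})
        rows = df.to_dict("records")
    return _layout_from_rows(rows)


def write_pool_layout(layout: PoolLayout, path: str | Path,
                      seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("sample_id\tindividual_id\tpool_id\trole\tpool_fraction\n")
        for s in layout:
            pool = s.pool_id if s.pool_id is not None else ""
            fh.write(f"{s.sample_id}\t{s.individual_id}\t{pool}\t"
                     f"{s.role.value}\t{s.pool_fraction:.10g}\n")


# ---------------------------------------------------------------------------
# Cohort frequency table
# ---------------------------------------------------------------------------

def read_frequency_table(path: str | Path) -> PopulationFrequencyTable:
    """Read cohort allele frequencies from TSV or a sites-only VCF (AF INFO)."""
    path = Path(path)
    freqs: dict[GenomicSite, float] = {}
    if path.suffix.lower() == ".vcf":
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                afs = rec.info.get("AF")
                if afs is None:
                    raise HopauditError(
                        f"record {rec.chrom}:{rec.pos} lacks the AF INFO field")
                if not isinstance(afs, tuple):
                    afs = (afs,)
                for alt, f in zip(rec.alts or (), afs):
                    f = float(f)
                    if not 0.0 <= f <= 1.0:
                        raise HopauditError(
                            f"frequency {f} at {rec.chrom}:{rec.pos} outside [0, 1]")
                    freqs[GenomicSite(rec.chrom, rec.pos, rec.ref, alt)] = f
        return PopulationFrequencyTable(freqs)
    with open(path) as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                continue
            row = dict(zip(header, fields))
            f = float(row["frequency"])
            if not 0.0 <= f <= 1.0:
                raise HopauditError(
                    f"{path.name} line {lineno}: frequency {f} outside [0, 1]")
            site = GenomicSite(row["chrom"], int(row["pos"]),
                               row["ref"], row["alt"])
            freqs[site] = f
    return PopulationFrequencyTable(freqs)


def write_frequency_table(table: PopulationFrequencyTable, path: str | Path,
                          seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("chrom\tpos\tref\talt\tfrequency\n")
        for site in table.sites():
            fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t"
                     f"{table.freqs[site]:.10g}\n")


# ---------------------------------------------------------------------------
# Pileup tables
# ---------------------------------------------------------------------------

def write_pileup(pileups: Iterable[PileupCounts], path: str | Path,
                 seed: int | None = None) -> None:
    """Write pileups to the internal TSV; origin-tagged pileups get one row
    per (site, origin library)."""
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("chrom\tpos\tref\tsample_id\tnA\tnC\tnG\tnT\torigin_sample\n")
        for pu in pileups:
            for i, (chrom, pos, ref) in enumerate(pu.sites):
                if pu.tagged:
                    for origin in sorted(pu.origin_counts):
                        row = pu.origin_counts[origin][i]
                        fh.write(f"{chrom}\t{pos}\t{ref}\t{pu.sample_id}\t"
                                 f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t"
                                 f"{origin}\n")
                else:
                    row = pu.counts[i]
                    fh.write(f"{chrom}\t{pos}\t{ref}\t{pu.sample_id}\t"
                             f"{row[0]}\t{row[1]}\t{row[2]}\t{row[3]}\t\n")


def read_pileup(path: str | Path) -> dict[str, PileupCounts]:
    """Read the internal pileup TSV; returns one PileupCounts per sample."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"chrom": str, "pos": np.int64, "ref": str, "sample_id": str,
               "nA": np.int64, "nC": np.int64, "nG": np.int64, "nT": np.int64},
    )
    if "origin_sample" in df.columns:
        df["origin_sample"] = df["origin_sample"].fillna("")
    else:
        df["origin_sample"] = ""
    out: dict[str, PileupCounts] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        sites: list[tuple[str, int, str]] = []
        site_row: dict[tuple[str, int], int] = {}
        for chrom, pos, ref in zip(grp["chrom"], grp["pos"], grp["ref"]):
            key = (chrom, int(pos))
            if key not in site_row:
                site_row[key] = len(sites)
                sites.append((chrom, int(pos), ref))
        counts = np.zeros((len(sites), 4), dtype=np.int64)
        tagged = bool((grp["origin_sample"] != "").any())
        origin_counts: dict[str, np.ndarray] = {}
        base_cols = grp[["nA", "nC", "nG", "nT"]].to_numpy()
        for k, (chrom, pos, origin) in enumerate(
                zip(grp["chrom"], grp["pos"], grp["origin_sample"])):
            i = site_row[(chrom, int(pos))]
            counts[i] += base_cols[k]
            if tagged:
                if origin == "":
                    raise HopauditError(
                        f"mixed tagged/untagged rows for sample {sid!r}")
                arr = origin_counts.setdefault(
                    origin, np.zeros((len(sites), 4), dtype=np.int64))
                arr[i] += base_cols[k]
        out[str(sid)] = PileupCounts(str(sid), sites, counts,
                                     origin_counts if tagged else None)
    return out
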