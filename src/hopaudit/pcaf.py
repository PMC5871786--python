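"""Pool-complement allelic fraction (PC-AF).

For a tumour sample sequenced in a multiplexed pool, its *pool complement* is
the set of co-multiplexed libraries from other individuals — the expected
source of index-hopping contamination. For each somatic call we sum, over the
complement libraries, the reads overlapping the call site (``pc_depth``) and
those supporting the variant allele (``pc_alt``); their ratio is the PC-AF.
A hop-derived artefact inherits strong support from the complement (the allele
is real germline variation there), while a genuinely private somatic variant
does not.

The complement excludes every co-pooled library of the call's own individual
(e.g. the matched normal), since shared germline variation would otherwise
masquerade as contamination support. Libraries excluded from downstream
analysis for QC reasons still belong to complements: they remain physical
contamination sources.

Counts are read counts as tabulated in the pileup; mate pairs overlapping the
same site are not collapsed to fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .datamodel import (
    HopauditError,
    BASE_INDEX,
    PileupCounts,
    PoolLayout,
    Thresholds,
    VariantCall,
)

logger = logging.getLogger("hopaudit")


@dataclass(frozen=True)
class PCAFRecord:
    """A variant call annotated with its pool-complement support.

    ``pcaf`` is ``None`` (undefined) when the complement depth falls below the
    configured minimum — including the empty-complement case ``pc_depth == 0``.
    The undefined state is explicit and never encoded as 0.
    """

    call: VariantCall
    pc_alt: int
    pc_depth: int
    pcaf: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.pc_alt <= self.pc_depth:
            raise HopauditError(
                f"pc_alt {self.pc_alt} outside [0, pc_depth={self.pc_depth}]"
            )
        if self.pcaf is not None and self.pc_depth > 0:
            assert abs(self.pcaf * self.pc_depth - self.pc_alt) < 1e-9


def pool_complement(sample_id: str, layout: PoolLayout) -> list[str]:
    """Samples sharing the query's pool but belonging to other individuals.

    Returns a sorted list; a solo-lane sample has an empty complement.
    """
    query = layout.sample(sample_id)
    if query.pool_id is None:
        return []
    return sorted(
        s.sample_id
        for s in layout
        if s.pool_id == query.pool_id
        and s.individual_id != query.individual_id
    )


def compute_pcaf(
    call: VariantCall,
    complement_pileups: Sequence[PileupCounts],
    min_pc_depth: int = Thresholds().min_pc_depth,
) -> PCAFRecord:
    """Sum complement base counts at the call site and form the PC-AF.

    A complement sample with no coverage of the site contributes zero reads.
    When the summed depth is below ``min_pc_depth`` the PC-AF is undefined.
    """
    site = call.site
    alt_idx = BASE_INDEX[site.alt]
    pc_alt = 0
    pc_depth = 0
    for pu in complement_pileups:
        counts = pu.base_counts(site.chrom, site.pos)
        pc_alt += int(counts[alt_idx])
        pc_depth += int(counts.sum())
    pcaf = pc_alt / pc_depth if pc_depth >= min_pc_depth and pc_depth > 0 else None
    return PCAFRecord(call, pc_alt, pc_depth, pcaf)


def annotate_calls(
    calls: Sequence[VariantCall],
    layout: PoolLayout,
    pileups: Mapping[str, PileupCounts],
    thresholds: Thresholds = Thresholds(),
) -> list[PCAFRecord]:
    """Compute a PC-AF record for every call, in input order.

    A complement sample missing from ``pileups`` contributes zero reads; this
    is logged once per sample. Per-sample counts of defined/undefined PC-AFs
    are logged at INFO level.
    """
    complements: dict[str, list[PileupCounts]] = {}
    warned: set[str] = set()
    records: list[PCAFRecord] = []
    stats: dict[str, list[int]] = {}
    for call in calls:
        sid = call.sample_id
        if sid not in complements:
            members = pool_complement(sid, layout)
            present: list[PileupCounts] = []
            for m in members:
                if m in pileups:
                    present.append(pileups[m])
                elif m not in warned:
                    warned.add(m)
                    logger.warning(
                        "no pileup for complement sample %s; it contributes "
                        "0 reads", m)
            complements[sid] = present
        rec = compute_pcaf(call, complements[sid], thresholds.min_pc_depth)
        records.append(rec)
        tally = stats.setdefault(sid, [0, 0])
        tally[0 if rec.pcaf is not None else 1] += 1
    for sid, (n_def, n_undef) in sorted(stats.items()):
        logger.info("sample %s: %d PC-AF(s) defined, %d undefined",
                    sid, n_def, n_undef)
    return records


def write_pcaf_table(records: Sequence[PCAFRecord], path: str | Path) -> None:
    """Per-call TSV: sample, locus, AF, complement counts and PC-AF
    (empty field when undefined)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\taf\tpc_alt\tpc_depth\tpcaf\n")
        for r in records:
            c = r.call
            pcaf = f"{r.pcaf:.6g}" if r.pcaf is not None else ""
            fh.write(f"{c.sample_id}\t{c.site.chrom}\t{c.site.pos}\t"
                     f"{c.site.ref}\t{c.site.alt}\t{c.af:.6g}\t"
                     f"{r.pc_alt}\t{r.pc_depth}\t{pcaf}\n")
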