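"""Shared fixtures: tiny layouts, pileups and VCF texts built in-memory."""

from __future__ import annotations

import numpy as np
import pytest

from hopaudit import PileupCounts, PoolLayout, Role, SampleMeta

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


@pytest.fixture
def calls_vcf(tmp_path):
    """Three SNVs (one of them from a multiallelic record) plus one indel."""
    body = (
        "1\t100\t.\tA\tG\t.\t.\t.\tGT:AD\t0/1:10,5\n"
        "1\t200\t.\tC\tT\t.\t.\t.\tGT:AD\t0/1:40,10\n"
        "1\t300\t.\tG\tA\t.\t.\t.\tGT:AD\t0/1:90,9\n"
        "1\t400\t.\tA\tAT\t.\t.\t.\tGT:AD\t0/1:30,4\n"
    )
    path = tmp_path / "calls.vcf"
    path.write_text(VCF_HEADER + body)
    return path


@pytest.fixture
def paired_pool_layout():
    """Four individuals, tumour+normal each, in one pool with equal shares."""
    metas = []
    for ind in "ABCD":
        metas.append(SampleMeta(f"{ind}_T", ind, "p1", Role.TUMOUR, 0.125))
        metas.append(SampleMeta(f"{ind}_N", ind, "p1", Role.NORMAL, 0.125))
    return PoolLayout(metas)


def make_pileup(sample_id, rows, origin_rows=None):
    """Build a PileupCounts from {(chrom, pos, ref): (nA, nC, nG, nT)} rows."""
    sites = [key for key in rows]
    counts = np.array([rows[key] for key in sites], dtype=np.int64)
    origins = None
    if origin_rows is not None:
        origins = {
            origin: np.array([table[key] for key in sites], dtype=np.int64)
            for origin, table in origin_rows.items()
        }
    return PileupCounts(sample_id, list(sites), counts, origins)
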