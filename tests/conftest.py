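"""Shared fixtures: call constructors, a small simulated genome, and a
tiny three-gene annotation setup used across modules."""

from __future__ import annotations

import pytest

from svpop.model import GeneModel, SVCall
from svpop.simulate import SimGenome, simulate_genome


def make_call(
    start: int,
    svlen: int,
    sv_type: str = "DEL",
    chrom: str = "chr1",
    caller: str = "sniffles",
    sample: str = "S1",
    support: int = 10,
    depth: int | None = 20,
) -> SVCall:
    return SVCall(
        sample_id=sample,
        caller_id=caller,
        sv_type=sv_type,
        chrom=chrom,
        start=start,
        end=start + svlen,
        svlen=svlen,
        support_reads=support,
        site_depth=depth,
    )


@pytest.fixture(scope="session")
def toy_genome() -> SimGenome:
    return simulate_genome(n_chroms=2, chrom_len=5_000_000, n_genes=20, seed=7)


@pytest.fixture(scope="session")
def three_genes() -> list[GeneModel]:
    """Plus-strand, minus-strand and a second plus-strand gene with known
    CDS/UTR layout, on one 10 Mb chromosome."""
    return [
        GeneModel(
            gene_id="G1", chrom="chr1", strand="+", start=10_000, end=20_000,
            cds=[(10_200, 11_000), (15_000, 15_800)],
            utr5=[(10_000, 10_200)], utr3=[(15_800, 16_100)],
        ),
        GeneModel(
            gene_id="G2", chrom="chr1", strand="-", start=50_000, end=60_000,
            cds=[(51_000, 52_000), (57_000, 58_000)],
            utr5=[(58_000, 58_300)], utr3=[(50_000, 50_400)],
        ),
        GeneModel(
            gene_id="G3", chrom="chr1", strand="+", start=100_000, end=104_000,
            cds=[(100_500, 101_500), (102_500, 103_500)],
        ),
    ]
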