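"""Shared fixtures: small synthetic references/alignments with manifests."""

from __future__ import annotations

from pathlib import Path

import pytest

from pileview.core import GenomicRegion
from pileview.fixtures import ReadProfile, make_reads, make_reference


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def small_reference(fixture_dir):
    """2 kb random reference, written + indexed."""
    path = fixture_dir / "ref.fa"
    seq = make_reference(2000, seed=101, out_path=path)
    return path, seq


@pytest.fixture(scope="session")
def small_bam(fixture_dir, small_reference):
    """100 paired reads over the small reference, with manifest."""
    path, seq = small_reference
    bam = fixture_dir / "reads.bam"
    manifest = make_reads(
        seq, 100, ReadProfile(read_length=80, insert_size_mean=200), seed=202, out_path=bam
    )
    return bam, manifest


@pytest.fixture(scope="session")
def full_region():
    return GenomicRegion("ref", 1, 2000)


@pytest.fixture(scope="session")
def vcf_file(fixture_dir):
    """Tiny plain-text VCF over the fixture chromosome."""
    path = fixture_dir / "sites.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=ref,length=2000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "ref\t150\t.\tA\tG\t.\t.\t.\n"
        "ref\t300\trs1\tACG\tA\t.\t.\t.\n"
        "ref\t500\t.\tT\t<DEL>\t.\t.\t.\n"
        "ref\t5000\t.\tC\tT\t.\t.\t.\n"
    )
    return path


@pytest.fixture(scope="session")
def bed_file(fixture_dir):
    path = fixture_dir / "regions.bed"
    path.write_text(
        "chr9\t5\t10\televen\n"  # other chromosome: ignored
        "ref\t99\t200\tpeak1\n"
        "ref\t0\t1\n"
        "ref\t1900\t2100\ttail\n"
    )
    return path
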