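"""Shared fixtures: tiny hand-written inputs plus one synthetic bundle."""

from __future__ import annotations

import textwrap

import pytest

from delsieve.simulate import FixtureSpec, write_fixture_bundle


def write_vcf(path, records, contig="chr1", contig_len=100):
    """Minimal VCF with an AF INFO field; records = (pos, ref, alt, af)."""
    header = textwrap.dedent(
        f"""\
        ##fileformat=VCFv4.2
        ##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
        ##contig=<ID={contig},length={contig_len}>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
        """
    )
    with open(path, "w") as fh:
        fh.write(header)
        for pos, ref, alt, af in sorted(records):
            info = f"AF={af}" if af is not None else "."
            fh.write(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t100\tPASS\t{info}\n")
    return path


def write_sam(path, reads, contig="chr1", contig_len=100):
    """Minimal SAM; reads = (qname, flag, pos1, cigar, seq, qual_str)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{contig}\tLN:{contig_len}\n")
        for qname, flag, pos1, cigar, seq, qual in sorted(reads, key=lambda r: r[2]):
            fh.write(
                f"{qname}\t{flag}\t{contig}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"
            )
    return path


@pytest.fixture(scope="session")
def strong_bundle(tmp_path_factory):
    """One strong-contrast synthetic bundle shared by integration tests."""
    spec = FixtureSpec(
        n_variants=8, depth_per_stratum=40, muaf=0.5,
        tp_signal_shift=6.0, noise_sd=2.0, seed=42,
    )
    out = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(spec, out)
    return spec, paths
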