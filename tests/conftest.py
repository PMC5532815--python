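"""Shared fixtures: constructed alignment files and a hand-designed count table."""

import numpy as np
import pandas as pd
import pysam
import pytest


def make_bam(path, reads, ref_name="chr1", ref_len=100_000):
    """Write an indexed BAM of fully matched single-end reads.

    ``reads`` is a list of (name, pos0, seq) with 0-based start positions;
    every read aligns gaplessly.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, pos0, seq in sorted(reads, key=lambda r: r[1]):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos0
            a.cigar = [(0, len(seq))]
            a.mapping_quality = 60
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.flag = 0
            bam.write(a)
    pysam.index(str(path))
    return str(path)


@pytest.fixture
def bam_builder(tmp_path):
    def build(reads, name="reads.bam", **kw):
        return make_bam(tmp_path / name, reads, **kw)
    return build


def _block(site_id, spec):
    """spec: list of (count, edited, unedited) blocks over individuals."""
    rows = []
    k = 0
    for count, e, u in spec:
        for _ in range(count):
            rows.append((site_id, f"ind{k}", e, u))
            k += 1
    return rows


@pytest.fixture(scope="session")
def toy_count_table():
    """A 20-individual count table with one site per filtering outcome.

    Hand-computed expectations (mean edited / mean total / q90-q10 of Phi):
      pass      : 2.0 / 10.0 / 0.20            -> retained
      boundary  : 4.0 / 20.0 / 0.10 (exact)    -> retained (inclusive bounds)
      zero_cov  : 2.9 / 10.5 / ~0.286          -> retained (5 uncovered inds
                   count in coverage means, not in quantiles)
      low_edited: 1.0 / 10.0 / 0.20            -> rejected (mean edited < 2)
      low_total : 2.5 /  4.0 / 0.25            -> rejected (mean total < 10)
      zero_sprd : 4.0 / 20.0 / 0.0             -> rejected (no variability)
      at_snp    : same counts as pass          -> rejected (known SNP position)
    """
    rows = []
    rows += _block("chr1:100", [(10, 1, 9), (10, 3, 7)])                # pass
    rows += _block("chr1:200", [(10, 3, 17), (10, 5, 15)])              # boundary
    rows += _block("chr1:300", [(5, 0, 0), (8, 2, 12), (7, 6, 8)])      # zero_cov
    rows += _block("chr1:400", [(10, 0, 10), (10, 2, 8)])               # low_edited
    rows += _block("chr1:500", [(10, 2, 2), (10, 3, 1)])                # low_total
    rows += _block("chr1:600", [(20, 4, 16)])                           # zero_sprd
    rows += _block("chr1:700", [(10, 1, 9), (10, 3, 7)])                # at_snp
    return pd.DataFrame(rows, columns=["site_id", "individual",
                                       "edited", "unedited"])


TOY_RETAINED = ["chr1:100", "chr1:200", "chr1:300"]
TOY_KNOWN_SNPS = [("chr1", 700)]
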