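"""Editing-site records and site-list IO.

An :class:`EditingSite` is an annotated A-to-I editing position (RADAR-style):
1-based genomic coordinate, strand of the edited transcript, and optional gene
and Alu-context labels. Site lists are read either from a BED file (0-based
half-open; converted at the reader boundary) or from a 1-based TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ParameterError


@dataclass(frozen=True)
class EditingSite:
    """An annotated A-to-I RNA editing site.

    ``pos`` is 1-based. ``strand`` is the strand of transcription: on ``+``
    the edited base reads G (vs unedited A) on the reference-forward strand,
    on ``-`` it reads C (vs T).
    """

    chrom: str
    pos: int
    strand: str
    gene: str = ""
    in_alu: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ParameterError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.pos}"


def read_sites_bed(path) -> list[EditingSite]:
    """Read editing sites from BED (0-based half-open, strand in column 6)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    sites = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if len(row) > 3 else ""
        strand = str(row[5]) if len(row) > 5 else "+"
        sites.append(EditingSite(chrom=str(row[0]), pos=int(row[1]) + 1,
                                 strand=strand, gene=name))
    return sites


def read_sites_tsv(path) -> list[EditingSite]:
    """Read editing sites from a 1-based TSV with columns
    chrom, pos, strand[, gene[, in_alu]]."""
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(EditingSite(
            chrom=str(row.chrom), pos=int(row.pos), strand=str(row.strand),
            gene=str(getattr(row, "gene", "")),
            in_alu=bool(getattr(row, "in_alu", False))))
    return sites


def sites_to_frame(sites) -> pd.DataFrame:
    return pd.DataFrame(
        {"site_id": [s.site_id for s in sites],
         "chrom": [s.chrom for s in sites],
         "pos": [s.pos for s in sites],
         "strand": [s.strand for s in sites],
         "gene": [s.gene for s in sites],
         "in_alu": [s.in_alu for s in sites]})
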