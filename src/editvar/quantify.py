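"""Editing-level quantification and candidate-site filtering.

The editing level at a site is Phi = edited / (edited + unedited), computed
from strand-aware read counts: on a ``+`` strand site the edited base reads G
and the unedited base A on the reference-forward strand; on a ``-`` strand
site they read C and T. Candidate sites for association analysis must show
adequate coverage and inter-individual variability and must not coincide with
a known genomic SNP (an A/G polymorphism masquerades as editing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .errors import CoordinateError, DataError
from .sites import EditingSite

_EDITED_BASE = {"+": "G", "-": "C"}
_UNEDITED_BASE = {"+": "A", "-": "T"}


def read_base_at(read, ref_pos0: int):
    """Query base of an aligned read at a 0-based reference position, or None
    if the position is not aligned (deletion, clip, splice)."""
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        if rpos == ref_pos0:
            return read.query_sequence[qpos], read.query_qualities[qpos] \
                if read.query_qualities is not None else 255
    return None, None


def _iter_reads(af, chrom, pos0, min_mapping_quality):
    for read in af.fetch(chrom, pos0, pos0 + 1):
        if (read.is_unmapped or read.is_secondary or read.is_supplementary
                or read.mapping_quality < min_mapping_quality):
            continue
        yield read


def count_alleles_at_site(alignments, site: EditingSite,
                          min_base_quality: int = 0,
                          min_mapping_quality: int = 0) -> tuple[int, int]:
    """Edited/unedited read counts at one site from a pysam AlignmentFile.

    Bases other than the edited/unedited pair, deletions and unaligned
    positions are ignored.
    """
    if site.chrom not in alignments.references:
        raise CoordinateError(f"{site.chrom} not in alignment references")
    edited_base = _EDITED_BASE[site.strand]
    unedited_base = _UNEDITED_BASE[site.strand]
    edited = unedited = 0
    for read in _iter_reads(alignments, site.chrom, site.pos - 1,
                            min_mapping_quality):
        base, qual = read_base_at(read, site.pos - 1)
        if base is None or (qual is not None and qual < min_base_quality):
            continue
        base = base.upper()
        if base == edited_base:
            edited += 1
        elif base == unedited_base:
            unedited += 1
    return edited, unedited


def count_alleles_at_sites(alignments, sites, individual: str = "sample",
                           min_base_quality: int = 0,
                           min_mapping_quality: int = 0) -> pd.DataFrame:
    """Count table for one individual's alignments over a site list.

    ``alignments`` is a pysam.AlignmentFile or a path to an indexed BAM/CRAM/
    SAM. Returns columns site_id, individual, edited, unedited, phi (phi is
    NaN where total coverage is 0).
    """
    close = False
    if not isinstance(alignments, pysam.AlignmentFile):
        alignments = pysam.AlignmentFile(str(alignments))
        close = True
    try:
        rows = []
        for site in sites:
            e, u = count_alleles_at_site(alignments, site, min_base_quality,
                                         min_mapping_quality)
            rows.append((site.site_id, individual, e, u))
    finally:
        if close:
            alignments.close()
    df = pd.DataFrame(rows, columns=["site_id", "individual", "edited", "unedited"])
    df["phi"] = compute_phi_vector(df["edited"].to_numpy(), df["unedited"].to_numpy())
    return df


def compute_phi(edited: int, unedited: int) -> float:
    """Editing level Phi = edited / (edited + unedited); requires coverage."""
    total = edited + unedited
    if total <= 0:
        raise DataError("Phi is undefined at zero total coverage")
    return edited / total


def compute_phi_vector(edited, unedited) -> np.ndarray:
    """Vectorized Phi with NaN at zero total coverage."""
    edited = np.asarray(edited, dtype=float)
    total = edited + np.asarray(unedited, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(total > 0, edited / np.where(total > 0, total, 1.0), np.nan)
    return phi


def filter_candidate_sites(table: pd.DataFrame, known_snp_positions=(),
                           min_mean_edited: float = 2.0,
                           min_mean_total: float = 10.0,
                           min_quantile_spread: float = 0.10,
                           n_individuals: int | None = None) -> list[str]:
    """Apply the candidate-site filters to a long count table.

    A site is retained iff, across individuals: mean edited coverage >=
    ``min_mean_edited``, mean total coverage >= ``min_mean_total``, the spread
    between the 90% and 10% quantiles of Phi is >= ``min_quantile_spread``
    (linear-interpolation sample quantiles, computed over individuals with
    nonzero coverage), and the site position is not a known SNP. Individuals
    with zero coverage still count in the denominator of the mean-coverage
    rules (means are per analyzed individual); ``n_individuals`` overrides the
    denominator when the table omits zero rows. All comparisons are inclusive.

    ``known_snp_positions`` holds "chrom:pos" strings (matching site_id) or
    (chrom, pos) tuples. Returns retained site_ids in table order.
    """
    if table.empty:
        return []
    snp_keys = set()
    for k in known_snp_positions:
        snp_keys.add(f"{k[0]}:{k[1]}" if isinstance(k, tuple) else str(k))
    retained = []
    for site_id, grp in table.groupby("site_id", sort=False):
        denom = n_individuals if n_individuals is not None else len(grp)
        edited = grp["edited"].to_numpy(dtype=float)
        total = edited + grp["unedited"].to_numpy(dtype=float)
        if edited.sum() / denom < min_mean_edited:
            continue
        if total.sum() / denom < min_mean_total:
            continue
        phi = edited[total > 0] / total[total > 0]
        if phi.size == 0:
            continue
        spread = np.quantile(phi, 0.9) - np.quantile(phi, 0.1)
        if spread < min_quantile_spread - 1e-12:
            continue
        if site_id in snp_keys:
            continue
        retained.append(site_id)
    return retained
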