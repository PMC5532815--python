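"""Linking cis-regulated editing SNPs to GWAS-catalog signals through LD.

r^2 is computed from phased haplotype frequencies: with alternate-allele
frequencies ``pA`` and ``pB`` at two loci and joint haplotype frequency
``f(AB)``,

    D = f(AB) - pA * pB,    r^2 = D^2 / (pA (1-pA) pB (1-pB)).

Catalog SNPs are pre-filtered at GWAS p < 1e-3 and a link is reported when
r^2 strictly exceeds 0.8 on the designated population subset (the four
European panels in the original analysis; configurable here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .genotypes import GenotypePanel


@dataclass(frozen=True)
class GwasRecord:
    snp_id: str
    chrom: str
    pos: int
    p_value: float
    trait: str
    source_gene: str = ""


@dataclass(frozen=True)
class GwasLink:
    query_snp: str
    gwas_snp: str
    r2: float
    trait: str


def compute_r2(haplotypes_a, haplotypes_b) -> float:
    """Haplotype r^2 between two equal-length phased 0/1 vectors."""
    a = np.asarray(haplotypes_a, dtype=float)
    b = np.asarray(haplotypes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("haplotype vectors must be 1-D and equal length")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise DataError("r^2 undefined for monomorphic haplotypes")
    d = np.mean(a * b) - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def read_gwas_catalog(path, p_threshold: float = 1e-3) -> list[GwasRecord]:
    """Read a GWAS-catalog TSV (snp_id, chrom, pos, p_value, trait) keeping
    records with p < ``p_threshold``."""
    df = pd.read_csv(path, sep="\t")
    return [GwasRecord(str(r.snp_id), str(r.chrom), int(r.pos),
                       float(r.p_value), str(r.trait),
                       str(getattr(r, "source_gene", "")))
            for r in df.itertuples(index=False)
            if float(r.p_value) < p_threshold]


def link_gwas(significant_snps, gwas_records, panel: GenotypePanel,
              r2_threshold: float = 0.8, search_radius: int = 1_000_000,
              samples=None, log=None) -> list[GwasLink]:
    """Emit a GwasLink for every (query, catalog) SNP pair on the same
    chromosome within ``search_radius`` whose haplotype r^2 strictly exceeds
    ``r2_threshold``.

    ``significant_snps`` is an iterable of (snp_id, chrom, pos) or of snp_ids
    present in the panel; ``samples`` restricts the haplotype panel to a
    population subset. Catalog SNPs absent from the panel are skipped (and
    reported through ``log`` when given).
    """
    if samples is not None:
        panel = panel.subset_samples(samples)
    index = {sid: j for j, sid in enumerate(panel.snp_ids)}

    def resolve(snp):
        if isinstance(snp, tuple):
            sid = snp[0]
        else:
            sid = snp
        return sid, index.get(sid)

    links = []
    for query in significant_snps:
        qid, qj = resolve(query)
        if qj is None:
            if log is not None:
                log(f"query SNP {qid} absent from genotype panel; skipped")
            continue
        qpos = panel.positions[qj]
        for rec in gwas_records:
            if rec.chrom != panel.chrom or abs(rec.pos - qpos) > search_radius:
                continue
            gj = index.get(rec.snp_id)
            if gj is None:
                if log is not None:
                    log(f"GWAS SNP {rec.snp_id} absent from genotype panel; skipped")
                continue
            try:
                r2 = compute_r2(panel.haplotype(qj), panel.haplotype(gj))
            except DataError:
                continue
            if r2 > r2_threshold:
                links.append(GwasLink(qid, rec.snp_id, r2, rec.trait))
    return links


def links_to_frame(links) -> pd.DataFrame:
    return pd.DataFrame([vars(l) for l in links],
                        columns=["query_snp", "gwas_snp", "r2", "trait"])
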