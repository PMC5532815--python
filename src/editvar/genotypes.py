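"""Phased genotype panels and VCF IO.

A :class:`GenotypePanel` holds phased biallelic haplotypes for one set of
individuals over one set of SNP positions: a ``(2N, M)`` 0/1 matrix whose rows
alternate the two haplotypes of each individual (row ``2k`` and ``2k+1`` belong
to individual ``k``). Genotype dosage is the per-individual haplotype sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import DataError, ParameterError


@dataclass
class GenotypePanel:
    chrom: str
    positions: np.ndarray          # (M,) 1-based, sorted
    haplotypes: np.ndarray         # (2N, M) int8 in {0,1}
    snp_ids: list = None           # length M
    samples: list = None           # length N
    ref: list = None               # REF allele per SNP (optional)
    alt: list = None               # ALT allele per SNP (optional)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ParameterError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] % 2 != 0:
            raise ParameterError("haplotype matrix must have an even number of rows")
        if self.haplotypes.shape[1] != self.positions.size:
            raise ParameterError("positions and haplotype columns disagree")
        if self.snp_ids is None:
            self.snp_ids = [f"{self.chrom}:{p}" for p in self.positions]
        if self.samples is None:
            self.samples = [f"ind{k}" for k in range(self.n_individuals)]

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[1]

    def dosage(self) -> np.ndarray:
        """(N, M) genotype dosage = sum of the two haplotype alleles."""
        return (self.haplotypes[0::2].astype(np.int16)
                + self.haplotypes[1::2].astype(np.int16))

    def allele_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def haplotype(self, snp_index: int) -> np.ndarray:
        """The (2N,) haplotype vector of one SNP."""
        return self.haplotypes[:, snp_index].astype(np.int8)

    def subset_snps(self, index) -> "GenotypePanel":
        index = np.asarray(index)
        return GenotypePanel(
            chrom=self.chrom,
            positions=self.positions[index],
            haplotypes=self.haplotypes[:, index],
            snp_ids=[self.snp_ids[i] for i in np.atleast_1d(index)],
            samples=list(self.samples),
            ref=None if self.ref is None else [self.ref[i] for i in np.atleast_1d(index)],
            alt=None if self.alt is None else [self.alt[i] for i in np.atleast_1d(index)])

    def subset_samples(self, names) -> "GenotypePanel":
        order = {s: k for k, s in enumerate(self.samples)}
        missing = [s for s in names if s not in order]
        if missing:
            raise DataError(f"samples absent from panel: {missing[:5]}")
        rows = np.concatenate([[2 * order[s], 2 * order[s] + 1] for s in names])
        return GenotypePanel(chrom=self.chrom, positions=self.positions,
                             haplotypes=self.haplotypes[rows],
                             snp_ids=list(self.snp_ids), samples=list(names),
                             ref=self.ref, alt=self.alt)

    # ---- IO ----------------------------------------------------------------

    def to_vcf(self, path) -> None:
        """Write the panel as an uncompressed phased VCF 4.2 file."""
        ref = self.ref or ["A"] * self.n_snps
        alt = self.alt or ["G"] * self.n_snps
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={self.chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            H = self.haplotypes
            for j in range(self.n_snps):
                gts = "\t".join(f"{H[2 * k, j]}|{H[2 * k + 1, j]}"
                                for k in range(self.n_individuals))
                fh.write(f"{self.chrom}\t{self.positions[j]}\t{self.snp_ids[j]}\t"
                         f"{ref[j]}\t{alt[j]}\t.\t.\t.\tGT\t{gts}\n")

    @classmethod
    def from_vcf(cls, path, chrom=None) -> "GenotypePanel":
        """Read phased biallelic SNPs from a VCF; multiallelic records skipped."""
        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        positions, ids, refs, alts, cols = [], [], [], [], []
        for rec in vf:
            if chrom is not None and rec.chrom != chrom:
                continue
            if rec.alts is None or len(rec.alts) != 1:
                continue
            col = np.empty(2 * len(samples), dtype=np.int8)
            ok = True
            for k, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or len(gt) != 2 or None in gt:
                    ok = False
                    break
                col[2 * k], col[2 * k + 1] = gt
            if not ok:
                continue
            if chrom is None:
                chrom = rec.chrom
            positions.append(rec.pos)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            refs.append(rec.ref)
            alts.append(rec.alts[0])
            cols.append(col)
        vf.close()
        if not cols:
            raise DataError(f"no usable phased biallelic records in {path}")
        return cls(chrom=chrom, positions=np.array(positions),
                   haplotypes=np.stack(cols, axis=1), snp_ids=ids,
                   samples=samples, ref=refs, alt=alts)
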