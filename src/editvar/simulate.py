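"""Synthetic cohorts for the editing-variation analyses.

This module generates the four kinds of input the pipeline consumes, with the
statistical structure the downstream models assume, so every stage is testable
without population-scale sequencing data:

* phased biallelic genotype panels with tunable allele frequency and
  distance-dependent linkage disequilibrium (Markov haplotype copying);
* per-site edited/unedited read counts whose logit editing level depends on
  genotype dosage plus individual-level noise (the generative twin of the
  edQTL binomial GLMM);
* paired two-allele counts with a known allelic shift ``delta`` (the
  generative twin of the hierarchical allele-specific editing model);
* inverted-repeat (IRAlu-like) sequences harbouring an editing site and a SNP.

All generators are pure functions of their seed: the same configuration and
seed reproduce output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .genotypes import GenotypePanel
from .sites import EditingSite

_RC = str.maketrans("ACGU", "UGCA")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``ld_decay`` is the correlation length of inter-SNP linkage in bp: the
    correlation between adjacent simulated SNPs ``d`` bp apart is
    ``exp(-d / ld_decay)`` (0 means independent SNPs). ``beta`` is the causal
    genotype effect per dosage unit on logit editing, ``alpha0`` the baseline
    logit editing level, ``sigma_ind`` the SD of individual-level logit noise.
    ``delta`` is the allelic shift of the paired allele-specific generator and
    ``sigma_allele1``/``sigma_allele2`` its per-allele logit-noise SDs.
    ``coverage_dispersion`` is the negative-binomial size parameter of the
    total read count; ``None`` (default) gives Poisson coverage.
    """

    n_individuals: int = 100
    n_sites: int = 50
    n_snps_per_site: int = 10
    maf: float = 0.3
    ld_decay: float = 20_000.0
    coverage_mean: float = 50.0
    coverage_dispersion: float | None = None
    beta: float = 0.0
    alpha0: float = -2.0
    sigma_ind: float = 0.3
    delta: float = 0.0
    sigma_allele1: float = 0.3
    sigma_allele2: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.maf <= 0.5):
            raise ParameterError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.coverage_mean <= 0:
            raise ParameterError("coverage_mean must be > 0")
        if self.coverage_dispersion is not None and self.coverage_dispersion <= 0:
            raise ParameterError("coverage_dispersion must be > 0 or None")
        for name in ("sigma_ind", "sigma_allele1", "sigma_allele2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.ld_decay < 0:
            raise ParameterError("ld_decay must be >= 0")
        for name in ("n_individuals", "n_sites", "n_snps_per_site"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GenotypeStudy:
    """Per-site cis genotype panels around simulated editing sites."""

    sites: list            # EditingSite per simulated site
    panels: list           # GenotypePanel per site (same individuals throughout)
    causal_index: list     # index of the designated causal SNP in each panel

    @property
    def samples(self):
        return self.panels[0].samples


def _simulate_haplotypes(rng, n_hap, positions, maf, ld_decay):
    """Markov haplotype copying: allele j repeats allele j-1 with probability
    exp(-d / ld_decay), else is a fresh Bernoulli(maf) draw."""
    m = positions.size
    H = np.empty((n_hap, m), dtype=np.int8)
    fresh = rng.random((n_hap, m)) < maf
    H[:, 0] = fresh[:, 0]
    if m > 1:
        d = np.diff(positions).astype(float)
        rho = np.exp(-d / ld_decay) if ld_decay > 0 else np.zeros_like(d)
        copy = rng.random((n_hap, m - 1)) < rho
        for j in range(1, m):
            H[:, j] = np.where(copy[:, j - 1], H[:, j - 1], fresh[:, j])
    return H


def simulate_genotypes(config: SimConfig, window: int = 200_000,
                       site_spacing: int = 1_000_000,
                       chrom: str = "chr1") -> GenotypeStudy:
    """Simulate phased genotype panels around ``n_sites`` editing sites.

    Each site gets ``n_snps_per_site`` SNPs at positions uniform in a
    ``+/- window`` cis interval; the SNP closest to the site is designated
    causal. Empirical allele frequency converges to ``maf`` and pairwise r^2
    decays with distance at the ``ld_decay`` correlation length.
    """
    rng = config.rng()
    samples = [f"ind{k}" for k in range(config.n_individuals)]
    sites, panels, causal = [], [], []
    for i in range(config.n_sites):
        site_pos = site_spacing * (i + 1)
        offs = np.sort(rng.integers(-window, window + 1, config.n_snps_per_site))
        positions = np.maximum(site_pos + offs, 1)
        H = _simulate_haplotypes(rng, 2 * config.n_individuals, positions,
                                 config.maf, config.ld_decay)
        site = EditingSite(chrom=chrom, pos=site_pos, strand="+",
                           gene=f"gene{i}", in_alu=True)
        panel = GenotypePanel(
            chrom=chrom, positions=positions, haplotypes=H,
            snp_ids=[f"rs{i}_{j}" for j in range(config.n_snps_per_site)],
            samples=samples)
        sites.append(site)
        panels.append(panel)
        causal.append(int(np.argmin(np.abs(positions - site_pos))))
    return GenotypeStudy(sites=sites, panels=panels, causal_index=causal)


def _draw_totals(rng, mean, dispersion, size):
    if dispersion is None:
        return rng.poisson(mean, size=size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_edqtl_counts(genotypes: GenotypeStudy, config: SimConfig) -> pd.DataFrame:
    """Simulate the edited/unedited count table implied by the edQTL model.

    For individual ``k`` with causal dosage ``g``: total reads are drawn with
    mean ``coverage_mean`` (Poisson or negative binomial),
    ``logit(phi_k) = alpha0 + beta * g + eps_k`` with
    ``eps_k ~ N(0, sigma_ind^2)``, and edited reads are
    ``Binomial(total_k, phi_k)``. Returns a long table with columns
    site_id, individual, edited, unedited, dosage, phi_true.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for site, panel, ci in zip(genotypes.sites, genotypes.panels,
                               genotypes.causal_index):
        g = panel.dosage()[:, ci].astype(float)
        eps = rng.normal(0.0, config.sigma_ind, size=g.size) \
            if config.sigma_ind > 0 else np.zeros_like(g)
        eta = config.alpha0 + config.beta * g + eps
        phi = 1.0 / (1.0 + np.exp(-eta))
        total = _draw_totals(rng, config.coverage_mean,
                             config.coverage_dispersion, g.size)
        edited = rng.binomial(total, phi)
        rows.append(pd.DataFrame({
            "site_id": site.site_id,
            "individual": panel.samples,
            "edited": edited,
            "unedited": total - edited,
            "dosage": g.astype(int),
            "phi_true": phi}))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class AsedObservation:
    """Paired two-allele edited/unedited counts for one replicate
    (one heterozygous individual, or one technical replicate)."""

    replicate_id: str
    edited_allele1: int
    unedited_allele1: int
    edited_allele2: int
    unedited_allele2: int

    @property
    def n_allele1(self) -> int:
        return self.edited_allele1 + self.unedited_allele1

    @property
    def n_allele2(self) -> int:
        return self.edited_allele2 + self.unedited_allele2

    @property
    def phi_allele1(self) -> float:
        n = self.n_allele1
        return self.edited_allele1 / n if n else float("nan")

    @property
    def phi_allele2(self) -> float:
        n = self.n_allele2
        return self.edited_allele2 / n if n else float("nan")

    def pooled_phi(self) -> float:
        n = self.n_allele1 + self.n_allele2
        return (self.edited_allele1 + self.edited_allele2) / n if n else float("nan")

    def swapped(self) -> "AsedObservation":
        return AsedObservation(self.replicate_id,
                               self.edited_allele2, self.unedited_allele2,
                               self.edited_allele1, self.unedited_allele1)


def simulate_ased_counts(config: SimConfig, n_replicates: int,
                         rng=None) -> list[AsedObservation]:
    """Simulate paired allele-specific counts under the hierarchical model.

    Per replicate ``k``: a baseline ``alpha_k ~ N(alpha0, 1)`` is drawn, the
    allele-1 logit editing level is ``N(alpha_k, sigma_allele1^2)``, the
    allele-2 level is ``N(alpha_k + delta, sigma_allele2^2)``, and counts are
    binomial given the per-allele coverage (mean ``coverage_mean`` per allele).
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    obs = []
    for k in range(n_replicates):
        alpha_k = rng.normal(config.alpha0, 1.0)
        a = rng.normal(alpha_k, config.sigma_allele1) \
            if config.sigma_allele1 > 0 else alpha_k
        b = rng.normal(alpha_k + config.delta, config.sigma_allele2) \
            if config.sigma_allele2 > 0 else alpha_k + config.delta
        n1 = _draw_totals(rng, config.coverage_mean, config.coverage_dispersion, None)
        n2 = _draw_totals(rng, config.coverage_mean, config.coverage_dispersion, None)
        i1 = rng.binomial(n1, 1.0 / (1.0 + np.exp(-a))) if n1 else 0
        i2 = rng.binomial(n2, 1.0 / (1.0 + np.exp(-b))) if n2 else 0
        obs.append(AsedObservation(f"rep{k}", int(i1), int(n1 - i1),
                                   int(i2), int(n2 - i2)))
    return obs


@dataclass
class IraluSim:
    """A simulated inverted-repeat substrate: two reverse-complementary arms
    around a spacer, with an editable A and a SNP at known offsets.

    ``sequence_allele1`` carries the perfectly pairing SNP base; in
    ``sequence_allele2`` that base is replaced by a mismatching one (a C
    opposite the editing A when the SNP sits at offset 0 on the opposite arm,
    mirroring the C/T polymorphism geometry seen at edited hairpins).
    """

    sequence_allele1: str
    sequence_allele2: str
    editing_offset: int       # 0-based offset of the editable A (arm 1)
    snp_offset: int           # 0-based offset of the SNP in the full sequence
    arm_length: int
    spacer_length: int


def simulate_iralu(seed: int, arm_length: int, snp_offset: int,
                   snp_arm: str = "opposite",
                   spacer_length: int = 8) -> IraluSim:
    """Build an IRAlu-like inverted repeat with an editing site and a SNP.

    ``snp_offset`` is relative to the editing site's structural partner
    position: with ``snp_arm='opposite'`` an offset of 0 places the SNP
    exactly opposite the editing site across the helix; with
    ``snp_arm='same'`` it is relative to the editing site itself (offset 0 is
    disallowed because the SNP would erase the editable A).
    """
    if arm_length < 20:
        raise ParameterError("arm_length must be >= 20")
    if snp_arm not in ("opposite", "same"):
        raise ParameterError("snp_arm must be 'opposite' or 'same'")
    rng = np.random.default_rng(seed)
    arm1 = list(rng.choice(list("ACGU"), size=arm_length))
    edit_in_arm = arm_length // 2
    arm1[edit_in_arm] = "A"
    arm1 = "".join(arm1)
    spacer = "".join(rng.choice(list("ACU"), size=spacer_length))
    arm2 = _revcomp_rna(arm1)
    seq = arm1 + spacer + arm2

    editing_offset = edit_in_arm
    # structural partner of arm-1 position i is the mirrored arm-2 position
    partner = arm_length + spacer_length + (arm_length - 1 - edit_in_arm)
    if snp_arm == "opposite":
        pos = partner - snp_offset   # +offset walks toward the hairpin loop
        if not (arm_length + spacer_length <= pos < len(seq)):
            raise ParameterError("snp_offset places the SNP outside the arm")
    else:
        if snp_offset == 0:
            raise ParameterError("same-arm SNP cannot coincide with the editing site")
        pos = editing_offset + snp_offset
        if not (0 <= pos < arm_length):
            raise ParameterError("snp_offset places the SNP outside the arm")

    pairing_base = seq[pos]
    mismatch = {"A": "C", "C": "A", "G": "A", "U": "C"}[pairing_base]
    alt = seq[:pos] + mismatch + seq[pos + 1:]
    return IraluSim(sequence_allele1=seq, sequence_allele2=alt,
                    editing_offset=editing_offset, snp_offset=pos,
                    arm_length=arm_length, spacer_length=spacer_length)


# ---- writers ----------------------------------------------------------------

def counts_to_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def study_to_vcf(study: GenotypeStudy, path) -> None:
    """Write all per-site panels as one phased VCF (positions are disjoint)."""
    merged = GenotypePanel(
        chrom=study.panels[0].chrom,
        positions=np.concatenate([p.positions for p in study.panels]),
        haplotypes=np.concatenate([p.haplotypes for p in study.panels], axis=1),
        snp_ids=[s for p in study.panels for s in p.snp_ids],
        samples=study.samples)
    merged.to_vcf(path)


def iralu_to_fasta(sim: IraluSim, path, name: str = "iralu") -> None:
    with open(path, "w") as fh:
        for label, seq in (("allele1", sim.sequence_allele1),
                           ("allele2", sim.sequence_allele2)):
            fh.write(f">{name}_{label} edit={sim.editing_offset} snp={sim.snp_offset}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
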