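"""Synthetic end-to-end benchmarks: planted-signal mixtures and recovery.

A mixture study plants a known fraction of signal sites (genotype effect
``beta`` on logit editing for the edQTL stage, allelic shift ``delta`` for
the ASED stage) among null sites, runs the full pipeline, and reports how
many planted sites are recovered at the requested FDR together with the
realized false-discovery counts. A companion structure stage simulates
inverted-repeat substrates whose "significant" SNPs sit near the editing site
in the hairpin and whose "control" SNPs sit far, and compares the impact
distributions between classes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ased import ased_scan
from .edqtl import edqtl_scan
from .simulate import (SimConfig, simulate_ased_counts, simulate_edqtl_counts,
                       simulate_genotypes, simulate_iralu)
from .structure import IraluPair, compare_impact_distributions, snp_structure_impact


@dataclass
class MixtureStudy:
    sites: list
    panels: dict                   # site_id -> GenotypePanel
    counts: pd.DataFrame           # edQTL count table
    ased_observations: dict        # site_id -> list[AsedObservation]
    signal_sites: set              # site_ids carrying the planted effects


def simulate_mixture_study(n_individuals: int = 200, n_sites: int = 300,
                           signal_fraction: float = 0.2, beta: float = 1.5,
                           delta: float = 2.0, n_replicates: int = 10,
                           coverage_mean: float = 50.0, sigma_ind: float = 0.3,
                           sigma_allele: float = 0.3, n_snps_per_site: int = 5,
                           maf: float = 0.3, seed: int = 0) -> MixtureStudy:
    """Plant ``signal_fraction`` of sites with both a genotype effect (beta)
    and an allelic shift (delta); the rest are null for both analyses."""
    n_signal = int(round(n_sites * signal_fraction))
    common = dict(n_individuals=n_individuals, n_snps_per_site=n_snps_per_site,
                  coverage_mean=coverage_mean, sigma_ind=sigma_ind,
                  sigma_allele1=sigma_allele, sigma_allele2=sigma_allele,
                  maf=maf)
    cfg_null = SimConfig(n_sites=n_sites - n_signal, beta=0.0, delta=0.0,
                         seed=seed, **common)
    cfg_sig = SimConfig(n_sites=max(n_signal, 1), beta=beta, delta=delta,
                        seed=seed + 1, **common)
    study_null = simulate_genotypes(cfg_null, chrom="chr1")
    counts_null = simulate_edqtl_counts(study_null, cfg_null)
    sites = list(study_null.sites)
    panels = {s.site_id: p for s, p in zip(study_null.sites, study_null.panels)}
    counts = [counts_null]
    signal_sites = set()
    if n_signal:
        study_sig = simulate_genotypes(cfg_sig, chrom="chr2")
        counts.append(simulate_edqtl_counts(study_sig, cfg_sig))
        sites += list(study_sig.sites)
        panels.update({s.site_id: p
                       for s, p in zip(study_sig.sites, study_sig.panels)})
        signal_sites = {s.site_id for s in study_sig.sites}

    rng = np.random.default_rng(seed + 2)
    ased_obs = {}
    for site in sites:
        cfg = cfg_sig if site.site_id in signal_sites else cfg_null
        ased_obs[site.site_id] = simulate_ased_counts(cfg, n_replicates, rng=rng)
    return MixtureStudy(sites=sites, panels=panels,
                        counts=pd.concat(counts, ignore_index=True),
                        ased_observations=ased_obs, signal_sites=signal_sites)


@dataclass
class PipelineResult:
    edqtl_best: pd.DataFrame
    ased_results: pd.DataFrame
    edqtl_recovered: int
    edqtl_false: int
    edqtl_called: int
    ased_recovered: int
    ased_false: int
    ased_called: int
    n_signal: int
    structure_summary: dict = field(default_factory=dict)
    elapsed_s: float = np.nan


def run_pipeline(study: MixtureStudy, fdr: float = 0.10,
                 n_permutations: int = 5, seed: int = 0,
                 structure_snps_per_class: int = 0,
                 arm_length: int = 60) -> PipelineResult:
    """edQTL scan + ASED scan (+ optional structure stage) on a mixture study."""
    t0 = time.time()
    best, _full, _null = edqtl_scan(study.sites, study.panels, study.counts,
                                    n_permutations=n_permutations, fdr=fdr,
                                    seed=seed)
    ased = ased_scan(study.ased_observations, q=fdr)

    sig_edqtl = set(best.loc[best["significant"], "site_id"])
    sig_ased = set(ased.loc[ased["significant"], "key"])
    planted = study.signal_sites

    summary = {}
    if structure_snps_per_class > 0:
        impacts = []
        rng = np.random.default_rng(seed + 7)
        for cls, offsets in (("significant", (0, 1, 2, 3)),
                             ("control", range(8, arm_length // 2))):
            for i in range(structure_snps_per_class):
                off = int(rng.choice(list(offsets)))
                sim = simulate_iralu(int(rng.integers(2 ** 31)), arm_length, off)
                pair = IraluPair(chrom="", alu1=(), alu2=(),
                                 orientation_class="",
                                 editing_offset=sim.editing_offset,
                                 snp_offset=sim.snp_offset)
                impacts.append(snp_structure_impact(
                    pair, sim.sequence_allele1, sim.sequence_allele2,
                    snp_class=cls))
        summary = compare_impact_distributions(impacts)

    return PipelineResult(
        edqtl_best=best, ased_results=ased,
        edqtl_recovered=len(sig_edqtl & planted),
        edqtl_false=len(sig_edqtl - planted), edqtl_called=len(sig_edqtl),
        ased_recovered=len(sig_ased & planted),
        ased_false=len(sig_ased - planted), ased_called=len(sig_ased),
        n_signal=len(planted), structure_summary=summary,
        elapsed_s=time.time() - t0)
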