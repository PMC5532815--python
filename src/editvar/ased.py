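"""Allele-specific editing (ASED): read assignment and the paired test.

Heterozygous SNPs expressed in the transcript assign RNA-seq reads to the two
haplotypes, giving paired edited/unedited counts per allele in every
replicate (one heterozygous individual, or one technical replicate of a
single individual). The paired hierarchical model is, for replicate ``k`` of
site ``i``:

    I_i1k ~ Binomial(n_i1k, Phi_i1k),  logit(Phi_i1k) ~ N(alpha_ik, sigma_i1^2)
    I_i2k ~ Binomial(n_i2k, Phi_i2k),  logit(Phi_i2k) ~ N(alpha_ik + delta_i, sigma_i2^2)

The replicate baseline ``alpha_ik`` is a free fixed effect shared by the two
alleles (the two haplotypes share one cellular environment), ``delta_i`` is
the allelic shift on the logit scale, and ``sigma_i1^2``/``sigma_i2^2``
absorb replicate-to-replicate overdispersion per allele. ``delta = 0`` is
tested by likelihood ratio against chi-square(1); sites are called at
Benjamini-Hochberg FDR 10%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.stats import chi2

from .errors import DataError, NonConvergenceError, UntestableError
from .quadrature import log_binom_logitnormal_grad
from .simulate import AsedObservation
from .sites import EditingSite

_LOG_SIGMA_BOUNDS = (np.log(1e-3), np.log(10.0))   # variance floor 1e-6


@dataclass(frozen=True)
class HetSnpAssignment:
    """A heterozygous SNP used to split reads between alleles at one site."""

    chrom: str
    pos: int                 # 1-based
    allele1: str             # reference-forward base of haplotype 1
    allele2: str
    site: EditingSite = None
    phased: bool = True

    def __post_init__(self):
        if self.allele1 == self.allele2:
            raise DataError("SNP alleles must differ")

    @property
    def is_ag_snp(self) -> bool:
        """A/G (or T/C on the reverse strand) SNPs can be edited themselves and
        masquerade as allelic signal; excluded from assignment by default."""
        return {self.allele1, self.allele2} in ({"A", "G"}, {"T", "C"})


def assign_reads_to_alleles(alignments, assignment: HetSnpAssignment,
                            other_het_snps=(), min_base_quality: int = 0,
                            min_mapping_quality: int = 0,
                            replicate_id: str = "sample") -> AsedObservation:
    """Tally paired allele-specific edited/unedited counts from alignments.

    A read contributes only if it is aligned across both the SNP and the
    editing site; its allele is the base it shows at the SNP (reads showing
    neither allele are discarded). If ``other_het_snps`` lists additional
    phased heterozygous SNPs (HetSnpAssignment, haplotype-consistent allele1/
    allele2), reads spanning several of them with conflicting allele calls are
    discarded. Edited/unedited status follows the strand rules of the
    quantification module.
    """
    from .quantify import _EDITED_BASE, _UNEDITED_BASE, _iter_reads, read_base_at

    site = assignment.site
    counts = np.zeros((2, 2), dtype=int)   # [allele-1][edited/unedited]
    for read in _iter_reads(alignments, site.chrom, site.pos - 1,
                            min_mapping_quality):
        site_base, qual = read_base_at(read, site.pos - 1)
        if site_base is None or (qual is not None and qual < min_base_quality):
            continue
        calls = []
        for snp in (assignment, *other_het_snps):
            base, bq = read_base_at(read, snp.pos - 1)
            if base is None:
                continue
            if bq is not None and bq < min_base_quality:
                continue
            if base.upper() == snp.allele1.upper():
                calls.append(1)
            elif base.upper() == snp.allele2.upper():
                calls.append(2)
        if not calls or len(set(calls)) > 1:
            continue
        snp_base, _ = read_base_at(read, assignment.pos - 1)
        if snp_base is None:
            continue                        # must overlap the defining SNP
        allele = calls[0]
        site_base = site_base.upper()
        if site_base == _EDITED_BASE[site.strand]:
            counts[allele - 1, 0] += 1
        elif site_base == _UNEDITED_BASE[site.strand]:
            counts[allele - 1, 1] += 1
    return AsedObservation(replicate_id, int(counts[0, 0]), int(counts[0, 1]),
                           int(counts[1, 0]), int(counts[1, 1]))


def filter_ased_observations(obs, min_pooled_phi: float = 0.01,
                             min_replicates: int = 3):
    """Replicate filters: both alleles covered and pooled Phi >= 1%; a site is
    analyzable only with >= ``min_replicates`` surviving replicates (else
    returns None)."""
    kept = [o for o in obs
            if o.n_allele1 > 0 and o.n_allele2 > 0
            and o.pooled_phi() >= min_pooled_phi]
    return kept if len(kept) >= min_replicates else None


@dataclass
class AsedFit:
    delta_hat: float
    p_value: float
    lrt_stat: float
    alpha_hat: np.ndarray
    sigma1: float
    sigma2: float
    loglik: float
    loglik_null: float
    phi_allele1_mean: float
    phi_allele2_mean: float
    n_replicates: int
    converged: bool
    ci_allele1: list = field(default_factory=list)   # per-replicate 95% CI
    ci_allele2: list = field(default_factory=list)


def _ased_negloglik(params, i1, n1, i2, n2, nodes):
    """Negative marginal log-likelihood and gradient; params are
    (delta, log sigma1, log sigma2, alpha_1..alpha_K)."""
    delta, ls1, ls2 = params[0], params[1], params[2]
    alpha = params[3:]
    ll1, dmu1, dls1 = log_binom_logitnormal_grad(i1, n1, alpha,
                                                 np.exp(ls1), nodes=nodes)
    ll2, dmu2, dls2 = log_binom_logitnormal_grad(i2, n2, alpha + delta,
                                                 np.exp(ls2), nodes=nodes)
    grad = -np.concatenate([[dmu2.sum(), dls1.sum(), dls2.sum()], dmu1 + dmu2])
    return -(ll1.sum() + ll2.sum()), grad


def _clamped_logit(x):
    return np.log(np.clip(x, 0.001, 0.999) / (1.0 - np.clip(x, 0.001, 0.999)))


def fit_ased_model(obs, nodes: int = 15, compute_ci: bool = True,
                   level: float = 0.95) -> AsedFit:
    """Maximum marginal likelihood fit of the paired allelic model.

    Free parameters: one baseline ``alpha_k`` per replicate, the allelic shift
    ``delta``, and the per-allele SDs. The double integral over the two latent
    logit editing levels factorizes given ``alpha_k``, so each factor is a 1-D
    binomial logit-normal marginal evaluated by adaptive Gauss-Hermite
    quadrature. The null fit constrains ``delta = 0``; the LRT statistic is
    referred to chi-square(1).
    """
    obs = list(obs)
    if len(obs) < 3:
        raise UntestableError("ASED fit requires >= 3 replicates")
    i1 = np.array([o.edited_allele1 for o in obs], dtype=float)
    n1 = np.array([o.n_allele1 for o in obs], dtype=float)
    i2 = np.array([o.edited_allele2 for o in obs], dtype=float)
    n2 = np.array([o.n_allele2 for o in obs], dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise DataError("every replicate needs nonzero coverage on both alleles")

    k = len(obs)
    alpha0 = _clamped_logit((i1 + i2) / (n1 + n2))
    bounds = ([(-20.0, 20.0), _LOG_SIGMA_BOUNDS, _LOG_SIGMA_BOUNDS]
              + [(-30.0, 30.0)] * k)
    args = (i1, n1, i2, n2, nodes)

    start_full = np.concatenate([[0.0, np.log(0.5), np.log(0.5)], alpha0])
    full = None
    for ls0 in (np.log(0.5), np.log(0.1), np.log(1.5)):
        s0 = start_full.copy()
        s0[1] = s0[2] = ls0
        res = minimize(_ased_negloglik, s0, args=args, method="L-BFGS-B",
                       jac=True, bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-11})
        if full is None or res.fun < full.fun:
            full = res
        if full.success:
            break

    def null_nll(params, *a):
        val, grad = _ased_negloglik(np.concatenate([[0.0], params]), *a)
        return val, grad[1:]

    start_null = np.concatenate([[np.log(0.5), np.log(0.5)], alpha0])
    null = None
    for ls0 in (np.log(0.5), np.log(0.1), np.log(1.5)):
        s0 = start_null.copy()
        s0[0] = s0[1] = ls0
        res = minimize(null_nll, s0, args=args, method="L-BFGS-B",
                       jac=True, bounds=bounds[1:],
                       options={"maxiter": 500, "ftol": 1e-11})
        if null is None or res.fun < null.fun:
            null = res
        if null.success:
            break
    # a null optimum above the full one at delta=0 signals a failed line
    # search, not a real likelihood gap; fall back to the full fit's ancillary
    # parameters evaluated at delta = 0
    at_zero = _ased_negloglik(np.concatenate([[0.0], full.x[1:]]), *args)[0]
    if at_zero < null.fun:
        null_fun = at_zero
    else:
        null_fun = null.fun
    if not np.isfinite(full.fun) or not np.isfinite(null_fun):
        raise NonConvergenceError("ASED optimizer did not converge",
                                  diagnostics={"full": full, "null": null})
    lrt = max(0.0, 2.0 * (null_fun - full.fun))
    fit = AsedFit(
        delta_hat=float(full.x[0]), p_value=float(chi2.sf(lrt, df=1)),
        lrt_stat=float(lrt), alpha_hat=full.x[3:].copy(),
        sigma1=float(np.exp(full.x[1])), sigma2=float(np.exp(full.x[2])),
        loglik=-float(full.fun), loglik_null=-float(null_fun),
        phi_allele1_mean=float(np.mean(i1 / n1)),
        phi_allele2_mean=float(np.mean(i2 / n2)),
        n_replicates=k, converged=True)
    if compute_ci:
        fit.ci_allele1 = [phi_confidence_interval(int(a), int(b), level)
                          for a, b in zip(i1, n1)]
        fit.ci_allele2 = [phi_confidence_interval(int(a), int(b), level)
                          for a, b in zip(i2, n2)]
    return fit


def phi_confidence_interval(edited: int, total: int,
                            level: float = 0.95) -> tuple[float, float]:
    """Likelihood-ratio 95% confidence interval for a binomial Phi.

    The interval is {phi0 : 2 [l(phi_hat) - l(phi0)] <= chi2_1(level)} for the
    binomial log-likelihood l; at boundary MLEs (0 or 1) the corresponding
    bound is exact 0 or 1.
    """
    if total <= 0:
        raise DataError("confidence interval undefined at zero coverage")
    y, n = float(edited), float(total)
    phat = y / n
    crit = chi2.ppf(level, df=1) / 2.0

    def ll(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = y * np.log(p) if y > 0 else 0.0
            t2 = (n - y) * np.log1p(-p) if y < n else 0.0
        return t1 + t2

    llhat = ll(phat)

    def g(p):
        return llhat - ll(p) - crit

    eps = 1e-12
    lower = 0.0 if y == 0 else (
        phat if g(eps) < 0 else brentq(g, eps, phat, xtol=1e-12))
    upper = 1.0 if y == n else (
        phat if g(1 - eps) < 0 else brentq(g, phat, 1 - eps, xtol=1e-12))
    return float(lower), float(upper)


def bh_fdr(p_values, q: float = 0.10) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    from statsmodels.stats.multitest import multipletests

    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p_values, alpha=q, method="fdr_bh")
    return reject


def ased_scan(site_observations: dict, q: float = 0.10, nodes: int = 15,
              min_pooled_phi: float = 0.01, min_replicates: int = 3,
              compute_ci: bool = False) -> pd.DataFrame:
    """Run the ASED test over many (site, SNP) observation lists.

    ``site_observations`` maps a key (e.g. "site_id|snp_id") to its list of
    :class:`AsedObservation`. Non-analyzable and non-convergent keys are
    reported with NaN p-values and excluded from the BH correction.
    """
    rows = []
    for key, obs in site_observations.items():
        kept = filter_ased_observations(obs, min_pooled_phi, min_replicates)
        if kept is None:
            rows.append((key, np.nan, np.nan, np.nan, np.nan, 0, "filtered"))
            continue
        try:
            fit = fit_ased_model(kept, nodes=nodes, compute_ci=compute_ci)
        except (UntestableError, NonConvergenceError):
            rows.append((key, np.nan, np.nan, np.nan, np.nan, len(kept),
                         "non_convergent"))
            continue
        rows.append((key, fit.delta_hat, fit.p_value, fit.phi_allele1_mean,
                     fit.phi_allele2_mean, fit.n_replicates, "ok"))
    df = pd.DataFrame(rows, columns=["key", "delta_hat", "p_value",
                                     "phi_allele1_mean", "phi_allele2_mean",
                                     "n_replicates", "status"])
    df["significant"] = False
    ok = df["status"] == "ok"
    if ok.any():
        df.loc[ok, "significant"] = bh_fdr(df.loc[ok, "p_value"].to_numpy(), q=q)
    return df


def read_ased_counts_tsv(path) -> dict:
    """Read a pre-computed allele-count TSV (columns: key, replicate_id,
    edited_allele1, unedited_allele1, edited_allele2, unedited_allele2)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for key, grp in df.groupby("key", sort=False):
        out[key] = [AsedObservation(str(r.replicate_id), int(r.edited_allele1),
                                    int(r.unedited_allele1), int(r.edited_allele2),
                                    int(r.unedited_allele2))
                    for r in grp.itertuples(index=False)]
    return out
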