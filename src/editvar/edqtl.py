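"""edQTL mapping: binomial GLMM association and permutation min-p FDR.

For each editing site, every cis SNP (within +/- 200 kb by default) is tested
for association between genotype dosage and editing level with a binomial
generalized linear mixed model: for individual ``k`` with ``y_k`` edited reads
out of ``n_k``,

    y_k ~ Binomial(n_k, phi_k),   logit(phi_k) = mu + beta * g_k + u_k,
    u_k ~ N(0, sigma^2).

The individual-level random effect absorbs biological overdispersion beyond
binomial sampling noise, so low-coverage individuals are down-weighted
automatically instead of contributing noisy point estimates of phi. The
marginal likelihood is evaluated by adaptive Gauss-Hermite quadrature and the
test of beta = 0 is a likelihood-ratio test against a chi-square(1) reference.

Study-wide significance uses a permutation scheme: individual labels of the
genotype panel are permuted jointly across the cis SNPs of a site (preserving
LD), the minimum p-value over cis SNPs is recorded per site per permutation,
and the pooled minima form the empirical null for the p-value cutoff ``z``
solving P(p0 < z) / P(p1 < z) = f at FDR level ``f``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logit
from scipy.stats import chi2

from .errors import UntestableError
from .genotypes import GenotypePanel
from .quadrature import log_binom_logitnormal_grad
from .sites import EditingSite

_LOG_SIGMA_BOUNDS = (np.log(1e-6), np.log(10.0))


@dataclass
class CisWindow:
    site: EditingSite
    panel: GenotypePanel          # cis SNPs only

    @property
    def distances(self) -> np.ndarray:
        return self.panel.positions - self.site.pos


@dataclass
class EdqtlResult:
    site_id: str
    snp_id: str
    beta: float
    p_value: float
    distance: int                 # signed bp, SNP pos - site pos
    sigma: float = np.nan
    mu: float = np.nan


@dataclass
class GlimmpsFit:
    beta: float
    p_value: float
    mu: float
    sigma: float
    loglik: float
    loglik_null: float
    lrt_stat: float
    n_used: int
    converged: bool


def select_cis_snps(site: EditingSite, panel: GenotypePanel,
                    window_halfwidth: int = 200_000,
                    maf_floor: float = 0.05) -> CisWindow:
    """All biallelic SNPs within the cis window (inclusive bounds) whose MAF
    among the analyzed individuals is >= ``maf_floor`` and > 0."""
    dist = np.abs(panel.positions - site.pos)
    maf = panel.maf()
    keep = (dist <= window_halfwidth) & (maf >= max(maf_floor, 1e-12)) & (maf > 0)
    return CisWindow(site=site, panel=panel.subset_snps(np.flatnonzero(keep)))


def _negloglik(params, y, n, design, nodes):
    """params = (coefficients over design columns..., log sigma)."""
    coef, log_sigma = params[:-1], params[-1]
    eta = design @ coef
    logI, dmu, dls = log_binom_logitnormal_grad(y, n, eta, np.exp(log_sigma),
                                                nodes=nodes)
    grad = -np.concatenate([dmu @ design, [dls.sum()]])
    return -logI.sum(), grad


def fit_glimmps(edited, total, dosage, nodes: int = 9,
                sigma_fixed: float | None = None,
                covariates=None) -> GlimmpsFit:
    """Fit the binomial GLMM and test beta = 0 by likelihood ratio.

    Individuals with zero total coverage are dropped. Raises
    :class:`UntestableError` when fewer than two distinct dosage values remain.
    ``sigma_fixed`` pins the random-effect SD instead of estimating it
    (``sigma_fixed=0`` reduces the model to plain binomial logistic
    regression). ``covariates`` is an optional (n_individuals, c) matrix of
    additive fixed effects (population, batch) present in both the full and
    the null model.
    """
    edited = np.asarray(edited, dtype=float)
    total = np.asarray(total, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    mask = total > 0
    y, n, g = edited[mask], total[mask], dosage[mask]
    if y.size < 3 or np.unique(g).size < 2:
        raise UntestableError("association requires >=2 dosage classes with coverage")
    if covariates is not None:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] != mask.size:
            X = X.T
        X = X[mask]
    else:
        X = np.empty((y.size, 0))

    phi = np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)
    lo = logit(phi)
    gc = g - g.mean()
    denom = np.sum(gc * gc)
    beta0 = float(np.sum(gc * (lo - lo.mean())) / denom) if denom > 0 else 0.0
    mu0 = float(lo.mean() - beta0 * g.mean())

    if sigma_fixed is not None:
        ls = np.log(max(sigma_fixed, 1e-8))
        sigma_bounds = [(ls, ls)]
    else:
        sigma_bounds = [_LOG_SIGMA_BOUNDS]
        ls = np.log(0.3)

    ones = np.ones((y.size, 1))
    design_full = np.column_stack([ones, g, X])
    design_null = np.column_stack([ones, X])
    nc = X.shape[1]
    full = minimize(_negloglik,
                    np.concatenate([[mu0, beta0], np.zeros(nc), [ls]]),
                    args=(y, n, design_full, nodes), method="L-BFGS-B",
                    jac=True,
                    bounds=[(-30, 30)] * (2 + nc) + sigma_bounds)
    null = minimize(_negloglik,
                    np.concatenate([[mu0 + beta0 * g.mean()], np.zeros(nc), [ls]]),
                    args=(y, n, design_null, nodes), method="L-BFGS-B",
                    jac=True,
                    bounds=[(-30, 30)] * (1 + nc) + sigma_bounds)
    lrt = max(0.0, 2.0 * (null.fun - full.fun))
    p = float(chi2.sf(lrt, df=1))
    return GlimmpsFit(beta=float(full.x[1]), p_value=p, mu=float(full.x[0]),
                      sigma=float(np.exp(full.x[-1])), loglik=-float(full.fun),
                      loglik_null=-float(null.fun), lrt_stat=float(lrt),
                      n_used=int(y.size), converged=bool(full.success and null.success))


def fit_binomial_glm(edited, total, dosage) -> tuple[float, float]:
    """Naive binomial logistic regression (no random effect): returns
    (beta, LRT p-value). Anti-conservative under overdispersion; kept as the
    comparator the GLMM is designed to improve on."""
    import statsmodels.api as sm

    edited = np.asarray(edited, dtype=float)
    total = np.asarray(total, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    mask = total > 0
    y, n, g = edited[mask], total[mask], dosage[mask]
    if y.size < 3 or np.unique(g).size < 2:
        raise UntestableError("association requires >=2 dosage classes with coverage")
    endog = np.column_stack([y, n - y])
    full = sm.GLM(endog, sm.add_constant(g), family=sm.families.Binomial()).fit()
    nullm = sm.GLM(endog, np.ones((y.size, 1)), family=sm.families.Binomial()).fit()
    lrt = max(0.0, 2.0 * (full.llf - nullm.llf))
    return float(full.params[1]), float(chi2.sf(lrt, df=1))


def call_edqtl_site(results: list[EdqtlResult]) -> EdqtlResult:
    """The edQTL SNP of a site: among SNPs attaining the minimal p-value, the
    one closest to the site; residual ties broken by lower genomic position."""
    if not results:
        raise UntestableError("no association results for site")
    pmin = min(r.p_value for r in results)
    best = [r for r in results if r.p_value == pmin]
    best.sort(key=lambda r: (abs(r.distance), r.distance))
    return best[0]


def permutation_fdr(observed_min_p, null_min_p, f: float = 0.10):
    """Permutation min-p FDR cutoff.

    Returns ``(z, significant)`` where ``z`` is the largest observed p-value
    such that [fraction of null min-p <= z] / [fraction of observed <= z]
    is <= ``f``, and ``significant`` flags observed p-values <= z. When no
    cutoff satisfies the bound, z = 0 and nothing is significant.
    """
    observed = np.asarray(observed_min_p, dtype=float)
    null = np.asarray(null_min_p, dtype=float)
    if null.size == 0:
        raise UntestableError("empty permutation null")
    order = np.sort(observed)
    null_sorted = np.sort(null)
    # fractions with <= via searchsorted on sorted arrays
    frac_null = np.searchsorted(null_sorted, order, side="right") / null.size
    frac_obs = np.searchsorted(order, order, side="right") / observed.size
    ok = frac_null / frac_obs <= f
    if not np.any(ok):
        return 0.0, np.zeros(observed.shape, dtype=bool)
    z = float(order[np.flatnonzero(ok).max()])
    return z, observed <= z


def permutation_null_min_p(edited, total, panel: GenotypePanel, site: EditingSite,
                           rng, n_permutations: int = 5, nodes: int = 9,
                           window_halfwidth: int = 200_000,
                           maf_floor: float = 0.05) -> list[float]:
    """Minimum cis p-value per permutation of individual genotype labels.

    The permutation is applied jointly to all cis SNPs (one shuffle of the
    individual index per permutation), preserving LD among SNPs while breaking
    genotype-phenotype association.
    """
    win = select_cis_snps(site, panel, window_halfwidth, maf_floor)
    dos = win.panel.dosage()
    out = []
    for _ in range(n_permutations):
        perm = rng.permutation(dos.shape[0])
        best = 1.0
        for j in range(dos.shape[1]):
            try:
                fit = fit_glimmps(edited, total, dos[perm, j], nodes=nodes)
            except UntestableError:
                continue
            best = min(best, fit.p_value)
        out.append(best)
    return out


def edqtl_scan(sites, panels, counts: pd.DataFrame,
               window_halfwidth: int = 200_000, maf_floor: float = 0.05,
               n_permutations: int = 5, fdr: float = 0.10,
               seed: int = 0, nodes: int = 9):
    """Full edQTL scan over sites.

    ``panels`` maps site_id -> GenotypePanel (or is a parallel list);
    ``counts`` is the long count table (site_id, individual, edited,
    unedited) with individuals ordered as in each panel. Returns
    ``(best_df, full_df, null_min_p)`` where ``best_df`` has one row per
    testable site with the best SNP, its statistics and a ``significant``
    flag at the permutation-FDR cutoff.
    """
    if not isinstance(panels, dict):
        panels = {s.site_id: p for s, p in zip(sites, panels)}
    rng = np.random.default_rng(seed)
    best_rows, full_rows, null_pool, observed = [], [], [], []
    for site in sites:
        panel = panels[site.site_id]
        grp = counts[counts["site_id"] == site.site_id].set_index("individual")
        grp = grp.reindex(panel.samples)
        y = grp["edited"].to_numpy(dtype=float)
        n = y + grp["unedited"].to_numpy(dtype=float)
        win = select_cis_snps(site, panel, window_halfwidth, maf_floor)
        results = []
        dos = win.panel.dosage()
        for j in range(win.panel.n_snps):
            try:
                fit = fit_glimmps(y, n, dos[:, j], nodes=nodes)
            except UntestableError:
                continue
            res = EdqtlResult(site_id=site.site_id, snp_id=win.panel.snp_ids[j],
                              beta=fit.beta, p_value=fit.p_value,
                              distance=int(win.panel.positions[j] - site.pos),
                              sigma=fit.sigma, mu=fit.mu)
            results.append(res)
            full_rows.append(res)
        if not results:
            continue
        best = call_edqtl_site(results)
        best_rows.append(best)
        observed.append(best.p_value)
        null_pool.extend(permutation_null_min_p(
            y, n, panel, site, rng, n_permutations, nodes,
            window_halfwidth, maf_floor))
    if not best_rows:
        raise UntestableError("no testable site in scan")
    z, sig = permutation_fdr(np.array(observed), np.array(null_pool), f=fdr)
    best_df = pd.DataFrame([vars(r) for r in best_rows])
    best_df["significant"] = sig
    full_df = pd.DataFrame([vars(r) for r in full_rows])
    return best_df, full_df, np.array(null_pool)
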