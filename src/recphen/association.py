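"""Per-SNP QC and additive linear-model GWAS within (cohort x sex) strata.

Marker QC follows standard family-data practice: minor allele frequency and
an exact Hardy-Weinberg test computed on parental founders only (children
are non-independent copies of parental alleles), with cut-offs MAF >= 2% and
HWE p >= 1e-4.  Association is ordinary least squares of the parent's
phenotype on minor-allele dosage (additive model) with an intercept; the
two-sided p-value comes from the t distribution with n-2 degrees of freedom.
Each stratum uses one observation per parent.  ``qq_lambda`` summarises test
calibration via the genomic inflation factor (median association chi-square
over its null median).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_formats import MISSING, GenotypeTable, MarkerMap, Pedigree

ASSOC_COLUMNS = ["snp", "chrom", "bp", "stratum", "beta", "se", "t", "p", "n"]

# smallest positive double: p-value floor for numerically perfect fits
P_FLOOR = float(np.finfo(float).tiny)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed
    that of the observed count.  Monomorphic input returns 1.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    n_minor = n_het + 2 * min(n_hom_major, n_hom_minor)
    rare = min(n_minor, 2 * n - n_minor)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | allele counts), common normalising terms dropped
    logp = (hets * np.log(2.0)
            - special.gammaln(hom_rare + 1)
            - special.gammaln(hets + 1)
            - special.gammaln(hom_common + 1))
    logp -= special.logsumexp(logp)
    p_obs = logp[np.flatnonzero(hets == n_het)[0]]
    total = np.exp(logp[logp <= p_obs + 1e-12]).sum()
    return float(min(total, 1.0))


def founder_genotype_counts(genos: GenotypeTable, pedigree: Pedigree) -> np.ndarray:
    """(n_markers, 3) founder genotype counts: hom-major, het, hom-minor."""
    fdose = genos.subset_rows(pedigree.founders)
    counts = np.stack([(fdose == d).sum(axis=0) for d in (0, 1, 2)], axis=1)
    return counts.astype(np.int64)


def qc_filter(genos: GenotypeTable, pedigree: Pedigree,
              hwe_max: float = 1e-4, maf_min: float = 0.02) -> np.ndarray:
    """Boolean keep-mask over markers: founder MAF >= maf_min and exact HWE
    p >= hwe_max."""
    counts = founder_genotype_counts(genos, pedigree)
    n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_minor = (counts[:, 1] + 2 * counts[:, 2]) / (2 * n)
    maf = np.minimum(freq_minor, 1 - freq_minor)
    keep = np.zeros(len(counts), dtype=bool)
    cache: dict[tuple, bool] = {}
    for j in range(len(counts)):
        if n[j] == 0 or np.isnan(maf[j]) or maf[j] < maf_min:
            continue
        key = tuple(counts[j])
        if key not in cache:
            cache[key] = hwe_exact_p(*counts[j]) >= hwe_max
        keep[j] = cache[key]
    return keep


# ---------------------------------------------------------------------------
# additive linear model
# ---------------------------------------------------------------------------

@dataclass
class AssocResult:
    beta: float
    se: float
    t: float
    p: float
    n: int


def additive_linear_test(y: np.ndarray, g: np.ndarray) -> AssocResult:
    """OLS of phenotype on dosage with intercept; two-sided t-test on the slope.

    Pairs with missing phenotype (NaN) or missing dosage are dropped.  A
    constant dosage or n < 3 yields missing statistics; a numerically perfect
    fit reports the p-value floor.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(g) & (g != MISSING)
    y, g = y[ok], g[ok]
    n = y.size
    if n < 3 or np.all(g == g[0]):
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n)
    gm, ym = g.mean(), y.mean()
    sxx = float(np.sum((g - gm) ** 2))
    sxy = float(np.sum((g - gm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    df = n - 2
    sigma2 = rss / df
    if sigma2 <= 0.0:
        return AssocResult(beta, 0.0, np.inf if beta != 0 else 0.0,
                           P_FLOOR if beta != 0 else 1.0, n)
    se = float(np.sqrt(sigma2 / sxx))
    t = beta / se
    p = float(max(2.0 * stats.t.sf(abs(t), df), P_FLOOR))
    return AssocResult(beta, se, t, p, n)


def bulk_linear_scan(y: np.ndarray, G: np.ndarray) -> pd.DataFrame:
    """Vectorised additive_linear_test over a (n_markers, n_samples) dosage
    matrix (MISSING = -1); identical formulas, one pass per cohort."""
    y = np.asarray(y, dtype=float)
    keep_obs = ~np.isnan(y)
    y = y[keep_obs]
    G = np.asarray(G)[:, keep_obs].astype(float)
    mask = G != MISSING
    Gm = np.where(mask, G, 0.0)
    n = mask.sum(axis=1)
    sy = mask @ y
    sx = Gm.sum(axis=1)
    sxx = (Gm * Gm).sum(axis=1)
    sxy = Gm @ y
    syy = mask @ (y * y)
    with np.errstate(invalid="ignore", divide="ignore"):
        cxx = sxx - sx * sx / n
        cxy = sxy - sx * sy / n
        cyy = syy - sy * sy / n
        beta = cxy / cxx
        rss = np.maximum(cyy - beta * cxy, 0.0)
        df = n - 2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / cxx)
        t = beta / se
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1)), np.nan)
    bad = (n < 3) | (cxx <= 0)
    perfect = ~bad & (sigma2 <= 0.0)
    t = np.where(perfect, np.where(beta != 0, np.inf, 0.0), t)
    p = np.where(perfect, np.where(beta != 0, P_FLOOR, 1.0), np.maximum(p, P_FLOOR))
    for arr in (beta, se, t, p):
        arr[bad] = np.nan
    return pd.DataFrame({"beta": beta, "se": se, "t": t, "p": p, "n": n})


def covariate_linear_test(y: np.ndarray, g: np.ndarray,
                          covariates: np.ndarray) -> AssocResult:
    """OLS of y on [1, g, covariates]; t-test on the dosage coefficient."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] == y.size and C.shape[1] != y.size:
        C = C.T  # accept (n, k) or (k, n)
    ok = ~np.isnan(y) & ~np.isnan(g) & (g != MISSING) & ~np.isnan(C).any(axis=0)
    y, g, C = y[ok], g[ok], C[:, ok]
    n = y.size
    X = np.column_stack([np.ones(n), g, C.T])
    k = X.shape[1]
    if n < k + 1 or np.all(g == g[0]):
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n)
    xtx = X.T @ X
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError:
        return AssocResult(np.nan, np.nan, np.nan, np.nan, n)
    coef = xtx_inv @ (X.T @ y)
    resid = y - X @ coef
    df = n - k
    sigma2 = float(resid @ resid) / df
    if sigma2 <= 0.0:
        return AssocResult(float(coef[1]), 0.0,
                           np.inf if coef[1] != 0 else 0.0,
                           P_FLOOR if coef[1] != 0 else 1.0, n)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = float(coef[1] / se)
    p = float(max(2.0 * stats.t.sf(abs(t), df), P_FLOOR))
    return AssocResult(float(coef[1]), se, t, p, n)


def run_gwas(pheno: pd.DataFrame, genos: GenotypeTable, marker_map: MarkerMap,
             pedigree: Pedigree, phenotype: str, sex: str,
             cohort: str | None = None, keep: np.ndarray | None = None,
             min_stratum: int = 10,
             covariate_columns: list[str] | None = None) -> pd.DataFrame:
    """Additive GWAS of one phenotype within one (cohort x sex) stratum.

    One observation per parent; markers may be pre-filtered with a QC
    ``keep`` mask.  ``covariate_columns`` optionally names extra phenotype
    table columns to adjust for (off by default).  Combined-sex pooling is
    deliberately not offered: the cross-sex "combined" analysis is a
    meta-analysis over strata (see meta_analysis).
    """
    sub = pheno[pheno["sex"] == sex]
    if cohort is not None:
        sub = sub[sub["cohort"] == cohort]
    sub = sub[~sub[phenotype].isna()]
    sub = sub[[genos.has(p) for p in sub["parent"]]]
    if len(sub) < min_stratum:
        raise ValueError(f"stratum {cohort}:{sex} has {len(sub)} phenotyped parents "
                         f"(< {min_stratum}); refusing unstable fits")
    y = sub[phenotype].to_numpy(dtype=float)
    G = genos.subset_rows(list(sub["parent"])).T  # (markers, parents)
    if keep is None:
        keep = np.ones(len(marker_map), dtype=bool)
    if covariate_columns:
        C = sub[list(covariate_columns)].to_numpy(dtype=float).T
        fits = [covariate_linear_test(y, G[j].astype(float), C)
                for j in np.flatnonzero(keep)]
        res = pd.DataFrame([(f.beta, f.se, f.t, f.p, f.n) for f in fits],
                           columns=["beta", "se", "t", "p", "n"])
    else:
        res = bulk_linear_scan(y, G[keep])
    label = f"{cohort}:{sex}" if cohort is not None else sex
    out = pd.DataFrame({
        "snp": marker_map.ids[keep],
        "chrom": marker_map.df["chrom"].to_numpy()[keep],
        "bp": marker_map.df["bp"].to_numpy()[keep],
        "stratum": label,
    })
    return pd.concat([out, res.reset_index(drop=True)], axis=1)[ASSOC_COLUMNS]


# ---------------------------------------------------------------------------
# calibration diagnostics
# ---------------------------------------------------------------------------

def qq_lambda(pvalues) -> tuple[pd.DataFrame, float]:
    """QQ table (-log10 expected vs observed) and genomic inflation factor.

    Expected quantiles are uniform order statistics i/(m+1); lambda_GC is the
    median of the chi-square(1) quantile transform of the p-values divided by
    the chi-square(1) median (~0.455).
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("need at least one valid p-value")
    obs = np.sort(p)
    m = obs.size
    exp = np.arange(1, m + 1) / (m + 1)
    table = pd.DataFrame({"expected_neglog10": -np.log10(exp),
                          "observed_neglog10": -np.log10(np.maximum(obs, P_FLOOR))})
    chi2 = stats.chi2.isf(obs, 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    return table, lam
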