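"""Simulation studies validating the pipeline against known truth.

Each routine generates synthetic cohorts with the bundled simulator, runs the
relevant pipeline stages from scratch, and returns a dictionary of summary
numbers (recovery rates, calibration statistics, recovered effect sizes).
They are used both by the test suite and by ``scripts/acceptance.py``.

Problem sizes are desk-scale by design: hundreds of families and 10^3-10^4
markers per study rather than cohort-consortium sizes.  For the effect-size
recovery studies the marker map is kept dense (thousands of markers per
chromosome) so that event-interval resolution losses attenuate recovered
effects by only a few percent; the arrays the method targets in practice are
denser still.
"""

from __future__ import annotations

import math
from dataclasses import replace
from fractions import Fraction

import numpy as np
import pandas as pd

from .association import (additive_linear_test, hwe_exact_p, qc_filter,
                          qq_lambda, run_gwas)
from .crossover_calling import call_cohort, find_informative_sites, sharing_states
from .io_formats import SEX_FEMALE, SEX_MALE
from .meta_analysis import fixed_effects_meta, run_meta
from .phenotypes import build_phenotype_table
from .synthetic_cohort import QtlConfig, SimConfig, paired_cohorts, simulate_cohort


def _pair_site_positions(cohort, min_children: int = 2) -> dict:
    """Per (parent, chrom): positions of informative sites usable by the
    first-reference sib pair (the sites the switch scan actually sees)."""
    out = {}
    mmap, genos = cohort.marker_map, cohort.genotypes
    bp_all = mmap.df["bp"].to_numpy()
    for fam in cohort.pedigree.families:
        kids = fam.children
        for parent, other in ((fam.father, fam.mother), (fam.mother, fam.father)):
            pdose, odose = genos.row(parent), genos.row(other)
            kdose = genos.subset_rows(kids)
            for chrom in mmap.chromosomes:
                sl = mmap.chrom_slice(chrom)
                sites = find_informative_sites(pdose[sl], odose[sl], kdose[:, sl],
                                               bp_all[sl], kids)
                _, pos = sharing_states(sites.codes[0], sites.codes[1], sites.bp)
                out[(parent, chrom)] = pos
    return out


def _callable_mask(truth: pd.DataFrame, site_pos: dict, min_run: int) -> np.ndarray:
    """Flag true crossovers with >= min_run determined informative sites
    between them and both the chromosome ends and the nearest other switch of
    the same parent (crossovers in either child interrupt the sharing runs)."""
    flags = np.zeros(len(truth), dtype=bool)
    truth = truth.reset_index(drop=True)
    for (parent, chrom), grp in truth.groupby(["parent", "chrom"], sort=False):
        pos = site_pos.get((parent, str(chrom)))
        if pos is None or pos.size == 0:
            continue
        xs = np.sort(grp["pos"].to_numpy())
        bounds = np.concatenate([[0], xs, [np.iinfo(np.int64).max]])
        # sites with bp in (x_j, x_{j+1}] belong to the run between switches
        counts = np.diff(np.searchsorted(pos, bounds, side="right"))
        ok = (counts[:-1] >= min_run) & (counts[1:] >= min_run)
        order = np.argsort(grp["pos"].to_numpy())
        idx = grp.index.to_numpy()[order]
        flags[idx] = ok
    return flags


def _match_events_to_truth(events: pd.DataFrame, truth: pd.DataFrame):
    """Per called event, how many true crossovers of the same parent fall in
    its interval; per true crossover, whether any event covers it."""
    hits_per_event = np.zeros(len(events), dtype=int)
    covered = np.zeros(len(truth), dtype=bool)
    truth_idx = {}
    for key, grp in truth.groupby(["parent", "chrom"], sort=False):
        truth_idx[(key[0], str(key[1]))] = (grp["pos"].to_numpy(), grp.index.to_numpy())
    for i, ev in enumerate(events.itertuples()):
        pos, tidx = truth_idx.get((ev.parent, str(ev.chrom)),
                                  (np.empty(0, dtype=np.int64),
                                   np.empty(0, dtype=np.int64)))
        inside = (pos > ev.start) & (pos <= ev.end)
        hits_per_event[i] = int(inside.sum())
        covered[tidx[inside]] = True
    return hits_per_event, covered


def crossover_recovery(seed: int, n_families: int = 200, n_markers: int = 1000,
                       lam: float = 2.0, epsilon: float = 0.0,
                       min_run: int = 5) -> dict:
    """Clean-data recovery study: 2-child families, one chromosome.

    Precision counts called events whose interval contains exactly one true
    crossover; recall is reported both over all true crossovers and over
    callable ones (>= min_run usable informative sites on each flank, per the
    caller's stated guarantee).
    """
    cfg = SimConfig(n_families=n_families, n_markers_per_chrom=n_markers,
                    lambda_male=lam, lambda_female=lam,
                    genotype_error_rate=epsilon, seed=seed)
    cohort = simulate_cohort(cfg)
    events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes,
                         min_run=min_run)
    hits, covered = _match_events_to_truth(events, cohort.truth)
    site_pos = _pair_site_positions(cohort)
    callable_ = _callable_mask(cohort.truth, site_pos, min_run)
    n_events = len(events)
    return {
        "n_events": float(n_events),
        "n_true": float(len(cohort.truth)),
        "n_callable": float(callable_.sum()),
        "precision": float((hits == 1).mean()) if n_events else 1.0,
        "precision_nonempty": float((hits >= 1).mean()) if n_events else 1.0,
        "recall_callable": float(covered[callable_].mean()) if callable_.any() else 1.0,
        "recall_all": float(covered.mean()) if len(cohort.truth) else 1.0,
    }


def error_robustness(seed: int, n_families: int = 200, n_markers: int = 1000,
                     lam: float = 2.0, epsilon: float = 2e-3) -> dict:
    """Spurious-event rate under genotyping error, with and without the
    five-consecutive-marker smoothing filter."""
    cfg = SimConfig(n_families=n_families, n_markers_per_chrom=n_markers,
                    lambda_male=lam, lambda_female=lam,
                    genotype_error_rate=epsilon, seed=seed)
    cohort = simulate_cohort(cfg)
    n_meioses = sum(len(f.children) for f in cohort.pedigree.families) * 2
    out = {}
    for min_run in (5, 1):
        events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes,
                             min_run=min_run)
        hits, _ = _match_events_to_truth(events, cohort.truth)
        out[f"spurious_per_meiosis_minrun{min_run}"] = float((hits == 0).sum() / n_meioses)
    r5 = out["spurious_per_meiosis_minrun5"]
    out["spurious_ratio_minrun1_vs_5"] = (
        out["spurious_per_meiosis_minrun1"] / r5 if r5 > 0 else float("inf"))
    return out


def phenotype_consistency(seed: int, n_families: int = 200,
                          n_markers: int = 20_000, usage: float = 0.4) -> dict:
    """Arithmetic identities of the phenotype table plus hotspot-usage
    recovery: pooled hotspot fraction of resolution-passing events vs the
    configured usage probability, with its Monte-Carlo SE.

    Crossovers localise to the gap between flanking informative markers and
    fall preferentially into large gaps, so a map dense enough to leave a
    usable number of <=30 kb events is required (the default gives mean
    informative spacing ~20 kb)."""
    cfg = SimConfig(n_families=n_families, n_markers_per_chrom=n_markers,
                    hotspot_usage_male=usage, hotspot_usage_female=usage, seed=seed)
    cohort = simulate_cohort(cfg)
    events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes)
    pheno = build_phenotype_table(events, cohort.pedigree,
                                  cohort.hotspots, cohort.motifs)
    counts = pheno["HS_CNT"] + pheno["NHS_CNT"]
    # identity 1: HS_CNT + NHS_CNT == (resolution-passing events)/k, re-derived
    widths = events["end"] - events["start"]
    res_events = events[widths <= 30_000]
    per_parent = res_events.groupby("parent").size()
    expected = pheno["parent"].map(per_parent).fillna(0).to_numpy() / pheno["k"].to_numpy()
    id1 = float(np.max(np.abs(counts.to_numpy() - expected), initial=0.0))
    # identity 2: HS_PCT * (HS_CNT + NHS_CNT) == HS_CNT where defined
    defined = ~pheno["HS_PCT"].isna()
    id2 = float(np.max(np.abs(
        (pheno.loc[defined, "HS_PCT"] * counts[defined] - pheno.loc[defined, "HS_CNT"])
        .to_numpy()), initial=0.0))
    n_res = len(res_events)
    n_hs = int(sum(cohort.hotspots.overlaps(str(r.chrom), r.start, r.end)
                   for r in res_events.itertuples()))
    frac = n_hs / n_res if n_res else float("nan")
    se = math.sqrt(usage * (1 - usage) / n_res) if n_res else float("nan")
    return {"identity_count_max_err": id1, "identity_pct_max_err": id2,
            "n_resolution_events": float(n_res), "hotspot_fraction": frac,
            "hotspot_fraction_se": se, "configured_usage": usage}


def sex_ratio_recovery(seed: int, n_families: int = 200, n_markers: int = 3000,
                       lam_male: float = 1.2, ratio: float = 1.55) -> dict:
    """Recover the configured female:male crossover-rate ratio from called ARC."""
    cfg = SimConfig(n_families=n_families, n_markers_per_chrom=n_markers,
                    lambda_male=lam_male, lambda_female=lam_male * ratio, seed=seed)
    cohort = simulate_cohort(cfg)
    events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes)
    pheno = build_phenotype_table(events, cohort.pedigree,
                                  cohort.hotspots, cohort.motifs)
    male = pheno.loc[pheno["sex"] == SEX_MALE, "ARC"].to_numpy()
    female = pheno.loc[pheno["sex"] == SEX_FEMALE, "ARC"].to_numpy()
    est = float(female.mean() / male.mean())
    # delta-method SE of the ratio of means
    se = est * math.sqrt(female.var(ddof=1) / (len(female) * female.mean() ** 2)
                         + male.var(ddof=1) / (len(male) * male.mean() ** 2))
    return {"arc_ratio": est, "arc_ratio_se": se, "configured_ratio": ratio,
            "arc_male_mean": float(male.mean()), "arc_female_mean": float(female.mean())}


# ---------------------------------------------------------------------------
# statistical engines vs independent oracles
# ---------------------------------------------------------------------------

def _hwe_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-rational enumeration of the conditional HWE test (independent of
    the gammaln implementation)."""
    n = n_aa + n_ab + n_bb
    nb = n_ab + 2 * min(n_aa, n_bb)
    rare = min(nb, 2 * n - nb)
    if rare == 0:
        return 1.0
    weights = {}
    for h in range(rare % 2, rare + 1, 2):
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        weights[h] = Fraction(math.factorial(n) * 2**h,
                              math.factorial(hom_r) * math.factorial(h)
                              * math.factorial(hom_c))
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(wt for wt in weights.values() if wt <= obs) / total)


def ols_oracle_max_error(seed: int, n_instances: int = 1000) -> float:
    """Max relative error of additive_linear_test vs normal equations solved
    with numpy.linalg.lstsq on random small instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(5, 60))
        g = rng.integers(0, 3, size=n).astype(float)
        if np.all(g == g[0]):
            g[0] = (g[0] + 1) % 3
        y = rng.normal(size=n) + g * rng.normal()
        res = additive_linear_test(y, g)
        X = np.stack([np.ones(n), g], axis=1)
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(rss[0]) if len(rss) else float(np.sum((y - X @ coef) ** 2))
        se = math.sqrt(rss / (n - 2) * np.linalg.inv(X.T @ X)[1, 1])
        worst = max(worst,
                    abs(res.beta - coef[1]) / max(abs(coef[1]), 1e-12),
                    abs(res.se - se) / max(se, 1e-12))
    return worst


def hwe_oracle_max_error(n_max: int = 50) -> float:
    """Max |difference| between hwe_exact_p and the exact-rational enumeration
    over every genotype-count triple with total <= n_max."""
    worst = 0.0
    for n in range(1, n_max + 1):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                worst = max(worst, abs(hwe_exact_p(n_aa, n_ab, n_bb)
                                       - _hwe_oracle(n_aa, n_ab, n_bb)))
    return worst


def meta_closed_form_max_error() -> float:
    """Worked inverse-variance examples: equal weights average, identity on a
    single study, and the (1,1)+(0,0.5) case."""
    checks = [
        (fixed_effects_meta([(1, 1), (3, 1)])[:2], (2.0, 1 / math.sqrt(2))),
        (fixed_effects_meta([(0.5, 0.2)])[:2], (0.5, 0.2)),
        (fixed_effects_meta([(1, 1), (0, 0.5)])[:2], (0.2, 1 / math.sqrt(5))),
    ]
    return max(max(abs(a - b) for a, b in zip(got, want)) for got, want in checks)


def engine_oracles(seed: int, n_instances: int = 1000, hwe_n_max: int = 50) -> dict:
    return {
        "ols_max_rel_err": ols_oracle_max_error(seed, n_instances),
        "hwe_max_abs_err": hwe_oracle_max_error(hwe_n_max),
        "meta_max_abs_err": meta_closed_form_max_error(),
    }


# ---------------------------------------------------------------------------
# GWAS calibration and QTL recovery
# ---------------------------------------------------------------------------

def null_calibration(seed: int, n_families: int = 500,
                     n_markers_per_chrom: int = 5000,
                     n_chromosomes: int = 2) -> dict:
    """Type-I error and genomic inflation of the male-stratum ARC GWAS on a
    cohort with no QTL (one observation per father, ~10^4 markers)."""
    cfg = SimConfig(n_families=n_families, n_chromosomes=n_chromosomes,
                    n_markers_per_chrom=n_markers_per_chrom, seed=seed)
    cohort = simulate_cohort(cfg)
    events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes)
    pheno = build_phenotype_table(events, cohort.pedigree,
                                  cohort.hotspots, cohort.motifs)
    keep = qc_filter(cohort.genotypes, cohort.pedigree)
    res = run_gwas(pheno, cohort.genotypes, cohort.marker_map, cohort.pedigree,
                   "ARC", sex=SEX_MALE, cohort=cfg.cohort, keep=keep)
    p = res["p"].to_numpy()
    p = p[~np.isnan(p)]
    _, lam = qq_lambda(p)
    m = p.size
    return {"type1_at_0.05": float((p < 0.05).mean()),
            "type1_se": math.sqrt(0.05 * 0.95 / m),
            "lambda_gc": lam, "n_markers_tested": float(m),
            "n_parents": float(res["n"].max())}


_QTL_STUDY = dict(n_families=250, n_chromosomes=3, n_markers_per_chrom=6000)


def _qtl_pipeline(cfg: SimConfig, phenotype: str):
    """Two cohorts on a shared panel -> per-stratum GWAS -> meta tables.

    Returns (combined-sex meta, female meta, male meta, causal snp id).
    """
    ca, cb = paired_cohorts(cfg)
    causal = ca.marker_map.ids[cfg.qtl.marker_index]
    tables = {}
    for cohort in (ca, cb):
        events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes)
        pheno = build_phenotype_table(events, cohort.pedigree, cohort.hotspots,
                                      cohort.motifs, cohort=cohort.config.cohort)
        keep = qc_filter(cohort.genotypes, cohort.pedigree)
        for sex in (SEX_FEMALE, SEX_MALE):
            tables[(cohort.config.cohort, sex)] = run_gwas(
                pheno, cohort.genotypes, cohort.marker_map, cohort.pedigree,
                phenotype, sex=sex, cohort=cohort.config.cohort, keep=keep)
    order = [("GDCS", SEX_FEMALE), ("GDCS", SEX_MALE),
             ("AGRE", SEX_FEMALE), ("AGRE", SEX_MALE)]
    combined = run_meta([tables[k] for k in order])
    female = run_meta([tables[order[0]], tables[order[2]]])
    male = run_meta([tables[order[1]], tables[order[3]]])
    return combined, female, male, causal


def qtl_recovery(seed: int, n_reps: int = 20, beta_count: float = 1.5) -> dict:
    """Additive count-QTL recovery across two cohorts x two sexes.

    Per replicate: does the causal marker rank first in the combined-sex
    meta-analysis, and what effect does the meta estimate?  Reports the
    top-rank fraction and the mean estimate with the mean per-replicate SE.
    """
    qtl = QtlConfig(marker_index=_QTL_STUDY["n_markers_per_chrom"] // 2,
                    beta_count=beta_count)
    top, betas, ses = [], [], []
    for r in range(n_reps):
        cfg = SimConfig(**_QTL_STUDY, qtl=qtl, seed=seed + 1000 * r)
        combined, _, _, causal = _qtl_pipeline(cfg, "ARC")
        row = combined.loc[combined["snp"] == causal]
        top.append(bool(len(row)) and combined["p"].idxmin() == row.index[0])
        betas.append(float(row["beta"].iloc[0]) if len(row) else float("nan"))
        ses.append(float(row["se"].iloc[0]) if len(row) else float("nan"))
    return {"top1_fraction": float(np.mean(top)),
            "beta_mean": float(np.nanmean(betas)),
            "beta_se_mean": float(np.nanmean(ses)),
            "beta_true": beta_count, "n_replicates": float(n_reps)}


def sex_antagonistic_recovery(seed: int, n_reps: int = 5,
                              beta: float = 1.5) -> dict:
    """Opposite-signed count QTL by sex: sex-stratified meta-analyses should
    recover the signed effects while the combined-sex |z| is attenuated."""
    qtl = QtlConfig(marker_index=_QTL_STUDY["n_markers_per_chrom"] // 2,
                    beta_count=beta, beta_count_male=-beta)
    bf, bm, sf, sm, atten = [], [], [], [], []
    for r in range(n_reps):
        cfg = SimConfig(**_QTL_STUDY, qtl=qtl, seed=seed + 1000 * r)
        combined, female, male, causal = _qtl_pipeline(cfg, "ARC")
        rf = female.loc[female["snp"] == causal].iloc[0]
        rm = male.loc[male["snp"] == causal].iloc[0]
        rc = combined.loc[combined["snp"] == causal].iloc[0]
        bf.append(rf["beta"]); sf.append(rf["se"])
        bm.append(rm["beta"]); sm.append(rm["se"])
        atten.append(abs(rc["z"]) < min(abs(rf["z"]), abs(rm["z"])))
    return {"beta_female_mean": float(np.mean(bf)), "se_female_mean": float(np.mean(sf)),
            "beta_male_mean": float(np.mean(bm)), "se_male_mean": float(np.mean(sm)),
            "beta_true_female": beta, "beta_true_male": -beta,
            "combined_attenuated_fraction": float(np.mean(atten)),
            "n_replicates": float(n_reps)}


def compensation_pattern(seed: int, beta_usage: float = 0.15) -> dict:
    """Hotspot-usage QTL (count effect zero): hotspot and non-hotspot count
    phenotypes should show opposite-signed effects at the causal marker while
    total recombination shows none."""
    qtl = QtlConfig(marker_index=_QTL_STUDY["n_markers_per_chrom"] // 2,
                    beta_usage=beta_usage)
    cfg = SimConfig(**_QTL_STUDY, qtl=qtl, seed=seed)
    ca, cb = paired_cohorts(cfg)
    causal = ca.marker_map.ids[qtl.marker_index]
    out = {}
    tables = {ph: [] for ph in ("HS_CNT", "NHS_CNT", "ARC")}
    for cohort in (ca, cb):
        events = call_cohort(cohort.pedigree, cohort.marker_map, cohort.genotypes)
        pheno = build_phenotype_table(events, cohort.pedigree, cohort.hotspots,
                                      cohort.motifs, cohort=cohort.config.cohort)
        keep = qc_filter(cohort.genotypes, cohort.pedigree)
        for ph in tables:
            for sex in (SEX_FEMALE, SEX_MALE):
                tables[ph].append(run_gwas(
                    pheno, cohort.genotypes, cohort.marker_map, cohort.pedigree,
                    ph, sex=sex, cohort=cohort.config.cohort, keep=keep))
    for ph, tabs in tables.items():
        meta = run_meta(tabs)
        row = meta.loc[meta["snp"] == causal].iloc[0]
        out[f"{ph}_beta"] = float(row["beta"])
        out[f"{ph}_se"] = float(row["se"])
        out[f"{ph}_z"] = float(row["z"])
    out["opposite_signs"] = float(np.sign(out["HS_CNT_beta"])
                                  != np.sign(out["NHS_CNT_beta"]))
    out["arc_within_3se_of_zero"] = float(abs(out["ARC_beta"]) <= 3 * out["ARC_se"])
    return out
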