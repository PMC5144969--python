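"""Inverse-variance fixed-effects meta-analysis of per-stratum GWAS results.

Per-study effect estimates are combined with weights w_i = 1/se_i^2 under a
common-effect model; the combined z = beta/se gives a two-sided normal
p-value.  Each record carries a direction string with one character per study
in a fixed study order ('+', '-', or '?' when the study contributed no usable
estimate) and a significance class using fixed cut-offs: p < 1e-7 genome-wide
significant, 1e-7 <= p < 1e-5 suggestive.  Cochran's Q and I^2 are reported
as heterogeneity diagnostics but never used for filtering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

META_COLUMNS = ["snp", "chrom", "bp", "beta", "se", "z", "p",
                "direction", "class", "q", "i2"]

GENOME_WIDE_P = 1e-7
SUGGESTIVE_P = 1e-5

CLASS_GENOME_WIDE = "genome_wide"
CLASS_SUGGESTIVE = "suggestive"
CLASS_NONE = "none"


def fixed_effects_meta(estimates) -> tuple[float, float, float, float]:
    """Combine (beta, se) pairs: returns (beta_meta, se_meta, z, p).

    Estimates with missing beta/se or se <= 0 are skipped; with no usable
    estimate all four values are NaN.
    """
    usable = [(b, s) for b, s in estimates
              if np.isfinite(b) and np.isfinite(s) and s > 0]
    if not usable:
        return (np.nan, np.nan, np.nan, np.nan)
    b = np.asarray([u[0] for u in usable])
    w = 1.0 / np.asarray([u[1] for u in usable]) ** 2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return beta, se, z, max(p, np.finfo(float).tiny)


def heterogeneity(estimates) -> tuple[float, float]:
    """Cochran's Q and I^2 (%) across usable estimates."""
    usable = [(b, s) for b, s in estimates
              if np.isfinite(b) and np.isfinite(s) and s > 0]
    if len(usable) < 2:
        return (np.nan, np.nan)
    b = np.asarray([u[0] for u in usable])
    w = 1.0 / np.asarray([u[1] for u in usable]) ** 2
    beta = (w * b).sum() / w.sum()
    q = float((w * (b - beta) ** 2).sum())
    df = len(usable) - 1
    i2 = float(max(0.0, (q - df) / q) * 100.0) if q > 0 else 0.0
    return q, i2


def direction_string(betas) -> str:
    """'+'/'-' per study in order; '?' for a missing estimate; 0 counts '+'."""
    out = []
    for b in betas:
        if b is None or not np.isfinite(b):
            out.append("?")
        else:
            out.append("-" if b < 0 else "+")
    return "".join(out)


def classify_significance(p: float) -> str:
    if not np.isfinite(p) or not (0.0 < p <= 1.0):
        return CLASS_NONE
    if p < GENOME_WIDE_P:
        return CLASS_GENOME_WIDE
    if p < SUGGESTIVE_P:
        return CLASS_SUGGESTIVE
    return CLASS_NONE


def run_meta(assoc_tables: list[pd.DataFrame], study_order: list[str] | None = None
             ) -> pd.DataFrame:
    """Meta-analyse per-study association tables over their shared markers.

    ``study_order`` fixes the direction-string column order (defaults to each
    table's stratum label in the order given).  Markers are matched by snp id;
    the intersection across studies is analysed.  A study with a degenerate
    fit at a marker contributes '?' to the direction string and no weight.
    """
    if not assoc_tables:
        raise ValueError("no association tables given")
    if study_order is None:
        study_order = [str(t["stratum"].iloc[0]) for t in assoc_tables]
    if len(study_order) != len(assoc_tables):
        raise ValueError("study_order length must match the number of tables")

    shared = set(assoc_tables[0]["snp"])
    for t in assoc_tables[1:]:
        shared &= set(t["snp"])
    if not shared:
        raise ValueError("no markers shared across studies")

    keep = assoc_tables[0]["snp"].isin(shared)
    base = assoc_tables[0].loc[keep, ["snp", "chrom", "bp"]].reset_index(drop=True)
    snps = base["snp"]
    B = np.stack([t.set_index("snp")["beta"].reindex(snps).to_numpy(dtype=float)
                  for t in assoc_tables])
    S = np.stack([t.set_index("snp")["se"].reindex(snps).to_numpy(dtype=float)
                  for t in assoc_tables])

    usable = np.isfinite(B) & np.isfinite(S) & (S > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(usable, 1.0 / S**2, 0.0)
        wsum = W.sum(axis=0)
        beta = (W * np.where(usable, B, 0.0)).sum(axis=0) / wsum
        se = wsum**-0.5
        z = beta / se
        q = (W * (np.where(usable, B, 0.0) - beta) ** 2).sum(axis=0)
        df = usable.sum(axis=0) - 1
        i2 = np.where(q > 0, np.maximum(0.0, (q - df) / np.maximum(q, 1e-300)) * 100.0, 0.0)
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)
    none = wsum == 0
    for arr in (beta, se, z):
        arr[none] = np.nan
    p[none] = np.nan
    q = np.where(df >= 1, q, np.nan)
    i2 = np.where(df >= 1, i2, np.nan)

    chars = np.where(usable, np.where(B < 0, "-", "+"), "?")
    directions = ["".join(col) for col in chars.T]
    classes = [classify_significance(v) for v in p]
    return pd.DataFrame({
        "snp": snps.to_numpy(), "chrom": base["chrom"].to_numpy(),
        "bp": base["bp"].to_numpy(), "beta": beta, "se": se, "z": z, "p": p,
        "direction": directions, "class": classes, "q": q, "i2": i2,
    })[META_COLUMNS]


def top_hits(meta: pd.DataFrame, n: int = 5) -> pd.DataFrame:
    """Sorted top-hit report shaped like a results table: snp, chrom, bp, p,
    direction, class, and an empty flanking-gene field."""
    out = meta.sort_values("p", kind="mergesort").head(n).copy()
    out["gene_list"] = ""
    return out[["snp", "chrom", "bp", "p", "direction", "class", "gene_list"]]
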