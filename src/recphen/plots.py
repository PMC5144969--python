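"""Manhattan and QQ summary plots for association/meta results."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .association import qq_lambda
from .meta_analysis import GENOME_WIDE_P, SUGGESTIVE_P


def manhattan_plot(results: pd.DataFrame, out_path: str, title: str = "") -> str:
    """Manhattan plot: -log10 p by genomic position, chromosomes alternately
    shaded, dotted lines at the genome-wide and suggestive cut-offs."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    offset = 0
    ticks, labels = [], []
    chroms = list(dict.fromkeys(results["chrom"].astype(str)))
    for i, chrom in enumerate(chroms):
        sub = results[results["chrom"].astype(str) == chrom]
        x = sub["bp"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p"].to_numpy()), s=4,
                   color="black" if i % 2 == 0 else "gray", rasterized=True)
        ticks.append(offset + sub["bp"].max() / 2)
        labels.append(chrom)
        offset += sub["bp"].max()
    ax.axhline(-np.log10(GENOME_WIDE_P), ls=":", color="black", lw=0.8)
    ax.axhline(-np.log10(SUGGESTIVE_P), ls=":", color="gray", lw=0.8)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def qq_plot(pvalues, out_path: str, title: str = "") -> str:
    """Observed vs expected -log10 p with the identity line and lambda_GC."""
    table, lam = qq_lambda(pvalues)
    fig, ax = plt.subplots(figsize=(3.6, 3.6))
    ax.scatter(table["expected_neglog10"], table["observed_neglog10"],
               s=5, color="black", rasterized=True)
    lim = max(table["expected_neglog10"].max(), table["observed_neglog10"].max())
    ax.plot([0, lim], [0, lim], color="red", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}\,p$")
    ax.set_ylabel(r"observed $-\log_{10}\,p$")
    ax.set_title(title or f"$\\lambda_{{GC}}$ = {lam:.3f}")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
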