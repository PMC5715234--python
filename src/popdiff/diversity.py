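"""Per-locus and panel-level diversity statistics.

For a biallelic locus with alt-allele frequency p and q = 1 - p:

* gene diversity (expected heterozygosity)  He  = 1 - (p^2 + q^2)
* polymorphism information content          PIC = 1 - (p^2 + q^2) - 2 p^2 q^2
  (the Botstein measure reduced to two alleles)
* observed heterozygosity                   Ho  = #hets / n_called
* minor allele frequency                    MAF = min(p, q)

He peaks at 0.5 and PIC at 0.375, both attained at p = 0.5; a monomorphic
locus scores 0 on all three.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypePanel, allele_frequencies

STAT_COLUMNS = ["maf", "gene_diversity", "het_obs", "pic", "call_rate"]


def gene_diversity(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2)


def pic(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2


def locus_stats(panel: GenotypePanel, subset=None) -> pd.DataFrame:
    """Compute MAF, gene diversity, observed heterozygosity, PIC and call
    rate for every locus over the given sample subset.

    Loci with no called genotype in the subset are flagged ``defined=False``
    and carry NaN statistics (they are excluded from summaries, never
    zero-filled).
    """
    idx = panel.sample_indices(subset)
    freqs = allele_frequencies(panel, subset)
    p = freqs["alt_freq"].to_numpy()
    n_called = freqs["n_called"].to_numpy()

    dose = panel.dosage[idx, :]
    n_het = (dose == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_obs = np.where(n_called > 0, n_het / n_called, np.nan)

    out = pd.DataFrame(
        {
            "maf": freqs["minor_freq"],
            "gene_diversity": gene_diversity(p),
            "het_obs": het_obs,
            "pic": pic(p),
            "call_rate": n_called / len(idx),
            "defined": freqs["defined"],
        },
        index=freqs.index,
    )
    out.loc[~out["defined"], STAT_COLUMNS[:4]] = np.nan
    return out


def panel_summary(stats_by_group: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean and (min, max) of each statistic per group.

    ``stats_by_group`` maps a group label (e.g. "CN", "US", "CN+US") to the
    output of :func:`locus_stats` computed on that group's samples; the
    combined group must be recomputed from pooled samples, not averaged.
    Undefined loci are dropped before summarising.
    """
    rows = []
    for group, stats in stats_by_group.items():
        usable = stats[stats["defined"]] if "defined" in stats else stats
        if usable.empty:
            raise ValueError(f"group {group!r} has no defined loci")
        for col in STAT_COLUMNS:
            vals = usable[col].dropna()
            rows.append(
                {
                    "group": group,
                    "statistic": col,
                    "mean": vals.mean(),
                    "min": vals.min(),
                    "max": vals.max(),
                    "n_loci": len(vals),
                }
            )
    return pd.DataFrame(rows)


def statistic_histogram(stats: pd.DataFrame, column: str, bins: int = 20) -> pd.DataFrame:
    """Histogram bin edges and counts for distribution plots of one statistic."""
    vals = stats[column].dropna().to_numpy()
    counts, edges = np.histogram(vals, bins=bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
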