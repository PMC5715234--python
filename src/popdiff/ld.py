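"""Pairwise linkage disequilibrium and decay-distance estimation.

r^2 is the squared Pearson correlation between dosage vectors over
pairwise-complete samples (composite/genotypic LD, which is valid for
unphased genotypes and coincides with gametic r^2 for fully inbred lines).
Pairs are formed within chromosomes only.  Significance uses the standard
allelic-association approximation chi^2 = n * r^2 on 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypePanel, allele_frequencies


@dataclass
class DecayProfile:
    """Binned mean r^2 against physical distance and the decay distance."""

    bin_edges: np.ndarray  # bp, len = n_bins + 1
    mean_r2: np.ndarray  # NaN for empty bins
    n_pairs: np.ndarray
    threshold: float
    decay_distance_bp: float | None  # None = never decays within observed range

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left_bp": self.bin_edges[:-1],
                "bin_right_bp": self.bin_edges[1:],
                "mean_r2": self.mean_r2,
                "n_pairs": self.n_pairs,
            }
        )


def pairwise_r2(
    panel: GenotypePanel,
    subset=None,
    max_distance: int | None = None,
    maf_min: float = 0.0,
) -> pd.DataFrame:
    """All within-chromosome locus pairs with distance, r^2 and sample count.

    Monomorphic loci (or loci below ``maf_min``) in the subset are excluded,
    as pairs involving them have undefined correlation.  Missing calls are
    handled by pairwise-complete deletion.  Returns a DataFrame with columns
    ``locus_i, locus_j, chrom, distance_bp, r2, n``.
    """
    idx = panel.sample_indices(subset)
    freqs = allele_frequencies(panel, subset)
    maf = freqs["minor_freq"].to_numpy()
    usable = freqs["defined"].to_numpy() & (maf > 0) & (maf >= maf_min)

    dose = panel.dosage[idx, :].astype(float)
    called = dose != MISSING
    X = np.where(called, dose, 0.0)
    M = called.astype(float)

    chroms = np.array([loc.chrom for loc in panel.loci])
    pos = np.array([loc.pos for loc in panel.loci])
    ids = np.array(panel.locus_ids())

    records = []
    for chrom in dict.fromkeys(chroms):
        sel = np.flatnonzero((chroms == chrom) & usable)
        if len(sel) < 2:
            continue
        Xc, Mc = X[:, sel], M[:, sel]
        # pairwise-complete moments via masked matrix products
        n = Mc.T @ Mc
        sx = Xc.T @ Mc  # sum of x_i over samples called at both i and j
        sxx = (Xc**2).T @ Mc
        sxy = Xc.T @ Xc
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = n * sxy - sx * sx.T
            var_i = n * sxx - sx**2
            r2 = cov**2 / (var_i * var_i.T)
        d = np.abs(pos[sel][:, None] - pos[sel][None, :])
        iu, ju = np.triu_indices(len(sel), k=1)
        keep = np.isfinite(r2[iu, ju]) & (n[iu, ju] >= 2)
        if max_distance is not None:
            keep &= d[iu, ju] <= max_distance
        iu, ju = iu[keep], ju[keep]
        records.append(
            pd.DataFrame(
                {
                    "locus_i": ids[sel][iu],
                    "locus_j": ids[sel][ju],
                    "chrom": chrom,
                    "distance_bp": d[iu, ju].astype(int),
                    "r2": np.clip(r2[iu, ju], 0.0, 1.0),
                    "n": n[iu, ju].astype(int),
                }
            )
        )
    if not records:
        raise ValueError("no usable within-chromosome locus pairs after filtering")
    return pd.concat(records, ignore_index=True)


def r2_significance(r2, n) -> np.ndarray:
    """Two-sided P for r^2 via chi^2 = n * r^2 on 1 df; undefined for n < 3."""
    r2 = np.atleast_1d(np.asarray(r2, dtype=float))
    n = np.atleast_1d(np.asarray(n, dtype=float))
    p = stats.chi2.sf(n * r2, df=1)
    return np.where(n >= 3, p, np.nan)


def significant_fraction(pairs: pd.DataFrame, alpha: float = 0.01) -> float:
    """Fraction of pairs whose r^2 is significant at the given alpha."""
    p = r2_significance(pairs["r2"], pairs["n"])
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no pairs with defined significance")
    return float((p < alpha).mean())


def ld_decay(
    pairs: pd.DataFrame, threshold: float = 0.1, bin_width: int = 500_000
) -> DecayProfile:
    """Bin mean r^2 by distance; the decay distance is the midpoint of the
    first bin below ``threshold`` from which the binned mean never rises back
    above it (a bin-resolution quantity)."""
    if pairs.empty:
        raise ValueError("no LD pairs supplied")
    d = pairs["distance_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    n_bins = int(np.ceil((d.max() + 1) / bin_width)) or 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width
    which = np.minimum((d // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    decay = None
    occupied = np.flatnonzero(counts > 0)
    below = means[occupied] < threshold
    # first occupied bin after which every occupied bin stays below threshold
    for k in range(len(occupied)):
        if below[k:].all():
            b = occupied[k]
            decay = float((edges[b] + edges[b + 1]) / 2.0)
            break
    return DecayProfile(edges, means, counts, threshold, decay)
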