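"""Selection-signal statistics for a two-gene-pool panel.

Three complementary statistics are computed per locus:

1. An allele-frequency-difference t statistic.  With subpopulation alt
   frequencies f1, f2 from n1 and n2 diploid individuals and the pooled
   frequency fexp = (f1 n1 + f2 n2)/(n1 + n2),

       t = (f1 - f2) / sqrt[ (1/(2 n1) + 1/(2 n2)) * fexp (1 - fexp) ]

   referred by default to Student's t with 2 n1 + 2 n2 - 2 df (allele
   counts minus two); a normal reference is available via ``df=None``.
   Tail probabilities are evaluated in log space so that -log10 P well
   beyond 300 stays finite and accurate.

2. Population-specific alleles: an allele with frequency exactly zero in
   one subpopulation, non-zero in the other, whose frequency difference is
   significant at ``alpha`` (default 0.001) under the same t test.  Both
   allele orientations (alt absent, or ref absent i.e. alt fixed) are
   checked.

3. EigenGWAS: regress the leading eigenvector of the standardized genetic
   relationship matrix on each locus's dosage; the per-locus chi-square is
   deflated by the genomic-control factor lambda_GC = median(chi2)/0.4549
   before P-values (PGC) are taken from a 1-df chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypePanel, allele_frequencies

_LN10 = np.log(10.0)
_CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


# ---------------------------------------------------------------------------
# allele-frequency difference t statistic
# ---------------------------------------------------------------------------

def allele_diff_test(f1, f2, n1, n2, df: str | None = "allele_counts") -> pd.DataFrame:
    """Vectorised t test for a subpopulation allele-frequency difference.

    Parameters are broadcastable arrays; ``n1``/``n2`` are diploid sample
    counts.  ``df="allele_counts"`` uses Student's t with 2n1 + 2n2 - 2
    degrees of freedom; ``df=None`` uses the standard normal.  Returns
    columns f1, f2, fexp, diff, abs_diff, t, neglog10_p, p_value (p_value
    underflows to 0.0 in the extreme tail; neglog10_p never does).
    """
    f1 = np.atleast_1d(np.asarray(f1, dtype=float))
    f2 = np.atleast_1d(np.asarray(f2, dtype=float))
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), f1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), f2.shape)
    if ((f1 < 0) | (f1 > 1) | (f2 < 0) | (f2 > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    fexp = (f1 * n1 + f2 * n2) / (n1 + n2)
    diff = f1 - f2
    var = (1.0 / (2.0 * n1) + 1.0 / (2.0 * n2)) * fexp * (1.0 - fexp)
    degenerate = var <= 0
    if (degenerate & (diff != 0)).any():
        raise AssertionError("fexp in {0,1} with f1 != f2: inconsistent inputs")
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(degenerate, 0.0, diff / np.sqrt(np.where(degenerate, 1.0, var)))
    if df == "allele_counts":
        dof = 2.0 * n1 + 2.0 * n2 - 2.0
        log_sf = stats.t.logsf(np.abs(t), dof)
    elif df is None:
        log_sf = stats.norm.logsf(np.abs(t))
    else:
        raise ValueError("df must be 'allele_counts' or None")
    log_p = np.log(2.0) + log_sf  # two-sided
    neglog10 = np.where(t == 0, 0.0, -log_p / _LN10)
    return pd.DataFrame(
        {
            "f1": f1,
            "f2": f2,
            "fexp": fexp,
            "diff": diff,
            "abs_diff": np.abs(diff),
            "t": t,
            "neglog10_p": neglog10,
            "p_value": np.where(t == 0, 1.0, np.exp(np.minimum(log_p, 0.0))),
        }
    )


def allele_diff_scan(
    panel: GenotypePanel, group1: str, group2: str, df: str | None = "allele_counts"
) -> pd.DataFrame:
    """Per-locus allele-frequency t test between two population labels."""
    fa = allele_frequencies(panel, group1)
    fb = allele_frequencies(panel, group2)
    ok = fa["defined"] & fb["defined"]
    res = allele_diff_test(
        fa["alt_freq"].where(ok, 0.0).to_numpy(),
        fb["alt_freq"].where(ok, 0.0).to_numpy(),
        np.maximum(fa["n_called"].to_numpy(), 1),
        np.maximum(fb["n_called"].to_numpy(), 1),
        df=df,
    )
    res.index = fa.index
    res["defined"] = ok
    res.loc[~ok, ["f1", "f2", "fexp", "diff", "abs_diff", "t", "neglog10_p", "p_value"]] = np.nan
    return res


def population_specific_alleles(
    panel: GenotypePanel, group1: str, group2: str, alpha: float = 0.001
) -> pd.DataFrame:
    """Loci carrying an allele private to one subpopulation.

    A locus is flagged for a group when one allele is absent (frequency
    exactly 0) in the other group, present in the flagged group, and the
    frequency difference passes the t test at ``alpha``.  Returns the
    flagged loci with columns chrom, pos, allele, carrier_group,
    carrier_freq, p_value.
    """
    scan = allele_diff_scan(panel, group1, group2)
    loci = {loc.id: loc for loc in panel.loci}
    rows = []
    for locus_id, r in scan[scan["defined"]].iterrows():
        if r["p_value"] >= alpha:
            continue
        loc = loci[locus_id]
        for f1a, f2a, allele in ((r["f1"], r["f2"], loc.alt_allele),
                                 (1 - r["f1"], 1 - r["f2"], loc.ref_allele)):
            if f1a > 0 and f2a == 0:
                carrier, freq = group1, f1a
            elif f2a > 0 and f1a == 0:
                carrier, freq = group2, f2a
            else:
                continue
            rows.append(
                {
                    "locus": locus_id,
                    "chrom": loc.chrom,
                    "pos": loc.pos,
                    "allele": allele,
                    "carrier_group": carrier,
                    "carrier_freq": freq,
                    "p_value": r["p_value"],
                    "neglog10_p": r["neglog10_p"],
                }
            )
    return pd.DataFrame(
        rows, columns=["locus", "chrom", "pos", "allele", "carrier_group",
                       "carrier_freq", "p_value", "neglog10_p"]
    )


# ---------------------------------------------------------------------------
# EigenGWAS
# ---------------------------------------------------------------------------

@dataclass
class EigenGwasResult:
    focal_k: int
    eigenvalues: np.ndarray  # top-k eigenvalues of the GRM
    eigenvectors: np.ndarray  # samples x k
    sample_ids: list[str]
    lambda_gc: float
    table: pd.DataFrame  # per locus: slope, chi2, chi2_gc, neglog10_pgc

    def to_frame(self) -> pd.DataFrame:
        return self.table


def grm(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Standardized genetic relationship matrix Z Z^T / m.

    z_il = (dosage_il - 2 p_l) / sqrt(2 p_l (1 - p_l)); missing dosages are
    mean-imputed, monomorphic loci excluded.  Returns (K, polymorphic_mask).
    """
    dose = panel.dosage.astype(float)
    dose[dose == MISSING] = np.nan
    mean = np.nanmean(dose, axis=0)
    inds = np.where(np.isnan(dose))
    dose[inds] = np.take(mean, inds[1])
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    Z = (dose[:, poly] - 2.0 * p[poly]) / np.sqrt(2.0 * p[poly] * (1.0 - p[poly]))
    return Z @ Z.T / poly.sum(), poly


def eigengwas(panel: GenotypePanel, k_top: int = 10, focal_k: int = 1) -> EigenGwasResult:
    """Three-step eigenvector association scan.

    (i) build the GRM; (ii) take its top ``k_top`` eigenpairs; (iii) regress
    the focal eigenvector on each locus dosage; chi2 = (slope/se)^2, deflated
    by lambda_GC before 1-df P-values are computed in log space.
    """
    if panel.n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not 1 <= focal_k <= k_top:
        raise ValueError("focal_k must lie in [1, k_top]")
    K, poly = grm(panel)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic loci")
    n = K.shape[0]
    k_top = min(k_top, n - 1)
    evals, evecs = np.linalg.eigh(K)
    order = np.argsort(evals)[::-1][:k_top]
    evals, evecs = evals[order], evecs[:, order]
    for k in range(k_top):  # deterministic signs
        j = np.argmax(np.abs(evecs[:, k]))
        if evecs[j, k] < 0:
            evecs[:, k] *= -1.0

    y = evecs[:, focal_k - 1]
    yc = y - y.mean()
    syy = (yc**2).sum()

    dose = panel.dosage.astype(float)
    dose[dose == MISSING] = np.nan
    mean = np.nanmean(dose, axis=0)
    inds = np.where(np.isnan(dose))
    dose[inds] = np.take(mean, inds[1])
    X = dose[:, poly] - mean[poly]

    sxx = (X**2).sum(axis=0)
    sxy = X.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        rss = syy - slope * sxy
        se2 = rss / (n - 2) / sxx
        chi2 = slope**2 / se2
    lam = float(np.median(chi2) / _CHI2_MEDIAN_1DF)
    chi2_gc = chi2 / lam
    log_p = stats.chi2.logsf(chi2_gc, df=1)
    table = pd.DataFrame(
        {
            "chrom": np.array([loc.chrom for loc in panel.loci])[poly],
            "pos": np.array([loc.pos for loc in panel.loci])[poly],
            "slope": slope,
            "chi2": chi2,
            "chi2_gc": chi2_gc,
            "p_gc": np.exp(np.minimum(log_p, 0.0)),
            "neglog10_pgc": -log_p / _LN10,
        },
        index=pd.Index(np.array(panel.locus_ids())[poly], name="locus"),
    )
    return EigenGwasResult(
        focal_k=focal_k,
        eigenvalues=evals,
        eigenvectors=evecs,
        sample_ids=list(panel.samples),
        lambda_gc=lam,
        table=table,
    )


# ---------------------------------------------------------------------------
# candidate ranking and annotation overlap
# ---------------------------------------------------------------------------

def rank_candidates(
    fst_table: pd.DataFrame,
    diff_table: pd.DataFrame,
    eigen_table: pd.DataFrame,
    top_n: int = 10,
) -> pd.DataFrame:
    """Combine the three per-locus statistics into one ranked candidate list.

    Each statistic contributes a descending rank (1 = strongest signal:
    highest theta, highest |t| -log10 P, highest EigenGWAS -log10 PGC); a
    locus's combined key is the best (minimum) of its three ranks, with ties
    broken by (chrom, pos).  Only loci present in all three tables are
    ranked.
    """
    common = fst_table.index.intersection(diff_table.index).intersection(eigen_table.index)
    if common.empty:
        raise ValueError("no loci shared by the three statistics")
    df = pd.DataFrame(index=common)
    df["chrom"] = fst_table.loc[common, "chrom"]
    df["pos"] = fst_table.loc[common, "pos"]
    df["theta"] = fst_table.loc[common, "theta"]
    df["abs_diff"] = diff_table.loc[common, "abs_diff"]
    df["neglog10_p_t"] = diff_table.loc[common, "neglog10_p"]
    df["neglog10_pgc"] = eigen_table.loc[common, "neglog10_pgc"]
    df["fst_rank"] = df["theta"].rank(ascending=False, method="min")
    df["t_rank"] = df["neglog10_p_t"].rank(ascending=False, method="min")
    df["eigengwas_rank"] = df["neglog10_pgc"].rank(ascending=False, method="min")
    df["combined_rank"] = df[["fst_rank", "t_rank", "eigengwas_rank"]].min(axis=1)
    df = df.sort_values(["combined_rank", "chrom", "pos"], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["consistent"] = (
        df[["fst_rank", "t_rank", "eigengwas_rank"]].max(axis=1) <= max(3 * top_n, 30)
    )
    return df.head(top_n)


def read_intervals(path) -> pd.DataFrame:
    """Read a BED-like TSV (chrom, start, end, label), skipping malformed
    records (end <= start) with a warning."""
    import warnings

    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"],
                     dtype={"chrom": str, "label": str})
    bad = df["end"] <= df["start"]
    if bad.any():
        warnings.warn(f"skipping {int(bad.sum())} malformed interval(s) with end <= start")
    return df[~bad].reset_index(drop=True)


def interval_overlap(candidates: pd.DataFrame, intervals: pd.DataFrame) -> pd.DataFrame:
    """Attach every half-open [start, end) interval containing each
    candidate's position; the ``annotations`` column is a semicolon-joined
    label list (empty string when none overlap)."""
    out = candidates.copy()
    labels = []
    for _, row in out.iterrows():
        hit = intervals[
            (intervals["chrom"].astype(str) == str(row["chrom"]))
            & (intervals["start"] <= row["pos"])
            & (row["pos"] < intervals["end"])
        ]
        labels.append(";".join(hit["label"].astype(str)))
    out["annotations"] = labels
    return out
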