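"""Genetic distances, marker-based kinship and neighbor-joining trees.

Rogers distance treats each individual as an allele-frequency vector per
locus (dosage/2 for a diploid); for biallelic loci the per-locus term
sqrt(0.5 * sum_a (p_ia - p_ja)^2) reduces to |x_i - x_j| with x = dosage/2,
and the distance is its average over pairwise-complete loci.  The
allele-sharing distance 1 - shared/(2L) coincides with it for biallelic
SNPs; both method tags are kept because inputs differ in provenance.

The kinship coefficient follows the marker-based estimator of Loiselle:

    K_ij = sum_l sum_a [ (p_ila - p_la)(p_jla - p_la) + p_la(1-p_la)/(n_l - 1) ]
           / sum_l sum_a p_la(1-p_la)

with reference frequencies p_la taken from the full panel and n_l the number
of alleles called at locus l.  Negative pair values are truncated to zero
after summation across loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class KinshipMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, >= 0 after truncation

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def distance_matrix(
    panel: GenotypePanel, method: str = "rogers", strict: bool = False
) -> DistanceMatrix:
    """Pairwise Rogers or allele-sharing distances over pairwise-complete loci.

    A pair with zero shared called loci gets NaN (or raises in strict mode).
    """
    if method not in ("rogers", "allele_sharing"):
        raise ValueError(f"unknown method {method!r}")
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dose = panel.dosage.astype(float)
    called = dose != MISSING
    X = np.where(called, dose / 2.0, 0.0)
    M = called.astype(float)

    n = panel.n_samples
    D = np.zeros((n, n))
    # both methods reduce to mean |x_i - x_j| over loci called in both samples
    for i in range(n - 1):
        valid = M[i] * M[i + 1:]
        diff = np.abs(X[i] - X[i + 1:]) * valid
        counts = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(counts > 0, diff.sum(axis=1) / counts, np.nan)
        D[i, i + 1:] = row
        D[i + 1:, i] = row
    if strict and np.isnan(D).any():
        bad = np.argwhere(np.isnan(np.triu(D, 1)))
        raise ValueError(f"sample pair with zero shared called loci: index {tuple(bad[0])}")
    return DistanceMatrix(list(panel.samples), D, method)


def loiselle_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Marker-based kinship with small-sample correction and zero truncation.

    For biallelic loci the two-allele sums share a factor of 2 that cancels
    in the ratio, so the computation uses the alt allele only.  Each pair's
    numerator and denominator run over the loci called in both samples;
    reference frequencies and allele counts n_l always come from the full
    panel.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    dose = panel.dosage.astype(float)
    called = dose != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, dose, 0.0).sum(axis=0) / (2.0 * n_called)
    pq = p * (1.0 - p)
    if not (np.nan_to_num(pq) > 0).any():
        raise ValueError("all loci monomorphic: kinship denominator is zero")
    n_alleles = 2.0 * n_called  # n_l in the estimator
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n_alleles > 1, pq / (n_alleles - 1.0), 0.0)

    usable = (n_called > 0) & np.isfinite(pq)
    X = np.where(called, dose / 2.0, 0.0)
    Ac = np.where(called & usable, X - p, 0.0)  # zero-filled deviations
    Mc = (called & usable).astype(float)

    num = Ac @ Ac.T + Mc @ (np.diag(np.nan_to_num(corr))) @ Mc.T
    den = Mc @ np.diag(np.nan_to_num(pq)) @ Mc.T
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(den > 0, num / den, np.nan)
    K = np.maximum(K, 0.0)  # truncation applied per pair, after the locus sum
    return KinshipMatrix(list(panel.samples), K)


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Unrooted neighbor-joining tree (Saitou–Nei) as a newick string.

    Negative branch lengths produced by the agglomeration are clamped to
    zero with the length transferred to the adjacent branch.
    """
    import skbio

    vals = np.asarray(dist.values, dtype=float)
    if vals.shape[0] < 3:
        raise ValueError("need at least 3 samples for a tree")
    if not np.isfinite(vals).all():
        raise ValueError("distance matrix has undefined entries")
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix is not symmetric")
    dm = skbio.DistanceMatrix(vals, ids=list(dist.sample_ids))
    tree = skbio.tree.nj(dm, neg_as_zero=True)
    return str(tree).strip()


def distance_distribution(
    dist: DistanceMatrix,
    groups: dict[str, str],
    bins: int = 20,
    bin_range: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Within-/between-group pair distance summaries and histograms.

    Returns one row per pair set ("within:<g>" per group, "between", "all")
    with mean/min/max, the pair count, and histogram counts over fixed bins.
    A singleton group yields an empty within set (NaN summaries, count 0).
    """
    missing = [s for s in dist.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without group label: {missing[:5]}")
    labels = np.array([groups[s] for s in dist.sample_ids])
    iu, ju = np.triu_indices(len(dist.sample_ids), k=1)
    d = dist.values[iu, ju]
    edges = np.linspace(*bin_range, bins + 1)

    def _row(name: str, mask: np.ndarray) -> dict:
        vals = d[mask]
        counts = np.histogram(vals, bins=edges)[0] if vals.size else np.zeros(bins, int)
        return {
            "set": name,
            "n_pairs": int(vals.size),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "min": float(vals.min()) if vals.size else np.nan,
            "max": float(vals.max()) if vals.size else np.nan,
            **{f"bin_{k}": int(c) for k, c in enumerate(counts)},
        }

    rows = []
    for g in dict.fromkeys(labels):
        rows.append(_row(f"within:{g}", (labels[iu] == g) & (labels[ju] == g)))
    rows.append(_row("between", labels[iu] != labels[ju]))
    rows.append(_row("all", np.ones_like(iu, dtype=bool)))
    return pd.DataFrame(rows)
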