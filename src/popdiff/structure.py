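"""PCA of the dosage matrix, Evanno delta-K, and cluster/origin crosstabs.

Bayesian admixture inference itself is out of scope: its per-K
log-likelihood outputs are post-processed here (Evanno's second-difference
statistic), and cluster assignments are taken as given, e.g. from an
external run or from thresholding the leading PCA axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel


@dataclass
class PCAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes
    eigenvalues: np.ndarray  # non-increasing
    variance_explained: np.ndarray  # fractions, sum <= 1
    scaling: str

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{k + 1}" for k in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


@dataclass
class EvannoResult:
    k_values: np.ndarray
    mean_loglik: np.ndarray
    sd_loglik: np.ndarray
    delta_k: np.ndarray  # NaN at the boundary K's
    best_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "K": self.k_values,
                "mean_L": self.mean_loglik,
                "sd_L": self.sd_loglik,
                "delta_K": self.delta_k,
            }
        )


def _imputed_centered_dosage(panel: GenotypePanel, scaling: str) -> np.ndarray:
    dose = panel.dosage.astype(float)
    dose[dose == MISSING] = np.nan
    mean = np.nanmean(dose, axis=0)
    inds = np.where(np.isnan(dose))
    dose[inds] = np.take(mean, inds[1])
    centered = dose - mean
    p = mean / 2.0
    poly = (p > 0) & (p < 1)
    centered = centered[:, poly]
    if scaling == "patterson":
        centered = centered / np.sqrt(p[poly] * (1.0 - p[poly]))
    elif scaling != "center_only":
        raise ValueError(f"unknown scaling {scaling!r}")
    return centered


def pca(panel: GenotypePanel, n_axes: int = 10, scaling: str = "patterson") -> PCAResult:
    """Principal components of the (centered, optionally Patterson-scaled)
    dosage matrix.  Missing dosages are mean-imputed per locus and
    monomorphic loci dropped.  Axis signs are fixed by making each axis's
    largest-magnitude locus loading positive, so results are deterministic.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least 2 samples")
    Z = _imputed_centered_dosage(panel, scaling)
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 polymorphic loci")
    max_axes = min(Z.shape) - 1 if min(Z.shape) > 1 else 1
    if n_axes > max_axes:
        warnings.warn(f"requested {n_axes} axes but only {max_axes} available; truncating")
        n_axes = max_axes
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(n_axes):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    eigvals = s**2 / (Z.shape[0] - 1)
    coords = U[:, :n_axes] * s[:n_axes]
    return PCAResult(
        sample_ids=list(panel.samples),
        coordinates=coords,
        eigenvalues=eigvals[:n_axes],
        variance_explained=eigvals[:n_axes] / eigvals.sum(),
        scaling=scaling,
    )


def evanno_delta_k(loglik_table: pd.DataFrame, strict: bool = False) -> EvannoResult:
    """Evanno's delta-K from a replicates x K log-likelihood table.

    Columns are consecutive K values (ints or parseable strings), rows are
    independent replicates.  delta-K at an interior K is
    mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd_r L_r(K); it is undefined
    at the boundary K's and wherever sd = 0 (error in strict mode).
    """
    ks = np.array([int(c) for c in loglik_table.columns])
    order = np.argsort(ks)
    ks = ks[order]
    L = loglik_table.to_numpy(dtype=float)[:, order]
    if L.shape[0] < 2:
        raise ValueError("need >= 2 replicates per K")
    if len(ks) < 3 or not (np.diff(ks) == 1).all():
        raise ValueError("need >= 3 consecutive K values")
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    delta = np.full(len(ks), np.nan)
    for j in range(1, len(ks) - 1):
        second = L[:, j + 1] - 2.0 * L[:, j] + L[:, j - 1]
        if sd[j] == 0:
            if strict:
                raise ValueError(f"sd of L is zero at K={ks[j]}; delta-K undefined")
            continue
        delta[j] = np.abs(second).mean() / sd[j]
    if np.isnan(delta).all():
        raise ValueError("delta-K undefined at every interior K")
    best = int(ks[np.nanargmax(delta)])
    return EvannoResult(ks, mean, sd, delta, best)


def membership_crosstab(
    assignments: dict[str, str], origins: dict[str, str]
) -> tuple[pd.DataFrame, float]:
    """Cluster x origin contingency table and percent concordance.

    Concordance maps each cluster to its majority origin and reports the
    percentage of samples whose origin matches their cluster's majority.
    """
    if set(assignments) != set(origins):
        raise ValueError("assignment and origin maps cover different samples")
    samples = sorted(assignments)
    table = pd.crosstab(
        pd.Series({s: assignments[s] for s in samples}, name="cluster"),
        pd.Series({s: origins[s] for s in samples}, name="origin"),
    )
    concordant = table.max(axis=1).sum()
    return table, 100.0 * concordant / table.to_numpy().sum()
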