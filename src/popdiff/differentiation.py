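"""Weir–Cockerham FST, sliding-window outlier scan, and distance-based AMOVA.

Per-locus differentiation uses the Weir–Cockerham (1984) moment estimator:
with r populations, per-population sample sizes n_i, alt-allele frequencies
p_i and observed heterozygote fractions h_i,

    n_bar = mean n_i                     n_c = (r n_bar - sum n_i^2 / (r n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar)      s^2 = sum n_i (p_i - p_bar)^2 / ((r-1) n_bar)
    h_bar = sum n_i h_i / (r n_bar)

    a = (n_bar / n_c) [ s^2 - (p_bar(1-p_bar) - s^2 (r-1)/r - h_bar/4) / (n_bar - 1) ]
    b = (n_bar / (n_bar - 1)) [ p_bar(1-p_bar) - s^2 (r-1)/r - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

    theta = a / (a + b + c)

Multilocus and window estimates are ratio-of-sums, sum(a) / sum(a+b+c) —
never the mean of per-locus ratios.  Negative per-locus components are kept
in the sums; per-locus theta may legitimately be negative.

AMOVA partitions locus-count-normalised squared Euclidean dosage distances
into among- and within-population variance components; significance comes
from a seeded label-permutation test with add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel


@dataclass
class AmovaResult:
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    percent_within: float
    phi_st: float
    p_value: float | None
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among_populations", "within_populations"],
                "variance_component": [self.sigma2_among, self.sigma2_within],
                "percent_of_total": [self.percent_among, self.percent_within],
                "phi_st": [self.phi_st, np.nan],
                "p_value": [self.p_value, np.nan],
            }
        )


def _group_indices(panel: GenotypePanel, groups: list[str] | None) -> dict[str, np.ndarray]:
    if groups is None:
        groups = sorted({g for g in panel.population.values() if g != "unassigned"})
    out = {g: panel.sample_indices(g) for g in groups}
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    return out


def wc_fst(panel: GenotypePanel, groups: list[str] | None = None) -> pd.DataFrame:
    """Weir–Cockerham variance components and theta for every locus.

    Returns a DataFrame indexed by locus id with columns chrom, pos, a, b, c,
    theta, per-group frequencies/sizes, and ``defined`` (False where the
    locus is monomorphic across groups or any group has < 2 called
    individuals; such loci are excluded from aggregate sums).
    """
    gidx = _group_indices(panel, groups)
    r = len(gidx)
    L = panel.n_loci

    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for k, idx in enumerate(gidx.values()):
        dose = panel.dosage[idx, :].astype(float)
        called = dose != MISSING
        n[k] = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(called, dose, 0.0).sum(axis=0) / (2.0 * n[k])
            h[k] = (dose == 1).sum(axis=0) / n[k]

    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n.mean(axis=0)
        n_c = (r * n_bar - (n**2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
        )
        c = h_bar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)

    defined = (n >= 2).all(axis=0) & (p_bar > 0) & (p_bar < 1) & np.isfinite(denom)
    out = pd.DataFrame(
        {
            "chrom": [loc.chrom for loc in panel.loci],
            "pos": [loc.pos for loc in panel.loci],
            "a": a,
            "b": b,
            "c": c,
            "theta": theta,
            "defined": defined,
        },
        index=pd.Index(panel.locus_ids(), name="locus"),
    )
    for k, g in enumerate(gidx):
        out[f"freq_{g}"] = p[k]
        out[f"n_{g}"] = n[k].astype(int)
    out.loc[~defined, ["a", "b", "c", "theta"]] = np.nan
    return out


def wc_fst_locus(panel: GenotypePanel, groups: list[str] | None, locus_id: str) -> pd.Series:
    """Components and theta for a single locus (row of :func:`wc_fst`)."""
    table = wc_fst(panel, groups)
    if locus_id not in table.index:
        raise KeyError(f"locus {locus_id!r} not in panel")
    return table.loc[locus_id]


def multilocus_fst(fst_table: pd.DataFrame) -> float:
    """Ratio-of-sums multilocus theta over the defined loci."""
    ok = fst_table["defined"]
    if not ok.any():
        raise ValueError("no defined loci for multilocus theta")
    a = fst_table.loc[ok, "a"].sum()
    abc = fst_table.loc[ok, ["a", "b", "c"]].to_numpy().sum()
    return float(a / abc)


def sliding_window_fst(
    fst_table: pd.DataFrame, window: int = 100_000, step: int = 10_000
) -> pd.DataFrame:
    """Ratio-of-sums theta in sliding windows tiling each chromosome.

    Windows are half-open [s, s + window) with s = 1, 1 + step, ...; a locus
    belongs to every window containing its position.  Empty windows are
    omitted.  Returns columns chrom, start, end, n_loci, theta.
    """
    rows = []
    tab = fst_table[fst_table["defined"]]
    for chrom, sub in tab.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        comp = sub[["a", "b", "c"]].to_numpy()
        order = np.argsort(pos)
        pos, comp = pos[order], comp[order]
        last_start = int(pos.max())  # windows beyond the last locus are empty
        for s in range(1, last_start + 1, step):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, s + window, side="left")
            if hi == lo:
                continue
            block = comp[lo:hi]
            a_sum = block[:, 0].sum()
            abc_sum = block.sum()
            rows.append(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": s + window,
                    "n_loci": hi - lo,
                    "theta": a_sum / abc_sum if abc_sum != 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def outlier_windows(windows: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Flag windows at or above the (1 - top_fraction) empirical theta
    quantile; ties at the cutoff are all included."""
    if windows.empty:
        raise ValueError("no windows supplied")
    theta = windows["theta"].to_numpy(dtype=float)
    cutoff = np.nanquantile(theta, 1.0 - top_fraction)
    out = windows.copy()
    out["outlier"] = theta >= cutoff
    return out


def amova(
    panel: GenotypePanel,
    groups: list[str] | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level AMOVA on squared Euclidean dosage distances.

    Distances are locus-count normalised (mean squared dosage difference
    over pairwise-complete loci), so missing data does not bias pair scale.
    The permutation P-value is (1 + #{perm Phi >= observed}) / (B + 1).
    """
    gidx = _group_indices(panel, groups)
    order = np.concatenate(list(gidx.values()))
    sizes = np.array([len(v) for v in gidx.values()])
    N, g = len(order), len(gidx)
    if N <= g:
        raise ValueError("need more samples than groups")

    dose = panel.dosage[order, :].astype(float)
    called = dose != MISSING
    X = np.where(called, dose, 0.0)
    M = called.astype(float)
    # squared distance over shared loci, normalised by shared-locus count
    G = X @ X.T
    S = (X**2) @ M.T
    cnt = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        D2 = (S + S.T - 2.0 * G) / cnt
    if not np.isfinite(D2).all():
        raise ValueError("sample pair with zero shared called loci")

    labels = np.repeat(np.arange(g), sizes)

    ss_t = D2.sum() / (2.0 * N)

    def _ss(lbl: np.ndarray) -> tuple[float, float]:
        Z = np.zeros((N, g))
        Z[np.arange(N), lbl] = 1.0
        quad = np.einsum("ik,ij,jk->k", Z, D2, Z, optimize=True)
        ss_w = (quad / (2.0 * Z.sum(axis=0))).sum()
        return ss_t - ss_w, ss_w

    def _phi(lbl: np.ndarray) -> tuple[float, float, float]:
        ss_a, ss_w = _ss(lbl)
        ms_a = ss_a / (g - 1)
        sigma_w = ss_w / (N - g)
        n0 = (N - (sizes**2).sum() / N) / (g - 1)
        sigma_a = (ms_a - sigma_w) / n0
        total = sigma_a + sigma_w
        return sigma_a, sigma_w, sigma_a / total

    sigma_a, sigma_w, phi = _phi(labels)

    p_value = None
    if n_permutations >= 1:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            if _phi(perm)[2] >= phi:
                hits += 1
        p_value = (1.0 + hits) / (n_permutations + 1.0)

    pa = max(sigma_a, 0.0)
    pw = max(sigma_w, 0.0)
    return AmovaResult(
        sigma2_among=sigma_a,
        sigma2_within=sigma_w,
        percent_among=100.0 * pa / (pa + pw),
        percent_within=100.0 * pw / (pa + pw),
        phi_st=phi,
        p_value=p_value,
        n_permutations=max(n_permutations, 0),
    )
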