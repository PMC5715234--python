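"""Two-population SNP-panel simulator with planted divergence outliers.

The generator follows the Balding–Nichols model: each locus gets an
ancestral frequency p ~ Uniform(0.05, 0.95), and each population draws its
own frequency from Beta(p (1-F)/F, (1-p)(1-F)/F), whose mean is p and whose
variance is F p (1-p) — so the single parameter F is the expected FST
between the populations.  A small set of planted loci uses a much larger F
to mimic strongly diverged (selected) regions.  Individuals are
near-fully-inbred diploids: with probability equal to the inbreeding
coefficient a genotype is 2 x Bernoulli(p_pop), otherwise Binomial(2,
p_pop).  Admixed individuals draw every locus from the 50/50 mixture of the
two population frequencies.  Loci are placed uniformly on a set of
chromosomes and sorted by position.  No linkage disequilibrium between loci
is modelled.

Defaults mirror a two-country soybean cultivar panel: 277 + 300 accessions,
5,195 SNPs on 20 chromosomes, background F = 0.1933, inbreeding 0.95, 5%
admixed individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel, Locus, write_panel, write_population_map

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n1: int = 277
    n2: int = 300
    n_loci: int = 5195
    n_chrom: int = 20
    chrom_length_bp: int = 50_000_000
    background_F: float = 0.1933
    n_selected: int = 10
    selected_F: float = 0.8
    inbreeding: float = 0.95
    admixed_fraction: float = 0.05
    missing_rate: float = 0.0
    pop_labels: tuple[str, str] = ("CN", "US")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_F < 1):
            raise ValueError("background_F must lie in [0, 1)")
        if self.n_selected and self.selected_F <= self.background_F:
            raise ValueError("selected_F must exceed background_F")
        if self.n_selected >= self.n_loci:
            raise ValueError("n_selected must be < n_loci")
        for name in ("inbreeding", "admixed_fraction", "missing_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1) or (name == "missing_rate" and v == 1):
                raise ValueError(f"{name} out of range: {v}")


@dataclass
class SimTruth:
    loci: pd.DataFrame  # locus, chrom, pos, ancestral_freq, freq_pop1, freq_pop2, F, outlier
    samples: pd.DataFrame  # sample, population, ancestry_pop1

    n_selected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_selected = int(self.loci["outlier"].sum())


def _bn_freq(
    rng: np.random.Generator,
    p: np.ndarray,
    F: np.ndarray,
    side: np.ndarray | None = None,
) -> np.ndarray:
    """Population frequency draw; F = 0 loci keep the ancestral frequency.

    ``side`` (+1/-1 per locus, 0 = unconstrained) conditions the draw to the
    requested side of the ancestral frequency via rejection sampling.  It is
    used for planted outlier loci, which emulate divergent selection: the two
    populations are pushed toward opposite alleles, so their frequency gap is
    large instead of averaging out by same-direction drift.
    """
    out = p.copy()
    pos = F > 0
    a = p[pos] * (1.0 - F[pos]) / F[pos]
    b = (1.0 - p[pos]) * (1.0 - F[pos]) / F[pos]
    draw = rng.beta(a, b)
    if side is not None:
        want = side[pos]
        anchor = p[pos]
        bad = (want != 0) & (np.sign(draw - anchor) != want)
        while bad.any():
            draw[bad] = rng.beta(a[bad], b[bad])
            bad &= np.sign(draw - anchor) != want
    out[pos] = draw
    return out


def _genotypes(
    rng: np.random.Generator, freq: np.ndarray, n: int, inbreeding: float
) -> np.ndarray:
    """n individuals x loci dosages under partial selfing."""
    L = freq.shape[0]
    selfed = rng.random((n, L)) < inbreeding
    hom = 2 * rng.binomial(1, freq[None, :], size=(n, L))
    outx = rng.binomial(2, freq[None, :], size=(n, L))
    return np.where(selfed, hom, outx).astype(np.int8)


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Draw a two-population panel plus its generating truth tables.

    Fully reproducible from ``config.seed``; all randomness flows through a
    single numpy Generator.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_loci

    # locus placement: uniform over chromosomes, sorted positions
    chrom = rng.integers(1, config.n_chrom + 1, size=L)
    pos = rng.integers(1, config.chrom_length_bp + 1, size=L)
    order = np.lexsort((pos, chrom))
    chrom, pos = chrom[order], pos[order]
    # avoid duplicate coordinates on a chromosome (keeps locus ids unique)
    for c in range(1, config.n_chrom + 1):
        m = chrom == c
        pos[m] = np.sort(pos[m] + np.arange(m.sum()))

    anc = rng.uniform(0.05, 0.95, size=L)
    F = np.full(L, config.background_F)
    outlier = np.zeros(L, dtype=bool)
    if config.n_selected:
        sel = rng.choice(L, size=config.n_selected, replace=False)
        F[sel] = config.selected_F
        outlier[sel] = True
        # divergent selection acts on standing variation: planted loci start
        # at intermediate ancestral frequency so the two pools can be driven
        # toward opposite alleles (frequency gaps in the 0.7-0.9 range)
        anc[sel] = rng.uniform(0.25, 0.75, size=config.n_selected)
    side = np.zeros(L, dtype=int)
    side[outlier] = rng.choice([-1, 1], size=int(outlier.sum()))
    p1 = _bn_freq(rng, anc, F, side)
    p2 = _bn_freq(rng, anc, F, -side)

    n_total = config.n1 + config.n2
    pop_idx = np.repeat([0, 1], [config.n1, config.n2])
    admixed = rng.random(n_total) < config.admixed_fraction
    ancestry = np.where(pop_idx == 0, 1.0, 0.0)
    ancestry[admixed] = 0.5

    pmix = 0.5 * (p1 + p2)
    dosage = np.empty((n_total, L), dtype=np.int8)
    for i in range(n_total):
        freq = pmix if admixed[i] else (p1 if pop_idx[i] == 0 else p2)
        dosage[i] = _genotypes(rng, freq, 1, config.inbreeding)[0]

    ref = _BASES[rng.integers(0, 4, size=L)]
    alt = np.array([_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in ref])
    loci = [
        Locus(f"snp{c}_{p}", str(c), int(p), r, a)
        for c, p, r, a in zip(chrom, pos, ref, alt)
    ]
    samples = [f"{config.pop_labels[k]}_{i:04d}" for i, k in enumerate(pop_idx)]
    population = {s: config.pop_labels[k] for s, k in zip(samples, pop_idx)}
    panel = GenotypePanel(loci, samples, population, dosage)
    if config.missing_rate > 0:
        panel = inject_missingness(panel, config.missing_rate, seed=int(rng.integers(2**31)))

    truth = SimTruth(
        loci=pd.DataFrame(
            {
                "locus": [l.id for l in loci],
                "chrom": chrom.astype(str),
                "pos": pos,
                "ancestral_freq": anc,
                "freq_pop1": p1,
                "freq_pop2": p2,
                "F": F,
                "outlier": outlier,
            }
        ),
        samples=pd.DataFrame(
            {"sample": samples, "population": [population[s] for s in samples],
             "ancestry_pop1": ancestry}
        ),
    )
    return panel, truth


def inject_missingness(panel: GenotypePanel, rate: float, seed: int | None = None) -> GenotypePanel:
    """Set calls to MISSING independently at the given rate (new panel)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return panel
    rng = np.random.default_rng(seed)
    mask = rng.random(panel.dosage.shape) < rate
    dosage = panel.dosage.copy()
    dosage[mask] = MISSING
    return GenotypePanel(list(panel.loci), list(panel.samples), dict(panel.population), dosage)


def write_fixture(panel: GenotypePanel, truth: SimTruth, out_dir, config: SimConfig | None = None):
    """Write VCF + population map + truth tables (+ config) to a directory.

    Returns the mapping of artefact name to path; ``load_panel`` on the VCF
    round-trips the panel exactly.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "panel.vcf"),
        "populations": os.path.join(out_dir, "populations.tsv"),
        "truth_loci": os.path.join(out_dir, "truth_loci.tsv"),
        "truth_samples": os.path.join(out_dir, "truth_samples.tsv"),
    }
    write_panel(panel, paths["vcf"], format="vcf")
    write_population_map(panel, paths["populations"])
    truth.loci.to_csv(paths["truth_loci"], sep="\t", index=False)
    truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
    if config is not None:
        paths["config"] = os.path.join(out_dir, "sim_config.txt")
        with open(paths["config"], "w") as fh:
            for k, v in asdict(config).items():
                fh.write(f"{k}={v}\n")
    return paths
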