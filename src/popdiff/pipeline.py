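"""End-to-end orchestration: filter -> diversity -> LD -> relatedness ->
structure -> differentiation -> selection scan, with every stage's result
written as a TSV report into one output directory."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .diversity import locus_stats, panel_summary
from .differentiation import amova, multilocus_fst, outlier_windows, sliding_window_fst, wc_fst
from .io import GenotypePanel, filter_missingness, load_panel
from .ld import ld_decay, pairwise_r2, r2_significance, significant_fraction
from .relatedness import distance_distribution, distance_matrix, loiselle_kinship, neighbor_joining
from .selection import (
    allele_diff_scan,
    eigengwas,
    interval_overlap,
    population_specific_alleles,
    rank_candidates,
    read_intervals,
)
from .structure import membership_crosstab, pca

log = logging.getLogger("popdiff")


@dataclass
class RunConfig:
    """Thresholds and inputs for a full run; defaults are the standard
    settings for a two-gene-pool cultivar panel analysis."""

    genotype_path: str = ""
    genotype_format: str = "vcf"
    population_path: str | None = None
    annotation_path: str | None = None
    group1: str = "CN"
    group2: str = "US"
    max_missing: float = 0.20
    ld_alpha: float = 0.01
    ld_decay_threshold: float = 0.1
    ld_bin_width: int = 500_000
    ld_max_distance: int | None = 20_000_000
    fst_window: int = 100_000
    fst_step: int = 10_000
    top_fraction: float = 0.05
    t_significance: float = 1e-6
    specific_allele_alpha: float = 0.001
    top_n: int = 10
    amova_permutations: int = 1000
    seed: int = 0
    out_dir: str = "popdiff_out"
    extra: dict = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig, panel: GenotypePanel | None = None) -> dict:
    """Execute the full analysis; returns {artefact name: path or value}.

    ``panel`` may be passed directly (e.g. from the simulator); otherwise it
    is loaded from ``config.genotype_path``.
    """
    import os

    os.makedirs(config.out_dir, exist_ok=True)
    outputs: dict = {}

    def _stage(name):
        log.info("stage: %s", name)
        return name

    def _write(name: str, df: pd.DataFrame, index=True) -> str:
        path = os.path.join(config.out_dir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=index, float_format="%.6g")
        outputs[name] = path
        return path

    try:
        stage = _stage("load")
        if panel is None:
            panel = load_panel(config.genotype_path, config.genotype_format,
                               config.population_path)
        log.info("loaded %d samples x %d loci", panel.n_samples, panel.n_loci)

        stage = _stage("filter")
        panel, report = filter_missingness(panel, config.max_missing)
        outputs["filter_report"] = {
            "n_input_loci": report.n_input_loci,
            "n_removed_loci": report.n_removed_loci,
            "n_retained_loci": report.n_retained_loci,
            "percent_retained": round(report.percent_retained, 2),
        }
        log.info("retained %d/%d loci (%.2f%%)", report.n_retained_loci,
                 report.n_input_loci, report.percent_retained)

        g1, g2 = config.group1, config.group2
        stage = _stage("diversity")
        stats = {
            g1: locus_stats(panel, g1),
            g2: locus_stats(panel, g2),
            f"{g1}+{g2}": locus_stats(panel, None),
        }
        _write("diversity_summary", panel_summary(stats), index=False)
        for g, s in stats.items():
            _write(f"locus_stats_{g.replace('+', '_')}", s)

        stage = _stage("ld")
        ld_out = {}
        for g in (g1, g2):
            pairs = pairwise_r2(panel, g, max_distance=config.ld_max_distance)
            pairs["p_value"] = r2_significance(pairs["r2"], pairs["n"])
            profile = ld_decay(pairs, config.ld_decay_threshold, config.ld_bin_width)
            _write(f"ld_decay_{g}", profile.to_frame(), index=False)
            ld_out[g] = {
                "significant_fraction": significant_fraction(pairs, config.ld_alpha),
                "decay_distance_bp": profile.decay_distance_bp,
            }
        outputs["ld_summary"] = ld_out

        stage = _stage("relatedness")
        dist = distance_matrix(panel, "rogers")
        _write("rogers_distance", dist.to_frame())
        _write("distance_distribution",
               distance_distribution(dist, panel.population), index=False)
        kin = loiselle_kinship(panel)
        _write("kinship", kin.to_frame())
        tree_path = os.path.join(config.out_dir, "nj_tree.nwk")
        with open(tree_path, "w") as fh:
            fh.write(neighbor_joining(dist) + "\n")
        outputs["nj_tree"] = tree_path

        stage = _stage("structure")
        pcr = pca(panel, n_axes=min(10, panel.n_samples - 1))
        _write("pca_coordinates", pcr.to_frame())
        # surrogate cluster assignment: sign of axis 1
        assign = {s: f"cluster{int(c > 0) + 1}"
                  for s, c in zip(pcr.sample_ids, pcr.coordinates[:, 0])}
        table, concordance = membership_crosstab(assign, panel.population)
        _write("membership_crosstab", table)
        outputs["concordance_percent"] = round(concordance, 2)

        stage = _stage("differentiation")
        fst = wc_fst(panel, [g1, g2])
        _write("fst_per_locus", fst)
        outputs["multilocus_fst"] = multilocus_fst(fst)
        am = amova(panel, [g1, g2], config.amova_permutations, config.seed)
        _write("amova", am.to_frame(), index=False)
        outputs["amova_percent_among"] = am.percent_among
        windows = outlier_windows(
            sliding_window_fst(fst, config.fst_window, config.fst_step),
            config.top_fraction,
        )
        _write("fst_windows", windows, index=False)

        stage = _stage("selection_scan")
        diff = allele_diff_scan(panel, g1, g2)
        _write("allele_diff", diff)
        outputs["fraction_significant_t"] = float(
            (diff["p_value"] < config.t_significance).mean()
        )
        specific = population_specific_alleles(panel, g1, g2, config.specific_allele_alpha)
        _write("population_specific_alleles", specific, index=False)
        eg = eigengwas(panel)
        outputs["lambda_gc"] = eg.lambda_gc
        _write("eigengwas", eg.table)
        candidates = rank_candidates(fst, diff, eg.table, config.top_n)
        if config.annotation_path:
            candidates = interval_overlap(candidates, read_intervals(config.annotation_path))
        _write("candidates", candidates)

        stage = _stage("summary")
        run_log = {
            "popdiff_version": __version__,
            "numpy_version": np.__version__,
            "config": {k: v for k, v in asdict(config).items() if k != "extra"},
            "outputs": {k: v for k, v in outputs.items() if isinstance(v, str)},
            "metrics": {k: v for k, v in outputs.items() if not isinstance(v, str)},
        }
        with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
            json.dump(run_log, fh, indent=2, default=str)
        outputs["run_log"] = os.path.join(config.out_dir, "run_log.json")
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage
        raise StageError(stage, exc) from exc
    return outputs
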