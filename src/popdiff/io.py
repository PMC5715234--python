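"""Loading, validation, filtering and writing of diploid biallelic SNP panels.

The central container is :class:`GenotypePanel`: a samples x loci matrix of
alt-allele dosages (0, 1, 2) with ``MISSING = -1`` as the no-call sentinel,
plus locus coordinates and a sample -> population map.  Two on-disk formats
are supported: VCF v4.x (read through cyvcf2) and a tab-delimited genotype
table with rows = loci and columns = samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1
UNASSIGNED: str = "unassigned"

_VALID_BASES = set("ACGT")


class PanelParseError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: marker id, chromosome, 1-based bp position, alleles."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.id}: ref and alt alleles are identical")


@dataclass
class GenotypePanel:
    """Samples x loci alt-allele dosage matrix with metadata.

    ``dosage[i, l]`` is the alt-allele count of sample ``i`` at locus ``l``,
    one of {0, 1, 2, MISSING}.  ``population`` maps every sample id to a
    population label (possibly ``UNASSIGNED``).
    """

    loci: list[Locus]
    samples: list[str]
    population: dict[str, str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n_samples, n_loci = self.dosage.shape
        if n_samples != len(self.samples) or n_loci != len(self.loci):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids are not unique")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or MISSING")
        for s in self.samples:
            self.population.setdefault(s, UNASSIGNED)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples x loci mask, True where the call is missing."""
        return self.dosage == MISSING

    def locus_ids(self) -> list[str]:
        return [loc.id for loc in self.loci]

    def sample_indices(self, subset: str | list[str] | None = None) -> np.ndarray:
        """Resolve a population label, explicit sample list or None (all)."""
        if subset is None:
            return np.arange(self.n_samples)
        if isinstance(subset, str):
            labels = set(self.population.values())
            if subset not in labels:
                raise KeyError(f"unknown population label {subset!r}; have {sorted(labels)}")
            idx = [i for i, s in enumerate(self.samples) if self.population[s] == subset]
        else:
            pos = {s: i for i, s in enumerate(self.samples)}
            try:
                idx = [pos[s] for s in subset]
            except KeyError as exc:
                raise KeyError(f"sample {exc.args[0]!r} not in panel") from None
        if not idx:
            raise ValueError("subset resolves to zero samples")
        return np.asarray(idx)

    def take_loci(self, keep: np.ndarray) -> "GenotypePanel":
        """Subset to the loci selected by a boolean mask or integer index array."""
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return GenotypePanel(
            loci=[self.loci[i] for i in idx],
            samples=list(self.samples),
            population=dict(self.population),
            dosage=self.dosage[:, idx].copy(),
        )


@dataclass
class PanelFilterReport:
    """Book-keeping for a locus filter: input/removed/retained counts."""

    n_input_loci: int
    n_removed_loci: int
    n_retained_loci: int
    percent_retained: float
    missing_fraction: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        assert self.n_input_loci == self.n_removed_loci + self.n_retained_loci


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_population_map(populations) -> dict[str, str]:
    if populations is None:
        return {}
    if isinstance(populations, dict):
        return dict(populations)
    df = pd.read_csv(populations, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise PanelParseError("population map needs 2 tab-separated columns: sample, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _apply_population_map(samples: list[str], pop_map: dict[str, str]) -> dict[str, str]:
    population = {}
    unknown = []
    for s in samples:
        if s in pop_map:
            population[s] = pop_map[s]
        else:
            population[s] = UNASSIGNED
            unknown.append(s)
    if unknown and pop_map:
        warnings.warn(
            f"{len(unknown)} sample(s) absent from population map, labelled "
            f"{UNASSIGNED!r}: {unknown[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    return population


def load_panel(path, format: str = "vcf", populations=None) -> GenotypePanel:
    """Load a genotype panel from ``path``.

    Parameters
    ----------
    path : str
        Input file. ``format="vcf"`` expects a VCF v4.x with biallelic SNP
        records; ``format="genotype_table"`` expects a TSV with columns
        ``id, chrom, pos, ref, alt`` followed by one column per sample, with
        calls written as two-letter nucleotide pairs (``AA``, ``AT``, ``NN``
        for missing) or as dosage dialects ``0/1``, ``1|0``.
    populations : path, dict or None
        Sample -> population assignment (2-column TSV or inline mapping).
    """
    pop_map = _read_population_map(populations)
    if format == "vcf":
        return _load_vcf(path, pop_map)
    if format == "genotype_table":
        return _load_genotype_table(path, pop_map)
    raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'genotype_table'")


def _load_vcf(path, pop_map: dict[str, str]) -> GenotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    loci: list[Locus] = []
    rows = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise PanelParseError(
                f"non-biallelic-SNP record at {rec.CHROM}:{rec.POS} ({rec.REF}->{rec.ALT})"
            )
        loci.append(
            Locus(
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
            )
        )
        # gts012: 0/1/2 = alt dosage, 3 = no call; phase is irrelevant here
        gt = np.asarray(rec.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        rows.append(gt)
    if not loci:
        raise PanelParseError(f"no variant records found in {path}")
    dosage = np.stack(rows, axis=1)
    return GenotypePanel(loci, samples, _apply_population_map(samples, pop_map), dosage)


_META_COLS = ["id", "chrom", "pos", "ref", "alt"]


def _call_to_dosage(call: str, ref: str, alt: str, locus_id: str, line_no: int) -> int:
    call = call.strip()
    if call in ("", ".", "NN", "./.", ".|.", "NA"):
        return MISSING
    if "/" in call or "|" in call:
        sep = "/" if "/" in call else "|"
        a, b = call.split(sep)
        if a == "." or b == ".":
            return MISSING
        try:
            return int(int(a) > 0) + int(int(b) > 0)
        except ValueError:
            raise PanelParseError(f"line {line_no}: bad call {call!r} at locus {locus_id}")
    if len(call) == 2:
        dose = 0
        for base in call.upper():
            if base == alt:
                dose += 1
            elif base != ref:
                raise PanelParseError(
                    f"line {line_no}: allele {base!r} at locus {locus_id} is neither "
                    f"ref {ref!r} nor alt {alt!r}"
                )
        return dose
    raise PanelParseError(f"line {line_no}: unparseable call {call!r} at locus {locus_id}")


def _load_genotype_table(path, pop_map: dict[str, str]) -> GenotypePanel:
    import io as _io

    with open(path, "r", newline="") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh]
    kept = []
    for ln in lines:
        if not ln.strip():
            continue
        if ln.startswith("#"):
            # the header row may itself be commented; other '#' lines are skipped
            if not kept and ln.lstrip("#").startswith(_META_COLS[0] + "\t"):
                kept.append(ln.lstrip("#"))
            continue
        kept.append(ln)
    if not kept:
        raise PanelParseError(f"no content lines in {path}")
    df = pd.read_csv(_io.StringIO("\n".join(kept)), sep="\t", dtype=str)
    missing_meta = [c for c in _META_COLS if c not in df.columns]
    if missing_meta:
        raise PanelParseError(f"genotype table lacks required columns {missing_meta}")
    sample_cols = [c for c in df.columns if c not in _META_COLS]
    if not sample_cols:
        raise PanelParseError("genotype table has no sample columns")
    loci = [
        Locus(r.id, str(r.chrom), int(r.pos), r.ref, r.alt)
        for r in df[_META_COLS].itertuples(index=False)
    ]
    dosage = np.empty((len(sample_cols), len(loci)), dtype=np.int8)
    for l, (_, row) in enumerate(df.iterrows()):
        for i, s in enumerate(sample_cols):
            dosage[i, l] = _call_to_dosage(str(row[s]), row["ref"], row["alt"], row["id"], l + 2)
    return GenotypePanel(loci, sample_cols, _apply_population_map(sample_cols, pop_map), dosage)


def write_panel(panel: GenotypePanel, path, format: str = "vcf") -> None:
    """Write a panel back to disk (inverse of :func:`load_panel`)."""
    if format == "vcf":
        _write_vcf(panel, path)
    elif format == "genotype_table":
        _write_genotype_table(panel, path)
    else:
        raise ValueError(f"unknown format {format!r}")


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(panel: GenotypePanel, path) -> None:
    chroms = list(dict.fromkeys(loc.chrom for loc in panel.loci))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popdiff\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for l, loc in enumerate(panel.loci):
            calls = "\t".join(_GT_CODE[int(d)] for d in panel.dosage[:, l])
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref_allele}\t"
                     f"{loc.alt_allele}\t.\t.\t.\tGT\t{calls}\n")


def _write_genotype_table(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_META_COLS + list(panel.samples)) + "\n")
        for l, loc in enumerate(panel.loci):
            calls = []
            for d in panel.dosage[:, l]:
                if d == MISSING:
                    calls.append("NN")
                else:
                    calls.append(loc.ref_allele * (2 - d) + loc.alt_allele * d)
            fh.write("\t".join([loc.id, loc.chrom, str(loc.pos),
                                loc.ref_allele, loc.alt_allele] + calls) + "\n")


def write_population_map(panel: GenotypePanel, path) -> None:
    with open(path, "w") as fh:
        for s in panel.samples:
            fh.write(f"{s}\t{panel.population[s]}\n")


# ---------------------------------------------------------------------------
# filtering and allele frequencies
# ---------------------------------------------------------------------------

def filter_missingness(
    panel: GenotypePanel, max_missing: float = 0.20
) -> tuple[GenotypePanel, PanelFilterReport]:
    """Drop loci whose missing-call fraction is strictly above ``max_missing``.

    A locus missing in exactly ``max_missing`` of the samples is retained
    (strict ``>`` rule).
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must lie in [0, 1]")
    if panel.n_loci == 0 or panel.n_samples == 0:
        raise ValueError("cannot filter an empty panel")
    miss_frac = panel.missing_mask.mean(axis=0)
    keep = miss_frac <= max_missing
    n_in = panel.n_loci
    n_keep = int(keep.sum())
    report = PanelFilterReport(
        n_input_loci=n_in,
        n_removed_loci=n_in - n_keep,
        n_retained_loci=n_keep,
        percent_retained=100.0 * n_keep / n_in,
        missing_fraction=pd.Series(miss_frac, index=panel.locus_ids()),
    )
    filtered = GenotypePanel(
        loci=[loc for loc, k in zip(panel.loci, keep) if k],
        samples=list(panel.samples),
        population=dict(panel.population),
        dosage=panel.dosage[:, keep].copy(),
    )
    return filtered, report


def allele_frequencies(panel: GenotypePanel, subset=None) -> pd.DataFrame:
    """Per-locus alt/minor allele frequencies over non-missing calls.

    Returns a DataFrame indexed by locus id with columns ``alt_freq``,
    ``minor_freq``, ``n_called`` (diploid individuals with a call) and
    ``defined`` (False where every call in the subset is missing; the
    frequency columns are NaN there).
    """
    idx = panel.sample_indices(subset)
    dose = panel.dosage[idx, :].astype(float)
    called = dose != MISSING
    dose[~called] = np.nan
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        alt = np.nansum(dose, axis=0) / (2.0 * n_called)
    alt[n_called == 0] = np.nan
    minor = np.minimum(alt, 1.0 - alt)
    return pd.DataFrame(
        {
            "alt_freq": alt,
            "minor_freq": minor,
            "n_called": n_called.astype(int),
            "defined": n_called > 0,
        },
        index=pd.Index(panel.locus_ids(), name="locus"),
    )
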