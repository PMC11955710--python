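"""Pooled allele-count processing.

Turns per-replicate pooled read counts into the filtered, imputed
allele-frequency matrix used by every downstream stage: alternative allele
frequency (AAF) computation, technical-replicate merging, three-rule SNP
filtering, and per-locus mean imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of a pool count table (long form, one row per
#: population x locus x technical replicate).
COUNT_COLUMNS = [
    "population",
    "chrom",
    "pos",
    "ref",
    "alt",
    "replicate",
    "alt_count",
    "ref_count",
]

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt"]


def compute_aaf(alt_count, ref_count):
    """Alternative allele frequency Alt / (Alt + Ref).

    Zero total depth yields NaN (missing), distinguishing an absent
    observation from a frequency of zero.  Accepts scalars or arrays.
    """
    alt = np.asarray(alt_count, dtype=float)
    ref = np.asarray(ref_count, dtype=float)
    if np.any(alt < 0) or np.any(ref < 0):
        raise ValueError("allele counts must be non-negative")
    depth = alt + ref
    with np.errstate(invalid="ignore", divide="ignore"):
        aaf = np.where(depth > 0, alt / np.where(depth > 0, depth, 1.0), np.nan)
    if np.isscalar(alt_count) and np.isscalar(ref_count):
        return float(aaf) if depth > 0 else float("nan")
    return aaf


def validate_counts(counts: pd.DataFrame) -> None:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if (counts["alt_count"] < 0).any() or (counts["ref_count"] < 0).any():
        raise ValueError("allele counts must be non-negative")
    keys = counts[["population", "chrom", "pos", "replicate"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].to_dict()
        raise ValueError(f"duplicate (population, locus, replicate) key: {dup}")


def merge_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum alt and ref read counts over technical replicates.

    Returns one row per (population, locus) with ``replicate`` dropped.
    Merging counts and then computing AAF is equivalent to the
    count-weighted mean of replicate AAFs.
    """
    validate_counts(counts)
    grouped = (
        counts.groupby(["population", "chrom", "pos", "ref", "alt"], sort=False)[
            ["alt_count", "ref_count"]
        ]
        .sum()
        .reset_index()
    )
    return grouped


@dataclass
class FilterSpec:
    """Three-rule SNP retention policy for pooled allele frequencies.

    A locus is kept iff it is (a) non-missing in more than
    ``min_sample_coverage`` of populations, (b) strictly inside
    ``per_pop_af_bounds`` in at least ``min_pops_in_bounds`` populations, and
    (c) has a mean AAF over non-missing populations inside
    ``mean_af_bounds``.  Bounds are open intervals.
    """

    min_sample_coverage: float = 0.95
    per_pop_af_bounds: tuple[float, float] = (0.05, 0.95)
    min_pops_in_bounds: int = 10
    mean_af_bounds: tuple[float, float] = (0.05, 0.95)

    def validate(self) -> None:
        if not (0.0 <= self.min_sample_coverage <= 1.0):
            raise ValueError("min_sample_coverage must lie in [0,1]")
        for lo, hi in (self.per_pop_af_bounds, self.mean_af_bounds):
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError(f"bounds ({lo},{hi}) must be ordered within [0,1]")
        if self.min_pops_in_bounds < 0:
            raise ValueError("min_pops_in_bounds must be >= 0")


class AlleleFrequencyMatrix:
    """Populations x loci matrix of alternative allele frequencies.

    ``values`` is a float array with NaN marking missing cells; ``loci`` is
    a frame with columns chrom / pos / ref / alt, positions strictly
    increasing within each chromosome.  ``stage`` tracks provenance
    (``raw`` -> ``filtered`` -> ``imputed``; the simulator emits ``true``).
    """

    def __init__(
        self,
        populations: list[str],
        loci: pd.DataFrame,
        values: np.ndarray,
        stage: str = "raw",
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(populations), len(loci)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(populations)} populations x {len(loci)} loci"
            )
        missing = [c for c in LOCUS_COLUMNS if c not in loci.columns]
        if missing:
            raise ValueError(f"locus table missing columns: {missing}")
        with np.errstate(invalid="ignore"):
            bad = (values < 0) | (values > 1)
        if np.any(bad):
            raise ValueError("allele frequencies must lie in [0,1] or be NaN")
        for chrom, sub in loci.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"locus positions not strictly increasing on {chrom}")
        self.populations = list(populations)
        self.loci = loci.reset_index(drop=True)
        self.values = values
        self.stage = stage

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.loci["chrom"], self.loci["pos"])]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def copy(self) -> "AlleleFrequencyMatrix":
        return AlleleFrequencyMatrix(
            list(self.populations), self.loci.copy(), self.values.copy(), self.stage
        )

    def to_frame(self) -> pd.DataFrame:
        """Loci as rows, populations as columns (the on-disk layout)."""
        df = self.loci.copy()
        for i, pop in enumerate(self.populations):
            df[pop] = self.values[i]
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, stage: str = "raw") -> "AlleleFrequencyMatrix":
        pops = [c for c in df.columns if c not in LOCUS_COLUMNS]
        values = df[pops].to_numpy(dtype=float).T
        return cls(pops, df[LOCUS_COLUMNS], values, stage=stage)

    @classmethod
    def from_tsv(cls, path, stage: str = "raw") -> "AlleleFrequencyMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls.from_frame(df, stage=stage)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AlleleFrequencyMatrix({self.n_populations} populations x "
            f"{self.n_loci} loci, stage={self.stage!r})"
        )


def counts_to_matrix(counts: pd.DataFrame, populations=None) -> AlleleFrequencyMatrix:
    """Merged count table -> raw AAF matrix (NaN at zero-depth cells)."""
    if "replicate" in counts.columns:
        counts = merge_replicates(counts)
    loci = (
        counts[LOCUS_COLUMNS]
        .drop_duplicates()
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    if populations is None:
        populations = sorted(counts["population"].unique())
    aaf = counts.assign(aaf=compute_aaf(counts["alt_count"], counts["ref_count"]))
    wide = aaf.pivot_table(
        index="population", columns=["chrom", "pos"], values="aaf", dropna=False
    )
    cols = pd.MultiIndex.from_arrays([loci["chrom"], loci["pos"]])
    wide = wide.reindex(index=populations, columns=cols)
    return AlleleFrequencyMatrix(populations, loci, wide.to_numpy(), stage="raw")


def filter_rules(freqs: AlleleFrequencyMatrix, spec: FilterSpec) -> pd.DataFrame:
    """Per-locus pass/fail for each of the three retention rules."""
    spec.validate()
    if freqs.n_loci == 0 or freqs.n_populations == 0:
        raise ValueError("cannot filter an empty matrix")
    v = freqs.values
    n_pops = freqs.n_populations
    observed = ~np.isnan(v)
    coverage_ok = observed.sum(axis=0) / n_pops > spec.min_sample_coverage
    lo, hi = spec.per_pop_af_bounds
    with np.errstate(invalid="ignore"):
        in_bounds = (v > lo) & (v < hi)
    bounds_ok = in_bounds.sum(axis=0) >= spec.min_pops_in_bounds
    mlo, mhi = spec.mean_af_bounds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_af = np.nanmean(v, axis=0)
    mean_ok = (mean_af > mlo) & (mean_af < mhi)
    return pd.DataFrame(
        {
            "coverage_ok": coverage_ok,
            "af_bounds_ok": bounds_ok,
            "mean_af_ok": np.nan_to_num(mean_ok, nan=False).astype(bool),
        }
    )


def filter_snps(
    freqs: AlleleFrequencyMatrix, spec: FilterSpec | None = None, return_report: bool = False
):
    """Apply the three retention rules; loci keep their original order."""
    spec = spec or FilterSpec()
    rules = filter_rules(freqs, spec)
    keep = rules.all(axis=1).to_numpy()
    report = {
        "n_input": freqs.n_loci,
        "n_retained": int(keep.sum()),
        "fail_coverage": int((~rules["coverage_ok"]).sum()),
        "fail_af_bounds": int((~rules["af_bounds_ok"]).sum()),
        "fail_mean_af": int((~rules["mean_af_ok"]).sum()),
    }
    logger.info("SNP filter: %s", report)
    out = AlleleFrequencyMatrix(
        list(freqs.populations),
        freqs.loci.loc[keep].reset_index(drop=True),
        freqs.values[:, keep],
        stage="filtered",
    )
    if return_report:
        return out, report
    return out


def impute_missing(freqs: AlleleFrequencyMatrix) -> AlleleFrequencyMatrix:
    """Replace each missing cell by the per-locus mean over observed populations."""
    v = freqs.values.copy()
    all_missing = np.isnan(v).all(axis=0)
    if np.any(all_missing):
        idx = np.where(all_missing)[0][:5]
        raise ValueError(f"loci missing in all populations (e.g. column {idx.tolist()})")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_means = np.nanmean(v, axis=0)
    nan_rows, nan_cols = np.where(np.isnan(v))
    v[nan_rows, nan_cols] = col_means[nan_cols]
    return AlleleFrequencyMatrix(list(freqs.populations), freqs.loci.copy(), v, stage="imputed")


# ---------------------------------------------------------------------------
# VCF / TSV ingestion


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t")
    validate_counts(counts)
    return counts


def read_vcf_counts(path, sample_splitter: str = "_rep") -> pd.DataFrame:
    """Read per-sample AD fields from a VCF into a pool count table.

    Sample names of the form ``<population><sample_splitter><k>`` map to
    population + replicate k; otherwise the whole name is the population and
    the replicate is 1.  Multi-allelic sites are skipped with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    parsed = []
    for s in samples:
        if sample_splitter in s:
            pop, rep = s.rsplit(sample_splitter, 1)
            parsed.append((pop, int(rep)))
        else:
            parsed.append((s, 1))
    rows = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        ad = var.format("AD")
        if ad is None:
            raise ValueError(f"VCF record {var.CHROM}:{var.POS} lacks FORMAT/AD")
        for (pop, rep), depths in zip(parsed, ad):
            ref_c = max(int(depths[0]), 0)
            alt_c = max(int(depths[1]), 0) if len(depths) > 1 else 0
            rows.append((pop, var.CHROM, var.POS, var.REF, var.ALT[0], rep, alt_c, ref_c))
    if n_multi:
        logger.warning("skipped %d multi-allelic site(s)", n_multi)
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    validate_counts(counts)
    return counts
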