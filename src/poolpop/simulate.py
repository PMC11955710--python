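"""Seeded synthetic-data generators.

Emulates the statistical structure of a pooled-GBS germplasm study:
drift-structured cluster allele frequencies (Balding-Nichols beta model),
pooled read counts from finite bulks with technical replicates, bioclimatic
variables tied to cluster geography with planted environment-associated
loci, plot-level phenotypes from a mixed model with a genomic covariance,
and pedigree / gene-model fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from poolpop.config import SimulationConfig, TraitConfig
from poolpop.poolfreq import COUNT_COLUMNS, AlleleFrequencyMatrix

logger = logging.getLogger(__name__)

# named substreams so each generator is reproducible independently of the
# order in which stages run
_STREAMS = {
    "frequencies": 11,
    "counts": 23,
    "bioclim": 37,
    "phenotypes": 41,
    "pedigree": 53,
    "genes": 67,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, seed-derived random substream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[name]]))


def _population_ids(config: SimulationConfig) -> tuple[list[str], pd.Series]:
    pops, clusters = [], []
    i = 0
    for c, n in enumerate(config.pops_per_cluster, start=1):
        for _ in range(n):
            i += 1
            pops.append(f"P{i:03d}")
            clusters.append(f"Cluster{c}")
    return pops, pd.Series(clusters, index=pops, name="cluster")


def _locus_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    frames = []
    for c, n in enumerate(per_chrom, start=1):
        pos = np.sort(rng.choice(np.arange(1, 50_000_000), size=n, replace=False))
        frames.append(pd.DataFrame({"chrom": f"chr{c}", "pos": pos, "ref": "A", "alt": "G"}))
    return pd.concat(frames, ignore_index=True)


def simulate_population_frequencies(
    config: SimulationConfig,
) -> tuple[AlleleFrequencyMatrix, pd.Series]:
    """True population allele frequencies under a beta drift model.

    Ancestral frequency per locus ~ Uniform(0.05, 0.95); cluster frequency
    ~ Beta(p(1-F)/F, (1-p)(1-F)/F) with F the cluster drift level;
    population frequency = cluster frequency plus a small within-cluster
    perturbation, clipped to [0, 1].

    Returns the frequency matrix (stage ``true``) and the population ->
    cluster assignment.
    """
    config.validate()
    rng = substream(config.seed, "frequencies")
    pops, clusters = _population_ids(config)
    loci = _locus_table(config, rng)
    n_loci = config.n_loci
    ancestral = rng.uniform(0.05, 0.95, size=n_loci)
    fsts = config.fst_per_cluster()
    values = np.empty((config.n_populations, n_loci))
    row = 0
    for c, (n_pops_c, fst) in enumerate(zip(config.pops_per_cluster, fsts)):
        shape = (1.0 - fst) / fst
        cluster_freq = rng.beta(ancestral * shape, (1.0 - ancestral) * shape)
        perturb = rng.normal(0.0, config.within_cluster_sd, size=(n_pops_c, n_loci))
        values[row : row + n_pops_c] = np.clip(cluster_freq[None, :] + perturb, 0.0, 1.0)
        row += n_pops_c
    freqs = AlleleFrequencyMatrix(pops, loci, values, stage="true")
    return freqs, clusters


def simulate_pool_counts(
    true_freqs: AlleleFrequencyMatrix, config: SimulationConfig
) -> pd.DataFrame:
    """Pooled read counts per population x locus x technical replicate.

    A bulk of ``pool_size`` individuals contributes ``2*pool_size`` allele
    draws; each technical replicate then samples reads binomially at the
    bulk allele frequency with a Poisson depth.  A per-(population, locus)
    dropout mask (rate ``missing_rate``) zeroes all replicates to exercise
    the downstream coverage filter.
    """
    config.validate()
    v = true_freqs.values
    if np.isnan(v).any() or v.min() < 0 or v.max() > 1:
        raise ValueError("true frequencies must be complete and lie in [0,1]")
    rng = substream(config.seed, "counts")
    n_pops, n_loci = v.shape
    bulk_draws = rng.binomial(2 * config.pool_size, v)
    bulk_freq = bulk_draws / (2.0 * config.pool_size)
    dropout = rng.random((n_pops, n_loci)) < config.missing_rate

    frames = []
    loci = true_freqs.loci
    for rep in range(1, config.n_tech_reps + 1):
        depth = rng.poisson(config.mean_depth, size=(n_pops, n_loci))
        depth[dropout] = 0
        alt = rng.binomial(depth, bulk_freq)
        ref = depth - alt
        frames.append(
            pd.DataFrame(
                {
                    "population": np.repeat(true_freqs.populations, n_loci),
                    "chrom": np.tile(loci["chrom"].to_numpy(), n_pops),
                    "pos": np.tile(loci["pos"].to_numpy(), n_pops),
                    "ref": np.tile(loci["ref"].to_numpy(), n_pops),
                    "alt": np.tile(loci["alt"].to_numpy(), n_pops),
                    "replicate": rep,
                    "alt_count": alt.ravel(),
                    "ref_count": ref.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


@dataclass
class BioclimSimulation:
    """Bioclim table, planted adaptive loci, and the rewritten frequencies."""

    bioclim: pd.DataFrame  # populations x Bio1..BioN
    adaptive: pd.DataFrame  # locus_index, locus_id, driver
    freqs: AlleleFrequencyMatrix  # adaptive loci overwritten

    @property
    def adaptive_loci(self) -> list[int]:
        return self.adaptive["locus_index"].tolist()


#: variable pairs forced to high correlation so collinearity pruning has
#: something to remove (1-based Bio indices)
COLLINEAR_PAIRS = [(1, 2), (4, 5), (10, 11), (16, 17)]

#: default environment drivers for planted adaptive loci
DEFAULT_DRIVERS = ["Bio3", "Bio6", "Bio8"]


def simulate_bioclim_and_adaptive(
    true_freqs: AlleleFrequencyMatrix,
    clusters: pd.Series,
    config: SimulationConfig,
    drivers: list[str] | None = None,
) -> BioclimSimulation:
    """Cluster-structured bioclim variables plus planted adaptive loci.

    Forced collinear pairs reach |r| >= 0.85 to exercise pruning.  Each
    adaptive locus has its population frequencies overwritten as
    inverse-logit(intercept + adaptive_slope * z(driver)), making its
    frequency-environment correlation strong at the default slope.
    """
    config.validate()
    rng = substream(config.seed, "bioclim")
    pops = true_freqs.populations
    cluster_labels = sorted(clusters.unique())
    cluster_idx = clusters.loc[pops].map({c: i for i, c in enumerate(cluster_labels)})
    n_pops, n_vars = len(pops), config.n_bioclim

    cluster_means = rng.normal(0.0, 2.0, size=(len(cluster_labels), n_vars))
    values = cluster_means[cluster_idx.to_numpy()] + rng.normal(0.0, 0.8, size=(n_pops, n_vars))
    names = [f"Bio{i}" for i in range(1, n_vars + 1)]
    bioclim = pd.DataFrame(values, index=pops, columns=names)
    bioclim.index.name = "population"

    for a, b in COLLINEAR_PAIRS:
        if a <= n_vars and b <= n_vars:
            base = bioclim[f"Bio{a}"]
            noise = rng.normal(0.0, 0.3 * base.std(ddof=0), size=n_pops)
            bioclim[f"Bio{b}"] = base + noise

    freqs = true_freqs.copy()
    if drivers is None:
        drivers = [d for d in DEFAULT_DRIVERS if d in names] or names[:1]
    if config.n_adaptive > 0:
        idx = np.sort(rng.choice(freqs.n_loci, size=config.n_adaptive, replace=False))
        locus_ids = freqs.locus_ids()
        rows = []
        for j, locus in enumerate(idx):
            driver = drivers[j % len(drivers)]
            z = bioclim[driver].to_numpy()
            z = (z - z.mean()) / z.std(ddof=0)
            base = float(np.clip(freqs.values[:, locus].mean(), 0.25, 0.75))
            intercept = logit(base)
            # logit-scale population noise keeps the locus polymorphic even
            # at slope 0, so planted loci stay comparable to background
            eps = rng.normal(0.0, 0.15, size=len(z))
            freqs.values[:, locus] = expit(intercept + config.adaptive_slope * z + eps)
            rows.append({"locus_index": int(locus), "locus_id": locus_ids[locus], "driver": driver})
        adaptive = pd.DataFrame(rows)
    else:
        adaptive = pd.DataFrame(columns=["locus_index", "locus_id", "driver"])
    return BioclimSimulation(bioclim=bioclim, adaptive=adaptive, freqs=freqs)


# ---------------------------------------------------------------------------
# phenotypes


def _check_psd(G: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=tol):
        raise ValueError("relationship matrix is not symmetric")
    G = 0.5 * (G + G.T)
    w = np.linalg.eigvalsh(G)
    if w.min() < -tol:
        raise ValueError(f"relationship matrix is not PSD (min eigenvalue {w.min():.3g})")
    return G


def simulate_phenotypes(
    G: np.ndarray,
    populations: list[str],
    config: SimulationConfig,
    traits: dict[str, TraitConfig] | None = None,
) -> pd.DataFrame:
    """Plot-level phenotypes from the generative mixed model.

    Population effects ~ MVN(0, G * sigma2_p); interaction and design
    effects i.i.d. normal with their configured variances; fixed year /
    location / season offsets added; a complete balanced row-column layout
    is emitted (one plot per population per replicate).
    """
    G = _check_psd(np.asarray(G, dtype=float))
    if G.shape[0] != len(populations):
        raise ValueError("G dimension does not match number of populations")
    traits = traits if traits is not None else config.trait_config
    rng = substream(config.seed, "phenotypes")
    n_pops = len(populations)
    # eigh-based square root is stable for exactly singular G
    w, Q = np.linalg.eigh(G)
    L = Q * np.sqrt(np.clip(w, 0.0, None))

    records = []
    for trait, tc in traits.items():
        tc.validate()
        if tc.n_rows * tc.n_cols < n_pops:
            raise ValueError(f"{trait}: row-column grid too small for {n_pops} populations")
        locs = [f"Loc{i}" for i in range(1, tc.n_locations + 1)]
        years = [f"Year{i}" for i in range(1, tc.n_years + 1)]
        seasons = [f"Season{i}" for i in range(1, tc.n_seasons + 1)]
        fx = tc.fixed_effect_scale
        loc_fx = np.linspace(-1, 1, tc.n_locations) * fx if tc.n_locations > 1 else np.zeros(1)
        year_fx = np.linspace(-1, 1, tc.n_years) * fx if tc.n_years > 1 else np.zeros(1)
        season_fx = np.linspace(-1, 1, tc.n_seasons) * fx if tc.n_seasons > 1 else np.zeros(1)

        u_p = np.sqrt(tc.sigma2_p) * (L @ rng.standard_normal(n_pops))
        u_pl = rng.normal(0, np.sqrt(tc.sigma2_pl), (n_pops, tc.n_locations))
        u_ps = rng.normal(0, np.sqrt(tc.sigma2_ps), (n_pops, tc.n_seasons))
        u_py = rng.normal(0, np.sqrt(tc.sigma2_py), (n_pops, tc.n_years))
        u_sy = rng.normal(0, np.sqrt(tc.sigma2_sy), (tc.n_seasons, tc.n_years))

        for n_i, loc in enumerate(locs):
            # one spatial layout per location x replicate, fixed over time
            layouts = {
                k: rng.permutation(tc.n_rows * tc.n_cols)[:n_pops]
                for k in range(tc.n_reps)
            }
            for o_i, year in enumerate(years):
                for j_i, season in enumerate(seasons):
                    for k in range(tc.n_reps):
                        b = rng.normal(0, np.sqrt(tc.sigma2_b))
                        row_fx = rng.normal(0, np.sqrt(tc.sigma2_r), tc.n_rows)
                        col_fx = rng.normal(0, np.sqrt(tc.sigma2_c), tc.n_cols)
                        cells = layouts[k]
                        rows_ = cells // tc.n_cols
                        cols_ = cells % tc.n_cols
                        resid = rng.normal(0, np.sqrt(tc.sigma2_e), n_pops)
                        y = (
                            tc.mean
                            + loc_fx[n_i]
                            + year_fx[o_i]
                            + season_fx[j_i]
                            + u_p
                            + u_pl[:, n_i]
                            + u_ps[:, j_i]
                            + u_py[:, o_i]
                            + u_sy[j_i, o_i]
                            + b
                            + row_fx[rows_]
                            + col_fx[cols_]
                            + resid
                        )
                        records.append(
                            pd.DataFrame(
                                {
                                    "population": populations,
                                    "location": loc,
                                    "year": year,
                                    "season": season,
                                    "replicate": k + 1,
                                    "row": rows_ + 1,
                                    "column": cols_ + 1,
                                    "trait": trait,
                                    "value": y,
                                }
                            )
                        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# pedigree and gene models


def simulate_pedigree(
    config: SimulationConfig, populations: list[str], n_crosses: int = 0
) -> pd.DataFrame:
    """All-founder pedigree plus an optional small crossed cohort."""
    ped = pd.DataFrame({"id": populations, "sire": "0", "dam": "0"})
    if n_crosses > 0:
        rng = substream(config.seed, "pedigree")
        extra = []
        for i in range(n_crosses):
            sire, dam = rng.choice(populations, size=2, replace=False)
            extra.append({"id": f"X{i + 1:03d}", "sire": sire, "dam": dam})
        ped = pd.concat([ped, pd.DataFrame(extra)], ignore_index=True)
    return ped


#: placement categories cycled over sampled loci: inside a gene, at the
#: 2,999 bp flank (assignable), at the 3,001 bp flank (not assignable),
#: and far intergenic
_GENE_PLACEMENTS = ["within", "flank_2999", "flank_3001", "intergenic"]


def simulate_gene_models(
    loci: pd.DataFrame, config: SimulationConfig, n_genes: int | None = None
) -> pd.DataFrame:
    """Gene-model fixtures placed relative to a sample of SNP positions.

    Cycles placements so the fixture set contains SNPs within genes, at
    2,999 / 3,001 bp flanks, and intergenic.  Returns a frame with GFF3-like
    columns (seqid, start, end, strand, gene_id, placement).
    """
    rng = substream(config.seed, "genes")
    if n_genes is None:
        n_genes = min(len(loci), 200)
    idx = np.sort(rng.choice(len(loci), size=n_genes, replace=False))
    strands = ["+", "-"]
    rows = []
    for g, locus in enumerate(idx):
        pos = int(loci["pos"].iloc[locus])
        chrom = loci["chrom"].iloc[locus]
        placement = _GENE_PLACEMENTS[g % len(_GENE_PLACEMENTS)]
        if placement == "within":
            start, end = max(1, pos - 500), pos + 500
        elif placement == "flank_2999":
            start, end = pos + 2999, pos + 3999
        elif placement == "flank_3001":
            start, end = pos + 3001, pos + 4001
        else:
            start, end = pos + 200_000, pos + 201_000
        rows.append(
            {
                "seqid": chrom,
                "start": start,
                "end": end,
                "strand": strands[g % 2],
                "gene_id": f"GENE{g + 1:04d}",
                "placement": placement,
                "anchor_locus": int(locus),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers (text formats only)


def write_vcf(counts: pd.DataFrame, path, contig_lengths: dict | None = None) -> None:
    """Write a pool count table as VCF 4.2 with per-sample AD and DP.

    Samples are named ``<population>_rep<k>``; AD carries (ref, alt) depths
    per the VCF convention.
    """
    key = ["chrom", "pos", "ref", "alt"]
    wide_alt = counts.pivot_table(
        index=key, columns=["population", "replicate"], values="alt_count", sort=False
    )
    wide_ref = counts.pivot_table(
        index=key, columns=["population", "replicate"], values="ref_count", sort=False
    )
    wide_alt = wide_alt.sort_index(axis=1)
    wide_ref = wide_ref[wide_alt.columns]
    samples = [f"{pop}_rep{rep}" for pop, rep in wide_alt.columns]
    contigs = counts["chrom"].drop_duplicates().tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolpop-simulate\n")
        for c in contigs:
            length = (contig_lengths or {}).get(c, 100_000_000)
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        alt_m = wide_alt.to_numpy()
        ref_m = wide_ref.to_numpy()
        index = wide_alt.index.to_frame(index=False)
        order = np.lexsort((index["pos"].to_numpy(), index["chrom"].to_numpy()))
        for i in order:
            chrom, pos, ref, alt = index.iloc[i]
            fields = [
                f"{int(ref_m[i, j])},{int(alt_m[i, j])}:{int(ref_m[i, j] + alt_m[i, j])}"
                for j in range(len(samples))
            ]
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tAD:DP\t" + "\t".join(fields) + "\n"
            )


def write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id};Name={g.gene_id}"
            fh.write(
                f"{g.seqid}\tpoolpop\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
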