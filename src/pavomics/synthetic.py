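"""Seeded synthetic data with the statistical structure of a multi-tissue
pan-transcriptome study in a biparental crossing panel.

The generator emulates a panel of inbred founders profiled by mRNA
sequencing in up to three tissues (one tissue covering only a subset of the
panel), with two disjoint mechanisms that remove a gene's expression in a
founder: physical deletion of the gene (gPAV — zero coverage in every
tissue) and transcriptional silencing (zero expression in one or more
tissues while the gene is still in the genome).  On top of the panel it
simulates a double round-robin crossing design: biparental populations
selfed to an advanced generation, genotyped with a SNP array on which a
deleted locus shows up as a systematically missing call, plus exonic
sequence variants in local linkage disequilibrium and additive phenotypes
with a chosen entry-mean heritability.

Every draw flows from ``SimConfig.seed``; identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "Truth",
    "ExpressionTensor",
    "PopulationGenotypes",
    "ConfigError",
    "simulate_panel",
    "simulate_populations",
    "simulate_variants",
    "simulate_phenotypes",
    "CALL_A",
    "CALL_B",
    "CALL_HET",
    "CALL_MISSING",
]

# progeny genotype codes (per population, relative to its two parents)
CALL_A = 0        # homozygous for parent-a allele
CALL_HET = 1
CALL_B = 2        # homozygous for parent-b allele
CALL_MISSING = -9


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic panel.

    Defaults mirror the design the generator emulates: 23 founder inbreds,
    three tissues with the third covering a six-inbred subset, 45 biparental
    populations of 35-146 progeny selfed from F1 for four generations (F5),
    and entry-mean heritability of 0.72.
    """

    n_inbreds: int = 23
    n_genes: int = 400
    n_tissues: int = 3
    #: fraction of the panel profiled per tissue (third tissue: 6 of 23)
    tissue_coverage: tuple[float, ...] | None = None
    frac_gpav: float = 0.10
    frac_silenced: float = 0.25
    #: probability that each further inbred shares a deletion / silencing
    sharing: float = 0.15
    #: probability a silenced (gene, inbred) is silenced in every tissue
    silencing_tissue_consistency: float = 0.67
    #: (mean, sd) of log gene length in bp
    gene_length_bp: tuple[float, float] = (8.0, 0.8)
    #: (mean, sd) of log expression level for expressed genes
    expr_lognormal: tuple[float, float] = (1.0, 1.0)
    #: sd of per-(gene, inbred) log expression noise
    expr_inbred_sd: float = 0.3
    library_size_reads: int = 2_000_000
    n_snps_array: int = 600
    #: number of array SNPs forced into the CDS of deleted (gPAV) genes;
    #: None places all SNPs at random
    n_snps_in_gpav: int | None = None
    n_populations: int = 45
    progeny_range: tuple[int, int] = (35, 146)
    selfing_generations: int = 4
    background_missing_rate: float = 0.002
    n_sv: int = 800
    ld_block_bp: float = 50_000.0
    sv_mean_depth: float = 20.0
    #: deliberate low-quality fractions, exercising each QC branch
    sv_bad_mq_frac: float = 0.02
    sv_low_depth_frac: float = 0.03
    sv_het_frac: float = 0.01
    sv_triallelic_frac: float = 0.005
    sv_missing_frac: float = 0.01
    h2: float = 0.72
    #: share of genetic variance driven by sequence variants (the rest is
    #: driven by expression levels of causal genes)
    causal_mix: float = 0.5
    n_causal_variants: int = 20
    n_causal_genes: int = 20
    n_chromosomes: int = 7
    #: per-gene coverage profiles use at most this many bins
    coverage_bins_cap: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_inbreds": self.n_inbreds,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "library_size_reads": self.library_size_reads,
            "n_snps_array": self.n_snps_array,
            "n_populations": self.n_populations,
            "n_sv": self.n_sv,
            "n_chromosomes": self.n_chromosomes,
            "coverage_bins_cap": self.coverage_bins_cap,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ConfigError(f"{name}: must be a positive integer, got {value!r}")
        fracs = {
            "frac_gpav": self.frac_gpav,
            "frac_silenced": self.frac_silenced,
            "sharing": self.sharing,
            "silencing_tissue_consistency": self.silencing_tissue_consistency,
            "background_missing_rate": self.background_missing_rate,
            "sv_bad_mq_frac": self.sv_bad_mq_frac,
            "sv_low_depth_frac": self.sv_low_depth_frac,
            "sv_het_frac": self.sv_het_frac,
            "sv_triallelic_frac": self.sv_triallelic_frac,
            "sv_missing_frac": self.sv_missing_frac,
            "h2": self.h2,
            "causal_mix": self.causal_mix,
        }
        for name, value in fracs.items():
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name}: must lie in [0, 1], got {value!r}")
        if self.frac_gpav + self.frac_silenced > 1.0:
            raise ConfigError(
                "frac_gpav + frac_silenced: gene classes are disjoint, sum must be <= 1"
            )
        if self.tissue_coverage is not None:
            if len(self.tissue_coverage) != self.n_tissues:
                raise ConfigError("tissue_coverage: needs one fraction per tissue")
            if any(not (0.0 < c <= 1.0) for c in self.tissue_coverage):
                raise ConfigError("tissue_coverage: fractions must lie in (0, 1]")
        lo, hi = self.progeny_range
        if not (2 <= lo <= hi):
            raise ConfigError(f"progeny_range: need 2 <= lo <= hi, got {self.progeny_range}")
        if self.selfing_generations < 0:
            raise ConfigError("selfing_generations: must be >= 0")
        if self.ld_block_bp < 0:
            raise ConfigError("ld_block_bp: must be >= 0")
        if self.sv_mean_depth <= 0:
            raise ConfigError("sv_mean_depth: must be > 0")

    @property
    def tissue_names(self) -> list[str]:
        base = ["leaf", "seedling", "apex"]
        if self.n_tissues <= 3:
            return base[: self.n_tissues]
        return base + [f"tissue{i}" for i in range(4, self.n_tissues + 1)]

    def effective_tissue_coverage(self) -> tuple[float, ...]:
        if self.tissue_coverage is not None:
            return self.tissue_coverage
        cov = [1.0] * self.n_tissues
        if self.n_tissues >= 3:
            cov[2] = min(1.0, 6 / self.n_inbreds)
        return tuple(cov)


@dataclass
class ExpressionTensor:
    """Per-tissue FPKM matrices with optional per-gene coverage profiles.

    ``fpkm[tissue]`` is a gene x inbred DataFrame restricted to the inbreds
    profiled in that tissue.  ``coverage[tissue][i]`` holds the binned read
    counts of gene ``i`` (rows = that tissue's inbreds, columns = bins);
    summing a gene's bins reproduces its read count, and FPKM is defined as
    ``count / (gene_kb * mapped_millions)``.
    """

    tissues: list[str]
    fpkm: dict[str, pd.DataFrame]
    gene_lengths: pd.Series
    coverage: dict[str, list[np.ndarray]] | None = None
    bin_edges: list[np.ndarray] | None = None
    library_sizes: dict[str, pd.Series] | None = None

    @property
    def genes(self) -> pd.Index:
        return self.fpkm[self.tissues[0]].index

    def inbreds(self, tissue: str) -> pd.Index:
        return self.fpkm[tissue].columns

    @property
    def all_inbreds(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.tissues:
            for s in self.fpkm[t].columns:
                seen.setdefault(s, None)
        return list(seen)


@dataclass
class Truth:
    """Ground truth behind a simulated panel, for recovery tests."""

    gpav_genes: set[tuple[str, str]]
    silenced_genes: set[tuple[str, str, str]]
    causal_effects: dict[str, pd.Series]
    true_genetic_values: pd.Series
    variant_alleles: pd.DataFrame = field(default_factory=pd.DataFrame)
    variant_positions: pd.DataFrame = field(default_factory=pd.DataFrame)
    snp_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    array_alleles: pd.DataFrame = field(default_factory=pd.DataFrame)

    def deleted_inbreds(self, gene: str) -> set[str]:
        return {s for g, s in self.gpav_genes if g == gene}


@dataclass
class PopulationGenotypes:
    """SNP-array calls for one biparental population.

    ``genotypes`` is SNP x progeny with codes ``CALL_A``/``CALL_HET``/
    ``CALL_B``/``CALL_MISSING``.
    """

    population_id: str
    parent_a: str
    parent_b: str
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.shape[1] < 2:
            raise ValueError(
                f"population {self.population_id}: needs >= 2 progeny, "
                f"got {self.genotypes.shape[1]}"
            )
        if self.parent_a == self.parent_b:
            raise ValueError(f"population {self.population_id}: parents must differ")

    @property
    def n_progeny(self) -> int:
        return self.genotypes.shape[1]

    def missing_proportion(self) -> pd.Series:
        """Per-SNP proportion of missing progeny calls."""
        return (self.genotypes == CALL_MISSING).mean(axis=1)


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------


def _draw_carriers(rng: np.random.Generator, n_inbreds: int, sharing: float) -> np.ndarray:
    """Indices of inbreds carrying a deletion/silencing: at least one, never
    the whole panel (otherwise the gene would be invariant)."""
    n_extra = rng.binomial(n_inbreds - 2, sharing) if n_inbreds > 2 else 0
    return rng.choice(n_inbreds, size=1 + n_extra, replace=False)


def _gene_annotation(rng: np.random.Generator, cfg: SimConfig) -> pd.DataFrame:
    mu, sd = cfg.gene_length_bp
    lengths = np.maximum(np.rint(rng.lognormal(mu, sd, cfg.n_genes)), 200).astype(int)
    chroms = np.arange(cfg.n_genes) % cfg.n_chromosomes
    order = np.argsort(chroms, kind="stable")
    starts = np.empty(cfg.n_genes, dtype=int)
    ends = np.empty(cfg.n_genes, dtype=int)
    pos = {}
    for i in order:
        c = chroms[i]
        gap = int(rng.exponential(4 * lengths.mean())) + 1
        start = pos.get(c, 0) + gap
        starts[i] = start
        ends[i] = start + lengths[i] - 1
        pos[c] = ends[i]
    # single CDS interval covering the central ~60% of the gene
    cds_start = starts + (lengths * 0.2).astype(int)
    cds_end = starts + (lengths * 0.8).astype(int)
    return pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(cfg.n_genes)],
            "chrom": [f"chr{c + 1}H" for c in chroms],
            "start": starts + 1,  # 1-based inclusive
            "end": ends + 1,
            "strand": rng.choice(["+", "-"], cfg.n_genes),
            "cds_start": cds_start + 1,
            "cds_end": cds_end + 1,
            "length": lengths,
        }
    ).set_index("gene_id", drop=False)


def simulate_panel(cfg: SimConfig) -> tuple[ExpressionTensor, pd.DataFrame, Truth]:
    """Simulate the founder panel: annotation, per-tissue FPKM + coverage,
    latent sequence-variant alleles, and the ground truth.

    Genes deleted in an inbred get zero reads in every tissue of that
    inbred; silenced genes get zero reads only in their designated tissues.
    FPKM is computed from simulated counts as
    ``count / (gene_kb * mapped_millions)``.
    """
    rng = np.random.default_rng(cfg.seed)
    inbreds = [f"inbred{i:02d}" for i in range(1, cfg.n_inbreds + 1)]
    anno = _gene_annotation(rng, cfg)
    genes = anno.index.to_list()
    lengths = anno["length"].to_numpy()

    # --- gene classes ------------------------------------------------------
    n_gpav = int(round(cfg.frac_gpav * cfg.n_genes))
    n_sil = int(round(cfg.frac_silenced * cfg.n_genes))
    cls = rng.permutation(cfg.n_genes)
    gpav_idx, sil_idx = cls[:n_gpav], cls[n_gpav : n_gpav + n_sil]

    tissue_names = cfg.tissue_names
    deleted = np.zeros((cfg.n_genes, cfg.n_inbreds), dtype=bool)
    gpav_genes: set[tuple[str, str]] = set()
    for gi in gpav_idx:
        for si in _draw_carriers(rng, cfg.n_inbreds, cfg.sharing):
            deleted[gi, si] = True
            gpav_genes.add((genes[gi], inbreds[si]))

    silenced = np.zeros((cfg.n_genes, cfg.n_inbreds, cfg.n_tissues), dtype=bool)
    silenced_genes: set[tuple[str, str, str]] = set()
    for gi in sil_idx:
        for si in _draw_carriers(rng, cfg.n_inbreds, cfg.sharing):
            if rng.random() < cfg.silencing_tissue_consistency:
                t_idx = np.arange(cfg.n_tissues)
            else:
                k = rng.integers(1, max(cfg.n_tissues, 2))
                t_idx = rng.choice(cfg.n_tissues, size=min(k, cfg.n_tissues), replace=False)
            for ti in t_idx:
                silenced[gi, si, ti] = True
                silenced_genes.add((genes[gi], inbreds[si], tissue_names[ti]))

    # --- expression & coverage --------------------------------------------
    mu, sd = cfg.expr_lognormal
    base_level = rng.lognormal(mu, sd, cfg.n_genes)
    inbred_factor = rng.lognormal(0.0, cfg.expr_inbred_sd, (cfg.n_genes, cfg.n_inbreds))
    propensity = base_level[:, None] * inbred_factor  # expected FPKM scale

    coverage_frac = cfg.effective_tissue_coverage()
    n_bins = np.minimum(lengths, cfg.coverage_bins_cap)
    bin_edges = [
        np.rint(np.linspace(0, lengths[g], n_bins[g] + 1)).astype(int)
        for g in range(cfg.n_genes)
    ]

    fpkm: dict[str, pd.DataFrame] = {}
    coverage: dict[str, list[np.ndarray]] = {}
    lib_sizes: dict[str, pd.Series] = {}
    for ti, tissue in enumerate(tissue_names):
        n_t = max(2, int(round(coverage_frac[ti] * cfg.n_inbreds)))
        t_inbreds = [inbreds[i] for i in sorted(rng.choice(cfg.n_inbreds, n_t, replace=False))] \
            if n_t < cfg.n_inbreds else list(inbreds)
        col_idx = [inbreds.index(s) for s in t_inbreds]

        w = propensity[:, col_idx] * lengths[:, None]  # read weight ~ level * length
        off = deleted[:, col_idx] | silenced[:, col_idx, ti]
        w = np.where(off, 0.0, w)
        counts = np.empty_like(w, dtype=np.int64)
        for j in range(len(col_idx)):
            p = w[:, j] / w[:, j].sum()
            counts[:, j] = rng.multinomial(cfg.library_size_reads, p)
        counts[off] = 0  # hard zero (multinomial already gives 0 at p=0)

        lib = counts.sum(axis=0).astype(float)
        t_fpkm = counts / (lengths[:, None] / 1e3) / (lib[None, :] / 1e6)
        fpkm[tissue] = pd.DataFrame(t_fpkm, index=genes, columns=t_inbreds)
        lib_sizes[tissue] = pd.Series(lib, index=t_inbreds)

        cov_t: list[np.ndarray] = []
        for g in range(cfg.n_genes):
            widths = np.diff(bin_edges[g]).astype(float)
            p = widths / widths.sum()
            prof = np.vstack(
                [rng.multinomial(counts[g, j], p) for j in range(len(col_idx))]
            )
            cov_t.append(prof)
        coverage[tissue] = cov_t

    expr = ExpressionTensor(
        tissues=tissue_names,
        fpkm=fpkm,
        gene_lengths=anno["length"],
        coverage=coverage,
        bin_edges=bin_edges,
        library_sizes=lib_sizes,
    )

    # --- latent sequence variants (exonic, in LD blocks) -------------------
    variant_alleles, variant_positions = _latent_variants(rng, cfg, anno, deleted, inbreds)

    # --- array SNPs ---------------------------------------------------------
    snp_table, array_alleles = _array_snps(rng, cfg, anno, gpav_idx, inbreds)

    # --- causal architecture & genetic values -------------------------------
    truth = Truth(
        gpav_genes=gpav_genes,
        silenced_genes=silenced_genes,
        causal_effects={},
        true_genetic_values=pd.Series(0.0, index=inbreds),
        variant_alleles=variant_alleles,
        variant_positions=variant_positions,
        snp_table=snp_table,
        array_alleles=array_alleles,
    )
    _assign_genetic_values(rng, cfg, truth, propensity, deleted, genes, inbreds)
    return expr, anno, truth


def _latent_variants(rng, cfg, anno, deleted, inbreds):
    """Biallelic 0/1 founder alleles at exonic positions; along each
    chromosome an inbred copies the previous variant's allele with
    probability exp(-d / ld_block_bp), producing distance-decaying LD."""
    gene_pick = rng.integers(0, cfg.n_genes, cfg.n_sv)
    offsets = rng.random(cfg.n_sv)
    rows = []
    for v, g in enumerate(gene_pick):
        row = anno.iloc[g]
        pos = int(row["cds_start"] + offsets[v] * (row["cds_end"] - row["cds_start"]))
        rows.append((f"sv{v:05d}", row["chrom"], pos, row["gene_id"]))
    tab = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "gene_id"])
    tab = tab.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    alleles = np.zeros((len(tab), cfg.n_inbreds), dtype=np.int8)
    prev_chrom, prev_pos, prev = None, None, None
    for i, rec in enumerate(tab.itertuples()):
        maf = rng.uniform(0.1, 0.5)
        fresh = (rng.random(cfg.n_inbreds) < maf).astype(np.int8)
        if rec.chrom == prev_chrom and cfg.ld_block_bp > 0:
            rho = float(np.exp(-(rec.pos - prev_pos) / cfg.ld_block_bp))
            copy = rng.random(cfg.n_inbreds) < rho
            alleles[i] = np.where(copy, prev, fresh)
        else:
            alleles[i] = fresh
        prev_chrom, prev_pos, prev = rec.chrom, rec.pos, alleles[i]
    mat = pd.DataFrame(alleles, index=tab["variant_id"].to_list(), columns=inbreds)
    return mat, tab.set_index("variant_id", drop=False)


def _array_snps(rng, cfg, anno, gpav_idx, inbreds):
    """Array SNP placement (optionally forcing SNPs into deleted genes'
    CDS) and binary founder alleles at frequency ~0.5."""
    n = cfg.n_snps_array
    rows = []
    forced = cfg.n_snps_in_gpav or 0
    if forced > len(gpav_idx) * 0 and len(gpav_idx) == 0 and forced > 0:
        raise ConfigError("n_snps_in_gpav: no gPAV genes simulated (frac_gpav = 0)")
    if forced > n:
        raise ConfigError("n_snps_in_gpav: cannot exceed n_snps_array")
    for k in range(forced):
        g = gpav_idx[k % len(gpav_idx)]
        row = anno.iloc[g]
        pos = int(rng.integers(row["cds_start"], row["cds_end"] + 1))
        rows.append((row["chrom"], pos, row["gene_id"]))
    for _ in range(n - forced):
        g = int(rng.integers(0, cfg.n_genes))
        row = anno.iloc[g]
        if rng.random() < 0.7:  # genic SNP, inside CDS
            pos = int(rng.integers(row["cds_start"], row["cds_end"] + 1))
            rows.append((row["chrom"], pos, row["gene_id"]))
        else:  # intergenic / non-CDS
            pos = int(row["end"]) + int(rng.integers(1, 5000))
            rows.append((row["chrom"], pos, ""))
    tab = pd.DataFrame(rows, columns=["chrom", "pos", "gene_id"])
    tab.insert(0, "snp_id", [f"snp{i:05d}" for i in range(n)])
    alleles = (rng.random((n, cfg.n_inbreds)) < 0.5).astype(np.int8)
    mat = pd.DataFrame(alleles, index=tab["snp_id"].to_list(), columns=inbreds)
    return tab.set_index("snp_id", drop=False), mat


def _assign_genetic_values(rng, cfg, truth, propensity, deleted, genes, inbreds):
    """Additive genetic values as a mixture of variant-driven and
    expression-driven effects (standardized layers weighted by causal_mix)."""
    n = len(inbreds)
    g_var = np.zeros(n)
    var_eff = pd.Series(dtype=float)
    if cfg.n_causal_variants > 0 and len(truth.variant_alleles) > 0:
        k = min(cfg.n_causal_variants, len(truth.variant_alleles))
        pick = rng.choice(len(truth.variant_alleles), k, replace=False)
        Z = truth.variant_alleles.to_numpy()[pick].astype(float)
        sd = Z.std(axis=1)
        keep = sd > 0
        Z = (Z[keep] - Z[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        beta = rng.normal(0.0, 1.0, keep.sum())
        g_var = beta @ Z
        var_eff = pd.Series(beta, index=truth.variant_alleles.index[pick][keep])
    g_expr = np.zeros(n)
    expr_eff = pd.Series(dtype=float)
    if cfg.n_causal_genes > 0:
        pick = rng.choice(len(genes), min(cfg.n_causal_genes, len(genes)), replace=False)
        X = np.log1p(np.where(deleted[pick], 0.0, propensity[pick]))
        sd = X.std(axis=1)
        keep = sd > 0
        X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        beta = rng.normal(0.0, 1.0, keep.sum())
        g_expr = beta @ X
        expr_eff = pd.Series(beta, index=[genes[i] for i in pick[keep]])

    def _std(v):
        s = v.std()
        return v / s if s > 0 else v

    w_v = np.sqrt(cfg.causal_mix)
    w_e = np.sqrt(1.0 - cfg.causal_mix)
    g = w_v * _std(g_var) + w_e * _std(g_expr)
    truth.causal_effects = {"variant": var_eff, "expression": expr_eff}
    truth.true_genetic_values = pd.Series(g, index=inbreds)


# ---------------------------------------------------------------------------
# biparental populations
# ---------------------------------------------------------------------------


def round_robin_pairs(inbreds: list[str], n_pairs: int) -> list[tuple[str, str]]:
    """Double round-robin crossing plan: chain each inbred with its next
    neighbour, then with its second-next, until n_pairs crosses."""
    n = len(inbreds)
    pairs = []
    for step in (1, 2, 3):
        for i in range(n):
            pairs.append((inbreds[i], inbreds[(i + step) % n]))
        if len(pairs) >= n_pairs:
            break
    if len(pairs) < n_pairs:
        raise ConfigError("n_populations: too many populations for the panel size")
    return pairs[:n_pairs]


def _selfed_genotype_probs(selfing_generations: int) -> tuple[float, float]:
    """(P(hom each), P(het)) for an F1 selfed ``selfing_generations`` times
    by single-seed descent."""
    p_het = 0.5 ** selfing_generations
    return (1.0 - p_het) / 2.0, p_het


def simulate_populations(truth: Truth, cfg: SimConfig) -> list[PopulationGenotypes]:
    """Genotype the double round-robin populations on the array SNPs.

    At a SNP inside a gene deleted in one parent, every progeny carrying at
    least one null copy gives a missing call — array genotype callers
    no-call hemizygous samples, whose intensities fall outside the diploid
    clusters, as well as null homozygotes — so the expected missing
    proportion is the carrier frequency of the absent allele under selfing
    (17/32 at F5).  A gene deleted in both parents yields all-missing
    calls.  Background missingness is added at ``background_missing_rate``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    inbreds = list(truth.array_alleles.columns)
    pairs = round_robin_pairs(inbreds, cfg.n_populations)
    snp_ids = truth.snp_table.index.to_list()
    snp_gene = truth.snp_table["gene_id"].to_numpy()
    arr = truth.array_alleles

    p_hom, p_het = _selfed_genotype_probs(cfg.selfing_generations)
    pops = []
    for k, (pa, pb) in enumerate(pairs):
        n_prog = int(rng.integers(cfg.progeny_range[0], cfg.progeny_range[1] + 1))
        if n_prog < 2:
            raise ConfigError("progeny_range: populations need >= 2 progeny")
        del_a = np.array([(g, pa) in truth.gpav_genes if g else False for g in snp_gene])
        del_b = np.array([(g, pb) in truth.gpav_genes if g else False for g in snp_gene])

        u = rng.random((len(snp_ids), n_prog))
        geno = np.full(u.shape, CALL_HET, dtype=np.int8)
        geno[u < p_hom] = CALL_A
        geno[u >= p_hom + p_het] = CALL_B

        calls = geno.copy()
        same = (arr[pa].to_numpy() == arr[pb].to_numpy())
        # monomorphic SNP (parents share the allele): every genotype reads as
        # that allele; encode as CALL_A
        calls[same & ~del_a & ~del_b] = CALL_A

        both = del_a & del_b
        calls[both] = CALL_MISSING
        # any null copy (homozygous null or hemizygous) -> no call
        only_a = del_a & ~del_b
        calls[only_a] = np.where(geno[only_a] != CALL_B, CALL_MISSING, CALL_B)
        only_b = del_b & ~del_a
        calls[only_b] = np.where(geno[only_b] != CALL_A, CALL_MISSING, CALL_A)

        if cfg.background_missing_rate > 0:
            bg = rng.random(calls.shape) < cfg.background_missing_rate
            calls = np.where(bg, CALL_MISSING, calls)

        gdf = pd.DataFrame(
            calls, index=snp_ids, columns=[f"pop{k:02d}_p{j:03d}" for j in range(n_prog)]
        )
        pops.append(PopulationGenotypes(f"pop{k:02d}", pa, pb, gdf))
    return pops


# ---------------------------------------------------------------------------
# sequence-variant call table
# ---------------------------------------------------------------------------


def simulate_variants(truth: Truth, cfg: SimConfig, expr: ExpressionTensor | None = None) -> pd.DataFrame:
    """Raw per-(variant, inbred, tissue) call records with mapping quality,
    depth and heterozygosity fields, including deliberately low-quality
    records that exercise every downstream QC branch."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    inbreds = list(truth.variant_alleles.columns)
    tissues = cfg.tissue_names[: min(2, cfg.n_tissues)]  # panel-wide tissues
    vids = truth.variant_alleles.index.to_list()
    n_v = len(vids)

    mq = np.full(n_v, 60)
    bad_mq = rng.random(n_v) < cfg.sv_bad_mq_frac
    mq[bad_mq] = 30
    triallelic = rng.random(n_v) < cfg.sv_triallelic_frac

    pos_tab = truth.variant_positions
    records = []
    alleles = truth.variant_alleles.to_numpy()
    for vi, vid in enumerate(vids):
        gene = pos_tab.loc[vid, "gene_id"]
        tri_inbred = rng.integers(0, len(inbreds)) if triallelic[vi] else -1
        for si, inbred in enumerate(inbreds):
            deleted = (gene, inbred) in truth.gpav_genes
            for tissue in tissues:
                if deleted:
                    depth = 0
                    call = ""
                elif rng.random() < cfg.sv_missing_frac:
                    depth = 0
                    call = ""
                else:
                    if rng.random() < cfg.sv_low_depth_frac:
                        depth = int(rng.integers(1, 5))
                    else:
                        depth = max(5, int(rng.poisson(cfg.sv_mean_depth)))
                    if si == tri_inbred:
                        call = "C"
                    else:
                        call = "B" if alleles[vi, si] else "A"
                is_het = bool(call) and (rng.random() < cfg.sv_het_frac)
                records.append(
                    (
                        vid,
                        pos_tab.loc[vid, "chrom"],
                        int(pos_tab.loc[vid, "pos"]),
                        inbred,
                        tissue,
                        call,
                        int(mq[vi]),
                        depth,
                        is_het,
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "variant_id",
            "chrom",
            "pos",
            "inbred",
            "tissue",
            "allele",
            "mapping_quality",
            "depth",
            "is_het",
        ],
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    truth: Truth,
    cfg: SimConfig,
    h2: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Entry means: true genetic value plus Gaussian noise scaled so that
    var(genetic) / var(total) equals h2 in expectation.

    h2 = 1 returns the genetic values unchanged; h2 = 0 returns pure noise.
    """
    h2 = cfg.h2 if h2 is None else h2
    if not (0.0 <= h2 <= 1.0):
        raise ConfigError(f"h2: must lie in [0, 1], got {h2!r}")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    g = truth.true_genetic_values
    sg = float(g.std(ddof=0))
    if h2 == 0.0:
        noise_sd = sg if sg > 0 else 1.0
        return pd.Series(rng.normal(0.0, noise_sd, len(g)), index=g.index, name="trait")
    if h2 == 1.0:
        return g.rename("trait").copy()
    noise_sd = sg * np.sqrt((1.0 - h2) / h2)
    return (g + rng.normal(0.0, noise_sd, len(g))).rename("trait")
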