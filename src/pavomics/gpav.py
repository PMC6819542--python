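"""Genomic presence/absence (gPAV) inference from segregating missing data.

A SNP inside a gene that is deleted in one parent of a biparental cross
shows systematically missing calls in the progeny that inherited two null
copies; deleted in both parents, every progeny call is missing.  The
procedure turns this signature into parental presence/absence calls:

1. Per population, the 90th percentile (Q90) of the major-allele frequency
   over fully-observed segregating SNPs captures random deviation from the
   expected 0.5 segregation ratio.
2. Each SNP's missing-call proportion m places it in category A (both
   parents present, m below 1 - Q90), B (one present / one absent) or C
   (both absent, m above Q90).
3. Across all populations sharing a parent, consistent categories give that
   parent a present or absent call at the SNP.

SNPs with at least one present and one absent parental call are gPAV-SNPs;
those inside a CDS and more than 30 bp from any insertion are genic
PAV-SNPs.  Against that truthier channel, the expression-based ePAV caller
is scored for power (1 - beta*), empirical type-I error (alpha*), and
per-inbred call concordance (o).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pav_calling import ABSENT, EPAVSet, PACallMatrix, PRESENT
from .synthetic import CALL_A, CALL_B, CALL_HET, CALL_MISSING, PopulationGenotypes

__all__ = [
    "ParentalPACalls",
    "PowerReport",
    "population_q90",
    "categorize_snp",
    "categorize_population",
    "assign_parental_calls",
    "infer_parental_calls",
    "designate_gpav_snp",
    "filter_genic_pav_snp",
    "estimate_power_error",
    "extrapolate_gpav_total",
]

PARENT_PRESENT = "present"
PARENT_ABSENT = "absent"
PARENT_UNDETERMINED = "undetermined"


@dataclass
class ParentalPACalls:
    """SNP x parent calls in {present, absent, undetermined}."""

    calls: pd.DataFrame


@dataclass
class PowerReport:
    """Power / type-I error / concordance of ePAV as a gPAV detector, in
    percent, with the scope (tissues, t, window mode) they were computed
    under."""

    power_1mb: float
    alpha_star: float
    concordance_o: float
    scope: tuple = ()

    def __post_init__(self) -> None:
        for v in (self.power_1mb, self.alpha_star, self.concordance_o):
            if not np.isnan(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"report values must lie in [0, 100], got {v}")


def population_q90(pop: PopulationGenotypes, q: float = 90.0) -> float:
    """Q90 of the per-SNP major-allele frequency over fully-observed,
    segregating SNPs of one population (linear-interpolation percentile).

    Het calls contribute half an allele count to each parent's allele.
    Monomorphic SNPs carry no information about segregation-ratio noise and
    are excluded.
    """
    g = pop.genotypes.to_numpy()
    complete = ~(g == CALL_MISSING).any(axis=1)
    if not complete.any():
        raise ValueError(f"population {pop.population_id}: no fully-observed SNP")
    g = g[complete]
    n = g.shape[1]
    count_a = (g == CALL_A).sum(axis=1) + 0.5 * (g == CALL_HET).sum(axis=1)
    freq_a = count_a / n
    maf = np.maximum(freq_a, 1.0 - freq_a)
    seg = (maf < 1.0)
    if not seg.any():
        raise ValueError(
            f"population {pop.population_id}: no segregating fully-observed SNP"
        )
    return float(np.percentile(maf[seg], q))


def categorize_snp(m: float, q90: float, strict_literal: bool = False) -> str:
    """Category of a SNP from its missing-call proportion m.

    Default bounds: A: [0, 1-Q90), B: [1-Q90, Q90], C: (Q90, 1] — the
    ordering consistent with Q90 >= 0.5 (A = both parents present,
    B = one absent, C = both absent).  ``strict_literal`` applies the
    bounds in the printed order A: [0, Q90), B: [Q90, 1-Q90], C: (1-Q90, 1],
    which is degenerate for Q90 > 0.5.
    """
    if not (0.0 <= m <= 1.0):
        raise ValueError(f"missing proportion must lie in [0, 1], got {m}")
    if not (0.5 <= q90 <= 1.0):
        raise ValueError(f"q90 must lie in [0.5, 1], got {q90}")
    lo, hi = (q90, 1.0 - q90) if strict_literal else (1.0 - q90, q90)
    if m < lo:
        return "A"
    if m <= hi:
        return "B"
    return "C"


def categorize_population(pop: PopulationGenotypes, q90: float | None = None) -> pd.Series:
    """Vectorised A/B/C categories for every SNP of a population."""
    if q90 is None:
        q90 = population_q90(pop)
    m = pop.missing_proportion().to_numpy()
    cat = np.where(m < 1.0 - q90, "A", np.where(m <= q90, "B", "C"))
    return pd.Series(cat, index=pop.genotypes.index)


def assign_parental_calls(
    categories: dict[str, list[pd.Series]], snp_ids: list | None = None
) -> ParentalPACalls:
    """Parental presence/absence calls from per-population SNP categories.

    ``categories`` maps each parent to the category Series of every
    population it founded.  A parent is absent at a SNP if all its
    populations are B or C with at least one C, present if all are A or B
    with at least one A; all-B (compatible with both states) and mixed
    A-and-C patterns are undetermined.
    """
    parents = list(categories)
    for p, series in categories.items():
        if len(series) == 0:
            raise ValueError(f"parent {p}: no populations")
    if snp_ids is None:
        snp_ids = list(categories[parents[0]][0].index)
    out = pd.DataFrame(PARENT_UNDETERMINED, index=snp_ids, columns=parents)
    for p in parents:
        cats = pd.concat(categories[p], axis=1).loc[snp_ids].to_numpy()
        has_a = (cats == "A").any(axis=1)
        has_c = (cats == "C").any(axis=1)
        all_bc = ~has_a
        all_ab = ~has_c
        col = np.where(
            all_bc & has_c,
            PARENT_ABSENT,
            np.where(all_ab & has_a, PARENT_PRESENT, PARENT_UNDETERMINED),
        )
        out[p] = col
    return ParentalPACalls(out)


def infer_parental_calls(
    pops: list[PopulationGenotypes], resolve_all_b: bool = False
) -> ParentalPACalls:
    """End-to-end: Q90 and categories per population, then parental calls.

    With ``resolve_all_b``, a parent left undetermined by an all-B pattern
    is assigned absent when every partner it was crossed with carries a
    present call at the SNP: category B means exactly one parent of the
    cross is absent, so a present partner pins the absence on this parent.
    """
    categories: dict[str, list[pd.Series]] = {}
    snp_ids = list(pops[0].genotypes.index)
    for pop in pops:
        cat = categorize_population(pop)
        categories.setdefault(pop.parent_a, []).append(cat)
        categories.setdefault(pop.parent_b, []).append(cat)
    calls = assign_parental_calls(categories, snp_ids)
    if resolve_all_b:
        cat_by_pop = [categorize_population(pop) for pop in pops]
        partners: dict[str, list[tuple[str, int]]] = {p: [] for p in calls.calls.columns}
        for k, pop in enumerate(pops):
            partners[pop.parent_a].append((pop.parent_b, k))
            partners[pop.parent_b].append((pop.parent_a, k))
        df = calls.calls
        for p in df.columns:
            if not partners[p]:
                continue
            cats = pd.concat([cat_by_pop[k] for _, k in partners[p]], axis=1)
            all_b = (cats.loc[snp_ids].to_numpy() == "B").all(axis=1)
            cand = df.index[(df[p] == PARENT_UNDETERMINED).to_numpy() & all_b]
            mates = [mate for mate, _ in partners[p]]
            ok = (df.loc[cand, mates] == PARENT_PRESENT).all(axis=1)
            df.loc[cand[ok.to_numpy()], p] = PARENT_ABSENT
    return calls


def designate_gpav_snp(calls: ParentalPACalls) -> set:
    """SNPs with at least one present and one absent parental call."""
    arr = calls.calls.to_numpy()
    keep = (arr == PARENT_PRESENT).any(axis=1) & (arr == PARENT_ABSENT).any(axis=1)
    return set(calls.calls.index[keep])


def filter_genic_pav_snp(
    gpav_snps: set,
    snp_table: pd.DataFrame,
    annotation: pd.DataFrame,
    insertion_positions: pd.DataFrame | None = None,
    min_insertion_distance: int = 30,
) -> set:
    """gPAV-SNPs that lie inside a CDS and are not within 30 bp of an
    insertion (distance <= 30 excludes; 31 bp away is kept).

    ``snp_table`` needs columns chrom/pos (indexed by SNP id); ``annotation``
    needs chrom/cds_start/cds_end; ``insertion_positions`` chrom/pos.
    """
    if annotation is None or len(annotation) == 0:
        raise ValueError("gene annotation with CDS intervals is required")
    out = set()
    ann_by_chrom = {c: sub for c, sub in annotation.groupby("chrom")}
    ins_by_chrom = (
        {c: sub["pos"].to_numpy() for c, sub in insertion_positions.groupby("chrom")}
        if insertion_positions is not None and len(insertion_positions)
        else {}
    )
    for snp in gpav_snps:
        rec = snp_table.loc[snp]
        sub = ann_by_chrom.get(rec["chrom"])
        if sub is None:
            continue
        in_cds = (sub["cds_start"] <= rec["pos"]) & (rec["pos"] <= sub["cds_end"])
        if not in_cds.any():
            continue
        ins = ins_by_chrom.get(rec["chrom"])
        if ins is not None and len(ins) and np.abs(ins - rec["pos"]).min() <= min_insertion_distance:
            continue
        out.add(snp)
    return out


def _snp_parental_to_pa(call: str) -> int | None:
    if call == PARENT_PRESENT:
        return PRESENT
    if call == PARENT_ABSENT:
        return ABSENT
    return None


def estimate_power_error(
    epav: EPAVSet,
    epav_consensus: PACallMatrix,
    genic_pav_snps: set,
    genic_snps: set,
    gene_of_snp: pd.Series,
    parental_calls: ParentalPACalls | None = None,
    literal_denominator: bool = False,
    scope: tuple = (),
) -> PowerReport:
    """Score the ePAV caller against the SNP-derived gPAV channel.

    power (1 - beta*): percentage of genic PAV-SNPs whose gene is an ePAV.
    alpha*: percentage of ePAV genes that contain a genic SNP but no genic
    PAV-SNP, relative to the ePAV genes containing a genic SNP (the
    evaluable subset); ``literal_denominator`` divides by all ePAV instead.
    o: percentage agreement between the consensus ePAV call and the
    parental SNP call over (gene, inbred) pairs at genic PAV-SNPs, skipping
    pairs where either side is no-call/undetermined.
    """
    if not genic_pav_snps:
        raise ValueError("power is undefined: the genic PAV-SNP set is empty")
    pav_genes = {gene_of_snp[s] for s in genic_pav_snps}
    n_hit = sum(1 for s in genic_pav_snps if gene_of_snp[s] in epav.genes)
    power = 100.0 * n_hit / len(genic_pav_snps)

    genic_genes = {gene_of_snp[s] for s in genic_snps}
    evaluable = [g for g in epav.genes if g in genic_genes]
    false_like = [g for g in evaluable if g not in pav_genes]
    denom = len(epav.genes) if literal_denominator else len(evaluable)
    alpha = 100.0 * len(false_like) / denom if denom else float("nan")

    concordance = float("nan")
    if parental_calls is not None:
        agree = total = 0
        calls = epav_consensus.calls
        for snp in genic_pav_snps:
            gene = gene_of_snp[snp]
            if gene not in calls.index:
                continue
            for inbred in parental_calls.calls.columns:
                if inbred not in calls.columns:
                    continue
                snp_pa = _snp_parental_to_pa(parental_calls.calls.at[snp, inbred])
                epav_call = calls.at[gene, inbred]
                if snp_pa is None or epav_call not in (PRESENT, ABSENT):
                    continue
                total += 1
                agree += int(epav_call == snp_pa)
        if total:
            concordance = 100.0 * agree / total
    return PowerReport(power, alpha, concordance, scope)


def extrapolate_gpav_total(
    n_epav: int, frac_gpav_among_epav: float, power: float
) -> tuple[int, int]:
    """Extrapolate the total number of gPAV genes.

    The number of gPAV among the detected ePAV is ``n_epav x fraction``;
    dividing by the detector's power gives the expected genome-wide total
    (e.g. 38,000 ePAV x 10% = 3,800 gPAV; at 50% power, ~7,600 in total).
    """
    if not (0.0 < power <= 1.0):
        raise ValueError(f"power must lie in (0, 1], got {power}")
    if not (0.0 <= frac_gpav_among_epav <= 1.0):
        raise ValueError(f"fraction must lie in [0, 1], got {frac_gpav_among_epav}")
    gpav_in_epav = int(round(n_epav * frac_gpav_among_epav))
    return gpav_in_epav, int(round(gpav_in_epav / power))
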