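"""Q90 categories, parental call assignment, gPAV-SNP designation and the
power / type-I error / extrapolation arithmetic."""

import numpy as np
import pandas as pd
import pytest

from pavomics import gpav
from pavomics.gpav import PARENT_ABSENT, PARENT_PRESENT, PARENT_UNDETERMINED
from pavomics.pav_calling import ABSENT, PACallMatrix, PRESENT, EPAVSet
from pavomics.synthetic import CALL_A, CALL_B, CALL_MISSING, PopulationGenotypes


def _pop(genotypes, parents=("p1", "p2"), pid="pop0"):
    g = pd.DataFrame(
        np.asarray(genotypes, dtype=np.int8),
        index=[f"s{k}" for k in range(len(genotypes))],
        columns=[f"c{k}" for k in range(len(genotypes[0]))],
    )
    return PopulationGenotypes(pid, parents[0], parents[1], g)


class TestQ90:
    def test_degenerate_half(self):
        # every SNP at exact 0.5 major allele frequency
        pop = _pop([[CALL_A, CALL_B, CALL_A, CALL_B]] * 5)
        assert gpav.population_q90(pop) == 0.5

    def test_percentile_convention(self):
        # frequencies 0.5, 0.52, ..., 0.70 over 50 progeny
        rows = []
        for f in np.linspace(0.5, 0.7, 11):
            k = int(round(f * 50))
            rows.append([CALL_A] * k + [CALL_B] * (50 - k))
        pop = _pop(rows)
        assert gpav.population_q90(pop) == pytest.approx(0.68)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [[CALL_A] * k + [CALL_B] * (30 - k) for k in rng.integers(10, 21, 40)]
        pop = _pop(rows)
        shuffled = _pop([rows[i] for i in rng.permutation(len(rows))])
        assert gpav.population_q90(pop) == gpav.population_q90(shuffled)

    def test_no_fully_observed_snp_errors(self):
        pop = _pop([[CALL_A, CALL_MISSING, CALL_B]])
        with pytest.raises(ValueError, match="fully-observed"):
            gpav.population_q90(pop)


class TestCategories:
    @pytest.mark.parametrize(
        "m, q90, expected",
        [(0.0, 0.6, "A"), (1.0, 0.6, "C"), (0.5, 0.6, "B"), (0.39, 0.6, "A"), (0.61, 0.6, "C")],
    )
    def test_corrected_bounds(self, m, q90, expected):
        assert gpav.categorize_snp(m, q90) == expected

    def test_monotone_in_missingness(self):
        order = {"A": 0, "B": 1, "C": 2}
        cats = [order[gpav.categorize_snp(m, 0.62)] for m in np.linspace(0, 1, 101)]
        assert cats == sorted(cats)

    def test_strict_literal_flag_uses_printed_bounds(self):
        # printed order: A: [0, Q90), B: [Q90, 1-Q90], C: (1-Q90, 1]
        assert gpav.categorize_snp(0.55, 0.6, strict_literal=True) == "A"
        assert gpav.categorize_snp(0.65, 0.6, strict_literal=True) == "C"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gpav.categorize_snp(1.2, 0.6)
        with pytest.raises(ValueError):
            gpav.categorize_snp(0.5, 0.4)


class TestParentalCalls:
    def _calls(self, cats):
        series = [pd.Series([c], index=["s0"]) for c in cats]
        return gpav.assign_parental_calls({"p": series}).calls.at["s0", "p"]

    @pytest.mark.parametrize(
        "cats, expected",
        [
            (["B", "C", "B", "C"], PARENT_ABSENT),
            (["A", "A", "B"], PARENT_PRESENT),
            (["A", "C", "A"], PARENT_UNDETERMINED),
            (["B", "B"], PARENT_UNDETERMINED),
            (["C"], PARENT_ABSENT),
            (["A"], PARENT_PRESENT),
        ],
    )
    def test_assignment_rules(self, cats, expected):
        assert self._calls(cats) == expected

    def test_parent_without_populations_errors(self):
        with pytest.raises(ValueError, match="populations"):
            gpav.assign_parental_calls({"p": []})


def test_gpav_snp_designation():
    calls = gpav.ParentalPACalls(
        pd.DataFrame(
            {
                "p1": [PARENT_PRESENT, PARENT_PRESENT, PARENT_UNDETERMINED],
                "p2": [PARENT_ABSENT, PARENT_PRESENT, PARENT_UNDETERMINED],
            },
            index=["s0", "s1", "s2"],
        )
    )
    assert gpav.designate_gpav_snp(calls) == {"s0"}


def test_genic_filter_boundaries():
    snp_table = pd.DataFrame(
        {"chrom": ["c1"] * 3, "pos": [150, 500, 150]}, index=["in_cds", "intron", "near_ins"]
    )
    anno = pd.DataFrame({"chrom": ["c1"], "cds_start": [100], "cds_end": [200]})
    # 31 bp away: kept; strictly within 30 bp: dropped
    far_ins = pd.DataFrame({"chrom": ["c1"], "pos": [181]})
    near_ins = pd.DataFrame({"chrom": ["c1"], "pos": [160]})
    assert gpav.filter_genic_pav_snp({"in_cds", "intron"}, snp_table, anno) == {"in_cds"}
    assert gpav.filter_genic_pav_snp({"in_cds"}, snp_table, anno, far_ins) == {"in_cds"}
    assert gpav.filter_genic_pav_snp({"near_ins"}, snp_table, anno, near_ins) == set()
    with pytest.raises(ValueError, match="annotation"):
        gpav.filter_genic_pav_snp({"in_cds"}, snp_table, pd.DataFrame())


class TestPowerReport:
    def _setup(self):
        gene_of = pd.Series({"s0": "g0", "s1": "g1", "s2": "g2", "s3": "g3"})
        consensus = PACallMatrix(
            pd.DataFrame(
                [[PRESENT, ABSENT]] * 4,
                index=["g0", "g1", "g2", "g3"],
                columns=["p1", "p2"],
            ),
            "consensus",
        )
        return gene_of, consensus

    def test_perfect_power(self):
        gene_of, consensus = self._setup()
        epav = EPAVSet({"g0", "g1"}, 1)
        rep = gpav.estimate_power_error(
            epav, consensus, {"s0", "s1"}, {"s0", "s1", "s2"}, gene_of
        )
        assert rep.power_1mb == 100.0

    def test_alpha_star_zero_when_no_epav_has_genic_snp(self):
        gene_of, consensus = self._setup()
        epav = EPAVSet({"gX"}, 1)  # not covered by any genic SNP
        rep = gpav.estimate_power_error(epav, consensus, {"s0"}, {"s0"}, gene_of)
        assert np.isnan(rep.alpha_star) or rep.alpha_star == 0.0

    def test_alpha_star_denominators(self):
        gene_of, consensus = self._setup()
        epav = EPAVSet({"g0", "g2", "g3"}, 1)  # g0 true gPAV; g2, g3 expression-only
        rep = gpav.estimate_power_error(
            epav, consensus, {"s0"}, {"s0", "s2", "s3"}, gene_of
        )
        assert rep.alpha_star == pytest.approx(100 * 2 / 3)
        literal = gpav.estimate_power_error(
            epav, consensus, {"s0"}, {"s0", "s2", "s3"}, gene_of, literal_denominator=True
        )
        assert literal.alpha_star == pytest.approx(100 * 2 / 3)

    def test_empty_pav_snp_set_errors(self):
        gene_of, consensus = self._setup()
        with pytest.raises(ValueError, match="empty"):
            gpav.estimate_power_error(EPAVSet(set(), 1), consensus, set(), {"s0"}, gene_of)


@pytest.mark.parametrize(
    "args, expected",
    [
        ((38_000, 0.10, 0.50), (3_800, 7_600)),
        ((1_000, 0.25, 0.5), (250, 500)),
        ((500, 0.2, 1.0), (100, 100)),
    ],
)
def test_extrapolation_arithmetic(args, expected):
    assert gpav.extrapolate_gpav_total(*args) == expected


def test_extrapolation_zero_power_rejected():
    with pytest.raises(ValueError, match="power"):
        gpav.extrapolate_gpav_total(1000, 0.1, 0.0)


# ---------------------------------------------------------------------------
# recovery on simulated populations
# ---------------------------------------------------------------------------


def test_exact_recovery_without_background_missingness():
    """With no background missingness and large populations, parental calls
    at SNPs in deleted genes match the truth wherever determined, and the
    all-B resolution recovers sole carriers."""
    from pavomics import SimConfig, simulate_panel, simulate_populations

    cfg = SimConfig(
        n_inbreds=10,
        n_genes=60,
        frac_gpav=0.3,
        frac_silenced=0.0,
        sharing=0.2,
        n_snps_array=80,
        n_snps_in_gpav=50,
        n_populations=20,
        progeny_range=(200, 200),
        background_missing_rate=0.0,
        library_size_reads=100_000,
        seed=21,
    )
    _, _, truth = simulate_panel(cfg)
    pops = simulate_populations(truth, cfg)
    calls = gpav.infer_parental_calls(pops, resolve_all_b=True).calls
    gene_of = truth.snp_table["gene_id"]
    mismatches = determined = 0
    for snp in calls.index:
        gene = gene_of[snp]
        if not gene:
            continue
        for parent in calls.columns:
            call = calls.at[snp, parent]
            if call == PARENT_UNDETERMINED:
                continue
            determined += 1
            true_absent = (gene, parent) in truth.gpav_genes
            if (call == PARENT_ABSENT) != true_absent:
                mismatches += 1
    assert determined > 0
    assert mismatches == 0


def test_alpha_star_tracks_silencing_fraction():
    """More transcriptional silencing inflates the empirical type-I error
    while the power against genic PAV-SNPs is unaffected."""
    from pavomics import (
        SimConfig,
        simulate_panel,
        simulate_populations,
    )
    from pavomics import pav_calling as pc

    alphas, powers = [], []
    for frac_sil in (0.0, 0.3):
        vals_a, vals_p = [], []
        for seed in range(3):
            cfg = SimConfig(
                n_genes=150,
                frac_gpav=0.2,
                frac_silenced=frac_sil,
                sharing=0.2,
                n_snps_array=200,
                n_snps_in_gpav=120,
                n_populations=45,
                progeny_range=(60, 60),
                background_missing_rate=0.0,
                library_size_reads=150_000,
                seed=100 + seed,
            )
            expr, anno, truth = simulate_panel(cfg)
            pops = simulate_populations(truth, cfg)
            calls = gpav.infer_parental_calls(pops, resolve_all_b=True)
            gsnps = gpav.designate_gpav_snp(calls)
            genic = {s for s in truth.snp_table.index if truth.snp_table.at[s, "gene_id"]}
            genic_pav = gpav.filter_genic_pav_snp(
                gsnps & genic, truth.snp_table, anno
            )
            if not genic_pav:
                continue
            consensus = pc.merge_tissues(
                [pc.call_tissue_pav(expr.fpkm[t], t) for t in expr.tissues]
            )
            epav = pc.designate_epav(consensus, 2)
            rep = gpav.estimate_power_error(
                epav, consensus, genic_pav, genic, truth.snp_table["gene_id"]
            )
            vals_a.append(rep.alpha_star)
            vals_p.append(rep.power_1mb)
        alphas.append(np.mean(vals_a))
        powers.append(np.mean(vals_p))
    assert alphas[1] > alphas[0]
    assert abs(powers[1] - powers[0]) < 25
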