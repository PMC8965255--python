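import numpy as np
import pandas as pd
import pytest

from isoqtl.genotypes import collapse_to_sdp
from isoqtl.qtl import (
    QtlPeak,
    ThresholdSet,
    bayes_credible_interval,
    classify_eqtl,
    covariate_scan,
    find_peak,
    genome_scan,
    lod_score,
    permutation_thresholds,
    QtlScan,
)
from isoqtl.simulate import SimulationConfig, simulate_ri_genotypes
from isoqtl.transcriptome import TranscriptModel

from test_genotypes import make_geno


class TestLodScore:
    def test_worked_example(self):
        # RSS0 = 5, RSS1 = 1 -> (4/2) log10(5) = 1.39794
        lod = lod_score(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1]))
        assert lod == pytest.approx(2 * np.log10(5.0), abs=1e-10)
        assert lod == pytest.approx(1.398, abs=5e-4)

    def test_constant_trait(self):
        assert lod_score(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.0

    def test_perfect_fit_capped(self):
        g = np.array([0, 0, 1, 1, 0, 1.0])
        assert lod_score(2 * g + 3, g) == 50.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            lod_score(np.arange(4.0), np.zeros(4))

    def test_closed_form_equivalence(self, rng):
        # regression-RSS route vs -(n/2) log10(1 - r^2)
        for _ in range(300):
            n = int(rng.integers(4, 40))
            g = rng.integers(0, 2, n).astype(float)
            if g.min() == g.max():
                continue
            y = rng.standard_normal(n) + g * rng.normal()
            r = np.corrcoef(y, g)[0, 1]
            closed = -(n / 2) * np.log10(1 - r * r)
            assert lod_score(y, g) == pytest.approx(closed, abs=1e-10)


class TestGenomeScan:
    def test_strain_intersection(self):
        g = make_geno([[0, 1], [1, 0], [0, 0], [1, 1]])
        trait = pd.Series([1.0, 2.0, 3.0], index=["S0", "S1", "S3"], name="t")
        scan = genome_scan(trait, g)
        assert scan.n_strains == 3

    def test_too_few_shared_strains(self):
        g = make_geno([[0], [1], [0]])
        trait = pd.Series([1.0], index=["S0"], name="t")
        with pytest.raises(ValueError, match="strains"):
            genome_scan(trait, g)

    def test_duplicate_markers_scanned_once_via_sdp(self, rng):
        A = rng.integers(0, 2, (10, 5))
        A = np.column_stack([A, A[:, 0]])  # duplicate of marker 0
        g = make_geno(A)
        sdp, mapping = collapse_to_sdp(g)
        trait = pd.Series(rng.standard_normal(10),
                          index=[f"S{i}" for i in range(10)], name="t")
        scan = genome_scan(trait, sdp)
        assert mapping["m5"] == "m0"
        assert "m5" not in set(scan.table["marker"])

    def test_permuted_trait_matches_null(self, rng):
        cfg = SimulationConfig(seed=2, n_chromosomes=10, markers_per_chromosome=10)
        g = simulate_ri_genotypes(cfg)
        sdp, _ = collapse_to_sdp(g)
        trait = pd.Series(rng.standard_normal(30), index=sdp.strain_ids, name="t")
        thr = permutation_thresholds(trait, sdp, n_perm=500, seed=1)
        # the observed max of a null trait should be a typical draw from the
        # permutation null: p not extreme
        scan = genome_scan(trait, sdp)
        p = thr.empirical_p(scan.max_lod)
        assert 0.001 < p <= 1.0


class TestThresholds:
    def test_p_floor(self):
        thr = ThresholdSet(np.linspace(0.1, 1.0, 100))
        assert thr.empirical_p(2.0) == pytest.approx(1 / 101)

    def test_quantile_monotonicity(self, rng):
        thr = ThresholdSet(rng.uniform(0, 5, 1000))
        assert thr.thresholds[0.63] <= thr.thresholds[0.05] <= thr.thresholds[0.01]

    def test_counts_ties_inclusively(self):
        thr = ThresholdSet(np.array([1.0] * 50 + [2.0] * 50))
        assert thr.empirical_p(2.0) == pytest.approx(51 / 101)

    def test_reproducible_under_seed(self):
        cfg = SimulationConfig(seed=4, n_chromosomes=5, markers_per_chromosome=5)
        g = simulate_ri_genotypes(cfg)
        trait = pd.Series(np.arange(30.0), index=g.strain_ids, name="t")
        a = permutation_thresholds(trait, g, n_perm=200, seed=9).maxima
        b = permutation_thresholds(trait, g, n_perm=200, seed=9).maxima
        np.testing.assert_array_equal(a, b)


def scan_from_lod(lods, positions=None, chrom="1"):
    n = len(lods)
    positions = positions or [10_000 * (i + 1) for i in range(n)]
    table = pd.DataFrame({
        "marker": [f"m{i}" for i in range(n)],
        "chromosome": [chrom] * n,
        "position": positions,
        "lod": lods,
    })
    return QtlScan("t", table)


def brute_force_ci(lods, positions, coverage=0.95):
    w = np.power(10.0, np.asarray(lods) - max(lods))
    w = w / w.sum()
    order = np.argsort(-np.asarray(lods), kind="stable")
    acc, chosen = 0.0, []
    for i in order:
        chosen.append(i)
        acc += w[i]
        if acc >= coverage:
            break
    lo, hi = min(chosen), max(chosen)
    lo = max(lo - 1, 0)
    hi = min(hi + 1, len(lods) - 1)
    return positions[lo], positions[hi]


class TestBayesCredibleInterval:
    def test_single_spike(self):
        scan = scan_from_lod([0.1, 0.1, 30.0, 0.1, 0.1])
        lo, hi = bayes_credible_interval(scan, "1")
        # the spike plus its flanking markers
        assert (lo, hi) == (20_000, 40_000)

    def test_flat_profile_spans_chromosome(self):
        scan = scan_from_lod([1.0] * 40)
        lo, hi = bayes_credible_interval(scan, "1")
        width = (hi - lo) / (40 * 10_000 - 10_000)
        assert width > 0.9

    def test_triangular_profile_matches_enumeration(self):
        lods = list(np.concatenate([np.linspace(0, 3, 6), np.linspace(3, 0, 6)[1:]]))
        scan = scan_from_lod(lods)
        positions = list(scan.table["position"])
        assert bayes_credible_interval(scan, "1") == brute_force_ci(lods, positions)

    def test_random_profiles_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            lods = rng.uniform(0, 6, n)
            scan = scan_from_lod(list(lods))
            positions = list(scan.table["position"])
            assert bayes_credible_interval(scan, "1") == brute_force_ci(
                list(lods), positions)


class TestCovariateScan:
    def test_covariate_marker_itself_zero(self, rng):
        cfg = SimulationConfig(seed=6, n_chromosomes=4, markers_per_chromosome=5)
        g = simulate_ri_genotypes(cfg)
        trait = pd.Series(rng.standard_normal(30), index=g.strain_ids, name="t")
        sdp, _ = collapse_to_sdp(g)
        cov = sdp.marker_ids[3]
        scan = covariate_scan(trait, sdp, cov)
        row = scan.table[scan.table["marker"] == cov]
        assert float(row["lod"].iloc[0]) == 0.0

    def test_independent_qtl_persists(self):
        # two unlinked planted QTL; conditioning on one leaves the other's peak
        rng = np.random.default_rng(8)
        n = 30
        A = rng.integers(0, 2, (n, 40))
        g = make_geno(A, chrom=[str(1 + j // 20) for j in range(40)])
        y = 1.5 * A[:, 5] + 1.5 * A[:, 25] + 0.5 * rng.standard_normal(n)
        trait = pd.Series(y, index=g.strain_ids, name="t")
        scan = covariate_scan(trait, g, "m5")
        peak = scan.peak()
        assert peak["marker"] == "m25"
        assert peak["lod"] > 3.0

    def test_linked_shadow_peak_vanishes(self):
        # two tightly linked markers tagging one QTL: conditioning on the
        # peak removes the linked signal
        rng = np.random.default_rng(9)
        n = 30
        a = rng.integers(0, 2, n)
        flip = rng.random(n) < 0.05
        b = np.where(flip, 1 - a, a)
        other = rng.integers(0, 2, (n, 10))
        A = np.column_stack([a, b, other])
        g = make_geno(A)
        y = 2.0 * a + 0.5 * rng.standard_normal(n)
        trait = pd.Series(y, index=g.strain_ids, name="t")
        plain = genome_scan(trait, g)
        lods = dict(zip(plain.table["marker"], plain.table["lod"]))
        assert lods["m1"] > 3.0  # shadow of the true QTL
        cond = covariate_scan(trait, g, "m0")
        clods = dict(zip(cond.table["marker"], cond.table["lod"]))
        assert clods["m1"] < 1.0


class TestClassifyEqtl:
    def make_peak(self, chrom, pos):
        return QtlPeak("t", "m", chrom, pos, 5.0, 0.001)

    def transcript(self, chrom="1", start=1_000_000, end=1_100_000):
        return TranscriptModel("tx", "g", chrom, "+", ((start, end),))

    def test_other_chromosome_distal(self):
        assert classify_eqtl(self.make_peak("2", 1_050_000),
                             self.transcript()) == "distal"

    def test_peak_in_gene_body_local(self):
        assert classify_eqtl(self.make_peak("1", 1_050_000),
                             self.transcript()) == "local"

    def test_window_boundary_inclusive(self):
        mid = (1_000_000 + 1_100_000) / 2
        at = self.make_peak("1", int(mid + 10_000_000))
        beyond = self.make_peak("1", int(mid + 10_000_001))
        assert classify_eqtl(at, self.transcript()) == "local"
        assert classify_eqtl(beyond, self.transcript()) == "distal"


class TestFindPeak:
    def test_peak_with_interval_and_tier(self, rng):
        cfg = SimulationConfig(seed=12, n_chromosomes=5,
                               markers_per_chromosome=4,
                               meiotic_recomb_fraction_per_interval=0.4,
                               planted_pqtl=[(10, 0.8)],
                               phenotype_within_sd=0.0)
        g = simulate_ri_genotypes(cfg)
        from isoqtl.simulate import simulate_phenotype
        phen = simulate_phenotype(g, cfg).strain_means
        phen.name = "p"
        sdp, _ = collapse_to_sdp(g)
        scan = genome_scan(phen, sdp)
        thr = permutation_thresholds(phen, sdp, n_perm=300, seed=0)
        peak = find_peak(scan, thr)
        assert peak.ci_lo <= peak.position <= peak.ci_hi
        assert 0 < peak.genomewide_p <= 1
        assert peak.tier in ("significant", "suggestive", "none")
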