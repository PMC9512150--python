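"""Variant-to-bin assignment, per-rank profiles, the quadratic fit and the
rank-group Mann-Whitney tests."""

import itertools

import numpy as np
import pytest

from rareburden import make_fixture
from rareburden.burden import (
    BIN_LABELS, BurdenCube, PerRankProfile, assign_variants, fit_quadratic,
    gene_region_bins, mann_whitney, per_rank_profile, rank_group_test,
)
from rareburden.exprprep import RankTable
from rareburden.phistat import compute_phi

from conftest import gene_frame, make_panel


def profile_of(mean_count):
    mean_count = np.asarray(mean_count, dtype=float)
    n = len(mean_count)
    return PerRankProfile(mean_count=mean_count,
                          n_genes=np.ones(n, dtype=int),
                          percentile=(np.arange(1, n + 1) - 0.5) / n)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

class TestAssignment:
    def test_tiny5_cis_profile(self):
        fx = make_fixture("tiny5")
        cube = assign_variants(fx.rare_set, fx.genes, mode="cis")
        prof = per_rank_profile(cube, fx.ranks)
        np.testing.assert_array_equal(prof.mean_count, fx.expected_cis_profile)

    def test_tiny5_distal_variant_in_u24(self):
        fx = make_fixture("tiny5")
        cube = assign_variants(fx.rare_set, fx.genes, mode="windows")
        by_bin = {b: int(cube.counts[:, :, k].sum())
                  for k, b in enumerate(cube.bins)}
        assert by_bin["U_0_2"] == 1
        assert by_bin["GENIC"] == 1
        assert by_bin["U_2_4"] == 1  # TSS-2100 is outside the cis region

    def test_minus_strand_upstream(self):
        # on a minus-strand gene the upstream windows sit past the end
        genes = gene_frame([dict(gene_id="g1", chrom="chr1", strand="-",
                                 start=5000, end=8000)])
        bins = dict((label, (lo, hi))
                    for label, lo, hi in gene_region_bins(genes.iloc[0]))
        assert bins["GENIC"] == (5000, 8000)
        assert bins["U_0_2"] == (8001, 10000)
        assert bins["U_2_4"] == (10001, 12000)

    def test_windows_partition_point_variants(self, planted_sim):
        """For point variants the window bins are disjoint: pooled counts
        equal the sum over all bins."""
        from rareburden.variantprep import select_rare_variants

        rare = select_rare_variants(planted_sim.variants)
        snps = rare.subset((rare.variants.sites.vclass == "SNP").to_numpy())
        cube = assign_variants(snps, planted_sim.genes, mode="windows")
        total_by_bin = cube.counts.sum(axis=2)
        pooled = cube.select(BIN_LABELS)
        np.testing.assert_array_equal(total_by_bin, pooled)
        # and every (variant, gene) pair lands in at most one bin
        assert cube.counts.max() >= 1

    def test_sv_can_span_bins(self):
        """An SV overlapping the gene boundary is counted in both GENIC and
        the adjacent upstream window."""
        from rareburden.formats import SamplePanel, VariantRecord, VariantTable
        from rareburden.variantprep import RareVariantSet

        panel = make_panel(2)
        genes = gene_frame([dict(gene_id="g1", chrom="chr1", strand="+",
                                 start=10000, end=12000)])
        rec = VariantRecord(variant_id="sv1", chrom="chr1", pos=9500,
                            end=10500, ref="N", alt="<DEL>", vclass="DEL",
                            length=1001,
                            genotypes=np.array([2, 0], dtype=np.int8))
        table = VariantTable.from_records([rec], panel)
        rare = RareVariantSet(table, np.array([0.01]), np.array([0.01]),
                              np.array([[True, False]]), 0.05)
        cube = assign_variants(rare, genes, mode="windows")
        k = {b: i for i, b in enumerate(cube.bins)}
        assert cube.counts[0, 0, k["GENIC"]] == 1
        assert cube.counts[0, 0, k["U_0_2"]] == 1


class TestProfile:
    def test_two_identical_genes_leave_means_unchanged(self):
        fx = make_fixture("tiny5")
        cube1 = assign_variants(fx.rare_set, fx.genes, mode="cis")
        counts2 = np.concatenate([cube1.counts, cube1.counts])
        cube2 = BurdenCube(["g1", "g2"], fx.panel, counts2, cube1.bins)
        ranks2 = RankTable(["g1", "g2"], fx.panel,
                           np.vstack([fx.ranks.ranks, fx.ranks.ranks]))
        prof = per_rank_profile(cube2, ranks2)
        np.testing.assert_array_equal(prof.mean_count, fx.expected_cis_profile)
        np.testing.assert_array_equal(prof.n_genes, 2)

    def test_no_variants_gives_zero_profile(self):
        fx = make_fixture("tiny5")
        cube = assign_variants(fx.rare_set, fx.genes, mode="cis")
        cube.counts[:] = 0
        prof = per_rank_profile(cube, fx.ranks)
        np.testing.assert_array_equal(prof.mean_count, np.zeros(5))

    def test_conservation_of_counts(self, planted_sim):
        """Sum over ranks of mean * n_genes equals the carrier events in
        the selected bins when every gene is ranked over the full panel."""
        from rareburden.exprprep import mean_expression, rank_samples
        from rareburden.variantprep import select_rare_variants

        rare = select_rare_variants(planted_sim.variants)
        mat = planted_sim.expression["wet"]
        ranks = rank_samples(mean_expression(mat), mat.genes, mat.panel)
        cube = assign_variants(rare, planted_sim.genes, mode="cis")
        prof = per_rank_profile(cube, ranks)
        total_events = cube.select(cube.bins)[
            [cube.genes.index(g) for g in ranks.genes]].sum()
        assert np.sum(prof.mean_count * prof.n_genes) == pytest.approx(
            total_events)


# ---------------------------------------------------------------------------
# quadratic fit
# ---------------------------------------------------------------------------

class TestQuadraticFit:
    def test_exact_symmetric_parabola(self):
        prof = PerRankProfile(
            mean_count=np.array([4.0, 1, 0, 1, 4]),
            n_genes=np.ones(5, dtype=int),
            percentile=np.array([0.1, 0.3, 0.5, 0.7, 0.9]))
        fit = fit_quadratic(prof)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.c > 0 and fit.convex
        # y = 25(x - 0.5)^2 exactly
        assert fit.c == pytest.approx(25.0)
        assert fit.b == pytest.approx(-25.0)
        assert fit.a == pytest.approx(6.25)

    def test_constant_profile(self):
        fit = fit_quadratic(profile_of([2.0] * 10))
        assert fit.c == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            y = rng.normal(size=n)
            prof = profile_of(y)
            fit = fit_quadratic(prof)
            x = prof.percentile
            X = np.column_stack([np.ones(n), x, x * x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose([fit.a, fit.b, fit.c], beta,
                                       rtol=1e-10, atol=1e-10)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_quadratic(profile_of([1.0, 2.0, 3.0]))


# ---------------------------------------------------------------------------
# Mann-Whitney rank-group tests
# ---------------------------------------------------------------------------

def brute_force_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if a > b else (0.5 if a == b else 0.0)
                   for a in xs for b in ys)

    u_obs = u_stat(x, y)
    center = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_matches_exact_enumeration(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            n1, n2 = rng.integers(3, 8, size=2)
            pooled = rng.permutation(20)[: n1 + n2].astype(float)
            x, y = pooled[:n1], pooled[n1:]
            u, p, method = mann_whitney(x, y)
            assert method == "exact"
            assert p == pytest.approx(brute_force_mw_p(x, y))

    def test_separated_groups_significant(self):
        prof = profile_of([10.0 + i * 0.01 for i in range(13)]
                          + [0.0 + i * 0.01 for i in range(13)])
        # build explicit groups: high all ~10, mid all ~0
        u, p, _ = mann_whitney(prof.mean_count[:13], prof.mean_count[13:])
        assert p < 0.001

    def test_identical_groups(self):
        u, p, _ = mann_whitney([5.0] * 6, [5.0] * 6)
        assert u == pytest.approx(18.0)  # n^2/2
        assert p == pytest.approx(1.0)


class TestRankGroupTest:
    def test_u_shaped_profile_detected(self):
        x = (np.arange(1, 101) - 0.5) / 100
        prof = profile_of(3 * (x - 0.5) ** 2)
        results = {t.label: t for t in rank_group_test(prof)}
        assert results["high_vs_mid"].p < 1e-6
        assert results["low_vs_mid"].p < 1e-6
        assert results["high_vs_mid"].n1 == 20
        assert results["high_vs_mid"].n2 == 20

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            rank_group_test(profile_of([1.0, 2.0, 3.0, 4.0]))
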