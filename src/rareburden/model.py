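"""Model/results interface to the rare-allele burden analysis.

:class:`RareBurdenModel` bundles the three prepared inputs — a rare-variant
catalog, gene models and per-gene expression ranks for one condition — and
``fit()`` runs the core analysis: the per-rank burden profile, its quadratic
fit, the extreme-vs-middle rank-group tests, and the φ = E_r/M_r statistic.
Results objects can be compared across strata or conditions by Fisher's
exact test on the extreme/middle counts or by the within-gene permutation
test.

    >>> sim = simulate(SimConfig(seed=1))
    >>> model = RareBurdenModel.from_simulation(sim, "wet")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import exprprep, variantprep
from .burden import (
    CIS_BINS, BurdenCube, PerRankProfile, QuadFit, RankGroupTest,
    assign_variants, fit_quadratic, per_rank_profile, rank_group_test,
)
from .exprprep import RankTable
from .formats import ExpressionMatrix, VariantTable
from .phistat import (
    PhiResult, StratumComparison, compute_phi, fisher_compare,
    permutation_test_phi,
)
from .variantprep import RareVariantSet


class RareBurdenModel:
    """Rare-variant burden vs expression-rank model for one condition.

    Parameters
    ----------
    rare_set : RareVariantSet
        The population rare-variant catalog (carriers of the minor allele).
    genes : pandas.DataFrame
        Gene table (1-based inclusive coordinates, strand-aware TSS).
    ranks : RankTable
        Per-gene expression ranks of the panel for this condition.
    mode : {"cis", "windows"}
        Region assignment: gene body + 0-2 kb upstream (the headline
        analysis), or all upstream distance windows.
    bins : tuple of str
        Bins pooled when profiling and computing φ (defaults to the cis
        set).
    """

    def __init__(self, rare_set: RareVariantSet, genes: pd.DataFrame,
                 ranks: RankTable, mode: str = "cis", bins=CIS_BINS,
                 condition: str = ""):
        self.rare_set = rare_set
        self.genes = genes.reset_index(drop=True)
        self.ranks = ranks
        self.mode = mode
        self.bins = tuple(bins)
        self.condition = condition or "unlabelled"
        self._cube: BurdenCube | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_tables(cls, variants: VariantTable, genes: pd.DataFrame,
                    expression: ExpressionMatrix, maf_threshold: float = 0.05,
                    apply_quality_filters: bool = True,
                    min_fraction: float = 0.85, mode: str = "cis",
                    bins=CIS_BINS) -> "RareBurdenModel":
        """Build from raw inputs, running variant and expression prep.

        Applies the hard quality filters (optionally), selects rare
        variants at the folded-MAF threshold with the class evidence rules,
        keeps robustly expressed genes, averages replicates and ranks
        samples per gene.
        """
        if apply_quality_filters:
            variants = variantprep.apply_hard_filters(variants)
        rare = variantprep.select_rare_variants(variants, maf_threshold)
        robust = set(exprprep.robust_gene_filter(expression,
                                                 min_fraction=min_fraction))
        keep = [g for g in expression.genes if g in robust]
        expr = expression.subset_genes(keep)
        means = exprprep.mean_expression(expr)
        ranks = exprprep.rank_samples(means, expr.genes, expr.panel)
        genes = genes[genes.gene_id.isin(ranks.genes)].reset_index(drop=True)
        return cls(rare, genes, ranks, mode=mode, bins=bins,
                   condition=expression.condition)

    @classmethod
    def from_files(cls, vcf_path, gene_path, expression_path, condition: str,
                   metadata_path=None, site_scores_path=None,
                   **kwargs) -> "RareBurdenModel":
        """Build from the external file formats (VCF, GFF3/BED, TSV)."""
        from . import formats

        variants = formats.read_vcf(vcf_path)
        genes = formats.read_gene_models(gene_path)
        if metadata_path is not None:
            genes = formats.attach_gene_metadata(genes, metadata_path)
        if site_scores_path is not None:
            scores = formats.read_site_scores(site_scores_path)
            formats.attach_site_scores(variants, scores)
        expression = formats.read_expression(expression_path, condition)
        return cls.from_tables(variants, genes, expression, **kwargs)

    @classmethod
    def from_simulation(cls, sim, condition: str,
                        **kwargs) -> "RareBurdenModel":
        """Build from an in-memory :class:`~rareburden.synthio.SimData`."""
        return cls.from_tables(sim.variants, sim.genes,
                               sim.expression[condition], **kwargs)

    # -- fitting -----------------------------------------------------------

    @property
    def cube(self) -> BurdenCube:
        """The (gene, sample, bin) carrier-count cube (computed lazily)."""
        if self._cube is None:
            self._cube = assign_variants(self.rare_set, self.genes,
                                         mode=self.mode)
        return self._cube

    def fit(self) -> "RareBurdenResults":
        """Run the burden analysis and return the results object."""
        profile = per_rank_profile(self.cube, self.ranks, bins=self.bins)
        quad = fit_quadratic(profile)
        tests = (rank_group_test(profile) if profile.n_ranks >= 15 else [])
        phi = compute_phi(self.cube, self.ranks, bins=self.bins,
                          label=self.condition)
        return RareBurdenResults(model=self, profile=profile, quad=quad,
                                 group_tests=tests, phi_result=phi)


@dataclass
class RareBurdenResults:
    """Fitted burden profile, quadratic curve, rank-group tests and φ."""

    model: RareBurdenModel
    profile: PerRankProfile
    quad: QuadFit
    group_tests: list[RankGroupTest]
    phi_result: PhiResult

    # -- headline quantities ----------------------------------------------

    @property
    def params(self) -> np.ndarray:
        """Quadratic coefficients (intercept, linear, quadratic)."""
        return np.array([self.quad.a, self.quad.b, self.quad.c])

    @property
    def rsquared(self) -> float:
        return self.quad.r2

    @property
    def f_pvalue(self) -> float:
        return self.quad.p

    @property
    def phi(self) -> float:
        return self.phi_result.phi

    @property
    def e_r(self) -> int:
        return self.phi_result.e_r

    @property
    def m_r(self) -> int:
        return self.phi_result.m_r

    # -- comparisons -------------------------------------------------------

    def compare(self, other: "RareBurdenResults") -> StratumComparison:
        """Fisher's exact comparison of the extreme/middle count tables."""
        return fisher_compare(self.phi_result, other.phi_result)

    def permutation_test(self, other: "RareBurdenResults",
                         n_perm: int = 1000, seed: int | None = None) -> float:
        """Within-gene permutation test of Δφ against ``other``."""
        return permutation_test_phi(
            self.model.cube, self.model.ranks,
            other.model.cube, other.model.ranks,
            n_perm=n_perm, seed=seed, bins=self.model.bins)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        """Human-readable summary table."""
        m = self.model
        lines = [
            "Rare-allele burden analysis",
            "=" * 46,
            f"condition:          {m.condition}",
            f"region bins:        {' + '.join(m.bins)} ({m.mode} mode)",
            f"genes analysed:     {len(m.ranks)}",
            f"rare variants:      {len(m.rare_set)}",
            f"samples:            {len(m.ranks.panel)}",
            "-" * 46,
            "quadratic fit  mean count ~ a + b*x + c*x^2",
            f"  a (intercept):    {self.quad.a: .4f}",
            f"  b (linear):       {self.quad.b: .4f}",
            f"  c (quadratic):    {self.quad.c: .4f}"
            f"   {'convex (U-shaped)' if self.quad.convex else 'not convex'}",
            f"  r^2:              {self.quad.r2: .4f}",
            f"  F-test p:         {self.quad.p: .3g}",
        ]
        for t in self.group_tests:
            lines.append(f"  MW {t.label:<12}  U = {t.u:.1f}, p = {t.p:.3g} "
                         f"({t.method})")
        lines += [
            "-" * 46,
            f"extreme counts E_r: {self.e_r}",
            f"middle counts  M_r: {self.m_r}",
            f"phi = E_r/M_r:      {self.phi:.4f}",
        ]
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Plot the per-rank profile with the fitted quadratic curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.profile.percentile, self.profile.mean_count, s=8,
                   alpha=0.6, label="per-rank mean")
        xs = np.linspace(0, 1, 200)
        ax.plot(xs, self.quad.predict(xs), color="C3",
                label=f"quadratic (r$^2$={self.quad.r2:.2f})")
        ax.set_xlabel("expression rank percentile")
        ax.set_ylabel("mean rare variants per rank")
        ax.set_title(f"rare-variant burden ({self.model.condition})")
        ax.legend()
        return ax
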