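"""Variant-to-gene assignment, per-rank burden profiles, the quadratic fit
and rank-group tests.

A rare variant is assigned to a gene's region bin — the gene body (GENIC) or
one of the strand-aware upstream distance windows (0-2 kb, 2-4 kb, ...,
>20 kb from the TSS) — and every carrier of the minor allele contributes one
count to that (gene, sample, bin) cell.  Summarising the counts along each
gene's expression ranks gives the per-rank profile whose U-shape is the
signature of rare-variant burden at expression extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .exprprep import RankTable
from .formats import BND, INDEL, SNP
from .variantprep import RareVariantSet

#: region-bin labels, gene body first, then upstream windows (kb from TSS)
BIN_LABELS = (
    "GENIC", "U_0_2", "U_2_4", "U_4_6", "U_6_8", "U_8_10", "U_10_12",
    "U_12_14", "U_14_16", "U_16_18", "U_18_20", "U_GT20",
)
#: upstream window bounds in bp, aligned with BIN_LABELS[1:]; the most
#: distal (>20 kb) window is capped at 100 kb to bound the search.
UPSTREAM_BOUNDS = [(0, 2000), (2000, 4000), (4000, 6000), (6000, 8000),
                   (8000, 10000), (10000, 12000), (12000, 14000),
                   (14000, 16000), (16000, 18000), (18000, 20000),
                   (20000, 100000)]

CIS_BINS = ("GENIC", "U_0_2")  # the headline analysis region
POINT_CLASSES = frozenset({SNP, INDEL, BND})


class BurdenCube:
    """Rare-variant carrier counts indexed by (gene, sample, region bin)."""

    def __init__(self, genes, panel, counts: np.ndarray,
                 bins: tuple[str, ...] = BIN_LABELS):
        self.genes = list(genes)
        self.panel = panel
        self.bins = tuple(bins)
        counts = np.asarray(counts)
        if counts.shape != (len(self.genes), len(panel), len(self.bins)):
            raise ValueError(f"counts shape {counts.shape} mismatch")
        self.counts = counts

    def select(self, bins) -> np.ndarray:
        """Sum counts over a set of bins -> (n_genes, n_samples)."""
        idx = [self.bins.index(b) for b in bins]
        return self.counts[:, :, idx].sum(axis=2)

    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Long format (gene_id, sample, bin, count), nonzero cells only."""
        g, s, b = np.nonzero(self.counts)
        return pd.DataFrame({
            "gene_id": [self.genes[i] for i in g],
            "sample": [self.panel.samples[j] for j in s],
            "bin": [self.bins[k] for k in b],
            "count": self.counts[g, s, b],
        })


def gene_region_bins(gene_row) -> list[tuple[str, int, int]]:
    """Absolute (label, lo, hi) 1-based inclusive intervals for one gene.

    Upstream windows are measured from the strand-aware TSS, extend away
    from the gene, and are not truncated at neighbouring genes.
    """
    out = [("GENIC", int(gene_row.start), int(gene_row.end))]
    tss = int(gene_row.tss)
    for (d_lo, d_hi), label in zip(UPSTREAM_BOUNDS, BIN_LABELS[1:]):
        if gene_row.strand == "+":
            lo, hi = tss - d_hi, tss - d_lo - 1
        else:
            lo, hi = tss + d_lo + 1, tss + d_hi
        if lo <= hi:
            out.append((label, lo, hi))
    return out


def assign_variants(rare_set: RareVariantSet, genes: pd.DataFrame,
                    mode: str = "cis", dosage_weighted: bool = False,
                    sv_overlap: bool = True) -> BurdenCube:
    """Assign rare variants to gene region bins and count carriers.

    ``mode="cis"`` restricts to the gene body plus the 0-2 kb upstream
    window; ``mode="windows"`` uses all bins.  SNPs, indels and breakends
    are assigned by position; SVs by any overlap of their [pos, end]
    interval (so one SV can hit several bins or genes), unless
    ``sv_overlap=False`` which falls back to start-position assignment.
    Each carrier of the minor allele contributes +1 per assigned
    (variant, bin); with ``dosage_weighted=True`` the contribution is the
    minor-allele dosage instead.
    """
    if mode == "cis":
        bins = CIS_BINS
    elif mode == "windows":
        bins = BIN_LABELS
    else:
        raise ValueError(f"mode must be 'cis' or 'windows', got {mode!r}")
    bin_index = {b: k for k, b in enumerate(bins)}

    trees: dict[str, IntervalTree] = {}
    for gi, row in genes.iterrows():
        tree = trees.setdefault(str(row.chrom), IntervalTree())
        for label, lo, hi in gene_region_bins(row):
            if label in bin_index:
                # intervaltree is half-open; [lo, hi] inclusive -> [lo, hi+1)
                tree.addi(lo, hi + 1, (gi, bin_index[label]))

    sites = rare_set.variants.sites
    if dosage_weighted:
        _, dosage = _carrier_dosage(rare_set)
        weights = dosage
    else:
        weights = rare_set.carriers.astype(np.int64)

    counts = np.zeros((len(genes), len(rare_set.panel), len(bins)), dtype=np.int64)
    chroms = sites.chrom.to_numpy()
    pos = sites.pos.to_numpy()
    end = sites.end.to_numpy()
    vclass = sites.vclass.to_numpy()
    for i in range(len(sites)):
        tree = trees.get(str(chroms[i]))
        if tree is None:
            continue
        if vclass[i] in POINT_CLASSES or not sv_overlap:
            hits = tree.at(int(pos[i]))
        else:
            hits = tree.overlap(int(pos[i]), int(end[i]) + 1)
        seen = set()
        for iv in hits:
            key = iv.data
            if key in seen:
                continue  # an SV spanning several intervals of one bin counts once
            seen.add(key)
            gi, bi = key
            counts[gi, :, bi] += weights[i]
    return BurdenCube(genes.gene_id.tolist(), rare_set.panel, counts, bins)


def _carrier_dosage(rare_set: RareVariantSet) -> tuple[np.ndarray, np.ndarray]:
    from .variantprep import minor_allele_carriers

    return minor_allele_carriers(rare_set.variants, rare_set.alt_freq)


# ---------------------------------------------------------------------------
# per-rank profile
# ---------------------------------------------------------------------------

@dataclass
class PerRankProfile:
    """Mean rare-variant count of the sample at each expression rank.

    ``mean_count[r-1]`` is the mean, over contributing genes, of the burden
    count of the sample holding rank ``r``; ``percentile`` is the rank
    midpoint (r - 0.5)/N on the full panel.
    """

    mean_count: np.ndarray
    n_genes: np.ndarray
    percentile: np.ndarray

    @property
    def n_ranks(self) -> int:
        return len(self.mean_count)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, self.n_ranks + 1),
            "percentile": self.percentile,
            "mean_count": self.mean_count,
            "n_genes": self.n_genes,
        })


def per_rank_profile(cube: BurdenCube, ranks: RankTable,
                     bins=CIS_BINS) -> PerRankProfile:
    """Summarise burden counts along expression ranks.

    Genes ranked over the full panel map rank r directly to slot r; genes
    with fewer ranked samples are mapped through their percentile, binned
    into N equal slots, so panels with patchy expression still contribute.
    """
    common = [g for g in ranks.genes if g in set(cube.genes)]
    if not common:
        raise ValueError("no genes shared between burden cube and rank table")
    cube_idx = {g: i for i, g in enumerate(cube.genes)}
    rank_idx = {g: i for i, g in enumerate(ranks.genes)}
    N = len(ranks.panel)
    counts = cube.select(bins)
    total = np.zeros(N)
    n_genes = np.zeros(N, dtype=np.int64)
    for g in common:
        ci, ri = cube_idx[g], rank_idx[g]
        valid = np.flatnonzero(~np.isnan(ranks.ranks[ri]))
        if ranks.n_g[ri] == N:
            slots = ranks.ranks[ri, valid].astype(int) - 1
        else:
            slots = np.minimum((ranks.percentile[ri, valid] * N).astype(int), N - 1)
        np.add.at(total, slots, counts[ci, valid])
        n_genes[np.unique(slots)] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_genes > 0, total / n_genes, 0.0)
    percentile = (np.arange(1, N + 1) - 0.5) / N
    return PerRankProfile(mean_count=mean, n_genes=n_genes, percentile=percentile)


# ---------------------------------------------------------------------------
# quadratic fit and rank-group tests
# ---------------------------------------------------------------------------

@dataclass
class QuadFit:
    """OLS fit of mean count on (percentile, percentile^2)."""

    a: float  # intercept
    b: float  # linear coefficient
    c: float  # quadratic coefficient (c > 0: convex, U-shaped)
    r2: float
    p: float  # overall F-test p-value

    @property
    def convex(self) -> bool:
        return self.c > 0

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b * x + self.c * x * x


def fit_quadratic(profile: PerRankProfile) -> QuadFit:
    """Least-squares quadratic in rank percentile, with the model F-test.

    Requires at least 4 rank points and a non-degenerate design (the rank
    percentiles are distinct by construction).
    """
    import statsmodels.api as sm

    x = np.asarray(profile.percentile, dtype=float)
    y = np.asarray(profile.mean_count, dtype=float)
    if len(x) < 4:
        raise ValueError("quadratic fit needs at least 4 rank points")
    if np.ptp(x) == 0:
        raise ValueError("singular design: all percentiles equal")
    if np.ptp(y) == 0:
        # a flat profile carries no curvature and explains nothing
        return QuadFit(a=float(y[0]), b=0.0, c=0.0, r2=0.0, p=1.0)
    X = sm.add_constant(np.column_stack([x, x * x]))
    res = sm.OLS(y, X).fit()
    return QuadFit(a=float(res.params[0]), b=float(res.params[1]),
                   c=float(res.params[2]), r2=float(res.rsquared),
                   p=float(res.f_pvalue))


@dataclass
class RankGroupTest:
    """Mann-Whitney comparison of per-rank means between two rank classes."""

    label: str
    u: float
    p: float
    n1: int
    n2: int
    method: str


def _percentile_group(profile: PerRankProfile, interval) -> np.ndarray:
    lo, hi = interval
    mask = (profile.percentile >= lo) & (profile.percentile < hi)
    if hi >= 1.0:  # top class is closed at 1 (the last rank belongs to it)
        mask |= profile.percentile >= hi
    return profile.mean_count[mask]


def mann_whitney(x, y, exact_max: int = 8) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U.

    Exact null enumeration when both groups have <= ``exact_max``
    observations and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    if len(x) <= exact_max and len(y) <= exact_max and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def rank_group_test(profile: PerRankProfile, low=(0.0, 0.20),
                    mid=(0.40, 0.60), high=(0.80, 1.0)) -> list[RankGroupTest]:
    """Compare the extreme 20% rank classes to the middle 40-60% class.

    Returns the high-vs-middle and low-vs-middle Mann-Whitney tests on the
    per-rank mean counts.  Group membership is by half-open percentile
    interval [lo, hi); the top class additionally absorbs percentile = hi
    and above so the last rank is never orphaned.
    """
    groups = {name: _percentile_group(profile, iv)
              for name, iv in (("low", low), ("mid", mid), ("high", high))}
    for name, vals in groups.items():
        if len(vals) == 0:
            raise ValueError(f"empty {name} rank group; need >= 15 ranks")
    out = []
    for label, a, b in (("high_vs_mid", groups["high"], groups["mid"]),
                        ("low_vs_mid", groups["low"], groups["mid"])):
        u, p, method = mann_whitney(a, b)
        out.append(RankGroupTest(label=label, u=u, p=p,
                                 n1=len(a), n2=len(b), method=method))
    return out
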