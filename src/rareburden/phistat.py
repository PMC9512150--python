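"""The extreme-to-middle burden ratio φ = E_r / M_r and its tests.

E_r totals rare-variant carrier counts over (gene, sample) pairs whose
expression rank falls in the extreme classes (bottom 10% or top 10% of
ranks); M_r totals the middle class (40-60%).  The two classes span equal
rank mass, so exchangeable counts give φ ≈ 1 and outlier enrichment pushes
φ above 1.  Two φ values are compared either by Fisher's exact test on the
2×2 table [[E_A, M_A], [E_B, M_B]] — whose sample odds ratio is exactly
φ_A/φ_B — or by a within-gene permutation test that breaks the
genotype-expression link while preserving both marginal structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .burden import CIS_BINS, BurdenCube
from .exprprep import RankTable

EXTREME_CUTS = (0.10, 0.90)
MIDDLE_CUTS = (0.40, 0.60)


@dataclass
class PhiResult:
    """φ with its component extreme/middle carrier totals."""

    e_r: int
    m_r: int
    extreme: tuple[float, float] = EXTREME_CUTS
    middle: tuple[float, float] = MIDDLE_CUTS
    label: str = ""

    @property
    def phi(self) -> float:
        """E_r/M_r; NaN (undefined) when the middle class is empty."""
        if self.m_r == 0:
            return float("nan")
        return self.e_r / self.m_r

    @property
    def defined(self) -> bool:
        return self.m_r > 0


def relative_increase(phi_a: float, phi_b: float) -> float:
    """Fractional increase of ``phi_a`` over ``phi_b`` (e.g. dry over wet)."""
    return phi_a / phi_b - 1.0


def _aligned(cube: BurdenCube, ranks: RankTable, bins):
    """Counts, rank matrix and per-gene rank totals over shared genes."""
    cube_idx = {g: i for i, g in enumerate(cube.genes)}
    common = [g for g in ranks.genes if g in cube_idx]
    if not common:
        raise ValueError("no genes shared between burden cube and rank table")
    rank_idx = {g: i for i, g in enumerate(ranks.genes)}
    ci = [cube_idx[g] for g in common]
    ri = [rank_idx[g] for g in common]
    counts = cube.select(bins)[ci]
    return counts, ranks.ranks[ri], ranks.n_g[ri]


def _masks(rank_matrix: np.ndarray, n_g: np.ndarray,
           extreme=EXTREME_CUTS, middle=MIDDLE_CUTS):
    """Boolean extreme/middle membership per (gene, sample).

    Class sizes are fixed per gene by rounding the nominal percentile mass
    to whole ranks: the lowest round(lo_cut*n) and highest
    round((1-hi_cut)*n) ranks are extreme, and the middle class is the
    centered block of round((mid_hi-mid_lo)*n) ranks.  With the default
    10% tails and 40-60% middle the two classes then span exactly equal
    rank mass for every n, so exchangeable counts give phi = 1 in
    expectation.
    """
    lo_cut, hi_cut = extreme
    mid_lo, mid_hi = middle
    n_g = np.asarray(n_g, dtype=float)

    def nearest(x):
        # round half up, stabilized against float representation error so
        # the low and high tails are always symmetric
        return np.floor(x + 0.5 + 1e-9)

    n_low = nearest(lo_cut * n_g)
    n_high = nearest((1.0 - hi_cut) * n_g)
    n_mid = nearest((mid_hi - mid_lo) * n_g)
    mid_start = np.floor((n_g - n_mid) / 2.0)
    r = rank_matrix
    with np.errstate(invalid="ignore"):
        ext = (r <= n_low[:, None]) | (r > (n_g - n_high)[:, None])
        mid = (r > mid_start[:, None]) & (r <= (mid_start + n_mid)[:, None])
    valid = ~np.isnan(r)
    return ext & valid, mid & valid


def compute_phi(cube: BurdenCube, ranks: RankTable, bins=CIS_BINS,
                extreme=EXTREME_CUTS, middle=MIDDLE_CUTS,
                label: str = "") -> PhiResult:
    """Total carrier counts in the extreme vs middle rank classes.

    The extreme class holds the lowest and highest 10% of each gene's
    ranks and the middle class the centered 40-60% block, with the
    percentile masses rounded to whole ranks per gene so both classes span
    exactly equal rank mass (see :func:`_masks`); disjoint by construction.
    """
    counts, rank_matrix, n_g = _aligned(cube, ranks, bins)
    ext, mid = _masks(rank_matrix, n_g, extreme, middle)
    return PhiResult(e_r=int(counts[ext].sum()), m_r=int(counts[mid].sum()),
                     extreme=extreme, middle=middle, label=label)


# ---------------------------------------------------------------------------
# Fisher contingency comparison of two strata
# ---------------------------------------------------------------------------

@dataclass
class StratumComparison:
    """2×2 contingency comparison of two φ values.

    ``odds_ratio = (E_A · M_B) / (M_A · E_B)`` equals φ_A/φ_B exactly;
    ``fisher_p`` is the two-sided Fisher exact p (summation of all tables
    with point probability <= that observed).
    """

    a: PhiResult
    b: PhiResult
    odds_ratio: float = field(init=False)
    fisher_p: float = field(init=False)

    def __post_init__(self) -> None:
        table = self.table
        if any(sum(row) == 0 for row in table) or any(
                table[0][j] + table[1][j] == 0 for j in (0, 1)):
            raise ValueError("zero margin in contingency table")
        e_a, m_a = table[0]
        e_b, m_b = table[1]
        self.odds_ratio = (e_a * m_b) / (m_a * e_b) if m_a * e_b else float("inf")
        _, self.fisher_p = stats.fisher_exact(table, alternative="two-sided")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a.e_r, self.a.m_r], [self.b.e_r, self.b.m_r]]


def fisher_compare(phi_a: PhiResult, phi_b: PhiResult) -> StratumComparison:
    """Fisher's exact comparison of two extreme/middle count tables."""
    return StratumComparison(a=phi_a, b=phi_b)


# ---------------------------------------------------------------------------
# permutation test for a difference in φ
# ---------------------------------------------------------------------------

def _phi_from(counts: np.ndarray, ext: np.ndarray, mid: np.ndarray) -> float:
    m = counts[mid].sum()
    return counts[ext].sum() / m if m else float("nan")


def _permuted_rows(rng, counts: np.ndarray, valid_lists) -> np.ndarray:
    """Independently permute each row of ``counts`` among its valid columns."""
    if valid_lists is None:  # every gene ranked over the full panel
        return rng.permuted(counts, axis=1)
    out = counts.copy()
    for i, valid in enumerate(valid_lists):
        out[i, valid] = counts[i, valid[rng.permutation(len(valid))]]
    return out


def permutation_test_phi(cube_a: BurdenCube, ranks_a: RankTable,
                         cube_b: BurdenCube, ranks_b: RankTable,
                         n_perm: int = 1000, seed: int | None = None,
                         bins=CIS_BINS, extreme=EXTREME_CUTS,
                         middle=MIDDLE_CUTS,
                         return_trace: bool = False):
    """Permutation test of Δφ = φ_A - φ_B between two datasets.

    The null is built by independently permuting, within every gene of both
    datasets, the sample-to-rank assignment (equivalently, the burden
    counts among that gene's ranked samples), recomputing Δφ each time.
    The p-value uses the add-one correction
    p = (1 + #{|Δφ_perm| >= |Δφ_obs|}) / (n_perm + 1), so it is never zero
    and the test is exchangeability-valid at finite resampling.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    prepared = []
    for cube, ranks in ((cube_a, ranks_a), (cube_b, ranks_b)):
        counts, rank_matrix, n_g = _aligned(cube, ranks, bins)
        ext, mid = _masks(rank_matrix, n_g, extreme, middle)
        nan = np.isnan(rank_matrix)
        valid_lists = None
        if nan.any():
            valid_lists = [np.flatnonzero(~nan[i])
                           for i in range(len(rank_matrix))]
        prepared.append((counts, ext, mid, valid_lists))

    (ca, ea, ma, va), (cb, eb, mb, vb) = prepared
    d_obs = _phi_from(ca, ea, ma) - _phi_from(cb, eb, mb)
    trace = np.empty(n_perm)
    for k in range(n_perm):
        pa = _permuted_rows(rng, ca, va)
        pb = _permuted_rows(rng, cb, vb)
        trace[k] = _phi_from(pa, ea, ma) - _phi_from(pb, eb, mb)
    n_extreme = int(np.sum(np.abs(trace) >= abs(d_obs)))
    p = (1 + n_extreme) / (n_perm + 1)
    if return_trace:
        return p, d_obs, trace
    return p
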