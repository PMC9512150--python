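"""Expression-side preparation: robust-expression filtering, TE-gene removal,
replicate averaging and per-gene ranking of samples.

The rank table is the backbone of the whole analysis: within each gene,
samples are ordered by mean expression (rank 1 = lowest) and mapped to the
midpoint percentile (rank - 0.5)/n, so that extreme/middle rank classes are
defined identically for panels of any size.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix, SamplePanel

logger = logging.getLogger(__name__)

MIN_RANKED_SAMPLES = 10  # genes ranked over fewer samples are dropped


def robust_gene_filter(matrix: ExpressionMatrix, min_fraction: float = 0.85,
                       min_replicates: int = 2) -> list[str]:
    """Genes robustly expressed across the panel.

    A gene is retained iff the number of samples with non-zero expression in
    at least ``min_replicates`` replicates reaches ``floor(min_fraction x
    n_samples)``.  With the defaults and a 129-sample panel the threshold is
    109 samples.
    """
    n_samples = len(matrix.panel)
    if n_samples == 0:
        raise ValueError("expression matrix has no samples")
    threshold = int(np.floor(min_fraction * n_samples))
    expressed = np.nan_to_num(matrix.values, nan=0.0) > 0.0
    n_ok = (expressed.sum(axis=2) >= min_replicates).sum(axis=1)
    keep = n_ok >= threshold
    logger.info("robust filter (>= %d non-zero-in-%d-reps samples): kept %d/%d genes",
                threshold, min_replicates, int(keep.sum()), len(matrix.genes))
    return [g for g, k in zip(matrix.genes, keep) if k]


def remove_te_genes(genes: pd.DataFrame, te_intervals,
                    reciprocal: float = 0.50) -> pd.DataFrame:
    """Drop genes with > ``reciprocal`` mutual overlap with a transposable
    element.

    ``te_intervals`` is an iterable of (chrom, start, end), 1-based
    inclusive, or a DataFrame with those columns.  The rule is strict: both
    the gene and the TE must be covered on more than the reciprocal fraction
    by their intersection for the gene to be removed, so a TE covered
    exactly 50% leaves the gene in place.
    """
    if isinstance(te_intervals, pd.DataFrame):
        te = list(zip(te_intervals["chrom"], te_intervals["start"], te_intervals["end"]))
    else:
        te = list(te_intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in te:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))

    def hit(row) -> bool:
        glen = row.end - row.start + 1
        for ts, te_end in by_chrom.get(str(row.chrom), ()):
            inter = min(row.end, te_end) - max(row.start, ts) + 1
            if inter <= 0:
                continue
            if inter / glen > reciprocal and inter / (te_end - ts + 1) > reciprocal:
                return True
        return False

    removed = genes.apply(hit, axis=1)
    n = int(removed.sum())
    if n:
        logger.info("removed %d genes with >%.0f%% reciprocal TE overlap",
                    n, 100 * reciprocal)
    return genes.loc[~removed].reset_index(drop=True)


def mean_expression(matrix: ExpressionMatrix) -> np.ndarray:
    """Per (gene, sample) arithmetic mean over non-missing replicates.

    Returns an (n_genes, n_samples) array; NaN where all replicates are
    missing.
    """
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmean(matrix.values, axis=2)


class RankTable:
    """Per-gene expression ranks of samples.

    ``ranks[g, s]`` is the 1-based ascending rank of sample ``s`` within
    gene ``g`` (1 = lowest expression), NaN where the sample has no value
    for the gene.  ``percentile = (rank - 0.5) / n_g`` where ``n_g`` is the
    number of ranked samples for that gene.
    """

    def __init__(self, genes, panel: SamplePanel, ranks: np.ndarray):
        self.genes = list(genes)
        self.panel = panel
        self.ranks = np.asarray(ranks, dtype=float)
        self.n_g = np.sum(~np.isnan(self.ranks), axis=1)
        with np.errstate(invalid="ignore"):
            self.percentile = (self.ranks - 0.5) / self.n_g[:, None]

    def __len__(self) -> int:
        return len(self.genes)

    def subset_genes(self, gene_ids) -> "RankTable":
        index = {g: i for i, g in enumerate(self.genes)}
        idx = [index[g] for g in gene_ids]
        return RankTable(list(gene_ids), self.panel, self.ranks[idx])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (gene_id, sample, rank, percentile)."""
        rows = []
        for i, g in enumerate(self.genes):
            for j, s in enumerate(self.panel.samples):
                if not np.isnan(self.ranks[i, j]):
                    rows.append((g, s, int(self.ranks[i, j]), self.percentile[i, j]))
        return pd.DataFrame(rows, columns=["gene_id", "sample", "rank", "percentile"])


def rank_samples(values: np.ndarray, genes, panel: SamplePanel,
                 tie_break: str = "panel", seed: int | None = None,
                 min_samples: int = MIN_RANKED_SAMPLES) -> RankTable:
    """Rank samples within each gene by mean expression.

    Ties are broken deterministically by canonical panel order by default
    (``tie_break="panel"``); ``tie_break="random"`` shuffles tied samples
    with the given seed, for sensitivity analysis.  Genes ranked over fewer
    than ``min_samples`` samples (default 10) are excluded and logged:
    extreme/middle percentile classes are meaningless on a handful of
    ranks.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    rng = np.random.default_rng(seed) if tie_break == "random" else None
    ranks = np.full_like(values, np.nan)
    kept = []
    for i in range(n_genes):
        valid = np.flatnonzero(~np.isnan(values[i]))
        if len(valid) < min_samples:
            continue
        if rng is not None:
            key = rng.permutation(len(valid))
        else:
            key = np.arange(len(valid))  # panel order
        order = np.lexsort((key, values[i, valid]))
        ranks[i, valid[order]] = np.arange(1, len(valid) + 1)
        kept.append(i)
    n_drop = n_genes - len(kept)
    if n_drop:
        logger.info("excluded %d genes ranked over fewer than %d samples",
                    n_drop, MIN_RANKED_SAMPLES)
    return RankTable([genes[i] for i in kept], panel, ranks[kept])
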