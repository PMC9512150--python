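"""Variant-level filtering, cross-sample SV merging and rare-variant selection.

The filters mirror a GATK/GRIDSS short-read calling workflow applied to a
selfing population:

* hard quality filters on SNPs and indels (QD, FS, MQ, SOR, rank-sum tests),
  with indels capped at 20 bp;
* depth-fold-change filters on deletions/duplications and a 20 bp – 200 kb
  size window on structural variants;
* removal of within-sample overlapping SV calls (possible complex
  rearrangements) before merging;
* single-linkage merging of per-sample SV calls at 50% reciprocal overlap
  with breakends within 1 kb (exact position match for unresolved
  breakends);
* folded minor-allele-frequency computation and rare-variant selection at
  MAF < 5%, with a class-specific evidence rule (SNPs/indels need one
  homozygous or three heterozygous minor-allele carriers; SV singletons are
  allowed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import (
    BND, DEL, DUP, INDEL, MISSING, SNP, SV_CLASSES, SamplePanel, VariantTable,
)

logger = logging.getLogger(__name__)

#: GATK-style hard-filter thresholds
SNP_FILTERS = dict(qd_min=2.0, fs_max=60.0, mq_min=40.0, sor_max=4.0,
                   mq_rank_sum_min=-12.5, read_pos_rank_sum_min=-8.0)
INDEL_FILTERS = dict(qd_min=2.0, fs_max=200.0, sor_max=10.0, max_length=20)

SV_MIN_LENGTH = 20       # exclusive: SVs are > 20 bp
SV_MAX_LENGTH = 200_000  # inclusive upper bound
DEL_DHFFC_MAX = 0.70     # deletions: depth fold-change vs flanks < 70%
DUP_DHBFC_MIN = 1.30     # duplications: fold-change vs GC-matched bins > 130%


def _passes(values: pd.Series, threshold: float, op: str) -> np.ndarray:
    """Elementwise comparison where a missing annotation passes.

    GATK emits the rank-sum annotations only at sites with heterozygous
    calls; treating an absent annotation as failing would silently drop
    every hom-only site.
    """
    v = values.to_numpy(dtype=float)
    ok = np.isnan(v)
    if op == ">":
        return ok | (v > threshold)
    if op == "<":
        return ok | (v < threshold)
    raise ValueError(op)


def apply_hard_filters(variants: VariantTable) -> VariantTable:
    """Apply SNP and indel hard quality filters; other classes pass through.

    SNPs: QD > 2, FS < 60, MQ > 40, SOR < 4, MQRankSum > -12.5,
    ReadPosRankSum > -8.  Indels: QD > 2, FS < 200, SOR < 10 and
    length <= 20 bp.
    """
    s = variants.sites
    is_snp = (s.vclass == SNP).to_numpy()
    is_indel = (s.vclass == INDEL).to_numpy()
    snp_ok = (
        _passes(s.qd, SNP_FILTERS["qd_min"], ">")
        & _passes(s.fs, SNP_FILTERS["fs_max"], "<")
        & _passes(s.mq, SNP_FILTERS["mq_min"], ">")
        & _passes(s.sor, SNP_FILTERS["sor_max"], "<")
        & _passes(s.mq_rank_sum, SNP_FILTERS["mq_rank_sum_min"], ">")
        & _passes(s.read_pos_rank_sum, SNP_FILTERS["read_pos_rank_sum_min"], ">")
    )
    indel_ok = (
        _passes(s.qd, INDEL_FILTERS["qd_min"], ">")
        & _passes(s.fs, INDEL_FILTERS["fs_max"], "<")
        & _passes(s.sor, INDEL_FILTERS["sor_max"], "<")
        & (s.length.to_numpy() <= INDEL_FILTERS["max_length"])
    )
    keep = np.where(is_snp, snp_ok, np.where(is_indel, indel_ok, True))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("hard filters removed %d of %d SNP/indel records",
                    n_drop, int(is_snp.sum() + is_indel.sum()))
    return variants.subset(keep)


def filter_sv_records(svs: VariantTable) -> VariantTable:
    """Depth and size filters on structural variants.

    Deletions require dhffc < 0.70; duplications require dhbfc > 1.30 (a
    DEL/DUP with no fold-change annotation is removed, conservatively).
    Insertions, inversions and breakends pass the depth step unchanged.
    All non-BND structural records must satisfy 20 bp < length <= 200 kb.
    Non-SV classes (SNPs, indels) pass through untouched, so a mixed table
    can be piped through both this and :func:`apply_hard_filters`.
    """
    s = svs.sites
    vclass = s.vclass.to_numpy()
    dhffc = s.dhffc.to_numpy(dtype=float)
    dhbfc = s.dhbfc.to_numpy(dtype=float)
    length = s.length.to_numpy()
    is_sv = s.vclass.isin(SV_CLASSES).to_numpy()

    depth_ok = np.ones(len(s), dtype=bool)
    is_del = vclass == DEL
    is_dup = vclass == DUP
    depth_ok[is_del] = ~np.isnan(dhffc[is_del]) & (dhffc[is_del] < DEL_DHFFC_MAX)
    depth_ok[is_dup] = ~np.isnan(dhbfc[is_dup]) & (dhbfc[is_dup] > DUP_DHBFC_MIN)
    n_noann = int((is_del & np.isnan(dhffc)).sum() + (is_dup & np.isnan(dhbfc)).sum())
    if n_noann:
        logger.info("%d DEL/DUP records lacked a depth fold-change and were removed",
                    n_noann)

    size_ok = np.where(vclass == BND, True,
                       (length > SV_MIN_LENGTH) & (length <= SV_MAX_LENGTH))
    return svs.subset(~is_sv | (depth_ok & size_ok))


def exclude_intra_sample_overlaps(svs: VariantTable) -> VariantTable:
    """Drop same-sample, same-chromosome non-BND SVs whose intervals overlap.

    Overlapping calls within one individual can represent complex
    rearrangements and make cross-sample merging ambiguous, so every member
    of an overlapping pair is removed.  Input rows must carry
    ``source_sample`` (per-sample call sets).  Abutting inclusive intervals
    ([100,200] and [201,300]) do not overlap.
    """
    s = svs.sites
    drop = np.zeros(len(s), dtype=bool)
    eligible = s.vclass.isin(SV_CLASSES - {BND}).to_numpy()
    groups = s.loc[eligible].groupby(["source_sample", "chrom"], dropna=False).indices
    for _, idx in groups.items():
        idx = np.asarray(idx)
        order = np.lexsort((s.end.to_numpy()[idx], s.pos.to_numpy()[idx]))
        idx = idx[order]
        pos = s.pos.to_numpy()[idx]
        end = s.end.to_numpy()[idx]
        # sweep: an interval overlaps a predecessor iff pos <= running max end
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if pos[b] > end[a]:
                    break
                drop[idx[a]] = drop[idx[b]] = True
    n = int(drop.sum())
    if n:
        logger.info("excluded %d within-sample overlapping SV calls", n)
    return svs.subset(~drop)


def _reciprocal_overlap(p1, e1, p2, e2) -> float:
    """Smaller of the two mutual coverage fractions of inclusive intervals."""
    inter = min(e1, e2) - max(p1, p2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - p1 + 1), inter / (e2 - p2 + 1))


def merge_svs(per_sample_svs: VariantTable, reciprocal: float = 0.50,
              bnd_window: int = 1000) -> tuple[VariantTable, pd.DataFrame]:
    """Merge per-sample SV calls into population records.

    Single-linkage clustering over same-class, same-chromosome calls: two
    calls join when each interval covers >= ``reciprocal`` of the other AND
    both breakends differ by <= ``bnd_window`` bp.  Unresolved breakends
    (BND) merge only on exact (chrom, pos) equality.  Each cluster emits one
    record with the coordinates of its first member (lowest pos, then lowest
    end) and the elementwise union (max alt count) of member genotypes.

    Returns the merged table and a merge report (cluster_id, member
    variant_ids, representative coordinates).
    """
    s = per_sample_svs.sites
    n = len(s)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    pos = s.pos.to_numpy()
    end = s.end.to_numpy()
    for (_, _), idx in s.groupby(["vclass", "chrom"]).indices.items():
        idx = np.asarray(idx)
        order = np.argsort(pos[idx], kind="stable")
        idx = idx[order]
        is_bnd = s.vclass.iloc[idx[0]] == BND
        for a in range(len(idx)):
            ia = idx[a]
            for b in range(a + 1, len(idx)):
                ib = idx[b]
                if pos[ib] - pos[ia] > bnd_window:
                    break
                if is_bnd:
                    if pos[ia] == pos[ib]:
                        union(ia, ib)
                elif (abs(int(end[ia]) - int(end[ib])) <= bnd_window
                      and _reciprocal_overlap(pos[ia], end[ia], pos[ib], end[ib])
                      >= reciprocal):
                    union(ia, ib)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    merged_rows, merged_gt, report = [], [], []
    # deterministic cluster order: by representative (chrom, pos, end)
    def rep_key(members):
        m = min(members, key=lambda i: (int(pos[i]), int(end[i])))
        return (s.chrom.iloc[m], int(pos[m]), int(end[m]), s.vclass.iloc[m])

    for cid, members in enumerate(sorted(clusters.values(), key=rep_key)):
        rep = min(members, key=lambda i: (int(pos[i]), int(end[i])))
        row = s.iloc[rep].copy()
        row["source_sample"] = None
        gt = per_sample_svs.gt[members].astype(np.int8)
        present = gt != MISSING
        merged = np.where(present.any(axis=0),
                          np.max(np.where(present, gt, 0), axis=0),
                          MISSING).astype(np.int8)
        # conflicting within-sample genotypes resolve to the max alt count
        n_calls = present.sum(axis=0)
        if (n_calls > 1).any():
            conflict = (n_calls > 1) & (np.where(present, gt, -9).max(axis=0)
                                        != np.where(present, gt, 9).min(axis=0))
            if conflict.any():
                logger.info("cluster %d: %d samples with conflicting genotypes; "
                            "kept max alt count", cid, int(conflict.sum()))
        merged_rows.append(row)
        merged_gt.append(merged)
        report.append(dict(
            cluster_id=cid,
            members=",".join(s.variant_id.iloc[i] for i in members),
            chrom=row["chrom"], pos=int(row["pos"]), end=int(row["end"]),
            vclass=row["vclass"], n_members=len(members),
        ))
    if not merged_rows:
        return (per_sample_svs.subset(np.zeros(0, dtype=int)), pd.DataFrame(report))
    sites = pd.DataFrame(merged_rows).reset_index(drop=True)
    gt = np.asarray(merged_gt, dtype=np.int8)
    return (VariantTable(sites, gt, per_sample_svs.panel),
            pd.DataFrame(report))


# ---------------------------------------------------------------------------
# allele frequency and rare-variant selection
# ---------------------------------------------------------------------------

def compute_allele_frequency(variants: VariantTable) -> pd.DataFrame:
    """Alternate-allele frequency and folded MAF per variant.

    Missing genotypes are excluded from both numerator and denominator:
    f = (sum of alt counts) / (2 x non-missing samples).  A variant with all
    genotypes missing gets NaN (undefined) and is flagged.

    Returns a frame with columns alt_freq, maf, n_called.
    """
    gt = variants.gt
    called = gt != MISSING
    n_called = called.sum(axis=1)
    alt = np.where(called, gt, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    maf = np.minimum(f, 1.0 - f)
    n_undef = int((n_called == 0).sum())
    if n_undef:
        logger.info("%d variants had no called genotypes (frequency undefined)",
                    n_undef)
    return pd.DataFrame({"alt_freq": f, "maf": maf, "n_called": n_called})


@dataclass
class RareVariantSet:
    """Rare variants with their folded frequencies and carrier matrix.

    ``carriers`` is boolean (n_variants, n_samples): True where the sample
    carries at least one copy of the *minor* allele.  When the alternate
    allele is the major one (alt_freq > 0.5) the carriers are the
    reference-allele carriers.
    """

    variants: VariantTable
    maf: np.ndarray
    alt_freq: np.ndarray
    carriers: np.ndarray
    maf_threshold: float

    @property
    def panel(self) -> SamplePanel:
        return self.variants.panel

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, mask) -> "RareVariantSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return RareVariantSet(self.variants.subset(idx), self.maf[idx],
                              self.alt_freq[idx], self.carriers[idx],
                              self.maf_threshold)


def minor_allele_carriers(variants: VariantTable,
                          alt_freq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Boolean carrier matrix and per-sample minor-allele dosage.

    The minor allele is frequency-defined: alt where alt_freq <= 0.5, ref
    otherwise.
    """
    gt = variants.gt
    called = gt != MISSING
    minor_is_alt = (alt_freq <= 0.5)[:, None]
    dosage = np.where(minor_is_alt, gt, 2 - gt)
    dosage = np.where(called, dosage, 0)
    return (dosage >= 1) & called, dosage


def select_rare_variants(variants: VariantTable,
                         maf_threshold: float = 0.05) -> RareVariantSet:
    """Select the rare-variant catalog at a folded-MAF threshold.

    SNPs and indels additionally require supporting evidence against
    genotyping error in singleton heterozygotes: at least one sample
    homozygous for the minor allele, or at least three heterozygous samples.
    SVs skip the evidence rule (singletons permitted) because SV calls rest
    on multiple independent read signals.  Variants with undefined frequency
    (no called genotypes) are excluded, as are monomorphic records
    (MAF = 0, which have no carriers).
    """
    freq = compute_allele_frequency(variants)
    maf = freq["maf"].to_numpy()
    alt_freq = freq["alt_freq"].to_numpy()
    carriers, dosage = minor_allele_carriers(variants, alt_freq)

    n_hom_minor = (dosage == 2).sum(axis=1)
    n_het = (dosage == 1).sum(axis=1)
    evidence = (n_hom_minor >= 1) | (n_het >= 3)

    is_sv = variants.sites.vclass.isin(SV_CLASSES).to_numpy()
    defined = ~np.isnan(maf)
    rare = defined & (maf < maf_threshold) & (maf > 0)
    keep = rare & (is_sv | evidence)
    idx = np.flatnonzero(keep)
    return RareVariantSet(
        variants=variants.subset(idx), maf=maf[idx], alt_freq=alt_freq[idx],
        carriers=carriers[idx], maf_threshold=maf_threshold,
    )
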