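"""Synthetic population generator with planted rare-variant expression
effects, plus tiny hand-built fixtures with exactly known outputs.

The generator emulates the structure of a selfing crop population assayed
for expression under two field conditions:

* a diploid, mostly-homozygous panel (129 samples by default);
* rare variants (folded MAF < 5%) of three classes (SNP, indel, SV) placed
  in gene bodies and strand-aware upstream windows, alongside common
  variants that must fail the rarity filter;
* triplicate log2(TPM+1) expression in a normal ("wet") and a stress
  ("dry") condition;
* a causal subset of the rare variants that shifts carrier expression away
  from the gene's optimum by ±δ (in units of the between-sample SD), with
  an exp(-d/λ) decay in the distance d from the TSS, amplified by κ under
  stress, and with the causal probability coupled to the fitness-consequence
  score, the gene's recombination rate, and its expression level.

Everything can be written out in the standard formats the pipeline reads
(VCF / GFF3 / TSV), so the full analysis is testable through its public
file interfaces, and the ground truth is kept for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pandas as pd

from .exprprep import RankTable
from .formats import (
    BND, DEL, DUP, INDEL, INS, INV, SNP, ExpressionMatrix, SamplePanel,
    VariantRecord, VariantTable, write_expression, write_vcf,
)
from .variantprep import RareVariantSet

#: placement mixture over region bins (gene body + upstream windows)
REGION_MIX = {
    "GENIC": 0.40, "U_0_2": 0.15, "U_2_4": 0.07, "U_4_6": 0.055,
    "U_6_8": 0.05, "U_8_10": 0.045, "U_10_12": 0.04, "U_12_14": 0.035,
    "U_14_16": 0.03, "U_16_18": 0.025, "U_18_20": 0.02, "U_GT20": 0.08,
}
_UP_BOUNDS = {
    "U_0_2": (0, 2000), "U_2_4": (2000, 4000), "U_4_6": (4000, 6000),
    "U_6_8": (6000, 8000), "U_8_10": (8000, 10000), "U_10_12": (10000, 12000),
    "U_12_14": (12000, 14000), "U_14_16": (14000, 16000),
    "U_16_18": (16000, 18000), "U_18_20": (18000, 20000),
    "U_GT20": (20000, 100000),
}
_SV_MIX = ((DEL, 0.40), (DUP, 0.20), (INS, 0.20), (INV, 0.15), (BND, 0.05))
_BASES = np.array(list("ACGT"))

#: slot width per gene; leaves the full 100 kb upstream search window of
#: every gene free of its neighbours on either strand
GENE_SLOT = 220_000


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    Defaults describe the emulated study conditions: 129 selfing samples,
    triplicate expression in two conditions, rare variants at < 5% folded
    MAF with class-specific evidence structure, and mild planted effects
    (δ = 1 between-sample SD, 2 kb distance-decay half-length, κ_dry = 1.3
    stress amplification).
    """

    n_samples: int = 129
    n_genes: int = 2000
    chrom: str = "chr1"
    gene_length: tuple[int, int] = (1000, 5000)
    n_rare: dict = field(default_factory=lambda: {SNP: 40000, INDEL: 8000, "SV": 3500})
    n_common: dict = field(default_factory=lambda: {SNP: 4000, INDEL: 800, "SV": 300})
    n_edge_het_snps: int = 200   # rare-frequency SNPs with only 2 het carriers
    selfing: float = 0.95        # P(carrier is homozygous for the minor allele)
    causal_fraction: dict = field(default_factory=lambda: {SNP: 0.20, INDEL: 0.25, "SV": 0.30})
    delta: float = 1.0           # effect size, units of between-sample SD
    decay_length: float = 2000.0  # λ of the exp(-d/λ) TSS-distance decay, bp
    kappa_dry: float = 1.3       # stress multiplier on every planted effect
    sign_bias: dict = field(default_factory=dict)  # per-class P(down)-0.5 shift
    rho_slope: float = 2.0       # causal-weight slope on the fitCons score
    recomb_slope: float = 1.0    # causal-weight slope on (low) recombination
    expr_slope: float = 1.0      # causal-weight slope on (low) expression
    baseline_range: tuple[float, float] = (2.0, 8.0)  # gene optima, log2(TPM+1)
    sample_sd: float = 1.0       # between-sample biological SD
    replicate_sd: float = 0.25   # within-sample technical SD
    n_replicates: int = 3
    dropout: float = 0.02        # per-measurement zeroing probability
    missing_rate: float = 0.01   # missing-call rate on common variants
    conditions: tuple[str, str] = ("wet", "dry")
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.selfing, self.dropout, self.missing_rate,
                     *self.causal_fraction.values()):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1]")
        if self.kappa_dry < 1.0:
            raise ValueError("kappa_dry must be >= 1")

    @property
    def chrom_length(self) -> int:
        return (self.n_genes + 1) * GENE_SLOT

    @classmethod
    def scaled(cls, n_genes: int, **overrides) -> "SimConfig":
        """A configuration scaled down from the 2000-gene default.

        Variant and edge-case counts shrink proportionally with the gene
        panel so per-gene burden density (and hence the scale of φ's
        sampling noise per gene) is preserved.
        """
        f = n_genes / 2000
        base = cls()
        kwargs = dict(
            n_genes=n_genes,
            n_rare={k: int(round(v * f)) for k, v in base.n_rare.items()},
            n_common={k: int(round(v * f)) for k, v in base.n_common.items()},
            n_edge_het_snps=int(round(base.n_edge_het_snps * f)),
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def max_minor_alleles(self) -> int:
        """Largest minor-allele count that keeps MAF strictly below 5%."""
        return int(np.floor(0.05 * 2 * self.n_samples)) - 1


@dataclass
class SimData:
    """A generated dataset plus its ground truth."""

    config: SimConfig
    panel: SamplePanel
    variants: VariantTable
    genes: pd.DataFrame
    expression: dict[str, ExpressionMatrix]
    truth: pd.DataFrame  # per variant: causal, delta, gene_id, bin, expected_rare

    def write(self, outdir) -> dict[str, Path]:
        """Write the dataset in the pipeline's external formats.

        Output is a function of the configuration only (byte-identical for
        identical configs, including the seed).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["vcf"] = outdir / "variants.vcf"
        write_vcf(self.variants, paths["vcf"])
        paths["gff3"] = outdir / "genes.gff3"
        _write_gff3(self.genes, paths["gff3"])
        for cond, mat in self.expression.items():
            p = outdir / f"expression_{cond}.tsv"
            write_expression(mat, p)
            paths[f"expression_{cond}"] = p
        paths["metadata"] = outdir / "gene_metadata.tsv"
        self.genes[["gene_id", "recomb_rate", "connectivity", "te_overlap"]].to_csv(
            paths["metadata"], sep="\t", index=False, na_rep="NA",
            float_format="%.6g")
        snp = self.variants.sites
        snp = snp[(snp.vclass == SNP) & snp.rho.notna()]
        paths["site_scores"] = outdir / "site_scores.tsv"
        snp[["chrom", "pos", "rho"]].to_csv(paths["site_scores"], sep="\t",
                                            index=False, float_format="%.6g")
        paths["truth"] = outdir / "truth.tsv"
        self.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep="NA",
                          float_format="%.6g")
        return paths


def _write_gff3(genes: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            attrs = f"ID={g.gene_id}"
            fh.write(f"{g.chrom}\t.\tgene\t{int(g.start)}\t{int(g.end)}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _place_genes(cfg: SimConfig, rng) -> pd.DataFrame:
    starts = (np.arange(cfg.n_genes) * GENE_SLOT) + 105_000
    lengths = rng.integers(cfg.gene_length[0], cfg.gene_length[1] + 1,
                           size=cfg.n_genes)
    if starts[-1] + lengths.max() + 100_000 > cfg.chrom_length:
        raise ValueError("too many genes for the chromosome length")
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    recomb = np.round(rng.lognormal(mean=0.8, sigma=0.7, size=cfg.n_genes), 4)
    # connectivity mixture populating both stated classes plus the gaps
    u = rng.random(cfg.n_genes)
    conn = np.where(u < 0.45, rng.uniform(0.16, 0.77, cfg.n_genes),
                    np.where(u < 0.85, rng.uniform(0.80, 0.99, cfg.n_genes),
                             rng.uniform(0.0, 1.0, cfg.n_genes)))
    df = pd.DataFrame({
        "gene_id": [f"g{i + 1:05d}" for i in range(cfg.n_genes)],
        "chrom": cfg.chrom, "strand": strands,
        "start": starts, "end": starts + lengths - 1,
        "recomb_rate": recomb, "connectivity": np.round(conn, 4),
        "te_overlap": 0.0,
    })
    df["tss"] = np.where(df.strand == "+", df.start, df.end)
    return df


def _draw_genotypes(cfg: SimConfig, rng, n_alleles: int, n_samples: int,
                    force_evidence: bool, force_het_only: bool = False
                    ) -> np.ndarray:
    """Genotype vector with a given minor-allele count under selfing.

    ``force_evidence`` guarantees >= 1 homozygote (possible for any count
    >= 2), so SNP/indel records satisfy the class evidence rule;
    ``force_het_only`` spreads every allele over distinct heterozygotes.
    """
    gt = np.zeros(n_samples, dtype=np.int8)
    if force_het_only:
        carriers = rng.choice(n_samples, size=n_alleles, replace=False)
        gt[carriers] = 1
        return gt
    loads = []  # per-carrier allele counts
    remaining = n_alleles
    while remaining > 0:
        slots_left = n_samples - len(loads)
        must_hom = remaining > 2 * (slots_left - 1)  # alleles must still fit
        if remaining >= 2 and (must_hom or rng.random() < cfg.selfing):
            loads.append(2)
            remaining -= 2
        else:
            loads.append(1)
            remaining -= 1
    if force_evidence and 2 not in loads and len(loads) >= 2:
        loads[0:2] = [2]  # fold two hets into one homozygote
    carriers = rng.choice(n_samples, size=len(loads), replace=False)
    gt[carriers] = loads
    return gt


def simulate(config: SimConfig | None = None) -> SimData:
    """Generate a full synthetic dataset with planted effects.

    Deterministic given the configuration: the same seed reproduces the
    same dataset bit for bit.  Variant attributes are drawn column-wise for
    speed; only the genotype composition (the selfing process) and the
    causal-shift accumulation run per variant.
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    panel = SamplePanel.from_ids(f"S{i + 1:03d}" for i in range(cfg.n_samples))
    genes = _place_genes(cfg, rng)

    bin_labels = list(REGION_MIX)  # index 0 is GENIC
    bin_probs = np.array(list(REGION_MIX.values()))
    d_lo = np.array([0] + [_UP_BOUNDS[b][0] for b in bin_labels[1:]])
    d_hi = np.array([0] + [_UP_BOUNDS[b][1] for b in bin_labels[1:]])
    a_max = cfg.max_minor_alleles
    n_alleles_total = 2 * cfg.n_samples
    common_lo = int(np.ceil(0.05 * n_alleles_total)) + 1
    common_hi = n_alleles_total - common_lo

    # causal-probability gene weights: low recombination and low expression
    # carry more un-purged deleterious variation
    recomb_rank = genes.recomb_rate.rank(pct=True).to_numpy()
    baseline = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    expr_rank = pd.Series(baseline).rank(pct=True).to_numpy()
    gene_weight = ((1.0 + cfg.recomb_slope * (0.5 - recomb_rank))
                   * (1.0 + cfg.expr_slope * (0.5 - expr_rank)))
    gene_weight = np.clip(gene_weight, 0.0, None)

    # emission plan: rare then common per class, then het-only edge SNPs
    class_key, rare, edge = [], [], []
    for key in (SNP, INDEL, "SV"):
        n_r, n_c = cfg.n_rare.get(key, 0), cfg.n_common.get(key, 0)
        class_key += [key] * (n_r + n_c)
        rare += [True] * n_r + [False] * n_c
        edge += [False] * (n_r + n_c)
    class_key += [SNP] * cfg.n_edge_het_snps
    rare += [True] * cfg.n_edge_het_snps
    edge += [True] * cfg.n_edge_het_snps
    class_key = np.array(class_key, dtype=object)
    rare = np.array(rare)
    edge = np.array(edge)
    M = len(class_key)

    gi = rng.integers(0, cfg.n_genes, size=M)
    bin_idx = rng.choice(len(bin_labels), size=M, p=bin_probs)

    vclass = class_key.copy()
    is_sv = class_key == "SV"
    sv_names, sv_probs = zip(*_SV_MIX)
    vclass[is_sv] = rng.choice(np.array(sv_names, dtype=object),
                               size=int(is_sv.sum()), p=np.array(sv_probs))
    length = np.ones(M, dtype=np.int64)
    is_indel = vclass == INDEL
    length[is_indel] = rng.integers(1, 21, size=int(is_indel.sum()))
    sized_sv = is_sv & (vclass != BND)
    length[sized_sv] = rng.integers(21, 5001, size=int(sized_sv.sum()))
    length[vclass == BND] = 0
    span = np.where(np.isin(vclass, (DEL, DUP, INV)), length, 1)

    g_start = genes.start.to_numpy()[gi]
    g_end = genes.end.to_numpy()[gi]
    g_tss = genes.tss.to_numpy()[gi]
    plus = genes.strand.to_numpy()[gi] == "+"
    genic = bin_idx == 0
    lo = np.where(genic, g_start,
                  np.where(plus, g_tss - d_hi[bin_idx],
                           g_tss + d_lo[bin_idx] + 1))
    hi = np.where(genic, g_end,
                  np.where(plus, g_tss - d_lo[bin_idx] - 1,
                           g_tss + d_hi[bin_idx]))
    hi = np.maximum(lo, hi - span + 1)
    pos = rng.integers(lo, hi + 1)
    end = np.where(vclass == BND, pos, pos + span - 1)

    n_alleles = np.empty(M, dtype=np.int64)
    m = rare & ~edge & is_sv
    n_alleles[m] = rng.integers(1, a_max + 1, size=int(m.sum()))
    m = rare & ~edge & ~is_sv
    n_alleles[m] = rng.integers(2, a_max + 1, size=int(m.sum()))
    n_alleles[edge] = 2
    m = ~rare
    n_alleles[m] = rng.integers(common_lo, common_hi + 1, size=int(m.sum()))

    gt = np.zeros((M, cfg.n_samples), dtype=np.int8)
    for i in range(M):
        gt[i] = _draw_genotypes(
            cfg, rng, int(n_alleles[i]), cfg.n_samples,
            force_evidence=bool(rare[i] and not edge[i] and not is_sv[i]),
            force_het_only=bool(edge[i]))
    if cfg.missing_rate > 0 and (~rare).any():
        # missing calls hit only major-allele homozygotes: dropping one
        # raises the minor-allele frequency, so a common variant can never
        # slip under the rarity threshold through missingness alone
        rows = np.flatnonzero(~rare)
        major_hom = np.where(n_alleles[rows] <= cfg.n_samples, 0, 2)
        miss = ((rng.random((len(rows), cfg.n_samples)) < cfg.missing_rate)
                & (gt[rows] == major_hom[:, None]))
        gt[rows] = np.where(miss, -1, gt[rows]).astype(np.int8)

    qd = np.round(rng.uniform(5, 30, M), 2)
    fs = np.round(rng.uniform(0, 20, M), 2)
    mq = np.round(rng.uniform(50, 60, M), 2)
    sor = np.round(rng.uniform(0.5, 2, M), 2)
    mqrs = np.round(rng.normal(0, 1, M), 2)
    rprs = np.round(rng.normal(0, 1, M), 2)
    # fitness-consequence mixture: both the rho < 0.1 and rho > 0.2 classes
    # are populated, with a band in between
    rho = np.full(M, np.nan)
    snp_m = vclass == SNP
    n_snp = int(snp_m.sum())
    u = rng.random(n_snp)
    rho_draw = np.where(u < 0.4, rng.uniform(0.0, 0.1, n_snp),
                        np.where(u < 0.7, rng.uniform(0.2, 0.8, n_snp),
                                 rng.uniform(0.1, 0.2, n_snp)))
    rho[snp_m] = np.round(rho_draw, 4)
    dhffc = np.full(M, np.nan)
    del_m = vclass == DEL
    dhffc[del_m] = np.round(rng.uniform(0.2, 0.6, int(del_m.sum())), 3)
    dhbfc = np.full(M, np.nan)
    dup_m = vclass == DUP
    dhbfc[dup_m] = np.round(rng.uniform(1.4, 2.0, int(dup_m.sum())), 3)

    ref_idx = rng.integers(0, 4, M)
    alt_idx = (ref_idx + rng.integers(1, 4, M)) % 4
    deletion_coin = rng.random(M) < 0.5
    ref = np.full(M, "N", dtype=object)
    alt = np.array([f"<{c}>" for c in vclass], dtype=object)
    ref[snp_m] = _BASES[ref_idx[snp_m]]
    alt[snp_m] = _BASES[alt_idx[snp_m]]
    for i in np.flatnonzero(is_indel):
        anchor = _BASES[ref_idx[i]]
        tail = _BASES[alt_idx[i]] * int(length[i])
        if deletion_coin[i]:
            ref[i], alt[i] = anchor + tail, anchor
        else:
            ref[i], alt[i] = anchor, anchor + tail

    dist = np.where(genic, 0, np.where(plus, g_tss - pos, pos - g_tss))
    p_causal = pd.Series(class_key).map(cfg.causal_fraction).to_numpy(float)
    p_causal = p_causal * gene_weight[gi]
    rho_mult = np.where(snp_m & ~np.isnan(rho),
                        np.maximum(0.0, 1.0 + cfg.rho_slope * (rho - 0.15)),
                        1.0)
    p_causal = np.minimum(p_causal * rho_mult, 1.0)
    causal = rare & ~edge & (rng.random(M) < p_causal)
    bias = np.array([cfg.sign_bias.get(k, 0.0) for k in class_key])
    sign = np.where(rng.random(M) < 0.5 + bias, -1.0, 1.0)
    delta_v = np.where(causal, sign * cfg.delta, 0.0)
    decay = np.exp(-dist / cfg.decay_length)

    shift = {c: np.zeros((cfg.n_genes, cfg.n_samples)) for c in cfg.conditions}
    kappa = {cond: (cfg.kappa_dry if ci == 1 else 1.0)
             for ci, cond in enumerate(cfg.conditions)}
    for i in np.flatnonzero(causal):
        carrier = (gt[i] >= 1).astype(float)
        base = delta_v[i] * decay[i] * cfg.sample_sd * carrier
        for cond in cfg.conditions:
            shift[cond][gi[i]] += base * kappa[cond]

    variant_id = np.array([f"v{i + 1:06d}" for i in range(M)], dtype=object)
    sites = pd.DataFrame({
        "variant_id": variant_id, "chrom": cfg.chrom, "pos": pos, "end": end,
        "ref": ref, "alt": alt, "vclass": vclass, "length": length,
        "qd": qd, "fs": fs, "mq": mq, "sor": sor, "mq_rank_sum": mqrs,
        "read_pos_rank_sum": rprs, "dhffc": dhffc, "dhbfc": dhbfc,
        "rho": rho, "source_sample": None,
    })
    variants = VariantTable(sites, gt, panel)
    truth = pd.DataFrame({
        "variant_id": variant_id, "vclass": vclass, "class_key": class_key,
        "gene_id": genes.gene_id.to_numpy()[gi],
        "bin": np.array(bin_labels, dtype=object)[bin_idx],
        "distance": dist, "causal": causal, "delta": delta_v,
        "expected_rare": rare & ~edge, "n_minor_alleles": n_alleles,
    })

    expression = {}
    for cond in cfg.conditions:
        sample_level = (baseline[:, None]
                        + rng.normal(0.0, cfg.sample_sd,
                                     (cfg.n_genes, cfg.n_samples))
                        + shift[cond])
        reps = (sample_level[:, :, None]
                + rng.normal(0.0, cfg.replicate_sd,
                             (cfg.n_genes, cfg.n_samples, cfg.n_replicates)))
        reps = np.clip(reps, 0.0, None)
        if cfg.dropout > 0:
            drop = rng.random(reps.shape) < cfg.dropout
            reps = np.where(drop, 0.0, reps)
        expression[cond] = ExpressionMatrix(cond, genes.gene_id.tolist(),
                                            panel, np.round(reps, 4))

    gene_cols = ["gene_id", "chrom", "strand", "start", "end", "tss",
                 "recomb_rate", "connectivity", "te_overlap"]
    return SimData(config=cfg, panel=panel, variants=variants,
                   genes=genes[gene_cols], expression=expression, truth=truth)


# ---------------------------------------------------------------------------
# deterministic tiny fixtures
# ---------------------------------------------------------------------------

def _rare_set_from(records, panel, carriers) -> RareVariantSet:
    table = VariantTable.from_records(records, panel)
    carriers = np.asarray(carriers, dtype=bool)
    maf = np.full(len(records), 0.01)
    return RareVariantSet(variants=table, maf=maf, alt_freq=maf.copy(),
                          carriers=carriers, maf_threshold=0.05)


def make_fixture(name: str) -> SimpleNamespace:
    """Hand-constructed datasets with documented expected outputs.

    ``tiny5``
        5 samples, one + strand gene [10000, 12000].  Variants: TSS-500
        (carrier S3, upstream 0-2 kb window), genic at 11000 (carrier S5)
        and TSS-2100 (carrier S1, upstream 2-4 kb window — outside the cis
        region).  Expression S1..S5 = 1..5, so sample k holds rank k.
        Expected cis per-rank profile: (0, 0, 1, 0, 1).
    ``ranks10``
        10 samples, one gene; genic variant counts per rank
        (2, 0, 0, 0, 1, 1, 0, 0, 0, 3).  Expected φ = (2+3)/(1+1) = 2.5.
    ``merge_cases``
        Per-sample SV calls exercising the merge boundary rules: a DEL pair
        at exactly 50% reciprocal overlap (merges), a DEL pair at 20%
        (does not), a BND pair at identical positions (merges) and one
        offset by 1 bp (does not).  Expected: 6 population records.
    """
    if name == "tiny5":
        panel = SamplePanel.from_ids(f"S{i}" for i in range(1, 6))
        gene = pd.DataFrame([dict(gene_id="g1", chrom="chr1", strand="+",
                                  start=10000, end=12000, tss=10000,
                                  recomb_rate=np.nan, connectivity=np.nan,
                                  te_overlap=np.nan)])
        z5 = np.zeros(5, dtype=np.int8)

        def rec(vid, pos):
            return VariantRecord(variant_id=vid, chrom="chr1", pos=pos,
                                 end=pos, ref="A", alt="T", vclass=SNP,
                                 length=1, genotypes=z5.copy())

        records = [rec("u02", 9500), rec("genic", 11000), rec("u24", 7900)]
        carriers = np.zeros((3, 5), dtype=bool)
        carriers[0, 2] = True   # TSS-500 carried by S3
        carriers[1, 4] = True   # genic carried by S5
        carriers[2, 0] = True   # TSS-2100 carried by S1
        for r, c in zip(records, carriers):
            r.genotypes = (c * 2).astype(np.int8)
        rare = _rare_set_from(records, panel, carriers)
        ranks = RankTable(["g1"], panel,
                          np.arange(1, 6, dtype=float).reshape(1, 5))
        return SimpleNamespace(panel=panel, genes=gene, rare_set=rare,
                               ranks=ranks,
                               expected_cis_profile=(0.0, 0.0, 1.0, 0.0, 1.0))

    if name == "ranks10":
        panel = SamplePanel.from_ids(f"S{i:02d}" for i in range(1, 11))
        gene = pd.DataFrame([dict(gene_id="g1", chrom="chr1", strand="+",
                                  start=1000, end=2000, tss=1000,
                                  recomb_rate=np.nan, connectivity=np.nan,
                                  te_overlap=np.nan)])
        counts_by_rank = (2, 0, 0, 0, 1, 1, 0, 0, 0, 3)
        records, carrier_rows = [], []
        k = 0
        for rank, n in enumerate(counts_by_rank, start=1):
            for _ in range(n):
                k += 1
                gt = np.zeros(10, dtype=np.int8)
                gt[rank - 1] = 2  # sample at rank r is S<r> (ascending values)
                records.append(VariantRecord(
                    variant_id=f"v{k}", chrom="chr1", pos=1000 + 10 * k,
                    end=1000 + 10 * k, ref="A", alt="T", vclass=SNP,
                    length=1, genotypes=gt))
                carrier_rows.append(gt >= 1)
        rare = _rare_set_from(records, panel, np.array(carrier_rows))
        ranks = RankTable(["g1"], panel,
                          np.arange(1, 11, dtype=float).reshape(1, 10))
        return SimpleNamespace(panel=panel, genes=gene, rare_set=rare,
                               ranks=ranks, counts_by_rank=counts_by_rank,
                               expected_phi=2.5)

    if name == "merge_cases":
        panel = SamplePanel.from_ids(["A", "B"])

        def sv(vid, sample, vclass, pos, end):
            gt = np.zeros(2, dtype=np.int8)
            gt[panel.index(sample)] = 2
            length = 0 if vclass == BND else end - pos + 1
            ann = {"dhffc": 0.5} if vclass == DEL else {}
            return VariantRecord(variant_id=vid, chrom="chr1", pos=pos,
                                 end=end, ref="N", alt=f"<{vclass}>",
                                 vclass=vclass, length=length, genotypes=gt,
                                 annotations=ann, source_sample=sample)

        records = [
            sv("mergeA", "A", DEL, 100, 199),     # 50% reciprocal with mergeB
            sv("mergeB", "B", DEL, 150, 249),
            sv("aloneA", "A", DEL, 10100, 10199),  # 20% reciprocal with aloneB
            sv("aloneB", "B", DEL, 10180, 10279),
            sv("bndA", "A", BND, 5000, 5000),      # exact match with bndB
            sv("bndB", "B", BND, 5000, 5000),
            sv("bndC", "A", BND, 20000, 20000),    # off by one from bndD
            sv("bndD", "B", BND, 20001, 20001),
        ]
        table = VariantTable.from_records(records, panel)
        return SimpleNamespace(panel=panel, per_sample_svs=table,
                               expected_n_merged=6,
                               expected_merged_pairs=(("mergeA", "mergeB"),
                                                      ("bndA", "bndB")))

    raise ValueError(f"unknown fixture {name!r}")
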