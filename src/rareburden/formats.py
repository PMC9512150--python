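"""Readers, writers and in-memory containers for the external file formats.

All genomic coordinates are held 1-based inclusive internally (the VCF
convention); BED input is converted on ingestion and converted back on
output.  Everything downstream consumes the containers built here:

* :class:`SamplePanel` — the ordered population of samples; canonical order
  for every genotype vector.
* :class:`VariantTable` — one row per biallelic variant (multiallelic VCF
  sites are split), with a dense genotype matrix coded as the count of
  alternate alleles (0/1/2, ``-1`` for missing).
* gene models as a :class:`pandas.DataFrame` (one row per gene, strand-aware
  TSS precomputed).
* :class:`ExpressionMatrix` — gene × sample × replicate values for one
  condition, on the log2(TPM+1) scale.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing call

#: canonical variant classes
SNP, INDEL, DEL, DUP, INS, INV, BND = "SNP", "INDEL", "DEL", "DUP", "INS", "INV", "BND"
SV_CLASSES = frozenset({DEL, DUP, INS, INV, BND})
VARIANT_CLASSES = frozenset({SNP, INDEL}) | SV_CLASSES

#: numeric site-annotation columns carried on every VariantTable
ANNOTATION_COLUMNS = (
    "qd", "fs", "mq", "sor", "mq_rank_sum", "read_pos_rank_sum",
    "dhffc", "dhbfc", "rho",
)

SITE_COLUMNS = (
    "variant_id", "chrom", "pos", "end", "ref", "alt", "vclass", "length",
) + ANNOTATION_COLUMNS + ("source_sample",)


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class SamplePanel:
    """Ordered, unique sample identifiers of a diploid population."""

    samples: tuple[str, ...]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("sample identifiers must be unique")

    def __len__(self) -> int:
        return len(self.samples)

    def index(self, sample: str) -> int:
        return self.samples.index(sample)

    @classmethod
    def from_ids(cls, ids) -> "SamplePanel":
        return cls(tuple(str(s) for s in ids))


@dataclass
class VariantRecord:
    """A single biallelic population variant.

    ``pos``/``end`` are 1-based inclusive.  ``genotypes`` counts alternate
    alleles per sample in panel order; ``-1`` marks a missing call.
    """

    variant_id: str
    chrom: str
    pos: int
    end: int
    ref: str
    alt: str
    vclass: str
    length: int
    genotypes: np.ndarray
    annotations: dict = field(default_factory=dict)
    source_sample: str | None = None

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise FormatError(f"unknown variant class {self.vclass!r}")
        if self.pos > self.end:
            raise FormatError(f"{self.variant_id}: pos {self.pos} > end {self.end}")
        if self.vclass == SNP and self.length != 1:
            raise FormatError(f"{self.variant_id}: SNP must have length 1")
        if self.length < 1 and self.vclass != BND:
            raise FormatError(f"{self.variant_id}: length must be >= 1")
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.max(initial=0) > 2 or g.min(initial=0) < -1:
            raise FormatError(f"{self.variant_id}: genotypes must be in {{0,1,2,-1}}")
        self.genotypes = g


class VariantTable:
    """A set of biallelic variants over one :class:`SamplePanel`.

    Attributes
    ----------
    sites : pandas.DataFrame
        One row per variant with columns :data:`SITE_COLUMNS`.
    gt : numpy.ndarray of int8, shape (n_variants, n_samples)
        Alternate-allele counts; ``-1`` for missing.
    panel : SamplePanel
    """

    def __init__(self, sites: pd.DataFrame, gt: np.ndarray, panel: SamplePanel):
        gt = np.asarray(gt, dtype=np.int8)
        if gt.shape != (len(sites), len(panel)):
            raise FormatError(
                f"genotype matrix shape {gt.shape} does not match "
                f"{len(sites)} variants x {len(panel)} samples"
            )
        sites = sites.reset_index(drop=True)
        for col in SITE_COLUMNS:
            if col not in sites.columns:
                sites[col] = np.nan if col in ANNOTATION_COLUMNS else None
        self.sites = sites[list(SITE_COLUMNS)]
        self.gt = gt
        self.panel = panel

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.sites)

    @property
    def n_variants(self) -> int:
        return len(self.sites)

    def subset(self, mask) -> "VariantTable":
        """Row-subset by boolean mask or integer positions (order preserved)."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(self.sites.iloc[idx], self.gt[idx], self.panel)

    def records(self):
        """Iterate rows as :class:`VariantRecord` (convenience, not fast)."""
        for i, row in self.sites.iterrows():
            ann = {k: row[k] for k in ANNOTATION_COLUMNS if pd.notna(row[k])}
            yield VariantRecord(
                variant_id=row.variant_id, chrom=row.chrom, pos=int(row.pos),
                end=int(row.end), ref=row.ref, alt=row.alt, vclass=row.vclass,
                length=int(row.length), genotypes=self.gt[i], annotations=ann,
                source_sample=row.source_sample,
            )

    @classmethod
    def from_records(cls, records, panel: SamplePanel) -> "VariantTable":
        records = list(records)
        rows = []
        gt = np.full((len(records), len(panel)), MISSING, dtype=np.int8)
        for i, r in enumerate(records):
            row = dict(
                variant_id=r.variant_id, chrom=r.chrom, pos=r.pos, end=r.end,
                ref=r.ref, alt=r.alt, vclass=r.vclass, length=r.length,
                source_sample=r.source_sample,
            )
            for k in ANNOTATION_COLUMNS:
                row[k] = r.annotations.get(k, np.nan)
            rows.append(row)
            gt[i] = r.genotypes
        sites = pd.DataFrame(rows, columns=list(SITE_COLUMNS))
        return cls(sites, gt, panel)

    @classmethod
    def concat(cls, tables) -> "VariantTable":
        tables = list(tables)
        panel = tables[0].panel
        if any(t.panel.samples != panel.samples for t in tables):
            raise FormatError("cannot concatenate tables over different panels")
        sites = pd.concat([t.sites for t in tables], ignore_index=True)
        gt = np.concatenate([t.gt for t in tables], axis=0)
        return cls(sites, gt, panel)


# ---------------------------------------------------------------------------
# coordinate dialects
# ---------------------------------------------------------------------------

def bed_to_internal(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive."""
    return start0 + 1, end0


def internal_to_bed(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open BED."""
    return start1 - 1, end1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_INFO_KEYS = {
    "QD": "qd", "FS": "fs", "MQ": "mq", "SOR": "sor",
    "MQRankSum": "mq_rank_sum", "ReadPosRankSum": "read_pos_rank_sum",
    "DHFFC": "dhffc", "DHBFC": "dhbfc",
}

_SYMBOLIC = re.compile(r"^<(\w+)(:[^>]*)?>$")


def _classify_alleles(ref: str, alt: str) -> tuple[str, int]:
    """Infer variant class and length from REF/ALT sequence alleles.

    SNP: both length 1.  INDEL: size difference 1-20 bp.  Larger differences
    are structural (INS if the alt is longer, DEL otherwise).
    """
    if len(ref) == 1 and len(alt) == 1:
        return SNP, 1
    diff = abs(len(ref) - len(alt))
    if diff == 0:
        # balanced multi-nucleotide substitution; treat as indel-scale event
        return INDEL, max(len(ref), 1)
    if diff <= 20:
        return INDEL, diff
    return (INS if len(alt) > len(ref) else DEL), diff


def read_vcf(path, panel: SamplePanel | None = None) -> VariantTable:
    """Read a VCF into a :class:`VariantTable`.

    Multiallelic sites are split into one record per ALT allele; per-sample
    genotypes count that specific alternate allele.  A call with any missing
    allele is coded missing.  Symbolic SV alleles require an ``SVTYPE`` INFO
    key plus ``END`` or ``SVLEN``; records with an unknown SVTYPE are skipped
    with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=False)
    file_panel = SamplePanel.from_ids(vcf.samples)
    if panel is None:
        panel = file_panel
    elif panel.samples != file_panel.samples:
        raise FormatError("VCF sample columns do not match the supplied panel")

    records = []
    for line_no, v in enumerate(vcf, start=1):
        alts = v.ALT or []
        # allele index per haplotype: v.genotypes = [a1, a2, phased]
        gts = v.genotypes
        for k, alt in enumerate(alts, start=1):
            geno = np.full(len(panel), MISSING, dtype=np.int8)
            for s, g in enumerate(gts):
                alleles = g[:-1]
                if len(alleles) == 0 or any(a is None or a < 0 for a in alleles):
                    continue
                if len(alleles) == 1:  # haploid call on a diploid panel
                    raise FormatError(
                        f"line {line_no}: haploid GT for sample "
                        f"{panel.samples[s]}"
                    )
                geno[s] = sum(1 for a in alleles if a == k)
            ann = {}
            for key, col in _INFO_KEYS.items():
                val = v.INFO.get(key)
                if val is not None:
                    ann[col] = float(val)
            m = _SYMBOLIC.match(alt)
            pos = v.POS
            if m:
                svtype = (v.INFO.get("SVTYPE") or m.group(1)).upper()
                if svtype not in SV_CLASSES:
                    warnings.warn(
                        f"line {line_no}: unknown SVTYPE {svtype!r}; record skipped"
                    )
                    continue
                end = v.INFO.get("END")
                if end is None:
                    svlen = v.INFO.get("SVLEN")
                    if svlen is None:
                        end = pos
                    else:
                        svlen = abs(int(svlen if np.isscalar(svlen) else svlen[0]))
                        end = pos + svlen - 1 if svtype != INS else pos
                end = int(end)
                length = 0 if svtype == BND else end - pos + 1
                if svtype == INS:
                    svlen = v.INFO.get("SVLEN")
                    if svlen is not None:
                        length = abs(int(svlen if np.isscalar(svlen) else svlen[0]))
                vclass = svtype
            else:
                vclass, length = _classify_alleles(v.REF, alt)
                end = pos + len(v.REF) - 1
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{pos}"
            if len(alts) > 1:
                vid = f"{vid}_alt{k}"
            records.append(VariantRecord(
                variant_id=vid, chrom=v.CHROM, pos=pos, end=end, ref=v.REF,
                alt=alt, vclass=vclass, length=max(length, 1) if vclass != BND else 0,
                genotypes=geno, annotations=ann,
            ))
    return VariantTable.from_records(records, panel)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER_INFO = """\
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias">
##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Mapping quality rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read position rank sum">
##INFO=<ID=DHFFC,Number=1,Type=Float,Description="Depth fold-change vs flanks">
##INFO=<ID=DHBFC,Number=1,Type=Float,Description="Depth fold-change vs GC-matched bins">
##INFO=<ID=RHO,Number=1,Type=Float,Description="Fitness consequence score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_INFO_OUT = [
    ("qd", "QD"), ("fs", "FS"), ("mq", "MQ"), ("sor", "SOR"),
    ("mq_rank_sum", "MQRankSum"), ("read_pos_rank_sum", "ReadPosRankSum"),
    ("dhffc", "DHFFC"), ("dhbfc", "DHBFC"), ("rho", "RHO"),
]


def write_vcf(table: VariantTable, path) -> None:
    """Write a :class:`VariantTable` as uncompressed VCF 4.2.

    Heterozygous calls are written unphased (0/1); phase is not modelled.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(_VCF_HEADER_INFO)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.panel.samples) + "\n")
        for i, row in table.sites.iterrows():
            info = []
            if row.vclass in SV_CLASSES:
                info.append(f"SVTYPE={row.vclass}")
                info.append(f"END={int(row.end)}")
                info.append(f"SVLEN={int(row.length)}")
            for col, key in _INFO_OUT:
                if pd.notna(row[col]):
                    info.append(f"{key}={row[col]:g}")
            alt = row.alt
            if row.vclass in SV_CLASSES and not str(alt).startswith("<"):
                alt = f"<{row.vclass}>"
            gts = "\t".join(_GT_STRINGS[int(g)] for g in table.gt[i])
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\t{row.variant_id}\t{row.ref}\t{alt}"
                f"\t.\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "gene_id", "chrom", "strand", "start", "end", "tss",
    "recomb_rate", "connectivity", "te_overlap",
]


def _finalize_genes(df: pd.DataFrame) -> pd.DataFrame:
    if (df["start"] > df["end"]).any():
        bad = df.loc[df.start > df.end, "gene_id"].iloc[0]
        raise FormatError(f"gene {bad}: start > end")
    if not df["strand"].isin(["+", "-"]).all():
        bad = df.loc[~df.strand.isin(["+", "-"]), "gene_id"].iloc[0]
        raise FormatError(f"gene {bad}: strand must be + or - (upstream is undefined otherwise)")
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    for col in ("recomb_rate", "connectivity", "te_overlap"):
        if col not in df.columns:
            df[col] = np.nan
    return df[GENE_COLUMNS].reset_index(drop=True)


def read_gene_models(path, dialect: str | None = None) -> pd.DataFrame:
    """Read gene models from GFF3 or 6-column BED into a gene table.

    The dialect is taken from the file extension unless given explicitly
    (``"gff3"`` or ``"bed"``).  BED coordinates (0-based half-open) are
    converted to the internal 1-based inclusive convention.  The strand-aware
    TSS is precomputed (= start on +, = end on -).
    """
    path = str(path)
    if dialect is None:
        if path.endswith((".gff", ".gff3")):
            dialect = "gff3"
        elif path.endswith(".bed"):
            dialect = "bed"
        else:
            raise FormatError(f"cannot infer dialect from {path!r}; pass dialect=")
    if dialect == "bed":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start0", "end0", "gene_id", "score", "strand"],
            dtype={"chrom": str, "gene_id": str, "strand": str},
        )
        df["start"] = df["start0"] + 1
        df["end"] = df["end0"]
    elif dialect == "gff3":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        rows = []
        for feat in db.features_of_type("gene"):
            rows.append(dict(
                gene_id=feat.id, chrom=feat.seqid, strand=feat.strand,
                start=feat.start, end=feat.end,
            ))
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return _finalize_genes(df)


def attach_gene_metadata(genes: pd.DataFrame, path) -> pd.DataFrame:
    """Merge a per-gene metadata TSV (recomb_rate, connectivity, te_overlap).

    Unmatched genes keep NaN; metadata rows without a matching gene are
    ignored.
    """
    meta = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    cols = [c for c in ("recomb_rate", "connectivity", "te_overlap") if c in meta.columns]
    out = genes.drop(columns=cols).merge(
        meta[["gene_id"] + cols], on="gene_id", how="left"
    )
    return _finalize_genes(out)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Per-replicate expression values for one condition.

    ``values`` has shape (n_genes, n_samples, n_replicates) with NaN marking
    missing measurements; the scale is log2(normalized TPM + 1), so values
    are non-negative where present.
    """

    def __init__(self, condition: str, genes, panel: SamplePanel, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[:2] != (len(genes), len(panel)):
            raise FormatError(
                f"expression array shape {values.shape} does not match "
                f"{len(genes)} genes x {len(panel)} samples"
            )
        with np.errstate(invalid="ignore"):
            if np.nanmin(values, initial=0.0) < 0:
                raise FormatError("expression values must be >= 0 (log2(TPM+1) scale)")
        self.condition = condition
        self.genes = list(genes)
        self.panel = panel
        self.values = values

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        idx = [index[g] for g in gene_ids]
        return ExpressionMatrix(self.condition, list(gene_ids), self.panel,
                                self.values[idx])


_REP_COL = re.compile(r"^(?P<sample>.+)__rep(?P<rep>\d+)$")


def read_expression(path, condition: str, n_replicates: int | None = None,
                    log2p1: bool = False) -> ExpressionMatrix:
    """Read a replicate-level expression TSV.

    Expected layout: a ``gene_id`` column plus one column per
    ``<sample>__rep<k>`` measurement.  ``NA`` becomes a missing value.  With
    ``log2p1=True`` raw values are transformed to log2(x+1); otherwise values
    are taken as already normalized.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise FormatError("expression TSV must have a gene_id column")
    genes = df["gene_id"].tolist()
    parsed = []
    for col in df.columns:
        if col == "gene_id":
            continue
        m = _REP_COL.match(col)
        if not m:
            raise FormatError(f"column {col!r} does not match <sample>__rep<k>")
        parsed.append((m.group("sample"), int(m.group("rep")), col))
    samples = list(dict.fromkeys(s for s, _, _ in parsed))
    reps_per_sample = {s: sorted(r for s2, r, _ in parsed if s2 == s) for s in samples}
    rep_counts = {len(v) for v in reps_per_sample.values()}
    if len(rep_counts) != 1:
        raise FormatError("replicate count differs across samples")
    n_reps = rep_counts.pop()
    if n_replicates is not None and n_reps != n_replicates:
        raise FormatError(f"expected {n_replicates} replicates, found {n_reps}")
    panel = SamplePanel.from_ids(samples)
    values = np.full((len(genes), len(samples), n_reps), np.nan)
    colmap = {(s, r): c for s, r, c in parsed}
    for j, s in enumerate(samples):
        for k, r in enumerate(reps_per_sample[s]):
            values[:, j, k] = pd.to_numeric(df[colmap[(s, r)]], errors="coerce").to_numpy()
    if log2p1:
        values = np.log2(values + 1.0)
    return ExpressionMatrix(condition, genes, panel, values)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    cols = {"gene_id": matrix.genes}
    for j, s in enumerate(matrix.panel.samples):
        for k in range(matrix.n_replicates):
            cols[f"{s}__rep{k + 1}"] = matrix.values[:, j, k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, na_rep="NA",
                              float_format="%.6g")


# ---------------------------------------------------------------------------
# per-site fitness-consequence scores
# ---------------------------------------------------------------------------

def read_site_scores(path) -> pd.DataFrame:
    """Read a (chrom, pos, rho) TSV of per-site fitness-consequence scores."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "rho"}
    if not required.issubset(df.columns):
        raise FormatError(f"site-score TSV must have columns {sorted(required)}")
    if ((df["rho"] < 0) | (df["rho"] > 1)).any():
        bad = df.loc[(df.rho < 0) | (df.rho > 1)].iloc[0]
        raise FormatError(f"rho = {bad.rho} at {bad.chrom}:{bad.pos} outside [0, 1]")
    return df[["chrom", "pos", "rho"]]


def attach_site_scores(variants: VariantTable, scores: pd.DataFrame) -> int:
    """Attach rho to SNP records matching on (chrom, pos); returns the number
    of score rows that matched a SNP.  Unmatched SNPs keep NaN; unmatched
    score rows are counted in the log only."""
    if ((scores["rho"] < 0) | (scores["rho"] > 1)).any():
        raise FormatError("rho outside [0, 1]")
    lookup = {(c, int(p)): r for c, p, r in
              zip(scores["chrom"], scores["pos"], scores["rho"])}
    matched = 0
    rho = variants.sites["rho"].to_numpy(copy=True)
    is_snp = (variants.sites["vclass"] == SNP).to_numpy()
    for i, (c, p) in enumerate(zip(variants.sites["chrom"], variants.sites["pos"])):
        if is_snp[i] and (c, int(p)) in lookup:
            rho[i] = lookup[(c, int(p))]
            matched += 1
    variants.sites["rho"] = rho
    unmatched = len(scores) - matched
    if unmatched:
        logger.info("%d site-score rows had no matching SNP", unmatched)
    return matched
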