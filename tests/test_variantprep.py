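"""Variant filters, SV merging and rare-variant selection, checked against
hand-enumerated examples and a brute-force per-variant oracle."""

import numpy as np
import pytest

from rareburden import make_fixture
from rareburden.formats import MISSING, SamplePanel, VariantRecord, VariantTable
from rareburden.variantprep import (
    apply_hard_filters, compute_allele_frequency, exclude_intra_sample_overlaps,
    filter_sv_records, merge_svs, select_rare_variants,
)

from conftest import make_panel, snp, table_of


def sv(vid, vclass, pos, end, genotypes, panel, sample=None, **ann):
    length = 0 if vclass == "BND" else end - pos + 1
    return VariantRecord(variant_id=vid, chrom="chr1", pos=pos, end=end,
                         ref="N", alt=f"<{vclass}>", vclass=vclass,
                         length=length,
                         genotypes=np.asarray(genotypes, dtype=np.int8),
                         annotations=ann, source_sample=sample)


def indel(vid, pos, length, genotypes, panel, **ann):
    return VariantRecord(variant_id=vid, chrom="chr1", pos=pos,
                         end=pos + length, ref="A" * (length + 1), alt="A",
                         vclass="INDEL", length=length,
                         genotypes=np.asarray(genotypes, dtype=np.int8),
                         annotations=ann)


# ---------------------------------------------------------------------------
# hard filters
# ---------------------------------------------------------------------------

class TestHardFilters:
    def test_examples(self):
        panel = make_panel(2)
        good = dict(qd=10, fs=10, mq=60, sor=1, mq_rank_sum=0,
                    read_pos_rank_sum=0)
        records = [
            snp("pass", 100, [0, 1], panel, **good),
            snp("lowmq", 200, [0, 1], panel, **{**good, "mq": 39}),
            indel("okindel", 300, 5, [0, 1], panel, qd=10, fs=100, sor=5),
            indel("longindel", 400, 25, [0, 1], panel, qd=10, fs=100, sor=5),
        ]
        kept = apply_hard_filters(table_of(records, panel))
        assert kept.sites.variant_id.tolist() == ["pass", "okindel"]

    def test_absent_annotation_passes(self):
        # rank-sum annotations are only emitted at het sites; hom-only
        # records must not be dropped for lacking them
        panel = make_panel(2)
        rec = snp("homonly", 100, [0, 2], panel, qd=10, fs=10, mq=60, sor=1)
        kept = apply_hard_filters(table_of([rec], panel))
        assert len(kept) == 1

    def test_idempotent(self, planted_sim):
        once = apply_hard_filters(planted_sim.variants)
        twice = apply_hard_filters(once)
        assert twice.sites.variant_id.tolist() == once.sites.variant_id.tolist()


# ---------------------------------------------------------------------------
# SV filters
# ---------------------------------------------------------------------------

class TestSvFilters:
    def test_depth_and_size_rules(self):
        panel = make_panel(2)
        records = [
            sv("del_ok", "DEL", 100, 399, [0, 1], panel, dhffc=0.60),
            sv("del_shallow", "DEL", 1000, 1299, [0, 1], panel, dhffc=0.80),
            sv("del_noann", "DEL", 2000, 2299, [0, 1], panel),
            sv("dup_weak", "DUP", 3000, 3299, [0, 1], panel, dhbfc=1.20),
            sv("dup_ok", "DUP", 4000, 4299, [0, 1], panel, dhbfc=1.50),
            sv("del_huge", "DEL", 5000, 255000, [0, 1], panel, dhffc=0.50),
            sv("inv_small", "INV", 300000, 300015, [0, 1], panel),  # 16 bp <= 20
            sv("bnd", "BND", 400000, 400000, [0, 1], panel),
        ]
        kept = filter_sv_records(table_of(records, panel))
        assert kept.sites.variant_id.tolist() == ["del_ok", "dup_ok", "bnd"]

    def test_idempotent(self):
        panel = make_panel(2)
        records = [sv("a", "DEL", 100, 399, [0, 1], panel, dhffc=0.6),
                   sv("b", "DUP", 1000, 1299, [0, 1], panel, dhbfc=1.5)]
        once = filter_sv_records(table_of(records, panel))
        twice = filter_sv_records(once)
        assert twice.sites.variant_id.tolist() == once.sites.variant_id.tolist()


class TestIntraSampleOverlap:
    def _calls(self, specs, panel):
        out = []
        for vid, sample, a, b in specs:
            g = np.zeros(len(panel), dtype=np.int8)
            g[panel.index(sample)] = 2
            out.append(sv(vid, "DEL", a, b, g, panel, sample=sample, dhffc=0.5))
        return table_of(out, panel)

    def test_same_sample_overlap_removed(self):
        panel = SamplePanel.from_ids(["A", "B"])
        table = self._calls([("x", "A", 100, 200), ("y", "A", 150, 300)], panel)
        assert len(exclude_intra_sample_overlaps(table)) == 0

    def test_cross_sample_overlap_kept(self):
        panel = SamplePanel.from_ids(["A", "B"])
        table = self._calls([("x", "A", 100, 200), ("y", "B", 150, 300)], panel)
        assert len(exclude_intra_sample_overlaps(table)) == 2

    def test_abutting_intervals_kept(self):
        # [100,200] and [201,300] share no base under inclusive coordinates
        panel = SamplePanel.from_ids(["A"])
        table = self._calls([("x", "A", 100, 200), ("y", "A", 201, 300)], panel)
        assert len(exclude_intra_sample_overlaps(table)) == 2


# ---------------------------------------------------------------------------
# SV merging
# ---------------------------------------------------------------------------

class TestMergeSvs:
    def test_boundary_cases(self):
        fx = make_fixture("merge_cases")
        merged, report = merge_svs(fx.per_sample_svs)
        assert len(merged) == fx.expected_n_merged
        member_sets = [set(m.split(",")) for m in report.members]
        for pair in fx.expected_merged_pairs:
            assert set(pair) in member_sets
        # the 20%-overlap DEL pair stays separate
        assert {"aloneA"} in member_sets and {"aloneB"} in member_sets
        assert {"bndC"} in member_sets and {"bndD"} in member_sets

    def test_merged_genotypes_are_the_union(self):
        fx = make_fixture("merge_cases")
        merged, report = merge_svs(fx.per_sample_svs)
        i = next(i for i, m in enumerate(report.members)
                 if set(m.split(",")) == {"mergeA", "mergeB"})
        np.testing.assert_array_equal(merged.gt[i], [2, 2])

    def test_representative_is_first_member(self):
        fx = make_fixture("merge_cases")
        merged, report = merge_svs(fx.per_sample_svs)
        i = next(i for i, m in enumerate(report.members)
                 if set(m.split(",")) == {"mergeA", "mergeB"})
        assert (merged.sites.pos.iloc[i], merged.sites.end.iloc[i]) == (100, 199)

    def test_order_independent(self):
        fx = make_fixture("merge_cases")
        table = fx.per_sample_svs
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(table))
        _, rep1 = merge_svs(table)
        _, rep2 = merge_svs(table.subset(perm))
        sets1 = {frozenset(m.split(",")) for m in rep1.members}
        sets2 = {frozenset(m.split(",")) for m in rep2.members}
        assert sets1 == sets2


# ---------------------------------------------------------------------------
# allele frequency and rare selection
# ---------------------------------------------------------------------------

class TestAlleleFrequency:
    def test_three_hets_among_129(self):
        panel = make_panel(129)
        g = np.zeros(129, dtype=np.int8)
        g[:3] = 1
        freq = compute_allele_frequency(table_of([snp("v", 1, g, panel)], panel))
        assert freq.alt_freq.iloc[0] == pytest.approx(3 / 258)

    def test_monomorphic(self):
        panel = make_panel(10)
        freq = compute_allele_frequency(
            table_of([snp("v", 1, np.zeros(10), panel)], panel))
        assert freq.alt_freq.iloc[0] == 0.0

    def test_seven_homs_not_rare(self):
        panel = make_panel(129)
        g = np.zeros(129, dtype=np.int8)
        g[:7] = 2
        freq = compute_allele_frequency(table_of([snp("v", 1, g, panel)], panel))
        assert freq.alt_freq.iloc[0] == pytest.approx(14 / 258)
        assert freq.maf.iloc[0] >= 0.05

    def test_missing_excluded_from_both_sides(self):
        panel = make_panel(4)
        g = np.array([1, 0, MISSING, MISSING], dtype=np.int8)
        freq = compute_allele_frequency(table_of([snp("v", 1, g, panel)], panel))
        assert freq.alt_freq.iloc[0] == pytest.approx(1 / 4)
        assert freq.n_called.iloc[0] == 2


class TestSelectRare:
    def test_evidence_rule_examples(self):
        panel = make_panel(129)

        def geno(*pairs):
            g = np.zeros(129, dtype=np.int8)
            for i, v in pairs:
                g[i] = v
            return g

        records = [
            snp("two_hets", 1, geno((0, 1), (1, 1)), panel),          # out
            snp("three_hets", 2, geno((0, 1), (1, 1), (2, 1)), panel),  # in
            snp("one_hom", 3, geno((0, 2)), panel),                   # in
            sv("sv_single", "DEL", 100, 399, geno((0, 1)), panel, dhffc=0.5),  # in
        ]
        rare = select_rare_variants(table_of(records, panel))
        assert rare.variants.sites.variant_id.tolist() == [
            "three_hets", "one_hom", "sv_single"]

    def test_major_alt_minor_is_ref(self):
        # alt fixed in all but one ref-hom sample: the reference allele is
        # the minor one and its carrier set is the ref carriers
        panel = make_panel(129)
        g = np.full(129, 2, dtype=np.int8)
        g[5] = 0
        rare = select_rare_variants(table_of([snp("v", 1, g, panel)], panel))
        assert len(rare) == 1
        assert rare.maf[0] == pytest.approx(2 / 258)
        assert rare.carriers[0, 5] and rare.carriers[0].sum() == 1

    def test_monotone_in_threshold(self, planted_sim):
        v = planted_sim.variants
        sizes = [len(select_rare_variants(v, maf_threshold=t))
                 for t in (0.01, 0.03, 0.05, 0.10)]
        assert sizes == sorted(sizes)

    def test_brute_force_oracle(self):
        """select_rare_variants agrees with an exhaustive per-variant
        recount of alleles and carriers on small random panels."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(4, 9))
            panel = make_panel(n)
            m = int(rng.integers(5, 51))
            gt = rng.choice([-1, 0, 1, 2], size=(m, n),
                            p=[0.05, 0.55, 0.2, 0.2]).astype(np.int8)
            vclasses = rng.choice(["SNP", "INDEL", "DEL"], size=m)
            records = []
            for i in range(m):
                if vclasses[i] == "DEL":
                    records.append(sv(f"v{i}", "DEL", 100 * i + 1, 100 * i + 50,
                                      gt[i], panel, dhffc=0.5))
                elif vclasses[i] == "INDEL":
                    records.append(indel(f"v{i}", 100 * i + 1, 3, gt[i], panel))
                else:
                    records.append(snp(f"v{i}", 100 * i + 1, gt[i], panel))
            threshold = float(rng.choice([0.05, 0.2, 0.4]))
            rare = select_rare_variants(table_of(records, panel), threshold)

            expected = []
            for i in range(m):
                called = [g for g in gt[i] if g != -1]
                if not called:
                    continue
                f = sum(called) / (2 * len(called))
                maf = min(f, 1 - f)
                if not (0 < maf < threshold):
                    continue
                minor_hom, het = (2, 1) if f <= 0.5 else (0, 1)
                n_hom = sum(1 for g in called if g == minor_hom)
                n_het = sum(1 for g in called if g == het)
                if vclasses[i] == "DEL" or n_hom >= 1 or n_het >= 3:
                    expected.append(f"v{i}")
            assert rare.variants.sites.variant_id.tolist() == expected, \
                f"trial {trial}"
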