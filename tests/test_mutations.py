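import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from evomex import mutations, simulate
from evomex.io import Feature, GenomeAnnotation, MutationRecord
from evomex.pipeline import TARGET_ALIASES, fixture_target_matrix


def _snp(pos, alt="T", lineage="F1", seqid="chr1", **extra):
    return MutationRecord(
        type="SNP", seqid=seqid, position=pos, new_seq=alt, lineage=lineage, extra=extra
    )


class TestMarginalFilter:
    def test_equal_read_mix_excluded(self):
        rec = _snp(10, new_read_count="10", ref_read_count="10")
        assert mutations.filter_marginal_calls([rec]) == []

    def test_majority_mutant_kept(self):
        rec = _snp(10, new_read_count="11", ref_read_count="9")
        assert mutations.filter_marginal_calls([rec]) == [rec]

    def test_no_support_info_passes(self):
        rec = _snp(10)
        assert mutations.filter_marginal_calls([rec]) == [rec]

    def test_idempotent(self):
        records = [_snp(10, frequency="1.0"), _snp(20, frequency="0.3"), _snp(30)]
        once = mutations.filter_marginal_calls(records)
        assert mutations.filter_marginal_calls(once) == once


class TestAncestralFilter:
    def test_identical_allele_in_all_lineages_removed(self):
        records = [_snp(100, "T", lineage=f"F{i}") for i in range(1, 9)]
        assert mutations.filter_ancestral(records) == []

    def test_same_gene_different_alleles_retained(self):
        records = [_snp(100 + i, "T", lineage=f"F{i}") for i in range(1, 9)]
        assert mutations.filter_ancestral(records) == records

    def test_exactly_planted_contaminants_removed(self):
        cfg = simulate.MutationSimConfig(n_mutations_per_lineage=6, n_ancestral=3, seed=5)
        records, truth = simulate.simulate_mutations(cfg)
        kept = mutations.filter_ancestral(records)
        removed = [r for r in records if r not in kept]
        assert {r.allele_key() for r in removed} == set(truth["ancestral"])
        # idempotent and order-stable
        assert mutations.filter_ancestral(kept) == kept


class TestCodingEffect:
    def test_inframe_duplication_extension(self, toy_annotation):
        gene = toy_annotation.genes()[0]
        rec = MutationRecord(
            type="AMP",
            seqid=gene.seqid,
            position=gene.start + 30,
            size=141,
            new_copy_number=2,
        )
        out = mutations.annotate_coding_effect(rec, toy_annotation)
        assert out.coding_effect == "in-frame-dup(+47 aa)"
        assert mutations.protein_extension_aa(out) == 47

    def test_three_bp_duplication(self, toy_annotation):
        gene = toy_annotation.genes()[0]
        rec = MutationRecord(
            type="AMP", seqid=gene.seqid, position=gene.start + 9, size=3, new_copy_number=2
        )
        out = mutations.annotate_coding_effect(rec, toy_annotation)
        assert out.coding_effect == "in-frame-dup(+1 aa)"

    def test_non_triplet_duplication_frameshift(self, toy_annotation):
        gene = toy_annotation.genes()[0]
        rec = MutationRecord(
            type="AMP", seqid=gene.seqid, position=gene.start + 9, size=4, new_copy_number=2
        )
        out = mutations.annotate_coding_effect(rec, toy_annotation)
        assert out.coding_effect == "frameshift"

    def test_snp_effects_match_translation_oracle(self, toy_annotation):
        """Randomized coding SNPs: classification must agree with an
        independent single-codon translation."""
        rng = np.random.default_rng(17)
        seq = toy_annotation.sequences["chr1"]
        genes = toy_annotation.genes()
        n_checked = 0
        for _ in range(100):
            gene = genes[rng.integers(len(genes))]
            pos = int(rng.integers(gene.start, gene.end))
            ref = seq[pos]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rec = MutationRecord(type="SNP", seqid="chr1", position=pos, new_seq=alt)
            out = mutations.annotate_coding_effect(rec, toy_annotation)
            # oracle: translate only the affected codon
            offset = pos - gene.start
            codon_start = gene.start + 3 * (offset // 3)
            ref_codon = seq[codon_start : codon_start + 3]
            mut_codon = list(ref_codon)
            mut_codon[pos - codon_start] = alt
            aa_ref = str(Seq(ref_codon).translate())
            aa_mut = str(Seq("".join(mut_codon)).translate())
            if aa_ref == aa_mut:
                expected = "synonymous"
            elif aa_mut == "*":
                expected = "nonsense"
            else:
                expected = "missense"
            assert out.coding_effect == expected, (pos, ref, alt)
            n_checked += 1
        assert n_checked == 100

    def test_upstream_assignment_window(self, toy_annotation):
        gene = toy_annotation.genes()[1]
        near = MutationRecord(
            type="SNP", seqid="chr1", position=gene.start - 500, new_seq="T"
        )
        out = mutations.annotate_coding_effect(near, toy_annotation)
        assert out.relation == "intergenic-upstream"
        assert out.target == gene.locus_tag

    def test_outside_any_region_rejected(self, toy_annotation):
        rec = MutationRecord(type="SNP", seqid="nowhere", position=5, new_seq="A")
        with pytest.raises(ValueError, match="outside"):
            mutations.annotate_coding_effect(rec, toy_annotation)


class TestISMediatedDeletion:
    def test_617kb_deletion_detected(self):
        cfg = simulate.MutationSimConfig(
            n_mutations_per_lineage=0, is_deletion_span=617_000, seed=2
        )
        records, truth = simulate.simulate_mutations(cfg)
        calls = mutations.detect_is_mediated_deletion(records, truth["annotation"])
        assert len(calls) == 1
        assert calls[0].size == 617_000
        assert calls[0].is_family == "ISMex25"

    def test_unbounded_deletion_ignored(self, toy_annotation):
        rec = MutationRecord(type="DEL", seqid="chr1", position=100, size=500)
        assert mutations.detect_is_mediated_deletion([rec], toy_annotation) == []

    def test_removed_genes_match_interval_oracle(self):
        cfg = simulate.MutationSimConfig(
            n_mutations_per_lineage=0, is_deletion_span=30_000, seed=3
        )
        records, truth = simulate.simulate_mutations(cfg)
        ann = truth["annotation"]
        (call,) = mutations.detect_is_mediated_deletion(records, ann)
        expected = {
            f.locus_tag
            for f in ann.features
            if f.type == "CDS" and f.start >= call.start and f.end <= call.end
        }
        assert set(call.removed_genes) == expected


class TestTargetMatrix:
    def test_fixture_parallelism_counts(self):
        counts = mutations.parallelism_counts(fixture_target_matrix())
        assert counts["pCM410"] == 8
        assert counts["icuAB"] == 6
        assert counts["gshA"] == 5
        assert counts["kefB"] == 3
        assert counts["rpoA"] == 2
        assert counts["ATP_synthase"] == 2

    def test_empty_records_empty_matrix(self):
        assert mutations.build_target_matrix([]).empty

    def test_invariant_to_order_and_duplication(self):
        recs = [
            _snp(10, lineage="F1"),
            _snp(20, lineage="F2"),
            _snp(30, lineage="F2"),
        ]
        for r, tgt in zip(recs, ["A", "B", "A"]):
            r.target = tgt
        base = mutations.parallelism_counts(mutations.build_target_matrix(recs))
        shuffled = mutations.parallelism_counts(
            mutations.build_target_matrix(list(reversed(recs)) + recs)
        )
        pd.testing.assert_series_equal(base, shuffled)

    def test_counts_match_bruteforce_on_random_records(self):
        rng = np.random.default_rng(9)
        lineages = [f"F{i}" for i in range(1, 9)]
        records = []
        for _ in range(120):
            r = _snp(int(rng.integers(0, 1000)), lineage=str(rng.choice(lineages)))
            r.target = f"T{rng.integers(0, 12)}"
            records.append(r)
        counts = mutations.parallelism_counts(mutations.build_target_matrix(records))
        expected = {
            t: len({r.lineage for r in records if r.target == t})
            for t in {r.target for r in records}
        }
        assert counts.to_dict() == expected


class TestLineageSummary:
    def test_single_lineage_totals(self):
        recs = [_snp(i * 10) for i in range(4)]
        for r in recs:
            r.relation = "coding"
        summary = mutations.lineage_summary(recs)
        assert summary.loc["F1", "total"] == 4
        assert summary.loc["F1", "coding"] == 4

    def test_correlation_identity(self):
        counts = pd.Series([4, 11, 18], index=["F2", "F3", "F8"])
        rho, p = mutations.count_covariate_correlation(counts, counts)
        assert rho == pytest.approx(1.0)

    def test_correlation_needs_three_lineages(self):
        counts = pd.Series([4, 11], index=["F2", "F3"])
        with pytest.raises(ValueError, match="at least 3"):
            mutations.count_covariate_correlation(counts, counts)

    def test_spearman_matches_rank_pearson(self):
        rng = np.random.default_rng(31)
        idx = [f"F{i}" for i in range(1, 9)]
        counts = pd.Series(rng.integers(1, 30, 8), index=idx, dtype=float)
        cov = pd.Series(rng.normal(size=8), index=idx)
        rho, _ = mutations.count_covariate_correlation(counts, cov)
        manual = np.corrcoef(counts.rank(), cov.rank())[0, 1]
        assert rho == pytest.approx(manual)
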