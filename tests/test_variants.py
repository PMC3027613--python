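"""Marker-gene alignment, SNP signatures, variant binning, consensus."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from metapyro.synthetic import (
    apply_variant,
    default_variant_defs,
    generate_variant_reads,
    make_marker_reference,
)
from metapyro.variants import (
    SnpSignature,
    VariantError,
    align_to_reference,
    bin_variants,
    build_consensus,
    cluster_by_signature,
    snp_signature,
)

from conftest import min_compatible_partition

REF = make_marker_reference(length=1450, seed=7)


def partition_accuracy(groups, truth) -> float:
    """Best-matching fraction of reads co-assigned with their true
    variant (Hungarian assignment of groups to variants)."""
    true = dict(zip(truth.table["read_id"], truth.table["variant_id"]))
    labels = sorted(set(true.values()))
    m = np.zeros((len(groups), len(labels)))
    for gi, g in enumerate(groups):
        for rid in g.members:
            m[gi, labels.index(true[rid])] += 1
    rows, cols = linear_sum_assignment(-m)
    return m[rows, cols].sum() / m.sum()


class TestAlignment:
    def test_exact_substring_maps_to_offset(self):
        read = REF[300:500]
        aligned = align_to_reference("r", read, REF)
        assert aligned.ref_start == 300
        assert aligned.ref_end == 500
        assert aligned.n_mismatches == 0

    def test_single_planted_snp_reported(self):
        variant = apply_variant(REF, {350: "A" if REF[350] != "A" else "C"})
        aligned = align_to_reference("r", variant[300:500], REF)
        assert aligned.n_mismatches == 1
        assert aligned.bases[350] != REF[350]

    def test_noisy_read_recovers_planted_offset(self):
        rng = np.random.default_rng(5)
        read = list(REF[300:500])
        for pos in rng.choice(200, size=4, replace=False):  # 2% errors
            read[pos] = "ACGT"["ACGT".index(read[pos]) - 1]
        aligned = align_to_reference("r", "".join(read), REF)
        assert aligned.ref_start == 300

    def test_empty_read_rejected(self):
        with pytest.raises(VariantError):
            align_to_reference("r", "", REF)


class TestSignature:
    def test_error_free_reference_read_is_empty(self):
        aligned = align_to_reference("r", REF[100:400], REF)
        assert snp_signature(aligned, REF).snps == {}

    def test_planted_snps_recovered_exactly(self):
        snps = {120: "ACGT"["ACGT".index(REF[120]) - 1],
                340: "ACGT"["ACGT".index(REF[340]) - 1]}
        variant = apply_variant(REF, snps)
        aligned = align_to_reference("r", variant[50:600], REF)
        assert snp_signature(aligned, REF).snps == snps

    def test_snp_near_read_end_trimmed(self):
        pos = 303  # 3 aligned bases from the read start
        variant = apply_variant(REF, {pos: "ACGT"["ACGT".index(REF[pos]) - 1]})
        aligned = align_to_reference("r", variant[300:500], REF)
        assert pos not in snp_signature(aligned, REF, end_trim=5).snps
        assert pos in snp_signature(aligned, REF, end_trim=0).snps

    def test_position_outside_interval_rejected(self):
        with pytest.raises(VariantError):
            SnpSignature("r", {10: "A"}, (100, 200))


class TestClustering:
    def test_single_variant_single_group(self):
        defs = [default_variant_defs(REF, n_variants=1)[0]]
        reads, truth = generate_variant_reads(REF, defs, 30, error_rate=0.0, seed=1)
        groups, _, _ = bin_variants(reads, REF)
        assert len(groups) == 1
        assert len(groups[0].members) == 30

    def test_two_variants_exact_recovery(self):
        """Two variants differing at 3 positions; error-free reads each
        covering at least one diagnostic site split into exactly two
        ground-truth groups."""
        base = {500: "A", 650: "C", 800: "G"}
        snps_a = {p: (b if REF[p] != b else "T") for p, b in base.items()}
        rng = np.random.default_rng(2)
        reads = []
        truth_ids = []
        va = apply_variant(REF, snps_a)
        for i in range(40):
            which = i % 2
            seq = va if which == 0 else REF
            # overlapping 300 bp windows, each covering >= 1 of the
            # three diagnostic positions
            start = int(rng.integers(250, 751))
            reads.append((f"m{i}", seq[start:start + 300]))
            truth_ids.append(which)
        groups, _, _ = bin_variants(reads, REF)
        assert len(groups) == 2
        split = {
            frozenset(truth_ids[int(r[1:])] for r in g.members) for g in groups
        }
        assert split == {frozenset({0}), frozenset({1})}

    def test_seven_variants_132_reads(self):
        """The marker mixture the pipeline targets: 7 variants across
        132 reads with 0.5% sequencing error resolve into 7 groups at
        >= 95% partition accuracy."""
        defs = default_variant_defs(REF, n_variants=7)
        reads, truth = generate_variant_reads(REF, defs, 132, error_rate=0.005, seed=0)
        groups, _, _ = bin_variants(reads, REF)
        assert len(groups) == 7
        assert partition_accuracy(groups, truth) >= 0.95

    def test_group_count_matches_bruteforce_partition_on_toys(self):
        """On error-free toy mixtures where every pair of variants is
        distinguishable, the group count equals the brute-force minimal
        compatible partition (= number of planted variants)."""
        rng = np.random.default_rng(4)
        for n_var in (2, 3, 4, 5):
            defs = default_variant_defs(REF, n_variants=n_var, snp_spacing=120)
            # near-full-length reads so every read pair co-covers a
            # distinguishing position (the regime where minimal
            # partition and SNP clustering must coincide)
            reads, truth = generate_variant_reads(
                REF, defs, 8, error_rate=0.0, seed=int(rng.integers(1 << 16)),
                read_length_range=(1100, 1450),
            )
            aligned = {rid: align_to_reference(rid, seq, REF) for rid, seq in reads}
            sigs = [snp_signature(aligned[rid], REF) for rid, _ in reads]
            groups = cluster_by_signature(sigs)
            oracle = min_compatible_partition(
                [(s.snps, s.interval) for s in sigs]
            )
            n_true = truth.table["variant_id"].nunique()
            assert len(groups) == oracle == min(n_true, 8)

    def test_deterministic_and_id_invariant(self):
        defs = default_variant_defs(REF, n_variants=3)
        reads, _ = generate_variant_reads(REF, defs, 40, error_rate=0.005, seed=9)
        groups1, _, _ = bin_variants(reads, REF)
        groups2, _, _ = bin_variants(reads, REF)
        assert [g.members for g in groups1] == [g.members for g in groups2]
        # relabel read ids, preserving order
        relabeled = [(f"x{i}", seq) for i, (_, seq) in enumerate(reads)]
        groups3, _, _ = bin_variants(relabeled, REF)
        orig_idx = [sorted(int(r[1:]) for r in g.members) for g in groups1]
        new_idx = [sorted(int(r[1:]) for r in g.members) for g in groups3]
        assert orig_idx == new_idx


class TestConsensus:
    def test_single_error_free_read(self):
        aligned = {"r": align_to_reference("r", REF[100:400], REF)}
        sig = snp_signature(aligned["r"], REF)
        group = cluster_by_signature([sig])[0]
        consensus = build_consensus(group, aligned, REF)
        # covered columns are uppercase read bases; the rest lowercase reference
        assert consensus[100:400] == REF[100:400]
        assert consensus[:100] == REF[:100].lower()
        assert consensus[400:] == REF[400:].lower()

    def test_error_free_group_reproduces_template(self):
        defs = [default_variant_defs(REF, n_variants=1)[0]]
        variant = apply_variant(REF, defs[0])
        reads, _ = generate_variant_reads(REF, defs, 40, error_rate=0.0, seed=3)
        groups, consensus, _ = bin_variants(reads, REF)
        covered = [i for i, c in enumerate(consensus["variant_1"]) if c.isupper()]
        got = consensus["variant_1"]
        assert all(got[i] == variant[i] for i in covered)

    def test_noisy_group_majority_recovers_template_at_depth(self):
        """1% errors wash out at columns with depth >= 5."""
        defs = [default_variant_defs(REF, n_variants=1)[0]]
        variant = apply_variant(REF, defs[0])
        reads, _ = generate_variant_reads(REF, defs, 20, error_rate=0.01, seed=8)
        groups, _, aligned = bin_variants(reads, REF)
        # reads with many errors may stay unclustered; the main group
        # must carry the bulk of the reads
        main = max(groups, key=lambda g: len(g.members))
        assert len(main.members) >= 15
        got = build_consensus(main, aligned, REF, min_depth=5)
        for i, c in enumerate(got):
            if c.isupper():
                assert c == variant[i]

    def test_tie_resolves_to_reference_base(self):
        other = "A" if REF[200] != "A" else "C"
        v = apply_variant(REF, {200: other})
        aligned = {
            "a": align_to_reference("a", REF[100:300], REF),
            "b": align_to_reference("b", v[100:300], REF),
        }
        sigs = [snp_signature(aligned[r], REF, end_trim=0) for r in ("a", "b")]
        group = cluster_by_signature(sigs)  # one SNP-free, one with the SNP
        merged = VariantGroupUnion(group)
        consensus = build_consensus(merged, aligned, REF)
        assert consensus[200] == REF[200]  # 1 vs 1 tie -> reference


def VariantGroupUnion(groups):
    """Collapse groups into one (for tie tests where the clusterer
    correctly keeps conflicting reads apart)."""
    base = groups[0]
    for g in groups[1:]:
        base.members.extend(g.members)
        base.intervals.extend(g.intervals)
        for pos, bases in g.support.items():
            slot = base.support.setdefault(pos, {})
            for b, c in bases.items():
                slot[b] = slot.get(b, 0) + c
    return base
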