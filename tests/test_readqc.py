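"""Read QC: GC computation, profile building, endpoint detection,
length filtering and duplicate removal."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from metapyro.readqc import (
    FilterReport,
    QCParams,
    Read,
    ReadQCError,
    build_gc_profile,
    detect_linear_endpoint,
    filter_by_length,
    gc_fraction,
    normalize_dataset,
    profile_from_arrays,
    remove_duplicates,
)
from metapyro.synthetic import (
    CommunitySpec,
    TaxonSpec,
    default_community,
    generate_reads,
    synthetic_gc_series,
)

from conftest import two_segment_breakpoint


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("GCGC", 1.0),
        ("ATAT", 0.0),
        ("ACGTN", 0.5),  # N excluded from numerator and denominator
        ("acgt", 0.5),
        ("GCN", 1.0),
    ],
)
def test_gc_fraction(seq, expected):
    assert gc_fraction(seq) == pytest.approx(expected)


@pytest.mark.parametrize("seq", ["", "NNN"])
def test_gc_fraction_undefined(seq):
    with pytest.raises(ReadQCError):
        gc_fraction(seq)


class TestGCProfile:
    def test_single_length_class(self):
        reads = [Read(f"r{i}", "ACGT" * 25) for i in range(100)]
        profile = build_gc_profile(reads)
        assert len(profile) == 1
        assert profile.lengths[0] == 100
        assert profile.n_reads[0] == 100
        assert profile.mean_gc[0] == pytest.approx(0.5)

    def test_two_length_classes(self):
        reads = [Read(f"a{i}", "A" * 100) for i in range(20)]
        reads += [Read(f"b{i}", "G" * 101) for i in range(20)]
        profile = build_gc_profile(reads)
        assert list(profile.lengths) == [100, 101]
        assert list(profile.mean_gc) == [0.0, 1.0]

    def test_sparse_lengths_excluded(self):
        reads = [Read(f"r{i}", "ACGT" * 25) for i in range(19)]
        assert len(build_gc_profile(reads, min_reads_per_point=20)) == 0

    def test_flat_community_within_binomial_bound(self):
        """A single-taxon 50% GC community with no drift gives a flat
        profile; each per-length mean stays within 3 binomial sd."""
        spec = CommunitySpec(
            taxa=(TaxonSpec("t", (("superkingdom", "Bacteria"),), 0.5, 1.0),),
            n_reads=60_000,
            backfold_breakpoint=None,
            gc_concentration=1e9,  # suppress the between-read beta spread
            seed=42,
        )
        reads, _ = generate_reads(spec)
        lens = np.array([len(r) for r in reads])
        gcs = np.array([gc_fraction(r.sequence) for r in reads])
        profile = profile_from_arrays(lens, gcs)
        # binomial sd of a mean of n_reads reads of given length; the
        # bound is per-point 4.5 sd, accounting for ~500 simultaneous
        # length classes (a 3 sd per-point bound would be expected to
        # fail somewhere by chance alone)
        sd = np.sqrt(0.25 / profile.lengths / profile.n_reads)
        assert np.all(np.abs(profile.mean_gc - 0.5) <= 4.5 * sd)


class TestEndpointDetection:
    def test_perfect_line_has_no_threshold(self):
        profile = synthetic_gc_series(n_points=300, slope=1e-4, noise_sd=0.0)
        result = detect_linear_endpoint(profile)
        assert result.threshold is None

    def test_planted_abrupt_drop_recovered(self):
        profile = synthetic_gc_series(
            n_points=500, breakpoint=400, step_drop=0.02, noise_sd=0.002, seed=5
        )
        result = detect_linear_endpoint(profile)
        assert result.threshold is not None
        assert 390 <= result.threshold <= 415
        oracle = two_segment_breakpoint(profile.lengths, profile.mean_gc)
        assert abs(result.threshold - oracle) <= 25

    def test_agrees_with_two_segment_oracle_on_generated_reads(self):
        """Reads generated with a planted backfolding breakpoint yield a
        mean-GC series whose independent two-segment change-point lies
        within +/-15 bp of the planted value."""
        spec = default_community(
            n_reads=200_000, duplicate_rate=0.0, backfold_breakpoint=400, seed=2
        )
        spec = CommunitySpec(**{**spec.__dict__, "backfold_gc_drop": 0.002})
        reads, truth = generate_reads(spec)
        lens = np.array([len(r) for r in reads])
        gcs = np.array([gc_fraction(r.sequence) for r in reads])
        profile = profile_from_arrays(lens, gcs)
        # stay inside the range where the decline is linear (beyond
        # ~550 bp the lowest-GC taxa saturate at the model floor)
        keep = profile.lengths <= 550
        oracle = two_segment_breakpoint(profile.lengths[keep], profile.mean_gc[keep])
        assert abs(oracle - truth.breakpoint) <= 15

    def test_too_few_points_is_explicit_error(self):
        profile = synthetic_gc_series(n_points=20)
        with pytest.raises(ReadQCError, match="points"):
            detect_linear_endpoint(profile)

    @given(shift=st.floats(min_value=-0.3, max_value=0.3))
    def test_invariant_under_constant_gc_shift(self, shift):
        """Adding a constant to all means changes the intercept only."""
        base = synthetic_gc_series(
            n_points=400, breakpoint=350, step_drop=0.015, noise_sd=0.002, seed=9
        )
        shifted = synthetic_gc_series(
            n_points=400, breakpoint=350, step_drop=0.015, noise_sd=0.002, seed=9,
            intercept=0.52 + shift,
        )
        r1 = detect_linear_endpoint(base)
        r2 = detect_linear_endpoint(shifted)
        assert r1.threshold == r2.threshold
        assert r1.slope == pytest.approx(r2.slope, abs=1e-12)

    def test_fixed_window_mode_detects_strong_drop(self):
        """Without absorbing points the fit never grows past the first
        30, so prediction error inflates with extrapolation distance; a
        strong drop near the window is still detected."""
        profile = synthetic_gc_series(
            n_points=500, breakpoint=250, step_drop=0.05, noise_sd=0.002, seed=5
        )
        result = detect_linear_endpoint(profile, fixed_window=True)
        assert result.threshold is not None
        assert 240 <= result.threshold <= 265


class TestLengthFilter:
    def test_no_threshold_keeps_all(self):
        reads = [Read("a", "ACGT" * 30), Read("b", "ACGT")]
        kept, removed = filter_by_length(reads, None)
        assert kept == reads and removed == 0

    def test_strictly_longer_than(self):
        reads = [Read("a", "A" * 100), Read("b", "A" * 262), Read("c", "A" * 263)]
        kept, removed = filter_by_length(reads, 262)
        assert [r.read_id for r in kept] == ["a", "b"]
        assert removed == 1


class TestDuplicateRemoval:
    def test_identical_reads_collapse(self):
        reads = [Read("a", "ACGTACGTACGTACGTACGTACGT"),
                 Read("b", "ACGTACGTACGTACGTACGTACGT")]
        reps, dup_map = remove_duplicates(reads)
        assert len(reps) == 1
        assert dup_map == {"b": "a"}

    def test_prefix_copy_with_one_substitution_is_duplicate(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        copy = list(seq[:90])
        copy[50] = "A" if copy[50] != "A" else "C"  # identity 89/90 >= 0.96
        reads = [Read("long", seq), Read("dup", "".join(copy))]
        reps, dup_map = remove_duplicates(reads)
        assert [r.read_id for r in reps] == ["long"]
        assert dup_map == {"dup": "long"}

    def test_different_first_base_not_duplicate(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        other = ("A" if seq[0] != "A" else "C") + seq[1:]
        reps, dup_map = remove_duplicates([Read("a", seq), Read("b", other)])
        assert len(reps) == 2 and not dup_map

    def test_longest_read_is_representative(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        reads = [Read("short", seq[:90]), Read("long", seq)]
        reps, dup_map = remove_duplicates(reads)
        assert [r.read_id for r in reps] == ["long"]
        assert dup_map == {"short": "long"}

    def test_idempotent(self):
        spec = default_community(n_reads=4000, duplicate_rate=0.2, seed=3)
        reads, _ = generate_reads(spec)
        reps, dup_map = remove_duplicates(reads)
        reps2, dup_map2 = remove_duplicates(reps)
        assert [r.read_id for r in reps2] == [r.read_id for r in reps]
        assert dup_map2 == {}

    def test_recovers_planted_duplicate_fraction(self):
        """Planted emPCR duplicates at rate 0.1 are recovered within 1%."""
        spec = default_community(
            n_reads=20_000, duplicate_rate=0.10, backfold_breakpoint=None, seed=11
        )
        reads, truth = generate_reads(spec)
        _, dup_map = remove_duplicates(reads)
        frac = len(dup_map) / len(reads)
        assert abs(frac - 0.10) <= 0.01
        # and the removed reads really are planted duplicates
        planted = set(
            truth.table.loc[truth.table.read_id != truth.table.dup_group, "read_id"]
        )
        false_removals = set(dup_map) - planted
        assert len(false_removals) / len(reads) < 0.005


class TestNormalizeDataset:
    def test_clean_dataset_passes_through(self):
        spec = default_community(
            n_reads=3000, duplicate_rate=0.0, backfold_breakpoint=None, seed=7
        )
        reads, _ = generate_reads(spec)
        kept, report, _ = normalize_dataset(reads)
        assert report.reads_out == len(reads)
        assert report.removed_length == report.removed_duplicates == 0
        assert [r.read_id for r in kept] == [r.read_id for r in reads]

    def test_report_conservation(self):
        spec = default_community(n_reads=20_000, duplicate_rate=0.1,
                                 backfold_gc_drop=0.004, seed=13)
        reads, _ = generate_reads(spec)
        _, report, _ = normalize_dataset(reads)
        assert report.reads_in == (
            report.reads_out + report.removed_length + report.removed_duplicates
        )
        assert report.removed_length > 0  # breakpoint found and applied

    def test_empty_input(self):
        kept, report, endpoint = normalize_dataset([])
        assert kept == [] and report.reads_in == report.reads_out == 0
        assert endpoint is None

    def test_report_rejects_non_conserving_counts(self):
        with pytest.raises(ReadQCError):
            FilterReport(reads_in=10, removed_length=1, removed_duplicates=1,
                         reads_out=9)
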