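"""GC-bias endpoint detection and duplicate removal.

Generates a 20,000-read community with a planted backfolding breakpoint
at 400 bp and 10% emPCR duplicates, then runs the full normalization.
"""

from metapyro import QCParams, default_community, generate_reads, normalize_dataset

spec = default_community(
    n_reads=20_000, duplicate_rate=0.10,
    backfold_breakpoint=400, backfold_gc_drop=0.004, seed=0,
)
reads, truth = generate_reads(spec)
kept, report, endpoint = normalize_dataset(reads, QCParams())

print(f"planted breakpoint : {truth.breakpoint} bp")
print(f"detected threshold : {report.threshold} bp")
print(f"reads in           : {report.reads_in}")
print(f"removed (length)   : {report.removed_length}")
print(f"removed (dupes)    : {report.removed_duplicates}")
print(f"reads out          : {report.reads_out}")

# The threshold should land a few bp past the planted breakpoint (the
# decline must accumulate past the noise floor before ten consecutive
# points reject the linear trend); every read longer than it is removed
# before duplicates are collapsed to their longest representative.
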