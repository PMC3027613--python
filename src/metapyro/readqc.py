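"""Read-level normalization for pyrosequencing metagenome datasets.

Long pyrosequencing reads show a systematic decline in mean GC content:
GC-rich single-stranded fragments fold back on themselves during
emulsion PCR, truncating amplification, so the surviving long reads are
AT-biased ("backfolding").  Left uncorrected this depresses the apparent
abundance of GC-rich organisms.  The normalization here

1. profiles mean GC per integer read length,
2. fits the linear phase of that profile and walks outward, flagging
   points whose externally studentized residual rejects the linear
   trend; a run of consecutive outliers marks the end of the linear
   phase and its first length becomes the filtering threshold,
3. removes reads longer than the threshold, and
4. collapses emulsion-PCR duplicate reads (near-identical copies
   starting at the same template position) to one representative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from scipy import stats


class ReadQCError(ValueError):
    pass


@dataclass(frozen=True)
class Read:
    """A sequencing read; GC fraction is computed lazily from sequence."""

    read_id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T) of a nucleotide string; N is excluded from both
    numerator and denominator.

    Raises ReadQCError for empty or all-N input, where the fraction is
    undefined.
    """
    if not sequence:
        raise ReadQCError("GC fraction of empty sequence is undefined")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise ReadQCError("GC fraction undefined: no A/C/G/T bases")
    return gc / (gc + at)


@dataclass
class GCLengthProfile:
    """Mean GC per integer read length.

    Lengths are strictly increasing; points supported by fewer than
    ``min_reads_per_point`` reads are excluded at construction, since
    sparse length classes in the tail otherwise dominate the residual
    variance of the endpoint scan.
    """

    lengths: np.ndarray  # int, strictly increasing
    n_reads: np.ndarray  # int, >= min_reads_per_point
    mean_gc: np.ndarray  # float in [0, 1]
    min_reads_per_point: int = 20

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=int)
        self.n_reads = np.asarray(self.n_reads, dtype=int)
        self.mean_gc = np.asarray(self.mean_gc, dtype=float)
        if not (len(self.lengths) == len(self.n_reads) == len(self.mean_gc)):
            raise ReadQCError("profile arrays must have equal length")
        if len(self.lengths) > 1 and not np.all(np.diff(self.lengths) > 0):
            raise ReadQCError("profile lengths must be strictly increasing")
        if np.any((self.mean_gc < 0) | (self.mean_gc > 1)):
            raise ReadQCError("mean GC outside [0, 1]")

    def __len__(self) -> int:
        return len(self.lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length": self.lengths, "n_reads": self.n_reads, "mean_gc": self.mean_gc}
        )


def build_gc_profile(
    reads: Iterable[Read], min_reads_per_point: int = 20
) -> GCLengthProfile:
    """One profile point per integer read length with enough support."""
    by_len: dict[int, list[float]] = {}
    for read in reads:
        by_len.setdefault(len(read), []).append(gc_fraction(read.sequence))
    lengths, ns, means = [], [], []
    for length in sorted(by_len):
        vals = by_len[length]
        if len(vals) >= min_reads_per_point:
            lengths.append(length)
            ns.append(len(vals))
            means.append(float(np.mean(vals)))
    return GCLengthProfile(
        np.array(lengths, dtype=int),
        np.array(ns, dtype=int),
        np.array(means, dtype=float),
        min_reads_per_point=min_reads_per_point,
    )


def profile_from_arrays(
    lengths: Sequence[int], gcs: Sequence[float], min_reads_per_point: int = 20
) -> GCLengthProfile:
    """Vectorized profile construction from parallel length/GC arrays."""
    lengths = np.asarray(lengths, dtype=int)
    gcs = np.asarray(gcs, dtype=float)
    order = np.argsort(lengths, kind="stable")
    lengths, gcs = lengths[order], gcs[order]
    uniq, start = np.unique(lengths, return_index=True)
    sums = np.add.reduceat(gcs, start)
    counts = np.diff(np.append(start, len(gcs)))
    keep = counts >= min_reads_per_point
    return GCLengthProfile(
        uniq[keep], counts[keep], sums[keep] / counts[keep],
        min_reads_per_point=min_reads_per_point,
    )


@dataclass
class EndpointResult:
    """Outcome of the linear-phase endpoint scan.

    ``threshold`` is the read length at the first point of the first run
    of ``run_length`` consecutive outliers, or None when the profile
    never leaves its linear trend.  ``tested`` tabulates every scanned
    point with its studentized residual and p-value.
    """

    threshold: int | None
    slope: float
    intercept: float
    tested: pd.DataFrame  # columns: length, t, p, outlier
    first_outlier_index: int | None

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "slope": self.slope,
            "intercept": self.intercept,
            "first_outlier_index": self.first_outlier_index,
        }


class _RunningOLS:
    """Simple linear regression with O(1) point insertion."""

    def __init__(self, x: np.ndarray, y: np.ndarray) -> None:
        self.n = len(x)
        self.sx = float(np.sum(x))
        self.sy = float(np.sum(y))
        self.sxx = float(np.sum(x * x))
        self.sxy = float(np.sum(x * y))
        self.syy = float(np.sum(y * y))

    def add(self, x: float, y: float) -> None:
        self.n += 1
        self.sx += x
        self.sy += y
        self.sxx += x * x
        self.sxy += x * y
        self.syy += y * y

    def fit(self) -> tuple[float, float, float, float, float]:
        """Return (slope, intercept, s2, xbar, sxx_centered)."""
        n = self.n
        xbar = self.sx / n
        ybar = self.sy / n
        sxx_c = self.sxx - n * xbar * xbar
        sxy_c = self.sxy - n * xbar * ybar
        syy_c = self.syy - n * ybar * ybar
        slope = sxy_c / sxx_c
        sse = max(syy_c - slope * sxy_c, 0.0)
        s2 = sse / (n - 2) if n > 2 else 0.0
        return slope, ybar - slope * xbar, s2, xbar, sxx_c


def detect_linear_endpoint(
    profile: GCLengthProfile,
    window_start: int = 100,
    window_size: int = 30,
    alpha: float = 0.05,
    run_length: int = 10,
    fixed_window: bool = False,
    one_sided: bool = False,
) -> EndpointResult:
    """Sequential outlier detection on the GC-versus-length profile.

    An ordinary least squares line is fitted to ``window_size`` profile
    points starting at the first length >= ``window_start`` (the early,
    high-variance part of the profile is skipped).  Points beyond the
    window are then inspected in increasing length order: each is tested
    as a *new* observation against the current fit via its externally
    studentized (prediction) residual, which under the linear null is
    t-distributed with n_fit − 2 degrees of freedom.  A p-value below
    ``alpha`` flags the point as an outlier; non-outliers are absorbed
    into the fit set and the line refit (unless ``fixed_window``).  The
    first run of ``run_length`` consecutive outliers ends the scan and
    its first point's length is the threshold.

    ``one_sided`` restricts outliers to points *below* the trend (the
    backfolding direction); the default is the directionless two-sided
    test.
    """
    start_idx = int(np.searchsorted(profile.lengths, window_start, side="left"))
    n_avail = len(profile) - start_idx
    if n_avail < window_size:
        raise ReadQCError(
            f"profile has {n_avail} points at lengths >= {window_start}, "
            f"need at least window_size={window_size}"
        )
    x = profile.lengths.astype(float)
    y = profile.mean_gc
    ols = _RunningOLS(x[start_idx : start_idx + window_size],
                      y[start_idx : start_idx + window_size])

    rows: list[tuple[int, float, float, bool]] = []
    run = 0
    run_start_idx: int | None = None
    threshold: int | None = None
    first_outlier_index: int | None = None

    for j in range(start_idx + window_size, len(profile)):
        slope, intercept, s2, xbar, sxx_c = ols.fit()
        resid = y[j] - (intercept + slope * x[j])
        if s2 <= 1e-24:
            # (numerically) perfect fit so far: any residual beyond
            # roundoff is an outlier
            deviates = abs(resid) > 1e-9
            t = np.inf if deviates else 0.0
            p = 0.0 if deviates else 1.0
            if one_sided and resid >= 0:
                p = 1.0
        else:
            se = np.sqrt(s2 * (1.0 + 1.0 / ols.n + (x[j] - xbar) ** 2 / sxx_c))
            t = resid / se
            df = ols.n - 2
            p = float(stats.t.cdf(t, df)) if one_sided else float(
                2.0 * stats.t.sf(abs(t), df)
            )
        outlier = p < alpha
        rows.append((int(x[j]), float(t), float(p), outlier))
        if outlier:
            run += 1
            if run == 1:
                run_start_idx = j
            if run == run_length:
                threshold = int(x[run_start_idx])
                first_outlier_index = run_start_idx
                break
        else:
            run = 0
            run_start_idx = None
            if not fixed_window:
                ols.add(x[j], y[j])

    slope, intercept, _, _, _ = ols.fit()
    tested = pd.DataFrame(rows, columns=["length", "t", "p", "outlier"])
    return EndpointResult(
        threshold=threshold,
        slope=slope,
        intercept=intercept,
        tested=tested,
        first_outlier_index=first_outlier_index,
    )


# -- filtering --------------------------------------------------------


def filter_by_length(
    reads: Sequence[Read], threshold: int | None
) -> tuple[list[Read], int]:
    """Drop reads strictly longer than the threshold (None keeps all)."""
    if threshold is None:
        return list(reads), 0
    kept = [r for r in reads if len(r) <= threshold]
    return kept, len(reads) - len(kept)


def remove_duplicates(
    reads: Sequence[Read], prefix_len: int = 20, identity: float = 0.96
) -> tuple[list[Read], dict[str, str]]:
    """Collapse emulsion-PCR duplicates to their longest representative.

    Duplicates begin at the same template position, so candidates are
    bucketed by an exact match of their first ``prefix_len`` bases.
    Within a bucket, reads are taken in descending length (ties broken
    by input order); a read is a duplicate of an earlier representative
    if it aligns end-gap-free against the representative's leading
    region with at least ``identity`` matching fraction over the
    shorter (read) length.  Reads shorter than ``prefix_len`` always
    form their own cluster.

    Returns the representatives in their original input order plus a
    map duplicate read_id -> representative read_id.  A second pass over
    the output removes nothing (idempotence).
    """
    if prefix_len < 1:
        raise ReadQCError("prefix_len must be >= 1")
    order = sorted(range(len(reads)), key=lambda i: (-len(reads[i]), i))
    buckets: dict[str, list[int]] = {}
    dup_map: dict[str, str] = {}
    rep_flags = [False] * len(reads)
    for i in order:
        read = reads[i]
        if len(read) < prefix_len:
            rep_flags[i] = True
            continue
        key = read.sequence[:prefix_len]
        assigned = False
        for ri in buckets.get(key, ()):
            rep = reads[ri]
            # end-gap-free alignment of the read against the leading
            # region of the (longer) representative
            res = edlib.align(read.sequence, rep.sequence, mode="SHW", task="distance")
            dist = res["editDistance"]
            if dist >= 0 and 1.0 - dist / len(read) >= identity:
                dup_map[read.read_id] = rep.read_id
                assigned = True
                break
        if not assigned:
            buckets.setdefault(key, []).append(i)
            rep_flags[i] = True
    representatives = [reads[i] for i in range(len(reads)) if rep_flags[i]]
    return representatives, dup_map


@dataclass
class FilterReport:
    """Read accounting across the normalization steps; always conserves
    reads_in = reads_out + removed_length + removed_duplicates."""

    reads_in: int
    removed_length: int
    removed_duplicates: int
    reads_out: int
    threshold: int | None = None

    def __post_init__(self) -> None:
        if self.reads_in != self.reads_out + self.removed_length + self.removed_duplicates:
            raise ReadQCError("FilterReport does not conserve reads")

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "removed_length": self.removed_length,
            "removed_duplicates": self.removed_duplicates,
            "reads_out": self.reads_out,
            "threshold": self.threshold,
        }


@dataclass
class QCParams:
    window_start: int = 100
    window_size: int = 30
    alpha: float = 0.05
    run_length: int = 10
    min_reads_per_point: int = 20
    prefix_len: int = 20
    identity: float = 0.96
    dedup: bool = True
    fixed_window: bool = False
    one_sided: bool = False


def normalize_dataset(
    reads: Sequence[Read], params: QCParams | None = None
) -> tuple[list[Read], FilterReport, EndpointResult | None]:
    """Full normalization: profile -> endpoint -> length filter -> dedup.

    Endpoint detection is skipped (no length filtering) when the profile
    is too short to support the scan window.
    """
    params = params or QCParams()
    profile = build_gc_profile(reads, params.min_reads_per_point)
    endpoint: EndpointResult | None = None
    threshold: int | None = None
    start_idx = int(np.searchsorted(profile.lengths, params.window_start))
    if len(profile) - start_idx >= params.window_size:
        endpoint = detect_linear_endpoint(
            profile,
            window_start=params.window_start,
            window_size=params.window_size,
            alpha=params.alpha,
            run_length=params.run_length,
            fixed_window=params.fixed_window,
            one_sided=params.one_sided,
        )
        threshold = endpoint.threshold
    kept, n_len = filter_by_length(reads, threshold)
    if params.dedup:
        kept, dup_map = remove_duplicates(kept, params.prefix_len, params.identity)
        n_dup = len(dup_map)
    else:
        n_dup = 0
    report = FilterReport(
        reads_in=len(reads),
        removed_length=n_len,
        removed_duplicates=n_dup,
        reads_out=len(kept),
        threshold=threshold,
    )
    return kept, report, endpoint
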