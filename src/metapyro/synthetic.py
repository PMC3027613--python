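"""Synthetic biogas-community data with full ground truth.

Every pipeline stage in this package consumes data that, in a real
study, comes from a sequencer or an external classifier/mapper.  This
module generates all of those inputs from a declarative community
specification, planting the phenomena the pipeline is built to detect —
a GC-versus-length decline with a breakpoint (emulating emPCR
backfolding), emulsion-PCR duplicate reads, classifier tables with
configurable noise, marker-gene variant mixtures, and read mappings
with depleted coverage on HGT-flagged genes — while recording the
ground truth for every read.

All randomness flows from integer seeds through ``numpy``'s Generator;
outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .coverage import GeneAnnotation
from .function import PathwayGroupMap
from .readqc import GCLengthProfile, Read
from .taxonomy import RANKS


class SpecError(ValueError):
    """Invalid community specification; the message names the field."""


# ---------------------------------------------------------------------
# community specification
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: lineage, genome GC and relative abundance."""

    taxon_id: str
    lineage: tuple[tuple[str, str], ...]  # (rank, name) pairs, broad to fine
    gc: float
    abundance: float


@dataclass(frozen=True)
class CommunitySpec:
    taxa: tuple[TaxonSpec, ...]
    n_reads: int = 20_000
    read_length_model: tuple[float, float, int, int] = (380.0, 110.0, 60, 700)
    backfold_breakpoint: int | None = 400
    backfold_gc_drop: float = 0.0
    linear_drift: float = 0.0
    duplicate_rate: float = 0.0
    marker_fraction: float = 0.01
    gc_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise SpecError("taxa: at least one taxon required")
        abundances = [t.abundance for t in self.taxa]
        if any(a <= 0 for a in abundances):
            raise SpecError("taxa: abundances must be positive")
        if abs(sum(abundances) - 1.0) > 1e-8:
            raise SpecError(f"taxa: abundances sum to {sum(abundances)}, expected 1")
        for t in self.taxa:
            if not 0.0 <= t.gc <= 1.0:
                raise SpecError(f"taxa: GC of {t.taxon_id!r} outside [0, 1]")
        mean, sd, lo, hi = self.read_length_model
        if not (lo <= mean <= hi):
            raise SpecError("read_length_model: need min <= mean <= max")
        if sd < 0:
            raise SpecError("read_length_model: sd must be >= 0")
        if lo < 1:
            raise SpecError("read_length_model: min length must be >= 1")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise SpecError("duplicate_rate: must be in [0, 1)")
        if not 0.0 <= self.marker_fraction <= 1.0:
            raise SpecError("marker_fraction: must be in [0, 1]")
        if self.gc_concentration <= 0:
            raise SpecError("gc_concentration: must be positive")
        if self.n_reads < 1:
            raise SpecError("n_reads: must be >= 1")
        if self.backfold_breakpoint is not None and self.backfold_breakpoint <= lo:
            raise SpecError("backfold_breakpoint: must exceed the minimum read length")


def default_community(
    n_reads: int = 20_000,
    duplicate_rate: float = 0.10,
    backfold_breakpoint: int | None = 400,
    backfold_gc_drop: float = 0.0008,
    seed: int = 0,
) -> CommunitySpec:
    """A small biogas-fermenter-like community: cellulolytic and
    fermentative Firmicutes/Bacteroidetes dominating, hydrogenotrophic
    Methanomicrobiales among the Archaea, with heterogeneous genome GC."""

    def lin(sk, ph, cl, od, fa, ge):
        return tuple(zip(RANKS[:6], (sk, ph, cl, od, fa, ge)))

    taxa = (
        TaxonSpec("clostridium", lin("Bacteria", "Firmicutes", "Clostridia",
                                     "Clostridiales", "Clostridiaceae", "Clostridium"),
                  0.37, 0.30),
        TaxonSpec("acetivibrio", lin("Bacteria", "Firmicutes", "Clostridia",
                                     "Clostridiales", "Ruminococcaceae", "Acetivibrio"),
                  0.41, 0.12),
        TaxonSpec("bacillus", lin("Bacteria", "Firmicutes", "Bacilli",
                                  "Bacillales", "Bacillaceae", "Bacillus"),
                  0.46, 0.10),
        TaxonSpec("streptococcus", lin("Bacteria", "Firmicutes", "Bacilli",
                                       "Lactobacillales", "Streptococcaceae",
                                       "Streptococcus"),
                  0.39, 0.06),
        TaxonSpec("bacteroides", lin("Bacteria", "Bacteroidetes", "Bacteroidia",
                                     "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
                  0.43, 0.15),
        TaxonSpec("dysgonomonas", lin("Bacteria", "Bacteroidetes", "Bacteroidia",
                                      "Bacteroidales", "Porphyromonadaceae",
                                      "Dysgonomonas"),
                  0.38, 0.05),
        TaxonSpec("pseudomonas", lin("Bacteria", "Proteobacteria",
                                     "Gammaproteobacteria", "Pseudomonadales",
                                     "Pseudomonadaceae", "Pseudomonas"),
                  0.62, 0.07),
        TaxonSpec("methanoculleus", lin("Archaea", "Euryarchaeota", "Methanomicrobia",
                                        "Methanomicrobiales", "Methanomicrobiaceae",
                                        "Methanoculleus"),
                  0.60, 0.09),
        TaxonSpec("methanosarcina", lin("Archaea", "Euryarchaeota", "Methanomicrobia",
                                        "Methanosarcinales", "Methanosarcinaceae",
                                        "Methanosarcina"),
                  0.42, 0.06),
    )
    return CommunitySpec(
        taxa=taxa,
        n_reads=n_reads,
        duplicate_rate=duplicate_rate,
        backfold_breakpoint=backfold_breakpoint,
        backfold_gc_drop=backfold_gc_drop,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Per-read truth: taxon, duplicate group, marker/variant labels.

    Every generated read appears exactly once in ``table``; a read's
    duplicate group is the id of the read it was copied from (its own
    id for originals).
    """

    table: pd.DataFrame  # read_id, taxon_id, dup_group, is_marker[, variant_id]
    breakpoint: int | None = None

    def __post_init__(self) -> None:
        if self.table["read_id"].duplicated().any():
            raise SpecError("ground truth lists a read more than once")

    def duplicate_groups(self) -> pd.Series:
        return self.table.groupby("dup_group").size()


# ---------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------

_LETTERS = np.frombuffer(b"ATCG", dtype=np.uint8)


def _sequences_from_gc(lengths: np.ndarray, gc_target: np.ndarray,
                       rng: np.random.Generator) -> list[str]:
    """Random sequences whose per-base GC probability is gc_target."""
    total = int(lengths.sum())
    per_base_gc = np.repeat(gc_target, lengths).astype(np.float32)
    is_gc = rng.random(total, dtype=np.float32) < per_base_gc
    which = rng.random(total, dtype=np.float32) < 0.5
    codes = _LETTERS[(is_gc.astype(np.uint8) << 1) | which.astype(np.uint8)]
    buf = codes.tobytes()
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    return [buf[offsets[i]:offsets[i + 1]].decode("ascii")
            for i in range(len(lengths))]


def _expected_gc(spec: CommunitySpec, taxon_gc: np.ndarray,
                 lengths: np.ndarray) -> np.ndarray:
    """Mean GC per read under the drift + backfolding model.

    The linear drift is anchored at the breakpoint (or the model mean
    length when no breakpoint is planted) so the community's overall GC
    stays near the genome values; beyond the breakpoint the mean drops
    by ``backfold_gc_drop`` per additional base.
    """
    bp = spec.backfold_breakpoint
    if bp is not None:
        mu = (
            taxon_gc
            + spec.linear_drift * (np.minimum(lengths, bp) - bp)
            - spec.backfold_gc_drop * np.maximum(lengths - bp, 0)
        )
    else:
        mu = taxon_gc + spec.linear_drift * (lengths - spec.read_length_model[0])
    return np.clip(mu, 0.02, 0.98)


def generate_reads(spec: CommunitySpec) -> tuple[list[Read], GroundTruth]:
    """Draw reads from the community with planted GC bias and duplicates.

    Originals: taxon per relative abundance; length from a truncated
    normal; per-read GC from a beta distribution centred on the
    taxon-and-length expected GC (concentration ``gc_concentration``);
    the sequence is then random with that per-base GC probability.
    Duplicates (``duplicate_rate`` of all reads) copy a random original
    from the same start, truncated by up to 10% and carrying up to 2%
    substitutions placed beyond the first 20 bases — pyrosequencing
    errors concentrate toward read ends, and this keeps the shared
    template start recognizable.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reads
    n_dup = int(round(spec.duplicate_rate * n))
    n_orig = n - n_dup

    abundances = np.array([t.abundance for t in spec.taxa])
    abundances = abundances / abundances.sum()
    taxon_idx = rng.choice(len(spec.taxa), size=n_orig, p=abundances)
    mean, sd, lo, hi = spec.read_length_model
    lengths = np.clip(np.rint(rng.normal(mean, sd, size=n_orig)), lo, hi).astype(int)
    taxon_gc = np.array([t.gc for t in spec.taxa])[taxon_idx]
    mu = _expected_gc(spec, taxon_gc, lengths)
    conc = spec.gc_concentration
    gc_target = rng.beta(mu * conc, (1.0 - mu) * conc)
    seqs = _sequences_from_gc(lengths, gc_target, rng)

    width = len(str(n))
    reads = [Read(f"r{i:0{width}d}", seq) for i, seq in enumerate(seqs)]
    taxon_ids = [spec.taxa[i].taxon_id for i in taxon_idx]
    dup_group = [r.read_id for r in reads]
    is_marker = rng.random(n_orig) < spec.marker_fraction

    # emPCR duplicates: near-copies of a random original
    if n_dup:
        originals = rng.integers(0, n_orig, size=n_dup)
        trunc = rng.uniform(0.0, 0.10, size=n_dup)
        for j, (oi, tr) in enumerate(zip(originals, trunc)):
            src = reads[oi].sequence
            keep = max(int(round(len(src) * (1.0 - tr))), 20)
            seq = bytearray(src[:keep], "ascii")
            n_sub = min(int(rng.binomial(keep, 0.01)), int(0.02 * keep))
            if n_sub and keep > 20:
                pos = rng.choice(np.arange(20, keep), size=min(n_sub, keep - 20),
                                 replace=False)
                for p in pos:
                    current = chr(seq[p])
                    choices = [b for b in "ACGT" if b != current]
                    seq[p] = ord(choices[rng.integers(0, 3)])
            rid = f"r{n_orig + j:0{width}d}"
            reads.append(Read(rid, seq.decode("ascii")))
            taxon_ids.append(taxon_ids[oi])
            dup_group.append(reads[oi].read_id)
            is_marker = np.append(is_marker, is_marker[oi])

    truth = GroundTruth(
        table=pd.DataFrame(
            {
                "read_id": [r.read_id for r in reads],
                "taxon_id": taxon_ids,
                "dup_group": dup_group,
                "is_marker": is_marker,
            }
        ),
        breakpoint=spec.backfold_breakpoint,
    )
    return reads, truth


# ---------------------------------------------------------------------
# profile-level series (for endpoint-detector studies)
# ---------------------------------------------------------------------


def synthetic_gc_series(
    n_points: int = 500,
    start_length: int = 50,
    intercept: float = 0.52,
    slope: float = 0.0,
    breakpoint: int | None = None,
    step_drop: float = 0.0,
    slope_drop: float = 0.0,
    noise_sd: float = 0.002,
    reads_per_point: int = 200,
    seed: int = 0,
) -> GCLengthProfile:
    """A per-length mean-GC series with an optional planted breakpoint.

    Below the breakpoint the mean follows ``intercept + slope*length``;
    at the breakpoint it drops by ``step_drop`` and additionally
    declines by ``slope_drop`` per base.  Gaussian point noise with
    standard deviation ``noise_sd`` emulates the sampling error of a
    per-length mean.
    """
    rng = np.random.default_rng(seed)
    lengths = np.arange(start_length, start_length + n_points)
    mean = intercept + slope * lengths.astype(float)
    if breakpoint is not None:
        beyond = lengths > breakpoint
        mean = mean - beyond * (step_drop + slope_drop * (lengths - breakpoint))
    gc = np.clip(mean + rng.normal(0.0, noise_sd, size=n_points), 0.0, 1.0)
    return GCLengthProfile(
        lengths, np.full(n_points, reads_per_point), gc,
        min_reads_per_point=min(reads_per_point, 20),
    )


# ---------------------------------------------------------------------
# classifier tables
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class ConfidenceModel:
    """How classifier tables deviate from the truth.

    ``noise`` mislabels that fraction of reads at ``noise_rank``: the
    read receives another community member's (internally consistent)
    lineage, with depressed confidence at and below that rank.
    ``conf_spread`` widens the confidence distribution:
    correct calls draw confidence 1 − conf_spread·Beta(1, 4), so with
    spread 0 every confidence is exactly 1.  Mislabeled calls draw
    confidence uniformly from [0.3, 0.9].
    """

    noise: float = 0.0
    noise_rank: str = "genus"
    conf_spread: float = 0.0


@dataclass(frozen=True)
class FunctionModel:
    """COG-table generation: each read receives up to ``max_cogs`` hits,
    each present with ``hit_prob``, drawn uniformly from the pathway
    group map; E-values are log-uniform in [1e-30, 1e-6]."""

    max_cogs: int = 1
    hit_prob: float = 0.3


def generate_assignment_tables(
    reads: Sequence[Read],
    truth: GroundTruth,
    spec: CommunitySpec,
    confidence_model: ConfidenceModel | None = None,
    function_model: FunctionModel | None = None,
    group_map: PathwayGroupMap | None = None,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emulated classifier output: long-form taxonomic assignments
    (read_id, rank, taxon, confidence, source) and a functional table
    (read_id, cog_id, evalue)."""
    cm = confidence_model or ConfidenceModel()
    fm = function_model or FunctionModel()
    gmap = group_map or PathwayGroupMap.default()
    rng = np.random.default_rng(seed)
    by_id = {t.taxon_id: t for t in spec.taxa}
    truth_tax = dict(zip(truth.table["read_id"], truth.table["taxon_id"]))
    truth_marker = dict(zip(truth.table["read_id"], truth.table["is_marker"]))

    tax_rows: list[tuple] = []
    noise_depth = RANKS.index(cm.noise_rank)
    taxon_ids = [t.taxon_id for t in spec.taxa]
    for read in reads:
        tid = truth_tax[read.read_id]
        lineage = list(by_id[tid].lineage)
        mislabel = cm.noise > 0 and rng.random() < cm.noise
        if mislabel:
            other = taxon_ids[rng.integers(0, len(taxon_ids))]
            while other == tid and len(taxon_ids) > 1:
                other = taxon_ids[rng.integers(0, len(taxon_ids))]
            lineage = list(by_id[other].lineage)
        source = "marker" if truth_marker[read.read_id] else "EGT"
        for rank, name in lineage:
            if mislabel and RANKS.index(rank) >= noise_depth:
                conf = float(rng.uniform(0.3, 0.9))
            elif cm.conf_spread > 0:
                conf = float(1.0 - cm.conf_spread * rng.beta(1.0, 4.0))
            else:
                conf = 1.0
            tax_rows.append((read.read_id, rank, name, conf, source))
    tax_table = pd.DataFrame(
        tax_rows, columns=["read_id", "rank", "taxon", "confidence", "source"]
    )

    cog_ids = sorted(gmap.mapping)
    cog_rows: list[tuple] = []
    if fm.max_cogs > 0 and cog_ids:
        for read in reads:
            n_hits = int(rng.binomial(fm.max_cogs, fm.hit_prob))
            if n_hits == 0:
                continue
            picks = rng.choice(len(cog_ids), size=n_hits, replace=False)
            for k in picks:
                evalue = 10.0 ** rng.uniform(-30, -6)
                cog_rows.append((read.read_id, cog_ids[k], evalue))
    cog_table = pd.DataFrame(cog_rows, columns=["read_id", "cog_id", "evalue"])
    return tax_table, cog_table


# ---------------------------------------------------------------------
# marker-gene variant mixtures
# ---------------------------------------------------------------------


def make_marker_reference(length: int = 1450, gc: float = 0.57, seed: int = 7) -> str:
    """A random marker-gene reference sequence (16S-length by default)."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(np.array(list("ATCG"))[rng.choice(4, size=length, p=p)])


def default_variant_defs(
    reference: str, n_variants: int = 7, snp_spacing: int = 40, seed: int = 11
) -> list[dict[int, str]]:
    """SNP sets for a mixture of closely related marker variants.

    Each variant carries one SNP per ``snp_spacing`` window, at a
    variant-specific offset within the window; offsets are drawn
    without replacement per window, so SNP positions are pairwise
    disjoint across variants and no two variants ever share a
    diagnostic site.  Any read window of roughly twice the spacing
    covers at least one such site.  The substituted base is a
    deterministic rotation of the reference base.
    """
    rng = np.random.default_rng(seed)
    length = len(reference)
    rotation = {b: "ACGT"[("ACGT".index(b) + 1) % 4] for b in "ACGT"}
    n_windows = length // snp_spacing
    if n_variants > snp_spacing - 10:
        raise SpecError("n_variants: too many variants for the SNP spacing")
    offset_table = np.stack([
        rng.choice(np.arange(5, snp_spacing - 5), size=n_variants, replace=False)
        for _ in range(n_windows)
    ])
    defs: list[dict[int, str]] = []
    for v in range(n_variants):
        snps: dict[int, str] = {}
        for w in range(n_windows):
            pos = int(w * snp_spacing + offset_table[w, v])
            snps[pos] = rotation[reference[pos]]
        defs.append(snps)
    return defs


def apply_variant(reference: str, snps: dict[int, str]) -> str:
    seq = list(reference)
    for pos, base in snps.items():
        if not 0 <= pos < len(reference):
            raise SpecError(f"variant SNP position {pos} outside reference")
        if base == reference[pos]:
            raise SpecError(f"variant SNP at {pos} equals the reference base")
        seq[pos] = base
    return "".join(seq)


def generate_variant_reads(
    reference_marker: str,
    variant_defs: Sequence[dict[int, str]],
    n_reads: int,
    error_rate: float = 0.0,
    seed: int = 0,
    read_length_range: tuple[int, int] = (200, 400),
) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Error-perturbed read windows from a mixture of marker variants.

    Variants are assigned cyclically so every variant receives
    floor/ceil(n/k) reads; each read is a uniform window of its
    variant's sequence with i.i.d. substitution errors at
    ``error_rate``.  Returns (read_id, sequence) pairs plus ground
    truth with the true variant id per read.
    """
    rng = np.random.default_rng(seed)
    variants = [apply_variant(reference_marker, d) for d in variant_defs]
    lo, hi = read_length_range
    if hi > len(reference_marker):
        raise SpecError("read_length_range: max exceeds the reference length")
    reads: list[tuple[str, str]] = []
    rows = []
    width = len(str(n_reads))
    for i in range(n_reads):
        v = i % len(variants)
        length = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(reference_marker) - length + 1))
        seq = bytearray(variants[v][start:start + length], "ascii")
        if error_rate > 0:
            errs = np.nonzero(rng.random(length) < error_rate)[0]
            for p in errs:
                current = chr(seq[p])
                choices = [b for b in "ACGT" if b != current]
                seq[p] = ord(choices[rng.integers(0, 3)])
        rid = f"m{i:0{width}d}"
        reads.append((rid, seq.decode("ascii")))
        rows.append((rid, f"variant_{v + 1}"))
    truth = GroundTruth(
        table=pd.DataFrame(rows, columns=["read_id", "variant_id"]).assign(
            taxon_id="methanoculleus", dup_group=[r[0] for r in rows], is_marker=True
        )
    )
    return reads, truth


# ---------------------------------------------------------------------
# reference genome and read mapping
# ---------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    """Gene annotation with HGT flags; sequence itself is not needed
    for coverage analysis."""

    length: int
    genes: list[GeneAnnotation]


def make_reference_genome(
    genome_length: int = 100_000,
    n_genes: int = 90,
    hgt_fraction: float = 0.2,
    seed: int = 3,
) -> ReferenceGenome:
    """Evenly spaced single-strand genes; a random ``hgt_fraction`` of
    them flagged as putative horizontal acquisitions."""
    rng = np.random.default_rng(seed)
    pitch = genome_length // n_genes
    gene_len = int(pitch * 0.85)
    hgt = rng.random(n_genes) < hgt_fraction
    genes = [
        GeneAnnotation(
            gene_id=f"gene_{i:04d}",
            start=i * pitch,
            end=i * pitch + gene_len,
            strand="+" if i % 2 == 0 else "-",
            hgt=bool(hgt[i]),
        )
        for i in range(n_genes)
    ]
    return ReferenceGenome(length=genome_length, genes=genes)


def generate_mapping(
    genome: ReferenceGenome,
    n_reads: int = 50_000,
    hgt_depletion: float = 0.0,
    read_length: tuple[int, int] = (80, 120),
    seed: int = 5,
) -> pd.DataFrame:
    """Read-to-genome mapping intervals with HGT depletion.

    Candidate reads fall uniformly on the genome; a read overlapping
    any HGT-flagged gene survives sampling only with probability
    1 − ``hgt_depletion`` (depletion 1 leaves HGT genes bare).  Returns
    a table (read_id, start, end) of the surviving mapped reads,
    0-based half-open.
    """
    if not 0.0 <= hgt_depletion <= 1.0:
        raise SpecError("hgt_depletion: must be in [0, 1]")
    rng = np.random.default_rng(seed)
    lo, hi = read_length
    lengths = rng.integers(lo, hi + 1, size=n_reads)
    starts = rng.integers(0, genome.length - lengths + 1)
    ends = starts + lengths
    # prefix-sum bitmap of HGT positions for O(1) overlap queries
    hgt_mask = np.zeros(genome.length + 1, dtype=np.int32)
    for g in genome.genes:
        if g.hgt:
            hgt_mask[g.start] += 1
            hgt_mask[g.end] -= 1
    hgt_cum = np.concatenate([[0], np.cumsum(np.cumsum(hgt_mask[:-1]) > 0)])
    overlaps_hgt = (hgt_cum[ends] - hgt_cum[starts]) > 0
    keep = ~overlaps_hgt | (rng.random(n_reads) >= hgt_depletion)
    idx = np.nonzero(keep)[0]
    width = len(str(n_reads))
    return pd.DataFrame(
        {
            "read_id": [f"map{i:0{width}d}" for i in idx],
            "start": starts[idx],
            "end": ends[idx],
        }
    )
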