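"""SNP-based binning of marker-gene reads into strain/species variants.

Closely related strains in one community carry marker genes (16S rRNA
and others) that differ at a handful of positions.  Reads covering the
marker cannot be co-assembled into a single consensus, but aligning
each read to a reference copy, recording its substitution pattern (SNP
signature), and grouping reads with consistent signatures separates the
variants; a reference-guided majority consensus per group then
reconstructs each variant's (partial) sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio import Align

_BASES = frozenset("ACGT")


class VariantError(ValueError):
    pass


@dataclass
class AlignedRead:
    """A read placed on reference coordinates (0-based, half-open).

    ``bases`` maps each covered reference position to the read base
    aligned there; positions deleted in the read are absent and read
    insertions are dropped (substitution-only view).
    """

    read_id: str
    ref_start: int
    ref_end: int
    bases: dict[int, str]
    n_mismatches: int


def _make_aligner(match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # free end gaps on the reference: the read aligns end-gap-free
    # inside the (longer) reference (glocal / semi-global); in
    # Bio.Align terms unaligned reference ends are end deletions
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def align_to_reference(
    read_id: str,
    read_seq: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignedRead:
    """Semi-global alignment of a read inside a reference sequence.

    End gaps on the reference are free, so the read is placed at its
    best offset; the read itself must align end to end.  Scoring is
    match +1 / mismatch −1 / gap −2 by default; the traceback is
    deterministic (first-ranked alignment of the dynamic program).
    """
    if not read_seq:
        raise VariantError(f"empty read {read_id!r}")
    aligner = _make_aligner(match, mismatch, gap)
    alignment = aligner.align(reference.upper(), read_seq.upper())[0]
    bases: dict[int, str] = {}
    n_mm = 0
    ref = reference.upper()
    query = read_seq.upper()
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            rb, qb = ref[t0 + k], query[q0 + k]
            bases[t0 + k] = qb
            if rb != qb:
                n_mm += 1
    if not bases:
        raise VariantError(f"read {read_id!r} did not align")
    return AlignedRead(
        read_id=read_id,
        ref_start=min(bases),
        ref_end=max(bases) + 1,
        bases=bases,
        n_mismatches=n_mm,
    )


@dataclass
class SnpSignature:
    """Substitution differences of one read against the reference."""

    read_id: str
    snps: dict[int, str]  # reference position -> observed (non-reference) base
    interval: tuple[int, int]  # covered reference interval, half-open

    def __post_init__(self) -> None:
        lo, hi = self.interval
        for pos, base in self.snps.items():
            if not (lo <= pos < hi):
                raise VariantError(
                    f"SNP position {pos} outside covered interval [{lo}, {hi})"
                )
            if base not in _BASES:
                raise VariantError(f"invalid SNP base {base!r} at {pos}")


def snp_signature(
    aligned: AlignedRead, reference: str, end_trim: int = 5
) -> SnpSignature:
    """Substitution-only SNP calls, ignoring ``end_trim`` aligned bases
    at either end of the read (alignment-edge artifacts) and all gap
    columns.  Non-ACGT read bases (e.g. N) never become SNP calls."""
    ref = reference.upper()
    positions = sorted(aligned.bases)
    core = positions[end_trim : len(positions) - end_trim] if end_trim else positions
    snps = {
        pos: aligned.bases[pos]
        for pos in core
        if aligned.bases[pos] in _BASES and aligned.bases[pos] != ref[pos]
    }
    # the covered interval is the region where SNPs were callable,
    # i.e. excluding the trimmed read ends
    if core:
        interval = (core[0], core[-1] + 1)
    else:
        interval = (aligned.ref_start, aligned.ref_start)
    return SnpSignature(read_id=aligned.read_id, snps=snps, interval=interval)


@dataclass
class VariantGroup:
    """One putative variant: member reads, their SNP observations and
    the intervals they cover.

    ``support`` counts, per reference position, how many member reads
    observed each non-reference base there.  The group's *signature* is
    the majority view: a position carries a SNP base only when more
    covering members observed it than observed the reference (ties go
    to the reference), so isolated sequencing errors drop out of the
    signature as the group grows.
    """

    members: list[str] = field(default_factory=list)
    intervals: list[tuple[int, int]] = field(default_factory=list)
    support: dict[int, dict[str, int]] = field(default_factory=dict)

    def covers(self, pos: int) -> bool:
        return any(lo <= pos < hi for lo, hi in self.intervals)

    def coverage(self, pos: int) -> int:
        return sum(1 for lo, hi in self.intervals if lo <= pos < hi)

    def covered_union(self) -> list[tuple[int, int]]:
        merged: list[tuple[int, int]] = []
        for lo, hi in sorted(self.intervals):
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        return merged

    @property
    def signature(self) -> dict[int, str]:
        sig: dict[int, str] = {}
        for pos, bases in self.support.items():
            best_count = max(bases.values())
            winners = sorted(b for b, c in bases.items() if c == best_count)
            ref_like = self.coverage(pos) - sum(bases.values())
            if best_count > ref_like and len(winners) == 1:
                sig[pos] = winners[0]
        return sig

    def absorb(self, sig: "SnpSignature") -> None:
        self.members.append(sig.read_id)
        self.intervals.append(sig.interval)
        for pos, base in sig.snps.items():
            self.support.setdefault(pos, {}).setdefault(base, 0)
            self.support[pos][base] += 1

    def release(self, sig: "SnpSignature") -> None:
        self.members.remove(sig.read_id)
        self.intervals.remove(sig.interval)
        for pos, base in sig.snps.items():
            self.support[pos][base] -= 1
            if self.support[pos][base] == 0:
                del self.support[pos][base]
            if not self.support[pos]:
                del self.support[pos]


def _joinable(sig: SnpSignature, group_sig: dict[int, str],
              group: VariantGroup, min_shared: int) -> bool:
    """Whether a read's signature is consistent with a group.

    Over the read SNP positions the group covers, the group signature
    must carry the same base at a majority of them (conflicting or
    unconfirmed positions count against), with at least ``min_shared``
    SNPs co-observed.  The majority requirement keeps single
    sequencing-error SNPs that happen to coincide with another
    variant's diagnostic site from chaining unrelated groups together.
    A SNP-free read joins a group that overlaps the read's interval and
    is SNP-free there.
    """
    covered = [pos for pos in sig.snps if group.covers(pos)]
    agree = sum(1 for pos in covered if group_sig.get(pos) == sig.snps[pos])
    if covered:
        return agree >= min_shared and 2 * agree >= len(covered)
    if sig.snps:
        return False
    lo, hi = sig.interval
    overlaps = any(
        max(lo, glo) < min(hi, ghi) for glo, ghi in group.covered_union()
    )
    return overlaps and not any(lo <= pos < hi for pos in group_sig)


def cluster_by_signature(
    signatures: Sequence[SnpSignature], min_shared: int = 1
) -> list[VariantGroup]:
    """Greedy signature clustering into variant groups.

    Reads are processed in descending signature size (stable in input
    order).  A read joins the first existing group it is consistent
    with: at least ``min_shared`` co-observed SNPs and agreement at a
    majority of the read's SNP positions the group covers (SNP-free
    reads instead join groups that are SNP-free over the read's
    interval); otherwise it founds a new group.  Group signatures are
    majority views over member observations, so isolated error SNPs do
    not stick.  Finally, groups whose covered intervals overlap and
    whose signatures agree there (the same majority criterion, applied
    group-to-group in both directions) are merged, stitching together
    same-variant groups founded in different reference regions.

    The procedure is deterministic for a given input order and does not
    depend on read ids.
    """
    order = sorted(range(len(signatures)), key=lambda i: -len(signatures[i].snps))
    groups: list[VariantGroup] = []
    for i in order:
        sig = signatures[i]
        placed = False
        for group in groups:
            if _joinable(sig, group.signature, group, min_shared):
                group.absorb(sig)
                placed = True
                break
        if not placed:
            fresh = VariantGroup()
            fresh.absorb(sig)
            groups.append(fresh)
    groups = _merge_groups(groups, min_shared)
    groups = _refine(groups, signatures, min_shared)
    return _merge_groups(groups, min_shared)


def _refine(groups: list[VariantGroup], signatures: Sequence[SnpSignature],
            min_shared: int, rounds: int = 2) -> list[VariantGroup]:
    """Reassignment passes that undo greedy order dependence.

    Early reads can found fragment groups before any group covers
    their region; once all groups exist, each read is re-tested against
    the groups in descending size order and moved when a larger group
    accepts it.  Emptied fragments disappear.
    """
    by_id = {sig.read_id: sig for sig in signatures}
    for _ in range(rounds):
        moved = False
        current: dict[str, VariantGroup] = {
            rid: g for g in groups for rid in g.members
        }
        for sig in signatures:
            home = current[sig.read_id]
            for group in sorted(groups, key=lambda g: -len(g.members)):
                if group is home or len(group.members) <= len(home.members):
                    break
                if _joinable(sig, group.signature, group, min_shared):
                    home.release(sig)
                    group.absorb(sig)
                    current[sig.read_id] = group
                    moved = True
                    break
        groups = [g for g in groups if g.members]
        if not moved:
            break
    return groups


def _one_way_agreement(sig_a: dict[int, str], b: VariantGroup,
                       sig_b: dict[int, str]) -> tuple[int, int]:
    """(#agreeing, #covered) of a's signature SNPs inside b's covered
    region; positions b covers without carrying the same base count
    against the majority."""
    agree = 0
    covered = 0
    for pos, base in sig_a.items():
        if not b.covers(pos):
            continue
        covered += 1
        if sig_b.get(pos) == base:
            agree += 1
    return agree, covered


def _groups_mergeable(
    a: VariantGroup, b: VariantGroup, min_shared: int,
    min_empty_overlap: int = 200,
) -> bool:
    """Groups merge when their covered intervals overlap and their
    signatures agree there, under the same majority criterion used for
    read joining, applied in both directions.

    Because a single co-observed site can be a sequencing error that
    happens to match, one shared site suffices only when the two
    signatures agree *perfectly* over the co-covered positions;
    otherwise at least two co-observed sites are required.  Two groups
    that are both SNP-free over the overlap merge only when the overlap
    is long (>= ``min_empty_overlap`` bases): a short SNP-free sliver
    is no evidence that two groups sample the same variant.
    """
    ov = []
    for lo1, hi1 in a.covered_union():
        for lo2, hi2 in b.covered_union():
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if lo < hi:
                ov.append((lo, hi))
    if not ov:
        return False
    sig_a, sig_b = a.signature, b.signature
    agree_f, cov_f = _one_way_agreement(sig_a, b, sig_b)
    agree_r, cov_r = _one_way_agreement(sig_b, a, sig_a)
    if cov_f or cov_r:
        if 2 * agree_f < cov_f or 2 * agree_r < cov_r:
            return False
        return max(agree_f, agree_r) >= min_shared
    if sum(hi - lo for lo, hi in ov) < min_empty_overlap:
        return False
    def empty_over(sig: dict[int, str]) -> bool:
        return not any(any(lo <= p < hi for lo, hi in ov) for p in sig)
    return empty_over(sig_a) and empty_over(sig_b)


def _merge_groups(groups: list[VariantGroup], min_shared: int) -> list[VariantGroup]:
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if _groups_mergeable(groups[i], groups[j], min_shared):
                    gi, gj = groups[i], groups[j]
                    gi.members.extend(gj.members)
                    gi.intervals.extend(gj.intervals)
                    for pos, bases in gj.support.items():
                        slot = gi.support.setdefault(pos, {})
                        for base, count in bases.items():
                            slot[base] = slot.get(base, 0) + count
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return groups


def build_consensus(
    group: VariantGroup,
    aligned_reads: dict[str, AlignedRead],
    reference: str,
    min_depth: int = 1,
) -> str:
    """Reference-guided majority consensus over the group's members.

    For every reference column covered by at least ``min_depth`` member
    reads, the consensus is the majority base (ties resolved to the
    reference base).  Columns below ``min_depth`` are emitted as the
    reference base in lowercase, marking the consensus as partial
    there.  The returned string has the reference's length.
    """
    ref = reference.upper()
    n = len(ref)
    counts: dict[int, dict[str, int]] = {}
    for read_id in group.members:
        ar = aligned_reads[read_id]
        for pos, base in ar.bases.items():
            if base in _BASES:
                counts.setdefault(pos, {}).setdefault(base, 0)
                counts[pos][base] += 1
    out = []
    for pos in range(n):
        col = counts.get(pos)
        depth = sum(col.values()) if col else 0
        if depth < min_depth:
            out.append(ref[pos].lower())
            continue
        best = max(col.values())
        winners = sorted(b for b, c in col.items() if c == best)
        if len(winners) > 1:
            out.append(ref[pos] if ref[pos] in winners else winners[0])
        else:
            out.append(winners[0])
    return "".join(out)


def bin_variants(
    reads: Sequence[tuple[str, str]],
    reference: str,
    end_trim: int = 5,
    min_shared: int = 1,
    min_depth: int = 1,
) -> tuple[list[VariantGroup], dict[str, str], dict[str, AlignedRead]]:
    """Full pipeline: align, call signatures, cluster, build consensus.

    ``reads`` is a sequence of (read_id, sequence).  Returns the variant
    groups sorted by descending size, a map group-index-keyed consensus
    sequences ("variant_1", ...), and the per-read alignments.
    """
    aligned = {rid: align_to_reference(rid, seq, reference) for rid, seq in reads}
    sigs = [snp_signature(aligned[rid], reference, end_trim) for rid, _ in reads]
    groups = cluster_by_signature(sigs, min_shared=min_shared)
    groups.sort(key=lambda g: (-len(g.members), min(lo for lo, _ in g.intervals)))
    consensus = {
        f"variant_{k + 1}": build_consensus(g, aligned, reference, min_depth)
        for k, g in enumerate(groups)
    }
    return groups, consensus, aligned
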