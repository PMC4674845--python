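"""Per-site features and focal re-alignment of clipped segments.

Each candidate site gets four features: reads clipped at the site, clipped
segments re-aligned at the site, discordant encompassing pairs, and the
coverage difference between its two flanking regions.  All four are then
normalized by the mean coverage of the site's anchor region (left flank for
donors, right flank for acceptors).

Re-alignment is side-consistent: a suffix clip (boundary = donor) is only
placed flush at acceptor sites downstream, a prefix clip only at donor
sites upstream.  The search is bounded by the mate's mapping position when
it lies on the far side, otherwise by ``max_jump``; candidate sites are
tried nearest-first and any placement that would leave the read pair
discordant is rejected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .candidate_sites import CandidateSite, Direction, Origin
from .io_align import (
    ClipEvent,
    ClipSide,
    CoverageTrack,
    Genome,
    InsertSizeModel,
    PairIndex,
)

DEFAULT_MAX_JUMP = 1_500_000
DEFAULT_MAX_MM_RATE = 0.04
DEFAULT_MAX_NEW_HITS = 5

FEATURE_NAMES = ("f_clip", "f_seg", "f_disc", "f_cov")


@dataclass
class FeatureVector:
    f_clip: int
    f_seg: int
    f_disc: int
    f_cov: float
    normalized: np.ndarray | None = None

    def raw(self) -> np.ndarray:
        return np.array(
            [self.f_clip, self.f_seg, self.f_disc, self.f_cov], dtype=float
        )


@dataclass(frozen=True)
class SearchBounds:
    b0: int
    b1: int
    b2: int
    bp: int | None = None


class RealignStatus(enum.Enum):
    MATCHED_SITE = "MATCHED_SITE"
    NEW_SITE = "NEW_SITE"
    UNALIGNED = "UNALIGNED"


@dataclass
class RealignmentResult:
    event: ClipEvent
    status: RealignStatus
    target_site: CandidateSite | None = None
    p_new: int | None = None
    mismatches: int = 0
    bounds: SearchBounds | None = None

    @property
    def target_pos(self) -> int | None:
        if self.target_site is not None:
            return self.target_site.pos
        return self.p_new

    def junction(self) -> tuple[int, int] | None:
        """(donor_pos, acceptor_pos) implied by the placement, or None."""
        pos = self.target_pos
        if pos is None:
            return None
        if self.event.side is ClipSide.SUFFIX:
            return (self.event.clip_pos, pos)
        return (pos, self.event.clip_pos)


def max_mismatches(clip_len: int, rate: float = DEFAULT_MAX_MM_RATE) -> int:
    """Mismatch tolerance for a flush placement: ceil(len * rate)."""
    return int(math.ceil(clip_len * rate))


class SiteIndex:
    """Sorted per-(contig, direction) positional index over candidate sites."""

    def __init__(self, sites: Iterable[CandidateSite]):
        self._data: dict[tuple[str, Direction], tuple[np.ndarray, list[CandidateSite]]] = {}
        buckets: dict[tuple[str, Direction], list[CandidateSite]] = {}
        for site in sites:
            buckets.setdefault((site.contig, site.direction), []).append(site)
        for key, group in buckets.items():
            group.sort(key=lambda s: s.pos)
            self._data[key] = (np.array([s.pos for s in group]), group)

    def in_range(
        self, contig: str, direction: Direction, lo: int, hi: int
    ) -> list[CandidateSite]:
        """Sites with lo <= pos <= hi, ascending by position."""
        entry = self._data.get((contig, direction))
        if entry is None:
            return []
        positions, group = entry
        i = int(np.searchsorted(positions, lo, side="left"))
        j = int(np.searchsorted(positions, hi, side="right"))
        return group[i:j]

    def nearest(
        self, contig: str, direction: Direction, pos: int, slack: int
    ) -> CandidateSite | None:
        hits = self.in_range(contig, direction, pos - slack, pos + slack)
        if not hits:
            return None
        return min(hits, key=lambda s: (abs(s.pos - pos), s.pos))


def count_clipped_reads(site: CandidateSite) -> int:
    """Distinct reads contributing a clip event merged into this site."""
    return len({(e.read_name, e.is_read1, e.side) for e in site.clip_events})


def placement_discordant(
    event: ClipEvent,
    placement_pos: int,
    pair_index: PairIndex,
    model: InsertSizeModel,
) -> bool | None:
    """Would placing the clipped segment leave the read pair discordant?

    The implied insert is the reference span of the completed fragment
    (mapped part + placed segment + mate) minus the length of the intron
    under test when it lies inside that span — i.e. the transcript-space
    insert.  Returns None (abstain) when the mate is unavailable or on a
    different contig.
    """
    mate = pair_index.mate_of(event.read_name, 1 if event.is_read1 else 2)
    if mate is None or not mate.is_mapped or mate.contig != event.contig:
        return None
    s, e = event.mapped_span
    if event.side is ClipSide.SUFFIX:
        donor, acceptor = event.clip_pos, placement_pos
        seg = (placement_pos, placement_pos + event.clip_len)
    else:
        donor, acceptor = placement_pos, event.clip_pos
        seg = (placement_pos - event.clip_len, placement_pos)
    left = min(s, seg[0], mate.pos)
    right = max(e, seg[1], mate.end)
    span = right - left
    if left <= donor and acceptor <= right:
        span -= acceptor - donor
    return model.is_discordant_insert(span)


def _mismatch_count(genome_arr: np.ndarray, pos: int, seg: np.ndarray) -> int:
    return int(np.count_nonzero(genome_arr[pos : pos + seg.size] != seg))


def _sliding_hits(
    genome_arr: np.ndarray, lo: int, hi: int, seg: np.ndarray, max_mm: int
) -> np.ndarray:
    """Start positions in [lo, hi] where the segment places with <= max_mm
    mismatches (ungapped)."""
    lo = max(0, lo)
    hi = min(hi, genome_arr.size - seg.size)
    if hi < lo:
        return np.empty(0, dtype=int)
    window = np.lib.stride_tricks.sliding_window_view(
        genome_arr[lo : hi + seg.size], seg.size
    )
    mism = np.count_nonzero(window != seg, axis=1)
    return np.flatnonzero(mism <= max_mm) + lo


def realign_clipped_segment(
    event: ClipEvent,
    site_index: SiteIndex,
    pair_index: PairIndex,
    model: InsertSizeModel,
    genome: Genome,
    max_jump: int = DEFAULT_MAX_JUMP,
    max_mm_rate: float = DEFAULT_MAX_MM_RATE,
    max_new_hits: int = DEFAULT_MAX_NEW_HITS,
) -> RealignmentResult:
    """Place one clipped segment flush against the far side of its junction.

    Trial order is nearest-first from the clip position; the first placement
    that matches the reference within the mismatch budget and does not make
    the pair discordant wins.  When no candidate site accepts the segment,
    an ungapped scan of the whole bounded region may report a NEW_SITE
    (ambiguous scans with more than ``max_new_hits`` hits are dropped).
    """
    if not event.clip_seq:
        raise ValueError(
            f"clip_seq empty for {event.read_name}; run hard-clip recovery first"
        )
    seg = np.frombuffer(event.clip_seq.upper().encode("ascii"), dtype=np.uint8)
    k = seg.size
    garr = genome.array(event.contig)
    clen = garr.size
    b0 = event.clip_pos
    max_mm = max_mismatches(k, max_mm_rate)

    mate_pos = event.mate_pos if event.mate_contig == event.contig else None
    if event.side is ClipSide.SUFFIX:
        bp = mate_pos if (mate_pos is not None and mate_pos >= b0) else None
        b1, b2 = b0, bp if bp is not None else min(b0 + max_jump, clen)
        trials = site_index.in_range(event.contig, Direction.ACCEPTOR, b0 + 1, b2)
        # ascending position == nearest-first from b0
    else:
        bp = mate_pos if (mate_pos is not None and mate_pos < b0) else None
        b1, b2 = bp if bp is not None else max(b0 - max_jump, 0), b0
        trials = site_index.in_range(event.contig, Direction.DONOR, b1, b0 - 1)
        trials = trials[::-1]  # descending == nearest-first from b0
    bounds = SearchBounds(b0=b0, b1=min(b1, b2), b2=max(b1, b2), bp=bp)

    for site in trials:
        p = site.pos
        if event.side is ClipSide.SUFFIX:
            if p + k > clen:
                continue
            mm = _mismatch_count(garr, p, seg)
        else:
            if p - k < 0:
                continue
            mm = _mismatch_count(garr, p - k, seg)
        if mm > max_mm:
            continue
        if placement_discordant(event, p, pair_index, model):
            continue
        return RealignmentResult(
            event, RealignStatus.MATCHED_SITE, target_site=site,
            mismatches=mm, bounds=bounds,
        )

    # local-alignment fallback over the whole bounded region
    if event.side is ClipSide.SUFFIX:
        hits = _sliding_hits(garr, b0 + 1, b2, seg, max_mm)
        order = hits  # ascending = nearest b0
    else:
        hits = _sliding_hits(garr, b1 - k, b0 - 1 - k, seg, max_mm) + k
        order = hits[::-1]
    if 0 < len(order) <= max_new_hits:
        p_new = int(order[0])
        mm = (
            _mismatch_count(garr, p_new, seg)
            if event.side is ClipSide.SUFFIX
            else _mismatch_count(garr, p_new - k, seg)
        )
        return RealignmentResult(
            event, RealignStatus.NEW_SITE, p_new=p_new, mismatches=mm, bounds=bounds
        )
    return RealignmentResult(event, RealignStatus.UNALIGNED, bounds=bounds)


def integrate_new_sites(
    sites: list[CandidateSite],
    results: Sequence[RealignmentResult],
    s: int,
) -> list[CandidateSite]:
    """Feed NEW_SITE placements back into the candidate list.

    A NEW_SITE within ``s`` bp of an existing site of the right direction is
    retargeted onto it; otherwise a REALIGN-origin site is appended.
    Returns the (possibly extended) site list.
    """
    index = SiteIndex(sites)
    added: list[CandidateSite] = []
    for res in results:
        if res.status is not RealignStatus.NEW_SITE:
            continue
        direction = (
            Direction.ACCEPTOR
            if res.event.side is ClipSide.SUFFIX
            else Direction.DONOR
        )
        near = index.nearest(res.event.contig, direction, res.p_new, s)
        if near is None:
            for cand in added:
                if (
                    cand.contig == res.event.contig
                    and cand.direction is direction
                    and abs(cand.pos - res.p_new) <= s
                ):
                    near = cand
                    break
        if near is None:
            near = CandidateSite(
                contig=res.event.contig,
                pos=res.p_new,
                direction=direction,
                origin=Origin.REALIGN,
                merged_from=[res.p_new],
            )
            added.append(near)
        res.target_site = near
    out = sites + added
    out.sort(key=lambda s: (s.contig, s.pos, s.direction.value))
    return out


def count_realigned_segments(
    site: CandidateSite, results: Iterable[RealignmentResult]
) -> int:
    return sum(1 for r in results if r.target_site is site)


def count_discordant_encompassing(
    site: CandidateSite, pair_index: PairIndex
) -> int:
    """Discordant pairs whose mates lie fully on opposite sides of the site."""
    pos = site.pos
    n = 0
    for ls, le, rs, re in pair_index.discordant_spans(site.contig):
        if le <= pos and rs >= pos:
            n += 1
    return n


def _region_mean(d: np.ndarray, start: int, end: int) -> float:
    start, end = max(0, start), min(len(d), end)
    if end <= start:
        return 0.0
    return float(d[start:end].mean())


def coverage_difference(
    site: CandidateSite, track: CoverageTrack, l: int = 25
) -> float:
    """Near-side minus far-side mean depth over l-bp flanks.

    Donor: left minus right; acceptor: right minus left.  Flanks are clamped
    to the contig and averaged over their actual length.
    """
    d = track[site.contig]
    left = _region_mean(d, site.pos - l, site.pos)
    right = _region_mean(d, site.pos, site.pos + l)
    return left - right if site.direction is Direction.DONOR else right - left


def anchor_mean_coverage(
    site: CandidateSite, track: CoverageTrack, l: int = 25
) -> float:
    """Mean depth of the site's expressed flank (left for donor, right for
    acceptor) — the normalization denominator."""
    d = track[site.contig]
    if site.direction is Direction.DONOR:
        return _region_mean(d, site.pos - l, site.pos)
    return _region_mean(d, site.pos, site.pos + l)


def normalize_features(
    fv: FeatureVector, site: CandidateSite, track: CoverageTrack, l: int = 25
) -> FeatureVector:
    anchor = anchor_mean_coverage(site, track, l)
    if anchor <= 0:
        fv.normalized = np.zeros(4)
    else:
        fv.normalized = fv.raw() / anchor
    return fv


def compute_feature_table(
    sites: Sequence[CandidateSite],
    results: Sequence[RealignmentResult],
    pair_index: PairIndex,
    track: CoverageTrack,
    l: int = 25,
) -> dict[int, FeatureVector]:
    """All four features, raw + normalized, keyed by id(site)."""
    seg_counts: dict[int, int] = {}
    for res in results:
        if res.target_site is not None:
            seg_counts[id(res.target_site)] = seg_counts.get(id(res.target_site), 0) + 1
    table: dict[int, FeatureVector] = {}
    for site in sites:
        fv = FeatureVector(
            f_clip=count_clipped_reads(site),
            f_seg=seg_counts.get(id(site), 0),
            f_disc=count_discordant_encompassing(site, pair_index),
            f_cov=coverage_difference(site, track, l),
        )
        table[id(site)] = normalize_features(fv, site, track, l)
    return table


def write_feature_tsv(
    sites: Sequence[CandidateSite],
    table: Mapping[int, FeatureVector],
    path: str | Path,
) -> None:
    cols = "\t".join(FEATURE_NAMES)
    ncols = "\t".join(f"n_{c}" for c in FEATURE_NAMES)
    with open(path, "w") as fh:
        fh.write(f"contig\tpos\tdirection\t{cols}\t{ncols}\n")
        for site in sites:
            fv = table[id(site)]
            norm = fv.normalized if fv.normalized is not None else np.zeros(4)
            fh.write(
                f"{site.contig}\t{site.pos}\t{site.direction.value}\t"
                f"{fv.f_clip}\t{fv.f_seg}\t{fv.f_disc}\t{fv.f_cov:.4f}\t"
                + "\t".join(f"{x:.6g}" for x in norm)
                + "\n"
            )
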