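"""Candidate splice-site calling: clip positions and coverage-change positions.

Sites within ``s`` bases of each other are combined (per direction); each
merged site is oriented as a donor or acceptor.  A suffix-clipped read
(reference-forward) supports a donor; a prefix-clipped read supports an
acceptor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_align import ClipEvent, ClipSide, CoverageTrack

DEFAULT_MERGE_S = 10
DEFAULT_REGION_L = 25


class Direction(enum.Enum):
    DONOR = "DONOR"
    ACCEPTOR = "ACCEPTOR"


class Origin(enum.Enum):
    CLIP = "CLIP"
    COVERAGE_CHANGE = "COVERAGE_CHANGE"
    REALIGN = "REALIGN"


@dataclass(eq=False)
class CandidateSite:
    contig: str
    pos: int
    direction: Direction
    origin: Origin
    clip_events: list[ClipEvent] = field(default_factory=list)
    merged_from: list[int] = field(default_factory=list)

    def __repr__(self) -> str:  # compact: sites appear in many dumps
        return (
            f"CandidateSite({self.contig}:{self.pos} {self.direction.value}"
            f" {self.origin.value} n={len(self.clip_events)})"
        )


@dataclass(frozen=True)
class SiteCallConfig:
    s: int = DEFAULT_MERGE_S
    l: int = DEFAULT_REGION_L

    def __post_init__(self) -> None:
        if self.s < 0 or self.l < 1:
            raise ValueError("require s >= 0 and l >= 1")


def _majority_direction(events: Sequence[ClipEvent]) -> Direction:
    n_suffix = sum(1 for e in events if e.side is ClipSide.SUFFIX)
    # ties resolve to donor (suffix evidence wins)
    return Direction.DONOR if 2 * n_suffix >= len(events) else Direction.ACCEPTOR


def call_clip_sites(events: Iterable[ClipEvent]) -> list[CandidateSite]:
    """One raw site per distinct clip position, carrying its events.

    Direction is provisional (majority clip side at the position); merging
    re-derives it over the whole cluster.
    """
    by_pos: dict[tuple[str, int], list[ClipEvent]] = {}
    for ev in events:
        by_pos.setdefault((ev.contig, ev.clip_pos), []).append(ev)
    sites = [
        CandidateSite(
            contig=contig,
            pos=pos,
            direction=_majority_direction(evs),
            origin=Origin.CLIP,
            clip_events=list(evs),
            merged_from=[pos],
        )
        for (contig, pos), evs in by_pos.items()
    ]
    sites.sort(key=lambda s: (s.contig, s.pos))
    return sites


def call_coverage_change_sites(track: CoverageTrack) -> list[CandidateSite]:
    """Sites where depth drops to zero (donor) or rises from zero (acceptor).

    A position i is a donor candidate when d[i-1] > 0 and d[i] == 0, and an
    acceptor candidate when d[i-1] == 0 and d[i] > 0.  Contig edges are not
    called.
    """
    sites: list[CandidateSite] = []
    for contig in track.contigs():
        d = track[contig]
        if d.size < 2:
            continue
        prev, cur = d[:-1], d[1:]
        drops = np.flatnonzero((prev > 0) & (cur == 0)) + 1
        rises = np.flatnonzero((prev == 0) & (cur > 0)) + 1
        for pos in drops:
            sites.append(
                CandidateSite(contig, int(pos), Direction.DONOR,
                              Origin.COVERAGE_CHANGE, merged_from=[int(pos)])
            )
        for pos in rises:
            sites.append(
                CandidateSite(contig, int(pos), Direction.ACCEPTOR,
                              Origin.COVERAGE_CHANGE, merged_from=[int(pos)])
            )
    sites.sort(key=lambda s: (s.contig, s.pos))
    return sites


def _cluster(group: list[CandidateSite], s: int) -> list[list[CandidateSite]]:
    """Greedy left-to-right clustering against the running representative."""
    clusters: list[list[CandidateSite]] = []
    rep: CandidateSite | None = None
    for site in group:
        if rep is not None and abs(site.pos - rep.pos) <= s:
            clusters[-1].append(site)
        else:
            clusters.append([site])
        members = clusters[-1]
        # representative: most clip events, ties -> leftmost
        rep = max(members, key=lambda m: (len(m.clip_events), -m.pos))
    return clusters


def merge_and_orient(
    raw_sites: Iterable[CandidateSite], config: SiteCallConfig | None = None
) -> list[CandidateSite]:
    """Merge raw sites within ``s`` bp (per contig and direction) and orient.

    The merged position is the member with the most clip events (ties go
    leftmost).  Mixed clip/coverage clusters take origin CLIP.  Coverage-
    change sites are suppressed when a clip-supported site of the same
    direction lies within ``s`` bp — clip evidence is strictly stronger.
    """
    config = config or SiteCallConfig()
    groups: dict[tuple[str, Direction], list[CandidateSite]] = {}
    for site in raw_sites:
        groups.setdefault((site.contig, site.direction), []).append(site)

    merged: list[CandidateSite] = []
    for (contig, direction), group in groups.items():
        group.sort(key=lambda s: s.pos)
        for members in _cluster(group, config.s):
            rep = max(members, key=lambda m: (len(m.clip_events), -m.pos))
            events = [e for m in members for e in m.clip_events]
            origin = (
                Origin.CLIP
                if events
                else members[0].origin
            )
            direction_out = _majority_direction(events) if events else direction
            merged.append(
                CandidateSite(
                    contig=contig,
                    pos=rep.pos,
                    direction=direction_out,
                    origin=origin,
                    clip_events=events,
                    merged_from=[m.pos for m in members],
                )
            )

    # suppress coverage-change sites shadowed by a clip site
    clip_pos: dict[tuple[str, Direction], list[int]] = {}
    for site in merged:
        if site.origin is Origin.CLIP:
            clip_pos.setdefault((site.contig, site.direction), []).append(site.pos)
    out = []
    for site in merged:
        if site.origin is Origin.COVERAGE_CHANGE:
            near = clip_pos.get((site.contig, site.direction), ())
            if any(abs(p - site.pos) <= config.s for p in near):
                continue
        out.append(site)
    out.sort(key=lambda s: (s.contig, s.pos, s.direction.value))
    return out


def write_sites_tsv(sites: Sequence[CandidateSite], path: str | Path) -> None:
    """Debug dump: contig, pos, direction, origin, n_clip_events."""
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdirection\torigin\tn_clip_events\n")
        for s in sites:
            fh.write(
                f"{s.contig}\t{s.pos}\t{s.direction.value}\t"
                f"{s.origin.value}\t{len(s.clip_events)}\n"
            )
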