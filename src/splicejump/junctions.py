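"""Junction assembly and the end-to-end pipeline.

A junction is called when (1) both endpoint sites are classified true,
(2) at least one clipped read connects the two sites through re-alignment,
and (3) the placement is concordant with the insert-size model for at least
one supporting read (the conflict filter).  Conflict-filtered junctions are
retained with a status flag for reporting.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import candidate_sites as cs
from . import features as ft
from . import io_align as ioa
from .candidate_sites import CandidateSite, Direction, SiteCallConfig
from .classifier import TrainedModel
from .features import RealignmentResult, RealignStatus, SiteIndex
from .io_align import (
    AlignmentRecord,
    ClipSide,
    CoverageTrack,
    Genome,
    InsertSizeModel,
    PairIndex,
    ReadClass,
)

log = logging.getLogger(__name__)


class JunctionStatus(enum.Enum):
    CALLED = "CALLED"
    CONFLICT_FILTERED = "CONFLICT_FILTERED"


@dataclass
class ConnectionEdge:
    donor_site: CandidateSite
    acceptor_site: CandidateSite
    results: list[RealignmentResult] = field(default_factory=list)

    @property
    def n_support(self) -> int:
        return len(self.results)

    @property
    def contig(self) -> str:
        return self.donor_site.contig


@dataclass
class SpliceJunction:
    contig: str
    donor_pos: int
    acceptor_pos: int
    n_clip: int
    n_seg: int
    n_disc: int
    status: JunctionStatus

    def key(self) -> tuple[str, int, int]:
        return (self.contig, self.donor_pos, self.acceptor_pos)


@dataclass
class PipelineConfig:
    """Every knob of the pipeline; defaults follow the method's published
    option values (s=10, l=25, max_jump=1,500,000)."""

    s: int = cs.DEFAULT_MERGE_S
    l: int = cs.DEFAULT_REGION_L
    max_jump: int = ft.DEFAULT_MAX_JUMP
    mapq_min: int = ioa.DEFAULT_MAPQ_MIN
    min_clip_len: int = ioa.DEFAULT_MIN_CLIP_LEN
    max_mm_rate: float = ft.DEFAULT_MAX_MM_RATE
    max_new_hits: int = ft.DEFAULT_MAX_NEW_HITS
    seed: int = 42
    insert_m: float | None = None  # override; otherwise estimated from proper pairs
    insert_v: float | None = None


@dataclass
class SiteAnalysis:
    """Everything the classifier and junction caller need, in one bundle."""

    records: list[AlignmentRecord]
    lengths: dict[str, int]
    model: InsertSizeModel
    pair_index: PairIndex
    track: CoverageTrack
    events: list
    sites: list[CandidateSite]
    results: list[RealignmentResult]
    features: dict[int, ft.FeatureVector]
    counts: dict[str, int]


def analyze(
    bam_path: str | Path,
    ref_path: str | Path,
    fastq_paths: Sequence[str | Path],
    cfg: PipelineConfig | None = None,
) -> SiteAnalysis:
    """Run the shared front half of the pipeline: load, classify, candidate
    sites, hard-clip recovery, re-alignment, feature table."""
    cfg = cfg or PipelineConfig()
    genome = Genome.from_fasta(ref_path)
    records = list(ioa.load_alignments(bam_path))
    lengths = ioa.contig_lengths(bam_path)

    if cfg.insert_m is not None and cfg.insert_v is not None:
        model = InsertSizeModel(cfg.insert_m, cfg.insert_v)
    else:
        model = ioa.estimate_insert_model(records, min_sample=20)
    pair_index = PairIndex.build(records, model)
    track = ioa.build_coverage(records, lengths, cfg.mapq_min)

    events = []
    n_by_class: dict[str, int] = {}
    for rec in records:
        klass = ioa.classify_read(rec, cfg.mapq_min)
        n_by_class[klass.value] = n_by_class.get(klass.value, 0) + 1
        if klass in (ReadClass.SOFT_CLIP, ReadClass.HARD_CLIP):
            events.extend(ioa.extract_clip_events(rec, cfg.min_clip_len))
    events, n_dropped = ioa.recover_hard_clips(events, fastq_paths)

    raw = cs.call_clip_sites(events) + cs.call_coverage_change_sites(track)
    sites = cs.merge_and_orient(raw, SiteCallConfig(cfg.s, cfg.l))
    site_index = SiteIndex(sites)

    results = [
        ft.realign_clipped_segment(
            ev, site_index, pair_index, model, genome,
            max_jump=cfg.max_jump, max_mm_rate=cfg.max_mm_rate,
            max_new_hits=cfg.max_new_hits,
        )
        for ev in events
        if ev.clip_seq
    ]
    sites = ft.integrate_new_sites(sites, results, cfg.s)
    table = ft.compute_feature_table(sites, results, pair_index, track, cfg.l)

    counts = {
        "records": len(records),
        "clip_events": len(events),
        "hard_clip_dropped": n_dropped,
        "candidate_sites": len(sites),
        "realigned": sum(
            1 for r in results if r.status is not RealignStatus.UNALIGNED
        ),
        **{f"reads_{k}": v for k, v in sorted(n_by_class.items())},
    }
    return SiteAnalysis(
        records=records, lengths=lengths, model=model, pair_index=pair_index,
        track=track, events=events, sites=sites, results=results,
        features=table, counts=counts,
    )


def build_connection_graph(
    sites: Sequence[CandidateSite], results: Sequence[RealignmentResult]
) -> list[ConnectionEdge]:
    """One oriented donor->acceptor edge per connected site pair, with its
    supporting re-alignment results."""
    site_of_event: dict[int, CandidateSite] = {}
    for site in sites:
        for ev in site.clip_events:
            site_of_event[id(ev)] = site
    edges: dict[tuple[int, int], ConnectionEdge] = {}
    order: list[tuple[int, int]] = []
    for res in results:
        if res.target_site is None:
            continue
        own = site_of_event.get(id(res.event))
        if own is None:
            continue
        if res.event.side is ClipSide.SUFFIX:
            donor, acceptor = own, res.target_site
        else:
            donor, acceptor = res.target_site, own
        if donor.contig != acceptor.contig or donor.pos >= acceptor.pos:
            continue
        key = (id(donor), id(acceptor))
        if key not in edges:
            edges[key] = ConnectionEdge(donor, acceptor)
            order.append(key)
        edges[key].results.append(res)
    return [edges[k] for k in order]


def conflict_check(
    edge: ConnectionEdge, pair_index: PairIndex, model: InsertSizeModel
) -> bool:
    """True when the edge is in insert-size conflict.

    Each supporting read votes by whether its placed segment leaves its pair
    discordant; reads without a usable mate abstain.  The junction conflicts
    only when every voting support is discordant — a single clean placement
    is positive evidence.
    """
    votes = []
    for res in edge.results:
        pos = res.target_pos
        if pos is None:
            continue
        v = ft.placement_discordant(res.event, pos, pair_index, model)
        if v is not None:
            votes.append(v)
    return bool(votes) and all(votes)


def _discordant_straddling(
    pair_index: PairIndex, contig: str, donor: int, acceptor: int
) -> int:
    n = 0
    for ls, le, rs, re in pair_index.discordant_spans(contig):
        if le <= donor and rs >= acceptor:
            n += 1
    return n


def call_junctions(
    edges: Sequence[ConnectionEdge],
    predictions: Mapping[int, bool],
    pair_index: PairIndex,
    model: InsertSizeModel,
) -> list[SpliceJunction]:
    """Apply the three calling conditions and the conflict filter.

    Edges with a false endpoint are dropped outright; conflicting edges are
    kept with status CONFLICT_FILTERED.  Edges collapsing onto the same
    (donor_pos, acceptor_pos) are one junction with pooled support.
    """
    pooled: dict[tuple[str, int, int], SpliceJunction] = {}
    for edge in edges:
        if not (
            predictions.get(id(edge.donor_site), False)
            and predictions.get(id(edge.acceptor_site), False)
        ):
            continue
        status = (
            JunctionStatus.CONFLICT_FILTERED
            if conflict_check(edge, pair_index, model)
            else JunctionStatus.CALLED
        )
        key = (edge.contig, edge.donor_site.pos, edge.acceptor_site.pos)
        n_clip = ft.count_clipped_reads(edge.donor_site) + ft.count_clipped_reads(
            edge.acceptor_site
        )
        if key in pooled:
            j = pooled[key]
            j.n_seg += edge.n_support
            if status is JunctionStatus.CALLED:
                j.status = JunctionStatus.CALLED
        else:
            pooled[key] = SpliceJunction(
                contig=key[0],
                donor_pos=key[1],
                acceptor_pos=key[2],
                n_clip=n_clip,
                n_seg=edge.n_support,
                n_disc=_discordant_straddling(pair_index, key[0], key[1], key[2]),
                status=status,
            )
    out = list(pooled.values())
    out.sort(key=lambda j: j.key())
    return out


def write_junctions_tsv(
    junctions: Sequence[SpliceJunction], path: str | Path
) -> None:
    """0-based half-open: donor_pos = first intronic base, acceptor_pos =
    first exonic base after the intron."""
    with open(path, "w") as fh:
        fh.write("contig\tdonor_pos\tacceptor_pos\tn_clip\tn_seg\tn_disc\tstatus\n")
        for j in junctions:
            fh.write(
                f"{j.contig}\t{j.donor_pos}\t{j.acceptor_pos}\t"
                f"{j.n_clip}\t{j.n_seg}\t{j.n_disc}\t{j.status.value}\n"
            )


def read_junctions_tsv(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 7 and parts[6] != JunctionStatus.CALLED.value:
                continue
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed12(
    junctions: Sequence[SpliceJunction], path: str | Path, anchor: int = 20
) -> None:
    """Browser export: one BED12 row per junction with two anchor blocks."""
    with open(path, "w") as fh:
        for i, j in enumerate(junctions):
            if j.status is not JunctionStatus.CALLED:
                continue
            start = max(0, j.donor_pos - anchor)
            end = j.acceptor_pos + anchor
            b1 = j.donor_pos - start
            fh.write(
                f"{j.contig}\t{start}\t{end}\tJUNC{i:05d}\t{j.n_seg}\t+\t"
                f"{start}\t{end}\t255,0,0\t2\t{b1},{anchor}\t"
                f"0,{j.acceptor_pos - start}\n"
            )


# ---------------------------------------------------------------------------
# per-read placement report (for mapped-base ratios)

def build_read_report(analysis: SiteAnalysis) -> list[tuple]:
    """Rows (read_name, mate, read_len, contig, ref_start, read_start, length)
    describing where each read's bases were placed.

    ``read_start`` indexes the read in reference-forward orientation.  The
    primary mapped block of every kept record is reported; re-aligned clip
    segments add one block each.
    """
    rows: list[tuple] = []
    for rec in analysis.records:
        if ioa.classify_read(rec) is ReadClass.DISCARD:
            continue
        pre = rec.cigar[0][1] if rec.cigar and rec.cigar[0][0] in "SH" else 0
        suf = (
            rec.cigar[-1][1]
            if len(rec.cigar) > 1 and rec.cigar[-1][0] in "SH"
            else 0
        )
        aligned_q = sum(n for op, n in rec.cigar if op in ("M", "I", "=", "X"))
        read_len = pre + aligned_q + suf
        rows.append(
            (rec.read_name, rec.mate, read_len, rec.contig, rec.pos, pre, aligned_q)
        )
    for res in analysis.results:
        pos = res.target_pos
        if pos is None:
            continue
        ev = res.event
        if ev.side is ClipSide.SUFFIX:
            # suffix clip occupies the read tail
            rows.append(
                (
                    ev.read_name,
                    1 if ev.is_read1 else 2,
                    -1,  # read_len known from the primary row
                    ev.contig,
                    pos,
                    -ev.clip_len,  # negative: offset from read end
                    ev.clip_len,
                )
            )
        else:
            rows.append(
                (
                    ev.read_name,
                    1 if ev.is_read1 else 2,
                    -1,
                    ev.contig,
                    pos - ev.clip_len,
                    0,
                    ev.clip_len,
                )
            )
    # resolve negative offsets / unknown lengths using the primary rows
    primary_len = {
        (name, mate): rl for name, mate, rl, *_ in rows if rl >= 0
    }
    resolved = []
    for name, mate, rl, contig, ref_start, read_start, length in rows:
        if rl < 0:
            rl = primary_len.get((name, mate), 0)
        if read_start < 0:
            read_start = rl + read_start
        resolved.append((name, mate, rl, contig, ref_start, read_start, length))
    return resolved


def write_read_report(rows: Sequence[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_name\tmate\tread_len\tcontig\tref_start\tread_start\tlength\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


@dataclass
class PipelineResult:
    analysis: SiteAnalysis
    predictions: dict[int, bool]
    edges: list[ConnectionEdge]
    junctions: list[SpliceJunction]
    read_report: list[tuple]


def run_pipeline(
    bam_path: str | Path,
    ref_path: str | Path,
    fastq_paths: Sequence[str | Path],
    model: TrainedModel,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """End-to-end: candidate sites -> classification -> junction calling.

    Deterministic given the config seed.  When ``out_dir`` is given, emits
    junctions.tsv, candidate_sites.tsv, features.tsv, read_report.tsv and a
    stage-count log.
    """
    cfg = cfg or PipelineConfig()
    try:
        analysis = analyze(bam_path, ref_path, fastq_paths, cfg)
    except Exception as exc:
        raise RuntimeError(f"[analyze] {exc}") from exc
    try:
        from .classifier import predict_sites

        predictions = predict_sites(model, analysis.sites, analysis.features)
    except Exception as exc:
        raise RuntimeError(f"[classify] {exc}") from exc
    try:
        edges = build_connection_graph(analysis.sites, analysis.results)
        junctions = call_junctions(
            edges, predictions, analysis.pair_index, analysis.model
        )
    except Exception as exc:
        raise RuntimeError(f"[call] {exc}") from exc
    report = build_read_report(analysis)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_junctions_tsv(junctions, out_dir / "junctions.tsv")
        cs.write_sites_tsv(analysis.sites, out_dir / "candidate_sites.tsv")
        ft.write_feature_tsv(
            analysis.sites, analysis.features, out_dir / "features.tsv"
        )
        write_read_report(report, out_dir / "read_report.tsv")
        with open(out_dir / "pipeline_log.tsv", "w") as fh:
            fh.write("stage\tcount\n")
            for k, v in analysis.counts.items():
                fh.write(f"{k}\t{v}\n")
            fh.write(f"edges\t{len(edges)}\n")
            called = sum(
                1 for j in junctions if j.status is JunctionStatus.CALLED
            )
            fh.write(f"junctions_called\t{called}\n")
            fh.write(f"junctions_conflict_filtered\t{len(junctions) - called}\n")
    return PipelineResult(
        analysis=analysis,
        predictions=predictions,
        edges=edges,
        junctions=junctions,
        read_report=report,
    )
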