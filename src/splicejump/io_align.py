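"""Alignment I/O: read classification, coverage, insert-size model, pair index.

All coordinates are 0-based, half-open internally; SAM's 1-based positions
are converted at the pysam boundary.  A clip boundary on the suffix side of
a read is the first reference base *after* the mapped span; on the prefix
side it is the first mapped base.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)

DEFAULT_MAPQ_MIN = 20
DEFAULT_MIN_CLIP_LEN = 8

_CIGAR_OPS = "MIDNSHP=X"
#: CIGAR ops that consume reference bases.
REF_CONSUMING = frozenset("MDN=X")
#: CIGAR ops that consume query bases.
QUERY_CONSUMING = frozenset("MIS=X")
#: ops contributing read depth (aligned or deleted-over reference bases).
COVER_OPS = frozenset("MD=X")

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class ReadClass(enum.Enum):
    FULL = "FULL"
    SOFT_CLIP = "SOFT_CLIP"
    HARD_CLIP = "HARD_CLIP"
    OTHER = "OTHER"
    DISCARD = "DISCARD"


class ClipSide(enum.Enum):
    PREFIX = "PREFIX"
    SUFFIX = "SUFFIX"


@dataclass
class AlignmentRecord:
    """A single alignment, decoupled from pysam for hand-built fixtures."""

    read_name: str
    contig: str | None
    pos: int
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    is_reverse: bool
    is_read1: bool
    mate_contig: str | None
    mate_pos: int
    template_len: int
    seq: str | None
    is_primary: bool = True
    is_mapped: bool = True
    is_mate_mapped: bool = True
    is_mate_reverse: bool = False
    is_proper: bool = False

    @property
    def mate(self) -> int:
        return 1 if self.is_read1 else 2

    def ref_span(self) -> int:
        """Reference bases consumed by the alignment."""
        return sum(n for op, n in self.cigar if op in REF_CONSUMING)

    @property
    def end(self) -> int:
        return self.pos + self.ref_span()

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignmentRecord":
        cig = tuple(
            (_CIGAR_OPS[op], n) for op, n in (aln.cigartuples or ())
        )
        return cls(
            read_name=aln.query_name,
            contig=aln.reference_name,
            pos=aln.reference_start if aln.reference_start >= 0 else 0,
            cigar=cig,
            mapq=aln.mapping_quality,
            is_reverse=aln.is_reverse,
            is_read1=not aln.is_read2,
            mate_contig=aln.next_reference_name,
            mate_pos=aln.next_reference_start,
            template_len=aln.template_length,
            seq=aln.query_sequence,
            is_primary=not (aln.is_secondary or aln.is_supplementary),
            is_mapped=not aln.is_unmapped,
            is_mate_mapped=not aln.mate_is_unmapped if aln.is_paired else False,
            is_mate_reverse=aln.mate_is_reverse if aln.is_paired else False,
            is_proper=aln.is_proper_pair,
        )


@dataclass
class ClipEvent:
    """One clipped end of a clip-mapped read."""

    read_name: str
    contig: str
    clip_pos: int
    side: ClipSide
    clip_len: int
    clip_seq: str
    mapped_span: tuple[int, int]
    mate_pos: int | None
    mate_contig: str | None = None
    is_reverse: bool = False
    is_read1: bool = True
    is_hard: bool = False


@dataclass(frozen=True)
class InsertSizeModel:
    """Normal-ish insert-size summary; the discordance window is [m-3v, m+3v]."""

    m: float
    v: float

    @property
    def lower(self) -> float:
        return self.m - 3.0 * self.v

    @property
    def upper(self) -> float:
        return self.m + 3.0 * self.v

    def is_discordant_insert(self, insert: float) -> bool:
        """Closed window: an insert exactly on the boundary is concordant."""
        insert = abs(insert)
        return insert < self.lower or insert > self.upper


class CoverageTrack:
    """Per-contig read-depth arrays."""

    def __init__(self, depth: dict[str, np.ndarray]):
        self.depth = depth

    def __getitem__(self, contig: str) -> np.ndarray:
        return self.depth[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.depth

    def contigs(self) -> list[str]:
        return list(self.depth)

    def total_mass(self) -> int:
        return int(sum(int(d.sum()) for d in self.depth.values()))


def load_alignments(
    bam_path: str | Path,
    region: str | tuple[str, int, int] | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream records from a sorted, indexed BAM in coordinate order.

    Secondary/supplementary and unmapped-but-placed records are yielded with
    their flags set rather than silently dropped; downstream classification
    decides what to discard.

    Raises
    ------
    FileNotFoundError
        If the BAM or its index is missing.
    ValueError
        If the file is truncated or unreadable.
    """
    bam_path = Path(bam_path)
    if not bam_path.exists():
        raise FileNotFoundError(f"BAM not found: {bam_path}")
    try:
        bam = pysam.AlignmentFile(str(bam_path), "rb")
    except (OSError, ValueError) as exc:  # pragma: no cover - htslib message
        raise ValueError(f"cannot open BAM {bam_path}: {exc}") from exc
    with bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"BAM index (.bai) missing for {bam_path}; run samtools index"
            )
        if region is None:
            it = bam.fetch()
        elif isinstance(region, str):
            it = bam.fetch(region=region)
        else:
            contig, start, end = region
            it = bam.fetch(contig, start, end)
        for aln in it:
            yield AlignmentRecord.from_pysam(aln)


def contig_lengths(bam_path: str | Path) -> dict[str, int]:
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        return dict(zip(bam.references, bam.lengths))


def classify_read(rec: AlignmentRecord, mapq_min: int = DEFAULT_MAPQ_MIN) -> ReadClass:
    """Bucket a record as FULL / SOFT_CLIP / HARD_CLIP / OTHER / DISCARD.

    Unmapped, low-mapping-quality and non-primary records are discarded.
    A record counts as clipped when either end carries a clip op; hard wins
    over soft when both appear (the hard end still needs FASTQ recovery).
    """
    if not rec.is_mapped or not rec.is_primary or rec.mapq < mapq_min:
        return ReadClass.DISCARD
    ops = {op for op, _ in rec.cigar}
    if "H" in ops:
        return ReadClass.HARD_CLIP
    if "S" in ops:
        return ReadClass.SOFT_CLIP
    if ops <= {"M", "I", "D", "=", "X"} and ops:
        return ReadClass.FULL
    return ReadClass.OTHER


def extract_clip_events(
    rec: AlignmentRecord, min_clip_len: int = DEFAULT_MIN_CLIP_LEN
) -> list[ClipEvent]:
    """0, 1 or 2 clip events for a clip-mapped record.

    Clips shorter than ``min_clip_len`` are suppressed: they are too
    ambiguous to re-align.  For a hard clip ``clip_seq`` is left empty until
    :func:`recover_hard_clips` fills it from the FASTQ.
    """
    if not rec.cigar:
        return []
    events: list[ClipEvent] = []
    span = (rec.pos, rec.pos + rec.ref_span())
    first_op, first_n = rec.cigar[0]
    last_op, last_n = rec.cigar[-1]

    def _mk(side: ClipSide, n: int, op: str) -> ClipEvent:
        seq = ""
        if op == "S" and rec.seq:
            seq = rec.seq[:n] if side is ClipSide.PREFIX else rec.seq[-n:]
        return ClipEvent(
            read_name=rec.read_name,
            contig=rec.contig,
            clip_pos=span[0] if side is ClipSide.PREFIX else span[1],
            side=side,
            clip_len=n,
            clip_seq=seq,
            mapped_span=span,
            mate_pos=rec.mate_pos if rec.is_mate_mapped else None,
            mate_contig=rec.mate_contig if rec.is_mate_mapped else None,
            is_reverse=rec.is_reverse,
            is_read1=rec.is_read1,
            is_hard=(op == "H"),
        )

    if first_op in "SH" and first_n >= min_clip_len:
        events.append(_mk(ClipSide.PREFIX, first_n, first_op))
    if last_op in "SH" and last_n >= min_clip_len and len(rec.cigar) > 1:
        events.append(_mk(ClipSide.SUFFIX, last_n, last_op))
    return events


def collect_proper_inserts(records: Iterable[AlignmentRecord]) -> list[int]:
    """Absolute template lengths of proper pairs, counted once per pair."""
    inserts = []
    for rec in records:
        if (
            rec.is_proper
            and rec.is_primary
            and rec.is_mapped
            and rec.is_mate_mapped
            and rec.contig == rec.mate_contig
            and rec.template_len > 0
        ):
            inserts.append(rec.template_len)
    return inserts


def estimate_insert_model(
    sample: Iterable[AlignmentRecord] | Iterable[float],
    min_sample: int = 2,
) -> InsertSizeModel:
    """Estimate (m, v) from proper pairs.

    Accepts either AlignmentRecords (template lengths extracted, one per
    pair) or raw insert sizes.  One rank-based trimming pass keeps the
    middle 99% so residual outliers do not inflate the estimate; the sample
    standard deviation (ddof=1) is used.
    """
    sample = list(sample)
    if sample and isinstance(sample[0], AlignmentRecord):
        inserts = collect_proper_inserts(sample)  # type: ignore[arg-type]
    else:
        inserts = [abs(float(x)) for x in sample]  # type: ignore[arg-type]
    n = len(inserts)
    if n < min_sample:
        raise ValueError(
            f"only {n} proper pairs available (need >= {min_sample}); "
            "supply the insert mean/sd explicitly via the pipeline config"
        )
    arr = np.sort(np.asarray(inserts, dtype=float))
    k = int(math.floor(n * 0.005))
    if k:
        arr = arr[k : n - k]
    m = float(arr.mean())
    v = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return InsertSizeModel(m=m, v=v)


def is_discordant_pair(
    rec_a: AlignmentRecord, rec_b: AlignmentRecord, model: InsertSizeModel
) -> bool:
    """True when a pair is aberrant: cross-contig, same-orientation, or
    insert size outside the closed window [m-3v, m+3v]."""
    if not (rec_a.is_mapped and rec_b.is_mapped):
        return True
    if rec_a.contig != rec_b.contig:
        return True
    if rec_a.is_reverse == rec_b.is_reverse:
        return True
    insert = abs(rec_a.template_len) or abs(rec_b.template_len)
    return model.is_discordant_insert(insert)


class PairIndex:
    """read_name -> the two primary mates, with a per-pair discordance flag."""

    def __init__(self) -> None:
        self._pairs: dict[str, dict[int, AlignmentRecord]] = {}
        self.discordant: dict[str, bool] = {}

    @classmethod
    def build(
        cls, records: Iterable[AlignmentRecord], model: InsertSizeModel
    ) -> "PairIndex":
        idx = cls()
        for rec in records:
            if not rec.is_primary or not rec.is_mapped:
                continue
            idx._pairs.setdefault(rec.read_name, {})[rec.mate] = rec
        for name, mates in idx._pairs.items():
            if len(mates) == 2:
                idx.discordant[name] = is_discordant_pair(mates[1], mates[2], model)
        return idx

    def get(self, read_name: str) -> dict[int, AlignmentRecord] | None:
        return self._pairs.get(read_name)

    def mate_of(self, read_name: str, mate: int) -> AlignmentRecord | None:
        mates = self._pairs.get(read_name)
        if not mates:
            return None
        return mates.get(2 if mate == 1 else 1)

    def discordant_spans(self, contig: str) -> list[tuple[int, int, int, int]]:
        """(left_start, left_end, right_start, right_end) for each
        same-contig discordant pair, sorted by left_start."""
        out = []
        for name, flag in self.discordant.items():
            if not flag:
                continue
            a, b = self._pairs[name][1], self._pairs[name][2]
            if a.contig != contig or b.contig != contig:
                continue
            sa, sb = (a.pos, a.end), (b.pos, b.end)
            left, right = (sa, sb) if sa[0] <= sb[0] else (sb, sa)
            out.append((left[0], left[1], right[0], right[1]))
        out.sort()
        return out


def build_coverage(
    records: Iterable[AlignmentRecord],
    lengths: dict[str, int],
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> CoverageTrack:
    """Read depth from aligned reference-consuming bases of kept reads.

    Clipped bases never add coverage; discarded reads (unmapped, low MAPQ,
    non-primary) are excluded.
    """
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in lengths.items()}
    for rec in records:
        if classify_read(rec, mapq_min) is ReadClass.DISCARD:
            continue
        if rec.contig not in diff:
            continue
        d = diff[rec.contig]
        ref = rec.pos
        for op, n in rec.cigar:
            if op in COVER_OPS:
                start = max(0, ref)
                end = min(len(d) - 1, ref + n)
                if end > start:
                    d[start] += 1
                    d[end] -= 1
            if op in REF_CONSUMING:
                ref += n
    depth = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
    return CoverageTrack(depth)


def _strip_mate_suffix(name: str) -> str:
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


def recover_hard_clips(
    events: Sequence[ClipEvent], fastq_paths: Sequence[str | Path]
) -> tuple[list[ClipEvent], int]:
    """Fill ``clip_seq`` for hard-clip events from the original FASTQ files.

    The FASTQ read is reverse-complemented for reverse-strand alignments so
    the recovered segment is in reference-forward orientation, matching the
    soft-clip convention.  Events whose read name cannot be found are
    dropped (counted and logged).  Soft-clip events pass through unchanged.

    ``fastq_paths`` is ordered (mate-1 file, mate-2 file); single-file input
    is searched for both mates.
    """
    needed: dict[tuple[str, int], str | None] = {}
    for ev in events:
        if ev.is_hard and not ev.clip_seq:
            needed[(ev.read_name, 1 if ev.is_read1 else 2)] = None
    if needed:
        for i, path in enumerate(fastq_paths):
            file_mate = i + 1 if len(fastq_paths) > 1 else None
            with pysam.FastxFile(str(path)) as fx:
                for entry in fx:
                    name = _strip_mate_suffix(entry.name)
                    if file_mate is None:
                        for mate in (1, 2):
                            if (name, mate) in needed and needed[(name, mate)] is None:
                                needed[(name, mate)] = entry.sequence
                    elif (name, file_mate) in needed:
                        needed[(name, file_mate)] = entry.sequence

    kept: list[ClipEvent] = []
    dropped = 0
    for ev in events:
        if not ev.is_hard or ev.clip_seq:
            kept.append(ev)
            continue
        seq = needed.get((ev.read_name, 1 if ev.is_read1 else 2))
        if seq is None:
            dropped += 1
            continue
        oriented = revcomp(seq) if ev.is_reverse else seq
        if ev.side is ClipSide.PREFIX:
            ev.clip_seq = oriented[: ev.clip_len]
        else:
            ev.clip_seq = oriented[-ev.clip_len :]
        kept.append(ev)
    if dropped:
        log.warning("dropped %d hard-clip events absent from FASTQ", dropped)
    return kept, dropped


class Genome:
    """Reference sequences as uppercase uint8 arrays for fast comparison."""

    def __init__(self, seqs: dict[str, str]):
        self._arrays = {
            name: np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            for name, seq in seqs.items()
        }

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        with pysam.FastaFile(str(path)) as fa:
            return cls({name: fa.fetch(name) for name in fa.references})

    def array(self, contig: str) -> np.ndarray:
        return self._arrays[contig]

    def length(self, contig: str) -> int:
        return int(self._arrays[contig].size)

    def fetch(self, contig: str, start: int, end: int) -> str:
        return self._arrays[contig][start:end].tobytes().decode("ascii")
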