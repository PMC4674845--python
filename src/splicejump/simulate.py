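"""Self-contained fixture generator: toy genome, spliced transcripts,
paired-end reads, a deterministic clip-reporting aligner emulation, and the
truth set used by every benchmark.

Two contigs ("train", "test") mirror a train-on-one-chromosome /
test-on-another design.  Reads are drawn from transcript space; the
emulated aligner maps each read's longest exonic block and clips the rest
(soft by default, a configurable fraction hard), fills mate fields and
template lengths from true placements, and writes a sorted, indexed BAM.
All outputs are byte-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .io_align import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    contigs: tuple[str, ...] = ("train", "test")
    n_transcripts: int = 18
    exons_per_transcript: int = 4
    exon_len_range: tuple[int, int] = (350, 550)
    # menu spans short (< 3v, concordant) through long (> 2000 bp) introns
    intron_len_menu: tuple[int, ...] = (60, 150, 500, 800, 2447)
    intergenic_gap: int = 400
    margin: int = 500
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 20.0
    error_rate: float = 0.0
    hard_clip_frac: float = 0.2
    proper_flag_sds: float = 4.0
    decoy: bool = False
    seed: int = 42


@dataclass
class TranscriptModel:
    contig: str
    exons: list[tuple[int, int]]
    weight: float = 1.0

    @property
    def tx_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> list[tuple[str, int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            out.append((self.contig, e1, s2))
        return out

    def to_genome_blocks(self, t_start: int, length: int) -> list[tuple[int, int, int]]:
        """Map a transcript interval to genome blocks.

        Returns (offset_in_interval, genome_start, block_len) tuples.
        """
        blocks = []
        cursor = 0  # transcript coordinate at current exon start
        for s, e in self.exons:
            exon_len = e - s
            lo = max(t_start, cursor)
            hi = min(t_start + length, cursor + exon_len)
            if hi > lo:
                blocks.append((lo - t_start, s + (lo - cursor), hi - lo))
            cursor += exon_len
        return blocks


@dataclass
class SimRead:
    """One mate of a simulated pair, in reference-forward orientation."""

    name: str
    mate: int  # 1 or 2
    contig: str
    blocks: list[tuple[int, int, int]]  # (read_offset, genome_start, length)
    oriented_seq: str  # reference-forward, with sequencing errors
    is_reverse: bool

    @property
    def fastq_seq(self) -> str:
        return revcomp(self.oriented_seq) if self.is_reverse else self.oriented_seq


@dataclass
class TruthSet:
    junctions: list[tuple[str, int, int]]
    read_blocks: dict[tuple[str, int], list[tuple[int, str, int, int]]] = field(
        default_factory=dict
    )

    def junctions_on(self, contig: str) -> list[tuple[str, int, int]]:
        return [j for j in self.junctions if j[0] == contig]


def generate_reference_and_transcripts(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[TranscriptModel], TruthSet]:
    """Random genome with non-overlapping transcripts laid left to right.

    The first introns of each contig cycle through a shuffled copy of the
    intron menu so every configured length class (short concordant, long
    discordant, > 2 kb) is guaranteed to appear.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    genomes: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    junctions: list[tuple[str, int, int]] = []

    for contig in cfg.contigs:
        cursor = cfg.margin
        menu = list(cfg.intron_len_menu)
        rng.shuffle(menu)
        menu_i = 0
        for _ in range(cfg.n_transcripts):
            exons = []
            pos = cursor
            for k in range(cfg.exons_per_transcript):
                elen = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
                if k < cfg.exons_per_transcript - 1:
                    if menu_i < len(menu):
                        ilen = menu[menu_i]
                        menu_i += 1
                    else:
                        ilen = int(rng.choice(cfg.intron_len_menu))
                    pos += ilen
            model = TranscriptModel(contig=contig, exons=exons)
            transcripts.append(model)
            junctions.extend(model.junctions())
            cursor = pos + cfg.intergenic_gap
        length = cursor + cfg.margin
        seq = rng.choice(BASES, size=length).tobytes().decode("ascii")
        genomes[contig] = seq

    if cfg.decoy:
        genomes = _plant_decoys(genomes, transcripts, cfg)
    return genomes, transcripts, TruthSet(junctions=junctions)


def _plant_decoys(
    genomes: dict[str, str], transcripts: list[TranscriptModel], cfg: SimConfig
) -> dict[str, str]:
    """Copy a donor-flank sequence into the middle of its (long) intron so a
    clipped segment has two flush placements, only one of them concordant."""
    out = dict(genomes)
    for model in transcripts:
        for contig, donor, acceptor in model.junctions():
            if acceptor - donor >= 2000:
                flank = out[contig][donor - 30 : donor]
                mid = (donor + acceptor) // 2
                g = out[contig]
                out[contig] = g[: mid - 30] + flank + g[mid:]
                # length-preserving: replace, do not insert
                out[contig] = out[contig][: len(g)]
                return out
    return out


def simulate_paired_reads(
    transcripts: Sequence[TranscriptModel],
    truth: TruthSet,
    cfg: SimConfig,
) -> list[SimRead]:
    """Draw fragments from transcript space with Normal(insert_mean, sd)
    lengths; copy reads from the spliced sequence with substitution errors.

    Mate 1 is the fragment's left end (forward), mate 2 its right end
    (reverse).  Fragments longer than the transcript are resampled; truth
    blocks record every base's genomic home.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    reads: list[SimRead] = []
    min_frag = cfg.read_len + 10

    for ti, model in enumerate(transcripts):
        tx_arr = _transcript_array(model, cfg)
        tx_len = model.tx_len
        n_frag = int(round(cfg.coverage * tx_len * model.weight / (2 * cfg.read_len)))
        for fi in range(n_frag):
            frag = 0
            while not (min_frag <= frag <= tx_len):
                frag = int(round(rng.normal(cfg.insert_mean, cfg.insert_sd)))
            start = int(rng.integers(0, tx_len - frag + 1))
            name = f"{model.contig}_t{ti}_f{fi}"
            for mate, t_start, is_rev in (
                (1, start, False),
                (2, start + frag - cfg.read_len, True),
            ):
                seg = tx_arr[t_start : t_start + cfg.read_len].copy()
                if cfg.error_rate > 0:
                    hit = rng.random(cfg.read_len) < cfg.error_rate
                    if hit.any():
                        shift = rng.integers(1, 4, size=int(hit.sum()))
                        idx = np.flatnonzero(hit)
                        seg[idx] = BASES[
                            (np.searchsorted(BASES, seg[idx]) + shift) % 4
                        ]
                oriented = seg.tobytes().decode("ascii")
                blocks = model.to_genome_blocks(t_start, cfg.read_len)
                reads.append(
                    SimRead(
                        name=name,
                        mate=mate,
                        contig=model.contig,
                        blocks=blocks,
                        oriented_seq=oriented,
                        is_reverse=is_rev,
                    )
                )
                truth.read_blocks[(name, mate)] = [
                    (off, model.contig, gstart, blen) for off, gstart, blen in blocks
                ]
    return reads


def _transcript_array(model: TranscriptModel, cfg: SimConfig) -> np.ndarray:
    # lazily attached by generate_fixture; standalone callers pass genome
    if not hasattr(model, "_seq_arr"):
        raise RuntimeError("attach transcript sequence with attach_sequences()")
    return model._seq_arr  # type: ignore[attr-defined]


def attach_sequences(
    transcripts: Sequence[TranscriptModel], genomes: dict[str, str]
) -> None:
    for model in transcripts:
        seq = "".join(genomes[model.contig][s:e] for s, e in model.exons)
        model._seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)  # type: ignore[attr-defined]


def emulate_aligner(
    reads: Sequence[SimRead],
    genomes: dict[str, str],
    cfg: SimConfig,
    out_bam: str | Path,
) -> Path:
    """Deterministic BWA-style aligner: map the longest exonic block of each
    read at its true locus, clip the remainder, fill mate/template fields.

    A read whose blocks all fall in one exon gets a full-match CIGAR.  A
    junction-crossing read keeps its longest block (ties: leftmost in the
    read) and the rest becomes a prefix/suffix clip — soft by default, hard
    with probability ``hard_clip_frac`` (per read).  Pairs are FR-oriented;
    the proper-pair flag mimics an aligner's internal insert model (within
    ``proper_flag_sds`` standard deviations of the configured mean).
    """
    out_bam = Path(out_bam)
    rng = np.random.default_rng([cfg.seed, 2])
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": name, "LN": len(seq)} for name, seq in genomes.items()
            ],
        }
    )

    # choose mapped block + clip style per read
    placements: dict[tuple[str, int], dict] = {}
    for read in reads:
        blocks = read.blocks
        bi = max(range(len(blocks)), key=lambda i: (blocks[i][2], -blocks[i][0]))
        off, gstart, blen = blocks[bi]
        pre, suf = off, len(read.oriented_seq) - off - blen
        hard = bool((pre or suf) and rng.random() < cfg.hard_clip_frac)
        placements[(read.name, read.mate)] = {
            "read": read,
            "pos": gstart,
            "end": gstart + blen,
            "pre": pre,
            "suf": suf,
            "hard": hard,
        }

    records = []
    for (name, mate), pl in placements.items():
        read: SimRead = pl["read"]
        other = placements.get((name, 2 if mate == 1 else 1))
        a = pysam.AlignedSegment(header)
        a.query_name = name
        pre, suf, hard = pl["pre"], pl["suf"], pl["hard"]
        clip_op = "H" if hard else "S"
        cig = ""
        if pre:
            cig += f"{pre}{clip_op}"
        cig += f"{len(read.oriented_seq) - pre - suf}M"
        if suf:
            cig += f"{suf}{clip_op}"
        a.cigarstring = cig
        seq = read.oriented_seq
        if hard:
            seq = seq[pre : len(seq) - suf]
        # SAM stores the reverse-strand read as reference-forward, which is
        # exactly our oriented_seq
        a.query_sequence = seq
        a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
        a.reference_id = list(genomes).index(read.contig)
        a.reference_start = pl["pos"]
        a.mapping_quality = 60
        flag = 0x1  # paired
        if read.is_reverse:
            flag |= 0x10
        flag |= 0x40 if mate == 1 else 0x80
        if other is not None:
            if other["read"].is_reverse:
                flag |= 0x20
            a.next_reference_id = list(genomes).index(other["read"].contig)
            a.next_reference_start = other["pos"]
            left = min(pl["pos"], other["pos"])
            right = max(pl["end"], other["end"])
            tlen = right - left
            a.template_length = tlen if pl["pos"] <= other["pos"] else -tlen
            # proper only when both mates map end-to-end: a clipped mate's
            # template length is truncated and would bias the insert model
            proper = (
                read.contig == other["read"].contig
                and read.is_reverse != other["read"].is_reverse
                and pl["pre"] == pl["suf"] == 0
                and other["pre"] == other["suf"] == 0
                and abs(tlen - cfg.insert_mean)
                <= cfg.proper_flag_sds * cfg.insert_sd
            )
            if proper:
                flag |= 0x2
        else:
            flag |= 0x8  # mate unmapped
            a.next_reference_id = -1
            a.next_reference_start = -1
        a.flag |= flag
        records.append(a)

    unsorted = out_bam.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as fh:
        for a in records:
            fh.write(a)
    pysam.sort("--no-PG", "-o", str(out_bam), str(unsorted))
    unsorted.unlink()
    pysam.index(str(out_bam))
    return out_bam


@dataclass
class Fixture:
    dir: Path
    ref_fasta: Path
    fastq1: Path
    fastq2: Path
    bam: Path
    truth_junctions_tsv: Path
    truth_reads_tsv: Path
    genomes: dict[str, str]
    transcripts: list[TranscriptModel]
    truth: TruthSet
    reads: list[SimRead]
    cfg: SimConfig


def generate_fixture(cfg: SimConfig, out_dir: str | Path) -> Fixture:
    """Generate and write the complete fixture into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genomes, transcripts, truth = generate_reference_and_transcripts(cfg)
    attach_sequences(transcripts, genomes)
    reads = simulate_paired_reads(transcripts, truth, cfg)

    ref = out_dir / "ref.fa"
    with open(ref, "w") as fh:
        for name, seq in genomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    pysam.faidx(str(ref))

    fq1, fq2 = out_dir / "reads_1.fastq", out_dir / "reads_2.fastq"
    with open(fq1, "w") as f1, open(fq2, "w") as f2:
        for read in reads:
            fh = f1 if read.mate == 1 else f2
            fh.write(
                f"@{read.name}\n{read.fastq_seq}\n+\n{'I' * len(read.fastq_seq)}\n"
            )

    bam = emulate_aligner(reads, genomes, cfg, out_dir / "align.bam")

    tj = out_dir / "truth_junctions.tsv"
    with open(tj, "w") as fh:
        fh.write("contig\tdonor_pos\tacceptor_pos\n")
        for contig, d, a in sorted(truth.junctions):
            fh.write(f"{contig}\t{d}\t{a}\n")

    tr = out_dir / "truth_reads.tsv"
    with open(tr, "w") as fh:
        fh.write("read_name\tmate\tread_start\tcontig\tref_start\tlength\n")
        for (name, mate), blocks in sorted(truth.read_blocks.items()):
            for off, contig, gstart, blen in blocks:
                fh.write(f"{name}\t{mate}\t{off}\t{contig}\t{gstart}\t{blen}\n")

    return Fixture(
        dir=out_dir,
        ref_fasta=ref,
        fastq1=fq1,
        fastq2=fq2,
        bam=bam,
        truth_junctions_tsv=tj,
        truth_reads_tsv=tr,
        genomes=genomes,
        transcripts=transcripts,
        truth=truth,
        reads=reads,
        cfg=cfg,
    )


def read_truth_junctions(path: str | Path) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, d, a = line.rstrip("\n").split("\t")[:3]
            out.append((contig, int(d), int(a)))
    return out


def read_truth_blocks(
    path: str | Path,
) -> dict[tuple[str, int], list[tuple[int, str, int, int]]]:
    out: dict[tuple[str, int], list[tuple[int, str, int, int]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, mate, off, contig, gstart, blen = line.rstrip("\n").split("\t")
            out.setdefault((name, int(mate)), []).append(
                (int(off), contig, int(gstart), int(blen))
            )
    return out
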