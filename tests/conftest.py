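"""Shared fixtures: simulated datasets and end-to-end runs, built once per
session and reused across test modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from splicejump import simulate as sim
from splicejump.classifier import (
    GridSearchConfig,
    TrainedModel,
    build_training_set,
    predict_sites,
    train_model,
)
from splicejump.io_align import AlignmentRecord
from splicejump.junctions import (
    JunctionStatus,
    PipelineConfig,
    SiteAnalysis,
    analyze,
    build_connection_graph,
    call_junctions,
)


def make_record(
    read_name="r",
    contig="chr",
    pos=0,
    cigar="100M",
    mapq=60,
    is_reverse=False,
    is_read1=True,
    mate_contig=None,
    mate_pos=-1,
    template_len=0,
    seq=None,
    is_primary=True,
    is_mapped=True,
    is_mate_mapped=False,
    is_mate_reverse=False,
    is_proper=False,
) -> AlignmentRecord:
    """Hand-built AlignmentRecord with a CIGAR string shorthand."""
    parsed = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        else:
            parsed.append((ch, int(n)))
            n = ""
    return AlignmentRecord(
        read_name=read_name,
        contig=contig,
        pos=pos,
        cigar=tuple(parsed),
        mapq=mapq,
        is_reverse=is_reverse,
        is_read1=is_read1,
        mate_contig=mate_contig,
        mate_pos=mate_pos,
        template_len=template_len,
        seq=seq,
        is_primary=is_primary,
        is_mapped=is_mapped,
        is_mate_mapped=is_mate_mapped,
        is_mate_reverse=is_mate_reverse,
        is_proper=is_proper,
    )


@dataclass
class E2ERun:
    fx: sim.Fixture
    analysis: SiteAnalysis
    model: TrainedModel
    predictions: dict
    junctions: list

    def called_on(self, contig):
        return [
            j
            for j in self.junctions
            if j.status is JunctionStatus.CALLED and j.contig == contig
        ]


def run_e2e(fx: sim.Fixture, cfg: PipelineConfig | None = None) -> E2ERun:
    """Train on the 'train' contig, classify everywhere, call junctions."""
    cfg = cfg or PipelineConfig()
    an = analyze(fx.bam, fx.ref_fasta, [fx.fastq1, fx.fastq2], cfg)
    train_sites = [s for s in an.sites if s.contig == "train"]
    examples = build_training_set(
        train_sites,
        an.features,
        truth_junctions=fx.truth.junctions_on("train"),
        slack=cfg.s,
        l=cfg.l,
        seed=cfg.seed,
    )
    model = train_model(examples, GridSearchConfig(seed=cfg.seed))
    preds = predict_sites(model, an.sites, an.features)
    edges = build_connection_graph(an.sites, an.results)
    junctions = call_junctions(edges, preds, an.pair_index, an.model)
    return E2ERun(fx=fx, analysis=an, model=model, predictions=preds, junctions=junctions)


@pytest.fixture(scope="session")
def clean_fx(tmp_path_factory) -> sim.Fixture:
    """Error-free fixture: two contigs, 108 truth junctions, ~20x coverage."""
    return sim.generate_fixture(
        sim.SimConfig(seed=7), tmp_path_factory.mktemp("fx_clean")
    )


@pytest.fixture(scope="session")
def noisy_fx(tmp_path_factory) -> sim.Fixture:
    return sim.generate_fixture(
        sim.SimConfig(seed=11, error_rate=0.01), tmp_path_factory.mktemp("fx_noisy")
    )


@pytest.fixture(scope="session")
def mini_fx(tmp_path_factory) -> sim.Fixture:
    """Small fixture for brute-force oracles and repeated pipeline runs."""
    return sim.generate_fixture(
        sim.SimConfig(seed=3, n_transcripts=4, coverage=12.0),
        tmp_path_factory.mktemp("fx_mini"),
    )


@pytest.fixture(scope="session")
def clean_run(clean_fx) -> E2ERun:
    return run_e2e(clean_fx)


@pytest.fixture(scope="session")
def noisy_run(noisy_fx) -> E2ERun:
    return run_e2e(noisy_fx)


@pytest.fixture(scope="session")
def clean_analysis(clean_run) -> SiteAnalysis:
    return clean_run.analysis
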