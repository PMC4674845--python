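"""Benchmarking: slack matching, precision/recall/F-value, overlap counts,
and mapped-base ratios."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

Junction = tuple[str, int, int]


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    slack: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f_value: float

    def rounded(self, ndigits: int = 4) -> "Metrics":
        return Metrics(
            round(self.precision, ndigits),
            round(self.recall, ndigits),
            round(self.f_value, ndigits),
        )


def match_with_slack(
    called: Sequence[Junction], benchmark: Sequence[Junction], slack: int
) -> MatchResult:
    """Greedy one-to-one matching: a called junction matches a benchmark one
    when BOTH boundary distances are <= slack; closest (summed distance)
    pairs are taken first.  Unmatched called -> FP, unmatched benchmark -> FN.
    """
    candidates = []
    for i, (ca, cd, cc) in enumerate(called):
        for j, (ba, bd, bc) in enumerate(benchmark):
            if ca != ba:
                continue
            dd, da = abs(cd - bd), abs(cc - bc)
            if dd <= slack and da <= slack:
                candidates.append((dd + da, i, j))
    candidates.sort()
    used_called: set[int] = set()
    used_bench: set[int] = set()
    pairs = []
    for cost, i, j in candidates:
        if i in used_called or j in used_bench:
            continue
        used_called.add(i)
        used_bench.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return MatchResult(
        tp=tp,
        fp=len(called) - tp,
        fn=len(benchmark) - tp,
        slack=slack,
        pairs=pairs,
    )


def compute_metrics(tp: int, fp: int, fn: int) -> Metrics:
    """precision = TP/(TP+FP), recall = TP/(TP+FN), F = 2PR/(P+R);
    zero denominators yield 0 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_value = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return Metrics(precision, recall, f_value)


def overlap_count(
    set_a: Sequence[Junction], set_b: Sequence[Junction], slack: int
) -> int:
    """How many junctions of one call set overlap the other within slack."""
    return match_with_slack(set_a, set_b, slack).tp


def slack_sweep(
    called: Sequence[Junction],
    benchmark: Sequence[Junction],
    lo: int = 0,
    hi: int = 15,
) -> pd.DataFrame:
    """Metrics for every slack in [lo, hi] (one row per slack)."""
    rows = []
    for slack in range(lo, hi + 1):
        res = match_with_slack(called, benchmark, slack)
        met = compute_metrics(res.tp, res.fp, res.fn)
        rows.append(
            {
                "slack": slack,
                "tp": res.tp,
                "fp": res.fp,
                "fn": res.fn,
                "precision": round(met.precision, 4),
                "recall": round(met.recall, 4),
                "f_value": round(met.f_value, 4),
            }
        )
    return pd.DataFrame(rows)


def mapped_base_ratio(
    report_rows: Iterable[tuple],
    truth_blocks: Mapping[tuple[str, int], list[tuple[int, str, int, int]]] | None = None,
    total_bases: int | None = None,
) -> float:
    """Fraction of read bases placed on the reference.

    ``report_rows`` are (read_name, mate, read_len, contig, ref_start,
    read_start, length) tuples from the pipeline's read report.  Without a
    truth set every placed base counts; with one (``(name, mate) -> list of
    (read_start, contig, ref_start, length)`` blocks, reference-forward
    read coordinates) a base counts only when placed at its true
    coordinate.  ``total_bases`` defaults to the summed read lengths of the
    distinct reads present in the report.
    """
    rows = list(report_rows)
    if total_bases is None:
        seen: dict[tuple[str, int], int] = {}
        for name, mate, read_len, *_ in rows:
            seen[(name, mate)] = max(seen.get((name, mate), 0), read_len)
        total_bases = sum(seen.values())
    if total_bases == 0:
        return 0.0

    if truth_blocks is None:
        placed = sum(length for *_, length in rows)
        return placed / total_bases

    correct = 0
    for name, mate, read_len, contig, ref_start, read_start, length in rows:
        blocks = truth_blocks.get((name, mate))
        if not blocks:
            continue
        for k in range(length):
            off = read_start + k
            pos = ref_start + k
            for b_off, b_contig, b_ref, b_len in blocks:
                if b_contig == contig and b_off <= off < b_off + b_len:
                    if b_ref + (off - b_off) == pos:
                        correct += 1
                    break
    return correct / total_bases


def read_report_rows(path: str | Path) -> list[tuple]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            name, mate, rl, contig, rs, qs, ln = line.rstrip("\n").split("\t")
            rows.append((name, int(mate), int(rl), contig, int(rs), int(qs), int(ln)))
    return rows
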