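"""SVM site classification: training-set construction, grid-searched
training, prediction, and model (de)serialization.

Labels come either from a simulation truth set (sites within a small slack
of a true junction boundary are positive) or from an annotation table
(annotated sites with local read coverage are positive; an equal number of
covered, unannotated candidate sites is sampled as negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .candidate_sites import CandidateSite, Direction
from .features import FeatureVector, anchor_mean_coverage
from .io_align import CoverageTrack

DEFAULT_SEED = 42
DEFAULT_LABEL_SLACK = 10


@dataclass
class LabeledExample:
    site: CandidateSite
    features: np.ndarray
    label: int


@dataclass(frozen=True)
class GridSearchConfig:
    c_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-3, 8, 2))
    gamma_grid: tuple[float, ...] = tuple(float(2.0**e) for e in range(-7, 4, 2))
    folds: int = 10
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class TrainedModel:
    pipeline: Pipeline
    best_c: float
    best_gamma: float
    cv_accuracy: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.pipeline.n_features_in_:
            raise ValueError(
                f"feature matrix must be (n, {self.pipeline.n_features_in_})"
            )
        return self.pipeline.predict(X).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "format": "splicejump-svm-v1",
                "pipeline": self.pipeline,
                "best_c": self.best_c,
                "best_gamma": self.best_gamma,
                "cv_accuracy": self.cv_accuracy,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format") != "splicejump-svm-v1":
            raise ValueError(f"not a splicejump model file: {path}")
        return cls(
            pipeline=blob["pipeline"],
            best_c=blob["best_c"],
            best_gamma=blob["best_gamma"],
            cv_accuracy=blob["cv_accuracy"],
        )


def _norm_features(site: CandidateSite, table: Mapping[int, FeatureVector]) -> np.ndarray:
    fv = table[id(site)]
    if fv.normalized is None:
        raise ValueError("features must be normalized before training")
    return np.asarray(fv.normalized, dtype=float)


def _truth_boundaries(
    truth_junctions: Iterable[tuple[str, int, int]]
) -> dict[tuple[str, Direction], set[int]]:
    out: dict[tuple[str, Direction], set[int]] = {}
    for contig, donor, acceptor in truth_junctions:
        out.setdefault((contig, Direction.DONOR), set()).add(donor)
        out.setdefault((contig, Direction.ACCEPTOR), set()).add(acceptor)
    return out


def _near(pos: int, positions: set[int], slack: int) -> bool:
    return any(abs(pos - p) <= slack for p in positions)


def build_training_set(
    sites: Sequence[CandidateSite],
    table: Mapping[int, FeatureVector],
    truth_junctions: Iterable[tuple[str, int, int]] | None = None,
    annotation: Iterable[tuple[str, int, str]] | None = None,
    track: CoverageTrack | None = None,
    slack: int = DEFAULT_LABEL_SLACK,
    l: int = 25,
    seed: int = DEFAULT_SEED,
) -> list[LabeledExample]:
    """Labeled examples from either a truth set or an annotation table.

    Simulation mode (``truth_junctions``): every candidate site is kept;
    label 1 iff it lies within ``slack`` of a true boundary of its own
    direction.

    Annotation mode (``annotation`` rows of (contig, pos, direction)):
    positives are candidate sites matching an annotated site within
    ``slack`` *and* having nonzero anchor coverage — annotated but silent
    sites are excluded.  Negatives are drawn (seeded, without replacement)
    from covered, unannotated candidates, exactly as many as positives.
    """
    if (truth_junctions is None) == (annotation is None):
        raise ValueError("provide exactly one of truth_junctions / annotation")

    if truth_junctions is not None:
        bounds = _truth_boundaries(truth_junctions)
        examples = [
            LabeledExample(
                site,
                _norm_features(site, table),
                int(_near(site.pos, bounds.get((site.contig, site.direction), set()), slack)),
            )
            for site in sites
        ]
        if not any(ex.label for ex in examples):
            raise ValueError("no positive examples: truth set matches no candidate site")
        return examples

    if track is None:
        raise ValueError("annotation mode requires a coverage track")
    ann: dict[tuple[str, Direction], set[int]] = {}
    for contig, pos, direction in annotation:
        d = Direction[direction] if isinstance(direction, str) else direction
        ann.setdefault((contig, d), set()).add(int(pos))

    positives, candidates_neg = [], []
    for site in sites:
        covered = anchor_mean_coverage(site, track, l) > 0
        annotated = _near(site.pos, ann.get((site.contig, site.direction), set()), slack)
        if annotated and covered:
            positives.append(site)
        elif covered and not annotated:
            candidates_neg.append(site)
    if not positives:
        raise ValueError("no positive examples: annotation matches no covered site")
    if len(candidates_neg) < len(positives):
        raise ValueError(
            f"cannot sample {len(positives)} negatives from "
            f"{len(candidates_neg)} covered unannotated sites"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(candidates_neg), size=len(positives), replace=False)
    negatives = [candidates_neg[i] for i in sorted(pick)]
    return [
        LabeledExample(s, _norm_features(s, table), 1) for s in positives
    ] + [
        LabeledExample(s, _norm_features(s, table), 0) for s in negatives
    ]


def train_model(
    examples: Sequence[LabeledExample],
    cfg: GridSearchConfig | None = None,
) -> TrainedModel:
    """Grid-searched RBF SVM with per-feature [0, 1] scaling.

    Hyperparameters maximize mean stratified k-fold CV accuracy; the final
    model is refit on all examples with the best pair.
    """
    cfg = cfg or GridSearchConfig()
    X = np.vstack([ex.features for ex in examples])
    y = np.array([ex.label for ex in examples], dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    folds = min(cfg.folds, int(counts.min()))
    if folds < 2:
        raise ValueError("need at least 2 examples per class for CV")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    pipe = Pipeline([("scale", MinMaxScaler()), ("svm", SVC(kernel="rbf"))])
    search = GridSearchCV(
        pipe,
        param_grid={"svm__C": list(cfg.c_grid), "svm__gamma": list(cfg.gamma_grid)},
        scoring="accuracy",
        cv=cv,
        refit=True,
    )
    search.fit(X, y)
    return TrainedModel(
        pipeline=search.best_estimator_,
        best_c=float(search.best_params_["svm__C"]),
        best_gamma=float(search.best_params_["svm__gamma"]),
        cv_accuracy=float(search.best_score_),
    )


def predict_sites(
    model: TrainedModel,
    sites: Sequence[CandidateSite],
    table: Mapping[int, FeatureVector],
) -> dict[int, bool]:
    """Hard true/false call per site, keyed by id(site)."""
    if not sites:
        return {}
    X = np.vstack([_norm_features(s, table) for s in sites])
    labels = model.predict(X)
    return {id(s): bool(lab) for s, lab in zip(sites, labels)}


def annotation_from_gtf(gtf_path: str | Path) -> list[tuple[str, int, str]]:
    """Internal exon boundaries of a GTF as (contig, pos, direction) rows.

    For each transcript's sorted exons, every exon end except the last is a
    donor and every exon start except the first an acceptor, converted to
    0-based half-open coordinates.  Annotation-track agnostic: only the
    transcript_id attribute is required on exon features.
    """
    tx: dict[str, list[tuple[str, int, int]]] = {}
    with open(gtf_path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "exon":
                continue
            contig, start, end, attrs = parts[0], int(parts[3]) - 1, int(parts[4]), parts[8]
            tid = None
            for fieldstr in attrs.split(";"):
                fieldstr = fieldstr.strip()
                if fieldstr.startswith("transcript_id"):
                    tid = fieldstr.split(None, 1)[1].strip().strip('"')
                    break
            if tid is None:
                continue
            tx.setdefault(tid, []).append((contig, start, end))
    rows: list[tuple[str, int, str]] = []
    for exons in tx.values():
        exons.sort(key=lambda e: e[1])
        for i, (contig, start, end) in enumerate(exons):
            if i > 0:
                rows.append((contig, start, "ACCEPTOR"))
            if i < len(exons) - 1:
                rows.append((contig, end, "DONOR"))
    rows.sort()
    return rows


def read_annotation_tsv(path: str | Path) -> list[tuple[str, int, str]]:
    rows = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            contig, pos, direction = line.split("\t")[:3]
            rows.append((contig, int(pos), direction.strip()))
    return rows
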