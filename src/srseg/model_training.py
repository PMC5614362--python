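"""Classifier-driven segmentation of super-regions.

The workflow mirrors interactive scribble training: per-supervoxel
descriptors are built from one or more feature channels, a classifier is
fit on the annotated supervoxels, class probabilities are predicted for
every supervoxel, the prediction is optionally smoothed by a Potts /
appearance Markov random field solved with iterated conditional modes
(ICM), and finally regions whose top-two probability margin clears a
confidence threshold are committed to the annotation level.  Iterating
train -> refine -> commit lets each round train on more regions than the
last, so the labelling grows increasingly robust until nothing is left
unlabeled.

Descriptors per region and channel are mean, standard deviation and the
25/50/75th percentiles — low-dimensional, robust to noise, and usable by
any of the classifier back-ends (random forest, SVM, online linear).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import SGDClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotation import UNLABELED
from .super_regions import adjacency_edges, region_means

CLASSIFIERS = ("ensemble_rf", "svm", "online_linear")
REFINEMENTS = ("none", "potts", "appearance")

DEFAULT_N_TREES = 100
DEFAULT_REFINE_LAMBDA = 10.0
_N_TREES_RANGE = (10, 100)
_REFINE_LAMBDA_RANGE = (1.0, 500.0)
_PROB_FLOOR = 1e-8  # probability clip for -log unaries
_MAX_ICM_SWEEPS = 50


@dataclass
class TrainConfig:
    predict_level: int
    sources: List[str]
    region: str = "supervoxel"
    classifier: str = "ensemble_rf"
    n_trees: int = DEFAULT_N_TREES
    refinement: str = "appearance"
    refine_lambda: float = DEFAULT_REFINE_LAMBDA
    confidence: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not self.sources:
            raise ValueError("TrainConfig.sources must be non-empty")
        if self.region not in ("voxel", "supervoxel"):
            raise ValueError(f"region must be 'voxel' or 'supervoxel', got {self.region!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.refinement not in REFINEMENTS:
            raise ValueError(f"refinement must be one of {REFINEMENTS}")
        if not (_N_TREES_RANGE[0] <= self.n_trees <= _N_TREES_RANGE[1]):
            raise ValueError(f"n_trees must be in {_N_TREES_RANGE}, got {self.n_trees}")
        if not (_REFINE_LAMBDA_RANGE[0] <= self.refine_lambda <= _REFINE_LAMBDA_RANGE[1]):
            raise ValueError(
                f"refine_lambda must be in {_REFINE_LAMBDA_RANGE}, got {self.refine_lambda}")


@dataclass
class PredictionResult:
    probs: np.ndarray  # (n_regions, n_classes), rows sum to 1
    class_ids: np.ndarray  # label id per probability column
    train_mask: np.ndarray  # bool, regions that carried user annotations
    train_labels: np.ndarray  # label id per region (UNLABELED where none)
    labels: np.ndarray  # current per-region label id assignment (argmax / refined)
    refined: bool = False
    energy_trace: list = field(default_factory=list)
    committed: Optional[np.ndarray] = None  # bool per region after commit

    def margins(self) -> np.ndarray:
        """Top-two probability margin per region, in [0, 1]."""
        if self.probs.shape[1] == 1:
            return np.ones(len(self.probs))
        part = np.sort(self.probs, axis=1)
        return part[:, -1] - part[:, -2]


# ---------------------------------------------------------------------------
# descriptors


def build_descriptors(svp, channels) -> np.ndarray:
    """Per-supervoxel feature matrix: 5 statistics per channel.

    Columns per channel are (mean, sd, p25, p50, p75); channels are laid
    out consecutively, so the matrix is (n_regions, 5 * n_channels).
    """
    channels = list(channels)
    if not channels:
        raise ValueError("build_descriptors needs at least one source channel")
    labels = svp.labels.ravel()
    n = svp.n_regions
    order = np.argsort(labels, kind="stable")
    counts = np.bincount(labels, minlength=n)
    splits = np.cumsum(counts)[:-1]
    cols = []
    for ch in channels:
        grid = np.asarray(getattr(ch, "data", ch), dtype=np.float64)
        if grid.shape != svp.labels.shape:
            raise ValueError("channel extent does not match the partition")
        vals = grid.ravel()[order]
        groups = np.split(vals, splits)
        mean = region_means(svp, grid)
        sd = np.array([g.std() for g in groups])
        pcts = np.array([np.percentile(g, [25, 50, 75]) for g in groups])
        cols.append(np.column_stack([mean, sd, pcts]))
    X = np.concatenate(cols, axis=1)
    if not np.isfinite(X).all():
        raise ValueError("descriptor matrix contains non-finite values")
    return X


def region_annotations(level, svp) -> np.ndarray:
    """Label id per supervoxel: majority vote of its annotated voxels
    (UNLABELED where the supervoxel has none).  Lowest id wins ties."""
    labels = svp.labels.ravel()
    ann = level.voxel_labels.ravel()
    out = np.full(svp.n_regions, UNLABELED, dtype=np.int64)
    annotated = ann != UNLABELED
    if not annotated.any():
        return out
    label_ids = np.unique(ann[annotated])
    votes = np.zeros((svp.n_regions, len(label_ids)), dtype=np.int64)
    for c, lid in enumerate(label_ids):
        votes[:, c] = np.bincount(labels[ann == lid], minlength=svp.n_regions)
    has = votes.sum(axis=1) > 0
    out[has] = label_ids[np.argmax(votes[has], axis=1)]
    return out


def _make_classifier(cfg: TrainConfig, seed: int):
    if cfg.classifier == "ensemble_rf":
        return RandomForestClassifier(n_estimators=cfg.n_trees, random_state=seed,
                                      n_jobs=1)
    if cfg.classifier == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(probability=True, random_state=seed))
    return make_pipeline(StandardScaler(),
                         SGDClassifier(loss="log_loss", random_state=seed))


# ---------------------------------------------------------------------------
# train / predict


def train_predict(ws, cfg: TrainConfig) -> PredictionResult:
    """Fit the configured classifier on annotated regions and predict all.

    Training regions keep their user label: their probability rows are the
    one-hot encoding of the annotation regardless of classifier output.
    Deterministic for a fixed ``cfg.seed``.
    """
    if ws.supervoxels is None and cfg.region == "supervoxel":
        raise ValueError("train_predict needs a supervoxel partition")
    level = ws.level(cfg.predict_level)
    svp = ws.supervoxels if cfg.region == "supervoxel" else _voxel_partition(ws)
    channels = [ws.channels[s] if s in ws.channels else ws.channel_data(s)
                for s in cfg.sources]
    X = build_descriptors(svp, channels)

    train_labels = region_annotations(level, svp)
    train_mask = train_labels != UNLABELED
    classes = np.unique(train_labels[train_mask])
    if len(classes) < 2:
        raise ValueError(
            f"training needs >= 2 annotated classes, found {len(classes)}")

    clf = _make_classifier(cfg, cfg.seed)
    clf.fit(X[train_mask], train_labels[train_mask])
    probs = clf.predict_proba(X)
    class_ids = np.asarray(clf.classes_ if not hasattr(clf, "steps")
                           else clf.steps[-1][1].classes_)
    # contract: annotated regions keep their user label
    for c, lid in enumerate(class_ids):
        rows = train_mask & (train_labels == lid)
        probs[rows] = 0.0
        probs[rows, c] = 1.0
    labels = class_ids[np.argmax(probs, axis=1)]
    return PredictionResult(probs=probs, class_ids=class_ids,
                            train_mask=train_mask, train_labels=train_labels,
                            labels=labels)


def _voxel_partition(ws):
    """Degenerate partition with one region per voxel (voxel-level training)."""
    from .super_regions import SupervoxelPartition

    shape = ws.roi.shape
    labels = np.arange(int(np.prod(shape)), dtype=np.int32).reshape(shape)
    return SupervoxelPartition(labels=labels, n_regions=labels.size,
                               params={"source": "__voxels__"})


# ---------------------------------------------------------------------------
# MRF refinement (ICM)


def refinement_energy(labels_idx, unary, edges, w_edges, refine_lambda):
    """Total energy: sum of unaries + lambda * sum of cut edge penalties."""
    e = float(unary[np.arange(len(labels_idx)), labels_idx].sum())
    cut = labels_idx[edges[:, 0]] != labels_idx[edges[:, 1]]
    return e + refine_lambda * float(w_edges[cut].sum())


def refine_predictions(pred: PredictionResult, refinement: str,
                       refine_lambda: float, svp, source=None) -> PredictionResult:
    """MAP smoothing of the predicted labels over the supervoxel graph.

    Unary cost is -log probability; a cut edge (neighbouring regions with
    different labels) costs ``refine_lambda`` times 1 (Potts) or times an
    appearance weight exp(-(dmean)^2 / 2 s^2) with s the median absolute
    neighbour mean difference, so similar-looking neighbours are expensive
    to separate.  Solved by ICM sweeps in fixed region order; the energy is
    non-increasing by construction and the trace is recorded.  Regions with
    user annotations are held fixed.
    """
    if refinement not in REFINEMENTS:
        raise ValueError(f"refinement must be one of {REFINEMENTS}")
    if refinement == "none":
        return pred
    if refinement == "appearance" and source is None:
        raise ValueError("appearance refinement needs a source channel")

    n, k = pred.probs.shape
    unary = -np.log(np.clip(pred.probs, _PROB_FLOOR, 1.0))
    edges = adjacency_edges(svp.labels)

    if refinement == "potts":
        w_edges = np.ones(len(edges))
    else:
        means = region_means(svp, np.asarray(getattr(source, "data", source)))
        dmean = np.abs(means[edges[:, 0]] - means[edges[:, 1]])
        s = np.median(dmean)
        if s <= 0:
            w_edges = np.ones(len(edges))
        else:
            w_edges = np.exp(-(dmean ** 2) / (2.0 * s ** 2))

    # neighbour lists
    nbr = [[] for _ in range(n)]
    for eidx, (i, j) in enumerate(edges):
        nbr[i].append((int(j), eidx))
        nbr[j].append((int(i), eidx))

    id_to_idx = {int(lid): c for c, lid in enumerate(pred.class_ids)}
    labels_idx = np.array([id_to_idx[int(l)] for l in pred.labels])
    fixed = pred.train_mask

    trace = [refinement_energy(labels_idx, unary, edges, w_edges, refine_lambda)]
    for _ in range(_MAX_ICM_SWEEPS):
        changed = False
        for i in range(n):
            if fixed[i]:
                continue
            cost = unary[i].copy()
            for j, eidx in nbr[i]:
                cost += refine_lambda * w_edges[eidx] * (
                    np.arange(k) != labels_idx[j])
            best = int(np.argmin(cost))
            if best != labels_idx[i]:
                labels_idx[i] = best
                changed = True
        trace.append(refinement_energy(labels_idx, unary, edges, w_edges, refine_lambda))
        if not changed:
            break

    return PredictionResult(probs=pred.probs, class_ids=pred.class_ids,
                            train_mask=pred.train_mask, train_labels=pred.train_labels,
                            labels=pred.class_ids[labels_idx], refined=True,
                            energy_trace=trace)


# ---------------------------------------------------------------------------
# commitment


def commit_predictions(ws, pred: PredictionResult, confidence: float,
                       level_id: int, svp=None, subregion=None,
                       labels=None) -> dict:
    """Promote confident predictions to annotations.

    A region is committed iff its top-two probability margin times 100 is at
    least ``confidence``: confidence 0 assigns every unlabeled region to its
    best match, confidence 100 assigns only regions where a single class
    holds all the probability.  ``subregion`` (six half-open bounds in ROI
    space) restricts which voxels are written; ``labels`` restricts which
    predicted labels are saved.  User annotations are never overwritten.
    """
    if not (0 <= confidence <= 100):
        raise ValueError(f"confidence must be in [0, 100], got {confidence}")
    svp = svp if svp is not None else ws.supervoxels
    level = ws.level(level_id)
    margin = pred.margins() * 100.0
    commit = margin >= confidence
    commit &= ~pred.train_mask  # annotations stay authoritative
    if labels is not None:
        commit &= np.isin(pred.labels, np.asarray(labels))
    region_label = np.where(commit, pred.labels, UNLABELED).astype(np.int32)

    voxel_new = region_label[svp.labels]
    write = voxel_new != UNLABELED
    # never overwrite existing annotations
    write &= level.voxel_labels == UNLABELED
    if subregion is not None:
        z0, z1, y0, y1, x0, x1 = subregion
        box = np.zeros_like(write)
        box[z0:z1, y0:y1, x0:x1] = True
        write &= box
    level.voxel_labels[write] = voxel_new[write]
    pred.committed = commit
    return {"committed_regions": int(commit.sum()),
            "committed_voxels": int(write.sum()),
            "unassigned_regions": int((~commit & ~pred.train_mask).sum())}


def iterate_training(ws, cfg: TrainConfig, rounds: int = 3,
                     source_for_refine=None) -> dict:
    """Loop train -> refine -> commit until no region is unlabeled.

    Stops early when the unlabeled-region count reaches zero; if a round
    commits nothing new, the remainder is committed at confidence 0 so the
    loop always terminates with a fully labelled level.  Returns per-round
    bookkeeping.
    """
    level = ws.level(cfg.predict_level)
    svp = ws.supervoxels
    history = []
    refine_src = source_for_refine
    if refine_src is None and cfg.sources:
        refine_src = ws.channels.get(cfg.sources[0], None)
    pred = None
    for rnd in range(rounds):
        before = level.unlabeled_count()
        if before == 0:
            break
        pred = train_predict(ws, cfg)
        if cfg.refinement != "none":
            pred = refine_predictions(pred, cfg.refinement, cfg.refine_lambda,
                                      svp, source=refine_src)
        stats = commit_predictions(ws, pred, cfg.confidence, cfg.predict_level, svp=svp)
        after = level.unlabeled_count()
        history.append({"round": rnd, "unlabeled_before": before,
                        "unlabeled_after": after, **stats})
        if after == 0:
            break
        if after >= before:  # stalled: flush the remainder
            commit_predictions(ws, pred, 0.0, cfg.predict_level, svp=svp)
            history[-1]["fallback_confidence_0"] = True
            break
    if level.unlabeled_count() > 0:
        if pred is None:
            pred = train_predict(ws, cfg)
            if cfg.refinement != "none":
                pred = refine_predictions(pred, cfg.refinement, cfg.refine_lambda,
                                          svp, source=refine_src)
        commit_predictions(ws, pred, 0.0, cfg.predict_level, svp=svp)
    return {"rounds": history, "unlabeled": level.unlabeled_count()}
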