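"""The two-level SVM network: site model plus per-type models.

Level 1 classifies a candidate lysine/arginine as methylated or not, trained
on all annotated sites against 1:1 sampled unannotated residues.  Level 2
assigns methylation types (mono/di, plus tri for lysine) with independent
one-vs-rest SVMs trained on the methylated instances only; at prediction
time the type models are consulted only for sites the level-1 model calls
positive.

Each task carries its own sliding-window size.  The defaults are the
window sizes selected by cross-validated accuracy scans (site 17 for both
residues; mono 23 for K / 17 for R; di 17 for K / 19 for R; tri 21);
:func:`scan_window_sizes` re-runs such a scan over sizes 9..23 with ties
broken toward the smaller window.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import joblib
import numpy as np

from .datasets import build_instances
from .features import (
    FeatureAssembler,
    FeatureSources,
    labels_for,
    type_labels_for,
)
from .selection import SubtypeSvmClassifier
from .seq_features import SEQ_SUBTYPES

logger = logging.getLogger(__name__)

ARCHIVE_SCHEMA_VERSION = 1

DEFAULT_WINDOWS = {
    "K": {"site": 17, "mono": 23, "di": 17, "tri": 21},
    "R": {"site": 17, "mono": 17, "di": 19},
}

WINDOW_SCAN_SIZES = tuple(range(9, 24, 2))


@dataclass
class TrainConfig:
    """Knobs for training the two-level network."""

    subtypes: tuple = SEQ_SUBTYPES
    windows: dict | None = None  # task -> w, overrides DEFAULT_WINDOWS
    cv_folds: int = 5
    negative_ratio: float = 1.0
    max_candidates: int | None = 40
    C_grid: tuple | None = None
    gamma_grid: tuple | None = None
    seq_config: object = None
    geometry_config: object = None

    def window_for(self, residue: str, task: str) -> int:
        if self.windows and task in self.windows:
            return int(self.windows[task])
        return DEFAULT_WINDOWS[residue][task]


@dataclass
class TaskModel:
    """One fitted task: its window, encoder state, and classifier."""

    task: str
    w: int
    assembler: FeatureAssembler
    classifier: SubtypeSvmClassifier


@dataclass
class TwoLevelNetwork:
    """Fitted site model (level 1) + type models (level 2) for one residue."""

    residue: str
    site: TaskModel
    types: dict = field(default_factory=dict)

    @property
    def tasks(self):
        return ["site"] + sorted(self.types)


@dataclass
class PredictionResult:
    site_prob: float
    site_call: bool
    type_probs: dict | None  # None when the site call is negative


def _tasks_for(residue: str):
    return ("mono", "di", "tri") if residue == "K" else ("mono", "di")


def _fit_task(task, instances, y, proteins, w, config, sources, seed):
    assembler = FeatureAssembler(
        proteins=proteins,
        w=w,
        subtypes=config.subtypes,
        seq_config=config.seq_config,
        geometry_config=config.geometry_config,
        sources=sources,
    )
    X = assembler.fit_transform(instances, y)
    clf = SubtypeSvmClassifier(
        feature_groups=assembler.feature_groups_,
        cv=config.cv_folds,
        random_state=seed,
        max_candidates=config.max_candidates,
        C_grid=config.C_grid,
        gamma_grid=config.gamma_grid,
    )
    clf.fit(X, y)
    logger.info(
        "task %s: w=%d, %d/%d features, CV acc %.3f",
        task, w, clf.support_.size, X.shape[1], clf.cv_accuracy_,
    )
    return TaskModel(task=task, w=w, assembler=assembler, classifier=clf)


def train_two_level(proteins, residue: str, config: TrainConfig | None = None,
                    seed: int = 0, sources: FeatureSources | None = None) -> TwoLevelNetwork:
    """Train the site model and the per-type models for one residue.

    Negatives for the site task are sampled 1:1 (by default) from
    unannotated residues of the same type on the same proteins.  Type
    models are one-vs-rest among the methylated instances; a type with
    fewer positives than CV folds is skipped with a warning.
    """
    if residue not in ("K", "R"):
        raise ValueError("residue must be K or R")
    config = config or TrainConfig()
    sources = sources or FeatureSources()
    prot_map = {p.id: p for p in proteins}

    instances = build_instances(
        proteins, residue, ratio=config.negative_ratio, seed=seed
    )
    y_site = labels_for(instances)
    if y_site.sum() == 0 or y_site.sum() == len(y_site):
        raise ValueError("site task needs both classes")
    site = _fit_task(
        "site", instances, y_site, prot_map,
        config.window_for(residue, "site"), config, sources, seed,
    )

    positives = [i for i in instances if i.is_positive]
    types: dict[str, TaskModel] = {}
    for t in _tasks_for(residue):
        y_t = type_labels_for(positives, t)
        if y_t.sum() < config.cv_folds or (len(y_t) - y_t.sum()) < config.cv_folds:
            logger.warning(
                "type model %r skipped: %d positive / %d negative instances",
                t, int(y_t.sum()), int(len(y_t) - y_t.sum()),
            )
            continue
        types[t] = _fit_task(
            t, positives, y_t, prot_map,
            config.window_for(residue, t), config, sources, seed + 1,
        )
    return TwoLevelNetwork(residue=residue, site=site, types=types)


def predict(network: TwoLevelNetwork, protein, position: int,
            sources: FeatureSources | None = None,
            threshold: float = 0.5) -> PredictionResult:
    """Predict the methylation status (and, if called, types) of one site."""
    if protein.sequence[position - 1] != network.residue:
        raise ValueError(
            f"residue mismatch: network is for {network.residue}, sequence has "
            f"{protein.sequence[position - 1]} at {position}"
        )
    from .datasets import SiteInstance

    inst = SiteInstance(protein.id, position, network.residue, "negative")
    site_prob = _score_task(network.site, inst, protein, sources)
    call = site_prob >= threshold
    type_probs = None
    if call:
        type_probs = {
            t: _score_task(m, inst, protein, sources)
            for t, m in network.types.items()
        }
    return PredictionResult(site_prob=site_prob, site_call=bool(call),
                            type_probs=type_probs)


def _score_task(model: TaskModel, inst, protein, sources) -> float:
    assembler = model.assembler
    assembler.proteins.setdefault(protein.id, protein)
    if sources is not None:
        assembler.sources = sources
    X = assembler.transform([inst])
    return float(model.classifier.positive_proba(X)[0])


def predict_proteins(network: TwoLevelNetwork, proteins,
                     sources: FeatureSources | None = None,
                     threshold: float = 0.5):
    """Scan every candidate residue of each protein; yields
    (protein_id, position, PredictionResult)."""
    for p in proteins:
        for i, c in enumerate(p.sequence):
            if c == network.residue:
                yield p.id, i + 1, predict(
                    network, p, i + 1, sources=sources, threshold=threshold
                )


def scan_window_sizes(proteins, residue: str, task: str = "site",
                      sizes=WINDOW_SCAN_SIZES, config: TrainConfig | None = None,
                      seed: int = 0, sources: FeatureSources | None = None):
    """Cross-validated accuracy for each window size; argmax, ties -> smaller w.

    Returns ``(best_w, {w: accuracy})``.
    """
    config = config or TrainConfig()
    sources = sources or FeatureSources()
    prot_map = {p.id: p for p in proteins}
    instances = build_instances(
        proteins, residue, ratio=config.negative_ratio, seed=seed
    )
    if task == "site":
        insts, y = instances, labels_for(instances)
    else:
        insts = [i for i in instances if i.is_positive]
        y = type_labels_for(insts, task)
    if len(insts) == 0 or len(np.unique(y)) < 2:
        raise ValueError(f"no usable instances for task {task!r}")
    acc_by_w = {}
    best_w, best_acc = None, -np.inf
    for w in sizes:
        if w % 2 == 0:
            raise ValueError("window sizes must be odd")
        model = _fit_task(task, insts, y, prot_map, w, config, sources, seed)
        acc = model.classifier.cv_accuracy_
        acc_by_w[w] = acc
        if acc > best_acc:  # strict: first (smallest) w wins ties
            best_w, best_acc = w, acc
    return best_w, acc_by_w


# ---------------------------------------------------------------------------
# Model archive


def save_network(network: TwoLevelNetwork, directory) -> None:
    """Write a model archive: JSON manifest + serialized estimators."""
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "schema_version": ARCHIVE_SCHEMA_VERSION,
        "residue": network.residue,
        "tasks": {},
    }
    for task in network.tasks:
        model = network.site if task == "site" else network.types[task]
        clf = model.classifier
        manifest["tasks"][task] = {
            "window": model.w,
            "subtypes": list(model.assembler.subtypes),
            "n_selected": int(clf.support_.size),
            "selected_columns": clf.support_.tolist(),
            "svm": {
                "C": clf.svm_params_.C,
                "gamma": clf.svm_params_.gamma,
                "cv_accuracy": clf.svm_params_.cv_accuracy,
            },
        }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    joblib.dump(network, os.path.join(directory, "network.joblib"))


def load_network(directory) -> TwoLevelNetwork:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("schema_version") != ARCHIVE_SCHEMA_VERSION:
        raise ValueError("unsupported model archive schema")
    return joblib.load(os.path.join(directory, "network.joblib"))
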