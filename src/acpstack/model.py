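"""Stacked two-layer random forest over n-gram features.

Layer 1 is a probability forest classifying individual 5-mers from binary
occurrences of the selected n-grams. Layer 2 classifies whole peptides from
summary statistics of their mers' class-probability sequences (location,
spread and contiguity of the per-class signal), so that evidence scattered
across a peptide's windows is aggregated into one decision.

Leakage control: the layer-2 training features are built from layer-1
*out-of-bag* probabilities -- each training mer is scored only by the trees
whose bootstrap sample excluded it. In-sample probabilities from a large
forest are near-degenerate (close to one-hot on the training labels) and
would let layer 2 memorise rather than aggregate.

Determinism: one master seed expands into independent per-stage streams
(fold shuffling, each forest), so identical seeds give byte-identical
serialised models.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import pickle
import tarfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier

from .errors import ModelFormatError, TrainingError, ValidationError
from .evalmetrics import multiclass_report
from .ngrams import (
    DEFAULT_K,
    FeatureMatrix,
    Mer,
    NGramDescriptor,
    build_feature_matrix,
    decompose_all,
    decompose_to_mers,
    extract_ngrams,
)
from .quipt import DEFAULT_ALPHA, select_informative
from .seqio import CLASSES, MAX_TRAINED_LENGTH, Peptide

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Argmax ties are broken toward the most conservative call first, so that
#: ambiguous peptides are never promoted to ACP.
TIE_PRIORITY = ("NEG", "AMP", "ACP")

_STATS = ("mean", "median", "min", "max", "var", "frac_gt_half", "longest_run_frac")

#: Names of the 22 peptide-level statistics, in schema order: 7 per class
#: (over the ordered mer-probability sequence) plus the mer count.
STAT_SCHEMA: tuple[str, ...] = tuple(
    f"{cls}_{stat}" for cls in CLASSES for stat in _STATS
) + ("n_mers",)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the stacked model.

    ``mtry=None`` means the classification-forest default, floor(sqrt(p))
    features per split, at each layer.
    """

    trees_layer1: int = 2000
    trees_layer2: int = 500
    mtry: int | None = None
    alpha: float = DEFAULT_ALPHA
    k: int = DEFAULT_K
    seed: int = 0
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        if self.trees_layer1 < 1 or self.trees_layer2 < 1:
            raise ValidationError("tree counts must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValidationError("mtry must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class MerPrediction:
    """Layer-1 class probabilities for a single 5-mer."""

    mer: Mer
    probabilities: np.ndarray  # 3-vector over (ACP, AMP, NEG)


@dataclass(frozen=True)
class PeptidePrediction:
    """Final per-peptide prediction (or a per-record error entry)."""

    id: str
    probabilities: np.ndarray | None
    decision: str | None
    warnings: tuple[str, ...] = ()
    error: str | None = None


@dataclass
class TrainedModel:
    """Everything needed to reproduce predictions: the selected feature
    list, both forests, the statistic schema, and training metadata."""

    config: ModelConfig
    selected: list[NGramDescriptor]
    layer1: RandomForestClassifier
    layer2: RandomForestClassifier
    stat_schema: tuple[str, ...]
    metadata: dict


def _seed_ints(seed: int, n: int) -> list[int]:
    """Expand a master seed into n independent 31-bit stream seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        if cur > best:
            best = cur
    return best


def compute_peptide_statistics(
    mer_probabilities: np.ndarray,
    classes: Sequence[str] = CLASSES,
) -> np.ndarray:
    """The 22 peptide-level statistics over an ordered mer-probability array.

    For each class c: mean, median, min, max, variance (population) of the
    p_c sequence; fraction of mers with p_c > 0.5; longest consecutive run
    with p_c > 0.5 divided by the mer count. The final entry is the mer
    count itself.
    """
    P = np.asarray(mer_probabilities, dtype=float)
    if P.ndim != 2 or P.shape[1] != len(classes):
        raise ValidationError("expected an n_mers x n_classes probability array")
    n = P.shape[0]
    if n < 1:
        raise ValidationError("at least one mer prediction is required")
    out: list[float] = []
    for c in range(len(classes)):
        p = P[:, c]
        above = p > 0.5
        out.extend(
            [
                float(p.mean()),
                float(np.median(p)),
                float(p.min()),
                float(p.max()),
                float(p.var()),
                float(above.mean()),
                _longest_run(above) / n,
            ]
        )
    out.append(float(n))
    return np.array(out)


def _decision(probs: np.ndarray, classes: Sequence[str] = CLASSES) -> str:
    """Argmax with ties broken toward NEG, then AMP, then ACP."""
    maxp = probs.max()
    candidates = {c for c, p in zip(classes, probs) if p == maxp}
    for c in TIE_PRIORITY:
        if c in candidates:
            return c
    raise ValidationError("no decision candidates")  # pragma: no cover


def _featurize_mers(
    mers: Sequence[Mer],
    selected: Sequence[NGramDescriptor],
    k: int,
) -> sp.csr_matrix:
    """Binary occurrence matrix restricted to the selected descriptors."""
    col = {d: j for j, d in enumerate(selected)}
    indptr = [0]
    indices: list[int] = []
    for mer in mers:
        js = sorted(col[d] for d in extract_ngrams(mer, k=k) if d in col)
        indices.extend(js)
        indptr.append(len(indices))
    return sp.csr_matrix(
        (np.ones(len(indices), dtype=np.uint8), indices, indptr),
        shape=(len(mers), len(selected)),
    )


def _group_offsets(mers: Sequence[Mer]) -> list[tuple[str, slice]]:
    """Contiguous (peptide id, row slice) groups of an ordered mer list."""
    groups: list[tuple[str, slice]] = []
    start = 0
    for i in range(1, len(mers) + 1):
        if i == len(mers) or mers[i].parent_id != mers[start].parent_id:
            groups.append((mers[start].parent_id, slice(start, i)))
            start = i
    return groups


def train(peptides: Sequence[Peptide], config: ModelConfig | None = None) -> TrainedModel:
    """Fit the full pipeline: decompose, featurise, select, stack.

    Requires all three classes present and every peptide of length >= k.
    Raises :class:`TrainingError` when the permutation test selects zero
    features (too little data for the configured alpha).
    """
    if config is None:
        config = ModelConfig()
    labels = [p.label for p in peptides]
    counts = {c: labels.count(c) for c in config.classes}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise TrainingError(f"training set lacks class(es): {missing}")
    for p in peptides:
        if len(p) < config.k:
            raise ValidationError(
                f"training peptide {p.id!r} shorter than k={config.k}"
            )

    seed_l1, seed_l2 = _seed_ints(config.seed, 2)
    logger.info("decomposing %d peptides into %d-mers", len(peptides), config.k)
    mers = decompose_all(peptides, k=config.k)
    fm = build_feature_matrix(mers, k=config.k)
    logger.info("feature matrix: %d mers x %d observed n-grams", *fm.shape)

    selected, report = select_informative(fm, alpha=config.alpha)
    if not selected:
        raise TrainingError(
            "the permutation test selected zero informative n-grams at "
            f"alpha={config.alpha}; provide more training data or raise alpha"
        )
    logger.info("selected %d informative n-grams (alpha=%g)", len(selected), config.alpha)

    X1 = fm.subset_columns(selected).values
    y1 = np.array([m.label for m in mers], dtype=object)
    mtry = config.mtry if config.mtry is not None else "sqrt"
    layer1 = RandomForestClassifier(
        n_estimators=config.trees_layer1,
        max_features=mtry,
        oob_score=True,
        random_state=seed_l1,
        n_jobs=1,
    )
    layer1.fit(X1, y1)
    if tuple(layer1.classes_) != tuple(config.classes):
        raise TrainingError("unexpected layer-1 class order")  # pragma: no cover

    oob = np.array(layer1.oob_decision_function_, dtype=float)
    nan_rows = np.isnan(oob).any(axis=1)
    if nan_rows.any():
        # a mer in every bootstrap of every tree has no OOB vote; fall back
        # to an uninformative uniform row rather than leaking in-bag scores
        oob[nan_rows] = 1.0 / len(config.classes)
    logger.info("layer-1 OOB accuracy: %.3f", layer1.oob_score_)

    groups = _group_offsets(mers)
    X2 = np.vstack([compute_peptide_statistics(oob[sl], config.classes) for _, sl in groups])
    pid_to_label = {p.id: p.label for p in peptides}
    y2 = np.array([pid_to_label[pid] for pid, _ in groups], dtype=object)
    layer2 = RandomForestClassifier(
        n_estimators=config.trees_layer2,
        max_features=mtry,
        random_state=seed_l2,
        n_jobs=1,
    )
    layer2.fit(X2, y2)

    metadata = {
        "schema_version": SCHEMA_VERSION,
        "class_counts": counts,
        "n_mers": len(mers),
        "n_observed_ngrams": fm.shape[1],
        "n_selected": len(selected),
        "seed": config.seed,
        "oob_unvoted_mers": int(nan_rows.sum()),
        "layer1_oob_accuracy": float(layer1.oob_score_),
    }
    model = TrainedModel(config, list(selected), layer1, layer2, STAT_SCHEMA, metadata)
    model.selection_report = report  # audit trail; not serialised
    return model


def predict_mers(model: TrainedModel, mers: Sequence[Mer]) -> np.ndarray:
    """Layer-1 class probabilities for a list of mers (rows sum to 1)."""
    X = _featurize_mers(mers, model.selected, model.config.k)
    return model.layer1.predict_proba(X)


def predict(
    model: TrainedModel,
    peptides: Sequence[Peptide],
    per_mer: bool = False,
) -> list[PeptidePrediction] | tuple[list[PeptidePrediction], list[MerPrediction]]:
    """Predict class probabilities and decisions for peptides.

    Records shorter than k residues (or otherwise invalid) yield per-record
    error entries instead of raising; peptides longer than the trained range
    are predicted with a warning attached.
    """
    valid: list[tuple[int, Peptide, list[Mer]]] = []
    results: list[PeptidePrediction | None] = [None] * len(peptides)
    for i, pep in enumerate(peptides):
        try:
            mers = decompose_to_mers(pep, k=model.config.k)
        except ValidationError as exc:
            results[i] = PeptidePrediction(pep.id, None, None, (), str(exc))
            continue
        valid.append((i, pep, mers))

    mer_reports: list[MerPrediction] = []
    if valid:
        all_mers = [m for _, _, mers in valid for m in mers]
        probs = predict_mers(model, all_mers)
        cursor = 0
        for i, pep, mers in valid:
            block = probs[cursor : cursor + len(mers)]
            cursor += len(mers)
            stats = compute_peptide_statistics(block, model.config.classes)
            pep_probs = model.layer2.predict_proba(stats.reshape(1, -1))[0]
            warn: tuple[str, ...] = ()
            if len(pep) > MAX_TRAINED_LENGTH:
                warn = (
                    f"length {len(pep)} exceeds the trained range "
                    f"(<= {MAX_TRAINED_LENGTH} residues)",
                )
            results[i] = PeptidePrediction(
                pep.id, pep_probs, _decision(pep_probs, model.config.classes), warn
            )
            if per_mer:
                mer_reports.extend(
                    MerPrediction(m, p) for m, p in zip(mers, block)
                )
    out = [r for r in results if r is not None]
    return (out, mer_reports) if per_mer else out


def predictions_to_frame(predictions: Sequence[PeptidePrediction]) -> pd.DataFrame:
    """Tabulate predictions: id, prob_ACP, prob_AMP, prob_NEG, decision, warnings."""
    rows = []
    for pred in predictions:
        row = {"id": pred.id}
        if pred.probabilities is None:
            row.update(prob_ACP=np.nan, prob_AMP=np.nan, prob_NEG=np.nan,
                       decision="", warnings="", error=pred.error or "")
        else:
            row.update(
                prob_ACP=pred.probabilities[0],
                prob_AMP=pred.probabilities[1],
                prob_NEG=pred.probabilities[2],
                decision=pred.decision,
                warnings="; ".join(pred.warnings),
                error="",
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assign_cv_folds(
    peptides: Sequence[Peptide],
    folds: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Length-stratified fold assignment.

    Within each class, peptides are sorted by length (ties shuffled by the
    seed) and dealt round-robin to folds, so every fold sees approximately
    the same length distribution and per-class fold sizes differ by at most
    one.
    """
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    labels = np.array([p.label for p in peptides], dtype=object)
    lengths = np.array([len(p) for p in peptides])
    rng = np.random.default_rng(seed)
    assignment = np.full(len(peptides), -1, dtype=int)
    for cls in sorted(set(labels.tolist()), key=str):
        idx = np.flatnonzero(labels == cls)
        if idx.size < folds:
            raise ValidationError(
                f"class {cls!r} has {idx.size} peptides, fewer than {folds} folds"
            )
        perm = rng.permutation(idx)  # randomises length ties
        order = perm[np.argsort(lengths[perm], kind="stable")]
        for rank, i in enumerate(order):
            assignment[i] = rank % folds
    return assignment


def cross_validate(
    peptides: Sequence[Peptide],
    config: ModelConfig | None = None,
    folds: int = 5,
) -> pd.DataFrame:
    """K-fold cross-validation reporting both model layers.

    For each fold the model is retrained on the remaining folds; held-out
    mers are scored by layer 1 and held-out peptides by the full stack.
    Returns one row per fold x layer with accuracy, AU1U and KapS.
    """
    if config is None:
        config = ModelConfig()
    fold_seed, *train_seeds = _seed_ints(config.seed, folds + 1)
    assignment = assign_cv_folds(peptides, folds=folds, seed=fold_seed)
    rows = []
    for f in range(folds):
        train_peps = [p for p, a in zip(peptides, assignment) if a != f]
        test_peps = [p for p, a in zip(peptides, assignment) if a == f]
        model = train(train_peps, replace(config, seed=train_seeds[f]))

        test_mers = decompose_all(test_peps, k=config.k)
        mer_probs = predict_mers(model, test_mers)
        mer_true = [m.label for m in test_mers]
        mer_dec = [_decision(p, config.classes) for p in mer_probs]
        rows.append({"fold": f, "layer": "mer",
                     **multiclass_report(mer_true, mer_probs, mer_dec, config.classes)})

        preds = predict(model, test_peps)
        pep_probs = np.vstack([p.probabilities for p in preds])
        pep_true = [p.label for p in test_peps]
        pep_dec = [p.decision for p in preds]
        rows.append({"fold": f, "layer": "peptide",
                     **multiclass_report(pep_true, pep_probs, pep_dec, config.classes)})
    return pd.DataFrame(rows)


def cv_summary(cv_table: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and se per layer and measure (sd across folds; se = sd/sqrt(k))."""
    long = cv_table.melt(id_vars=["fold", "layer"], var_name="measure")
    g = long.groupby(["layer", "measure"])["value"]
    out = g.agg(mean="mean", sd="std").reset_index()
    k = cv_table["fold"].nunique()
    out["se"] = out["sd"] / np.sqrt(k)
    return out


# ---------------------------------------------------------------------------
# Serialisation: a gzip-compressed tar archive with a text manifest and
# pickled forests. All archive metadata is fixed so identical models give
# byte-identical files.
# ---------------------------------------------------------------------------


def _tar_add(tar: tarfile.TarFile, name: str, data: bytes) -> None:
    info = tarfile.TarInfo(name=name)
    info.size = len(data)
    info.mtime = 0
    info.uid = info.gid = 0
    info.uname = info.gname = ""
    tar.addfile(info, io.BytesIO(data))


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialise a trained model to a schema-versioned archive."""
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "config": {
            "trees_layer1": model.config.trees_layer1,
            "trees_layer2": model.config.trees_layer2,
            "mtry": model.config.mtry,
            "alpha": model.config.alpha,
            "k": model.config.k,
            "seed": model.config.seed,
            "classes": list(model.config.classes),
        },
        "stat_schema": list(model.stat_schema),
        "selected_descriptors": [d.text for d in model.selected],
        "metadata": model.metadata,
    }
    manifest_bytes = json.dumps(manifest, indent=2, sort_keys=True).encode()
    with open(path, "wb") as fh:
        with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
            with tarfile.open(fileobj=gz, mode="w") as tar:
                _tar_add(tar, "manifest.json", manifest_bytes)
                _tar_add(tar, "layer1.pkl", pickle.dumps(model.layer1, protocol=5))
                _tar_add(tar, "layer2.pkl", pickle.dumps(model.layer2, protocol=5))


def load_model(path: str | Path) -> TrainedModel:
    """Load a model archive; incompatible or truncated archives raise
    :class:`ModelFormatError`, never crash."""
    try:
        with tarfile.open(path, mode="r:gz") as tar:
            members = {m.name: tar.extractfile(m).read() for m in tar.getmembers()}
    except (tarfile.TarError, EOFError, OSError, gzip.BadGzipFile) as exc:
        raise ModelFormatError(f"cannot read model archive {path}: {exc}") from exc
    for required in ("manifest.json", "layer1.pkl", "layer2.pkl"):
        if required not in members:
            raise ModelFormatError(f"model archive {path} lacks {required}")
    try:
        manifest = json.loads(members["manifest.json"])
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"corrupt manifest in {path}: {exc}") from exc
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ModelFormatError(
            f"model archive {path} has schema version {version}, "
            f"this build reads version {SCHEMA_VERSION}"
        )
    cfg = manifest["config"]
    config = ModelConfig(
        trees_layer1=cfg["trees_layer1"],
        trees_layer2=cfg["trees_layer2"],
        mtry=cfg["mtry"],
        alpha=cfg["alpha"],
        k=cfg["k"],
        seed=cfg["seed"],
        classes=tuple(cfg["classes"]),
    )
    selected = [NGramDescriptor.from_text(t) for t in manifest["selected_descriptors"]]
    layer1 = pickle.loads(members["layer1.pkl"])
    layer2 = pickle.loads(members["layer2.pkl"])
    return TrainedModel(
        config, selected, layer1, layer2,
        tuple(manifest["stat_schema"]), manifest["metadata"],
    )
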