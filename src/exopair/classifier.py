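"""Two-pair ΔCT diagnostic classification.

The validated biomarker panel consists of two ΔCT features per sample,

    f1 = CT(miR-1246)  − CT(miR-4436b-5p)
    f2 = CT(miR-197-3p) − CT(miR-671-5p)

each invariant to per-sample global CT shifts.  Neither feature alone
separates the disease class from both control classes; jointly they
resolve three clusters — healthy (Normal), Kawasaki disease (KD) and
non-KD febrile controls (ADV/EBV/JIA/SF pooled).  Classification is
nearest-centroid in feature space, the simplest decision rule consistent
with that cluster geometry, behind a pluggable interface.  Because
different sites use different instruments and reagents, per-centre
additive feature offsets can be estimated from designated standard
samples and removed before classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairwise import CtDataset

logger = logging.getLogger(__name__)

DEFAULT_PAIR_1 = ("miR-1246", "miR-4436b-5p")
DEFAULT_PAIR_2 = ("miR-197-3p", "miR-671-5p")

FEBRILE_GROUPS = ("ADV", "EBV", "JIA", "SF")
FEBRILE_CLASS = "nonKD-febrile"
DEFAULT_CLASS_ORDER = ("Normal", "KD", FEBRILE_CLASS)

UNCLASSIFIABLE = "unclassifiable"


def pool_febrile(groups: pd.Series,
                 febrile: Sequence[str] = FEBRILE_GROUPS) -> pd.Series:
    """Map cohort group labels to the three diagnostic classes."""
    return groups.where(~groups.isin(list(febrile)), FEBRILE_CLASS)


@dataclass
class DiagnosticFeatureSet:
    """Per-sample ΔCT features with centre labels and (optionally) truth."""

    table: pd.DataFrame          # columns = feature names, index = sample ids
    centres: pd.Series
    labels: pd.Series | None = None
    pairs: Sequence[tuple[str, str]] = (DEFAULT_PAIR_1, DEFAULT_PAIR_2)

    def __post_init__(self) -> None:
        if not self.table.index.equals(self.centres.index):
            raise ValueError("centres index does not match feature index")
        if self.labels is not None and not self.table.index.equals(
                self.labels.index):
            raise ValueError("labels index does not match feature index")

    @property
    def feature_names(self) -> list[str]:
        return list(self.table.columns)

    def subset_features(self, names: Sequence[str]) -> "DiagnosticFeatureSet":
        return DiagnosticFeatureSet(self.table[list(names)], self.centres,
                                    self.labels, self.pairs)

    def subset_samples(self, ids: Sequence[str]) -> "DiagnosticFeatureSet":
        ids = list(ids)
        lab = self.labels.loc[ids] if self.labels is not None else None
        return DiagnosticFeatureSet(self.table.loc[ids], self.centres.loc[ids],
                                    lab, self.pairs)


@dataclass
class CentroidModel:
    """Per-class feature centroids plus per-centre additive offsets."""

    centroids: Mapping[str, np.ndarray]
    feature_names: list[str]
    class_order: Sequence[str]
    centre_offsets: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.centroids) < 2:
            raise ValueError("need at least 2 classes")
        for cls, c in self.centroids.items():
            if not np.all(np.isfinite(c)):
                raise ValueError(f"non-finite centroid for class {cls!r}")


def compute_features(ds: CtDataset,
                     pair1: tuple[str, str] = DEFAULT_PAIR_1,
                     pair2: tuple[str, str] | None = DEFAULT_PAIR_2,
                     label_map: bool = True) -> DiagnosticFeatureSet:
    """ΔCT features per sample from the configured miRNA pairs.

    Samples with any missing member CT are dropped (and logged).  With
    ``label_map`` the dataset's group labels are pooled into the three
    diagnostic classes and attached as truth.
    """
    pairs = [pair1] + ([pair2] if pair2 is not None else [])
    for t, r in pairs:
        for m in (t, r):
            if m not in ds.values.columns:
                raise ValueError(f"pair member {m!r} absent from dataset")
    cols = {}
    for k, (t, r) in enumerate(pairs, start=1):
        cols[f"f{k}"] = ds.values[t] - ds.values[r]
    table = pd.DataFrame(cols)
    keep = table.notna().all(axis=1)
    if not keep.all():
        dropped = list(table.index[~keep])
        logger.info("dropped %d sample(s) with missing pair-member CT: %s",
                    len(dropped), dropped)
    table = table.loc[keep]
    labels = pool_febrile(ds.groups.loc[keep]) if label_map else None
    return DiagnosticFeatureSet(table=table, centres=ds.centres.loc[keep],
                                labels=labels, pairs=pairs)


def fit_centroids(features: DiagnosticFeatureSet,
                  calibration: "DiagnosticFeatureSet | Sequence[str] | None" = None,
                  class_order: Sequence[str] = DEFAULT_CLASS_ORDER,
                  min_calibration: int = 3) -> CentroidModel:
    """Fit class centroids and (optionally) per-centre calibration offsets.

    Class centroids are per-class feature means over the labelled training
    samples.  ``calibration`` designates labelled standard samples — either
    a separate feature set (e.g. standards run at each deployment centre)
    or sample ids within ``features`` (those are then excluded from the
    centroid means so a shifted centre cannot drag them).  Each centre with
    at least ``min_calibration`` standards gets an additive offset equal to
    the component-wise median residual of its standards from their
    true-class centroid; other centres get zero offset.
    """
    if features.labels is None:
        raise ValueError("fitting requires labelled samples")
    cal: DiagnosticFeatureSet | None = None
    if calibration is not None:
        if isinstance(calibration, DiagnosticFeatureSet):
            cal = calibration
        else:
            ids = list(calibration)
            cal = features.subset_samples(ids)
            rest = [s for s in features.table.index if s not in set(ids)]
            features = features.subset_samples(rest)
        if cal.labels is None:
            raise ValueError("calibration standards must be labelled")
    fit_classes = [c for c in class_order if (features.labels == c).any()]
    if len(fit_classes) < 2:
        raise ValueError("need labelled samples from at least 2 classes")
    centroids: dict[str, np.ndarray] = {}
    for cls in fit_classes:
        sel = features.labels == cls
        if int(sel.sum()) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        centroids[cls] = features.table.loc[sel].mean(axis=0).to_numpy()

    offsets: dict[str, np.ndarray] = {}
    if cal is not None:
        missing = [c for c in cal.labels.unique() if c not in centroids]
        if missing:
            raise ValueError(f"calibration standards from unfitted class(es) "
                             f"{missing}")
        resid = cal.table.to_numpy() - np.stack(
            [centroids[c] for c in cal.labels])
        resid = pd.DataFrame(resid, index=cal.table.index,
                             columns=features.feature_names)
        for centre in cal.centres.unique():
            sel = cal.centres == centre
            if int(sel.sum()) >= min_calibration:
                offsets[centre] = resid.loc[sel].median(axis=0).to_numpy()
            else:
                logger.warning(
                    "centre %s has %d < %d calibration standards; no offset",
                    centre, int(sel.sum()), min_calibration)
    return CentroidModel(centroids=centroids,
                         feature_names=features.feature_names,
                         class_order=list(class_order),
                         centre_offsets=offsets)


def classify(features: DiagnosticFeatureSet,
             model: CentroidModel) -> pd.DataFrame:
    """Nearest-centroid class assignment after centre-offset correction.

    Returns a DataFrame with the predicted class and the Euclidean
    distance to each class centroid.  Ties go to the first class in the
    model's declared class order; samples with non-finite features are
    flagged ``unclassifiable``.
    """
    if features.feature_names != model.feature_names:
        raise ValueError(
            f"feature mismatch: data has {features.feature_names}, model "
            f"expects {model.feature_names}")
    X = features.table.to_numpy(dtype=float).copy()
    for centre, off in model.centre_offsets.items():
        X[(features.centres == centre).to_numpy()] -= off

    classes = [c for c in model.class_order if c in model.centroids]
    cents = np.stack([model.centroids[c] for c in classes])
    dists = np.sqrt(((X[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2))
    best = np.argmin(dists, axis=1)  # argmin takes the first minimum: tie rule
    pred = np.array(classes, dtype=object)[best]
    bad = ~np.isfinite(X).all(axis=1)
    pred[bad] = UNCLASSIFIABLE
    out = pd.DataFrame({"predicted": pred}, index=features.table.index)
    for k, cls in enumerate(classes):
        out[f"dist_{cls}"] = dists[:, k]
    return out


@dataclass
class EvaluationResult:
    """Confusion table plus KD-centric error rates."""

    confusion: pd.DataFrame
    kd_sensitivity: float
    kd_specificity: float
    false_positives: int   # non-KD samples called KD
    false_negatives: int   # KD samples called something else
    accuracy: float


def evaluate(predicted: pd.Series, truth: pd.Series,
             positive_class: str = "KD") -> EvaluationResult:
    """Score predictions against true classes.

    Sensitivity and specificity are computed for the positive class
    (KD by default): a false positive is a non-KD sample called KD, a
    false negative a KD sample called anything else.
    """
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs "
                         f"{len(truth)} truth labels")
    predicted, truth = predicted.align(truth, join="inner")[0], \
        truth.align(predicted, join="inner")[0]
    confusion = pd.crosstab(truth.rename("true"),
                            predicted.rename("predicted"), dropna=False)
    is_pos = truth == positive_class
    called_pos = predicted == positive_class
    tp = int((is_pos & called_pos).sum())
    fn = int((is_pos & ~called_pos).sum())
    fp = int((~is_pos & called_pos).sum())
    tn = int((~is_pos & ~called_pos).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    acc = float((predicted == truth).mean())
    return EvaluationResult(confusion=confusion, kd_sensitivity=sens,
                            kd_specificity=spec, false_positives=fp,
                            false_negatives=fn, accuracy=acc)
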