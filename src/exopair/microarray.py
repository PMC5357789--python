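"""Stage-1 candidate screening on pooled two-condition microarray profiles.

The pooled arrays compare normalized log2 signal intensities of ~1900
human miRNA probes between two conditions (healthy vs disease, and
disease before vs after treatment).  Candidates are probes showing an
"on/off switch": strong signal (log2 > 3.5) in one condition while below
the array's detection floor (log2 < −3) in the other, with a >200-fold
change, in *both* comparisons.  A second selection direction keeps probes
abundant only in the disease condition (log2 > 4.5 in KD, undetected in
both healthy and treated samples).  Vendor normalization is taken as
given; this module consumes normalized log2 intensities and performs no
background correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass
class MicroarrayComparison:
    """Paired log2 intensities of two pooled conditions over one probe set."""

    mirna_ids: Sequence[str]
    intensity_a: np.ndarray
    intensity_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"

    def __post_init__(self) -> None:
        self.intensity_a = np.asarray(self.intensity_a, dtype=float)
        self.intensity_b = np.asarray(self.intensity_b, dtype=float)
        n = len(self.mirna_ids)
        if len(self.intensity_a) != n or len(self.intensity_b) != n:
            raise ValueError("intensity arrays do not match miRNA id list")
        if len(set(self.mirna_ids)) != n:
            raise ValueError("duplicate miRNA ids in comparison")
        if not (np.isfinite(self.intensity_a).all()
                and np.isfinite(self.intensity_b).all()):
            raise ValueError("non-finite intensity values")

    @property
    def conditions(self) -> tuple[str, str]:
        return (self.label_a, self.label_b)

    def intensity(self, condition: str) -> np.ndarray:
        if condition == self.label_a:
            return self.intensity_a
        if condition == self.label_b:
            return self.intensity_b
        raise ValueError(f"condition {condition!r} not in comparison "
                         f"{self.conditions}")


@dataclass
class ArrayScreenCriteria:
    """Thresholds of the array screen (all on the log2-intensity scale,
    except ``fold_threshold`` which is a linear fold change)."""

    expressed_threshold: float = 1.0
    fold_threshold: float = 200.0
    on_threshold: float = 3.5
    off_threshold: float = -3.0
    high_threshold: float = 4.5
    #: floor sub-detection-limit intensities at ``off_threshold`` before
    #: computing the fold change (signals below the floor are noise)
    floor_fold_at_off: bool = True

    def __post_init__(self) -> None:
        if not self.on_threshold > self.off_threshold:
            raise ValueError("on_threshold must exceed off_threshold")
        if not self.fold_threshold > 1.0:
            raise ValueError(f"fold_threshold must be > 1, got "
                             f"{self.fold_threshold}")


def _check_same_ids(cmp_a: MicroarrayComparison,
                    cmp_b: MicroarrayComparison) -> None:
    if list(cmp_a.mirna_ids) != list(cmp_b.mirna_ids):
        only_a = set(cmp_a.mirna_ids) - set(cmp_b.mirna_ids)
        only_b = set(cmp_b.mirna_ids) - set(cmp_a.mirna_ids)
        raise ValueError(
            "comparisons cover different miRNA sets "
            f"(only in first: {sorted(only_a)[:5]}, "
            f"only in second: {sorted(only_b)[:5]}) or differ in order")


def count_expressed_both(cmp: MicroarrayComparison,
                         criteria: ArrayScreenCriteria | None = None) -> int:
    """Number of probes detected above ``expressed_threshold`` in *both*
    conditions (strict inequality)."""
    criteria = criteria or ArrayScreenCriteria()
    if len(cmp.mirna_ids) == 0:
        raise ValueError("empty comparison")
    t = criteria.expressed_threshold
    return int(np.sum((cmp.intensity_a > t) & (cmp.intensity_b > t)))


def _onoff_mask(cmp: MicroarrayComparison,
                criteria: ArrayScreenCriteria) -> np.ndarray:
    a, b = cmp.intensity_a, cmp.intensity_b
    on_off = ((a > criteria.on_threshold) & (b < criteria.off_threshold)) | \
             ((b > criteria.on_threshold) & (a < criteria.off_threshold))
    if criteria.floor_fold_at_off:
        fa = np.maximum(a, criteria.off_threshold)
        fb = np.maximum(b, criteria.off_threshold)
    else:
        fa, fb = a, b
    fold = 2.0 ** np.abs(fa - fb)
    return on_off & (fold > criteria.fold_threshold)


def select_onoff_candidates(cmp_a: MicroarrayComparison,
                            cmp_b: MicroarrayComparison,
                            criteria: ArrayScreenCriteria | None = None
                            ) -> list[str]:
    """Probes with a strict on/off switch and >fold_threshold change in
    BOTH comparisons.

    "On" means log2 intensity above ``on_threshold`` in one condition;
    "off" means below ``off_threshold`` (the detection floor) in the
    other.  By default the fold change is computed on floored
    intensities (values below the floor are set to the floor first), so
    near the floor the on/off predicate, not the fold rule, binds.
    """
    criteria = criteria or ArrayScreenCriteria()
    _check_same_ids(cmp_a, cmp_b)
    mask = _onoff_mask(cmp_a, criteria) & _onoff_mask(cmp_b, criteria)
    return [m for m, keep in zip(cmp_a.mirna_ids, mask) if keep]


def select_opposite_tendency(cmp_a: MicroarrayComparison,
                             cmp_b: MicroarrayComparison,
                             criteria: ArrayScreenCriteria | None = None,
                             kd_label: str = "KD") -> list[str]:
    """Probes abundant only in the disease condition.

    Selected probes have log2 intensity above ``high_threshold`` in the
    condition named ``kd_label`` in both comparisons, and below the
    detection floor in the non-KD condition of both.  The KD condition is
    located by label, not by column position.
    """
    criteria = criteria or ArrayScreenCriteria()
    _check_same_ids(cmp_a, cmp_b)
    for cmp in (cmp_a, cmp_b):
        if kd_label not in cmp.conditions:
            raise ValueError(f"condition {kd_label!r} absent from comparison "
                             f"{cmp.conditions}")
    mask = np.ones(len(cmp_a.mirna_ids), dtype=bool)
    for cmp in (cmp_a, cmp_b):
        kd = cmp.intensity(kd_label)
        other_label = cmp.label_b if cmp.label_a == kd_label else cmp.label_a
        other = cmp.intensity(other_label)
        mask &= (kd > criteria.high_threshold) & (other < criteria.off_threshold)
    return [m for m, keep in zip(cmp_a.mirna_ids, mask) if keep]


def cluster_profiles(cmp: MicroarrayComparison
                     ) -> tuple[np.ndarray, list[int]]:
    """Ward-linkage hierarchical clustering of probes on their two
    intensities.

    Probes are clustered as points in the (intensity_a, intensity_b)
    plane with the Euclidean metric and Ward's minimum-variance linkage —
    the clustergram construction.  Returns the scipy linkage matrix and
    the sizes of the top three dendrogram branches (descending; fewer
    entries if the tree has fewer leaves than branches requested).
    """
    n = len(cmp.mirna_ids)
    if n < 3:
        raise ValueError(f"clustering needs >= 3 miRNAs, got {n}")
    pts = np.column_stack([cmp.intensity_a, cmp.intensity_b])
    link = hierarchy.linkage(pdist(pts), method="ward")
    labels = hierarchy.fcluster(link, t=3, criterion="maxclust")
    sizes = sorted(np.bincount(labels)[1:].tolist(), reverse=True)
    return link, [s for s in sizes if s > 0]
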