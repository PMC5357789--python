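"""Reference-free pairwise ΔCT screening.

qPCR quantification of exosomal miRNA has no credible housekeeping
reference: exosome preparations lack a background transcriptome, and the
RNA-extraction yield varies strongly from sample to sample.  The screen
implemented here sidesteps the problem by trying *every* candidate miRNA
as the internal reference for every other one.  For a sample ``s`` and an
ordered pair ``(i, j)``,

    ΔCT_ij(s) = CT_s(i) - CT_s(j)

so any per-sample global CT shift (extraction efficiency, input volume,
storage) cancels exactly.  Each ΔCT feature is then compared between
clinical groups with a two-sided pooled-variance Student t-test, giving
one p-value matrix per group comparison; a biomarker pair is one that is
significant where the disease signal should be and non-significant where
it should not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Group labels used by the study design.  The vocabulary is open — any
#: label carried by a dataset is accepted — but these are the canonical ones.
KNOWN_GROUPS = ("Normal", "KD", "+IVIG", "ADV", "EBV", "JIA", "SF")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CtDataset:
    """Per-sample CT matrix (replicate-averaged) with group/centre labels.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per miRNA, entries in
        cycles.  ``NaN`` marks a masked (missing) measurement.
    groups, centres
        Per-sample labels, aligned with ``values.index``.
    replicate_counts
        Optional DataFrame of the number of replicates averaged per cell.
    """

    values: pd.DataFrame
    groups: pd.Series
    centres: pd.Series
    replicate_counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.groups.index):
            raise ValueError("groups index does not match sample index")
        if not self.values.index.equals(self.centres.index):
            raise ValueError("centres index does not match sample index")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate miRNA ids: {sorted(set(dup))}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        sel = self.groups == group
        if not sel.any():
            raise ValueError(f"no samples with group label {group!r}")
        return self.values.loc[sel]

    def subset_mirnas(self, mirnas: Sequence[str]) -> "CtDataset":
        rc = None
        if self.replicate_counts is not None:
            rc = self.replicate_counts[list(mirnas)]
        return CtDataset(self.values[list(mirnas)].copy(), self.groups,
                         self.centres, rc)


@dataclass
class PairPvalueMatrix:
    """Two-sided t-test p-values over all ordered miRNA pairs for one comparison.

    ``pvalues[i, j]`` tests ΔCT(target=i, reference=j) between the two
    groups; the matrix is symmetric (a two-sided test on negated values)
    and the diagonal is undefined (NaN).  ``degenerate[i, j]`` flags cells
    where both groups had zero within-group variance, for which the
    p-value is set to 1 (equal means) or 0 (unequal means) by convention.
    """

    comparison: tuple[str, str]
    mirna_ids: list[str]
    pvalues: np.ndarray
    tstats: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        m = len(self.mirna_ids)
        if self.pvalues.shape != (m, m):
            raise ValueError("p-value matrix shape does not match miRNA ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvalues, index=self.mirna_ids,
                            columns=self.mirna_ids)

    def pvalue(self, target: str, reference: str) -> float:
        i = self.mirna_ids.index(target)
        j = self.mirna_ids.index(reference)
        return float(self.pvalues[i, j])


@dataclass
class SelectionCriteria:
    """Multi-criteria significance pattern defining a biomarker pair.

    A *forward* pair is significant (p < alpha, strict) in every comparison
    of ``require_significant`` and non-significant (p > alpha, strict) in
    every comparison of ``require_nonsignificant``.  An *opposite* pair
    satisfies the exact inversion.
    """

    alpha: float = 0.01
    require_significant: Sequence[tuple[str, str]] = (
        ("KD", "Normal"), ("KD", "+IVIG"))
    require_nonsignificant: Sequence[tuple[str, str]] = (("Normal", "ADV"),)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        overlap = set(self.require_significant) & set(self.require_nonsignificant)
        if overlap:
            raise ValueError(f"comparison lists overlap: {sorted(overlap)}")

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        return list(self.require_significant) + list(self.require_nonsignificant)


@dataclass
class BiomarkerPair:
    """A selected (target, reference) miRNA pair with its evidence."""

    target: str
    reference: str
    trend: str  # "forward" | "opposite"
    pvalues: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target == self.reference:
            raise ValueError("self-reference: target equals reference")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.target, self.reference))


# ---------------------------------------------------------------------------
# replicate averaging & filtering
# ---------------------------------------------------------------------------

REQUIRED_CT_COLUMNS = ("sample_id", "group", "centre", "mirna_id",
                       "replicate", "ct")


def average_replicates(raw: pd.DataFrame,
                       n_replicates: int | None = None) -> CtDataset:
    """Collapse replicate-level CT records to one arithmetic mean per cell.

    ``raw`` is a long-format table with columns ``sample_id, group, centre,
    mirna_id, replicate, ct``.  Cells whose replicates are all missing are
    masked with a warning.  If ``n_replicates`` is given, cells with a
    different replicate count are reported (but kept).
    """
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    if raw.empty:
        raise ValueError("empty CT record table")

    meta = raw.groupby("sample_id", sort=False).agg(
        group=("group", "first"), centre=("centre", "first"))
    inconsistent = raw.groupby("sample_id")["group"].nunique()
    if (inconsistent > 1).any():
        bad = list(inconsistent.index[inconsistent > 1])
        raise ValueError(f"inconsistent group labels for sample(s): {bad}")

    grouped = raw.groupby(["sample_id", "mirna_id"], sort=False)["ct"]
    means = grouped.mean().unstack("mirna_id")
    counts = grouped.count().unstack("mirna_id").fillna(0).astype(int)
    # keep input sample order
    means = means.loc[meta.index]
    counts = counts.loc[meta.index]

    n_masked = int(means.isna().to_numpy().sum())
    if n_masked:
        logger.warning("%d (sample, miRNA) cells have no usable replicate "
                       "and were masked", n_masked)
    if n_replicates is not None:
        off = (counts != n_replicates) & (counts > 0)
        if off.to_numpy().any():
            logger.warning("%d cells deviate from the expected %d replicates",
                           int(off.to_numpy().sum()), n_replicates)

    return CtDataset(values=means,
                     groups=meta["group"].rename("group"),
                     centres=meta["centre"].rename("centre"),
                     replicate_counts=counts)


def filter_ct_ceiling(ds: CtDataset, ceiling: float = 35.0
                      ) -> tuple[CtDataset, list[str]]:
    """Drop every miRNA whose CT exceeds ``ceiling`` in *any* sample.

    CT values near the end of the amplification programme are dominated by
    stochastic amplification noise, so a miRNA that is unquantifiable in
    even one cohort sample is excluded from the screen entirely (the whole
    column is removed).  The rule is strict: CT exactly equal to the
    ceiling is retained.  Masked cells do not trigger removal.

    Returns the reduced dataset and the list of removed miRNA ids.
    """
    over = (ds.values > ceiling).any(axis=0)
    removed = list(ds.values.columns[over])
    kept = [m for m in ds.mirna_ids if m not in removed]
    if not kept:
        raise ValueError("no quantifiable miRNAs: every miRNA exceeds the "
                         f"CT ceiling of {ceiling}")
    if removed:
        logger.info("CT ceiling %.3g removed %d miRNA(s): %s",
                    ceiling, len(removed), removed)
    return ds.subset_mirnas(kept), removed


# ---------------------------------------------------------------------------
# ΔCT and the p-value matrix
# ---------------------------------------------------------------------------

def delta_ct(ds: CtDataset, target: str, reference: str) -> pd.Series:
    """Per-sample ΔCT = CT(target) − CT(reference).

    Samples masked for either miRNA are dropped (and logged).  Antisymmetric
    in its arguments; invariant to any per-sample global CT shift.
    """
    if target == reference:
        raise ValueError(f"self-reference: {target!r} used as its own reference")
    for m in (target, reference):
        if m not in ds.values.columns:
            raise ValueError(f"miRNA {m!r} not in dataset")
    d = ds.values[target] - ds.values[reference]
    dropped = list(d.index[d.isna()])
    if dropped:
        logger.info("ΔCT(%s, %s): dropped %d sample(s) with missing CT: %s",
                    target, reference, len(dropped), dropped)
    return d.dropna().rename(f"dCT({target}-{reference})")


def _pooled_t_matrix(dx: np.ndarray, dy: np.ndarray, equal_var: bool = True
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-sided t-test between two stacks of ΔCT matrices.

    ``dx``/``dy`` have shape (n_samples, m, m) and may contain NaN; each
    (i, j) cell is tested on its complete cases (per-pair complete-case
    analysis).  Returns (t, p, degenerate-flag) matrices of shape (m, m).
    """
    n1 = np.sum(~np.isnan(dx), axis=0).astype(float)
    n2 = np.sum(~np.isnan(dy), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(dx, axis=0)
        m2 = np.nanmean(dy, axis=0)
        v1 = np.nanvar(dx, axis=0, ddof=1)
        v2 = np.nanvar(dy, axis=0, ddof=1)
        if equal_var:
            df = n1 + n2 - 2
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            se2_1, se2_2 = v1 / n1, v2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1 ** 2 / (n1 - 1) + se2_2 ** 2 / (n2 - 1))
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = (se == 0.0)
    if degenerate.any():
        equal_means = degenerate & np.isclose(m1, m2)
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
        t = np.where(degenerate, np.where(equal_means, 0.0, np.inf), t)
    return t, p, degenerate


def pvalue_matrix(ds: CtDataset, group_x: str, group_y: str,
                  equal_var: bool = True) -> PairPvalueMatrix:
    """All-pairs ΔCT t-test matrix for one group comparison.

    For every ordered miRNA pair (i, j), ``P[i, j]`` is the two-sided
    pooled-variance Student t-test p-value comparing ΔCT_ij between the
    samples of ``group_x`` and ``group_y``.  Welch's unequal-variance
    variant is available via ``equal_var=False`` but is not the default.
    """
    X = ds.group_values(group_x).to_numpy(dtype=float)
    Y = ds.group_values(group_y).to_numpy(dtype=float)
    if X.shape[0] < 2 or Y.shape[0] < 2:
        raise ValueError(
            f"both groups need >= 2 samples ({group_x}: {X.shape[0]}, "
            f"{group_y}: {Y.shape[0]})")
    m = X.shape[1]
    if m < 2:
        raise ValueError("need >= 2 miRNAs after filtering")

    dx = X[:, :, None] - X[:, None, :]
    dy = Y[:, :, None] - Y[:, None, :]
    t, p, degenerate = _pooled_t_matrix(dx, dy, equal_var=equal_var)
    diag = np.eye(m, dtype=bool)
    p[diag] = np.nan
    t[diag] = np.nan
    degenerate[diag] = False
    return PairPvalueMatrix(comparison=(group_x, group_y),
                            mirna_ids=ds.mirna_ids,
                            pvalues=p, tstats=t, degenerate=degenerate)


def permutation_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p-value of the two-sample t statistic.

    Enumerates every relabeling of the pooled observations into groups of
    the original sizes (C(n1+n2, n1) of them) and counts relabelings whose
    |t| is at least the observed |t|.  Used as the model-free reference for
    the pooled-t p-values; feasible only for small groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)

    def tstat(a: np.ndarray, b: np.ndarray) -> float:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        df = len(a) + len(b) - 2
        sp2 = ((len(a) - 1) * va + (len(b) - 1) * vb) / df
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        if se == 0.0:
            return 0.0 if np.isclose(a.mean(), b.mean()) else np.inf
        return (a.mean() - b.mean()) / se

    t_obs = abs(tstat(x, y))
    idx = np.arange(n)
    count = 0
    total = 0
    for comb in combinations(idx, n1):
        sel = np.zeros(n, dtype=bool)
        sel[list(comb)] = True
        t_perm = abs(tstat(pooled[sel], pooled[~sel]))
        # >= with tolerance: the observed relabeling always counts itself
        if t_perm >= t_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# pair selection
# ---------------------------------------------------------------------------

def kd_normal_ct_shift(ds: CtDataset, disease: str = "KD",
                       control: str = "Normal") -> dict[str, float]:
    """Per-miRNA mean CT difference (disease − control), for orienting pairs."""
    d = ds.group_values(disease).mean(axis=0) - ds.group_values(control).mean(axis=0)
    return {m: float(v) for m, v in d.items()}


def _orient(i: str, j: str, shift: Mapping[str, float] | None) -> tuple[str, str]:
    """Canonical (target, reference) orientation of an unordered pair.

    The target is the member with the larger |mean CT shift| in the
    disease-vs-control comparison; ties (and absent shift info) fall back
    to lexicographic order of the miRNA ids.
    """
    if shift is not None:
        si, sj = abs(shift.get(i, 0.0)), abs(shift.get(j, 0.0))
        if si > sj:
            return i, j
        if sj > si:
            return j, i
    return (i, j) if i <= j else (j, i)


def select_pairs(matrices: Mapping[tuple[str, str], PairPvalueMatrix],
                 criteria: SelectionCriteria,
                 orientation: Mapping[str, float] | None = None
                 ) -> list[BiomarkerPair]:
    """Select biomarker pairs satisfying the multi-criteria p-value pattern.

    ``matrices`` maps each comparison named in ``criteria`` to its p-value
    matrix (all over the same miRNA set).  Unordered duplicates are
    reported once, oriented by ``orientation`` (per-miRNA disease CT
    shifts, see :func:`kd_normal_ct_shift`).  Comparisons are strict on
    both sides of alpha, so a p-value exactly equal to alpha satisfies
    neither a significance nor a non-significance requirement.
    """
    needed = criteria.comparisons
    for comp in needed:
        if comp not in matrices:
            raise ValueError(f"no p-value matrix supplied for comparison {comp}")
    ids = matrices[needed[0]].mirna_ids
    for comp in needed[1:]:
        if matrices[comp].mirna_ids != ids:
            raise ValueError(
                "p-value matrices cover different miRNA sets: "
                f"{comp} differs from {needed[0]}")

    alpha = criteria.alpha
    selected: list[BiomarkerPair] = []
    for a, b in combinations(range(len(ids)), 2):
        ps = {comp: float(matrices[comp].pvalues[a, b]) for comp in needed}
        if any(np.isnan(p) for p in ps.values()):
            continue
        forward = (all(ps[c] < alpha for c in criteria.require_significant)
                   and all(ps[c] > alpha for c in criteria.require_nonsignificant))
        opposite = (all(ps[c] > alpha for c in criteria.require_significant)
                    and all(ps[c] < alpha for c in criteria.require_nonsignificant))
        if not (forward or opposite):
            continue
        target, reference = _orient(ids[a], ids[b], orientation)
        selected.append(BiomarkerPair(
            target=target, reference=reference,
            trend="forward" if forward else "opposite", pvalues=ps))
    return selected


def stricter_screen(matrix: PairPvalueMatrix, alpha2: float = 1e-4) -> int:
    """Count unordered pairs below a more stringent significance level."""
    m = len(matrix.mirna_ids)
    iu = np.triu_indices(m, k=1)
    p = matrix.pvalues[iu]
    return int(np.sum(p < alpha2))


def run_screen(ds: CtDataset, criteria: SelectionCriteria,
               ct_ceiling: float = 35.0, equal_var: bool = True
               ) -> tuple[list[BiomarkerPair],
                          dict[tuple[str, str], PairPvalueMatrix], list[str]]:
    """Convenience end-to-end screen: ceiling filter → matrices → selection.

    Returns (selected pairs, p-value matrices per comparison, removed miRNAs).
    """
    filtered, removed = filter_ct_ceiling(ds, ceiling=ct_ceiling)
    matrices = {comp: pvalue_matrix(filtered, *comp, equal_var=equal_var)
                for comp in criteria.comparisons}
    disease, control = criteria.require_significant[0] if \
        criteria.require_significant else ("KD", "Normal")
    try:
        orientation = kd_normal_ct_shift(filtered, disease, control)
    except ValueError:
        orientation = None
    pairs = select_pairs(matrices, criteria, orientation=orientation)
    return pairs, matrices, removed
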