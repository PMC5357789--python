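"""Readers and writers for the pipeline's text formats.

All formats are plain tab-delimited text with explicit headers (the
datasets are small), plus JSON for structured sidecars:

* **CT long table** — one replicate measurement per row, columns
  ``sample_id, group, centre, mirna_id, replicate, ct``; ``NA`` (or an
  empty field) masks a missing CT.
* **Intensity table** — column 1 = miRNA id, remaining columns = named
  conditions, values = normalized log2 intensities.  A GEO
  series-matrix-style dialect with ``!``-prefixed comment lines is
  accepted.
* **P-value matrix** — square TSV with miRNA ids on both axes and ``NA``
  on the diagonal.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import DiagnosticFeatureSet
from .microarray import MicroarrayComparison
from .pairwise import (BiomarkerPair, CtDataset, PairPvalueMatrix,
                       REQUIRED_CT_COLUMNS)
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CT long table
# ---------------------------------------------------------------------------

def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Parse a long-format replicate-level CT table.

    Returns the validated record DataFrame (``ct`` as float, NaN where the
    file said ``NA``).  Missing columns and non-numeric CT values are
    reported by name and line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    ct_raw = df["ct"].str.strip()
    masked = ct_raw.isin(["NA", "NaN", "nan", ""])
    ct = pd.to_numeric(ct_raw.where(~masked, np.nan), errors="coerce")
    bad = ct.isna() & ~masked
    if bad.any():
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in df.index[bad][:10]]
        raise ValueError(f"{path}: non-numeric ct value(s) at line(s) {lines}")
    if masked.any():
        logger.warning("%s: %d masked (NA) CT value(s)", path, int(masked.sum()))
    out = df.copy()
    out["ct"] = ct
    out["replicate"] = pd.to_numeric(out["replicate"], errors="coerce")
    if out["replicate"].isna().any():
        lines = [int(i) + 2 for i in out.index[out["replicate"].isna()][:10]]
        raise ValueError(f"{path}: non-numeric replicate at line(s) {lines}")
    out["replicate"] = out["replicate"].astype(int)
    return out


def write_ct_table(raw: pd.DataFrame, path: str | Path) -> None:
    """Write replicate-level CT records; NaN CT is serialized as ``NA``."""
    out = raw[list(REQUIRED_CT_COLUMNS)].copy()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path,
                         dialect: str = "plain") -> pd.DataFrame:
    """Read a miRNA × condition log2-intensity table.

    ``dialect='geo-series-matrix'`` additionally skips ``!``-prefixed
    comment lines.  Returns a DataFrame indexed by miRNA id with one
    column per condition.
    """
    path = Path(path)
    if dialect not in ("plain", "geo-series-matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = path.read_text()
    if dialect == "geo-series-matrix":
        text = "\n".join(line for line in text.splitlines()
                         if not line.startswith("!"))
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate miRNA id(s): {dup[:5]}")
    return df.astype(float)


def write_intensity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.6f")


def comparison_from_table(table: pd.DataFrame, condition_a: str,
                          condition_b: str) -> MicroarrayComparison:
    """Build a two-condition comparison from named table columns."""
    for c in (condition_a, condition_b):
        if c not in table.columns:
            raise ValueError(f"condition column {c!r} not in table "
                             f"(have {list(table.columns)})")
    return MicroarrayComparison(
        mirna_ids=list(table.index),
        intensity_a=table[condition_a].to_numpy(),
        intensity_b=table[condition_b].to_numpy(),
        label_a=condition_a, label_b=condition_b)


# ---------------------------------------------------------------------------
# p-value matrices, pairs, features, truth
# ---------------------------------------------------------------------------

def write_pvalue_matrix(matrix: PairPvalueMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", na_rep="NA",
                             index_label="mirna_id")


def read_pvalue_matrix(path: str | Path,
                       comparison: tuple[str, str] = ("X", "Y")
                       ) -> PairPvalueMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    p = df.to_numpy(dtype=float)
    return PairPvalueMatrix(comparison=comparison,
                            mirna_ids=list(df.index), pvalues=p,
                            tstats=np.full_like(p, np.nan),
                            degenerate=np.zeros_like(p, dtype=bool))


def write_pairs_table(pairs: list[BiomarkerPair], path: str | Path) -> None:
    rows = []
    for p in pairs:
        row = {"target": p.target, "reference": p.reference, "trend": p.trend}
        for comp, pv in p.pvalues.items():
            row[f"p[{comp[0]} vs {comp[1]}]"] = pv
        rows.append(row)
    cols = ["target", "reference", "trend"]
    pd.DataFrame(rows, columns=cols + sorted(
        {k for r in rows for k in r} - set(cols))).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_features_table(features: DiagnosticFeatureSet,
                         predictions: pd.DataFrame | None,
                         path: str | Path) -> None:
    """Per-sample feature/prediction TSV (also the scatter-plot data file)."""
    out = features.table.copy()
    out["centre"] = features.centres
    if features.labels is not None:
        out["true_class"] = features.labels
    if predictions is not None:
        out = out.join(predictions)
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
               float_format="%.6f")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1,
                                     sort_keys=True) + "\n")


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_ct_matrix(ds: CtDataset, path: str | Path) -> None:
    """Replicate-averaged CT matrix with group/centre annotation columns."""
    out = pd.concat([ds.groups.rename("group"), ds.centres.rename("centre"),
                     ds.values], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA",
               float_format="%.6f")
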