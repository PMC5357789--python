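"""Umbrella pipeline: simulate → screen-array → screen-pairs → classify.

A :class:`PipelineConfig` declares which stages run and every threshold
they use; :func:`run_pipeline` executes the toggled stages into a run
directory and writes a machine-readable JSON summary that, together with
the seed, makes the run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as eio
from .classifier import (DEFAULT_PAIR_1, DEFAULT_PAIR_2, classify,
                         compute_features, evaluate, fit_centroids)
from .microarray import (ArrayScreenCriteria, count_expressed_both,
                         select_onoff_candidates, select_opposite_tendency)
from .pairwise import SelectionCriteria, run_screen
from .synthetic import (generate_ct_replicates, generate_microarray,
                        microarray_scenario, screening_scenario,
                        validation_scenario)
from .pairwise import average_replicates

logger = logging.getLogger(__name__)


def _parse_comparisons(items: Sequence[str | Sequence[str]]
                       ) -> list[tuple[str, str]]:
    out = []
    for it in items:
        if isinstance(it, str):
            x, _, y = it.partition(":")
            if not y:
                raise ValueError(f"comparison {it!r} is not 'GroupX:GroupY'")
            out.append((x, y))
        else:
            out.append((it[0], it[1]))
    return out


@dataclass
class PipelineConfig:
    """Full declarative configuration of one pipeline run."""

    seed: int = 0
    out: str = "exopair-run"
    # stage toggles
    simulate: bool = True
    screen_array: bool = True
    screen_pairs: bool = True
    run_classifier: bool = True
    # microarray thresholds
    expressed_threshold: float = 1.0
    fold_threshold: float = 200.0
    on_threshold: float = 3.5
    off_threshold: float = -3.0
    high_threshold: float = 4.5
    # pairwise screen
    alpha: float = 0.01
    ct_ceiling: float = 35.0
    comparisons: Sequence[str] = ("KD:Normal", "KD:+IVIG", "Normal:ADV")
    require_significant: Sequence[str] = ("KD:Normal", "KD:+IVIG")
    require_nonsignificant: Sequence[str] = ("Normal:ADV",)
    # classifier
    pair1: Sequence[str] = DEFAULT_PAIR_1
    pair2: Sequence[str] = DEFAULT_PAIR_2
    # external inputs (used when simulate is off)
    ct_path: str | None = None
    array_table_path: str | None = None
    validation_ct_path: str | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        # normalize sequence fields so YAML round trips compare equal
        for name in ("comparisons", "require_significant",
                     "require_nonsignificant", "pair1", "pair2"):
            setattr(self, name, tuple(getattr(self, name)))

    def validate(self) -> None:
        for name in ("alpha",):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if not self.comparisons:
            raise ValueError("no comparisons declared")
        declared = set(_parse_comparisons(self.comparisons))
        for name in ("require_significant", "require_nonsignificant"):
            extra = set(_parse_comparisons(getattr(self, name))) - declared
            if extra:
                raise ValueError(f"{name} references undeclared comparison(s) "
                                 f"{sorted(extra)}")
        if not self.simulate:
            if self.screen_pairs and self.ct_path is None:
                raise ValueError("screen_pairs without simulate requires ct_path")
            if self.screen_array and self.array_table_path is None:
                raise ValueError("screen_array without simulate requires "
                                 "array_table_path")
        ArrayScreenCriteria(expressed_threshold=self.expressed_threshold,
                            fold_threshold=self.fold_threshold,
                            on_threshold=self.on_threshold,
                            off_threshold=self.off_threshold,
                            high_threshold=self.high_threshold)

    # --- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("comparisons", "require_significant",
                  "require_nonsignificant", "pair1", "pair2"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def selection_criteria(self) -> SelectionCriteria:
        return SelectionCriteria(
            alpha=self.alpha,
            require_significant=tuple(_parse_comparisons(self.require_significant)),
            require_nonsignificant=tuple(
                _parse_comparisons(self.require_nonsignificant)))

    def array_criteria(self) -> ArrayScreenCriteria:
        return ArrayScreenCriteria(
            expressed_threshold=self.expressed_threshold,
            fold_threshold=self.fold_threshold,
            on_threshold=self.on_threshold,
            off_threshold=self.off_threshold,
            high_threshold=self.high_threshold)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the toggled stages and write all outputs plus a summary.

    Returns the summary dict (also written as ``summary.json`` in the run
    directory).  Any stage failure raises :class:`StageError`; outputs of
    completed stages are retained.
    """
    config.validate()
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")  # effective configuration, always

    summary: dict = {"seed": config.seed,
                     "thresholds": {
                         "alpha": config.alpha,
                         "ct_ceiling": config.ct_ceiling,
                         "expressed": config.expressed_threshold,
                         "fold": config.fold_threshold,
                         "on": config.on_threshold,
                         "off": config.off_threshold,
                         "high": config.high_threshold}}

    raw_ct = None
    validation_raw = None

    stage = "simulate"
    try:
        if config.simulate:
            arr_cfg = microarray_scenario(seed=config.seed)
            cmp_a, cmp_b, arr_truth = generate_microarray(arr_cfg)
            import pandas as pd
            tab = pd.DataFrame({cmp_a.label_a: cmp_a.intensity_a,
                                cmp_a.label_b: cmp_a.intensity_b,
                                cmp_b.label_b: cmp_b.intensity_b},
                               index=list(cmp_a.mirna_ids))
            eio.write_intensity_table(tab, out / "microarray.tsv")
            eio.write_truth(arr_truth, out / "microarray.truth.json")

            ct_cfg = screening_scenario(seed=config.seed + 1)
            raw_ct, ct_truth = generate_ct_replicates(ct_cfg)
            eio.write_ct_table(raw_ct, out / "ct_screen.tsv")
            eio.write_truth(ct_truth, out / "ct_screen.truth.json")

            val_cfg = validation_scenario(seed=config.seed + 2)
            validation_raw, val_truth = generate_ct_replicates(val_cfg)
            eio.write_ct_table(validation_raw, out / "ct_validation.tsv")
            eio.write_truth(val_truth, out / "ct_validation.truth.json")
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    stage = "screen-array"
    try:
        if config.screen_array:
            if config.simulate:
                table = eio.read_intensity_table(out / "microarray.tsv")
            else:
                table = eio.read_intensity_table(config.array_table_path)
            cmp_a = eio.comparison_from_table(table, "Normal", "KD")
            cmp_b = eio.comparison_from_table(table, "KD", "+IVIG")
            crit = config.array_criteria()
            onoff = select_onoff_candidates(cmp_a, cmp_b, crit)
            opposite = select_opposite_tendency(cmp_a, cmp_b, crit)
            union = sorted(set(onoff) | set(opposite))
            (out / "array_candidates.tsv").write_text(
                "mirna_id\tselection\n" + "".join(
                    f"{m}\t{'opposite' if m in opposite else 'onoff'}\n"
                    for m in union))
            summary["array_screen"] = {
                "expressed_both": {
                    f"{cmp.label_a} vs {cmp.label_b}":
                        count_expressed_both(cmp, crit)
                    for cmp in (cmp_a, cmp_b)},
                "onoff_candidates": sorted(onoff),
                "opposite_tendency": sorted(opposite),
                "candidate_union": union}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "screen-pairs"
    try:
        if config.screen_pairs:
            if raw_ct is None:
                raw_ct = eio.read_ct_table(config.ct_path)
            ds = average_replicates(raw_ct)
            pairs, matrices, removed = run_screen(
                ds, config.selection_criteria(), ct_ceiling=config.ct_ceiling)
            for comp, mat in matrices.items():
                name = f"pvalues_{comp[0]}_vs_{comp[1]}.tsv".replace("+", "plus")
                eio.write_pvalue_matrix(mat, out / name)
            eio.write_pairs_table(pairs, out / "selected_pairs.tsv")
            summary["pair_screen"] = {
                "removed_by_ceiling": removed,
                "selected_pairs": [
                    {"target": p.target, "reference": p.reference,
                     "trend": p.trend} for p in pairs]}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "classify"
    try:
        if config.run_classifier:
            if validation_raw is None:
                if config.validation_ct_path is None:
                    raise ValueError("classifier without simulate requires "
                                     "validation_ct_path")
                validation_raw = eio.read_ct_table(config.validation_ct_path)
            vds = average_replicates(validation_raw)
            feats = compute_features(vds, tuple(config.pair1),
                                     tuple(config.pair2))
            model = fit_centroids(feats)
            preds = classify(feats, model)
            eio.write_features_table(feats, preds, out / "features.tsv")
            result = evaluate(preds["predicted"], feats.labels)
            summary["classifier"] = {
                "confusion": {str(k): {str(c): int(v) for c, v in row.items()}
                              for k, row in result.confusion.iterrows()},
                "kd_sensitivity": result.kd_sensitivity,
                "kd_specificity": result.kd_specificity,
                "accuracy": result.accuracy}
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    (out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True) + "\n")
    return summary
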