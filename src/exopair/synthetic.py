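"""Synthetic cohorts with known planted truth.

Two generators mirror the two experimental assays of the screening
workflow:

* :func:`generate_microarray` — pooled two-condition log2-intensity
  profiles over a large probe set, with planted "on/off" candidates
  (present in one condition, below the detection floor in the other) and
  planted "opposite-tendency" candidates (abundant only in the disease
  condition), over a Gaussian detected/undetected background.

* :func:`generate_ct_dataset` — per-sample qRT-PCR CT matrices over a
  small candidate panel.  The error model is additive Gaussian on the CT
  scale (CT is already logarithmic: one cycle ≈ 2-fold abundance):

      CT(s, m, r) = baseline(m) + effect(group(s), m) + offset(s)
                    + centre(c(s)) + centre_mirna(c(s), m) + ε,
      ε ~ Normal(0, replicate_sd)

  ``offset(s) ~ Normal(0, sample_offset_sd)`` is a per-sample *global*
  shift modelling RNA-extraction-efficiency variation — exactly the
  nuisance that self-referencing ΔCT normalization must cancel.

Factory functions provide the study-design scenarios (cohort sizes,
candidate panel, planted effect tables) used throughout the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pairwise import CtDataset, average_replicates

ARRAY_CONDITIONS = ("Normal", "KD", "+IVIG")

#: The 11-miRNA qRT-PCR candidate panel of the default screening scenario.
#: Three panel members carry explicitly synthetic names: the screening
#: study design fixes the panel size at 11 but only 8 candidates have
#: field names attached to them here.
CANDIDATE_PANEL = (
    "miR-1246", "miR-4436b-5p", "miR-197-3p", "miR-671-5p",
    "miR-1260a", "miR-4701-5p", "miR-885-5p", "miR-328",
    "miR-sim-9", "miR-sim-10", "miR-sim-11",
)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort (CT and/or microarray).

    All CT quantities are in cycles; microarray quantities in log2
    intensity units.  ``group_effects[(group, mirna)]`` is an additive CT
    shift applied to that group (negative = up-regulated, lower CT).
    """

    n_mirnas: int = 11
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"Normal": 20, "KD": 20, "+IVIG": 20, "ADV": 5})
    group_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mirna_ids: Sequence[str] | None = None
    baseline_ct: Sequence[float] | None = None  # drawn U(20, 30) if None
    sample_offset_sd: float = 1.0
    centres: Sequence[str] = ("Centre1",)
    centre_offsets: Mapping[str, float] = field(default_factory=dict)
    # per-(centre, miRNA) shifts; unlike the scalar centre offset these do
    # NOT cancel in ΔCT and model instrument/reagent differences that
    # require calibration
    centre_mirna_offsets: Mapping[tuple[str, str], float] = field(
        default_factory=dict)
    replicate_sd: float = 0.3
    n_replicates: int = 3
    array_background_mean: float = 0.0
    array_background_sd: float = 1.5
    planted_onoff: Sequence[int] = ()
    # condition that is "on" for each planted on/off probe, per comparison
    # (comparison A: Normal vs KD; comparison B: KD vs +IVIG); default:
    # silenced in disease (on in Normal and in +IVIG)
    planted_onoff_on: Mapping[int, tuple[str, str]] = field(default_factory=dict)
    planted_opposite: Sequence[int] = ()
    expected_pairs: Sequence[tuple[str, str, str]] = ()  # (target, ref, trend)
    seed: int = 0

    def validate(self) -> None:
        if self.n_mirnas < 1:
            raise ValueError(f"n_mirnas must be >= 1, got {self.n_mirnas}")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1, got {n}")
        for name in ("sample_offset_sd", "replicate_sd", "array_background_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1, got {self.n_replicates}")
        if len(self.centres) < 1:
            raise ValueError("centres must name at least one centre")
        if self.mirna_ids is not None and len(self.mirna_ids) != self.n_mirnas:
            raise ValueError("mirna_ids length does not match n_mirnas")
        if self.baseline_ct is not None and len(self.baseline_ct) != self.n_mirnas:
            raise ValueError("baseline_ct length does not match n_mirnas")
        onoff, opposite = set(self.planted_onoff), set(self.planted_opposite)
        if onoff & opposite:
            raise ValueError("planted_onoff and planted_opposite overlap: "
                             f"{sorted(onoff & opposite)}")
        for idx in onoff | opposite:
            if not 0 <= idx < self.n_mirnas:
                raise ValueError(f"planted index {idx} outside "
                                 f"[0, n_mirnas={self.n_mirnas})")

    def resolved_mirna_ids(self) -> list[str]:
        if self.mirna_ids is not None:
            return list(self.mirna_ids)
        width = len(str(self.n_mirnas))
        return [f"miR-sim-{i + 1:0{width}d}" for i in range(self.n_mirnas)]


@dataclass
class SyntheticTruth:
    """Ground-truth record backing parameter-recovery tests."""

    config: SyntheticConfig
    sample_offsets: pd.Series | None = None
    noise_free_ct: pd.DataFrame | None = None
    expected_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    onoff_ids: list[str] = field(default_factory=list)
    opposite_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        # JSON-compatible: tuple-keyed maps become lists of records
        cfg["group_effects"] = [
            {"group": g, "mirna": m, "cycles": v}
            for (g, m), v in self.config.group_effects.items()]
        cfg["centre_mirna_offsets"] = [
            {"centre": c, "mirna": m, "cycles": v}
            for (c, m), v in self.config.centre_mirna_offsets.items()]
        cfg["centre_offsets"] = dict(self.config.centre_offsets)
        cfg["n_per_group"] = dict(self.config.n_per_group)
        cfg["planted_onoff_on"] = {
            str(k): list(v) for k, v in self.config.planted_onoff_on.items()}
        cfg["mirna_ids"] = self.config.resolved_mirna_ids()
        out = {
            "config": cfg,
            "expected_pairs": [list(p) for p in self.expected_pairs],
            "onoff_ids": self.onoff_ids,
            "opposite_ids": self.opposite_ids,
        }
        if self.sample_offsets is not None:
            out["sample_offsets"] = self.sample_offsets.round(10).to_dict()
        if self.noise_free_ct is not None:
            out["noise_free_ct"] = {
                s: row.round(10).to_dict()
                for s, row in self.noise_free_ct.iterrows()}
        return out


# ---------------------------------------------------------------------------
# CT generation
# ---------------------------------------------------------------------------

def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    centres = list(config.centres)
    k = 0
    for group, n in config.n_per_group.items():
        for i in range(n):
            rows.append({"sample_id": f"{group}-{i + 1:03d}", "group": group,
                         "centre": centres[k % len(centres)]})
            k += 1
    return pd.DataFrame(rows).set_index("sample_id")


def generate_ct_replicates(config: SyntheticConfig) -> tuple[pd.DataFrame,
                                                             SyntheticTruth]:
    """Replicate-level long-format CT records plus the planted truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mirnas = config.resolved_mirna_ids()
    samples = _sample_table(config)

    if config.baseline_ct is None:
        baseline = rng.uniform(20.0, 30.0, size=config.n_mirnas)
    else:
        baseline = np.asarray(config.baseline_ct, dtype=float)

    offsets = rng.normal(0.0, config.sample_offset_sd, size=len(samples))
    sample_offsets = pd.Series(offsets, index=samples.index, name="offset")

    effects = np.zeros((len(samples), config.n_mirnas))
    for (group, mirna), shift in config.group_effects.items():
        if mirna not in mirnas:
            raise ValueError(f"group_effects names unknown miRNA {mirna!r}")
        j = mirnas.index(mirna)
        effects[(samples["group"] == group).to_numpy(), j] += shift

    centre_shift = np.zeros((len(samples), config.n_mirnas))
    for c, v in config.centre_offsets.items():
        centre_shift[(samples["centre"] == c).to_numpy(), :] += v
    for (c, mirna), v in config.centre_mirna_offsets.items():
        j = mirnas.index(mirna)
        centre_shift[(samples["centre"] == c).to_numpy(), j] += v

    clean = baseline[None, :] + effects + offsets[:, None] + centre_shift
    noise_free = pd.DataFrame(clean, index=samples.index, columns=mirnas)

    records = []
    for r in range(1, config.n_replicates + 1):
        eps = rng.normal(0.0, config.replicate_sd, size=clean.shape)
        ct = clean + eps
        rep = pd.DataFrame(ct, index=samples.index, columns=mirnas)
        long = rep.stack().rename("ct").reset_index()
        long.columns = ["sample_id", "mirna_id", "ct"]
        long["replicate"] = r
        records.append(long)
    raw = pd.concat(records, ignore_index=True)
    raw = raw.merge(samples.reset_index(), on="sample_id")
    raw = raw[["sample_id", "group", "centre", "mirna_id", "replicate", "ct"]]
    # stable, design-defined row order
    raw = raw.sort_values(["sample_id", "mirna_id", "replicate"],
                          kind="stable", ignore_index=True)

    truth = SyntheticTruth(config=config, sample_offsets=sample_offsets,
                           noise_free_ct=noise_free,
                           expected_pairs=list(config.expected_pairs))
    return raw, truth


def generate_ct_dataset(config: SyntheticConfig) -> tuple[CtDataset,
                                                          SyntheticTruth]:
    """Replicate-averaged CT dataset plus the planted truth."""
    raw, truth = generate_ct_replicates(config)
    ds = average_replicates(raw, n_replicates=config.n_replicates)
    return ds, truth


# ---------------------------------------------------------------------------
# microarray generation
# ---------------------------------------------------------------------------

@dataclass
class MicroarrayTriple:
    """Pooled log2 intensities for the three array conditions."""

    mirna_ids: list[str]
    intensities: pd.DataFrame  # columns: Normal, KD, +IVIG


def generate_microarray(config: SyntheticConfig
                        ) -> tuple["MicroarrayComparison",
                                   "MicroarrayComparison", SyntheticTruth]:
    """Two pooled-array comparisons (Normal vs KD, KD vs +IVIG) with truth.

    Planted on/off probes sit above log2 intensity 5 in their "on"
    condition and below the −3 detection floor in the "off" one, so they
    clear both the on/off predicate and the >200-fold rule.  Planted
    opposite-tendency probes are abundant (log2 > 5 > 4.5) only in KD and
    undetected in Normal and +IVIG.  Background probes are iid Gaussian
    per condition.
    """
    from .microarray import MicroarrayComparison  # local: avoid cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    mirnas = config.resolved_mirna_ids()
    m = config.n_mirnas

    intens = rng.normal(config.array_background_mean,
                        config.array_background_sd, size=(m, 3))
    tab = pd.DataFrame(intens, index=mirnas, columns=list(ARRAY_CONDITIONS))

    def on_level() -> float:
        return float(rng.uniform(5.0, 7.0))

    def off_level() -> float:
        return float(rng.uniform(-6.0, -3.3))

    for idx in config.planted_onoff:
        on_a, on_b = config.planted_onoff_on.get(idx, ("Normal", "+IVIG"))
        row = {c: off_level() for c in ARRAY_CONDITIONS}
        row[on_a] = on_level()
        row[on_b] = on_level() if on_b != on_a else row[on_a]
        tab.iloc[idx] = [row[c] for c in ARRAY_CONDITIONS]

    for idx in config.planted_opposite:
        tab.iloc[idx] = [off_level(), on_level(), off_level()]  # N, KD, +IVIG

    cmp_a = MicroarrayComparison(
        mirna_ids=mirnas, intensity_a=tab["Normal"].to_numpy(),
        intensity_b=tab["KD"].to_numpy(), label_a="Normal", label_b="KD")
    cmp_b = MicroarrayComparison(
        mirna_ids=mirnas, intensity_a=tab["KD"].to_numpy(),
        intensity_b=tab["+IVIG"].to_numpy(), label_a="KD", label_b="+IVIG")

    truth = SyntheticTruth(
        config=config,
        onoff_ids=[mirnas[i] for i in config.planted_onoff],
        opposite_ids=[mirnas[i] for i in config.planted_opposite],
        expected_pairs=list(config.expected_pairs))
    return cmp_a, cmp_b, truth


# ---------------------------------------------------------------------------
# study-design scenarios
# ---------------------------------------------------------------------------

#: Planted CT effect table of the default screening scenario (cycles,
#: applied to the named group only; negative = up-regulated).  The design
#: makes (miR-1246, miR-4436b-5p) the unique forward pair and
#: (miR-197-3p, miR-671-5p) the unique opposite pair: every other panel
#: member carries mutually distinct KD *and* ADV effects, so every
#: non-planted pair deterministically violates at least one selection
#: criterion (a KD-effect gap breaks the non-significance requirements, an
#: ADV-effect gap breaks the Normal-vs-ADV non-significance requirement).
SCREEN_KD_EFFECTS = {
    "miR-1246": -3.0, "miR-4436b-5p": 0.0,
    "miR-197-3p": -2.0, "miR-671-5p": -2.0,
    "miR-1260a": 1.0, "miR-4701-5p": 2.0, "miR-885-5p": 3.0, "miR-328": 4.0,
    "miR-sim-9": -1.0, "miR-sim-10": -4.0, "miR-sim-11": -5.0,
}
SCREEN_ADV_EFFECTS = {
    "miR-1246": 0.0, "miR-4436b-5p": 0.0,
    "miR-197-3p": -4.0, "miR-671-5p": -2.0,
    "miR-1260a": 2.0, "miR-4701-5p": 4.0, "miR-885-5p": 6.0, "miR-328": -6.0,
    "miR-sim-9": -8.0, "miR-sim-10": -10.0, "miR-sim-11": -12.0,
}

#: Fixed per-miRNA baseline CTs of the screening scenario, in cycles.
#: Chosen so that baseline + the largest positive planted effect + a
#: 3-sigma sample offset stays below the 35-cycle quantification ceiling:
#: the ceiling rule is part of the screen, not of the cohort design.
SCREEN_BASELINE_CT = tuple(float(v) for v in np.linspace(21.0, 25.0, 11))


def screening_scenario(seed: int = 0, *,
                       kd_effect: float = -3.0,
                       replicate_sd: float = 0.3,
                       sample_offset_sd: float = 1.0) -> SyntheticConfig:
    """The qRT-PCR screening cohort: 20 Normal / 20 KD / 20 +IVIG / 5 ADV.

    Plants one forward biomarker pair (miR-1246 over reference
    miR-4436b-5p, KD shift ``kd_effect`` cycles) and one opposite pair
    (miR-197-3p over miR-671-5p, differing only between Normal and ADV).
    """
    effects: dict[tuple[str, str], float] = {}
    for mirna, v in SCREEN_KD_EFFECTS.items():
        if mirna == "miR-1246":
            v = kd_effect
        if v != 0.0:
            effects[("KD", mirna)] = v
    for mirna, v in SCREEN_ADV_EFFECTS.items():
        if v != 0.0:
            effects[("ADV", mirna)] = v
    return SyntheticConfig(
        n_mirnas=len(CANDIDATE_PANEL),
        mirna_ids=list(CANDIDATE_PANEL),
        baseline_ct=list(SCREEN_BASELINE_CT),
        n_per_group={"Normal": 20, "KD": 20, "+IVIG": 20, "ADV": 5},
        group_effects=effects,
        replicate_sd=replicate_sd,
        sample_offset_sd=sample_offset_sd,
        expected_pairs=(("miR-1246", "miR-4436b-5p", "forward"),
                        ("miR-197-3p", "miR-671-5p", "opposite")),
        seed=seed)


def null_scenario(seed: int = 0, *, n_mirnas: int = 11,
                  n_per_group: Mapping[str, int] | None = None,
                  replicate_sd: float = 0.3,
                  sample_offset_sd: float = 1.0) -> SyntheticConfig:
    """No group effects at all — for type-I error calibration."""
    return SyntheticConfig(
        n_mirnas=n_mirnas,
        n_per_group=dict(n_per_group or {"Normal": 20, "KD": 20}),
        group_effects={},
        replicate_sd=replicate_sd,
        sample_offset_sd=sample_offset_sd,
        seed=seed)


def validation_scenario(seed: int = 0, *, separation: float = 5.0,
                        centre2_shift: float = 2.0,
                        replicate_sd: float = 0.6) -> SyntheticConfig:
    """The two-centre validation cohort behind the diagnostic classifier.

    54 Normal / 54 KD / 36 non-KD febrile (10 ADV, 13 EBV, 12 JIA, 1 SF)
    over the 4 validated miRNAs.  Feature geometry: with
    f1 = CT(miR-1246) − CT(miR-4436b-5p) and
    f2 = CT(miR-197-3p) − CT(miR-671-5p), class centroids sit at
    Normal (0, 0), KD (−s, 0), febrile (−s, −s) with s = ``separation`` —
    so f1 alone cannot split KD from febrile and f2 alone cannot split KD
    from Normal; only the two features jointly separate the three classes.
    Centre2 carries a per-miRNA instrument shift of ``centre2_shift``
    cycles on the two target miRNAs (shifting both features), plus a
    global +1-cycle offset that ΔCT cancels by itself.
    """
    mirnas = ["miR-1246", "miR-4436b-5p", "miR-197-3p", "miR-671-5p"]
    febrile = ("ADV", "EBV", "JIA", "SF")
    effects: dict[tuple[str, str], float] = {("KD", "miR-1246"): -separation}
    for g in febrile:
        effects[(g, "miR-1246")] = -separation
        effects[(g, "miR-197-3p")] = -separation
    return SyntheticConfig(
        n_mirnas=4, mirna_ids=mirnas,
        n_per_group={"Normal": 54, "KD": 54, "ADV": 10, "EBV": 13,
                     "JIA": 12, "SF": 1},
        group_effects=effects,
        centres=("Centre1", "Centre2"),
        centre_offsets={"Centre2": 1.0},
        centre_mirna_offsets={("Centre2", "miR-1246"): centre2_shift,
                              ("Centre2", "miR-197-3p"): centre2_shift},
        replicate_sd=replicate_sd,
        sample_offset_sd=1.0,
        seed=seed)


def microarray_scenario(seed: int = 0, *, n_mirnas: int = 1887,
                        n_onoff: int = 6, n_opposite: int = 5
                        ) -> SyntheticConfig:
    """Pooled-array screen over the full probe set (1887 human miRNAs).

    Plants ``n_onoff`` on/off probes (silenced in KD) and ``n_opposite``
    opposite-tendency probes (abundant only in KD); the candidate union of
    the two screens has size ``n_onoff + n_opposite`` (11 by default).
    """
    if n_onoff + n_opposite > n_mirnas:
        raise ValueError("more planted probes than miRNAs")
    return SyntheticConfig(
        n_mirnas=n_mirnas,
        n_per_group={"Normal": 5, "KD": 5, "+IVIG": 5},  # pooled per array
        planted_onoff=tuple(range(n_onoff)),
        planted_opposite=tuple(range(n_onoff, n_onoff + n_opposite)),
        seed=seed)
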