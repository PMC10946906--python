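"""Ground-truthed synthetic data for the three experimental designs.

Three generators emulate the study's designs with known ground truth:

* a two-group experiment (drug-cocktail-treated vs vehicle-treated cells,
  20 replicates per group) with a small planted discriminating signature
  among ~2000 null background genes;
* a plate-structured compound screen (960 compounds, each plate carrying
  4 positive-control wells treated with the cocktail and 4 vehicle wells)
  with planted mimicker / neutral / anti-mimicker compounds;
* a dose series (vehicle plus four ascending doses) with planted monotone-up,
  monotone-down, flat and non-monotone genes.

All noise is multiplicative lognormal parameterized by a coefficient of
variation; the lognormal is mean-corrected so the expected value of each
measurement equals its planted mean.  Every generator draws from a named
stream derived from a single seed, so identical configurations produce
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PlateLibrary

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "GroundTruth",
    "generate_two_group",
    "generate_plate_library",
    "generate_dose_series",
]

#: default planted signature: the cocktail's fold-change profile over the
#: three signature genes (two down-regulated, one up-regulated)
COCKTAIL_PROFILE = (("ANXA2", 0.51), ("FBN1", 0.65), ("TPPP3", 1.45))

# named sub-streams so the three generators are statistically independent
# even when run from one seed
_STREAMS = {"two_group": 11, "plate": 23, "dose": 37, "annotations": 53}


class ConfigurationError(ValueError):
    """Raised when a generator configuration is inconsistent."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-data generators.

    Defaults reproduce the study's designs: 20 replicates per group, the
    three-gene cocktail fold-change profile (0.51, 0.65, 1.45) planted among
    2000 genes, a 960-compound library on plates with 4 positive-control and
    4 vehicle wells, and a five-level dose series.
    """

    seed: int = 0
    # two-group design
    n_per_group: int = 20
    n_genes: int = 2000
    planted_signature: tuple[tuple[str, float], ...] = COCKTAIL_PROFILE
    noise_cv: float = 0.15
    baseline_range: tuple[float, float] = (10.0, 1000.0)
    # screen design
    n_compounds: int = 960
    compounds_per_plate: int = 80
    wells_pos_per_plate: int = 4
    wells_veh_per_plate: int = 4
    mimicker_fraction: float = 0.05
    anti_mimicker_fraction: float = 0.05
    excludable_fraction: float = 0.10
    #: well-level technical CV of the plate screen (RT-qPCR-scale precision,
    #: tighter than the sample-level RNA-seq noise_cv)
    screen_noise_cv: float = 0.05
    plate_effect_cv: float = 0.0
    # dose design
    dose_levels: tuple[str, ...] = ("vehicle", "0.1", "1", "10", "100")
    reps_per_dose: int = 4
    trend_fractions: tuple[tuple[str, float], ...] = (
        ("up", 0.05), ("down", 0.05), ("non-monotone", 0.05))
    trend_max_fc: float = 2.0

    def validate(self) -> None:
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        for gene, fc in self.planted_signature:
            if not fc > 0:
                raise ConfigurationError(
                    f"planted fold change for {gene!r} must be positive, got {fc}")
        if self.n_per_group < 3:
            raise ConfigurationError("n_per_group must be at least 3")
        lo, hi = self.baseline_range
        if not (0 < lo <= hi):
            raise ConfigurationError("baseline_range must be positive and ordered")
        if self.n_compounds < 1 or self.compounds_per_plate < 1:
            raise ConfigurationError("need at least one compound per plate")
        if self.wells_pos_per_plate < 1 or self.wells_veh_per_plate < 1:
            raise ConfigurationError("each plate needs control wells")
        if self.mimicker_fraction + self.anti_mimicker_fraction > 1:
            raise ConfigurationError("mimicker fractions exceed 1")
        if not 0 <= self.excludable_fraction <= 1:
            raise ConfigurationError("excludable_fraction outside [0, 1]")
        if self.screen_noise_cv < 0:
            raise ConfigurationError("screen_noise_cv must be non-negative")
        if self.plate_effect_cv < 0:
            raise ConfigurationError("plate_effect_cv must be non-negative")
        if len(self.dose_levels) < 3:
            raise ConfigurationError(
                "need at least 3 dose levels for a monotone trend design")
        if self.reps_per_dose < 2:
            raise ConfigurationError("reps_per_dose must be at least 2")
        if sum(f for _, f in self.trend_fractions) > 1:
            raise ConfigurationError("trend fractions exceed 1")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class GroundTruth:
    """What the generator planted, keyed by the emitted identifiers."""

    signature_genes: list[str] = field(default_factory=list)
    #: gene id -> planted treated/vehicle fold change
    fold_changes: dict[str, float] = field(default_factory=dict)
    #: compound id -> "mimicker" | "neutral" | "anti-mimicker"
    compound_class: dict[str, str] = field(default_factory=dict)
    #: gene id -> "up" | "down" | "flat" | "non-monotone"
    gene_trend: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "signature_genes": list(self.signature_genes),
            "fold_changes": dict(self.fold_changes),
            "compound_class": dict(self.compound_class),
            "gene_trend": dict(self.gene_trend),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            signature_genes=list(d.get("signature_genes", [])),
            fold_changes=dict(d.get("fold_changes", {})),
            compound_class=dict(d.get("compound_class", {})),
            gene_trend=dict(d.get("gene_trend", {})),
        )


def _rng(config: GeneratorConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


def _noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise factors with unit mean and given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def _baselines(rng: np.random.Generator, config: GeneratorConfig,
               n: int) -> np.ndarray:
    lo, hi = config.baseline_range
    return np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))


def _gene_ids(config: GeneratorConfig) -> list[str]:
    planted = [g for g, _ in config.planted_signature]
    n_background = config.n_genes - len(planted)
    return planted + [f"G{i:05d}" for i in range(1, n_background + 1)]


def generate_two_group(config: GeneratorConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-group (treated vs vehicle) matrix with a planted signature.

    Planted genes have treated-group expected value ``baseline * fold_change``;
    background genes have fold change 1.
    """
    config.validate()
    if config.n_genes < len(config.planted_signature):
        raise ConfigurationError("n_genes smaller than the planted signature")
    rng = _rng(config, "two_group")
    genes = _gene_ids(config)
    fc_map = dict(config.planted_signature)
    n = config.n_per_group

    baseline = _baselines(rng, config, config.n_genes)
    fc = np.array([fc_map.get(g, 1.0) for g in genes])
    expected = np.tile(baseline[:, None], (1, 2 * n))
    expected[:, :n] *= fc[:, None]  # treated columns first
    values = expected * _noise(rng, config.noise_cv, expected.shape)

    samples = [f"T{i:02d}" for i in range(1, n + 1)] + \
              [f"V{i:02d}" for i in range(1, n + 1)]
    design = pd.Series(["treated"] * n + ["vehicle"] * n, index=samples)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        design)
    truth = GroundTruth(signature_genes=list(fc_map), fold_changes=dict(fc_map))
    return matrix, truth


def _compound_classes(rng: np.random.Generator,
                      config: GeneratorConfig,
                      compound_ids: list[str]) -> dict[str, str]:
    n = len(compound_ids)
    n_mim = round(config.mimicker_fraction * n)
    n_anti = round(config.anti_mimicker_fraction * n)
    order = rng.permutation(n)
    classes = {}
    for pos, idx in enumerate(order):
        if pos < n_mim:
            cls = "mimicker"
        elif pos < n_mim + n_anti:
            cls = "anti-mimicker"
        else:
            cls = "neutral"
        classes[compound_ids[idx]] = cls
    return classes


def generate_plate_library(
        config: GeneratorConfig,
        ges: list[str]) -> tuple[PlateLibrary, GroundTruth]:
    """Plate-structured screen measurements over the signature genes.

    Every plate carries the configured vehicle and positive-control wells;
    positive controls follow the cocktail profile, planted mimickers mimic it
    (expected intraplate scores of 1), anti-mimickers invert it, and neutral
    compounds have expected fold change 1 on every gene.  Compounds fill
    plates in id order; an optional multiplicative per-plate factor emulates
    plate effects.
    """
    config.validate()
    if not ges:
        raise ConfigurationError("ges gene list is empty")
    fc_map = dict(config.planted_signature)
    for g in ges:
        if g not in fc_map:
            raise ConfigurationError(
                f"gene {g!r} is not in the planted signature profile")

    rng = _rng(config, "plate")
    n_digits = max(4, len(str(config.n_compounds)))
    compound_ids = [f"C{i:0{n_digits}d}" for i in range(1, config.n_compounds + 1)]
    classes = _compound_classes(rng, config, compound_ids)
    class_fc = {
        "mimicker": np.array([fc_map[g] for g in ges]),
        "neutral": np.ones(len(ges)),
        "anti-mimicker": np.array([1.0 / fc_map[g] for g in ges]),
    }
    pos_fc = np.array([fc_map[g] for g in ges])
    baseline = _baselines(rng, config, len(ges))

    n_plates = math.ceil(config.n_compounds / config.compounds_per_plate)
    plate_factor = _noise(rng, config.plate_effect_cv, n_plates)

    wells_rows: list[tuple] = []
    meas_rows: list[tuple] = []

    def emit(plate: str, well: str, role: str, cid: str,
             profile: np.ndarray, factor: float) -> None:
        wells_rows.append((plate, well, role, cid))
        vals = baseline * profile * factor * _noise(
            rng, config.screen_noise_cv, len(ges))
        for g, v in zip(ges, vals):
            meas_rows.append((plate, well, g, v))

    for p in range(n_plates):
        plate = f"P{p + 1:02d}"
        factor = float(plate_factor[p])
        for w in range(config.wells_pos_per_plate):
            emit(plate, f"POS{w + 1}", "positive_control", "", pos_fc, factor)
        for w in range(config.wells_veh_per_plate):
            emit(plate, f"VEH{w + 1}", "vehicle", "", np.ones(len(ges)), factor)
        lo = p * config.compounds_per_plate
        for w, cid in enumerate(compound_ids[lo:lo + config.compounds_per_plate]):
            emit(plate, f"CPD{w + 1:02d}", "compound", cid,
                 class_fc[classes[cid]], factor)

    annotations = _annotations(config, compound_ids)
    lib = PlateLibrary(
        wells=pd.DataFrame(wells_rows,
                           columns=["plate_id", "well_id", "role", "compound_id"]),
        measurements=pd.DataFrame(meas_rows,
                                  columns=["plate_id", "well_id", "gene", "value"]),
        annotations=annotations)
    truth = GroundTruth(signature_genes=list(ges),
                        fold_changes={g: fc_map[g] for g in ges},
                        compound_class=classes)
    return lib, truth


def _annotations(config: GeneratorConfig,
                 compound_ids: list[str]) -> pd.DataFrame:
    """Approval / withdrawal / black-box flags with a configured excludable share."""
    rng = _rng(config, "annotations")
    n = len(compound_ids)
    n_exc = round(config.excludable_fraction * n)
    excl = rng.permutation(n)[:n_exc]
    approved = np.ones(n, dtype=bool)
    withdrawn = np.zeros(n, dtype=bool)
    black_box = np.zeros(n, dtype=bool)
    for j, idx in enumerate(sorted(excl)):
        reason = j % 3  # cycle through the three exclusion reasons
        if reason == 0:
            approved[idx] = False
        elif reason == 1:
            withdrawn[idx] = True
        else:
            black_box[idx] = True
    return pd.DataFrame({
        "compound_id": compound_ids,
        "name": [f"Drug {c}" for c in compound_ids],
        "approved": approved,
        "withdrawn": withdrawn,
        "black_box": black_box,
    })


def _trend_profile(kind: str, n_levels: int, max_fc: float) -> np.ndarray:
    """Per-dose expected fold changes for one trend class."""
    ramp = np.linspace(0.0, 1.0, n_levels)
    if kind == "up":
        return max_fc ** ramp
    if kind == "down":
        return max_fc ** -ramp
    if kind == "flat":
        return np.ones(n_levels)
    if kind == "non-monotone":
        # hump: rises to max_fc mid-series then returns to baseline
        tri = 1.0 - np.abs(2.0 * ramp - 1.0)
        return max_fc ** tri
    raise ConfigurationError(f"unknown trend class {kind!r}")


def generate_dose_series(
        config: GeneratorConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Dose-series matrix with planted monotone / flat / non-monotone genes.

    The configured fractions of genes are assigned to each planted trend
    class (remaining genes are flat); dose-group expected means follow the
    class profile exactly, so the zero-noise limit recovers the planted
    orderings.
    """
    config.validate()
    rng = _rng(config, "dose")
    genes = [f"G{i:05d}" for i in range(1, config.n_genes + 1)]
    n_levels = len(config.dose_levels)

    counts = {k: round(f * config.n_genes) for k, f in config.trend_fractions}
    order = rng.permutation(config.n_genes)
    trend: dict[str, str] = {}
    pos = 0
    for kind, cnt in counts.items():
        for idx in order[pos:pos + cnt]:
            trend[genes[idx]] = kind
        pos += cnt
    for idx in order[pos:]:
        trend[genes[idx]] = "flat"

    baseline = _baselines(rng, config, config.n_genes)
    profiles = {k: _trend_profile(k, n_levels, config.trend_max_fc)
                for k in ("up", "down", "flat", "non-monotone")}
    expected = np.empty((config.n_genes, n_levels * config.reps_per_dose))
    for i, g in enumerate(genes):
        row = np.repeat(profiles[trend[g]], config.reps_per_dose) * baseline[i]
        expected[i] = row
    values = expected * _noise(rng, config.noise_cv, expected.shape)

    samples, labels = [], []
    for dose in config.dose_levels:
        for r in range(1, config.reps_per_dose + 1):
            samples.append(f"{dose}_r{r}")
            labels.append(dose)
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                     columns=samples),
        pd.Series(labels, index=samples))
    return matrix, GroundTruth(gene_trend=trend)
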