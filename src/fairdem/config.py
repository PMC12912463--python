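"""Configuration objects for every pipeline stage.

All stages are driven by small dataclasses that serialize to/from plain YAML
so that a run is fully described by one text file plus one master seed.
Stage seeds are derived from the master seed by hashing the stage name, so a
single integer reproduces the whole study while each stage stays
independently re-runnable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import yaml

MEASURES = ("m1", "m2", "m3")

#: Joint probabilities of being low SES on a pair of measures, used to build
#: the default concordance-target matrix.  With marginals (0.21, 0.05, 0.27)
#: these give conditional concordances of 12% (m1->m2) and 40% (m1->m3),
#: matching the limited cross-measure overlap seen in real deprivation
#: indices, plus a strong 60% m2->m3 overlap (a national upper-quartile area
#: is usually also a state upper-decile area).
DEFAULT_LOW_SES_JOINTS = {(0, 1): 0.0252, (0, 2): 0.084, (1, 2): 0.030}


def concordance_from_joints(
    low_fracs: tuple[float, float, float],
    joints: dict[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Build the (non-symmetric) concordance matrix C[i, j] = P(low_j | low_i)
    from pairwise joint probabilities of being low on both measures."""
    joints = DEFAULT_LOW_SES_JOINTS if joints is None else joints
    p = np.asarray(low_fracs, dtype=float)
    C = np.eye(3)
    for (i, j), joint in joints.items():
        C[i, j] = joint / p[i]
        C[j, i] = joint / p[j]
    return C


def category_prevalence_profile(
    n_categories: int,
    head: tuple[tuple[float, float], ...],
    tail_start: float = 0.50,
    tail_decay: float = 0.8,
    tail_uplift: float = 1.35,
    case_cap: float = 0.90,
) -> dict[str, np.ndarray]:
    """Per-category 5-year window prevalence targets by case status.

    ``head`` lists explicit (case, control) prevalences for the leading
    categories; the tail declines geometrically from ``tail_start`` with a
    constant case/control uplift (capped), mimicking the long-tailed ranking
    of diagnosis-category prevalences with cases elevated throughout.
    """
    control = np.empty(n_categories)
    case = np.empty(n_categories)
    for c in range(n_categories):
        if c < len(head):
            case[c], control[c] = head[c]
        else:
            control[c] = tail_start * tail_decay ** (c - len(head))
            case[c] = min(case_cap, control[c] * tail_uplift)
    return {"case": case, "control": control}


#: Population-cohort archetype heads: hypertension-like (0.762 vs 0.670) and
#: nervous-system-like (0.613 vs 0.384) leading categories.
_POPULATION_HEAD = ((0.762, 0.670), (0.613, 0.384))
#: Research-panel archetype heads (0.854 vs 0.784; 0.700 vs 0.546).
_RESEARCH_PANEL_HEAD = ((0.854, 0.784), (0.700, 0.546))


def default_category_prevalence(n_categories: int) -> dict[str, np.ndarray]:
    return category_prevalence_profile(n_categories, _POPULATION_HEAD)


@dataclass
class PopulationConfig:
    """Generative parameters for the synthetic patient/visit tables.

    Defaults emulate the larger population-cohort archetype (~20,000 persons,
    ~37% incident cases, visit means ~76 vs ~56 per 5-year window); see
    :func:`research_panel` for the smaller research-panel archetype.
    """

    n_patients: int = 20_000
    case_fraction: float = 0.375
    sex_female_fraction: float = 0.57
    n_categories: int = 20
    low_ses_fraction: tuple[float, float, float] = (0.21, 0.05, 0.27)
    concordance_targets: np.ndarray | None = None
    visits_per_year_mean: dict[str, float] = field(
        default_factory=lambda: {"case": 15.24, "control": 11.16}
    )
    empty_year_prob: dict[str, float] = field(
        default_factory=lambda: {"low": 0.034, "high": 0.024}
    )
    category_prevalence: dict[str, np.ndarray] | None = None
    ses_signal_strength: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.concordance_targets is None:
            self.concordance_targets = concordance_from_joints(self.low_ses_fraction)
        else:
            self.concordance_targets = np.asarray(self.concordance_targets, dtype=float)
        if self.category_prevalence is None:
            self.category_prevalence = default_category_prevalence(self.n_categories)
        else:
            self.category_prevalence = {
                k: np.asarray(v, dtype=float) for k, v in self.category_prevalence.items()
            }
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        probs = [self.case_fraction, self.sex_female_fraction, *self.low_ses_fraction]
        probs += list(self.empty_year_prob.values())
        for status in ("case", "control"):
            probs += list(np.atleast_1d(self.category_prevalence[status]))
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.ses_signal_strength < 0:
            raise ValueError("ses_signal_strength must be nonnegative")
        C = self.concordance_targets
        if C.shape != (3, 3) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("concordance_targets must be 3x3 with unit diagonal")
        # Consistency: joint(i,j) must agree whichever way it is conditioned.
        p = np.asarray(self.low_ses_fraction)
        for i in range(3):
            for j in range(i + 1, 3):
                if not np.isclose(C[i, j] * p[i], C[j, i] * p[j], atol=1e-6):
                    raise ValueError(
                        f"concordance_targets[{i},{j}] and [{j},{i}] imply "
                        "different joint probabilities"
                    )
        for status in ("case", "control"):
            if len(self.category_prevalence[status]) != self.n_categories:
                raise ValueError("category_prevalence length must equal n_categories")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["concordance_targets"] = self.concordance_targets.tolist()
        d["category_prevalence"] = {
            k: np.asarray(v).tolist() for k, v in self.category_prevalence.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PopulationConfig":
        d = dict(d)
        if "low_ses_fraction" in d:
            d["low_ses_fraction"] = tuple(d["low_ses_fraction"])
        return cls(**d)


def population(**overrides: Any) -> PopulationConfig:
    """Population-cohort archetype (the package default)."""
    return PopulationConfig(**overrides)


def research_panel(**overrides: Any) -> PopulationConfig:
    """Research-panel archetype: ~3,000 persons, ~22% cases, denser visits."""
    params: dict[str, Any] = dict(
        n_patients=3_000,
        case_fraction=0.223,
        sex_female_fraction=0.485,
        visits_per_year_mean={"case": 18.66, "control": 15.9},
        low_ses_fraction=(0.21, 0.05, 0.25),
        concordance_targets=concordance_from_joints(
            (0.21, 0.05, 0.25), {(0, 1): 0.0252, (0, 2): 0.084, (1, 2): 0.028}
        ),
        category_prevalence=category_prevalence_profile(
            overrides.get("n_categories", 20), _RESEARCH_PANEL_HEAD,
            tail_start=0.55, tail_decay=0.8, tail_uplift=1.25, case_cap=0.95,
        ),
    )
    params.update(overrides)
    return PopulationConfig(**params)


@dataclass
class TimelineConfig:
    """Observation/prediction window geometry and cohort filters."""

    observation_years: int = 5
    prediction_years: int = 1
    min_age_at_incident: int = 50
    control_case_ratio: float | str = "all"
    age_bin_width: int = 10
    age_bin_anchor: int = 45

    def __post_init__(self) -> None:
        if self.observation_years < 1 or self.prediction_years < 1:
            raise ValueError("observation_years and prediction_years must be >= 1")
        if self.age_bin_width < 1:
            raise ValueError("age_bin_width must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TimelineConfig":
        return cls(**d)


@dataclass
class MeasureRule:
    """Dichotomization rule for one SES measure.

    kinds:
      - ``upper-range``: low SES iff value >= ``low_min`` (deprivation
        percentile scale, e.g. 76-100 low on a 0-100 range);
      - ``decile-range``: low SES iff value >= ``low_min`` on a decile scale
        (e.g. 8-10 low on 1-10);
      - ``bottom-quartile``: low SES iff value < the quartile cut.  The cut is
        ``reference_threshold`` when given (a fixed source-population
        quantile, the usual convention for housing-based indices); otherwise
        the ``quantile`` of the cohort's empirical distribution.
    """

    kind: str
    value_range: tuple[float, float]
    low_min: float | None = None
    reference_threshold: float | None = None
    quantile: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("upper-range", "decile-range", "bottom-quartile"):
            raise ValueError(f"unknown dichotomization rule kind {self.kind!r}")
        if self.kind in ("upper-range", "decile-range") and self.low_min is None:
            raise ValueError(f"rule kind {self.kind!r} requires low_min")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MeasureRule":
        d = dict(d)
        d["value_range"] = tuple(d["value_range"])
        return cls(**d)


@dataclass
class SesDichotomyConfig:
    """Per-measure dichotomization rules (defaults match the three synthetic
    measure scales: housing-quartile, national 0-100, state decile)."""

    rules: dict[str, MeasureRule] = field(
        default_factory=lambda: {
            "m1": MeasureRule("bottom-quartile", (0.0, 100.0), reference_threshold=25.0),
            "m2": MeasureRule("upper-range", (0.0, 100.0), low_min=76.0),
            "m3": MeasureRule("decile-range", (1.0, 10.0), low_min=8.0),
        }
    )

    def to_dict(self) -> dict[str, Any]:
        return {"rules": {m: r.to_dict() for m, r in self.rules.items()}}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SesDichotomyConfig":
        return cls(rules={m: MeasureRule.from_dict(r) for m, r in d["rules"].items()})


@dataclass
class SplitConfig:
    train_fraction: float = 0.70
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SplitConfig":
        return cls(**d)


@dataclass
class MitigationConfig:
    """Protected-attribute oversampling parameters (k-NN SMOTE for mixed
    continuous/nominal features; neighbor count 5 and seed 42 by default)."""

    balance_measure: str = "m1"
    k_neighbors: int = 5
    seed: int = 42
    nominal_features: list[str] | None = None

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MitigationConfig":
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end audit run description."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    timeline: TimelineConfig = field(default_factory=TimelineConfig)
    dichotomy: SesDichotomyConfig = field(default_factory=SesDichotomyConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    model_families: list[str] = field(
        default_factory=lambda: [
            "random_forest",
            "logistic_regression",
            "svm",
            "naive_bayes",
        ]
    )
    grid_preset: str = "default"  # "default" (CV-tuned grids) or "fast"
    balance_measures: list[str] = field(default_factory=lambda: ["m1", "m2", "m3"])
    evaluation_measures: list[str] = field(default_factory=lambda: list(MEASURES))
    bootstrap_samples: int = 1000
    patient_table: str | None = None  # None -> synthetic
    visit_table: str | None = None
    mapping_table: str | None = None
    output_dir: str = "fairdem_run"
    master_seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        return {
            "population": self.population.to_dict(),
            "timeline": self.timeline.to_dict(),
            "dichotomy": self.dichotomy.to_dict(),
            "split": self.split.to_dict(),
            "model_families": list(self.model_families),
            "grid_preset": self.grid_preset,
            "balance_measures": list(self.balance_measures),
            "evaluation_measures": list(self.evaluation_measures),
            "bootstrap_samples": self.bootstrap_samples,
            "patient_table": self.patient_table,
            "visit_table": self.visit_table,
            "mapping_table": self.mapping_table,
            "output_dir": self.output_dir,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        d["population"] = PopulationConfig.from_dict(d["population"])
        d["timeline"] = TimelineConfig.from_dict(d["timeline"])
        d["dichotomy"] = SesDichotomyConfig.from_dict(d["dichotomy"])
        d["split"] = SplitConfig.from_dict(d["split"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def config_hash(cfg: Any) -> str:
    """Stable short hash of any config object exposing ``to_dict``."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stage seed < 2^31 from the master seed and stage name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
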