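"""Run configuration: one structured YAML file drives the whole experiment.

Units are fixed throughout: µV, seconds, Hz; marker positions are integer
sample indices.  All randomness flows from the single ``seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .cohort import ArtifactFlags, CohortSpec
from .modeling import MODEL_IDS, CVConfig
from .montage import FRONTAL_17
from .preprocess import PreprocConfig


@dataclass(frozen=True)
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    models: tuple[str, ...] = MODEL_IDS
    combos: tuple[str, ...] | None = None     # None = all 15
    tuning_budget: int = 25
    tree_sizes: tuple[int, ...] = (50, 100, 200)
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.models:
            if m not in MODEL_IDS:
                raise ValueError(f"unknown model id {m!r}")
        for ch in self.cohort.channels:
            if ch not in FRONTAL_17:
                raise ValueError(f"unknown electrode {ch!r} in montage")


def paper_profile(seed: int = 0) -> RunConfig:
    """The full-scale experiment: 60/60 subjects, 3 kHz, 5 min rest, 80 pulses,
    all nine models over all 15 feature-set combinations."""
    return RunConfig(cohort=CohortSpec(seed=seed),
                     cv=CVConfig(seed=seed), seed=seed)


def fast_profile(seed: int = 0) -> RunConfig:
    """A small smoke-test profile: 12/12 subjects, 18 s rest, 10 pulses at
    500 Hz, the three linear models, reduced tuning budget and inner folds."""
    cohort = CohortSpec(n_per_group=12, seed=seed, fs=500.0,
                        rest_duration=18.0, n_pulses=10)
    cv = CVConfig(outer_k=5, inner_k=3, seed=seed)
    return RunConfig(cohort=cohort, preproc=PreprocConfig(run_ica=False),
                     cv=cv, models=("LDA", "LR", "SVM"),
                     tuning_budget=6, tree_sizes=(25, 50), seed=seed)


def reduced_cohort(seed: int = 0, n_per_group: int = 60, **overrides) -> CohortSpec:
    """Paper-sized groups with reduced recording lengths and rate (18 s rest
    = 3 epochs, 16 pulses, 500 Hz): the profile used for simulation studies
    where many cohorts are generated."""
    kwargs = dict(n_per_group=n_per_group, seed=seed, fs=500.0,
                  rest_duration=18.0, n_pulses=16)
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _build(cls, defaults, data: dict):
    unknown = set(data) - set(defaults.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown {cls} field(s): {sorted(unknown)}")
    return replace(defaults, **data)


def load_config(path) -> RunConfig:
    """Read a RunConfig from YAML; missing sections fall back to defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 0))
    profile = fast_profile(seed) if raw.get("profile") == "fast" else paper_profile(seed)

    cohort_raw = dict(raw.get("cohort", {}))
    if "artifact_flags" in cohort_raw:
        cohort_raw["artifact_flags"] = ArtifactFlags(**cohort_raw["artifact_flags"])
    if "channels" in cohort_raw:
        cohort_raw["channels"] = tuple(cohort_raw["channels"])
    cohort = _build("cohort", profile.cohort, cohort_raw)
    preproc = _build("preproc", profile.preproc, dict(raw.get("preproc", {})))
    cv = _build("cv", profile.cv, dict(raw.get("cv", {})))
    kwargs = {}
    for key in ("tuning_budget",):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "models" in raw:
        kwargs["models"] = tuple(raw["models"])
    if "combos" in raw:
        kwargs["combos"] = tuple(raw["combos"])
    return replace(profile, cohort=cohort, preproc=preproc, cv=cv, seed=seed, **kwargs)
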