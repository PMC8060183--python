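"""Flat text (YAML) configuration mirroring ScenarioSpec and FitOptions.

A scenario file holds the design and the population truth:

    name: custom
    max_score: 70
    n_subjects: 150
    visit_times: [0, 3, 6, 9, 12]
    covariates: false
    pop:
      theta_beta: -0.3
      theta_alpha: 0.1
      theta_sigma: 0.1
      omega2_beta: 1.0
      omega2_alpha: 0.000625
      omega2_sigma: 0.1        # optional -> log-normal sigma model

A fit-options file holds any subset of the FitOptions fields.
"""

from __future__ import annotations

from dataclasses import fields as dc_fields

import yaml

from .laplace import FitOptions
from .model import PopulationParams
from .simulate import CovariateGenerator, ScenarioSpec

__all__ = ["load_scenario", "save_scenario", "load_fit_options"]

_POP_FIELDS = {f.name for f in dc_fields(PopulationParams)}
_OPT_FIELDS = {f.name for f in dc_fields(FitOptions)}


def load_scenario(path) -> ScenarioSpec:
    """Read a scenario specification from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    pop_raw = raw.get("pop", {})
    unknown = set(pop_raw) - _POP_FIELDS
    if unknown:
        raise ValueError(f"unknown population parameters: {sorted(unknown)}")
    cov = CovariateGenerator() if raw.get("covariates", False) else None
    return ScenarioSpec(
        name=str(raw.get("name", "custom")),
        max_score=int(raw["max_score"]),
        n_subjects=int(raw["n_subjects"]),
        visit_times=tuple(float(t) for t in raw["visit_times"]),
        pop=PopulationParams(**pop_raw),
        covariate_generator=cov)


def save_scenario(spec: ScenarioSpec, path) -> None:
    """Write a scenario specification to a YAML file (round-trippable)."""
    pop = {f.name: getattr(spec.pop, f.name) for f in dc_fields(PopulationParams)
           if getattr(spec.pop, f.name) is not None}
    doc = dict(name=spec.name, max_score=spec.max_score,
               n_subjects=spec.n_subjects,
               visit_times=[float(t) for t in spec.visit_times],
               covariates=spec.covariate_generator is not None, pop=pop)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_fit_options(path) -> FitOptions:
    """Read estimation options from a YAML file; unset fields keep defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _OPT_FIELDS
    if unknown:
        raise ValueError(f"unknown fit options: {sorted(unknown)}")
    return FitOptions(**raw)
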