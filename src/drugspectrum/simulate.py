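"""Synthetic cohort generation for the attribute-spectrum pipeline.

Real antihypertensive-response cohorts live in hospital information systems
and are not redistributable, so the pipeline is exercised on simulated ones.
Each patient is assigned an intended outcome group (successful / unsuccessful
blood-pressure control); attribute values are sampled per group on the
normalised [0, 1] scale and mapped back to native units through the builtin
attribute table, so normalising the generated cohort recovers the sampled
values exactly.  Post-initiation BP day-series are drawn so that outcome
labelling reproduces the intended group.

Three distribution families are supported per attribute:

``truncated_normal``
    Normal(loc, scale) restricted to [0, 1] (exact truncated sampling).
``uniform``
    Uniform on [loc - scale, loc + scale] intersected with [0, 1].
``two_block``
    A dominance-crossover construction: the group with the lower location
    parameter is uniform below the ``crossover`` value and the other group
    uniform above it, giving a known ground-truth breakpoint.

Sex is generated as a Bernoulli draw with the group's ``loc`` as the female
probability, mapped to codes 1 (male) / 2 (female).

Default group locations are calibrated to the published reference-cohort group
means; scale defaults to 0.15 on the normalised scale.  All randomness derives
from one integer seed through fixed-key ``numpy.random.SeedSequence``
substreams, so output is reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cohort as _cohort
from .cohort import BPSeries, COHORT_COLUMNS, SUCCESSFUL, UNSUCCESSFUL
from .normalize import ATTRIBUTE_ORDER, AttributeSpec, default_attribute_table
from .reference import REFERENCE_GROUP_MEANS

__all__ = [
    "AttributeGenSpec",
    "CohortConfig",
    "GroupParams",
    "default_gen_specs",
    "generate_bp_series",
    "generate_cohort",
    "generate_cohort_with_truth",
    "cohort_config_from_yaml",
    "cohort_config_to_yaml",
]

_FAMILIES = ("truncated_normal", "uniform", "two_block")

#: Default within-group dispersion on the normalised scale.
DEFAULT_SCALE = 0.15

# Base 5-day BP levels (mmHg) for each intended outcome; chosen comfortably
# inside / outside the 140/90 control thresholds.
_SUCCESS_BASE = (125.0, 78.0)
_FAIL_BASE = (152.0, 96.0)

# Substream roles for counter-based sub-seeding.
_ROLE_GROUP = 0
_ROLE_ATTR = 1
_ROLE_BP = 2


@dataclass(frozen=True)
class GroupParams:
    """Location and scale of one outcome group's distribution on [0, 1]."""

    loc: float
    scale: float = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if not 0.0 <= self.loc <= 1.0:
            raise ValueError(f"loc must lie in [0, 1], got {self.loc}")
        if not self.scale > 0.0:
            raise ValueError(f"scale must be > 0, got {self.scale}")


@dataclass(frozen=True)
class AttributeGenSpec:
    """Generation recipe for one attribute: family plus per-group parameters."""

    attribute_name: str
    distribution_family: str
    successful_params: GroupParams
    unsuccessful_params: GroupParams
    crossover: float | None = None

    def __post_init__(self) -> None:
        if self.distribution_family not in _FAMILIES:
            raise ValueError(f"unknown family {self.distribution_family!r}")
        if self.distribution_family == "two_block":
            if self.crossover is None:
                raise ValueError("two_block family requires a crossover value")
            if not 0.0 < self.crossover < 1.0:
                raise ValueError(f"crossover must lie in (0, 1), got {self.crossover}")

    def params(self, group: str) -> GroupParams:
        return self.successful_params if group == SUCCESSFUL else self.unsuccessful_params


@dataclass(frozen=True)
class CohortConfig:
    """Full recipe for one synthetic cohort."""

    n_patients: int
    success_fraction: float = 0.5
    attribute_specs: tuple[AttributeGenSpec, ...] = field(default_factory=tuple)
    bp_noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.success_fraction <= 1.0:
            raise ValueError("success_fraction must lie in [0, 1]")
        if self.bp_noise_sd < 0.0:
            raise ValueError("bp_noise_sd must be >= 0")
        names = [s.attribute_name for s in self.attribute_specs]
        if len(set(names)) != len(names):
            raise ValueError("attribute names must be unique")


def default_gen_specs(
    shift: float = 0.0, scale: float = DEFAULT_SCALE
) -> tuple[AttributeGenSpec, ...]:
    """Truncated-normal specs for all 19 attributes, located at the published
    reference-cohort group means.

    ``shift`` is added to the successful location and subtracted from the
    unsuccessful one (on top of the published between-group gap); ``shift=0``
    reproduces the published means as locations.
    """
    specs = []
    for name in ATTRIBUTE_ORDER:
        _, succ, unsucc = REFERENCE_GROUP_MEANS[name]
        specs.append(
            AttributeGenSpec(
                attribute_name=name,
                distribution_family="truncated_normal",
                successful_params=GroupParams(float(np.clip(succ + shift, 0, 1)), scale),
                unsuccessful_params=GroupParams(float(np.clip(unsucc - shift, 0, 1)), scale),
            )
        )
    return tuple(specs)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream keyed on (seed, role, ...) integers."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def _sample_group(
    spec: AttributeGenSpec, group: str, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``size`` normalised values for one group of one attribute."""
    if size == 0:
        return np.empty(0)
    p = spec.params(group)
    if spec.attribute_name == "Sex":
        # Bernoulli: loc is the probability of code 2 (female) -> normalised 1.
        return (rng.random(size) < p.loc).astype(float)
    fam = spec.distribution_family
    if fam == "truncated_normal":
        a = (0.0 - p.loc) / p.scale
        b = (1.0 - p.loc) / p.scale
        return stats.truncnorm.rvs(a, b, loc=p.loc, scale=p.scale, size=size, random_state=rng)
    if fam == "uniform":
        lo = max(0.0, p.loc - p.scale)
        hi = min(1.0, p.loc + p.scale)
        return rng.uniform(lo, hi, size)
    # two_block: group with the lower loc occupies [0, crossover), the other
    # [crossover, 1] — all mass on one side of the intended breakpoint.
    c = spec.crossover
    succ_below = spec.successful_params.loc <= spec.unsuccessful_params.loc
    below = (group == SUCCESSFUL) == succ_below
    return rng.uniform(0.0, c, size) if below else rng.uniform(c, 1.0, size)


def generate_bp_series(
    intended_label: str, bp_noise_sd: float, seed: int
) -> BPSeries:
    """Generate one 5-day (SBP, DBP) series whose labelling matches ``intended_label``.

    Daily values are the intended group's base level plus Normal(0, sd) noise;
    series whose 5-day means land on the wrong side of the 140/90 thresholds
    are resampled, with a deterministic reflection about the base level as a
    final fallback.  Fixed seed implies an identical series.
    """
    if bp_noise_sd < 0:
        raise ValueError("bp_noise_sd must be >= 0")
    if intended_label not in (SUCCESSFUL, UNSUCCESSFUL):
        raise ValueError(f"unknown label {intended_label!r}")
    rng = _stream(seed, _ROLE_BP)
    sbp, dbp = _bp_matrix(np.array([intended_label == SUCCESSFUL]), bp_noise_sd, rng)
    return BPSeries(sbp=sbp[0], dbp=dbp[0])


def _bp_matrix(
    success_mask: np.ndarray, sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised BP series for ``len(success_mask)`` patients."""
    n = len(success_mask)
    days = _cohort.N_OUTCOME_DAYS
    base_sbp = np.where(success_mask, _SUCCESS_BASE[0], _FAIL_BASE[0])[:, None]
    base_dbp = np.where(success_mask, _SUCCESS_BASE[1], _FAIL_BASE[1])[:, None]
    sbp = base_sbp + rng.normal(0.0, sd, (n, days))
    dbp = base_dbp + rng.normal(0.0, sd, (n, days))

    def wrong(sbp_m, dbp_m):
        ok = (sbp_m.mean(axis=1) < _cohort.SBP_THRESHOLD) & (
            dbp_m.mean(axis=1) < _cohort.DBP_THRESHOLD
        )
        return np.where(success_mask, ~ok, ok)

    for _ in range(50):
        bad = wrong(sbp, dbp)
        if not bad.any():
            break
        k = int(bad.sum())
        sbp[bad] = base_sbp[bad] + rng.normal(0.0, sd, (k, days))
        dbp[bad] = base_dbp[bad] + rng.normal(0.0, sd, (k, days))
    bad = wrong(sbp, dbp)
    if bad.any():  # reflect about the base level: flips the mean to the right side
        sbp[bad] = 2 * base_sbp[bad] - sbp[bad]
        dbp[bad] = 2 * base_dbp[bad] - dbp[bad]
    return np.maximum(sbp, 1.0), np.maximum(dbp, 1.0)


def generate_cohort_with_truth(
    config: CohortConfig,
    table: dict[str, AttributeSpec] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a cohort table plus a ground-truth record for test harnesses.

    Returns ``(cohort, truth)`` where ``cohort`` follows the canonical CSV
    schema (unlabelled; labelling it reproduces the intended groups) and
    ``truth`` holds the intended labels and the generating parameters.
    """
    table = default_attribute_table() if table is None else table
    for spec in config.attribute_specs:
        if spec.attribute_name not in table:
            raise KeyError(f"unknown attribute {spec.attribute_name!r}")

    n = config.n_patients
    success = _stream(config.seed, _ROLE_GROUP).random(n) < config.success_fraction

    data: dict[str, np.ndarray] = {
        "patient_id": np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    }
    for j, spec in enumerate(config.attribute_specs):
        z = np.empty(n)
        for gi, (group, mask) in enumerate(
            ((SUCCESSFUL, success), (UNSUCCESSFUL, ~success))
        ):
            rng = _stream(config.seed, _ROLE_ATTR, j, gi)
            z[mask] = _sample_group(spec, group, int(mask.sum()), rng)
        aspec = table[spec.attribute_name]
        data[spec.attribute_name] = aspec.attr_min + z * aspec.span

    data["monotherapy"] = np.ones(n, dtype=bool)
    data["on_label_dose"] = np.ones(n, dtype=bool)
    sbp, dbp = _bp_matrix(success, config.bp_noise_sd, _stream(config.seed, _ROLE_BP))
    for d in range(_cohort.N_OUTCOME_DAYS):
        data[f"sbp_d{d + 1}"] = sbp[:, d]
        data[f"dbp_d{d + 1}"] = dbp[:, d]

    df = pd.DataFrame(data)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"config does not cover required attributes: {missing}")
    df = df.loc[:, list(COHORT_COLUMNS)]

    truth = {
        "seed": config.seed,
        "n_patients": n,
        "success_fraction": config.success_fraction,
        "bp_noise_sd": config.bp_noise_sd,
        "intended_labels": [SUCCESSFUL if s else UNSUCCESSFUL for s in success],
        "attribute_specs": [
            {
                "attribute_name": s.attribute_name,
                "distribution_family": s.distribution_family,
                "successful_params": {"loc": s.successful_params.loc, "scale": s.successful_params.scale},
                "unsuccessful_params": {"loc": s.unsuccessful_params.loc, "scale": s.unsuccessful_params.scale},
                "crossover": s.crossover,
            }
            for s in config.attribute_specs
        ],
    }
    return df, truth


def generate_cohort(
    config: CohortConfig, table: dict[str, AttributeSpec] | None = None
) -> pd.DataFrame:
    """Generate a synthetic cohort table (see :func:`generate_cohort_with_truth`)."""
    return generate_cohort_with_truth(config, table)[0]


def _gen_spec_from_dict(entry: dict) -> AttributeGenSpec:
    return AttributeGenSpec(
        attribute_name=entry["attribute_name"],
        distribution_family=entry["distribution_family"],
        successful_params=GroupParams(**entry["successful_params"]),
        unsuccessful_params=GroupParams(**entry["unsuccessful_params"]),
        crossover=entry.get("crossover"),
    )


def cohort_config_from_yaml(path) -> CohortConfig:
    """Load a :class:`CohortConfig` from YAML; omitted attribute_specs fall
    back to :func:`default_gen_specs`."""
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    specs = payload.get("attribute_specs")
    specs = (
        default_gen_specs()
        if specs is None
        else tuple(_gen_spec_from_dict(e) for e in specs)
    )
    return CohortConfig(
        n_patients=payload["n_patients"],
        success_fraction=payload.get("success_fraction", 0.5),
        attribute_specs=specs,
        bp_noise_sd=payload.get("bp_noise_sd", 5.0),
        seed=payload.get("seed", 0),
    )


def cohort_config_to_yaml(config: CohortConfig, path) -> None:
    payload = {
        "n_patients": config.n_patients,
        "success_fraction": config.success_fraction,
        "bp_noise_sd": config.bp_noise_sd,
        "seed": config.seed,
        "attribute_specs": [
            {
                "attribute_name": s.attribute_name,
                "distribution_family": s.distribution_family,
                "successful_params": {"loc": s.successful_params.loc, "scale": s.successful_params.scale},
                "unsuccessful_params": {"loc": s.unsuccessful_params.loc, "scale": s.unsuccessful_params.scale},
                "crossover": s.crossover,
            }
            for s in config.attribute_specs
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
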