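"""Min-max normalisation of clinical attributes against a fixed reference table.

Every attribute is mapped onto [0, 1] with the affine transform

    z = (x - attr_min) / (attr_max - attr_min)

where ``attr_min``/``attr_max`` are fixed constants per attribute (the observed
extremes in the reference cohort), not re-estimated from data.  Clinical
laboratory reference intervals are pushed through the same map so they can be
drawn on the normalised spectrum.

The builtin table covers the 19 attributes of the metoprolol response analysis
(haematology, renal function, lipids, electrolytes, glucose, demographics and
haemodynamics).  The table also carries the normalised reference bounds as
published alongside the constants; :func:`verify_reference_table` recomputes
them and flags the small number of published bounds that are not reproducible
from the printed raw ranges (see its docstring).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ATTRIBUTE_ORDER",
    "AttributeSpec",
    "NormalizedCohort",
    "default_attribute_table",
    "denormalize_value",
    "normalize_value",
    "normalize_reference",
    "normalize_cohort",
    "reference_discrepancies",
    "round_half_up",
    "verify_reference_table",
    "attribute_table_to_yaml",
    "attribute_table_from_yaml",
]

#: Canonical attribute order used for CSV columns, spectra and reports.
ATTRIBUTE_ORDER: tuple[str, ...] = (
    "HCT", "HB", "PLT", "Cr", "Urea", "UA", "Cys", "TC", "LDL", "HDL",
    "K", "Na", "FPG", "Age", "Sex", "SBP", "DBP", "PP", "HR",
)


@dataclass(frozen=True)
class AttributeSpec:
    """Normalisation constants and optional clinical reference range for one attribute.

    Parameters
    ----------
    name, units
        Attribute identifier and its native measurement units.
    attr_max, attr_min
        Extremes defining the affine map onto [0, 1]; ``attr_min < attr_max``.
    ref_low, ref_high
        Clinical reference interval in native units, if one exists (Age and
        Sex have none).  Must satisfy ``attr_min <= ref_low <= ref_high <= attr_max``.
    """

    name: str
    units: str
    attr_max: float
    attr_min: float
    ref_low: float | None = None
    ref_high: float | None = None

    def __post_init__(self) -> None:
        if not self.attr_min < self.attr_max:
            raise ValueError(f"{self.name}: attr_min must be < attr_max")
        if (self.ref_low is None) != (self.ref_high is None):
            raise ValueError(f"{self.name}: reference range must set both bounds")
        if self.ref_low is not None:
            if not (self.attr_min <= self.ref_low <= self.ref_high <= self.attr_max):
                raise ValueError(f"{self.name}: reference range outside [attr_min, attr_max]")

    @property
    def span(self) -> float:
        return self.attr_max - self.attr_min

    @property
    def has_reference(self) -> bool:
        return self.ref_low is not None


# name -> (units, attr_max, attr_min, ref_low, ref_high).  The DBP reference is
# stored as (60, 90): the published normalised upper bound 0.480 back-maps to
# 90 mmHg even though the printed raw range reads "60-60"; see
# verify_reference_table, which checks against the printed raw ranges.
_BUILTIN: dict[str, tuple[str, float, float, float | None, float | None]] = {
    "HCT": ("L/L", 0.54, 0.13, 0.35, 0.45),
    "HB": ("g/L", 185.0, 44.0, 110.0, 150.0),
    "PLT": ("10^9/L", 494.0, 2.0, 100.0, 300.0),
    "Cr": ("umol/L", 1161.0, 4.0, 44.0, 132.0),
    "Urea": ("mmol/L", 34.0, 0.86, 3.1, 7.1),
    "UA": ("umol/L", 743.0, 13.4, 150.0, 420.0),
    "Cys": ("mg/L", 8.58, 0.08, 0.59, 1.03),
    "TC": ("mmol/L", 9.62, 0.21, 3.1, 5.7),
    "LDL": ("mmol/L", 6.54, 0.01, 1.5, 3.36),
    "HDL": ("mmol/L", 2.85, 0.08, 0.8, 1.6),
    "K": ("mmol/L", 6.17, 2.42, 3.5, 5.5),
    "Na": ("mmol/L", 172.2, 124.0, 135.0, 145.0),
    "FPG": ("mmol/L", 22.9, 0.76, 3.9, 6.1),
    "Age": ("years", 104.0, 7.0, None, None),
    "Sex": ("code (1=male, 2=female)", 2.0, 1.0, None, None),
    "SBP": ("mmHg", 263.0, 67.0, 90.0, 140.0),
    "DBP": ("mmHg", 168.0, 18.0, 60.0, 90.0),
    "PP": ("mmHg", 128.5, 10.0, 20.0, 60.0),
    "HR": ("1/min", 172.0, 20.0, 60.0, 100.0),
}

#: Normalised reference bounds as published with the table (3-dp values).
PUBLISHED_NORMALISED_REFERENCE: dict[str, tuple[float, float]] = {
    "HCT": (0.537, 0.780), "HB": (0.468, 0.752), "PLT": (0.200, 0.606),
    "Cr": (0.035, 0.111), "Urea": (0.070, 0.188), "UA": (0.187, 0.557),
    "Cys": (0.060, 0.112), "TC": (0.307, 0.583), "LDL": (0.228, 0.513),
    "HDL": (0.260, 0.549), "K": (0.288, 0.821), "Na": (0.228, 0.436),
    "FPG": (0.142, 0.241), "SBP": (0.117, 0.372), "DBP": (0.280, 0.480),
    "PP": (0.084, 0.422), "HR": (0.263, 0.526),
}

#: Raw reference ranges exactly as published (DBP was printed "60-60").
PUBLISHED_RAW_REFERENCE: dict[str, tuple[float, float]] = {
    name: (spec[3], spec[4]) for name, spec in _BUILTIN.items() if spec[3] is not None
}
PUBLISHED_RAW_REFERENCE["DBP"] = (60.0, 60.0)


def default_attribute_table() -> dict[str, AttributeSpec]:
    """Return the builtin 19-attribute table, keyed by name in canonical order."""
    return {
        name: AttributeSpec(name, *_BUILTIN[name])
        for name in ATTRIBUTE_ORDER
    }


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as the published table does (not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def normalize_value(x, spec: AttributeSpec, mode: str = "strict"):
    """Map raw value(s) ``x`` onto [0, 1] via the attribute's affine transform.

    ``mode="strict"`` raises :class:`ValueError` if any value leaves [0, 1]
    (the table's extremes are observed bounds, so violations signal bad input);
    ``mode="clip"`` clamps instead.  Accepts scalars or arrays.
    """
    if mode not in ("strict", "clip"):
        raise ValueError(f"unknown mode {mode!r}")
    z = (np.asarray(x, dtype=float) - spec.attr_min) / spec.span
    out_of_range = (z < 0.0) | (z > 1.0)
    if np.any(out_of_range):
        if mode == "strict":
            bad = np.asarray(x, dtype=float)[out_of_range] if z.ndim else float(x)
            raise ValueError(
                f"{spec.name}: value(s) outside [{spec.attr_min}, {spec.attr_max}]: {bad}"
            )
        z = np.clip(z, 0.0, 1.0)
    return float(z) if z.ndim == 0 else z


def denormalize_value(z, spec: AttributeSpec):
    """Inverse of :func:`normalize_value`: map [0, 1] back to native units."""
    x = spec.attr_min + np.asarray(z, dtype=float) * spec.span
    return float(x) if x.ndim == 0 else x


def normalize_reference(spec: AttributeSpec) -> tuple[float, float]:
    """Normalise the clinical reference interval of ``spec`` (unrounded).

    Raises :class:`ValueError` for attributes without a reference range
    (Age, Sex).  Use :func:`round_half_up` at 3 decimals for display.
    """
    if not spec.has_reference:
        raise ValueError(f"{spec.name} has no clinical reference range")
    return (
        normalize_value(spec.ref_low, spec),
        normalize_value(spec.ref_high, spec),
    )


@dataclass
class NormalizedCohort:
    """A patients x attributes matrix of normalised values plus outcome labels.

    ``values`` is indexed by patient id with one column per attribute, every
    entry in [0, 1]; ``labels`` is aligned to the same index with values
    ``"successful"`` / ``"unsuccessful"``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            raise ValueError("values and labels must share the same patient index")

    @property
    def attribute_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_patients(self) -> int:
        return len(self.values)

    def group_values(self, group: str) -> pd.DataFrame:
        """Rows belonging to ``group`` ('all', 'successful' or 'unsuccessful')."""
        if group == "all":
            return self.values
        if group in ("successful", "unsuccessful"):
            return self.values.loc[self.labels == group]
        raise ValueError(f"unknown group {group!r}")

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out["label"] = self.labels
        return out


def normalize_cohort(
    cohort: pd.DataFrame,
    table: Mapping[str, AttributeSpec] | None = None,
    mode: str = "strict",
) -> NormalizedCohort:
    """Normalise a cleaned, labelled cohort table into a :class:`NormalizedCohort`.

    ``cohort`` must carry the attribute columns, a ``patient_id`` column and a
    ``label`` column.  Sex (codes 1/2) maps to {0, 1} like any other attribute.
    """
    table = default_attribute_table() if table is None else table
    if "label" not in cohort.columns:
        raise ValueError("cohort must be labelled before normalisation")
    names = [c for c in cohort.columns if c in set(ATTRIBUTE_ORDER) | set(table)]
    missing = [c for c in names if c not in table]
    if missing:
        raise KeyError(f"attributes absent from the attribute table: {missing}")
    index = pd.Index(cohort["patient_id"], name="patient_id")
    values = pd.DataFrame(
        {name: normalize_value(cohort[name].to_numpy(), table[name], mode=mode) for name in names},
        index=index,
    )
    labels = pd.Series(cohort["label"].to_numpy(), index=index, name="label")
    return NormalizedCohort(values=values, labels=labels)


def verify_reference_table(
    table: Mapping[str, AttributeSpec] | None = None,
) -> pd.DataFrame:
    """Recompute the published normalised reference bounds and flag mismatches.

    For each published raw reference bound the normalised value is recomputed
    and rounded half-up to 3 decimals, then compared with the published 3-dp
    figure.  Three published bounds are not reproducible from the printed raw
    ranges under any standard rounding — Urea lower (computed 0.068 vs 0.070),
    PLT lower (0.199 vs 0.200) and DBP upper (the printed raw range "60-60"
    implies 0.280, vs the published 0.480 which back-maps to 90 mmHg) — and are
    reported with ``matches=False`` rather than silently matched.

    Returns a long-format frame with one row per (attribute, bound).
    """
    table = default_attribute_table() if table is None else table
    rows = []
    for name in table:
        if name not in PUBLISHED_RAW_REFERENCE:
            continue
        spec = table[name]
        raw = PUBLISHED_RAW_REFERENCE[name]
        published = PUBLISHED_NORMALISED_REFERENCE[name]
        for bound, raw_v, pub_v in zip(("low", "high"), raw, published):
            computed = round_half_up(normalize_value(raw_v, spec), 3)
            rows.append(
                {
                    "attribute": name,
                    "bound": bound,
                    "raw_value": raw_v,
                    "computed": computed,
                    "published": pub_v,
                    "matches": abs(computed - pub_v) < 5e-13,
                }
            )
    return pd.DataFrame(rows)


def reference_discrepancies(
    table: Mapping[str, AttributeSpec] | None = None,
) -> list[tuple[str, str]]:
    """(attribute, bound) pairs whose published normalised value is irreproducible."""
    frame = verify_reference_table(table)
    bad = frame.loc[~frame["matches"], ["attribute", "bound"]]
    return list(bad.itertuples(index=False, name=None))


def attribute_table_to_yaml(table: Mapping[str, AttributeSpec], path) -> None:
    payload = [
        {
            "name": s.name,
            "units": s.units,
            "attr_max": s.attr_max,
            "attr_min": s.attr_min,
            "ref_low": s.ref_low,
            "ref_high": s.ref_high,
        }
        for s in table.values()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def attribute_table_from_yaml(path) -> dict[str, AttributeSpec]:
    with open(path, encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    specs = [AttributeSpec(**entry) for entry in payload]
    return {s.name: s for s in specs}
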