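"""Three-way attribute categorisation and the importance-support rule.

An attribute is *drug-related* ("important") when the successful and
unsuccessful groups' distributions of its normalised values are (a) asymmetric
and (b) separated by a *breakpoint* — a value below which one outcome group
dominates and above which the other does.  Attributes fall into three
categories: symmetric; asymmetric with a breakpoint; asymmetric but with the
groups interleaved so no breakpoint exists.

Quantitatively:

* asymmetry statistic = total-variation distance between the two groups'
  binned distributions, ``0.5 * sum(|delta|)``; asymmetric iff >= ``tau``
  (default 0.10).
* breakpoint candidate = the interior bin edge maximising the absolute
  difference of the two empirical CDFs (the two-sample Kolmogorov–Smirnov
  location), ties broken toward the smallest edge.
* dominance purity = fraction of each side's probability mass belonging to
  the group that dominates that side, averaged over the two sides; a
  breakpoint is declared iff the rows are asymmetric and purity >= threshold
  (default 0.75).  Interleaved groups give purity near 0.5.

A separate support rule flags attributes whose absolute between-group mean
difference exceeds 0.05.  The two verdicts are reported side by side and are
not forced to agree (in the published reference cohort HR is important under
the breakpoint rule yet unsupported by the mean-difference rule).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedCohort, round_half_up
from .spectrum import DifferenceGrid, SpectrumGrid, build_spectrum, difference_spectrum

__all__ = [
    "AttributeClassification",
    "ClassificationParams",
    "assess_asymmetry",
    "average_difference",
    "classify_attribute",
    "classify_cohort",
    "classification_report",
    "detect_breakpoint",
    "render_classification_table",
    "supports_importance",
]


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds governing the categorisation."""

    n_bins: int = 50
    tau: float = 0.10                 # TVD threshold for asymmetry
    purity_threshold: float = 0.75    # dominance purity for a breakpoint
    mean_diff_threshold: float = 0.05  # |mean difference| support rule

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        for name in ("tau", "purity_threshold", "mean_diff_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class AttributeClassification:
    """Full per-attribute verdict with all sub-statistics."""

    attribute_name: str
    asymmetric: bool
    has_breakpoint: bool
    breakpoint: float | None
    asymmetry_stat: float
    purity: float
    mean_successful: float
    mean_unsuccessful: float
    mean_difference: float
    important: bool
    supported_by_mean_diff: bool
    degenerate_breakpoint: bool = False

    def __post_init__(self) -> None:
        if self.important and not (self.asymmetric and self.has_breakpoint):
            raise ValueError("important requires asymmetric and has_breakpoint")
        if (self.breakpoint is None) == self.has_breakpoint:
            raise ValueError("breakpoint must be present iff has_breakpoint")


def assess_asymmetry(delta_row: np.ndarray, tau: float = 0.10) -> tuple[float, bool]:
    """Total-variation distance of a signed frequency-difference row.

    Returns ``(stat, stat >= tau)``; 0 for identical distributions, 1 for
    disjoint ones.
    """
    delta_row = np.asarray(delta_row, dtype=float)
    stat = 0.5 * float(np.abs(delta_row).sum())
    return stat, stat >= tau


def detect_breakpoint(
    succ_row: np.ndarray,
    unsucc_row: np.ndarray,
    bin_edges: np.ndarray,
    purity_threshold: float = 0.75,
    tau: float = 0.10,
) -> tuple[bool, float | None, float]:
    """Locate a dominance breakpoint between two binned group distributions.

    The candidate is the interior bin edge maximising |F_s - F_u| (F being
    the cumulative frequencies), ties broken toward the smallest edge.  The
    candidate is promoted to a breakpoint iff the rows are asymmetric
    (TVD >= ``tau``) and the dominance purity at the candidate reaches
    ``purity_threshold``.  Returns ``(has_breakpoint, breakpoint, purity)``;
    the breakpoint is ``None`` unless declared.  Degenerate inputs (both
    groups concentrated identically, zero CDF difference everywhere) never
    yield a breakpoint.
    """
    succ_row = np.asarray(succ_row, dtype=float)
    unsucc_row = np.asarray(unsucc_row, dtype=float)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if succ_row.shape != unsucc_row.shape or len(bin_edges) != len(succ_row) + 1:
        raise ValueError("rows must share a shape compatible with bin_edges")

    f_s = np.cumsum(succ_row)
    f_u = np.cumsum(unsucc_row)
    # CDF difference at interior edges edges[1..B-1]
    gap = np.abs(f_s - f_u)[:-1]
    if gap.size == 0 or gap.max() <= 1e-12:
        return False, None, 0.5

    k = int(np.argmax(gap))  # argmax returns the first (smallest-edge) maximum
    candidate = float(bin_edges[k + 1])

    s_below, u_below = float(f_s[k]), float(f_u[k])
    s_above, u_above = float(succ_row.sum() - s_below), float(unsucc_row.sum() - u_below)
    succ_dominates_below = s_below > u_below

    def side_purity(dominant: float, other: float) -> float:
        total = dominant + other
        return dominant / total if total > 0 else 0.5

    if succ_dominates_below:
        purity = 0.5 * (side_purity(s_below, u_below) + side_purity(u_above, s_above))
    else:
        purity = 0.5 * (side_purity(u_below, s_below) + side_purity(s_above, u_above))

    _, asymmetric = assess_asymmetry(succ_row - unsucc_row, tau)
    has_bp = bool(asymmetric and purity >= purity_threshold)
    return has_bp, (candidate if has_bp else None), purity


def average_difference(cohort: NormalizedCohort) -> pd.DataFrame:
    """Per-attribute group means and their successful-minus-unsuccessful difference.

    Raises :class:`ValueError` when either outcome group is empty.
    """
    succ = cohort.group_values("successful")
    unsucc = cohort.group_values("unsuccessful")
    if len(succ) == 0 or len(unsucc) == 0:
        raise ValueError("both outcome groups must be non-empty")
    out = pd.DataFrame(
        {
            "mean_successful": succ.mean(axis=0),
            "mean_unsuccessful": unsucc.mean(axis=0),
        }
    )
    out["mean_difference"] = out["mean_successful"] - out["mean_unsuccessful"]
    out.index.name = "attribute"
    return out


def supports_importance(mean_difference: float, threshold: float = 0.05) -> bool:
    """True iff |mean difference| strictly exceeds ``threshold``."""
    return bool(abs(mean_difference) > threshold)


def classify_attribute(
    attribute_name: str,
    succ_row: np.ndarray,
    unsucc_row: np.ndarray,
    bin_edges: np.ndarray,
    mean_successful: float,
    mean_unsuccessful: float,
    params: ClassificationParams | None = None,
) -> AttributeClassification:
    """Combine asymmetry, breakpoint and mean-difference evidence for one attribute."""
    params = params or ClassificationParams()
    stat, asymmetric = assess_asymmetry(
        np.asarray(succ_row, float) - np.asarray(unsucc_row, float), params.tau
    )
    has_bp, bp, purity = detect_breakpoint(
        succ_row, unsucc_row, bin_edges, params.purity_threshold, params.tau
    )
    mean_diff = mean_successful - mean_unsuccessful
    # A binary attribute concentrates all mass in the outermost bins; its only
    # meaningful interior split is flagged as degenerate.
    interior = np.asarray(succ_row, float)[1:-1].sum() + np.asarray(unsucc_row, float)[1:-1].sum()
    degenerate = bool(has_bp and interior == 0.0)
    return AttributeClassification(
        attribute_name=attribute_name,
        asymmetric=bool(asymmetric),
        has_breakpoint=has_bp,
        breakpoint=bp,
        asymmetry_stat=stat,
        purity=purity,
        mean_successful=float(mean_successful),
        mean_unsuccessful=float(mean_unsuccessful),
        mean_difference=float(mean_diff),
        important=bool(asymmetric and has_bp),
        supported_by_mean_diff=supports_importance(mean_diff, params.mean_diff_threshold),
        degenerate_breakpoint=degenerate,
    )


def classify_cohort(
    cohort: NormalizedCohort, params: ClassificationParams | None = None
) -> tuple[list[AttributeClassification], dict]:
    """Classify every attribute of a normalised, labelled cohort.

    Returns the per-attribute classifications (in cohort column order) and a
    JSON-ready report that echoes all thresholds used.
    """
    params = params or ClassificationParams()
    succ = build_spectrum(cohort, "successful", params.n_bins)
    unsucc = build_spectrum(cohort, "unsuccessful", params.n_bins)
    if succ.n == 0 or unsucc.n == 0:
        raise ValueError("both outcome groups must be non-empty")
    means = average_difference(cohort)
    results = [
        classify_attribute(
            name,
            succ.frequencies[i],
            unsucc.frequencies[i],
            succ.bin_edges,
            means.loc[name, "mean_successful"],
            means.loc[name, "mean_unsuccessful"],
            params,
        )
        for i, name in enumerate(succ.attribute_names)
    ]
    report = classification_report(results, params, succ.n, unsucc.n)
    return results, report


def classification_report(
    results: list[AttributeClassification],
    params: ClassificationParams,
    n_successful: int,
    n_unsuccessful: int,
) -> dict:
    return {
        "params": asdict(params),
        "n_successful": int(n_successful),
        "n_unsuccessful": int(n_unsuccessful),
        "attributes": [asdict(r) for r in results],
    }


def render_classification_table(results: list[AttributeClassification]) -> str:
    """Plain-text verdict table: asymmetry, breakpoint (2 dp), importance, support."""
    header = (
        f"{'Attribute':<10}{'Asymmetric':<12}{'Breakpoint':<12}"
        f"{'Estimate':<10}{'MeanDiff':<10}{'Important':<11}{'|Diff|>thr':<10}"
    )
    lines = [header, "-" * len(header)]
    for r in results:
        est = "-" if r.breakpoint is None else f"{round_half_up(r.breakpoint, 2):.2f}"
        if r.degenerate_breakpoint:
            est += "*"
        lines.append(
            f"{r.attribute_name:<10}{('Yes' if r.asymmetric else 'No'):<12}"
            f"{('Yes' if r.has_breakpoint else ('/' if not r.asymmetric else 'No')):<12}"
            f"{est:<10}{r.mean_difference:>+8.4f}  "
            f"{('Yes' if r.important else 'No'):<11}"
            f"{('Yes' if r.supported_by_mean_diff else 'No'):<10}"
        )
    if any(r.degenerate_breakpoint for r in results):
        lines.append("* degenerate split of a binary attribute")
    return "\n".join(lines)


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
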