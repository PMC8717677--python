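"""Per-attribute frequency spectra and the two-group difference spectrum.

The *attribute spectrum* of a cohort is an attributes x bins grid: each
attribute's normalised values are histogrammed over B equal-width bins on
[0, 1] (default B=50, i.e. 0.02 resolution).  Bins are half-open [lo, hi)
with the final bin closed so 1.0 stays in range.  The difference spectrum
subtracts the unsuccessful group's *frequencies* from the successful group's,
bin-wise — frequencies rather than counts, because the groups differ in size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .normalize import NormalizedCohort

__all__ = ["DifferenceGrid", "SpectrumGrid", "build_spectrum", "difference_spectrum"]

GROUPS = ("all", "successful", "unsuccessful")
DEFAULT_N_BINS = 50


@dataclass
class SpectrumGrid:
    """Histogram grid for one patient group: counts and frequencies per attribute."""

    attribute_names: list[str]
    bin_edges: np.ndarray
    counts: np.ndarray
    frequencies: np.ndarray
    group: str
    n: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: attribute, bin_low, bin_high, count, frequency."""
        rows = []
        for i, name in enumerate(self.attribute_names):
            for b in range(self.n_bins):
                rows.append(
                    {
                        "attribute": name,
                        "bin_low": self.bin_edges[b],
                        "bin_high": self.bin_edges[b + 1],
                        "count": int(self.counts[i, b]),
                        "frequency": self.frequencies[i, b],
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DifferenceGrid:
    """Signed successful-minus-unsuccessful frequency differences per attribute."""

    attribute_names: list[str]
    bin_edges: np.ndarray
    delta: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.attribute_names):
            for b in range(self.n_bins):
                rows.append(
                    {
                        "attribute": name,
                        "bin_low": self.bin_edges[b],
                        "bin_high": self.bin_edges[b + 1],
                        "delta": self.delta[i, b],
                    }
                )
        return pd.DataFrame(rows)


def build_spectrum(
    cohort: NormalizedCohort, group: str = "all", n_bins: int = DEFAULT_N_BINS
) -> SpectrumGrid:
    """Histogram every attribute of ``group`` over B equal-width bins on [0, 1].

    An empty group yields an explicit all-zero grid (n=0, zero frequencies)
    rather than a division error.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    values = cohort.group_values(group)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    names = list(values.columns)
    counts = np.zeros((len(names), n_bins), dtype=np.int64)
    for i, name in enumerate(names):
        counts[i], _ = np.histogram(values[name].to_numpy(), bins=edges)
    n = len(values)
    frequencies = counts / n if n > 0 else np.zeros_like(counts, dtype=float)
    return SpectrumGrid(
        attribute_names=names,
        bin_edges=edges,
        counts=counts,
        frequencies=frequencies,
        group=group,
        n=n,
    )


def difference_spectrum(
    successful: SpectrumGrid, unsuccessful: SpectrumGrid
) -> DifferenceGrid:
    """Successful-minus-unsuccessful frequency difference, element-wise."""
    if successful.attribute_names != unsuccessful.attribute_names:
        raise ValueError("grids must share the same attributes in the same order")
    if not np.array_equal(successful.bin_edges, unsuccessful.bin_edges):
        raise ValueError("grids must share identical bin edges")
    return DifferenceGrid(
        attribute_names=list(successful.attribute_names),
        bin_edges=successful.bin_edges.copy(),
        delta=successful.frequencies - unsuccessful.frequencies,
    )
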