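"""Heatmap rendering of attribute spectra and difference spectra.

Attributes run along the x-axis, the normalised value along the y-axis, and
colour encodes frequency (or the signed frequency difference).  Group spectra
use a perceptually-uniform dark-purple-to-yellow map; difference spectra use a
diverging map with limits symmetric about zero.  Clinical reference intervals
are overlaid as two short red horizontal bars per attribute column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .normalize import AttributeSpec, normalize_reference
from .spectrum import DifferenceGrid, SpectrumGrid

__all__ = ["PlotConfig", "plot_difference", "plot_spectrum"]

REFERENCE_BAR_GID = "reference-bar"

# Fixed salt so repeated SVG renders are byte-identical.
_SVG_RC = {"svg.hashsalt": "drugspectrum"}


@dataclass(frozen=True)
class PlotConfig:
    colormap_name: str = "viridis"
    diverging_colormap_name: str = "RdBu_r"
    output_format: str = "png"
    show_reference_bars: bool = True
    dpi: int = 150

    def __post_init__(self) -> None:
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.output_format.lower() not in ("png", "svg"):
            raise ValueError("output_format must be 'png' or 'svg'")


def _render(
    matrix: np.ndarray,
    names: list[str],
    cmap: str,
    vmin: float,
    vmax: float,
    title: str,
    cbar_label: str,
) -> tuple[plt.Figure, plt.Axes]:
    n_attr = len(names)
    fig, ax = plt.subplots(figsize=(max(6.0, 0.55 * n_attr), 5.0))
    im = ax.imshow(
        matrix.T,
        origin="lower",
        aspect="auto",
        extent=(-0.5, n_attr - 0.5, 0.0, 1.0),
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
        interpolation="nearest",
    )
    ax.set_xticks(range(n_attr))
    ax.set_xticklabels(names, rotation=90)
    ax.set_ylabel("normalised value")
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label=cbar_label)
    return fig, ax


def _add_reference_bars(
    ax: plt.Axes, names: list[str], specs: Mapping[str, AttributeSpec]
) -> None:
    for j, name in enumerate(names):
        spec = specs.get(name)
        if spec is None or not spec.has_reference:
            continue
        low, high = normalize_reference(spec)
        lc = ax.hlines([low, high], j - 0.4, j + 0.4, colors="red", linewidths=1.5)
        lc.set_gid(REFERENCE_BAR_GID)


def _save(fig: plt.Figure, path, config: PlotConfig) -> None:
    fmt = config.output_format.lower()
    kwargs = {"format": fmt, "dpi": config.dpi}
    if fmt == "svg":
        kwargs["metadata"] = {"Date": None}  # strip the timestamp: reproducible bytes
    with plt.rc_context(_SVG_RC):
        fig.savefig(path, **kwargs)


def plot_spectrum(
    grid: SpectrumGrid,
    specs: Mapping[str, AttributeSpec],
    config: PlotConfig | None = None,
    path=None,
    use_counts: bool = False,
) -> plt.Figure:
    """Render one group's spectrum as a heatmap; writes ``path`` if given.

    Returns the figure (caller closes it).  ``use_counts`` switches the colour
    scale from frequencies to raw counts.
    """
    config = config or PlotConfig()
    matrix = grid.counts.astype(float) if use_counts else grid.frequencies
    fig, ax = _render(
        matrix,
        grid.attribute_names,
        config.colormap_name,
        vmin=0.0,
        vmax=float(matrix.max()) or 1.0,
        title=f"Attribute spectrum ({grid.group}, n={grid.n})",
        cbar_label="count" if use_counts else "frequency",
    )
    if config.show_reference_bars:
        _add_reference_bars(ax, grid.attribute_names, specs)
    if path is not None:
        _save(fig, path, config)
    return fig


def plot_difference(
    grid: DifferenceGrid,
    specs: Mapping[str, AttributeSpec],
    config: PlotConfig | None = None,
    path=None,
) -> plt.Figure:
    """Render the successful-minus-unsuccessful difference spectrum.

    The colour scale is diverging and symmetric about zero so equal excesses
    in either group get equal visual weight.
    """
    config = config or PlotConfig()
    limit = float(np.abs(grid.delta).max()) or 1.0
    fig, ax = _render(
        grid.delta,
        grid.attribute_names,
        config.diverging_colormap_name,
        vmin=-limit,
        vmax=limit,
        title="Difference spectrum (successful - unsuccessful)",
        cbar_label="frequency difference",
    )
    if config.show_reference_bars:
        _add_reference_bars(ax, grid.attribute_names, specs)
    if path is not None:
        _save(fig, path, config)
    return fig
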