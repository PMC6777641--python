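"""Faceted plots of colonization data with optional statistical annotation.

Four kinds are available: ``dotplot`` (facet labels at the bottom),
``dotplot2`` (facet labels on top), ``barplot`` (mean with SE whiskers) and
``boxplot`` (median, quartiles, 1.5*IQR whiskers, outlier points).  Each
facet is one variable; within a facet samples appear in sample order and
every biological replicate contributes exactly one point (dot kinds).

Figure geometry is computed first into a plain :class:`FigureDescription`
(deterministic given the dataset, the spec and the jitter seed) and only
then rendered with matplotlib; this keeps the statistics testable without
touching a rendering backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import PlotError
from .inference import annotations
from .summaries import summarize
from .tabular_io import Dataset

PLOT_KINDS = ("dotplot", "dotplot2", "barplot", "boxplot")
SAVE_FORMATS = ("pdf", "svg", "eps", "png", "jpeg")

#: Okabe-Ito colorblind-safe qualitative palette.
DEFAULT_PALETTE = ("#E69F00", "#56B4E9", "#009E73", "#F0E442",
                   "#0072B2", "#D55E00", "#CC79A7", "#999999")

_UNITS_PER_INCH = {"in": 1.0, "cm": 2.54, "mm": 25.4}


@dataclass
class PlotSpec:
    """User-facing plot options."""

    kind: str = "dotplot"
    title: str | None = None
    palette: Sequence[str] = DEFAULT_PALETTE
    annot: str = "none"  # none | asterisks | letters
    method: str = "none"
    alpha: float = 0.05
    jitter_seed: int = 42


@dataclass
class SampleGeometry:
    """Drawn elements for one sample within one facet."""

    sample: str
    x: float
    points: list[tuple[float, float]] = field(default_factory=list)
    bar_height: float | None = None
    bar_se: float | None = None
    box: dict | None = None  # median, q1, q3, whisk_lo, whisk_hi, outliers

    @property
    def top(self) -> float:
        """Highest drawn y coordinate of this sample's elements."""
        candidates = [y for _, y in self.points]
        if self.bar_height is not None:
            candidates.append(self.bar_height + (self.bar_se or 0.0))
        if self.box is not None:
            candidates.append(self.box["whisk_hi"])
            candidates.extend(self.box["outliers"])
        return max(candidates)

    @property
    def bottom(self) -> float:
        candidates = [y for _, y in self.points]
        if self.bar_height is not None:
            candidates.append(0.0)
        if self.box is not None:
            candidates.append(self.box["whisk_lo"])
            candidates.extend(self.box["outliers"])
        return min(candidates)


@dataclass
class FacetDescription:
    variable: str
    groups: list[SampleGeometry]
    annotations: list[tuple[str, float, float, str]]  # sample, x, y, mark
    ylim: tuple[float, float]


@dataclass
class FigureDescription:
    kind: str
    title: str | None
    facets: list[FacetDescription]
    samples: list[str]
    palette: list[str]
    facet_label_position: str  # "bottom" or "top"
    ylabel: str = "Colonization (%)"


def _box_stats(values: np.ndarray) -> dict:
    """Median, quartiles, whiskers at the furthest point within 1.5*IQR and
    outliers beyond."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "whisk_lo": float(inside.min()), "whisk_hi": float(inside.max()),
            "outliers": [float(v) for v in values
                         if v < lo_fence or v > hi_fence]}


def build_figure(ds: Dataset, spec: PlotSpec) -> FigureDescription:
    """Compute the complete facet geometry for a dataset and plot spec."""
    if spec.kind not in PLOT_KINDS:
        raise PlotError(f"unknown plot kind {spec.kind!r}; "
                        f"expected one of {list(PLOT_KINDS)}")
    if spec.annot not in ("none", "asterisks", "letters"):
        raise PlotError(f"unknown annotation style {spec.annot!r}")
    if spec.annot != "none" and len(ds.sample_order) < 2:
        raise PlotError("statistical annotation needs at least 2 samples")
    if not 0.0 < spec.alpha < 1.0:
        raise PlotError("alpha must lie in (0, 1)")

    summary = summarize(ds)
    per_rep = summary.per_replicate
    variables = list(summary.variables)
    samples = list(ds.sample_order)
    rng = np.random.default_rng(spec.jitter_seed)

    marks = None
    if spec.annot != "none":
        marks = annotations(ds, spec.annot, spec.method, spec.alpha).marks

    facets = []
    for v in variables:
        groups = []
        for pos, sample in enumerate(samples):
            values = per_rep.loc[per_rep["Samples"] == sample, v] \
                .to_numpy(dtype=float)
            geo = SampleGeometry(sample=sample, x=float(pos))
            if spec.kind in ("dotplot", "dotplot2"):
                jitter = rng.uniform(-0.1, 0.1, size=values.size)
                geo.points = [(float(pos + dx), float(y))
                              for dx, y in zip(jitter, values)]
            elif spec.kind == "barplot":
                row = summary.per_sample[summary.per_sample["Samples"] == sample]
                geo.bar_height = float(row[v].iloc[0])
                se = float(row[f"{v}_se"].iloc[0])
                geo.bar_se = 0.0 if np.isnan(se) else se
            else:  # boxplot
                geo.box = _box_stats(values)
            groups.append(geo)
        lo = min(g.bottom for g in groups)
        hi = max(g.top for g in groups)
        span = (hi - lo) or 1.0
        annots = []
        if marks is not None:
            for geo in groups:
                mark = marks[v].get(geo.sample, "")
                if mark:
                    annots.append((geo.sample, geo.x,
                                   geo.top + 0.05 * span, mark))
            hi = max([hi] + [y for _, _, y, _ in annots])
        pad = 0.05 * span
        facets.append(FacetDescription(v, groups, annots,
                                       (min(lo, 0.0) - pad, hi + pad)))
    label_pos = "bottom" if spec.kind == "dotplot" else "top"
    palette = list(spec.palette) if spec.palette else list(DEFAULT_PALETTE)
    return FigureDescription(spec.kind, spec.title, facets, samples,
                             palette, label_pos)


def render(desc: FigureDescription):
    """Render a FigureDescription into a matplotlib Figure."""
    import matplotlib.pyplot as plt

    n = len(desc.facets)
    fig, axes = plt.subplots(1, n, sharey=True, squeeze=False,
                             figsize=(max(2.2 * n, 4), 4.5),
                             layout="constrained")
    axes = axes[0]
    colors = [desc.palette[i % len(desc.palette)]
              for i in range(len(desc.samples))]
    for ax, facet in zip(axes, desc.facets):
        for color, geo in zip(colors, facet.groups):
            if geo.points:
                xs, ys = zip(*geo.points)
                ax.scatter(xs, ys, color=color, s=30, zorder=3,
                           edgecolors="none")
            if geo.bar_height is not None:
                ax.bar(geo.x, geo.bar_height, width=0.7, color=color,
                       yerr=geo.bar_se, capsize=3, zorder=2)
            if geo.box is not None:
                box = geo.box
                ax.bxp([{"med": box["median"], "q1": box["q1"],
                         "q3": box["q3"], "whislo": box["whisk_lo"],
                         "whishi": box["whisk_hi"], "fliers": box["outliers"]}],
                       positions=[geo.x], widths=0.6, showfliers=True,
                       patch_artist=True,
                       boxprops={"facecolor": color, "alpha": 0.7})
        for _, x, y, mark in facet.annotations:
            ax.text(x, y, mark, ha="center", va="bottom", fontsize=11)
        ax.set_xticks(range(len(desc.samples)))
        ax.set_xticklabels(desc.samples, rotation=45, ha="right")
        ax.set_ylim(*facet.ylim)
        if desc.facet_label_position == "bottom":
            ax.set_xlabel(facet.variable)
        else:
            ax.set_title(facet.variable, fontsize=10)
    axes[0].set_ylabel(desc.ylabel)
    if desc.title:
        fig.suptitle(desc.title, ha="center")
    return fig


def plot(ds: Dataset, spec: PlotSpec | None = None, **kwargs):
    """Build and render a figure in one step; kwargs override PlotSpec fields."""
    if spec is None:
        spec = PlotSpec(**kwargs)
    return render(build_figure(ds, spec))


def save_figure(fig, path: str, width: float = 7.0, height: float = 5.0,
                units: str = "in", dpi: int = 300) -> str:
    """Save a figure at the requested physical size and resolution.

    The format is implied by the file extension (pdf, svg, eps, png, jpeg);
    width and height are interpreted in ``units`` (cm, in or mm).
    """
    ext = path.rsplit(".", 1)[-1].lower() if "." in path else ""
    if ext not in SAVE_FORMATS:
        raise PlotError(f"unsupported figure format {ext!r}; "
                        f"supported: {list(SAVE_FORMATS)}")
    if units not in _UNITS_PER_INCH:
        raise PlotError(f"unknown units {units!r}; expected cm, in or mm")
    factor = _UNITS_PER_INCH[units]
    fig.set_size_inches(width / factor, height / factor)
    fig.savefig(path, dpi=dpi, format=ext)
    return path
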