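"""Replicate-aware summaries of colonization data.

Rows sharing the same (sample, replicate) labels are technical replicates of
one biological replicate: for grid data they are collapsed by unweighted
arithmetic mean, for Trouvelot data they are pooled as root fragments before
index computation.  The per-sample table then reports mean and standard
error (s / sqrt(n), with s the n-1 sample standard deviation) across
biological replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AMQuantError
from .tabular_io import Dataset
from .trouvelot import indices_per_replicate


@dataclass
class SummaryTable:
    """The two summary tables produced from one dataset.

    ``per_replicate`` has one row per biological replicate; ``per_sample``
    one row per sample in sample order, with a ``<var>`` mean column per
    variable followed by the ``<var>_se`` standard errors.  SE is NaN (not
    zero) for samples with a single biological replicate.
    """

    per_replicate: pd.DataFrame
    per_sample: pd.DataFrame
    variables: tuple[str, ...]


def collapse_technical(ds: Dataset) -> pd.DataFrame:
    """Collapse technical replicates into one row per biological replicate.

    Grid rows sharing (sample, replicate) — and ``trt`` if present — are
    averaged per variable; Trouvelot rows are pooled as fragments and
    converted to indices.  Output rows follow sample order, then replicate
    first-appearance order within each sample.
    """
    if not ds.records:
        raise AMQuantError("empty dataset")
    if ds.scoring_type == "trouvelot":
        return indices_per_replicate(ds)
    variables = ds.variables
    groups: dict[tuple, list] = {}
    rep_order: dict[str, list[tuple]] = {s: [] for s in ds.sample_order}
    for rec in ds.records:
        key = (rec.sample, rec.replicate, rec.trt)
        if key not in groups:
            rep_order[rec.sample].append(key)
        groups.setdefault(key, []).append(rec.values)
    rows = []
    for sample in ds.sample_order:
        for key in rep_order[sample]:
            _, replicate, trt = key
            row = {"Samples": sample, "Replicates": replicate}
            if ds.has_trt:
                row["trt"] = trt
            for v in variables:
                vals = [rv[v] for rv in groups[key] if v in rv]
                row[v] = float(np.mean(vals))
            rows.append(row)
    return pd.DataFrame(rows)


def summarize(ds: Dataset) -> SummaryTable:
    """Produce the per-replicate and per-sample (mean ± SE) summary tables."""
    per_replicate = collapse_technical(ds)
    variables = tuple(v for v in per_replicate.columns
                      if v not in ("Samples", "Replicates", "trt"))
    rows = []
    for sample in ds.sample_order:
        block = per_replicate[per_replicate["Samples"] == sample]
        row: dict[str, object] = {"Samples": sample}
        for v in variables:
            vals = block[v].to_numpy(dtype=float)
            row[v] = float(np.mean(vals))
        for v in variables:
            vals = block[v].to_numpy(dtype=float)
            n = len(vals)
            row[f"{v}_se"] = (float(np.std(vals, ddof=1) / math.sqrt(n))
                              if n > 1 else float("nan"))
        rows.append(row)
    per_sample = pd.DataFrame(rows)
    return SummaryTable(per_replicate, per_sample, variables)
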