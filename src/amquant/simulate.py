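"""Synthetic colonization datasets for both scoring dialects.

All generators are deterministic given their seed; seeds are mandatory so
no hidden global random state is involved.  Every simulated dataset passes
the validators of :mod:`amquant.tabular_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import SimulationError
from .tabular_io import Dataset, GridRecord, TrouvelotRecord, GRID_VARIABLES
from .trouvelot import TrouvelotScore, format_score


@dataclass
class GridSimParams:
    """Parameters for gridline-intersect simulation.

    ``samples`` maps each sample label to its per-variable mean percentage;
    values are drawn from a normal truncated to [0, 100].
    """

    samples: Mapping[str, Mapping[str, float]]
    n_replicates: int = 7
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")
        if not self.samples:
            raise SimulationError("at least one sample is required")
        variable_sets = set()
        for label, means in self.samples.items():
            variable_sets.add(frozenset(means))
            for var, mu in means.items():
                if var not in GRID_VARIABLES:
                    raise SimulationError(f"unknown grid variable {var!r}")
                if not 0.0 <= float(mu) <= 100.0:
                    raise SimulationError(
                        f"mean {mu!r} for {label}/{var} outside [0, 100]")
        if len(variable_sets) > 1:
            raise SimulationError("all samples must declare the same variables")


def _replicate_labels(n: int) -> list[str]:
    """A, B, ..., Z, R27, R28, ..."""
    letters = [chr(ord("A") + i) for i in range(min(n, 26))]
    return letters + [f"R{i + 1}" for i in range(26, n)]


def simulate_grid(params: GridSimParams) -> Dataset:
    """Draw a grid dataset: truncated-normal replicate values per sample."""
    rng = np.random.default_rng(params.seed)
    records = []
    sample_order = list(params.samples)
    for sample in sample_order:
        means = params.samples[sample]
        for replicate in _replicate_labels(params.n_replicates):
            values = {}
            for var in GRID_VARIABLES:
                if var not in means:
                    continue
                mu = float(means[var])
                if params.noise_sd == 0:
                    values[var] = mu
                else:
                    a = (0.0 - mu) / params.noise_sd
                    b = (100.0 - mu) / params.noise_sd
                    values[var] = float(stats.truncnorm.rvs(
                        a, b, loc=mu, scale=params.noise_sd, random_state=rng))
            records.append(GridRecord(sample, replicate, values))
    return Dataset("grid", records, sample_order)


@dataclass
class TrouvelotSimParams:
    """Parameters for Trouvelot-score simulation.

    ``samples`` maps each label to a dict with ``class_probs`` (length 6,
    over mycorrhization classes 0-5) and ``arb_probs`` (length 4, arbuscule
    classes A0-A3, used for colonized fragments).
    """

    samples: Mapping[str, Mapping[str, Sequence[float]]]
    fragments_per_replicate: int = 30
    replicates_per_sample: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.fragments_per_replicate < 1 or self.replicates_per_sample < 1:
            raise SimulationError("fragment and replicate counts must be >= 1")
        if not self.samples:
            raise SimulationError("at least one sample is required")
        for label, cfg in self.samples.items():
            cp = np.asarray(cfg["class_probs"], dtype=float)
            ap = np.asarray(cfg["arb_probs"], dtype=float)
            if cp.shape != (6,) or ap.shape != (4,):
                raise SimulationError(
                    f"{label}: class_probs must have length 6 and arb_probs 4")
            for name, p in (("class_probs", cp), ("arb_probs", ap)):
                if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                    raise SimulationError(
                        f"{label}: {name} must be non-negative and sum to 1")


def simulate_trouvelot(params: TrouvelotSimParams) -> Dataset:
    """Draw a trouvelot dataset of per-fragment score codes."""
    rng = np.random.default_rng(params.seed)
    records = []
    sample_order = list(params.samples)
    for sample in sample_order:
        cfg = params.samples[sample]
        class_probs = np.asarray(cfg["class_probs"], dtype=float)
        arb_probs = np.asarray(cfg["arb_probs"], dtype=float)
        for rep in range(1, params.replicates_per_sample + 1):
            classes = rng.choice(6, size=params.fragments_per_replicate,
                                 p=class_probs)
            arbs = rng.choice(4, size=params.fragments_per_replicate,
                              p=arb_probs)
            for c, a in zip(classes, arbs):
                score = TrouvelotScore(int(c), int(a) if c > 0 else 0)
                records.append(TrouvelotRecord(sample, str(rep),
                                               format_score(score)))
    return Dataset("trouvelot", records, sample_order)
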