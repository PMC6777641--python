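"""Trouvelot score parsing and colonization index computation.

Each root fragment is scored with a mycorrhization class 0-5 (density and
coverage of colonization) and, when colonized, an arbuscule class A0-A3,
giving codes like ``3A2`` or the bare ``0`` for an uncolonized fragment.

From the per-replicate class tallies five indices are computed:

* ``F``  — frequency of mycorrhiza in the root system (%)
* ``M``  — intensity of colonization in the root system (%)
* ``m``  — intensity of colonization within colonized fragments (%)
* ``a``  — arbuscule abundance in colonized parts (%)
* ``A``  — arbuscule abundance in the root system (%), ``A = a*M/100``

The class-intensity weights (1, 5, 30, 70, 95 for classes 1-5) and the
arbuscule weights (10, 50, 100 for A1-A3) follow the conventional
implementation of the Trouvelot method (the Mycocalc convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ScoreError
from .tabular_io import Dataset, TROUVELOT_VARIABLES

#: Intensity contribution of each mycorrhization class.
MYC_WEIGHTS = np.array([0.0, 1.0, 5.0, 30.0, 70.0, 95.0])

#: Relative arbuscule abundance factor of each arbuscule class (A0..A3).
ARB_FACTORS = np.array([0.0, 10.0, 50.0, 100.0])

_SCORE_RE = re.compile(r"^(?:0|([1-5])A([0-3]))$", re.IGNORECASE)


@dataclass(frozen=True)
class TrouvelotScore:
    """A parsed score code: mycorrhization class 0-5, arbuscule class 0-3."""

    myc_class: int
    arb_class: int

    def __post_init__(self):
        if not 0 <= self.myc_class <= 5:
            raise ScoreError(f"mycorrhization class {self.myc_class} out of range 0-5")
        if not 0 <= self.arb_class <= 3:
            raise ScoreError(f"arbuscule class {self.arb_class} out of range 0-3")
        if self.myc_class == 0 and self.arb_class != 0:
            raise ScoreError("an uncolonized fragment cannot carry arbuscules")


def parse_score(code: str) -> TrouvelotScore:
    """Parse a score code (``"0"`` or ``"<c>A<a>"``), case-insensitively.

    >>> parse_score("3A3")
    TrouvelotScore(myc_class=3, arb_class=3)
    """
    text = str(code).strip()
    match = _SCORE_RE.match(text)
    if not match:
        raise ScoreError(f"invalid score code {code!r}; expected '0' or "
                         "'<class>A<arbuscules>' with class 1-5 and arbuscules 0-3")
    if match.group(1) is None:
        return TrouvelotScore(0, 0)
    return TrouvelotScore(int(match.group(1)), int(match.group(2)))


def format_score(score: TrouvelotScore) -> str:
    """Canonical text form of a score; inverse of :func:`parse_score`."""
    if score.myc_class == 0:
        return "0"
    return f"{score.myc_class}A{score.arb_class}"


@dataclass
class ClassCounts:
    """Fragment tallies for one biological replicate.

    ``joint[c, a]`` counts fragments of mycorrhization class ``c`` and
    arbuscule class ``a``.
    """

    joint: np.ndarray  # shape (6, 4), integer counts

    @property
    def N(self) -> int:
        return int(self.joint.sum())

    @property
    def n(self) -> np.ndarray:
        """Marginal counts per mycorrhization class (length 6)."""
        return self.joint.sum(axis=1)

    @property
    def n0(self) -> int:
        return int(self.n[0])


def tally_classes(scores: Sequence[TrouvelotScore]) -> ClassCounts:
    """Tally a non-empty sequence of parsed scores into joint class counts."""
    if len(scores) == 0:
        raise ScoreError("cannot tally an empty fragment list")
    joint = np.zeros((6, 4), dtype=int)
    for s in scores:
        joint[s.myc_class, s.arb_class] += 1
    return ClassCounts(joint)


@dataclass(frozen=True)
class TrouvelotIndices:
    """The five colonization indices, all percentages in [0, 100]."""

    F: float
    M: float
    m: float
    a: float
    A: float

    def as_dict(self) -> dict[str, float]:
        return {"F": self.F, "M": self.M, "m": self.m, "a": self.a, "A": self.A}


def compute_indices(counts: ClassCounts) -> TrouvelotIndices:
    """Compute F, M, m, a, A from fragment class counts.

    With ``N`` fragments of which ``n0`` are uncolonized and weights ``w``::

        F = 100 * (N - n0) / N
        M = sum_c w[c] * n[c] / N
        m = M * N / (N - n0)                     (0 when all uncolonized)
        mA_j = sum_c w[c] * n[c, j] / (N - n0) * 100 / m    for j = 1..3
        a = (100 * mA3 + 50 * mA2 + 10 * mA1) / 100
        A = a * M / 100
    """
    N = counts.N
    if N < 1:
        raise ScoreError("index computation needs at least one fragment")
    n = counts.n
    n0 = counts.n0
    F = 100.0 * (N - n0) / N
    M = float(MYC_WEIGHTS @ n) / N
    if n0 < N:
        m = M * N / (N - n0)
    else:
        m = 0.0
    if m > 0:
        # per-arbuscule-class intensity within colonized fragments
        mA = (MYC_WEIGHTS @ counts.joint) / (N - n0) * 100.0 / m  # length 4
        a = float(ARB_FACTORS @ mA) / 100.0
    else:
        a = 0.0
    A = a * M / 100.0
    return TrouvelotIndices(F, M, m, a, A)


def indices_from_codes(codes: Iterable[str]) -> TrouvelotIndices:
    """Convenience: parse, tally and compute indices for raw score codes."""
    return compute_indices(tally_classes([parse_score(c) for c in codes]))


def indices_per_replicate(ds: Dataset) -> pd.DataFrame:
    """Compute indices for every biological replicate of a trouvelot Dataset.

    All rows sharing (sample, replicate) — and ``trt``, when that factor is
    present — are pooled as fragments of one biological replicate.  Rows are
    ordered by sample first-appearance order, then replicate first-appearance
    within each sample.
    """
    if ds.scoring_type != "trouvelot":
        raise ScoreError("indices_per_replicate requires a trouvelot dataset")
    if not ds.records:
        raise ScoreError("empty dataset")
    groups: dict[tuple, list[TrouvelotScore]] = {}
    rep_order: dict[str, list[tuple]] = {s: [] for s in ds.sample_order}
    for rec in ds.records:
        key = (rec.sample, rec.replicate, rec.trt)
        if key not in groups:
            rep_order[rec.sample].append(key)
        groups.setdefault(key, []).append(parse_score(rec.scoring))
    rows = []
    for sample in ds.sample_order:
        for key in rep_order[sample]:
            _, replicate, trt = key
            idx = compute_indices(tally_classes(groups[key]))
            row = {"Samples": sample, "Replicates": replicate}
            if ds.has_trt:
                row["trt"] = trt
            row.update({v: getattr(idx, v) for v in TROUVELOT_VARIABLES})
            rows.append(row)
    return pd.DataFrame(rows)
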