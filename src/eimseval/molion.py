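"""Molecular-ion abundance accuracy: predicted vs experimental M+ intensity.

The mass-weighted dot product is dominated by the heaviest ions, so a
mispredicted molecular-ion (M+) abundance is the single most damaging error
a predicted EI spectrum can carry.  This module extracts the M+ relative
abundance (percent of base peak, peak at m/z == nominal MW, exact integer
match, no M+1 isotope handling), takes the signed difference
``pred - exp`` in percentage points, classifies each prediction as accurate
/ underestimated / overestimated within a symmetric window (±2 or ±10
points), and summarises per structural subclass by the mean of absolute
differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import groupby

from .spectral_io import Spectrum

__all__ = [
    "MolIonComparison",
    "ClassSummary",
    "molecular_ion_abundance",
    "compare_molecular_ions",
    "classify_prediction",
    "class_summary",
]


@dataclass(frozen=True)
class MolIonComparison:
    """Experimental vs predicted molecular-ion abundance for one compound."""

    mol_id: str
    nominal_mw: int
    exp_abundance: float
    pred_abundance: float
    subclass: str = "unclassified"
    classification: str | None = None
    flags: frozenset[str] = frozenset()

    @property
    def signed_diff(self) -> float:
        """pred − exp, percentage points of base-peak-relative abundance."""
        return self.pred_abundance - self.exp_abundance


@dataclass(frozen=True)
class ClassSummary:
    """Per-subclass accuracy summary of molecular-ion predictions."""

    subclass: str
    n: int
    mean_abs_diff: float
    n_under: int
    n_over: int
    n_accurate: int


def molecular_ion_abundance(s: Spectrum) -> float:
    """Relative abundance (percent of base peak) of the peak at the nominal MW.

    Returns 0 when the molecular ion is absent; requires ``nominal_mw``.
    """
    if s.nominal_mw is None:
        raise ValueError(f"spectrum {s.id!r} has no nominal molecular weight")
    p = s.peak_at(float(s.nominal_mw))
    return p.intensity if p is not None else 0.0


def compare_molecular_ions(pred: Spectrum, exp: Spectrum) -> MolIonComparison:
    """Signed molecular-ion abundance difference (pred − exp) for one pair."""
    if pred.nominal_mw != exp.nominal_mw:
        raise ValueError(
            f"molecular weight mismatch: {pred.id!r} MW {pred.nominal_mw} vs "
            f"{exp.id!r} MW {exp.nominal_mw}"
        )
    return MolIonComparison(
        mol_id=exp.id,
        nominal_mw=exp.nominal_mw,
        exp_abundance=molecular_ion_abundance(exp),
        pred_abundance=molecular_ion_abundance(pred),
        subclass=exp.subclass,
    )


def classify_prediction(c: MolIonComparison, window_pct: float = 2.0) -> str:
    """Accurate within ±window, else under/overestimated by its sign."""
    if window_pct <= 0:
        raise ValueError("window must be positive")
    if abs(c.signed_diff) <= window_pct:
        return "accurate"
    return "underestimated" if c.signed_diff < 0 else "overestimated"


def _round_half_up_1dp(x: float) -> float:
    return math.floor(x * 10 + 0.5) / 10


def class_summary(
    comparisons: list[MolIonComparison], window_pct: float = 2.0
) -> list[ClassSummary]:
    """Per-subclass mean absolute difference and accuracy counts.

    The mean absolute difference is reported to one decimal (half-up);
    classes appear in first-seen order and empty classes are omitted.
    """
    order: list[str] = []
    for c in comparisons:
        if c.subclass not in order:
            order.append(c.subclass)
    grouped = {k: list(g) for k, g in groupby(
        sorted(comparisons, key=lambda c: order.index(c.subclass)),
        key=lambda c: c.subclass,
    )}
    out = []
    for subclass in order:
        rows = grouped[subclass]
        labels = [classify_prediction(c, window_pct) for c in rows]
        out.append(
            ClassSummary(
                subclass=subclass,
                n=len(rows),
                mean_abs_diff=_round_half_up_1dp(
                    sum(abs(c.signed_diff) for c in rows) / len(rows)
                ),
                n_under=labels.count("underestimated"),
                n_over=labels.count("overestimated"),
                n_accurate=labels.count("accurate"),
            )
        )
    return out
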