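"""Cosine and mass-weighted dot-product spectral similarity on the 0-1000 scale.

The weighted dot product (Wdot) is the Stein-Scott match factor used by EI
library search engines: each peak's intensity is re-weighted as

    W = intensity**m * mz**n      (m = 0.6, n = 3.0 by default)

and the score is the cosine of the two weighted intensity vectors formed
over the *union* of the spectra's m/z values, scaled by A = 1000.  The mass
weighting emphasises high-m/z ions, in particular the molecular ion, which
is why Wdot usually discriminates isomeric small molecules better than a
plain cosine.  The unweighted cosine score uses the same construction with
raw intensities.

Peak matching is exact integer m/z equality after nominal binning; there is
no tolerance window, matching the unit-mass resolution of classic EI
library spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral_io import Peak, Spectrum, SpectrumLibrary

__all__ = [
    "SimilarityWeights",
    "SimilarityScore",
    "BANDING_SCHEMES",
    "align_union",
    "weighted_intensity",
    "cosine_score",
    "wdot_score",
    "score_band",
    "score_pair",
    "similarity_matrix",
]


@dataclass(frozen=True)
class SimilarityWeights:
    """Exponents and scale of the weighted dot product.

    ``intensity_exponent`` (m) and ``mass_exponent`` (n) default to the
    canonical 0.6 and 3.0; ``scale_a`` is the output scale (1000).
    """

    intensity_exponent: float = 0.6
    mass_exponent: float = 3.0
    scale_a: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.intensity_exponent, self.mass_exponent, self.scale_a) <= 0:
            raise ValueError("similarity weights must be strictly positive")


DEFAULT_WEIGHTS = SimilarityWeights()

#: Banding schemes mapping a score to a quality label.  ``fig_bands`` is the
#: scheme used for class colouring (>800 excellent, >600 good, >400 fair,
#: otherwise poor); ``classic`` is the coarser library-search rule of thumb
#: (>850 good, >600 moderate, otherwise poor).  Thresholds are exclusive:
#: a score must strictly exceed a threshold to enter the higher band.
BANDING_SCHEMES: dict[str, tuple[tuple[float, str], ...]] = {
    "fig_bands": ((800.0, "excellent"), (600.0, "good"), (400.0, "fair"), (-np.inf, "poor")),
    "classic": ((850.0, "good"), (600.0, "moderate"), (-np.inf, "poor")),
}


def align_union(a: Spectrum, b: Spectrum) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair the two spectra's intensities over the union of their m/z values.

    Returns ``(mz, ia, ib)`` sorted by ascending m/z, with intensity 0 where
    a spectrum has no peak at that m/z.
    """
    mz_a = np.asarray(a.mz, dtype=float)
    mz_b = np.asarray(b.mz, dtype=float)
    union = np.union1d(mz_a, mz_b)
    ia = np.zeros(union.shape)
    ib = np.zeros(union.shape)
    ia[np.searchsorted(union, mz_a)] = a.intensities
    ib[np.searchsorted(union, mz_b)] = b.intensities
    return union, ia, ib


def weighted_intensity(p: Peak, w: SimilarityWeights = DEFAULT_WEIGHTS) -> float:
    """Stein-Scott per-peak weight ``intensity**m * mz**n`` (0 for intensity 0)."""
    if p.intensity == 0:
        return 0.0
    return p.intensity**w.intensity_exponent * p.mz**w.mass_exponent


def _scaled_cosine(va: np.ndarray, vb: np.ndarray, scale_a: float) -> float:
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cannot score an empty (all-zero) spectrum")
    ratio = np.dot(va, vb) / (na * nb)
    # snap float round-off so proportional vectors score exactly scale_a
    if abs(ratio - 1.0) < 1e-12:
        ratio = 1.0
    return float(min(ratio, 1.0) * scale_a)


def cosine_score(a: Spectrum, b: Spectrum, w: SimilarityWeights = DEFAULT_WEIGHTS) -> float:
    """Unweighted cosine similarity of the intensity vectors, scaled to 0-1000."""
    _, ia, ib = align_union(a, b)
    return _scaled_cosine(ia, ib, w.scale_a)


def wdot_score(a: Spectrum, b: Spectrum, w: SimilarityWeights = DEFAULT_WEIGHTS) -> float:
    """Mass-weighted dot-product similarity, scaled to 0-1000.

    Symmetric in its arguments, invariant to overall intensity rescaling of
    either spectrum, and exactly ``scale_a`` iff the weighted vectors are
    proportional (in particular for identical spectra).
    """
    mz, ia, ib = align_union(a, b)
    mass_w = mz**w.mass_exponent
    va = ia**w.intensity_exponent * mass_w
    vb = ib**w.intensity_exponent * mass_w
    return _scaled_cosine(va, vb, w.scale_a)


def score_band(score: float, scheme: str = "fig_bands", scale_a: float = 1000.0) -> str:
    """Map a similarity score to its quality band label."""
    if not 0 <= score <= scale_a:
        raise ValueError(f"score {score} outside [0, {scale_a}]")
    for threshold, label in BANDING_SCHEMES[scheme]:
        if score > threshold:
            return label
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class SimilarityScore:
    """Cosine and Wdot values for one spectrum pair, with the Wdot band."""

    cosine: float
    wdot: float
    band: str

    def rounded(self) -> tuple[int, int]:
        """Integer display values (scores are carried at full precision)."""
        return round(self.cosine), round(self.wdot)


def score_pair(
    a: Spectrum,
    b: Spectrum,
    w: SimilarityWeights = DEFAULT_WEIGHTS,
    scheme: str = "fig_bands",
) -> SimilarityScore:
    wd = wdot_score(a, b, w)
    return SimilarityScore(
        cosine=cosine_score(a, b, w), wdot=wd, band=score_band(wd, scheme, w.scale_a)
    )


# --- fast path for many-vs-many scoring -----------------------------------

def _weighted_vector(s: Spectrum, w: SimilarityWeights, weighted: bool) -> tuple[np.ndarray, np.ndarray]:
    mz = np.asarray(s.mz, dtype=float)
    inten = np.asarray(s.intensities, dtype=float)
    v = inten**w.intensity_exponent * mz**w.mass_exponent if weighted else inten
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError(f"spectrum {s.id!r} has no nonzero peaks")
    return mz, v / norm


def _pair_from_vectors(
    a: tuple[np.ndarray, np.ndarray], b: tuple[np.ndarray, np.ndarray], scale_a: float
) -> float:
    # zeros off the intersection contribute nothing to the dot product
    mz_a, va = a
    mz_b, vb = b
    common, idx_a, idx_b = np.intersect1d(mz_a, mz_b, return_indices=True)
    if common.size == 0:
        return 0.0
    ratio = np.dot(va[idx_a], vb[idx_b])
    if abs(ratio - 1.0) < 1e-12:
        ratio = 1.0
    return float(min(ratio, 1.0) * scale_a)


def similarity_matrix(
    rows: SpectrumLibrary,
    cols: SpectrumLibrary,
    w: SimilarityWeights = DEFAULT_WEIGHTS,
    metric: str = "wdot",
) -> pd.DataFrame:
    """All-pairs similarity scores as a DataFrame indexed by spectrum ids.

    ``metric`` is ``"wdot"`` or ``"cosine"``.  A self-comparison
    (``rows is cols`` entrywise) has ``scale_a`` on the diagonal, and
    swapping the two libraries transposes the matrix.
    """
    if metric not in ("wdot", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("similarity_matrix requires non-empty libraries")
    weighted = metric == "wdot"
    try:
        row_vecs = [_weighted_vector(s, w, weighted) for s in rows]
        col_vecs = [_weighted_vector(s, w, weighted) for s in cols]
    except ValueError as exc:
        raise ValueError(f"similarity_matrix: {exc}") from exc
    out = np.empty((len(rows), len(cols)))
    for i, rv in enumerate(row_vecs):
        for j, cv in enumerate(col_vecs):
            out[i, j] = _pair_from_vectors(rv, cv, w.scale_a)
    return pd.DataFrame(out, index=rows.ids(), columns=cols.ids())
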