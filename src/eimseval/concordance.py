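"""Peak-level concordance between predicted and experimental spectra.

Similarity scores blend peak presence and abundance; the Jaccard index
isolates presence.  After an abundance threshold (default 2% of base peak,
raised to 20% to focus on the dominant fragmentation channels), the two
spectra are reduced to m/z sets and compared:

    matched  = |predicted ∩ experimental|
    missing  = |experimental \\ predicted|   (ions the prediction failed to make)
    extra    = |predicted \\ experimental|   (falsely predicted new ions)
    jaccard  = matched / (matched + missing + extra)
    pct_matched = 100 * matched / (matched + missing)

Intensities do not enter beyond the threshold: Jaccard deliberately ignores
ion abundances.  The threshold is applied to both spectra so that "extra"
counts only ions predicted above the same abundance floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .spectral_io import Spectrum

__all__ = [
    "ConcordanceResult",
    "apply_abundance_threshold",
    "concordance",
    "concordance_summary",
    "spearman_correlation",
]


@dataclass(frozen=True)
class ConcordanceResult:
    """Set comparison of one predicted/experimental spectrum pair."""

    threshold_pct: float
    matched: int
    missing: int
    extra: int

    @property
    def jaccard(self) -> float:
        union = self.matched + self.missing + self.extra
        return self.matched / union if union else 0.0

    @property
    def pct_matched(self) -> float:
        """Percent of experimental peaks that the prediction reproduces."""
        n_exp = self.matched + self.missing
        return 100.0 * self.matched / n_exp if n_exp else 0.0


def apply_abundance_threshold(s: Spectrum, threshold_pct: float) -> Spectrum:
    """Drop peaks below ``threshold_pct`` percent of base peak.

    The base peak itself is always retained.  Requires a normalized spectrum
    (base peak 100); a threshold >= 100 is rejected as degenerate.
    """
    if threshold_pct >= 100:
        raise ValueError(f"abundance threshold {threshold_pct} leaves no spectrum")
    base = s.base_peak
    peaks = tuple(p for p in s.peaks if p.intensity >= threshold_pct or p is base)
    return s.with_peaks(peaks)


def concordance(
    predicted: Spectrum,
    experimental: Spectrum,
    threshold_pct: float = 2.0,
    include_molecular_ion: bool = True,
) -> ConcordanceResult:
    """Thresholded m/z set comparison of a predicted vs experimental spectrum.

    Both spectra must be nominal-binned and normalized.  With
    ``include_molecular_ion=False`` the peak at each spectrum's nominal
    molecular weight is excluded, restricting the comparison to fragments.
    """
    pred_set = {p.mz for p in apply_abundance_threshold(predicted, threshold_pct).peaks}
    exp_set = {p.mz for p in apply_abundance_threshold(experimental, threshold_pct).peaks}
    if not include_molecular_ion:
        pred_set.discard(float(predicted.nominal_mw))
        exp_set.discard(float(experimental.nominal_mw))
    if not exp_set:
        raise ValueError(
            f"experimental spectrum {experimental.id!r} empty after {threshold_pct}% threshold"
        )
    return ConcordanceResult(
        threshold_pct=threshold_pct,
        matched=len(pred_set & exp_set),
        missing=len(exp_set - pred_set),
        extra=len(pred_set - exp_set),
    )


def concordance_summary(
    pairs: list[tuple[Spectrum, Spectrum, str]],
    threshold_pct: float = 2.0,
    include_molecular_ion: bool = True,
) -> pd.DataFrame:
    """Per-pair concordance table with per-subclass and overall mean rows.

    ``pairs`` holds ``(predicted, experimental, subclass)`` triples.  The
    returned frame has one row per pair (columns ``id``, ``subclass``,
    ``matched``, ``missing``, ``extra``, ``pct_matched``, ``jaccard``) and
    exposes per-subclass means and the unweighted overall means through
    ``df.attrs["per_subclass"]`` and ``df.attrs["overall"]``.
    """
    if not pairs:
        raise ValueError("concordance_summary needs at least one pair")
    rows = []
    for pred, exp, subclass in pairs:
        r = concordance(pred, exp, threshold_pct, include_molecular_ion)
        rows.append(
            {
                "id": exp.id,
                "subclass": subclass,
                "matched": r.matched,
                "missing": r.missing,
                "extra": r.extra,
                "pct_matched": r.pct_matched,
                "jaccard": r.jaccard,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["per_subclass"] = (
        df.groupby("subclass")[["pct_matched", "extra", "jaccard"]].mean()
    )
    df.attrs["overall"] = df[["pct_matched", "extra", "jaccard"]].mean()
    return df


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (tie-averaged ranks) and two-sided p-value."""
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman_correlation needs equal-length inputs of size >= 3")
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("rank correlation undefined for a constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
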