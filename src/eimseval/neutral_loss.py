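"""Neutral-loss annotation of unit-mass EI spectra.

Purines and pyrimidines fragment through a handful of characteristic
neutral ejections: hydrogen cyanide (HCN, 27 u), carbon monoxide (CO,
28 u), water (18 u), cyanamide (CN2H2, 42 u), cyanic/isocyanic acid
(NCOH/HNCO, 43 u — indistinguishable isomers at unit mass, reported as one
ambiguous loss), and methyl isocyanate (CH3NCO, 57 u) when N3 carries a
methyl group.  Annotation is pure integer arithmetic on the spectrum: a
generation-1 hit is a peak at ``MW − delta`` at or above an intensity
floor; generation-2 hits chain one further loss from each generation-1
fragment (e.g. the M−54 signature of two sequential HCN losses).
"""

from __future__ import annotations

from dataclasses import dataclass

from .spectral_io import Spectrum

__all__ = [
    "NeutralLossDef",
    "NeutralLossHit",
    "default_loss_table",
    "detect_neutral_losses",
    "loss_prevalence",
]


@dataclass(frozen=True)
class NeutralLossDef:
    """A named neutral loss and its nominal mass delta in u."""

    name: str
    delta: int

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("neutral-loss delta must be positive")


@dataclass(frozen=True)
class NeutralLossHit:
    """One annotated loss: parent m/z minus delta lands on an observed peak."""

    loss: NeutralLossDef
    parent_mz: int
    fragment_mz: int
    fragment_intensity: float
    generation: int


def default_loss_table() -> list[NeutralLossDef]:
    """The standard purine/pyrimidine neutral-loss table (user-extensible)."""
    return [
        NeutralLossDef("H2O", 18),
        NeutralLossDef("HCN", 27),
        NeutralLossDef("CO", 28),
        NeutralLossDef("CN2H2", 42),
        NeutralLossDef("HNCO_or_NCOH", 43),
        NeutralLossDef("CH3NCO", 57),
    ]


def detect_neutral_losses(
    s: Spectrum,
    losses: list[NeutralLossDef] | None = None,
    min_intensity: float = 2.0,
    max_generation: int = 1,
) -> list[NeutralLossHit]:
    """Annotate losses from the molecular ion (and optionally one step further).

    Generation 1 starts at the nominal molecular weight; with
    ``max_generation=2`` each generation-1 fragment is treated as a parent
    for one further loss.  Hits are sorted by descending fragment m/z; an
    empty list is a valid result.  ``min_intensity`` (percent of base peak,
    default 2%) suppresses annotation of noise-level peaks.
    """
    if s.nominal_mw is None:
        raise ValueError(f"spectrum {s.id!r} has no nominal molecular weight")
    if max_generation not in (1, 2):
        raise ValueError("max_generation must be 1 or 2")
    losses = default_loss_table() if losses is None else losses
    peak_map = {int(p.mz): p.intensity for p in s.peaks}

    def _hits_from(parent: int, generation: int) -> list[NeutralLossHit]:
        found = []
        for loss in losses:
            frag = parent - loss.delta
            inten = peak_map.get(frag)
            if frag >= 1 and inten is not None and inten >= min_intensity:
                found.append(NeutralLossHit(loss, parent, frag, inten, generation))
        return found

    hits = _hits_from(int(s.nominal_mw), generation=1)
    if max_generation == 2:
        for h in list(hits):
            hits.extend(_hits_from(h.fragment_mz, generation=2))
    hits.sort(key=lambda h: (-h.fragment_mz, h.generation, h.loss.name))
    return hits


def loss_prevalence(
    pairs: list[tuple[Spectrum, str]],
    loss: NeutralLossDef,
    min_intensity: float = 2.0,
) -> dict[str, float]:
    """Fraction of spectra exhibiting ``loss`` (generation 1), per subclass.

    Returns a mapping of subclass label to fraction in [0, 1], plus an
    ``"overall"`` entry.  Prevalence counts peak presence only and is thus
    invariant to intensity rescaling.
    """
    totals: dict[str, int] = {}
    exhibiting: dict[str, int] = {}
    for s, subclass in pairs:
        totals[subclass] = totals.get(subclass, 0) + 1
        hits = detect_neutral_losses(s, [loss], min_intensity, max_generation=1)
        if hits:
            exhibiting[subclass] = exhibiting.get(subclass, 0) + 1
    out = {k: exhibiting.get(k, 0) / totals[k] for k in totals}
    out["overall"] = sum(exhibiting.values()) / sum(totals.values())
    return out
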