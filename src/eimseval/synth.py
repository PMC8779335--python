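"""Synthetic unit-mass EI spectrum pairs, cohorts, and decoy libraries.

The evaluation pipeline is exercised against generated data that mimics the
statistical structure of a predicted-vs-experimental comparison of small
heteroaromatics (purine/pyrimidine derivatives, nominal MW 110-210 u):

* a *reference* spectrum has a molecular ion at the nominal MW whose
  survival fraction is usually 100% (aromatic stabilisation makes M+ the
  base peak for ~3 of 4 compounds) but can be anywhere in (0, 100];
  fragment ions sit at characteristic neutral-loss offsets (HCN 27 u,
  CO 28 u, HNCO/NCOH 43 u, ...) drawn per-subclass, padded with random
  fragments, plus a few sub-threshold noise peaks;
* a *predicted* partner is derived from it by a seeded perturbation whose
  error modes are the ones the evaluation measures: per-fragment dropout,
  spurious extra peaks, multiplicative intensity noise, and an additive
  molecular-ion abundance shift;
* a *decoy library* adds structurally-similar near-duplicates (sharing a
  majority of fragment m/z values with jittered intensities) and unrelated
  fillers to exercise rank ambiguity.

Dropout is abundance-tilted: an in-silico trajectory ensemble samples rare
(low-abundance) fragmentation channels less reliably than dominant ones, so
weak fragment ions are dropped more often.  The configured ``dropout_prob``
is preserved as the per-spectrum mean removal probability; the tilt is

    p_i = clip(d + tilt * d * (1 - d) * (c - log10 I_i), 0, 1)

with ``c`` the spectrum's mean fragment log10-intensity, so the limit cases
d = 0 (identity) and d = 1 (all fragments dropped) are exact.  The
molecular ion is never dropped (all real predicted spectra contained it).

All generators are reproducible from ``(spec, cfg, seed)``; per-spectrum
random streams are split from the master seed so libraries are
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .molion import MolIonComparison
from .spectral_io import Peak, Spectrum, SpectrumLibrary, normalize_to_base_peak

__all__ = [
    "ClassSpec",
    "PerturbationConfig",
    "MILD_PERTURBATION",
    "default_class_specs",
    "generate_reference_spectrum",
    "perturb_spectrum",
    "generate_evaluation_set",
    "table2_fixture",
    "table2_frame",
]

_LOSS_DELTAS = {"H2O": 18, "HCN": 27, "CO": 28, "CN2H2": 42, "HNCO_or_NCOH": 43, "CH3NCO": 57}
_MIN_FRAGMENT_MZ = 26  # EI fragments below CN (26 u) are rare in heteroaromatics


@dataclass(frozen=True)
class ClassSpec:
    """Generative parameters of one structural subclass.

    ``molion_base_prob`` is the probability that the molecular ion is the
    base peak; otherwise its survival is drawn uniformly from
    ``molion_survival`` (percent of base peak).  ``loss_profile`` maps
    neutral-loss names to per-spectrum emission probabilities.
    """

    subclass: str
    mw_range: tuple[int, int] = (110, 210)
    n_fragments: tuple[int, int] = (10, 18)
    loss_profile: dict[str, float] = field(default_factory=dict)
    molion_base_prob: float = 0.75
    molion_survival: tuple[float, float] = (5.0, 95.0)
    n_noise_peaks: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if not all(0 <= p <= 1 for p in self.loss_profile.values()):
            raise ValueError("loss probabilities must lie in [0, 1]")
        if self.mw_range[0] <= _MIN_FRAGMENT_MZ:
            raise ValueError("mw_range too small to place fragments")


@dataclass(frozen=True)
class PerturbationConfig:
    """Seeded error model turning a reference spectrum into a 'predicted' one.

    ``dropout_prob``: mean per-fragment removal probability (abundance-tilted
    by ``abundance_tilt``); ``extra_peak_rate``: expected Poisson count of
    spurious peaks (placed uniformly on unoccupied integer m/z in
    [26, MW-1], intensities log-uniform on [2, 20)); ``intensity_noise_sigma``:
    log-scale sigma of multiplicative fragment-intensity noise;
    ``molion_shift``: (mean, sd) of a normal additive shift of the
    molecular-ion abundance in percentage points, clipped to (0, 100].
    """

    dropout_prob: float = 0.0
    extra_peak_rate: float = 0.0
    intensity_noise_sigma: float = 0.0
    molion_shift: tuple[float, float] = (0.0, 0.0)
    abundance_tilt: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.extra_peak_rate < 0 or self.intensity_noise_sigma < 0:
            raise ValueError("rates must be non-negative")


#: Documented "mild" perturbation used for rank-recovery checks: 10% mean
#: fragment dropout, ~3 spurious peaks per spectrum, 0.2 log-scale intensity
#: noise, no molecular-ion shift.
MILD_PERTURBATION = PerturbationConfig(
    dropout_prob=0.10, extra_peak_rate=3.0, intensity_noise_sigma=0.2
)

_PURINE_LOSSES = {"HCN": 0.89, "CO": 0.5, "HNCO_or_NCOH": 0.6, "CN2H2": 0.2, "H2O": 0.1}
_PYRIMIDINE_LOSSES = {"HCN": 0.57, "CO": 0.4, "HNCO_or_NCOH": 0.7, "CH3NCO": 0.3, "H2O": 0.1}


def default_class_specs() -> list[ClassSpec]:
    """Twelve structural subclasses of purine/pyrimidine derivatives.

    HCN-loss probabilities follow the observed prevalence (89% of purines,
    57% of pyrimidines, absent in pyridopyrimidines and aza-purines).
    """

    def purine(name: str, mw: tuple[int, int], **over: float) -> ClassSpec:
        return ClassSpec(name, mw_range=mw, loss_profile={**_PURINE_LOSSES, **over})

    return [
        ClassSpec("Pyrimidines", mw_range=(110, 172), loss_profile=dict(_PYRIMIDINE_LOSSES)),
        purine("Methylpurines", (134, 165)),
        purine("AminoHydroxyPurines", (135, 170)),
        purine("Adenines", (135, 175)),
        purine("Xanthines", (152, 196)),
        purine("Hypoxanthines", (136, 165)),
        purine("Guanines", (151, 195), CN2H2=0.8),
        purine("Lumazines", (164, 195), H2O=0.4),
        purine("Quinazolinediones", (162, 193)),
        purine("Remycins", (179, 208)),
        purine("Pyridopyrimidinediones", (163, 192), HCN=0.0),
        purine("Azapurines", (121, 180), HCN=0.0),
    ]


def _loguniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return 10 ** rng.uniform(math.log10(lo), math.log10(hi), size)


def generate_reference_spectrum(
    spec: ClassSpec, seed, mol_id: str = "M1", name: str | None = None
) -> Spectrum:
    """Draw one normalized reference spectrum; deterministic for a fixed seed.

    The molecular ion's survival intensity is controlled exactly: when it is
    not the base peak, the strongest fragment is pinned to 100 so that the
    sampled survival is the final percent-of-base-peak abundance.
    """
    rng = np.random.default_rng(seed)
    mw = int(rng.integers(spec.mw_range[0], spec.mw_range[1] + 1))

    molion_is_base = rng.random() < spec.molion_base_prob
    molion = 100.0 if molion_is_base else float(rng.uniform(*spec.molion_survival))

    frag_mzs: list[int] = []
    for loss_name in sorted(spec.loss_profile):
        delta = _LOSS_DELTAS[loss_name]
        if rng.random() < spec.loss_profile[loss_name] and mw - delta >= _MIN_FRAGMENT_MZ:
            if mw - delta not in frag_mzs:
                frag_mzs.append(mw - delta)
    n_frag = int(rng.integers(spec.n_fragments[0], spec.n_fragments[1] + 1))
    n_frag = max(n_frag, len(frag_mzs))
    # keep random fills off the known loss offsets so the loss profile is the
    # exact prevalence oracle for generated cohorts
    reserved = {mw - d for d in _LOSS_DELTAS.values()}
    candidates = [
        m for m in range(_MIN_FRAGMENT_MZ, mw - 14)
        if m not in frag_mzs and m not in reserved
    ]
    n_fill = min(n_frag - len(frag_mzs), len(candidates))
    frag_mzs.extend(rng.choice(candidates, size=n_fill, replace=False).tolist())
    if not frag_mzs:
        raise ValueError(f"class {spec.subclass!r}: no fragment positions available")

    # fragment intensities: log-uniform, rare channels weak, all above a 2%
    # abundance floor; cap below the base peak
    intens = _loguniform(rng, 5.0, 95.0, size=len(frag_mzs))
    if not molion_is_base:
        intens[int(np.argmax(intens))] = 100.0

    peaks = {mw: molion}
    peaks.update({int(m): float(v) for m, v in zip(frag_mzs, intens)})

    n_noise = int(rng.integers(spec.n_noise_peaks[0], spec.n_noise_peaks[1] + 1))
    open_mz = [m for m in range(_MIN_FRAGMENT_MZ, mw) if m not in peaks]
    for m in rng.choice(open_mz, size=min(n_noise, len(open_mz)), replace=False):
        peaks[int(m)] = float(rng.uniform(0.3, 1.9))

    s = Spectrum(
        id=mol_id,
        name=name or f"synthetic {spec.subclass} {mol_id}",
        nominal_mw=mw,
        peaks=tuple(Peak(float(m), v) for m, v in sorted(peaks.items())),
        subclass=spec.subclass,
    )
    return normalize_to_base_peak(s)


_TILT_FLOOR = 2.0  # percent of base peak; peaks below it are noise-level


def _dropout_probs(intens: np.ndarray, cfg: PerturbationConfig) -> np.ndarray:
    """Abundance-tilted per-fragment dropout probabilities.

    The tilt is centered over fragments at or above the 2% abundance floor,
    so the configured ``dropout_prob`` is exactly the mean removal
    probability of the observable fragment population; noise-level peaks get
    the untilted rate.
    """
    d = cfg.dropout_prob
    probs = np.full(intens.shape, d)
    observable = intens >= _TILT_FLOOR
    if d in (0.0, 1.0) or cfg.abundance_tilt == 0 or observable.sum() < 2:
        return probs
    log_i = np.log10(intens[observable])
    tilt = cfg.abundance_tilt * d * (1 - d) * (log_i.mean() - log_i)
    probs[observable] = np.clip(d + tilt, 0.0, 1.0)
    return probs


def perturb_spectrum(s: Spectrum, cfg: PerturbationConfig) -> Spectrum:
    """Apply the seeded error model; an all-zero config is the exact identity.

    The molecular ion is never dropped; fragment dropout is abundance-tilted
    (see module docstring); extra peaks land on unoccupied m/z below the
    molecular ion; the result is renormalized to base peak 100.
    """
    if s.nominal_mw is None:
        raise ValueError(f"spectrum {s.id!r} needs a nominal molecular weight")
    rng = np.random.default_rng(cfg.seed)
    mw = float(s.nominal_mw)

    frags = [p for p in s.peaks if p.mz != mw]
    molion = s.peak_at(mw)

    intens = np.array([p.intensity for p in frags])
    keep = rng.random(len(frags)) >= _dropout_probs(intens, cfg) if frags else []
    peaks: dict[float, float] = {}
    for p, k in zip(frags, keep):
        if k:
            noise = math.exp(rng.normal(0.0, cfg.intensity_noise_sigma)) if cfg.intensity_noise_sigma else 1.0
            peaks[p.mz] = p.intensity * noise

    if molion is not None:
        shift = float(rng.normal(*cfg.molion_shift)) if cfg.molion_shift != (0.0, 0.0) else 0.0
        peaks[mw] = min(max(molion.intensity + shift, 0.5), 100.0)

    n_extra = int(rng.poisson(cfg.extra_peak_rate)) if cfg.extra_peak_rate else 0
    if n_extra:
        open_mz = [m for m in range(_MIN_FRAGMENT_MZ, int(mw)) if float(m) not in peaks]
        chosen = rng.choice(open_mz, size=min(n_extra, len(open_mz)), replace=False)
        for m in chosen:
            peaks[float(m)] = float(_loguniform(rng, 2.0, 20.0))

    out = s.with_peaks(tuple(Peak(m, v) for m, v in sorted(peaks.items())))
    return normalize_to_base_peak(out)


def _make_decoy(exp: Spectrum, rng: np.random.Generator, decoy_id: str) -> Spectrum:
    """A structurally-similar near-duplicate sharing >=50% of fragment m/z."""
    mw = float(exp.nominal_mw)
    frags = [p for p in exp.peaks if p.mz != mw]
    peaks: dict[float, float] = {}
    if frags:
        n_keep = max(1, math.ceil(0.6 * len(frags)))
        for i in rng.choice(len(frags), size=n_keep, replace=False):
            p = frags[i]
            peaks[p.mz] = p.intensity * math.exp(rng.normal(0.0, 0.5))
    open_mz = [m for m in range(_MIN_FRAGMENT_MZ, int(mw) - 14) if float(m) not in peaks]
    n_new = min(round(0.4 * len(frags)) + 1, len(open_mz))
    for m in rng.choice(open_mz, size=n_new, replace=False):
        peaks[float(m)] = float(_loguniform(rng, 5.0, 95.0))
    peaks[mw] = float(rng.uniform(10.0, 100.0))
    decoy = Spectrum(
        id=decoy_id,
        name=f"decoy of {exp.name}",
        nominal_mw=exp.nominal_mw,
        peaks=tuple(Peak(m, v) for m, v in sorted(peaks.items())),
        subclass=exp.subclass,
    )
    return normalize_to_base_peak(decoy)


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % 2**31)


def generate_evaluation_set(
    n_compounds: int = 80,
    class_specs: list[ClassSpec] | None = None,
    cfg: PerturbationConfig | None = None,
    decoys_per_compound: int = 5,
    n_fillers: int = 20,
    seed: int = 0,
) -> tuple[SpectrumLibrary, SpectrumLibrary, SpectrumLibrary]:
    """Build paired predicted/experimental libraries plus a decoy search library.

    Compounds are assigned round-robin over ``class_specs`` (default: the 12
    subclasses).  The decoy library contains every experimental entry,
    ``decoys_per_compound`` near-duplicates per compound and ``n_fillers``
    unrelated spectra.  Ids pair predicted to experimental entries
    one-to-one; everything is reproducible from ``seed``.
    """
    if n_compounds < 1:
        raise ValueError("need at least one compound")
    class_specs = class_specs or default_class_specs()
    cfg = cfg or PerturbationConfig()
    master = np.random.SeedSequence(seed)
    comp_ss, filler_ss = master.spawn(2)
    children = comp_ss.spawn(n_compounds)

    experimental, predicted, decoys = [], [], []
    for i, child in enumerate(children):
        spec = class_specs[i % len(class_specs)]
        gen_ss, pert_ss, decoy_ss = child.spawn(3)
        mol_id = f"C{i + 1:03d}"
        exp = generate_reference_spectrum(spec, _child_seed(gen_ss), mol_id=mol_id)
        experimental.append(exp)
        predicted.append(perturb_spectrum(exp, replace(cfg, seed=_child_seed(pert_ss))))
        drng = np.random.default_rng(_child_seed(decoy_ss))
        for k in range(decoys_per_compound):
            decoys.append(_make_decoy(exp, drng, f"{mol_id}_D{k + 1}"))

    frng_children = filler_ss.spawn(max(n_fillers, 1))
    fillers = [
        generate_reference_spectrum(
            class_specs[j % len(class_specs)], _child_seed(frng_children[j]), mol_id=f"F{j + 1:03d}"
        )
        for j in range(n_fillers)
    ]
    return (
        SpectrumLibrary(predicted, source_label="predicted"),
        SpectrumLibrary(experimental, source_label="experimental"),
        SpectrumLibrary(experimental + decoys + fillers, source_label="search"),
    )


def table2_frame() -> pd.DataFrame:
    """The packaged molecular-ion reference table as a DataFrame (verbatim)."""
    with resources.files("eimseval.data").joinpath("molecular_ion_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def table2_fixture() -> list[MolIonComparison]:
    """The 38 packaged molecular-ion comparisons with subclass labels.

    Values are stored verbatim from the printed reference table; the one row
    whose printed difference disagrees in sign with pred - exp (mol 122) is
    flagged ``printed_sign_mismatch``.
    """
    out = []
    for row in table2_frame().itertuples(index=False):
        flags = set()
        if int(row.printed_diff) != row.pred_abundance - row.exp_abundance:
            flags.add("printed_sign_mismatch")
        out.append(
            MolIonComparison(
                mol_id=str(row.mol_id),
                nominal_mw=int(row.nominal_mw),
                exp_abundance=float(row.exp_abundance),
                pred_abundance=float(row.pred_abundance),
                subclass=str(row.subclass),
                flags=frozenset(flags),
            )
        )
    return out
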