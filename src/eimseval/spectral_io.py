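"""Unit-mass EI spectra and spectrum libraries in NIST-style MSP text format.

The in-memory model is deliberately small: a :class:`Spectrum` is an
identified, optionally class-labelled list of ``(m/z, intensity)`` peaks with
a nominal molecular weight, and a :class:`SpectrumLibrary` is an id-unique
collection of spectra.  Intensities are canonically expressed as percent of
the base peak (base peak = 100), the convention in which EI library spectra
and molecular-ion abundances are reported.

Two MSP peak-line dialects circulate in public EI libraries and both are
accepted on input: whitespace-separated ``mz intensity`` pairs (one or more
per line) and ``mz:intensity;`` runs.  Output always uses one
space-separated pair per line, so ``parse_msp(write_msp(lib)) == lib``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "Peak",
    "Spectrum",
    "SpectrumLibrary",
    "MSPParseError",
    "parse_msp",
    "write_msp",
    "normalize_to_base_peak",
    "bin_nominal",
]


class MSPParseError(ValueError):
    """Raised for malformed MSP records (bad peak lines, count mismatches)."""


@dataclass(frozen=True)
class Peak:
    """A single spectral peak: nominal m/z (u) and relative abundance.

    Intensity is percent of the base peak on the canonical scale, i.e. in
    ``(0, 100]`` for a normalized spectrum.
    """

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz < 1:
            raise ValueError(f"peak m/z must be >= 1, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class Spectrum:
    """An identified EI mass spectrum at unit mass resolution.

    Parameters
    ----------
    id:
        Unique identifier within a library.
    name:
        Compound name (free text).
    nominal_mw:
        Nominal molecular weight in u; the molecular ion, when present, sits
        at this m/z.  ``None`` only transiently before inference.
    subclass:
        Structural subclass label, or ``"unclassified"``.
    peaks:
        Peaks in strictly increasing m/z order, no duplicates.
    flags:
        Provenance/validation flags, e.g. ``mw_inferred`` when the molecular
        weight was taken as the largest observed m/z, or ``mw_inconsistent``
        when a peak exceeds the declared molecular weight.
    """

    id: str
    name: str
    nominal_mw: int | None
    peaks: tuple[Peak, ...]
    subclass: str = "unclassified"
    flags: frozenset[str] = frozenset()
    comment: str = ""

    def __post_init__(self) -> None:
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError(f"spectrum {self.id!r}: peaks must be strictly increasing in m/z")

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(p.mz for p in self.peaks)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(p.intensity for p in self.peaks)

    @property
    def base_peak(self) -> Peak:
        return max(self.peaks, key=lambda p: p.intensity)

    def peak_at(self, mz: float) -> Peak | None:
        for p in self.peaks:
            if p.mz == mz:
                return p
        return None

    def with_peaks(self, peaks: tuple[Peak, ...]) -> "Spectrum":
        return replace(self, peaks=peaks)


@dataclass
class SpectrumLibrary:
    """A collection of spectra with unique ids."""

    entries: list[Spectrum] = field(default_factory=list)
    source_label: str = ""

    def __post_init__(self) -> None:
        ids = [s.id for s in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate spectrum ids in library: {dupes}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, spectrum_id: str) -> Spectrum:
        for s in self.entries:
            if s.id == spectrum_id:
                return s
        raise KeyError(spectrum_id)

    def ids(self) -> list[str]:
        return [s.id for s in self.entries]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectrumLibrary):
            return NotImplemented
        return self.entries == other.entries and self.source_label == other.source_label


_SUBCLASS_RE = re.compile(r"subclass=([^;\"]+)")
# a:b; runs, possibly several per line
_COLON_PAIR_RE = re.compile(r"([-+0-9.eE]+)\s*:\s*([-+0-9.eE]+)\s*;?")


def _parse_peak_line(line: str) -> list[tuple[float, float]]:
    if ":" in line:
        pairs = _COLON_PAIR_RE.findall(line)
        if not pairs:
            raise ValueError("no mz:intensity pairs found")
        return [(float(a), float(b)) for a, b in pairs]
    tokens = line.replace(";", " ").split()
    if len(tokens) % 2 != 0 or not tokens:
        raise ValueError("odd token count in peak line")
    vals = [float(t) for t in tokens]
    return list(zip(vals[::2], vals[1::2]))


def _finish_record(
    fields: dict[str, str], pairs: list[tuple[float, float]], index: int
) -> Spectrum:
    name = fields.get("name", "")
    if not name and not pairs:
        raise MSPParseError(f"record {index}: empty record")
    declared = fields.get("num peaks")
    if declared is not None and int(declared) != len(pairs):
        raise MSPParseError(
            f"record {index} ({name!r}): Num Peaks: {declared} but {len(pairs)} peak lines"
        )
    if not pairs:
        raise MSPParseError(f"record {index} ({name!r}): no peaks")

    merged: dict[float, float] = {}
    had_dupes = False
    for mz, inten in pairs:
        if mz in merged:
            had_dupes = True
        merged[mz] = merged.get(mz, 0.0) + inten
    if had_dupes:
        warnings.warn(
            f"record {index} ({name!r}): duplicate m/z values merged by summation",
            stacklevel=2,
        )

    flags: set[str] = set()
    comment = fields.get("comment", "")
    m = _SUBCLASS_RE.search(comment)
    subclass = m.group(1).strip() if m else "unclassified"
    if m:  # subclass lives in its own field; keep the rest of the comment
        comment = " ".join(_SUBCLASS_RE.sub("", comment).split())

    mw_field = fields.get("mw")
    max_mz = max(merged)
    if mw_field is not None:
        nominal_mw = int(round(float(mw_field)))
        if nominal_mw < max_mz:
            flags.add("mw_inconsistent")
    else:
        # molecular ion is the heaviest peak in well-behaved EI spectra
        nominal_mw = int(round(max_mz))
        flags.add("mw_inferred")

    spectrum_id = fields.get("id") or fields.get("db#") or name or f"record{index}"
    peaks = tuple(
        Peak(mz, inten) for mz, inten in sorted(merged.items()) if inten > 0
    )
    return Spectrum(
        id=spectrum_id,
        name=name or spectrum_id,
        nominal_mw=nominal_mw,
        peaks=peaks,
        subclass=subclass,
        flags=frozenset(flags),
        comment=comment,
    )


def parse_msp(text: str, source_label: str = "") -> SpectrumLibrary:
    """Parse NIST-style MSP text into a :class:`SpectrumLibrary`.

    Records are separated by blank lines.  Recognised header fields are
    ``Name:``, ``ID:`` (or ``DB#:``), ``MW:``, ``Comment:`` (a
    ``subclass=<label>`` token inside it sets the subclass) and
    ``Num Peaks:``; unknown fields are ignored.  A ``Num Peaks`` count that
    disagrees with the listed peaks raises :class:`MSPParseError`, as does a
    malformed peak line (the error names the record and line number).
    """
    entries: list[Spectrum] = []
    fields: dict[str, str] = {}
    pairs: list[tuple[float, float]] = []
    in_record = False
    record_index = 0

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            if in_record:
                entries.append(_finish_record(fields, pairs, record_index))
                fields, pairs, in_record = {}, [], False
            continue
        if not in_record:
            record_index += 1
            in_record = True
        key_match = re.match(r"^([A-Za-z][A-Za-z0-9 _#/-]*):\s*(.*)$", line)
        if key_match and not line[0].isdigit():
            fields[key_match.group(1).strip().lower()] = key_match.group(2).strip()
            continue
        try:
            pairs.extend(_parse_peak_line(line))
        except ValueError as exc:
            name = fields.get("name", f"record {record_index}")
            raise MSPParseError(
                f"record {record_index} ({name!r}), line {lineno}: malformed peak line {raw!r}: {exc}"
            ) from None
    if in_record:
        entries.append(_finish_record(fields, pairs, record_index))
    return SpectrumLibrary(entries=entries, source_label=source_label)


def _fmt(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def write_msp(library: SpectrumLibrary, scale_999: bool = False) -> str:
    """Serialise a library to MSP text; an empty library yields an empty string.

    Field order is fixed (Name, ID, MW, Comment, Num Peaks, peaks) so output
    is deterministic and re-parsing yields an equal library.  With
    ``scale_999`` intensities are exported on the 0-999 integer scale used by
    some library distributions (this breaks exact round-tripping).
    """
    blocks: list[str] = []
    for s in library:
        lines = [f"Name: {s.name}", f"ID: {s.id}"]
        if s.nominal_mw is not None:
            lines.append(f"MW: {s.nominal_mw}")
        comment = s.comment
        if s.subclass != "unclassified" and "subclass=" not in comment:
            comment = (comment + " " if comment else "") + f"subclass={s.subclass}"
        if comment:
            lines.append(f"Comment: {comment}")
        lines.append(f"Num Peaks: {len(s.peaks)}")
        for p in s.peaks:
            inten = round(p.intensity * 9.99) if scale_999 else p.intensity
            lines.append(f"{_fmt(p.mz)} {_fmt(inten)}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def normalize_to_base_peak(s: Spectrum) -> Spectrum:
    """Rescale so the base peak is exactly 100; zero-intensity peaks are dropped.

    Idempotent and scale invariant; raises ``ValueError`` on an all-zero
    spectrum.
    """
    top = max((p.intensity for p in s.peaks), default=0.0)
    if top <= 0:
        raise ValueError(f"spectrum {s.id!r}: cannot normalize all-zero spectrum")
    # ratios, not a multiplicative factor: pins the base peak to exactly 100
    # and makes the result invariant to a common intensity rescaling
    peaks = tuple(
        Peak(p.mz, 100.0 if p.intensity == top else p.intensity / top * 100.0)
        for p in s.peaks
        if p.intensity > 0
    )
    return s.with_peaks(peaks)


def bin_nominal(s: Spectrum) -> Spectrum:
    """Round each m/z to the nearest integer (half away from zero) and merge.

    Peaks landing on the same integer are merged by summing intensities; the
    result is renormalized to base peak 100.  Integer-m/z spectra pass
    through unchanged apart from renormalization.
    """
    merged: dict[int, float] = {}
    for p in s.peaks:
        mz = int(math.floor(p.mz + 0.5))  # half away from zero for mz >= 1
        merged[mz] = merged.get(mz, 0.0) + p.intensity
    peaks = tuple(Peak(float(mz), inten) for mz, inten in sorted(merged.items()))
    return normalize_to_base_peak(s.with_peaks(peaks))
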