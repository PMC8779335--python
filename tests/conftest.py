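import math

import pytest

from eimseval.spectral_io import Peak, Spectrum, SpectrumLibrary


def make_spectrum(peaks, mw=None, sid="s", name=None, subclass="unclassified"):
    """Build a spectrum from (mz, intensity) pairs; MW defaults to max mz."""
    pairs = sorted(peaks)
    if mw is None:
        mw = int(round(max(mz for mz, _ in pairs)))
    return Spectrum(
        id=sid,
        name=name or sid,
        nominal_mw=mw,
        peaks=tuple(Peak(float(mz), float(i)) for mz, i in pairs),
        subclass=subclass,
    )


def brute_force_score(a, b, m=0.6, n=3.0, scale_a=1000.0, weighted=True):
    """Independent plain-Python evaluation of the (weighted) dot-product score.

    Loops over the explicit m/z union with per-peak weights
    intensity**m * mz**n; deliberately shares no code with the package's
    vectorised implementation.
    """
    ia = {p.mz: p.intensity for p in a.peaks}
    ib = {p.mz: p.intensity for p in b.peaks}
    union = sorted(set(ia) | set(ib))

    def w(d, mz):
        inten = d.get(mz, 0.0)
        if inten == 0.0:
            return 0.0
        return inten**m * mz**n if weighted else inten

    dot = sum(w(ia, mz) * w(ib, mz) for mz in union)
    na = math.sqrt(sum(w(ia, mz) ** 2 for mz in union))
    nb = math.sqrt(sum(w(ib, mz) ** 2 for mz in union))
    return dot / (na * nb) * scale_a


@pytest.fixture
def two_peak_pair():
    """The worked 2-peak pair: cosine 800, Wdot ~994.5."""
    a = make_spectrum([(50, 100), (100, 50)], sid="a")
    b = make_spectrum([(50, 50), (100, 100)], sid="b")
    return a, b


@pytest.fixture
def small_library():
    entries = [
        make_spectrum([(43, 10), (83, 30), (126, 100)], sid="uracil-like"),
        make_spectrum([(43, 20), (108, 100), (135, 80)], mw=135, sid="adenine-like"),
        make_spectrum([(28, 15), (109, 40), (152, 100)], sid="xanthine-like"),
    ]
    return SpectrumLibrary(entries, source_label="small")


def random_spectrum(rng, sid="r", max_peaks=6):
    """A small random unit-mass spectrum for property tests."""
    n = int(rng.integers(1, max_peaks + 1))
    mzs = sorted(rng.choice(range(26, 200), size=n, replace=False).tolist())
    intens = rng.uniform(1.0, 100.0, size=n)
    intens[int(rng.integers(0, n))] = 100.0
    return make_spectrum(list(zip(mzs, intens)), sid=sid)
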