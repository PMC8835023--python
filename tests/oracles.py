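"""Independent brute-force oracles for isotope-pattern math.

These deliberately avoid the package's closed-form multinomial route: the
natural-pattern oracle expands the isotopologue polynomial one atom at a
time with exact Fraction arithmetic, and the labeling oracle enumerates
individual site outcomes. They share only the constants tables with the
implementation.
"""

from fractions import Fraction
from itertools import product

from midaflux import constants
from midaflux.mida import ElementalComposition


def _fraction_abundances() -> dict[str, list[tuple[int, Fraction]]]:
    """(shift, abundance) pairs per element as exact fractions."""
    out = {}
    for elem, arr in constants.isotope_abundances().items():
        pairs = [(s, Fraction(a).limit_denominator(10**12)) for s, a in enumerate(arr) if a > 0]
        total = sum(p for _, p in pairs)
        out[elem] = [(s, p / total) for s, p in pairs]
    return out


def brute_natural_pattern(comp: ElementalComposition, channels: int) -> list[float]:
    """Atom-by-atom polynomial expansion of the natural isotopologue pattern.

    Returns the raw (untruncated-mass, unnormalized-over-window) channel
    probabilities M0..M[channels-1].
    """
    abund = _fraction_abundances()
    poly = [Fraction(1)] + [Fraction(0)] * (channels - 1)
    for elem in constants.ELEMENTS:
        single = abund[elem]
        for _ in range(getattr(comp, elem)):
            new = [Fraction(0)] * channels
            for m, coeff in enumerate(poly):
                if coeff == 0:
                    continue
                for shift, p in single:
                    if m + shift < channels:
                        new[m + shift] += coeff * p
            poly = new
    return [float(x) for x in poly]


def brute_label_pattern_enumerate(n_sites: int, p: float, channels: int) -> list[float]:
    """Label-count distribution by exhaustive enumeration of all 2**n site
    outcomes (feasible up to n ~ 14)."""
    out = [0.0] * channels
    for outcome in product((0, 1), repeat=n_sites):
        k = sum(outcome)
        if k < channels:
            out[k] += p ** k * (1 - p) ** (n_sites - k)
    return out


def brute_label_pattern_sitewise(n_sites: int, p: float, channels: int) -> list[float]:
    """Label-count distribution by site-by-site polynomial expansion with
    exact fractions (for n too large to enumerate)."""
    pf = Fraction(p).limit_denominator(10**12)
    poly = [Fraction(1)] + [Fraction(0)] * (channels - 1)
    for _ in range(n_sites):
        new = [Fraction(0)] * channels
        for m, coeff in enumerate(poly):
            if m < channels:
                new[m] += coeff * (1 - pf)
            if m + 1 < channels:
                new[m + 1] += coeff * pf
        poly = new
    return [float(x) for x in poly]


def brute_convolve(a: list[float], b: list[float], channels: int) -> list[float]:
    out = [0.0] * channels
    for i, x in enumerate(a):
        for j, y in enumerate(b):
            if i + j < channels:
                out[i + j] += x * y
    return out


def normalize(a: list[float]) -> list[float]:
    s = sum(a)
    return [x / s for x in a]
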