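"""Mass isotopomer distribution analysis (MIDA) kernel.

Heavy-water labeling experiments measure the mass-isotopomer distribution
(MID) of a polymer — a peptide, a fatty acid, a sterol — as fractional
abundances M0, M1, ... Mk. During biosynthesis each of *n* C–H positions
equilibrates with body water, so a molecule made while body water holds a
deuterium fraction *p* carries Binomial(n, p) extra mass units on top of its
natural isotopologue pattern. A measured pool is a mixture of pre-existing
(natural pattern) and newly made (enriched pattern) molecules, and the
mixing fraction is the fraction newly synthesized:

    f = EM / EMmax

where EM is the excess abundance of a chosen channel over the unlabeled
baseline and EMmax the excess that a 100%-new molecule would show at the
same (n, p). At p ~ 0.05 the highest-signal channel is M0, whose excess is
negative (depletion); M1/M2 excesses are positive and serve as internal
consistency checks.

All distributions here live on the reported channel window (M0..M3 for
peptides, M0..M2 for GC-MS analytes) and are renormalized over that window;
baseline, enriched and measured patterns are treated identically, so the
precursor–product ratio stays exactly linear in the mixing fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants
from .errors import DegenerateEnrichmentError, ValidationError

__all__ = [
    "ElementalComposition",
    "MassIsotopomerDistribution",
    "LabelParameters",
    "ExcessEnrichment",
    "KineticsResult",
    "FractionEstimate",
    "CARBAMIDOMETHYL",
    "composition_from_peptide",
    "natural_isotope_distribution",
    "label_site_count",
    "enriched_distribution",
    "excess_enrichment",
    "theoretical_max_em",
    "fractional_synthesis",
    "rate_constant",
]

# f = EM/EMmax values slightly outside [0, 1] are measurement noise around
# the boundaries; further out they are failed measurements.
CLAMP_LOW = -0.02
CLAMP_HIGH = 1.05


@dataclass(frozen=True)
class ElementalComposition:
    """Counts of C, H, N, O, S atoms in one molecular species."""

    C: int = 0
    H: int = 0
    N: int = 0
    O: int = 0
    S: int = 0

    def __post_init__(self):
        for elem in constants.ELEMENTS:
            if getattr(self, elem) < 0:
                raise ValidationError(f"negative atom count for {elem}")
        if self.total_atoms == 0:
            raise ValidationError("composition must contain at least one atom")

    @property
    def total_atoms(self) -> int:
        return sum(getattr(self, e) for e in constants.ELEMENTS)

    @property
    def monoisotopic_mass(self) -> float:
        return sum(
            getattr(self, e) * constants.MONOISOTOPIC_MASS[e] for e in constants.ELEMENTS
        )

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return ElementalComposition(
            **{e: getattr(self, e) + getattr(other, e) for e in constants.ELEMENTS}
        )

    def formula(self) -> str:
        return "".join(
            f"{e}{getattr(self, e)}" for e in constants.ELEMENTS if getattr(self, e)
        )


WATER = ElementalComposition(H=2, O=1)
#: iodoacetamide alkylation adduct on cysteine (+C2H3NO)
CARBAMIDOMETHYL = ElementalComposition(C=2, H=3, N=1, O=1)


@dataclass(frozen=True)
class MassIsotopomerDistribution:
    """Ordered fractional abundances (M0, M1, ..., Mk), summing to 1."""

    abundances: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", arr)
        if arr.ndim != 1 or arr.size < 1:
            raise ValidationError("distribution must be a 1-d array")
        if np.any(arr < -1e-12):
            raise ValidationError("negative isotopomer abundance")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"distribution must sum to 1 (got {arr.sum():.12f}); "
                "use from_raw() to renormalize"
            )

    @classmethod
    def from_raw(cls, raw) -> "MassIsotopomerDistribution":
        """Build from unnormalized (e.g. truncated) channel abundances."""
        raw = np.asarray(raw, dtype=float)
        total = raw.sum()
        if total <= 0:
            raise ValidationError("cannot normalize an all-zero distribution")
        return cls(raw / total)

    @property
    def n_channels(self) -> int:
        return self.abundances.size

    def __getitem__(self, channel: int) -> float:
        return float(self.abundances[channel])

    def mix(self, other: "MassIsotopomerDistribution", alpha: float
            ) -> "MassIsotopomerDistribution":
        """Convex mixture (1-alpha)*self + alpha*other."""
        if self.n_channels != other.n_channels:
            raise ValidationError("channel count mismatch in mixture")
        return MassIsotopomerDistribution(
            (1.0 - alpha) * self.abundances + alpha * other.abundances
        )


@dataclass(frozen=True)
class LabelParameters:
    """Precursor body-water deuterium enrichment p and active site count n.

    n may be non-integral (effective site counts for lipids and residue
    tables); distributions at non-integral n are linear interpolations
    between the two neighbouring integer-site distributions.
    """

    p: float
    n: float

    def __post_init__(self):
        if not 0.0 <= self.p < 1.0:
            raise ValidationError(f"precursor enrichment p={self.p} outside [0, 1)")
        if self.n <= 0:
            raise ValidationError(f"label site count n={self.n} must be positive")


@dataclass(frozen=True)
class ExcessEnrichment:
    """Excess abundance of one channel over baseline, with its asymptote."""

    channel: int
    em: float
    em_max: float

    @property
    def degenerate(self) -> bool:
        return self.em_max == 0.0


@dataclass(frozen=True)
class FractionEstimate:
    """Fractional synthesis with its quality flag.

    flag is one of ``ok``, ``clamped_low``, ``clamped_high``, ``failed``.
    ``raw`` keeps the unclamped ratio for QC.
    """

    f: float
    flag: str
    raw: float


@dataclass(frozen=True)
class KineticsResult:
    """Fractional synthesis f, first-order rate constant k (/day), time t (days)."""

    f: float
    k: float
    t: float

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ValidationError(f"f={self.f} outside [0, 1]")
        if self.k < 0:
            raise ValidationError("k must be non-negative")
        if abs(self.f - (1.0 - math.exp(-self.k * self.t))) > 1e-9:
            raise ValidationError("inconsistent (f, k, t) triple")

    @classmethod
    def from_f(cls, f: float, t: float) -> "KineticsResult":
        return cls(f=f, k=rate_constant(f, t), t=t)

    @classmethod
    def from_k(cls, k: float, t: float) -> "KineticsResult":
        return cls(f=1.0 - math.exp(-k * t), k=k, t=t)


# ---------------------------------------------------------------------------
# compositions


def composition_from_peptide(
    sequence: str,
    fixed_mods: dict[str, ElementalComposition] | None = None,
    formulas: dict[str, dict[str, int]] | None = None,
) -> ElementalComposition:
    """Elemental composition of a peptide with fixed modifications.

    Composition = sum of residue formulas + one water (termini) + one
    modification delta per matching residue. The default fixed modification
    is carbamidomethylation of cysteine (iodoacetamide alkylation).
    """
    if not sequence:
        raise ValidationError("empty peptide sequence")
    if fixed_mods is None:
        fixed_mods = {"C": CARBAMIDOMETHYL}
    formulas = formulas or constants.residue_formulas()
    total = WATER
    for pos, residue in enumerate(sequence):
        if residue not in formulas:
            raise ValidationError(
                f"unknown residue {residue!r} at position {pos} in {sequence!r}"
            )
        total = total + ElementalComposition(**formulas[residue])
        if residue in fixed_mods:
            total = total + fixed_mods[residue]
    return total


def label_site_count(sequence: str, site_table: dict[str, float] | None = None) -> float:
    """Total effective deuterium-incorporation sites of a peptide (sum over
    residues of the per-residue site table)."""
    if not sequence:
        raise ValidationError("empty peptide sequence")
    table = site_table or constants.residue_site_table()
    n = 0.0
    for residue in sequence:
        if residue not in table:
            raise ValidationError(f"residue {residue!r} missing from site table")
        n += table[residue]
    return n


# ---------------------------------------------------------------------------
# isotope patterns


def _element_pattern(single: np.ndarray, n_atoms: int, length: int) -> np.ndarray:
    """Closed-form aggregated pattern of ``n_atoms`` identical atoms.

    Enumerates multinomial terms over the heavy isotopes whose total nominal
    shift stays below ``length``; channel m collects the exact probability of
    a total shift of m. Cheap because length is small (<= ~8 channels).
    """
    heavy = [(s, float(p)) for s, p in enumerate(single) if s > 0 and p > 0]
    p0 = float(single[0])
    out = np.zeros(length)

    def rec(idx: int, atoms_left: int, shift: int, coef: float) -> None:
        if idx == len(heavy):
            out[shift] += coef * p0 ** atoms_left
            return
        s, p = heavy[idx]
        k = 0
        term = coef
        while k <= atoms_left and shift + k * s < length:
            rec(idx + 1, atoms_left - k, shift + k * s, term)
            term *= p * (atoms_left - k) / (k + 1)
            k += 1

    rec(0, n_atoms, 0, 1.0)
    return out


def _natural_raw(comp: ElementalComposition, length: int,
                 abundances: dict[str, np.ndarray] | None = None) -> np.ndarray:
    abundances = abundances or constants.isotope_abundances()
    pattern = np.zeros(length)
    pattern[0] = 1.0
    for elem in constants.ELEMENTS:
        count = getattr(comp, elem)
        if count == 0:
            continue
        pattern = np.convolve(pattern, _element_pattern(abundances[elem], count, length))[
            :length
        ]
    return pattern


def natural_isotope_distribution(
    comp: ElementalComposition, channels: int = 4
) -> MassIsotopomerDistribution:
    """Natural-abundance (unlabeled baseline) MID at nominal-mass resolution.

    Per-element aggregated patterns are computed in closed form and convolved
    across elements; the first ``channels`` values are exact probabilities,
    renormalized over the reported window.
    """
    if channels < 2:
        raise ValidationError("need at least 2 channels")
    return MassIsotopomerDistribution.from_raw(_natural_raw(comp, channels))


def _binomial_pmf(n: int, p: float, length: int) -> np.ndarray:
    out = np.zeros(length)
    for k in range(min(n, length - 1) + 1):
        out[k] = math.comb(n, k) * p ** k * (1.0 - p) ** (n - k)
    return out


def enriched_distribution(
    comp: ElementalComposition, lp: LabelParameters, channels: int = 4
) -> MassIsotopomerDistribution:
    """MID of a 100%-newly-synthesized molecule at precursor enrichment p.

    The natural pattern is convolved with the Binomial(n, p) distribution of
    label atoms over the n active sites. Non-integral n interpolates linearly
    between the renormalized distributions at floor(n) and ceil(n).
    """
    if lp.p >= 1.0:
        raise ValidationError("p must be < 1")
    nat_raw = _natural_raw(comp, channels)

    def at_sites(sites: int) -> np.ndarray:
        if sites == 0 or lp.p == 0.0:
            raw = nat_raw
        else:
            raw = np.convolve(nat_raw, _binomial_pmf(sites, lp.p, channels))[:channels]
        return raw / raw.sum()

    lo = math.floor(lp.n)
    hi = math.ceil(lp.n)
    if lo == hi:
        return MassIsotopomerDistribution(at_sites(lo))
    frac = lp.n - lo
    return MassIsotopomerDistribution((1.0 - frac) * at_sites(lo) + frac * at_sites(hi))


# ---------------------------------------------------------------------------
# enrichment and kinetics


def excess_enrichment(
    measured: MassIsotopomerDistribution,
    baseline: MassIsotopomerDistribution,
    channel: int = 0,
) -> float:
    """Signed excess abundance of one channel over the unlabeled baseline."""
    if measured.n_channels != baseline.n_channels:
        raise ValidationError("measured and baseline channel counts differ")
    if not 0 <= channel < measured.n_channels:
        raise ValidationError(f"channel {channel} out of range")
    return measured[channel] - baseline[channel]


def theoretical_max_em(
    comp: ElementalComposition, lp: LabelParameters, channel: int = 0,
    channels: int = 4,
) -> float:
    """Asymptotic excess of ``channel`` for a fully newly-synthesized pool.

    ``channels`` fixes the reported window over which both baseline and
    enriched patterns are renormalized (M0..M3 for peptides, M0..M2 for
    GC-MS analytes); it must match the window of the measured data. Zero at
    p = 0 (degenerate: downstream f is undefined); negative for M0 at p > 0
    (depletion of the monoisotopic species).
    """
    if lp.p == 0.0:
        return 0.0
    if channel >= channels:
        raise ValidationError(f"channel {channel} outside window of {channels}")
    base = natural_isotope_distribution(comp, channels)
    enr = enriched_distribution(comp, lp, channels)
    return excess_enrichment(enr, base, channel)


def fractional_synthesis(em: float, em_max: float) -> FractionEstimate:
    """Fraction newly synthesized, f = EM / EMmax, with boundary clamping.

    Ratios in (-0.02, 0) clamp to 0 and (1, 1.05) to 1 with a quality flag;
    ratios beyond those bands are recorded as failed measurements (f = NaN)
    and should be excluded downstream.
    """
    if em_max == 0.0:
        raise DegenerateEnrichmentError(
            "EMmax = 0: degenerate precursor enrichment (p = 0?)"
        )
    raw = em / em_max
    if 0.0 <= raw <= 1.0:
        return FractionEstimate(f=raw, flag="ok", raw=raw)
    if CLAMP_LOW < raw < 0.0:
        return FractionEstimate(f=0.0, flag="clamped_low", raw=raw)
    if 1.0 < raw < CLAMP_HIGH:
        return FractionEstimate(f=1.0, flag="clamped_high", raw=raw)
    return FractionEstimate(f=math.nan, flag="failed", raw=raw)


def rate_constant(f: float, t: float) -> float:
    """First-order replacement rate constant k = -ln(1 - f)/t (per day)."""
    if t <= 0:
        raise ValidationError("labeling duration t must be positive")
    if not 0.0 <= f < 1.0:
        raise ValidationError(f"f={f} must lie in [0, 1) for a finite k")
    return -math.log1p(-f) / t
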