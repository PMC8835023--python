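"""GC-MS lipid kinetics: de novo lipogenesis and sterol synthesis.

Palmitate (in triglyceride and phospholipid fractions), cholesterol (free
and esterified) and glycerol are measured as three-channel isotopomer
abundances (M0, M1, M2) together with a concurrently run unenriched
standard. The standard absorbs instrument abundance-sensitivity bias: the
excess enrichment of each channel is the renormalized measured abundance
minus the renormalized standard abundance. The fraction of the pool newly
synthesized during labeling (f_DNL for palmitate, fractional sterol
synthesis for cholesterol) is then the MIDA precursor-product ratio
EM / EMmax at the analyte's effective site count n and body-water
enrichment p, and absolute synthesis is f times the pool mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import constants, mida
from .errors import ValidationError

LIPID_CHANNELS = 3
ABUNDANCE_SUM_RANGE = (0.98, 1.02)

#: cross-channel f estimates differing by more than this raise the MIDA
#: internal-consistency flag
CROSS_CHANNEL_TOLERANCE = 0.05
#: channels whose |EMmax| falls below this carry no usable signal and are
#: excluded from the consistency check
EM_MAX_FLOOR = 1e-3


@dataclass
class LipidMeasurement:
    """One GC-MS analyte measurement with its matched unenriched standard."""

    analyte: str          # palmitate | cholesterol | glycerol
    fraction: str         # TG | PL | free | esterified
    sample: str
    group: str
    time_h: float
    abundances: np.ndarray       # measured M0..M2
    standard: np.ndarray         # matched unenriched standard M0..M2

    def __post_init__(self):
        for name in ("abundances", "standard"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != LIPID_CHANNELS:
                raise ValidationError(
                    f"{name} must have {LIPID_CHANNELS} channels, got {arr.size}"
                )
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} outside [0, 1]")
            lo, hi = ABUNDANCE_SUM_RANGE
            if not lo <= arr.sum() <= hi:
                raise ValidationError(
                    f"{name} sum {arr.sum():.4f} outside quality gate [{lo}, {hi}]"
                )
            setattr(self, name, arr)


@dataclass
class DNLResult:
    """Fractional (and optionally absolute) de novo synthesis of one sample."""

    analyte: str
    fraction: str
    sample: str
    group: str
    time_h: float
    f_dnl: float
    flag: str
    em: np.ndarray                      # per-channel excess over standard
    f_by_channel: dict[int, float] = field(default_factory=dict)
    cross_channel_flag: bool = False
    absolute_dnl_g: float | None = None


def baseline_correct(m: LipidMeasurement) -> np.ndarray:
    """Per-channel excess of the measurement over its unenriched standard.

    Both patterns are renormalized over the three reported channels first,
    so the excesses close to zero: EM0 + EM1 + EM2 = 0.
    """
    measured = m.abundances / m.abundances.sum()
    standard = m.standard / m.standard.sum()
    return measured - standard


def _analyte_params(analyte: str, registry: dict | None = None
                    ) -> tuple[mida.ElementalComposition, float]:
    registry = registry or constants.analyte_registry()
    if analyte not in registry:
        raise ValidationError(f"unknown analyte {analyte!r}; known: {sorted(registry)}")
    entry = registry[analyte]
    comp = mida.ElementalComposition(**entry["composition"])
    return comp, float(entry["n_sites"])


def analyte_em_max(analyte: str, p: float, channel: int = 0,
                   registry: dict | None = None) -> float:
    """EMmax of one channel for a registered analyte at enrichment p."""
    comp, n = _analyte_params(analyte, registry)
    return mida.theoretical_max_em(
        comp, mida.LabelParameters(p=p, n=n), channel, channels=LIPID_CHANNELS
    )


def fractional_dnl(
    em: np.ndarray,
    p: float,
    analyte: str,
    channel: int = 0,
    registry: dict | None = None,
) -> tuple[mida.FractionEstimate, dict[int, float], bool]:
    """Fraction of the analyte pool derived from de novo synthesis.

    Uses the M0-depletion channel by default; per-channel estimates are
    cross-reported, and disagreement beyond CROSS_CHANNEL_TOLERANCE among
    channels with usable EMmax raises the consistency flag.
    """
    if not 0.0 < p <= 0.2:
        raise ValidationError(f"degenerate precursor enrichment p={p}")
    em = np.asarray(em, dtype=float)
    by_channel: dict[int, float] = {}
    for ch in range(LIPID_CHANNELS):
        em_max = analyte_em_max(analyte, p, ch, registry)
        if abs(em_max) >= EM_MAX_FLOOR:
            by_channel[ch] = em[ch] / em_max
    est = mida.fractional_synthesis(
        em[channel], analyte_em_max(analyte, p, channel, registry)
    )
    usable = list(by_channel.values())
    inconsistent = bool(usable) and (max(usable) - min(usable)) > CROSS_CHANNEL_TOLERANCE
    return est, by_channel, inconsistent


def absolute_dnl(f_dnl: float, pool_mass_g: float) -> float:
    """Grams of analyte synthesized de novo: f times the pool mass."""
    if pool_mass_g < 0:
        raise ValidationError("pool mass must be non-negative")
    return f_dnl * pool_mass_g


def dnl_from_measurement(
    m: LipidMeasurement,
    p: float,
    channel: int = 0,
    pool_mass_g: float | None = None,
    registry: dict | None = None,
) -> DNLResult:
    """Full chain for one sample: baseline correction, MIDA ratio, optional
    absolute synthesis."""
    em = baseline_correct(m)
    est, by_channel, inconsistent = fractional_dnl(em, p, m.analyte, channel, registry)
    absolute = None
    if pool_mass_g is not None and not np.isnan(est.f):
        absolute = absolute_dnl(est.f, pool_mass_g)
    return DNLResult(
        analyte=m.analyte, fraction=m.fraction, sample=m.sample, group=m.group,
        time_h=m.time_h, f_dnl=est.f, flag=est.flag, em=em,
        f_by_channel=by_channel, cross_channel_flag=inconsistent,
        absolute_dnl_g=absolute,
    )


def dnl_table(
    lipids: pd.DataFrame,
    p: float | dict[str, float],
    channel: int = 0,
    registry: dict | None = None,
) -> pd.DataFrame:
    """Vectorized DNL over a lipid table with columns analyte, fraction,
    sample, group, time_h, m0..m2, std_m0..std_m2."""
    required = {"analyte", "fraction", "sample", "group", "time_h",
                "m0", "m1", "m2", "std_m0", "std_m1", "std_m2"}
    missing = required - set(lipids.columns)
    if missing:
        raise ValidationError(f"lipid table missing columns: {sorted(missing)}")
    p_of = (lambda s: p[s]) if isinstance(p, dict) else (lambda s: p)
    results = []
    for row in lipids.itertuples(index=False):
        m = LipidMeasurement(
            analyte=row.analyte, fraction=row.fraction, sample=row.sample,
            group=row.group, time_h=row.time_h,
            abundances=np.array([row.m0, row.m1, row.m2]),
            standard=np.array([row.std_m0, row.std_m1, row.std_m2]),
        )
        r = dnl_from_measurement(m, p_of(row.sample), channel, registry=registry)
        results.append(
            {
                "analyte": r.analyte, "fraction": r.fraction, "sample": r.sample,
                "group": r.group, "time_h": r.time_h, "f_dnl": r.f_dnl,
                "quality_flag": r.flag, "em0": r.em[0], "em1": r.em[1],
                "em2": r.em[2], "cross_channel_flag": r.cross_channel_flag,
            }
        )
    return pd.DataFrame(results)


def dnl_group_stats(
    results: pd.DataFrame,
    treated: str,
    control: str,
) -> pd.DataFrame:
    """Group comparison of f_DNL per analyte, fraction and time point.

    Reports group means and SDs, a two-tailed Welch t-test p per time point,
    and a one-way ANOVA p across time points per analyte/fraction/group.
    Groups with a single sample are flagged and get no p-value.
    """
    rows = []
    ok = results[results["quality_flag"] != "failed"]
    for (analyte, fraction, time_h), sub in ok.groupby(
        ["analyte", "fraction", "time_h"], sort=True
    ):
        f_t = sub.loc[sub["group"] == treated, "f_dnl"].dropna().to_numpy()
        f_c = sub.loc[sub["group"] == control, "f_dnl"].dropna().to_numpy()
        row = {
            "analyte": analyte, "fraction": fraction, "time_h": time_h,
            "mean_treated": f_t.mean() if len(f_t) else np.nan,
            "sd_treated": f_t.std(ddof=1) if len(f_t) > 1 else np.nan,
            "n_treated": len(f_t),
            "mean_control": f_c.mean() if len(f_c) else np.nan,
            "sd_control": f_c.std(ddof=1) if len(f_c) > 1 else np.nan,
            "n_control": len(f_c),
            "single_sample_flag": len(f_t) < 2 or len(f_c) < 2,
        }
        if len(f_t) >= 2 and len(f_c) >= 2:
            if np.ptp(f_t) == 0 and np.ptp(f_c) == 0:
                row["p_value"] = 1.0 if f_t.mean() == f_c.mean() else 0.0
            else:
                row["p_value"] = float(stats.ttest_ind(f_t, f_c, equal_var=False).pvalue)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if table.empty:
        return table

    anova = {}
    for (analyte, fraction, group), sub in ok.groupby(
        ["analyte", "fraction", "group"], sort=True
    ):
        samples = [g["f_dnl"].dropna().to_numpy()
                   for _, g in sub.groupby("time_h") if len(g) >= 2]
        if len(samples) >= 2:
            anova[(analyte, fraction, group)] = float(stats.f_oneway(*samples).pvalue)
    table["anova_p_treated"] = [
        anova.get((a, fr, treated), np.nan)
        for a, fr in zip(table["analyte"], table["fraction"])
    ]
    table["anova_p_control"] = [
        anova.get((a, fr, control), np.nan)
        for a, fr in zip(table["analyte"], table["fraction"])
    ]
    return table
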