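"""Synthetic-data generator emulating the in vivo labeling protocols.

Three generators mirror the study designs the analysis modules expect:

* ``simulate_proteome`` — a two-group (treated/control) liver proteome
  labeled from t0, five animals per group, harvests at 6–72 h; every
  peptide's M0–M3 pattern is built from the MIDA forward model at a known
  per-protein turnover k, so protein fractional synthesis, group ratios and
  pathway summaries all have ground truth.
* ``simulate_lipids`` — GC-MS palmitate/cholesterol isotopomer tables with
  matched unenriched standards, built at configured true f values per
  group and time, including an instrument abundance-sensitivity offset that
  the baseline correction must absorb.
* ``simulate_prelabel_study`` — the 7-week pre-label / 2-week washout
  design with fast liver and slow adipose pools, then one of three transfer
  mechanisms during a 72 h treatment window: free-fatty-acid flux (moves
  palmitate label only), intact-glycerolipid flux (moves palmitate and
  glycerol jointly, preserving the source moiety ratio), or dietary influx
  (dilutes both liver moieties with unlabeled material).

All randomness flows from a single integer seed through
``numpy.random.default_rng``; a fixed seed reproduces tables exactly.
Ground truth is returned alongside every measurement table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import lipids as lipids_mod
from . import mida, redistribution
from .errors import ValidationError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

SCENARIOS = ("ffa_transfer", "intact_tg_transfer", "dietary_influx")


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel measurement noise on fractional abundances.

    ``gaussian``: independent Gaussian with the given SD, then clip and
    renormalize. ``multinomial``: ion-counting statistics at the given
    total ion count.
    """

    kind: str = "gaussian"
    sd: float = 0.003
    total_ion_count: int = 200_000

    def __post_init__(self):
        if self.kind not in ("gaussian", "multinomial"):
            raise ValidationError(f"unknown noise model {self.kind!r}")
        if self.sd < 0:
            raise ValidationError("noise SD must be non-negative")
        if self.total_ion_count <= 0:
            raise ValidationError("total ion count must be positive")

    def apply(self, mid: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "multinomial":
            counts = rng.multinomial(self.total_ion_count, mid / mid.sum())
            return counts / self.total_ion_count
        noisy = mid + rng.normal(0.0, self.sd, size=mid.shape) if self.sd > 0 else mid
        noisy = np.clip(noisy, 0.0, None)
        return noisy / noisy.sum()


@dataclass(frozen=True)
class ProteomeSpec:
    """Two-group labeled-proteome design (treated vs control)."""

    n_proteins: int = 100
    animals_per_group: int = 5
    time_points_h: tuple[float, ...] = (6.0, 12.0, 24.0, 48.0, 72.0)
    p: float = 0.05
    noise: NoiseModel = NoiseModel(sd=0.003)
    #: mean of the shifted-geometric peptides-per-protein distribution
    mean_peptides: float = 4.0
    #: log-normal turnover distribution, clipped to k_range (per day)
    k_log_mean: float = -1.2
    k_log_sd: float = 0.8
    k_range: tuple[float, float] = (0.05, 2.0)
    n_pathways: int = 10
    #: treated-group multiplier on k per pathway; pathways absent here get
    #: default_effect. pathway_9 models the chaperone-like subset.
    effect_by_pathway: dict = field(default_factory=dict)
    default_effect: float = 1.0
    treated_label: str = "tunicamycin"
    control_label: str = "control"


def _random_sequences(rng: np.random.Generator, n: int) -> list[str]:
    seqs: list[str] = []
    seen = set()
    while len(seqs) < n:
        length = int(rng.integers(8, 21))
        body = "".join(rng.choice(list(AMINO_ACIDS), size=length - 1))
        seq = body + str(rng.choice(["K", "R"]))
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return seqs


def _forward_mid(sequence: str, f: float, p: float,
                 cache: dict) -> np.ndarray:
    """Noiseless measured M0..M3 of a peptide at fractional synthesis f."""
    if sequence not in cache:
        comp = mida.composition_from_peptide(sequence)
        n = mida.label_site_count(sequence)
        base = mida.natural_isotope_distribution(comp, 4)
        enr = mida.enriched_distribution(comp, mida.LabelParameters(p=p, n=n), 4)
        cache[sequence] = (base, enr)
    base, enr = cache[sequence]
    return base.mix(enr, f).abundances


def simulate_proteome(
    spec: ProteomeSpec = ProteomeSpec(), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Peptide measurement table plus per-protein ground truth.

    Per protein: draw k and peptide count, compute f = 1 - exp(-k t) per
    group and time, build each peptide's measured MID as the baseline/
    enriched mixture at f, and apply the noise model.
    """
    rng = np.random.default_rng(seed)
    n_prot = spec.n_proteins
    sequences_per_protein = []
    n_peps = np.minimum(rng.geometric(1.0 / spec.mean_peptides, n_prot), 12)
    all_seqs = _random_sequences(rng, int(n_peps.sum()))
    pos = 0
    for count in n_peps:
        sequences_per_protein.append(all_seqs[pos:pos + count])
        pos += count

    k_control = np.clip(
        rng.lognormal(spec.k_log_mean, spec.k_log_sd, n_prot), *spec.k_range
    )
    pathways = [f"pathway_{i % spec.n_pathways}" for i in range(n_prot)]
    effects = np.array(
        [spec.effect_by_pathway.get(pw, spec.default_effect) for pw in pathways]
    )

    cache: dict = {}
    pep_rows = []
    truth_rows = []
    groups = (
        (spec.control_label, k_control),
        (spec.treated_label, k_control * effects),
    )
    for i in range(n_prot):
        acc = f"P{i:04d}"
        for group, k_vec in groups:
            k = float(k_vec[i])
            for t_h in spec.time_points_h:
                f_true = 1.0 - np.exp(-k * t_h / 24.0)
                truth_rows.append(
                    {
                        "accession": acc, "pathway": pathways[i], "group": group,
                        "time_h": t_h, "k_per_day": k, "f": f_true,
                        "effect": float(effects[i]),
                        "n_peptides": len(sequences_per_protein[i]),
                    }
                )
                for a in range(spec.animals_per_group):
                    sample = f"{group}_{a}"
                    for seq in sequences_per_protein[i]:
                        clean = _forward_mid(seq, f_true, spec.p, cache)
                        noisy = spec.noise.apply(clean, rng)
                        pep_rows.append(
                            (seq, acc, sample, group, t_h, *noisy)
                        )

    peptides = pd.DataFrame(
        pep_rows,
        columns=["sequence", "accession", "sample", "group", "time_h",
                 "m0", "m1", "m2", "m3"],
    )
    truth = pd.DataFrame(truth_rows)
    return peptides, truth


@dataclass(frozen=True)
class LipidSpec:
    """GC-MS lipid design: true synthesis fractions per analyte/group/time."""

    animals_per_group: int = 5
    p: float = 0.05
    noise: NoiseModel = NoiseModel(sd=0.002)
    #: true f keyed (analyte, fraction, group) -> {time_h: f}
    true_f: dict = field(default_factory=dict)
    #: instrument abundance-sensitivity bias added to measured AND standard
    standard_offset: tuple[float, ...] = (0.0, 0.001, 0.0005)
    treated_label: str = "tunicamycin"
    control_label: str = "control"

    def with_default_design(self) -> "LipidSpec":
        """Suppressed-DNL design: control ~0.30 flat, treated falling to 0.05."""
        times = (12.0, 24.0, 48.0, 72.0)
        control = {t: 0.30 for t in times}
        treated = {12.0: 0.25, 24.0: 0.15, 48.0: 0.05, 72.0: 0.05}
        true_f = {}
        for analyte, fraction in (
            ("palmitate", "TG"), ("palmitate", "PL"),
            ("cholesterol", "free"), ("cholesterol", "esterified"),
        ):
            true_f[(analyte, fraction, self.control_label)] = dict(control)
            true_f[(analyte, fraction, self.treated_label)] = dict(treated)
        return replace(self, true_f=true_f)


def simulate_lipids(
    spec: LipidSpec | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lipid measurement table (with matched standards) plus ground truth."""
    if spec is None:
        spec = LipidSpec().with_default_design()
    if not spec.true_f:
        spec = spec.with_default_design()
    rng = np.random.default_rng(seed)
    offset = np.asarray(spec.standard_offset, dtype=float)
    registry = None  # package defaults

    rows, truth_rows = [], []
    for (analyte, fraction, group), by_time in sorted(spec.true_f.items()):
        comp, n = lipids_mod._analyte_params(analyte, registry)
        base = mida.natural_isotope_distribution(comp, 3)
        enr = mida.enriched_distribution(
            comp, mida.LabelParameters(p=spec.p, n=n), 3
        )
        for t_h, f_true in sorted(by_time.items()):
            truth_rows.append(
                {"analyte": analyte, "fraction": fraction, "group": group,
                 "time_h": t_h, "f_true": f_true}
            )
            for a in range(spec.animals_per_group):
                clean = base.mix(enr, f_true).abundances + offset
                measured = spec.noise.apply(clean, rng)
                standard = spec.noise.apply(base.abundances + offset, rng)
                rows.append(
                    {
                        "analyte": analyte, "fraction": fraction,
                        "sample": f"{group}_{a}", "group": group, "time_h": t_h,
                        "m0": measured[0], "m1": measured[1], "m2": measured[2],
                        "std_m0": standard[0], "std_m1": standard[1],
                        "std_m2": standard[2],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class PrelabelSpec:
    """7-week pre-label / 2-week washout / 72 h treatment design."""

    animals_per_group: int = 4
    plateau_p: float = 0.05
    noise_sd: float = 0.002
    label_days: float = 49.0
    washout_days: float = 14.0
    treatment_days: float = 3.0
    k_liver_tg: float = 0.7
    k_adipose_tg: float = 0.02
    k_liver_pl: float = 0.5
    k_adipose_pl: float = 0.02
    #: basal fraction of liver palmitate carried over from adipose-derived
    #: free fatty acids (sustains nonzero liver palmitate after washout)
    basal_fa_recycling: float = 0.3
    #: basal fraction of liver glycerol label from residual intact uptake
    basal_glycerol_carryover: float = 0.1
    #: fraction of the adipose pool enrichment transferred / diluting during
    #: the treatment window
    transfer_fraction: float = 0.3
    adipose_depletion: float = 0.15
    glycerol_replacement: float = 0.3
    treated_label: str = "tunicamycin"
    control_label: str = "control"


def _pool_asymptote_scale(analyte: str, p: float) -> float:
    """|EMmax(M0)| per unit p for an analyte: converts precursor enrichment
    to the asymptotic product excess."""
    return abs(lipids_mod.analyte_em_max(analyte, p, 0)) / p


from functools import lru_cache


@lru_cache(maxsize=32)
def _prelabel_truth(scenario: str, spec: PrelabelSpec
                    ) -> tuple[dict, dict, dict]:
    """Noiseless (control, treated, washout) pool enrichments for a design.

    Deterministic given (scenario, spec); cached so replicate studies only
    redraw measurement noise instead of re-solving identical pool dynamics.
    """
    protocol = redistribution.LabelingProtocol.prelabel_washout(
        label_days=spec.label_days, washout_days=spec.washout_days,
        extra_days=spec.treatment_days, bolus_target=spec.plateau_p,
    )
    grid = np.linspace(0.0, protocol.total_days, 400)
    p_t = redistribution.body_water_timecourse(protocol, grid)

    c_palm = _pool_asymptote_scale("palmitate", spec.plateau_p)
    c_gly = _pool_asymptote_scale("glycerol", spec.plateau_p)

    pool_k = {
        ("liver", "TG"): spec.k_liver_tg,
        ("liver", "PL"): spec.k_liver_pl,
        ("adipose", "TG"): spec.k_adipose_tg,
        ("adipose", "PL"): spec.k_adipose_pl,
    }
    washout: dict[tuple[str, str, str], float] = {}
    for (tissue, fraction), k in pool_k.items():
        for moiety, c in (("palmitate", c_palm), ("glycerol", c_gly)):
            state = redistribution.pool_enrichment_dynamics(
                k, p_t, c, grid, pool_id=f"{tissue}-{fraction}-{moiety}"
            )
            washout[(tissue, fraction, moiety)] = state.final

    # basal adipose->liver carryover keeps liver pools detectably labeled
    control: dict[tuple[str, str, str], float] = dict(washout)
    for fraction in ("TG", "PL"):
        control[("liver", fraction, "palmitate")] += (
            spec.basal_fa_recycling * washout[("adipose", fraction, "palmitate")]
        )
        control[("liver", fraction, "glycerol")] += (
            spec.basal_glycerol_carryover * washout[("adipose", fraction, "glycerol")]
        )

    treated = dict(control)
    phi = spec.transfer_fraction
    for fraction in ("TG", "PL"):
        adip_palm = control[("adipose", fraction, "palmitate")]
        adip_gly = control[("adipose", fraction, "glycerol")]
        if scenario == "ffa_transfer":
            treated[("liver", fraction, "palmitate")] += phi * adip_palm
            treated[("liver", fraction, "glycerol")] *= 1.0 - spec.glycerol_replacement
            treated[("adipose", fraction, "palmitate")] *= 1.0 - spec.adipose_depletion
        elif scenario == "intact_tg_transfer":
            treated[("liver", fraction, "palmitate")] += phi * adip_palm
            treated[("liver", fraction, "glycerol")] += phi * adip_gly
        else:  # dietary_influx: unlabeled material dilutes both liver moieties
            treated[("liver", fraction, "palmitate")] *= 1.0 - phi
            treated[("liver", fraction, "glycerol")] *= 1.0 - phi

    return control, treated, washout


def simulate_prelabel_study(
    scenario: str,
    spec: PrelabelSpec = PrelabelSpec(),
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Tissue/moiety enrichment table for one transfer scenario, plus truth.

    The control arm is the pure washout trajectory of each pool (liver fast,
    adipose slow) with basal adipose-to-liver recycling; the treated arm
    applies the scenario's mechanism during the 72 h treatment window.
    Enrichments are |M0 depletion| excess fractions.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rng = np.random.default_rng(seed)
    control, treated, washout = _prelabel_truth(scenario, spec)

    rows = []
    for group, values in ((spec.control_label, control), (spec.treated_label, treated)):
        for (tissue, fraction, moiety), e in sorted(values.items()):
            for a in range(spec.animals_per_group):
                noisy = e + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd else 0.0)
                rows.append(
                    {
                        "tissue": tissue, "fraction": fraction, "moiety": moiety,
                        "sample": f"{group}_{a}", "group": group,
                        "enrichment": max(noisy, 0.0),
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "scenario": scenario,
        "control": {"/".join(k): v for k, v in control.items()},
        "treated": {"/".join(k): v for k, v in treated.items()},
        "washout": {"/".join(k): v for k, v in washout.items()},
        "source_glycerol_palmitate_ratio": (
            control[("adipose", "TG", "glycerol")]
            / control[("adipose", "TG", "palmitate")]
        ),
    }
    return table, truth


def comparisons_from_table(
    table: pd.DataFrame,
    treated: str,
    control: str,
    fraction: str = "TG",
) -> tuple[dict[str, redistribution.MoietyComparison], float]:
    """Build the classifier's three input streams from a tidy enrichment
    table, plus the adipose glycerol/palmitate source ratio."""
    sub = table[table["fraction"] == fraction]

    def stream(tissue: str, moiety: str) -> redistribution.MoietyComparison:
        s = sub[(sub["tissue"] == tissue) & (sub["moiety"] == moiety)]
        return redistribution.MoietyComparison(
            treated=s.loc[s["group"] == treated, "enrichment"].to_numpy(),
            control=s.loc[s["group"] == control, "enrichment"].to_numpy(),
        )

    streams = {
        "liver_palmitate": stream("liver", "palmitate"),
        "liver_glycerol": stream("liver", "glycerol"),
        "adipose_palmitate": stream("adipose", "palmitate"),
    }
    adipose_gly = stream("adipose", "glycerol")
    source_ratio = float(
        adipose_gly.control.mean() / streams["adipose_palmitate"].control.mean()
    )
    return streams, source_ratio
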