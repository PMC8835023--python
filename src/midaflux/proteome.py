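"""Peptide-to-protein fractional synthesis rate (FSR) pipeline.

Workflow for a heavy-water labeling proteomics experiment:

1. every peptide's measured M0–M3 pattern is converted to a fractional
   synthesis f by the MIDA precursor–product ratio (``peptide_fsr``);
2. peptide f values are aggregated per protein × animal, keeping proteins
   supported by at least two peptide isotope measurements
   (``aggregate_protein``);
3. treated and control groups are compared per protein and time point with a
   Welch two-tailed t-test on per-animal protein f (``group_compare``);
4. significant proteins are rolled up into peptide-count-weighted KEGG
   pathway summaries (``kegg_pathway_summary``);
5. optionally, protein synthesis log2 fold-changes are set against mRNA
   log2 fold-changes (``mrna_fsr_concordance``).

Tables are pandas DataFrames with documented column names; scalar entry
points accept the dataclasses below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import mida
from .errors import ValidationError

#: reported channel window for peptide extracts
PEPTIDE_CHANNELS = 4
#: acceptable total abundance before renormalization (quality gate)
ABUNDANCE_SUM_RANGE = (0.98, 1.02)

HOURS_PER_DAY = 24.0


@dataclass
class PeptideMeasurement:
    """One peptide's observed M0–M3 with sample metadata."""

    sequence: str
    accession: str
    sample: str
    group: str
    time_h: float
    abundances: np.ndarray  # M0..M3 fractional abundances
    charge: int | None = None
    retention_time: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.abundances, dtype=float)
        if arr.size != PEPTIDE_CHANNELS:
            raise ValidationError(f"expected {PEPTIDE_CHANNELS} channels, got {arr.size}")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("abundances must lie in [0, 1]")
        lo, hi = ABUNDANCE_SUM_RANGE
        if not lo <= arr.sum() <= hi:
            raise ValidationError(
                f"abundance sum {arr.sum():.4f} outside quality gate [{lo}, {hi}]"
            )
        if self.time_h <= 0:
            raise ValidationError("time_h must be positive")
        self.abundances = arr


def _check_p(p: float) -> None:
    if not 0.0 < p <= 0.2:
        raise ValidationError(
            f"body-water enrichment p={p} outside the supported (0, 0.2] range"
        )


@dataclass(frozen=True)
class _PeptideModel:
    """Cached per-sequence MIDA quantities at fixed (p, channel)."""

    baseline: float
    em_max: float
    n_sites: float


def _peptide_model(sequence: str, p: float, site_table, channel: int) -> _PeptideModel:
    comp = mida.composition_from_peptide(sequence)
    n = mida.label_site_count(sequence, site_table)
    baseline = mida.natural_isotope_distribution(comp, PEPTIDE_CHANNELS)
    em_max = mida.theoretical_max_em(
        comp, mida.LabelParameters(p=p, n=n), channel, channels=PEPTIDE_CHANNELS
    )
    return _PeptideModel(baseline=baseline[channel], em_max=em_max, n_sites=n)


def peptide_fsr(
    m: PeptideMeasurement,
    p: float,
    site_table: dict[str, float] | None = None,
    baseline: mida.MassIsotopomerDistribution | None = None,
    channel: int = 0,
) -> mida.FractionEstimate:
    """Fractional synthesis of one peptide from its measured MID.

    ``baseline`` defaults to the computed natural-abundance distribution; a
    matched unenriched measurement may be supplied instead.
    """
    _check_p(p)
    model = _peptide_model(m.sequence, p, site_table, channel)
    base = model.baseline if baseline is None else baseline[channel]
    measured = mida.MassIsotopomerDistribution.from_raw(m.abundances)
    em = measured[channel] - base
    return mida.fractional_synthesis(em, model.em_max)


def peptide_fsr_table(
    peptides: pd.DataFrame,
    p: float | dict[str, float],
    site_table: dict[str, float] | None = None,
    channel: int = 0,
) -> pd.DataFrame:
    """Vectorized ``peptide_fsr`` over a peptide table.

    ``peptides`` needs columns sequence, accession, sample, group, time_h,
    m0..m3. ``p`` is a single enrichment or a per-sample mapping. Returns
    the table with ``f``, ``f_raw`` and ``quality_flag`` columns appended.
    """
    required = {"sequence", "accession", "sample", "group", "time_h",
                "m0", "m1", "m2", "m3"}
    missing = required - set(peptides.columns)
    if missing:
        raise ValidationError(f"peptide table missing columns: {sorted(missing)}")

    p_of = (lambda s: p[s]) if isinstance(p, dict) else (lambda s: p)
    cache: dict[tuple[str, float], _PeptideModel] = {}

    mids = peptides[["m0", "m1", "m2", "m3"]].to_numpy(dtype=float)
    mids = mids / mids.sum(axis=1, keepdims=True)

    f_vals, raws, flags = [], [], []
    for (seq, sample), m0 in zip(
        peptides[["sequence", "sample"]].itertuples(index=False), mids[:, channel]
    ):
        p_s = p_of(sample)
        _check_p(p_s)
        key = (seq, p_s)
        if key not in cache:
            cache[key] = _peptide_model(seq, p_s, site_table, channel)
        model = cache[key]
        est = mida.fractional_synthesis(m0 - model.baseline, model.em_max)
        f_vals.append(est.f)
        raws.append(est.raw)
        flags.append(est.flag)

    out = peptides.copy()
    out["f"] = f_vals
    out["f_raw"] = raws
    out["quality_flag"] = flags
    return out


def aggregate_protein(peptide_f: pd.DataFrame, min_peptides: int = 2) -> pd.DataFrame:
    """Protein-level FSR per animal: unweighted mean of peptide f.

    Proteins with fewer than ``min_peptides`` peptide isotope measurements
    in a sample are excluded; failed-measurement peptides never contribute.
    Returns columns accession, sample, group, time_h, f, k, n_peptides,
    dispersion (SD of peptide f).
    """
    ok = peptide_f[peptide_f["quality_flag"] != "failed"].copy()
    cols = ["accession", "sample", "group", "time_h", "f", "k", "n_peptides",
            "dispersion"]
    if ok.empty:
        return pd.DataFrame(columns=cols)
    grouped = (
        ok.groupby(["accession", "sample", "group", "time_h"], sort=True)["f"]
        .agg(f="mean", n_peptides="count", dispersion="std")
        .reset_index()
    )
    grouped = grouped[grouped["n_peptides"] >= min_peptides].reset_index(drop=True)
    t_days = grouped["time_h"].to_numpy() / HOURS_PER_DAY
    f = grouped["f"].to_numpy()
    grouped["k"] = np.where(
        f < 1.0, -np.log1p(-np.clip(f, None, 1 - 1e-12)) / t_days, np.inf
    )
    return grouped[cols]


@dataclass
class GroupComparisonResult:
    """Per-protein treated/control comparison plus bookkeeping."""

    table: pd.DataFrame
    one_sided: pd.DataFrame  # proteins detected in only one group
    n_omitted: int = 0


def group_compare(proteins: pd.DataFrame, treated: str, control: str
                  ) -> GroupComparisonResult:
    """Treated-vs-control synthesis ratios per protein and time point.

    Per-animal protein f values enter a two-tailed Welch t-test; the ratio
    is of group mean f. Benjamini–Hochberg q-values are reported alongside
    raw p. Proteins present in only one group go to the ``one_sided`` table.
    """
    rows, one_sided_rows = [], []
    for (acc, time_h), sub in proteins.groupby(["accession", "time_h"], sort=True):
        f_t = sub.loc[sub["group"] == treated, "f"].to_numpy()
        f_c = sub.loc[sub["group"] == control, "f"].to_numpy()
        if len(f_t) == 0 or len(f_c) == 0:
            detected_in = treated if len(f_t) else control
            one_sided_rows.append(
                {"accession": acc, "time_h": time_h, "group": detected_in,
                 "n_animals": max(len(f_t), len(f_c))}
            )
            continue
        mean_t, mean_c = f_t.mean(), f_c.mean()
        row = {
            "accession": acc,
            "time_h": time_h,
            "f_treated": mean_t,
            "f_control": mean_c,
            "n_treated": len(f_t),
            "n_control": len(f_c),
        }
        if mean_c > 0 and mean_t > 0:
            row["ratio"] = mean_t / mean_c
            row["log2_ratio"] = math.log2(mean_t / mean_c)
        else:
            row["ratio"] = np.nan
            row["log2_ratio"] = np.nan
        if len(f_t) >= 2 and len(f_c) >= 2:
            if np.ptp(f_t) == 0 and np.ptp(f_c) == 0:
                row["p_value"] = 1.0 if mean_t == mean_c else 0.0
            else:
                row["p_value"] = float(
                    stats.ttest_ind(f_t, f_c, equal_var=False).pvalue
                )
        else:
            row["p_value"] = np.nan
        rows.append(row)

    table = pd.DataFrame(rows)
    if not table.empty:
        mask = table["p_value"].notna()
        q = np.full(len(table), np.nan)
        if mask.any():
            q[mask.to_numpy()] = stats.false_discovery_control(
                table.loc[mask, "p_value"].to_numpy()
            )
        table["q_value"] = q
    one_sided = pd.DataFrame(
        one_sided_rows, columns=["accession", "time_h", "group", "n_animals"]
    )
    return GroupComparisonResult(table=table, one_sided=one_sided,
                                 n_omitted=len(one_sided))


def kegg_pathway_summary(
    comparisons: pd.DataFrame,
    peptide_counts: dict[str, int] | pd.Series,
    mapping: pd.DataFrame,
    min_proteins: int = 5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Peptide-count-weighted pathway means of significant log2 ratios.

    ``mapping`` has columns accession, pathway (one protein may map to many
    pathways). Only proteins with p < ``alpha`` contribute; pathways backed
    by fewer than ``min_proteins`` significant proteins are dropped.
    """
    if mapping is None or mapping.empty:
        raise ValidationError("empty protein-to-pathway mapping")
    need = {"accession", "pathway"}
    if not need <= set(mapping.columns):
        raise ValidationError(f"mapping needs columns {sorted(need)}")

    sig = comparisons[
        comparisons["p_value"].notna()
        & (comparisons["p_value"] < alpha)
        & comparisons["log2_ratio"].notna()
    ].copy()
    counts = pd.Series(peptide_counts, name="peptide_count")
    sig = sig.merge(counts.rename_axis("accession").reset_index(), on="accession")
    merged = sig.merge(mapping.drop_duplicates(), on="accession")

    rows = []
    for (pathway, time_h), sub in merged.groupby(["pathway", "time_h"], sort=True):
        sub = sub.drop_duplicates(subset=["accession"])
        if len(sub) < min_proteins:
            continue
        w = sub["peptide_count"].to_numpy(dtype=float)
        rows.append(
            {
                "pathway": pathway,
                "time_h": time_h,
                "weighted_log2_ratio": float(
                    np.average(sub["log2_ratio"].to_numpy(), weights=w)
                ),
                "n_proteins": len(sub),
                "total_peptides": int(w.sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pathway", "time_h", "weighted_log2_ratio", "n_proteins",
                 "total_peptides"],
    )


@dataclass
class ConcordanceReport:
    """mRNA fold-change vs protein-synthesis fold-change agreement."""

    spearman_rho: float
    spearman_p: float
    sign_agreement: float
    n_shared: int
    divergent: pd.DataFrame = field(default_factory=pd.DataFrame)


def mrna_fsr_concordance(
    mrna_log2fc: pd.Series | dict[str, float],
    fsr_log2: pd.Series | dict[str, float],
    id_map: dict[str, str] | None = None,
    divergence_threshold: float = 0.5,
) -> ConcordanceReport:
    """Spearman correlation and sign agreement between mRNA and synthesis
    fold-changes over shared genes.

    ``id_map`` translates protein accessions (keys of ``fsr_log2``) to gene
    ids; genes with opposite signs and both |log2| above the threshold are
    listed as divergent.
    """
    mrna = pd.Series(mrna_log2fc, dtype=float)
    fsr = pd.Series(fsr_log2, dtype=float)
    if id_map:
        fsr.index = [id_map.get(a, a) for a in fsr.index]
    shared = mrna.index.intersection(fsr.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared genes (< 3)")
    x, y = mrna[shared], fsr[shared]
    rho, pval = stats.spearmanr(x, y)
    signs = np.sign(x.to_numpy()) == np.sign(y.to_numpy())
    divergent_mask = (
        (np.sign(x.to_numpy()) != np.sign(y.to_numpy()))
        & (x.abs().to_numpy() > divergence_threshold)
        & (y.abs().to_numpy() > divergence_threshold)
    )
    divergent = pd.DataFrame(
        {
            "gene": shared[divergent_mask],
            "mrna_log2fc": x.to_numpy()[divergent_mask],
            "fsr_log2": y.to_numpy()[divergent_mask],
        }
    )
    return ConcordanceReport(
        spearman_rho=float(rho),
        spearman_p=float(pval),
        sign_agreement=float(signs.mean()),
        n_shared=len(shared),
        divergent=divergent,
    )
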