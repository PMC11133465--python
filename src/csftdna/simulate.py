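"""Synthetic cohort generator for CSF / plasma tumor-DNA monitoring studies.

Emulates a lumbar-puncture cohort of advanced lung-cancer patients with
suspected leptomeningeal disease: per-patient reporter mutations, two
compartments with very different tumor-DNA content (CSF far above plasma),
position-specific background sequencing error, heterozygous germline SNPs,
focal gene amplifications, compartment-restricted emergent resistance clones,
and survival times whose hazard depends on CSF-tDNA detection status.

The generator is deterministic under a fixed master seed: every sample draws
from a child stream keyed by (patient, compartment, timepoint), so adding or
removing one sample never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .containers import (
    ConfigurationError,
    PositionErrorProfile,
    SampleCounts,
    SelectorPanel,
    ValidationError,
    VARIANT_KEY,
    substream,
)
from .clinical import PatientClinical

_BASES = np.array(list("ACGT"))

# plausible panel genes with their chromosomes; a lung-cancer capture design
_PANEL_GENES = [
    ("EGFR", "chr7", 55086714), ("TP53", "chr17", 7571720), ("KRAS", "chr12", 25358180),
    ("ALK", "chr2", 29415640), ("MET", "chr7", 116312444), ("ERBB2", "chr17", 37844167),
    ("PIK3CA", "chr3", 178866311), ("CDKN2A", "chr9", 21967751), ("RB1", "chr13", 48877883),
    ("KIT", "chr4", 55524095), ("BRAF", "chr7", 140419127), ("STK11", "chr19", 1205798),
    ("KEAP1", "chr19", 10596796), ("NF1", "chr17", 29421945), ("SMAD4", "chr18", 48556583),
    ("CTNNB1", "chr3", 41236328), ("PTEN", "chr10", 89622870), ("ROS1", "chr6", 117609463),
    ("RET", "chr10", 43572517), ("NTRK1", "chr1", 156785432),
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal law parameterized by its median and log-scale sigma."""

    median: float
    sigma: float

    def draw(self, rng: np.random.Generator, size: int | None = None):
        return np.exp(rng.normal(math.log(self.median), self.sigma, size=size))


@dataclass(frozen=True)
class SurvivalParams:
    """Exponential survival model with a detection-dependent hazard.

    baseline_hazard_per_day corresponds to a ~24-month median survival for
    tDNA-negative patients; the hazard of tDNA-positive patients is multiplied
    by ``hazard_ratio_detected``.
    """

    baseline_hazard_per_day: float = math.log(2) / 730.0
    hazard_ratio_detected: float = 6.6
    censor_horizon_days: float = 1500.0
    cns_hazard_per_day: float = math.log(2) / 365.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the emulation targets: 24 patients, CSF mean-VAF median
    32.7% vs plasma 1.8%, deduplicated depth medians 150x (CSF), 1879x
    (plasma) and 1099x (germline).
    """

    n_patients: int = 24
    n_controls: int = 30
    panel_size: int = 2000
    reporters_per_patient: int = 20
    # medians are on the tumor-derived mean-VAF scale (what the assay reports)
    csf_tumor_fraction_dist: LogNormalSpec = LogNormalSpec(0.327, 0.8)
    plasma_tumor_fraction_dist: LogNormalSpec = LogNormalSpec(0.018, 0.8)
    csf_plasma_correlation: float = 0.45
    fraction_tdna_negative: float = 0.2
    depth_by_compartment: dict = field(default_factory=lambda: {
        "CSF": 150.0, "plasma": 1879.0, "germline": 1099.0,
        "tumor": 500.0, "pleural_effusion": 500.0, "control": 1879.0,
    })
    depth_dispersion: float = 20.0  # negative-binomial size parameter
    base_error_rate_mean: float = 1e-4
    base_error_rate_shape: float = 2.0  # Beta alpha; beta set to match the mean
    clonal_vaf: float = 0.5
    subclonal_fraction: float = 0.0  # fraction of reporters at half the clonal VAF
    tumor_purity: float = 0.6  # tumor fraction of the baseline tissue biopsy
    n_germline_snps: int = 5
    amplified_gene_fraction: float = 0.125
    amplification_fold: float = 3.0
    amplified_gene: str = "MET"
    resistance_scenario_fraction: float = 0.3
    post_sample_fraction: float = 0.5
    post_timepoint_days: float = 180.0
    cytology_intercept: float = 2.46  # logistic in log10 tumor fraction
    cytology_slope: float = 1.5
    survival_params: SurvivalParams = SurvivalParams()
    seed: int = 0


def validate_config(config: SimulationConfig) -> None:
    """Raise :class:`ConfigurationError` naming the first invalid field."""
    for name in ("fraction_tdna_negative", "amplified_gene_fraction",
                 "resistance_scenario_fraction", "post_sample_fraction",
                 "subclonal_fraction", "tumor_purity"):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
    for name in ("n_patients", "n_controls", "panel_size", "reporters_per_patient"):
        if getattr(config, name) < 0:
            raise ConfigurationError(f"{name} must be non-negative")
    if config.panel_size < config.reporters_per_patient:
        raise ConfigurationError("panel_size must be >= reporters_per_patient")
    for comp, d in config.depth_by_compartment.items():
        if d <= 0:
            raise ConfigurationError(f"depth_by_compartment[{comp!r}] must be > 0")
    if not 0.0 < config.clonal_vaf <= 1.0:
        raise ConfigurationError("clonal_vaf must lie in (0, 1]")
    if config.base_error_rate_mean <= 0 or config.base_error_rate_mean >= 1:
        raise ConfigurationError("base_error_rate_mean must lie in (0, 1)")
    if not -1.0 <= config.csf_plasma_correlation <= 1.0:
        raise ConfigurationError("csf_plasma_correlation must lie in [-1, 1]")
    if config.survival_params.baseline_hazard_per_day <= 0:
        raise ConfigurationError("survival_params.baseline_hazard_per_day must be > 0")
    if config.survival_params.censor_horizon_days < 0:
        raise ConfigurationError("survival_params.censor_horizon_days must be >= 0")


@dataclass
class GroundTruth:
    """Generating truth for a simulated cohort (the recovery oracle)."""

    reporters: dict[str, pd.DataFrame]  # patient -> chrom,pos,ref,alt,gene,vaf
    germline_snps: dict[str, pd.DataFrame]
    tumor_fraction: dict[str, float]  # sample_id -> fraction
    patients: pd.DataFrame  # patient_id, tdna_positive, csf_tf, plasma_tf, egfr_driven
    amplifications: pd.DataFrame  # patient_id, sample_id, gene, fold
    emergent: pd.DataFrame  # patient_id, compartment, kind, chrom,pos,ref,alt,gene,vaf
    error_rates: pd.DataFrame  # chrom,pos,ref,alt,error_rate (true rates)
    survival_params: SurvivalParams


def simulate_panel(config: SimulationConfig) -> tuple[SelectorPanel, pd.DataFrame]:
    """Build the selector and its per-position true (ref, alt, error-rate) map."""
    rng = substream(config.seed, "panel")
    per_gene = np.full(len(_PANEL_GENES), config.panel_size // len(_PANEL_GENES))
    per_gene[: config.panel_size - per_gene.sum()] += 1
    rows = []
    for (gene, chrom, start), n in zip(_PANEL_GENES, per_gene):
        for i in range(int(n)):
            rows.append((chrom, start + i, gene))
    pos = pd.DataFrame(rows, columns=["chrom", "pos", "gene"])
    pos["coding"] = rng.random(len(pos)) < 0.85
    panel = SelectorPanel(pos)

    p = panel.positions
    ref_i = rng.integers(0, 4, size=len(p))
    alt_i = (ref_i + rng.integers(1, 4, size=len(p))) % 4
    a = config.base_error_rate_shape
    b = a * (1.0 - config.base_error_rate_mean) / config.base_error_rate_mean
    truth = pd.DataFrame({
        "chrom": p["chrom"], "pos": p["pos"],
        "ref": _BASES[ref_i], "alt": _BASES[alt_i],
        "error_rate": rng.beta(a, b, size=len(p)),
    })
    return panel, truth


def true_error_profile(error_rates: pd.DataFrame) -> PositionErrorProfile:
    """Wrap true per-position rates as a profile usable by the simulator."""
    rates = error_rates.copy()
    rates["total_control_depth"] = 0
    rates["usable"] = True
    return PositionErrorProfile(rates=rates, n_controls=0, pseudocounts=(0.0, 0.0),
                                policy="truth")


def simulate_sample_counts(
    truth_vafs: pd.DataFrame | dict,
    tumor_fraction: float,
    depth_mean: float,
    error_profile: PositionErrorProfile,
    seed: int | np.random.Generator,
    *,
    dispersion: float = 20.0,
    constant_vafs: pd.DataFrame | dict | None = None,
    depth_multiplier: pd.Series | None = None,
    sample_id: str = "sim",
) -> SampleCounts:
    """Draw one sample's count table over every position in ``error_profile``.

    Depth at each position is negative-binomial around ``depth_mean`` (times
    the optional per-position ``depth_multiplier``, used for focal
    amplifications).  The alt count is binomial with success probability
    ``tumor_fraction * truth_vaf + constant_vaf + error_rate`` clipped to
    [0, 1]; ``constant_vafs`` carry tumor-fraction-independent signal such as
    heterozygous germline SNPs.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValidationError(f"tumor_fraction must lie in [0, 1], got {tumor_fraction}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    base = error_profile.rates[VARIANT_KEY + ["error_rate"]].copy()

    def _merge(extra, col):
        if extra is None:
            base[col] = 0.0
            return
        if isinstance(extra, dict):
            extra = pd.DataFrame(
                [(c, p, r, a, v) for (c, p, r, a), v in extra.items()],
                columns=VARIANT_KEY + [col],
            )
        else:
            extra = extra.rename(columns={"vaf": col})[VARIANT_KEY + [col]]
        if extra.duplicated(subset=VARIANT_KEY).any():
            raise ValidationError("duplicate positions in truth VAF mapping")
        known = pd.MultiIndex.from_frame(extra[VARIANT_KEY]).isin(
            pd.MultiIndex.from_frame(base[VARIANT_KEY]))
        if not known.all():
            missing = extra.loc[~known, VARIANT_KEY]
            raise ValidationError(
                f"truth positions outside the profiled panel: "
                f"{missing.head().to_dict('records')}"
            )
        merged = base[VARIANT_KEY].merge(extra, on=VARIANT_KEY, how="left")
        base[col] = merged[col].fillna(0.0).to_numpy()

    _merge(truth_vafs, "truth_vaf")
    _merge(constant_vafs, "const_vaf")

    mu = np.full(len(base), float(depth_mean))
    if depth_multiplier is not None:
        idx = pd.MultiIndex.from_frame(base[["chrom", "pos"]])
        mult = depth_multiplier.reindex(idx).fillna(1.0).to_numpy()
        mu = mu * mult
    r = float(dispersion)
    depth = rng.negative_binomial(r, r / (r + mu))
    p = np.clip(tumor_fraction * base["truth_vaf"].to_numpy()
                + base["const_vaf"].to_numpy()
                + base["error_rate"].to_numpy(), 0.0, 1.0)
    alt = rng.binomial(depth, p)
    counts = pd.DataFrame({
        "chrom": base["chrom"], "pos": base["pos"],
        "ref": base["ref"], "alt": base["alt"],
        "depth": depth, "alt_count": alt,
    })
    return SampleCounts(sample_id=sample_id, counts=counts)


def _draw_tumor_fractions(config: SimulationConfig, rng: np.random.Generator,
                          n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlated (CSF, plasma) tumor fractions plus the tDNA-negative mask.

    The configured log-normal medians are on the observed mean-VAF scale;
    the internal tumor fraction is that target divided by the clonal VAF,
    clipped at 1 (clipping only truncates the upper tail, leaving the median
    untouched while the configured median stays below the clonal VAF ceiling).
    """
    rho = config.csf_plasma_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    csf_target = np.exp(math.log(config.csf_tumor_fraction_dist.median)
                        + config.csf_tumor_fraction_dist.sigma * z[:, 0])
    pl_target = np.exp(math.log(config.plasma_tumor_fraction_dist.median)
                       + config.plasma_tumor_fraction_dist.sigma * z[:, 1])
    csf_tf = np.clip(csf_target / config.clonal_vaf, 0.0, 1.0)
    pl_tf = np.clip(pl_target / config.clonal_vaf, 0.0, 1.0)
    negative = rng.random(n) < config.fraction_tdna_negative
    csf_tf[negative] = 0.0
    pl_tf[negative] = 0.0
    return csf_tf, pl_tf, negative


def simulate_cohort(config: SimulationConfig):
    """Generate (panel, samples, clinical, truth) for a full cohort.

    Every patient gets a germline sample, a baseline tumor-tissue sample
    (purity ``tumor_purity``) and baseline CSF + plasma samples; a
    configurable subset additionally gets post-treatment CSF + plasma, among
    whom resistance scenarios (plasma-restricted emergent SNV, with a subset
    also carrying an emergent amplification) are planted.  Tumor-free control
    samples for error-model fitting are appended with compartment ``plasma``
    and patient id ``CTRL*``.
    """
    validate_config(config)
    panel, err_truth = simulate_panel(config)
    profile = true_error_profile(err_truth)
    rng = substream(config.seed, "cohort")

    n = config.n_patients
    patient_ids = [f"LUP{100 + i}" for i in range(n)]
    csf_tf, pl_tf, negative = _draw_tumor_fractions(config, rng, n)

    coding_pos = panel.positions[panel.positions["coding"]].reset_index(drop=True)
    err_idx = pd.MultiIndex.from_frame(err_truth[["chrom", "pos"]])

    n_post = int(round(config.post_sample_fraction * n))
    n_resist = int(round(config.resistance_scenario_fraction * n))
    n_amp = int(round(config.amplified_gene_fraction * n))
    post_patients = set(patient_ids[:n_post])
    resist_patients = set(patient_ids[:min(n_resist, n_post)])
    amp_patients = set(patient_ids[:min(n_amp, n_post)])

    snv_resistance_pool = coding_pos[coding_pos["gene"].isin(
        ["EGFR", "PIK3CA", "KRAS", "CDKN2A", "RB1", "ALK", "KIT", "MET"])]

    reporters: dict[str, pd.DataFrame] = {}
    germline_snps: dict[str, pd.DataFrame] = {}
    tumor_fraction: dict[str, float] = {}
    samples: list[SampleCounts] = []
    amp_rows, emergent_rows = [], []

    def _variants_at(rows: pd.DataFrame) -> pd.DataFrame:
        loc = err_idx.get_indexer(pd.MultiIndex.from_frame(rows[["chrom", "pos"]]))
        out = err_truth.iloc[loc][VARIANT_KEY].reset_index(drop=True)
        out["gene"] = rows["gene"].to_numpy()
        return out

    for i, pid in enumerate(patient_ids):
        prng = substream(config.seed, pid, "truth")
        rep_rows = coding_pos.iloc[
            prng.choice(len(coding_pos), size=config.reporters_per_patient, replace=False)
        ].reset_index(drop=True)
        rep = _variants_at(rep_rows)
        vafs = np.full(len(rep), config.clonal_vaf)
        sub = prng.random(len(rep)) < config.subclonal_fraction
        vafs[sub] = config.clonal_vaf / 2.0
        rep["vaf"] = vafs
        reporters[pid] = rep

        snp_rows = panel.positions.iloc[
            prng.choice(panel.n_positions, size=config.n_germline_snps, replace=False)
        ].reset_index(drop=True)
        snps = _variants_at(snp_rows)
        snps["vaf"] = 0.5
        germline_snps[pid] = snps

        emergent = None
        if pid in resist_patients:
            pool = snv_resistance_pool
            row = pool.iloc[[int(prng.integers(len(pool)))]].reset_index(drop=True)
            emergent = _variants_at(row)
            emergent["vaf"] = config.clonal_vaf / 2.0
            emergent_rows.append({
                "patient_id": pid, "compartment": "plasma", "kind": "snv",
                **emergent.iloc[0][VARIANT_KEY + ["gene"]].to_dict(),
                "vaf": float(emergent.iloc[0]["vaf"]),
            })

        def _make(comp, tname, tf, tdays, state, snv_extra=None, amp_gene=None):
            sid = f"{pid}_{comp}_{tname}"
            tvaf = reporters[pid][VARIANT_KEY + ["vaf"]]
            if snv_extra is not None:
                # reporter VAF wins if the emergent clone hits a reporter position
                tvaf = pd.concat([tvaf, snv_extra[VARIANT_KEY + ["vaf"]]],
                                 ignore_index=True).drop_duplicates(
                    subset=VARIANT_KEY, keep="first")
            mult = None
            if amp_gene is not None:
                gmask = panel.positions["gene"] == amp_gene
                mult = pd.Series(
                    np.where(gmask, config.amplification_fold, 1.0),
                    index=pd.MultiIndex.from_frame(panel.positions[["chrom", "pos"]]))
                amp_rows.append({"patient_id": pid, "sample_id": sid,
                                 "gene": amp_gene, "fold": config.amplification_fold})
            sc = simulate_sample_counts(
                tvaf, tf, config.depth_by_compartment[comp], profile,
                substream(config.seed, pid, comp, tname),
                dispersion=config.depth_dispersion,
                constant_vafs=germline_snps[pid][VARIANT_KEY + ["vaf"]],
                depth_multiplier=mult, sample_id=sid)
            sc.patient_id = pid
            sc.compartment = comp
            sc.timepoint_days = tdays
            sc.treatment_state = state
            tumor_fraction[sid] = float(tf)
            samples.append(sc)

        _make("germline", "t0", 0.0, 0.0, "pre")
        _make("tumor", "t0", config.tumor_purity, 0.0, "pre")
        _make("CSF", "t0", csf_tf[i], 0.0, "pre")
        _make("plasma", "t0", pl_tf[i], 0.0, "pre")
        if pid in post_patients:
            drift = float(np.exp(prng.normal(0.0, 0.3)))
            post_csf = min(1.0, csf_tf[i] * drift)
            post_pl = min(1.0, pl_tf[i] * drift)
            amp_gene = config.amplified_gene if pid in amp_patients else None
            if amp_gene is not None:
                emergent_rows.append({
                    "patient_id": pid, "compartment": "plasma", "kind": "cnv",
                    "chrom": None, "pos": None, "ref": None, "alt": None,
                    "gene": amp_gene, "vaf": np.nan,
                })
            _make("CSF", "t180", post_csf, config.post_timepoint_days, "post")
            _make("plasma", "t180", post_pl, config.post_timepoint_days, "post",
                  snv_extra=emergent, amp_gene=amp_gene)

    for j in range(config.n_controls):
        sid = f"CTRL{j:03d}"
        sc = simulate_sample_counts(
            None, 0.0, config.depth_by_compartment["control"], profile,
            substream(config.seed, sid, "control"),
            dispersion=config.depth_dispersion, sample_id=sid)
        sc.patient_id = sid
        sc.compartment = "plasma"
        sc.timepoint_days = 0.0
        sc.treatment_state = "pre"
        samples.append(sc)

    patients = pd.DataFrame({
        "patient_id": patient_ids,
        "tdna_positive": ~negative,
        "csf_tumor_fraction": csf_tf,
        "plasma_tumor_fraction": pl_tf,
        "egfr_driven": [i < int(round(n * 20 / 24)) for i in range(n)],
        "has_post_samples": [pid in post_patients for pid in patient_ids],
    })
    truth = GroundTruth(
        reporters=reporters,
        germline_snps=germline_snps,
        tumor_fraction=tumor_fraction,
        patients=patients,
        amplifications=pd.DataFrame(
            amp_rows, columns=["patient_id", "sample_id", "gene", "fold"]),
        emergent=pd.DataFrame(
            emergent_rows,
            columns=["patient_id", "compartment", "kind"] + VARIANT_KEY + ["gene", "vaf"]),
        error_rates=err_truth,
        survival_params=config.survival_params,
    )
    clinical = simulate_clinical(truth, config.survival_params,
                                 substream(config.seed, "clinical"), config=config)
    return panel, samples, clinical, truth


def simulate_clinical(truth: GroundTruth, survival_params: SurvivalParams,
                      seed, *, config: SimulationConfig | None = None
                      ) -> list[PatientClinical]:
    """Clinical table consistent with the generating truth.

    Overall-survival times are exponential with the baseline hazard times the
    configured hazard ratio for tDNA-positive patients, censored at the
    horizon.  Cytology positivity follows a logistic law in log10 CSF tumor
    fraction, so high-burden patients are nearly always cytology-positive
    while low-burden tDNA-positive patients can be cytology-negative.
    """
    if survival_params.baseline_hazard_per_day <= 0:
        raise ConfigurationError("survival_params.baseline_hazard_per_day must be > 0")
    cfg = config if config is not None else SimulationConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    horizon = survival_params.censor_horizon_days
    for row in truth.patients.itertuples(index=False):
        detected = bool(row.tdna_positive)
        tf = float(row.csf_tumor_fraction)
        hr = survival_params.hazard_ratio_detected if detected else 1.0
        t_os = rng.exponential(1.0 / (survival_params.baseline_hazard_per_day * hr))
        t_cns = rng.exponential(1.0 / (survival_params.cns_hazard_per_day * hr))
        if tf > 0:
            p_cyt = float(expit(cfg.cytology_intercept
                                + cfg.cytology_slope * math.log10(max(tf * cfg.clonal_vaf, 1e-6))))
        else:
            p_cyt = 0.02
        cyt = bool(rng.random() < p_cyt)
        mri = bool(rng.random() < (0.8 if tf > 0 else 0.15))
        sym = bool(rng.random() < (0.9 if tf > 0 else 0.6))
        pcr = bool(row.egfr_driven and tf > 0 and rng.random() < 0.7)
        if getattr(row, "has_post_samples", False):
            plasma_nm = float(np.exp(rng.normal(math.log(500.0), 0.4)))
            pen = float(np.exp(rng.normal(math.log(2.5), 0.5)))
            csf_nm = plasma_nm * pen / 100.0
        else:
            plasma_nm = csf_nm = None
        out.append(PatientClinical(
            patient_id=row.patient_id,
            cytology_positive=cyt,
            egfr_csf_pcr_positive=pcr,
            mri_unequivocal_lmd=mri,
            progressive_symptoms=sym,
            os_time_days=float(min(t_os, horizon)),
            os_event=bool(t_os <= horizon),
            cns_progression_time_days=float(min(t_cns, horizon)),
            cns_event=bool(t_cns <= horizon),
            csf_osimertinib_nM=csf_nm,
            plasma_osimertinib_nM=plasma_nm,
        ))
    return out


def controls_of(samples: list[SampleCounts]) -> list[SampleCounts]:
    """The tumor-free control samples of a simulated cohort."""
    return [s for s in samples if s.patient_id and s.patient_id.startswith("CTRL")]


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    return replace(config, seed=int(seed))
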