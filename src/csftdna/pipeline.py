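"""End-to-end orchestration: error model -> calls -> reporters -> detection ->
SCNA -> resistance -> clinical, with file outputs and a reproducibility log."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calling, clinical as clin, detection, io, resistance, scna
from .containers import (
    ConfigurationError,
    SampleCounts,
    UndefinedResultError,
    ValidationError,
)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

try:
    __version__ = _pkg_version("csftdna")
except PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for one pipeline run.

    Every numeric default that appears in output headers comes from here;
    there are no hidden constants downstream.
    """

    panel_bed: str = "panel.bed"
    counts_dir: str = "counts"
    sample_sheet: str = "sample_sheet.tsv"
    clinical_tsv: str = "clinical.tsv"
    out_dir: str = "out"
    control_prefix: str = "CTRL"
    detection_cutoff: float = detection.DETECTION_CUTOFF
    mc_iterations: int = detection.DEFAULT_B
    alpha: float = 0.05
    germline_vaf_threshold: float = calling.GERMLINE_VAF_THRESHOLD
    z_amp: float = scna.Z_AMP_DEFAULT
    z_del: float = scna.Z_DEL_DEFAULT
    time_match_window_days: float = resistance.TIME_MATCH_WINDOW_DAYS
    cnv_genes: list[str] = field(default_factory=lambda: ["MET", "ERBB2", "EGFR"])
    endpoint: str = "OS"  # OS | cns
    survival_inclusion: str = "definitive"  # definitive | all
    missing_germline_policy: str = "warn"  # warn | fail
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_cutoff < 1.0:
            raise ConfigurationError("detection_cutoff must lie in (0, 1)")
        if self.endpoint not in ("OS", "cns"):
            raise ConfigurationError("endpoint must be 'OS' or 'cns'")
        if self.survival_inclusion not in ("definitive", "all"):
            raise ConfigurationError("survival_inclusion must be 'definitive' or 'all'")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        """Load a YAML config; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def simulate_to_dir(config: SimulationConfig, out_dir) -> None:
    """Write a simulated cohort in the pipeline's input formats."""
    out = Path(out_dir)
    (out / "counts").mkdir(parents=True, exist_ok=True)
    panel, samples, clinical_records, truth = simulate_cohort(config)
    io.write_bed(panel, out / "panel.bed")
    for s in samples:
        io.write_counts_tsv(s, out / "counts" / f"{s.sample_id}.tsv")
    io.write_sample_sheet(samples, out / "sample_sheet.tsv")
    io.write_clinical(clinical_records, out / "clinical.tsv")
    io.write_truth_json(truth, out / "truth.json")


def _pick_pre_sample(samples: list[SampleCounts]) -> SampleCounts | None:
    """Pre-TKI sample preference: tumor, then pleural effusion, then pre CSF."""
    for comp in ("tumor", "pleural_effusion", "CSF"):
        cands = [s for s in samples
                 if s.compartment == comp and (s.treatment_state or "pre") == "pre"]
        if cands:
            return cands[0]
    return None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage on the configured inputs; returns the stats bundle.

    Patients whose inputs are incomplete (e.g. a deleted germline sample) are
    flagged and, where a stage cannot proceed for them, skipped for that
    stage; the pipeline completes for everyone else.  A rerun with the same
    config and seed reproduces every output byte-identically.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    notes: list[str] = []
    try:
        panel = io.read_bed(config.panel_bed)
        sheet = io.read_sample_sheet(config.sample_sheet)
        samples = io.read_counts_dir(config.counts_dir, sheet)
        clinical_records = io.read_clinical(config.clinical_tsv)
        by_id = {s.sample_id: s for s in samples}

        controls = [s for s in samples
                    if (s.patient_id or "").startswith(config.control_prefix)]
        study = [s for s in samples if s not in controls]
        patients = sorted({s.patient_id for s in study if s.patient_id})

        stage = "error_model"
        profile = calling.estimate_error_profile(controls)
        io.write_error_model(profile, out / "error_model.tsv")

        stage = "calls"
        calls_dir = out / "calls"
        calls_dir.mkdir(exist_ok=True)
        per_sample_calls: dict[str, pd.DataFrame] = {}
        for s in sorted(study, key=lambda x: x.sample_id):
            if s.compartment == "germline":
                continue
            germ = next((g for g in study if g.patient_id == s.patient_id
                         and g.compartment == "germline"), None)
            res = calling.call_variants_tumor_naive(s, profile, panel,
                                                    alpha=config.alpha)
            kept, removed = calling.exclude_germline(
                res.calls, germ, profile,
                germline_vaf_threshold=config.germline_vaf_threshold,
                alpha=config.alpha, missing_policy="warn")
            if germ is None:
                notes.append(f"{s.sample_id}: no germline sample; "
                             "SNP exclusion skipped")
            coding = calling.filter_coding(kept, panel)
            ann = kept.copy()
            key = ["chrom", "pos", "ref", "alt"]
            coding_idx = pd.MultiIndex.from_frame(coding[key])
            kept_idx = pd.MultiIndex.from_frame(ann[key])
            ann["filter"] = np.where(kept_idx.isin(coding_idx), "PASS", "noncoding")
            removed = removed.assign(filter="germline")
            shared = [c for c in ann.columns if c in removed.columns]
            vcf_rows = pd.concat([ann, removed[shared]], ignore_index=True)
            io.write_vcf(vcf_rows, calls_dir / f"{s.sample_id}.vcf", panel)
            per_sample_calls[s.sample_id] = coding

        stage = "reporter_sets"
        reporters = {}
        for pid in patients:
            psamples = [s for s in study if s.patient_id == pid]
            try:
                rs = calling.build_reporter_set(
                    psamples, profile, panel, alpha=config.alpha,
                    germline_vaf_threshold=config.germline_vaf_threshold,
                    missing_germline_policy=config.missing_germline_policy)
            except ValidationError as exc:
                notes.append(f"{pid}: reporter set skipped ({exc})")
                continue
            notes.extend(f"{pid}: {w}" for w in rs.warnings)
            reporters[pid] = rs
            rs.variants.to_csv(out / "calls" / f"{pid}.reporters.tsv",
                               sep="\t", index=False)

        stage = "detection"
        det_results = []
        for s in sorted(study, key=lambda x: x.sample_id):
            if s.compartment == "germline" or s.patient_id not in reporters:
                continue
            rs = reporters[s.patient_id]
            if len(rs) == 0:
                notes.append(f"{s.sample_id}: empty reporter set, detection undefined")
                continue
            try:
                det_results.append(detection.detection_index(
                    s, rs, profile, B=config.mc_iterations, seed=config.seed,
                    cutoff=config.detection_cutoff))
            except UndefinedResultError as exc:
                notes.append(str(exc))
        det_tab = detection.detection_table(det_results, by_id)
        det_tab.to_csv(out / "detection.tsv", sep="\t", index=False)

        stage = "scna"
        bg_norms = pd.DataFrame([scna.normalize_depth(c, panel) for c in controls])
        scna_rows = []
        for s in sorted(study, key=lambda x: x.sample_id):
            if s.compartment == "germline":
                continue
            zmap = scna.scna_zscores(scna.normalize_depth(s, panel), bg_norms)
            scna_rows += scna.call_scna(zmap, config.z_amp, config.z_del,
                                        config.cnv_genes, sample_id=s.sample_id)
        scna_tab = scna.scna_table(scna_rows)
        scna_tab.to_csv(out / "scna.tsv", sep="\t", index=False)
        scna_by_sample = {sid: g for sid, g in scna_tab.groupby("sample_id")}

        def _cnv_alts(sid):
            g = scna_by_sample.get(sid)
            if g is None:
                return []
            hits = g[g["call"].isin(["amplification", "deletion"])]
            return [resistance.CnvAlteration(gene=r.gene, direction=r.call)
                    for r in hits.itertuples(index=False)]

        stage = "resistance"
        concord_frames, res_rows = [], []
        for pid in patients:
            psamples = [s for s in study if s.patient_id == pid]
            pre = _pick_pre_sample(psamples)
            post_plasma = next((s for s in psamples if s.compartment == "plasma"
                                and s.treatment_state == "post"), None)
            post_csf = next((s for s in psamples if s.compartment == "CSF"
                             and s.treatment_state == "post"), None)
            if post_plasma is None and post_csf is None:
                continue
            if pre is None:
                notes.append(f"{pid}: no pre-TKI sample, excluded from "
                             "resistance analysis")
                continue
            pre_alts = (resistance.calls_from_dataframe(
                per_sample_calls.get(pre.sample_id, pd.DataFrame(
                    columns=["chrom", "pos", "ref", "alt", "gene", "coding"])))
                + _cnv_alts(pre.sample_id))
            comp_calls = {}
            for comp, post in (("plasma", post_plasma), ("CSF", post_csf)):
                if post is None:
                    comp_calls[comp] = []
                    continue
                post_alts = (resistance.calls_from_dataframe(
                    per_sample_calls.get(post.sample_id, pd.DataFrame(
                        columns=["chrom", "pos", "ref", "alt", "gene", "coding"])))
                    + _cnv_alts(post.sample_id))
                calls_, log = resistance.emergent_variants(
                    pre_alts, post_alts, patient_id=pid, compartment=comp,
                    timepoint_days=post.timepoint_days, pre_sample=pre)
                notes.extend(f"{pid}: {line}" for line in log)
                comp_calls[comp] = calls_
                res_rows += [{
                    "patient_id": pid, "compartment": comp,
                    "alteration": c.alteration.label(),
                    "emergent": c.emergent, "present_pre": c.present_pre,
                } for c in calls_]
            if post_plasma is not None and post_csf is not None:
                try:
                    concord_frames.append(resistance.compare_compartments(
                        comp_calls["plasma"], comp_calls["CSF"],
                        post_plasma.timepoint_days, post_csf.timepoint_days,
                        max_gap_days=config.time_match_window_days))
                except ValidationError as exc:
                    notes.append(f"{pid}: {exc}")
        res_tab = pd.DataFrame(res_rows, columns=["patient_id", "compartment",
                                                  "alteration", "emergent",
                                                  "present_pre"])
        res_tab.to_csv(out / "resistance.tsv", sep="\t", index=False)
        concord = (pd.concat(concord_frames, ignore_index=True) if concord_frames
                   else pd.DataFrame(columns=["patient_id", "alteration", "kind",
                                              "gene", "category"]))
        resistance.patient_summary(concord).to_csv(
            out / "resistance_summary.tsv", sep="\t", index=False)

        stage = "clinical"
        stats = _clinical_stage(config, clinical_records, det_tab, out, notes)

        stats["run"] = {
            "seed": config.seed, "version": __version__,
            "config_hash": config.digest(), "n_patients": len(patients),
            "n_samples": len(samples), "n_controls": len(controls),
            "notes": notes,
        }
        with open(out / "stats.json", "w") as fh:
            json.dump(stats, fh, indent=1, default=_jsonable)
        (out / "run_log.partial.json").unlink(missing_ok=True)
        logger.info("pipeline complete: seed=%s version=%s config=%s",
                    config.seed, __version__, config.digest())
        return stats
    except Exception:
        with open(out / "run_log.partial.json", "w") as fh:
            json.dump({"failed_stage": stage, "notes": notes}, fh, indent=1)
        logger.exception("pipeline failed at stage %s", stage)
        raise


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _clinical_stage(config: PipelineConfig, clinical_records, det_tab: pd.DataFrame,
                    out: Path, notes: list[str]) -> dict:
    """LMD classification, modality sensitivities, survival and associations."""
    baseline_csf = det_tab[(det_tab["compartment"] == "CSF")
                           & (det_tab["timepoint_days"] == 0)]
    det_by_patient = dict(zip(baseline_csf["patient_id"], baseline_csf["detected"]))
    vaf_by_patient = dict(zip(baseline_csf["patient_id"], baseline_csf["mean_vaf"]))
    baseline_plasma = det_tab[(det_tab["compartment"] == "plasma")
                              & (det_tab["timepoint_days"] == 0)]
    plasma_vaf = dict(zip(baseline_plasma["patient_id"], baseline_plasma["mean_vaf"]))

    statuses = {r.patient_id: clin.classify_lmd(r) for r in clinical_records}
    lmd_tab = pd.DataFrame([{
        "patient_id": pid, "study_category": s.study_category,
        "eano_esmo": s.eano_esmo, "data_complete": s.data_complete,
    } for pid, s in statuses.items()])
    lmd_tab.to_csv(out / "lmd_status.tsv", sep="\t", index=False)

    sens_rows = []
    modalities = {
        "cytology": lambda r: r.cytology_positive,
        "mri": lambda r: r.mri_unequivocal_lmd,
        "csf_tdna": lambda r: det_by_patient.get(r.patient_id),
    }
    stats: dict = {"sensitivity": {}}
    for name, getter in modalities.items():
        cohort = [(statuses[r.patient_id], getter(r)) for r in clinical_records]
        try:
            sens, num, den = clin.modality_sensitivity(cohort)
            sens_rows.append({"modality": name, "sensitivity_pct": 100 * sens,
                              "numerator": num, "denominator": den})
            stats["sensitivity"][name] = {"pct": 100 * sens, "n": num, "d": den}
        except UndefinedResultError as exc:
            notes.append(f"sensitivity[{name}]: {exc}")
    pd.DataFrame(sens_rows).to_csv(out / "sensitivity.tsv", sep="\t", index=False)

    rows = []
    for r in clinical_records:
        det = det_by_patient.get(r.patient_id)
        if det is None:
            continue
        if (config.survival_inclusion == "definitive"
                and statuses[r.patient_id].study_category != "definitive"):
            continue
        if config.endpoint == "OS":
            t, e = r.os_time_days, r.os_event
        else:
            t, e = r.cns_progression_time_days, r.cns_event
        if t is None or e is None:
            continue
        rows.append((t, e, "detected" if det else "not_detected"))
    surv_row = {}
    if rows:
        t, e, g = zip(*rows)
        if len(set(g)) == 2:
            cmp_ = clin.km_logrank(t, e, g, endpoint=config.endpoint,
                                   reference="not_detected")
            surv_row = {
                "endpoint": cmp_.endpoint, "hazard_ratio": cmp_.hazard_ratio,
                "hr_ci_low": cmp_.hr_ci_low, "hr_ci_high": cmp_.hr_ci_high,
                "logrank_p": cmp_.logrank_p, "n_not_detected": cmp_.n_group1,
                "n_detected": cmp_.n_group2,
            }
            stats["survival"] = surv_row
        else:
            notes.append("survival: only one detection group present, "
                         "comparison skipped")
    pd.DataFrame([surv_row] if surv_row else []).to_csv(
        out / "survival.tsv", sep="\t", index=False)

    assoc_rows = []
    paired = [(vaf_by_patient[p], plasma_vaf[p]) for p in vaf_by_patient
              if p in plasma_vaf]
    if len(paired) >= 3:
        x, y = zip(*paired)
        try:
            sp = clin.spearman_corr(x, y)
            assoc_rows.append({"analysis": "csf_vs_plasma_vaf", "kind": sp.kind,
                               "statistic": sp.statistic, "p_value": sp.p_value,
                               "n": sp.n})
        except UndefinedResultError as exc:
            notes.append(f"association: {exc}")
        mw = clin.mann_whitney(list(x), list(y))
        assoc_rows.append({"analysis": "csf_vs_plasma_vaf_levels", "kind": mw.kind,
                           "statistic": mw.statistic, "p_value": mw.p_value,
                           "n": mw.n})
    pens = []
    for r in clinical_records:
        if r.csf_osimertinib_nM is not None and r.plasma_osimertinib_nM:
            pens.append(clin.penetration_rate(r.csf_osimertinib_nM,
                                              r.plasma_osimertinib_nM))
    if pens:
        stats["osimertinib_penetration_pct"] = {
            "median": float(np.median(pens)), "n": len(pens)}
    stats["associations"] = assoc_rows
    pd.DataFrame(assoc_rows).to_csv(out / "associations.tsv", sep="\t", index=False)
    return stats
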