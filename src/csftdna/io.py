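"""Readers and writers for the pipeline's file formats.

Dialects (all tab-separated, headered, plain text):

* counts: ``sample_id chrom pos ref alt depth alt_count`` — one substitution
  per row, ``pos`` 1-based, one sample per file.
* sample sheet: ``sample_id patient_id compartment timepoint_days
  treatment_state``.
* clinical: one row per patient, booleans as ``1/0``, empty field = unknown.
* selector: BED with 0-based half-open intervals and ``gene``/``coding``
  columns; the 1-based per-position representation used everywhere else is
  converted here and only here.
* variant calls: VCF 4.2 via pysam (INFO: VAF, DEPTH, ALTC, PBIN, GENE;
  FILTER: germline, noncoding, background).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .clinical import PatientClinical
from .containers import (
    COUNT_COLUMNS,
    PositionErrorProfile,
    SampleCounts,
    SelectorPanel,
    ValidationError,
    VARIANT_KEY,
)

_SHEET_COLUMNS = ["sample_id", "patient_id", "compartment", "timepoint_days",
                  "treatment_state"]
_CLINICAL_BOOLS = ["cytology_positive", "egfr_csf_pcr_positive",
                   "mri_unequivocal_lmd", "progressive_symptoms", "os_event",
                   "cns_event"]
_CLINICAL_FLOATS = ["os_time_days", "cns_progression_time_days",
                    "csf_osimertinib_nM", "plasma_osimertinib_nM"]


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_counts_tsv(path, sheet_row: dict | None = None) -> SampleCounts:
    """Read one sample's counts table; metadata comes from the sample sheet row."""
    path = Path(path)
    df = _read_tsv(path, ["sample_id"] + COUNT_COLUMNS)
    sids = df["sample_id"].unique()
    if len(sids) != 1:
        raise ValidationError(f"{path}: expected exactly one sample_id, got {list(sids)}")
    for col in ("pos", "depth", "alt_count"):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ValidationError(f"{path}:{line}: non-numeric value in field {col!r}")
    bad = (df["alt_count"] > df["depth"]) | (df["alt_count"] < 0) | (df["depth"] < 0)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValidationError(f"{path}:{line}: alt_count exceeds depth (or negative)")
    meta = sheet_row or {}
    return SampleCounts(
        sample_id=str(sids[0]),
        counts=df[COUNT_COLUMNS].reset_index(drop=True),
        patient_id=meta.get("patient_id"),
        compartment=meta.get("compartment"),
        timepoint_days=meta.get("timepoint_days"),
        treatment_state=meta.get("treatment_state"),
    )


def write_counts_tsv(sample: SampleCounts, path) -> None:
    out = sample.counts[COUNT_COLUMNS].copy()
    out.insert(0, "sample_id", sample.sample_id)
    out.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = _read_tsv(path, _SHEET_COLUMNS)
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample_id in sample sheet")
    return df[_SHEET_COLUMNS]


def write_sample_sheet(samples: list[SampleCounts], path) -> None:
    rows = [{"sample_id": s.sample_id, "patient_id": s.patient_id,
             "compartment": s.compartment, "timepoint_days": s.timepoint_days,
             "treatment_state": s.treatment_state} for s in samples]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts_dir(counts_dir, sheet: pd.DataFrame) -> list[SampleCounts]:
    """Load every sample named in the sheet from ``<counts_dir>/<sample_id>.tsv``."""
    counts_dir = Path(counts_dir)
    out = []
    for row in sheet.to_dict("records"):
        p = counts_dir / f"{row['sample_id']}.tsv"
        if not p.exists():
            raise ValidationError(f"counts file missing for sample {row['sample_id']}: {p}")
        out.append(read_counts_tsv(p, row))
    return out


def read_bed(path) -> SelectorPanel:
    """Read a selector BED (0-based half-open) into per-position 1-based form."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValidationError(f"{path}:{ln}: expected >= 5 BED fields")
            chrom, start, end, gene, coding = parts[:5]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: non-integer interval") from exc
            if end_i <= start_i:
                raise ValidationError(f"{path}:{ln}: empty or inverted interval")
            for pos in range(start_i + 1, end_i + 1):  # to 1-based inclusive
                rows.append((chrom, pos, gene, coding in ("1", "True", "true")))
    return SelectorPanel(pd.DataFrame(rows, columns=["chrom", "pos", "gene", "coding"]))


def write_bed(panel: SelectorPanel, path) -> None:
    regions = panel.regions()
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.gene}\t{int(r.coding)}\n")


def read_clinical(path) -> list[PatientClinical]:
    df = _read_tsv(path, ["patient_id"])

    def _b(v):
        if pd.isna(v):
            return None
        return bool(int(v))

    def _f(v):
        return None if pd.isna(v) else float(v)

    out = []
    for row in df.to_dict("records"):
        kwargs = {"patient_id": str(row["patient_id"])}
        for col in _CLINICAL_BOOLS:
            kwargs[col] = _b(row.get(col))
        for col in _CLINICAL_FLOATS:
            kwargs[col] = _f(row.get(col))
        out.append(PatientClinical(**kwargs))
    return out


def write_clinical(records: list[PatientClinical], path) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        for col in _CLINICAL_BOOLS:
            v = getattr(r, col)
            row[col] = "" if v is None else int(v)
        for col in _CLINICAL_FLOATS:
            v = getattr(r, col)
            row[col] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_error_model(profile: PositionErrorProfile, path) -> None:
    out = profile.rates.copy()
    with open(path, "w") as fh:
        fh.write(f"# n_controls={profile.n_controls} "
                 f"pseudocounts={profile.pseudocounts[0]:.6g},"
                 f"{profile.pseudocounts[1]:.6g} policy={profile.policy}\n")
        out.to_csv(fh, sep="\t", index=False)


def read_error_model(path) -> PositionErrorProfile:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValidationError(f"{path}: missing error-model metadata header")
        meta = dict(kv.split("=", 1) for kv in header[1:].split())
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    a, b = (float(x) for x in meta["pseudocounts"].split(","))
    return PositionErrorProfile(rates=df, n_controls=int(meta["n_controls"]),
                                pseudocounts=(a, b), policy=meta.get("policy", "explicit"))


def _vcf_header(panel: SelectorPanel) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in sorted(panel.positions["chrom"].unique()):
        header.contigs.add(chrom, length=2_000_000_000)
    header.filters.add("germline", None, None, "Excluded as germline SNP")
    header.filters.add("noncoding", None, None, "Non-protein-coding position")
    header.filters.add("background", None, None, "Not above background error")
    header.info.add("VAF", 1, "Float", "Variant allele fraction")
    header.info.add("DEPTH", 1, "Integer", "Deduplicated depth")
    header.info.add("ALTC", 1, "Integer", "Alt allele count")
    header.info.add("PBIN", 1, "Float", "One-sided binomial tail probability")
    header.info.add("GENE", 1, "String", "Gene symbol")
    return header


def write_vcf(calls: pd.DataFrame, path, panel: SelectorPanel) -> None:
    """Write calls as VCF 4.x; a ``filter`` column (if present) sets FILTER."""
    header = _vcf_header(panel)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in calls.sort_values(VARIANT_KEY).itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom, start=int(row.pos) - 1, stop=int(row.pos),
                alleles=(row.ref, row.alt))
            rec.info["VAF"] = float(getattr(row, "vaf", np.nan))
            rec.info["DEPTH"] = int(row.depth)
            rec.info["ALTC"] = int(row.alt_count)
            if hasattr(row, "p_value") and not pd.isna(row.p_value):
                rec.info["PBIN"] = float(row.p_value)
            gene = getattr(row, "gene", None)
            if gene is not None and not pd.isna(gene):
                rec.info["GENE"] = str(gene)
            filt = getattr(row, "filter", "PASS")
            rec.filter.add(filt if isinstance(filt, str) and filt else "PASS")
            vf.write(rec)


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            rows.append({
                "chrom": rec.contig, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else None,
                "depth": rec.info.get("DEPTH"), "alt_count": rec.info.get("ALTC"),
                "vaf": rec.info.get("VAF"), "p_value": rec.info.get("PBIN"),
                "gene": rec.info.get("GENE"),
                "filter": ";".join(rec.filter.keys()) or "PASS",
            })
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth",
                                       "alt_count", "vaf", "p_value", "gene",
                                       "filter"])


def write_truth_json(truth, path) -> None:
    """Serialize a :class:`~csftdna.simulate.GroundTruth` to JSON."""
    payload = {
        "reporters": {p: df.to_dict("records") for p, df in truth.reporters.items()},
        "germline_snps": {p: df.to_dict("records")
                          for p, df in truth.germline_snps.items()},
        "tumor_fraction": truth.tumor_fraction,
        "patients": truth.patients.to_dict("records"),
        "amplifications": truth.amplifications.to_dict("records"),
        "emergent": truth.emergent.to_dict("records"),
        "survival_params": {
            "baseline_hazard_per_day": truth.survival_params.baseline_hazard_per_day,
            "hazard_ratio_detected": truth.survival_params.hazard_ratio_detected,
            "censor_horizon_days": truth.survival_params.censor_horizon_days,
            "cns_hazard_per_day": truth.survival_params.cns_hazard_per_day,
        },
    }

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default, allow_nan=True)
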