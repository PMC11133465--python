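"""Background error model and tumor-naive variant calling.

Stereotyped base-substitution errors are suppressed by pooling alt counts
across tumor-free control samples into a position- and substitution-specific
error rate.  A variant is then called when the one-sided binomial tail
probability of the observed alt count at that rate clears a
Bonferroni-adjusted threshold over the panel.  Germline SNPs are excluded
against the matched germline sample, non-coding positions are dropped, and
the patient's joint reporter set is the union of calls across baseline
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    PositionErrorProfile,
    ReporterSet,
    SampleCounts,
    SelectorPanel,
    ValidationError,
    VARIANT_KEY,
)

logger = logging.getLogger(__name__)

#: default prior pseudo-depth for the shrinkage pseudocount policy
DEFAULT_PRIOR_DEPTH = 1000.0

#: default germline VAF at or above which a candidate is excluded as a SNP
GERMLINE_VAF_THRESHOLD = 0.02

#: minimum depth for a position to count as covered in the germline sample
GERMLINE_MIN_DEPTH = 20


def estimate_error_profile(
    controls: list[SampleCounts],
    pseudocounts: tuple[float, float] | str = "shrink",
    prior_depth: float = DEFAULT_PRIOR_DEPTH,
) -> PositionErrorProfile:
    """Pool control samples into per-position background error rates.

    For each (position, substitution), ``error_rate = (sum alt + a) /
    (sum depth + b)``.  With an explicit ``pseudocounts=(a, b)`` those values
    are used as given.  The default policy ``"shrink"`` sets ``b =
    prior_depth`` and ``a = prior_depth * pooled_rate`` where ``pooled_rate``
    is the panel-wide alt fraction over all controls: rates are shrunk toward
    the global background instead of toward an absolute count, which keeps
    every rate positive (a Monte Carlo null requirement) without inflating
    rates at ultra-low-error positions.

    Positions with zero pooled control depth are flagged unusable rather than
    silently assigned a rate.
    """
    if len(controls) < 2:
        raise ValidationError("error-model estimation needs >= 2 control samples")
    key = controls[0].counts[VARIANT_KEY]
    alt = np.zeros(len(key), dtype=float)
    depth = np.zeros(len(key), dtype=float)
    ref_idx = pd.MultiIndex.from_frame(key)
    for c in controls:
        idx = pd.MultiIndex.from_frame(c.counts[VARIANT_KEY])
        loc = ref_idx.get_indexer(idx)
        if (loc < 0).any():
            raise ValidationError(
                f"control {c.sample_id} covers positions absent from the first control")
        np.add.at(alt, loc, c.counts["alt_count"].to_numpy(float))
        np.add.at(depth, loc, c.counts["depth"].to_numpy(float))

    if pseudocounts == "shrink":
        pooled = alt.sum() / depth.sum() if depth.sum() > 0 else 0.0
        a, b = prior_depth * pooled, prior_depth
        policy = "shrink"
    else:
        a, b = float(pseudocounts[0]), float(pseudocounts[1])
        policy = "explicit"

    usable = depth > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(usable, (alt + a) / (depth + b), np.nan)
    n_unusable = int((~usable).sum())
    if n_unusable:
        logger.warning("%d panel positions had zero control depth and are unusable",
                       n_unusable)
    rates = key.copy()
    rates["error_rate"] = rate
    rates["total_control_depth"] = depth
    rates["usable"] = usable
    return PositionErrorProfile(rates=rates, n_controls=len(controls),
                                pseudocounts=(a, b), policy=policy)


def binomial_tail(alt_count, depth, error_rate) -> np.ndarray:
    """P(X >= alt_count) for X ~ Binomial(depth, error_rate); 1 at alt_count=0."""
    alt_count = np.asarray(alt_count)
    return stats.binom.sf(alt_count - 1, np.asarray(depth), np.asarray(error_rate))


@dataclass
class CallResult:
    """Called variants plus the QC tallies of what was skipped."""

    calls: pd.DataFrame
    n_tested: int
    n_tests_bonferroni: int
    alpha: float
    n_missing_profile: int = 0
    n_outside_panel: int = 0
    warnings: list[str] = field(default_factory=list)


def call_variants_tumor_naive(
    sample: SampleCounts,
    profile: PositionErrorProfile,
    panel: SelectorPanel,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> CallResult:
    """Call variants against the background error model.

    A position is called when its one-sided binomial tail probability falls
    at or below ``alpha / n_tests`` (Bonferroni over the panel; ``n_tests``
    defaults to the panel position count).  Positions outside the panel or
    missing a usable error rate are excluded and counted in the QC report.
    Calls are sorted by position and annotated with gene and coding flags.
    """
    c = sample.counts
    in_panel = panel.contains(c)
    n_outside = int((~in_panel).sum())
    c = c[in_panel].reset_index(drop=True)
    rates = profile.lookup(c)
    missing = rates.isna()
    n_missing = int(missing.sum())
    c = c[~missing.to_numpy()].reset_index(drop=True)
    rates = rates[~missing.to_numpy()].reset_index(drop=True)

    if n_tests is None:
        n_tests = panel.n_positions
    threshold = alpha / n_tests
    p = binomial_tail(c["alt_count"], c["depth"], rates)
    called = (p <= threshold) & (c["alt_count"].to_numpy() > 0)

    calls = c[called].copy()
    calls["vaf"] = calls["alt_count"] / calls["depth"].replace(0, np.nan)
    calls["p_value"] = p[called]
    ann = calls.merge(panel.positions, on=["chrom", "pos"], how="left")
    calls["gene"] = ann["gene"].to_numpy()
    calls["coding"] = ann["coding"].to_numpy()
    calls = calls.sort_values(VARIANT_KEY).reset_index(drop=True)

    warnings = []
    if n_missing:
        warnings.append(f"{n_missing} positions lacked a usable error rate")
    if n_outside:
        warnings.append(f"{n_outside} positions fell outside the panel")
    return CallResult(calls=calls, n_tested=len(c), n_tests_bonferroni=int(n_tests),
                      alpha=alpha, n_missing_profile=n_missing,
                      n_outside_panel=n_outside, warnings=warnings)


def exclude_germline(
    candidates: pd.DataFrame,
    germline: SampleCounts | None,
    profile: PositionErrorProfile | None = None,
    germline_vaf_threshold: float = GERMLINE_VAF_THRESHOLD,
    alpha: float = 0.05,
    n_tests: int | None = None,
    missing_policy: str = "fail",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove candidates that look germline in the matched normal sample.

    A candidate is excluded when its germline VAF is at or above the
    (inclusive) threshold, or when the same binomial test calls it in the
    germline sample.  Returns (kept, removed) where ``removed`` carries a
    ``reason`` column.  With no germline sample, ``missing_policy`` selects
    between failing and passing everything through with a warning flag.
    """
    if germline is None:
        if missing_policy == "fail":
            raise ValidationError("no germline sample available for SNP exclusion")
        kept = candidates.copy()
        kept["germline_checked"] = False
        removed = candidates.iloc[0:0].copy()
        removed["reason"] = pd.Series(dtype=str)
        return kept, removed

    g = germline.counts
    merged = candidates.merge(
        g[VARIANT_KEY + ["depth", "alt_count"]].rename(
            columns={"depth": "g_depth", "alt_count": "g_alt"}),
        on=VARIANT_KEY, how="left")
    g_depth = merged["g_depth"].fillna(0).to_numpy(float)
    g_alt = merged["g_alt"].fillna(0).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_vaf = np.where(g_depth > 0, g_alt / g_depth, 0.0)

    is_snp = (g_depth >= GERMLINE_MIN_DEPTH) & (g_vaf >= germline_vaf_threshold)
    reason = np.where(is_snp, "germline_vaf", "")

    if profile is not None:
        rates = profile.lookup(merged).to_numpy()
        ok = ~np.isnan(rates) & (g_depth > 0)
        if n_tests is None:
            n_tests = len(profile.rates)
        p = np.ones(len(merged))
        p[ok] = binomial_tail(g_alt[ok], g_depth[ok], rates[ok])
        called_in_germline = ok & (p <= alpha / n_tests) & (g_alt > 0)
        reason = np.where(~is_snp & called_in_germline, "germline_called", reason)
        is_snp = is_snp | called_in_germline

    kept = candidates[~is_snp].copy()
    kept["germline_checked"] = True
    removed = candidates[is_snp].copy()
    removed["reason"] = reason[is_snp]
    if len(removed):
        logger.info("excluded %d germline candidates (%s)", len(removed),
                    removed["reason"].value_counts().to_dict())
    return kept.reset_index(drop=True), removed.reset_index(drop=True)


def filter_coding(candidates: pd.DataFrame, panel: SelectorPanel) -> pd.DataFrame:
    """Retain protein-coding candidates; unannotated positions count as non-coding."""
    if len(candidates) == 0:
        return candidates.copy()
    ann = candidates.merge(panel.positions[["chrom", "pos", "coding"]],
                           on=["chrom", "pos"], how="left", suffixes=("", "_panel"))
    coding_col = "coding_panel" if "coding_panel" in ann.columns else "coding"
    coding = ann[coding_col].astype("boolean").fillna(False).to_numpy(bool)
    n_unann = int(ann[coding_col].isna().sum())
    if n_unann:
        logger.warning("%d candidate positions unannotated; treated as non-coding",
                       n_unann)
    return candidates[coding].reset_index(drop=True)


def build_reporter_set(
    patient_samples: list[SampleCounts],
    profile: PositionErrorProfile,
    panel: SelectorPanel,
    alpha: float = 0.05,
    germline_vaf_threshold: float = GERMLINE_VAF_THRESHOLD,
    baseline_states: tuple[str, ...] = ("pre",),
    missing_germline_policy: str = "fail",
) -> ReporterSet:
    """Union of coding, germline-excluded calls across a patient's baseline samples.

    Baseline samples are the non-germline samples whose treatment state is in
    ``baseline_states`` (tumor and pleural-effusion samples always qualify).
    Provenance (which samples each variant was called in) is recorded; the
    output is invariant to sample ordering.
    """
    non_germ = [s for s in patient_samples if s.compartment != "germline"]
    if not non_germ:
        raise ValidationError("reporter set needs at least one non-germline sample")
    patient_id = non_germ[0].patient_id or "unknown"
    germline = next((s for s in patient_samples if s.compartment == "germline"), None)
    baseline = [s for s in non_germ
                if s.compartment in ("tumor", "pleural_effusion")
                or (s.treatment_state or "pre") in baseline_states]

    warnings: list[str] = []
    frames = []
    for s in sorted(baseline, key=lambda x: x.sample_id):
        res = call_variants_tumor_naive(s, profile, panel, alpha=alpha)
        warnings += [f"{s.sample_id}: {w}" for w in res.warnings]
        kept, _ = exclude_germline(res.calls, germline, profile,
                                   germline_vaf_threshold=germline_vaf_threshold,
                                   alpha=alpha, missing_policy=missing_germline_policy)
        if germline is None:
            warnings.append(f"{s.sample_id}: no germline sample; SNP exclusion skipped")
        kept = filter_coding(kept, panel)
        kept = kept.assign(source=s.sample_id)
        frames.append(kept[VARIANT_KEY + ["gene", "coding", "source"]])

    if frames and sum(len(f) for f in frames):
        allc = pd.concat(frames, ignore_index=True)
        grouped = (allc.groupby(VARIANT_KEY + ["gene", "coding"], sort=True)["source"]
                   .apply(lambda s: ";".join(sorted(s))).reset_index()
                   .rename(columns={"source": "sources"}))
    else:
        grouped = pd.DataFrame(columns=VARIANT_KEY + ["gene", "coding", "sources"])
    return ReporterSet(patient_id=patient_id, variants=grouped, warnings=warnings)
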