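"""Tumor-DNA quantification over a patient's joint reporter set.

The sample-level tumor-DNA measure is the unweighted mean VAF over the
patient's reporters.  Significance comes from a Monte Carlo detection index:
B null replicates draw alt counts at each reporter from Binomial(observed
depth, background error rate), and the index is the fraction of null mean
VAFs at or above the observed one, with a +1 pseudocount so the index is a
valid p-value bounded below by 1/(B+1).  Samples with index <= 0.05 are
classified as tumor-DNA detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    PositionErrorProfile,
    ReporterSet,
    SampleCounts,
    UndefinedResultError,
    ValidationError,
    VARIANT_KEY,
    substream,
)

#: detection index at or below which tumor DNA is classified as detected
DETECTION_CUTOFF = 0.05

#: default number of Monte Carlo null iterations
DEFAULT_B = 10_000


@dataclass(frozen=True)
class DetectionResult:
    sample_id: str
    n_reporters_evaluated: int
    mean_vaf: float
    detection_index: float
    detected: bool
    mc_iterations: int
    seed: int


def _reporter_counts(sample: SampleCounts, reporters: ReporterSet) -> pd.DataFrame:
    """The sample's count rows at the reporter positions (all of them)."""
    rep = reporters.variants[VARIANT_KEY]
    merged = rep.merge(sample.counts, on=VARIANT_KEY, how="left")
    if merged["depth"].isna().any():
        missing = merged[merged["depth"].isna()][VARIANT_KEY]
        raise ValidationError(
            f"sample {sample.sample_id} has no counts at reporter positions: "
            f"{missing.head().to_dict('records')}")
    return merged


def mean_vaf(sample: SampleCounts, reporters: ReporterSet) -> tuple[float, int]:
    """Unweighted mean VAF over reporters with depth > 0.

    Returns (mean_vaf, n_evaluated); reporters with zero depth are excluded
    from the average and from the evaluated count.  Zero evaluable reporters
    is an undefined result, not 0.
    """
    if len(reporters) == 0:
        raise UndefinedResultError(
            f"patient {reporters.patient_id}: empty reporter set, mean VAF undefined")
    m = _reporter_counts(sample, reporters)
    evaluable = m["depth"] > 0
    n_eval = int(evaluable.sum())
    if n_eval == 0:
        raise UndefinedResultError(
            f"sample {sample.sample_id}: zero evaluable reporters (all depth 0)")
    v = (m.loc[evaluable, "alt_count"] / m.loc[evaluable, "depth"]).to_numpy(float)
    return float(v.mean()), n_eval


def detection_index(
    sample: SampleCounts,
    reporters: ReporterSet,
    profile: PositionErrorProfile,
    B: int = DEFAULT_B,
    seed: int = 0,
    cutoff: float = DETECTION_CUTOFF,
) -> DetectionResult:
    """Monte Carlo detection index for one sample.

    The null conditions on the observed depths: for b in 1..B, alt counts at
    each evaluable reporter are drawn Binomial(depth, error_rate) and averaged
    the same way as the observed statistic.  index = (1 + #{null mean VAF >=
    observed}) / (B + 1).  The random stream is derived from (seed, sample id,
    reporter-set content hash), so adding other samples to a run never
    perturbs this sample's index.
    """
    if B < 1000:
        raise ValidationError(f"B must be >= 1000, got {B}")
    obs, n_eval = mean_vaf(sample, reporters)  # raises on zero evaluable
    m = _reporter_counts(sample, reporters)
    m = m[m["depth"] > 0].reset_index(drop=True)
    rates = profile.lookup(m)
    if rates.isna().any():
        missing = m[rates.isna().to_numpy()][VARIANT_KEY]
        raise ValidationError(
            f"reporters missing from error profile: {missing.to_dict('records')}")

    rep_hash = pd.util.hash_pandas_object(
        reporters.variants[VARIANT_KEY], index=False).sum()
    rng = substream(seed, sample.sample_id, int(rep_hash % (1 << 32)))

    depth = m["depth"].to_numpy(np.int64)
    err = rates.to_numpy(float)
    null_alt = rng.binomial(depth[None, :], err[None, :], size=(B, len(depth)))
    null_mean = (null_alt / depth[None, :]).mean(axis=1)
    index = (1.0 + int((null_mean >= obs).sum())) / (B + 1.0)
    return DetectionResult(
        sample_id=sample.sample_id, n_reporters_evaluated=n_eval, mean_vaf=obs,
        detection_index=float(index), detected=classify_detection(index, cutoff),
        mc_iterations=int(B), seed=int(seed))


def classify_detection(index: float, cutoff: float = DETECTION_CUTOFF) -> bool:
    """Detected if and only if the index is at or below the cutoff (inclusive)."""
    if not 0.0 < index <= 1.0:
        raise ValidationError(f"detection index must lie in (0, 1], got {index}")
    return index <= cutoff


def detection_table(results: list[DetectionResult],
                    samples: dict[str, SampleCounts] | None = None) -> pd.DataFrame:
    """Tabulate detection results (one row per sample) for TSV export."""
    rows = []
    for r in results:
        s = samples.get(r.sample_id) if samples else None
        rows.append({
            "sample_id": r.sample_id,
            "patient_id": s.patient_id if s else None,
            "compartment": s.compartment if s else None,
            "timepoint_days": s.timepoint_days if s else None,
            "n_reporters": r.n_reporters_evaluated,
            "mean_vaf": r.mean_vaf,
            "detection_index": r.detection_index,
            "detected": r.detected,
        })
    return pd.DataFrame(rows)
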