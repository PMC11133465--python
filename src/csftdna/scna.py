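"""Gene-level somatic copy-number calling by z-score against background samples.

Depth at each gene is normalized to the sample's on-target mean, then scored
against a background cohort that captures region-specific coverage
variability: z = (x - mean_bg) / sd_bg with the unbiased standard deviation.
Focal amplifications and deletions are called at a symmetric 3-sigma
threshold by default, optionally restricted to a gene list of interest
(e.g. MET, ERBB2, EGFR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SampleCounts, SelectorPanel, ValidationError

logger = logging.getLogger(__name__)

Z_AMP_DEFAULT = 3.0
Z_DEL_DEFAULT = 3.0


@dataclass(frozen=True)
class SCNAResult:
    sample_id: str
    gene: str
    normalized_depth: float
    z_score: float | None
    log2_ratio: float | None
    call: str  # amplification | deletion | neutral | uncallable


def normalize_depth(sample: SampleCounts, panel: SelectorPanel) -> pd.Series:
    """Per-gene mean depth divided by the panel-wide mean depth.

    Genes with no covered position (all depths zero or absent) are dropped
    from the mapping and logged.  Normalization removes library size, so a
    global scaling of the sample's depths leaves the output unchanged.
    """
    m = panel.positions[["chrom", "pos", "gene"]].merge(
        sample.counts[["chrom", "pos", "depth"]], on=["chrom", "pos"], how="left")
    overall = m["depth"].mean()
    if not overall > 0:
        raise ValidationError(f"sample {sample.sample_id}: no on-target coverage")
    by_gene = m.groupby("gene", sort=True)["depth"].agg(["mean", "count"])
    covered = m.dropna(subset=["depth"]).groupby("gene")["depth"].sum() > 0
    out = (by_gene["mean"] / overall)[covered.reindex(by_gene.index, fill_value=False)]
    dropped = set(by_gene.index) - set(out.index)
    if dropped:
        logger.warning("sample %s: genes with zero coverage dropped: %s",
                       sample.sample_id, sorted(dropped))
    return out.rename("normalized_depth")


def scna_zscores(sample_norm: pd.Series,
                 background_norms: list[pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """z-score and log2 ratio of a sample's normalized depths against background.

    Needs at least three background samples per gene; genes whose background
    standard deviation is zero are flagged uncallable (z and log2_ratio NaN).
    """
    bg = (background_norms if isinstance(background_norms, pd.DataFrame)
          else pd.DataFrame(background_norms))
    if len(bg) < 3:
        raise ValidationError("scna_zscores needs >= 3 background samples")
    genes = sample_norm.index.intersection(bg.columns)
    mean_bg = bg[genes].mean(axis=0)
    sd_bg = bg[genes].std(axis=0, ddof=1)
    x = sample_norm[genes]
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean_bg) / sd_bg
        l2 = np.log2(x / mean_bg)
    callable_ = (sd_bg > 0) & (mean_bg > 0)
    out = pd.DataFrame({
        "normalized_depth": x,
        "z": z.where(callable_),
        "log2_ratio": l2.where(callable_),
        "callable": callable_,
    })
    return out.sort_index()


def call_scna(zmap: pd.DataFrame, z_amp: float = Z_AMP_DEFAULT,
              z_del: float = Z_DEL_DEFAULT, cnv_genes: list[str] | None = None,
              sample_id: str = "sample") -> list[SCNAResult]:
    """Threshold z-scores into amplification / deletion / neutral calls.

    When ``cnv_genes`` is given, calls are restricted to those genes;
    otherwise every scored panel gene is reported.
    """
    if z_amp <= 0 or z_del <= 0:
        raise ValidationError("z thresholds must be > 0")
    genes = zmap.index if cnv_genes is None else [g for g in zmap.index
                                                 if g in set(cnv_genes)]
    out = []
    for gene in genes:
        row = zmap.loc[gene]
        if not bool(row["callable"]):
            call = "uncallable"
            z = l2 = None
        else:
            z = float(row["z"])
            l2 = float(row["log2_ratio"])
            if z >= z_amp:
                call = "amplification"
            elif z <= -z_del:
                call = "deletion"
            else:
                call = "neutral"
        out.append(SCNAResult(sample_id=sample_id, gene=str(gene),
                              normalized_depth=float(row["normalized_depth"]),
                              z_score=z, log2_ratio=l2, call=call))
    return out


def loo_background_zscores(background_norms: list[pd.Series] | pd.DataFrame
                           ) -> pd.DataFrame:
    """Leave-one-out self z-scores of the background cohort.

    Each background sample is scored against the mean and unbiased sd of the
    remaining samples — the calibration check that background members look
    approximately standard normal.
    """
    bg = (background_norms if isinstance(background_norms, pd.DataFrame)
          else pd.DataFrame(background_norms)).reset_index(drop=True)
    if len(bg) < 4:
        raise ValidationError("leave-one-out calibration needs >= 4 background samples")
    rows = []
    for i in range(len(bg)):
        rest = bg.drop(index=i)
        z = (bg.iloc[i] - rest.mean(axis=0)) / rest.std(axis=0, ddof=1)
        rows.append(z)
    return pd.DataFrame(rows).reset_index(drop=True)


def scna_table(results: list[SCNAResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": r.sample_id, "gene": r.gene,
        "normalized_depth": r.normalized_depth, "z": r.z_score,
        "log2_ratio": r.log2_ratio, "call": r.call,
    } for r in results])
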