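"""Emergent resistance alterations after targeted therapy, by compartment.

Post-TKI calls are restricted to resistance-associated gene whitelists
(exonic SNVs in EGFR, PIK3CA, KRAS, CDKN2A, RB1, ALK, KIT, MET; copy-number
changes in MET, ERBB2, EGFR).  An alteration is emergent when present in the
post-TKI sample and absent from the pre-TKI sample, with a minimum pre-TKI
coverage guard so an uncovered position is never mistaken for emergence.
Emergent sets from time-matched plasma and CSF (collected within 14 days of
each other) are then partitioned into plasma-only / CSF-only / shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .containers import SampleCounts, ValidationError

logger = logging.getLogger(__name__)

SNV_RESISTANCE_GENES = frozenset(
    {"EGFR", "PIK3CA", "KRAS", "CDKN2A", "RB1", "ALK", "KIT", "MET"})
CNV_RESISTANCE_GENES = frozenset({"MET", "ERBB2", "EGFR"})

#: minimum pre-TKI depth at an SNV position for an "absent pre" claim
MIN_PRE_DEPTH = 50

#: maximum days between time-matched plasma and CSF samples (inclusive)
TIME_MATCH_WINDOW_DAYS = 14.0


@dataclass(frozen=True)
class SnvAlteration:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    coding: bool = True

    def label(self) -> str:
        return f"{self.gene} {self.chrom}:{self.pos}{self.ref}>{self.alt}"


@dataclass(frozen=True)
class CnvAlteration:
    gene: str
    direction: str  # amplification | deletion

    def label(self) -> str:
        return f"{self.gene} {self.direction}"


@dataclass(frozen=True)
class ResistanceCall:
    patient_id: str
    alteration: SnvAlteration | CnvAlteration
    compartment: str
    timepoint_days: float | None
    emergent: bool
    present_pre: bool
    present_post: bool


def _identity(alt) -> tuple:
    if isinstance(alt, SnvAlteration):
        return ("snv", alt.chrom, alt.pos, alt.ref, alt.alt)
    return ("cnv", alt.gene, alt.direction)


def emergent_variants(
    pre_calls: list,
    post_calls: list,
    snv_whitelist: frozenset = SNV_RESISTANCE_GENES,
    cnv_whitelist: frozenset = CNV_RESISTANCE_GENES,
    patient_id: str = "unknown",
    compartment: str = "plasma",
    timepoint_days: float | None = None,
    pre_sample: SampleCounts | None = None,
    min_pre_depth: int = MIN_PRE_DEPTH,
) -> tuple[list[ResistanceCall], list[str]]:
    """Whitelist-restricted post-TKI alterations absent from the pre-TKI sample.

    SNV identity is (chrom, pos, ref, alt); CNV identity is (gene,
    direction).  Non-whitelisted or non-exonic alterations are never
    considered.  When ``pre_sample`` counts are supplied, an SNV whose
    pre-TKI position has depth below ``min_pre_depth`` is not called emergent
    (logged as ``low_pre_depth``): absence cannot be asserted there.
    Returns (calls, log).
    """
    pre_ids = {_identity(a) for a in pre_calls}
    log: list[str] = []
    pre_depth: dict[tuple, float] = {}
    if pre_sample is not None:
        for row in pre_sample.counts.itertuples(index=False):
            pre_depth[(row.chrom, row.pos)] = max(
                pre_depth.get((row.chrom, row.pos), 0), row.depth)

    calls: list[ResistanceCall] = []
    seen = set()
    for alt in post_calls:
        ident = _identity(alt)
        if ident in seen:
            continue
        seen.add(ident)
        if isinstance(alt, SnvAlteration):
            if alt.gene not in snv_whitelist:
                continue
            if not alt.coding:
                log.append(f"{alt.label()}: non-exonic, skipped")
                continue
        else:
            if alt.gene not in cnv_whitelist:
                continue
        present_pre = ident in pre_ids
        emergent = not present_pre
        if (emergent and isinstance(alt, SnvAlteration) and pre_sample is not None):
            d = pre_depth.get((alt.chrom, alt.pos), 0)
            if d < min_pre_depth:
                log.append(f"{alt.label()}: low_pre_depth ({d}x < {min_pre_depth}x), "
                           "not called emergent")
                emergent = False
        calls.append(ResistanceCall(
            patient_id=patient_id, alteration=alt, compartment=compartment,
            timepoint_days=timepoint_days, emergent=emergent,
            present_pre=present_pre, present_post=True))
    return calls, log


def compare_compartments(
    plasma_emergent: list[ResistanceCall],
    csf_emergent: list[ResistanceCall],
    plasma_timepoint_days: float | None = None,
    csf_timepoint_days: float | None = None,
    max_gap_days: float = TIME_MATCH_WINDOW_DAYS,
) -> pd.DataFrame:
    """Partition emergent alterations into plasma-only / csf-only / shared.

    Each emergent alteration lands in exactly one category, so the category
    counts sum to the size of the union.  When both timepoints are supplied,
    a gap above ``max_gap_days`` (inclusive window) rejects the pair.
    """
    if plasma_timepoint_days is not None and csf_timepoint_days is not None:
        gap = abs(plasma_timepoint_days - csf_timepoint_days)
        if gap > max_gap_days:
            raise ValidationError(
                f"plasma/CSF samples {gap:.0f} days apart exceed the "
                f"{max_gap_days:.0f}-day time-matching window")
    p = {_identity(c.alteration): c for c in plasma_emergent if c.emergent}
    c = {_identity(x.alteration): x for x in csf_emergent if x.emergent}
    rows = []
    for ident in sorted(set(p) | set(c), key=str):
        call = p.get(ident, c.get(ident))
        if ident in p and ident in c:
            cat = "shared"
        elif ident in p:
            cat = "plasma_only"
        else:
            cat = "csf_only"
        rows.append({
            "patient_id": call.patient_id,
            "alteration": call.alteration.label(),
            "kind": ident[0],
            "gene": call.alteration.gene,
            "category": cat,
        })
    return pd.DataFrame(rows, columns=["patient_id", "alteration", "kind", "gene",
                                       "category"])


def patient_summary(concordance: pd.DataFrame) -> pd.DataFrame:
    """Per-patient counts of each concordance category."""
    if len(concordance) == 0:
        return pd.DataFrame(columns=["patient_id", "plasma_only", "csf_only",
                                     "shared", "total"])
    tab = (concordance.groupby("patient_id")["category"]
           .value_counts().unstack(fill_value=0))
    for col in ("plasma_only", "csf_only", "shared"):
        if col not in tab.columns:
            tab[col] = 0
    tab["total"] = tab[["plasma_only", "csf_only", "shared"]].sum(axis=1)
    return tab[["plasma_only", "csf_only", "shared", "total"]].reset_index()


def calls_from_dataframe(calls: pd.DataFrame) -> list[SnvAlteration]:
    """Adapt a caller output frame (chrom,pos,ref,alt,gene,coding) to alterations."""
    return [SnvAlteration(chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref),
                          alt=str(r.alt), gene=str(r.gene), coding=bool(r.coding))
            for r in calls.itertuples(index=False)]
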