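"""Shared data containers for the CSF-tDNA pipeline.

Coordinate conventions: the selector panel is stored per position in 1-based
coordinates (matching the counts tables and VCF); BED serialization converts
to 0-based half-open in exactly one place (:mod:`csftdna.io`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPARTMENTS = ("CSF", "plasma", "tumor", "pleural_effusion", "germline")

#: column order of a per-position counts table
COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "depth", "alt_count"]

#: columns that identify a single-nucleotide substitution
VARIANT_KEY = ["chrom", "pos", "ref", "alt"]


class CsftdnaError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(CsftdnaError):
    """Invalid configuration; message names the offending field."""


class ValidationError(CsftdnaError):
    """Malformed input data."""


class UndefinedResultError(CsftdnaError):
    """A statistic whose value is undefined for the given input.

    Raised instead of silently returning 0 (e.g. mean VAF over zero
    evaluable reporters, penetration rate with zero plasma concentration).
    """


def substream(seed: int, *keys) -> np.random.Generator:
    """Deterministic child random generator for ``(seed, *keys)``.

    Keys are hashed with CRC-32 of their string form, so the stream for a
    given (patient, compartment, timepoint) never depends on how many other
    samples exist in the run.
    """
    spawn = tuple(zlib.crc32(str(k).encode("utf-8")) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn))


@dataclass
class SelectorPanel:
    """Targeted capture panel: per-position gene and coding annotation.

    ``positions`` columns: chrom, pos (1-based), gene, coding (bool).
    """

    positions: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"chrom", "pos", "gene", "coding"} - set(self.positions.columns)
        if missing:
            raise ValidationError(f"panel positions missing columns: {sorted(missing)}")
        dup = self.positions.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValidationError("panel contains duplicate positions")
        self.positions = self.positions.sort_values(["chrom", "pos"]).reset_index(drop=True)

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def genes(self) -> list[str]:
        return sorted(self.positions["gene"].unique())

    def regions(self) -> pd.DataFrame:
        """Merged regions as 0-based half-open intervals.

        Consecutive positions sharing (chrom, gene, coding) collapse into one
        region, so the output is non-overlapping by construction.
        """
        pos = self.positions
        rows = []
        for (chrom, gene, coding), grp in pos.groupby(["chrom", "gene", "coding"], sort=True):
            p = grp["pos"].sort_values().to_numpy()
            breaks = np.flatnonzero(np.diff(p) > 1)
            starts = np.r_[0, breaks + 1]
            ends = np.r_[breaks, len(p) - 1]
            for s, e in zip(starts, ends):
                rows.append((chrom, int(p[s]) - 1, int(p[e]), gene, bool(coding)))
        out = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "coding"])
        return out.sort_values(["chrom", "start"]).reset_index(drop=True)

    def position_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.positions[["chrom", "pos"]])

    def contains(self, chrom_pos: pd.DataFrame) -> np.ndarray:
        """Boolean mask: which (chrom, pos) rows lie inside the panel."""
        idx = pd.MultiIndex.from_frame(chrom_pos[["chrom", "pos"]])
        return idx.isin(self.position_index())


@dataclass
class SampleCounts:
    """Per-position deduplicated depth and alt-allele counts for one sample."""

    sample_id: str
    counts: pd.DataFrame
    patient_id: str | None = None
    compartment: str | None = None
    timepoint_days: float | None = None
    treatment_state: str | None = None

    def __post_init__(self) -> None:
        missing = set(COUNT_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValidationError(
                f"sample {self.sample_id}: counts missing columns {sorted(missing)}"
            )
        if self.compartment is not None and self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"sample {self.sample_id}: unknown compartment {self.compartment!r}"
            )
        c = self.counts
        bad = (c["alt_count"] < 0) | (c["alt_count"] > c["depth"]) | (c["depth"] < 0)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = c.iloc[i]
            raise ValidationError(
                f"sample {self.sample_id}: alt_count/depth invalid at "
                f"{row['chrom']}:{row['pos']} (depth={row['depth']}, alt={row['alt_count']})"
            )
        self.counts = c.reset_index(drop=True)

    @property
    def vaf(self) -> pd.Series:
        """alt_count / depth; NaN where depth is zero."""
        depth = self.counts["depth"].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(depth > 0, self.counts["alt_count"].to_numpy(float) / depth, np.nan)
        return pd.Series(v, index=self.counts.index, name="vaf")

    def variant_index(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_frame(self.counts[VARIANT_KEY])


@dataclass
class PositionErrorProfile:
    """Position- and substitution-specific background error rates.

    ``rates`` columns: chrom, pos, ref, alt, error_rate, total_control_depth,
    usable (bool; False when no control covered the position).  The
    pseudocount policy actually applied is recorded in ``pseudocounts``
    (numerator a, denominator b) and ``policy``.
    """

    rates: pd.DataFrame
    n_controls: int
    pseudocounts: tuple[float, float]
    policy: str = "explicit"

    def __post_init__(self) -> None:
        missing = {"error_rate", "total_control_depth", "usable"}.union(VARIANT_KEY) - set(
            self.rates.columns
        )
        if missing:
            raise ValidationError(f"error profile missing columns: {sorted(missing)}")
        r = self.rates.loc[self.rates["usable"], "error_rate"]
        if ((r < 0) | (r >= 1)).any():
            raise ValidationError("error rates must lie in [0, 1)")
        self.rates = self.rates.reset_index(drop=True)

    def lookup(self, variants: pd.DataFrame) -> pd.Series:
        """Error rate per variant row; NaN where the profile has no usable rate."""
        usable = self.rates[self.rates["usable"]]
        merged = variants[VARIANT_KEY].merge(usable[VARIANT_KEY + ["error_rate"]],
                                             on=VARIANT_KEY, how="left")
        return pd.Series(merged["error_rate"].to_numpy(), index=variants.index,
                         name="error_rate")


@dataclass
class ReporterSet:
    """Patient-level joint mutation list tracked across samples.

    ``variants`` columns: chrom, pos, ref, alt, gene, coding, sources
    (semicolon-joined sample ids the call came from).
    """

    patient_id: str
    variants: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = set(VARIANT_KEY) | {"gene", "coding", "sources"}
        missing = cols - set(self.variants.columns)
        if missing:
            raise ValidationError(f"reporter set missing columns: {sorted(missing)}")
        if self.variants.duplicated(subset=VARIANT_KEY).any():
            raise ValidationError(f"patient {self.patient_id}: duplicate reporter variants")
        self.variants = self.variants.sort_values(VARIANT_KEY).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)
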