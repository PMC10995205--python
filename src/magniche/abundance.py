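"""Detection filtering, library-size normalization, relative abundance, prevalence.

Coverage entries below the detection threshold (covered fraction < 10 % by
default) are zeroed out. Mean coverages are then scaled to the smallest
library size (Gbp) and converted to within-sample relative abundances (%).
Both layers are retained: normalized coverage supports cross-sample
comparison, relative abundance feeds the specificity and ordination stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleRecord, SchemaError

logger = logging.getLogger("magniche.abundance")


@dataclass
class AbundanceMatrix:
    """MAG × sample relative abundances (%) with detection mask and normalized coverage.

    Per-sample relative abundances sum to 100 over detected MAGs whenever at
    least one MAG is detected; undetected entries are exactly zero. Samples in
    which no MAG was detected are listed in ``flagged_samples`` and carry NaN
    relative abundances rather than silently-zeroed columns.
    """

    relative_abundance: pd.DataFrame  # MAG x sample, percent
    normalized_coverage: pd.DataFrame
    detected: pd.DataFrame  # boolean mask, same shape
    flagged_samples: list[str] = field(default_factory=list)

    @property
    def mag_ids(self) -> list[str]:
        return list(self.relative_abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.relative_abundance.columns)

    def subset(self, mag_ids: Sequence[str] | None = None,
               sample_ids: Sequence[str] | None = None) -> "AbundanceMatrix":
        """Restrict to a MAG and/or sample subset and re-close relative abundances."""
        rows = list(mag_ids) if mag_ids is not None else self.mag_ids
        cols = list(sample_ids) if sample_ids is not None else self.sample_ids
        cov = self.normalized_coverage.loc[rows, cols]
        det = self.detected.loc[rows, cols]
        return _close(cov, det)


def apply_detection_filter(coverage: pd.DataFrame, min_covered_fraction: float = 0.10) -> pd.DataFrame:
    """Zero out entries whose covered fraction is below the detection threshold.

    The threshold is inclusive: covered_fraction exactly at the cutoff counts
    as detected. Adds a boolean ``detected`` column.
    """
    out = coverage.copy()
    detected = (out["covered_fraction"] >= min_covered_fraction) & (out["mean_coverage"] > 0)
    out.loc[~detected, "mean_coverage"] = 0.0
    out["detected"] = detected
    return out


def _close(norm_cov: pd.DataFrame, detected: pd.DataFrame) -> AbundanceMatrix:
    totals = norm_cov.sum(axis=0)
    flagged = [s for s in norm_cov.columns if totals[s] == 0]
    if flagged:
        logger.warning("sample(s) with no detected MAG: %s", flagged)
    denom = totals.replace(0, np.nan)
    rel = 100.0 * norm_cov.div(denom, axis=1)
    return AbundanceMatrix(
        relative_abundance=rel,
        normalized_coverage=norm_cov,
        detected=detected,
        flagged_samples=flagged,
    )


def normalize(coverage: pd.DataFrame, samples: Sequence[SampleRecord]) -> AbundanceMatrix:
    """Scale mean coverages to the smallest library size, then close to percent.

    normalized_coverage(m, s) = mean_coverage(m, s) × min_library / library(s);
    relative_abundance(m, s) = 100 × normalized_coverage / per-sample total over
    detected MAGs.
    """
    lib = {s.sample_id: s.library_size_gbp for s in samples}
    unknown = set(coverage["sample_id"]) - set(lib)
    if unknown:
        raise SchemaError(f"coverage references unknown sample(s): {sorted(unknown)[:5]}")
    min_lib = min(lib.values())

    if "detected" not in coverage.columns:
        coverage = apply_detection_filter(coverage)
    wide = coverage.pivot(index="mag_id", columns="sample_id", values="mean_coverage").fillna(0.0)
    det = (
        coverage.pivot(index="mag_id", columns="sample_id", values="detected")
        .fillna(False)
        .astype(bool)
    )
    # keep every sample even if it has no coverage rows
    for s in lib:
        if s not in wide.columns:
            wide[s] = 0.0
            det[s] = False
    order = [s.sample_id for s in samples]
    wide, det = wide[order], det[order]

    scale = pd.Series({sid: min_lib / lib[sid] for sid in order})
    norm_cov = wide.mul(scale, axis=1)
    return _close(norm_cov, det)


def prevalence(abund: AbundanceMatrix, samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Fraction of samples of each type in which each MAG is detected."""
    types = sorted({s.sample_type for s in samples})
    out = {}
    for t in types:
        ids = [s.sample_id for s in samples if s.sample_type == t]
        if not ids:
            raise SchemaError(f"no samples of type {t!r}")
        out[t] = abund.detected[ids].sum(axis=1) / len(ids)
    return pd.DataFrame(out)
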