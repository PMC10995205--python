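"""Three-criterion habitat-specificity classifier.

A MAG is called host-specific when, simultaneously:

1. its mean relative abundance across host (coral) samples exceeds its mean
   across seawater samples (ratio > 1; a MAG absent from seawater but present
   in coral has ratio +inf and satisfies the criterion);
2. it is detected in fewer than 50 % of seawater samples (strict);
3. its relative abundance is below 0.1 % in every seawater sample (strict).

All means include zeros for samples where the MAG is undetected, so criteria
1 and 3 are computed on the same closed abundance scale. A MAG detected in no
sample at all is labelled ``undetected`` and excluded downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .io import MAGRecord, RunConfig, SampleRecord, SchemaError

HOST_SPECIFIC = "host_specific"
SEAWATER_SPECIFIC = "seawater_specific"
UNDETECTED = "undetected"


@dataclass(frozen=True)
class SpecificityResult:
    mag_id: str
    mean_abund_coral: float
    mean_abund_seawater: float
    ratio: float  # may be +inf
    seawater_prevalence: float
    max_seawater_abund: float
    flag_ratio: bool
    flag_prevalence: bool
    flag_abundance: bool
    label: str


def classify_specificity(
    abund: AbundanceMatrix,
    prevalence: pd.DataFrame,
    samples: Sequence[SampleRecord],
    config: RunConfig | None = None,
) -> list[SpecificityResult]:
    config = config or RunConfig()
    coral = [s.sample_id for s in samples if s.sample_type == "coral"]
    seawater = [s.sample_id for s in samples if s.sample_type == "seawater"]
    if not coral or not seawater:
        raise SchemaError("both coral and seawater samples are required")
    if "seawater" not in prevalence.columns:
        raise SchemaError("prevalence table lacks a seawater column")

    rel = abund.relative_abundance.fillna(0.0)
    results = []
    for mag_id in abund.mag_ids:
        if mag_id not in prevalence.index:
            raise SchemaError(f"MAG {mag_id!r} absent from prevalence table")
        row_c = rel.loc[mag_id, coral].to_numpy(dtype=float)
        row_s = rel.loc[mag_id, seawater].to_numpy(dtype=float)
        mean_c = float(row_c.mean())
        mean_s = float(row_s.mean())
        if mean_s > 0:
            ratio = mean_c / mean_s
        elif mean_c > 0:
            ratio = math.inf
        else:
            ratio = float("nan")
        prev_s = float(prevalence.at[mag_id, "seawater"])
        max_s = float(row_s.max()) if len(row_s) else 0.0

        if not abund.detected.loc[mag_id].any():
            label = UNDETECTED
            f1 = f2 = f3 = False
        else:
            f1 = ratio > 1.0  # inf > 1 is True; nan comparisons are False
            f2 = prev_s < config.prevalence_max
            f3 = bool((row_s < config.seawater_abund_max).all())
            label = HOST_SPECIFIC if (f1 and f2 and f3) else SEAWATER_SPECIFIC
        results.append(
            SpecificityResult(
                mag_id=mag_id, mean_abund_coral=mean_c, mean_abund_seawater=mean_s,
                ratio=ratio, seawater_prevalence=prev_s, max_seawater_abund=max_s,
                flag_ratio=f1, flag_prevalence=f2, flag_abundance=f3, label=label,
            )
        )
    return results


def results_to_frame(results: Sequence[SpecificityResult]) -> pd.DataFrame:
    rows = [
        {
            "mag_id": r.mag_id,
            "mean_abund_coral": r.mean_abund_coral,
            "mean_abund_seawater": r.mean_abund_seawater,
            "ratio": r.ratio,
            "seawater_prevalence": r.seawater_prevalence,
            "max_seawater_abund": r.max_seawater_abund,
            "flag_ratio": r.flag_ratio,
            "flag_prevalence": r.flag_prevalence,
            "flag_abundance": r.flag_abundance,
            "label": r.label,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _phylum(taxonomy: str) -> str:
    for part in taxonomy.split(";"):
        part = part.strip()
        if part.startswith("p__"):
            return part[3:] or "unclassified"
    return "unclassified"


def summarize_specificity(
    results: Sequence[SpecificityResult], mags: Sequence[MAGRecord] | None = None
) -> dict:
    """Label counts overall and, when MAG records are supplied, per phylum."""
    if not results:
        raise SchemaError("no specificity results to summarize")
    counts = {HOST_SPECIFIC: 0, SEAWATER_SPECIFIC: 0, UNDETECTED: 0}
    for r in results:
        counts[r.label] += 1
    summary = {"counts": counts, "total": len(results)}
    if mags is not None:
        tax = {m.mag_id: _phylum(m.taxonomy) for m in mags}
        per_phylum: dict[str, dict[str, int]] = {}
        for r in results:
            p = tax.get(r.mag_id, "unclassified")
            per_phylum.setdefault(p, {HOST_SPECIFIC: 0, SEAWATER_SPECIFIC: 0, UNDETECTED: 0})
            per_phylum[p][r.label] += 1
        summary["per_phylum"] = per_phylum
    return summary
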