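"""MAG quality scoring, quality filtering, and ANI-threshold dereplication.

Quality is the standard completeness − 3 × contamination score; a bin is
retained when its score is ≥ 50 and its completeness is ≥ 75 % (both
inclusive). Dereplication collapses strain-level duplicates (ANI ≥ 99 % by
default) to a single representative, either within each sampling site or
across the whole catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MAGRecord, RunConfig, SchemaError

logger = logging.getLogger("magniche.qc")


@dataclass(frozen=True)
class QualityAssessment:
    mag_id: str
    quality_score: float
    passes_quality: bool
    passes_completeness: bool

    @property
    def retained(self) -> bool:
        return self.passes_quality and self.passes_completeness


@dataclass
class DereplicationResult:
    """A partition of the input MAGs into ANI clusters with one representative each."""

    clusters: list[set[str]]
    representatives: list[str]
    mode: str

    @property
    def representative_set(self) -> set[str]:
        return set(self.representatives)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rep, members in zip(self.representatives, self.clusters):
            for m in sorted(members):
                rows.append({"mag_id": m, "representative": rep, "is_representative": m == rep})
        return pd.DataFrame(rows, columns=["mag_id", "representative", "is_representative"])


def quality_score(completeness: float, contamination: float) -> float:
    """completeness − 3 × contamination (may be negative)."""
    if not 0.0 <= completeness <= 100.0:
        raise SchemaError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise SchemaError(f"contamination {contamination} < 0")
    return completeness - 3.0 * contamination


def assess(mags: Iterable[MAGRecord], config: RunConfig | None = None) -> list[QualityAssessment]:
    config = config or RunConfig()
    out = []
    for m in mags:
        score = quality_score(m.completeness, m.contamination)
        out.append(
            QualityAssessment(
                mag_id=m.mag_id,
                quality_score=score,
                passes_quality=score >= config.quality_min,
                passes_completeness=m.completeness >= config.completeness_min,
            )
        )
    return out


def filter_mags(
    mags: Sequence[MAGRecord], config: RunConfig | None = None
) -> tuple[list[QualityAssessment], list[MAGRecord]]:
    """Assess every MAG; retain those passing both quality and completeness thresholds."""
    assessments = assess(mags, config)
    retained = [m for m, a in zip(mags, assessments) if a.retained]
    logger.info("quality filter: retained %d / %d MAGs", len(retained), len(mags))
    return assessments, retained


def _symmetrize(ani: pd.DataFrame, tol: float = 1.0) -> pd.DataFrame:
    """Max-symmetrization of a (possibly directional) ANI matrix."""
    a = ani.to_numpy(dtype=float)
    if np.nanmax(np.abs(a - a.T)) > tol:
        logger.warning("ANI matrix asymmetric beyond tolerance %.2f; using max of directions", tol)
    sym = np.maximum(a, a.T)
    np.fill_diagonal(sym, 100.0)
    return pd.DataFrame(sym, index=ani.index, columns=ani.columns)


def dereplicate(
    mags: Sequence[MAGRecord],
    ani: pd.DataFrame,
    threshold: float = 99.0,
    mode: str = "overall",
) -> DereplicationResult:
    """Greedy centroid clustering at the ANI threshold.

    MAGs are visited in order of descending quality score (ties broken
    lexicographically on mag_id); each unassigned MAG becomes a representative
    and absorbs every unassigned MAG with ANI ≥ threshold to it. Representatives
    are therefore pairwise below the threshold, and every absorbed MAG is at or
    above threshold to its representative. In ``per_site`` mode the procedure
    runs independently within each site.
    """
    if mode not in ("per_site", "overall"):
        raise ValueError(f"mode must be 'per_site' or 'overall', got {mode!r}")
    if not mags:
        return DereplicationResult(clusters=[], representatives=[], mode=mode)
    ids = [m.mag_id for m in mags]
    missing = [i for i in ids if i not in ani.index]
    if missing:
        raise SchemaError(f"MAG(s) missing from ANI matrix: {missing[:5]}")
    sym = _symmetrize(ani.loc[ids, ids])

    by_quality = sorted(
        mags, key=lambda m: (-quality_score(m.completeness, m.contamination), m.mag_id)
    )
    groups: list[list[MAGRecord]]
    if mode == "per_site":
        sites: dict[str, list[MAGRecord]] = {}
        for m in by_quality:
            sites.setdefault(m.site, []).append(m)
        groups = [sites[s] for s in sorted(sites)]
    else:
        groups = [list(by_quality)]

    clusters: list[set[str]] = []
    representatives: list[str] = []
    for group in groups:
        unassigned = {m.mag_id for m in group}
        for m in group:
            if m.mag_id not in unassigned:
                continue
            members = {
                other for other in unassigned
                if sym.at[m.mag_id, other] >= threshold
            }
            members.add(m.mag_id)
            unassigned -= members
            clusters.append(members)
            representatives.append(m.mag_id)
    return DereplicationResult(clusters=clusters, representatives=representatives, mode=mode)
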