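"""Group-wise comparative statistics.

Kruskal–Wallis comparisons of genomic features between habitat groups,
two-sided Fisher's-exact enrichment of functional annotations on
presence/absence, abundance-weighted Mann–Whitney enrichment of orthologous
clusters across water-quality categories, and the shared Benjamini–Hochberg
FDR machinery. All tests are two-sided.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .abundance import AbundanceMatrix
from .io import FeatureMatrix, SampleRecord, SchemaError

logger = logging.getLogger("magniche.stats")


@dataclass(frozen=True)
class TestResult:
    feature_id: str
    statistic: float
    raw_p: float
    adjusted_p: float
    direction: str
    group_summary: dict


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up BH adjustment, returned in input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def kruskal_wallis(*groups: Sequence[float]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with chi-square p on k − 1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) < 3:
        raise ValueError("need at least three observations in total")
    if all(np.array_equal(a, arrays[0]) for a in arrays[1:]) or (
        len({x for a in arrays for x in a}) == 1
    ):
        # all observations identical: H = 0, p = 1 (scipy raises on zero variance)
        h, p = 0.0, 1.0
    else:
        h, p = scipy.stats.kruskal(*arrays)
    medians = {f"group{i + 1}_median": float(np.median(a)) for i, a in enumerate(arrays)}
    medians.update({f"group{i + 1}_n": int(a.size) for i, a in enumerate(arrays)})
    direction = f"group{int(np.argmax([np.median(a) for a in arrays])) + 1}"
    return TestResult(
        feature_id="", statistic=float(h), raw_p=float(p), adjusted_p=float(p),
        direction=direction, group_summary=medians,
    )


def compare_genomic_features(
    mags_df: pd.DataFrame, labels: pd.Series,
    features: Sequence[str] = ("genome_size", "gc", "n_genes", "coding_density"),
) -> pd.DataFrame:
    """Kruskal–Wallis comparison of genomic features between habitat groups,
    BH-adjusted across the compared features."""
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise SchemaError("need two habitat groups to compare genomic features")
    rows = []
    for feat in features:
        vals = [mags_df.loc[labels[labels == g].index, feat].to_numpy(float) for g in groups]
        res = kruskal_wallis(*vals)
        row = {"feature": feat, "H": res.statistic, "raw_p": res.raw_p}
        for g, v in zip(groups, vals):
            row[f"median_{g}"] = float(np.median(v))
        rows.append(row)
    out = pd.DataFrame(rows)
    out["adjusted_p"] = benjamini_hochberg(out["raw_p"].to_numpy())
    return out


def fisher_exact_two_sided(table: np.ndarray) -> tuple[float, float]:
    """Two-sided Fisher exact p (sum of hypergeometric point probabilities
    ≤ the observed one) and the sample odds ratio."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p = scipy.stats.fisher_exact(t, alternative="two-sided")
    return float(p), float(odds)


def fisher_enrichment(
    features: FeatureMatrix,
    labels: pd.Series,
    group_a: str = "host_specific",
    group_b: str = "seawater_specific",
) -> pd.DataFrame:
    """Per-feature two-sided Fisher exact test on presence/absence between two
    MAG groups, BH-adjusted within the feature namespace.

    Counts are binarized at ≥ 1 copy. Features absent from every MAG are
    skipped (noted in the log). Significance is conventionally read at
    adjusted_p ≤ 0.05 (inclusive).
    """
    ids_a = [m for m in features.mag_ids if labels.get(m) == group_a]
    ids_b = [m for m in features.mag_ids if labels.get(m) == group_b]
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise SchemaError("each group needs at least two MAGs for enrichment testing")
    presence = features.binarize()
    n_a, n_b = len(ids_a), len(ids_b)
    rows = []
    skipped = 0
    for feat in presence.columns:
        pa = int(presence.loc[ids_a, feat].sum())
        pb = int(presence.loc[ids_b, feat].sum())
        if pa == 0 and pb == 0:
            skipped += 1
            continue
        p, odds = fisher_exact_two_sided(np.array([[pa, n_a - pa], [pb, n_b - pb]]))
        direction = group_a if pa / n_a >= pb / n_b else group_b
        rows.append(
            {
                "feature_id": feat, "namespace": features.namespace,
                "present_a": pa, "absent_a": n_a - pa,
                "present_b": pb, "absent_b": n_b - pb,
                "odds_ratio": odds, "raw_p": p, "direction": direction,
            }
        )
    if skipped:
        logger.info("%s: skipped %d feature(s) absent from all MAGs", features.namespace, skipped)
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "namespace", "present_a", "absent_a", "present_b",
                 "absent_b", "odds_ratio", "raw_p", "direction"],
    )
    out["adjusted_p"] = benjamini_hochberg(out["raw_p"].to_numpy()) if len(out) else []
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (tie-corrected).

    Exact by enumeration of all group assignments when n1·n2 ≤ 400 (the exact
    null of the U statistic under exchangeability, valid with ties); normal
    approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    if n1 * n2 <= 400 and math.comb(n1 + n2, n1) <= 200_000:
        obs_dev = abs(u1 - mu)
        count = 0
        total = 0
        for idx in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
            total += 1
        p = count / total
    else:
        _, p = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u1), float(min(p, 1.0))


def weighted_cluster_enrichment(
    clusters: FeatureMatrix,
    abund: AbundanceMatrix,
    samples: Sequence[SampleRecord],
    factor: str = "wq_category",
) -> pd.DataFrame:
    """Abundance-weighted cluster enrichment between category pairs.

    Per sample s, the weight of cluster c is Σ_m count(c, m) × relative
    abundance(m, s): cluster frequency weighted by the abundance of the
    organisms encoding it. For every unordered category pair, a two-sided
    Mann–Whitney U test compares the weights; raw p is the primary readout
    (conventionally read at P < 0.05) and a BH-adjusted p per pair is added.
    """
    sample_cat = {}
    for s in samples:
        val = getattr(s, factor) if hasattr(s, factor) else s.env.get(factor)
        if val is not None:
            sample_cat[s.sample_id] = val
    shared_mags = [m for m in clusters.mag_ids if m in abund.relative_abundance.index]
    if not shared_mags:
        raise SchemaError("cluster matrix and abundance matrix share no MAGs")
    shared_samples = [s for s in abund.sample_ids if s in sample_cat]
    rel = abund.relative_abundance.loc[shared_mags, shared_samples].fillna(0.0)
    counts = clusters.counts.loc[shared_mags]
    # weights: clusters x samples
    weights = counts.T.to_numpy(float) @ rel.to_numpy(float)
    wdf = pd.DataFrame(weights, index=counts.columns, columns=shared_samples)

    cats: dict[str, list[str]] = {}
    for sid in shared_samples:
        cats.setdefault(sample_cat[sid], []).append(sid)
    rows = []
    for c1, c2 in itertools.combinations(sorted(cats), 2):
        s1, s2 = cats[c1], cats[c2]
        if len(s1) < 2 or len(s2) < 2:
            logger.warning("pair (%s, %s) skipped: a category has < 2 samples", c1, c2)
            continue
        pair_rows = []
        for clust in wdf.index:
            w1 = wdf.loc[clust, s1].to_numpy(float)
            w2 = wdf.loc[clust, s2].to_numpy(float)
            if np.all(w1 == 0) and np.all(w2 == 0):
                continue
            u, p = mann_whitney_u(w1, w2)
            direction = c1 if np.median(w1) >= np.median(w2) else c2
            pair_rows.append(
                {
                    "cluster_id": clust, "category_1": c1, "category_2": c2,
                    "U": u, "raw_p": p, "direction": direction,
                    "median_1": float(np.median(w1)), "median_2": float(np.median(w2)),
                }
            )
        if pair_rows:
            pr = pd.DataFrame(pair_rows)
            pr["adjusted_p"] = benjamini_hochberg(pr["raw_p"].to_numpy())
            rows.append(pr)
    if not rows:
        return pd.DataFrame(
            columns=["cluster_id", "category_1", "category_2", "U", "raw_p",
                     "direction", "median_1", "median_2", "adjusted_p"]
        )
    return pd.concat(rows, ignore_index=True)
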