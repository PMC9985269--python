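"""ASV-table processing: filtering, rarefaction, alpha diversity, ordination.

This layer mirrors a standard amplicon workflow for a feeding trial:

* drop ASVs whose total count across all samples is at or below a small
  threshold (default ≤ 2 counts);
* rarefy every sample without replacement to the depth of the shallowest
  retained sample;
* alpha diversity per sample — observed ASVs, Chao1, Shannon (natural log),
  inverse Simpson, Fisher's alpha and Faith's phylogenetic diversity;
* the Canoco-style response transform log10(10,000 · relative_abundance + 1);
* unconstrained (PCA) and constrained (RDA) ordination, the latter with a
  permutation test of the group constraint (default 500 permutations);
* the normality-gated group test used throughout the figure legends:
  Shapiro–Wilk per group, then one-way ANOVA if every group looks normal,
  Kruskal–Wallis otherwise, with no multiple-testing correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, CountTable

logger = logging.getLogger(__name__)

ALL_INDICES = ("observed", "chao1", "shannon", "invsimpson", "fisher", "pd")


def filter_low_count_asvs(table: CountTable, max_total_excluded: int = 2) -> CountTable:
    """Keep taxa whose total count across all samples exceeds the threshold.

    A taxon totalling exactly ``max_total_excluded`` counts is removed
    (the filter excludes taxa "occurring in <= N counts").
    """
    if max_total_excluded < 0:
        raise ValueError("max_total_excluded must be non-negative")
    totals = table.counts.sum(axis=1)
    keep = totals[totals > max_total_excluded].index
    return CountTable(table.counts.loc[keep].copy(), table.metadata.copy())


def rarefy(table: CountTable, depth: int, seed: int = 0) -> CountTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning, mirroring the exclusion of under-sequenced libraries before
    alpha-diversity analysis.  Deterministic per seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    kept = [s for s in table.samples if totals[s] >= depth]
    dropped = sorted(set(table.samples) - set(kept))
    if dropped:
        logger.warning("dropping %d samples below depth %d: %s", len(dropped), depth, dropped)
    out = {}
    for s in kept:
        out[s] = rng.multivariate_hypergeometric(table.counts[s].to_numpy(), depth)
    counts = pd.DataFrame(out, index=table.taxa)
    return CountTable(counts, table.metadata.loc[kept].copy())


def min_depth(table: CountTable, exclude_below: int = 1000) -> int:
    """Depth of the shallowest sample with at least ``exclude_below`` reads."""
    totals = table.sample_totals()
    eligible = totals[totals >= exclude_below]
    if eligible.empty:
        raise ValueError("no sample reaches the minimum usable depth")
    return int(eligible.min())


def _chao1(counts: np.ndarray) -> float:
    obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return obs + f1 * f1 / (2.0 * f2)
    # bias-corrected form avoids division by zero when no doubletons exist
    return obs + f1 * (f1 - 1) / 2.0


def _fisher_alpha(counts: np.ndarray) -> float:
    from skbio.diversity.alpha import fisher_alpha

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(fisher_alpha(counts))


def _faith_pd(counts: np.ndarray, taxa, tree) -> float:
    """Total branch length of the union of root-to-tip paths of observed taxa."""
    observed = {t for t, c in zip(taxa, counts) if c > 0}
    if not observed:
        return np.nan
    edges = set()
    for tip in tree.tips():
        if tip.name in observed:
            node = tip
            while node.parent is not None:
                edges.add(id(node))
                node = node.parent
    by_id = {id(n): n for n in tree.traverse()}
    return float(sum(by_id[e].length or 0.0 for e in edges))


def alpha_diversity(
    table: CountTable, indices=ALL_INDICES, tree=None
) -> pd.DataFrame:
    """Per-sample diversity indices (rows = samples, columns = indices).

    Shannon uses the natural log; inverse Simpson is 1/Σp²; Chao1 is
    S_obs + F1²/(2·F2) with the bias-corrected form when F2 = 0; Fisher's
    alpha solves S = α·ln(1 + N/α); Faith PD is the total branch length of
    the pruned tree spanning the observed taxa.  Empty samples yield NaN for
    every index and are logged.
    """
    indices = list(indices)
    if "pd" in indices and tree is None:
        raise ValueError("Faith PD requires a phylogenetic tree")
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        missing = set(table.taxa) - tip_names
        if "pd" in indices and missing:
            raise ValueError(f"tree does not cover taxa: {sorted(missing)[:5]}...")
    rows = {}
    for s in table.samples:
        counts = table.counts[s].to_numpy()
        total = counts.sum()
        row = {}
        if total == 0:
            logger.warning("sample %s is empty; indices undefined", s)
            rows[s] = {i: np.nan for i in indices}
            continue
        p = counts[counts > 0] / total
        for idx in indices:
            if idx == "observed":
                row[idx] = float((counts > 0).sum())
            elif idx == "chao1":
                row[idx] = _chao1(counts)
            elif idx == "shannon":
                row[idx] = float(-(p * np.log(p)).sum())
            elif idx == "invsimpson":
                row[idx] = float(1.0 / (p * p).sum())
            elif idx == "fisher":
                row[idx] = _fisher_alpha(counts)
            elif idx == "pd":
                row[idx] = _faith_pd(counts, table.taxa, tree)
            else:
                raise ValueError(f"unknown index {idx!r}")
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")[indices]


def log_transform(ab: AbundanceTable) -> pd.DataFrame:
    """Canoco-style response transform: log10(10,000 · p + 1), elementwise."""
    values = ab.abundances
    if (values.to_numpy() < 0).any():
        raise ValueError("relative abundances must be non-negative")
    return np.log10(10_000.0 * values + 1.0)


@dataclass
class OrdinationResult:
    """Scores and variance decomposition of a PCA or RDA.

    ``percent_explained`` is per returned axis, as a percentage of the total
    response variance; for the constrained analysis ``p_value`` is the
    permutation p-value of the group constraint and ``n_permutations`` the
    number of relabelings used.
    """

    method: str
    sample_scores: pd.DataFrame
    variable_scores: pd.DataFrame
    percent_explained: np.ndarray
    p_value: float | None = None
    n_permutations: int | None = None


def _constrained_trace(y: np.ndarray, labels: np.ndarray) -> float:
    """Variance of the group-mean fitted values (the RDA constrained trace)."""
    fitted = np.empty_like(y)
    for g in np.unique(labels):
        sel = labels == g
        fitted[sel] = y[sel].mean(axis=0)
    return float((fitted**2).sum())


def ordinate(
    response: pd.DataFrame,
    constraints=None,
    n_perm: int = 500,
    seed: int = 0,
) -> OrdinationResult:
    """PCA (unconstrained) or RDA (constrained by group labels).

    Parameters
    ----------
    response
        Samples as rows, variables as columns (already transformed as
        desired).
    constraints
        Optional per-sample group labels; if given, the analysis is an RDA on
        group indicators and a permutation test (random relabeling) yields
        the p-value via the +1-corrected estimator, never exactly zero.
    """
    if response.shape[0] < 3:
        raise ValueError("ordination needs at least 3 samples")
    y = response.to_numpy(dtype=float)
    y = y - y.mean(axis=0, keepdims=True)
    total = float((y**2).sum())
    if total <= 0:
        raise ValueError("response matrix is constant")

    if constraints is None:
        u, sv, vt = np.linalg.svd(y, full_matrices=False)
        eig = sv**2
        k = int((eig > 1e-12 * eig.max()).sum())
        scores = pd.DataFrame(
            u[:, :k] * sv[:k], index=response.index,
            columns=[f"PC{i+1}" for i in range(k)],
        )
        var_scores = pd.DataFrame(
            vt[:k].T, index=response.columns, columns=scores.columns
        )
        return OrdinationResult("pca", scores, var_scores, 100.0 * eig[:k] / total)

    labels = np.asarray(pd.Series(list(constraints)))
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("constrained ordination needs >= 2 groups")
    fitted = np.empty_like(y)
    for g in groups:
        sel = labels == g
        fitted[sel] = y[sel].mean(axis=0)
    u, sv, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = sv**2
    k = min(len(groups) - 1, y.shape[1])
    k = min(k, int((eig > 1e-12 * max(eig.max(), 1e-300)).sum()) or 1)
    scores = pd.DataFrame(
        u[:, :k] * sv[:k], index=response.index,
        columns=[f"RDA{i+1}" for i in range(k)],
    )
    var_scores = pd.DataFrame(vt[:k].T, index=response.columns, columns=scores.columns)

    observed = float(eig.sum())
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _constrained_trace(y, perm) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return OrdinationResult(
        "rda", scores, var_scores, 100.0 * eig[:k] / total, p, n_perm
    )


@dataclass
class GroupTestResult:
    test: str  # "anova" or "kruskal"
    statistic: float
    p_value: float
    shapiro_p: dict


def group_compare(values, groups) -> GroupTestResult:
    """Shapiro-gated comparison of a numeric readout across groups.

    Shapiro–Wilk is run on each group's residuals (values minus group mean);
    if every group passes at alpha = 0.05 the groups are compared by ordinary
    one-way ANOVA, otherwise by Kruskal–Wallis.  A constant group makes the
    normality test undefined and routes to Kruskal–Wallis with a warning.
    No multiple-testing correction is applied.
    """
    values = np.asarray(list(values), dtype=float)
    groups = np.asarray(list(groups))
    per_group = [values[groups == g] for g in pd.unique(groups)]
    if len(per_group) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 3 for g in per_group):
        raise ValueError("each group needs at least 3 values")

    shapiro_p = {}
    degenerate = False
    for g, vals in zip(pd.unique(groups), per_group):
        resid = vals - vals.mean()
        if np.ptp(resid) == 0:
            logger.warning("group %s is constant; normality test undefined", g)
            degenerate = True
            shapiro_p[g] = np.nan
        else:
            shapiro_p[g] = float(stats.shapiro(resid).pvalue)

    normal = (not degenerate) and all(p >= 0.05 for p in shapiro_p.values())
    if normal:
        stat, p = stats.f_oneway(*per_group)
        return GroupTestResult("anova", float(stat), float(p), shapiro_p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.kruskal(*per_group)
    return GroupTestResult("kruskal", float(stat), float(p), shapiro_p)
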