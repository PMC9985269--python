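"""Transcriptome layer: tpm, gene scores, GSR enrichment, GO collapsing.

The host-gut expression analysis works at the level of Gene Ontology terms:

* raw counts (if that is what is supplied) are converted to transcripts per
  million with gene lengths;
* a per-gene differential score is computed between two diet groups (Welch
  t-test on log2(tpm + 1); score = −log10 p) — or an external table of
  DESeq2-style scores can be supplied instead;
* gene-score resampling (GSR) assigns each GO term an empirical p-value by
  comparing the mean score of its genes against means of random same-size
  gene sets drawn from the whole expressed universe;
* per-term expression is obtained by collapsing (summing) the tpm of member
  genes, and term-level log2 fold changes between diets follow with a
  pseudocount guard;
* within-group Bray–Curtis dissimilarities quantify how homogeneous each
  diet's transcriptomes are, compared across groups by the normality-gated
  test.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .community import group_compare

logger = logging.getLogger(__name__)


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: 1e6 · (c_g/L_g) / Σ_h (c_h/L_h) per sample."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = totals[totals == 0].index.tolist()
        raise ValueError(f"all-zero samples: {bad}")
    return 1e6 * rate.div(totals, axis=1)


def gene_scores(
    expr: pd.DataFrame, samples_a, samples_b
) -> pd.DataFrame:
    """Per-gene differential table between control (a) and treatment (b).

    Welch t-test on log2(tpm + 1); two-sided p; score = −log10 p; log2FC is
    the mean log2(tpm + 1) difference, positive when higher in the treatment
    group.  Genes constant in both groups get p = 1 and score 0.
    """
    a = np.log2(expr[list(samples_a)].to_numpy() + 1.0)
    b = np.log2(expr[list(samples_b)].to_numpy() + 1.0)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need at least 2 samples per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    lfc = b.mean(axis=1) - a.mean(axis=1)
    return pd.DataFrame(
        {"score": -np.log10(np.maximum(p, 1e-300)), "log2FC": lfc, "p": p},
        index=expr.index,
    )


def clean_annotation(ann: dict, universe) -> dict:
    """Restrict every term's gene set to the expression universe."""
    universe = set(universe)
    out = {}
    for term, genes in ann.items():
        kept = sorted(set(genes) & universe)
        dropped = len(set(genes)) - len(kept)
        if dropped:
            logger.warning("term %s: %d annotated genes absent from universe", term, dropped)
        if kept:
            out[term] = kept
    return out


def gsr_enrichment(
    scores: pd.DataFrame, ann: dict, n_resample: int = 10_000, seed: int = 0
) -> pd.Series:
    """Gene-score-resampling empirical p per GO term.

    The term statistic is the mean gene score over its member genes; the null
    is the mean over ``n_resample`` random gene sets of the same size drawn
    without replacement from the whole universe.  p uses the +1-corrected
    estimator, so it is never zero.  Null distributions are cached per term
    size, which makes the cost linear in the number of distinct sizes.
    """
    if scores.empty:
        raise ValueError("empty gene universe")
    ann = clean_annotation(ann, scores.index)
    rng = np.random.default_rng(seed)
    values = scores["score"].to_numpy(dtype=float)
    n_universe = len(values)
    null_cache: dict[int, np.ndarray] = {}
    out = {}
    for term, genes in ann.items():
        size = len(genes)
        if size > n_universe:
            raise ValueError(f"term {term} larger than the gene universe")
        if size not in null_cache:
            keys = rng.random((n_resample, n_universe))
            idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
            null_cache[size] = values[idx].mean(axis=1)
        observed = values[scores.index.get_indexer(genes)].mean()
        hits = int((null_cache[size] >= observed - 1e-12).sum())
        out[term] = (1 + hits) / (n_resample + 1)
    return pd.Series(out, name="gsr_p")


def collapse_to_go(expr: pd.DataFrame, ann: dict, how: str = "sum") -> pd.DataFrame:
    """GO × sample matrix of collapsed member-gene tpm.

    Genes annotated to several terms contribute to each (no double-count
    correction).  ``how`` is "sum" (default, preserves the tpm scale) or
    "mean".  Terms with no expressed member yield a zero row with a warning.
    """
    if how not in ("sum", "mean"):
        raise ValueError("how must be 'sum' or 'mean'")
    rows = {}
    index = expr.index
    for term, genes in ann.items():
        present = [g for g in genes if g in index]
        if not present:
            logger.warning("term %s has no expressed genes; zero row", term)
            rows[term] = np.zeros(expr.shape[1])
            continue
        block = expr.loc[present]
        rows[term] = block.sum(axis=0) if how == "sum" else block.mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)


def go_fold_change(
    go_matrix: pd.DataFrame, samples_ctrl, samples_trt, pseudocount: float = 1.0
) -> pd.Series:
    """Per-term log2((mean_trt + c) / (mean_ctrl + c)); positive = up in treatment."""
    if not list(samples_ctrl) or not list(samples_trt):
        raise ValueError("both groups must be non-empty")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    m_ctrl = go_matrix[list(samples_ctrl)].mean(axis=1)
    m_trt = go_matrix[list(samples_trt)].mean(axis=1)
    return np.log2((m_trt + pseudocount) / (m_ctrl + pseudocount)).rename("log2FC")


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    """BC(u, v) = Σ|u − v| / Σ(u + v) on non-negative profiles."""
    denom = float((u + v).sum())
    if denom == 0:
        return np.nan
    return float(np.abs(u - v).sum() / denom)


def within_group_dissimilarity(expr: pd.DataFrame, groups: pd.Series):
    """Pairwise Bray–Curtis within each group, plus the cross-group gate test.

    Returns (DataFrame with columns group/sample_a/sample_b/distance,
    GroupTestResult comparing the within-group distance sets).
    """
    rows = []
    for g in pd.unique(groups):
        members = groups.index[groups == g]
        if len(members) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        for a, b in combinations(members, 2):
            d = bray_curtis(expr[a].to_numpy(), expr[b].to_numpy())
            if np.isnan(d):
                logger.warning("distance undefined for all-zero pair (%s, %s)", a, b)
                continue
            rows.append({"group": g, "sample_a": a, "sample_b": b, "distance": d})
    dist = pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "distance"])
    test = group_compare(dist["distance"], dist["group"])
    return dist, test
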