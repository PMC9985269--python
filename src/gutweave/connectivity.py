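"""Taxa co-/anti-occurrence networks per diet group.

Workflow, per diet within a timepoint: taxa are admitted when they occur in
at least a fraction of the group's samples (default ≥ 3/10) and reach a mean
within-group relative abundance of at least 10 counts per million; every
admitted unordered taxon pair gets an association r ("r-score") and
two-sided p on relative abundances; pairs with p ≤ 0.1 become network edges,
signed co-occurring (r > 0, drawn solid in the source figures) or
anti-occurring (r < 0, dashed).  Edges are then classified by the exact set
of diets containing them (shared by all, unique to one, or intermediate),
and the per-diet count of significantly associated pairs (p ≤ 0.05,
−log10 p ≥ 1.30) is summarised as a normalized cumulative-frequency curve.

Default association is Spearman rank correlation — robust for compositional,
zero-inflated abundance data; Pearson is available for comparison.  P-values
are asymptotic by default, with an exact/Monte-Carlo permutation mode that
enumerates all orderings for n ≤ 7 and samples 10,000 permutations above.
No compositionality correction and no multiple-testing correction are
applied; pair p-values are used raw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations, permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AbundanceTable, CountTable

logger = logging.getLogger(__name__)

PERM_EXACT_MAX_N = 7
PERM_SAMPLES = 10_000


@dataclass
class NetworkConfig:
    prevalence_min_frac: float = 0.3
    abundance_min_ppm: float = 10.0
    edge_p_max: float = 0.1
    sig_pair_p_max: float = 0.05
    association_method: str = "spearman"
    p_mode: str = "asymptotic"  # or "exact_permutation"
    abundance_mode: str = "group_mean"  # or "per_sample_max"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.prevalence_min_frac <= 1:
            raise ValueError("prevalence_min_frac must lie in (0, 1]")
        if self.abundance_min_ppm < 0:
            raise ValueError("abundance_min_ppm must be non-negative")
        for name in ("edge_p_max", "sig_pair_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.association_method not in ("spearman", "pearson"):
            raise ValueError("association_method must be spearman or pearson")
        if self.p_mode not in ("asymptotic", "exact_permutation"):
            raise ValueError("p_mode must be asymptotic or exact_permutation")


def eligible_taxa(table: CountTable, cfg: NetworkConfig, group_samples) -> list:
    """Taxa passing the prevalence and abundance gates within a sample group."""
    cfg.validate()
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("empty sample group")
    sub = table.subset_samples(group_samples)
    n = len(group_samples)
    min_present = math.ceil(cfg.prevalence_min_frac * n)
    prevalence = (sub.counts > 0).sum(axis=1)
    rel = sub.relative_abundance().abundances
    if cfg.abundance_mode == "group_mean":
        abundant = rel.mean(axis=1) >= cfg.abundance_min_ppm / 1e6
    else:
        abundant = rel.max(axis=1) >= cfg.abundance_min_ppm / 1e6
    keep = (prevalence >= min_present) & abundant
    return [t for t in sub.taxa if keep[t]]


def _perm_pvalue(x: np.ndarray, y: np.ndarray, method: str, rng) -> tuple:
    """Association r and two-sided permutation p.

    For n <= 7 all n! orderings of y are enumerated (exact p, no +1
    correction); otherwise 10,000 random permutations are drawn and the
    +1-corrected estimator is used.
    """
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    r_obs = float(xc @ yc / denom)
    n = len(x)
    if n <= PERM_EXACT_MAX_N:
        null = np.array([xc @ yc[list(p)] for p in permutations(range(n))]) / denom
        p = float((np.abs(null) >= abs(r_obs) - 1e-12).mean())
    else:
        idx = np.argsort(rng.random((PERM_SAMPLES, n)), axis=1)
        null = (yc[idx] @ xc) / denom
        hits = int((np.abs(null) >= abs(r_obs) - 1e-12).sum())
        p = (1 + hits) / (PERM_SAMPLES + 1)
    return r_obs, p


def pairwise_association(
    ab: AbundanceTable, cfg: NetworkConfig, group_samples, taxa=None, group_label=""
) -> pd.DataFrame:
    """Association r and two-sided p for every unordered taxon pair.

    Returns a DataFrame with columns taxon_a, taxon_b, r, p, n, group.
    Pairs involving a zero-variance taxon are skipped with a warning.
    """
    cfg.validate()
    group_samples = list(group_samples)
    if len(group_samples) < 4:
        raise ValueError("need at least 4 samples for pairwise association")
    data = ab.abundances.loc[taxa if taxa is not None else ab.abundances.index, group_samples]
    rng = np.random.default_rng(cfg.seed)
    rows = []
    mat = data.to_numpy()
    names = list(data.index)
    variances = mat.var(axis=1)
    for i, j in combinations(range(len(names)), 2):
        if variances[i] == 0 or variances[j] == 0:
            logger.warning("skipping pair (%s, %s): zero variance", names[i], names[j])
            continue
        x, y = mat[i], mat[j]
        if cfg.p_mode == "exact_permutation":
            r, p = _perm_pvalue(x, y, cfg.association_method, rng)
        elif cfg.association_method == "spearman":
            r, p = stats.spearmanr(x, y)
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {"taxon_a": names[i], "taxon_b": names[j], "r": float(r),
             "p": float(p), "n": len(group_samples), "group": group_label}
        )
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "r", "p", "n", "group"])


@dataclass
class OccurrenceNetwork:
    """Signed taxon association network for one group."""

    graph: nx.Graph
    group: str = ""

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}


def build_network(
    assoc: pd.DataFrame, cfg: NetworkConfig, node_sizes: pd.Series, group_label: str = ""
) -> OccurrenceNetwork:
    """Edges are exactly the pairs with p ≤ edge_p_max (boundary included).

    Node attribute ``mean_abundance`` carries the group-mean relative
    abundance (figure node size); edge sign is "co" for r > 0, "anti"
    otherwise.
    """
    cfg.validate()
    g = nx.Graph(group=group_label)
    for taxon, size in node_sizes.items():
        g.add_node(taxon, mean_abundance=float(size))
    for row in assoc.itertuples():
        if row.p <= cfg.edge_p_max:
            g.add_edge(
                row.taxon_a, row.taxon_b,
                r=float(row.r), p=float(row.p),
                sign="co" if row.r > 0 else "anti",
            )
    return OccurrenceNetwork(g, group_label)


def classify_edges(networks: dict) -> pd.DataFrame:
    """Label every edge by the exact set of diets whose network contains it.

    Returns a DataFrame with one row per distinct unordered pair appearing in
    any network: columns taxon_a, taxon_b, diets (sorted tuple) and
    ``edge_class`` ∈ {"all-diets", "unique-to-<d>", "shared-partial"}.
    """
    if len(networks) < 2:
        raise ValueError("need at least 2 networks to classify edges")
    universes = [frozenset(n.graph.nodes) for n in networks.values()]
    if len(set(universes)) != 1:
        raise ValueError("networks must share a common taxon universe")
    all_diets = set(networks)
    membership: dict[frozenset, set] = {}
    for diet, net in networks.items():
        for e in net.edges:
            membership.setdefault(e, set()).add(diet)
    rows = []
    for pair, diets in membership.items():
        a, b = sorted(pair)
        if diets == all_diets:
            cls = "all-diets"
        elif len(diets) == 1:
            cls = f"unique-to-{next(iter(diets))}"
        else:
            cls = "shared-partial"
        rows.append({"taxon_a": a, "taxon_b": b,
                     "diets": tuple(sorted(diets)), "edge_class": cls})
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "diets", "edge_class"])


NEGLOG10_REFERENCE = -math.log10(0.05)  # 1.3010: the dotted reference line


@dataclass
class PairSummary:
    sig_counts: dict  # group -> count of pairs with p <= sig_pair_p_max
    curves: dict  # group -> DataFrame(neglog10_p, cumulative_frequency)
    reference: float = NEGLOG10_REFERENCE


def significant_pair_summary(assocs: dict, cfg: NetworkConfig) -> PairSummary:
    """Per-group significant-pair count and normalized cumulative curve.

    The curve gives, at each observed −log10 p, the fraction of all tested
    pairs with −log10 p at or below that value; it is monotone non-decreasing
    and reaches 1.  The count uses p ≤ sig_pair_p_max (default 0.05, i.e.
    −log10 p ≥ 1.30).
    """
    cfg.validate()
    counts = {}
    curves = {}
    for group, assoc in assocs.items():
        p = assoc["p"].to_numpy()
        counts[group] = int((p <= cfg.sig_pair_p_max).sum())
        neglog = np.sort(-np.log10(np.maximum(p, 1e-300)))
        cum = np.arange(1, len(neglog) + 1) / max(len(neglog), 1)
        curves[group] = pd.DataFrame(
            {"neglog10_p": neglog, "cumulative_frequency": cum}
        )
    return PairSummary(counts, curves)
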