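"""Dirichlet-multinomial ASV-count simulator with latent-factor co-occurrence.

The generator emulates 16S amplicon count tables from a juvenile-zebrafish
feeding trial: a handful of diet × timepoint groups, ten or so guts per group,
sequencing depths spread roughly tenfold across samples, and a community in
which some taxon pairs genuinely co-vary.

Mechanism (a latent-factor copula on log abundances):

1. a base relative-abundance profile is drawn once per table from a
   Dirichlet(base_concentration) over taxa;
2. taxa are assigned round-robin to ``n_latent_factors`` latent factors
   (two or more taxa per factor share a factor and form the planted
   co-occurring pairs recorded in the ground truth);
3. per sample, each taxon's log abundance is perturbed by
   ``sqrt(s)·z_factor + sqrt(1−s)·eps`` with s = ``factor_strength``, so the
   latent correlation between same-factor taxa is exactly s and s = 0 makes
   taxa exchangeable given the base profile;
4. optional per-group log-fold effects shift chosen taxa;
5. reads are drawn multinomial(depth, softmax(log profile)) with depth
   log-uniform in ``depth_range``.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..containers import CountTable

# default groups mirror a 3-diet x 2-timepoint gut design
DEFAULT_GROUPS = (
    ("control", 54), ("butyrate", 54), ("saponin", 54),
    ("control", 68), ("butyrate", 68), ("saponin", 68),
)


@dataclass
class CommunitySimConfig:
    """Parameters of the ASV-table generator.

    Defaults match the scale of the emulated study: 204 taxa (the ASV count
    surviving the low-count filter), 10 guts per diet × timepoint group, and
    per-sample depths spanning 31,814–577,719 reads.
    """

    n_taxa: int = 204
    n_samples_per_group: int = 10
    groups: Sequence[tuple] = DEFAULT_GROUPS
    base_concentration: float = 1.0
    depth_range: tuple = (31_814, 577_719)
    n_latent_factors: int = 5
    factor_strength: float = 0.0
    latent_scale: float = 1.5
    group_factor_strength: Mapping[tuple, float] = field(default_factory=dict)
    group_effect_taxa: Mapping[tuple, tuple] = field(default_factory=dict)
    source: str = "gut"
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.n_samples_per_group < 1:
            raise ValueError("n_samples_per_group must be >= 1")
        lo, hi = self.depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("depth_range must satisfy 0 < min <= max")
        if not 0.0 <= self.factor_strength <= 1.0:
            raise ValueError("factor_strength must lie in [0, 1]")
        for g, s in self.group_factor_strength.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"factor strength for group {g} must lie in [0, 1]")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        if self.n_latent_factors < 0:
            raise ValueError("n_latent_factors must be >= 0")


def _group_key(key) -> tuple:
    """Normalize a group key: (diet, tp) tuple, [diet, tp] list, or
    "diet@tp" string (the YAML-friendly form)."""
    if isinstance(key, str):
        diet, tp = key.split("@")
        return diet, int(tp)
    diet, tp = key
    return diet, tp


def _factor_assignment(n_taxa: int, n_factors: int) -> np.ndarray:
    """Round-robin taxon → factor map; -1 where no factor is used."""
    if n_factors == 0:
        return np.full(n_taxa, -1)
    return np.arange(n_taxa) % n_factors


def simulate_asv_table(config: CommunitySimConfig):
    """Draw a :class:`CountTable` plus ground truth.

    Returns
    -------
    table : CountTable
    truth : dict with keys ``factor_of_taxon`` (index → factor id),
        ``planted_pairs`` (set of unordered taxon-id pairs sharing a factor),
        ``group_effects`` and ``base_profile``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    taxa = [f"ASV{i:04d}" for i in range(config.n_taxa)]
    base = rng.dirichlet(np.full(config.n_taxa, config.base_concentration))
    # guard against log(0) for extremely small Dirichlet draws
    log_base = np.log(np.maximum(base, 1e-12))

    factor_of = _factor_assignment(config.n_taxa, config.n_latent_factors)
    planted = set()
    for f in range(config.n_latent_factors):
        members = [taxa[i] for i in np.flatnonzero(factor_of == f)]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                planted.add(frozenset((members[i], members[j])))

    c = config.latent_scale
    lo, hi = config.depth_range
    strength_of = {_group_key(k): v for k, v in config.group_factor_strength.items()}
    effect_of = {_group_key(k): v for k, v in config.group_effect_taxa.items()}

    columns = {}
    meta_rows = []
    for diet, tp in config.groups:
        effect = np.zeros(config.n_taxa)
        key = (diet, tp)
        # per-group co-occurrence strength overrides the global knob
        s = strength_of.get(key, config.factor_strength)
        if key in effect_of:
            idx, lfc = effect_of[key]
            effect[np.asarray(idx, dtype=int)] = lfc
        for k in range(config.n_samples_per_group):
            sample_id = f"{diet}_{tp}_{k:02d}"
            z = rng.standard_normal(max(config.n_latent_factors, 1))
            eps = rng.standard_normal(config.n_taxa)
            latent = np.where(
                factor_of >= 0,
                np.sqrt(s) * z[np.maximum(factor_of, 0)] + np.sqrt(1.0 - s) * eps,
                eps,
            )
            eta = log_base + c * latent + effect
            p = np.exp(eta - eta.max())
            p /= p.sum()
            depth = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            columns[sample_id] = rng.multinomial(depth, p)
            meta_rows.append(
                {"sample": sample_id, "diet": diet, "timepoint": tp, "source": config.source}
            )

    counts = pd.DataFrame(columns, index=taxa)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    truth = {
        "factor_of_taxon": dict(zip(taxa, factor_of.tolist())),
        "planted_pairs": planted,
        "group_effects": dict(config.group_effect_taxa),
        "base_profile": pd.Series(base, index=taxa),
    }
    return CountTable(counts, metadata), truth


def simulate_tree(taxon_ids: Sequence[str], seed: int = 0) -> str:
    """Random binary tree over ``taxon_ids`` as a newick string.

    Built by random pairwise joins (a coalescent-style topology) with
    exponential branch lengths, giving positive lengths everywhere and a leaf
    set equal to the input ids.  Deterministic per seed.
    """
    ids = list(taxon_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon ids")
    rng = np.random.default_rng(seed)
    nodes = [(tid, 0.0) for tid in ids]  # (newick fragment, height)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (na, ha), (nb, hb) = nodes[i], nodes[j]
        height = max(ha, hb) + float(rng.exponential(1.0)) + 1e-3
        frag = f"({na}:{height - ha:.6f},{nb}:{height - hb:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append((frag, height))
    return nodes[0][0] + ";"
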