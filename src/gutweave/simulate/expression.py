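"""Lognormal expression simulator with GO-level group effects.

Emulates the transcriptome layer: tpm-scale values for a few thousand genes
over small diet × timepoint groups (the emulated study profiled n = 5 guts
per diet per timepoint), with an overlapping GO-style annotation and
log2-fold effects planted on whole terms within chosen groups.

Values are lognormal around a per-gene baseline; genes belonging to an
affected term are shifted multiplicatively by the stated log2 effect in that
group.  Columns are NOT re-closed to one million: forcing the compositional
closure would dilute every planted effect by a factor depending on how many
terms are affected, which would falsify the recorded ground truth.  The
values are on a tpm-like scale (baseline column sums are ~1e6/n_genes·genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_GROUPS = (
    ("control", 54), ("butyrate", 54), ("saponin", 54),
    ("control", 68), ("butyrate", 68), ("saponin", 68),
)


def _group_key(key) -> tuple:
    """Accept (diet, tp) tuples, [diet, tp] lists, or "diet@tp" strings."""
    if isinstance(key, str):
        diet, tp = key.split("@")
        return diet, int(tp)
    diet, tp = key
    return diet, tp


@dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    n_samples_per_group: int = 5
    groups: Sequence[tuple] = DEFAULT_GROUPS
    n_go_terms: int = 50
    term_size_range: tuple = (10, 20)
    overlap_frac: float = 0.25
    affected_terms: Mapping[tuple, Sequence[tuple]] = field(default_factory=dict)
    dispersion: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.term_size_range
        if lo < 1 or hi < lo:
            raise ValueError("term_size_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.overlap_frac <= 1.0:
            raise ValueError("overlap_frac must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_genes < 1 or self.n_go_terms < 0:
            raise ValueError("n_genes and n_go_terms must be non-negative counts")
        term_ids = {f"GO:{t:07d}" for t in range(self.n_go_terms)}
        for group, effects in self.affected_terms.items():
            for term, _ in effects:
                if term not in term_ids:
                    raise ValueError(f"affected term {term} does not exist")


def _build_annotation(cfg: ExpressionSimConfig, rng: np.random.Generator, genes):
    """Consecutive gene blocks; each term shares ``overlap_frac`` of its genes
    with the previous term (wrap-around over the gene list)."""
    ann = {}
    cursor = 0
    for t in range(cfg.n_go_terms):
        size = int(rng.integers(cfg.term_size_range[0], cfg.term_size_range[1] + 1))
        step = max(1, int(round(size * (1.0 - cfg.overlap_frac))))
        members = [genes[(cursor + k) % cfg.n_genes] for k in range(size)]
        ann[f"GO:{t:07d}"] = sorted(set(members))
        cursor += step
    return ann


def simulate_expression(config: ExpressionSimConfig):
    """Return (expression DataFrame gene × sample, metadata, annotation, truth).

    truth maps group → {term: log2_effect} exactly as planted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    annotation = _build_annotation(config, rng, genes)

    # per-gene baseline mean on a tpm-like scale; the moderate spread keeps
    # term sums from being dominated by a single extreme gene
    base_log_mean = rng.normal(np.log(1e6 / config.n_genes), 0.5, size=config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}

    affected = {_group_key(k): v for k, v in config.affected_terms.items()}
    columns = {}
    meta_rows = []
    truth = {}
    for diet, tp in config.groups:
        key = (diet, tp)
        shift = np.zeros(config.n_genes)
        if key in affected:
            truth[key] = {}
            for term, log2_effect in affected[key]:
                truth[key][term] = log2_effect
                for g in annotation[term]:
                    # a gene shared by several affected terms takes the
                    # strongest single effect, not the sum, so the recorded
                    # per-term ground truth stays exact under overlap
                    idx = gene_index[g]
                    if abs(log2_effect) > abs(shift[idx]) / np.log(2.0):
                        shift[idx] = log2_effect * np.log(2.0)
        for k in range(config.n_samples_per_group):
            sample_id = f"{diet}_{tp}_{k:02d}"
            vals = np.exp(
                base_log_mean + shift + config.dispersion * rng.standard_normal(config.n_genes)
            )
            columns[sample_id] = vals
            meta_rows.append({"sample": sample_id, "diet": diet, "timepoint": tp})

    expr = pd.DataFrame(columns, index=genes)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    return expr, metadata, annotation, truth
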