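"""Experimental-design constants of the emulated zebrafish feeding trial.

These are the printed facts of the study the pipeline emulates: a 3-diet ×
2-timepoint design with 10 gut samples per group for 16S profiling, a total
high-quality read yield, per-sample depth extremes, and the feed inclusion
rates of the two supplements.  They parameterize the synthetic generators'
defaults and the worked-example arithmetic.
"""

TOTAL_HIGH_QUALITY_READS = 17_203_234
N_DIETS = 3
N_TIMEPOINTS = 2
N_GUT_SAMPLES_PER_GROUP = 10
MIN_SAMPLE_DEPTH = 31_814
MAX_SAMPLE_DEPTH = 577_719
RAREFACTION_DEPTH = MIN_SAMPLE_DEPTH

BUTYRATE_G_PER_KG = 1.0
SAPONIN_G_PER_KG = 3.3


def n_amplicon_samples() -> int:
    """Gut samples in the 16S design: diets × timepoints × fish per group."""
    return N_DIETS * N_TIMEPOINTS * N_GUT_SAMPLES_PER_GROUP


def mean_reads_per_sample() -> float:
    """Average per-sample read count implied by the total yield and design."""
    return TOTAL_HIGH_QUALITY_READS / n_amplicon_samples()


def g_per_kg_to_percent(g_per_kg: float) -> float:
    """Feed inclusion rate: grams per kilogram of feed as a percentage."""
    return g_per_kg / 1000.0 * 100.0
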