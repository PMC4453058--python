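"""Calibration and recovery experiments on the synthetic generator.

These are the package's standard self-checks, each phrased as a plain
function returning numbers:

* type-I calibration of the cross-phylum correlation screen under the
  null generator (no shared environmental offset): the mean fraction of
  phylum pairs with p < alpha should sit at the chance level alpha;
* signal recovery: a shared per-sample offset with SD of a few GC points
  should make essentially all phylum pairs significantly positively
  correlated;
* enrichment recovery: giving Actinobacteria-dominated gut samples a
  positive GC offset should push the top-GC/dominated overlap k above
  its hypergeometric null mean nK/N and make the rank-sum test flag the
  dominated group.

Replicate counts and per-collection sizes mirror the surveyed study
design (10 phyla; ~100 samples per collection; 111-gut panels with ~24
dominated samples).
"""

from __future__ import annotations

import numpy as np

from .cross_phylum_correlation import significance_summary, spearman_matrix
from .gc_metrics import build_gc_matrix
from .gut_enrichment import enrichment_table, hypergeom_pmf
from .sequence_io import screen_reads
from .synthetic_community import (
    EnvironmentProfile,
    SyntheticConfig,
    actinobacteria_gut_scenario,
    default_phylum_profiles,
    generate_collection,
    simulate_gc_matrix,
)

__all__ = [
    "table3a_hypergeometric",
    "null_calibration",
    "signal_recovery",
    "enrichment_recovery",
]


def table3a_hypergeometric(
    overlaps: tuple[int, ...] = (5, 9, 10, 11), N: int = 111, K: int = 24, n: int = 24
) -> dict[int, float]:
    """Point hypergeometric probabilities for the gut-panel design.

    With 111 gut samples, 24 of them Actinobacteria-dominated and top-GC
    sets sized to match, these are the chance probabilities of observing
    exactly k dominated samples among the 24 most GC-rich.
    """
    return {k: hypergeom_pmf(k, N=N, K=K, n=n)[0] for k in overlaps}


def _null_config(seed: int, n_samples: int, reads_per_sample: int) -> SyntheticConfig:
    return SyntheticConfig(
        phyla=default_phylum_profiles(),
        environments=[EnvironmentProfile("env", n_samples=n_samples)],
        reads_per_sample=reads_per_sample,
        offset_sd=0.0,  # no environmental coupling
        seed=seed,
    )


def null_calibration(
    n_collections: int = 500,
    n_samples: int = 100,
    reads_per_sample: int = 200,
    alpha: float = 0.05,
    seed_base: int = 0,
) -> float:
    """Mean fraction of phylum pairs with p < alpha under the null.

    Each collection draws its GC matrix from the generator with
    offset_sd = 0, so per-phylum means vary only through read sampling
    and are independent across phyla; the expected fraction is alpha.
    """
    fractions = []
    for i in range(n_collections):
        cfg = _null_config(seed_base + i + 1, n_samples, reads_per_sample)
        matrix, _, _ = simulate_gc_matrix(cfg)
        results = spearman_matrix(matrix)
        ps = [r.p_value for r in results if np.isfinite(r.p_value)]
        fractions.append(float(np.mean([p < alpha for p in ps])))
    return float(np.mean(fractions))


def signal_recovery(
    seed: int = 1,
    n_samples: int = 100,
    reads_per_sample: int = 300,
    read_length: int = 150,
    offset_sd: float = 3.0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Read-level end-to-end run with a shared per-sample GC offset.

    Generates actual sequences, screens them, builds the GC matrix and
    runs the correlation screen. Returns the fraction of phylum pairs
    that are significantly positively correlated, the median rho and the
    mean per-phylum significant fraction.
    """
    cfg = SyntheticConfig(
        phyla=default_phylum_profiles(),
        environments=[EnvironmentProfile("env", n_samples=n_samples)],
        reads_per_sample=reads_per_sample,
        read_length=read_length,
        offset_sd=offset_sd,
        seed=seed,
    )
    collection = generate_collection(cfg)
    screened, _ = screen_reads(collection.reads)
    matrix = build_gc_matrix(screened)
    results = spearman_matrix(matrix)
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    sig_pos = [r for r in testable if r.p_value < alpha and r.rho > 0]
    summary = significance_summary(results, alpha=alpha)
    return {
        "fraction_significant_positive": len(sig_pos) / len(testable),
        "median_rho": float(np.median([r.rho for r in testable])),
        "mean_significant_fraction": summary.attrs["mean_fraction"],
        "n_pairs": len(testable),
    }


def enrichment_recovery(
    n_collections: int = 200,
    dominated_offset: float = 5.0,
    alpha: float = 0.05,
    seed_base: int = 0,
) -> dict[str, float]:
    """Recovery of the dominance/GC coupling in simulated gut panels.

    Each collection is a 111-sample gut panel whose ~24
    Actinobacteria-dominated samples receive ``dominated_offset`` GC
    points across all phyla. Reported: the fraction of collections where
    the mean overlap k (across phyla) exceeds its hypergeometric null
    mean nK/N, and the fraction where the rank-sum test flags the
    dominated group (higher GC, p < alpha) for a majority of phyla.
    """
    exceeds = 0
    mw_flags = 0
    for i in range(n_collections):
        cfg = actinobacteria_gut_scenario(
            dominated_offset=dominated_offset, seed=seed_base + i + 1
        )
        matrix, abundance, _ = simulate_gc_matrix(cfg)
        results = enrichment_table(matrix, abundance, "Actinobacteria")
        if not results:
            continue
        mean_k = float(np.mean([r.k for r in results]))
        mean_null = float(np.mean([r.n * r.K / r.N for r in results]))
        if mean_k > mean_null:
            exceeds += 1
        n_flagged = sum(
            1 for r in results if r.p_mw < alpha and r.mean_gc_top > r.mean_gc_rest
        )
        if n_flagged > len(results) / 2:
            mw_flags += 1
    return {
        "fraction_k_above_null_mean": exceeds / n_collections,
        "fraction_mw_flags_majority": mw_flags / n_collections,
        "null_mean_overlap_24_24_111": 24 * 24 / 111,
    }
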