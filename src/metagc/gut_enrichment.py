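"""Actinobacteria-dominance enrichment analysis of human-gut samples.

Gut communities split into two regimes: samples dominated by the GC-rich
phylum Actinobacteria and samples led by Bacteroidetes/Firmicutes/
Proteobacteria. The analysis asks whether the dominated samples are also
the ones in which *other* phyla are unusually GC-rich — evidence that
whatever favors Actinobacteria also pushes every resident phylum toward
GC.

Procedure, per phylum: rank the N gut samples by that phylum's mean GC,
take the top K; rank them by focal-phylum (Actinobacteria) abundance and
select the dominated subset of size n (either abundance >= 0.5 or the
top-q fraction); count the overlap k and score it against the
hypergeometric distribution. A rank-sum (Mann-Whitney) test additionally
compares the phylum's GC values between the dominated samples and the
rest.

The hypergeometric probability reported as the headline number is the
point mass P(X = k) = C(K,k) C(N-K,n-k) / C(N,n) (computed in log-gamma
space); the upper tail P(X >= k) is also returned.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, exp, lgamma, sqrt
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gc_metrics import GCMatrix

__all__ = [
    "EnrichmentResult",
    "select_dominated",
    "top_gc_set",
    "hypergeom_pmf",
    "mann_whitney",
    "enrichment_table",
    "enrichment_frame",
]

MW_EXACT_MAX = 8


def _lchoose(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> tuple[float, float]:
    """Point mass P(X = k) and upper tail P(X >= k), in log-gamma space.

    X counts marked items among n draws without replacement from N items
    of which K are marked. An impossible k (k > min(K, n) or
    n - k > N - K) yields probability 0 for the point mass by convention.
    """
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError(f"negative overlap k={k}")
    lo = max(0, n - (N - K))
    hi = min(K, n)
    if k < lo or k > hi:
        pmf = 0.0
    else:
        pmf = exp(_lchoose(K, k) + _lchoose(N - K, n - k) - _lchoose(N, n))
    tail = sum(
        exp(_lchoose(K, j) + _lchoose(N - K, n - j) - _lchoose(N, n))
        for j in range(max(k, lo), hi + 1)
    )
    return pmf, min(tail, 1.0)


SelectionRule = Literal["threshold", "top_fraction"]


def select_dominated(
    abundance: pd.DataFrame,
    focal_phylum: str,
    rule: SelectionRule = "threshold",
    threshold: float = 0.5,
    q: float = 0.22,
) -> set[str]:
    """Samples dominated by the focal phylum.

    "threshold": samples whose focal relative abundance is >= ``threshold``
    (default 0.5). "top_fraction": the ceil(q*N) samples with the highest
    focal abundance. Ties break by sample id for determinism. The two
    rules need not select the same set.
    """
    if focal_phylum not in abundance.columns:
        raise KeyError(f"focal phylum {focal_phylum!r} not in abundance table")
    col = abundance[focal_phylum].fillna(0.0)
    if rule == "threshold":
        return set(col.index[col >= threshold])
    if rule == "top_fraction":
        n_top = int(np.ceil(q * len(col)))
        order = sorted(col.index, key=lambda s: (-col[s], s))
        return set(order[:n_top])
    raise ValueError(f"unknown selection rule {rule!r}")


def top_gc_set(gc: GCMatrix, phylum: str, K: int) -> set[str]:
    """The K samples with the highest mean GC in ``phylum`` (ties by id)."""
    col = gc.mean[phylum].dropna()
    if len(col) < K:
        raise ValueError(
            f"phylum {phylum!r}: only {len(col)} non-missing cells, need {K}"
        )
    order = sorted(col.index, key=lambda s: (-col[s], s))
    return set(order[:K])


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (reported as min(U_a, U_b)) and two-sided p.

    Ranks are midranks. For groups both of size <= 8 the p-value is an
    exact permutation tail over all C(n_a+n_b, n_a) group assignments
    (valid under ties); otherwise the normal approximation with tie and
    continuity correction is used. Degenerate pooled data (all values
    identical) gives p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled, method="average")
    ra = ranks[:na].sum()
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    u = min(u_a, u_b)
    mean_u = na * nb / 2.0

    if na <= MW_EXACT_MAX and nb <= MW_EXACT_MAX:
        total = comb(na + nb, na)
        obs_dev = abs(u_a - mean_u)
        count = 0
        idx = range(na + nb)
        for chosen in itertools.combinations(idx, na):
            r = ranks[list(chosen)].sum()
            u_perm = r - na * (na + 1) / 2.0
            if abs(u_perm - mean_u) >= obs_dev - 1e-12:
                count += 1
        return u, count / total

    # Normal approximation, tie-corrected variance, continuity correction.
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u, 1.0
    z = (abs(u_a - mean_u) - 0.5) / sqrt(var_u)
    z = max(z, 0.0)
    return u, float(min(1.0, 2.0 * sps.norm.sf(z)))


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-phylum overlap of the top-GC sample set with the dominated set."""

    phylum: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    p_hyper_tail: float
    p_mw: float
    mean_gc_top: float
    mean_gc_rest: float

    def __post_init__(self) -> None:
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValueError(f"{self.phylum}: overlap k={self.k} impossible")


def enrichment_table(
    gc: GCMatrix,
    abundance: pd.DataFrame,
    focal_phylum: str,
    rule: SelectionRule = "threshold",
    threshold: float = 0.5,
    q: float = 0.22,
) -> list[EnrichmentResult]:
    """Per-phylum enrichment of GC-rich samples within the dominated set.

    The dominated set (size n) is selected once from the abundance table;
    for each phylum the top-GC set is sized K = n (restricted to samples
    with a non-missing cell for that phylum, so N may differ slightly by
    phylum when cells are missing). ``mean_gc_top``/``mean_gc_rest``
    compare dominated vs remaining samples for that phylum, matching the
    rank-sum test's grouping.
    """
    common = [s for s in gc.samples if s in abundance.index]
    dominated_all = select_dominated(
        abundance.loc[common], focal_phylum, rule=rule, threshold=threshold, q=q
    )
    results: list[EnrichmentResult] = []
    for phylum in gc.phyla:
        col = gc.mean.loc[common, phylum].dropna()
        avail = set(col.index)
        dominated = dominated_all & avail
        N = len(avail)
        n = len(dominated)
        if n == 0 or n == N:
            continue  # enrichment undefined without a two-group split
        K = n
        sub = gc.subset(avail)
        top = top_gc_set(sub, phylum, K)
        k = len(top & dominated)
        pmf, tail = hypergeom_pmf(k, N=N, K=K, n=n)
        gc_dom = col[sorted(dominated)].to_numpy()
        gc_rest = col[sorted(avail - dominated)].to_numpy()
        u, p_mw = mann_whitney(gc_dom, gc_rest)
        results.append(
            EnrichmentResult(
                phylum=phylum,
                N=N,
                K=K,
                n=n,
                k=k,
                p_hyper=pmf,
                p_hyper_tail=tail,
                p_mw=p_mw,
                mean_gc_top=float(gc_dom.mean()),
                mean_gc_rest=float(gc_rest.mean()),
            )
        )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of enrichment results (one row per phylum)."""
    return pd.DataFrame(
        [
            (
                r.phylum,
                r.N,
                r.K,
                r.n,
                r.k,
                r.p_hyper,
                r.p_hyper_tail,
                r.p_mw,
                r.mean_gc_top,
                r.mean_gc_rest,
            )
            for r in results
        ],
        columns=[
            "phylum",
            "N",
            "K",
            "n",
            "k",
            "p_hyper",
            "p_hyper_tail",
            "p_mw",
            "mean_gc_top",
            "mean_gc_rest",
        ],
    )
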