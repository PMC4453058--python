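"""Cross-phylum Spearman correlation screening.

The question: does the mean GC of one phylum co-vary with the mean GC of
the other phyla across samples? Under pure phylogenetic determination of
nucleotide composition the per-phylum means are independent across
samples, so about 5% of pairs reach p < 0.05 by chance; a shared
environmental pressure on GC shows up as an excess of significant,
positive rank correlations. The analysis is therefore summarized as the
per-phylum fraction of significantly correlated partners, compared
against the 5% chance baseline — deliberately without multiple-testing
correction, since the baseline itself plays that role.

Spearman's rho is computed from midranks (tie-corrected); two-sided
p-values come from the t approximation t = rho*sqrt((n-2)/(1-rho^2)) with
n-2 df, or from exact permutation over all n! rank orders for small n
(default n <= 9, where full enumeration is affordable).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gc_metrics import GCMatrix
from .sequence_io import SampleMeta

__all__ = [
    "CorrelationResult",
    "spearman_rho",
    "spearman_test",
    "spearman_matrix",
    "results_frames",
    "significance_summary",
    "run_subsets",
]

EXACT_N_MAX = 9

PValueMethod = Literal["auto", "asymptotic", "exact"]


@dataclass(frozen=True)
class CorrelationResult:
    phylum_a: str
    phylum_b: str
    rho: float
    p_value: float
    n_samples: int

    @property
    def testable(self) -> bool:
        return np.isfinite(self.rho)


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Tie-corrected Spearman rho: Pearson correlation of midranks.

    Returns NaN when either variable is constant (rank variance zero).
    """
    rx = _midranks(np.asarray(x, dtype=float))
    ry = _midranks(np.asarray(y, dtype=float))
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _asymptotic_p(rho: float, n: int) -> float:
    if n < 3 or not np.isfinite(rho):
        return float("nan")
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * sps.t.sf(abs(t), df=n - 2))


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided permutation p over all n! orderings of the y midranks."""
    rx = _midranks(x)
    ry = _midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    rhos = ((perms - ry.mean()) * (rx - rx.mean())).mean(axis=1) / (sx * sy)
    obs = abs(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def spearman_test(
    x: Sequence[float],
    y: Sequence[float],
    method: PValueMethod = "auto",
) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair of aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned")
    n = len(x)
    rho = spearman_rho(x, y)
    if not np.isfinite(rho):
        return rho, float("nan")
    if method == "exact" or (method == "auto" and n <= EXACT_N_MAX):
        return rho, _exact_p(x, y)
    return rho, _asymptotic_p(rho, n)


def spearman_matrix(
    gc: GCMatrix,
    subset: Iterable[str] | None = None,
    method: PValueMethod = "auto",
    min_samples: int = 5,
) -> list[CorrelationResult]:
    """All-pairs Spearman correlations of per-phylum GC across samples.

    For each unordered phylum pair only samples where both cells are
    non-missing are used (pairwise-complete). Pairs with fewer than
    ``min_samples`` usable samples are marked untestable (NaN rho/p) and
    excluded from summary denominators.
    """
    mat = gc.subset(subset) if subset is not None else gc
    mean = mat.mean
    results: list[CorrelationResult] = []
    phyla = list(mean.columns)
    for a, b in itertools.combinations(phyla, 2):
        pair = mean[[a, b]].dropna()
        n = len(pair)
        if n < min_samples:
            results.append(CorrelationResult(a, b, float("nan"), float("nan"), n))
            continue
        rho, p = spearman_test(pair[a].to_numpy(), pair[b].to_numpy(), method)
        results.append(CorrelationResult(a, b, rho, p, n))
    return results


def results_frames(
    results: Sequence[CorrelationResult], phyla: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric rho and p matrices (unit diagonal; p=0 on the diagonal)."""
    if phyla is None:
        phyla = sorted({r.phylum_a for r in results} | {r.phylum_b for r in results})
    rho = pd.DataFrame(np.nan, index=phyla, columns=phyla, dtype=float)
    p = pd.DataFrame(np.nan, index=phyla, columns=phyla, dtype=float)
    np.fill_diagonal(rho.values, 1.0)
    np.fill_diagonal(p.values, 0.0)
    for r in results:
        rho.loc[r.phylum_a, r.phylum_b] = rho.loc[r.phylum_b, r.phylum_a] = r.rho
        p.loc[r.phylum_a, r.phylum_b] = p.loc[r.phylum_b, r.phylum_a] = r.p_value
    return rho, p


def significance_summary(
    results: Sequence[CorrelationResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-phylum count/fraction of significantly correlated partners.

    The denominator for each phylum is its number of testable partners
    (untestable pairs are excluded). The collection-level mean fraction is
    attached as ``df.attrs["mean_fraction"]``; the chance baseline equals
    ``alpha``.
    """
    phyla = sorted({r.phylum_a for r in results} | {r.phylum_b for r in results})
    sig = {ph: 0 for ph in phyla}
    tested = {ph: 0 for ph in phyla}
    for r in results:
        if not r.testable or not np.isfinite(r.p_value):
            continue
        for ph in (r.phylum_a, r.phylum_b):
            tested[ph] += 1
            if r.p_value < alpha:
                sig[ph] += 1
    df = pd.DataFrame(
        {
            "n_significant": [sig[ph] for ph in phyla],
            "n_tested": [tested[ph] for ph in phyla],
        },
        index=pd.Index(phyla, name="phylum"),
    )
    with np.errstate(invalid="ignore"):
        df["fraction"] = df["n_significant"] / df["n_tested"]
    df.attrs["alpha"] = alpha
    valid = df["fraction"].dropna()
    df.attrs["mean_fraction"] = float(valid.mean()) if len(valid) else float("nan")
    return df


def run_subsets(
    gc: GCMatrix,
    samples: Sequence[SampleMeta] | Mapping[str, str],
    focal_environment: str | None = None,
    method: PValueMethod = "auto",
    alpha: float = 0.05,
    min_samples: int = 5,
) -> dict[str, dict]:
    """Correlation analysis on sample subsets keyed by environment.

    Always runs "all"; with a ``focal_environment`` also runs
    "env=<name>" (that environment only) and "all_minus_<name>". Each
    entry holds the pair results, the symmetric rho/p frames and the
    significance summary.
    """
    if isinstance(samples, Mapping):
        env_of = dict(samples)
    else:
        env_of = {s.sample_id: s.environment for s in samples}
    in_matrix = [s for s in gc.samples if s in env_of]

    subsets: dict[str, list[str]] = {"all": in_matrix}
    if focal_environment is not None:
        subsets[f"env={focal_environment}"] = [
            s for s in in_matrix if env_of[s] == focal_environment
        ]
        subsets[f"all_minus_{focal_environment}"] = [
            s for s in in_matrix if env_of[s] != focal_environment
        ]

    out: dict[str, dict] = {}
    for key, ids in subsets.items():
        results = spearman_matrix(gc, subset=ids, method=method, min_samples=min_samples)
        rho, p = results_frames(results, phyla=gc.phyla)
        out[key] = {
            "n_samples": len(ids),
            "results": results,
            "rho": rho,
            "p": p,
            "summary": significance_summary(results, alpha=alpha),
        }
    return out


def write_correlation_tables(
    subset_results: Mapping[str, dict], outdir, alpha: float = 0.05
) -> None:
    """One rho TSV per subset with significant entries flagged '*', plus
    a combined per-phylum significant-fraction summary TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary_rows = []
    for key, res in subset_results.items():
        rho, p = res["rho"], res["p"]
        flagged = rho.round(3).astype(str)
        star = (p < alpha) & np.isfinite(rho) & ~np.eye(len(rho), dtype=bool)
        flagged = flagged.where(~star, flagged + "*")
        safe = key.replace("=", "_")
        flagged.to_csv(outdir / f"spearman_rho_{safe}.tsv", sep="\t")
        p.to_csv(outdir / f"spearman_p_{safe}.tsv", sep="\t", float_format="%.4g")
        summ = res["summary"].copy()
        summ.insert(0, "subset", key)
        summary_rows.append(summ.reset_index())
    pd.concat(summary_rows, ignore_index=True).to_csv(
        outdir / "significant_fractions.tsv", sep="\t", index=False
    )
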