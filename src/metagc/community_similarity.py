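"""Genus presence/absence sets per environment and Jaccard similarity.

Genus-level calls on short reads are too unreliable for abundance
estimation, but presence/absence across a whole environment is robust
enough to ask whether environments exclude entire genera. Each
environment is reduced to the set of genus labels seen in any of its
reads and environments are compared with the Jaccard index
|A intersect B| / |A union B|. No confidence threshold is applied to
genus calls by default (an optional threshold is available).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ReadRecord, SampleMeta

__all__ = ["genus_sets", "jaccard", "jaccard_matrix", "write_genus_sets"]


def genus_sets(
    reads: Sequence[ReadRecord],
    samples: Sequence[SampleMeta] | Mapping[str, str],
    min_conf: float | None = None,
) -> dict[str, set[str]]:
    """Set of genera observed in each environment.

    Every environment in ``samples`` gets a set (possibly empty). Reads
    without a genus label are ignored; ``min_conf`` optionally applies a
    confidence threshold to the genus calls (off by default).
    """
    if isinstance(samples, Mapping):
        env_of = dict(samples)
    else:
        env_of = {s.sample_id: s.environment for s in samples}
    sets: dict[str, set[str]] = {env: set() for env in env_of.values()}
    for r in reads:
        if r.genus is None or r.sample_id not in env_of:
            continue
        if min_conf is not None and r.confidence < min_conf:
            continue
        sets[env_of[r.sample_id]].add(r.genus)
    return sets


def jaccard(a: set[str], b: set[str]) -> float:
    """Jaccard similarity |A∩B| / |A∪B|; NaN when both sets are empty."""
    union = a | b
    if not union:
        return float("nan")
    return len(a & b) / len(union)


def jaccard_matrix(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Symmetric environments x environments Jaccard matrix.

    Diagonal is 1 for non-empty sets (NaN for empty ones, where the index
    is undefined).
    """
    envs = list(sets)
    mat = pd.DataFrame(np.nan, index=envs, columns=envs, dtype=float)
    for i, e1 in enumerate(envs):
        for e2 in envs[i:]:
            val = jaccard(sets[e1], sets[e2])
            mat.loc[e1, e2] = mat.loc[e2, e1] = val
    return mat


def write_genus_sets(sets: Mapping[str, set[str]], outdir: str | Path) -> None:
    """One sorted genus-per-line text file per environment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for env, genera in sets.items():
        (outdir / f"genera_{env}.txt").write_text(
            "".join(g + "\n" for g in sorted(genera))
        )
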