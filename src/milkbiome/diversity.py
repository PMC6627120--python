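"""Alpha diversity: Shannon, Chao1, rarefaction and the minimum-depth filter.

Shannon-Weaver entropy H = -sum p_i log(p_i) summarizes evenness and
richness together; Chao1 extrapolates unseen richness from the counts of
singletons (F1) and doubletons (F2).  Rarefaction subsamples reads without
replacement to show how a metric grows with sequencing depth; in the study
design, samples whose depth falls below the plateau of that curve (1000
reads) are excluded, with a strict ``<`` comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tableio import CountTable, CountTableError

__all__ = [
    "shannon",
    "chao1",
    "observed_features",
    "alpha_diversity_table",
    "RarefactionCurve",
    "rarefaction_curve",
    "filter_min_depth",
]


def _as_counts(counts) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise CountTableError("expected a 1-D count vector")
    if (x < 0).any():
        raise CountTableError("negative count")
    if x.sum() == 0:
        raise CountTableError("all-zero count vector")
    return x


def shannon(counts, base: float | None = None) -> float:
    """Shannon-Weaver index H = -sum_{x_i>0} p_i log_base(p_i).

    ``base=None`` uses the natural logarithm (the default here; base 2 is
    common in other ecosystems and available via ``base=2``).
    """
    x = _as_counts(counts)
    p = x[x > 0] / x.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def observed_features(counts) -> int:
    """Number of features with a positive count."""
    x = _as_counts(counts)
    return int((x > 0).sum())


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Bias-corrected form (default) S_obs + F1(F1-1)/(2(F2+1)) is defined
    even when no doubletons exist; the classic form S_obs + F1^2/(2 F2) is
    available with ``bias_corrected=False`` (requires F2 > 0 when F1 > 0).
    """
    x = _as_counts(counts)
    s_obs = float((x > 0).sum())
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    if bias_corrected:
        return s_obs + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    if f1 > 0 and f2 == 0:
        raise CountTableError("classic Chao1 undefined with singletons but no doubletons")
    return s_obs + (f1 * f1 / (2.0 * f2) if f2 > 0 else 0.0)


def alpha_diversity_table(table: CountTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample Shannon, Chao1, observed features and depth."""
    rows = {}
    for s in table.sample_ids:
        x = table.counts[s].to_numpy()
        rows[s] = {
            "shannon": shannon(x, base=base),
            "chao1": chao1(x),
            "observed_features": observed_features(x),
            "depth": int(x.sum()),
        }
    return pd.DataFrame(rows).T


@dataclass
class RarefactionCurve:
    """Mean and sd of a metric at increasing subsampling depths."""

    depths: list[int]
    mean: pd.DataFrame      # sample x depth; NaN where depth > sample depth
    sd: pd.DataFrame
    metric: str
    n_iterations: int
    seed: int
    skipped: dict[str, list[int]]   # sample -> depths exceeding its total


_METRICS = {
    "shannon": lambda v: shannon(v),
    "chao1": lambda v: chao1(v),
    "observed": lambda v: float(observed_features(v)),
}


def _subsample_without_replacement(
    x: np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``depth`` reads without replacement (multivariate hypergeometric)."""
    return rng.multivariate_hypergeometric(x.astype(np.int64), depth)


def rarefaction_curve(
    table: CountTable,
    depths: list[int],
    metric: str = "shannon",
    n_iter: int = 10,
    seed: int = 0,
) -> RarefactionCurve:
    """Rarefy each sample to each depth ``n_iter`` times and average the metric.

    Subsampling is without replacement, so a depth equal to the sample's
    total reproduces the sample exactly (sd 0).  Depths exceeding a
    sample's total are skipped and reported, not extrapolated.
    """
    if not depths:
        raise CountTableError("empty depth list")
    if any(d <= 0 for d in depths):
        raise CountTableError("depths must be positive")
    if n_iter < 1:
        raise CountTableError("n_iter must be >= 1")
    if metric not in _METRICS:
        raise CountTableError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    rng = np.random.default_rng(seed)
    mean = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    sd = pd.DataFrame(index=table.sample_ids, columns=depths, dtype=float)
    skipped: dict[str, list[int]] = {}
    for s in table.sample_ids:
        x = table.counts[s].to_numpy()
        total = x.sum()
        for d in depths:
            if d > total:
                skipped.setdefault(s, []).append(d)
                continue
            vals = np.array([
                fn(_subsample_without_replacement(x, d, rng))
                for _ in range(n_iter)
            ])
            mean.loc[s, d] = vals.mean()
            sd.loc[s, d] = vals.std()
    return RarefactionCurve(list(depths), mean, sd, metric, n_iter, seed, skipped)


def filter_min_depth(
    table: CountTable, min_reads: int = 1000
) -> tuple[CountTable, list[str]]:
    """Drop biological samples with fewer than ``min_reads`` reads.

    The comparison is strict (``depth < min_reads`` removed), so a sample
    at exactly the threshold is kept.  Control and replicate columns are
    never removed by this filter.
    """
    if min_reads < 0:
        raise CountTableError("min_reads must be >= 0")
    depths = table.depths()
    removed = [
        s for s in table.biological_samples if depths[s] < min_reads
    ]
    kept = [s for s in table.sample_ids if s not in removed]
    if not any(table.sample_roles[s] == "biological" for s in kept):
        raise CountTableError("depth filter removed every biological sample")
    return table.subset_samples(kept), removed
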