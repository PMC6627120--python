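"""Permutation and classical inference.

PERMANOVA partitions the total sum of squared inter-sample distances into
among- and within-group components and compares the pseudo-F statistic to
its permutation distribution under random relabelling.  Alpha-diversity
group differences use one-way ANOVA; families of p-values across
covariates and taxonomy levels are corrected with the Benjamini-Hochberg
step-up procedure; replicate reproducibility is the R-squared of regressing
duplicate OTU counts on their originals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .clustering import DistanceMatrix
from .tableio import CountTable, CountTableError

__all__ = [
    "PermanovaResult",
    "FdrReport",
    "permanova",
    "bh_adjust",
    "alpha_anova",
    "replicate_r2",
    "covariate_scan",
]


@dataclass
class PermanovaResult:
    """Single-factor PERMANOVA decomposition and permutation p-value."""

    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """sum over groups of (1/n_g) * sum of squared distances within g."""
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss += sub.sum() / (2.0 * len(idx))   # each pair counted twice
    return ss


def permanova(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA of ``d`` against group labels.

    SS_T = (1/N) sum_{j<k} d_jk^2; SS_W sums the analogous within-group
    quantities; SS_A = SS_T - SS_W; pseudo-F = [SS_A/(a-1)] / [SS_W/(N-a)].
    The p-value is (1 + #{F_perm >= F_obs}) / (B + 1) over B unrestricted
    random permutations of the labels, so it can never be 0 and never
    exceeds 1.  Deterministic for a given ``seed``.
    """
    if permutations < 1:
        raise CountTableError("need at least 1 permutation")
    labels = pd.Series(groups)
    labels = labels.loc[[s for s in d.ids if s in labels.index]].dropna()
    ids = list(labels.index)
    if len(ids) < 2:
        raise CountTableError("fewer than 2 labelled samples")
    sub = d.subset(ids)
    codes, uniques = pd.factorize(labels.to_numpy())
    a = len(uniques)
    n = len(ids)
    if a < 2:
        raise CountTableError("PERMANOVA needs >= 2 groups")
    if a >= n:
        raise CountTableError("every sample in its own group")
    d2 = sub.values.to_numpy(dtype=float) ** 2
    ss_t = d2.sum() / (2.0 * n)
    ss_w = _ss_within(d2, codes, a)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, n - a
    if ss_w <= 0:
        f_obs = np.inf
    else:
        f_obs = (ss_a / df_a) / (ss_w / df_w)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        ss_w_p = _ss_within(d2, perm, a)
        if ss_w_p <= 0:
            f_p = np.inf
        else:
            f_p = ((ss_t - ss_w_p) / df_a) / (ss_w_p / df_w)
        if f_p >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (permutations + 1.0)
    return PermanovaResult(
        ss_among=float(ss_a), ss_within=float(ss_w), ss_total=float(ss_t),
        df_among=df_a, df_within=df_w, pseudo_f=float(f_obs), p_value=float(p),
        n_permutations=permutations, seed=seed, n_samples=n, n_groups=a,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise CountTableError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def alpha_anova(
    alpha_table: pd.DataFrame, groups: pd.Series | dict, metric: str = "shannon"
) -> tuple[float, float]:
    """One-way ANOVA of an alpha-diversity metric between groups.

    For a single factor the Type II test coincides with the classical
    one-way decomposition: F = MS_between / MS_within.
    """
    labels = pd.Series(groups).dropna()
    common = [s for s in alpha_table.index if s in labels.index]
    labels = labels.loc[common]
    values = alpha_table.loc[common, metric]
    grouped = [values[labels == g].to_numpy() for g in labels.unique()]
    if len(grouped) < 2:
        raise CountTableError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in grouped):
        raise CountTableError("each group needs >= 2 samples")
    f, p = stats.f_oneway(*grouped)
    return float(f), float(p)


def replicate_r2(table: CountTable, pair: tuple[str, str]) -> float:
    """R-squared of regressing a duplicate's OTU counts on the original's.

    Each feature contributes one point (original count, duplicate count);
    the coefficient of determination of the least-squares line measures
    how reproducibly the two library preparations rank and scale the OTUs.
    """
    orig, rep = pair
    for s in pair:
        if s not in table.counts.columns:
            raise CountTableError(f"sample {s!r} not in table")
    x = table.counts[orig].to_numpy(dtype=float)
    y = table.counts[rep].to_numpy(dtype=float)
    if len(x) < 2:
        raise CountTableError("need >= 2 features")
    if x.std() == 0:
        raise CountTableError("zero-variance predictor column")
    res = stats.linregress(x, y)
    return float(res.rvalue**2)


@dataclass
class FdrReport:
    """Raw and BH-adjusted p-values across covariates and taxonomy levels."""

    table: pd.DataFrame     # columns: covariate, level, p, q, significant
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


def covariate_scan(
    distances: dict[str, DistanceMatrix],
    metadata: pd.DataFrame,
    covariates: list[str],
    permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> FdrReport:
    """PERMANOVA of every covariate at every taxonomy level, BH-corrected.

    ``distances`` maps a taxonomy-level name to its distance matrix.  One
    p-value is produced per (covariate, level) cell; the whole family is
    then BH-adjusted together.  Results are sorted by (covariate, level)
    so the significant set does not depend on input order.
    """
    rows = []
    for ci, cov in enumerate(sorted(covariates)):
        for li, (level, d) in enumerate(sorted(distances.items())):
            labels = metadata[cov].dropna()
            res = permanova(
                d, labels, permutations=permutations,
                seed=seed + 1000 * ci + li,
            )
            rows.append({"covariate": cov, "level": level,
                         "p": res.p_value, "pseudo_f": res.pseudo_f})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return FdrReport(out, alpha)
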