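"""Compositional (Aitchison) geometry.

Count tables carry only relative information, so log-ratio methods are
used: zeros are first replaced by a Bayesian-multiplicative prior
adjustment (zero cells receive a small pseudo-proportion, nonzero cells
are shrunk multiplicatively so ratios among them are preserved exactly);
the centered log-ratio (CLR) transform maps each sample to log proportions
centered by their mean; Aitchison distance is the Euclidean distance
between CLR vectors and is a true metric on the open simplex.  Log-ratio
biplots are the SVD of the double-centered CLR matrix with lambda-scaling
to balance the total spread of sample and taxon markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tableio import CountTable, CountTableError

__all__ = [
    "ZeroReplacedComposition",
    "BiplotModel",
    "zero_replace",
    "clr",
    "clr_table",
    "aitchison_distance",
    "aitchison_distance_matrix",
    "logratio_biplot",
]


@dataclass
class ZeroReplacedComposition:
    """Strictly positive proportions after Bayesian-multiplicative adjustment."""

    proportions: pd.DataFrame      # feature x sample, columns sum to 1
    alpha: np.ndarray              # per-feature prior strength
    replaced_mask: pd.DataFrame    # True where a zero was imputed

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if arr.size and arr.min() <= 0:
            raise CountTableError("zero-replaced composition must be strictly positive")


def zero_replace(
    table: CountTable, alpha: float | np.ndarray = 0.5
) -> ZeroReplacedComposition:
    """Bayesian-multiplicative replacement of zero counts.

    For sample j with total n_j and per-feature prior strengths alpha_i,
    each zero cell becomes delta_ij = alpha_i / (n_j + sum_k alpha_k) and
    each nonzero cell becomes (x_ij/n_j) * (1 - sum of that sample's
    deltas), so columns still sum to 1 and ratios among observed parts are
    untouched.  The default alpha = 0.5 per feature is a Jeffreys-style
    prior.
    """
    x = table.counts.to_numpy(dtype=float)
    n_feat, n_samp = x.shape
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (n_feat,)).copy()
    if (a <= 0).any():
        raise CountTableError("alpha must be strictly positive")
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        bad = [table.sample_ids[j] for j in np.where(totals <= 0)[0]]
        raise CountTableError(f"zero-total sample(s): {bad}")
    a_sum = a.sum()
    zeros = x == 0
    delta = a[:, None] / (totals[None, :] + a_sum)       # candidate imputations
    removed = (delta * zeros).sum(axis=0)                # mass given to zeros, per sample
    props = np.where(zeros, delta, (x / totals[None, :]) * (1.0 - removed[None, :]))
    return ZeroReplacedComposition(
        pd.DataFrame(props, index=table.counts.index, columns=table.counts.columns),
        a,
        pd.DataFrame(zeros, index=table.counts.index, columns=table.counts.columns),
    )


def clr(composition) -> np.ndarray:
    """Centered log-ratio of one strictly positive composition vector."""
    x = np.asarray(composition, dtype=float)
    if (x <= 0).any():
        raise CountTableError(
            "clr requires strictly positive parts; apply zero_replace first")
    lx = np.log(x)
    return lx - lx.mean()


def clr_table(comp: ZeroReplacedComposition) -> pd.DataFrame:
    """CLR of every sample; feature x sample, each column sums to 0."""
    x = comp.proportions.to_numpy(dtype=float)
    lx = np.log(x)
    out = lx - lx.mean(axis=0, keepdims=True)
    return pd.DataFrame(out, index=comp.proportions.index,
                        columns=comp.proportions.columns)


def aitchison_distance(comp_a, comp_b) -> float:
    """Euclidean distance between CLR images of two compositions."""
    a = np.asarray(comp_a, dtype=float)
    b = np.asarray(comp_b, dtype=float)
    if a.shape != b.shape:
        raise CountTableError("compositions must share a feature set")
    return float(np.linalg.norm(clr(a) - clr(b)))


def aitchison_distance_matrix(comp: ZeroReplacedComposition):
    """Pairwise Aitchison distances between all samples."""
    from .clustering import DistanceMatrix  # local import to avoid a cycle

    z = clr_table(comp).to_numpy().T       # samples x features
    sq = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(np.maximum(sq, 0.0))
    np.fill_diagonal(d, 0.0)
    ids = list(comp.proportions.columns)
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "aitchison")


@dataclass
class BiplotModel:
    """Rank-reduced log-ratio biplot with lambda spread balancing."""

    row_coords: pd.DataFrame       # samples x axes
    col_coords: pd.DataFrame       # features x axes
    singular_values: np.ndarray
    lam: float
    variance_explained: np.ndarray
    gamma: float


def logratio_biplot(
    comp: ZeroReplacedComposition,
    n_axes: int = 2,
    lambda_rule: str | float = "spread_balance",
    gamma: float = 0.0,
) -> BiplotModel:
    """SVD biplot of the double-centered CLR matrix.

    With the samples x features CLR matrix Z column-centered to M = U S V',
    sample markers are U S^gamma and taxon markers V S^(1-gamma) (gamma=0,
    column-principal, by default).  ``spread_balance`` multiplies sample
    markers and divides taxon markers by lambda =
    (sum||taxon||^2 / sum||sample||^2)^(1/4), equalizing the two total
    spreads without changing marker inner products.
    """
    z = clr_table(comp).to_numpy().T    # samples x features
    n, p = z.shape
    if n < 2 or p < 2:
        raise CountTableError("biplot needs >= 2 samples and >= 2 features")
    m = z - z.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    rank = int((s > s.max() * 1e-12).sum()) if s.size else 0
    if n_axes > rank:
        raise CountTableError(f"n_axes={n_axes} exceeds rank {rank}")
    u, s, vt = u[:, :n_axes], s[:n_axes], vt[:n_axes]
    rows = u * s**gamma
    cols = vt.T * s ** (1.0 - gamma)
    if lambda_rule == "spread_balance":
        lam = float(((cols**2).sum() / (rows**2).sum()) ** 0.25)
    else:
        lam = float(lambda_rule)
        if lam <= 0:
            raise CountTableError("lambda must be positive")
    rows = rows * lam
    cols = cols / lam
    axes = [f"Axis{i + 1}" for i in range(n_axes)]
    total = (m**2).sum()
    return BiplotModel(
        row_coords=pd.DataFrame(rows, index=comp.proportions.columns, columns=axes),
        col_coords=pd.DataFrame(cols, index=comp.proportions.index, columns=axes),
        singular_values=s,
        lam=lam,
        variance_explained=s**2 / total if total > 0 else s,
        gamma=gamma,
    )
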