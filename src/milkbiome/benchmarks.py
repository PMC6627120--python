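"""Simulation studies that characterize the pipeline end to end.

Each function runs a seeded experiment on synthetic cohorts and returns
summary rates or errors: decontamination accuracy, community-type
recovery, PERMANOVA calibration and power, co-occurrence sign recovery,
and replicate reproducibility.  They back both the acceptance checks and
the reproduction script, so problem sizes are arguments with the study
defaults.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import clustering, coda, composition, decontam, inference, network, synthetic
from .clustering import DistanceMatrix
from .synthetic import SPIKE_FEATURE

__all__ = [
    "decontamination_recovery",
    "community_type_recovery",
    "permanova_type_one_error",
    "permanova_power",
    "network_sign_recovery",
    "replicate_reproducibility",
]


def decontamination_recovery(
    seeds: list[int],
    fractions: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2),
    n_per_cluster: int = 20,
    n_ntc: int = 4,
) -> pd.DataFrame:
    """Does NTC subtraction move compositions toward the truth?

    For each (seed, contamination fraction) cell: generate a cohort,
    build the background catalog from its spiked NTCs, subtract, and
    compare mean absolute error of relative abundances against the
    contamination-free ground truth before and after.  Also records the
    maximum absolute count change on features absent from the NTCs
    (must be 0: no collateral removal).
    """
    rows = []
    for seed in seeds:
        for frac in fractions:
            spec = synthetic.default_spec(
                n_per_cluster={f"cluster_{i}": n_per_cluster for i in (1, 2, 3)},
                contamination_fraction=frac,
                n_ntc=n_ntc,
                seed=seed,
            )
            table, _, _, truth = synthetic.generate_cohort(spec)
            catalog = decontam.identify_background(table, SPIKE_FEATURE)
            cleaned = decontam.subtract_background(table, catalog)
            bio = table.biological_samples
            raw = composition.to_relative(table.subset_samples(bio)).proportions
            post = composition.to_relative(cleaned.subset_samples(bio)).proportions
            truthp = truth.true_composition[bio]
            err_pre = float((raw - truthp).abs().to_numpy().mean())
            err_post = float((post - truthp).abs().to_numpy().mean())
            untouched = [f for f in table.feature_ids
                         if f not in catalog.mean_reads and f != SPIKE_FEATURE]
            drift = int(
                (cleaned.counts.loc[untouched]
                 - table.counts.loc[untouched, cleaned.sample_ids])
                .abs().to_numpy().max()
            )
            rows.append({"seed": seed, "fraction": frac,
                         "error_pre": err_pre, "error_post": err_post,
                         "improved": err_post < err_pre,
                         "max_untouched_drift": drift})
    return pd.DataFrame(rows)


def _cluster_one(seed: int, n_per_cluster: int, concentration: float,
                 k_range: range) -> tuple[int | None, float]:
    spec = synthetic.default_spec(
        n_per_cluster={f"cluster_{i}": n_per_cluster for i in (1, 2, 3)},
        concentration=concentration,
        seed=seed,
    )
    table, _, _, truth = synthetic.generate_cohort(spec)
    catalog = decontam.identify_background(table, SPIKE_FEATURE)
    cleaned = decontam.subtract_background(table, catalog)
    comp = composition.to_relative(
        cleaned.subset_samples(cleaned.biological_samples))
    d = clustering.bray_curtis(comp)
    model = clustering.hierarchical_cluster(d, cut_height=0.8)
    model = clustering.select_k(d, model, k_range)
    k = model.selected_k
    labels = clustering.cut_into_k(model, k) if k else model.labels
    true = pd.Series(truth.true_cluster).loc[labels.index]
    return k, float(adjusted_rand_score(true, labels))


def community_type_recovery(
    seeds: list[int],
    n_per_cluster: int = 40,
    concentration: float = 200.0,
    k_range: range = range(2, 9),
) -> pd.DataFrame:
    """Three-community-type recovery by Bray-Curtis complete linkage + CH.

    One cohort per seed (Staphylococcus-dominant / mixed /
    Streptococcus-dominant); reports the Calinski-Harabasz-selected k and
    the adjusted Rand index of the k-cut labels against the true types.
    """
    rows = []
    for seed in seeds:
        k, ari = _cluster_one(seed, n_per_cluster, concentration, k_range)
        rows.append({"seed": seed, "selected_k": k, "ari": ari})
    return pd.DataFrame(rows)


def _gaussian_dm(x: np.ndarray) -> DistanceMatrix:
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(np.maximum(sq, 0.0))
    ids = [f"S{i}" for i in range(len(x))]
    return DistanceMatrix(pd.DataFrame(d, index=ids, columns=ids), "euclidean")


def permanova_type_one_error(
    n_replicates: int = 1000,
    n_per_group: int = 10,
    n_features: int = 2,
    permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate on structureless data (should be ~ alpha).

    Each replicate draws iid Gaussian CLR-like coordinates, assigns
    arbitrary two-group labels, and runs PERMANOVA at the given
    permutation count.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ["a"] * n_per_group + ["b"] * n_per_group
    rejections = 0
    for i in range(n_replicates):
        x = rng.normal(size=(n, n_features))
        d = _gaussian_dm(x)
        res = inference.permanova(
            d, pd.Series(groups, index=d.ids),
            permutations=permutations, seed=int(rng.integers(2**31 - 1)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_replicates


def permanova_power(
    n_replicates: int = 200,
    n_per_group: int = 30,
    n_features: int = 2,
    shift: float = 1.0,
    permutations: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power against a two-group mean shift of ``shift`` pooled SDs.

    The shift is applied along one CLR-space coordinate with unit noise
    SD per coordinate, n_per_group samples per group.  The default
    coordinate space is the CLR image of a 3-part composition (2 effective
    dimensions) — the smallest non-degenerate compositional geometry — so
    the nominal effect size is not diluted across pure-noise axes; power
    at a fixed shift decreases as ``n_features`` grows.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_group
    groups = ["a"] * n_per_group + ["b"] * n_per_group
    rejections = 0
    for i in range(n_replicates):
        x = rng.normal(size=(n, n_features))
        x[n_per_group:, 0] += shift
        d = _gaussian_dm(x)
        res = inference.permanova(
            d, pd.Series(groups, index=d.ids),
            permutations=permutations, seed=int(rng.integers(2**31 - 1)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_replicates


def network_sign_recovery(
    seeds: list[int],
    n_samples: int = 60,
    r_cutoff: float = 0.28,
) -> pd.DataFrame:
    """Does the co-occurrence network recover the planted guild signs?

    Success requires, at the given cutoff: a negative
    Streptococcus-Staphylococcus edge, a positive
    Staphylococcus-Corynebacterium edge, and positive edges from
    Streptococcus to each other oral-guild genus.
    """
    rows = []
    oral_rest = [g for g in synthetic.ORAL_GUILD if g != "Streptococcus"]
    for seed in seeds:
        table, tax = synthetic.generate_guild_cohort(seed, n_samples=n_samples)
        nw = network.build_network(table, tax, mra_threshold=0.005,
                                   r_cutoff=r_cutoff)
        strep_staph = nw.edge_r("Streptococcus", "Staphylococcus")
        staph_coryne = nw.edge_r("Staphylococcus", "Corynebacterium")
        within_oral = [nw.edge_r("Streptococcus", g) for g in oral_rest]
        ok = (
            strep_staph is not None and strep_staph < 0
            and staph_coryne is not None and staph_coryne > 0
            and all(r is not None and r > 0 for r in within_oral)
        )
        rows.append({"seed": seed, "recovered": ok,
                     "r_strep_staph": strep_staph,
                     "r_staph_coryne": staph_coryne,
                     "n_edges": len(nw.edges)})
    return pd.DataFrame(rows)


def replicate_reproducibility(seed: int = 0, depth: int = 100_000) -> float:
    """R-squared between duplicate library preparations at high depth.

    Draws a study-like sample, resamples it twice multinomially at
    ``depth`` reads (two duplicate preparations of one extract), and
    regresses one duplicate's OTU counts on the other's.
    """
    spec = synthetic.default_spec(
        n_per_cluster={"cluster_1": 1, "cluster_2": 1, "cluster_3": 1},
        otus_per_genus=3,
        seed=seed,
    )
    table, _, _, _ = synthetic.generate_cohort(spec)
    s = table.biological_samples[1]   # a mixed-profile sample
    t = synthetic.generate_replicate_pair(table, s, depth=depth, seed=seed + 1)
    t = synthetic.generate_replicate_pair(t, s, depth=depth, seed=seed + 2)
    return inference.replicate_r2(t, (s + "_rep", s + "_rep2"))
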