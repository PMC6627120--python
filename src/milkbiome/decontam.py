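"""Spiked-NTC in-silico contamination correction.

Reagents and extraction kits carry low-level bacterial DNA that is
amplified alongside the real community.  Spiking no-template controls with
DNA of a taxon absent from the samples forces those reagent contaminants to
be sequenced at sample-like depth, so they can be catalogued.  Correction
then proceeds in two steps: (1) remove the spike taxon from the spiked-NTC
columns and catalogue the remaining "background" features with their mean
read count across NTCs; (2) subtract each background feature's mean read
count from every biological sample, flooring at zero.  Features never seen
in an NTC are left untouched, which bounds over-compensation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tableio import CountTable, CountTableError, SampleMetadata

__all__ = ["BackgroundCatalog", "identify_background", "subtract_background"]


@dataclass
class BackgroundCatalog:
    """Background (reagent-contaminant) features and their NTC mean reads."""

    mean_reads: dict[str, float]      # feature -> mean count across spiked NTCs
    n_ntc_used: int
    spike_feature: str

    def __post_init__(self) -> None:
        if self.spike_feature in self.mean_reads:
            raise CountTableError("spike feature must be excluded from catalog")
        if any(v < 0 for v in self.mean_reads.values()):
            raise CountTableError("negative mean read count in catalog")

    @property
    def background_features(self) -> set[str]:
        return set(self.mean_reads)


def identify_background(
    table: CountTable,
    spike_feature: str,
    metadata: SampleMetadata | None = None,
    run_column: str | None = None,
) -> BackgroundCatalog | dict[str, BackgroundCatalog]:
    """Catalogue background features from the spiked-NTC columns.

    A feature is background if it has a positive count in any spiked NTC
    (the spike taxon itself excluded).  Its catalogued value is the
    arithmetic mean of its counts over *all* spiked NTCs — zeros included
    in the denominator, so a feature seen in one of two NTCs at 8 reads is
    catalogued at 4.

    If ``run_column`` names a metadata column, one catalog is built per
    sequencing run and a dict keyed by run label is returned.
    """
    ntcs = table.ntc_samples
    if not ntcs:
        raise CountTableError("no spiked-NTC columns in table")
    if spike_feature not in table.counts.index:
        raise CountTableError(f"spike feature {spike_feature!r} absent from table")
    if run_column is not None:
        if metadata is None:
            raise CountTableError("run_column given without metadata")
        runs = metadata.covariates.loc[ntcs, run_column]
        out = {}
        for run, grp in runs.groupby(runs):
            sub = table.subset_samples(list(grp.index))
            out[run] = identify_background(sub, spike_feature)
        return out
    block = table.counts[ntcs]
    present = block.gt(0).any(axis=1)
    present[spike_feature] = False
    means = block.loc[present].mean(axis=1)
    return BackgroundCatalog(
        mean_reads={f: float(m) for f, m in means.items()},
        n_ntc_used=len(ntcs),
        spike_feature=spike_feature,
    )


def _rounded(mean: float, rounding: str) -> float:
    if rounding == "half_up":
        return float(np.floor(mean + 0.5))
    if rounding == "floor":
        return float(np.floor(mean))
    if rounding == "none":
        return mean
    raise CountTableError(f"unknown rounding mode {rounding!r}")


def subtract_background(
    table: CountTable,
    catalog: BackgroundCatalog,
    rounding: str = "half_up",
) -> CountTable:
    """Remove the catalogued background from the biological samples.

    For each background feature the (rounded) NTC mean read count is
    subtracted from every biological and replicate column, floored at zero;
    features not in the catalog are bit-identical before and after.  The
    spiked-NTC columns, now consumed, are dropped from the output.

    ``rounding``: ``half_up`` (default) subtracts the half-up-rounded mean;
    ``floor`` the floored mean; ``none`` subtracts the real-valued mean and
    floors the result.
    """
    keep = [s for s in table.sample_ids
            if table.sample_roles[s] != "ntc_spiked"]
    counts = table.counts[keep].copy()
    for feature, mean in catalog.mean_reads.items():
        if feature not in counts.index:
            warnings.warn(
                f"catalog feature {feature!r} absent from table; skipped",
                stacklevel=2,
            )
            continue
        removed = _rounded(mean, rounding)
        cleaned = np.maximum(
            np.floor(counts.loc[feature].to_numpy(dtype=float) - removed), 0.0
        )
        counts.loc[feature] = cleaned.astype(np.int64)
    roles = {s: table.sample_roles[s] for s in keep}
    replicate_of = {s: p for s, p in table.replicate_of.items() if s in keep}
    return CountTable(counts.astype(np.int64), roles, replicate_of)
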