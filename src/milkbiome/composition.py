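"""Relative abundance, low-abundance grouping and the core bacteriome."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tableio import CountTable, CountTableError, TaxonomyMap, collapse_label

__all__ = [
    "CompositionTable",
    "CoreReport",
    "to_relative",
    "mean_relative_abundance",
    "abundance_filter",
    "core_features",
]

OTHER_LABEL = "other"


@dataclass
class CompositionTable:
    """Feature x sample proportions; every column sums to 1 (within 1e-9)."""

    proportions: pd.DataFrame
    sample_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.proportions.to_numpy(dtype=float)
        if arr.size:
            if arr.min() < 0:
                raise CountTableError("negative proportion")
        if not self.sample_roles:
            self.sample_roles = {
                s: "biological" for s in self.proportions.columns}

    @property
    def feature_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.columns)

    def biological_columns(self) -> pd.DataFrame:
        cols = [s for s in self.sample_ids
                if self.sample_roles.get(s, "biological") == "biological"]
        return self.proportions[cols]


def to_relative(table: CountTable) -> CompositionTable:
    """Close each sample to proportions: p_ij = x_ij / n_j."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise CountTableError(
            f"zero-total sample(s): {list(zero.index)}; cannot normalize")
    props = table.counts.div(totals, axis=1)
    return CompositionTable(props, dict(table.sample_roles))


def mean_relative_abundance(comp: CompositionTable) -> pd.Series:
    """Per-feature arithmetic mean proportion over biological samples (MRA)."""
    bio = comp.biological_columns()
    if bio.shape[1] == 0:
        raise CountTableError("no biological samples")
    return bio.mean(axis=1)


def abundance_filter(
    comp: CompositionTable, threshold: float, mode: str = "dataset_mra"
) -> CompositionTable:
    """Drop or pool low-abundance features.

    ``dataset_mra``
        Keep only features whose mean relative abundance exceeds
        ``threshold``; columns are NOT renormalized, so retained entries
        are unchanged.  This mode gives a fixed feature set across samples,
        as clustering and network construction require.
    ``per_sample_other``
        Within each sample, move every entry below ``threshold`` into a
        single ``"other"`` row; column sums are preserved exactly.  Meant
        for stacked-bar style summaries.
    """
    if not 0 <= threshold < 1:
        raise CountTableError("threshold must be in [0, 1)")
    if mode == "dataset_mra":
        mra = mean_relative_abundance(comp)
        keep = mra.index[mra > threshold]
        if len(keep) == 0:
            raise CountTableError("abundance filter removed every feature")
        return CompositionTable(
            comp.proportions.loc[keep].copy(), dict(comp.sample_roles))
    if mode == "per_sample_other":
        props = comp.proportions
        low = props < threshold
        kept = props.where(~low, 0.0)
        other = props.where(low, 0.0).sum(axis=0)
        keep_rows = kept.index[(kept > 0).any(axis=1)]
        if len(keep_rows) == 0 and other.sum() == 0:
            raise CountTableError("abundance filter removed every feature")
        out = kept.loc[keep_rows]
        out.loc[OTHER_LABEL] = other
        return CompositionTable(out, dict(comp.sample_roles))
    raise CountTableError(f"unknown abundance_filter mode {mode!r}")


@dataclass
class CoreReport:
    """Features present in at least ``threshold`` of biological samples."""

    threshold: float
    prevalence: pd.Series                 # per-feature fraction of samples
    core_features: list[str]
    core_taxa: dict[str, str] = field(default_factory=dict)

    @property
    def n_core(self) -> int:
        return len(self.core_features)


def core_features(
    table: CountTable,
    threshold: float = 0.8,
    tax: TaxonomyMap | None = None,
    rank: str = "genus",
) -> CoreReport:
    """The core bacteriome: features with prevalence >= ``threshold``.

    Prevalence of feature i is the fraction of biological samples with a
    strictly positive count.  The threshold comparison is inclusive ("at
    least"), so a feature in exactly 80% of samples is core at 0.8.  If a
    taxonomy is supplied the core features are additionally summarized by
    their ``rank``-level taxa.
    """
    if not 0 < threshold <= 1:
        raise CountTableError("threshold must be in (0, 1]")
    bio = table.counts[table.biological_samples]
    if bio.shape[1] == 0:
        raise CountTableError("no biological samples")
    prevalence = bio.gt(0).mean(axis=1)
    core = [f for f in table.feature_ids if prevalence[f] >= threshold]
    core_taxa = {}
    if tax is not None:
        for f in core:
            lineage = tax.lineage.get(f)
            core_taxa[f] = (
                collapse_label(lineage, rank) if lineage is not None else "unassigned"
            )
    return CoreReport(threshold, prevalence, core, core_taxa)
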