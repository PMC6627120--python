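"""Count tables, taxonomy maps and sample metadata.

The pipeline's feature unit is the OTU (a ~97%-identity cluster of 16S
sequences); tables are feature x sample matrices of non-negative integer
read counts in the classic QIIME orientation (features as rows).  Every
downstream stage consumes the containers defined here, so all structural
validation lives in this module.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "RANK_PREFIXES",
    "CountTable",
    "TaxonomyMap",
    "SampleMetadata",
    "CountTableError",
    "read_count_table",
    "write_count_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "collapse_to_rank",
]

#: Fixed taxonomic ranks, most to least inclusive.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__")

#: Sample role flags.  ``ntc_spiked`` marks a no-template extraction control
#: spiked with DNA of a known taxon so that reagent contaminants are
#: sequenced at sample-like depth; ``replicate`` marks a duplicate library
#: preparation of another sample's extract.
ROLES = ("biological", "ntc_spiked", "replicate")


class CountTableError(ValueError):
    """Raised on malformed count tables, taxonomy or metadata files."""


@dataclass
class CountTable:
    """A feature x sample matrix of non-negative integer read counts.

    Parameters
    ----------
    counts
        DataFrame with feature IDs as the index and sample IDs as columns.
    sample_roles
        Maps each sample ID to one of :data:`ROLES`.  Missing samples
        default to ``"biological"``.
    replicate_of
        For samples with role ``replicate``, the sample whose extract was
        re-processed.
    """

    counts: pd.DataFrame
    sample_roles: dict[str, str] = field(default_factory=dict)
    replicate_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dups = c.index[c.index.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate feature IDs: {dups}")
        if c.columns.has_duplicates:
            dups = c.columns[c.columns.duplicated()].unique().tolist()
            raise CountTableError(f"duplicate sample IDs: {dups}")
        arr = c.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                i, j = np.argwhere(np.mod(arr, 1) != 0)[0]
                raise CountTableError(
                    f"non-integer count at feature {c.index[i]!r}, "
                    f"sample {c.columns[j]!r}"
                )
            self.counts = c = c.astype(np.int64)
            arr = c.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise CountTableError(
                f"negative count at feature {c.index[i]!r}, sample {c.columns[j]!r}"
            )
        roles = {}
        for s in c.columns:
            role = self.sample_roles.get(s, "biological")
            if role not in ROLES:
                raise CountTableError(f"unknown role {role!r} for sample {s!r}")
            roles[s] = role
        self.sample_roles = roles

    # -- basic accessors -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def depths(self) -> pd.Series:
        """Per-sample library size n_j (column totals)."""
        return self.counts.sum(axis=0)

    def samples_with_role(self, role: str) -> list[str]:
        return [s for s in self.sample_ids if self.sample_roles[s] == role]

    @property
    def biological_samples(self) -> list[str]:
        return self.samples_with_role("biological")

    @property
    def ntc_samples(self) -> list[str]:
        return self.samples_with_role("ntc_spiked")

    def subset_samples(self, samples: Iterable[str]) -> "CountTable":
        samples = list(samples)
        missing = [s for s in samples if s not in self.counts.columns]
        if missing:
            raise CountTableError(f"unknown sample IDs: {missing}")
        return CountTable(
            self.counts[samples].copy(),
            {s: self.sample_roles[s] for s in samples},
            {s: p for s, p in self.replicate_of.items() if s in samples},
        )


@dataclass
class TaxonomyMap:
    """Feature ID -> ordered lineage (kingdom ... genus); ``None`` = unassigned."""

    lineage: dict[str, tuple[str | None, ...]]

    def __post_init__(self) -> None:
        for fid, ranks in self.lineage.items():
            if len(ranks) != len(RANKS):
                raise CountTableError(
                    f"lineage for {fid!r} has {len(ranks)} ranks, expected {len(RANKS)}"
                )

    def rank_of(self, feature_id: str, rank: str) -> str | None:
        return self.lineage[feature_id][RANKS.index(rank)]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineage

    def __len__(self) -> int:
        return len(self.lineage)


@dataclass
class SampleMetadata:
    """Per-sample covariates (study site, delivery mode, age group, ...).

    Missing values are represented as NaN / ``None``.  The reserved column
    ``role`` carries sample-role flags and the reserved column
    ``replicate_of`` the replicate partner; both are optional.
    """

    covariates: pd.DataFrame  # index = sample IDs

    def __post_init__(self) -> None:
        if self.covariates.index.has_duplicates:
            dups = self.covariates.index[self.covariates.index.duplicated()]
            raise CountTableError(f"duplicate sample IDs in metadata: {list(dups)}")

    def check_samples(self, table: CountTable) -> None:
        missing = set(table.sample_ids) - set(self.covariates.index)
        if missing:
            raise CountTableError(
                f"samples absent from metadata: {sorted(missing)}"
            )

    def group_labels(self, covariate: str, samples: Iterable[str]) -> pd.Series:
        """Labels for ``samples``, dropping samples with a missing value."""
        col = self.covariates.loc[list(samples), covariate]
        return col.dropna()


# -- I/O -----------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    lines = [ln for ln in text.split("\n") if ln.strip() != ""]
    if not lines:
        raise CountTableError(f"{path}: empty file")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    for i, r in enumerate(rows):
        if len(r) != width:
            raise CountTableError(
                f"{path}: ragged row {i + 1} ({len(r)} fields, expected {width})"
            )
    return pd.DataFrame(rows[1:], columns=rows[0])


def read_count_table(
    path: str | Path, roles: str | Path | None = None
) -> CountTable:
    """Read a tab-separated count table (features as rows, samples as columns).

    The first column holds feature IDs; an optional leading ``#OTU ID``
    header token is accepted.  If ``roles`` points to a metadata file with a
    ``role`` column, sample roles are taken from it; otherwise every sample
    is flagged biological.
    """
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = None
    try:
        counts = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise CountTableError(f"{path}: non-numeric cell ({exc})") from exc
    arr = counts.to_numpy()
    if np.any(np.mod(arr, 1) != 0):
        i, j = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise CountTableError(
            f"{path}: non-integer count at feature {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    if arr.size and arr.min() < 0:
        i, j = np.argwhere(arr < 0)[0]
        raise CountTableError(
            f"{path}: negative count at feature {counts.index[i]!r}, "
            f"sample {counts.columns[j]!r}"
        )
    counts = counts.astype(np.int64)
    sample_roles: dict[str, str] = {}
    replicate_of: dict[str, str] = {}
    if roles is not None:
        meta = read_metadata(roles)
        if "role" in meta.covariates.columns:
            for s, r in meta.covariates["role"].items():
                if s in counts.columns and isinstance(r, str) and r:
                    sample_roles[s] = r
        if "replicate_of" in meta.covariates.columns:
            for s, p in meta.covariates["replicate_of"].items():
                if s in counts.columns and isinstance(p, str) and p:
                    replicate_of[s] = p
    return CountTable(counts, sample_roles, replicate_of)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.counts.copy()
    df.index.name = "#OTU ID"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of feature ID and semicolon lineage.

    Lineages use the QIIME rank-prefix dialect
    (``k__Bacteria;p__Firmicutes;...;g__Streptococcus``); an empty value
    after a prefix means the rank is unassigned.  Missing trailing ranks are
    also unassigned.
    """
    lineage: dict[str, tuple[str | None, ...]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip():
                raise CountTableError(
                    f"{path}: line {lineno}: expected 'feature<TAB>lineage'"
                )
            fid, lin = parts[0].strip(), parts[1].strip()
            ranks: list[str | None] = [None] * len(RANKS)
            if lin:
                for i, tok in enumerate(lin.split(";")):
                    tok = tok.strip()
                    if i >= len(RANKS):
                        raise CountTableError(
                            f"{path}: line {lineno}: more than {len(RANKS)} ranks"
                        )
                    if not tok:
                        continue
                    if not tok.startswith(RANK_PREFIXES[i]):
                        raise CountTableError(
                            f"{path}: line {lineno}: token {tok!r} lacks rank "
                            f"prefix {RANK_PREFIXES[i]!r}"
                        )
                    name = tok[len(RANK_PREFIXES[i]):]
                    ranks[i] = name if name else None
            lineage[fid] = tuple(ranks)
    return TaxonomyMap(lineage)


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for fid, ranks in tax.lineage.items():
            toks = [
                f"{pref}{name if name is not None else ''}"
                for pref, name in zip(RANK_PREFIXES, ranks)
            ]
            fh.write(f"{fid}\t{';'.join(toks)}\n")


def read_metadata(path: str | Path) -> SampleMetadata:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = None
    df = df.replace({"": np.nan, "NA": np.nan})
    # numeric columns come back as strings; convert where possible
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.notna().sum() == df[col].notna().sum():
            df[col] = converted
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    df = meta.covariates.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t", lineterminator="\n", encoding="utf-8")


# -- rank collapsing -----------------------------------------------------


def collapse_label(ranks: tuple[str | None, ...], rank: str) -> str:
    """Collapse key/label for a lineage at ``rank``.

    Features assigned at the rank are keyed by the full lineage down to that
    rank, so e.g. two unrelated families' unassigned genera are never
    merged; the display label is the rank name itself when assigned, else
    the most resolved assigned rank with a trailing unassigned marker
    (``"Enterobacteriaceae;g__"``).
    """
    depth = RANKS.index(rank)
    head = ranks[: depth + 1]
    if head[depth] is not None:
        return head[depth]
    # walk back to the most resolved assigned ancestor
    last = None
    for i in range(depth, -1, -1):
        if head[i] is not None:
            last = i
            break
    if last is None:
        return f"unassigned;{RANK_PREFIXES[depth]}"
    markers = "".join(f";{RANK_PREFIXES[i]}" for i in range(last + 1, depth + 1))
    return f"{head[last]}{markers}"


def collapse_to_rank(
    table: CountTable, tax: TaxonomyMap, rank: str
) -> tuple[CountTable, TaxonomyMap]:
    """Sum features sharing a taxon at ``rank``; column totals are conserved.

    Features unassigned at the rank collapse under a label derived from
    their most resolved assigned ancestor (keyed by full lineage prefix so
    distinct parents stay distinct).  Returns the collapsed table and a
    taxonomy for the collapsed labels.
    """
    if rank not in RANKS:
        raise CountTableError(f"unknown rank {rank!r}; expected one of {RANKS}")
    depth = RANKS.index(rank)
    keys: dict[str, tuple] = {}
    labels: dict[str, str] = {}
    for fid in table.feature_ids:
        ranks = tax.lineage.get(fid, (None,) * len(RANKS))
        label = collapse_label(ranks, rank)
        key = ranks[: depth + 1] if ranks[depth] is None else (label,)
        keys[fid] = key
        labels[fid] = label
    # group by key, order by first appearance
    groups: dict[tuple, list[str]] = {}
    for fid in table.feature_ids:
        groups.setdefault(keys[fid], []).append(fid)
    out_rows = {}
    out_lineage = {}
    for key, fids in groups.items():
        label = labels[fids[0]]
        if label in out_rows:  # two distinct keys share a display label
            suffix = 2
            while f"{label}_{suffix}" in out_rows:
                suffix += 1
            label = f"{label}_{suffix}"
        out_rows[label] = table.counts.loc[fids].sum(axis=0)
        lin = list(tax.lineage.get(fids[0], (None,) * len(RANKS)))
        for i in range(depth + 1, len(RANKS)):
            lin[i] = None
        out_lineage[label] = tuple(lin)
    collapsed = pd.DataFrame(out_rows).T
    collapsed.columns = table.counts.columns
    return (
        CountTable(collapsed, dict(table.sample_roles), dict(table.replicate_of)),
        TaxonomyMap(out_lineage),
    )
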