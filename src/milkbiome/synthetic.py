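"""Synthetic breast-milk bacteriome cohorts.

Generates feature x sample count tables with the statistical structure the
downstream analyses assume: three community types driven by the balance of
*Staphylococcus* and *Streptococcus* (a Staphylococcus-dominant type, a
mixed type, and a Streptococcus-dominant type), a shared low-level reagent
contamination background that appears both in biological samples and in
no-template controls, spiked NTCs carrying a known spike taxon on top of
that background, and duplicate library preparations of the same extract.

Biological counts are Dirichlet-multinomial: each sample's composition is a
Dirichlet draw around its cluster's expected genus profile (concentration
controls within-cluster spread) and reads are a multinomial draw at a
log-normal library size.  Contaminant reads are added on top as an
independent multinomial over a fixed background profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tableio import RANKS, CountTable, SampleMetadata, TaxonomyMap

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SpecError",
    "default_spec",
    "generate_cohort",
    "generate_replicate_pair",
    "CORE_GENERA",
    "CONTAMINANT_GENERA",
    "SPIKE_FEATURE",
]


class SpecError(ValueError):
    """Raised for invalid cohort specifications."""


#: Genera routinely recovered from human breast milk; the first nine form
#: the core set used for default cluster profiles.
CORE_GENERA = (
    "Streptococcus",
    "Staphylococcus",
    "Rothia",
    "Corynebacterium",
    "Veillonella",
    "Gemella",
    "Acinetobacter",
    "Micrococcus",
    "Enterobacteriaceae_unassigned",
)

#: Typical DNA-extraction-kit contaminants used for the background profile.
CONTAMINANT_GENERA = ("Ralstonia", "Bradyrhizobium", "Sphingomonas", "Delftia")

SPIKE_FEATURE = "OTU_spike_Msmegmatis"

_LINEAGES = {
    "Streptococcus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    "Staphylococcus": ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Staphylococcaceae", "Staphylococcus"),
    "Rothia": ("Bacteria", "Actinobacteria", "Actinobacteria", "Micrococcales", "Micrococcaceae", "Rothia"),
    "Corynebacterium": ("Bacteria", "Actinobacteria", "Actinobacteria", "Corynebacteriales", "Corynebacteriaceae", "Corynebacterium"),
    "Veillonella": ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Veillonellaceae", "Veillonella"),
    "Gemella": ("Bacteria", "Firmicutes", "Bacilli", "Bacillales", "Bacillales_fam", "Gemella"),
    "Acinetobacter": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Acinetobacter"),
    "Micrococcus": ("Bacteria", "Actinobacteria", "Actinobacteria", "Micrococcales", "Micrococcaceae", "Micrococcus"),
    "Enterobacteriaceae_unassigned": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacteriales", "Enterobacteriaceae", None),
    "Lactobacillus": ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Lactobacillaceae", "Lactobacillus"),
    "Bifidobacterium": ("Bacteria", "Actinobacteria", "Actinobacteria", "Bifidobacteriales", "Bifidobacteriaceae", "Bifidobacterium"),
    "Pseudomonas": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas"),
    "Enhydrobacter": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales", "Moraxellaceae", "Enhydrobacter"),
    "Ralstonia": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Burkholderiaceae", "Ralstonia"),
    "Bradyrhizobium": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales", "Bradyrhizobiaceae", "Bradyrhizobium"),
    "Sphingomonas": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"),
    "Delftia": ("Bacteria", "Proteobacteria", "Betaproteobacteria", "Burkholderiales", "Comamonadaceae", "Delftia"),
    "Mycobacterium": ("Bacteria", "Actinobacteria", "Actinobacteria", "Corynebacteriales", "Mycobacteriaceae", "Mycobacterium"),
}


def _default_profiles() -> dict[str, dict[str, float]]:
    """Expected genus compositions of the three community types.

    Type 1 is Staphylococcus-dominant, type 2 carries roughly equal
    Staphylococcus/Streptococcus, type 3 is Streptococcus-dominant; the
    remaining mass is spread over the other core genera plus low-level
    Lactobacillus/Bifidobacterium/Pseudomonas/Enhydrobacter.
    """
    minor = {
        "Rothia": 0.06,
        "Corynebacterium": 0.045,
        "Veillonella": 0.03,
        "Gemella": 0.025,
        "Acinetobacter": 0.022,
        "Micrococcus": 0.015,
        "Enterobacteriaceae_unassigned": 0.02,
        "Lactobacillus": 0.01,
        "Bifidobacterium": 0.009,
        "Pseudomonas": 0.008,
        "Enhydrobacter": 0.006,
    }
    profiles = {}
    # both dominants stay present at low level in every type: Streptococcus
    # and Staphylococcus are near-universal in breast milk (they are core)
    for name, staph, strep in (
        ("cluster_1", 0.75, 0.05),
        ("cluster_2", 0.40, 0.40),
        ("cluster_3", 0.05, 0.75),
    ):
        rest = 1.0 - staph - strep
        scale = rest / sum(minor.values())
        prof = {g: p * scale for g, p in minor.items()}
        prof["Staphylococcus"] = staph
        prof["Streptococcus"] = strep
        profiles[name] = prof
    return profiles


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``cluster_profiles`` maps cluster name -> expected genus composition
    (proportions summing to 1).  ``concentration`` is the Dirichlet
    concentration (effective sample size of the prior): larger values give
    tighter clusters.  Library sizes are log-normal with ``depth_median``
    and log-sd ``depth_sigma``; the study-scale default median is 8000
    reads.  ``contamination_fraction`` is the expected share of a sample's
    reads that come from the reagent background; the background composition
    is ``contamination_profile``.  Spiked NTCs carry ``spike_reads``
    (expected) spike reads plus background at
    ``contamination_fraction x depth_median`` expected reads.
    """

    n_per_cluster: dict[str, int] = field(default_factory=lambda: {
        "cluster_1": 40, "cluster_2": 40, "cluster_3": 40})
    cluster_profiles: dict[str, dict[str, float]] = field(
        default_factory=_default_profiles)
    concentration: float = 200.0
    depth_median: float = 8000.0
    depth_sigma: float = 0.6
    contamination_fraction: float = 0.05
    contamination_profile: dict[str, float] = field(default_factory=lambda: {
        "Ralstonia": 0.45, "Bradyrhizobium": 0.25,
        "Sphingomonas": 0.20, "Delftia": 0.10})
    spike_reads: float = 5000.0
    n_ntc: int = 4
    n_shallow: int = 0          # samples forced below the 1000-read depth filter
    shallow_depth: int = 300
    otus_per_genus: int = 1     # >1 fans each genus into several OTUs
    seed: int = 0

    def validate(self) -> None:
        if not self.cluster_profiles:
            raise SpecError("no cluster profiles")
        for name, prof in self.cluster_profiles.items():
            if not prof:
                raise SpecError(f"empty profile for {name!r}")
            vals = np.array(list(prof.values()), float)
            if (vals < 0).any():
                raise SpecError(f"negative proportion in profile {name!r}")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise SpecError(
                    f"profile {name!r} sums to {vals.sum()}, expected 1")
        cont = np.array(list(self.contamination_profile.values()), float)
        if (cont < 0).any() or abs(cont.sum() - 1.0) > 1e-12:
            raise SpecError("contamination profile must be a composition")
        if any(n < 0 for n in self.n_per_cluster.values()) or self.n_ntc < 0:
            raise SpecError("negative sample counts")
        if self.depth_median <= 0:
            raise SpecError("depth_median must be positive")
        if not 0 <= self.contamination_fraction < 1:
            raise SpecError("contamination_fraction must be in [0, 1)")
        if self.concentration <= 0:
            raise SpecError("concentration must be positive")
        if self.otus_per_genus < 1:
            raise SpecError("otus_per_genus must be >= 1")


def default_spec(**overrides) -> CohortSpec:
    """The study-like cohort: 3 x 40 samples, concentration 200, 4 spiked NTCs."""
    return CohortSpec(**overrides)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    true_cluster: dict[str, str]
    true_composition: pd.DataFrame     # feature x sample, columns sum to 1
    contaminant_features: set[str]
    contaminant_reads: pd.DataFrame    # feature x sample integer matrix


def _feature_ids(spec: CohortSpec) -> tuple[dict[str, list[str]], list[str]]:
    """Map genus -> OTU IDs and the full ordered feature list."""
    genera: list[str] = []
    for prof in spec.cluster_profiles.values():
        for g in prof:
            if g not in genera:
                genera.append(g)
    for g in spec.contamination_profile:
        if g not in genera:
            genera.append(g)
    per_genus: dict[str, list[str]] = {}
    ordered: list[str] = []
    k = 1
    for g in genera:
        ids = []
        for _ in range(spec.otus_per_genus):
            ids.append(f"OTU_{k}")
            k += 1
        per_genus[g] = ids
        ordered.extend(ids)
    ordered.append(SPIKE_FEATURE)
    return per_genus, ordered


def _taxonomy(per_genus: dict[str, list[str]]) -> TaxonomyMap:
    lineage: dict[str, tuple[str | None, ...]] = {}
    for g, ids in per_genus.items():
        lin = _LINEAGES.get(g)
        if lin is None:
            lin = ("Bacteria", None, None, None, None, g)
        for fid in ids:
            lineage[fid] = tuple(lin)
    lineage[SPIKE_FEATURE] = _LINEAGES["Mycobacterium"]
    return TaxonomyMap(lineage)


def generate_cohort(
    spec: CohortSpec,
) -> tuple[CountTable, TaxonomyMap, SampleMetadata, GroundTruth]:
    """Draw a full cohort: biological samples, spiked NTCs, ground truth.

    Deterministic given ``spec.seed``.  Biological counts are
    Dirichlet-multinomial draws around the cluster profile plus an
    independent multinomial of contaminant reads; NTC columns contain only
    spike and background reads.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    per_genus, features = _feature_ids(spec)
    tax = _taxonomy(per_genus)
    n_feat = len(features)
    fidx = {f: i for i, f in enumerate(features)}

    # split each genus's expected proportion over its OTUs (fixed per cohort)
    split: dict[str, np.ndarray] = {}
    for g, ids in per_genus.items():
        if len(ids) == 1:
            split[g] = np.ones(1)
        else:
            split[g] = rng.dirichlet(np.full(len(ids), 5.0))

    cont_vec = np.zeros(n_feat)
    for g, p in spec.contamination_profile.items():
        for fid, w in zip(per_genus[g], split[g]):
            cont_vec[fidx[fid]] += p * w
    contaminant_features = {
        f for f in features
        if cont_vec[fidx[f]] > 0
    }

    columns: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    true_cluster: dict[str, str] = {}
    true_comp: dict[str, np.ndarray] = {}
    cont_reads: dict[str, np.ndarray] = {}

    shallow_left = spec.n_shallow
    sample_no = 1
    for cname, n in spec.n_per_cluster.items():
        prof = spec.cluster_profiles[cname]
        base = np.zeros(n_feat)
        for g, p in prof.items():
            for fid, w in zip(per_genus[g], split[g]):
                base[fidx[fid]] += p * w
        alpha = base * spec.concentration
        # Dirichlet with zero alpha components is degenerate; draw on support
        support = alpha > 0
        for _ in range(n):
            sid = f"S{sample_no:03d}"
            sample_no += 1
            if shallow_left > 0:
                depth = spec.shallow_depth
                shallow_left -= 1
            else:
                depth = max(1, int(round(
                    spec.depth_median * np.exp(rng.normal(0.0, spec.depth_sigma)))))
            theta = np.zeros(n_feat)
            theta[support] = rng.dirichlet(alpha[support])
            bio = rng.multinomial(depth, theta)
            n_cont = rng.binomial(depth, spec.contamination_fraction)
            cont = rng.multinomial(n_cont, cont_vec) if n_cont > 0 else np.zeros(
                n_feat, dtype=np.int64)
            columns[sid] = bio + cont
            roles[sid] = "biological"
            true_cluster[sid] = cname
            total_bio = bio.sum()
            true_comp[sid] = bio / total_bio if total_bio else theta
            cont_reads[sid] = cont

    ntc_background = spec.contamination_fraction * spec.depth_median
    for i in range(spec.n_ntc):
        sid = f"NTC{i + 1:02d}"
        n_bg = rng.poisson(ntc_background)
        bg = rng.multinomial(n_bg, cont_vec) if n_bg > 0 else np.zeros(
            n_feat, dtype=np.int64)
        col = bg.astype(np.int64)
        col[fidx[SPIKE_FEATURE]] += rng.poisson(spec.spike_reads)
        columns[sid] = col
        roles[sid] = "ntc_spiked"
        cont_reads[sid] = bg

    counts = pd.DataFrame(columns, index=features, dtype=np.int64)
    table = CountTable(counts, roles)
    meta = SampleMetadata(pd.DataFrame(
        {"role": pd.Series(roles),
         "cluster": pd.Series({s: true_cluster.get(s, "") for s in counts.columns})},
    ).loc[list(counts.columns)])
    truth = GroundTruth(
        true_cluster=true_cluster,
        true_composition=pd.DataFrame(true_comp, index=features),
        contaminant_features=contaminant_features,
        contaminant_reads=pd.DataFrame(cont_reads, index=features).astype(np.int64),
    )
    return table, tax, meta, truth


#: Expected relative abundances of the two covarying guilds in
#: :func:`generate_guild_cohort`: oral-cavity commensals led by
#: Streptococcus, and skin commensals led by Staphylococcus.
ORAL_GUILD = {"Streptococcus": 0.45, "Rothia": 0.08,
              "Veillonella": 0.05, "Gemella": 0.04}
SKIN_GUILD = {"Staphylococcus": 0.30, "Corynebacterium": 0.06}


def generate_guild_cohort(
    seed: int,
    n_samples: int = 60,
    depth: int = 20000,
    seesaw_sd: float = 0.8,
    noise_sd: float = 0.15,
) -> tuple[CountTable, TaxonomyMap]:
    """A cohort with planted guild covariance for network testing.

    A latent per-sample "see-saw" factor u ~ N(0, seesaw_sd) scales the
    oral guild up by exp(+u) and the skin guild down by exp(-u) (plus
    per-genus log-normal noise), so genera within a guild co-vary
    positively while Streptococcus and Staphylococcus anti-covary — the
    sign structure expected of breast-milk co-occurrence networks.
    """
    rng = np.random.default_rng(seed)
    bystanders = ("Acinetobacter", "Micrococcus")
    genera = list(ORAL_GUILD) + list(SKIN_GUILD) + list(bystanders)
    tax = TaxonomyMap({
        g: _LINEAGES.get(g, ("Bacteria", None, None, None, None, g))
        for g in genera
    })
    cols = {}
    for j in range(n_samples):
        u = rng.normal(0.0, seesaw_sd)
        mean = {}
        for g, base in ORAL_GUILD.items():
            mean[g] = base * np.exp(u + noise_sd * rng.normal())
        for g, base in SKIN_GUILD.items():
            mean[g] = base * np.exp(-u + noise_sd * rng.normal())
        for g in bystanders:
            mean[g] = 0.02 * np.exp(2 * noise_sd * rng.normal())
        p = np.array([mean[g] for g in genera])
        cols[f"S{j:03d}"] = rng.multinomial(depth, p / p.sum())
    return CountTable(pd.DataFrame(cols, index=genera)), tax


def generate_replicate_pair(
    table: CountTable, sample: str, depth: int, seed: int
) -> CountTable:
    """Append a duplicate library preparation of ``sample``.

    The replicate column is a multinomial resample of the sample's observed
    proportions at ``depth`` reads, flagged ``replicate`` with its partner
    recorded, emulating repeat library preparation and sequencing of one
    DNA extract.
    """
    if sample not in table.counts.columns:
        raise SpecError(f"unknown sample ID {sample!r}")
    if depth <= 0:
        raise SpecError("replicate depth must be positive")
    rng = np.random.default_rng(seed)
    x = table.counts[sample].to_numpy()
    total = x.sum()
    if total == 0:
        raise SpecError(f"sample {sample!r} has zero reads")
    rep = rng.multinomial(depth, x / total)
    rep_id = f"{sample}_rep"
    i = 2
    while rep_id in table.counts.columns:
        rep_id = f"{sample}_rep{i}"
        i += 1
    counts = table.counts.copy()
    counts[rep_id] = rep
    roles = dict(table.sample_roles)
    roles[rep_id] = "replicate"
    replicate_of = dict(table.replicate_of)
    replicate_of[rep_id] = sample
    return CountTable(counts, roles, replicate_of)
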