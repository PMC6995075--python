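"""Synthetic paired swab/water communities with known ground truth.

The generator emulates the sampling design of a stream-survey skin
microbiome study: each site along an environmental gradient has a water
community whose log-composition shifts linearly with the site's temperature
(slope ``gradient_effect``); each fish taxon carries an indigenous skin
community; and a swab sample is a multinomial draw from the mixture
``(1 - rho) * indigenous(taxon) + rho * water(site)`` after Dirichlet
overdispersion, where ``rho`` is the contamination fraction.  Flagged
"eutrophic" sites multiply the indigenous Bacteroidetes feature
probabilities by an enrichment factor ``delta`` before renormalising, which
reproduces the dysbiosis signature downstream stages should detect.

Every feature receives a ranked lineage (with phylum labels including
Proteobacteria and Bacteroidetes) and a leaf on a random bifurcating tree
with exponential branch lengths, so phylogenetic metrics run unmodified on
simulated output.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .data_model import FeatureTable, TaxonomyTable, validate_metadata

_NORTH_STREAMS = {"H", "J"}

# phylum composition of generated lineages, cycled deterministically
_WATER_PHYLA = ("Proteobacteria", "Proteobacteria", "Proteobacteria",
                "Bacteroidetes", "Actinobacteriota")
_SKIN_PHYLA = ("Proteobacteria", "Proteobacteria", "Firmicutes",
               "Bacteroidetes")


@dataclass
class SimulationConfig:
    """Study-design parameters for the paired swab/water generator.

    Defaults mirror the scale of the field survey the pipeline targets:
    five sites in four streams across two basins, four fish per site
    (20 swabs) plus one water sample per site, a read depth around 3,000
    per sample, a ~200-ASV feature universe, and a contamination fraction
    of 0.3.
    """

    sites_per_stream: dict = field(
        default_factory=lambda: {"H": 1, "J": 1, "S": 1, "T": 2})
    n_fish_per_site: int = 4
    n_water_per_site: int = 1
    fish_taxa: dict = field(
        default_factory=lambda: {"Cyprinidae": None, "Nemacheilidae": None})
    n_indigenous_features: int = 40
    n_water_features: int = 120
    contamination_fraction: float = 0.3
    gradient_effect: float = 1.0
    dysbiosis_sites: tuple = ("J.1",)
    dysbiosis_delta: float = 3.0
    depth_mean: int = 3000
    overdispersion: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination fraction must lie in [0, 1]")
        if self.overdispersion <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.dysbiosis_delta < 1:
            raise ValueError("dysbiosis enrichment factor must be >= 1")
        if min(self.n_fish_per_site, self.n_indigenous_features,
               self.n_water_features, self.depth_mean) <= 0:
            raise ValueError("all counts must be positive")

    @property
    def sites(self) -> list[str]:
        out = []
        for stream, k in self.sites_per_stream.items():
            out.extend(f"{stream}.{i + 1}" for i in range(k))
        return out


@dataclass
class SimulationTruth:
    indigenous_features: dict       # taxon -> list of feature ids
    water_features: list
    realized_contamination: pd.Series  # per swab sample
    phylum: pd.Series                  # per feature
    water_pools: pd.DataFrame          # site x water-feature probabilities


@dataclass
class SimulationOutput:
    table: FeatureTable
    metadata: pd.DataFrame
    tree: TreeNode
    taxonomy: TaxonomyTable
    truth: SimulationTruth


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _random_tree(feature_ids: list[str], rng) -> TreeNode:
    """Random bifurcating rooted tree with Exponential(1) branch lengths."""

    def build(ids: list[str]) -> str:
        if len(ids) == 1:
            return f"{ids[0]}:{rng.exponential():.6f}"
        split = int(rng.integers(1, len(ids)))
        shuffled = list(rng.permutation(ids))
        left, right = shuffled[:split], shuffled[split:]
        return (f"({build(left)},{build(right)}):{rng.exponential():.6f}")

    newick = f"({build(list(feature_ids))});"
    tree = TreeNode.read([newick])
    # collapse the artificial single-child root chain
    while len(tree.children) == 1 and not tree.children[0].is_tip():
        tree = tree.children[0]
        tree.parent = None
    for node in tree.traverse(include_self=True):
        if node.length is None:
            node.length = 0.0
    return tree


def _lineage(phylum: str, genus: str) -> str:
    return f"Bacteria;{phylum};{phylum}_class;{phylum}_order;" \
           f"{phylum}_family;{genus}"


def simulate(config: SimulationConfig = SimulationConfig()) -> SimulationOutput:
    """Generate one paired swab/water dataset with ground truth."""
    rng = np.random.default_rng(config.seed)
    sites = config.sites
    taxa = list(config.fish_taxa)
    if not taxa:
        raise ValueError("at least one fish taxon is required")
    occupancy = {}
    for t, occ in config.fish_taxa.items():
        occ = list(occ) if occ is not None else list(sites)
        if not occ:
            raise ValueError(f"fish taxon {t!r} has empty site occupancy")
        occupancy[t] = occ

    water_ids = [f"W{i:04d}" for i in range(config.n_water_features)]
    indigenous: dict[str, list[str]] = {}
    for ti, t in enumerate(taxa):
        indigenous[t] = [f"F{ti}{i:04d}"
                         for i in range(config.n_indigenous_features)]
    all_ids = water_ids + [f for ids in indigenous.values() for f in ids]

    phylum = {}
    for i, f in enumerate(water_ids):
        phylum[f] = _WATER_PHYLA[i % len(_WATER_PHYLA)]
    for t in taxa:
        for i, f in enumerate(indigenous[t]):
            phylum[f] = _SKIN_PHYLA[i % len(_SKIN_PHYLA)]
    phylum = pd.Series(phylum).loc[all_ids]
    taxonomy = TaxonomyTable(pd.Series(
        {f: _lineage(phylum[f], f"Genus_{f}") for f in all_ids}).loc[all_ids])

    # environmental gradient over sites (temperature proxy, standardised z)
    n_sites = len(sites)
    temperature = np.linspace(16.0, 28.0, n_sites)
    z = (temperature - temperature.mean()) / temperature.std()

    # water pools: log-composition shifts linearly with z
    base = rng.normal(0.0, 1.5, size=config.n_water_features)
    loading = rng.normal(0.0, 1.0, size=config.n_water_features)
    water_pool = {}
    for s, zs in zip(sites, z):
        water_pool[s] = _softmax(base + config.gradient_effect * zs * loading)
    water_pools = pd.DataFrame(water_pool, index=water_ids).T

    # indigenous pools per fish taxon
    indig_pool = {t: _softmax(rng.normal(0.0, 1.5,
                                         size=config.n_indigenous_features))
                  for t in taxa}

    index = {f: i for i, f in enumerate(all_ids)}
    n_feat = len(all_ids)

    def draw(probs_by_feature: dict[str, float], depth: int) -> np.ndarray:
        ids = list(probs_by_feature)
        p = np.array([probs_by_feature[f] for f in ids])
        p = p / p.sum()
        alpha = config.overdispersion * p
        q = rng.dirichlet(np.maximum(alpha, 1e-12))
        counts = rng.multinomial(depth, q)
        full = np.zeros(n_feat, dtype=np.int64)
        for f, c in zip(ids, counts):
            full[index[f]] += c
        return full

    rows, meta_rows, realized = {}, [], {}
    env_noise = rng.normal(0.0, 1.0, size=(n_sites, 3))
    for si, (site, zs) in enumerate(zip(sites, z)):
        stream = site.split(".")[0]
        basin = "north" if stream in _NORTH_STREAMS else "south"
        eutrophic = site in set(config.dysbiosis_sites)
        env = {
            "temperature": float(temperature[si]),
            "conductivity": float(320.0 + 60.0 * zs + 8.0 * env_noise[si, 0]),
            "ph": float(7.6 + 0.25 * zs + 0.05 * env_noise[si, 1]),
            "dissolved_oxygen": float(92.0 - 9.0 * zs + 2.0 * env_noise[si, 2]),
        }

        # ambient water sample(s) per site
        for wi in range(config.n_water_per_site):
            depth = max(1, int(rng.poisson(config.depth_mean)))
            wid = f"{site}.water{wi + 1}" if config.n_water_per_site > 1 \
                else f"{site}.water"
            rows[wid] = draw(dict(zip(water_ids, water_pools.loc[site])),
                             depth)
            meta_rows.append({"sample_id": wid, "sample_type": "water",
                              "site": site, "stream": stream, "basin": basin,
                              "fish_taxon": np.nan, "eutrophic": eutrophic,
                              **env})

        occupants = [t for t in taxa if site in occupancy[t]]
        for fi in range(config.n_fish_per_site):
            taxon = occupants[fi % len(occupants)] if occupants else None
            if taxon is None:
                continue
            skin = dict(zip(indigenous[taxon], indig_pool[taxon]))
            if eutrophic:
                boosted = {f: (p * config.dysbiosis_delta
                               if phylum[f] == "Bacteroidetes" else p)
                           for f, p in skin.items()}
                total = sum(boosted.values())
                skin = {f: p / total for f, p in boosted.items()}
            depth = max(1, int(rng.poisson(config.depth_mean)))
            k = int(rng.binomial(depth, config.contamination_fraction))
            counts = np.zeros(n_feat, dtype=np.int64)
            if depth - k > 0:
                counts += draw(skin, depth - k)
            if k > 0:
                counts += draw(dict(zip(water_ids, water_pools.loc[site])), k)
            sid = f"{site}.fish{fi + 1}"
            rows[sid] = counts
            realized[sid] = k / depth
            meta_rows.append({"sample_id": sid, "sample_type": "swab",
                              "site": site, "stream": stream, "basin": basin,
                              "fish_taxon": taxon, "eutrophic": eutrophic,
                              **env})

    table = FeatureTable(pd.DataFrame.from_dict(rows, orient="index",
                                                columns=all_ids))
    meta = validate_metadata(
        pd.DataFrame(meta_rows).set_index("sample_id"))
    tree = _random_tree(all_ids, rng)
    truth = SimulationTruth(
        indigenous_features={t: list(v) for t, v in indigenous.items()},
        water_features=list(water_ids),
        realized_contamination=pd.Series(realized, name="contamination"),
        phylum=phylum,
        water_pools=water_pools,
    )
    return SimulationOutput(table, meta, tree, taxonomy, truth)


def truth_recovery_score(result, truth: SimulationTruth,
                         swab_features=None) -> tuple[float, float]:
    """Sensitivity and specificity of indigenous-ASV recovery.

    Sensitivity is the retained fraction of indigenous features present in
    the swabs; specificity is the removed fraction of water-only features
    present in the swabs.  ``swab_features`` restricts "present in swabs"
    (default: every feature the correction examined).
    """
    indigenous = {f for ids in truth.indigenous_features.values() for f in ids}
    if not indigenous:
        raise ValueError("truth has no indigenous features")
    water_only = set(truth.water_features) - indigenous
    universe = set(result.per_feature.index)
    present = universe if swab_features is None else \
        universe & set(swab_features)
    retained = set(result.retained_features)
    removed = universe - retained

    indig_present = indigenous & present
    water_present = water_only & present
    sensitivity = len(retained & indig_present) / len(indig_present) \
        if indig_present else float("nan")
    specificity = len(removed & water_present) / len(water_present) \
        if water_present else float("nan")
    return sensitivity, specificity
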