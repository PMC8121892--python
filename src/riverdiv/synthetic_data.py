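"""Synthetic river networks, fish communities, and eDNA read tables.

The generator emulates the study design the analysis pipeline assumes: a
dendritic catchment (tributary chains joining a mainstem that ends at one
outlet), a taxon pool with niche positions along the upstream-downstream
axis, a downstream-increasing richness gradient, optional planted
biogeographic zones with zone-private taxa, two 12S assays with per-taxon
amplification efficiency and unequal reference coverage, six replicate
water samples per site, lognormal read depths with multinomial read
allocation, and low-level random contamination that also shows up in the
negative controls. A :class:`SyntheticTruth` object records the planted
presences and zone labels so recovery can be scored.

All randomness flows through numpy Generators seeded from a single user
seed, with fixed per-stage offsets, so every artefact is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from riverdiv.river_network import RiverNetwork, distance_to_outlet
from riverdiv.tables_io import ReadCountTable

# stage offsets for substream seeding
_NETWORK, _COMMUNITIES, _READS = 11, 23, 37

BANKS = ("left", "left", "centre", "centre", "right", "right")


@dataclass
class ScenarioConfig:
    """Parameters of one simulated catchment study.

    Defaults are sized to a single-campaign catchment survey: four rivers
    of ten sites (one river is the mainstem), ~70 km between neighbouring
    sites, a 250-taxon reference pool, six replicates per site and two
    assays with slightly unequal reference coverage.
    """

    n_rivers: int = 4
    sites_per_river: int = 10
    edge_length_log_mean: float = np.log(60.0)  # km; lognormal median
    edge_length_log_sd: float = 0.45
    n_taxa: int = 250
    zone_structure: str = "four_zone"  # null | two_zone | four_zone
    zone_effect: float = 0.6  # fraction of the pool that is zone-private
    gradient_slope: float = -0.0008  # per-km log-occupancy change upstream
    base_occupancy: float = 0.55  # occupancy probability at the outlet
    niche_breadth_km: float | None = 250.0  # None = no niche structure
    zone_private_occupancy: float = 0.5  # flat occupancy of endemics in-zone
    replicates_per_site: int = 6
    depth_log_mean: float = 10.0  # lognormal of per-sample read depth
    depth_log_sd: float = 0.4
    abundance_log_sd: float = 1.0  # per site x taxon relative abundance
    efficiency_alpha: float = 8.0  # Beta prior of per-taxon amplification
    efficiency_beta: float = 2.0
    n_taxa_missing_kelly: int = 6  # taxa absent from the kelly reference
    n_taxa_missing_mifish: int = 2
    contam_taxa_per_sample: float = 2.0  # Poisson mean of contaminant taxa
    contam_read_weight: float = 0.0008  # relative read share per contaminant
    n_negatives: int = 6
    negative_depth_mean: float = 60.0  # Poisson mean reads per negative

    def __post_init__(self) -> None:
        if self.zone_structure not in ("null", "two_zone", "four_zone"):
            raise ValueError(f"unknown zone structure {self.zone_structure!r}")
        if not 0 <= self.zone_effect <= 1:
            raise ValueError("zone_effect must be in [0, 1]")
        if not 0 < self.base_occupancy < 1:
            raise ValueError("base_occupancy must be in (0, 1)")
        if self.n_rivers < 1:
            raise ValueError("need at least one river")

    @property
    def n_zones(self) -> int:
        return {"null": 1, "two_zone": 2, "four_zone": 4}[self.zone_structure]

    @classmethod
    def preset(cls, name: str) -> "ScenarioConfig":
        """Named study conditions used throughout the test-suite.

        ``null``: no spatial structure at all (flat occupancy, no zones);
        ``distance_decay``: smooth taxon turnover along the network from
        narrow niches, no discrete zones; ``two_zone`` / ``four_zone``:
        planted biogeographic zones on top of the gradient.
        """
        if name == "null":
            return cls(zone_structure="null", gradient_slope=0.0, niche_breadth_km=None)
        if name == "distance_decay":
            return cls(zone_structure="null", niche_breadth_km=150.0)
        if name in ("two_zone", "four_zone"):
            return cls(zone_structure=name)
        raise ValueError(f"unknown scenario {name!r}")


@dataclass
class SyntheticTruth:
    """Planted ground truth behind one simulated read dataset."""

    presence: pd.DataFrame  # sites x taxa, 0/1
    zones: pd.Series  # site -> zone label 1..n_zones
    occupancy: pd.DataFrame  # sites x taxa Bernoulli probabilities
    kelly_reference: pd.Series  # taxon -> in kelly reference (bool)
    mifish_reference: pd.Series
    config: ScenarioConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "presence": {s: self.presence.loc[s].to_dict() for s in self.presence.index},
            "zones": self.zones.to_dict(),
            "kelly_reference": self.kelly_reference.astype(bool).to_dict(),
            "mifish_reference": self.mifish_reference.astype(bool).to_dict(),
            "config": {k: (v if v is None or isinstance(v, (int, float, str, bool)) else float(v))
                       for k, v in asdict(self.config).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _site_name(river: int, idx: int) -> str:
    return f"R{river + 1}S{idx + 1:02d}"


def generate_network(cfg: ScenarioConfig, seed: int) -> RiverNetwork:
    """Dendritic site network: tributaries joining a mainstem at one outlet.

    River 1 is the mainstem; its most-downstream site is the outlet.
    Tributaries attach at mainstem sites spread evenly upstream. Every
    node is a sampling site; edge lengths are lognormal km. Per-site
    environmental variables (altitude, width, pH, conductivity, TDS)
    co-vary with the position along the river continuum and ride on the
    network's ``site_attrs``.
    """
    rng = np.random.default_rng((seed, _NETWORK))
    edges: list[tuple[str, str, float]] = []
    rivers: dict[str, int] = {}

    def elen() -> float:
        return float(rng.lognormal(cfg.edge_length_log_mean, cfg.edge_length_log_sd))

    m = cfg.sites_per_river
    for i in range(m):
        rivers[_site_name(0, i)] = 0
        if i:
            edges.append((_site_name(0, i - 1), _site_name(0, i), elen()))
    for r in range(1, cfg.n_rivers):
        # junction site on the mainstem, spread from downstream to upstream
        j = min(m - 1, int(np.ceil(r * m / cfg.n_rivers)))
        for i in range(m):
            rivers[_site_name(r, i)] = r
            upstream_of = _site_name(0, j) if i == 0 else _site_name(r, i - 1)
            edges.append((upstream_of, _site_name(r, i), elen()))
    net = RiverNetwork.from_edges(edges, outlet=_site_name(0, 0))
    sites = list(rivers)
    d = distance_to_outlet(net, sites)
    noise = rng.normal(size=(5, len(sites)))
    attrs = pd.DataFrame(
        {
            "river": [f"river_{rivers[s] + 1}" for s in sites],
            "altitude_m": np.maximum(2.0, 5 + 0.85 * d.to_numpy() + 25 * noise[0]),
            "width_m": np.maximum(5.0, 260 * np.exp(-d.to_numpy() / 350) + 12 * noise[1]),
            "ph": 7.6 - 0.0006 * d.to_numpy() + 0.25 * noise[2],
            "conductivity_us_cm": np.maximum(
                20.0, 420 * np.exp(-d.to_numpy() / 500) + 30 * noise[3]
            ),
            "tds_mg_l": np.maximum(10.0, 230 * np.exp(-d.to_numpy() / 500) + 20 * noise[4]),
        },
        index=pd.Index(sites, name="node"),
    )
    net.site_attrs = attrs
    for s in sites:
        net.graph.nodes[s].update(attrs.loc[s].to_dict())
    return net


def _zone_of_river(river_idx: int, cfg: ScenarioConfig) -> int:
    if cfg.n_zones == 1:
        return 1
    if cfg.n_zones == 2:
        # mainstem + first tributary vs the remaining tributaries
        return 1 if river_idx <= (cfg.n_rivers - 1) // 2 else 2
    return river_idx % cfg.n_zones + 1


def generate_communities(net: RiverNetwork, cfg: ScenarioConfig, seed: int) -> SyntheticTruth:
    """Plant taxon presences on the network's sites.

    Each taxon carries a niche optimum (a distance-to-outlet, uniform
    over the catchment) with a Gaussian occupancy kernel of the
    configured breadth; the baseline occupancy decreases upstream at
    ``gradient_slope`` per km (log scale). A ``zone_effect`` fraction of
    the pool is zone-private and never occurs outside its zone's rivers.
    Presence is an independent Bernoulli draw per site and taxon.
    """
    rng = np.random.default_rng((seed, _COMMUNITIES))
    sites = net.nodes
    d = distance_to_outlet(net, sites).to_numpy()
    river_idx = np.array(
        [int(net.site_attrs.loc[s, "river"].split("_")[1]) - 1 for s in sites]
    )
    zones = pd.Series([_zone_of_river(r, cfg) for r in river_idx], index=sites, name="zone")
    taxa = [f"t{i + 1:03d}" for i in range(cfg.n_taxa)]
    n_private = int(round(cfg.zone_effect * cfg.n_taxa)) if cfg.n_zones > 1 else 0
    taxon_zone = np.zeros(cfg.n_taxa, dtype=int)  # 0 = cosmopolitan
    taxon_zone[:n_private] = np.arange(n_private) % cfg.n_zones + 1
    optima = rng.uniform(0, d.max() if d.max() > 0 else 1.0, size=cfg.n_taxa)
    if cfg.niche_breadth_km is None:
        kernel = np.ones((len(sites), cfg.n_taxa))
    else:
        kernel = np.exp(
            -((d[:, None] - optima[None, :]) ** 2) / (2 * cfg.niche_breadth_km**2)
        )
    occ = cfg.base_occupancy * np.exp(cfg.gradient_slope * d)[:, None] * kernel
    # zone endemics are zone specialists: flat occupancy inside their zone,
    # zero outside, unaffected by the catchment-wide niche kernel
    private = taxon_zone[None, :] > 0
    in_zone = taxon_zone[None, :] == zones.to_numpy()[:, None]
    occ = np.where(private, cfg.zone_private_occupancy * in_zone, occ)
    occ = np.clip(occ, 0.0, 0.95)
    presence = (rng.random(occ.shape) < occ).astype(np.int64)
    ref_rng = rng
    order = ref_rng.permutation(cfg.n_taxa)
    kelly_missing = set(order[: cfg.n_taxa_missing_kelly])
    mifish_missing = set(
        order[cfg.n_taxa_missing_kelly : cfg.n_taxa_missing_kelly + cfg.n_taxa_missing_mifish]
    )
    return SyntheticTruth(
        presence=pd.DataFrame(presence, index=sites, columns=taxa),
        zones=zones,
        occupancy=pd.DataFrame(occ, index=sites, columns=taxa),
        kelly_reference=pd.Series([i not in kelly_missing for i in range(cfg.n_taxa)], index=taxa),
        mifish_reference=pd.Series([i not in mifish_missing for i in range(cfg.n_taxa)], index=taxa),
        config=cfg,
    )


def _sample_counts(
    rng: np.random.Generator,
    weights: np.ndarray,
    depth: int,
) -> np.ndarray:
    if depth <= 0 or weights.sum() <= 0:
        return np.zeros(len(weights), dtype=np.int64)
    return rng.multinomial(depth, weights / weights.sum())


def generate_reads(
    truth: SyntheticTruth, cfg: ScenarioConfig, seed: int
) -> tuple[ReadCountTable, ReadCountTable]:
    """Simulate the two assays' per-sample read-count tables.

    Per replicate, a lognormal read depth is allocated multinomially over
    the site's present taxa with site-level lognormal relative abundances
    scaled by the assay's per-taxon amplification efficiency; taxa
    outside an assay's reference get zero reads in that assay. Each
    sample additionally carries a Poisson number of random contaminant
    taxa at a small relative read share, and the negative controls carry
    only such contamination.
    """
    rng = np.random.default_rng((seed, _READS))
    sites = list(truth.presence.index)
    taxa = list(truth.presence.columns)
    n_taxa = len(taxa)
    efficiency = {
        "kelly": rng.beta(cfg.efficiency_alpha, cfg.efficiency_beta, size=n_taxa)
        * truth.kelly_reference.to_numpy(),
        "mifish": rng.beta(cfg.efficiency_alpha, cfg.efficiency_beta, size=n_taxa)
        * truth.mifish_reference.to_numpy(),
    }
    abundance = np.exp(rng.normal(0.0, cfg.abundance_log_sd, size=(len(sites), n_taxa)))
    abundance *= truth.presence.to_numpy()
    tables = {}
    for primer in ("kelly", "mifish"):
        rows, meta_rows = [], []
        for si, site in enumerate(sites):
            base_w = abundance[si] * efficiency[primer]
            for rep in range(1, cfg.replicates_per_site + 1):
                depth = int(rng.lognormal(cfg.depth_log_mean, cfg.depth_log_sd))
                w = base_w.copy()
                total_w = w.sum()
                n_cont = rng.poisson(cfg.contam_taxa_per_sample)
                if n_cont and total_w > 0:
                    cont = rng.choice(n_taxa, size=min(n_cont, n_taxa), replace=False)
                    # contamination enters before PCR: taxa the assay cannot
                    # amplify yield no contaminant reads either
                    amplifiable = efficiency[primer][cont] > 0
                    w[cont] += (
                        cfg.contam_read_weight * total_w * amplifiable
                        / (1 - min(cfg.contam_read_weight * len(cont), 0.5))
                    )
                rows.append(_sample_counts(rng, w, depth))
                meta_rows.append(
                    {
                        "sample_id": f"{site}_{primer}_r{rep}",
                        "site_id": site,
                        "replicate_index": rep,
                        "bank": BANKS[(rep - 1) % len(BANKS)],
                        "primer": primer,
                        "is_negative": False,
                    }
                )
        for neg in range(1, cfg.n_negatives + 1):
            depth = int(rng.poisson(cfg.negative_depth_mean))
            n_cont = rng.poisson(cfg.contam_taxa_per_sample)
            w = np.zeros(n_taxa)
            if n_cont:
                cont = rng.choice(n_taxa, size=min(n_cont, n_taxa), replace=False)
                w[cont] = rng.dirichlet(np.ones(len(cont))) * (efficiency[primer][cont] > 0)
            rows.append(_sample_counts(rng, w, depth if n_cont else 0))
            meta_rows.append(
                {
                    "sample_id": f"NEG{neg:02d}_{primer}",
                    "site_id": "",
                    "replicate_index": neg,
                    "bank": "centre",
                    "primer": primer,
                    "is_negative": True,
                }
            )
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        counts = pd.DataFrame(
            np.array(rows, dtype=np.int64), index=meta.index, columns=taxa
        )
        tables[primer] = ReadCountTable(counts=counts, meta=meta)
    return tables["kelly"], tables["mifish"]


@dataclass
class SimulatedStudy:
    """Everything one simulated campaign produces."""

    network: RiverNetwork
    truth: SyntheticTruth
    kelly: ReadCountTable
    mifish: ReadCountTable
    env: pd.DataFrame = field(repr=False, default=None)


def simulate_scenario(scenario: str | ScenarioConfig, seed: int) -> SimulatedStudy:
    """Generate network, truth and both read tables for one scenario."""
    cfg = ScenarioConfig.preset(scenario) if isinstance(scenario, str) else scenario
    net = generate_network(cfg, seed)
    truth = generate_communities(net, cfg, seed)
    kelly, mifish = generate_reads(truth, cfg, seed)
    env = net.site_attrs.drop(columns=["river"])
    return SimulatedStudy(network=net, truth=truth, kelly=kelly, mifish=mifish, env=env)
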