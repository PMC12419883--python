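"""Seeded generators for trees, traits and proxy variables.

The simulated data mirror the structure the analysis expects: a pure-birth
(Yule) tree, a log response evolving by Brownian motion along it, three
log-proxy variables affinely coupled to the log response with Gaussian
noise, and a "fossil" mask removing the response (but not the proxies) from
a fraction of tips.  All draws flow from one generator seeded per run, so
fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo_graph import Node, PhyloTree, write_newick

__all__ = ["ProxyParams", "SimulationConfig", "simulate_tree",
           "simulate_traits", "simulate_dataset", "write_fixture"]

#: raw CSV column -> in-memory log-predictor column
PROXY_COLUMNS = {
    "osteo_volume": "lnOsteo_volume",
    "can_harmean": "lnCan_harmean",
    "can_min": "lnCan_min",
}


@dataclass(frozen=True)
class ProxyParams:
    """ln(proxy) = intercept + slope * ln(response) + N(0, noise_sd)."""

    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 0.05


def _default_proxies() -> dict[str, ProxyParams]:
    return {
        "osteo_volume": ProxyParams(2.0, 1.0, 0.05),
        "can_harmean": ProxyParams(-2.3, 1.0, 0.05),
        "can_min": ProxyParams(-2.5, 1.0, 0.05),
    }


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_tips: int = 40
    birth_rate: float = 1.0
    sigma2: float = 0.25          # Brownian rate of the log response
    root_state: float = 4.6       # ln of the root response value
    fossil_fraction: float = 0.5
    proxies: dict[str, ProxyParams] = field(default_factory=_default_proxies)

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError(f"need n_tips >= 4, got {self.n_tips}")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not 0.0 <= self.fossil_fraction < 1.0:
            raise ValueError("fossil fraction must lie in [0, 1)")
        if self.birth_rate <= 0:
            raise ValueError("birth rate must be positive")
        if set(self.proxies) != set(PROXY_COLUMNS):
            raise ValueError(f"proxies must be exactly {sorted(PROXY_COLUMNS)}")
        n_fossil = round(self.n_tips * self.fossil_fraction)
        if self.n_tips - n_fossil < 5:
            raise ValueError("fossil fraction leaves fewer than 5 training tips")


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> PhyloTree:
    """Pure-birth tree with ``n_tips`` contemporaneous tips.

    Lineages split at exponential waiting times (rate = birth_rate per
    lineage); after the last split a final holding time is drawn and all
    pendant edges are cut there, so the tree is exactly ultrametric.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    root = Node()
    t = 0.0
    active = [root.add_child(Node()), root.add_child(Node())]
    births = {id(c): 0.0 for c in active}
    while len(active) < config.n_tips:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active[i]
        node.length = t - births[id(node)]
        c1, c2 = node.add_child(Node()), node.add_child(Node())
        births[id(c1)] = births[id(c2)] = t
        active[i] = c1
        active.append(c2)
    t += rng.exponential(1.0 / (config.birth_rate * config.n_tips))
    for node in active:
        node.length = t - births[id(node)]
    # label tips in input (preorder) order before the validating constructor
    tips: list[Node] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.children:
            tips.append(node)
        stack.extend(reversed(node.children))
    width = len(str(config.n_tips))
    for i, tip in enumerate(tips, start=1):
        tip.label = f"t{i:0{width}d}"
    return PhyloTree(root)


def simulate_traits(
    tree: PhyloTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evolve the response and proxies on ``tree``; mask fossil tips.

    Returns ``(table, truth)``: the in-memory trait table (log proxies, raw
    responses, fossil responses set to NaN) and a truth frame holding the
    masked tips' unmasked responses.  RBC width and length are deterministic
    scaled correlates of the simulated area.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sd = np.sqrt(config.sigma2)
    values = {id(tree.root): config.root_state}
    for node in tree.preorder():
        if node.parent is not None:
            step = rng.normal(0.0, sd * np.sqrt(node.length)) if node.length > 0 else 0.0
            values[id(node)] = values[id(node.parent)] + step

    tips = tree.tips()
    ln_area = np.array([values[id(t)] for t in tips])
    area = np.exp(ln_area)
    width = 0.9 * np.sqrt(area)
    length = 1.5 * np.sqrt(area)

    data = {"taxon": [t.label for t in tips]}
    for raw_name in sorted(PROXY_COLUMNS):
        p = config.proxies[raw_name]
        noise = rng.normal(0.0, p.noise_sd, size=len(tips)) if p.noise_sd > 0 else 0.0
        data[PROXY_COLUMNS[raw_name]] = p.intercept + p.slope * ln_area + noise
    data["RBC_width"] = width
    data["RBC_area"] = area
    data["RBC_length"] = length
    table = pd.DataFrame(data)

    n_fossil = round(config.n_tips * config.fossil_fraction)
    masked = np.sort(rng.choice(len(tips), size=n_fossil, replace=False))
    status = np.array(["extant"] * len(tips), dtype=object)
    status[masked] = "fossil"
    table.insert(1, "status", status)

    truth = table.loc[masked, ["taxon", "RBC_width", "RBC_area", "RBC_length"]].reset_index(drop=True)
    table.loc[masked, ["RBC_width", "RBC_area", "RBC_length"]] = np.nan
    return table, truth


def simulate_dataset(config: SimulationConfig) -> tuple[PhyloTree, pd.DataFrame, pd.DataFrame]:
    """Tree + traits from a single seeded generator (the canonical entry)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    table, truth = simulate_traits(tree, config, rng)
    return tree, table, truth


def write_fixture(tree: PhyloTree, table: pd.DataFrame, truth: pd.DataFrame, directory) -> dict[str, Path]:
    """Write tree.nwk + matrix.csv (raw values) + truth.csv into ``directory``.

    The matrix stores unlogged proxy values so it round-trips through the
    character-matrix reader; regenerating with the same seed reproduces the
    files byte for byte.
    """
    from .cli_io import table_to_raw

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": directory / "tree.nwk",
        "matrix": directory / "matrix.csv",
        "truth": directory / "truth.csv",
    }
    paths["tree"].write_text(write_newick(tree) + "\n")
    table_to_raw(table).to_csv(paths["matrix"], index=False)
    truth.to_csv(paths["truth"], index=False)
    return paths
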