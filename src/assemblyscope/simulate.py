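"""Synthetic study generator: phylogeny, trait-structured species pool,
communities assembled under known regimes, and correlated environmental
covariates.

The generator emulates a multi-site soil 16S survey: a Yule phylogeny of
the regional pool, Brownian-motion environmental optima on that phylogeny
(so niches carry phylogenetic signal and the tip-shuffle null has power),
log-normal regional abundances (realistic rank-abundance curves with
singletons), and per-sample read vectors drawn multinomially with taxon
weights combining regional abundance, a Gaussian niche kernel around the
sample's environment, and log-normal demographic drift. Four assembly
regimes map onto the classical process quadrants:

- ``variable_selection``: environments vary along a gradient within each
  site; selection tracks them.
- ``homogeneous_selection``: one constant environment per site, with a
  per-sample recruitment lottery so different samples assemble different
  (ecologically equivalent) members of the same fit clade.
- ``neutral_dispersal``: selection switched off (infinite niche breadth);
  all samples draw from the shared pool.
- ``dispersal_limited``: selection off, and each sample only sees its own
  disjoint-leaning block of the pool.

A soil-organic-carbon-like covariate (``SOC``) is an affine function of
the sample environment plus Gaussian noise, so environment-linked turnover
is recoverable by Mantel tests and pairwise regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import OtuTable

REGIMES = (
    "variable_selection",
    "homogeneous_selection",
    "neutral_dispersal",
    "dispersal_limited",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic assembly scenario.

    ``selection_sd`` is the Gaussian niche breadth sigma (same units as the
    environmental axis; small = strong selection). When left ``None`` it
    resolves to a regime-appropriate default: 0.45 for variable selection
    (broad niches spanning a steep within-site gradient, so communities
    keep enough taxa for the turnover statistics) and 0.22 for homogeneous
    selection (narrow filtering to one optimum, so the fit set is a small,
    phylogenetically concentrated slice of the pool). ``trait_signal`` is the
    Brownian rate of optimum evolution per unit branch length on the
    unit-height tree, so tip optima have variance ~ trait_signal.
    ``env_gradient`` gives one (min, max) environment interval per site.
    ``pool_fraction`` is the fraction of the regional pool each sample can
    draw from in the dispersal-limited regime (disjoint-leaning blocks);
    ``lottery_fraction`` is the fraction each sample can recruit from in the
    homogeneous-selection lottery (independent random subsets).
    ``drift_sdlog`` is the standard deviation of per-sample log-normal
    demographic noise; ``abundance_sdlog`` sets the evenness of the
    regional log-normal abundance distribution.
    """

    regime: str = "variable_selection"
    n_taxa: int = 800
    n_samples_per_site: int = 8
    n_sites: int = 3
    selection_sd: float | None = None
    trait_signal: float = 1.0
    reads_per_sample: int = 5000
    env_gradient: tuple = ((-2.0, 0.0), (-1.0, 1.0), (0.0, 2.0))
    pool_fraction: float = 0.25
    lottery_fraction: float = 0.4
    drift_sdlog: float = 0.3
    abundance_sdlog: float = 0.5
    soc_slope: float = 15.0
    soc_intercept: float = 40.0
    soc_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_taxa < 10:
            raise ValueError("n_taxa must be >= 10")
        if self.n_sites != len(self.env_gradient):
            raise ValueError("env_gradient must list one (min, max) per site")
        if self.selection_sd is not None and self.selection_sd <= 0:
            raise ValueError("selection_sd must be positive when given")
        if not 0 < self.pool_fraction <= 1:
            raise ValueError("pool_fraction must be in (0, 1]")
        if not 0 < self.lottery_fraction <= 1:
            raise ValueError("lottery_fraction must be in (0, 1]")


_DEFAULT_NICHE_SD = {"variable_selection": 0.45, "homogeneous_selection": 0.22}


def resolved_selection_sd(config: "ScenarioConfig") -> float | None:
    """Niche breadth in effect: explicit value, regime default, or None
    (no selection) for the neutral and dispersal-limited regimes."""
    if config.regime in ("neutral_dispersal", "dispersal_limited"):
        return None
    if config.selection_sd is not None:
        return config.selection_sd
    return _DEFAULT_NICHE_SD[config.regime]


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Pure-birth (Yule) tree scaled to unit root height.

    Waiting times between speciations are exponential with rate equal to
    the number of extant lineages; a uniformly chosen lineage splits at
    each event. The result is ultrametric with every tip at depth 1 and
    tips named ``otu0000``, ``otu0001``, ... in left-to-right order.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.extend([first, second])
    birth = {id(first): 0.0, id(second): 0.0}
    active = [first, second]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active[k]
        node.length = t - birth.pop(id(node))
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        birth[id(left)] = birth[id(right)] = t
        active[k] = left
        active.append(right)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth[id(node)]
    scale = t_end if t_end > 0 else 1.0
    for node in root.traverse(include_self=False):
        node.length = node.length / scale
    for i, tip in enumerate(root.tips()):
        tip.name = f"otu{i:04d}"
    return root


def evolve_optima(tree: TreeNode, rate: float, seed: int) -> pd.Series:
    """Brownian-motion environmental optima along the tree from root value 0.

    Each branch adds a Normal(0, sqrt(rate * branch_length)) increment, so a
    tip's optimum has variance rate x root-to-tip depth.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    rng = np.random.default_rng(seed)
    values = {id(tree): 0.0}
    out = {}
    for node in tree.preorder(include_self=False):
        step = rng.normal(0.0, np.sqrt(rate * (node.length or 0.0)))
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return pd.Series(out).sort_index()


def niche_weights(
    optima: np.ndarray,
    env: float,
    selection_sd: float | None,
    regional: np.ndarray,
) -> np.ndarray:
    """Taxon sampling weights: regional abundance x Gaussian niche kernel.

    ``selection_sd=None`` (or the neutral regime) removes the kernel, i.e.
    infinite niche breadth.
    """
    if selection_sd is None:
        return regional.copy()
    return regional * np.exp(-((optima - env) ** 2) / (2.0 * selection_sd**2))


def simulate_community(
    optima: np.ndarray,
    env: float,
    config: ScenarioConfig,
    seed: int,
    regional: np.ndarray,
    pool_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multinomial read vector for one sample under the scenario's regime."""
    rng = np.random.default_rng(seed)
    sd = resolved_selection_sd(config)
    w = niche_weights(np.asarray(optima, float), env, sd, np.asarray(regional, float))
    if config.drift_sdlog > 0:
        w = w * rng.lognormal(0.0, config.drift_sdlog, size=w.size)
    if pool_mask is not None:
        w = w * pool_mask
    if w.sum() <= 0:
        raise ValueError("all taxon weights zero; selection too strong for this pool")
    return rng.multinomial(config.reads_per_sample, w / w.sum())


def simulate_study(config: ScenarioConfig):
    """Full synthetic study: OTU table, phylogeny, and sample metadata.

    Returns ``(OtuTable, TreeNode, metadata DataFrame)``. Metadata carries a
    site label per sample plus SOC (affine in the sample environment with
    Gaussian noise) and pH (weakly anti-correlated with the environment).
    Sub-seeds are fixed offsets from ``config.seed`` so each layer is
    independently reproducible.
    """
    tree = simulate_tree(config.n_taxa, config.seed)
    optima = evolve_optima(tree, config.trait_signal, config.seed + 1)
    rng = np.random.default_rng(config.seed + 2)
    regional = rng.lognormal(0.0, config.abundance_sdlog, size=config.n_taxa)
    taxa = list(optima.index)
    opt = optima.to_numpy()
    cols = {}
    meta_rows = []
    sample_no = 0
    for s in range(config.n_sites):
        lo, hi = config.env_gradient[s]
        site = f"site{s + 1}"
        for j in range(config.n_samples_per_site):
            if config.regime == "variable_selection" and config.n_samples_per_site > 1:
                env = lo + (hi - lo) * j / (config.n_samples_per_site - 1)
            else:
                env = (lo + hi) / 2.0
            pool_mask = None
            if config.regime == "homogeneous_selection":
                # recruitment lottery: each sample colonizes from its own
                # random subset of the regional pool, so selection filters
                # different (ecologically equivalent) close relatives in
                # different samples; without it, identical filters produce
                # identical supports and presence-based phylogenetic
                # turnover has nothing to measure
                lot_rng = np.random.default_rng(config.seed + 2000 + sample_no)
                n_pool = max(2, int(round(config.lottery_fraction * config.n_taxa)))
                idx = lot_rng.choice(config.n_taxa, size=n_pool, replace=False)
                pool_mask = np.zeros(config.n_taxa)
                pool_mask[idx] = 1.0
            if config.regime == "dispersal_limited":
                # disjoint-leaning local pools: each site permutes the
                # regional pool once and samples take consecutive blocks, so
                # pool overlap between samples is below the random
                # expectation (zero when pool_fraction <= 1/samples-per-site)
                site_rng = np.random.default_rng(config.seed + 1000 + s)
                order = site_rng.permutation(config.n_taxa)
                n_pool = max(2, int(round(config.pool_fraction * config.n_taxa)))
                start = (j * config.n_taxa) // config.n_samples_per_site
                idx = order[np.arange(start, start + n_pool) % config.n_taxa]
                pool_mask = np.zeros(config.n_taxa)
                pool_mask[idx] = 1.0
            counts = simulate_community(
                opt, env, config, config.seed + 5000 + sample_no, regional, pool_mask
            )
            sid = f"{site}_s{j + 1}"
            cols[sid] = counts
            soc = (
                config.soc_intercept
                + config.soc_slope * env
                + rng.normal(0.0, config.soc_noise_sd)
            )
            ph = 7.0 - 0.5 * env + rng.normal(0.0, 0.1)
            meta_rows.append(
                {"sample_id": sid, "group": site, "env": env, "SOC": soc, "pH": ph}
            )
            sample_no += 1
    table = OtuTable(pd.DataFrame(cols, index=taxa))
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    return table, tree, metadata
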