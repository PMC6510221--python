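"""Bray-Curtis dissimilarity and the richness/abundance-preserving null model.

The null model re-assembles each sample while preserving its observed
richness and total read count: taxa are first drawn without replacement with
probability proportional to their occurrence frequency across samples, each
drawn taxon receives one individual, and the remaining individuals are
distributed multinomially with probability proportional to the taxa's mean
relative abundances across samples. The deviation of observed Bray-Curtis
dissimilarity from its null expectation (the "null deviation") measures how
far community turnover departs from the chance expectation: values near zero
indicate stochastic assembly, large magnitudes indicate deterministic
structuring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import OtuTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NullModelConfig:
    """Configuration shared by the Bray-Curtis null models.

    ``reps`` null iterations (999 by default), a seed for the single
    generator driving all draws, and the taxon-selection weighting:
    ``occurrence_frequency`` (default) or ``uniform`` for sensitivity
    analysis. Each null assembly preserves the sample's richness and total
    abundance exactly.
    """

    reps: int = 999
    seed: int = 0
    pool_weighting: str = "occurrence_frequency"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.pool_weighting not in ("occurrence_frequency", "uniform"):
            raise ValueError(f"unknown pool_weighting {self.pool_weighting!r}")


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min(x,y)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative counts")
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined when both samples are empty")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def pool_statistics(table: OtuTable) -> tuple[np.ndarray, np.ndarray]:
    """Occurrence frequency and mean relative abundance of each taxon.

    Frequency is the fraction of samples where the taxon has a positive
    count; mean relative abundance averages the taxon's within-sample
    proportions across samples.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("samples with zero total reads in null-model pool")
    freq = (counts > 0).mean(axis=1)
    mean_ra = (counts / totals).mean(axis=1)
    return freq, mean_ra


def assemble_null_community(
    richness: int,
    total: int,
    freq: np.ndarray,
    mean_ra: np.ndarray,
    rng: np.random.Generator,
    pool_weighting: str = "occurrence_frequency",
) -> np.ndarray:
    """Assemble one null community with fixed richness and total abundance.

    Taxon selection is sequential weighted sampling without replacement with
    weights proportional to occurrence frequency (implemented via
    exponential keys, which draws from the identical distribution). Every
    selected taxon gets one individual; the remaining ``total - richness``
    individuals are placed multinomially with weights proportional to mean
    relative abundance. With ``pool_weighting='uniform'`` both steps use
    uniform weights over taxa present in the pool.
    """
    freq = np.asarray(freq, dtype=float)
    mean_ra = np.asarray(mean_ra, dtype=float)
    candidates = np.flatnonzero(freq > 0)
    if richness > candidates.size:
        raise ValueError(
            f"richness {richness} exceeds pool size {candidates.size}"
        )
    if total < richness:
        raise ValueError(f"total {total} below richness {richness}")
    if pool_weighting == "uniform":
        sel_w = np.ones(candidates.size)
        fill_w = np.ones(candidates.size)
    else:
        sel_w = freq[candidates]
        fill_w = mean_ra[candidates]
    if richness == candidates.size:
        chosen = candidates
    else:
        # exponential-keys trick == sequential weighted draw w/o replacement
        keys = rng.exponential(size=candidates.size) / sel_w
        chosen = candidates[np.argpartition(keys, richness - 1)[:richness]]
    out = np.zeros(freq.size, dtype=np.int64)
    out[chosen] = 1
    extra = total - richness
    if extra > 0:
        w = fill_w[np.searchsorted(candidates, chosen)]
        if w.sum() <= 0:
            raise ValueError("selected taxa have zero fill weight")
        out[chosen] += rng.multinomial(extra, w / w.sum())
    # conservation is a hard contract of the null model
    assert int((out > 0).sum()) == richness and int(out.sum()) == total
    return out


def _pair_index(sample_ids: list[str]) -> pd.DataFrame:
    ids = list(sample_ids)
    rows = [
        (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j"])


def null_bray_curtis_distribution(
    table: OtuTable, config: NullModelConfig
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Observed and null Bray-Curtis for every sample pair.

    Per rep, every sample is re-assembled once under the null (preserving
    its richness and total) and all pairwise dissimilarities are computed on
    the assembled set. Returns (pair table, observed condensed BC, null BC
    array of shape reps x n_pairs).
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("samples with zero total reads")
    freq, mean_ra = pool_statistics(table)
    richness = (counts > 0).sum(axis=0)
    rng = np.random.default_rng(config.seed)
    obs = pdist(counts.T, metric="braycurtis")
    null = np.empty((config.reps, obs.size))
    for r in range(config.reps):
        sim = np.column_stack(
            [
                assemble_null_community(
                    int(richness[k]), int(totals[k]), freq, mean_ra, rng,
                    config.pool_weighting,
                )
                for k in range(table.n_samples)
            ]
        )
        null[r] = pdist(sim.T, metric="braycurtis")
    pairs = _pair_index(table.sample_ids)
    return pairs, obs, null


def null_deviation(table: OtuTable, config: NullModelConfig) -> pd.DataFrame:
    """Null deviation of Bray-Curtis beta-diversity for every sample pair.

    Returns one row per pair with the observed dissimilarity, the null mean
    and standard deviation over ``config.reps`` assemblies, the plain
    deviation (observed - null mean), and the relative deviation
    ((observed - null mean) / null mean; NaN when the null mean is 0).
    """
    pairs, obs, null = null_bray_curtis_distribution(table, config)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    out = pairs.copy()
    out["bc_observed"] = obs
    out["bc_null_mean"] = null_mean
    out["bc_null_sd"] = null_sd
    out["null_deviation"] = obs - null_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(null_mean > 0, (obs - null_mean) / null_mean, np.nan)
    out["relative_null_deviation"] = rel
    return out


def site_null_deviation_summary(
    results: pd.DataFrame,
    metadata: pd.DataFrame,
    statistic: str = "relative_null_deviation",
) -> pd.DataFrame:
    """Per-site mean/sd/n of a null-deviation statistic over within-site pairs.

    Pairs spanning two sites are excluded; sites with fewer than two samples
    (hence no within-site pair) are skipped with a warning.
    """
    if statistic not in results.columns:
        raise KeyError(f"unknown statistic {statistic!r}")
    group = metadata["group"]
    rows = []
    for g in pd.unique(group):
        members = set(group.index[group == g])
        mask = results["sample_i"].isin(members) & results["sample_j"].isin(members)
        vals = results.loc[mask, statistic].dropna()
        if len(vals) == 0:
            logger.warning("group %r has no within-group pairs; skipped", g)
            continue
        rows.append(
            {
                "group": g,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=0)),
                "n_pairs": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
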