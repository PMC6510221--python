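"""Phylogenetic turnover: abundance-weighted betaMNTD and its tip-shuffle
null, the beta nearest-taxon index (betaNTI).

betaMNTD is the mean phylogenetic distance between each taxon in one
community and its nearest relative in the other, weighted by relative
abundance. The null shuffles taxon identities across the tips of the
phylogeny (equivalently, jointly permutes the rows and columns of the
cophenetic matrix), preserving community compositions and the multiset of
distances. betaNTI is the z-score of the observed betaMNTD against that
null; |betaNTI| > 2 is conventionally read as evidence for selection
(variable selection above +2, homogeneous selection below -2).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .beta import NullModelConfig, _pair_index
from .io import MismatchError, OtuTable

logger = logging.getLogger(__name__)


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Tip-to-tip path-length distances of a tree with non-negative branches."""
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length in tree")
    return tree.tip_tip_distances()


def beta_mntd(x, y, dm: DistanceMatrix, abundance_weighted: bool = True) -> float:
    """Between-community mean nearest-taxon distance.

    ``x`` and ``y`` are count or abundance vectors aligned with ``dm.ids``
    (or pandas Series indexed by taxon ID). A taxon present in both
    communities has nearest-taxon distance 0. Only relative abundances
    matter; when ``abundance_weighted`` is false, present taxa are weighted
    uniformly.
    """
    x = _align(x, dm)
    y = _align(y, dm)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if ix.size == 0 or iy.size == 0:
        raise ValueError("both communities must be non-empty")
    return _beta_mntd_indexed(
        dm.data, ix, iy, _weights(x, ix, abundance_weighted),
        _weights(y, iy, abundance_weighted),
    )


def _align(v, dm: DistanceMatrix) -> np.ndarray:
    if isinstance(v, pd.Series):
        missing = set(v.index[np.asarray(v) > 0]) - set(dm.ids)
        if missing:
            raise MismatchError(f"taxa absent from distance matrix: {sorted(missing)[:5]}")
        return v.reindex(dm.ids, fill_value=0).to_numpy(dtype=float)
    v = np.asarray(v, dtype=float)
    if v.size != len(dm.ids):
        raise ValueError("vector length does not match distance matrix")
    return v


def _weights(v: np.ndarray, idx: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        w = v[idx]
        return w / w.sum()
    return np.full(idx.size, 1.0 / idx.size)


def _beta_mntd_indexed(d, ix, iy, fx, fy) -> float:
    sub = d[np.ix_(ix, iy)]
    return float(0.5 * (fx @ sub.min(axis=1) + fy @ sub.min(axis=0)))


def beta_nti(
    table: OtuTable,
    tree: TreeNode,
    config: NullModelConfig,
    abundance_weighted: bool = True,
    per_pair_shuffles: bool = False,
) -> pd.DataFrame:
    """betaMNTD, its tip-shuffle null, and betaNTI for every sample pair.

    The shuffle pool is the set of taxa in ``table``; by default one shuffle
    per rep is shared by all pairs (statistically matched to per-pair
    shuffles but much cheaper); ``per_pair_shuffles`` draws an independent
    permutation for each pair instead. Pairs whose null standard deviation
    is 0 (shuffle-invariant geometry, e.g. an equal-branch star tree) get
    ``bnti = NaN`` and ``undefined = True`` rather than a silent 0.
    """
    if config.reps < 2:
        raise ValueError("need reps >= 2 for a defined null standard deviation")
    taxa = table.taxon_ids
    dm_full = cophenetic_matrix(tree)
    missing = set(taxa) - set(dm_full.ids)
    if missing:
        raise MismatchError(f"table taxa absent from tree: {sorted(missing)[:5]}")
    d = dm_full.filter(taxa).data
    counts = table.counts.astype(float)
    n = table.n_samples
    present = [np.flatnonzero(counts[:, k] > 0) for k in range(n)]
    wts = [
        _weights(counts[:, k], present[k], abundance_weighted) for k in range(n)
    ]
    pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def all_pairs(dmat: np.ndarray) -> np.ndarray:
        return np.array(
            [
                _beta_mntd_indexed(dmat, present[i], present[j], wts[i], wts[j])
                for i, j in pair_idx
            ]
        )

    obs = all_pairs(d)
    rng = np.random.default_rng(config.seed)
    n_taxa = len(taxa)
    null = np.empty((config.reps, len(pair_idx)))
    for r in range(config.reps):
        if per_pair_shuffles:
            for q, (i, j) in enumerate(pair_idx):
                perm = rng.permutation(n_taxa)
                dp = d[np.ix_(perm, perm)]
                null[r, q] = _beta_mntd_indexed(
                    dp, present[i], present[j], wts[i], wts[j]
                )
        else:
            perm = rng.permutation(n_taxa)
            null[r] = all_pairs(d[np.ix_(perm, perm)])
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=0)
    out = _pair_index(table.sample_ids)
    out["bmntd_observed"] = obs
    out["bmntd_null_mean"] = null_mean
    out["bmntd_null_sd"] = null_sd
    undefined = null_sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(undefined, np.nan, (obs - null_mean) / null_sd)
    out["bnti"] = bnti
    out["undefined"] = undefined
    if undefined.any():
        logger.warning(
            "%d sample pairs have null sd 0; betaNTI flagged undefined",
            int(undefined.sum()),
        )
    return out


def bnti_matrix(results: pd.DataFrame, value: str = "bnti") -> DistanceMatrix:
    """Pivot a pairwise result table into a symmetric DistanceMatrix."""
    ids = list(
        pd.unique(pd.concat([results["sample_i"], results["sample_j"]]))
    )
    pos = {s: k for k, s in enumerate(ids)}
    data = np.zeros((len(ids), len(ids)))
    for _, row in results.iterrows():
        i, j = pos[row["sample_i"]], pos[row["sample_j"]]
        data[i, j] = data[j, i] = row[value]
    return DistanceMatrix(data, ids=ids)
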