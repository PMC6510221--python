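"""Alpha-diversity estimators: sobs, Chao1, ACE, Shannon, Simpson, Faith's PD,
and Good's coverage.

All estimators operate on a single sample's integer count vector. Shannon
defaults to natural log (nats) and Simpson to the Gini-Simpson form
(1 - sum p_i^2), mirroring the conventions of mothur's summary output.
Faith's PD is root-inclusive: the stem path from the community's taxa up to
the tree root is counted, matching QIIME-style implementations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import MismatchError, OtuTable

logger = logging.getLogger(__name__)


def _as_counts(column) -> np.ndarray:
    arr = np.asarray(column, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if (arr < 0).any():
        raise ValueError("negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers")
    return np.round(arr).astype(np.int64)


def sobs(column) -> int:
    """Observed richness: number of taxa with a positive count."""
    return int((_as_counts(column) > 0).sum())


def chao1(column) -> float:
    """Bias-corrected Chao1 richness: Sobs + F1(F1-1) / (2(F2+1))."""
    c = _as_counts(column)
    s = int((c > 0).sum())
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return s + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ace(column, rare_threshold: int = 10) -> float:
    """Abundance-based coverage estimator.

    Taxa with counts <= ``rare_threshold`` form the rare class. When the
    rare-class coverage C_ace is zero (every rare taxon is a singleton) the
    estimator is undefined and bias-corrected Chao1 is returned instead,
    with a warning.
    """
    c = _as_counts(column)
    c = c[c > 0]
    rare = c[c <= rare_threshold]
    abund = c[c > rare_threshold]
    s_rare = rare.size
    s_abund = abund.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        logger.warning("ACE undefined (all rare taxa are singletons); returning Chao1")
        return chao1(column)
    ks = np.arange(1, rare_threshold + 1)
    fk = np.array([(rare == k).sum() for k in ks])
    gamma2 = max(
        (s_rare / c_ace) * np.sum(ks * (ks - 1) * fk) / (n_rare * (n_rare - 1)) - 1.0
        if n_rare > 1
        else 0.0,
        0.0,
    )
    return s_abund + s_rare / c_ace + (f1 / c_ace) * gamma2


def shannon(column, base: float | None = None) -> float:
    """Shannon entropy of the relative abundances (natural log by default)."""
    c = _as_counts(column)
    total = c.sum()
    if total == 0:
        raise ValueError("Shannon undefined for an all-zero sample")
    p = c[c > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def simpson(column, variant: str = "gini") -> float:
    """Simpson's index: ``gini`` -> 1 - sum p^2, ``dominance`` -> sum p^2."""
    if variant not in ("gini", "dominance"):
        raise ValueError(f"unknown Simpson variant {variant!r}")
    c = _as_counts(column)
    total = c.sum()
    if total == 0:
        raise ValueError("Simpson undefined for an all-zero sample")
    p = c / total
    d = float((p**2).sum())
    return d if variant == "dominance" else 1.0 - d


def goods_coverage(column) -> float:
    """Good's coverage 1 - F1/N: estimated fraction of reads from seen taxa."""
    c = _as_counts(column)
    n = int(c.sum())
    if n == 0:
        raise ValueError("Good's coverage undefined for an all-zero sample")
    f1 = int((c == 1).sum())
    return 1.0 - f1 / n


def faith_pd(counts: pd.Series, tree: TreeNode) -> float:
    """Faith's phylogenetic diversity of the taxa with positive counts.

    Sum of branch lengths over the union of root-to-tip paths of the present
    taxa (root-inclusive).
    """
    present = set(counts.index[np.asarray(counts) > 0])
    if not present:
        return 0.0
    tips = {t.name: t for t in tree.tips()}
    missing = present - set(tips)
    if missing:
        raise MismatchError(f"taxa absent from tree: {sorted(missing)[:5]}")
    seen = set()
    total = 0.0
    for name in present:
        node = tips[name]
        while node.parent is not None and id(node) not in seen:
            seen.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return total


def alpha_table(table: OtuTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """One row of alpha-diversity estimates per sample.

    Columns: sobs, chao1, ace, shannon, simpson, goods_coverage, and
    faith_pd when a tree is supplied.
    """
    rows = []
    for s in table.sample_ids:
        col = table.sample(s)
        row = {
            "sample_id": s,
            "sobs": sobs(col),
            "chao1": chao1(col),
            "ace": ace(col),
            "shannon": shannon(col),
            "simpson": simpson(col),
            "goods_coverage": goods_coverage(col),
        }
        if tree is not None:
            row["faith_pd"] = faith_pd(col, tree)
        rows.append(row)
    return pd.DataFrame(rows)
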