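"""Assembly-process classification and environment linkage.

Sample pairs are labelled from their (betaNTI, RC_bray) values using the
conventional thresholds: betaNTI > +2 variable selection, betaNTI < -2
homogeneous selection; otherwise RC_bray > +0.95 dispersal limitation,
RC_bray < -0.95 homogenizing dispersal, and anything inside all thresholds
is "undominated". Boundary values fall to undominated (the printed rules
are strict inequalities). Environment linkage uses Mantel tests and
pairwise (distance-on-distance) regression with permutation p-values,
because pairwise observations sharing a sample are not independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)

PROCESS_LABELS = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def classify_pair(bnti: float, rc: float) -> str:
    """Assembly-process label for one sample pair."""
    if not np.isfinite(bnti) or not np.isfinite(rc):
        raise ValueError("betaNTI and RC_bray must both be defined")
    if abs(rc) > 1:
        raise ValueError("RC_bray outside [-1, +1]")
    if bnti > 2:
        return "variable_selection"
    if bnti < -2:
        return "homogeneous_selection"
    if rc > 0.95:
        return "dispersal_limitation"
    if rc < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def classify_pairs(bnti_results: pd.DataFrame, rc_results: pd.DataFrame) -> pd.DataFrame:
    """Join betaNTI and RC_bray tables on sample pair and label each pair.

    Pairs with undefined betaNTI get label NaN and are excluded from
    fractions (counted separately).
    """
    merged = bnti_results.merge(
        rc_results[["sample_i", "sample_j", "rc_bray"]],
        on=["sample_i", "sample_j"],
        how="inner",
        validate="one_to_one",
    )
    if len(merged) != len(bnti_results):
        raise ValueError("betaNTI and RC_bray tables cover different sample pairs")
    labels = []
    for _, row in merged.iterrows():
        if not np.isfinite(row["bnti"]):
            labels.append(None)
        else:
            labels.append(classify_pair(row["bnti"], row["rc_bray"]))
    merged["process"] = labels
    return merged


def process_fractions(classified: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-site fraction of within-site pairs assigned to each process.

    Fractions are over pairs with a defined label and sum to 1 per site;
    the count of undefined pairs is reported alongside. Sites without any
    within-site pair are skipped with a warning.
    """
    group = metadata["group"]
    rows = []
    for g in pd.unique(group):
        members = set(group.index[group == g])
        mask = classified["sample_i"].isin(members) & classified["sample_j"].isin(members)
        sub = classified.loc[mask]
        if len(sub) == 0:
            logger.warning("group %r has no within-group pairs; skipped", g)
            continue
        defined = sub["process"].notna()
        n_def = int(defined.sum())
        row = {"group": g, "n_pairs": n_def, "n_undefined": int((~defined).sum())}
        for label in PROCESS_LABELS:
            row[label] = (
                float((sub.loc[defined, "process"] == label).mean()) if n_def else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def env_difference_matrix(metadata: pd.DataFrame, variable: str) -> DistanceMatrix:
    """Pairwise absolute differences |v_i - v_j| of one metadata variable.

    Samples with a missing value are dropped (pairwise exclusion happens by
    restricting the matrix to samples with data).
    """
    if variable not in metadata.columns:
        raise KeyError(f"unknown metadata variable {variable!r}")
    v = metadata[variable].dropna()
    if len(v) == 0:
        raise ValueError(f"variable {variable!r} has no recorded values")
    arr = v.to_numpy(dtype=float)
    data = np.abs(arr[:, None] - arr[None, :])
    return DistanceMatrix(data, ids=list(v.index))


def _condensed(dm: DistanceMatrix) -> np.ndarray:
    return squareform(dm.data, checks=False)


def _match(a: DistanceMatrix, b: DistanceMatrix) -> tuple[DistanceMatrix, DistanceMatrix]:
    if set(a.ids) != set(b.ids):
        shared = [i for i in a.ids if i in set(b.ids)]
        if len(shared) < 3:
            raise ValueError("matrices share fewer than 3 samples")
        a = a.filter(shared)
        b = b.filter(shared)
    else:
        b = b.filter(a.ids)
    return a, b


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[float, float]:
    """Mantel test: Pearson r between two distance matrices.

    The permutation null jointly permutes rows and columns of one matrix;
    the one-sided p-value is (1 + #{perm r >= observed r}) / (1 +
    permutations). ``alternative`` may be ``greater``, ``less`` or
    ``two-sided``.
    """
    a, b = _match(a, b)
    n = len(a.ids)
    if n < 3:
        raise ValueError("Mantel test needs at least 3 samples")
    va = _condensed(a)
    vb = _condensed(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("Mantel test undefined for a constant matrix")
    r_obs = float(stats.pearsonr(va, vb)[0])
    rng = np.random.default_rng(seed)
    bmat = b.data
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        vp = squareform(bmat[np.ix_(perm, perm)], checks=False)
        r_p = float(stats.pearsonr(va, vp)[0])
        if alternative == "greater":
            count += r_p >= r_obs
        elif alternative == "less":
            count += r_p <= r_obs
        elif alternative == "two-sided":
            count += abs(r_p) >= abs(r_obs)
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + count) / (1 + permutations)
    return r_obs, float(p)


@dataclass(frozen=True)
class PairwiseRegressionResult:
    slope: float
    intercept: float
    r: float
    r2: float
    p_permutation: float
    p_naive: float
    n_pairs: int


def pairwise_regression(
    x: DistanceMatrix,
    y: DistanceMatrix,
    permutations: int = 999,
    seed: int = 0,
) -> PairwiseRegressionResult:
    """OLS of a pairwise statistic on pairwise environmental differences.

    Both inputs are sample-by-sample matrices; the regression runs on their
    vectorized upper triangles. Because pairs sharing a sample are not
    independent, the reported p-value comes from a Mantel-style permutation
    of sample labels (two-sided on r); the parametric OLS p-value is also
    returned, labelled naive.
    """
    x, y = _match(x, y)
    vx = _condensed(x)
    vy = _condensed(y)
    if vx.size < 3:
        raise ValueError("pairwise regression needs at least 3 pairs")
    if vx.std() == 0:
        raise ValueError("zero variance in the predictor matrix")
    fit = stats.linregress(vx, vy)
    rng = np.random.default_rng(seed)
    n = len(x.ids)
    r_obs = fit.rvalue
    count = 0
    ymat = y.data
    for _ in range(permutations):
        perm = rng.permutation(n)
        vp = squareform(ymat[np.ix_(perm, perm)], checks=False)
        if vp.std() == 0:
            continue
        r_p = float(stats.pearsonr(vx, vp)[0])
        count += abs(r_p) >= abs(r_obs)
    return PairwiseRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        r2=float(fit.rvalue**2),
        p_permutation=float((1 + count) / (1 + permutations)),
        p_naive=float(fit.pvalue),
        n_pairs=int(vx.size),
    )
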