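"""End-to-end pipeline: simulate (or load) -> rarefy -> alpha -> null
deviation -> betaNTI -> RC_bray -> process classification -> environment
linkage -> co-occurrence network.

Every stochastic stage derives its own seed from one master seed via the
fixed offsets in :data:`assemblyscope.io.SEED_OFFSETS`, so a pipeline run
is bit-reproducible and individual stages can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import alpha as alpha_mod
from . import io as asio
from .beta import NullModelConfig, null_deviation, site_null_deviation_summary
from .network import cooccurrence_network, write_graphml
from .phylo import beta_nti, bnti_matrix
from .processes import (
    classify_pairs,
    env_difference_matrix,
    mantel,
    pairwise_regression,
    process_fractions,
)
from .raupcrick import rc_bray

logger = logging.getLogger(__name__)


def run_pipeline(
    table: asio.OtuTable,
    tree,
    metadata: pd.DataFrame,
    outdir,
    seed: int = 0,
    reps: int = 999,
    rarefaction_depth: int | None = 4020,
    env_variable: str = "SOC",
    rho_min: float = 0.6,
    network_alpha: float = 0.05,
    prevalence_min: int = 5,
) -> dict:
    """Run every analysis stage and write TSV/GraphML outputs to ``outdir``.

    Returns a summary dict (also written as ``summary.json``) with the
    per-site null deviations, process fractions, the environment Mantel and
    regression results, and the network topology block.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    off = asio.SEED_OFFSETS
    if rarefaction_depth is not None:
        table = asio.rarefy(table, rarefaction_depth, seed + off["rarefy"])
    table = table.drop_empty_taxa()
    asio.write_otu_table(table, outdir / "table_rarefied.tsv")
    metadata = metadata.loc[[s for s in metadata.index if s in set(table.sample_ids)]]

    alpha_df = alpha_mod.alpha_table(table, tree)
    asio.write_long_table(alpha_df, outdir / "alpha.tsv")

    # null deviation is a within-site statistic: the null-model pool for
    # each site is that site's own samples
    nd_parts = []
    for g in pd.unique(metadata["group"]):
        ids = [s for s in table.sample_ids if metadata.loc[s, "group"] == g]
        if len(ids) < 2:
            logger.warning("site %r has fewer than 2 samples; skipped", g)
            continue
        sub = table.subset_samples(ids).drop_empty_taxa()
        nd_cfg = NullModelConfig(reps=reps, seed=seed + off["null_deviation"])
        nd_parts.append(null_deviation(sub, nd_cfg))
    nd = pd.concat(nd_parts, ignore_index=True)
    asio.write_long_table(nd, outdir / "null_deviation.tsv")
    nd_summary = site_null_deviation_summary(nd, metadata)
    asio.write_long_table(nd_summary, outdir / "null_deviation_by_site.tsv")

    bnti_cfg = NullModelConfig(reps=reps, seed=seed + off["beta_nti"])
    bnti = beta_nti(table, tree, bnti_cfg)
    asio.write_long_table(bnti, outdir / "bnti.tsv")

    rc_cfg = NullModelConfig(reps=reps, seed=seed + off["rc_bray"])
    rc = rc_bray(table, rc_cfg)
    asio.write_long_table(rc, outdir / "rc_bray.tsv")

    classified = classify_pairs(bnti, rc)
    asio.write_long_table(classified, outdir / "processes.tsv")
    fractions = process_fractions(classified, metadata)
    asio.write_long_table(fractions, outdir / "process_fractions.tsv")

    summary: dict = {
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
        "null_deviation_by_site": nd_summary.to_dict(orient="records"),
        "process_fractions": fractions.to_dict(orient="records"),
    }

    if env_variable in metadata.columns and metadata[env_variable].notna().sum() >= 3:
        bm = bnti_matrix(classified, "bnti")
        env_dm = env_difference_matrix(metadata, env_variable)
        r, p = mantel(bm, env_dm, permutations=999, seed=seed + off["mantel"])
        reg = pairwise_regression(
            env_dm, bm, permutations=999, seed=seed + off["regression"]
        )
        asio.write_distance_matrix(bm, outdir / "bnti_matrix.tsv")
        asio.write_distance_matrix(env_dm, outdir / f"{env_variable}_distance.tsv")
        summary["mantel"] = {"variable": env_variable, "r": r, "p": p}
        summary["pairwise_regression"] = {
            "variable": env_variable,
            "slope": reg.slope,
            "r": reg.r,
            "r2": reg.r2,
            "p_permutation": reg.p_permutation,
        }

    # co-occurrence networks are built per site, like the per-site analyses
    topologies = {}
    for g in pd.unique(metadata["group"]):
        ids = [s for s in table.sample_ids if metadata.loc[s, "group"] == g]
        if len(ids) < 4:
            logger.warning("site %r has fewer than 4 samples; network skipped", g)
            continue
        sub = table.subset_samples(ids).drop_empty_taxa()
        net = cooccurrence_network(
            sub, rho_min=rho_min, alpha=network_alpha, prevalence_min=prevalence_min
        )
        if len(net.edges):
            asio.write_long_table(net.edges, outdir / f"network_{g}_edges.tsv")
            asio.write_long_table(net.nodes, outdir / f"network_{g}_nodes.tsv")
            write_graphml(net, outdir / f"network_{g}.graphml")
        topologies[g] = net.topology
    summary["network_topology"] = topologies

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
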