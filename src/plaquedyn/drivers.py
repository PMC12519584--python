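"""Stage-lagged "delta correlation" driver inference.

For a stage transition s -> s+1, each candidate source taxon's stage-s mean
relative abundance (per subject) is rank-correlated with each candidate
target taxon's abundance *change* into stage s+1 (stage-(s+1) mean minus
stage-s mean, per subject).  Positive, FDR-significant correlations are read
as directed driver edges: more of A in stage s predicts growth of B into
stage s+1.  Also provides the generic paired-table cross-correlation used
for module-by-function association.
"""
from __future__ import annotations

import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from .core_io import CommunityTable, to_relative

logger = logging.getLogger("plaquedyn")

__all__ = [
    "stage_means",
    "stage_delta",
    "delta_correlation",
    "infer_driver_edges",
    "paired_feature_correlation",
    "export_network",
    "read_network",
]


def stage_means(
    table: CommunityTable, metadata: pd.DataFrame, stage_partition: pd.Series
) -> dict[str, pd.DataFrame]:
    """Per-subject arithmetic mean of relative abundances within each stage.

    Returns ``{stage: subjects x taxa frame}``; subjects with no sample in a
    stage are omitted from that stage's frame.
    """
    rel = table if table.is_relative else to_relative(table)
    md = metadata.set_index("sample_id")
    md = md[md.index.isin(rel.samples)]
    stages = sorted(set(stage_partition.values))
    out: dict[str, pd.DataFrame] = {}
    for stage in stages:
        tps = set(stage_partition.index[stage_partition == stage])
        sel = md[md["timepoint"].isin(tps)]
        if len(sel) == 0:
            raise ValueError(f"stage {stage!r} has no samples")
        frames = {}
        for subject, grp in sel.groupby("subject_id"):
            frames[subject] = rel.data[list(grp.index)].mean(axis=1)
        out[stage] = pd.DataFrame(frames).T  # subjects x taxa
        out[stage].index.name = "subject_id"
    return out


def stage_delta(stage_s: pd.DataFrame, stage_s1: pd.DataFrame) -> pd.DataFrame:
    """Per-subject abundance change between consecutive stages.

    Restricted to subjects present in both stages; fewer than 3 shared
    subjects is an error.
    """
    shared = stage_s.index.intersection(stage_s1.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} subjects shared between stages (need >= 3)")
    taxa = stage_s.columns.intersection(stage_s1.columns)
    return stage_s1.loc[shared, taxa] - stage_s.loc[shared, taxa]


@lru_cache(maxsize=16)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (ties handled by
    permuting the observed average ranks)."""
    rx = rankdata(x)
    ry = rankdata(y)
    perms = _perm_matrix(len(x))
    ryp = ry[perms]  # all permutations of y's ranks
    rxc = rx - rx.mean()
    ryc = ryp - ryp.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum(axis=1))
    rhos = (ryc @ rxc) / denom
    return float((np.abs(rhos) >= abs(rho_obs) - 1e-12).mean())


def delta_correlation(
    source_abund: pd.DataFrame,
    target_delta: pd.DataFrame,
    exact_max_n: int = 9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of every source's stage abundance with every
    target's stage delta across subjects.

    Returns (rho, p) frames of shape sources x targets.  P-values use the
    t approximation, switching to the exact permutation null when the number
    of subjects is <= ``exact_max_n``.  Constant vectors give NaN (flagged
    undefined and excluded from later testing).
    """
    if list(source_abund.index) != list(target_delta.index):
        shared = source_abund.index.intersection(target_delta.index)
        if len(shared) != len(source_abund.index) or len(shared) != len(target_delta.index):
            raise ValueError("source and target frames must be aligned on the same subjects")
        target_delta = target_delta.loc[source_abund.index]
    n = len(source_abund.index)
    if n < 5:
        logger.warning("only %d subjects; delta correlations will be underpowered", n)
    rho = pd.DataFrame(
        np.nan, index=source_abund.columns, columns=target_delta.columns, dtype=float
    )
    pval = rho.copy()
    exact = n <= exact_max_n
    for a in source_abund.columns:
        x = source_abund[a].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        for b in target_delta.columns:
            y = target_delta[b].to_numpy(dtype=float)
            if np.std(y) == 0:
                continue
            r, p = spearmanr(x, y)
            if exact:
                p = _exact_spearman_p(x, y, r)
            rho.loc[a, b] = r
            pval.loc[a, b] = p
    return rho, pval


def infer_driver_edges(
    rho: pd.DataFrame,
    pval: pd.DataFrame,
    transition: str,
    n_subjects: int,
    alpha: float = 0.05,
    fdr: bool = True,
) -> pd.DataFrame:
    """Directed driver edges for one transition.

    BH adjustment runs across all tested (source, target) pairs of the
    transition; edges are retained when rho > 0 and q < alpha, sorted by q
    then descending rho.  Empty input yields an empty frame.
    """
    r = rho.rename_axis(index="source", columns="target")
    pv = pval.rename_axis(index="source", columns="target")
    tidy = r.stack().rename("rho").to_frame().join(pv.stack().rename("p")).reset_index()
    tidy = tidy.dropna(subset=["rho", "p"])
    cols = ["source", "target", "transition", "rho", "p", "q", "n"]
    if len(tidy) == 0:
        return pd.DataFrame(columns=cols)
    if fdr:
        tidy["q"] = multipletests(tidy["p"], method="fdr_bh")[1]
    else:
        tidy["q"] = tidy["p"]
    edges = tidy[(tidy["rho"] > 0) & (tidy["q"] < alpha)].copy()
    edges["transition"] = transition
    edges["n"] = n_subjects
    edges = edges.sort_values(["q", "rho"], ascending=[True, False]).reset_index(drop=True)
    return edges[cols]


def paired_feature_correlation(
    tableX: pd.DataFrame, tableY: pd.DataFrame, method: str = "spearman"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-correlation of rows of X against rows of Y over shared columns.

    X and Y are feature-by-unit frames (e.g. module mean abundances and
    functional-entry expression over the same samples).  Returns (rho, p)
    frames of shape X-features x Y-features with two-sided p-values.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    shared = tableX.columns.intersection(tableY.columns)
    if len(shared) == 0:
        raise ValueError("no shared units between the two tables")
    if len(shared) < 4:
        logger.warning("only %d shared units; correlations will be unstable", len(shared))
    X = tableX[shared].to_numpy(dtype=float)
    Y = tableY[shared].to_numpy(dtype=float)
    n = len(shared)
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
        Y = np.apply_along_axis(rankdata, 1, Y)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sx = np.sqrt((Xc**2).sum(axis=1))
    sy = np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Yc.T) / np.outer(sx, sy)
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = R * np.sqrt((n - 2) / (1.0 - R**2))
    from scipy.stats import t as t_dist

    P = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    P = np.where(np.abs(R) >= 1.0, 0.0, P)
    P = np.where(np.isnan(R), np.nan, P)
    rho = pd.DataFrame(R, index=tableX.index, columns=tableY.index)
    pval = pd.DataFrame(P, index=tableX.index, columns=tableY.index)
    return rho, pval


def export_network(edges: pd.DataFrame, path, fmt: str = "tsv") -> None:
    """Write the driver edge list as TSV or GraphML (directed, attributed)."""
    if fmt == "tsv":
        edges.to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        G = nx.DiGraph()
        for _, row in edges.iterrows():
            G.add_edge(
                row["source"], row["target"],
                transition=str(row["transition"]), rho=float(row["rho"]),
                p=float(row["p"]), q=float(row["q"]), n=int(row["n"]),
            )
        nx.write_graphml(G, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_network(path) -> pd.DataFrame:
    """Read a TSV edge list written by :func:`export_network` (lossless)."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "transition": str})
    if len(df) == 0:
        df = pd.DataFrame(columns=["source", "target", "transition", "rho", "p", "q", "n"])
    return df
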