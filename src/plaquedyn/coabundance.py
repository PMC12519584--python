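"""Covariant species modules: soft-threshold correlation network, topological
overlap, hierarchical module detection, representative profiles, and
module-timepoint / stage association.

The detection route follows the weighted co-expression network recipe:
taxon-taxon correlation -> soft-threshold adjacency (|r|^power, default
power 12) -> topological overlap matrix (TOM) -> average-linkage clustering
of 1 - TOM -> static tree cut (a 4-level height ladder standing in for the
dynamic split-sensitivity setting) -> size filter (default 7) -> modules
relabeled by size and named with the standard ordered color palette.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata
from skbio import DistanceMatrix

from .core_io import CommunityTable, stage_of_hours

logger = logging.getLogger("plaquedyn")

__all__ = [
    "WGCNA_COLORS",
    "correlation_matrix",
    "adjacency",
    "tom_similarity",
    "ModuleSet",
    "detect_modules",
    "module_profile",
    "module_time_association",
    "assign_stages",
    "CUT_HEIGHTS",
]

#: standard ordered module color palette; module ids are size-ranked
WGCNA_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue",
]

#: static tree-cut heights; deeper split levels cut lower
CUT_HEIGHTS = {1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80}


def correlation_matrix(table: CommunityTable, method: str = "pearson") -> pd.DataFrame:
    """Taxon x taxon correlation across samples (diagonal 1).

    Constant taxa are flagged and given 0 off-diagonal correlation rather
    than NaN so the downstream adjacency stays well defined.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    X = table.values
    if X.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant taxa assigned correlation 0", int(constant.sum()))
    Xs = X.copy()
    Xs[constant] = np.random.default_rng(0).normal(size=(int(constant.sum()), X.shape[1]))
    C = np.corrcoef(Xs)
    C[constant, :] = 0.0
    C[:, constant] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=table.taxa, columns=table.taxa)


def adjacency(cor: pd.DataFrame, power: float = 12, signed: bool = False) -> pd.DataFrame:
    """Soft-threshold adjacency: |r|^power (unsigned) or ((1+r)/2)^power (signed)."""
    if power < 1:
        raise ValueError("power must be >= 1")
    C = cor.to_numpy(dtype=float)
    A = ((1.0 + C) / 2.0) ** power if signed else np.abs(C) ** power
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=cor.index, columns=cor.columns)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), with
    k_i the node connectivity; TOM_ii = 1.  Values stay in [0, 1]; the
    clustering dissimilarity is 1 - TOM.
    """
    A = adj.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < 0 or A.max() > 1 or np.abs(np.diag(A)).max() > 0:
        raise ValueError("adjacency values must lie in [0,1] with zero diagonal")
    k = A.sum(axis=1)
    num = A @ A + A
    den = np.minimum.outer(k, k) + 1.0 - A
    T = num / den
    np.fill_diagonal(T, 1.0)
    return pd.DataFrame(T, index=adj.index, columns=adj.columns)


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned/grey) with size-ranked color names."""

    labels: pd.Series  # taxon -> module id (int, 0 unassigned)
    colors: dict[int, str]
    params: dict = field(default_factory=dict)

    @property
    def module_ids(self) -> list[int]:
        return sorted(i for i in self.labels.unique() if i != 0)

    def members(self, module_id: int) -> list[str]:
        return list(self.labels.index[self.labels == module_id])

    def color_labels(self) -> pd.Series:
        return self.labels.map(self.colors).rename("module_color")


def detect_modules(tom_dissim: pd.DataFrame, min_size: int = 7, split_depth: int = 4) -> ModuleSet:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The tree is cut at the height ladder {0.95, 0.90, 0.85, 0.80} indexed by
    ``split_depth`` 1..4 (deeper splits cut lower); clusters smaller than
    ``min_size`` fall into module 0.  Modules are relabeled by decreasing
    size and given the standard color names.
    """
    n = tom_dissim.shape[0]
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if min_size > n:
        raise ValueError("min_size exceeds number of taxa")
    if split_depth not in CUT_HEIGHTS:
        raise ValueError(f"split_depth must be in {sorted(CUT_HEIGHTS)}")
    Dm = tom_dissim.to_numpy(dtype=float)
    Dm = 0.5 * (Dm + Dm.T)
    np.fill_diagonal(Dm, 0.0)
    Z = linkage(squareform(Dm, checks=False), method="average")
    raw = fcluster(Z, t=CUT_HEIGHTS[split_depth], criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = [int(c) for c in sizes.index if sizes[c] >= min_size]
    # size-descending, tie-broken by the cluster's first taxon name for determinism
    first_taxon = {c: min(tom_dissim.index[raw == c]) for c in keep}
    keep.sort(key=lambda c: (-sizes[c], first_taxon[c]))
    remap = {c: i + 1 for i, c in enumerate(keep)}
    labels = pd.Series(
        [remap.get(int(c), 0) for c in raw], index=tom_dissim.index, name="module"
    )
    colors = {0: "grey"}
    for i in range(len(keep)):
        colors[i + 1] = WGCNA_COLORS[i] if i < len(WGCNA_COLORS) else f"module{i + 1}"
    return ModuleSet(labels, colors, {"min_size": min_size, "split_depth": split_depth})


def module_profile(table: CommunityTable, labels: pd.Series) -> tuple[pd.DataFrame, set[int]]:
    """Representative (eigentaxon-style) profile per module.

    First principal component of the standardized member x sample matrix,
    sign-oriented to correlate positively with the members' mean standardized
    profile, rescaled to unit variance.  Modules whose members are all
    constant are flagged degenerate and returned as NaN rows.
    """
    profiles, degenerate = {}, set()
    for mid in sorted(i for i in labels.unique() if i != 0):
        members = labels.index[labels == mid]
        if len(members) < 2:
            raise ValueError(f"module {mid} has fewer than 2 members")
        X = table.data.loc[members].to_numpy(dtype=float)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        ok = sd[:, 0] > 0
        if not ok.any():
            degenerate.add(int(mid))
            profiles[mid] = np.full(X.shape[1], np.nan)
            continue
        Xs = (X[ok] - mu[ok]) / sd[ok]
        _, _, vt = np.linalg.svd(Xs, full_matrices=False)
        pc = vt[0]
        mean_profile = Xs.mean(axis=0)
        if np.dot(pc, mean_profile) < 0:
            pc = -pc
        pc = (pc - pc.mean()) / pc.std()
        profiles[mid] = pc
    out = pd.DataFrame(profiles, index=table.samples).T
    out.index.name = "module"
    return out, degenerate


def module_time_association(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame,
    stage_partition: pd.Series | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlate module profiles with timepoint indicators across samples.

    For every (module, timepoint) pair: Pearson r between the profile and the
    timepoint's 0/1 indicator, with two-sided p.  Each module's stage is the
    stage containing its most positively associated timepoint.  Timepoints
    with fewer than 2 samples are excluded with a warning; constant profiles
    yield NaN correlations.
    """
    md = metadata.set_index("sample_id").loc[list(profiles.columns)]
    rows = []
    for tp, grp in md.groupby("timepoint", sort=False):
        if len(grp) < 2:
            logger.warning("timepoint %s has < 2 samples; excluded from association", tp)
            continue
        indicator = md.index.isin(grp.index).astype(float)
        hours = float(grp["hours"].iloc[0])
        for mid, prof in profiles.iterrows():
            v = prof.to_numpy(dtype=float)
            if np.isnan(v).any() or v.std() == 0 or indicator.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = pearsonr(v, indicator)
            rows.append(
                {"module": mid, "timepoint": tp, "hours": hours, "r": r, "p": p,
                 "significant": bool(p < alpha) if p == p else False}
            )
    assoc = pd.DataFrame(
        rows, columns=["module", "timepoint", "hours", "r", "p", "significant"]
    )
    if len(assoc) == 0:
        return assoc, pd.Series(dtype=object, name="stage")
    if stage_partition is None:
        stage_partition = pd.Series(
            {tp: stage_of_hours(h) for tp, h in assoc.groupby("timepoint")["hours"].first().items()}
        )
    stages = {}
    for mid, grp in assoc.groupby("module"):
        grp = grp.dropna(subset=["r"])
        pos = grp[grp["r"] > 0]
        if len(pos) == 0:
            stages[mid] = "none"
            continue
        best_tp = pos.loc[pos["r"].idxmax(), "timepoint"]
        stages[mid] = stage_partition.get(best_tp, "none")
    return assoc, pd.Series(stages, name="stage")


def _contiguous_cluster(hours: np.ndarray, Dtp: np.ndarray, n_groups: int = 3) -> list[int]:
    """Agglomerate time-ordered timepoints, merging only adjacent clusters by
    average inter-cluster distance, until ``n_groups`` remain."""
    clusters: list[list[int]] = [[i] for i in range(len(hours))]
    while len(clusters) > n_groups:
        costs = []
        for i in range(len(clusters) - 1):
            a, b = clusters[i], clusters[i + 1]
            costs.append(np.mean([Dtp[x, y] for x in a for y in b]))
        i = int(np.argmin(costs))
        clusters[i] = clusters[i] + clusters[i + 1]
        del clusters[i + 1]
    out = np.empty(len(hours), dtype=int)
    for g, cl in enumerate(clusters):
        for i in cl:
            out[i] = g
    return list(out)


def assign_stages(
    metadata: pd.DataFrame,
    mode: str = "fixed",
    distance_matrix: DistanceMatrix | None = None,
) -> pd.Series:
    """Partition post-perturbation timepoints into early / middle / late.

    ``fixed`` applies the printed schedule split (early <= 7 h, middle
    through 1 week, late from 2 weeks); ``cluster`` groups timepoint
    centroids of the community distance matrix into 3 contiguous-in-time
    groups by constrained average-linkage agglomeration.
    """
    if mode not in ("fixed", "cluster"):
        raise ValueError(f"unknown mode {mode!r}")
    tps = (
        metadata[metadata["hours"] >= 0][["timepoint", "hours"]]
        .drop_duplicates()
        .sort_values("hours")
        .reset_index(drop=True)
    )
    if mode == "fixed":
        return pd.Series(
            [stage_of_hours(h) for h in tps["hours"]], index=tps["timepoint"], name="stage"
        )
    if len(tps) < 3:
        raise ValueError("cluster mode needs >= 3 post-perturbation timepoints")
    if distance_matrix is None:
        raise ValueError("cluster mode requires a sample distance matrix")
    md = metadata.set_index("sample_id")
    md = md[md.index.isin(distance_matrix.ids)]
    ids_of = {tp: list(md.index[md["timepoint"] == tp]) for tp in tps["timepoint"]}
    n = len(tps)
    Dtp = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids_of[tps["timepoint"][i]], ids_of[tps["timepoint"][j]]
            Dtp[i, j] = Dtp[j, i] = np.mean(
                [distance_matrix[x, y] for x in a for y in b]
            )
    groups = _contiguous_cluster(tps["hours"].to_numpy(), Dtp)
    names = ["early", "middle", "late"]
    return pd.Series(
        [names[g] for g in groups], index=tps["timepoint"], name="stage"
    )
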