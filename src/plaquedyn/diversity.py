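"""Recovery-trajectory statistics: Shannon diversity, weighted UniFrac, PCoA,
and the per-timepoint paired distance to each subject's baseline sample.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import t as t_dist
from skbio import DistanceMatrix, TreeNode

from .core_io import CommunityTable, DegenerateSampleError, to_relative

logger = logging.getLogger("plaquedyn")

__all__ = [
    "shannon",
    "weighted_unifrac",
    "distance_matrix",
    "Ordination",
    "pcoa",
    "baseline_trajectory",
    "branch_decomposition",
]


def shannon(counts, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i (bits by default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise DegenerateSampleError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def branch_decomposition(tree: TreeNode, taxa: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch tip membership over ``taxa``.

    Returns ``(lengths, membership)`` where ``membership[b, j]`` marks taxon j
    descending from branch b.  Zero-length branches are skipped (they cannot
    contribute to any branch-length-weighted metric).
    """
    idx = {t: i for i, t in enumerate(taxa)}
    memb: dict[int, np.ndarray] = {}
    rows, lengths = [], []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            v = np.zeros(len(taxa), dtype=bool)
            if node.name in idx:
                v[idx[node.name]] = True
        else:
            v = np.zeros(len(taxa), dtype=bool)
            for child in node.children:
                v |= memb[id(child)]
        memb[id(node)] = v
        if node.parent is not None and node.length:
            rows.append(v.copy())
            lengths.append(float(node.length))
    return np.asarray(lengths), np.asarray(rows)


def _as_rel_vector(sample, taxa: list[str]) -> np.ndarray:
    if isinstance(sample, dict):
        sample = pd.Series(sample)
    if isinstance(sample, pd.Series):
        v = sample.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
    else:
        v = np.asarray(sample, dtype=float)
        if v.shape != (len(taxa),):
            raise ValueError("sample vector length does not match taxa")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError("weighted UniFrac requires relative-abundance vectors summing to 1")
    return v


def weighted_unifrac(tree: TreeNode, sample_a, sample_b, normalized: bool = True) -> float:
    """Weighted UniFrac distance between two relative-abundance communities.

    Raw form sums ``l_b * |p_a(b) - p_b(b)|`` over branches, where ``p_x(b)``
    is the fraction of community x descending from branch b.  The normalized
    form divides by ``sum_j d_j (a_j + b_j)`` with ``d_j`` the root-to-tip
    distance, bounding the result to [0, 1].
    """
    taxa = [t.name for t in tree.tips()]
    a = _as_rel_vector(sample_a, taxa)
    b = _as_rel_vector(sample_b, taxa)
    lengths, memb = branch_decomposition(tree, taxa)
    raw = float(lengths @ np.abs(memb @ (a - b)))
    if not normalized:
        return raw
    depth = lengths @ memb  # root-to-tip distance per taxon
    denom = float(depth @ (a + b))
    return raw / denom if denom > 0 else 0.0


def distance_matrix(
    table: CommunityTable, tree: TreeNode | None = None, metric: str = "weighted_unifrac",
    normalized: bool = True,
) -> DistanceMatrix:
    """All pairwise sample distances under weighted UniFrac or Bray-Curtis."""
    rel = table if table.is_relative else to_relative(table)
    A = rel.values  # taxa x samples
    ids = rel.samples
    if metric == "bray_curtis":
        D = squareform(pdist(A.T, metric="braycurtis"))
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted_unifrac requires a tree")
        tips = {t.name for t in tree.tips()}
        if not set(rel.taxa) <= tips:
            raise ValueError("table taxa missing from tree; align the dataset first")
        lengths, memb = branch_decomposition(tree, rel.taxa)
        B = memb @ A  # branch x samples proportions
        depth = lengths @ memb
        d_tot = depth @ A  # per-sample abundance-weighted root-to-tip depth
        n = len(ids)
        D = np.zeros((n, n))
        for i in range(n):
            raw = lengths @ np.abs(B - B[:, [i]])
            if normalized:
                denom = d_tot + d_tot[i]
                with np.errstate(invalid="ignore", divide="ignore"):
                    row = np.where(denom > 0, raw / denom, 0.0)
            else:
                row = raw
            D[i] = row
        D = 0.5 * (D + D.T)  # exact symmetry against fp noise
        np.fill_diagonal(D, 0.0)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(D, ids=ids)


@dataclass
class Ordination:
    """PCoA result: sample coordinates on axes ordered by eigenvalue."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(D: DistanceMatrix, k: int = 2) -> Ordination:
    """Classical metric multidimensional scaling (Gower double-centering).

    Axes use positive eigenvalues only; negative eigenvalues (non-Euclidean
    input) are reported but never embedded.  ``k`` larger than the positive
    spectrum is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    M = D.data if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    ids = list(D.ids) if isinstance(D, DistanceMatrix) else [str(i) for i in range(len(M))]
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-12
    n_pos = int((eigvals > tol).sum())
    k_eff = min(k, n_pos)
    if k_eff < k:
        warnings.warn(f"only {n_pos} positive eigenvalues; truncating k={k} to {k_eff}")
    if k_eff == 0:
        coords = np.zeros((n, k))
        k_eff = k
    else:
        coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    pos_sum = eigvals[eigvals > tol].sum()
    prop = (eigvals[:n_pos] / pos_sum) if pos_sum > 0 else np.zeros(0)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return Ordination(pd.DataFrame(coords, index=ids, columns=cols), eigvals, prop)


def baseline_trajectory(D: DistanceMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Mean paired distance to each subject's pre-scaling baseline, by timepoint.

    For every post-baseline timepoint, collects distance(sample_t,
    sample_baseline) within each subject and reports the mean with a
    Student-t 95% CI.  Subjects lacking a baseline sample are excluded with a
    warning; if none has one, raises ``ValueError``.
    """
    md = metadata.set_index("sample_id")
    md = md[md.index.isin(D.ids)]
    base_of: dict[str, str] = {}
    for subject, grp in md.groupby("subject_id"):
        base = grp[grp["hours"] < 0]
        if len(base) == 0:
            logger.warning("subject %s has no baseline sample; excluded", subject)
            continue
        base_of[subject] = base.index[0]
    if not base_of:
        raise ValueError("no subject has a baseline (pre-scaling) sample")

    post = md[md["hours"] >= 0]
    rows = []
    for (tp, hours), grp in post.groupby(["timepoint", "hours"], sort=False):
        dists = []
        for sid, row in grp.iterrows():
            b = base_of.get(row["subject_id"])
            if b is None:
                continue
            dists.append(D[sid, b])
        if not dists:
            continue
        d = np.asarray(dists)
        n = len(d)
        mean = d.mean()
        if n > 1 and d.std(ddof=1) > 0:
            half = t_dist.ppf(0.975, n - 1) * d.std(ddof=1) / np.sqrt(n)
        else:
            half = 0.0
            if n == 1:
                logger.warning("timepoint %s has a single paired distance; CI degenerate", tp)
        rows.append(
            {"timepoint": tp, "hours": hours, "mean": mean,
             "ci_low": mean - half, "ci_high": mean + half, "n": n}
        )
    out = pd.DataFrame(rows).sort_values("hours").reset_index(drop=True)
    return out
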