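"""Ecological community-assembly inference via phylogenetic null models.

Implements abundance-weighted between-community mean nearest taxon distance
(betaMNTD), its standardized effect size against a tip-shuffle null (betaNTI),
the abundance-based Raup-Crick null on Bray-Curtis (RC-bray), and the
five-way partition of pairwise assembly processes:

* betaNTI < -2  -> homogeneous selection
* betaNTI > +2  -> variable selection
* |betaNTI| <= 2 and RC > +0.95  -> dispersal limitation
* |betaNTI| <= 2 and RC < -0.95  -> homogenizing dispersal
* otherwise                      -> undominated

The betaNTI null randomizes each community's taxon positions on the
phylogeny independently per iteration (abundances fixed, tip labels
shuffled), so that even identical communities are scored against a
dispersed-null expectation.  The RC null reassembles each sample preserving
its richness and total abundance, drawing species with probability
proportional to their occupancy frequency across the table and individuals
proportional to mean relative abundance.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis
from skbio import TreeNode

from .core_io import CommunityTable, DegenerateSampleError, to_relative

logger = logging.getLogger("plaquedyn")

__all__ = [
    "PROCESSES",
    "patristic_matrix",
    "bmntd",
    "bnti",
    "raup_crick_bray",
    "partition_processes",
    "assembly_analysis",
]

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)


def patristic_matrix(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Tip-to-tip (patristic) distance matrix ordered like ``taxa``."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(idx, idx)]


def _bmntd_from_dist(D: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> float:
    ia = np.flatnonzero(fa > 0)
    ib = np.flatnonzero(fb > 0)
    if ia.size == 0 or ib.size == 0:
        raise DegenerateSampleError("empty community in betaMNTD")
    da = D[np.ix_(ia, ib)].min(axis=1)  # nearest neighbour in b for each taxon of a
    db = D[np.ix_(ib, ia)].min(axis=1)
    return 0.5 * float(fa[ia] @ da + fb[ib] @ db)


def bmntd(tree: TreeNode, rel_a, rel_b) -> float:
    """Abundance-weighted betaMNTD between two relative-abundance communities.

    Taxa shared by both communities contribute zero nearest-taxon distance to
    their own term, so identical communities score 0.
    """
    taxa = [t.name for t in tree.tips()]

    def vec(x):
        if isinstance(x, dict):
            x = pd.Series(x)
        if isinstance(x, pd.Series):
            return x.reindex(taxa).fillna(0.0).to_numpy(dtype=float)
        v = np.asarray(x, dtype=float)
        if v.shape != (len(taxa),):
            raise ValueError("community vector length does not match tree tips")
        return v

    D = patristic_matrix(tree, taxa)
    return _bmntd_from_dist(D, vec(rel_a), vec(rel_b))


def bnti(
    tree: TreeNode,
    table: CommunityTable,
    pairs: list[tuple[str, str]],
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """betaNTI for sample pairs: SES of betaMNTD under a tip-shuffle null.

    Each null iteration draws an independent permutation of taxon positions
    for every sample involved and recomputes betaMNTD.  Pairs whose null
    standard deviation vanishes get ``bnti = NaN`` (undefined flag), never
    +/-inf.  Deterministic under ``seed``.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99 for a usable null distribution")
    rel = table if table.is_relative else to_relative(table)
    taxa = sorted(rel.taxa)  # canonical order: results do not depend on row order
    D = patristic_matrix(tree, taxa)
    A = rel.data.loc[taxa]
    samples = sorted({s for p in pairs for s in p})
    vec = {s: A[s].to_numpy(dtype=float) for s in samples}
    pres = {s: np.flatnonzero(vec[s] > 0) for s in samples}

    observed = np.array([_bmntd_from_dist(D, vec[a], vec[b]) for a, b in pairs])

    rng = np.random.default_rng(int(seed))
    n_tax = len(taxa)
    nulls = np.empty((n_null, len(pairs)))
    for it in range(n_null):
        perm = {s: rng.permutation(n_tax) for s in samples}
        for k, (a, b) in enumerate(pairs):
            pa, pb = perm[a][pres[a]], perm[b][pres[b]]
            sub = D[np.ix_(pa, pb)]
            fa, fb = vec[a][pres[a]], vec[b][pres[b]]
            nulls[it, k] = 0.5 * (fa @ sub.min(axis=1) + fb @ sub.min(axis=0))

    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ses = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    return pd.DataFrame(
        {
            "sample_i": [a for a, _ in pairs],
            "sample_j": [b for _, b in pairs],
            "bmntd_obs": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "bnti": ses,
            "n_null": n_null,
        }
    )


def _as_counts(table: CommunityTable, total: int = 10_000) -> np.ndarray:
    """Integer count matrix; relative tables are scaled to ``total`` reads
    with presence preserved (every positive relative abundance keeps >= 1)."""
    vals = table.values
    if np.all(np.mod(vals, 1) == 0) and not table.is_relative:
        return vals.astype(np.int64)
    rel = vals / vals.sum(axis=0, keepdims=True)
    counts = np.rint(rel * total).astype(np.int64)
    counts[(rel > 0) & (counts == 0)] = 1
    return counts


def raup_crick_bray(
    table: CommunityTable,
    pair: tuple[str, str],
    n_null: int = 999,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Abundance-based Raup-Crick deviation of Bray-Curtis for one pair.

    Null communities preserve each sample's observed richness and total
    abundance; species enter with probability proportional to their occupancy
    frequency across the whole table, then remaining individuals are assigned
    multinomially in proportion to species' mean relative abundances.
    ``rc = 2 * ((n_less + 0.5 * n_ties) / n_null - 0.5)`` lies in [-1, 1].
    """
    if len(table.samples) < 2:
        raise ValueError("Raup-Crick needs >= 2 samples to define occupancy frequencies")
    if rng is None:
        rng = np.random.default_rng(int(seed))
    counts = _as_counts(table)
    occupancy = (counts > 0).mean(axis=1)
    rel = counts / counts.sum(axis=0, keepdims=True)
    mean_rel = rel.mean(axis=1)
    col = {s: i for i, s in enumerate(table.samples)}
    ia, ib = col[pair[0]], col[pair[1]]
    obs = braycurtis(counts[:, ia], counts[:, ib])

    p_occ = occupancy / occupancy.sum()
    n_tax = counts.shape[0]

    def null_sample(j: int) -> np.ndarray:
        r = int((counts[:, j] > 0).sum())
        N = int(counts[:, j].sum())
        chosen = rng.choice(n_tax, size=r, replace=False, p=p_occ)
        out = np.zeros(n_tax, dtype=np.int64)
        out[chosen] = 1
        if N > r:
            w = mean_rel[chosen]
            w = w / w.sum() if w.sum() > 0 else np.full(r, 1.0 / r)
            out[chosen] += rng.multinomial(N - r, w)
        return out

    null_bc = np.empty(n_null)
    for it in range(n_null):
        null_bc[it] = braycurtis(null_sample(ia), null_sample(ib))
    n_less = int((null_bc < obs - 1e-12).sum())
    n_ties = int((np.abs(null_bc - obs) <= 1e-12).sum())
    rc = 2.0 * ((n_less + 0.5 * n_ties) / n_null - 0.5)
    return {"sample_i": pair[0], "sample_j": pair[1], "bray_obs": obs, "rc": rc, "n_null": n_null}


def partition_processes(
    results: pd.DataFrame,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Assign the five-way ecological process to every pair.

    ``results`` needs a ``bnti`` column and, for pairs with
    ``|bnti| <= bnti_threshold``, an ``rc`` column; a missing RC there raises
    a ``ValueError`` naming the pair.  If a ``timepoint`` column is present,
    per-timepoint process proportions (summing to 1) are returned as well.
    """
    df = results.copy()
    procs = []
    for _, row in df.iterrows():
        b = row["bnti"]
        if pd.isna(b):
            procs.append("undefined")
            continue
        if b < -bnti_threshold:
            procs.append("homogeneous_selection")
        elif b > bnti_threshold:
            procs.append("variable_selection")
        else:
            rc = row.get("rc", np.nan)
            if pd.isna(rc):
                raise ValueError(
                    f"pair ({row['sample_i']}, {row['sample_j']}) needs an RC value "
                    f"(|bnti| <= {bnti_threshold}) but none was given"
                )
            if rc > rc_threshold:
                procs.append("dispersal_limitation")
            elif rc < -rc_threshold:
                procs.append("homogenizing_dispersal")
            else:
                procs.append("undominated")
    df["process"] = procs

    proportions = None
    if "timepoint" in df.columns:
        rows = []
        for tp, grp in df[df["process"] != "undefined"].groupby("timepoint", sort=False):
            frac = grp["process"].value_counts(normalize=True)
            rows.append({"timepoint": tp, **{p: float(frac.get(p, 0.0)) for p in PROCESSES}})
        proportions = pd.DataFrame(rows)
    return df, proportions


def assembly_analysis(
    table: CommunityTable,
    tree: TreeNode,
    metadata: pd.DataFrame,
    n_null: int = 999,
    rc_n_null: int | None = None,
    seed: int = 0,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Full per-timepoint assembly partition over within-timepoint subject pairs."""
    rc_n_null = rc_n_null or n_null
    md = metadata.set_index("sample_id")
    pairs, tp_of_pair = [], []
    for tp, grp in md.groupby("timepoint", sort=False):
        ids = [s for s in grp.index if s in set(table.samples)]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                pairs.append((ids[i], ids[j]))
                tp_of_pair.append(tp)
    res = bnti(tree, table, pairs, n_null=n_null, seed=seed)
    res["timepoint"] = tp_of_pair

    rng = np.random.default_rng(int(seed) + 1)
    rc_vals = np.full(len(res), np.nan)
    need = res.index[res["bnti"].abs() <= bnti_threshold]
    for i in need:
        rc_vals[i] = raup_crick_bray(
            table, (res.at[i, "sample_i"], res.at[i, "sample_j"]), n_null=rc_n_null, rng=rng
        )["rc"]
    res["rc"] = rc_vals
    return partition_processes(res, bnti_threshold, rc_threshold)
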