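"""Synthetic longitudinal plaque communities with planted structure.

Emulates the study design the pipeline targets: ~30 subjects sampled at 12
timepoints (pre-scaling baseline plus 0, 1, 4, 7 h; 1, 3, 7, 14 d; 1, 3 mo;
1 y), 100-200 taxa on a pure-birth phylogeny, compositional counts at a fixed
sequencing depth, a perturbation at t0 with staged recovery, covariant taxon
modules peaking in the early / middle / late reconstruction stages, optional
phylogenetically clustered ("selection") community draws, and planted
cross-stage driver effects.  Every downstream inference step can therefore be
scored against known truth.

Latent model
------------
Each taxon gets a lognormal baseline weight (sigma=1, shared across
subjects), multiplied by a per-subject lognormal effect (sd ``noise_sd``) and
by its module's stage-shaped multiplier: a piecewise-linear tent on the
log10(1+hours) axis.  Early/middle modules bloom (1 + a * tent), late modules
dip and return to baseline (1 - a * tent, exactly back to 1 at the final
timepoint).  Driver effects add ``gamma * (subject's source latent stage-s
mean)`` to the target's latent abundance at every stage s+1 timepoint, after
which columns renormalize.  Observation draws a per-sample lognormal noise
factor per taxon and then multinomial counts at the configured depth.
"""
from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import TreeNode

from .core_io import (
    BASELINE_HOURS,
    BASELINE_LABEL,
    TIMEPOINT_HOURS,
    CommunityTable,
    stage_of_hours,
    write_metadata,
    write_table,
    write_tree,
)

__all__ = [
    "ModuleSpec",
    "DriverSpec",
    "ScenarioConfig",
    "GroundTruth",
    "simulate_tree",
    "simulate_recovery_series",
    "simulate_assembly_pair_set",
    "correlated_blocks",
    "driver_benchmark_config",
    "write_scenario",
]

#: (start_h, peak_h, end_h) of the tent multiplier for each module stage;
#: early blooms fade by day 1, middle blooms span day 1 - week 2, and late
#: modules dip to their nadir at 72 h (day 3, the planted maximal
#: disruption), recovering fully by month 3 and holding baseline thereafter.
TENT_PARAMS: dict[str, tuple[float, float, float]] = {
    "early": (0.0, 4.0, 24.0),
    "middle": (7.0, 72.0, 336.0),
    "late": (0.0, 72.0, 2160.0),
}

#: which stage transitions a driver may span (adjacent stages only)
ADJACENT_TRANSITIONS = (("early", "middle"), ("middle", "late"))

DEFAULT_TIMEPOINTS: list[tuple[str, float]] = [(BASELINE_LABEL, BASELINE_HOURS)] + [
    (lab, h) for lab, h in TIMEPOINT_HOURS.items()
]


@dataclass
class ModuleSpec:
    module_id: str
    n_members: int
    peak_stage: str  # early | middle | late
    amplitude: float
    #: multiplier on members' lognormal baseline weights; early transient
    #: colonizers are rare at baseline, so their default is < 1
    baseline_scale: float = 1.0


@dataclass
class DriverSpec:
    source: str
    target: str
    transition: tuple[str, str]  # e.g. ("early", "middle")
    gamma: float


def _default_modules() -> list[ModuleSpec]:
    # sizes follow the study's five stage-characteristic modules; the early
    # modules hold low-abundance environmental transients
    return [
        ModuleSpec("black", 15, "early", 2.0, baseline_scale=0.3),
        ModuleSpec("pink", 14, "early", 2.0, baseline_scale=0.3),
        ModuleSpec("red", 16, "middle", 2.0),
        ModuleSpec("blue", 29, "late", 0.7),
        ModuleSpec("greenyellow", 9, "late", 0.7),
    ]


@dataclass
class ScenarioConfig:
    """Full description of one simulated longitudinal scenario."""

    n_subjects: int = 30
    timepoints: list[tuple[str, float]] = field(default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    n_taxa: int = 150
    depth: int = 10_000
    module_spec: list[ModuleSpec] = field(default_factory=_default_modules)
    driver_spec: list[DriverSpec] = field(default_factory=list)
    assembly_mode: str = "neutral"  # selection | neutral (used by pair-set draws)
    noise_sd: float = 0.3
    #: fraction of noise variance shared within a module: members covary
    #: beyond their common stage curve, which is what makes them a
    #: detectable co-abundance module under soft-threshold networks
    module_cor: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if self.assembly_mode not in ("selection", "neutral"):
            raise ValueError(f"unknown assembly_mode {self.assembly_mode!r}")
        hours = [h for _, h in self.timepoints]
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise ValueError("timepoint offsets must be strictly increasing")
        if sum(m.n_members for m in self.module_spec) > self.n_taxa:
            raise ValueError("module member counts exceed n_taxa")
        if not 0.0 <= self.module_cor <= 1.0:
            raise ValueError("module_cor must lie in [0, 1]")
        for m in self.module_spec:
            if m.peak_stage not in TENT_PARAMS:
                raise ValueError(f"unknown peak stage {m.peak_stage!r}")
        taxa = set(self.taxa)
        for d in self.driver_spec:
            if d.source not in taxa or d.target not in taxa:
                raise ValueError(f"driver references unknown taxon: {d.source}->{d.target}")
            if tuple(d.transition) not in ADJACENT_TRANSITIONS:
                raise ValueError(f"driver transition {d.transition} is not between adjacent stages")
            if d.gamma < 0:
                raise ValueError("driver effect size must be >= 0")

    @property
    def taxa(self) -> list[str]:
        return [f"taxon_{i + 1}" for i in range(self.n_taxa)]

    def module_members(self) -> dict[str, list[str]]:
        """Taxa of each planted module (contiguous blocks of the taxon list)."""
        out: dict[str, list[str]] = {}
        start = 0
        for m in self.module_spec:
            out[m.module_id] = self.taxa[start : start + m.n_members]
            start += m.n_members
        return out


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream inference."""

    module_labels: pd.Series  # taxon -> module_id ("none" = background)
    true_edges: list[tuple[str, str, tuple[str, str]]]
    latent: np.ndarray  # (n_subjects, n_timepoints, n_taxa) expected rel. abundances
    subjects: list[str]
    timepoint_labels: list[str]
    taxa: list[str]

    def latent_frame(self, subject_idx: int) -> pd.DataFrame:
        return pd.DataFrame(
            self.latent[subject_idx].T, index=self.taxa, columns=self.timepoint_labels
        )


def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Rooted ultrametric tree under a pure-birth (Yule) process.

    Tips are labeled ``taxon_1 .. taxon_n``; identical seeds give identical
    newick strings.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa for a tree")
    rng = _random.Random(int(seed))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # the process stops at the n-th speciation, leaving the youngest pair with
    # zero-length edges; run it on for the waiting time to the next event
    dt = rng.expovariate(n_taxa * 1.0)
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.edge.length = (leaf.edge.length or 0.0) + dt
        leaf.taxon.label = f"taxon_{i + 1}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read(StringIO(newick), format="newick")
    tree.length = None  # no branch above the root
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
    return tree


def _tent(hours: float, start: float, peak: float, end: float) -> float:
    """Piecewise-linear bump on the log10(1+hours) axis; 0 outside [start, end]."""
    if hours < start or hours > end:
        return 0.0
    u = np.log10(1.0 + hours)
    u0, up, u1 = (np.log10(1.0 + x) for x in (start, peak, end))
    if u <= up:
        return float((u - u0) / (up - u0)) if up > u0 else 1.0
    return float((u1 - u) / (u1 - up)) if u1 > up else 1.0


def _module_multiplier(spec: ModuleSpec, hours: float) -> float:
    if hours < 0:  # pre-scaling baseline is untouched
        return 1.0
    start, peak, end = TENT_PARAMS[spec.peak_stage]
    t = _tent(hours, start, peak, end)
    if spec.peak_stage == "late":
        return 1.0 - spec.amplitude * t  # dip then recover
    return 1.0 + spec.amplitude * t  # bloom then fade


def simulate_recovery_series(
    config: ScenarioConfig, tree: TreeNode
) -> tuple[CommunityTable, pd.DataFrame, GroundTruth]:
    """Simulate the longitudinal recovery experiment.

    Returns the observed count table (columns sum exactly to ``depth``), the
    sample metadata frame, and the planted :class:`GroundTruth`.
    """
    taxa = config.taxa
    tips = {t.name for t in tree.tips()}
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise ValueError(f"tree lacks tips for {len(missing)} configured taxa, e.g. {missing[:3]}")

    labels = [lab for lab, _ in config.timepoints]
    hours = np.array([h for _, h in config.timepoints], dtype=float)
    n_sub, n_tp, n_tax = config.n_subjects, len(labels), config.n_taxa

    ss = np.random.SeedSequence(int(config.seed))
    base_ss, subj_ss, obs_ss = ss.spawn(3)
    rng_base = np.random.default_rng(base_ss)
    subj_rngs = [np.random.default_rng(s) for s in subj_ss.spawn(n_sub)]
    rng_obs = np.random.default_rng(obs_ss)

    baseline_w = rng_base.lognormal(mean=0.0, sigma=1.0, size=n_tax)

    members = config.module_members()
    for spec in config.module_spec:
        for t in members[spec.module_id]:
            baseline_w[config.taxa.index(t)] *= spec.baseline_scale
    taxon_idx = {t: i for i, t in enumerate(taxa)}
    module_of = pd.Series("none", index=pd.Index(taxa, name="taxon"), name="module")
    for mid, membs in members.items():
        module_of.loc[membs] = mid

    # stage multiplier per (timepoint, taxon)
    mult = np.ones((n_tp, n_tax))
    for spec in config.module_spec:
        idx = [taxon_idx[t] for t in members[spec.module_id]]
        for j, h in enumerate(hours):
            mult[j, idx] = _module_multiplier(spec, h)

    stage_of_tp = np.array([stage_of_hours(h) for h in hours])

    # module index per taxon (-1 = background) for correlated noise draws
    mod_idx = np.full(n_tax, -1)
    for k, spec in enumerate(config.module_spec):
        for t in members[spec.module_id]:
            mod_idx[taxon_idx[t]] = k
    n_mod = len(config.module_spec)
    rho = config.module_cor
    in_mod = mod_idx >= 0

    def correlated_noise(rng: np.random.Generator) -> np.ndarray:
        """Lognormal noise with a shared within-module component."""
        resid = rng.normal(0.0, config.noise_sd, size=n_tax)
        if n_mod == 0 or rho == 0:
            return np.exp(resid)
        shared = rng.normal(0.0, config.noise_sd, size=n_mod)
        z = resid.copy()
        z[in_mod] = (np.sqrt(rho) * shared[mod_idx[in_mod]]
                     + np.sqrt(1.0 - rho) * resid[in_mod])
        return np.exp(z)

    latent = np.empty((n_sub, n_tp, n_tax))
    for s in range(n_sub):
        subj_eff = correlated_noise(subj_rngs[s]) if config.noise_sd > 0 else np.ones(n_tax)
        w = baseline_w[None, :] * subj_eff[None, :] * mult  # (n_tp, n_tax)
        lat = w / w.sum(axis=1, keepdims=True)
        # driver effects: computed from pre-driver latent stage means, then renormalize
        add = np.zeros_like(lat)
        for d in config.driver_spec:
            s_from, s_to = d.transition
            src_mean = lat[stage_of_tp == s_from, taxon_idx[d.source]].mean()
            add[stage_of_tp == s_to, taxon_idx[d.target]] += d.gamma * src_mean
        lat = lat + add
        latent[s] = lat / lat.sum(axis=1, keepdims=True)

    sample_ids, rows = [], []
    counts = np.empty((n_tax, n_sub * n_tp), dtype=np.int64)
    col = 0
    for s in range(n_sub):
        subject = f"S{s + 1:02d}"
        for j, lab in enumerate(labels):
            sid = f"{subject}_{lab}"
            noise = correlated_noise(rng_obs) if config.noise_sd > 0 else np.ones(n_tax)
            p = latent[s, j] * noise
            p = p / p.sum()
            counts[:, col] = rng_obs.multinomial(config.depth, p)
            sample_ids.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "timepoint": lab,
                    "hours": hours[j],
                    "stage": stage_of_tp[j],
                }
            )
            col += 1

    table = CommunityTable(pd.DataFrame(counts, index=taxa, columns=sample_ids))
    metadata = pd.DataFrame(rows)
    truth = GroundTruth(
        module_labels=module_of,
        true_edges=[(d.source, d.target, tuple(d.transition)) for d in config.driver_spec if d.gamma > 0],
        latent=latent,
        subjects=[f"S{s + 1:02d}" for s in range(n_sub)],
        timepoint_labels=labels,
        taxa=taxa,
    )
    return table, metadata, truth


def _smallest_clade(tree: TreeNode, min_tips: int) -> list[str]:
    """Tips of the smallest clade holding at least ``min_tips`` tips."""
    best: list[str] | None = None
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            continue
        tips = [t.name for t in node.tips()]
        if len(tips) >= min_tips and (best is None or len(tips) < len(best)):
            best = tips
    assert best is not None
    return best


def simulate_assembly_pair_set(
    mode: str, tree: TreeNode, n_communities: int, richness: int, seed: int
) -> CommunityTable:
    """Draw communities under phylogenetic selection or neutrally.

    ``selection`` confines every community's members to one phylogenetically
    clustered clade (the same clade for all communities), emulating a shared
    environmental filter; ``neutral`` picks members uniformly at random.
    Abundances are lognormal, normalized to relative form.
    """
    if mode not in ("selection", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    tips = [t.name for t in tree.tips()]
    if richness > len(tips):
        raise ValueError("richness exceeds number of tree tips")
    rng = np.random.default_rng(int(seed))
    pool = _smallest_clade(tree, richness) if mode == "selection" else tips
    cols = {}
    for c in range(n_communities):
        chosen = rng.choice(len(pool), size=richness, replace=False)
        ab = rng.lognormal(0.0, 1.0, size=richness)
        v = pd.Series(0.0, index=tips)
        v.iloc[[tips.index(pool[i]) for i in chosen]] = ab / ab.sum()
        cols[f"C{c + 1}"] = v
    df = pd.DataFrame(cols)
    return CommunityTable(df, is_relative=True)


def correlated_blocks(
    n_blocks: int = 3,
    block_size: int = 10,
    n_background: int = 0,
    n_samples: int = 40,
    within_cor: float = 0.9,
    seed: int = 0,
) -> tuple[CommunityTable, pd.Series]:
    """Block-structured profiles for module-detection benchmarks.

    Taxa inside a block share a latent factor so their pairwise correlation is
    ~``within_cor``; between-block correlation is ~0.  Returns the table and
    the planted block labels (0 = background).
    """
    rng = np.random.default_rng(int(seed))
    rho = np.sqrt(within_cor)
    rowsets, labels = [], []
    for b in range(n_blocks):
        factor = rng.normal(size=n_samples)
        noise = rng.normal(size=(block_size, n_samples))
        rowsets.append(rho * factor[None, :] + np.sqrt(1 - rho**2) * noise)
        labels += [b + 1] * block_size
    if n_background:
        rowsets.append(rng.normal(size=(n_background, n_samples)))
        labels += [0] * n_background
    X = np.vstack(rowsets)
    taxa = [f"taxon_{i + 1}" for i in range(X.shape[0])]
    samples = [f"S{j + 1}" for j in range(n_samples)]
    # shift positive so the matrix is a valid abundance table
    X = X - X.min() + 0.1
    table = CommunityTable(pd.DataFrame(X, index=taxa, columns=samples))
    return table, pd.Series(labels, index=taxa, name="block")


def driver_benchmark_config(
    seed: int,
    gamma: float = 20.0,
    n_edges: int = 5,
    n_sources: int = 10,
    n_targets: int = 10,
    n_subjects: int = 30,
    n_taxa: int = 100,
) -> tuple[ScenarioConfig, TreeNode, list[tuple[str, str]]]:
    """Scenario with planted driver edges between detectable taxa.

    Builds an early source module (``n_sources`` members) and a middle target
    module (``n_targets``), giving ``n_sources * n_targets`` candidate pairs,
    and plants ``n_edges`` early->middle drivers of strength ``gamma``.  A
    driverless reference run ranks module members by baseline abundance and
    edges connect abundance-rank-matched source/target pairs: a driver whose
    source sits below the counting-noise floor is unrecoverable by any
    method, so the benchmark plants effects only where the design permits
    detection.  Returns (config, tree, planted edge list).
    """
    mods = [
        ModuleSpec("black", n_sources, "early", 1.0),
        ModuleSpec("red", n_targets, "middle", 2.0),
        ModuleSpec("blue", 20, "late", 0.7),
    ]
    # module_cor=0: member noise is independent so recovered edges reflect
    # the planted driver effects, not shared module fluctuation
    cfg0 = ScenarioConfig(n_subjects=n_subjects, n_taxa=n_taxa, seed=seed,
                          module_spec=mods, module_cor=0.0)
    tree = simulate_tree(n_taxa, seed=seed)
    _, _, truth0 = simulate_recovery_series(cfg0, tree)
    base = pd.Series(truth0.latent[:, 0, :].mean(axis=0), index=truth0.taxa)
    members = cfg0.module_members()
    srcs = sorted(members["black"], key=lambda t: -base[t])[:n_edges]
    tgts = sorted(members["red"], key=lambda t: -base[t])[:n_edges]
    planted = list(zip(srcs, tgts))
    drivers = [DriverSpec(s, t, ("early", "middle"), gamma) for s, t in planted]
    cfg = ScenarioConfig(
        n_subjects=n_subjects, n_taxa=n_taxa, seed=seed, module_spec=mods,
        driver_spec=drivers, module_cor=0.0,
    )
    return cfg, tree, planted


def write_scenario(
    config: ScenarioConfig, tree: TreeNode, out_dir, table=None, metadata=None, truth=None
) -> dict[str, Path]:
    """Write a simulated scenario (table/tree/metadata/ground truth) to TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if table is None:
        table, metadata, truth = simulate_recovery_series(config, tree)
    paths = {
        "table": out / "table.tsv",
        "tree": out / "tree.nwk",
        "metadata": out / "metadata.tsv",
        "modules": out / "true_modules.tsv",
        "edges": out / "true_edges.tsv",
    }
    write_table(table, paths["table"])
    write_tree(tree, paths["tree"])
    write_metadata(metadata, paths["metadata"])
    truth.module_labels.rename_axis("taxon").to_frame().to_csv(paths["modules"], sep="\t")
    pd.DataFrame(
        [(s, t, f"{a}->{b}") for s, t, (a, b) in truth.true_edges],
        columns=["source", "target", "transition"],
    ).to_csv(paths["edges"], sep="\t", index=False)
    return paths
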