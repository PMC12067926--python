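"""Generators for phylogenetically structured ecotoxicology test data.

The simulator realises the environmental-filtering model the analysis is
designed to detect: chemicals carry effects on taxa that are either
phylogenetically conserved (whole clades inhibited) or placed at random, the
effects depress logistic growth of isolates and communities, and community
read-count tables are produced under conserved vs random filtering so every
pipeline stage can be scored against known truth.

Conventions:

* effects live on a log-relative-growth scale — 0 means no effect, negative
  means inhibition;
* an isolate's logistic carrying capacity is multiplied by
  ``2·expit(effect)`` (1 at effect 0, → 0 under strong inhibition, < 2 for
  rare growth increases);
* a taxon's community abundance is multiplied by
  ``exp(filtering_strength · effect)`` before renormalisation and
  multinomial read sampling.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model.birthdeath import birth_death_tree
from scipy.special import expit

from .trees import as_newick, phylo_vcv, tip_labels

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_trait",
    "clade_effects",
    "assign_genera",
    "simulate_growth_assay",
    "simulate_communities",
    "simulate_community_growth",
    "simulate_dataset",
    "write_dataset",
]

SCENARIOS = ("conserved", "random", "none")


@dataclass
class SimulationConfig:
    """Study-design and model parameters for a full synthetic dataset.

    Defaults mirror the emulated experiment: a 26-isolate panel screened in
    3 biological replicates of hourly 72-h growth curves, and a sequenced
    community design of 23 chemical treatments plus a DMSO control with
    2 replicates at ≥ 10⁵ reads per sample.
    """

    n_tips: int = 26
    birth_rate: float = 1.0
    # trait model
    sigma2: float = 1.0
    lam: float = 1.0
    n_chemicals: int = 23
    n_conserved: int = 8
    clade_effect: float = -2.0
    clade_min_frac: float = 0.2
    clade_max_frac: float = 0.5
    # growth model
    capacity: float = 1.0
    growth_rate: float = 0.3
    lag_time: float = 24.0
    noise_sd: float = 0.01
    t_max: float = 72.0
    n_times: int = 73
    n_growth_replicates: int = 3
    # community model
    base_log_sd: float = 1.0
    filtering_strength: float = 5.0
    scenario: str = "conserved"
    read_depth: int = 100_000
    n_community_replicates: int = 2
    n_genera: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 4:
            raise ValueError("n_tips must be at least 4")
        for name in ("birth_rate", "sigma2", "noise_sd", "base_log_sd", "capacity", "growth_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.lam <= 1:
            raise ValueError("lam must lie in [0, 1]")
        if self.read_depth < 1_000:
            raise ValueError("read_depth must be at least 1000")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if not 0 < self.n_conserved <= self.n_chemicals:
            raise ValueError("n_conserved must be in (0, n_chemicals]")


@dataclass
class SyntheticDataset:
    """A complete simulated study plus the ground truth needed to score it."""

    tree: dendropy.Tree
    effects: pd.DataFrame  # tips × chemicals, log-relative-growth scale
    growth_curves: pd.DataFrame  # long isolate assay table
    community_curves: pd.DataFrame  # long community assay table
    abundance: pd.DataFrame  # samples × taxa read counts
    treatments: pd.Series  # sample → chemical label
    taxonomy: pd.Series  # taxon → genus
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------
# tree and trait generators


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int | None = None) -> dendropy.Tree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips, in time units.

    The process is stopped at the n-th speciation and the tips are extended
    by the Exp(n·birth_rate) waiting time to the next (unobserved) event, so
    the tree is ultrametric with no zero-length terminal branches and the
    expected crown depth is Σ_{k=2..n} 1/(birth_rate·k).
    """
    if n_tips < 4:
        raise ValueError("n_tips must be at least 4")
    rng = _random.Random(seed)
    tree = birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"t{i:03d}"
    return tree


def simulate_trait(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    lam: float = 1.0,
    seed: int | None = None,
    mean: float = 0.0,
) -> pd.Series:
    """Trait drawn from N(mean, σ²·V(λ)) over the tips.

    V is the Brownian covariance of the tree and λ scales its off-diagonal
    entries: λ = 1 is Brownian motion, λ = 0 independent tips.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if not 0 <= lam <= 1:
        raise ValueError("lam must lie in [0, 1]")
    V = phylo_vcv(tree)
    Vl = lam * V.to_numpy()
    np.fill_diagonal(Vl, np.diag(V.to_numpy()))
    rng = np.random.default_rng(seed)
    # allow semi-definite covariances (zero-length internal branches)
    L = np.linalg.cholesky(sigma2 * Vl + 1e-12 * np.eye(len(V)))
    x = mean + L @ rng.standard_normal(len(V))
    return pd.Series(x, index=V.index, name="trait")


def clade_effects(
    tree: dendropy.Tree,
    magnitude: float = -2.0,
    min_frac: float = 0.2,
    max_frac: float = 0.5,
    seed: int | None = None,
    mode: str = "resistant_clade",
) -> tuple[pd.Series, list[str]]:
    """Phylogenetically conserved effect vector (the clade-filtering scenario).

    In the default ``"resistant_clade"`` mode one monophyletic clade
    containing between ``min_frac`` and ``max_frac`` of the tips is resistant
    (effect 0) and every other tip — whole clades of the remainder — is
    inhibited by ``magnitude``, so the survivors of strong filtering are
    closely related and the filtered community is phylogenetically
    clustered. ``"susceptible_clade"`` inverts this: only the chosen clade is
    inhibited. Falls back to the closest-sized clade if the size window is
    empty.

    Returns ``(effects, filtered_tips)`` — the effect Series and the tips
    the chemical inhibits.
    """
    if mode not in ("resistant_clade", "susceptible_clade"):
        raise ValueError("mode must be 'resistant_clade' or 'susceptible_clade'")
    labels = tip_labels(tree)
    n = len(labels)
    rng = np.random.default_rng(seed)
    clades = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        tips = [l.taxon.label for l in node.leaf_iter()]
        clades.append(tips)
    in_window = [c for c in clades if min_frac * n <= len(c) <= max_frac * n]
    if in_window:
        chosen = in_window[rng.integers(len(in_window))]
    else:
        target = 0.5 * (min_frac + max_frac) * n
        chosen = min(clades, key=lambda c: abs(len(c) - target))
    eff = pd.Series(0.0, index=labels, name="effect")
    if mode == "resistant_clade":
        filtered = [l for l in labels if l not in set(chosen)]
    else:
        filtered = list(chosen)
    eff.loc[filtered] = magnitude
    return eff, filtered


def assign_genera(tree: dendropy.Tree, n_genera: int) -> pd.Series:
    """Partition tips into ``n_genera`` monophyletic genera.

    Splits the largest remaining clade until the requested number of groups
    is reached; names are Genus01, Genus02, … in tree order.
    """
    if n_genera < 1:
        raise ValueError("n_genera must be positive")
    groups = [tree.seed_node]
    while len(groups) < n_genera:
        splittable = [g for g in groups if not g.is_leaf()]
        if not splittable:
            break
        biggest = max(splittable, key=lambda g: sum(1 for _ in g.leaf_iter()))
        groups.remove(biggest)
        groups.extend(biggest.child_nodes())
    taxonomy = {}
    for k, node in enumerate(groups, start=1):
        for leaf in node.leaf_iter():
            taxonomy[leaf.taxon.label] = f"Genus{k:02d}"
    return pd.Series(taxonomy, name="genus").loc[tip_labels(tree)]


# ---------------------------------------------------------------------------
# growth curves


def capacity_multiplier(effect) -> np.ndarray:
    """Map a log-relative-growth effect to a carrying-capacity multiplier.

    ``2·expit(effect)``: 1 at no effect, → 0 under strong inhibition,
    bounded above by 2 for growth-promoting effects.
    """
    return 2.0 * expit(np.asarray(effect, dtype=float))


def _logistic_curve(t: np.ndarray, capacity: float, rate: float, lag: float) -> np.ndarray:
    return capacity / (1.0 + np.exp(-rate * (t - lag)))


def simulate_growth_assay(
    effects: pd.DataFrame,
    capacity: float = 1.0,
    growth_rate: float = 0.3,
    lag_time: float = 24.0,
    noise_sd: float = 0.01,
    t_max: float = 72.0,
    n_times: int = 73,
    n_replicates: int = 3,
    seed: int | None = None,
    control_label: str = "DMSO",
) -> pd.DataFrame:
    """Hourly logistic growth curves for every culture × chemical × replicate.

    ``effects`` is tips(cultures) × chemicals on the log-relative-growth
    scale; each curve is a logistic with carrying capacity
    ``capacity · 2·expit(effect)`` plus i.i.d. Gaussian observation noise.
    Control (DMSO) curves use multiplier 1. Returns the long assay table
    consumed by :func:`phylotox.growth_metrics.build_response_matrix`.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n_times)
    chems = [control_label] + list(effects.columns)
    frames = []
    for culture in effects.index:
        for chem in chems:
            mult = 1.0 if chem == control_label else float(capacity_multiplier(effects.loc[culture, chem]))
            base = _logistic_curve(t, capacity * mult, growth_rate, lag_time)
            for rep in range(1, n_replicates + 1):
                od = base + rng.normal(0.0, noise_sd, size=n_times)
                frames.append(
                    pd.DataFrame(
                        {
                            "culture_id": culture,
                            "chemical_id": chem,
                            "replicate": rep,
                            "time_h": t,
                            "od": od,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def simulate_community_growth(
    effects: pd.DataFrame,
    base_abundance: pd.Series,
    community_id: str = "COMMUNITY",
    **kwargs,
) -> pd.DataFrame:
    """Whole-community growth curves under each chemical.

    The community's carrying-capacity multiplier under a chemical is the
    base-abundance-weighted mean of its member taxa's multipliers — surviving
    biomass sets the community yield — so community growth declines exactly
    when abundant taxa are inhibited.
    """
    w = base_abundance.loc[effects.index]
    w = w / w.sum()
    mult = capacity_multiplier(effects).T @ w.to_numpy()  # per chemical
    community_effects = pd.DataFrame(
        # invert the per-isolate map so the shared curve generator applies
        # the intended multiplier directly
        {c: [float(np.log(m / (2.0 - m)))] for c, m in zip(effects.columns, mult)},
        index=[community_id],
    )
    return simulate_growth_assay(community_effects, **kwargs)


# ---------------------------------------------------------------------------
# community read-count tables


def simulate_communities(
    effects: pd.DataFrame,
    base_abundance: pd.Series,
    scenario: str = "conserved",
    filtering_strength: float = 5.0,
    read_depth: int = 100_000,
    n_replicates: int = 2,
    seed: int | None = None,
    control_label: str = "DMSO",
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Multinomial read-count tables under chemical filtering.

    Under each treatment every taxon's base abundance is multiplied by
    ``exp(filtering_strength · effect)`` — with the effect vector taken as
    given (``"conserved"``), tip-permuted per chemical (``"random"``), or
    zeroed (``"none"``) — renormalised, and sampled as ``read_depth``
    multinomial reads per replicate. Control samples use the unmodified base
    community.

    Returns ``(counts, treatments, permutations)``: samples × taxa counts,
    the sample → treatment map, and the per-chemical tip permutation used in
    the random scenario (ground truth).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    taxa = list(effects.index)
    base = base_abundance.loc[taxa].to_numpy(dtype=float)
    if (base <= 0).any():
        raise ValueError("base abundances must be positive")
    rows, labels, treatments = [], [], {}
    permutations: dict[str, list[int]] = {}

    def add_sample(chem: str, rel: np.ndarray, rep: int) -> None:
        counts = rng.multinomial(read_depth, rel / rel.sum())
        name = f"{chem}__rep{rep}"
        rows.append(counts)
        labels.append(name)
        treatments[name] = chem

    for rep in range(1, n_replicates + 1):
        add_sample(control_label, base.copy(), rep)
    for chem in effects.columns:
        e = effects[chem].to_numpy(dtype=float)
        if scenario == "random":
            perm = rng.permutation(len(taxa))
            permutations[chem] = perm.tolist()
            e = e[perm]
        elif scenario == "none":
            e = np.zeros_like(e)
        rel = base * np.exp(filtering_strength * e)
        for rep in range(1, n_replicates + 1):
            add_sample(chem, rel, rep)
    counts = pd.DataFrame(rows, index=pd.Index(labels, name="sample"), columns=taxa)
    return counts, pd.Series(treatments, name="treatment"), permutations


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """Generate a complete synthetic study from a :class:`SimulationConfig`.

    The first ``n_conserved`` chemicals carry clade-structured effects (one
    resistant clade; whole clades of the remainder inhibited by
    ``clade_effect``); the remaining chemicals are inactive (effect 0
    everywhere), mimicking a screening panel that mixes impactful compounds
    with no-impact controls, so their growth responses are pure assay noise
    with no phylogenetic signal. The same effects drive the isolate growth
    assay, the community growth assay and the community read tables, so
    downstream estimates can be scored against truth. The ``scenario``
    switch ("conserved" / "random" / "none") controls whether the community
    tables apply these effects as given, tip-permuted, or not at all.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = SimulationConfig(**{**asdict(config), **overrides})
    root = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_tips, config.birth_rate, seed=int(root.integers(2**31)))
    labels = tip_labels(tree)

    effects = {}
    truth_chem = {}
    for k in range(config.n_chemicals):
        chem = f"chem{k + 1:03d}"
        if k < config.n_conserved:
            eff, filtered = clade_effects(
                tree,
                magnitude=config.clade_effect,
                min_frac=config.clade_min_frac,
                max_frac=config.clade_max_frac,
                seed=int(root.integers(2**31)),
            )
            truth_chem[chem] = {"kind": "conserved", "filtered_tips": filtered}
        else:
            eff = pd.Series(0.0, index=labels)
            truth_chem[chem] = {"kind": "inactive", "filtered_tips": []}
        effects[chem] = eff
        truth_chem[chem]["effects"] = eff.round(6).to_dict()
    effects = pd.DataFrame(effects).loc[labels]

    growth_kwargs = dict(
        capacity=config.capacity,
        growth_rate=config.growth_rate,
        lag_time=config.lag_time,
        noise_sd=config.noise_sd,
        t_max=config.t_max,
        n_times=config.n_times,
        n_replicates=config.n_growth_replicates,
    )
    curves = simulate_growth_assay(effects, seed=int(root.integers(2**31)), **growth_kwargs)

    base = pd.Series(
        np.exp(root.normal(0.0, config.base_log_sd, size=len(labels))), index=labels
    )
    community_curves = simulate_community_growth(
        effects, base, seed=int(root.integers(2**31)), **growth_kwargs
    )
    counts, treatments, perms = simulate_communities(
        effects,
        base,
        scenario=config.scenario,
        filtering_strength=config.filtering_strength,
        read_depth=config.read_depth,
        n_replicates=config.n_community_replicates,
        seed=int(root.integers(2**31)),
    )
    taxonomy = assign_genera(tree, config.n_genera)
    truth = {
        "true_lambda": config.lam,
        "scenario": config.scenario,
        "filtering_strength": config.filtering_strength,
        "chemicals": truth_chem,
        "random_scenario_permutations": perms,
        "base_abundance": base.round(6).to_dict(),
    }
    return SyntheticDataset(
        tree=tree,
        effects=effects,
        growth_curves=curves,
        community_curves=community_curves,
        abundance=counts,
        treatments=treatments,
        taxonomy=taxonomy,
        truth=truth,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write a dataset as plain-text files (Newick, TSV, JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "tree.nwk").write_text(as_newick(dataset.tree))
    dataset.effects.rename_axis("taxon").to_csv(out / "traits.tsv", sep="\t")
    dataset.growth_curves.to_csv(out / "curves.tsv", sep="\t", index=False)
    dataset.community_curves.to_csv(out / "community_curves.tsv", sep="\t", index=False)
    table = dataset.abundance.T.rename_axis("taxon")
    table.insert(0, "genus", dataset.taxonomy)
    table.to_csv(out / "abundances.tsv", sep="\t")
    dataset.treatments.rename_axis("sample").to_csv(out / "treatments.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(dataset.truth, indent=1))
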