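"""Community composition, diversity and phylogenetic-structure metrics.

Operates on samples × taxa abundance tables (counts or relative abundances)
together with a community phylogeny. Implements the compositional distances
(Bray-Curtis, abundance-weighted UniFrac), their PCoA ordination, alpha
diversity (richness, Shannon entropy in nats), and the standardised effect
size of mean pairwise phylogenetic distance (SES.MPD) under a taxon-label
randomisation null. Negative SES.MPD indicates phylogenetic clustering —
the signature of clade-level environmental filtering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .trees import patristic_distances, tip_labels

__all__ = [
    "Ordination",
    "bray_curtis",
    "weighted_unifrac",
    "pcoa",
    "diversity",
    "ses_mpd",
    "replicate_mean",
    "normalize_table",
    "read_abundance_table",
]

DETECTION_THRESHOLD = 1e-4


@dataclass
class Ordination:
    """PCoA embedding: centred sample coordinates on positive-eigenvalue axes.

    ``eigenvalues`` keeps the full spectrum, negatives included (no Cailliez
    or Lingoes correction); ``proportion_explained`` is relative to the
    positive eigenvalue mass only.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("abundance table has negative entries")
    zero = table.index[X.sum(axis=1) == 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total abundance: {zero}")
    return table


def normalize_table(table: pd.DataFrame) -> pd.DataFrame:
    """Convert counts to relative abundances (rows sum to 1)."""
    _check_table(table)
    return table.div(table.sum(axis=1), axis=0)


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity BC(a,b) = Σ|aᵢ−bᵢ| / Σ(aᵢ+bᵢ)."""
    _check_table(table)
    if len(table) < 2:
        raise ValueError("need at least 2 samples")
    D = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def weighted_unifrac(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    normalized: bool = True,
) -> pd.DataFrame:
    """Pairwise abundance-weighted UniFrac distances.

    Each branch contributes its length times the absolute difference of the
    two samples' summed descendant relative abundances,
    ``raw = sum_b l_b * |A_b - B_b|``. The normalised variant divides by the
    maximum value attainable for the two abundance placements at the tips,
    ``sum_i d_i (a_i + b_i)`` with ``d_i`` the root-to-tip distance, scaling
    distances to [0, 1]. Samples are converted to relative abundances first.
    """
    _check_table(table)
    taxa = list(table.columns)
    missing = set(taxa) - set(tip_labels(tree))
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    rel = normalize_table(table)
    X = rel.to_numpy(dtype=float)
    n_samples, n_taxa = X.shape
    col = {t: k for k, t in enumerate(taxa)}

    # postorder accumulation: per-branch descendant abundance of every sample
    nodes = [nd for nd in tree.postorder_node_iter() if nd is not tree.seed_node]
    lengths = np.array([nd.edge.length or 0.0 for nd in nodes])
    node_abund = np.zeros((len(nodes), n_samples))
    acc: dict[dendropy.Node, np.ndarray] = {}
    depth_term = np.zeros(n_samples)  # sum_i d_i * x_si for the normalisation
    root_dist: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is not tree.seed_node:
            root_dist[nd] = root_dist[nd.parent_node] + (nd.edge.length or 0.0)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            a = X[:, col[nd.taxon.label]] if nd.taxon.label in col else np.zeros(n_samples)
            depth_term += root_dist[nd] * a
        else:
            a = sum(acc.pop(c) for c in nd.child_nodes())
        acc[nd] = a
        node_abund[i] = a

    D = np.zeros((n_samples, n_samples))
    for i in range(n_samples):
        diff = np.abs(node_abund[:, i, None] - node_abund[:, i + 1:])
        raw = lengths @ diff
        if normalized:
            denom = depth_term[i] + depth_term[i + 1:]
            with np.errstate(invalid="ignore"):
                raw = np.where(denom > 0, raw / denom, 0.0)
        D[i, i + 1:] = D[i + 1:, i] = raw
    return pd.DataFrame(D, index=rel.index, columns=rel.index)


def pcoa(D: pd.DataFrame) -> Ordination:
    """Principal coordinates analysis of a distance matrix.

    Double-centres −½·J·D²·J, eigendecomposes, and returns coordinates
    (eigenvector × √eigenvalue) for positive eigenvalues, ordered by
    descending eigenvalue. Negative eigenvalues are reported unchanged.
    """
    M = D.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (M**2) @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    pos_mass = eigval[pos].sum()
    prop = eigval[pos] / pos_mass if pos_mass > 0 else np.zeros(pos.sum())
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return Ordination(
        coordinates=pd.DataFrame(coords, index=D.index, columns=cols),
        eigenvalues=eigval,
        proportion_explained=prop,
    )


def diversity(
    table: pd.DataFrame,
    threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample species richness and Shannon entropy (nats).

    Taxa at or below the relative-abundance detection ``threshold`` are
    treated as absent; Shannon entropy renormalises over the detected taxa.
    """
    rel = normalize_table(table)
    rows = {}
    for sample, p in rel.iterrows():
        pv = p.to_numpy(dtype=float)
        pv = pv[pv > threshold]
        if pv.size == 0:
            raise ValueError(f"sample {sample!r} has no taxa above threshold")
        pv = pv / pv.sum()
        rows[sample] = {"richness": int(pv.size), "shannon": float(-(pv * np.log(pv)).sum())}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def ses_mpd(
    table: pd.DataFrame,
    tree: dendropy.Tree,
    n_rand: int = 999,
    seed: int | None = None,
    abundance_weighted: bool = False,
    threshold: float = DETECTION_THRESHOLD,
) -> pd.DataFrame:
    """Standardised effect size of mean pairwise phylogenetic distance.

    For each sample, MPD is the mean patristic distance among its detected
    taxa (the abundance-weighted variant weights each pair by pᵢ·pⱼ). The
    null model shuffles taxon labels on the distance matrix — equivalently,
    redraws the same number of taxa at random from the pool — holding
    richness (and the abundance multiset, if weighted) fixed.

    Returns a DataFrame per sample with mpd_obs, null_mean, null_sd, ses,
    p_rank (lower-tail: small p means phylogenetic clustering) and a
    ``degenerate`` flag for samples where the null is a point mass (e.g. the
    sample contains every taxon in the pool).
    """
    rel = normalize_table(table)
    Dfull = patristic_distances(tree)
    missing = set(rel.columns) - set(Dfull.index)
    if missing:
        raise ValueError(f"taxa absent from tree: {sorted(missing)}")
    pool = [t for t in rel.columns]
    D = Dfull.loc[pool, pool].to_numpy(dtype=float)
    n_pool = len(pool)
    rng = np.random.default_rng(seed)

    def mpd(idx: np.ndarray, w: np.ndarray | None) -> float:
        sub = D[np.ix_(idx, idx)]
        if w is None:
            iu = np.triu_indices(len(idx), k=1)
            return float(sub[iu].mean())
        ww = np.outer(w, w)
        iu = np.triu_indices(len(idx), k=1)
        return float((sub[iu] * ww[iu]).sum() / ww[iu].sum())

    rows = {}
    for sample, p in rel.iterrows():
        pv = p.to_numpy(dtype=float)
        present = np.flatnonzero(pv > threshold)
        if present.size < 2:
            rows[sample] = dict(
                mpd_obs=np.nan, null_mean=np.nan, null_sd=np.nan,
                ses=np.nan, p_rank=np.nan, richness=int(present.size), degenerate=True,
            )
            continue
        w = pv[present] / pv[present].sum() if abundance_weighted else None
        obs = mpd(present, w)
        nulls = np.empty(n_rand)
        for r in range(n_rand):
            idx = rng.permutation(n_pool)[: present.size]
            nulls[r] = mpd(idx, w)
        null_mean, null_sd = float(nulls.mean()), float(nulls.std(ddof=1))
        if null_sd == 0.0:
            rows[sample] = dict(
                mpd_obs=obs, null_mean=null_mean, null_sd=0.0,
                ses=np.nan, p_rank=np.nan, richness=int(present.size), degenerate=True,
            )
            continue
        ses = (obs - null_mean) / null_sd
        p_rank = (1.0 + np.sum(nulls <= obs)) / (n_rand + 1.0)
        rows[sample] = dict(
            mpd_obs=obs, null_mean=null_mean, null_sd=null_sd,
            ses=float(ses), p_rank=float(p_rank), richness=int(present.size),
            degenerate=False,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def replicate_mean(values: pd.Series, treatments: pd.Series) -> pd.Series:
    """Average a per-sample metric across replicates of each treatment."""
    treatments = treatments.reindex(values.index)
    if treatments.isna().any():
        raise ValueError("every sample needs a treatment label")
    return values.groupby(treatments).mean()


def read_abundance_table(
    path: str | Path,
    sep: str | None = None,
    taxonomy_column: str | None = "genus",
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a taxon-rows × sample-columns abundance TSV/CSV.

    Returns ``(table, taxonomy)`` with the table transposed to samples × taxa
    and ``taxonomy`` the taxon → genus mapping if the column is present.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(path, sep=sep, index_col=0)
    taxonomy = None
    if taxonomy_column and taxonomy_column in raw.columns:
        taxonomy = raw[taxonomy_column]
        raw = raw.drop(columns=[taxonomy_column])
    table = raw.T.astype(float)
    table.index.name = "sample"
    _check_table(table)
    return table, taxonomy
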