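"""Strain comparison: median rankings, PCA with cos2, Pearson clustergrams.

Per-strain sampling distributions are summarised by their per-reaction
medians.  Reactions are ranked by the spread of medians across strains —
absolute (max - min) or percent relative to the grand median — with reactions
whose flux magnitude never exceeds 1e-12 mmol gDW^-1 h^-1 filtered out of the
percent ranking as numerically meaningless.  Strains are compared globally by
PCA (with squared-cosine quality-of-representation scores, FactoMineR-style)
and by average-linkage hierarchical clustering on 1 - Pearson correlation of
their median flux vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .sampling import SampleSet

#: Fluxes below this magnitude are treated as numerically zero in the
#: percent-difference ranking.
MINISCULE_FLUX = 1e-12


@dataclass
class MedianTable:
    """strains x reactions matrix of per-reaction sample medians."""

    strains: list[str]
    reaction_ids: list[str]
    medians: np.ndarray

    def row(self, strain: str) -> np.ndarray:
        return self.medians[self.strains.index(strain)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.medians, index=self.strains, columns=self.reaction_ids)


@dataclass
class RankingEntry:
    reaction_id: str
    spread: float
    medians: dict[str, float]


@dataclass
class ReactionRanking:
    entries: list[RankingEntry]
    mode: str  # "absolute" | "percent"
    k: int

    def reaction_ids(self) -> list[str]:
        return [e.reaction_id for e in self.entries]

    def to_frame(self, model=None) -> pd.DataFrame:
        """Table-style output: reaction id, optional gene association and
        subsystem from ``model``, per-strain medians, spread."""
        recs = []
        for e in self.entries:
            rec: dict = {"reaction_id": e.reaction_id}
            if model is not None and model.has_reaction(e.reaction_id):
                rxn = model.reaction(e.reaction_id)
                rec["gene_association"] = rxn.gene_association
                rec["subsystem"] = rxn.subsystem
            rec.update({f"median_{s}": m for s, m in e.medians.items()})
            rec["spread"] = e.spread
            recs.append(rec)
        return pd.DataFrame(recs)


@dataclass
class PcaResult:
    scores: np.ndarray  # observations x components
    loadings: np.ndarray  # variables x components (unit-norm eigenvectors)
    variance_explained: np.ndarray  # fraction per component, sums to 1
    cos2_variables: np.ndarray  # variables x components
    cos2_individuals: np.ndarray  # observations x components
    variable_names: list[str] = field(default_factory=list)
    observation_names: list[str] = field(default_factory=list)


@dataclass
class ClusterResult:
    strains: list[str]
    correlation: np.ndarray  # strains x strains Pearson matrix
    merge_tree: list[tuple[int, int, float]]  # scipy-style ordered merges
    linkage_name: str
    linkage_matrix: np.ndarray

    def first_merge(self) -> tuple[str, str]:
        """The pair of original strains joined at the lowest height."""
        i, j, _ = self.merge_tree[0]
        leaves = _leaf_sets(self.linkage_matrix, len(self.strains))
        pair = sorted(leaves[i] | leaves[j])
        return self.strains[pair[0]], self.strains[pair[1]]

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.strains)


# ---------------------------------------------------------------------------
# medians and rankings


def reaction_medians(sample_sets: list[SampleSet]) -> MedianTable:
    """Column medians of each strain's sample matrix.

    When a strain was sampled at several time points, pass the sets for one
    time point at a time (strain labels must be unique here).
    """
    if not sample_sets:
        raise ValueError("need at least one sample set")
    rids = sample_sets[0].reaction_ids
    for ss in sample_sets[1:]:
        if ss.reaction_ids != rids:
            raise ValueError("sample sets do not share reaction ids")
    strains = [ss.strain for ss in sample_sets]
    if len(set(strains)) != len(strains):
        raise ValueError(f"duplicate strain labels: {strains}")
    medians = np.vstack([np.median(ss.samples, axis=0) for ss in sample_sets])
    return MedianTable(strains, list(rids), medians)


def _build_ranking(
    table: MedianTable, spreads: np.ndarray, keep: np.ndarray, mode: str, k: int
) -> ReactionRanking:
    # sort by spread descending, ties lexicographic by reaction id
    order = sorted(
        (j for j in range(len(table.reaction_ids)) if keep[j]),
        key=lambda j: (-spreads[j], table.reaction_ids[j]),
    )
    entries = [
        RankingEntry(
            table.reaction_ids[j],
            float(spreads[j]),
            {s: float(table.medians[i, j]) for i, s in enumerate(table.strains)},
        )
        for j in order[:k]
    ]
    return ReactionRanking(entries, mode, k)


def rank_absolute_median_difference(table: MedianTable, k: int = 20) -> ReactionRanking:
    """Top-k reactions by the range (max - min) of strain medians."""
    if len(table.strains) < 2:
        raise ValueError("ranking needs at least 2 strains")
    spreads = table.medians.max(axis=0) - table.medians.min(axis=0)
    keep = np.ones(spreads.size, dtype=bool)
    return _build_ranking(table, spreads, keep, "absolute", k)


def rank_percent_median_difference(
    table: MedianTable, k: int = 20, min_abs_flux: float = MINISCULE_FLUX
) -> ReactionRanking:
    """Top-k by percent spread, excluding reactions with miniscule medians.

    A reaction whose largest |median| over strains is below ``min_abs_flux``
    carries no usable signal and is excluded before ranking.  Percent spread
    is 100 * (max - min) / max(|grand median|, min_abs_flux).
    """
    if len(table.strains) < 2:
        raise ValueError("ranking needs at least 2 strains")
    rng_ = table.medians.max(axis=0) - table.medians.min(axis=0)
    keep = np.abs(table.medians).max(axis=0) >= min_abs_flux
    grand = np.abs(np.median(table.medians, axis=0))
    spreads = 100.0 * rng_ / np.maximum(grand, min_abs_flux)
    return _build_ranking(table, spreads, keep, "percent", k)


# ---------------------------------------------------------------------------
# PCA with cos2


def pca_with_cos2(
    flux_matrix: np.ndarray,
    scale: bool = True,
    variable_names: list[str] | None = None,
    observation_names: list[str] | None = None,
) -> PcaResult:
    """Centered (and optionally unit-variance scaled) PCA via SVD.

    All min(n_obs - 1, n_vars) components are kept.  cos2 of a variable on a
    component is its squared correlation with that component; over all
    components these sum to 1 for scaled PCA.  cos2 of an observation is its
    squared score divided by its squared distance to the origin in the
    centered space.
    """
    X = np.asarray(flux_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 observations and >= 2 variables")
    if np.any(~np.isfinite(X)):
        raise ValueError("PCA input contains missing/non-finite values")
    n, p = X.shape
    names = variable_names or [f"v{j}" for j in range(p)]
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=0)
        dead = [names[j] for j in range(p) if sd[j] == 0]
        if dead:
            raise ValueError(f"constant variables cannot be scaled: {dead}")
        Xc = Xc / sd

    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(n - 1, p)
    U, s, Vt = U[:, :ncomp], s[:ncomp], Vt[:ncomp]
    # deterministic sign: largest-|.| loading of each component is positive
    for c in range(ncomp):
        jmax = np.argmax(np.abs(Vt[c]))
        if Vt[c, jmax] < 0:
            Vt[c] *= -1
            U[:, c] *= -1

    scores = U * s
    loadings = Vt.T
    eig = s**2
    var_exp = eig / eig.sum() if eig.sum() > 0 else np.zeros_like(eig)

    # variable coordinates = loading * sqrt(eigenvalue/n) / sd(variable); for
    # scaled PCA this is the correlation of the variable with the component
    col_norm = np.linalg.norm(Xc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_coord = loadings * s[None, :] / col_norm[:, None]
    var_coord = np.nan_to_num(var_coord)
    cos2_vars = var_coord**2

    d2 = np.sum(Xc**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2_ind = scores**2 / d2[:, None]
    cos2_ind = np.nan_to_num(cos2_ind)

    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var_exp,
        cos2_variables=cos2_vars,
        cos2_individuals=cos2_ind,
        variable_names=names,
        observation_names=observation_names or [f"obs{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# clustering


def cluster_strains(
    table: MedianTable,
    subset: list[str] | None = None,
    linkage_name: str = "average",
) -> ClusterResult:
    """Agglomerative clustering of strains on 1 - Pearson correlation.

    ``subset`` restricts the median vectors to the given reactions (e.g. a
    top-20 ranking or an aroma-associated set); the distance is invariant to
    positive rescaling of any strain's vector.
    """
    if len(table.strains) < 2:
        raise ValueError("clustering needs at least 2 strains")
    M = table.medians
    if subset is not None:
        missing = [r for r in subset if r not in table.reaction_ids]
        if missing:
            raise KeyError(f"subset reactions not in table: {missing}")
        if len(subset) < 2:
            raise ValueError("Pearson distance needs at least 2 reactions in the subset")
        cols = [table.reaction_ids.index(r) for r in subset]
        M = M[:, cols]
    corr = np.corrcoef(M)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    nstr = len(table.strains)
    dist = 1.0 - corr
    condensed = dist[np.triu_indices(nstr, k=1)]
    condensed = np.maximum(condensed, 0.0)
    Z = linkage(condensed, method=linkage_name)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in Z]
    return ClusterResult(list(table.strains), corr, merges, linkage_name, Z)


def _leaf_sets(Z: np.ndarray, n: int) -> dict[int, set[int]]:
    """Map each node id (leaf or internal) to its set of leaf indices."""
    sets = {i: {i} for i in range(n)}
    for idx, (a, b, _, _) in enumerate(Z):
        sets[n + idx] = sets[int(a)] | sets[int(b)]
    return sets


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


# ---------------------------------------------------------------------------
# histograms


def histogram_report(
    sample_sets: list[SampleSet], reaction_ids: list[str], bins: int = 10
) -> pd.DataFrame:
    """Relative-frequency histograms per reaction per strain on a shared range.

    Tidy frame with columns strain, reaction_id, bin_left, bin_right,
    frequency; frequencies sum to 1 per (strain, reaction).
    """
    recs = []
    for rid in reaction_ids:
        cols = [ss.column(rid) for ss in sample_sets]
        lo = min(c.min() for c in cols)
        hi = max(c.max() for c in cols)
        if hi == lo:  # fixed reaction: single occupied bin
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, bins + 1)
        for ss, col in zip(sample_sets, cols):
            counts, _ = np.histogram(col, bins=edges)
            freq = counts / counts.sum()
            for b in range(bins):
                recs.append(
                    {
                        "strain": ss.strain,
                        "reaction_id": rid,
                        "bin_left": edges[b],
                        "bin_right": edges[b + 1],
                        "frequency": freq[b],
                    }
                )
    return pd.DataFrame(recs)
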