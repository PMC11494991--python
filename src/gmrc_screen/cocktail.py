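"""Compound-effect clustering and cocktail (representative) selection.

Compounds are clustered by the similarity of their community effect profiles
e_c = mu_c - mu_MD (how each compound shifts every taxon relative to the
untreated cultured model), using 1 - Pearson correlation as the distance and
agglomerative average linkage.  A cocktail takes the top-scoring compound of
each cluster, dropping clusters whose best score falls below a threshold --
the rule that excluded the low-scoring representative of one cluster and
yielded a seven-member cocktail in the motivating screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from gmrc_screen.screening import CompoundScore, score_compound


def effect_profiles(
    profiles: pd.DataFrame,
    md: pd.Series,
    taxa: list[str] | None = None,
) -> pd.DataFrame:
    """Effect profile matrix, compounds x taxa: e_c(t) = mu_c(t) - mu_MD(t).

    ``profiles`` holds one column per compound on the transformed scale;
    ``taxa`` optionally restricts to (e.g. prevalence-filtered) taxa.
    """
    if md is None:
        raise ValueError("missing MD reference profile")
    use = list(profiles.index) if taxa is None else list(taxa)
    missing = [t for t in use if t not in profiles.index or t not in md.index]
    if missing:
        raise KeyError(f"taxa missing from profiles: {missing[:5]}")
    e = profiles.loc[use].sub(md.loc[use], axis=0).T
    e.index.name = "compound_id"
    return e


def correlation_distance(effects: pd.DataFrame) -> DistanceMatrix:
    """1 - Pearson correlation between compound effect profiles; d in [0, 2]."""
    arr = effects.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = [c for c, z in zip(effects.index, sd == 0) if z]
        raise ValueError(f"zero-variance effect profile for compound(s): {bad}")
    r = np.corrcoef(arr)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    return DistanceMatrix(d, ids=list(effects.index))


@dataclass(frozen=True)
class ClusterAssignment:
    """Compound -> cluster labels (1..k) plus the linkage tree."""

    labels: pd.Series
    linkage_matrix: np.ndarray
    k: int

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def hierarchical_cluster(
    dm: DistanceMatrix, k: int, method: str = "average"
) -> ClusterAssignment:
    """Agglomerative clustering of the compound distance matrix, cut to k
    clusters.  Cluster labels are renumbered 1..k by order of first member in
    the input id order, making the labeling input-order canonical."""
    ids = list(dm.ids)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of compounds ({len(ids)})")
    z = linkage(squareform(dm.data, checks=False), method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    # renumber by first appearance
    mapping: dict[int, int] = {}
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    labels = pd.Series([mapping[v] for v in raw], index=ids, name="cluster")
    if labels.nunique() != k:
        raise RuntimeError(
            f"cut produced {labels.nunique()} clusters instead of {k}"
        )
    return ClusterAssignment(labels=labels, linkage_matrix=z, k=k)


@dataclass(frozen=True)
class CocktailDesign:
    """Per-cluster top scorers above the admission threshold."""

    members: pd.DataFrame          # compound_id index; columns cluster, score
    excluded_clusters: pd.DataFrame  # cluster index; columns max_score, reason
    theta: float = 0.0

    @property
    def compound_ids(self) -> list[str]:
        return list(self.members.index)


def select_representatives(
    clusters: ClusterAssignment,
    scores: pd.DataFrame,
    theta: float = 0.0,
) -> CocktailDesign:
    """One representative (argmax score; ties to the lexicographically
    smallest id) per cluster; clusters whose best score is below ``theta``
    are excluded with a reason.  Members are ordered by score descending."""
    missing = [c for c in clusters.labels.index if c not in scores.index]
    if missing:
        raise KeyError(f"compounds without a score: {missing[:5]}")
    member_rows = []
    excl_rows = []
    for cl in range(1, clusters.k + 1):
        comp = clusters.members(cl)
        s = scores.loc[comp, "score"]
        best = float(s.max())
        if best < theta:
            excl_rows.append(
                {"cluster": cl, "max_score": best, "reason": f"max score < {theta}"}
            )
            continue
        winners = sorted(s.index[s == best])
        member_rows.append({"compound_id": winners[0], "cluster": cl, "score": best})
    members = pd.DataFrame(
        member_rows, columns=["compound_id", "cluster", "score"]
    ).set_index("compound_id")
    members = members.sort_index(kind="stable").sort_values(
        "score", ascending=False, kind="stable"
    )
    excluded = pd.DataFrame(
        excl_rows, columns=["cluster", "max_score", "reason"]
    ).set_index("cluster")
    return CocktailDesign(members=members, excluded_clusters=excluded, theta=theta)


def evaluate_cocktail(
    cocktail_profile: pd.Series,
    nd: pd.Series,
    md: pd.Series,
    key_genera,
    cocktail_id: str = "cocktail",
    mode: str = "signed",
) -> CompoundScore:
    """Score a cocktail-treated well profile with the same distance statistic
    used for single compounds."""
    return score_compound(
        cocktail_profile, nd, md, key_genera, compound_id=cocktail_id, mode=mode
    )
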