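"""Alpha/beta diversity, ordination and community summary statistics.

Covers the descriptive statistics of the screening workflow: Chao1 and
Shannon alpha diversity, analytic rarefaction, Bray-Curtis dissimilarity,
principal coordinate analysis, ANOSIM, the Firmicutes/Bacteroidetes ratio and
top-k genus selection.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import rankdata
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import shannon as _skbio_shannon

from gmrc_screen.tables import FeatureTable, TaxonomyMap, aggregate_to_rank

# phylum synonym unification (old/new nomenclature)
_FIRMICUTES = {"firmicutes", "bacillota"}
_BACTEROIDETES = {"bacteroidetes", "bacteroidota"}


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Per-sample observed richness, bias-corrected Chao1 and Shannon H (nats).

    Chao1 = S_obs + F1(F1-1) / (2(F2+1)) with F1/F2 the singleton/doubleton
    counts; H = -sum p ln p over nonzero proportions.
    """
    records = []
    for s in table.sample_ids:
        counts = table.data[s].to_numpy()
        if counts.sum() == 0:
            raise ValueError(f"empty sample: {s!r}")
        records.append(
            {
                "sample_id": s,
                "observed": int((counts > 0).sum()),
                "chao1": float(_skbio_chao1(counts, bias_corrected=True)),
                "shannon": float(_skbio_shannon(counts, base=math.e)),
            }
        )
    return pd.DataFrame(records).set_index("sample_id")


def rarefaction_expected(counts: np.ndarray, depth: int) -> float:
    """Expected richness E[S_n] when subsampling ``depth`` reads without
    replacement: E[S_n] = sum_t [1 - C(N - x_t, n) / C(N, n)]."""
    x = np.asarray(counts)
    x = x[x > 0]
    n_total = int(x.sum())
    if depth < 0 or depth > n_total:
        raise ValueError(f"depth must be in [0, {n_total}], got {depth}")
    if depth == 0:
        return 0.0

    def log_choose(a: np.ndarray, b: int) -> np.ndarray:
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    rest = n_total - x
    p_absent = np.zeros(len(x))
    ok = rest >= depth
    p_absent[ok] = np.exp(log_choose(rest[ok].astype(float), depth) - log_choose(np.array(float(n_total)), depth))
    return float(np.sum(1.0 - p_absent))


def bray_curtis(table: FeatureTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between samples, on relative abundances.

    BC_ij = sum_t |p_ti - p_tj| / sum_t (p_ti + p_tj) in [0, 1].
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    rel = table.relative_abundance().to_numpy().T  # samples x taxa
    d = squareform(pdist(rel, metric="braycurtis"))
    return DistanceMatrix(d, ids=table.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA result: sample coordinates on positive-eigenvalue axes."""

    coordinates: pd.DataFrame        # samples x axes, columns PC1..PCk
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues only
    n_negative: int                  # negative eigenvalues dropped


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical metric MDS via Gower centering.

    B = -1/2 J D^2 J with J the centering matrix; coordinates are
    v_k sqrt(lambda_k) for positive eigenvalues, axes ordered by eigenvalue.
    Negative eigenvalues (non-Euclidean input) are dropped and their count
    reported; no Lingoes/Cailliez correction is applied.
    """
    d = dm.data.astype(float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    b = (b + b.T) / 2
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    atol = 1e-12 * max(1.0, float(abs(eigvals).max(initial=1.0)))
    pos = eigvals > atol
    n_negative = int((eigvals < -atol).sum())
    if not pos.any():
        coords = pd.DataFrame(np.zeros((n, 1)), index=list(dm.ids), columns=["PC1"])
        return OrdinationResult(coords, eigvals, np.array([0.0]), n_negative)
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigvals,
        lam / lam.sum(),
        n_negative,
    )


def _anosim_r(rank_condensed: np.ndarray, labels: np.ndarray, pair_idx: np.ndarray) -> float:
    n = len(labels)
    within = labels[pair_idx[:, 0]] == labels[pair_idx[:, 1]]
    r_w = rank_condensed[within].mean()
    r_b = rank_condensed[~within].mean()
    return float((r_b - r_w) / (n * (n - 1) / 4.0))


def _distinct_permutations(labels: tuple):
    """Yield distinct permutations of a label multiset (lexicographic)."""
    pool = sorted(labels)
    n = len(pool)

    def rec(remaining: list, prefix: list):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        seen = set()
        for i, lab in enumerate(remaining):
            if lab in seen:
                continue
            seen.add(lab)
            yield from rec(remaining[:i] + remaining[i + 1:], prefix + [lab])

    yield from rec(pool, [])


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4).
    When the number of distinct labelings is at most ``n_perm`` the null is
    enumerated exhaustively and p = #{R_perm >= R_obs} / #labelings;
    otherwise p = (#{R_perm >= R_obs} + 1) / (n_perm + 1) over random
    label shuffles driven by ``seed``.
    """
    ids = list(dm.ids)
    if isinstance(groups, pd.Series):
        labels = np.asarray([groups[i] for i in ids])
    elif isinstance(groups, dict):
        labels = np.asarray([groups[i] for i in ids])
    else:
        labels = np.asarray(list(groups))
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs at least 2 groups")
    n = len(ids)
    cond = dm.condensed_form()
    ranks = rankdata(cond)
    pair_idx = np.array(list(itertools.combinations(range(n), 2)))
    r_obs = _anosim_r(ranks, labels, pair_idx)

    n_labelings = math.factorial(n)
    for c in counts:
        n_labelings //= math.factorial(int(c))
    if n_labelings <= n_perm:
        hits = sum(
            _anosim_r(ranks, np.asarray(perm), pair_idx) >= r_obs - 1e-12
            for perm in _distinct_permutations(tuple(labels))
        )
        return r_obs, hits / n_labelings
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm, pair_idx) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (hits + 1) / (n_perm + 1)


def fb_ratio(table: FeatureTable, tax: TaxonomyMap) -> pd.Series:
    """Per-sample Firmicutes / Bacteroidetes count ratio, a coarse dysbiosis
    indicator.  Synonyms Bacteroidota/Bacteroidetes and Firmicutes/Bacillota
    are unified.  Zero Bacteroidetes yields +inf with a warning."""
    phyla = aggregate_to_rank(table, tax, "phylum")
    low = {p.lower(): p for p in phyla.taxon_ids}
    f = np.zeros(table.shape[1])
    b = np.zeros(table.shape[1])
    for name, orig in low.items():
        if name in _FIRMICUTES:
            f += phyla.data.loc[orig].to_numpy()
        elif name in _BACTEROIDETES:
            b += phyla.data.loc[orig].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(b > 0, f / np.where(b > 0, b, 1), np.inf)
    if (b == 0).any():
        bad = [s for s, bz in zip(table.sample_ids, b == 0) if bz]
        warnings.warn(f"zero Bacteroidetes counts; F/B undefined for {bad}")
    return pd.Series(ratio, index=table.sample_ids, name="fb_ratio")


def top_genera(table: FeatureTable, k: int) -> list[str]:
    """Top-k taxa by mean relative abundance across samples; ties broken
    lexicographically; k truncated to the number of taxa."""
    if k < 1:
        raise ValueError("k must be >= 1")
    means = table.relative_abundance().mean(axis=1)
    ordered = means.sort_index(kind="stable").sort_values(
        ascending=False, kind="stable"
    )
    return list(ordered.index[: min(k, len(ordered))])
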