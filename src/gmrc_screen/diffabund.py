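"""Negative-binomial two-group differential abundance and key-genus selection.

A deliberately closed-form variant of the DESeq2 recipe: median-of-ratios
size factors, per-taxon method-of-moments dispersion under the NB
mean-variance relation var = mu + alpha mu^2, a Wald test on the log2 fold
change of normalized group means, and Benjamini-Hochberg correction.  No
dispersion shrinkage toward a trend, no Cook's-distance outlier handling and
no independent filtering are performed, keeping every quantity a documented
closed-form function of the counts.

Key genera are those shifted significantly *and in the same direction* in
both the in vivo contrast (M vs N) and the in vitro contrast (MD vs ND); they
form the panel over which compounds are scored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from gmrc_screen.tables import FeatureTable, SampleMetadata

_LN2 = np.log(2.0)
_DISPERSION_FLOOR = 1e-8


def size_factors(table: FeatureTable, fallback: bool = True) -> pd.Series:
    """DESeq2-style median-of-ratios size factors, rescaled to geometric mean 1.

    The reference set is the taxa with nonzero counts in every sample; when
    none exists and ``fallback`` is true, per-taxon geometric means are taken
    over the positive counts only (the "poscounts" convention).
    """
    x = table.counts.astype(float)
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        ref = x[all_nonzero]
        log_geo = np.mean(np.log(ref), axis=1)
        ratios = np.log(ref) - log_geo[:, None]
    elif fallback:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        log_geo = np.nanmean(logx, axis=1)
        ratios = logx - log_geo[:, None]
        if np.all(np.isnan(ratios)):
            raise ValueError("cannot estimate size factors: all-zero table")
    else:
        raise ValueError(
            "no taxon has nonzero counts in every sample and fallback is disabled"
        )
    log_s = np.nanmedian(ratios, axis=0)
    log_s = log_s - np.mean(log_s)  # geometric mean 1
    return pd.Series(np.exp(log_s), index=table.sample_ids, name="size_factor")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _moment_dispersion(y: np.ndarray, group_sizes: tuple[int, int]) -> np.ndarray:
    """Per-taxon moment estimator of the NB dispersion alpha from pooled
    within-group residuals: solves E[RSS] = sum_G (n_G - 1)(mu_G + alpha mu_G^2).
    """
    n_a, n_b = group_sizes
    ya, yb = y[:, :n_a], y[:, n_a:]
    mu_a = ya.mean(axis=1)
    mu_b = yb.mean(axis=1)
    rss = ((ya - mu_a[:, None]) ** 2).sum(axis=1) + ((yb - mu_b[:, None]) ** 2).sum(axis=1)
    num = rss - ((n_a - 1) * mu_a + (n_b - 1) * mu_b)
    den = (n_a - 1) * mu_a ** 2 + (n_b - 1) * mu_b ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, _DISPERSION_FLOOR)


def nb_wald_test(
    table: FeatureTable,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    min_prevalence: int = 1,
) -> pd.DataFrame:
    """NB Wald test of group B vs group A (log2 fold change of B over A).

    Counts are normalized by median-of-ratios size factors; group means get a
    +0.5 pseudocount so the fold change stays finite for all-zero groups; the
    standard error follows from the delta method under var = mu + alpha mu^2.
    Taxa with nonzero counts in fewer than ``min_prevalence`` of the involved
    samples are reported untested (NaN statistics, excluded from BH).

    Returns a DataFrame indexed by taxon with columns ``base_mean``, ``log2fc``,
    ``se``, ``wald``, ``pvalue``, ``qvalue``, ``dispersion``, ``tested``.
    """
    samples_a = meta.samples_in_group(group_a)
    samples_b = meta.samples_in_group(group_b)
    for name, smp in ((group_a, samples_a), (group_b, samples_b)):
        if not smp:
            raise ValueError(f"group absent from metadata: {name!r}")
        if len(smp) < 2:
            raise ValueError(f"group {name!r} needs >= 2 samples, has {len(smp)}")
    sub = table.select_samples(samples_a + samples_b)
    s = size_factors(sub)
    y = sub.counts / s.to_numpy()[None, :]
    n_a, n_b = len(samples_a), len(samples_b)

    tested = (sub.counts > 0).sum(axis=1) >= min_prevalence
    mu_a = y[:, :n_a].mean(axis=1)
    mu_b = y[:, n_a:].mean(axis=1)
    alpha = _moment_dispersion(y, (n_a, n_b))

    mu_a_t = mu_a + 0.5
    mu_b_t = mu_b + 0.5
    log2fc = np.log2(mu_b_t / mu_a_t)
    var_a = (mu_a_t + alpha * mu_a_t ** 2) / n_a
    var_b = (mu_b_t + alpha * mu_b_t ** 2) / n_b
    se = np.sqrt(var_a / mu_a_t ** 2 + var_b / mu_b_t ** 2) / _LN2
    wald = log2fc / se
    pvalue = 2.0 * norm.sf(np.abs(wald))

    out = pd.DataFrame(
        {
            "base_mean": y.mean(axis=1),
            "log2fc": log2fc,
            "se": se,
            "wald": wald,
            "pvalue": pvalue,
            "qvalue": np.nan,
            "dispersion": alpha,
            "tested": tested,
        },
        index=sub.taxon_ids,
    )
    out.index.name = "taxon_id"
    out.loc[~tested, ["log2fc", "se", "wald", "pvalue"]] = np.nan
    if tested.any():
        out.loc[tested, "qvalue"] = bh_adjust(out.loc[tested, "pvalue"].to_numpy())
    out.attrs["size_factors"] = s
    out.attrs["groups"] = (group_a, group_b)
    return out


def select_key_genera(
    vivo: pd.DataFrame,
    vitro: pd.DataFrame,
    alpha_level: float = 0.05,
    require: str = "both",
) -> pd.DataFrame:
    """Consistent-trend key-genus selection over two contrasts.

    A genus is selected when its BH-adjusted p-value is below ``alpha_level``
    in the in vivo contrast (M vs N) and -- with ``require='both'``, the
    default -- also in the in vitro contrast (MD vs ND), with matching
    nonzero fold-change signs.  ``require='vivo'`` is the relaxed mode:
    in vitro only the direction must agree.

    Returns a DataFrame indexed by genus, sorted by |in vivo log2fc|
    descending, with columns ``direction`` (+1/-1), ``log2fc_vivo``,
    ``qvalue_vivo``, ``log2fc_vitro``, ``qvalue_vitro``.
    """
    if require not in ("both", "vivo"):
        raise ValueError("require must be 'both' or 'vivo'")
    shared = vivo.index.intersection(vitro.index)
    rows = []
    for g in shared:
        b1, q1 = vivo.loc[g, "log2fc"], vivo.loc[g, "qvalue"]
        b2, q2 = vitro.loc[g, "log2fc"], vitro.loc[g, "qvalue"]
        if not (np.isfinite(b1) and np.isfinite(b2) and np.isfinite(q1)):
            continue
        sig = q1 < alpha_level and (require == "vivo" or (np.isfinite(q2) and q2 < alpha_level))
        if sig and np.sign(b1) == np.sign(b2) != 0:
            rows.append(
                {
                    "genus": g,
                    "direction": int(np.sign(b1)),
                    "log2fc_vivo": float(b1),
                    "qvalue_vivo": float(q1),
                    "log2fc_vitro": float(b2),
                    "qvalue_vitro": float(q2),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "genus",
            "direction",
            "log2fc_vivo",
            "qvalue_vivo",
            "log2fc_vitro",
            "qvalue_vitro",
        ],
    ).set_index("genus")
    return out.reindex(out["log2fc_vivo"].abs().sort_values(ascending=False).index)
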