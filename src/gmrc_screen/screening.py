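"""Distance-based compound remodeling score and growth-based screening rules.

The core statistic: for each key genus g the score measures how much closer a
compound-treated community sits to the healthy cultured reference (ND) than
the untreated dysbiotic baseline (MD) does,

    delta_g(c) = |mu_MD(g) - mu_ND(g)| - |mu_c(g) - mu_ND(g)|,

summed over the key-genus panel, S(c) = sum_g delta_g(c).  Shifts toward ND
count positive, shifts away (including overshoot past ND) count negative;
S(MD) = 0 and S is bounded by S_max = sum_g |mu_MD(g) - mu_ND(g)|, attained
when the compound restores every key genus exactly to the ND mean.

Profiles mu are replicate means of log10 pseudocounted relative abundances
(see :func:`gmrc_screen.tables.transform_log_relative`).

Also here: the MIC rule (lowest concentration inhibiting over 90% of growth),
the mixed-community viability filter (concentrations causing over 80% OD600
reduction are excluded) and the cocktail alpha-diversity exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from gmrc_screen.tables import SampleMetadata, TransformedTable


# ---------------------------------------------------------------------------
# group profiles
# ---------------------------------------------------------------------------

def group_profiles(
    tt: TransformedTable, meta: SampleMetadata
) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate-mean transformed profile per group.

    Groups are the canonical N/M/ND/MD sets plus one group per treatment id.
    Returns ``(profiles, n_replicates)`` where ``profiles`` is taxa x groups.
    The mean is taken on the transformed scale (mean of logs, not log of
    mean), which keeps the score additive over genera.
    """
    groups: dict[str, list[str]] = {}
    for g in ("N", "M", "ND", "MD"):
        smp = [s for s in meta.samples_in_group(g) if s in tt.sample_ids]
        if smp:
            groups[g] = smp
    for t in meta.treatments():
        smp = [s for s in meta.samples_in_group(t) if s in tt.sample_ids]
        if smp:
            groups[t] = smp
    if not groups:
        raise ValueError("no group has samples present in the transformed table")
    profiles = pd.DataFrame(
        {g: tt.data[smp].mean(axis=1) for g, smp in groups.items()}
    )
    n_rep = pd.Series({g: len(smp) for g, smp in groups.items()}, name="n_replicates")
    return profiles, n_rep


# ---------------------------------------------------------------------------
# remodeling score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundScore:
    """Per-genus closeness improvements and total remodeling score."""

    compound_id: str
    delta: pd.Series     # per key genus
    total: float         # S(c) = sum(delta)
    s_max: float         # sum_g |mu_MD - mu_ND|


def score_compound(
    compound: pd.Series,
    nd: pd.Series,
    md: pd.Series,
    key_genera,
    compound_id: str = "compound",
    mode: str = "signed",
) -> CompoundScore:
    """Score one compound profile against the ND/MD references over the key
    genera.

    ``mode='signed'`` (default) sums the signed closeness improvements, so
    moves away from ND subtract from the score; ``mode='absolute'`` sums
    their absolute values (rewarding any movement relative to MD's distance).
    """
    if mode not in ("signed", "absolute"):
        raise ValueError("mode must be 'signed' or 'absolute'")
    if isinstance(key_genera, (pd.DataFrame, pd.Series)):
        genera = list(key_genera.index)
    else:
        genera = list(key_genera)
    for name, prof in (("compound", compound), ("ND", nd), ("MD", md)):
        missing = [g for g in genera if g not in prof.index]
        if missing:
            raise KeyError(f"genus missing from {name} profile: {missing}")
    mu_c = compound.loc[genera].to_numpy(dtype=float)
    mu_nd = nd.loc[genera].to_numpy(dtype=float)
    mu_md = md.loc[genera].to_numpy(dtype=float)
    delta = np.abs(mu_md - mu_nd) - np.abs(mu_c - mu_nd)
    if mode == "absolute":
        delta = np.abs(delta)
    s_max = float(np.abs(mu_md - mu_nd).sum())
    return CompoundScore(
        compound_id=compound_id,
        delta=pd.Series(delta, index=genera, name="delta"),
        total=float(delta.sum()),
        s_max=s_max,
    )


def score_all(
    profiles: pd.DataFrame,
    nd: pd.Series,
    md: pd.Series,
    key_genera,
    mode: str = "signed",
) -> pd.DataFrame:
    """Score every column of ``profiles``; ranked descending by S, ties broken
    lexicographically by compound id.  Returns a DataFrame indexed by
    compound with columns ``score`` and ``s_max``."""
    if profiles.shape[1] < 1:
        raise ValueError("need at least one compound profile")
    rows = {}
    for c in profiles.columns:
        sc = score_compound(profiles[c], nd, md, key_genera, compound_id=c, mode=mode)
        rows[c] = (sc.total, sc.s_max)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["score", "s_max"])
    out.index.name = "compound_id"
    out = out.sort_index(kind="stable")
    return out.sort_values("score", ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# growth-based rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MICResult:
    """MIC call for one compound: lowest tested concentration inhibiting over
    90% of growth, or None when never reached."""

    compound_id: str
    mic: float | None
    max_tested: float
    inhibition: pd.Series  # per concentration

    @property
    def reached(self) -> bool:
        return self.mic is not None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.reached:
            return f"MIC({self.compound_id}) = {self.mic}"
        return f"MIC({self.compound_id}) not reached > {self.max_tested}"


_GROWTH_COLUMNS = (
    "compound_id",
    "concentration",
    "od600_t0",
    "od600_t24",
    "control_od600_t0",
    "control_od600_t24",
)


def _check_growth(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _GROWTH_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"growth records missing column(s): {missing}")
    if (records["concentration"] <= 0).any():
        raise ValueError("concentrations must be positive")
    return records.sort_values("concentration", kind="stable")


def mic(records: pd.DataFrame, threshold: float = 0.90) -> MICResult:
    """MIC of one compound from a concentration ladder of growth records.

    Inhibition at the 24 h endpoint is I = 1 - OD_treated / OD_control; the
    MIC is the lowest concentration with I strictly greater than ``threshold``
    (an inhibition of exactly 90% does not qualify).
    """
    rec = _check_growth(records)
    if rec["compound_id"].nunique() != 1:
        raise ValueError("mic() expects records for a single compound")
    if len(rec) < 2:
        raise ValueError("need a ladder of >= 2 concentrations")
    if (rec["control_od600_t24"] <= 0).any():
        raise ValueError("missing or non-positive control OD600")
    inhibition = 1.0 - rec["od600_t24"].to_numpy() / rec["control_od600_t24"].to_numpy()
    conc = rec["concentration"].to_numpy()
    above = inhibition > threshold
    mic_value = float(conc[above][0]) if above.any() else None
    return MICResult(
        compound_id=str(rec["compound_id"].iloc[0]),
        mic=mic_value,
        max_tested=float(conc.max()),
        inhibition=pd.Series(inhibition, index=conc, name="inhibition"),
    )


def viability_filter(records: pd.DataFrame, max_reduction: float = 0.80) -> pd.DataFrame:
    """Admissible concentrations for mixed-community incubation.

    The OD600 *gain* over the incubation (delta OD = OD24 - OD0) is compared
    with the drug-free control; a concentration is kept iff
    1 - deltaOD_treated / deltaOD_control <= ``max_reduction`` (strictly more
    than 80% reduction is excluded, by default).

    Returns the records with added ``reduction`` and ``admissible`` columns.
    """
    rec = _check_growth(records).copy()
    d_treated = rec["od600_t24"] - rec["od600_t0"]
    d_control = rec["control_od600_t24"] - rec["control_od600_t0"]
    if (d_control <= 0).any():
        raise ValueError("non-positive control delta OD600")
    rec["reduction"] = 1.0 - d_treated / d_control
    rec["admissible"] = rec["reduction"] <= max_reduction
    return rec


def cocktail_alpha_exclusion(
    alpha: pd.DataFrame,
    conditions: dict[str, list[str]],
    md_samples: list[str],
    tau: float = 0.5,
) -> pd.DataFrame:
    """Exclude cocktail conditions that collapse alpha diversity.

    A condition is excluded when its mean Shannon index drops below
    ``tau`` times the mean Shannon index of the MD reference wells.
    ``alpha`` is the output of :func:`gmrc_screen.diversity.alpha_diversity`.
    """
    missing = [s for s in md_samples if s not in alpha.index]
    if missing:
        raise ValueError(f"MD reference records missing: {missing}")
    md_mean = float(alpha.loc[md_samples, "shannon"].mean())
    rows = []
    for cond, samples in conditions.items():
        m = float(alpha.loc[samples, "shannon"].mean())
        rows.append(
            {
                "condition": cond,
                "mean_shannon": m,
                "md_mean_shannon": md_mean,
                "excluded": m < tau * md_mean,
            }
        )
    return pd.DataFrame(rows).set_index("condition")
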