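"""Seeded synthetic screening study with planted ground truth.

Emulates the full experimental design of an in vitro compound screen against
a dysbiotic gut community: uncultured control/model groups (N/M, n=5), their
cultured counterparts (ND/MD, n=3), and one treatment well group per
compound (n=3).  The generator plants

* a disease panel of genera shifted between model and control with known
  signed log2 fold changes (the literature-named SIRS genera --
  *Enterobacter*, *Escherichia-Shigella*, *Bacteroides*, *Parabacteroides*,
  *Enterococcus* up; *Lactobacillus*, *Bifidobacterium* down -- are always
  present with those directions),
* an abundance-biased culture drop-out reproducing the observed loss of
  richness between uncultured and cultured communities,
* compound families sharing target-taxon sets, each compound restoring its
  targets a known fraction rho toward the healthy cultured state (negative
  rho models a community-disturbing compound that pushes targets further
  away), and
* negative-binomial count noise (var = mu + alpha mu^2) on log-normal
  library sizes.

Identical seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gmrc_screen.tables import FeatureTable, SampleMetadata, TaxonomyMap

#: literature-named genera with their phylum and disease direction
#: (+1 increased in the model, -1 decreased)
NAMED_GENERA: dict[str, tuple[str, int]] = {
    "Enterobacter": ("Proteobacteria", +1),
    "Escherichia-Shigella": ("Proteobacteria", +1),
    "Bacteroides": ("Bacteroidota", +1),
    "Parabacteroides": ("Bacteroidota", +1),
    "Enterococcus": ("Firmicutes", +1),
    "Lactobacillus": ("Firmicutes", -1),
    "Bifidobacterium": ("Actinobacteriota", -1),
}

_DEFAULT_PHYLA = {
    "Firmicutes": 0.45,
    "Bacteroidota": 0.30,
    "Proteobacteria": 0.15,
    "Actinobacteriota": 0.07,
    "Verrucomicrobiota": 0.03,
}


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic screening study.

    Defaults mirror the motivating study design: 120 genera, a 17-genus
    disease panel with |log2FC| ~ U(1, 3), culture retention 62/80, NB
    dispersion 0.05, libraries ~ LogNormal(ln 30000, 0.3), n=5 in vivo and
    n=3 in vitro replicates, and 51 compounds in 8 families.
    """

    n_taxa: int = 120
    phylum_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PHYLA)
    )
    sigma_baseline: float = 1.5
    n_disease: int = 17
    disease_lfc_range: tuple[float, float] = (1.0, 3.0)
    culture_retention: float = 62.0 / 80.0
    dispersion: float = 0.05
    library_log_mean: float = math.log(30_000.0)
    library_log_sd: float = 0.3
    n_vivo: int = 5
    n_vitro: int = 3
    n_compounds: int = 51
    n_families: int = 8
    #: per-family (lo, hi) restoration-fraction range; None = (0.05, 0.95)
    #: for every family.  Negative values model disturbing compounds.
    family_rho_ranges: Sequence[tuple[float, float]] | None = None
    #: explicit per-compound rho overriding the family ranges (length
    #: n_compounds); useful for planting a known rho ladder.
    rho_values: Sequence[float] | None = None
    #: fraction range of the disease panel each family targets
    family_target_fraction: tuple[float, float] = (0.6, 0.9)
    #: sd of the per-compound off-target log-perturbation
    sigma_off: float = 0.05
    #: sd of the shared per-family off-target signature (the mode-of-action
    #: fingerprint that makes family members resemble each other even at
    #: small rho)
    sigma_family: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        probs = np.array(list(self.phylum_probs.values()), dtype=float)
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError("phylum probabilities must be >= 0 and sum to 1")
        if not (0 < self.culture_retention <= 1):
            raise ConfigError("culture retention must be in (0, 1]")
        if self.n_taxa < self.n_disease:
            raise ConfigError("n_taxa must be >= n_disease")
        if self.n_disease < len(NAMED_GENERA):
            raise ConfigError(
                f"n_disease must be >= {len(NAMED_GENERA)} (named genera)"
            )
        for v in ("n_taxa", "n_vivo", "n_vitro", "n_compounds", "n_families"):
            if getattr(self, v) < 1:
                raise ConfigError(f"{v} must be positive")
        if self.n_families > self.n_compounds:
            raise ConfigError("n_families must be <= n_compounds")
        ranges = self.family_rho_ranges
        if ranges is not None:
            if len(ranges) != self.n_families:
                raise ConfigError("family_rho_ranges must have one entry per family")
            for lo, hi in ranges:
                if not (-1 <= lo <= hi <= 1):
                    raise ConfigError("rho ranges must satisfy -1 <= lo <= hi <= 1")
        if self.rho_values is not None and len(self.rho_values) != self.n_compounds:
            raise ConfigError("rho_values must have length n_compounds")
        if (
            self.sigma_off < 0
            or self.sigma_family < 0
            or self.sigma_baseline <= 0
            or self.dispersion < 0
        ):
            raise ConfigError("noise parameters must be non-negative (sigma_b > 0)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth of a simulated study."""

    disease: pd.DataFrame          # genus index; columns direction, log2fc
    family_of: pd.Series           # compound -> family id (1..F)
    targets: dict[int, list[str]]  # family -> target genera
    rho: pd.Series                 # compound -> restoration fraction
    dropped_taxa: list[str]
    retained_taxa: list[str]
    mean_profiles: pd.DataFrame    # true relative-abundance mean per group

    def to_json(self, path: str | Path) -> None:
        doc = {
            "disease": {
                g: {"direction": int(r["direction"]), "log2fc": float(r["log2fc"])}
                for g, r in self.disease.iterrows()
            },
            "family_of": {c: int(f) for c, f in self.family_of.items()},
            "targets": {str(f): list(t) for f, t in self.targets.items()},
            "rho": {c: float(r) for c, r in self.rho.items()},
            "dropped_taxa": self.dropped_taxa,
            "retained_taxa": self.retained_taxa,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


def _softmax(log_w: np.ndarray) -> np.ndarray:
    z = np.exp(log_w - log_w.max())
    return z / z.sum()


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with var = mu + alpha mu^2 (Poisson when alpha ~ 0)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if alpha <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
        return out
    n = 1.0 / alpha
    p = n / (n + mu[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


def _compound_log_profile(
    log_md: np.ndarray,
    log_nd: np.ndarray,
    target_mask: np.ndarray,
    rho: float,
    off_noise: np.ndarray,
) -> np.ndarray:
    """Mean log relative-abundance profile of a treated well before
    renormalization: targets interpolate fraction ``rho`` of the way from the
    MD log profile toward the ND one; non-targets get the off-target
    log-perturbation."""
    log_c = log_md.copy()
    log_c[target_mask] = (1.0 - rho) * log_md[target_mask] + rho * log_nd[target_mask]
    log_c[~target_mask] += off_noise[~target_mask]
    return log_c


def simulate_study(
    config: SimulationConfig,
) -> tuple[FeatureTable, TaxonomyMap, SampleMetadata, GroundTruth]:
    """Generate the full synthetic study (counts, taxonomy, metadata, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- taxa, phyla, taxonomy -------------------------------------------
    named = list(NAMED_GENERA)
    n_anon = config.n_taxa - len(named)
    width = max(3, len(str(config.n_taxa)))
    taxa = named + [f"Genus_{i + 1:0{width}d}" for i in range(n_anon)]
    phyla_pool = list(config.phylum_probs)
    probs = np.array([config.phylum_probs[p] for p in phyla_pool])
    phylum = {g: NAMED_GENERA[g][0] for g in named}
    for g in taxa[len(named):]:
        phylum[g] = phyla_pool[rng.choice(len(phyla_pool), p=probs)]
    lineages = {
        g: (
            "k__Bacteria",
            f"p__{phylum[g]}",
            f"c__{phylum[g]}_c",
            f"o__{phylum[g]}_o",
            f"f__{phylum[g]}_f",
            f"g__{g}",
        )
        for g in taxa
    }
    tax = TaxonomyMap(lineages)

    # --- baseline and disease effects ------------------------------------
    a = rng.normal(0.0, config.sigma_baseline, size=config.n_taxa)
    med = float(np.median(a))
    # plant the named genera in the detectable (above-median) abundance range
    for i in range(len(named)):
        a[i] = med + abs(rng.normal(0.0, config.sigma_baseline / 2.0))
    eligible = [
        i for i in range(len(named), config.n_taxa) if a[i] >= med
    ]
    extra = rng.choice(eligible, size=config.n_disease - len(named), replace=False)
    disease_idx = np.array(list(range(len(named))) + sorted(int(i) for i in extra))
    signs = np.array(
        [NAMED_GENERA[taxa[i]][1] for i in range(len(named))]
        + list(rng.choice([-1, 1], size=config.n_disease - len(named))),
        dtype=int,
    )
    lo, hi = config.disease_lfc_range
    mags = rng.uniform(lo, hi, size=config.n_disease)
    lfc = signs * mags  # log2 scale, model vs control

    log_n = a.copy()
    log_m = a.copy()
    log_m[disease_idx] += lfc * math.log(2.0)

    # --- culture drop-out (abundance-biased, disease panel exempt) -------
    n_drop = int(round((1.0 - config.culture_retention) * config.n_taxa))
    droppable = np.array(
        [i for i in range(config.n_taxa) if i not in set(disease_idx)]
    )
    n_drop = min(n_drop, len(droppable))
    w = np.exp(-a[droppable])  # rarer taxa more likely lost
    dropped = rng.choice(droppable, size=n_drop, replace=False, p=w / w.sum())
    retained_mask = np.ones(config.n_taxa, dtype=bool)
    retained_mask[dropped] = False

    p_n = _softmax(log_n)
    p_m = _softmax(log_m)
    log_nd = np.where(retained_mask, log_n, -np.inf)
    log_md = np.where(retained_mask, log_m, -np.inf)
    p_nd = np.where(retained_mask, p_n, 0.0)
    p_nd /= p_nd.sum()
    p_md = np.where(retained_mask, p_m, 0.0)
    p_md /= p_md.sum()

    # --- compound families ------------------------------------------------
    compounds = [f"C{i + 1:02d}" for i in range(config.n_compounds)]
    family_of = pd.Series(
        (np.arange(config.n_compounds) % config.n_families) + 1,
        index=compounds,
        name="family",
    )
    flo, fhi = config.family_target_fraction
    targets: dict[int, list[str]] = {}
    for f in range(1, config.n_families + 1):
        size = int(rng.integers(
            max(1, round(flo * config.n_disease)),
            max(2, round(fhi * config.n_disease) + 1),
        ))
        pick = rng.choice(disease_idx, size=min(size, len(disease_idx)), replace=False)
        targets[f] = sorted(taxa[int(i)] for i in pick)
    if config.rho_values is not None:
        rho = pd.Series(list(config.rho_values), index=compounds, name="rho", dtype=float)
    else:
        # Within each family the restoration fractions sit on a shuffled
        # ladder with a clear lead compound: the lead takes the top of the
        # family's range and the runner-up is separated by 40% of the range,
        # the rest spaced evenly below.  The separation keeps the planted
        # best member identifiable at the study's replicate depth (n=3
        # wells); without it the best-in-family question is unanswerable by
        # any method when two fractions nearly tie.
        ranges = config.family_rho_ranges or [(0.05, 0.95)] * config.n_families
        rho = pd.Series(np.nan, index=compounds, name="rho", dtype=float)
        for f in range(1, config.n_families + 1):
            members = [c for c in compounds if family_of[c] == f]
            lo_r, hi_r = ranges[f - 1]
            m = len(members)
            if m == 1:
                ladder = np.array([hi_r])
            else:
                ladder = np.concatenate(
                    [np.linspace(lo_r, lo_r + 0.6 * (hi_r - lo_r), m - 1), [hi_r]]
                )
            rho[members] = rng.permutation(ladder)

    taxa_index = pd.Index(taxa, name="taxon_id")
    mean_profiles = pd.DataFrame(
        {"N": p_n, "M": p_m, "ND": p_nd, "MD": p_md}, index=taxa_index
    )

    # finite log profiles restricted to retained taxa, for interpolation
    r_idx = np.where(retained_mask)[0]
    log_md_r = np.log(p_md[r_idx])
    log_nd_r = np.log(p_nd[r_idx])
    taxon_pos = {taxa[int(i)]: k for k, i in enumerate(r_idx)}

    family_sig = {
        f: (
            rng.normal(0.0, config.sigma_family, size=len(r_idx))
            if config.sigma_family > 0
            else np.zeros(len(r_idx))
        )
        for f in range(1, config.n_families + 1)
    }
    compound_p: dict[str, np.ndarray] = {}
    for c in compounds:
        t_mask = np.zeros(len(r_idx), dtype=bool)
        for g in targets[family_of[c]]:
            t_mask[taxon_pos[g]] = True
        off = family_sig[family_of[c]] + (
            rng.normal(0.0, config.sigma_off, size=len(r_idx))
            if config.sigma_off > 0
            else 0.0
        )
        log_c = _compound_log_profile(log_md_r, log_nd_r, t_mask, float(rho[c]), off)
        p_c_full = np.zeros(config.n_taxa)
        p_c_full[r_idx] = _softmax(log_c)
        compound_p[c] = p_c_full
        mean_profiles[c] = p_c_full

    # --- draw counts ------------------------------------------------------
    sample_specs: list[tuple[str, str, np.ndarray, str, str, str, int]] = []
    for grp, n_rep, p, cult, dis in (
        ("N", config.n_vivo, p_n, "uncultured", "control"),
        ("M", config.n_vivo, p_m, "uncultured", "model"),
        ("ND", config.n_vitro, p_nd, "cultured", "control"),
        ("MD", config.n_vitro, p_md, "cultured", "model"),
    ):
        for r in range(1, n_rep + 1):
            sample_specs.append((f"{grp}_{r}", grp, p, cult, dis, "none", r))
    for c in compounds:
        for r in range(1, config.n_vitro + 1):
            sample_specs.append(
                (f"{c}_{r}", c, compound_p[c], "cultured", "model", c, r)
            )

    counts = {}
    meta_rows = []
    for sid, grp, p, cult, dis, treat, rep in sample_specs:
        lib = float(np.exp(rng.normal(config.library_log_mean, config.library_log_sd)))
        counts[sid] = _nb_counts(rng, lib * p, config.dispersion)
        meta_rows.append(
            {
                "sample_id": sid,
                "group_label": grp,
                "culture_status": cult,
                "disease_status": dis,
                "treatment_id": treat,
                "replicate": rep,
            }
        )

    table = FeatureTable(pd.DataFrame(counts, index=taxa_index))
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(
        disease=pd.DataFrame(
            {"direction": signs, "log2fc": lfc},
            index=pd.Index([taxa[int(i)] for i in disease_idx], name="genus"),
        ),
        family_of=family_of,
        targets=targets,
        rho=rho,
        dropped_taxa=sorted(taxa[int(i)] for i in dropped),
        retained_taxa=sorted(taxa[int(i)] for i in r_idx),
        mean_profiles=mean_profiles,
    )
    return table, tax, meta, truth


# ---------------------------------------------------------------------------
# growth curves / MIC fixtures
# ---------------------------------------------------------------------------

def simulate_growth(
    config: SimulationConfig,
    concentrations: Sequence[float] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0),
    no_effect_fraction: float = 0.2,
    hill: float = 8.0,
    od_noise_sd: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Growth/OD600 records per compound x concentration with known true MIC.

    Expected relative growth follows a steep Hill curve
    g(x) = 1 / (1 + (x / IC50)^hill), monotone non-increasing in
    concentration; a ``no_effect_fraction`` of compounds get IC50 far above
    the ladder (MIC never reached).  The true MIC is read off the noiseless
    inhibition curve 1 - g.

    Returns ``(records, truth)``: records with the growth-record columns
    consumed by :func:`gmrc_screen.screening.mic`, truth with per-compound
    ``ic50`` and ``true_mic`` (NaN when not reached).
    """
    config.validate()
    conc = np.asarray(sorted(concentrations), dtype=float)
    if len(conc) < 2 or (conc <= 0).any():
        raise ConfigError("need a ladder of >= 2 positive concentrations")
    rng = np.random.default_rng(config.seed + 1)
    compounds = [f"C{i + 1:02d}" for i in range(config.n_compounds)]
    od0, od24_control = 0.05, 1.05
    rows, truth_rows = [], []
    for c in compounds:
        if rng.uniform() < no_effect_fraction:
            ic50 = np.inf
        else:
            ic50 = float(np.exp(rng.uniform(np.log(conc[0] / 2), np.log(conc[-1]))))
        growth = 1.0 / (1.0 + (conc / ic50) ** hill) if np.isfinite(ic50) else np.ones_like(conc)
        # endpoint inhibition as the MIC rule sees it (OD24 ratio, noiseless)
        inhibition = 1.0 - (od0 + (od24_control - od0) * growth) / od24_control
        above = inhibition > 0.90
        true_mic = float(conc[above][0]) if above.any() else np.nan
        noise = rng.normal(0.0, od_noise_sd, size=len(conc)) if od_noise_sd > 0 else 0.0
        od24 = np.clip(od0 + (od24_control - od0) * growth + noise, od0, None)
        for x, o in zip(conc, od24):
            rows.append(
                {
                    "compound_id": c,
                    "concentration": float(x),
                    "od600_t0": od0,
                    "od600_t24": float(o),
                    "control_od600_t0": od0,
                    "control_od600_t24": od24_control,
                }
            )
        truth_rows.append({"compound_id": c, "ic50": ic50, "true_mic": true_mic})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows).set_index("compound_id")


def write_study(
    out_dir: str | Path,
    config: SimulationConfig,
) -> None:
    """Simulate and write the study tables (TSV) plus ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tax, meta, truth = simulate_study(config)
    table.to_tsv(out / "feature_table.tsv")
    tax.to_tsv(out / "taxonomy.tsv")
    meta.to_tsv(out / "metadata.tsv")
    truth.to_json(out / "ground_truth.json")
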