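"""End-to-end screening pipeline: counts in, cocktail report out.

Stage order: load -> aggregate to rank -> prevalence filter -> diversity
diagnostics (alpha, Bray-Curtis/PCoA, ANOSIM, F/B) -> differential abundance
(M vs N and MD vs ND) -> key genera -> log-relative transform -> group
profiles -> compound scores -> effect clustering -> cocktail -> report.
A stage failure aborts with the stage named; given identical inputs, seed and
parameters the report is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from gmrc_screen._version import __version__
from gmrc_screen.cocktail import (
    correlation_distance,
    effect_profiles,
    hierarchical_cluster,
    select_representatives,
)
from gmrc_screen.diffabund import nb_wald_test, select_key_genera
from gmrc_screen.diversity import alpha_diversity, anosim, bray_curtis, fb_ratio, pcoa
from gmrc_screen.screening import group_profiles, score_all
from gmrc_screen.tables import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    aggregate_to_rank,
    filter_prevalence,
    transform_log_relative,
)

log = logging.getLogger("gmrc_screen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineParams:
    """Tunable knobs of the screening pipeline."""

    rank: str = "genus"
    min_prevalence: int = 2
    pseudocount: float = 0.5
    alpha_level: float = 0.05
    key_genus_mode: str = "both"   # 'both' or 'vivo' (relaxed)
    score_mode: str = "signed"
    k_clusters: int = 8
    linkage: str = "average"
    theta: float = 0.0
    anosim_permutations: int = 999
    seed: int = 0


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_screening_pipeline(
    table: FeatureTable,
    tax: TaxonomyMap,
    meta: SampleMetadata,
    params: PipelineParams = PipelineParams(),
) -> dict:
    """Run the full screening analysis; returns the run report as a plain,
    JSON-serialisable dict (no timestamps, so reports are reproducible)."""

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("validate")
    try:
        missing = meta.missing_canonical_groups()
        if missing:
            raise PipelineError(
                f"missing canonical group: {', '.join(missing)}"
            )
        known = set(table.sample_ids)
        meta_samples = [s for s in meta.sample_ids if s in known]
        if not meta_samples:
            raise PipelineError("no metadata sample present in the table")

        current = stage("aggregate")
        genus = aggregate_to_rank(table, tax, params.rank)

        current = stage("prevalence_filter")
        genus = filter_prevalence(genus, params.min_prevalence)

        current = stage("diversity")
        alpha = alpha_diversity(genus)
        dm = bray_curtis(genus)
        ord_res = pcoa(dm)
        canonical = {
            s: meta.canonical_group(s)
            for s in genus.sample_ids
            if meta.canonical_group(s) is not None
        }
        can_ids = list(canonical)
        r_stat, p_anosim = anosim(
            dm.filter(can_ids),
            [canonical[s] for s in can_ids],
            n_perm=params.anosim_permutations,
            seed=params.seed,
        )
        fb = fb_ratio(table, tax)

        current = stage("differential_abundance")
        vivo = nb_wald_test(genus, meta, "N", "M")
        vitro = nb_wald_test(genus, meta, "ND", "MD")

        current = stage("key_genera")
        key = select_key_genera(
            vivo, vitro, alpha_level=params.alpha_level, require=params.key_genus_mode
        )

        current = stage("transform")
        tt = transform_log_relative(genus, pseudocount=params.pseudocount)

        current = stage("group_profiles")
        profiles, n_rep = group_profiles(tt, meta)
        for g in ("ND", "MD"):
            if g not in profiles.columns:
                raise PipelineError(f"missing canonical group: {g}")
        treatments = [c for c in profiles.columns if c not in ("N", "M", "ND", "MD")]
        if not treatments:
            raise PipelineError("no treatment wells to score")

        current = stage("scores")
        if len(key) == 0:
            raise PipelineError("no key genera selected; nothing to score")
        scores = score_all(
            profiles[treatments], profiles["ND"], profiles["MD"], key,
            mode=params.score_mode,
        )

        current = stage("clustering")
        effects = effect_profiles(profiles[treatments], profiles["MD"])
        dist = correlation_distance(effects)
        k = min(params.k_clusters, len(treatments))
        clusters = hierarchical_cluster(dist, k, method=params.linkage)

        current = stage("cocktail")
        design = select_representatives(clusters, scores, theta=params.theta)

        current = stage("report")
        report = {
            "version": __version__,
            "params": asdict(params),
            "n_samples": len(meta_samples),
            "n_taxa_input": table.shape[0],
            "n_taxa_rank": genus.shape[0],
            "n_treatments": len(treatments),
            "alpha_diversity": alpha.round(10).reset_index().to_dict("records"),
            "fb_ratio": {
                s: (None if not np.isfinite(v) else round(float(v), 10))
                for s, v in fb.items()
            },
            "pcoa": {
                "proportion_explained": [
                    round(float(v), 10) for v in ord_res.proportion_explained[:3]
                ],
                "n_negative_eigenvalues": ord_res.n_negative,
            },
            "anosim": {"R": round(float(r_stat), 10), "p": round(float(p_anosim), 10)},
            "key_genera": _round_floats(key.reset_index().to_dict("records")),
            "scores": _round_floats(scores.reset_index().to_dict("records")),
            "clusters": {c: int(v) for c, v in clusters.labels.items()},
            "cocktail": {
                "members": _round_floats(design.members.reset_index().to_dict("records")),
                "excluded_clusters": _round_floats(
                    design.excluded_clusters.reset_index().to_dict("records")
                ),
                "theta": params.theta,
            },
            "warnings": [],
        }
        return report
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapping
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc


def write_report(report: dict, out_dir: str | Path) -> Path:
    """Write the report bundle: report.json plus score/key-genus TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    pd.DataFrame(report["scores"]).to_csv(out / "scores.tsv", sep="\t", index=False)
    pd.DataFrame(report["key_genera"]).to_csv(
        out / "key_genera.tsv", sep="\t", index=False
    )
    return path
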