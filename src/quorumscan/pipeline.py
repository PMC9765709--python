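"""End-to-end orchestration: profiles -> hits -> propeptides -> systems."""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from . import synthetic_data
from .context_classifier import QSSystemRecord, build_systems, summarize
from .io import GenomeBundle
from .propeptide_finder import (
    PropeptideCall,
    SignalHeuristicParams,
    call_propeptides,
)
from .receptor_search import (
    ProfileModel,
    ReceptorHit,
    SearchThresholds,
    assign_family,
    attach_coordinates,
    build_profile,
    calibrate,
    scan_proteome,
)
from .repeat_analysis import RepeatReport, detect_repeats

#: seed for the internal profile construction/calibration randomness;
#: independent of any genome seed so profiles never adapt to the input
PROFILE_SEED = 90210


@dataclasses.dataclass
class PipelineResult:
    hits: list[ReceptorHit]  # final assigned receptors (Rgg-filtered)
    calls_by_receptor: dict[str, list[PropeptideCall]]
    reports_by_receptor: dict[str, list[RepeatReport]]
    systems: list[QSSystemRecord]
    summary: pd.DataFrame


def build_family_models(
    families: Sequence[str] = synthetic_data.FAMILIES,
    n_seed_sequences: int = 8,
    seed_mutation_rate: float = 0.05,
    n_decoys: int = 500,
    seed: int = PROFILE_SEED,
) -> dict[str, ProfileModel]:
    """Calibrated profile models from the shipped family seed alignments."""
    models = {}
    for i, family in enumerate(families):
        alignment = synthetic_data.family_seed_alignment(
            family, n_sequences=n_seed_sequences, mutation_rate=seed_mutation_rate,
            seed=seed,
        )
        model = build_profile(alignment, family=family)
        models[family] = calibrate(
            model,
            n_decoys=n_decoys,
            decoy_length=model.length,
            seed=seed + 17 * i,
        )
    return models


def run_pipeline(
    bundle: GenomeBundle,
    models: Mapping[str, ProfileModel] | None = None,
    thresholds: SearchThresholds | None = None,
    signal_params: SignalHeuristicParams | None = None,
) -> PipelineResult:
    """Scan, assign families, call propeptides, analyse repeats, classify."""
    thresholds = thresholds or SearchThresholds()
    signal_params = signal_params or SignalHeuristicParams()
    if models is None:
        models = build_family_models()
    all_hits: list[ReceptorHit] = []
    for family in models:
        all_hits.extend(scan_proteome(bundle.proteome, models[family], thresholds))
    assigned = assign_family(all_hits, propeptide_lookup=None)
    attach_coordinates(assigned, bundle.genes)
    assigned = [h for h in assigned if h.replicon_id is not None]

    calls_by_receptor: dict[str, list[PropeptideCall]] = {}
    for hit in assigned:
        calls_by_receptor[hit.protein_id] = call_propeptides(
            hit, bundle, signal_params
        )
    # Rgg rule: candidates without a confirmed propeptide are discarded
    final = []
    for hit in assigned:
        if hit.assigned_family == "Rgg" and not calls_by_receptor[hit.protein_id]:
            continue
        hit.needs_propeptide_confirmation = False
        final.append(hit)

    reports_by_receptor = {
        pid: [
            detect_repeats(c.protein, propeptide_id=f"{pid}_call{k}")
            for k, c in enumerate(calls)
        ]
        for pid, calls in calls_by_receptor.items()
        if pid in {h.protein_id for h in final}
    }
    systems = build_systems(
        final,
        calls_by_receptor,
        bundle.mge,
        reports_by_receptor=reports_by_receptor,
        replicons=bundle.replicons.keys(),
    )
    return PipelineResult(
        hits=final,
        calls_by_receptor=calls_by_receptor,
        reports_by_receptor=reports_by_receptor,
        systems=systems,
        summary=summarize(systems),
    )
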