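"""End-to-end orchestration of the differential-enrichment analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .design import comparisons_for
from .differential import ComparisonResult, run_comparison
from .enrichment import cluster_table, test_clusters
from .io import AnalysisConfig, IntensityTable
from .merge import compose_enriched_set, upset_counts
from .preprocess import (
    filter_identifications,
    filter_min_quantified,
    impute_frame,
    log2_transform,
    median_center,
    partition_presence_absence,
)


@dataclass
class PipelineResults:
    """All tables produced by one pipeline run plus the run manifest."""

    config: AnalysisConfig
    comparisons: dict[str, ComparisonResult]
    merged: pd.DataFrame
    upset: pd.DataFrame
    clusters: pd.DataFrame | None
    background_ids: list[str]
    manifest: dict

    @property
    def enriched_ids(self) -> set[str]:
        return set(self.merged.loc[self.merged["enriched"], "protein_id"])


def run_pipeline(
    table: IntensityTable,
    config: AnalysisConfig,
    annotation: dict[str, set[str]] | None = None,
) -> PipelineResults:
    """Run filters → normalization → per-comparison testing → merging.

    The identification-level filters define the MS-identified background
    used for cluster over-representation; every stochastic step (the
    conditional-draw imputation) is seeded from ``config.seed`` through
    per-comparison substreams, so identical inputs and configuration give
    identical outputs.
    """
    manifest: dict = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_input": table.n_proteins,
    }

    identified, removed = filter_identifications(table, config)
    manifest["n_identified"] = identified.n_proteins
    manifest["removed_by_reason"] = removed
    background_ids = identified.protein_ids

    quantified = filter_min_quantified(identified, config)
    manifest["n_quantified"] = quantified.n_proteins

    normalized = median_center(log2_transform(quantified))

    comparisons = comparisons_for(table.design)
    if not comparisons:
        raise ValueError("design supports no MBR+ vs control comparison")
    streams = np.random.SeedSequence(config.seed).spawn(len(comparisons))

    results: dict[str, ComparisonResult] = {}
    manifest["comparisons"] = {}
    for (control, prep), stream in zip(comparisons, streams):
        frame = partition_presence_absence(normalized, control, prep, config)
        impute_frame(
            frame,
            seed=np.random.default_rng(stream),
            mode=config.imputation_mode,
        )
        res = run_comparison(frame, config)
        results[res.label] = res
        # statuses after refinement by the FC gate
        counts = res.table["status"].value_counts().to_dict()
        manifest["comparisons"][res.label] = {
            "status_counts": {k: int(v) for k, v in counts.items()},
            "n_total": int(len(res.table)),
            "d0": res.meta["d0"],
            "s0_sq": res.meta["s0_sq"],
            "pi0": res.meta["pi0"],
        }

    merged = compose_enriched_set(list(results.values()), config)
    manifest["n_enriched"] = int(merged["enriched"].sum())

    sig_sets = {
        label: res.significant_ids(enriched_only=True)
        for label, res in results.items()
    }
    upset = upset_counts(sig_sets)

    clusters = None
    if annotation is not None:
        enriched = set(merged.loc[merged["enriched"], "protein_id"])
        target = enriched & set(background_ids)
        clusters = cluster_table(
            test_clusters(target, set(background_ids), annotation)
        )

    return PipelineResults(
        config=config,
        comparisons=results,
        merged=merged,
        upset=upset,
        clusters=clusters,
        background_ids=background_ids,
        manifest=manifest,
    )
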