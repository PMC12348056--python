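"""One reproducible run: simulate -> demux -> annotate -> doublets -> evaluate.

Every stage is the corresponding library function; this module only wires
them together, writes the intermediate tables and assembles the report.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import core_io, demux, doublets, metrics, species_ref, synthdata
from .core_io import RunConfig
from .synthdata import SimDesign

logger = logging.getLogger(__name__)


def design_from_name(
    name: str, mode: str = "sc", n_droplets: int = 20_000, seed: int = 0
) -> SimDesign:
    """Resolve a named study design (barnyard2 / barnyard6 / barnyard12 / pbmc)."""
    if name == "pbmc":
        return synthdata.pbmc_design(n_droplets=n_droplets, seed=seed)
    if name.startswith("barnyard"):
        plex = int(name.removeprefix("barnyard"))
        return synthdata.barnyard_design(plex, mode=mode, n_droplets=n_droplets, seed=seed)
    raise ValueError(f"unknown design {name!r}")


def tag_type_map(design: SimDesign) -> dict[str, object]:
    """Map each tag to the species (two-species pools) or type set of its sample."""
    species = {s.species for s in design.samples}
    if len(species) > 1:
        return {s.tag_id: s.species for s in design.samples}
    mapping: dict[str, object] = {}
    for s in design.samples:
        types = set(s.type_fractions)
        mapping[s.tag_id] = next(iter(types)) if len(types) == 1 else frozenset(types)
    return mapping


def design_map(design: SimDesign) -> dict[str, str]:
    """sample -> species (two-species pools) or dominant type, for validation."""
    species = {s.species for s in design.samples}
    if len(species) > 1:
        return {s.name: s.species for s in design.samples}
    return {
        s.name: max(s.type_fractions, key=s.type_fractions.get) for s in design.samples
    }


def pooled_type_fractions(design: SimDesign) -> dict[str, float]:
    pooled: dict[str, float] = {}
    for s in design.samples:
        for t, f in s.type_fractions.items():
            pooled[t] = pooled.get(t, 0.0) + s.pool_fraction * f
    return pooled


def run_pipeline(
    design: SimDesign,
    config: RunConfig,
    out_dir: str | Path,
    write_outputs: bool = True,
) -> metrics.MetricsReport:
    """Execute all stages on one simulated dataset and return the report.

    Writes (under ``out_dir``): the dataset directory (``data/``) with
    truth.tsv, calls.tsv, ref.tsv, scores.tsv, final_cells.tsv and
    report.json.  Deterministic: the same design and config yield a
    byte-identical report.
    """
    out = Path(out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("simulating %d droplets, seed %d", design.n_droplets, design.seed)
    tags, expr, truth = synthdata.simulate_dataset(design)
    if write_outputs:
        core_io.write_counts(tags, expr, out / "data")
        core_io.write_truth(truth, out / "data" / "truth.tsv")

    calls = demux.demux_all(tags, config)
    n_by_status = pd.Series([c.call_status for c in calls]).value_counts()
    logger.info("demux calls: %s", n_by_status.to_dict())
    if write_outputs:
        core_io.calls_to_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)

    reference = species_ref.reference_annotation(
        expr, design_map(design), tau=config.species_threshold,
        min_species_umis=config.min_species_umis,
    )
    if write_outputs:
        reference.to_csv(out / "ref.tsv", sep="\t", index=False)

    oca, oca_ex = metrics.compute_oca(calls, reference, tag_type_map(design))

    # stage 1: drop tag-called doublets; stage 2 operates on assigned singlets
    kept, removed = doublets.barcode_doublet_filter(calls)
    singlet_calls = [c for c in kept if c.call_status == "singlet"]
    singlet_ids = [c.droplet_id for c in singlet_calls]
    id_to_row = {d: i for i, d in enumerate(expr.droplet_ids)}
    rows = [id_to_row[d] for d in singlet_ids]
    sub_expr = core_io.ExpressionMatrix(
        droplet_ids=singlet_ids,
        gene_ids=expr.gene_ids,
        gene_class=expr.gene_class,
        counts=expr.counts[rows],
    )
    n_synth = int(round(config.synthetic_doublet_ratio * len(singlet_ids)))
    synthetic = doublets.simulate_artificial_doublets(
        sub_expr, n_synth, seed=config.random_seed
    )
    scores = doublets.knn_doublet_score(
        sub_expr, synthetic, k=config.knn_k,
        expected_doublet_rate=config.expected_doublet_rate,
        n_pcs=config.n_pcs, seed=config.random_seed,
    )
    totals = np.asarray(sub_expr.counts.sum(axis=1)).ravel()
    tag_labels = np.array([c.assigned_tags[0] for c in singlet_calls])
    flags = doublets.depth_outlier_flags(totals, tag_labels, config.depth_outlier_sd)
    residual = doublets.residual_doublet_filter(singlet_ids, scores, flags, config)
    if write_outputs:
        pd.DataFrame(
            {"droplet_id": singlet_ids, "doublet_score": scores, "depth_outlier": flags}
        ).to_csv(out / "scores.tsv", sep="\t", index=False)
        pd.Series(residual.kept_ids).to_csv(
            out / "final_cells.tsv", sep="\t", header=False, index=False
        )

    tag_props = metrics.per_tag_proportions(calls, tags.tag_ids)
    input_props = {s.tag_id: s.pool_fraction for s in design.samples}
    dbl_pre, dbl_post = metrics.doublet_ratios(
        truth, [c.droplet_id for c in calls], residual.kept_ids
    )
    neg_rate = sum(c.call_status == "negative" for c in calls) / len(calls)

    rare_fracs = rare_detected = None
    if design.rare_type is not None:
        rare_fracs, rare_detected = metrics.rare_population_recovery(
            residual.kept_ids, truth, calls, pooled_type_fractions(design)
        )

    report = metrics.build_report(
        oca=oca,
        oca_excluding_negatives=oca_ex,
        tag_proportions=tag_props,
        input_proportions=input_props,
        doublet_pre=dbl_pre,
        doublet_post=dbl_post,
        negative_rate_observed=neg_rate,
        rare_fractions=rare_fracs,
        rare_detected=rare_detected,
        config=config,
    )
    if write_outputs:
        report.to_json(out / "report.json")
    logger.info(
        "OCA %.4f, deviation %.2f pp, doublets %.4f -> %.6f",
        report.oca, report.mixing_deviation,
        report.doublet_ratio_pre, report.doublet_ratio_post,
    )
    return report
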