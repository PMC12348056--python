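"""Evaluation statistics and the structured run report.

The headline statistic is the overall classification accuracy (OCA):

    OCA = (matching singlets + matching nonsinglets) / total droplets,

where a singlet call matches when the reference also calls the droplet a
singlet of the type its tag's sample belongs to (matching is type-level:
several pooled samples may share a cell line or species, and the reference
can only see the type), a doublet call matches a multiplet reference, and a
negative call matches an undefined reference.  A doublet call against a
confident singlet reference is a mismatch.

Ratio fidelity is scored as the worst-case per-sample deviation (percentage
points) between demultiplexed proportions and the known input proportions;
doublet ratios are reported before and after the two filtering stages; and
rare-population recovery reports, per tag, the fraction of retained singlets
of each true cell type.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import DemuxCall, RunConfig
from .species_ref import REF_MULTIPLET, REF_SINGLET, REF_UNDEFINED


@dataclass
class MetricsReport:
    """All evaluation outputs of one pipeline run, JSON-serializable."""

    oca: float
    oca_excluding_negatives: float
    per_tag_proportions: dict[str, float]
    mixing_deviation: float
    doublet_ratio_pre: float
    doublet_ratio_post: float
    negative_rate_observed: float
    rare_population_fractions: dict[str, dict[str, float]]
    rare_population_detected: dict[str, bool]
    config: dict
    seed: int

    def __post_init__(self) -> None:
        for name in ("oca", "doublet_ratio_pre", "doublet_ratio_post", "negative_rate_observed"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.per_tag_proportions:
            total = sum(self.per_tag_proportions.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"per_tag_proportions sum to {total}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        with open(path) as fh:
            return cls(**json.load(fh))


def _check_aligned(calls: list[DemuxCall], reference: pd.DataFrame) -> None:
    if len(calls) != len(reference):
        raise ValueError("calls and reference have different lengths")
    if [c.droplet_id for c in calls] != reference["droplet_id"].tolist():
        raise ValueError("calls and reference are not droplet-aligned")


def compute_oca(
    calls: list[DemuxCall],
    reference: pd.DataFrame,
    tag_to_type: dict[str, str],
) -> tuple[float, float]:
    """Overall classification accuracy against the reference annotation.

    ``tag_to_type`` maps each tag id to the species or cell type of its
    sample — or to a set of types when the sample is itself a mixture (a
    PBMC donor contains every type, so any confident type reference matches
    its tags).  Returns (oca, oca_excluding_negatives); the first — computed
    over every droplet — is the headline number, the second drops droplets
    whose *call* is negative from the denominator.
    """
    _check_aligned(calls, reference)
    ref_status = reference["ref_status"].to_numpy()
    ref_label = reference["ref_label"].to_numpy()

    matches = 0
    matches_nonneg = 0
    n_nonneg = 0
    for i, call in enumerate(calls):
        if call.call_status == "singlet":
            accept = tag_to_type[call.assigned_tags[0]]
            accepted = ref_label[i] == accept if isinstance(accept, str) else ref_label[i] in accept
            ok = ref_status[i] == REF_SINGLET and accepted
        elif call.call_status == "doublet":
            ok = ref_status[i] == REF_MULTIPLET
        else:
            ok = ref_status[i] == REF_UNDEFINED
        matches += ok
        if call.call_status != "negative":
            n_nonneg += 1
            matches_nonneg += ok
    oca = matches / len(calls) if calls else float("nan")
    oca_ex = matches_nonneg / n_nonneg if n_nonneg else float("nan")
    return oca, oca_ex


def per_tag_proportions(calls: list[DemuxCall], tag_ids: list[str]) -> dict[str, float]:
    """Share of assigned singlets per tag (sums to 1 when any singlet exists)."""
    counts = {t: 0 for t in tag_ids}
    for c in calls:
        if c.call_status == "singlet":
            counts[c.assigned_tags[0]] += 1
    total = sum(counts.values())
    if total == 0:
        return {t: float("nan") for t in tag_ids}
    return {t: counts[t] / total for t in tag_ids}


def mixing_deviation(
    observed: np.ndarray, input_proportions: np.ndarray, tol: float = 1e-6
) -> float:
    """Worst-case |observed - input| in percentage points."""
    obs = np.asarray(observed, dtype=float)
    inp = np.asarray(input_proportions, dtype=float)
    if obs.shape != inp.shape:
        raise ValueError("proportion vectors differ in length")
    for name, v in (("observed", obs), ("input", inp)):
        if abs(v.sum() - 1.0) > tol:
            raise ValueError(f"{name} proportions sum to {v.sum()}, expected 1")
    return float(np.max(np.abs(obs - inp)) * 100.0)


def doublet_ratios(
    truth: pd.DataFrame, kept_pre: list[str], kept_post: list[str]
) -> tuple[float, float]:
    """True-doublet fraction among (pre-filter, post-filter) droplet sets.

    ``kept_pre`` is typically every called droplet before any filtering and
    ``kept_post`` the final retained set; both ratios use simulation truth.
    """
    is_dbl = dict(zip(truth["droplet_id"], truth["status"] == "doublet"))
    def frac(ids: list[str]) -> float:
        if not ids:
            return 0.0
        return sum(is_dbl[d] for d in ids) / len(ids)
    return frac(kept_pre), frac(kept_post)


def rare_population_recovery(
    final_ids: list[str],
    truth: pd.DataFrame,
    calls: list[DemuxCall],
    expected_fractions: dict[str, float] | None = None,
) -> tuple[dict[str, dict[str, float]], dict[str, bool]]:
    """Per-tag cell-type composition of the retained singlets.

    Returns (fractions, detected): ``fractions[tag][cell_type]`` is the share
    of retained singlets assigned to ``tag`` whose true type is
    ``cell_type``; a type counts as detected when its recovered share is at
    least half its expected share in every tag.
    """
    final = set(final_ids)
    tag_of = {
        c.droplet_id: c.assigned_tags[0]
        for c in calls
        if c.call_status == "singlet" and c.droplet_id in final
    }
    sub = truth[truth["droplet_id"].isin(tag_of)].copy()
    sub["tag"] = sub["droplet_id"].map(tag_of)

    fractions: dict[str, dict[str, float]] = {}
    for tag, grp in sub.groupby("tag", sort=True):
        comp = grp["cell_type_1"].value_counts(normalize=True)
        fractions[str(tag)] = {str(t): float(f) for t, f in comp.items()}

    detected: dict[str, bool] = {}
    if expected_fractions:
        for ctype, exp in expected_fractions.items():
            detected[ctype] = bool(fractions) and all(
                per_tag.get(ctype, 0.0) >= 0.5 * exp for per_tag in fractions.values()
            )
    return fractions, detected


def build_report(
    *,
    oca: float,
    oca_excluding_negatives: float,
    tag_proportions: dict[str, float],
    input_proportions: dict[str, float],
    doublet_pre: float,
    doublet_post: float,
    negative_rate_observed: float,
    rare_fractions: dict[str, dict[str, float]] | None,
    rare_detected: dict[str, bool] | None,
    config: RunConfig,
) -> MetricsReport:
    """Assemble the serializable run report from the stage outputs."""
    for name, v in (("oca", oca), ("doublet_pre", doublet_pre)):
        if v is None:
            raise ValueError(f"missing stage output {name}")
    tags = sorted(tag_proportions)
    deviation = mixing_deviation(
        np.array([tag_proportions[t] for t in tags]),
        np.array([input_proportions[t] for t in tags]),
    )
    return MetricsReport(
        oca=oca,
        oca_excluding_negatives=oca_excluding_negatives,
        per_tag_proportions=tag_proportions,
        mixing_deviation=deviation,
        doublet_ratio_pre=doublet_pre,
        doublet_ratio_post=doublet_post,
        negative_rate_observed=negative_rate_observed,
        rare_population_fractions=rare_fractions or {},
        rare_population_detected=rare_detected or {},
        config=dataclasses.asdict(config),
        seed=config.random_seed,
    )
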