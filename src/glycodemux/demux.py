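"""Confidence-ratio tag classification of droplets.

Each droplet's tag-count vector is background-corrected, then called:

* ``negative`` when the corrected total is below ``min_tag_umis``;
* ``singlet`` on the arg-max tag when the confidence ratio — the top tag's
  share of the corrected total — reaches ``singlet_threshold`` (default 0.9);
* ``doublet`` on the top two tags when it does not but the second tag still
  holds at least ``doublet_second_tag_min_fraction`` of the corrected total;
* ``negative`` (unassigned) otherwise.

Background per tag is estimated robustly as the median count of that tag
over droplets whose top tag is a different tag, i.e. over droplets for which
that tag can only be contamination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DemuxCall, RunConfig, TagCountMatrix


class EstimationError(ValueError):
    """Raised when too little data is available to estimate background."""


MIN_DROPLETS_FOR_BACKGROUND = 100


@dataclass
class BackgroundEstimate:
    """Expected per-droplet background count for each tag."""

    per_tag_background: np.ndarray

    def __post_init__(self) -> None:
        self.per_tag_background = np.asarray(self.per_tag_background, dtype=float)
        if self.per_tag_background.size and self.per_tag_background.min() < 0:
            raise ValueError("background estimates must be non-negative")


def estimate_background(tags: TagCountMatrix, config: RunConfig) -> BackgroundEstimate:
    """Median off-target count per tag; zeros under ``background_mode='none'``."""
    k = tags.n_tags
    if config.background_mode == "none":
        return BackgroundEstimate(np.zeros(k))
    if tags.n_droplets < MIN_DROPLETS_FOR_BACKGROUND:
        raise EstimationError(
            f"background estimation needs >= {MIN_DROPLETS_FOR_BACKGROUND} droplets, "
            f"got {tags.n_droplets}"
        )
    counts = tags.counts
    top = np.argmax(counts, axis=1)
    bg = np.zeros(k)
    for t in range(k):
        others = counts[top != t, t]
        bg[t] = float(np.median(others)) if others.size else 0.0
    return BackgroundEstimate(bg)


def corrected_counts(tag_counts: np.ndarray, bg: BackgroundEstimate) -> np.ndarray:
    return np.maximum(np.asarray(tag_counts, dtype=float) - bg.per_tag_background, 0.0)


def confidence_ratio(tag_counts: np.ndarray, bg: BackgroundEstimate) -> float:
    """Top tag's share of the background-corrected total; 0 when that total is 0."""
    corr = corrected_counts(tag_counts, bg)
    total = corr.sum()
    if total <= 0:
        return 0.0
    return float(corr.max() / total)


def classify_droplet(
    tag_counts: np.ndarray,
    bg: BackgroundEstimate,
    config: RunConfig,
    droplet_id: str = "",
    tag_ids: list[str] | None = None,
) -> DemuxCall:
    """Apply the confidence-ratio rule to one droplet's tag counts."""
    raw = np.asarray(tag_counts)
    if tag_ids is None:
        tag_ids = [str(i) for i in range(raw.size)]
    corr = corrected_counts(raw, bg)
    total = corr.sum()
    total_raw = int(raw.sum())

    if total < config.min_tag_umis:
        ratio = 0.0 if total <= 0 else float(corr.max() / total)
        return DemuxCall(droplet_id, "negative", (), ratio, total_raw)

    order = np.argsort(-corr, kind="stable")  # stable: ties -> lowest index first
    top = int(order[0])
    second = int(order[1]) if corr.size > 1 else top
    ratio = float(corr[top] / total)
    ambiguous = bool(corr.size > 1 and corr[top] == corr[second])

    if ratio >= config.singlet_threshold:
        return DemuxCall(droplet_id, "singlet", (tag_ids[top],), ratio, total_raw, ambiguous)
    second_frac = float(corr[second] / total) if corr.size > 1 else 0.0
    if second_frac >= config.doublet_second_tag_min_fraction:
        return DemuxCall(
            droplet_id, "doublet", (tag_ids[top], tag_ids[second]), ratio, total_raw, ambiguous
        )
    return DemuxCall(droplet_id, "negative", (), ratio, total_raw, ambiguous)


def demux_all(tags: TagCountMatrix, config: RunConfig) -> list[DemuxCall]:
    """Classify every droplet; order follows the input droplet order.

    Vectorized re-statement of :func:`classify_droplet` (the two agree
    exactly; the scalar version is the executable definition).
    """
    bg = estimate_background(tags, config)
    counts = tags.counts
    n, k = counts.shape
    corr = np.maximum(counts.astype(float) - bg.per_tag_background, 0.0)
    total = corr.sum(axis=1)
    total_raw = counts.sum(axis=1)

    order = np.argsort(-corr, axis=1, kind="stable")
    top = order[:, 0]
    second = order[:, 1] if k > 1 else top
    rows = np.arange(n)
    top_c = corr[rows, top]
    second_c = corr[rows, second] if k > 1 else np.zeros(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, top_c / np.where(total > 0, total, 1.0), 0.0)
        second_frac = np.where(total > 0, second_c / np.where(total > 0, total, 1.0), 0.0)
    ambiguous = (k > 1) & (top_c == second_c)

    is_neg_low = total < config.min_tag_umis
    is_singlet = ~is_neg_low & (ratio >= config.singlet_threshold)
    is_doublet = (
        ~is_neg_low
        & ~is_singlet
        & (second_frac >= config.doublet_second_tag_min_fraction)
    )

    tag_ids = tags.tag_ids
    calls: list[DemuxCall] = []
    for i in range(n):
        if is_singlet[i]:
            status, assigned = "singlet", (tag_ids[top[i]],)
        elif is_doublet[i]:
            status, assigned = "doublet", (tag_ids[top[i]], tag_ids[second[i]])
        else:
            status, assigned = "negative", ()
        calls.append(
            DemuxCall(
                droplet_id=tags.droplet_ids[i],
                call_status=status,
                assigned_tags=assigned,
                confidence_ratio=float(ratio[i]),
                total_tag_umis=int(total_raw[i]),
                ambiguous=bool(ambiguous[i]),
            )
        )
    return calls
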