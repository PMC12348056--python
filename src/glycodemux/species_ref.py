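"""Expression-based reference annotation for scoring demultiplexing.

In two-species pools the transcriptome itself nearly labels every droplet:
a droplet's human-gene UMI share ``h`` is ~1 for human cells, ~0 for mouse
cells, and ~0.5 for cross-species multiplets.  The reference annotation
thresholds ``h`` at ``tau`` (default 0.9) to call human / mouse / mixed, and
maps the species to the pool's sample(s) of that species.  Since several
pooled samples may share a species or cell line, matching against this
reference is evaluated at the type level.

Single-species pools (PBMC donors, multi-line pools) use marker-block votes
instead: the top cell type's share of marker-gene UMIs plays the role of
``h``.

Droplets with fewer than ``min_species_umis`` informative UMIs are labeled
``undefined``: a reference that cannot see the transcriptome has no standing
to call the droplet anything.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix

REF_SINGLET = "singlet"
REF_MULTIPLET = "multiplet"
REF_UNDEFINED = "undefined"


def species_fraction(expr_row: np.ndarray, gene_class: list[str]) -> float:
    """Human-gene UMI share h = human / (human + mouse); NaN when both are 0."""
    row = np.asarray(expr_row).ravel()
    classes = np.asarray(gene_class)
    human = row[classes == "species:human"].sum()
    mouse = row[classes == "species:mouse"].sum()
    total = human + mouse
    if total <= 0:
        return float("nan")
    return float(human / total)


def species_classify(h: float, tau: float) -> str:
    """human if h >= tau, mouse if h <= 1 - tau, mixed between, undefined for NaN."""
    if not 0.5 < tau <= 1.0:
        raise ValueError(f"tau must be in (0.5, 1], got {tau}")
    if np.isnan(h):
        return "undefined"
    if h >= tau:
        return "human"
    # h <= 1 - tau, written as 1 - h >= tau so the rule is floating-point
    # symmetric under h -> 1 - h
    if 1.0 - h >= tau:
        return "mouse"
    return "mixed"


def _label_mode(gene_class: list[str]) -> str:
    classes = set(gene_class)
    if any(c.startswith("species:") for c in classes):
        return "species"
    if any(c.startswith("marker:") for c in classes):
        return "marker"
    raise ValueError("gene_class carries neither species: nor marker: labels")


def reference_annotation(
    expr: ExpressionMatrix,
    design_map: dict[str, str],
    tau: float = 0.9,
    min_species_umis: int = 100,
) -> pd.DataFrame:
    """Per-droplet reference labels from species or marker expression.

    ``design_map`` maps each sample name to its species (species mode) or
    cell type (marker mode); it is only validated here — matching calls to
    the reference happens in the metrics layer, at the type level.

    Returns a frame with columns ``droplet_id``, ``ref_status`` (singlet /
    multiplet / undefined), ``ref_label`` (species or type for singlets,
    empty otherwise) and ``purity`` (the thresholded share).
    """
    mode = _label_mode(expr.gene_class)
    classes = np.asarray(expr.gene_class)
    counts = expr.counts

    if mode == "species":
        targets = sorted(
            {c.split(":", 1)[1] for c in classes if c.startswith("species:")}
        )
        missing = set(design_map.values()) - set(targets)
        if missing:
            raise ValueError(f"design_map species absent from gene_class: {missing}")
        cols = np.stack(
            [
                np.asarray(counts[:, classes == f"species:{t}"].sum(axis=1)).ravel()
                for t in targets
            ],
            axis=1,
        )
    else:
        targets = sorted({c.split(":", 1)[1] for c in classes if c.startswith("marker:")})
        missing = set(design_map.values()) - set(targets)
        if missing:
            raise ValueError(f"design_map cell types absent from gene_class: {missing}")
        cols = np.stack(
            [
                np.asarray(counts[:, classes == f"marker:{t}"].sum(axis=1)).ravel()
                for t in targets
            ],
            axis=1,
        )

    total = cols.sum(axis=1)
    top_idx = np.argmax(cols, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(total > 0, cols[np.arange(len(total)), top_idx] / np.where(total > 0, total, 1), np.nan)

    # binary species mode keeps the symmetric human/mouse rule: the purity of
    # the top species >= tau is equivalent to h >= tau or h <= 1 - tau
    undefined = (total <= 0) | (total < min_species_umis)
    is_singlet = ~undefined & (purity >= tau)

    labels = np.array(targets, dtype=object)[top_idx]
    status = np.where(undefined, REF_UNDEFINED, np.where(is_singlet, REF_SINGLET, REF_MULTIPLET))
    ref_label = np.where(status == REF_SINGLET, labels, "")
    return pd.DataFrame(
        {
            "droplet_id": expr.droplet_ids,
            "ref_status": status,
            "ref_label": ref_label,
            "purity": purity,
        }
    )
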