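"""Two-stage doublet handling.

Stage 1 removes droplets the tag classifier already called doublets
(cross-tag doublets carry two sample tags and need no expression evidence).
Stage 2 targets the residual, same-tag doublets with an expression-based
scorer: artificial doublets are synthesized by summing random droplet pairs,
embedded together with the observed droplets (library-size normalization,
log1p, top principal components), and each observed droplet is scored by the
fraction of artificial doublets among its k nearest neighbors, converted to
a posterior doublet probability under the expected doublet rate.  Because
same-tag doublets in pure-line pools are homotypic — their normalized
profile matches the singlet profile and mainly their depth doubles — the
residual filter additionally removes per-tag total-UMI outliers.

A detectability correction converts the observed cross-tag doublet fraction
into a total doublet rate: with pool fractions p_s, a doublet is cross-tag
with probability 1 - sum(p_s^2), so total = cross / (1 - sum(p_s^2)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core_io import DemuxCall, ExpressionMatrix, RunConfig

logger = logging.getLogger(__name__)


def barcode_doublet_filter(
    calls: list[DemuxCall],
) -> tuple[list[DemuxCall], list[DemuxCall]]:
    """Split calls into (kept, removed): removed are the tag-called doublets.

    Negatives are kept here (they are not doublets); downstream stages that
    need a tag assignment drop them separately.
    """
    kept = [c for c in calls if c.call_status != "doublet"]
    removed = [c for c in calls if c.call_status == "doublet"]
    return kept, removed


def estimate_total_doublet_rate(
    cross_tag_doublet_fraction: float, pool_fractions: np.ndarray
) -> float:
    """Detectability-corrected total doublet rate.

    Only pairs from different samples are visible as cross-tag doublets;
    that happens with probability 1 - sum(p_s^2) for an arbitrary doublet.
    """
    p = np.asarray(pool_fractions, dtype=float)
    detectable = 1.0 - float(np.sum(p**2))
    if detectable <= 0:
        raise ValueError(
            "cross-tag doublets are undetectable with a single pooled sample"
        )
    return float(cross_tag_doublet_fraction) / detectable


def simulate_artificial_doublets(
    expr: ExpressionMatrix, n_synth: int, seed: int
) -> sp.csr_matrix:
    """Sum ``n_synth`` uniformly drawn pairs of distinct droplets."""
    n = expr.n_droplets
    if n < 2:
        raise ValueError("need at least 2 droplets to synthesize doublets")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_synth)
    j = rng.integers(0, n - 1, size=n_synth)
    j = np.where(j >= i, j + 1, j)  # uniform over pairs with i != j
    return (expr.counts[i] + expr.counts[j]).tocsr()


def _embed(counts: sp.csr_matrix, n_pcs: int, seed: int) -> np.ndarray:
    """Library-size normalize to the median total, log1p, top PCs."""
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    totals[totals == 0] = 1.0
    target = float(np.median(totals))
    scaled = sp.diags(target / totals) @ counts
    logged = np.log1p(np.asarray(scaled.todense()))
    n_comp = min(n_pcs, logged.shape[1] - 1, logged.shape[0] - 1)
    if n_comp < n_pcs:
        logger.warning("embedding dimension reduced to %d", n_comp)
    pca = PCA(n_components=n_comp, svd_solver="randomized", random_state=seed)
    return pca.fit_transform(logged)


def knn_doublet_score(
    expr: ExpressionMatrix,
    synthetic: sp.csr_matrix,
    k: int,
    expected_doublet_rate: float,
    n_pcs: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Per-droplet doublet score in [0, 1].

    The raw statistic is the fraction f of artificial doublets among a
    droplet's k nearest neighbors in the joint embedding.  With rho =
    n_synthetic / n_observed, f/( (1-f) rho ) estimates the local density
    ratio of doublet-like to singlet-like profiles, which a prior equal to
    ``expected_doublet_rate`` turns into a posterior — so a typical droplet
    scores ~ the expected rate and a droplet embedded among artificial
    doublets scores ~1.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_obs = expr.n_droplets
    n_synth = synthetic.shape[0]
    combined = sp.vstack([expr.counts.tocsr(), synthetic.tocsr()], format="csr")
    emb = _embed(combined, n_pcs, seed)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_obs])
    neigh = idx[:, 1:]  # drop self (each observed point is its own neighbor)
    frac = (neigh >= n_obs).mean(axis=1)

    rho = n_synth / n_obs
    d = expected_doublet_rate
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = frac / np.maximum((1.0 - frac) * rho, 1e-12)
    score = d * lr / (d * lr + (1.0 - d))
    return np.clip(np.where(frac >= 1.0, 1.0, score), 0.0, 1.0)


def _otsu_threshold(scores: np.ndarray) -> tuple[float, float]:
    """Best two-class split of the scores; returns (threshold, separation).

    Separation is the between-class mean gap in pooled-sd units; callers fall
    back to a quantile rule when the distribution is not credibly bimodal.
    """
    s = np.sort(scores)
    if s.size < 4 or s[0] == s[-1]:
        return float("inf"), 0.0
    candidates = np.unique(np.quantile(s, np.linspace(0.02, 0.98, 97)))
    best_t, best_var = candidates[0], -1.0
    for t in candidates:
        lo = s[s <= t]
        hi = s[s > t]
        if lo.size == 0 or hi.size == 0:
            continue
        w0, w1 = lo.size / s.size, hi.size / s.size
        between = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if between > best_var:
            best_var, best_t = between, t
    lo = s[s <= best_t]
    hi = s[s > best_t]
    if lo.size < 2 or hi.size < 2:
        return float(best_t), 0.0
    pooled = np.sqrt(lo.var() + hi.var())
    sep = (hi.mean() - lo.mean()) / pooled if pooled > 0 else np.inf
    return float(best_t), float(sep)


@dataclass
class ResidualFilterResult:
    kept_ids: list[str]
    removed_ids: list[str]
    score_threshold: float
    threshold_source: str  # "bimodal" | "quantile"
    n_removed_by_score: int
    n_removed_by_depth: int


def depth_outlier_flags(
    totals: np.ndarray, tag_labels: np.ndarray, n_sd: float = 1.96
) -> np.ndarray:
    """Flag droplets whose log total UMIs exceed mean + n_sd * sd within their tag."""
    totals = np.asarray(totals, dtype=float)
    logt = np.log(np.maximum(totals, 1.0))
    flags = np.zeros(totals.size, dtype=bool)
    for tag in np.unique(tag_labels):
        mask = tag_labels == tag
        vals = logt[mask]
        if vals.size < 2:
            continue
        cutoff = vals.mean() + n_sd * vals.std()
        flags[mask] = vals > cutoff
    return flags


def residual_doublet_filter(
    droplet_ids: list[str],
    scores: np.ndarray,
    depth_flags: np.ndarray,
    config: RunConfig,
) -> ResidualFilterResult:
    """Drop droplets past the score threshold or flagged as depth outliers.

    The score threshold comes from a two-class split of the score
    distribution when that split is credibly bimodal (separation >= 2 pooled
    sd); otherwise from the 1 - expected_doublet_rate quantile.  Scores are
    compared strictly (> threshold), so a degenerate all-equal distribution
    removes nothing.
    """
    scores = np.asarray(scores, dtype=float)
    depth_flags = np.asarray(depth_flags, dtype=bool)
    if not (len(droplet_ids) == scores.size == depth_flags.size):
        raise ValueError("droplet_ids, scores and depth_flags must align")

    otsu_t, sep = _otsu_threshold(scores)
    frac_hi = float((scores > otsu_t).mean()) if np.isfinite(otsu_t) and scores.size else 1.0
    plausible = frac_hi <= max(5.0 * config.expected_doublet_rate, 0.02)
    if np.isfinite(otsu_t) and sep >= 2.0 and plausible:
        threshold, source = otsu_t, "bimodal"
    else:
        threshold = float(np.quantile(scores, 1.0 - config.expected_doublet_rate)) if scores.size else 1.0
        source = "quantile"

    by_score = scores > threshold
    remove = by_score | depth_flags
    kept = [d for d, r in zip(droplet_ids, remove) if not r]
    removed = [d for d, r in zip(droplet_ids, remove) if r]
    logger.info(
        "residual filter: threshold %.4f (%s), removed %d by score, %d by depth",
        threshold, source, int(by_score.sum()), int(depth_flags.sum()),
    )
    return ResidualFilterResult(
        kept_ids=kept,
        removed_ids=removed,
        score_threshold=threshold,
        threshold_source=source,
        n_removed_by_score=int(by_score.sum()),
        n_removed_by_depth=int(depth_flags.sum()),
    )
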