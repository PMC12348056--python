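"""Synthetic multiplexed droplet datasets with full ground truth.

The generator emulates pooled-sample droplet experiments in which each
sample's cells (or nuclei) carry a distinct surface-anchored DNA sample tag:
every droplet yields a tag-count vector and a gene-count vector.  Droplets
are independently negative (an unlabeled cell: ambient tag signal only),
doublet (two parent cells drawn independently from the pool), or singlet.

Counts follow a lognormal-depth / multinomial-allocation model:

* a labeled parent's tag total ``T ~ round(LogNormal(meanlog, sdlog))`` is
  allocated multinomially with probability ``1 - b`` on its own tag and
  ``b / (k - 1)`` on each other tag (``b`` = tag background);
* its gene total ``G ~ round(LogNormal)`` is allocated over the parent cell
  type's expression profile mixed with fraction ``a`` of a contaminant
  (ambient) profile — the opposite species' profile in two-species pools,
  the pool average otherwise;
* doublet counts are the sums of two independently generated parents;
* negative droplets draw low-depth ambient totals and allocate tags
  uniformly, genes over the pool-average ambient profile.

Built-in designs mirror the pooling experiments the pipeline is evaluated
on: 2-plex human/mouse barnyard pools (one human and one mouse cell line),
6-plex and 12-plex pools of three human lines, and a two-donor PBMC pool
with a rare pDC-like subpopulation at ~0.5%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_io import ExpressionMatrix, TagCountMatrix

# TruSeq-style 6-bp sample indices (pairwise well separated).
TAG_INDEX_POOL = [
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA", "ACAGTG", "GCCAAT",
    "CAGATC", "ACTTGA", "GATCAG", "TAGCTT", "GGCTAC", "CTTGTA",
]

# Expression profiles are part of the experimental conditions, not of the
# per-run randomness, so they derive from a fixed internal seed.
_PROFILE_SEED = 20240901

SC_DOUBLET_RATE = 0.0542
SN_DOUBLET_RATE = 0.0149


@dataclass
class SampleSpec:
    """One pooled sample: its tag, its species and its cell-type make-up."""

    name: str
    tag_id: str
    tag_index: str
    species: str
    pool_fraction: float
    type_fractions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.type_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"type fractions of {self.name} sum to {total}")


@dataclass
class SimDesign:
    """Complete recipe for one simulated dataset."""

    n_droplets: int
    samples: list[SampleSpec]
    doublet_rate: float
    negative_rate: float
    tag_meanlog: float
    tag_sdlog: float
    tag_background: float
    gene_meanlog: float
    gene_sdlog: float
    ambient_cross_species: float
    neg_tag_meanlog: float
    neg_tag_sdlog: float
    neg_gene_meanlog: float
    neg_gene_sdlog: float
    gene_ids: list[str]
    gene_class: list[str]
    celltype_profiles: dict[str, np.ndarray]
    contam_profiles: dict[str, np.ndarray]
    ambient_profile: np.ndarray
    seed: int
    rare_type: str | None = None
    rare_fraction: float | None = None
    mode: str = "sc"

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValueError("n_droplets must be positive")
        pool = sum(s.pool_fraction for s in self.samples)
        if not math.isclose(pool, 1.0, abs_tol=1e-9):
            raise ValueError(f"pool fractions sum to {pool}, expected 1")
        for rate, name in [
            (self.doublet_rate, "doublet_rate"),
            (self.negative_rate, "negative_rate"),
            (self.tag_background, "tag_background"),
            (self.ambient_cross_species, "ambient_cross_species"),
        ]:
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        tag_ids = [s.tag_id for s in self.samples]
        if len(set(tag_ids)) != len(tag_ids):
            raise ValueError("sample tag_ids are not unique")
        n_genes = len(self.gene_ids)
        if len(self.gene_class) != n_genes:
            raise ValueError("gene_class length mismatch")
        for t, prof in self.celltype_profiles.items():
            if prof.shape != (n_genes,):
                raise ValueError(f"profile for {t} has wrong length")
        for s in self.samples:
            for t in s.type_fractions:
                if t not in self.celltype_profiles:
                    raise ValueError(f"sample {s.name} uses unknown cell type {t}")

    @property
    def pool_fractions(self) -> np.ndarray:
        return np.array([s.pool_fraction for s in self.samples])

    @property
    def tag_ids(self) -> list[str]:
        return [s.tag_id for s in self.samples]


def _dirichlet_flat(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.gamma(1.0, 1.0, n)
    return w / w.sum()


def _normalize(p: np.ndarray) -> np.ndarray:
    return p / p.sum()


def simulate_dataset(
    design: SimDesign,
) -> tuple[TagCountMatrix, ExpressionMatrix, pd.DataFrame]:
    """Draw one dataset: tag counts, gene counts and the ground-truth table.

    Bit-exact reproducible for a fixed design (one generator, fixed draw
    order).  The truth table records per droplet the status, the contributing
    sample(s) as a sorted multiset, and the parent cell type(s)/species.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_droplets
    k = len(design.samples)
    n_genes = len(design.gene_ids)
    pool = design.pool_fractions

    u = rng.random(n)
    is_neg = u < design.negative_rate
    is_dbl = (~is_neg) & (u < design.negative_rate + design.doublet_rate)
    is_sgl = ~(is_neg | is_dbl)

    parent1 = rng.choice(k, size=n, p=pool)
    parent2 = rng.choice(k, size=n, p=pool)

    T1 = np.round(rng.lognormal(design.tag_meanlog, design.tag_sdlog, n)).astype(np.int64)
    T2 = np.round(rng.lognormal(design.tag_meanlog, design.tag_sdlog, n)).astype(np.int64)
    Tneg = np.round(rng.lognormal(design.neg_tag_meanlog, design.neg_tag_sdlog, n)).astype(np.int64)
    G1 = np.round(rng.lognormal(design.gene_meanlog, design.gene_sdlog, n)).astype(np.int64)
    G2 = np.round(rng.lognormal(design.gene_meanlog, design.gene_sdlog, n)).astype(np.int64)
    Gneg = np.round(rng.lognormal(design.neg_gene_meanlog, design.neg_gene_sdlog, n)).astype(np.int64)

    # parent cell types, drawn per sample in fixed sample order
    all_types = sorted(design.celltype_profiles)
    type_code = {t: i for i, t in enumerate(all_types)}
    type1 = np.zeros(n, dtype=np.int64)
    type2 = np.zeros(n, dtype=np.int64)
    for target, parent in ((type1, parent1), (type2, parent2)):
        for s_idx, spec in enumerate(design.samples):
            rows = np.flatnonzero(parent == s_idx)
            names = sorted(spec.type_fractions)
            probs = _normalize(np.array([spec.type_fractions[t] for t in names]))
            drawn = rng.choice(len(names), size=rows.size, p=probs)
            target[rows] = np.array([type_code[t] for t in names])[drawn]

    # ---- tag counts -------------------------------------------------------
    tag_counts = np.zeros((n, k), dtype=np.int64)
    for s_idx in range(k):
        pvec = np.full(k, design.tag_background / (k - 1)) if k > 1 else np.ones(1)
        if k > 1:
            pvec[s_idx] = 1.0 - design.tag_background
        rows = np.flatnonzero((is_sgl | is_dbl) & (parent1 == s_idx))
        if rows.size:
            tag_counts[rows] += rng.multinomial(T1[rows], pvec)
        rows = np.flatnonzero(is_dbl & (parent2 == s_idx))
        if rows.size:
            tag_counts[rows] += rng.multinomial(T2[rows], pvec)
    neg_rows = np.flatnonzero(is_neg)
    if neg_rows.size:
        tag_counts[neg_rows] = rng.multinomial(Tneg[neg_rows], np.full(k, 1.0 / k))

    # ---- gene counts ------------------------------------------------------
    gene_counts = np.zeros((n, n_genes), dtype=np.int64)
    a = design.ambient_cross_species
    for s_idx, spec in enumerate(design.samples):
        contam = design.contam_profiles[spec.name]
        for t_name in sorted(spec.type_fractions):
            t_idx = type_code[t_name]
            profile = _normalize(
                (1.0 - a) * design.celltype_profiles[t_name] + a * contam
            )
            rows = np.flatnonzero((is_sgl | is_dbl) & (parent1 == s_idx) & (type1 == t_idx))
            if rows.size:
                gene_counts[rows] += rng.multinomial(G1[rows], profile)
            rows = np.flatnonzero(is_dbl & (parent2 == s_idx) & (type2 == t_idx))
            if rows.size:
                gene_counts[rows] += rng.multinomial(G2[rows], profile)
    if neg_rows.size:
        gene_counts[neg_rows] = rng.multinomial(
            Gneg[neg_rows], _normalize(design.ambient_profile)
        )

    # ---- assemble ---------------------------------------------------------
    droplet_ids = [f"BC{i:06d}" for i in range(n)]
    tags = TagCountMatrix(
        droplet_ids=droplet_ids,
        tag_ids=design.tag_ids,
        tag_indices=[s.tag_index for s in design.samples],
        counts=tag_counts,
    )
    expr = ExpressionMatrix(
        droplet_ids=droplet_ids,
        gene_ids=list(design.gene_ids),
        gene_class=list(design.gene_class),
        counts=sp.csr_matrix(gene_counts),
    )

    status = np.where(is_neg, "negative", np.where(is_dbl, "doublet", "singlet"))
    names = np.array([s.name for s in design.samples])
    species = np.array([s.species for s in design.samples])
    types = np.array(all_types)

    s1 = names[parent1].astype(object)
    t1 = types[type1].astype(object)
    sp1 = species[parent1].astype(object)
    s2 = np.where(is_dbl, names[parent2], "").astype(object)
    t2 = np.where(is_dbl, types[type2], "").astype(object)
    sp2 = np.where(is_dbl, species[parent2], "").astype(object)
    # sort doublet parents by sample name so the multiset is canonical
    swap = is_dbl & (s2 != "") & (np.asarray(s1, dtype=object) > np.asarray(s2, dtype=object))
    for a_col, b_col in ((s1, s2), (t1, t2), (sp1, sp2)):
        tmp = a_col[swap].copy()
        a_col[swap] = b_col[swap]
        b_col[swap] = tmp
    s1[is_neg] = ""
    t1[is_neg] = ""
    sp1[is_neg] = ""

    truth = pd.DataFrame(
        {
            "droplet_id": droplet_ids,
            "status": status,
            "sample_1": s1,
            "sample_2": s2,
            "cell_type_1": t1,
            "cell_type_2": t2,
            "species_1": sp1,
            "species_2": sp2,
        }
    )
    return tags, expr, truth


# ---------------------------------------------------------------------------
# built-in designs


def _mode_noise(mode: str) -> dict:
    """Default droplet/noise rates by assay mode.

    sc mode uses the measured single-cell doublet rate (5.42%) and ~1%
    unlabeled droplets; sn mode the single-nucleus rate (1.49%) with slightly
    more unlabeled nuclei and lower tag background.
    """
    if mode == "sc":
        return dict(doublet_rate=SC_DOUBLET_RATE, negative_rate=0.01, tag_background=0.02)
    if mode == "sn":
        return dict(doublet_rate=SN_DOUBLET_RATE, negative_rate=0.015, tag_background=0.01)
    raise ValueError(f"mode must be 'sc' or 'sn', got {mode!r}")


_DEPTH = dict(
    tag_meanlog=math.log(300.0),
    tag_sdlog=0.30,
    gene_meanlog=math.log(3000.0),
    gene_sdlog=0.15,
    ambient_cross_species=0.01,
    neg_tag_sdlog=0.5,
    neg_gene_meanlog=math.log(50.0),
    neg_gene_sdlog=0.5,
)


def _neg_tag_meanlog(k: int, b: float, tag_meanlog: float) -> float:
    # unlabeled cells collect ambient tag at the per-tag contamination level
    # of a typical labeled cell, summed over all k tags: k/(k-1) * b * median(T)
    return math.log(max(k / max(k - 1, 1) * b * math.exp(tag_meanlog), 1.0))


def barnyard_design(
    plex: int,
    mode: str = "sc",
    n_droplets: int = 20_000,
    seed: int = 0,
    pool_fractions: list[float] | None = None,
    line_counts: dict[str, int] | None = None,
) -> SimDesign:
    """Cell-line pooling designs.

    ``plex=2`` pools one human line (HEK293T) with one mouse line (NIH3T3) at
    1:1 — the classic barnyard mix whose species signal provides the
    reference annotation.  ``plex=6`` pools 2+2+2 samples of the human lines
    HEK293T / MDA-MB-231 / MCF7; ``plex=12`` pools 5+2+5 of the same lines
    (the mapping is overridable via ``line_counts``).  ``mode`` sets the
    default doublet rate (sc 5.42%, sn 1.49%), the negative rate and the tag
    background.
    """
    if plex not in (2, 6, 12):
        raise ValueError(f"plex must be 2, 6 or 12, got {plex}")
    noise = _mode_noise(mode)
    prof_rng = np.random.default_rng(_PROFILE_SEED)

    if plex == 2:
        gene_ids = [f"hg_gene_{i:03d}" for i in range(100)] + [
            f"mm_gene_{i:03d}" for i in range(100)
        ]
        gene_class = ["species:human"] * 100 + ["species:mouse"] * 100
        human_prof = np.concatenate([_dirichlet_flat(prof_rng, 100), np.zeros(100)])
        mouse_prof = np.concatenate([np.zeros(100), _dirichlet_flat(prof_rng, 100)])
        profiles = {"HEK293T": human_prof, "NIH3T3": mouse_prof}
        fractions = pool_fractions or [0.5, 0.5]
        samples = [
            SampleSpec("HEK293T_1", "Tag1", TAG_INDEX_POOL[0], "human", fractions[0], {"HEK293T": 1.0}),
            SampleSpec("NIH3T3_1", "Tag2", TAG_INDEX_POOL[1], "mouse", fractions[1], {"NIH3T3": 1.0}),
        ]
        contam = {"HEK293T_1": mouse_prof, "NIH3T3_1": human_prof}
    else:
        if plex == 6:
            counts = line_counts or {"HEK293T": 2, "MDA-MB-231": 2, "MCF7": 2}
        else:
            counts = line_counts or {"HEK293T": 5, "MDA-MB-231": 2, "MCF7": 5}
        if sum(counts.values()) != plex:
            raise ValueError(f"line_counts {counts} do not sum to plex={plex}")
        lines = list(counts)
        n_common, n_marker = 100, 20
        gene_ids = [f"hg_common_{i:03d}" for i in range(n_common)]
        gene_class = ["common"] * n_common
        common = _dirichlet_flat(prof_rng, n_common)
        profiles = {}
        for li, line in enumerate(lines):
            gene_ids += [f"{line}_marker_{i:02d}" for i in range(n_marker)]
            gene_class += [f"marker:{line}"] * n_marker
        n_genes = n_common + n_marker * len(lines)
        for li, line in enumerate(lines):
            prof = np.zeros(n_genes)
            prof[:n_common] = 0.7 * common
            start = n_common + li * n_marker
            prof[start : start + n_marker] = 0.3 * _dirichlet_flat(prof_rng, n_marker)
            profiles[line] = prof
        samples = []
        tag_no = 0
        for line in lines:
            for rep in range(counts[line]):
                samples.append(
                    SampleSpec(
                        f"{line}_{rep + 1}",
                        f"Tag{tag_no + 1}",
                        TAG_INDEX_POOL[tag_no],
                        "human",
                        1.0 / plex,
                        {line: 1.0},
                    )
                )
                tag_no += 1
        if pool_fractions is not None:
            for s_spec, p in zip(samples, pool_fractions):
                s_spec.pool_fraction = p
        ambient = _normalize(sum(profiles[line] * counts[line] for line in lines))
        contam = {s.name: ambient for s in samples}

    ambient_profile = _normalize(
        sum(profiles[next(iter(s.type_fractions))] * s.pool_fraction for s in samples)
    )
    return SimDesign(
        n_droplets=n_droplets,
        samples=samples,
        gene_ids=gene_ids,
        gene_class=gene_class,
        celltype_profiles=profiles,
        contam_profiles=contam,
        ambient_profile=ambient_profile,
        seed=seed,
        mode=mode,
        neg_tag_meanlog=_neg_tag_meanlog(plex, noise["tag_background"], _DEPTH["tag_meanlog"]),
        **noise,
        **_DEPTH,
    )


PBMC_TYPE_FRACTIONS = {
    "T_cell": 0.60,
    "B_cell": 0.08,
    "NK_cell": 0.10,
    "CD14_Mono": 0.15,
    "CD16_Mono": 0.03,
    "DC": 0.03,
    "pDC": 0.005,
}


def pbmc_design(n_droplets: int = 20_000, seed: int = 0) -> SimDesign:
    """Two human PBMC donors pooled 1:1, single-nucleus mode.

    Cell-type fractions follow typical PBMC composition (T 60%, B 8%, NK 10%,
    CD14 monocytes 15%, CD16 monocytes 3%, DC 3%, pDC 0.5%), renormalized to
    sum to one.  Each type expresses a disjoint 20-gene marker block (30% of
    its reads) over a shared 100-gene baseline (70%), giving marker-based
    type identification the same role the species signal plays in barnyard
    pools.
    """
    if n_droplets < 1_000:
        raise ValueError("pbmc_design needs n_droplets >= 1000")
    noise = _mode_noise("sn")
    prof_rng = np.random.default_rng(_PROFILE_SEED + 1)
    types = list(PBMC_TYPE_FRACTIONS)
    n_common, n_marker = 100, 20
    gene_ids = [f"hg_common_{i:03d}" for i in range(n_common)]
    gene_class = ["common"] * n_common
    for t in types:
        gene_ids += [f"{t}_marker_{i:02d}" for i in range(n_marker)]
        gene_class += [f"marker:{t}"] * n_marker
    n_genes = n_common + n_marker * len(types)
    common = _dirichlet_flat(prof_rng, n_common)
    profiles = {}
    for ti, t in enumerate(types):
        prof = np.zeros(n_genes)
        prof[:n_common] = 0.7 * common
        start = n_common + ti * n_marker
        prof[start : start + n_marker] = 0.3 * _dirichlet_flat(prof_rng, n_marker)
        profiles[t] = prof

    total = sum(PBMC_TYPE_FRACTIONS.values())
    fractions = {t: f / total for t, f in PBMC_TYPE_FRACTIONS.items()}
    samples = [
        SampleSpec("PBMC_donor1", "Tag1", TAG_INDEX_POOL[0], "human", 0.5, dict(fractions)),
        SampleSpec("PBMC_donor2", "Tag2", TAG_INDEX_POOL[1], "human", 0.5, dict(fractions)),
    ]
    ambient = _normalize(sum(profiles[t] * fractions[t] for t in types))
    return SimDesign(
        n_droplets=n_droplets,
        samples=samples,
        gene_ids=gene_ids,
        gene_class=gene_class,
        celltype_profiles=profiles,
        contam_profiles={s.name: ambient for s in samples},
        ambient_profile=ambient,
        seed=seed,
        rare_type="pDC",
        rare_fraction=fractions["pDC"],
        mode="sn",
        neg_tag_meanlog=_neg_tag_meanlog(2, noise["tag_background"], _DEPTH["tag_meanlog"]),
        **noise,
        **_DEPTH,
    )
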