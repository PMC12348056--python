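"""Two-stage doublet handling: filters, detectability correction, kNN score."""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import roc_auc_score

from glycodemux.core_io import DemuxCall, ExpressionMatrix, RunConfig
from glycodemux.doublets import (
    barcode_doublet_filter,
    depth_outlier_flags,
    estimate_total_doublet_rate,
    knn_doublet_score,
    residual_doublet_filter,
    simulate_artificial_doublets,
)


def mk_call(i, status, tags=()):
    ratio = {"singlet": 0.95, "doublet": 0.5, "negative": 0.0}[status]
    return DemuxCall(f"b{i}", status, tuple(tags), ratio, 100)


class TestBarcodeFilter:
    def test_no_doublets_keeps_all(self):
        calls = [mk_call(i, "singlet", ("Tag1",)) for i in range(10)]
        kept, removed = barcode_doublet_filter(calls)
        assert len(kept) == 10 and not removed

    def test_removes_exactly_the_doublets(self):
        calls = [mk_call(i, "singlet", ("Tag1",)) for i in range(94)]
        calls += [mk_call(100 + i, "doublet", ("Tag1", "Tag2")) for i in range(6)]
        kept, removed = barcode_doublet_filter(calls)
        assert len(removed) == 6
        assert all(c.call_status == "doublet" for c in removed)

    def test_negatives_kept_not_counted_as_doublets(self):
        calls = [mk_call(0, "negative"), mk_call(1, "doublet", ("Tag1", "Tag2"))]
        kept, removed = barcode_doublet_filter(calls)
        assert [c.call_status for c in kept] == ["negative"]

    def test_cross_sample_doublet_removal_rate(self, sc_data, sc_calls):
        """>95% of true cross-sample doublets are caught by tags alone."""
        _, _, truth = sc_data
        status_of = {c.droplet_id: c.call_status for c in sc_calls}
        cross = truth[
            (truth["status"] == "doublet") & (truth["sample_1"] != truth["sample_2"])
        ]
        removed = sum(status_of[d] == "doublet" for d in cross["droplet_id"])
        assert removed / len(cross) > 0.95

    def test_never_removes_true_singlet_in_noiseless_data(self, sc_data):
        # noiseless variant checked end-to-end in test_demux; here the filter
        # itself: singlet calls are never in the removed set
        calls = [mk_call(i, "singlet", ("Tag1",)) for i in range(5)]
        _, removed = barcode_doublet_filter(calls)
        assert not removed


class TestDetectabilityCorrection:
    def test_zero_is_zero(self):
        assert estimate_total_doublet_rate(0.0, np.array([0.5, 0.5])) == 0.0

    def test_two_equal_samples(self):
        est = estimate_total_doublet_rate(0.0271, np.array([0.5, 0.5]))
        assert est == pytest.approx(0.0542)

    def test_twelve_equal_samples(self):
        p = np.full(12, 1 / 12)
        assert estimate_total_doublet_rate(0.11, p) == pytest.approx(12 * 0.11 / 11)

    def test_single_sample_undefined(self):
        with pytest.raises(ValueError):
            estimate_total_doublet_rate(0.01, np.array([1.0]))

    def test_inverts_generator_detectability(self, sc_design, sc_data):
        """cross-sample truth fraction / (1 - sum p^2) recovers d within 3 MC se."""
        _, _, truth = sc_data
        n = len(truth)
        cross = (
            (truth["status"] == "doublet") & (truth["sample_1"] != truth["sample_2"])
        ).mean()
        est = estimate_total_doublet_rate(cross, sc_design.pool_fractions)
        se = np.sqrt(cross * (1 - cross) / n) / 0.5
        assert abs(est - sc_design.doublet_rate) < 3 * se


def tiny_expr(counts):
    counts = np.asarray(counts)
    return ExpressionMatrix(
        droplet_ids=[f"b{i}" for i in range(counts.shape[0])],
        gene_ids=[f"g{j}" for j in range(counts.shape[1])],
        gene_class=["species:human"] * counts.shape[1],
        counts=sp.csr_matrix(counts),
    )


class TestArtificialDoublets:
    def test_two_droplets_sum(self):
        expr = tiny_expr([[1, 0], [0, 1]])
        synth = simulate_artificial_doublets(expr, 20, seed=0)
        assert np.all(np.asarray(synth.todense()) == [1, 1])

    def test_seed_reproducible(self, sc_data):
        _, expr, _ = sc_data
        a = simulate_artificial_doublets(expr, 500, seed=3)
        b = simulate_artificial_doublets(expr, 500, seed=3)
        assert (a != b).nnz == 0

    def test_mean_total_doubles(self, sc_data):
        _, expr, _ = sc_data
        synth = simulate_artificial_doublets(expr, 5_000, seed=0)
        mean_obs = expr.counts.sum() / expr.n_droplets
        mean_synth = synth.sum() / synth.shape[0]
        assert mean_synth == pytest.approx(2 * mean_obs, rel=0.02)

    def test_too_few_droplets(self):
        with pytest.raises(ValueError):
            simulate_artificial_doublets(tiny_expr([[1, 2]]), 5, seed=0)


class TestKnnScore:
    def test_droplet_order_invariance(self, sc_data):
        _, expr, _ = sc_data
        sub = ExpressionMatrix(
            expr.droplet_ids[:800], expr.gene_ids, expr.gene_class, expr.counts[:800]
        )
        synth = simulate_artificial_doublets(sub, 800, seed=1)
        s1 = knn_doublet_score(sub, synth, k=10, expected_doublet_rate=0.05, seed=1)
        perm = np.random.default_rng(0).permutation(800)
        sub_p = ExpressionMatrix(
            [sub.droplet_ids[i] for i in perm], sub.gene_ids, sub.gene_class,
            sub.counts[perm],
        )
        s2 = knn_doublet_score(sub_p, synth, k=10, expected_doublet_rate=0.05, seed=1)
        # same droplets, same synthetic set -> same scores up to reordering
        assert np.allclose(np.sort(s1), np.sort(s2), atol=1e-6)

    def test_auroc_on_default_simulation(self, sc_data, sc_calls, sc_config):
        """Residual (same-tag) doublets separate from singlets at AUROC > 0.9."""
        _, expr, truth = sc_data
        singlet_ids = [c.droplet_id for c in sc_calls if c.call_status == "singlet"]
        row = {d: i for i, d in enumerate(expr.droplet_ids)}
        sub = ExpressionMatrix(
            singlet_ids, expr.gene_ids, expr.gene_class,
            expr.counts[[row[d] for d in singlet_ids]],
        )
        synth = simulate_artificial_doublets(sub, 2 * len(singlet_ids), seed=1)
        scores = knn_doublet_score(
            sub, synth, k=sc_config.knn_k,
            expected_doublet_rate=sc_config.expected_doublet_rate, seed=1,
        )
        tr = truth.set_index("droplet_id").loc[singlet_ids]
        is_dbl = (tr["status"] == "doublet").to_numpy()
        same = is_dbl & (tr["sample_1"] == tr["sample_2"]).to_numpy()
        mask = same | ~is_dbl
        assert roc_auc_score(same[mask], scores[mask]) > 0.9


class TestResidualFilter:
    def cfg(self):
        return RunConfig(random_seed=1, expected_doublet_rate=0.05)

    def test_all_zero_scores_remove_nothing(self):
        ids = [f"b{i}" for i in range(100)]
        res = residual_doublet_filter(
            ids, np.zeros(100), np.zeros(100, dtype=bool), self.cfg()
        )
        assert res.kept_ids == ids and not res.removed_ids

    def test_depth_outlier_flags(self):
        rng = np.random.default_rng(0)
        totals = np.exp(rng.normal(8.0, 0.15, 500))
        totals[0] *= 2.0  # injected doubled-depth droplet
        tags = np.array(["Tag1"] * 500)
        flags = depth_outlier_flags(totals, tags, 1.96)
        assert flags[0]
        assert flags.mean() < 0.06

    def test_injected_doublet_removed(self, sc_data, sc_config):
        """A droplet with doubled depth and a mixed profile fails both rules."""
        _, expr, truth = sc_data
        singlet_rows = np.flatnonzero((truth["status"] == "singlet").to_numpy())[:2000]
        counts = expr.counts[singlet_rows].tolil()
        # inject: sum of a human and a mouse cell (rows 0 and 1 are arbitrary)
        human = np.flatnonzero(truth["species_1"].to_numpy()[singlet_rows] == "human")[0]
        mouse = np.flatnonzero(truth["species_1"].to_numpy()[singlet_rows] == "mouse")[0]
        injected = (counts.tocsr()[human] + counts.tocsr()[mouse])
        counts = sp.vstack([counts.tocsr(), injected], format="csr")
        ids = [f"b{i}" for i in range(counts.shape[0])]
        sub = ExpressionMatrix(ids, expr.gene_ids, expr.gene_class, counts)
        synth = simulate_artificial_doublets(sub, 2 * len(ids), seed=1)
        scores = knn_doublet_score(sub, synth, 20, 0.05, seed=1)
        flags = depth_outlier_flags(
            np.asarray(counts.sum(axis=1)).ravel(), np.array(["Tag1"] * len(ids)), 1.96
        )
        res = residual_doublet_filter(ids, scores, flags, self.cfg())
        assert ids[-1] in res.removed_ids

    def test_alignment_validated(self):
        with pytest.raises(ValueError):
            residual_doublet_filter(["a"], np.zeros(2), np.zeros(2, bool), self.cfg())
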