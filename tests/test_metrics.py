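"""Evaluation statistics: OCA, ratio fidelity, doublet ratios, reporting."""

import dataclasses
import json

import numpy as np
import pandas as pd
import pytest

from glycodemux.core_io import DemuxCall, RunConfig
from glycodemux.metrics import (
    MetricsReport,
    build_report,
    compute_oca,
    doublet_ratios,
    mixing_deviation,
    per_tag_proportions,
    rare_population_recovery,
)

TAG_TO_TYPE = {"Tag1": "human", "Tag2": "mouse"}


def mk_call(i, status, tags=()):
    ratio = {"singlet": 0.95, "doublet": 0.5, "negative": 0.0}[status]
    return DemuxCall(f"b{i}", status, tuple(tags), ratio, 100)


def mk_ref(rows):
    return pd.DataFrame(
        {
            "droplet_id": [f"b{i}" for i in range(len(rows))],
            "ref_status": [r[0] for r in rows],
            "ref_label": [r[1] for r in rows],
        }
    )


class TestOCA:
    def test_all_matching_singlets(self):
        calls = [mk_call(i, "singlet", ("Tag1",)) for i in range(10)]
        ref = mk_ref([("singlet", "human")] * 10)
        oca, _ = compute_oca(calls, ref, TAG_TO_TYPE)
        assert oca == 1.0

    def test_printed_definition_arithmetic(self):
        """90 matching singlets + 5 matching nonsinglets over 100 -> 0.95."""
        calls = [mk_call(i, "singlet", ("Tag1",)) for i in range(90)]
        rows = [("singlet", "human")] * 90
        for i in range(90, 95):
            calls.append(mk_call(i, "doublet", ("Tag1", "Tag2")))
            rows.append(("multiplet", ""))
        for i in range(95, 100):
            calls.append(mk_call(i, "singlet", ("Tag2",)))
            rows.append(("singlet", "human"))  # wrong type -> mismatch
        oca, _ = compute_oca(calls, mk_ref(rows), TAG_TO_TYPE)
        assert oca == pytest.approx(0.95)

    def test_doublet_call_vs_confident_singlet_is_mismatch(self):
        calls = [mk_call(0, "doublet", ("Tag1", "Tag2"))]
        oca, _ = compute_oca(calls, mk_ref([("singlet", "human")]), TAG_TO_TYPE)
        assert oca == 0.0

    def test_negative_matches_undefined(self):
        calls = [mk_call(0, "negative")]
        oca, _ = compute_oca(calls, mk_ref([("undefined", "")]), TAG_TO_TYPE)
        assert oca == 1.0

    def test_type_set_matching(self):
        """A tag mapping to a set of types accepts any of them."""
        calls = [mk_call(0, "singlet", ("Tag1",))]
        ref = mk_ref([("singlet", "B_cell")])
        oca, _ = compute_oca(calls, ref, {"Tag1": frozenset({"T_cell", "B_cell"})})
        assert oca == 1.0

    def test_brute_force_equivalence_random_pairs(self):
        """OCA equals an independent droplet-by-droplet tally on 1,000 random
        call/reference pairs."""
        rng = np.random.default_rng(7)
        statuses = ["singlet", "doublet", "negative"]
        ref_rows = []
        calls = []
        for i in range(1_000):
            s = statuses[rng.integers(3)]
            tags = {"singlet": ("Tag1",) if rng.random() < 0.5 else ("Tag2",),
                    "doublet": ("Tag1", "Tag2"), "negative": ()}[s]
            calls.append(mk_call(i, s, tags))
            rs = ["singlet", "multiplet", "undefined"][rng.integers(3)]
            label = ["human", "mouse"][rng.integers(2)] if rs == "singlet" else ""
            ref_rows.append((rs, label))
        oca, oca_ex = compute_oca(calls, mk_ref(ref_rows), TAG_TO_TYPE)

        hits = hits_nonneg = n_nonneg = 0
        for c, (rs, label) in zip(calls, ref_rows):
            if c.call_status == "singlet":
                ok = rs == "singlet" and TAG_TO_TYPE[c.assigned_tags[0]] == label
            elif c.call_status == "doublet":
                ok = rs == "multiplet"
            else:
                ok = rs == "undefined"
            hits += ok
            if c.call_status != "negative":
                n_nonneg += 1
                hits_nonneg += ok
        assert oca == pytest.approx(hits / 1_000)
        assert oca_ex == pytest.approx(hits_nonneg / n_nonneg)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        calls = [mk_call(i, "singlet", ("Tag1",) if rng.random() < 0.6 else ("Tag2",))
                 for i in range(200)]
        rows = [("singlet", ["human", "mouse"][rng.integers(2)]) for _ in range(200)]
        oca, _ = compute_oca(calls, mk_ref(rows), TAG_TO_TYPE)
        perm = rng.permutation(200)
        ref = mk_ref(rows)
        ref_p = ref.iloc[perm].reset_index(drop=True)
        oca_p, _ = compute_oca([calls[i] for i in perm], ref_p, TAG_TO_TYPE)
        assert oca_p == pytest.approx(oca)

    def test_misaligned_inputs_rejected(self):
        calls = [mk_call(0, "singlet", ("Tag1",))]
        ref = mk_ref([("singlet", "human"), ("singlet", "human")])
        with pytest.raises(ValueError):
            compute_oca(calls, ref, TAG_TO_TYPE)


class TestMixingDeviation:
    def test_paper_proportions(self):
        dev = mixing_deviation(np.array([0.523, 0.477]), np.array([0.5, 0.5]))
        assert dev == pytest.approx(2.3)

    def test_identical_is_zero(self):
        assert mixing_deviation(np.array([0.4, 0.6]), np.array([0.4, 0.6])) == 0.0

    def test_symmetry_and_zero_iff_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.dirichlet(np.ones(4))
            b = rng.dirichlet(np.ones(4))
            assert mixing_deviation(a, b) == pytest.approx(mixing_deviation(b, a))
            assert (mixing_deviation(a, b) == 0.0) == bool(np.allclose(a, b))

    def test_multinomial_sampling_noise(self):
        """At n=10,000 and p=0.5 the deviation stays below 1.5 points."""
        rng = np.random.default_rng(11)
        draws = rng.multinomial(10_000, [0.5, 0.5], size=200) / 10_000
        devs = [mixing_deviation(d, np.array([0.5, 0.5])) for d in draws]
        assert np.quantile(devs, 0.99) < 1.5

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError):
            mixing_deviation(np.array([0.6, 0.6]), np.array([0.5, 0.5]))


class TestDoubletRatios:
    def mk_truth(self, statuses):
        return pd.DataFrame(
            {"droplet_id": [f"b{i}" for i in range(len(statuses))], "status": statuses}
        )

    def test_no_doublets(self):
        truth = self.mk_truth(["singlet"] * 5)
        ids = [f"b{i}" for i in range(5)]
        assert doublet_ratios(truth, ids, ids) == (0.0, 0.0)

    def test_filtering_lowers_ratio(self):
        truth = self.mk_truth(["singlet"] * 8 + ["doublet"] * 2)
        pre = [f"b{i}" for i in range(10)]
        post = [f"b{i}" for i in range(8)] + ["b8"]
        pre_r, post_r = doublet_ratios(truth, pre, post)
        assert pre_r == pytest.approx(0.2)
        assert post_r == pytest.approx(1 / 9)


class TestRareRecovery:
    def mk_inputs(self):
        n = 400
        types = ["T_cell"] * 380 + ["pDC"] * 20
        truth = pd.DataFrame(
            {
                "droplet_id": [f"b{i}" for i in range(n)],
                "status": ["singlet"] * n,
                "cell_type_1": types,
            }
        )
        calls = [
            mk_call(i, "singlet", ("Tag1",) if i % 2 == 0 else ("Tag2",))
            for i in range(n)
        ]
        return truth, calls

    def test_fractions_and_detection(self):
        truth, calls = self.mk_inputs()
        fracs, detected = rare_population_recovery(
            [f"b{i}" for i in range(400)], truth, calls,
            {"T_cell": 0.95, "pDC": 0.05},
        )
        assert set(fracs) == {"Tag1", "Tag2"}
        for tag in fracs:
            assert fracs[tag]["pDC"] == pytest.approx(0.05, abs=0.02)
        assert detected["pDC"] and detected["T_cell"]

    def test_absent_type_not_detected(self):
        truth, calls = self.mk_inputs()
        fracs, detected = rare_population_recovery(
            [f"b{i}" for i in range(400)], truth, calls, {"NK_cell": 0.1}
        )
        assert all("NK_cell" not in per_tag for per_tag in fracs.values())
        assert not detected["NK_cell"]


class TestReport:
    def mk_report(self):
        cfg = RunConfig(random_seed=42)
        return build_report(
            oca=0.97,
            oca_excluding_negatives=0.98,
            tag_proportions={"Tag1": 0.523, "Tag2": 0.477},
            input_proportions={"Tag1": 0.5, "Tag2": 0.5},
            doublet_pre=0.0542,
            doublet_post=0.0003,
            negative_rate_observed=0.01,
            rare_fractions=None,
            rare_detected=None,
            config=cfg,
        )

    def test_round_trip(self, tmp_path):
        rep = self.mk_report()
        rep.to_json(tmp_path / "report.json")
        back = MetricsReport.from_json(tmp_path / "report.json")
        assert back == rep

    def test_invariants_and_echo(self):
        rep = self.mk_report()
        assert sum(rep.per_tag_proportions.values()) == pytest.approx(1.0, abs=1e-9)
        assert rep.seed == 42
        assert rep.config["singlet_threshold"] == 0.9
        assert rep.mixing_deviation == pytest.approx(2.3)

    def test_bad_fraction_rejected(self):
        rep = self.mk_report()
        with pytest.raises(ValueError):
            dataclasses.replace(rep, oca=1.2)
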