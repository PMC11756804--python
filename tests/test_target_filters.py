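import numpy as np
import pandas as pd
import pytest

from cernapipe import PipelineConfig, lnc_mir_pairs, merge_mrna_predictions, mir_mrna_pairs


def _de(ids_dirs, layer="mirna"):
    rows = []
    for fid, d in ids_dirs.items():
        lfc = {"up": 3.0, "down": -3.0, "ns": 0.1}[d]
        rows.append({"feature_id": fid, "layer": layer, "log2fc": lfc,
                     "pvalue": 1e-6 if d != "ns" else 0.9,
                     "fdr": 1e-5 if d != "ns" else 0.95, "direction": d})
    return pd.DataFrame(rows)


LNC_DE = _de({"L1": "up", "L2": "down"}, layer="lncrna")
MIR_DE = _de({"m1": "down", "m2": "up", "m3": "ns"})
MRNA_DE = _de({"G1": "up", "G2": "down", "G3": "ns"}, layer="mrna")


def _mirdb(rows):
    return pd.DataFrame(rows, columns=["lncrna_id", "mirna_id", "target_score", "conservation"])


class TestLncMirPairs:
    def test_boundary_semantics(self):
        # score exactly 60 inclusive; conservation exactly 0.5 strict
        pred = _mirdb([("L1", "m1", 60.0, 0.51), ("L1", "m1", 60.0, 0.50)])
        # duplicate pair collapses to best (60, 0.51) -> retained
        with pytest.warns(UserWarning, match="duplicate"):
            pairs, tally = lnc_mir_pairs({"L1"}, pred, MIR_DE, LNC_DE)
        assert len(pairs) == 1 and tally["retained"] == 1
        pred2 = _mirdb([("L1", "m1", 59.9, 0.8), ("L1", "m2", 60.0, 0.5)])
        pairs2, tally2 = lnc_mir_pairs({"L1"}, pred2, MIR_DE, LNC_DE)
        assert len(pairs2) == 0
        assert tally2["low_target_score"] == 1 and tally2["low_conservation"] == 1

    def test_same_direction_excluded(self):
        pred = _mirdb([("L1", "m2", 80.0, 0.8)])  # L1 up, m2 up
        pairs, tally = lnc_mir_pairs({"L1"}, pred, MIR_DE, LNC_DE)
        assert len(pairs) == 0 and tally["same_direction"] == 1

    def test_non_de_mirna_excluded(self):
        pred = _mirdb([("L1", "m3", 80.0, 0.8)])
        pairs, tally = lnc_mir_pairs({"L1"}, pred, MIR_DE, LNC_DE)
        assert tally["mirna_not_de"] == 1

    def test_non_core_lncrna_excluded_and_zero_pair_core_reported(self):
        pred = _mirdb([("L2", "m2", 80.0, 0.8)])  # L2 is DE but not core
        pairs, tally = lnc_mir_pairs({"L1"}, pred, MIR_DE, LNC_DE)
        assert tally["not_core_lncrna"] == 1
        assert tally["lncrnas_without_mirna"] == ["L1"]

    def test_unknown_id_skipped(self):
        pred = _mirdb([("L1", "ghost-miR", 80.0, 0.8)])
        _, tally = lnc_mir_pairs({"L1"}, pred, MIR_DE, LNC_DE)
        assert tally["unknown_id"] == 1

    def test_core_lncrna_must_be_de(self):
        with pytest.raises(ValueError, match="not differentially expressed"):
            lnc_mir_pairs({"m3"}, _mirdb([]), MIR_DE, _de({"m3": "ns"}, "lncrna"))

    def test_per_mirna_same_trend_scope_removes_globally(self):
        # m2 (up) shares trend with core L1 (up) -> under per-miRNA scope the
        # opposite-direction pairing with L2 is removed too
        lnc_de = _de({"L1": "up", "L2": "down"}, "lncrna")
        pred = _mirdb([("L1", "m2", 80.0, 0.8), ("L2", "m2", 80.0, 0.8)])
        per_pair, _ = lnc_mir_pairs({"L1", "L2"}, pred, MIR_DE, lnc_de)
        assert set(per_pair["lncrna_id"]) == {"L2"}
        cfg = PipelineConfig(same_trend_scope="mirna")
        per_mir, tally = lnc_mir_pairs({"L1", "L2"}, pred, MIR_DE, lnc_de, cfg)
        assert len(per_mir) == 0 and tally["same_direction"] == 2


def _merged(rows):
    ts = pd.DataFrame(
        [r for r in rows if r.get("context_score") is not None],
        columns=["mirna_id", "mrna_id", "context_score"],
    )
    mr = pd.DataFrame(
        [r for r in rows if r.get("miranda_score") is not None],
        columns=["mirna_id", "mrna_id", "miranda_score", "miranda_energy"],
    )
    return merge_mrna_predictions(ts, mr)


class TestMirMrnaPairs:
    def test_boundary_semantics(self):
        # context -0.4 inclusive, miranda 141 > 140 strict, energy -20.5 < -20
        rows = [{"mirna_id": "m1", "mrna_id": "G1", "context_score": -0.4,
                 "miranda_score": 141.0, "miranda_energy": -20.5}]
        pairs, _ = mir_mrna_pairs({"m1"}, _merged(rows), MRNA_DE, MIR_DE)
        assert len(pairs) == 1
        for col, v, reason in [
            ("context_score", -0.39, "context_score"),
            ("miranda_score", 140.0, "miranda_score"),
            ("miranda_energy", -20.0, "miranda_energy"),
        ]:
            bad = [dict(rows[0], **{col: v})]
            pairs, tally = mir_mrna_pairs({"m1"}, _merged(bad), MRNA_DE, MIR_DE)
            assert len(pairs) == 0 and tally[reason] == 1

    def test_single_tool_excluded(self):
        rows = [{"mirna_id": "m1", "mrna_id": "G1", "context_score": -0.6}]
        pairs, tally = mir_mrna_pairs({"m1"}, _merged(rows), MRNA_DE, MIR_DE)
        assert len(pairs) == 0 and tally["single_tool"] == 1

    def test_direction_and_de_gates(self):
        rows = [
            {"mirna_id": "m1", "mrna_id": "G2", "context_score": -0.6,
             "miranda_score": 160.0, "miranda_energy": -25.0},  # both down
            {"mirna_id": "m1", "mrna_id": "G3", "context_score": -0.6,
             "miranda_score": 160.0, "miranda_energy": -25.0},  # G3 ns
        ]
        pairs, tally = mir_mrna_pairs({"m1"}, _merged(rows), MRNA_DE, MIR_DE)
        assert len(pairs) == 0
        assert tally["same_direction"] == 1 and tally["mrna_not_de"] == 1

    def test_mirna_outside_stage_set_excluded(self):
        rows = [{"mirna_id": "m2", "mrna_id": "G2", "context_score": -0.6,
                 "miranda_score": 160.0, "miranda_energy": -25.0}]
        _, tally = mir_mrna_pairs({"m1"}, _merged(rows), MRNA_DE, MIR_DE)
        assert tally["not_in_mirna_set"] == 1


class TestInvariants:
    def _random_inputs(self, seed, n_rows=50):
        rng = np.random.default_rng(seed)
        lncs = [f"L{i}" for i in range(6)]
        mirs = [f"m{i}" for i in range(8)]
        lnc_de = _de({l: rng.choice(["up", "down"]) for l in lncs}, "lncrna")
        mir_de = _de({m: rng.choice(["up", "down", "ns"]) for m in mirs})
        pred = _mirdb(
            [
                (
                    rng.choice(lncs + ["ghost"]),
                    rng.choice(mirs),
                    float(rng.uniform(30, 100)),
                    float(rng.uniform(0.2, 1.0)),
                )
                for _ in range(n_rows)
            ]
        ).drop_duplicates(["lncrna_id", "mirna_id"])
        return set(lncs), pred, mir_de, lnc_de

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_tally_plus_retained_accounts_for_every_row(self, seed):
        core, pred, mir_de, lnc_de = self._random_inputs(seed)
        pairs, tally = lnc_mir_pairs(core, pred, mir_de, lnc_de)
        reasons = sum(
            v for k, v in tally.items()
            if k not in ("retained", "duplicates_collapsed", "lncrnas_without_mirna")
        )
        assert reasons + tally["retained"] + tally["duplicates_collapsed"] == len(pred)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_row_order_invariance(self, seed):
        core, pred, mir_de, lnc_de = self._random_inputs(seed)
        a, _ = lnc_mir_pairs(core, pred, mir_de, lnc_de)
        b, _ = lnc_mir_pairs(core, pred.sample(frac=1.0, random_state=0), mir_de, lnc_de)
        key = ["lncrna_id", "mirna_id"]
        pd.testing.assert_frame_equal(
            a.sort_values(key).reset_index(drop=True),
            b.sort_values(key).reset_index(drop=True),
        )

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_brute_force_conjunct_oracle(self, seed):
        core, pred, mir_de, lnc_de = self._random_inputs(seed)
        cfg = PipelineConfig()
        pairs, _ = lnc_mir_pairs(core, pred, mir_de, lnc_de, cfg)
        lnc_dir = dict(zip(lnc_de["feature_id"], lnc_de["direction"]))
        mir_dir = dict(zip(mir_de["feature_id"], mir_de["direction"]))
        expected = set()
        for r in pred.itertuples(index=False):
            if (
                r.lncrna_id in lnc_dir
                and r.mirna_id in mir_dir
                and r.target_score >= 60
                and r.conservation > 0.5
                and r.lncrna_id in core
                and mir_dir[r.mirna_id] in ("up", "down")
                and lnc_dir[r.lncrna_id] != mir_dir[r.mirna_id]
            ):
                expected.add((r.lncrna_id, r.mirna_id))
        assert set(zip(pairs["lncrna_id"], pairs["mirna_id"])) == expected

    def test_retained_pair_directions_are_opposite(self, dataset, pipeline_result):
        lm = pipeline_result.lnc_mir
        assert (lm["lnc_direction"] != lm["mir_direction"]).all()
        mm = pipeline_result.mir_mrna
        assert (mm["mir_direction"] != mm["mrna_direction"]).all()
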