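import numpy as np
import pandas as pd
import pytest

from budburst.transitions import (STAGES, TRANSITION_STAGES, TRANSITIONS,
                                  build_transition_datasets, encode_transition,
                                  merge_stages, validate_trajectories)

RANK = {s: i for i, s in enumerate(STAGES)}


def traj_frame(stages, doys=None, **keys):
    doys = doys if doys is not None else 130 + 7 * np.arange(len(stages))
    base = {"site": "s", "year": 2016, "species": "sp", "seed_source": "src",
            "tree": "t1", "bud": "b1"}
    base.update(keys)
    return pd.DataFrame([{**base, "doy": int(d), "stage": int(s)}
                         for d, s in zip(doys, stages)])


def brute_force_encode(stages, source, target, mode="strict"):
    """Independent re-encoder from the stated risk-set rule."""
    ranks = [RANK[s] for s in stages]
    tr = RANK[target]
    t_m = next((i for i, r in enumerate(ranks) if r >= tr), None)
    if t_m == 0:
        return []
    out = []
    end = t_m if t_m is not None else len(stages)
    for i in range(end):
        if mode == "strict" and stages[i] != source:
            continue
        out.append((i, 0))
    if t_m is not None:
        out.append((t_m, 1))
    return out


class TestMergeStages:
    def test_one_and_two_become_merged_label(self):
        obs = traj_frame([0, 1, 2, 3])
        merged = merge_stages(obs)
        assert merged["stage"].tolist() == [0, 12, 12, 3]

    def test_out_of_range_stage_rejected(self):
        with pytest.raises(ValueError, match="0..6"):
            merge_stages(traj_frame([0, 7]))


class TestValidate:
    def test_clean_trajectory_passes(self):
        report = validate_trajectories(merge_stages(traj_frame([0, 1, 3, 5, 6])))
        assert report.clean

    def test_stage_regression_reported(self):
        report = validate_trajectories(merge_stages(traj_frame([0, 3, 1])))
        assert report.violations[0]["problem"] == "stage_regression"

    def test_duplicate_census_reported_and_strict_raises(self):
        obs = merge_stages(traj_frame([0, 1], doys=[130, 130]))
        report = validate_trajectories(obs)
        assert report.violations[0]["problem"] == "duplicate_census"
        with pytest.raises(ValueError, match="violation"):
            validate_trajectories(obs, mode="strict")

    def test_lenient_drops_only_offenders(self):
        good = merge_stages(traj_frame([0, 1, 3], bud="b1"))
        bad = merge_stages(traj_frame([3, 0, 0], bud="b2"))
        report = validate_trajectories(pd.concat([good, bad]), mode="lenient")
        assert set(report.clean_obs["bud"]) == {"b1"}


class TestEncode:
    def test_first_transition_hand_enumeration(self):
        obs = merge_stages(traj_frame([0, 0, 1, 3, 5, 6]))
        enc = encode_transition(obs, "0->12")
        assert enc["outcome"].tolist() == [0, 0, 1]
        assert enc["doy"].tolist() == [130, 137, 144]

    def test_skipped_stage_counts_as_success(self):
        # stage jump 3 -> 5 completes 3->4 (and 4->5) at the same census
        obs = merge_stages(traj_frame([0, 0, 1, 3, 5, 6]))
        enc = encode_transition(obs, "3->4")
        assert enc["outcome"].tolist() == [0, 1]
        enc45 = encode_transition(obs, "4->5")
        assert enc45["outcome"].tolist() == [1]

    def test_never_at_risk_contributes_nothing(self):
        obs = merge_stages(traj_frame([0, 0, 0, 0]))
        assert len(encode_transition(obs, "12->3")) == 0

    def test_already_complete_at_first_census_excluded(self):
        obs = merge_stages(traj_frame([6, 6, 6]))
        for tid in TRANSITIONS:
            assert len(encode_transition(obs, tid)) == 0

    def test_cumulative_mode_includes_pre_source_records(self):
        obs = merge_stages(traj_frame([0, 0, 1, 3, 5, 6]))
        enc = encode_transition(obs, "3->4", mode="cumulative")
        # every census from the start until the first record >= 4
        assert enc["outcome"].tolist() == [0, 0, 0, 0, 1]

    @pytest.mark.parametrize("mode", ["strict", "cumulative"])
    def test_matches_brute_force_on_random_monotone_trajectories(self, mode, rng):
        doys = 130 + 7 * np.arange(8)
        for rep in range(300):
            ranks = np.sort(rng.integers(0, 6, size=8))
            stages = [STAGES[r] for r in ranks]
            obs = traj_frame(stages, doys)
            for tid in TRANSITIONS:
                src, tgt = TRANSITION_STAGES[tid]
                expect = brute_force_encode(stages, src, tgt, mode)
                enc = encode_transition(obs, tid, mode=mode)
                got = [(int((d - 130) / 7), int(o))
                       for d, o in zip(enc["doy"], enc["outcome"])]
                assert got == expect, (stages, tid, mode)

    def test_encoding_invariant_to_input_order(self, rng):
        obs = merge_stages(traj_frame([0, 1, 1, 3, 4, 6]))
        shuffled = obs.sample(frac=1.0, random_state=7)
        for tid in TRANSITIONS:
            a = encode_transition(obs, tid).reset_index(drop=True)
            b = encode_transition(shuffled, tid).reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)

    def test_strict_risk_sets_disjoint_except_successes(self):
        obs = merge_stages(traj_frame([0, 1, 3, 4, 5, 6]))
        seen = {}
        for tid in TRANSITIONS:
            enc = encode_transition(obs, tid)
            for _, row in enc.iterrows():
                key = row["doy"]
                if row["outcome"] == 0:
                    assert key not in seen or seen[key] == 0
                    seen.setdefault(key, 0)


class TestBuildDatasets:
    def _covariates(self, doys):
        return pd.DataFrame({
            "site": "s", "year": 2016, "doy": doys,
            "gdd_mean": np.linspace(100, 400, len(doys)),
            "frost_prob": np.linspace(0.6, 0.1, len(doys)),
        })

    def test_counts_match_hand_enumeration(self):
        obs = pd.concat([
            merge_stages(traj_frame([0, 1, 3, 5], bud="b1")),
            merge_stages(traj_frame([0, 0, 1, 1], bud="b2")),
        ])
        cov = self._covariates(130 + 7 * np.arange(4))
        ds = build_transition_datasets(obs, cov)
        # b1: 0->12 [0,1]; b2: 0->12 [0,0,1]
        assert len(ds["0->12"]) == 5
        # b1 contributes [0,1]; b2 two at-risk records [0,0]
        assert len(ds["12->3"]) == 4
        assert len(ds["3->4"]) == 2    # b1 [0, 1]
        assert ds["0->12"]["gdd_mean"].notna().all()

    def test_missing_covariate_doy_is_an_error(self):
        obs = merge_stages(traj_frame([0, 1, 3, 5]))
        cov = self._covariates([130, 137, 151])
        with pytest.raises(ValueError, match="missing"):
            build_transition_datasets(obs, cov)

    def test_all_complete_buds_warn_and_yield_empty(self):
        obs = merge_stages(traj_frame([6, 6, 6, 6]))
        cov = self._covariates(130 + 7 * np.arange(4))
        with pytest.warns(UserWarning, match="empty"):
            ds = build_transition_datasets(obs, cov)
        assert all(len(d) == 0 for d in ds.values())
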