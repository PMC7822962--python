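"""Stimulus design generation and response simulation."""

import numpy as np
import pytest
from scipy.stats import chisquare

import crowdmix as cm
from crowdmix.circular import circ_diff
from crowdmix.models import ParamVector
from crowdmix.synthetic import (
    GEOMETRY,
    DesignConfig,
    GenerativeScenario,
    generate_dataset,
    generate_design,
    simulate_responses,
    trials_to_frame,
)


class TestDesign:
    def test_default_counts(self):
        trials = generate_design(DesignConfig(seed=1))
        assert len(trials) == 600
        by_cond = {}
        for t in trials:
            by_cond[t.condition] = by_cond.get(t.condition, 0) + 1
        assert by_cond == {"uncrowded": 200, "two_flanker": 200, "four_flanker": 200}

    def test_min_target_flanker_separation(self):
        trials = generate_design(DesignConfig(seed=2, n_observers=3))
        seps = [
            abs(circ_diff(f, t.target_ori))
            for t in trials
            for f in t.flanker_oris
        ]
        assert min(seps) >= 15.0

    def test_determinism(self):
        a = generate_design(DesignConfig(seed=3))
        b = generate_design(DesignConfig(seed=3))
        assert a == b
        c = generate_design(DesignConfig(seed=4))
        assert a != c

    def test_exp1_geometry(self):
        trials = generate_design(DesignConfig(experiment="exp1", seed=5))
        two = next(t for t in trials if t.condition == "two_flanker")
        four = next(t for t in trials if t.condition == "four_flanker")
        assert two.target_ecc == 7.0
        assert two.roles == ("1I", "1O") and two.eccentricities == (5.5, 8.5)
        assert four.roles == ("2I", "1I", "1O", "2O")
        assert four.eccentricities == (4.0, 5.5, 8.5, 10.0)
        # adjacent items are 1.5 deg apart including the target at 7
        positions = sorted(four.eccentricities + (7.0,))
        assert np.allclose(np.diff(positions), 1.5)

    def test_exp2_geometry_outward_target(self):
        trials = generate_design(DesignConfig(experiment="exp2", seed=6))
        two = next(t for t in trials if t.condition == "two_flanker")
        four = next(t for t in trials if t.condition == "four_flanker")
        assert two.target_ecc == 8.5
        assert two.roles == ("2I", "1I") and two.eccentricities == (5.5, 7.0)
        assert four.roles == ("3I", "2I", "1I", "1O")
        assert four.eccentricities == (4.0, 5.5, 7.0, 10.0)

    def test_hemifield_balanced(self):
        trials = generate_design(DesignConfig(seed=7))
        lefts = sum(t.hemifield == "left" for t in trials)
        assert lefts == 300

    def test_orientations_on_discrete_grid(self):
        trials = generate_design(DesignConfig(seed=8))
        oris = {t.target_ori for t in trials} | {f for t in trials for f in t.flanker_oris}
        assert all(o == int(o) and 1 <= o <= 180 for o in oris)

    def test_flanker_offsets_cover_allowed_band(self):
        # offsets should spread over +/-15..90, roughly uniformly
        trials = generate_design(
            DesignConfig(seed=9, n_observers=10, conditions=("two_flanker",))
        )
        offs = np.array(
            [circ_diff(f, t.target_ori) for t in trials for f in t.flanker_oris]
        )
        assert np.all(np.abs(offs) >= 15)
        assert offs.min() < -80 and offs.max() > 80
        frac_positive = np.mean(offs > 0)
        assert 0.45 < frac_positive < 0.55


class TestSimulation:
    def test_pure_guess_uniform(self):
        cfg = DesignConfig(
            n_observers=1, trials_per_condition=20_000, conditions=("uncrowded",), seed=10
        )
        scenario = GenerativeScenario(
            params={"uncrowded": ("standard", ParamVector(gamma=1.0, sigma=15.0))}, seed=11
        )
        responses = simulate_responses(generate_design(cfg), scenario)
        vals = np.array([r.response_ori for r in responses])
        counts, _ = np.histogram(vals, bins=np.linspace(0, 180, 19))
        assert chisquare(counts).pvalue > 0.01

    def test_degenerate_outer_misreport(self):
        cfg = DesignConfig(
            n_observers=1, trials_per_condition=500, conditions=("two_flanker",), seed=12
        )
        scenario = GenerativeScenario(
            params={
                "two_flanker": (
                    "two_misreport",
                    ParamVector(gamma=0.0, sigma=5.0, betas=(0.0, 1.0)),
                )
            },
            seed=13,
        )
        responses = simulate_responses(generate_design(cfg), scenario)
        rel = np.array(
            [circ_diff(r.response_ori, r.flanker_oris[r.roles.index("1O")]) for r in responses]
        )
        assert np.all([r.latent_source == "1O" for r in responses])
        assert np.mean(np.abs(rel) < 15) > 0.95

    def test_latent_target_fraction_matches_p_t(self):
        truth = ParamVector(gamma=0.1, sigma=15.0, betas=(0.1, 0.2))  # P_T = 0.6
        cfg = DesignConfig(
            n_observers=1, trials_per_condition=100_000, conditions=("two_flanker",), seed=14
        )
        scenario = GenerativeScenario(params={"two_flanker": ("two_misreport", truth)}, seed=15)
        responses = simulate_responses(generate_design(cfg), scenario)
        frac = np.mean([r.latent_source == "target" for r in responses])
        assert frac == pytest.approx(0.6, abs=0.01)

    def test_uncrowded_scenario_must_be_standard(self):
        scenario = GenerativeScenario(
            params={"uncrowded": ("misreport", ParamVector(0.1, 15.0, (0.2,)))}
        )
        with pytest.raises(ValueError):
            scenario.model_for("uncrowded")

    def test_model_condition_mismatch_rejected(self):
        cfg = DesignConfig(
            n_observers=1, trials_per_condition=5, conditions=("four_flanker",), seed=16
        )
        scenario = GenerativeScenario(
            params={
                "four_flanker": (
                    "two_misreport",
                    ParamVector(gamma=0.1, sigma=15.0, betas=(0.1, 0.1)),
                )
            },
            seed=17,
        )
        with pytest.raises(ValueError):
            simulate_responses(generate_design(cfg), scenario)


class TestDataset:
    def test_thirteen_observers_shape(self):
        df = generate_dataset(DesignConfig(n_observers=13, seed=18))
        assert len(df) == 13 * 600
        assert df["observer_id"].nunique() == 13

    def test_empty_condition_list(self):
        df = generate_dataset(DesignConfig(conditions=(), seed=19))
        assert len(df) == 0

    def test_fixed_seed_byte_identical_csv(self, tmp_path):
        cfg = DesignConfig(seed=20)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_flanker_columns_match_condition(self):
        df = generate_dataset(DesignConfig(seed=21))
        un = df[df["condition"] == "uncrowded"]
        assert un[[f"ori_{r}" for r in ("3I", "2I", "1I", "1O", "2O")]].isna().all().all()
        two = df[df["condition"] == "two_flanker"]
        assert two["ori_1I"].notna().all() and two["ori_1O"].notna().all()
        assert two["ori_2I"].isna().all()
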