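"""Closed-loop campaigns: bookkeeping, determinism, persistence, resume."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phasemap import (
    AcquisitionConfig,
    CampaignConfig,
    compare_strategies,
    resume_campaign,
    run_campaign,
)
from phasemap.errors import ConfigMismatch, CorruptState


def small_cfg(system2d, **kwargs):
    space, model = system2d
    defaults = dict(
        space=space,
        model=model,
        acquisition=AcquisitionConfig(mode="hybrid", batch_size=3),
        n_iterations=3,
        monitor_resolution=11,
        master_seed=7,
    )
    defaults.update(kwargs)
    return CampaignConfig(**defaults)


class TestLoopStructure:
    def test_budget_accounting_and_trace_length(self, system2d):
        cfg = small_cfg(system2d)
        state = run_campaign(cfg)
        assert len(state.samples) == 3 * 3
        assert state.completed_iterations == 3
        # KL needs two posteriors: trace has one entry fewer than iterations
        assert len(state.trace) == 2
        assert state.termination == "budget exhausted"

    def test_single_iteration_has_no_trace(self, system2d):
        cfg = small_cfg(system2d, n_iterations=1)
        state = run_campaign(cfg)
        assert len(state.trace) == 0
        assert len(state.samples) == 3

    def test_early_stop_with_infinite_threshold(self, system2d):
        cfg = small_cfg(
            system2d,
            n_iterations=6,
            convergence_threshold=np.inf,
            patience=1,
            early_stop=True,
        )
        state = run_campaign(cfg)
        assert state.completed_iterations == 2
        assert state.termination.startswith("converged")

    def test_early_stop_default_off(self, system2d):
        cfg = small_cfg(system2d, convergence_threshold=np.inf, patience=1)
        state = run_campaign(cfg)
        assert state.completed_iterations == 3

    def test_all_samples_in_bounds_and_balanced(self, system2d):
        space, _ = system2d
        state = run_campaign(small_cfg(system2d))
        for _, _, s in state.samples:
            assert space.contains(s.composition.flows)
            assert s.composition.flows.sum() + s.composition.counter_flow == pytest.approx(
                space.total_flow
            )

    def test_length_scales_within_bounds_every_iteration(self, system2d):
        space, _ = system2d
        state = run_campaign(small_cfg(system2d))
        for fitted in state.surrogate_states:
            ls = fitted.kernel_state.length_scales
            assert np.all(ls >= space.ranges / 100 - 1e-9)
            assert np.all(ls <= space.ranges + 1e-9)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_logs(self, system2d, tmp_path):
        dirs = [tmp_path / "a", tmp_path / "b"]
        for d in dirs:
            cfg = small_cfg(system2d, output_dir=str(d))
            run_campaign(cfg)
        assert (dirs[0] / "samples.csv").read_bytes() == (dirs[1] / "samples.csv").read_bytes()
        assert (dirs[0] / "trace.csv").read_bytes() == (dirs[1] / "trace.csv").read_bytes()

    def test_different_seed_changes_samples(self, system2d):
        a = run_campaign(small_cfg(system2d, master_seed=1))
        b = run_campaign(small_cfg(system2d, master_seed=2))
        assert not np.array_equal(
            a.samples_dataframe()["ps_fraction"], b.samples_dataframe()["ps_fraction"]
        )


class TestResume:
    def test_resume_zero_iterations_is_noop(self, system2d, tmp_path):
        cfg = small_cfg(system2d, output_dir=str(tmp_path / "run"))
        run_campaign(cfg)
        state = resume_campaign(tmp_path / "run", 0)
        assert state.completed_iterations == 3
        assert len(state.samples) == 9

    def test_resumed_equals_straight_through(self, system2d, tmp_path):
        """2+2 resumed iterations reproduce a straight 4-iteration run."""
        straight = run_campaign(small_cfg(system2d, n_iterations=4))
        cfg = small_cfg(system2d, n_iterations=2, output_dir=str(tmp_path / "half"))
        run_campaign(cfg)
        resumed = resume_campaign(tmp_path / "half", 2)
        pd.testing.assert_frame_equal(
            straight.samples_dataframe(), resumed.samples_dataframe()
        )
        assert np.allclose(straight.trace.rss, resumed.trace.rss)

    def test_modified_space_rejected(self, system2d, system3d, tmp_path):
        cfg = small_cfg(system2d, output_dir=str(tmp_path / "run"))
        run_campaign(cfg)
        space3, model3 = system3d
        other = CampaignConfig(
            space=space3, model=model3,
            acquisition=AcquisitionConfig(batch_size=3), n_iterations=3,
        )
        with pytest.raises(ConfigMismatch):
            resume_campaign(tmp_path / "run", 1, expected_config=other)

    def test_corrupt_state_rejected(self, tmp_path):
        (tmp_path / "state.json").write_text("{not json")
        with pytest.raises(CorruptState):
            resume_campaign(tmp_path, 1)


class TestConfigSerialization:
    def test_yaml_round_trip(self, system2d, tmp_path):
        cfg = small_cfg(system2d)
        path = tmp_path / "campaign.yaml"
        cfg.to_yaml(path)
        loaded = CampaignConfig.from_yaml(path)
        assert loaded.to_dict() == cfg.to_dict()

    def test_unbalanceable_space_rejected_for_campaigns(self, system2d):
        from phasemap import DesignSpace, VariableSpec

        space = DesignSpace(
            (
                VariableSpec("A", 1.0, "M", 0.0, 60.0),
                VariableSpec("B", 1.0, "M", 0.0, 60.0),
            )
        )
        _, model = system2d
        with pytest.raises(ValueError):
            CampaignConfig(space=space, model=model)


class TestCompare:
    def test_single_mode_rejected(self, system2d):
        with pytest.raises(ValueError):
            compare_strategies(small_cfg(system2d), ["hybrid"], n_seeds=1)

    def test_comparison_table_shape(self, system2d):
        cfg = small_cfg(system2d, n_iterations=2)
        table = compare_strategies(cfg, ["random", "exploit"], n_seeds=2)
        assert len(table) == 4
        assert set(table["mode"]) == {"random", "exploit"}
        assert table["boundary_error"].notna().all()
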