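"""Phase analysis: classification, stability regions, spinodal, adsorption."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydropore import analysis
from hydropore.analysis import (
    StatePointSummary,
    classify_conformation,
    default_grid,
    derive_seed,
    detect_spinodal,
    stability_regions,
    summarize,
)
from hydropore.chain import max_contact_points
from hydropore.energetics import ModelParams, ThermoState
from hydropore.engine import SystemState
from hydropore.lattice import GridSpec


def make_summary(T, P, mean_ncp=0.0, mean_v=1.2, mean_vtot=1700.0):
    return StatePointSummary(
        T_star=T, P_star=P, n_samples=100,
        mean_N_CP=mean_ncp, se_N_CP=0.1,
        mean_N_HB=900.0, se_N_HB=5.0,
        mean_N_HB_phi=40.0, se_N_HB_phi=1.0,
        mean_v_rel=mean_v, se_v_rel=0.01,
        mean_V_tot=mean_vtot, se_V_tot=5.0,
        max_N_CP=mean_ncp + 3, adsorbed_fraction=0.5, gas=mean_v > 2.0,
    )


class TestClassification:
    def test_globule_strictly_above_half(self):
        assert classify_conformation(13.0, 36) == "globule"
        assert classify_conformation(12.5, 36) == "coil"  # strict '>'
        assert classify_conformation(12.500001, 36) == "globule"

    def test_scales_with_length(self):
        # bound for a 16-mer is 9, so the globule threshold is 4.5
        assert max_contact_points(16) == 9
        assert classify_conformation(5.0, 16) == "globule"
        assert classify_conformation(4.5, 16) == "coil"


class TestSummarize:
    def _df(self):
        n = 100
        return pd.DataFrame({
            "N_CP": np.full(n, 10.0),
            "N_HB": np.full(n, 900.0),
            "N_HB_phi": np.full(n, 40.0),
            "v_rel": np.full(n, 1.25),
            "V_tot": np.full(n, 2450.0),
            "wall_contacts": np.concatenate([np.zeros(40), np.ones(60)]),
            "com_height": np.full(n, 20.0),
        })

    def test_means_and_flags(self):
        s = summarize(self._df(), 0.3, 0.1)
        assert s.mean_N_CP == 10.0
        assert s.se_N_CP == 0.0
        assert s.adsorbed_fraction == pytest.approx(0.6)
        assert not s.gas
        assert s.n_samples == 100

    def test_gas_flag(self):
        df = self._df()
        df["v_rel"] = 2.4
        assert summarize(df, 0.55, -0.1).gas

    def test_no_wall_adsorption_nan(self):
        s = summarize(self._df(), 0.3, 0.1, has_wall=False)
        assert np.isnan(s.adsorbed_fraction)


class TestStabilityRegions:
    def test_nesting_on_synthetic_grid(self):
        summaries = [
            make_summary(t, p, mean_ncp=25.0 * np.exp(-8 * ((t - 0.15) ** 2 + p**2)))
            for t in (0.05, 0.1, 0.15, 0.2, 0.3)
            for p in (-0.1, 0.0, 0.1, 0.3)
        ]
        regions = stability_regions(summaries)
        assert set(regions) == {0.30, 0.40, 0.50}
        assert regions[0.50].points <= regions[0.40].points <= regions[0.30].points

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_nesting_property(self, seed):
        rng = np.random.default_rng(seed)
        summaries = [
            make_summary(t, p, mean_ncp=float(rng.uniform(0, 25)))
            for t in np.linspace(0.05, 0.5, 6)
            for p in np.linspace(-0.2, 0.6, 5)
        ]
        regions = stability_regions(summaries)
        assert regions[0.50].points <= regions[0.40].points <= regions[0.30].points

    def test_threshold_counting(self):
        ncp_max = max_contact_points(36)
        summaries = [make_summary(0.1, 0.0, mean_ncp=0.45 * ncp_max)]
        regions = stability_regions(summaries)
        assert (0.1, 0.0) in regions[0.30]
        assert (0.1, 0.0) in regions[0.40]
        assert (0.1, 0.0) not in regions[0.50]


class TestSpinodal:
    def _scan(self, T_gas, T_vals):
        return [
            make_summary(t, 0.0, mean_v=2.5 if t >= T_gas else 1.2,
                         mean_vtot=4200.0 if t >= T_gas else 2100.0)
            for t in T_vals
        ]

    def test_detects_first_gas_temperature(self):
        ss = self._scan(0.5, (0.3, 0.4, 0.5, 0.6))
        assert detect_spinodal(ss) == 0.5

    def test_liquid_everywhere_returns_none(self):
        ss = self._scan(9.9, (0.3, 0.4, 0.5, 0.6))
        assert detect_spinodal(ss) is None

    def test_jump_criterion_alone(self):
        ss = [
            make_summary(0.3, 0.0, mean_v=1.2, mean_vtot=2000.0),
            make_summary(0.4, 0.0, mean_v=1.9, mean_vtot=3500.0),
        ]
        assert detect_spinodal(ss, criterion="jump") == 0.4
        assert detect_spinodal(ss, criterion="volume") is None

    def test_stable_under_grid_refinement(self):
        coarse = self._scan(0.5, (0.3, 0.4, 0.5, 0.6))
        fine = self._scan(0.5, (0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6))
        assert detect_spinodal(coarse) == detect_spinodal(fine) == 0.5

    def test_mixed_pressures_rejected(self):
        ss = [make_summary(0.3, 0.0), make_summary(0.4, 0.1)]
        with pytest.raises(ValueError, match="single pressure"):
            detect_spinodal(ss)

    def test_unknown_criterion(self):
        with pytest.raises(ValueError, match="criterion"):
            detect_spinodal([make_summary(0.3, 0.0)], criterion="banana")


class TestSeedsAndGrid:
    def test_derive_seed_deterministic(self):
        assert derive_seed(42, 3) == derive_seed(42, 3)
        assert derive_seed(42, 3) != derive_seed(42, 4)
        assert 0 <= derive_seed(42, 3) < 2**31

    def test_default_grid_shape(self):
        grid = default_grid()
        Ts = sorted({t for t, _ in grid})
        Ps = sorted({p for _, p in grid})
        assert Ps == pytest.approx(list(np.arange(-0.2, 0.61, 0.1)))
        assert Ts[0] == 0.05
        assert Ts[-1] == 0.6
        # fine resolution below 0.2
        assert 0.075 in Ts and 0.125 in Ts

    def test_empty_grid_rejected(self):
        from hydropore.engine import RunConfig

        with pytest.raises(ValueError, match="empty"):
            analysis.sweep_phase_diagram([], RunConfig(n_steps=10, n_equil=0))


class TestAdsorption:
    def _df(self):
        return pd.DataFrame({
            "wall_contacts": [0.0, 1.0, 4.0, 0.0],
            "com_height": [20.0, 38.0, 39.0, 21.0],
        })

    def test_metrics(self):
        m = analysis.adsorption_metrics(self._df())
        assert m["adsorbed_fraction"] == pytest.approx(0.5)
        assert m["mean_wall_contacts"] == pytest.approx(1.25)

    def test_requires_wall(self):
        with pytest.raises(ValueError, match="wall"):
            analysis.adsorption_metrics(self._df(), has_wall=False)


class TestExportFields:
    def test_all_matched_counts(self, rng):
        spec = GridSpec(L=10, wall_row=None)
        state = SystemState.initialize(spec, None, ModelParams(), ThermoState(0.3), rng)
        state.sigma[:] = 0  # every facing pair matches
        counts, edges = analysis.export_fields(state)
        assert np.all(counts == 4)
        assert len(edges) == 200  # 2 L^2 bonds
        assert set(edges["kind"]) == {"bulk"}

    def test_gas_state_no_bonds(self, rng):
        spec = GridSpec(L=10, wall_row=None)
        state = SystemState.initialize(
            spec, None, ModelParams(), ThermoState(0.3), rng, v_rel=2.5
        )
        state.sigma[:] = 0
        counts, edges = analysis.export_fields(state)
        assert np.all(counts == 0)
        assert len(edges) == 0

    def test_shell_tags(self, rng):
        spec = GridSpec(L=10)  # wall at row 0
        state = SystemState.initialize(spec, None, ModelParams(), ThermoState(0.3), rng)
        state.sigma[:] = 0
        _, edges = analysis.export_fields(state)
        shell_edges = edges[edges["kind"] == "shell"]
        # shell rows y = 1 and y = 9: ten horizontal bonds each
        assert len(shell_edges) == 20
        assert set(shell_edges["y1"]) <= {1, 9}
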