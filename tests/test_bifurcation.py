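"""Stimulus scans, pattern classification, thresholds and sweeps."""

import numpy as np
import pytest

from klkbarrier.bifurcation import (
    CONTINUOUS,
    IRREVERSIBLE,
    REVERSIBLE,
    BifurcationDiagram,
    classify_pattern,
    low_branch_threshold,
    production_curves,
    scan_mu,
    summarize_cell,
    sweep_feedback_grid,
    total_klk5_curve,
)
from klkbarrier.model import ModelState, build_parameters, lekti_production
from klkbarrier.steady import STABLE, UNSTABLE, SteadyState


def _fake_state(pact: float, stability: str) -> SteadyState:
    return SteadyState(
        state=ModelState(1.0, 1.0, 0.1, 0.1, 1.0, pact),
        residual_norm=0.0,
        stability=stability,
        leading_eigenvalue_real=-1.0 if stability == STABLE else 1.0,
    )


def _toy_diagram(mu_grid, low_on, high_on):
    """Constructed diagram: low branch on low_on, high branch on high_on."""
    branches = []
    for mu in mu_grid:
        col = []
        if low_on[0] <= mu <= low_on[1]:
            col.append(_fake_state(0.1, STABLE))
        if high_on[0] <= mu <= high_on[1]:
            col.append(_fake_state(5.0, STABLE))
        branches.append(col)
    return BifurcationDiagram(np.asarray(mu_grid, float), branches, params=None)


class TestClassifyPatternOnToyDiagrams:
    grid = np.round(np.arange(0.0, 1.01, 0.1), 10)

    def test_reversible_bistable(self):
        d = _toy_diagram(self.grid, low_on=(0.0, 0.6), high_on=(0.2, 1.0))
        s = classify_pattern(d)
        assert s.pattern == REVERSIBLE
        assert s.mu_on == pytest.approx(0.6)
        assert s.mu_off == pytest.approx(0.2)
        assert s.delta_mu == pytest.approx(0.4)

    def test_irreversible_bistable(self):
        d = _toy_diagram(self.grid, low_on=(0.0, 0.6), high_on=(0.0, 1.0))
        s = classify_pattern(d)
        assert s.pattern == IRREVERSIBLE
        assert s.mu_off is None and s.delta_mu is None
        assert s.mu_on == pytest.approx(0.6)

    def test_continuous_monostable(self):
        d = _toy_diagram(self.grid, low_on=(0.0, 1.0), high_on=(2.0, 3.0))
        s = classify_pattern(d)
        assert s.pattern == CONTINUOUS
        assert s.mu_on is None

    def test_stable_state_gap_is_discontinuous(self):
        branches = [
            [_fake_state(0.1, STABLE)] if (mu < 0.3 or mu > 0.7)
            else [_fake_state(1.0, UNSTABLE)]
            for mu in self.grid
        ]
        d = BifurcationDiagram(self.grid, branches, params=None)
        assert classify_pattern(d).pattern == "discontinuous_monostable"


class TestScanMu:
    def test_grid_length_contract(self, hc1_nofeedback):
        grid = np.linspace(0.0, 10.0, 11)
        d = scan_mu(hc1_nofeedback, grid)
        assert len(d.branches) == len(grid)

    def test_no_activation_single_branch(self, hc1_nofeedback):
        """With KLK5 activation disabled the zero branch is the only one."""
        p = hc1_nofeedback.with_(kA=0.0, kP=0.0)
        d = scan_mu(p, np.linspace(0.0, 60.0, 13))
        assert all(len(col) == 1 for col in d.branches)
        assert all(col[0].stability == STABLE for col in d.branches)

    def test_feedback_bistable_window(self, hc1):
        """KLK5 feedback at mid strength: three coexisting states."""
        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        d = scan_mu(p, np.linspace(0.0, 60.0, 61))
        assert max(len(col) for col in d.branches) == 3
        assert d.stable_counts().max() == 2

    def test_states_sorted_by_pact(self, hc1):
        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        d = scan_mu(p, np.linspace(0.0, 60.0, 31))
        for col in d.branches:
            pacts = [s.Pact for s in col]
            assert pacts == sorted(pacts)


class TestThresholds:
    def test_hysteresis_ordering(self, hc1):
        s = summarize_cell(hc1.with_(alphaK=0.5, alphaL=0.0), mu_max=60.0)
        assert s.pattern == REVERSIBLE
        assert 0.0 < s.mu_off < s.mu_on
        assert s.delta_mu == pytest.approx(s.mu_on - s.mu_off)

    def test_threshold_independent_of_feedback_strength(self, hc1):
        """mu_on is a property of the zero branch, where Pact = 0."""
        a = low_branch_threshold(hc1.with_(alphaK=0.2, alphaL=0.0), 60.0)
        b = low_branch_threshold(hc1.with_(alphaK=0.8, alphaL=0.4), 60.0)
        assert a == pytest.approx(b, rel=1e-3)

    def test_self_activation_alone_gives_hysteresis(self, hc1_nofeedback):
        """Saturating KLK5 self-activation sustains bistability at alphaK=0."""
        s = summarize_cell(hc1_nofeedback, mu_max=60.0)
        assert s.pattern == REVERSIBLE
        assert s.mu_off > 0

    def test_irreversible_at_strong_feedback(self, hc1):
        s = summarize_cell(hc1.with_(alphaK=1.0, alphaL=0.0), mu_max=60.0)
        assert s.pattern == IRREVERSIBLE
        assert s.mu_off is None

    def test_fast_path_agrees_with_scan_classification(self, hc1):
        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        fast = summarize_cell(p, mu_max=60.0)
        scanned = classify_pattern(scan_mu(p, np.linspace(0.0, 60.0, 61)))
        assert fast.pattern == scanned.pattern == REVERSIBLE
        assert fast.mu_on == pytest.approx(scanned.mu_on, rel=1e-3)
        assert fast.mu_off == pytest.approx(scanned.mu_off, rel=1e-3)

    def test_low_branch_threshold_brackets_verdict_change(self, hc1):
        from klkbarrier.bifurcation import _low_branch_verdict

        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        mu_on = low_branch_threshold(p, 60.0)
        assert _low_branch_verdict(p, mu_on * 0.999)
        assert not _low_branch_verdict(p, mu_on * 1.001)

    def test_pattern_stable_under_grid_doubling(self, hc1):
        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        a = classify_pattern(scan_mu(p, np.linspace(0, 60, 41)))
        b = classify_pattern(scan_mu(p, np.linspace(0, 60, 81)))
        assert a.pattern == b.pattern
        assert a.mu_on == pytest.approx(b.mu_on, rel=1e-3)


@pytest.fixture(scope="module")
def small_sweep():
    return sweep_feedback_grid("HC", 1, (0.2, 1.0), (0.0, 0.5),
                               resolution=5, mu_max=60.0)


class TestSweep:
    def test_grid_size(self, small_sweep):
        assert len(small_sweep) == 25

    def test_stronger_klk_feedback_more_severe(self, small_sweep):
        """Irreversible bistability appears toward the strong-alphaK edge."""
        severity_map = {CONTINUOUS: 0, "discontinuous_monostable": 0,
                        REVERSIBLE: 1, IRREVERSIBLE: 2}
        for aL in small_sweep["alphaL"].unique():
            row = small_sweep[small_sweep["alphaL"] == aL].sort_values("alphaK")
            sev = row["pattern"].map(severity_map).dropna()
            assert sev.iloc[-1] >= sev.iloc[0]
        assert (small_sweep["pattern"] == IRREVERSIBLE).any()

    def test_delta_mu_nondecreasing_in_alphaK(self, small_sweep):
        """Stronger KLK feedback means more persistent inflammation."""
        seen = 0
        for aL in small_sweep["alphaL"].unique():
            row = small_sweep[
                (small_sweep["alphaL"] == aL)
                & (small_sweep["pattern"] == REVERSIBLE)
            ].sort_values("alphaK")
            d = row["delta_mu"].to_numpy()
            seen += len(d)
            assert np.all(np.diff(d) >= -1e-6)
        assert seen >= 2

    def test_hysteresis_ordering_in_every_reversible_cell(self, small_sweep):
        rev = small_sweep[small_sweep["pattern"] == REVERSIBLE]
        assert len(rev) > 0
        assert (rev["mu_off"] < rev["mu_on"]).all()

    def test_no_activation_gives_monostable_cells(self):
        sw = sweep_feedback_grid("HC", 1, (0.0, 0.5), (0.0, 0.5),
                                 resolution=2, mu_max=60.0,
                                 overrides={"kA": 0.0, "kP": 0.0})
        assert (sw["pattern"] == CONTINUOUS).all()


class TestADComparison:
    def test_lower_inflammation_threshold_for_ad(self):
        """AD conditions ignite at lower stimulus than healthy skin."""
        thresholds = {}
        for cond in ("HC", "AD-LEKTI", "AD-pH"):
            p = build_parameters(cond, 1, {"alphaK": 0.6, "alphaL": 0.1})
            thresholds[cond] = low_branch_threshold(p, 60.0)
        assert thresholds["AD-LEKTI"] < thresholds["HC"]
        assert thresholds["AD-pH"] < thresholds["HC"]


@pytest.fixture(scope="module")
def hc_diagram():
    p = build_parameters("HC", 1, {"alphaK": 0.5, "alphaL": 0.1})
    return p, scan_mu(p, np.linspace(0.0, 60.0, 25))


class TestDerivedCurves:
    def test_production_monotone_in_pact(self, hc_diagram):
        p, d = hc_diagram
        pc = production_curves(p, d.mu_grid, diagram=d)
        for _, grp in pc.groupby("mu"):
            grp = grp.sort_values("Pact")
            assert grp["f_K"].is_monotonic_increasing
            assert grp["f_L"].is_monotonic_increasing  # variant 1 positive fb

    def test_ad_lekti_halves_f_l(self):
        hc = build_parameters("HC", 1, {"alphaK": 0.5})
        ad = build_parameters("AD-LEKTI", 1, {"alphaK": 0.5})
        for mu in (0.0, 3.0, 20.0):
            for pact in (0.0, 3.0, 12.0):
                assert lekti_production(mu, pact, ad) == pytest.approx(
                    0.5 * lekti_production(mu, pact, hc)
                )

    def test_variant2_high_state_produces_less_lekti(self):
        p = build_parameters("HC", 2, {})
        assert lekti_production(3.0, 10.0, p) < lekti_production(3.0, 0.0, p)

    def test_total_klk5_high_branch_exceeds_low(self, hc1):
        """Ignited branch holds more total KLK5 material at the same mu."""
        p = hc1.with_(alphaK=0.5, alphaL=0.0)
        grid = np.linspace(26.0, 48.0, 8)  # inside the bistable window
        tot = total_klk5_curve(p, grid)
        assert (tot["total_klk5"] >= 0).all()
        both = 0
        for _, grp in tot.groupby("mu"):
            stable = grp[grp["stability"] == STABLE].sort_values("Pact")
            if len(stable) == 2:
                both += 1
                assert stable["total_klk5"].iloc[1] > stable["total_klk5"].iloc[0]
        assert both >= 4

    def test_total_zero_at_origin(self, hc1_nofeedback):
        tot = total_klk5_curve(hc1_nofeedback, np.linspace(0.0, 1.0, 3))
        at_zero = tot[tot["mu"] == 0.0]
        assert at_zero["total_klk5"].iloc[0] == pytest.approx(0.0, abs=1e-9)
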