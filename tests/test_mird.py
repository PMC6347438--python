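"""MIRD dose sum, wall correction, effective dose and regulatory screening."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bloodpool_dosim.biodistribution import FULL_RETENTION, TiaVector
from bloodpool_dosim.errors import SchemaMismatchError, ValidationError
from bloodpool_dosim.mird import (
    AdminLimitResult,
    HollowOrganSpec,
    RegulatoryLimits,
    SValueMatrix,
    TissueWeights,
    absorbed_doses,
    admin_limits,
    compare_agents,
    effective_dose,
    total_effective_dose,
    wall_correction,
)


def smatrix(values, names=None):
    names = names or [f"r{i}" for i in range(len(values))]
    return SValueMatrix(pd.DataFrame(values, index=names, columns=names))


# Hand-sized ã vectors in these unit tests can exceed the 18F physical-decay
# ceiling; carry them on a very long-lived nuclide so only the dose arithmetic
# is under test.
from bloodpool_dosim.physics import Radionuclide as _R

_CARRIER = _R("long-lived", 1e9)


def tia(entries, nuclide=None):
    return TiaVector(entries, nuclide or _CARRIER, FULL_RETENTION)


class TestSValueMatrix:
    def test_self_dose_dominance_enforced(self):
        with pytest.raises(ValidationError, match="dominance"):
            smatrix([[1.0, 5.0], [2.0, 1.0]])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            smatrix([[1.0, -0.1], [0.1, 1.0]])


class TestAbsorbedDoses:
    def test_zero_tia_zero_dose(self, f18):
        s = smatrix([[3.0, 1.0], [0.5, 4.0]])
        doses = absorbed_doses(tia({"r0": 0.0, "r1": 0.0}, f18), s)
        assert doses == {"r0": 0.0, "r1": 0.0}

    def test_hand_matrix_vector_product(self, f18):
        s = smatrix([[3.0, 1.0], [0.5, 4.0]])
        doses = absorbed_doses(tia({"r0": 1.0, "r1": 2.0}), s)
        assert doses["r0"] == pytest.approx(5.0)
        assert doses["r1"] == pytest.approx(8.5)

    def test_missing_source_lists_offenders(self, f18):
        s = smatrix([[3.0, 1.0], [0.5, 4.0]])
        with pytest.raises(SchemaMismatchError, match="nowhere"):
            absorbed_doses(tia({"nowhere": 1.0}, f18), s)

    @given(seed=st.integers(0, 500))
    def test_equals_double_loop_oracle(self, seed):
        """Random 10x10 instance vs an element-wise double loop."""
        from bloodpool_dosim.physics import Radionuclide

        f18 = Radionuclide("F-18", 109.77)
        rng = np.random.default_rng(seed)
        n = 10
        m = rng.uniform(0, 0.5, (n, n))
        np.fill_diagonal(m, m.max() + rng.uniform(0.1, 1.0, n))  # dominance
        s = smatrix(m)
        a = rng.uniform(0, 2.639 / n, n)
        vec = tia(dict(zip(s.sources, a)), f18)
        doses = absorbed_doses(vec, s)
        for i, target in enumerate(s.targets):
            oracle = sum(a[j] * m[i, j] for j in range(n))
            assert doses[target] == pytest.approx(oracle, rel=1e-12, abs=1e-15)

    def test_linear_in_tia(self, f18):
        s = smatrix([[3.0, 1.0], [0.5, 4.0]])
        d1 = absorbed_doses(tia({"r0": 0.5, "r1": 0.25}, f18), s)
        d2 = absorbed_doses(tia({"r0": 1.0, "r1": 0.5}, f18), s)
        for k in d1:
            assert d2[k] == pytest.approx(2 * d1[k], rel=1e-12)


class TestWallCorrection:
    def test_zero_delta_is_noop(self, f18):
        doses = {"gut": 5.0}
        spec = HollowOrganSpec("gut", 0.1, 0.2, 0.0)
        out = wall_correction(doses, tia({"gut": 1.0}, f18), spec)
        assert out == doses

    def test_surface_term_replaced_by_wall_term(self, f18):
        # electron component changes from 0.5*2/0.2 = 5 to 2/0.1 = 20
        doses = {"gut": 30.0}
        spec = HollowOrganSpec("gut", wall_mass_kg=0.1, contents_mass_kg=0.2,
                               delta_electron=2.0)
        out = wall_correction(doses, tia({"gut": 1.0}, f18), spec)
        assert out["gut"] == pytest.approx(30.0 - 5.0 + 20.0)

    def test_equal_mass_equal_tia_doubles_electron_term(self, f18):
        """With m_wall == m_contents and ã_wall == ã_contents the corrected
        electron term is exactly twice the surface-convention term."""
        delta, mass, a = 2.0, 0.15, 1.3
        surface = 0.5 * a * delta / mass
        doses = {"gut": surface}  # dose consisting solely of the electron term
        spec = HollowOrganSpec("gut", mass, mass, delta)
        out = wall_correction(doses, tia({"gut": a}, f18), spec)
        assert out["gut"] == pytest.approx(2.0 * surface, rel=1e-12)

    def test_only_the_specified_organ_changes_and_stays_nonnegative(self, f18):
        doses = {"gut": 1.0, "liver": 2.0}
        spec = HollowOrganSpec("gut", 1.0, 0.001, 5.0)  # huge surface term
        out = wall_correction(doses, tia({"gut": 0.5}, f18), spec)
        assert out["liver"] == 2.0
        assert out["gut"] >= 0.0

    def test_absent_organ_warns_noop(self, f18):
        doses = {"liver": 2.0}
        spec = HollowOrganSpec("gut", 0.1, 0.2, 2.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = wall_correction(doses, tia({"liver": 1.0}, f18), spec)
        assert out == doses


class TestEffectiveDose:
    def test_uniform_dose_is_reproduced(self, icrp60_weights, organ_dose_table):
        """E of a uniform dose D equals D: the weights sum to 1."""
        doses = {o: 1.0 for o in organ_dose_table.index}
        assert effective_dose(doses, icrp60_weights) == pytest.approx(1.0, rel=1e-9)

    def test_single_weighted_tissue(self):
        w = TissueWeights({"lungs": 0.12}, 0.88, ("rest",))
        assert effective_dose({"lungs": 1.0, "rest": 0.0}, w) == pytest.approx(0.12)

    def test_missing_tissue_named(self, icrp60_weights):
        with pytest.raises(SchemaMismatchError, match="gonads"):
            effective_dose({"lungs": 1.0}, icrp60_weights)

    def test_surrogates_used(self, icrp60_weights, organ_dose_table):
        """oesophagus <- thymus and gonads <- testes surrogate mapping."""
        doses = organ_dose_table["full_retention"].to_dict()
        e_with = effective_dose(doses, icrp60_weights)
        doses2 = dict(doses, thymus=doses["thymus"] * 2)
        e_shift = effective_dose(doses2, icrp60_weights)
        # thymus enters via the oesophagus weight AND the remainder mean
        expected_delta = doses["thymus"] * (0.05 + 0.05 / 10)
        assert e_shift - e_with == pytest.approx(expected_delta, rel=1e-9)

    def test_published_table_recomputation_reported(
        self, icrp60_weights, organ_dose_table
    ):
        """Recomputing E from the published organ doses with textbook ICRP-60
        weights gives ~2.5E-02 mSv/MBq; the published headline coefficient
        (3.90E-02) folds in opaque software conventions and is treated as an
        input elsewhere, so only sanity bounds are asserted here."""
        e = effective_dose(organ_dose_table["full_retention"].to_dict(), icrp60_weights)
        assert 0.015 < e < 0.039

    def test_linearity_of_mixture(self, icrp60_weights, organ_dose_table):
        a = organ_dose_table["full_retention"].to_dict()
        b = organ_dose_table["free_fdg_25pct"].to_dict()
        mix = {k: 0.3 * a[k] + 0.7 * b[k] for k in a}
        assert effective_dose(mix, icrp60_weights) == pytest.approx(
            0.3 * effective_dose(a, icrp60_weights)
            + 0.7 * effective_dose(b, icrp60_weights),
            rel=1e-12,
        )


class TestAdminLimits:
    def test_heart_wall_five_admins(self, organ_dose_table, cfr_limits):
        """Published heart-wall coefficient at 370 MBq/administration against
        the 150 mSv annual other-organ limit caps at 5 administrations."""
        doses = organ_dose_table["full_retention"].to_dict()
        res = admin_limits(doses, 0.039, 370.0, cfr_limits)
        assert res.limiting_organ == "heart_wall"
        assert res.max_annual_admins == 5
        assert res.max_annual_admins == math.floor(150.0 / (7.78e-2 * 370.0))

    def test_all_zero_no_binding_constraint(self, cfr_limits):
        res = admin_limits({"liver": 0.0}, 0.0, 370.0, cfr_limits)
        assert not res.binding
        assert res.limiting_organ is None

    def test_exactly_at_single_limit(self, cfr_limits):
        # one organ exactly at its 50 mSv single-admin limit
        res = admin_limits({"liver": 50.0 / 370.0}, 0.0, 370.0, cfr_limits)
        assert res.max_annual_admins == 3  # floor(150/50)
        assert res.max_single_admin_mbq == pytest.approx(370.0)

    def test_restricted_category_uses_tighter_limits(self, cfr_limits):
        res = admin_limits({"testes": 50.0 / 370.0}, 0.0, 370.0, cfr_limits)
        assert res.max_annual_admins == 0  # 50 mSv > 30 mSv single limit

    @given(activity=st.floats(10.0, 2000.0))
    def test_antitone_in_activity(self, activity, organ_dose_table, cfr_limits):
        """More activity per administration never allows more administrations."""
        doses = organ_dose_table["full_retention"].to_dict()
        lo = admin_limits(doses, 0.039, activity, cfr_limits)
        hi = admin_limits(doses, 0.039, activity * 1.5, cfr_limits)
        assert hi.max_annual_admins <= lo.max_annual_admins


class TestTotalEffectiveDose:
    @pytest.mark.parametrize(
        "activity, expected", [(370.0, 14.4), (185.0, 7.2), (0.0, 0.0)]
    )
    def test_planned_range(self, activity, expected):
        assert total_effective_dose(3.90e-02, activity) == expected

    def test_raw_product(self):
        assert total_effective_dose(7.0e-03, 1110.0, ndigits=None) == pytest.approx(7.77)


class TestCompareAgents:
    def test_identical_reports_unity_ratios(self, organ_dose_table):
        d = organ_dose_table["full_retention"].to_dict()
        out = compare_agents({"a": d, "b": d})
        assert np.allclose(out["ratio_b"], 1.0)

    def test_scenario_contrast_ratios(self, organ_dose_table):
        out = compare_agents(
            {
                "full_retention": organ_dose_table["full_retention"].to_dict(),
                "free_fdg_25pct": organ_dose_table["free_fdg_25pct"].to_dict(),
            }
        )
        assert out.loc["bladder", "ratio_free_fdg_25pct"] == pytest.approx(
            3.98e-02 / 9.70e-03, rel=1e-9
        )
        assert out.loc["brain", "ratio_free_fdg_25pct"] == pytest.approx(
            1.49e-02 / 7.16e-03, rel=1e-9
        )

    def test_scaled_report_scales_ratios(self, organ_dose_table):
        d = organ_dose_table["full_retention"].to_dict()
        out = compare_agents({"a": d, "b": {k: 2 * v for k, v in d.items()}})
        assert np.allclose(out["ratio_b"], 2.0)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValidationError):
            compare_agents({"a": {"x": 1.0}, "b": {"y": 1.0}})


def test_synthetic_dominant_matrix_puts_peak_dose_on_a_source(f18):
    """With self-dose dominance, the highest-dose organ is a source with ã>0."""
    from bloodpool_dosim.synthetic import default_phantom, make_smatrix

    s = make_smatrix(default_phantom(), f18)
    entries = {"heart_wall": 1.2, "liver": 0.8}
    doses = absorbed_doses(TiaVector(entries, f18, FULL_RETENTION), s)
    assert max(doses, key=doses.get) in entries
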