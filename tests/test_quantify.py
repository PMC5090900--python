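"""Activity, solubility, expression and specificity quantification."""

import numpy as np
import pandas as pd
import pytest

from aarscan.quantify import (
    ConfigurationError,
    MeasurementSet,
    NotDetermined,
    assemble_profiles,
    profiles_to_frame,
    read_blot_table,
    read_hydrocarbon_table,
    relative_activity,
    relative_expression,
    relative_specificity,
    solubility,
    specificity_fractions,
)


def make_tables(spec):
    """Build hydro/blot frames from {variant: dict(totals=[...], fractions=(...),
    soluble=[...], insoluble=[...], detected=bool)}."""
    hydro_rows, blot_rows = [], []
    for vid, cfg in spec.items():
        fracs = np.asarray(cfg.get("fractions", (0.4, 0.5, 0.1)))
        for rep, total in enumerate(cfg["totals"], start=1):
            amounts = total * fracs
            hydro_rows.append(
                dict(
                    variant_id=vid,
                    replicate=rep,
                    amount_c15=amounts[0],
                    amount_c17_1=amounts[1],
                    amount_c17_0=amounts[2],
                )
            )
        for rep, (s, p) in enumerate(zip(cfg["soluble"], cfg["insoluble"]), start=1):
            blot_rows.append(
                dict(
                    variant_id=vid,
                    replicate=rep,
                    soluble_volume=s,
                    insoluble_volume=p,
                    soluble_detected=cfg.get("detected", True),
                    insoluble_detected=True,
                )
            )
    return pd.DataFrame(hydro_rows), pd.DataFrame(blot_rows)


def mset(hydro, blot, vid):
    return MeasurementSet(
        vid, hydro[hydro.variant_id == vid], blot[blot.variant_id == vid]
    )


class TestFractions:
    def test_symmetric_pair(self):
        assert specificity_fractions((1, 1, 0)).tolist() == [0.5, 0.5, 0.0]

    def test_single_product_profile(self):
        # the all-pentadecane profile, for any positive amount
        for x in (0.2, 1.0, 7.5):
            assert specificity_fractions((x, 0, 0)).tolist() == [1.0, 0.0, 0.0]

    def test_all_zero_is_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            specificity_fractions((0, 0, 0))

    def test_scaling_invariance(self):
        a = specificity_fractions((2.0, 5.0, 1.0))
        b = specificity_fractions((20.0, 50.0, 10.0))
        assert np.allclose(a, b)
        assert a.sum() == pytest.approx(1.0)


class TestSolubility:
    def test_one_to_four_is_twenty_percent(self):
        assert solubility(1, 4) == 20.0

    def test_no_insoluble_is_hundred(self):
        assert solubility(3, 0) == 100.0

    def test_equal_bands_fifty(self):
        assert solubility(2.5, 2.5) == 50.0

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            solubility(0, 0)

    def test_non_detect_propagates(self):
        with pytest.raises(NotDetermined):
            solubility(float("nan"), 1.0)


class TestRelativeSpecificity:
    def test_identical_triples(self):
        assert np.allclose(relative_specificity((0.4, 0.5, 0.1), (0.4, 0.5, 0.1)), 1.0)

    def test_doubled_pentadecane_fraction(self):
        out = relative_specificity((0.75, 0.2, 0.05), (0.375, 0.5, 0.125))
        assert out[0] == pytest.approx(2.0)

    def test_zero_reference_fraction_undefined(self):
        out = relative_specificity((0.5, 0.5, 0.0), (0.5, 0.5, 0.0))
        assert np.isnan(out[2])


class TestRelativeActivity:
    def test_reference_against_itself(self):
        hydro, blot = make_tables({"ref": dict(totals=[4, 4, 4], soluble=[2, 2, 2], insoluble=[1, 1, 1])})
        ref = mset(hydro, blot, "ref")
        assert relative_activity(ref, ref) == (1.0, 0.0)

    def test_double_total_equal_soluble(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[8], soluble=[2], insoluble=[1]),
            }
        )
        ratio, _ = relative_activity(mset(hydro, blot, "v"), mset(hydro, blot, "ref"))
        assert ratio == pytest.approx(2.0)

    def test_hand_arithmetic_example(self):
        # variant 6/2 = 3 vs reference 4/2 = 2 -> 1.5
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[6], soluble=[2], insoluble=[1]),
            }
        )
        ratio, _ = relative_activity(mset(hydro, blot, "v"), mset(hydro, blot, "ref"))
        assert ratio == pytest.approx(1.5)

    def test_non_detect_raises(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[6], soluble=[0], insoluble=[1], detected=False),
            }
        )
        with pytest.raises(NotDetermined):
            relative_activity(mset(hydro, blot, "v"), mset(hydro, blot, "ref"))

    def test_invariant_to_global_blot_rescaling(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4, 5], soluble=[2, 2.5], insoluble=[1, 1]),
                "v": dict(totals=[6, 7], soluble=[1, 1.5], insoluble=[2, 2]),
            }
        )
        base, _ = relative_activity(mset(hydro, blot, "v"), mset(hydro, blot, "ref"))
        scaled = blot.copy()
        scaled[["soluble_volume", "insoluble_volume"]] *= 37.0
        rescaled, _ = relative_activity(mset(hydro, scaled, "v"), mset(hydro, scaled, "ref"))
        assert rescaled == pytest.approx(base)


class TestRelativeExpression:
    def test_hand_arithmetic(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[1], insoluble=[1]),
                "v": dict(totals=[4], soluble=[3], insoluble=[1]),
            }
        )
        ratio, _ = relative_expression(mset(hydro, blot, "v"), mset(hydro, blot, "ref"))
        assert ratio == pytest.approx(2.0)


class TestAssembleProfiles:
    def test_reference_only_all_ratios_one(self):
        hydro, blot = make_tables({"ref": dict(totals=[4, 5, 6], soluble=[2, 2, 2], insoluble=[1, 1, 1])})
        (profile,) = assemble_profiles(hydro, blot, "ref")
        assert profile.relative_activity == 1.0
        assert profile.relative_expression == 1.0
        assert profile.total_relative == 1.0
        assert profile.relative_activity_se == 0.0

    def test_missing_reference_is_configuration_error(self):
        hydro, blot = make_tables({"v": dict(totals=[4], soluble=[2], insoluble=[1])})
        with pytest.raises(ConfigurationError):
            assemble_profiles(hydro, blot, "ref")

    def test_variant_missing_from_blot_not_determined(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[6], soluble=[2], insoluble=[1]),
            }
        )
        hydro2 = pd.concat(
            [
                hydro,
                pd.DataFrame(
                    [
                        dict(
                            variant_id="orphan",
                            replicate=1,
                            amount_c15=1.0,
                            amount_c17_1=1.0,
                            amount_c17_0=0.0,
                        )
                    ]
                ),
            ],
            ignore_index=True,
        )
        profiles = {p.variant_id: p for p in assemble_profiles(hydro2, blot, "ref")}
        orphan = profiles["orphan"]
        assert not orphan.activity_determined
        assert not orphan.solubility_determined
        assert orphan.fractions["c15"] == pytest.approx(0.5)

    def test_fractions_sum_to_one_and_ses_finite(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4, 5], soluble=[2, 2], insoluble=[1, 1]),
                "v": dict(totals=[6, 7], soluble=[2, 3], insoluble=[1, 2], fractions=(0.7, 0.25, 0.05)),
            }
        )
        for profile in assemble_profiles(hydro, blot, "ref"):
            assert sum(profile.fractions.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(np.isfinite(v) for v in profile.fraction_ses.values())

    def test_ado_covariate_warns_when_variable(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[6], soluble=[2], insoluble=[1]),
            }
        )
        blot["ado_soluble_volume"] = [1.0, 10.0]
        with pytest.warns(UserWarning, match="ADO"):
            assemble_profiles(hydro, blot, "ref")

    def test_table_readers_validate(self, tmp_path):
        hydro, blot = make_tables({"ref": dict(totals=[4], soluble=[2], insoluble=[1])})
        hp, bp = tmp_path / "h.tsv", tmp_path / "b.tsv"
        hydro.to_csv(hp, sep="\t", index=False)
        blot.to_csv(bp, sep="\t", index=False)
        assert len(read_hydrocarbon_table(hp)) == 1
        assert read_blot_table(bp)["soluble_detected"].all()
        bad = hydro.copy()
        bad.loc[0, "amount_c15"] = -1.0
        bad.to_csv(hp, sep="\t", index=False)
        with pytest.raises(ValueError, match="negative"):
            read_hydrocarbon_table(hp)

    def test_profiles_frame_has_one_row_per_variant(self):
        hydro, blot = make_tables(
            {
                "ref": dict(totals=[4], soluble=[2], insoluble=[1]),
                "v": dict(totals=[6], soluble=[2], insoluble=[1]),
            }
        )
        frame = profiles_to_frame(assemble_profiles(hydro, blot, "ref"))
        assert list(frame["variant_id"]) == ["ref", "v"]
        assert "fraction_c15" in frame.columns
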