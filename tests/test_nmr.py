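import numpy as np
import pandas as pd
import pytest

from retromimic import InputError, parse_sequence, retro_d_transform
from retromimic.nmr import (
    align_profiles_by_type,
    cis_trans_populations,
    compute_csd,
    load_random_coil,
    read_shift_table,
    temperature_coefficients,
    write_shift_table,
)
from retromimic.synthetic import gen_shift_table


def make_table(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "residue_index",
            "residue_code",
            "nucleus",
            "species",
            "temperature_K",
            "shift_ppm",
        ],
    )


class TestCSD:
    def test_zero_profile_when_observed_equals_reference(self, hai):
        table, _ = gen_shift_table(hai, noise_sigma=0.0)
        at298 = table[table["temperature_K"] == 298.0]
        profile = compute_csd(at298)
        assert np.abs(profile.table["csd_ppm"]).max() <= 1e-12
        assert profile.rc_source

    def test_simple_subtraction(self):
        rc = load_random_coil()
        ref = rc[(rc.residue_code == "A") & (rc.nucleus == "CA")][
            "shift_ppm"
        ].iloc[0]
        table = make_table([[1, "A", "CA", "major", 298.0, ref + 0.8]])
        profile = compute_csd(table)
        assert profile.table["csd_ppm"].iloc[0] == pytest.approx(0.8)

    def test_known_vector_recovered_exactly(self, hai):
        truth = {(2, "CA"): 1.3, (5, "HA"): -0.25, (3, "CB"): 0.4}
        table, _ = gen_shift_table(hai, true_csd=truth, noise_sigma=0.0)
        profile = compute_csd(table[table["temperature_K"] == 298.0])
        lookup = {
            (r.residue_index, r.nucleus): r.csd_ppm
            for r in profile.table.itertuples()
        }
        for key, val in truth.items():
            assert lookup[key] == pytest.approx(val, abs=1e-12)
        # everything not imposed stays at random coil
        others = [
            v for k, v in lookup.items() if k not in truth and k[1] != "HN"
        ]
        assert np.abs(others).max() <= 1e-12

    def test_missing_reference_named(self):
        rc = load_random_coil()
        rc_no_trp = rc[rc.residue_code != "W"]
        table = make_table([[1, "W", "CA", "major", 298.0, 57.0]])
        with pytest.raises(InputError, match="'W'"):
            compute_csd(table, rc_table=rc_no_trp, rc_source="pruned")

    def test_antisymmetric_under_swap(self):
        # forward: observed vs reference; backward: reference values taken
        # as the observation with the observed shifts as reference
        observed = make_table(
            [
                [1, "A", "CA", "major", 298.0, 53.1],
                [2, "R", "HA", "major", 298.0, 4.10],
            ]
        )
        reference = pd.DataFrame(
            {
                "residue_code": ["A", "R"],
                "nucleus": ["CA", "HA"],
                "shift_ppm": [52.3, 4.34],
            }
        )
        forward = compute_csd(observed, rc_table=reference, rc_source="ref")
        swapped_obs = make_table(
            [
                [1, "A", "CA", "major", 298.0, 52.3],
                [2, "R", "HA", "major", 298.0, 4.34],
            ]
        )
        swapped_ref = pd.DataFrame(
            {
                "residue_code": ["A", "R"],
                "nucleus": ["CA", "HA"],
                "shift_ppm": [53.1, 4.10],
            }
        )
        back = compute_csd(swapped_obs, rc_table=swapped_ref, rc_source="obs")
        merged = forward.table.merge(
            back.table, on=["residue_index", "nucleus"], suffixes=("_f", "_b")
        )
        assert np.allclose(merged["csd_ppm_f"], -merged["csd_ppm_b"], atol=1e-12)


class TestAlignment:
    def test_hai_pairing(self, hai, retro_hai):
        p_table, _ = gen_shift_table(hai, noise_sigma=0.0)
        r_table, _ = gen_shift_table(retro_hai, noise_sigma=0.0)
        p = compute_csd(p_table[p_table.temperature_K == 298.0])
        r = compute_csd(r_table[r_table.temperature_K == 298.0])
        paired = align_profiles_by_type(p, r, hai, retro_hai)
        assert (
            paired["retro_residue_index"] == 8 - paired["residue_index"]
        ).all()
        assert (
            paired["residue_code"].str.upper()
            == paired["retro_residue_code"].str.upper()
        ).all()

    def test_identity_pair_rejected(self, hai):
        table, _ = gen_shift_table(hai, noise_sigma=0.0)
        p = compute_csd(table[table.temperature_K == 298.0])
        with pytest.raises(InputError):
            align_profiles_by_type(p, p, hai, hai)

    def test_mimicking_pair_correlates_better_than_scramble(self, hai, retro_hai):
        rng = np.random.default_rng(0)
        true_vec = {(i, "CA"): v for i, v in enumerate(
            rng.normal(0, 1.0, size=7), start=1
        )}
        # retro-D mimics: same CSD on the type-aligned residue
        retro_vec = {(8 - i, "CA"): v for (i, _), v in true_vec.items()}
        p_table, _ = gen_shift_table(hai, true_csd=true_vec, noise_sigma=0.02, seed=1)
        r_table, _ = gen_shift_table(
            retro_hai, true_csd=retro_vec, noise_sigma=0.02, seed=2
        )
        scram_vec = {(i, "CA"): v for i, v in zip(
            range(1, 8), rng.permutation(list(true_vec.values()))
        )}
        s_table, _ = gen_shift_table(
            retro_hai, true_csd={(8 - i, "CA"): v for (i, _), v in scram_vec.items()},
            noise_sigma=0.02, seed=3,
        )
        p = compute_csd(p_table[p_table.temperature_K == 298.0])
        r = compute_csd(r_table[r_table.temperature_K == 298.0])
        s = compute_csd(s_table[s_table.temperature_K == 298.0])
        paired = align_profiles_by_type(p, r, hai, retro_hai)
        scrambled = align_profiles_by_type(p, s, hai, retro_hai)
        ca = paired[paired.nucleus == "CA"]
        ca_s = scrambled[scrambled.nucleus == "CA"]
        corr = np.corrcoef(ca.parent_csd_ppm, ca.retro_csd_ppm)[0, 1]
        corr_s = np.corrcoef(ca_s.parent_csd_ppm, ca_s.retro_csd_ppm)[0, 1]
        assert corr > corr_s


class TestTemperatureCoefficients:
    def test_exact_line_recovered(self):
        temps = np.arange(278.0, 309.0, 5.0)
        rows = [
            [1, "A", "HN", "major", t, 8.24 - 6.0e-3 * (t - 278.0)]
            for t in temps
        ]
        out = temperature_coefficients(make_table(rows))
        assert out["slope_ppb_per_K"].iloc[0] == pytest.approx(-6.0, abs=1e-9)
        assert not out["shielded_flag"].iloc[0]

    def test_constant_shift_flagged(self):
        rows = [[1, "A", "HN", "major", t, 8.24] for t in (278.0, 288.0, 298.0)]
        out = temperature_coefficients(make_table(rows))
        assert out["slope_ppb_per_K"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["shielded_flag"].iloc[0]

    def test_generator_round_trip(self, hai):
        slopes = {i: -8.0 + i for i in range(1, 8)}  # -7 ... -1 ppb/K
        table, _ = gen_shift_table(hai, hn_slopes_ppb_per_k=slopes, noise_sigma=0.0)
        out = temperature_coefficients(table)
        for r in out.itertuples():
            assert r.slope_ppb_per_K == pytest.approx(
                slopes[r.residue_index], abs=1e-9
            )

    def test_too_few_points_skipped_with_warning(self):
        rows = [
            [1, "A", "HN", "major", 278.0, 8.2],
            [1, "A", "HN", "major", 288.0, 8.1],
            [2, "R", "HN", "major", 278.0, 8.3],
            [2, "R", "HN", "major", 288.0, 8.2],
            [2, "R", "HN", "major", 298.0, 8.1],
        ]
        with pytest.warns(UserWarning, match="residue 1"):
            out = temperature_coefficients(make_table(rows))
        assert out["residue_index"].tolist() == [2]

    def test_equivariance_under_added_linear_term(self):
        temps = (278.0, 283.0, 288.0, 298.0, 308.0)
        rng = np.random.default_rng(2)
        base = [[1, "A", "HN", "major", t, 8.2 + rng.normal(0, 0.01)] for t in temps]
        df = make_table(base)
        out0 = temperature_coefficients(df)
        c = 2.5e-3  # ppm/K
        df2 = df.copy()
        df2["shift_ppm"] = df2["shift_ppm"] + c * df2["temperature_K"]
        out1 = temperature_coefficients(df2)
        assert out1["slope_ppb_per_K"].iloc[0] - out0["slope_ppb_per_K"].iloc[
            0
        ] == pytest.approx(c * 1000, abs=1e-6)

    def test_ols_sampling_calibration(self):
        # sigma = 0.002 ppm at 7 temperatures: the OLS slope should land
        # within +/-0.5 ppb/K of truth in at least 95% of repetitions
        temps = np.arange(278.0, 309.0, 5.0)
        truth = -6.0e-3  # ppm/K
        rng = np.random.default_rng(3)
        x = temps - temps.mean()
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            y = 8.24 + truth * x + rng.normal(0, 0.002, size=temps.size)
            slope = (x @ (y - y.mean())) / (x @ x)
            hits += abs(slope - truth) * 1000 <= 0.5
        assert hits / n_rep >= 0.95


class TestPopulations:
    def test_three_to_one(self):
        pops = cis_trans_populations({"trans": 3.0, "cis": 1.0})
        assert pops["trans"] == pytest.approx(0.75)
        assert pops["cis"] == pytest.approx(0.25)

    def test_single_species(self):
        assert cis_trans_populations({"trans": 2.2}) == {"trans": 1.0}

    def test_methods_agree_on_same_input(self):
        intensities = {"trans": 0.8, "cis": 0.2}
        a = cis_trans_populations(intensities, method="amide-1d")
        b = cis_trans_populations(intensities, method="pro-cd-hsqc")
        assert a == b

    def test_scale_invariance(self):
        base = cis_trans_populations({"trans": 3.0, "cis": 1.0})
        scaled = cis_trans_populations({"trans": 300.0, "cis": 100.0})
        for k in base:
            assert base[k] == pytest.approx(scaled[k])

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            cis_trans_populations({"trans": 0.0, "cis": 0.0})

    def test_generator_cis_fraction_round_trip(self, hai):
        _, intensities = gen_shift_table(hai, cis_fraction=0.25)
        pops = cis_trans_populations(intensities)
        assert pops["cis"] == pytest.approx(0.25)


def test_shift_table_io_round_trip(tmp_path, hai):
    table, _ = gen_shift_table(hai, noise_sigma=0.01, seed=5)
    path = tmp_path / "shifts.tsv"
    write_shift_table(table, path)
    back = read_shift_table(path)
    pd.testing.assert_frame_equal(
        back.sort_values(["residue_index", "nucleus", "temperature_K"]).reset_index(
            drop=True
        ),
        table.sort_values(["residue_index", "nucleus", "temperature_K"]).reset_index(
            drop=True
        ),
        check_exact=False,
    )


def test_duplicate_rows_rejected():
    rows = [
        [1, "A", "CA", "major", 298.0, 52.5],
        [1, "A", "CA", "major", 298.0, 52.6],
    ]
    with pytest.raises(InputError, match="duplicate"):
        compute_csd(make_table(rows))
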