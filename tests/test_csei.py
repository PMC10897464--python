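"""Voxel fitting round trips and composition conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perilipid.csei import (FitOptions, composition_from_ndb, fit_volume,
                            fit_voxel, maps_from_truth)
from perilipid.phantom import generate_phantom, simulate_echo_series
from perilipid.spectral import NMIDB_COEFF, signal_model

from conftest import small_spec


def _simulate(spectrum, ff, ndb, psi, r2s, te):
    nmidb = NMIDB_COEFF * ndb ** 2
    return signal_model(1 - ff, ff, ndb, nmidb, psi, r2s, te, spectrum)


def test_noiseless_voxel_recovers_all_parameters(spectrum, te16):
    s = _simulate(spectrum, 0.8, 2.5, 30.0, 30.0, te16)
    r = fit_voxel(s, te16, spectrum)
    assert r.converged
    assert abs(r.fat_fraction - 0.8) < 1e-3 * 0.8
    assert abs(r.ndb - 2.5) < 1e-3 * 2.5
    assert abs(r.psi_hz - 30.0) < 1e-3 * 30.0
    assert abs(r.r2star - 30.0) < 1e-3 * 30.0


def test_water_only_voxel_flags_unidentifiable_composition(spectrum, te16):
    s = signal_model(1.0, 0.0, 2.0, 0.37, 10.0, 20.0, te16, spectrum)
    r = fit_voxel(s, te16, spectrum)
    assert r.fat_fraction <= 1e-6


def test_all_zero_signal_returns_nonconverged_not_exception(spectrum, te16):
    r = fit_voxel(np.zeros(16, dtype=complex), te16, spectrum)
    assert not r.converged


def test_large_field_offset_resolved_by_candidate_grid(spectrum, te16):
    """A field offset near the aliasing band edge must not produce a
    water-fat swap."""
    s = _simulate(spectrum, 0.85, 2.0, -350.0, 40.0, te16)
    r = fit_voxel(s, te16, spectrum)
    assert abs(r.fat_fraction - 0.85) < 1e-3
    assert abs(r.psi_hz + 350.0) < 0.5


def test_fitted_ndb_is_monotone_in_true_ndb(spectrum, te16):
    fitted = []
    for ndb in np.linspace(1.0, 4.0, 7):
        s = _simulate(spectrum, 0.9, ndb, 20.0, 40.0, te16)
        fitted.append(fit_voxel(s, te16, spectrum).ndb)
    assert np.all(np.diff(fitted) > 0)


def test_magnitude_mode_recovers_composition(spectrum, te16):
    s = _simulate(spectrum, 0.85, 2.2, 0.0, 35.0, te16)
    r = fit_voxel(s, te16, spectrum, FitOptions(mode="magnitude"))
    assert abs(r.fat_fraction - 0.85) < 1e-3
    assert abs(r.ndb - 2.2) < 1e-2


def test_free_nmidb_mode_round_trip(spectrum, te16):
    s = signal_model(0.1, 0.9, 2.4, 0.45, 15.0, 30.0, te16, spectrum)
    r = fit_voxel(s, te16, spectrum, FitOptions(constrain_nmidb=False))
    assert abs(r.ndb - 2.4) < 5e-3
    assert abs(r.nmidb - 0.45) < 5e-3


class TestCompositionFromNdb:
    @pytest.mark.parametrize("ndb,nmidb,expected", [
        (0.0, 0.0, (0.0, 0.0, 1.0)),
        (3.0, 0.0, (1.0, 0.0, 0.0)),
        (2.4, 0.45, (0.50, 0.15, 0.35)),
    ])
    def test_known_values(self, ndb, nmidb, expected):
        np.testing.assert_allclose(composition_from_ndb(ndb, nmidb), expected,
                                   atol=1e-12)

    def test_excess_nmidb_is_a_domain_error(self):
        with pytest.raises(ValueError, match="MUFA"):
            composition_from_ndb(1.0, 0.6)

    @settings(derandomize=True, max_examples=100)
    @given(ndb=st.floats(0.0, 3.0), frac=st.floats(0.0, 1.0))
    def test_fractions_sum_to_one(self, ndb, frac):
        m, p, s = composition_from_ndb(ndb, frac * ndb / 2.0)
        assert abs(m + p + s - 1.0) <= 1e-9
        for x in (m, p, s):
            assert -1e-12 <= x <= 1.0 + 1e-12


def test_volume_round_trip_on_noiseless_phantom(spectrum):
    """Voxelwise fitting of a noiseless phantom recovers the true ndb map
    to 1e-3 on adipose voxels; background stays invalid."""
    spec = small_spec(grid_shape=(16, 16, 8), breast_semiaxes_mm=(28.0, 48.0, 14.0),
                      chest_wall_mm=10.0, subcutaneous_mm=6.0,
                      tumour_radius_mm=0.0, rim_effect_amplitude=0.0)
    truth = generate_phantom(spec)
    series = simulate_echo_series(truth, spectrum, n_echoes=16, snr=np.inf)
    # free nmidb: the phantom draws it independently of ndb, so the
    # constrained single-unknown fit would carry a small model mismatch
    maps = fit_volume(series, spectrum, FitOptions(constrain_nmidb=False),
                      background_mask=truth.labels == 0)
    adipose = (truth.labels == 4) & maps.valid_mask
    assert adipose.sum() > 20
    np.testing.assert_allclose(maps.ndb[adipose], truth.ndb[adipose], atol=1e-3)
    np.testing.assert_allclose(maps.fat_fraction[adipose],
                               truth.fat_fraction[adipose], atol=1e-3)
    assert not maps.valid_mask[truth.labels == 0].any()
    v = maps.valid_mask
    np.testing.assert_allclose(maps.mufa[v] + maps.pufa[v] + maps.sfa[v],
                               1.0, atol=1e-9)


def test_volume_fit_is_voxel_local_under_slice_permutation(spectrum):
    spec = small_spec(grid_shape=(10, 10, 4), breast_semiaxes_mm=(16.0, 30.0, 7.0),
                      chest_wall_mm=6.0, tumour_radius_mm=0.0,
                      rim_effect_amplitude=0.0, subcutaneous_mm=3.0)
    truth = generate_phantom(spec)
    series = simulate_echo_series(truth, spectrum, n_echoes=16, snr=np.inf)
    perm = [2, 0, 3, 1]
    from perilipid.phantom import EchoSeries
    permuted = EchoSeries(series.signal[:, :, perm, :], series.echo_times_ms,
                          series.voxel_spacing_mm)
    m1 = fit_volume(series, spectrum, background_mask=truth.labels == 0)
    m2 = fit_volume(permuted, spectrum,
                    background_mask=(truth.labels == 0)[:, :, perm])
    np.testing.assert_array_equal(m1.ndb[:, :, perm], m2.ndb)


def test_echoes_used_cannot_exceed_acquired(spectrum, truth_small):
    series = simulate_echo_series(truth_small, spectrum, n_echoes=8, snr=np.inf)
    with pytest.raises(ValueError, match="echoes"):
        fit_volume(series, spectrum, FitOptions(n_echoes_used=16))


def test_maps_from_truth_match_composition_rule(truth_small):
    maps = maps_from_truth(truth_small)
    v = maps.valid_mask
    np.testing.assert_allclose(maps.mufa[v] + maps.pufa[v] + maps.sfa[v],
                               1.0, atol=1e-9)
    np.testing.assert_allclose(maps.pufa[v], truth_small.nmidb[v] / 3.0)
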