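"""Index registry: printed formulas, bounds, scale invariance, assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from ricelpn.indices import (
    INDEX_REGISTRY,
    NORMALIZED_DIFFERENCE,
    RATIO_TYPE,
    FeatureTable,
    RegistryError,
    build_feature_table,
    compute_index,
    paper_feature_preset,
)
from ricelpn.synth import SensorModel, Spectrum, simulate_dataset

# toy spectrum with bands exactly at every wavelength the registry needs,
# shaped like a plausible canopy curve (low red trough, high NIR)
_R = {
    430: 0.08, 445: 0.09, 460: 0.10, 470: 0.11, 500: 0.12, 530: 0.13,
    550: 0.15, 554: 0.155, 560: 0.14, 570: 0.145, 670: 0.05, 677: 0.052,
    680: 0.054, 700: 0.10, 705: 0.13, 710: 0.16, 720: 0.22, 750: 0.38,
    760: 0.40, 790: 0.43, 800: 0.44, 810: 0.445, 850: 0.45,
}

# independently transcribed arithmetic for every printed formula
_EXPECTED = {
    "NDVI": (_R[800] - _R[670]) / (_R[800] + _R[670]),
    "DCNI": ((_R[720] - _R[700]) / (_R[700] - _R[670])) / (_R[700] - _R[670] + 0.03),
    "MTCI": (_R[750] - _R[710]) / (_R[710] - _R[680]),
    "GNDVI": (_R[750] - _R[550]) / (_R[750] + _R[550]),
    "NDRE": (_R[790] - _R[720]) / (_R[790] + _R[720]),
    "SIPI": (_R[800] - _R[445]) / (_R[800] - _R[680]),
    "PRI": (_R[570] - _R[530]) / (_R[570] + _R[530]),
    "SRPI": _R[430] / _R[680],
    "PSSR": _R[800] / _R[500],
    "PSRI": (_R[680] - _R[500]) / _R[750],
    "RARS": _R[760] / _R[500],
    "GI": _R[554] / _R[677],
    "PSND": (_R[800] - _R[470]) / (_R[800] + _R[470]),
    "OSAVI": 1.16 * (_R[800] - _R[670]) / (_R[800] + _R[670] + 0.16),
    "RENDVI": (_R[750] - _R[705]) / (_R[750] + _R[705]),
    "SR": _R[750] / _R[550],
    "PBI": _R[810] / _R[560],
    "LCI": (_R[850] - _R[710]) / (_R[850] + _R[680]),
    "NPCI": (_R[670] - _R[460]) / (_R[670] + _R[460]),
    "MSR": (_R[800] / _R[760] - 1) / math.sqrt(_R[800] / _R[670] + 1),
}


def _toy_spectrum(scale=1.0):
    wl = np.array(sorted(_R), dtype=float)
    refl = np.array([_R[w] for w in sorted(_R)]) * scale
    return Spectrum(wavelengths=wl, reflectance=refl)


class TestFormulas:
    @pytest.mark.parametrize("acronym", sorted(INDEX_REGISTRY))
    def test_printed_formula_reproduces_hand_value(self, acronym):
        assert compute_index(_toy_spectrum(), acronym) == pytest.approx(
            _EXPECTED[acronym], rel=1e-12
        )

    def test_registry_has_twenty_indices(self):
        assert len(INDEX_REGISTRY) == 20

    def test_ndvi_hand_case(self):
        # R800 = 0.50, R670 = 0.05 -> 0.45/0.55
        wl = np.array([670.0, 800.0])
        s = Spectrum(wavelengths=wl, reflectance=np.array([0.05, 0.50]))
        assert compute_index(s, "NDVI") == pytest.approx(0.45 / 0.55)

    def test_flat_spectrum_ndvi_zero_and_dcni_undefined(self, flat_spectrum):
        assert compute_index(flat_spectrum, "NDVI") == 0.0
        assert math.isnan(compute_index(flat_spectrum, "DCNI"))

    def test_unknown_acronym_rejected(self, flat_spectrum):
        with pytest.raises(RegistryError):
            compute_index(flat_spectrum, "NOPE")

    def test_canonical_msr_variant(self):
        s = _toy_spectrum()
        r800, r670 = _R[800], _R[670]
        expected = (r800 / r670 - 1) / math.sqrt(r800 / r670 + 1)
        assert compute_index(s, "MSR", canonical_msr=True) == pytest.approx(expected)


class TestIndexProperties:
    @pytest.mark.parametrize("acronym", NORMALIZED_DIFFERENCE)
    def test_normalized_difference_bounded(self, acronym):
        rng = np.random.default_rng(5)
        wl = np.array(sorted(_R), dtype=float)
        for _ in range(20):
            s = Spectrum(wavelengths=wl, reflectance=rng.uniform(0.01, 1.0, wl.size))
            assert -1.0 <= compute_index(s, acronym) <= 1.0

    @pytest.mark.parametrize("acronym", RATIO_TYPE)
    def test_ratio_indices_scale_invariant(self, acronym):
        assert compute_index(_toy_spectrum(), acronym) == pytest.approx(
            compute_index(_toy_spectrum(scale=0.5), acronym), rel=1e-12
        )

    def test_all_indices_finite_on_positive_nonflat_spectrum(self):
        rng = np.random.default_rng(8)
        wl = np.array(sorted(_R), dtype=float)
        s = Spectrum(wavelengths=wl, reflectance=rng.uniform(0.05, 0.9, wl.size))
        for acronym in INDEX_REGISTRY:
            assert math.isfinite(compute_index(s, acronym))


class TestFeatureTable:
    def test_default_assembly_has_244_columns(self):
        samples, spectra = simulate_dataset(replicates=1, subsamples_per_plot=2, seed=3)
        table = build_feature_table(spectra, lpn=samples["lpn"].to_numpy())
        assert table.values.shape == (12, 224 + 20)
        assert table.target is not None and len(table.target) == 12

    def test_indices_only_assembly(self):
        _, spectra = simulate_dataset(replicates=1, subsamples_per_plot=1, seed=3)
        table = build_feature_table(spectra, include_bands=False)
        assert table.values.shape[1] == 20

    def test_drop_policy_removes_undefined_samples(self, flat_spectrum):
        _, spectra = simulate_dataset(replicates=1, subsamples_per_plot=1, seed=3)
        mixed = spectra + [flat_spectrum]  # flat spectrum has undefined DCNI etc.
        with pytest.warns(UserWarning, match="undefined"):
            table = build_feature_table(mixed, lpn=np.ones(len(mixed)))
        assert len(table.values) == len(mixed) - 1
        assert not table.values.isna().any().any()

    def test_impute_policy_keeps_all_rows(self, flat_spectrum):
        _, spectra = simulate_dataset(replicates=1, subsamples_per_plot=1, seed=3)
        mixed = spectra + [flat_spectrum]
        table = build_feature_table(mixed, undefined_policy="impute")
        assert len(table.values) == len(mixed)
        assert not table.values.isna().any().any()

    def test_duplicate_feature_names_rejected(self):
        df = pd.DataFrame([[1.0, 2.0]], columns=["a", "a"])
        with pytest.raises(Exception):
            FeatureTable(values=df)

    def test_paper_preset_resolves_on_default_grid(self):
        sensor = SensorModel()
        samples, spectra = simulate_dataset(replicates=1, subsamples_per_plot=1, seed=3)
        table = build_feature_table(spectra, lpn=samples["lpn"].to_numpy())
        preset = paper_feature_preset(table, sensor.wavelengths)
        assert len(preset) == 7
        assert {"PSND", "MTCI", "DCNI"} <= set(preset)
        assert sum(n.startswith("B_") for n in preset) == 4
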