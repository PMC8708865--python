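"""Taxonomic and functional diversity indices."""

import numpy as np
import pandas as pd
import pytest

from lakeso.diversity import (
    community_diversity,
    cwvar,
    fdis,
    gower_dissimilarity,
    shannon,
    trait_modality_shannon,
)
from lakeso.synthetic import default_trait_matrix


class TestShannon:
    @pytest.mark.parametrize(
        "biomass,expected",
        [
            ([1, 1, 1, 1], np.log(4)),
            ([5.0], 0.0),
            ([0.5, 0.25, 0.25], -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))),
        ],
    )
    def test_values(self, biomass, expected):
        assert shannon(biomass) == pytest.approx(expected, abs=1e-12)

    def test_zero_taxa_ignored(self):
        assert shannon([1, 1, 0, 0]) == pytest.approx(np.log(2))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0.0, 0.0])

    def test_log_base_option(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)


class TestGower:
    def test_identical_rows_zero(self):
        traits = default_trait_matrix()
        d = gower_dissimilarity(pd.concat([traits.iloc[[0]], traits.iloc[[0]]]))
        assert d.iloc[0, 1] == 0.0

    def test_single_categorical_difference_is_one_sixth(self):
        traits = pd.DataFrame(
            {
                "mld": [10.0, 10.0, 40.0],
                "n_fixation": ["N", "N", "Y"],
                "si_fixation": ["Y", "Y", "N"],
                "mixotrophy": ["N", "N", "Y"],
                "coloniality": ["Y", "Y", "N"],
                "pigment": ["Brown", "Green", "Red"],
            },
            index=["a", "b", "c"],
        )
        d = gower_dissimilarity(traits)
        assert d.loc["a", "b"] == pytest.approx(1 / 6)

    def test_maximal_difference_is_one(self):
        traits = pd.DataFrame(
            {
                "mld": [10.0, 80.0],
                "n_fixation": ["N", "Y"],
                "si_fixation": ["Y", "N"],
                "mixotrophy": ["N", "Y"],
                "coloniality": ["Y", "N"],
                "pigment": ["Brown", "Red"],
            }
        )
        assert gower_dissimilarity(traits).iloc[0, 1] == pytest.approx(1.0)

    def test_zero_range_trait_dropped_with_warning(self):
        traits = pd.DataFrame({"mld": [5.0, 5.0], "pigment": ["Brown", "Red"]})
        with pytest.warns(UserWarning, match="zero range"):
            d = gower_dissimilarity(traits)
        assert d.iloc[0, 1] == pytest.approx(1.0)  # only the pigment mismatch left


class TestFDis:
    def test_single_genus_zero(self):
        assert fdis([3.0], traits=pd.DataFrame({"mld": [5.0]})) == 0.0

    def test_two_points_equal_weights(self):
        d = np.array([[0.0, 0.8], [0.8, 0.0]])
        assert fdis([1.0, 1.0], dissimilarity=d) == pytest.approx(0.4, abs=1e-12)

    def test_two_points_unequal_weights(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        # centroid sits at the 0.75-weighted point: 0.75*0.25 + 0.25*0.75
        assert fdis([0.75, 0.25], dissimilarity=d) == pytest.approx(0.375, abs=1e-12)

    def test_matches_1d_weighted_deviation_oracle(self, rng):
        """With one quantitative trait, F_Dis equals the biomass-weighted
        mean absolute deviation of range-normalized values."""
        for _ in range(50):
            n = int(rng.integers(2, 7))
            x = rng.uniform(0, 120, n)
            if np.ptp(x) == 0:
                continue
            w = rng.dirichlet(np.ones(n))
            xn = x / np.ptp(x)
            oracle = float(w @ np.abs(xn - w @ xn))
            assert fdis(w, traits=pd.DataFrame({"mld": x})) == pytest.approx(oracle, abs=1e-10)

    def test_insensitive_to_rare_duplicate_genus(self):
        traits = default_trait_matrix()
        b = np.array([5.0, 3.0, 2.0, 1.0, 4.0, 2.0, 1.0, 0.5, 0.5, 1.0, 0.3, 0.2])
        base = fdis(b, traits=traits)
        dup = pd.concat([traits, traits.iloc[[0]].rename(index={traits.index[0]: "dup"})])
        b2 = np.append(b * (1 - 1e-9), b.sum() * 1e-9)
        assert abs(fdis(b2, traits=dup) - base) < 1e-6

    def test_scale_invariance(self):
        traits = default_trait_matrix()
        b = np.linspace(1, 12, 12)
        assert fdis(b, traits=traits) == pytest.approx(fdis(17.3 * b, traits=traits), abs=1e-12)


class TestCWvar:
    def test_equal_mld_zero(self):
        assert cwvar([1, 2, 3], [7.0, 7.0, 7.0]) == 0.0

    def test_two_genus_hand_value(self):
        # CWM = 15, CWvar = 0.5*25 + 0.5*25 = 25
        assert cwvar([1.0, 1.0], [10.0, 20.0]) == pytest.approx(25.0)

    def test_degenerate_weight(self):
        assert cwvar([1.0, 0.0], [10.0, 20.0]) == 0.0


class TestTraitModalityShannon:
    def test_single_modality_zero(self):
        assert trait_modality_shannon([1, 2, 3], ["Y", "Y", "Y"]) == 0.0

    def test_even_binary_split(self):
        assert trait_modality_shannon([2, 2], ["Y", "N"]) == pytest.approx(np.log(2))

    def test_pigment_shares_value(self):
        shares = [0.4, 0.3, 0.2, 0.1, 0.0]
        mods = ["Brown", "Green", "Blue-Green", "Yellow", "Red"]
        expected = -sum(p * np.log(p) for p in shares if p > 0)
        assert trait_modality_shannon(shares, mods) == pytest.approx(expected, abs=1e-12)

    def test_modalities_pooled_across_taxa(self):
        # two taxa sharing a modality act as one statistical individual
        assert trait_modality_shannon([1, 1, 2], ["Y", "Y", "N"]) == pytest.approx(np.log(2))


def test_all_indices_scale_invariant_and_bounded(rng):
    traits = default_trait_matrix()
    s = len(traits)
    for _ in range(200):
        b = rng.lognormal(1.0, 1.5, size=s)
        rec = community_diversity(b, traits)
        rec2 = community_diversity(b * rng.uniform(0.01, 100), traits)
        for name in rec.__dataclass_fields__:
            assert getattr(rec, name) == pytest.approx(getattr(rec2, name), rel=1e-9, abs=1e-12)
        assert 0 <= rec.h_prime <= np.log(s) + 1e-12
        assert rec.f_dis >= 0 and rec.cwvar_mld >= 0
        for h in (rec.h_nfix, rec.h_si, rec.h_mix, rec.h_col):
            assert 0 <= h <= np.log(2) + 1e-12
        assert 0 <= rec.h_pig <= np.log(5) + 1e-12
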