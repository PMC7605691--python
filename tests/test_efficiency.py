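"""Water-efficiency indicators, Tukey compact letter display, Bartlett check."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import studentized_range

from seedwater import (
    SimConfig,
    compute_we,
    efficiency_table,
    generate_experiment,
    tukey_letters,
    volume_fraction,
)
from seedwater.core import DomainError, FitError


class TestComputeWe:
    @pytest.mark.parametrize("vg,tva,published", [
        (42.5, 2.40, 17.694),   # S. parahyba tube V4, HWE (cm/L)
        (8.4, 2.40, 3.510),     # S. parahyba tube V4, DWE (mm/L)
        (37.4, 0.85, 44.039),   # C. speciosa tube V4, HWE
        (6.9, 0.85, 8.138),     # C. speciosa tube V4, DWE
        (27.4, 1.08, 25.401),   # C. myrianthum tube V4, HWE
    ])
    def test_published_cells_within_one_percent(self, vg, tva, published):
        """Printed final size / printed volume reproduces the published WE cell."""
        assert compute_we(vg, tva) == pytest.approx(published, rel=0.01)

    def test_zero_growth(self):
        assert compute_we(0.0, 5.0) == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            compute_we(10.0, 0.0)

    @given(c=st.floats(0.0, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_homogeneity_in_growth(self, c):
        assert compute_we(c * 3.0, 1.7) == pytest.approx(c * compute_we(3.0, 1.7))


class TestVolumeFraction:
    def test_cs_subperiod_share(self):
        """0.540 L of the 0.85 L phase total is 63.5% of the water applied."""
        assert volume_fraction(0.540, 0.85) == pytest.approx(63.5, abs=0.05)

    def test_nonpositive_total_rejected(self):
        with pytest.raises(DomainError):
            volume_fraction(1.0, 0.0)


class TestEfficiencyTable:
    def test_tube_phase_reproduces_published_table(self, fixture_ds):
        """12 tube records whose HWE/DWE equal the published cells to 3 decimals."""
        records = efficiency_table(fixture_ds, phase="tube")
        assert len(records) == 12
        by_cell = {(r.species, r.treatment): r for r in records}
        assert by_cell[("S_parahyba", "V4")].hwe == pytest.approx(17.694, abs=5e-4)
        assert by_cell[("S_parahyba", "V1")].dwe == pytest.approx(7.582, abs=5e-4)
        assert by_cell[("C_speciosa", "V1")].hwe == pytest.approx(80.653, abs=5e-4)
        assert by_cell[("C_speciosa", "V1")].dwe == pytest.approx(17.002, abs=5e-4)
        assert by_cell[("C_myrianthum", "V3")].hwe == pytest.approx(26.877, abs=5e-4)
        # treatment means only: no group letters
        assert all(r.letter_h is None and r.letter_d is None for r in records)

    def test_tube_we_decreases_with_applied_volume(self, fixture_ds):
        """WE rises as the applied volume falls: V1 > V2 > V3 > V4 per species."""
        records = efficiency_table(fixture_ds, phase="tube")
        for sp in {r.species for r in records}:
            hwe = [r.hwe for r in records if r.species == sp]  # ordered V1..V4
            dwe = [r.dwe for r in records if r.species == sp]
            assert all(a > b for a, b in zip(hwe, hwe[1:]))
            assert all(a >= b for a, b in zip(dwe, dwe[1:]))

    def test_uniform_growth_gives_identical_records(self):
        ds, _ = generate_experiment(SimConfig(noise_cv=0.0, gpf_true=0.0, seed=1))
        records = efficiency_table(ds, phase="tube")
        # same final size per treatment, so WE varies only through volume
        sizes = {round(r.hwe * ds.treatments[(r.species, "tube", r.treatment)].total_volume, 9)
                 for r in records}
        assert len(sizes) == 1

    def test_letters_attached_on_replicate_data(self):
        ds, _ = generate_experiment(SimConfig(seed=5, noise_cv=0.05, gpf_true=0.43))
        records = efficiency_table(ds, phase="tube", letters=True)
        assert all(r.letter_h and r.letter_d for r in records)


class TestTukeyLetters:
    def test_identical_groups_share_a(self):
        g = {"g1": [1.0, 2.0, 3.0], "g2": [1.0, 2.0, 3.0]}
        letters = tukey_letters(g).letters
        assert letters == {"g1": "a", "g2": "a"}

    def test_two_separated_clusters_get_two_letter_classes(self):
        # seed checked against the studentized-range oracle: within-cluster
        # pairs non-significant, cross-cluster pairs significant
        rng = np.random.default_rng(0)
        groups = {f"g{i}": rng.normal(m, 0.1, 10) for i, m in enumerate([0, 0, 10, 10])}
        letters = tukey_letters(groups).letters
        assert len(set(letters.values())) == 2
        assert letters["g2"] == letters["g3"] == "a"  # larger means lettered first
        assert letters["g0"] == letters["g1"] == "b"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_letters_agree_with_studentized_range_oracle(self, seed):
        """Shared letter iff the Tukey-Kramer studentized-range test accepts."""
        rng = np.random.default_rng(seed)
        means = rng.uniform(0, 4, size=4)
        n = 8
        groups = {f"g{i}": rng.normal(m, 1.0, n) for i, m in enumerate(means)}
        res = tukey_letters(groups, alpha=0.05)

        arrs = {k: np.asarray(v) for k, v in groups.items()}
        k = len(arrs)
        dof = sum(a.size - 1 for a in arrs.values())
        mse = sum(np.sum((a - a.mean()) ** 2) for a in arrs.values()) / dof
        qcrit = studentized_range.ppf(0.95, k, dof)
        labels = sorted(arrs)
        for i in range(k):
            for j in range(i + 1, k):
                a, b = arrs[labels[i]], arrs[labels[j]]
                q = abs(a.mean() - b.mean()) / np.sqrt(
                    mse / 2 * (1 / a.size + 1 / b.size))
                significant = q > qcrit
                shared = set(res.letters[labels[i]]) & set(res.letters[labels[j]])
                assert significant == (not shared), (labels[i], labels[j])

    def test_letter_display_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(i, 0.5, 6) for i in range(4)}
        forward = tukey_letters(groups).letters
        reversed_in = tukey_letters(dict(reversed(list(groups.items())))).letters
        assert forward == reversed_in

    def test_bartlett_rejection_warns_but_still_letters(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 0.01, 12), "b": rng.normal(0.5, 5.0, 12)}
        with pytest.warns(UserWarning, match="Bartlett"):
            res = tukey_letters(groups)
        assert set(res.letters) == {"a", "b"}
        assert res.p_bartlett < 0.05

    def test_degenerate_variance_with_unequal_means_rejected(self):
        groups = {"a": [1.0, 1.0, 1.0], "b": [2.0, 2.0, 2.0]}
        with pytest.raises(FitError, match="zero within-group variance"):
            tukey_letters(groups)

    def test_minimum_group_requirements(self):
        with pytest.raises(FitError):
            tukey_letters({"only": [1.0, 2.0]})
        with pytest.raises(FitError):
            tukey_letters({"a": [1.0], "b": [1.0, 2.0]})
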