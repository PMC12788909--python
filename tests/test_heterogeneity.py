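"""Variant comparison machinery: averaging, differences, paired statistics."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from atrosim.constitutive import MaterialParams, MaterialTable, bulk_modulus
from atrosim.heterogeneity import (
    cohens_d,
    difference_fields,
    effect_label,
    region_pct_heatmap,
    run_family_experiment,
    volume_average_params,
    wilcoxon_paired,
)
from atrosim.phantom import PhantomSpec
from atrosim.regions import ANATOMICAL_LABELS, scheme_groups

RNG = np.random.default_rng(23)


def _table(mu_map=None, alpha=-15.0):
    params = {}
    for lab in ANATOMICAL_LABELS:
        mu = 1.0 if mu_map is None else mu_map.get(lab, 1.0)
        params[lab] = MaterialParams(mu, alpha, 0.49)
    params["CSF"] = MaterialParams(0.1, 2.0, 0.3)
    params["VENTRICLE"] = MaterialParams(0.1, 2.0, 0.3)
    return MaterialTable(scheme="17R", params=params)


class TestVolumeAveraging:
    def test_equal_volume_mean(self):
        t = _table({"FC": 1.0, "MC": 3.0})
        vols = {lab: 1.0 for lab in ANATOMICAL_LABELS}
        t9 = volume_average_params(t, vols, "9R")
        # Cortex group: FC,MC,VC,CI,TL with mu {1,3,1,1,1} equal volumes
        assert t9["Cortex"].mu == pytest.approx((1 + 3 + 1 + 1 + 1) / 5)

    def test_weighted_mean_hand_value(self):
        t = _table({"Me": 2.0, "P": 6.0})
        vols = {lab: 1.0 for lab in ANATOMICAL_LABELS}
        vols["Me"], vols["P"] = 1.0, 3.0
        t9 = volume_average_params(t, vols, "9R")
        assert t9["Brain stem"].mu == pytest.approx(5.0)   # (2*1 + 6*3)/4

    def test_single_constituent_group_unchanged(self):
        t = _table({"CC": 0.73})
        vols = {lab: 2.0 for lab in ANATOMICAL_LABELS}
        t9 = volume_average_params(t, vols, "9R")
        assert t9["Corpus callosum"].mu == t["CC"].mu
        assert t9["Corpus callosum"].alpha == t["CC"].alpha

    def test_kappa_rederived_and_csf_untouched(self, table17):
        vols = {lab: 1.0 for lab in ANATOMICAL_LABELS}
        t4 = volume_average_params(table17, vols, "4R")
        for group, p in t4.params.items():
            if group in ("CSF", "VENTRICLE"):
                assert p == table17[group]
            else:
                assert p.kappa == pytest.approx(bulk_modulus(p.mu, p.nu))

    def test_zero_volume_group_rejected(self, table17):
        vols = {lab: 0.0 for lab in ANATOMICAL_LABELS}
        with pytest.raises(ValueError, match="zero total volume"):
            volume_average_params(table17, vols, "2R")


class TestWilcoxon:
    @staticmethod
    def exhaustive_p(d):
        """Independent oracle: full enumeration of the signed-rank null."""
        d = np.asarray(d, float)
        d = d[d != 0]
        ranks = stats.rankdata(np.abs(d))
        w = ranks[d > 0].sum()
        dist = np.array([ranks[np.array(s, bool)].sum()
                         for s in product([0, 1], repeat=d.size)])
        n = dist.size
        return min(1.0, 2 * min((dist <= w).sum(), (dist >= w).sum()) / n)

    def test_identical_samples_give_p_one(self):
        x = RNG.standard_normal(20)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_paired(x, x) == 1.0

    @pytest.mark.parametrize("n", [5, 6, 8, 10])
    def test_matches_exhaustive_enumeration(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n)
            assert wilcoxon_paired(x, y) == pytest.approx(
                self.exhaustive_p(x - y), abs=1e-12)

    def test_strictly_positive_differences_n6(self):
        x = np.arange(1.0, 7.0)
        y = x - np.linspace(0.3, 0.9, 6)
        assert wilcoxon_paired(x, y) == pytest.approx(2 / 64)

    def test_large_shift_detected_at_n100(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        y = x + rng.standard_normal(200) * 0.1 + 2.0
        assert wilcoxon_paired(x, y) < 1e-3

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired(np.ones(4), np.ones(5))


class TestCohensD:
    def test_identical_samples(self):
        x = RNG.standard_normal(10)
        assert cohens_d(x, x.copy()) == 0.0

    def test_hand_value(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(-1.0)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, a):
        x = np.array([0.3, 1.2, -0.7, 2.0])
        y = np.array([1.1, 0.2, 0.5, -0.3])
        assert cohens_d(a * x, a * y) == pytest.approx(cohens_d(x, y), rel=1e-9)

    def test_degenerate_input_signalled(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])


@pytest.mark.parametrize(
    "d,label",
    [(0.0, "negligible"), (0.19, "negligible"), (0.2, "small"), (-0.3, "small"),
     (0.5, "medium"), (-0.79, "medium"), (0.8, "large"), (-1.0, "large")],
)
def test_effect_labels(d, label):
    assert effect_label(d) == label


def test_region_pct_heatmap_hand_mean():
    df = pd.DataFrame([
        {"phantom": 0, "variant": "1R", "region": "FC", "metric": "sigma_vm",
         "abs_pct_diff": 2.0},
        {"phantom": 1, "variant": "1R", "region": "FC", "metric": "sigma_vm",
         "abs_pct_diff": 4.0},
    ])
    hm = region_pct_heatmap(df)
    assert hm.loc[("sigma_vm", "FC"), "1R"] == pytest.approx(3.0)


@pytest.fixture(scope="module")
def report():
    """Identity experiment: homogeneous 17R parameters on an 18^3 phantom."""
    spec = PhantomSpec(grid_shape=(18, 18, 18), random_seed=3)
    return run_family_experiment(spec, table_17R=_table(), horizon=5.0,
                                 dt=5.0, keep_runs=True)


class TestFamilyExperimentIdentity:
    """With homogeneous 17R parameters every variant coarsens to the
    same material, so the whole pipeline must report exact zeros."""

    def test_all_difference_metrics_zero(self, report):
        assert np.allclose(report.per_phantom["mean_abs_diff"], 0.0)
        assert np.allclose(report.per_phantom["cohens_d"].dropna(), 0.0)
        assert (report.per_phantom["p_value"].dropna() == 1.0).all()

    def test_difference_fields_identity_and_symmetry(self, report):
        r17 = report.runs[(0, "17R")]
        r1 = report.runs[(0, "1R")]
        for v in difference_fields(r17, r17).values():
            assert np.abs(v).max() == 0.0
        ab = difference_fields(r17, r1)
        ba = difference_fields(r1, r17)
        for m in ab:
            assert np.array_equal(ab[m], ba[m])

    def test_heatmap_zero_against_itself(self, report):
        hm = report.heatmap
        assert np.nanmax(np.abs(hm.to_numpy())) == pytest.approx(0.0, abs=1e-12)

    def test_mesh_mismatch_rejected(self, report):
        from atrosim.fem import run_simulation
        from atrosim.phantom import generate_phantom
        other = generate_phantom(PhantomSpec(grid_shape=(20, 20, 20), random_seed=3))
        run_other = run_simulation(other, _table(), horizon=0.0, dt=1.0)
        with pytest.raises(ValueError, match="different meshes"):
            difference_fields(report.runs[(0, "17R")], run_other)

    def test_pairing_invariant_under_common_shuffle(self, report):
        """Shuffling elements identically in both runs leaves p and d
        unchanged (exact pairing on the shared mesh)."""
        r17 = report.runs[(0, "17R")]
        x = r17.readouts[-1].sigma_vm
        y = x + RNG.standard_normal(x.size) * 0.01
        perm = RNG.permutation(x.size)
        assert wilcoxon_paired(x, y) == pytest.approx(
            wilcoxon_paired(x[perm], y[perm]))
        assert cohens_d(x, y) == pytest.approx(cohens_d(x[perm], y[perm]))


def test_perturbed_region_localizes_differences(phantom18, table17):
    """Stiffening a single region must concentrate the displacement
    difference field in and around that region."""
    from atrosim.fem import run_simulation

    t_mod = MaterialTable("17R", dict(table17.params))
    p = table17["CB"]
    t_mod.params["CB"] = MaterialParams(p.mu * 3.0, p.alpha, p.nu)
    base = run_simulation(phantom18, table17, horizon=10.0, dt=5.0)
    mod = run_simulation(phantom18, t_mod, horizon=10.0, dt=5.0)
    diff = difference_fields(base, mod)["displacement"]
    # max-difference element lies inside or adjacent to the cerebellum
    cent = phantom18.element_centroids()
    cb_cent = cent[phantom18.element_region == "CB"]
    d_to_cb = np.linalg.norm(
        cent[np.argmax(diff)] - cb_cent.mean(axis=0))
    assert d_to_cb < np.linalg.norm(cent - cb_cent.mean(axis=0), axis=1).mean()
    assert diff.max() > 0
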