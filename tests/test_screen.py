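"""Rule-based microinfarct screening: diameter convention, verdicts, specificity."""

import numpy as np
import pytest

from qmi.phantom import GM, LesionSpec, PhantomSpec, build_phantom, make_compartments
from qmi.screen import ScreenParams, detect_acmi, max_diameter


def dice(a, b):
    return 2 * np.sum(a & b) / (np.sum(a) + np.sum(b))


class TestMaxDiameter:
    def test_single_voxel_isotropic(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = True
        assert max_diameter(m, (1, 1, 1)) == pytest.approx(1.0)

    def test_adjacent_inplane_anisotropic(self):
        # centers 0.8 mm apart + mean extent (0.8+0.8+2.0)/3 = 1.2 -> 2.0 mm
        m = np.zeros((5, 5, 5), dtype=bool)
        m[2, 2, 2] = m[2, 3, 2] = True
        assert max_diameter(m, (0.8, 0.8, 2.0)) == pytest.approx(2.0)

    def test_five_voxel_line_fails_5mm_rule(self):
        m = np.zeros((9, 9, 3), dtype=bool)
        m[2:7, 4, 1] = True
        d = max_diameter(m, (1, 1, 1))
        assert d == pytest.approx(5.0)
        assert not d < 5.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            max_diameter(np.zeros((3, 3, 3), dtype=bool), (1, 1, 1))

    def test_large_component_boundary_reduction_consistent(self):
        m = np.zeros((30, 30, 6), dtype=bool)
        m[5:25, 5:25, 1:5] = True  # 1600 voxels: triggers boundary path
        coords = np.argwhere(m) * np.array([1.0, 1.0, 1.0])
        from scipy.spatial.distance import pdist
        expected = pdist(coords).max() + 1.0
        assert max_diameter(m, (1, 1, 1)) == pytest.approx(expected)


@pytest.fixture(scope="module")
def noisy_maps(small_grid, cortex_center):
    """Cortex mask plus noisy DWI/MD maps with one injected 3 mm lesion
    (DWI +30%, MD -20%)."""
    def make(diameter_mm=3.0, dwi_frac=0.30, md_frac=-0.20, seed=17):
        spec = PhantomSpec(
            n_visits=3, noise_sd=0.0, param_noise_frac=0.02, seed=seed,
            lesion_specs=[LesionSpec(
                center=cortex_center, diameter_mm=diameter_mm, onset_visit=1,
                stage_deltas={"acute": {"dwi_b3000": dwi_frac * 0.55,
                                        "md": md_frac * 0.8e-3},
                              "post": {}})],
            **small_grid)
        study, truth = build_phantom(spec)
        v = study.visits[1]
        return (v.maps["dwi_b3000"].values, v.maps["md"].values,
                study.cortex_mask, truth.lesion_masks[0])
    return make


class TestDetect:
    def test_injected_lesion_detected_with_overlap(self, noisy_maps, small_grid):
        dwi, md, cortex, truth_mask = noisy_maps()
        cands = detect_acmi(dwi, md, cortex,
                            voxel_size_mm=small_grid["voxel_size_mm"])
        accepted = [c for c in cands if c.accepted]
        assert len(accepted) == 1
        assert dice(accepted[0].mask, truth_mask) >= 0.5

    def test_oversized_lesion_rejected_by_size(self, noisy_maps, small_grid):
        """An elongated DWI-hyperintense streak longer than 5 mm is found
        but rejected by the size rule."""
        dwi, md, cortex, truth_mask = noisy_maps()
        dwi = dwi.copy()
        dwi[truth_mask] = 0.55  # erase the compact lesion
        # tangential 9-voxel cortical run: 8 * 0.8 + 1.2 = 7.6 mm >= 5 mm
        run = self._longest_inplane_run(cortex)
        assert len(run) >= 9
        for (i, j, k) in run[:9]:
            dwi[i, j, k] = 0.55 * 1.3
            md[i, j, k] = 0.8e-3 * 0.8
        cands = detect_acmi(dwi, md, cortex,
                            voxel_size_mm=small_grid["voxel_size_mm"])
        assert sum(c.accepted for c in cands) == 0
        assert sum(c.verdict == "rejected_size" for c in cands) >= 1

    @staticmethod
    def _longest_inplane_run(cortex):
        z = cortex.shape[2] // 2
        best = []
        for i in range(cortex.shape[0]):
            run = []
            for j in range(cortex.shape[1]):
                if cortex[i, j, z]:
                    run.append((i, j, z))
                    if len(run) > len(best):
                        best = list(run)
                else:
                    run = []
        return best

    def test_md_hyperintense_lesion_rejected(self, noisy_maps, small_grid):
        dwi, md, cortex, _ = noisy_maps(md_frac=+0.30)
        cands = detect_acmi(dwi, md, cortex,
                            voxel_size_mm=small_grid["voxel_size_mm"])
        assert sum(c.accepted for c in cands) == 0
        assert any(c.verdict == "rejected_md" for c in cands)

    def test_accepted_candidates_stay_in_cortex(self, noisy_maps, small_grid):
        dwi, md, cortex, _ = noisy_maps()
        for c in detect_acmi(dwi, md, cortex,
                             voxel_size_mm=small_grid["voxel_size_mm"]):
            if c.accepted:
                assert not np.any(c.mask & ~cortex)

    def test_raising_threshold_never_adds_detections(self, noisy_maps, small_grid):
        dwi, md, cortex, _ = noisy_maps()
        counts = []
        for z in (2.0, 3.0, 4.0, 6.0, 10.0):
            cands = detect_acmi(dwi, md, cortex, ScreenParams(z_dwi=z),
                                small_grid["voxel_size_mm"])
            counts.append(sum(c.accepted for c in cands))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_cortical_sd_rejected(self, small_grid):
        comp = make_compartments(**small_grid)
        cortex = comp == GM
        flat = np.where(cortex, 1.0, 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            detect_acmi(flat, flat, cortex,
                        voxel_size_mm=small_grid["voxel_size_mm"])

    def test_zero_lesion_specificity_over_seeds(self, small_grid):
        """On lesion-free phantoms with default noise, the detector accepts
        nothing in at least 95% of seeds (20-seed smoke test)."""
        comp = make_compartments(**small_grid)
        cortex = comp == GM
        clean = sum(1 for seed in range(20)
                    if self._n_accepted(cortex, seed, small_grid) == 0)
        assert clean >= 19

    @staticmethod
    def _n_accepted(cortex, seed, small_grid):
        rng = np.random.default_rng(seed)
        gm_dwi, gm_md = 0.55, 0.8e-3
        dwi = np.where(cortex, gm_dwi, 0.5) \
            + 0.02 * gm_dwi * rng.standard_normal(cortex.shape)
        md = np.where(cortex, gm_md, 0.7e-3) \
            + 0.02 * gm_md * rng.standard_normal(cortex.shape)
        cands = detect_acmi(dwi, md, cortex,
                            voxel_size_mm=small_grid["voxel_size_mm"])
        return sum(c.accepted for c in cands)
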