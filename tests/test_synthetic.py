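"""The synthetic-cohort generator: geometry, determinism, group structure."""

import numpy as np
import pandas as pd
import pytest

from vrconnectome.connectome import binarize, count_connections
from vrconnectome.synthetic import (
    BundleSpec,
    SyntheticConfig,
    apply_lesion,
    default_config,
    make_cohort,
    make_parcellation,
    make_phantom,
    make_streamlines,
    null_config,
    region_centroids,
    small_config,
)
from vrconnectome.tracking import track_at_threshold
from vrconnectome.io import labels_at
from dataclasses import replace


class TestParcellation:
    def test_90_regions_split_45_45(self):
        parc = make_parcellation(default_config())
        assert parc.n_regions == 90
        assert len(parc.left_ids) == 45 and len(parc.right_ids) == 45
        # left centroids strictly left of the volume midline
        mid_x = parc.labels.voxel_to_world(
            np.array([[parc.labels.shape[0] / 2, 0, 0]]))[0, 0]
        cents = region_centroids(parc)
        for rid in parc.left_ids:
            assert cents[int(rid)][0] < mid_x
        for rid in parc.right_ids:
            assert cents[int(rid)][0] > mid_x

    def test_toy_four_regions(self, toy_parcellation):
        labels = set(np.unique(toy_parcellation.labels.data)) - {0}
        assert labels == {1, 2, 3, 4}
        assert list(toy_parcellation.left_ids) == [1, 2]

    def test_every_voxel_label_in_table(self, small_cohort):
        parc = small_cohort.parcellation
        present = set(np.unique(parc.labels.data)) - {0}
        assert present <= set(int(i) for i in parc.table["id"])

    def test_infeasible_packing_raises(self):
        cfg = SyntheticConfig(seed=0, n_regions=90, grid_shape=(10, 10, 10))
        with pytest.raises(ValueError, match="too small"):
            make_parcellation(cfg)

    def test_odd_region_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            SyntheticConfig(n_regions=7)


class TestPhantom:
    def test_anchor_tube_fa_near_peak(self, tube_phantom):
        cfg, parc, phantom = tube_phantom
        fa = phantom.fa.data
        # voxels of the 0.53 tube: direction +x and FA > 0.4
        mask = (fa > 0.45)
        assert mask.sum() > 50
        assert abs(fa[mask].mean() - 0.53) < 0.03

    def test_zero_bundles_background_fa(self):
        cfg = SyntheticConfig(seed=1, n_regions=8, bundles=())
        parc = make_parcellation(cfg)
        phantom = make_phantom(cfg, parc, ())
        assert (phantom.fa.data < 0.1).all()
        assert (phantom.directions == 0).all()

    def test_short_tube_fails_flt_long_tube_survives(self):
        """A ~40 mm tube yields tracked fibers at FLT 30 mm; a ~24 mm tube
        yields none."""
        cfg = SyntheticConfig(
            seed=2, n_regions=12, voxel_size_mm=3.0, hemisphere_gap_vox=12,
            min_bundle_length_mm=0.0, tube_radius_mm=3.5,
            bundles=(BundleSpec(1, 2, peak_fa=0.5, bow_mm=0.0),),  # ~19 mm tube
        )
        parc = make_parcellation(cfg)
        short = make_phantom(cfg, parc, cfg.bundles)
        fibers, _ = track_at_threshold(short.directions, short.fa, 0.1, flt_mm=30.0)
        assert fibers == []

        cfg_long = replace(cfg, bundles=(BundleSpec(1, 7, peak_fa=0.5, bow_mm=0.0),))
        longp = make_phantom(cfg_long, parc, cfg_long.bundles)
        fibers, _ = track_at_threshold(longp.directions, longp.fa, 0.1, flt_mm=30.0)
        assert len(fibers) > 0

    def test_lesion_zeroes_sphere(self, tube_phantom):
        cfg, parc, phantom = tube_phantom
        nz = np.argwhere(phantom.fa.data > 0.2)
        center = phantom.fa.voxel_to_world(nz[[0]])[0]
        lesioned = apply_lesion(phantom.fa, center, radius_mm=5.0)
        assert lesioned.data[tuple(nz[0])] == 0.0
        assert phantom.fa.data[tuple(nz[0])] > 0.2  # original untouched


class TestStreamlines:
    def test_endpoints_in_bundle_regions(self, tube_phantom):
        cfg, parc, phantom = tube_phantom
        rng = np.random.default_rng(5)
        fibers = make_streamlines(phantom, phantom.bundles[:1], rng, n_fibers=[5])
        assert len(fibers) == 5
        spec = phantom.bundles[0].spec
        for fib in fibers:
            ends = labels_at(fib.points[[0, -1]], parc.labels)
            assert set(int(e) for e in ends) == {spec.region_a, spec.region_b}

    def test_same_seed_identical(self, tube_phantom):
        cfg, parc, phantom = tube_phantom
        a = make_streamlines(phantom, phantom.bundles, np.random.default_rng(9))
        b = make_streamlines(phantom, phantom.bundles, np.random.default_rng(9))
        assert len(a) == len(b)
        for fa_, fb in zip(a, b):
            np.testing.assert_array_equal(fa_.points, fb.points)
            np.testing.assert_array_equal(fa_.fa, fb.fa)

    def test_fa_maxima_near_bundle_peak(self, tube_phantom):
        cfg, parc, phantom = tube_phantom
        rng = np.random.default_rng(11)
        fibers = make_streamlines(phantom, phantom.bundles[:1], rng, n_fibers=[20])
        peaks = np.array([f.fa.max() for f in fibers])
        # within a few jitter SDs of the tube peak 0.53
        assert np.all(np.abs(peaks - 0.53) < 5 * 0.02 + 0.02)


class TestCohort:
    def test_fixed_seed_bit_identical(self, small_cfg):
        a = make_cohort(small_cfg)
        b = make_cohort(small_cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        for sid in a.fibers:
            for fa_, fb in zip(a.fibers[sid], b.fibers[sid]):
                np.testing.assert_array_equal(fa_.points, fb.points)
                np.testing.assert_array_equal(fa_.fa, fb.fa)
            assert a.stim_maps[sid].pos_regions == b.stim_maps[sid].pos_regions

    def test_na_aphasia_level_zero_gia_positive(self, small_cohort):
        rec = small_cohort.records
        assert (rec.loc[rec.group == "NA", "aphasia_level"] == 0).all()
        assert (rec.loc[rec.group == "GIA", "aphasia_level"] >= 1).all()
        assert rec["tumor_size_cm3"].min() >= 0.0

    def _mean_left_edges(self, cohort):
        parc = cohort.parcellation
        left = set(int(i) for i in parc.left_ids)
        out = {"NA": [], "GIA": []}
        for sid, grp in zip(cohort.records.subject_id, cohort.records.group):
            counts, _ = count_connections(cohort.fibers[sid], parc)
            adj = binarize(counts)
            ids = list(parc.node_ids)
            lidx = [i for i, r in enumerate(ids) if r in left]
            out[grp].append(np.triu(adj[np.ix_(lidx, lidx)], 1).sum())
        return np.mean(out["NA"]), np.mean(out["GIA"])

    def test_deficit_reduces_gia_left_edges(self):
        cfg = replace(small_config(seed=77, n_per_group=12), left_deficit=0.5)
        na, gia = self._mean_left_edges(make_cohort(cfg))
        assert gia < na

    def test_null_config_has_no_deficit_drops(self):
        cohort = make_cohort(null_config(seed=13, n_per_group=8))
        for truth in cohort.ground_truth.values():
            assert truth["n_deficit_drops"] == 0
        na, gia = self._mean_left_edges(cohort)
        assert abs(na - gia) < 0.35 * max(na, 1e-9)

    def test_aphasia_negatively_linked_to_left_connectivity(self):
        """The designed monotone link: GIA subjects with more deficit drops
        carry higher aphasia levels."""
        cohort = make_cohort(small_config(seed=21, n_per_group=30))
        rec = cohort.records
        gia = rec[rec.group == "GIA"]
        drops = np.array([cohort.ground_truth[s]["n_deficit_drops"]
                          for s in gia.subject_id])
        from scipy.stats import spearmanr

        rho, _ = spearmanr(drops, gia.aphasia_level)
        assert rho > 0.3

    def test_pos_rarer_than_neg(self, small_cohort):
        rec = small_cohort.records
        assert rec["n_pos"].mean() < rec["n_neg"].mean()

    def test_default_cohort_region_count_means(self):
        """POS/NEG region-set sizes land near the emulated study means
        (~8.4 POS, ~16.6 NEG per subject on the 45-region hemisphere)."""
        rec = make_cohort(default_config(seed=31, n_per_group=15)).records
        assert 6.0 < rec["n_pos"].mean() < 11.0
        assert 13.0 < rec["n_neg"].mean() < 20.0
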