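"""Generator contracts: determinism, exact content, loop closure."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mitoglia import (
    DomainError,
    SegmentationParams,
    compute_cell_metrics,
    generate_cell,
    generate_cohort,
    measure_components,
    naive_params,
    onc_hyperfused_params,
    rasterize_cell,
    segment_cell_channels,
)
from mitoglia.synthetic import SyntheticCellParams

SPACING = (0.2, 0.2, 0.2)


class TestGenerateCell:
    def test_same_params_and_seed_bit_identical(self):
        p = naive_params()
        a = generate_cell(p, seed=42)
        b = generate_cell(p, seed=42)
        assert len(a.mitochondria) == len(b.mitochondria)
        for oa, ob in zip(a.mitochondria, b.mitochondria):
            assert oa.volume == ob.volume
            np.testing.assert_array_equal(oa.centroid, ob.centroid)
        assert set(a.filament.nodes) == set(b.filament.nodes)
        for nid in a.filament.nodes:
            np.testing.assert_array_equal(a.filament.nodes[nid][1],
                                          b.filament.nodes[nid][1])

    def test_total_volume_hits_target_exactly(self):
        p = naive_params(content_cv=0.0)
        cell = generate_cell(p, seed=5)
        total = sum(o.volume for o in cell.mitochondria)
        assert total == pytest.approx(
            p.target_content_pct / 100 * p.cell_volume, rel=1e-12
        )

    def test_perinuclear_bias_one_gives_100_percent(self):
        cell = generate_cell(naive_params(perinuclear_bias=1.0), seed=8)
        m = compute_cell_metrics(cell)
        assert m.perinuclear_pct == pytest.approx(100.0)

    def test_infeasible_content_is_parameter_error(self):
        with pytest.raises(DomainError, match="exceeds"):
            generate_cell(naive_params(target_content_pct=99.0,
                                       vesicle_content_pct=5.0), seed=1)

    def test_invalid_knob_ranges_rejected(self):
        with pytest.raises(DomainError):
            SyntheticCellParams(perinuclear_bias=1.5)
        with pytest.raises(DomainError):
            SyntheticCellParams(elongation=0.5)

    def test_hyperfused_cells_carry_dominant_organelle(self):
        p = onc_hyperfused_params(hyperfused_fraction=1.0)
        cell = generate_cell(p, seed=3)
        volumes = sorted(o.volume for o in cell.mitochondria)
        assert volumes[-1] == pytest.approx(
            min(p.hyperfused_volume, 0.8 * cell.metadata["mito_total_volume"])
        )
        # across seeds, the largest-organelle metric shifts up vs. the
        # non-hyperfused version of the same parameters
        control = onc_hyperfused_params(hyperfused_fraction=0.0)
        largest_h = [max(o.volume for o in generate_cell(p, seed=s).mitochondria)
                     for s in range(15)]
        largest_c = [max(o.volume for o in generate_cell(control, seed=100 + s).mitochondria)
                     for s in range(15)]
        assert np.mean(largest_h) > np.mean(largest_c)


class TestRasterize:
    def test_single_spherical_organelle_volume(self):
        # one ~4.19 μm³ ball (elongation 1) rasterized at fine isotropic
        # spacing: foreground volume within 5% of the analytic 4/3 π r³
        p = naive_params(elongation=1.0, content_cv=0.0,
                         target_content_pct=100 * 4.18879 / 1500,
                         vesicle_content_pct=0.0,
                         n_primary_branches=2, branch_length_mean=5.0,
                         max_branch_depth=1)
        cell = generate_cell(p, seed=11)
        cell.mitochondria = cell.mitochondria[:1]
        cell.metadata["mito_axes"] = cell.metadata["mito_axes"][:1]
        cell.metadata["mito_dirs"] = cell.metadata["mito_dirs"][:1]
        v = cell.mitochondria[0].volume
        ras = rasterize_cell(cell, (0.05, 0.05, 0.05))
        vox = (ras.mito_truth == 1).sum() * np.prod(ras.mitochondria.spacing)
        assert vox == pytest.approx(v, rel=0.05)

    def test_empty_organelle_list_gives_zero_channel(self):
        cell = generate_cell(naive_params(), seed=2)
        cell.mitochondria = []
        cell.metadata["mito_axes"] = np.zeros((0, 3))
        cell.metadata["mito_dirs"] = np.zeros((0, 3))
        ras = rasterize_cell(cell, SPACING)
        assert ras.mitochondria.data.sum() == 0

    def test_segmentation_recovers_exact_count_with_separation(self):
        p = naive_params(min_separation=0.8, elongation=1.2, volume_sigma0=0.3,
                         n_mito_base=20, target_content_pct=4.0, content_cv=0.0,
                         branch_length_mean=8.0)
        cell = generate_cell(p, seed=21)
        n_true = len(cell.mitochondria)
        ras = rasterize_cell(cell, SPACING)
        labels = segment_cell_channels(
            ras.cell_mask, ras.mitochondria, SegmentationParams(threshold=0.5)
        )
        assert labels.max() == n_true

    def test_loop_closure_metrics_correlate_with_truth(self):
        """rasterize → segment → measure recovers per-cell median volume,
        count, and perinuclear fraction (Spearman ρ > 0.9 over cells)."""
        truth_rows, est_rows = [], []
        for seed in range(10):
            p = naive_params(
                min_separation=0.3,
                branch_length_mean=8.0,
                max_branch_depth=2,
                fragmentation=float(np.random.default_rng(seed).uniform(0.6, 1.5)),
            )
            cell = generate_cell(p, seed=100 + seed)
            t = compute_cell_metrics(cell)
            ras = rasterize_cell(cell, SPACING)
            labels = segment_cell_channels(
                ras.cell_mask, ras.mitochondria, SegmentationParams(threshold=0.5)
            )
            recs = measure_components(labels, SPACING)
            for r in recs:
                r.centroid = r.centroid + ras.origin
            est_cell = type(cell)(
                cell_id="est", cell_volume=cell.cell_volume,
                soma_center=cell.soma_center, mitochondria=recs,
            )
            e = compute_cell_metrics(est_cell)
            truth_rows.append([t.median_mito_volume, t.n_mito, t.perinuclear_pct])
            est_rows.append([e.median_mito_volume, e.n_mito, e.perinuclear_pct])
        truth_arr = np.array(truth_rows)
        est_arr = np.array(est_rows)
        for k in range(3):
            rho = spearmanr(truth_arr[:, k], est_arr[:, k]).statistic
            assert rho > 0.9


class TestGenerateCohort:
    def test_reproducible_and_labeled(self):
        specs = {"naive": naive_params(), "onc": onc_hyperfused_params()}
        cells_a, truth = generate_cohort(specs, 3, seed=7)
        cells_b, _ = generate_cohort(specs, 3, seed=7)
        assert [c.cell_id for c in cells_a] == [c.cell_id for c in cells_b]
        assert {c.group for c in cells_a} == {"naive", "onc"}
        assert set(truth["group"]) == {"naive", "onc"}
        va = [o.volume for c in cells_a for o in c.mitochondria]
        vb = [o.volume for c in cells_b for o in c.mitochondria]
        np.testing.assert_array_equal(va, vb)

    def test_zero_cells_is_error(self):
        with pytest.raises(DomainError):
            generate_cohort({"naive": naive_params()}, 0, seed=1)

    def test_planted_fragmentation_shifts_metrics_in_direction(self):
        """The injury-like preset must show lower median volume, higher count,
        higher content, higher perinuclear fraction than the baseline —
        the qualitative signature of a responsive microglial phenotype."""
        from mitoglia import onc_params
        from mitoglia.profiles import collect_cell_features

        cells, _ = generate_cohort(
            {"naive": naive_params(), "onc": onc_params()}, 15, seed=33
        )
        feats = collect_cell_features(cells)
        by = feats.groupby("group")
        med = by["median_mito_volume"].mean()
        assert med["onc"] < med["naive"]
        assert by["n_mito"].mean()["onc"] > by["n_mito"].mean()["naive"]
        assert by["pct_mito_volume"].mean()["onc"] > by["pct_mito_volume"].mean()["naive"]
        assert by["perinuclear_pct"].mean()["onc"] > by["perinuclear_pct"].mean()["naive"]
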