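"""Synthetic generators: determinism, planted truth and boundary cases."""

import math

import numpy as np
import pandas as pd
import pytest

from hypobias.signatures import GeneSignature
from hypobias.synth import (
    gen_expression,
    gen_invasion_phantom,
    gen_methyl_cohort,
    gen_single_cell,
    gen_tumour_mask,
    match_planted_regions,
    write_single_cell,
)


class TestMethylCohort:
    def test_forced_hypo_fraction_one(self):
        _, _, truth = gen_methyl_cohort(n_regions=10, hypo_fraction=1.0, seed=3)
        assert len(truth.planted_regions) == 10
        assert all(r["delta_beta"] < 0 for r in truth.planted_regions)
        assert truth.planted_hypo_fraction == 1.0

    def test_zero_noise_zero_effect_identical_matrices(self):
        _, pairs, _ = gen_methyl_cohort(
            noise_sd=0.0, delta_beta_magnitude=0.0, seed=1
        )
        tum, ctrl = pairs[0]
        np.testing.assert_array_equal(tum.to_numpy(), ctrl.to_numpy())

    def test_seed_determinism_bitwise(self):
        a = gen_methyl_cohort(seed=11)
        b = gen_methyl_cohort(seed=11)
        pd.testing.assert_frame_equal(a[0], b[0])
        for (t1, c1), (t2, c2) in zip(a[1], b[1]):
            pd.testing.assert_frame_equal(t1, t2)
            pd.testing.assert_frame_equal(c1, c2)
        assert a[2].planted_regions == b[2].planted_regions

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="pack"):
            gen_methyl_cohort(n_probes=100, n_regions=40)

    def test_planted_regions_disjoint_and_probe_backed(self):
        man, _, truth = gen_methyl_cohort(seed=5)
        regions = truth.planted_regions
        by_chrom: dict = {}
        for r in regions:
            by_chrom.setdefault(r["chrom"], []).append((r["start"], r["end"]))
            n_inside = (
                (man["chrom"] == r["chrom"])
                & (man["pos"] >= r["start"])
                & (man["pos"] < r["end"])
            ).sum()
            assert n_inside == r["n_probes"] >= 6
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))

    def test_truth_fraction_matches_directions(self):
        _, _, truth = gen_methyl_cohort(n_regions=40, hypo_fraction=0.3, seed=2)
        n_hypo = sum(r["delta_beta"] < 0 for r in truth.planted_regions)
        assert truth.planted_hypo_fraction == pytest.approx(n_hypo / 40)

    def test_betas_in_open_unit_interval(self):
        _, pairs, _ = gen_methyl_cohort(seed=9, noise_sd=0.1)
        for t, c in pairs:
            for m in (t, c):
                assert ((m.to_numpy() > 0) & (m.to_numpy() < 1)).all()


class TestExpression:
    def test_zero_fc_equal_group_means(self):
        sig = GeneSignature("s", [f"SG{i}" for i in range(20)])
        tpm, truth = gen_expression(
            n_genes=300, signature=sig, background_signatures=[],
            planted_log2fc=0.0, seed=4,
        )
        enr = tpm[truth["enriched_samples"]].loc[sorted(sig.genes)].mean(axis=1)
        ctl_cols = [c for c in tpm.columns if c not in truth["enriched_samples"]]
        ctl = tpm[ctl_cols].loc[sorted(sig.genes)].mean(axis=1)
        # equal in expectation; generous band for sampling noise
        assert enr.sum() == pytest.approx(ctl.sum(), rel=0.2)

    def test_tpm_columns_sum_to_1e6(self):
        tpm, _ = gen_expression(seed=1)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_signature_must_fit_universe(self):
        sig = GeneSignature("big", [f"G{i}" for i in range(50)])
        with pytest.raises(ValueError):
            gen_expression(n_genes=10, signature=sig, background_signatures=[])

    def test_determinism(self):
        a, _ = gen_expression(seed=8)
        b, _ = gen_expression(seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestSingleCell:
    def test_pure_fraction_all_one_type(self):
        _, _, _, truth = gen_single_cell(
            n_patients=2, cells_per_patient=30,
            fractions={"cancer-AC-like": 1.0}, seed=0,
        )
        assert set(truth.cell_labels) == {"cancer-AC-like"}

    def test_total_cells(self):
        counts, genes, barcodes, truth = gen_single_cell(
            n_patients=3, cells_per_patient=40, seed=1
        )
        assert counts.shape[1] == 120 == len(barcodes) == len(truth.cell_labels)
        assert counts.shape[0] == len(genes)

    def test_fractions_validated(self):
        with pytest.raises(ValueError, match="sum to 1"):
            gen_single_cell(fractions={"TAM": 0.4})

    def test_patient_fractions_sum_to_one(self):
        _, _, _, truth = gen_single_cell(n_patients=2, cells_per_patient=37, seed=2)
        for fr in truth.patient_fractions.values():
            assert sum(fr.values()) == pytest.approx(1.0)

    def test_mtx_round_trip(self, tmp_path):
        from scipy.io import mmread

        counts, genes, barcodes, _ = gen_single_cell(
            n_patients=1, cells_per_patient=10, seed=3
        )
        write_single_cell(counts, genes, barcodes, tmp_path)
        back = mmread(tmp_path / "matrix.mtx").tocsr()
        assert (back != counts).nnz == 0


class TestTumourMask:
    def test_empty_halo_truth_gross_equals_core(self):
        _, _, truth = gen_tumour_mask(halo=())
        assert truth["gross_area_um2"] == truth["core_area_um2"]

    def test_core_pixel_count_matches_analytic_area(self):
        _, stain, truth = gen_tumour_mask(core_radius=100, pixel_size=1.0, halo=())
        assert stain.pixels.sum() == pytest.approx(math.pi * 100**2, rel=0.01)

    def test_seed_determinism(self):
        a = gen_tumour_mask(seed=6)
        b = gen_tumour_mask(seed=6)
        np.testing.assert_array_equal(a[1].pixels, b[1].pixels)

    def test_core_must_fit(self):
        with pytest.raises(ValueError):
            gen_tumour_mask(image_size=100, pixel_size=1.0, core_radius=60)

    def test_halo_disks_clear_of_core(self):
        _, stain, truth = gen_tumour_mask(seed=4)
        c = (stain.pixels.shape[0] - 1) / 2
        for h in truth["halo"]:
            d = math.hypot(h["cy"] - c, h["cx"] - c)
            assert d > truth["core_radius_um"] + h["radius_um"]


def test_phantom_truth_and_recovery_helper():
    _, _, truth = gen_invasion_phantom(core_radius=100, gross_radius=200)
    assert truth["invasiveness_index"] == pytest.approx(4.0)
    # match_planted_regions on a perfect call set
    man, pairs, mtruth = gen_methyl_cohort(seed=13)
    from hypobias.dmrcall import call_dmrs

    dmrs = call_dmrs(man, *pairs[0])
    prec, rec = match_planted_regions(dmrs, mtruth)
    assert prec == 1.0 and rec == 1.0
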