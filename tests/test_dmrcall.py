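"""Kernel smoothing and DMR calling geometry."""

import numpy as np
import pandas as pd
import pytest

from hypobias.dmrcall import (
    DmrParams,
    call_dmrs,
    dmr_summary,
    probe_calls,
    probe_direction_summary,
    read_dmrs_bed,
    smooth_delta,
    write_dmrs_bed,
)

from conftest import beta_frame, make_manifest


def kernel_oracle(positions, delta, lam, C):
    """Independent scalar-loop Gaussian kernel-weighted mean."""
    sigma = lam / C
    out = []
    for i, pi in enumerate(positions):
        num = den = 0.0
        for pj, dj in zip(positions, delta):
            if abs(pj - pi) <= lam:
                w = np.exp(-0.5 * ((pj - pi) / sigma) ** 2)
                num += w * dj
                den += w
        out.append(num / den)
    return np.array(out)


class TestSmoothDelta:
    def test_single_probe_is_identity(self):
        assert smooth_delta([500], [0.37])[0] == pytest.approx(0.37)

    def test_constant_vector_unchanged(self):
        pos = [0, 100, 300, 900, 1500]
        out = smooth_delta(pos, [0.2] * 5)
        np.testing.assert_allclose(out, 0.2)

    def test_three_probe_hand_oracle(self):
        pos = [0.0, 100.0, 200.0]
        delta = [0.4, 0.4, -0.4]
        out = smooth_delta(pos, delta, lam=1000, C=2)
        np.testing.assert_allclose(out, kernel_oracle(pos, delta, 1000, 2), atol=1e-12)

    def test_random_agrees_with_oracle(self):
        rng = np.random.default_rng(7)
        pos = np.sort(rng.integers(0, 10_000, size=40)).astype(float)
        delta = rng.normal(size=40)
        np.testing.assert_allclose(
            smooth_delta(pos, delta), kernel_oracle(pos, delta, 1000, 2), atol=1e-10
        )

    def test_unsorted_positions_error(self):
        with pytest.raises(ValueError, match="sorted"):
            smooth_delta([100, 50], [0.1, 0.2])


def test_params_validation():
    with pytest.raises(ValueError):
        DmrParams(min_probes=1)
    with pytest.raises(ValueError):
        DmrParams(beta_cutoff=0.0)
    with pytest.raises(ValueError):
        DmrParams(lam=-1)
    assert DmrParams().sigma == pytest.approx(500.0)


def _cluster_input(n_probes, delta=-0.4, spacing=100, base=0.7):
    man = make_manifest([1000 + spacing * i for i in range(n_probes)])
    ctrl = beta_frame([[base]] * n_probes, ["c"])
    tum = beta_frame([[base + delta]] * n_probes, ["t"])
    return man, tum, ctrl


class TestCallDmrs:
    def test_planted_cluster_one_hypo_dmr(self):
        man, tum, ctrl = _cluster_input(6)
        dmrs = call_dmrs(man, tum, ctrl)
        assert len(dmrs) == 1
        r = dmrs.iloc[0]
        assert r["direction"] == "hypo"
        assert r["n_probes"] == 6
        assert (r["start"], r["end"]) == (1000, 1501)
        assert r["mean_delta_beta"] == pytest.approx(-0.4)

    def test_five_probes_below_minimum_no_dmr(self):
        man, tum, ctrl = _cluster_input(5)
        assert len(call_dmrs(man, tum, ctrl)) == 0

    def test_two_clusters_beyond_lambda_split(self):
        positions = [1000 + 100 * i for i in range(6)]
        positions += [positions[-1] + 5000 + 100 * i for i in range(6)]
        man = make_manifest(positions)
        ctrl = beta_frame([[0.7]] * 12, ["c"])
        tum = beta_frame([[0.3]] * 12, ["t"])
        dmrs = call_dmrs(man, tum, ctrl)
        assert len(dmrs) == 2
        assert (dmrs["n_probes"] == 6).all()

    def test_swap_groups_flips_direction_keeps_coords(self):
        man, tum, ctrl = _cluster_input(8)
        fwd = call_dmrs(man, tum, ctrl)
        rev = call_dmrs(man, ctrl, tum)
        assert list(fwd["direction"]) == ["hypo"]
        assert list(rev["direction"]) == ["hyper"]
        pd.testing.assert_frame_equal(
            fwd[["chrom", "start", "end", "n_probes"]],
            rev[["chrom", "start", "end", "n_probes"]],
        )

    def test_emitted_probes_all_pass_cutoff(self):
        man, tum, ctrl = _cluster_input(10)
        params = DmrParams()
        calls = probe_calls(man, tum, ctrl, params)
        dmrs = call_dmrs(man, tum, ctrl, params)
        for _, r in dmrs.iterrows():
            inside = calls[
                (calls["chrom"] == r["chrom"])
                & (calls["pos"] >= r["start"])
                & (calls["pos"] < r["end"])
                & calls["candidate"]
            ]
            assert (inside["smoothed"].abs() >= params.beta_cutoff).all()
            assert len(inside) == r["n_probes"]

    def test_empty_input_gives_empty_frame(self):
        man = make_manifest([100])
        empty = beta_frame(np.empty((0, 1)), ["t"])
        assert len(call_dmrs(man, empty, empty)) == 0

    def test_probe_direction_summary_counts(self):
        man, tum, ctrl = _cluster_input(6)
        summ = probe_direction_summary(probe_calls(man, tum, ctrl))
        assert summ["raw_hypo"] == 6
        assert summ["candidate_hypo"] == 6
        assert summ["candidate_hyper"] == 0


def test_bed_round_trip(tmp_path):
    man, tum, ctrl = _cluster_input(6)
    dmrs = call_dmrs(man, tum, ctrl)
    path = tmp_path / "dmrs.bed"
    write_dmrs_bed(dmrs, path)
    back = read_dmrs_bed(path)
    assert list(back["direction"]) == ["hypo"]
    assert back.loc[0, ["start", "end"]].tolist() == [1000, 1501]
    assert back.loc[0, "score"] == 400
    write_dmrs_bed(dmrs.iloc[:0], tmp_path / "empty.bed")
    assert len(read_dmrs_bed(tmp_path / "empty.bed")) == 0


def test_dmr_summary():
    man, tum, ctrl = _cluster_input(7)
    summ = dmr_summary(call_dmrs(man, tum, ctrl))
    assert summ == {
        "n_dmrs": 1,
        "n_hypo": 1,
        "n_hyper": 0,
        "n_probes_hypo": 7,
        "n_probes_hyper": 0,
    }
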