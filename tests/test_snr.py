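import numpy as np
import pytest

from neuritekit.morphology import NeuronNode, NodeClass, Segment, read_swc
from neuritekit.snr import (
    DegenerateSegmentError,
    MissingLabelError,
    SNRCategory,
    SNRConfig,
    UndefinedCorrelationError,
    categorize_snr,
    correlate_portions,
    profile_neuron,
    profile_segment,
    vr_portion,
)
from neuritekit.synthgen import MorphologySpec, RenderSpec, generate_morphology, render_volume
from neuritekit.volume import Volume, segment_bbox, voxelize_segment


def _seg(points, radii, seg_id=0):
    nodes = [
        NeuronNode(i + 1, 3, x, y, z, r, i if i else -1)
        for i, ((x, y, z), r) in enumerate(zip(points, radii))
    ]
    return Segment(seg_id, nodes, (NodeClass.SOMA, NodeClass.TIP))


def _tube_volume(seg, dims, fg, bg):
    data = np.full(dims, float(bg))
    for v in voxelize_segment(seg, dims):
        data[v] = fg
    return Volume(data)


class TestCategorizeSnr:
    @pytest.mark.parametrize("snr,expected", [
        (0.5, SNRCategory.VERY_LOW),
        (1.0, SNRCategory.VERY_LOW),     # boundary closed on the right
        (1.0 + 1e-12, SNRCategory.LOW),
        (1.2, SNRCategory.LOW),
        (1.2 + 1e-12, SNRCategory.MID),
        (1.4, SNRCategory.MID),
        (1.41, SNRCategory.HIGH),
        (100.0, SNRCategory.HIGH),
    ])
    def test_right_closed_intervals(self, snr, expected):
        assert categorize_snr(snr) is expected

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            categorize_snr(float("nan"))


class TestProfileSegment:
    def test_constant_tube_over_constant_background(self):
        seg = _seg([(8, 10, 10), (14, 10, 10)], [1.5, 1.5])
        vol = _tube_volume(seg, (20, 20, 24), fg=200.0, bg=100.0)
        rec = profile_segment(seg, vol)
        assert rec.f_mean == 200.0
        assert rec.bcrt_mean == 100.0  # constant background, any 20% has mean 100
        assert rec.snr == pytest.approx(200.0 / (100.0 + 1e-6), rel=1e-9)
        assert rec.category is SNRCategory.HIGH

    def test_mid_category_just_below_boundary(self):
        # foreground mean 1.4, critical-background mean 1.0:
        # snr = 1.4/(1+eps) slightly below 1.4 -> mid (interval (1.2, 1.4])
        seg = _seg([(5, 5, 3), (5, 5, 7)], [1.0, 1.0])
        vol = _tube_volume(seg, (11, 11, 11), fg=1.4, bg=1.0)
        rec = profile_segment(seg, vol)
        assert rec.snr == pytest.approx(1.4 / (1 + 1e-6), rel=1e-9)
        assert rec.category is SNRCategory.MID

    def test_uniform_volume_is_very_low(self):
        seg = _seg([(5, 5, 3), (5, 5, 7)], [1.0, 1.0])
        vol = Volume(np.full((11, 11, 11), 7.0))
        rec = profile_segment(seg, vol)
        assert rec.snr < 1.0
        assert rec.category is SNRCategory.VERY_LOW

    def test_bcrt_is_ceil_of_fraction_and_brightest(self):
        seg = _seg([(5, 5, 5)], [1.0])
        dims = (11, 11, 11)
        rng = np.random.default_rng(0)
        data = rng.uniform(0, 100, dims)
        vol = Volume(data)
        rec = profile_segment(seg, vol)
        box = segment_bbox(seg)
        fg = voxelize_segment(seg, dims)
        bg_vals = sorted(
            (
                data[z, y, x]
                for z in range(box.origin[0], box.origin[0] + box.shape[0])
                for y in range(box.origin[1], box.origin[1] + box.shape[1])
                for x in range(box.origin[2], box.origin[2] + box.shape[2])
                if (z, y, x) not in fg
            ),
            reverse=True,
        )
        k = int(np.ceil(0.2 * len(bg_vals)))
        assert rec.n_background == len(bg_vals)
        assert rec.bcrt_mean == pytest.approx(np.mean(bg_vals[:k]), rel=1e-12)

    def test_degenerate_foreground_raises(self):
        seg = _seg([(50, 50, 50)], [1.0])
        vol = Volume(np.zeros((10, 10, 10)))
        with pytest.raises(DegenerateSegmentError, match="foreground"):
            profile_segment(seg, vol)

    def test_scale_invariance(self):
        seg = _seg([(6, 8, 8), (12, 8, 8)], [1.0, 1.0])
        rng = np.random.default_rng(1)
        data = rng.uniform(50, 150, (16, 16, 18))
        r1 = profile_segment(seg, Volume(data), SNRConfig())
        r2 = profile_segment(seg, Volume(data * 3.0), SNRConfig())
        assert r2.snr == pytest.approx(r1.snr, rel=1e-6)

    def test_raising_foreground_never_decreases_snr(self):
        seg = _seg([(6, 8, 8), (12, 8, 8)], [1.0, 1.0])
        rng = np.random.default_rng(2)
        data = rng.uniform(50, 150, (16, 16, 18))
        base = profile_segment(seg, Volume(data)).snr
        boosted = data.copy()
        for v in voxelize_segment(seg, (16, 16, 18)):
            boosted[v] += 40.0
        assert profile_segment(seg, Volume(boosted)).snr >= base

    def test_bcrt_tie_rule_deterministic(self):
        seg = _seg([(5, 5, 5)], [1.0])
        vol = Volume(np.full((11, 11, 11), 9.0))  # all background tied
        r1 = profile_segment(seg, vol)
        r2 = profile_segment(seg, vol)
        assert r1 == r2


class TestProfileNeuron:
    def test_weighted_snr_arithmetic(self):
        # two segments, lengths 1:3, designed contrasts 1.0 and 2.0
        swc = (
            "1 1 10 10 10 1 -1\n"
            "2 3 14 10 10 1 1\n"   # branch at node 2
            "3 3 16 10 10 1 2\n"   # short arm, length 2
            "4 3 14 16 10 1 2\n"   # long arm, length 6
        )
        tree = read_swc(swc)
        from neuritekit.morphology import decompose_segments
        segs = decompose_segments(tree)
        lens = {s.id: s.length for s in segs}
        amps = {s.id: (0.0 if lens[s.id] == min(lens.values()) else 100.0) for s in segs}
        spec = RenderSpec(bg_level=100.0, bg_noise_sd=0.0, dims=(21, 27, 27), seed=0)
        vol = render_volume(tree, spec, segment_amplitudes=amps)
        prof = profile_neuron(tree, vol)
        table = {r.segment_id: r for r in prof.segments}
        expect = sum(lens[i] * table[i].snr for i in lens) / sum(lens.values())
        assert prof.weighted_snr == pytest.approx(expect, rel=1e-12)
        assert min(r.snr for r in prof.segments) <= prof.weighted_snr <= max(
            r.snr for r in prof.segments
        )

    def test_category_fractions_sum_to_one(self):
        tree = generate_morphology(MorphologySpec(n_branch_events=3, dims=(48, 48, 48), seed=11))
        vol = render_volume(tree, RenderSpec(dims=(48, 48, 48), bg_noise_sd=5.0, seed=11))
        prof = profile_neuron(tree, vol)
        assert sum(prof.category_length_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_vlsnr_portion_by_length(self):
        tree = generate_morphology(MorphologySpec(n_branch_events=2, dims=(48, 48, 48), seed=4))
        from neuritekit.morphology import decompose_segments
        segs = decompose_segments(tree)
        low = {segs[0].id}
        amps = {s.id: (-40.0 if s.id in low else 100.0) for s in segs}
        vol = render_volume(tree, RenderSpec(bg_level=100.0, dims=(48, 48, 48), seed=4),
                            segment_amplitudes=amps)
        prof = profile_neuron(tree, vol)
        total = sum(s.length for s in segs)
        expected = sum(s.length for s in segs if s.id in low) / total
        assert prof.vlsnr_portion == pytest.approx(expected, rel=1e-9)

    def test_basnr_is_fraction_below_weighted_mean(self):
        tree = generate_morphology(MorphologySpec(n_branch_events=3, dims=(48, 48, 48), seed=9))
        vol = render_volume(tree, RenderSpec(dims=(48, 48, 48), bg_noise_sd=8.0, seed=9))
        prof = profile_neuron(tree, vol)
        lens = np.array([r.length for r in prof.segments])
        snrs = np.array([r.snr for r in prof.segments])
        expect = lens[snrs < prof.weighted_snr].sum() / lens.sum()
        assert prof.basnr_portion == pytest.approx(expect, rel=1e-12)


class TestVrPortion:
    def _labeled(self, labels):
        swc = "#columns id,type,x,y,z,radius,parent,gen_method\n"
        swc += f"1 1 0 0 0 1 -1 {labels[0]}\n"
        swc += f"2 3 2 0 0 1 1 {labels[1]}\n"
        swc += f"3 3 4 0 0 1 2 {labels[2]}\n"
        return read_swc(swc)

    def test_all_vr_is_one(self):
        assert vr_portion(self._labeled(["VR", "VR", "VR"])) == 1.0

    def test_half_split_by_length(self):
        assert vr_portion(self._labeled(["nonVR", "VR", "nonVR"])) == pytest.approx(0.5)

    def test_missing_labels_listed(self):
        tree = read_swc("1 1 0 0 0 1 -1\n2 3 1 0 0 1 1\n")
        with pytest.raises(MissingLabelError, match=r"\[2\]"):
            vr_portion(tree)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_edge_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        from conftest import random_tree
        tree = random_tree(rng, 40)
        for n in tree.nodes:
            n.labels["gen_method"] = "VR" if rng.random() < 0.4 else "nonVR"
        vr_len = tot = 0.0
        for p, c in tree.edges():
            ln = tree.edge_length(p, c)
            tot += ln
            if tree.node(c).labels["gen_method"] == "VR":
                vr_len += ln
        assert vr_portion(tree) == pytest.approx(vr_len / tot, rel=1e-12)


class TestCorrelatePortions:
    def test_exact_line(self):
        pts = [(2 * x, x) for x in (0.1, 0.3, 0.5, 0.7)]
        res = correlate_portions(pts)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_y_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            correlate_portions([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            correlate_portions([(0.1, 0.1), (0.2, 0.2)])

    def test_noisy_line_recovers_analytic_correlation(self):
        rng = np.random.default_rng(5)
        sd_noise = 0.05
        x = rng.uniform(0.1, 0.9, 50)
        y = x + rng.normal(0, sd_noise, 50)
        res = correlate_portions(list(zip(y, x)))
        var_x = 0.8**2 / 12
        analytic = np.sqrt(var_x / (var_x + sd_noise**2))
        assert abs(res["pearson_r"] - analytic) < 0.1
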