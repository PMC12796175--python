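import numpy as np
import pytest

from plantarqc.cnn import PlantarCNN
from plantarqc.explain import (AttributionMap, RenderConfig,
                               compute_attribution, render_triptych,
                               threshold_and_smooth, threshold_attribution)
from plantarqc.spm import Cluster, SPMDecision
from plantarqc.types import PressureSample, Side


class _LinearStub:
    """Minimal model: logit[c] = <W_c, grid> + <V_c, embedding>."""

    def __init__(self, w, v, emb_table):
        self.w = w                      # (5, 64, 64)
        self.v = v                      # (5, 8)
        self._emb = emb_table

        class _Cfg:
            n_classes = 5
        self.config = _Cfg()

        class _Emb:
            params = {"E": emb_table}
        self.embedding = _Emb()

    def forward(self, x, sides=None, training=False,
                embedding_override=None):
        emb = (self._emb[np.asarray(sides)] if embedding_override is None
               else embedding_override)
        self._cache = (np.asarray(x), np.asarray(emb))
        return (np.tensordot(x, self.w, axes=([1, 2], [1, 2]))
                + emb @ self.v.T)

    def backward(self, dlogits):
        dx = np.tensordot(dlogits, self.w, axes=([1], [0]))
        de = dlogits @ self.v
        return dx, de


@pytest.fixture(scope="module")
def linear_stub():
    rng = np.random.default_rng(0)
    w = rng.standard_normal((5, 64, 64)) * 0.01
    v = rng.standard_normal((5, 8)) * 0.1
    emb = rng.standard_normal((2, 8)).astype(np.float32)
    return _LinearStub(w, v, emb)


@pytest.fixture(scope="module")
def background(cohort_stack):
    return cohort_stack[:8], np.array([0] * 8)


class TestComputeAttribution:
    def test_additivity_exact_for_linear_model(self, linear_stub,
                                               cohort_stack, background):
        bg, bgs = background
        attr = compute_attribution(linear_stub, cohort_stack[10], Side.LEFT,
                                   bg, bgs, fold_stats=(0.1, 0.3),
                                   n_steps=8)
        assert attr.additivity_gap < 1e-6

    def test_constant_model_gives_zero_attributions(self, cohort_stack,
                                                    background):
        bg, bgs = background
        stub = _LinearStub(np.zeros((5, 64, 64)), np.zeros((5, 8)),
                           np.zeros((2, 8), dtype=np.float32))
        attr = compute_attribution(stub, cohort_stack[0], Side.LEFT, bg, bgs,
                                   fold_stats=(0.0, 1.0), n_steps=4)
        assert np.allclose(attr.values, 0)
        assert np.allclose(attr.embedding_values, 0)

    def test_single_pixel_model_concentrates_attribution(self, cohort_stack,
                                                         background):
        bg, bgs = background
        w = np.zeros((5, 64, 64))
        w[2, 0, 0] = 3.0                # the model reads only pixel (0, 0)
        stub = _LinearStub(w, np.zeros((5, 8)),
                           np.zeros((2, 8), dtype=np.float32))
        grid = cohort_stack[0].copy()
        grid[0, 0] = 0.7
        attr = compute_attribution(stub, grid, Side.LEFT, bg, bgs,
                                   fold_stats=(0.0, 1.0), target_class=2,
                                   n_steps=4)
        mask = np.ones((64, 64), dtype=bool)
        mask[0, 0] = False
        assert np.allclose(attr.values[mask], 0)
        assert attr.values[0, 0] != 0

    def test_additivity_within_tolerance_on_cnn(self, toy_problem,
                                                toy_model):
        """The 1%-relative additivity contract on a trained network."""
        grids, sides, labels = toy_problem
        model, _ = toy_model
        bg, bgs = grids[:8], sides[:8]
        for i in (15, 42):
            attr = compute_attribution(model, grids[i],
                                       Side.LEFT if sides[i] == 0
                                       else Side.RIGHT,
                                       bg, bgs, fold_stats=(0.0, 1.0),
                                       n_steps=64)
            assert attr.additivity_gap < 0.01

    def test_empty_background_rejected(self, linear_stub):
        with pytest.raises(ValueError):
            compute_attribution(linear_stub, np.zeros((64, 64)), Side.LEFT,
                                np.zeros((0, 64, 64)), [],
                                fold_stats=(0, 1))


class TestThresholding:
    def test_twenty_percent_rule(self):
        v = np.zeros((64, 64))
        v[0, 0], v[0, 1], v[0, 2] = 1.0, 0.19, -0.5
        out = threshold_attribution(v, 0.20)
        assert out[0, 0] == 1.0
        assert out[0, 1] == 0.0
        assert out[0, 2] == -0.5

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((64, 64))
        once = threshold_attribution(v, 0.2)
        assert np.array_equal(threshold_attribution(once, 0.2), once)

    def test_uniform_map_survives_entirely(self):
        v = np.full((64, 64), 0.3)
        assert np.array_equal(threshold_attribution(v, 0.2), v)

    def test_zero_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((64, 64))
        assert np.array_equal(threshold_attribution(v, 0.0), v)


def _attr(values):
    return AttributionMap(values=values, embedding_values=np.zeros(8),
                          target_class=1, baseline_expectation=0.0,
                          model_output=float(values.sum()), n_background=4)


class TestThresholdAndSmooth:
    def test_all_zero_map_unchanged(self):
        out = threshold_and_smooth(_attr(np.zeros((64, 64))))
        assert np.all(out.values == 0)

    def test_sign_pattern_of_extremes_preserved(self):
        rng = np.random.default_rng(2)
        v = rng.standard_normal((64, 64))
        out = threshold_and_smooth(_attr(v))
        peak = np.abs(v).max()
        strong = np.abs(v) >= 0.5 * peak
        assert np.all(np.sign(out.values[strong]) == np.sign(v[strong]))

    def test_smoothing_stays_local(self):
        v = np.zeros((64, 64))
        v[32, 32] = 1.0
        out = threshold_and_smooth(_attr(v), RenderConfig(bilateral_win=5))
        nz = np.argwhere(out.values != 0)
        assert np.all(np.abs(nz - 32).max(axis=1) <= 5)


class TestRenderTriptych:
    def _decision(self, significant=()):
        return SPMDecision(pmap=np.ones((64, 64)), clusters=list(significant),
                           fwe_threshold=0, significant=list(significant),
                           is_outlier=bool(significant))

    def test_writes_readable_figure(self, tmp_path, valid_sample):
        attr = _attr(np.random.default_rng(0).standard_normal((64, 64)))
        attr.sample_id = valid_sample.sample_id
        out = tmp_path / "fig.png"
        cluster = Cluster(pixels=frozenset({(5, 5), (5, 6)}), size=2)
        render_triptych(valid_sample, self._decision([cluster]), attr,
                        str(out))
        import imageio.v3 as iio
        img = iio.imread(out)
        assert img.ndim == 3 and img.shape[0] > 100

    def test_rendering_pure_given_inputs(self, tmp_path, valid_sample):
        attr = _attr(np.random.default_rng(1).standard_normal((64, 64)))
        attr.sample_id = valid_sample.sample_id
        a, b = tmp_path / "a.png", tmp_path / "b.png"
        render_triptych(valid_sample, self._decision(), attr, str(a))
        render_triptych(valid_sample, self._decision(), attr, str(b))
        import imageio.v3 as iio
        assert np.array_equal(iio.imread(a), iio.imread(b))

    def test_mismatched_sample_id_rejected(self, tmp_path, valid_sample):
        attr = _attr(np.zeros((64, 64)))
        attr.sample_id = "someone-else"
        with pytest.raises(ValueError):
            render_triptych(valid_sample, self._decision(), attr,
                            str(tmp_path / "x.png"))
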