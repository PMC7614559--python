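import warnings

import numpy as np
import pytest

from massdetect import (
    OracleClassifier,
    PatchScore,
    adapted_total_params,
    baseline_score,
    head_parameter_count,
    score_patches,
    select_candidates,
)
from massdetect.patchex import PatchSet


def blob_patch(side=64, amplitude=0.3, sigma=8.0):
    yy, xx = np.mgrid[0:side, 0:side]
    blob = np.exp(-(((yy - side / 2) ** 2 + (xx - side / 2) ** 2) / (2 * sigma**2)))
    patch = 0.2 + amplitude * blob
    conc = blob >= 0.5
    return patch, conc


class TestBaselineScore:
    def test_equal_means_is_half(self):
        patch = np.full((32, 32), 0.4)
        conc = np.zeros((32, 32), dtype=bool)
        conc[10:20, 10:20] = True
        assert baseline_score(patch, conc) == pytest.approx(0.5)

    def test_saturates_for_large_contrast(self):
        patch, conc = blob_patch(amplitude=0.8)
        assert baseline_score(patch, conc) > 0.99

    def test_monotone_in_contrast(self):
        lo, conc = blob_patch(amplitude=0.1)
        hi, _ = blob_patch(amplitude=0.3)
        assert baseline_score(hi, conc) > baseline_score(lo, conc)

    def test_empty_conc_scores_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert baseline_score(np.ones((8, 8)), np.zeros((8, 8))) == 0.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            baseline_score(np.ones((8, 8)), np.ones((8, 9)))


class TestSelectCandidates:
    def test_threshold_branch(self):
        assert select_candidates([0.9, 0.2, 0.7], threshold=0.5, t=10) == [0, 2]

    def test_fallback_top_t(self):
        assert select_candidates([0.4, 0.2, 0.3], threshold=0.5, t=2) == [0, 2]

    def test_fewer_than_t(self):
        assert select_candidates([0.4], threshold=0.5, t=10) == [0]

    def test_ties_break_to_lower_index(self):
        assert select_candidates([0.3, 0.3, 0.3], threshold=0.5, t=2) == [0, 1]

    def test_accepts_patchscores(self):
        scores = [PatchScore(0, 0.1), PatchScore(1, 0.9)]
        assert select_candidates(scores, threshold=0.5, t=1) == [1]

    def test_empty_warns(self):
        with pytest.warns(UserWarning):
            assert select_candidates([], threshold=0.5, t=3) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_never_empty_on_nonempty_scores(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(rng.integers(1, 20)).tolist()
        assert select_candidates(scores, threshold=1.0, t=4)  # nothing clears 1.0: fallback path

    def test_t_validation(self):
        with pytest.raises(ValueError):
            select_candidates([0.5], t=0)


class TestHeadParameters:
    def test_default_head_count(self):
        assert head_parameter_count(1000, 256, 2) == 256_512

    def test_minimal(self):
        assert head_parameter_count(1, 1, 1) == 2

    def test_small(self):
        assert head_parameter_count(10, 5, 2) == 60

    @pytest.mark.parametrize("d_in,d_hidden,d_out", [(3, 4, 5), (7, 2, 9)])
    def test_linear_in_each_argument(self, d_in, d_hidden, d_out):
        base = head_parameter_count(d_in, d_hidden, d_out)
        assert head_parameter_count(2 * d_in, d_hidden, d_out) == base + d_in * d_hidden
        assert head_parameter_count(d_in, d_hidden, 2 * d_out) == base + d_hidden * d_out

    @pytest.mark.parametrize(
        "original,total", [(25.56, 25.82), (20.02, 20.28), (0.0, 0.26), (143.68, 143.94)]
    )
    def test_adapted_totals(self, original, total):
        assert adapted_total_params(original) == total


class TestScorePatches:
    class ConstantClassifier:
        input_side = 16
        channels = 1

        def __call__(self, batch):
            return [0.25] * len(batch)

    class ShapeCheckingClassifier:
        input_side = 16
        channels = 3

        def __call__(self, batch):
            assert batch.shape == (1, 16, 16, 3)
            return [float(batch.mean() > 0.5)]

    class FailingClassifier:
        input_side = 16
        channels = 1

        def __call__(self, batch):
            raise RuntimeError("boom")

    def test_empty(self):
        assert score_patches([], self.ConstantClassifier()) == []

    def test_order_preserved(self):
        patches = [np.full((32, 32), v) for v in (0.1, 0.9, 0.5)]
        scores = score_patches(patches, self.ConstantClassifier())
        assert [s.index for s in scores] == [0, 1, 2]

    def test_resize_and_channel_replication(self):
        scores = score_patches([np.full((40, 40), 0.9)], self.ShapeCheckingClassifier())
        assert scores[0].score == 1.0

    def test_failure_names_patch_index(self):
        with pytest.raises(RuntimeError, match="patch 0"):
            score_patches([np.zeros((16, 16))] * 3, self.FailingClassifier())


class TestOracleClassifier:
    def test_scores_overlap_exactly(self):
        gt = np.zeros((64, 64), dtype=bool)
        gt[10:20, 10:20] = True
        hit = np.zeros((16, 16), dtype=bool)
        hit[4:8, 4:8] = True
        miss = np.zeros((16, 16), dtype=bool)
        miss[0:4, 0:4] = True
        ps = PatchSet(
            patches=[np.zeros((16, 16))] * 2,
            conc_patches=[hit, miss],
            eboxes=[],
            source_labels=[1, 2],
            origins=[(8, 8), (40, 40)],
        )
        scores = OracleClassifier([gt]).score_patchset(ps)
        assert [s.score for s in scores] == [1.0, 0.0]

    def test_plain_call_rejected(self):
        with pytest.raises(TypeError):
            OracleClassifier([np.zeros((4, 4), dtype=bool)])(np.zeros((1, 4, 4)))
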