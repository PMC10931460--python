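"""Dataset splitting, video-level prediction aggregation, the training loop's
checkpointing contract, the ablation harness, and diagnostic plots."""

import numpy as np
import pandas as pd
import pytest

from ccanet.metrics import PredictionRecord
from ccanet.model import DepressionRegressor
from ccanet.plots import error_boxplot, qq_plot
from ccanet.training import (TrainConfig, evaluate_model, predict_video,
                             run_ablation, split_dataset, train_model)

from conftest import tiny_model


def _quick_cfg(**kw):
    base = dict(epochs=1, batch_size=16, seed=0)
    base.update(kw)
    return TrainConfig(**base)


class TestSplit:
    def test_three_to_one_proportion(self, tiny_dataset):
        videos, _ = tiny_dataset
        train, val = split_dataset(videos, (3, 1), seed=0)
        assert len(train) == 9 and len(val) == 3

    def test_hundred_videos_split_75_25(self):
        from ccanet.synthetic import LabeledVideo, SyntheticFrame
        frame = SyntheticFrame(np.zeros((3, 32, 32), np.float32),
                               (0, 0, 32, 32), (0.0,) * 10, 1.0)
        videos = [LabeledVideo(f"v{i}", [frame], 1.0) for i in range(100)]
        train, val = split_dataset(videos, (3, 1), seed=1)
        assert len(train) == 75 and len(val) == 25

    def test_same_seed_same_split(self, tiny_dataset):
        videos, _ = tiny_dataset
        a = split_dataset(videos, (3, 1), seed=5)
        b = split_dataset(videos, (3, 1), seed=5)
        assert [v.video_id for v in a[0]] == [v.video_id for v in b[0]]

    def test_disjoint_partition(self, tiny_dataset):
        videos, _ = tiny_dataset
        train, val = split_dataset(videos, (3, 1), seed=2)
        tids = {v.video_id for v in train}
        vids = {v.video_id for v in val}
        assert not (tids & vids)
        assert len(tids | vids) == len(videos)

    def test_too_few_rejected(self, tiny_dataset):
        videos, _ = tiny_dataset
        with pytest.raises(ValueError):
            split_dataset(videos[:3])


class TestPredictVideo:
    def test_mean_aggregation(self, tiny_dataset):
        videos, _ = tiny_dataset
        model = tiny_model(seed=1)
        model.eval()
        rec = predict_video(model, videos[0].frames, video_id="x",
                            true_score=videos[0].bdi_score)
        assert rec.video_score == pytest.approx(
            np.clip(np.mean(rec.frame_scores), 0, 63))

    def test_clamped_to_bdi_range(self):
        class Stub:
            def eval(self):
                pass

            def __call__(self, t):
                from ccanet.nn import Tensor
                return Tensor(np.full((t.shape[0], 1), 70.0))

        frames = [np.zeros((3, 32, 32), np.float32)]
        rec = predict_video(Stub(), frames)
        assert rec.video_score == 63.0

    def test_empty_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            predict_video(tiny_model(seed=0), [])


class TestTrainModel:
    def test_single_epoch_history_and_best_checkpoint(self, tiny_dataset):
        videos, _ = tiny_dataset
        model = tiny_model(seed=2)
        res = train_model(videos, model, _quick_cfg(epochs=2))
        assert len(res.history) == 2
        assert res.best_val_loss == res.history.val_loss.min()
        assert res.best_epoch == int(res.history.val_loss.idxmin())

    def test_loss_decreases_on_learnable_signal(self):
        from ccanet.synthetic import make_regression_dataset
        videos, _ = make_regression_dataset(16, 4, seed=11, height=32,
                                            width=32, noise_sigma=0.01)
        model = tiny_model(seed=3)
        res = train_model(videos, model, _quick_cfg(epochs=3, batch_size=32))
        assert res.history.train_loss.iloc[-1] < res.history.train_loss.iloc[0]

    def test_checkpoint_roundtrip_preserves_predictions(self, tiny_dataset,
                                                        tmp_path):
        videos, _ = tiny_dataset
        model = tiny_model(seed=4)
        res = train_model(videos, model, _quick_cfg())
        path = tmp_path / "ckpt.npz"
        model.save(path, norm_stats=(res.norm_mean, res.norm_std))
        loaded, norm, _ = DepressionRegressor.load(path)
        a, _ = evaluate_model(model, videos[:2],
                              norm=(res.norm_mean, res.norm_std))
        b, _ = evaluate_model(loaded, videos[:2], norm=norm)
        np.testing.assert_allclose([r.video_score for r in a],
                                   [r.video_score for r in b], atol=1e-5)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_model([], tiny_model(), _quick_cfg())


class TestAblation:
    def test_two_variants_two_rows_and_determinism(self, tiny_dataset):
        videos, _ = tiny_dataset
        factory = lambda v: tiny_model(variant=v, seed=6)
        a = run_ablation(videos, ["none", "cca"], _quick_cfg(),
                         model_factory=factory)
        b = run_ablation(videos, ["none", "cca"], _quick_cfg(),
                         model_factory=factory)
        assert list(a.Models) == ["none", "cca"]
        pd.testing.assert_frame_equal(a, b)
        assert (a.MAE <= a.RMSE + 1e-12).all()

    def test_failing_variant_recorded_not_raised(self, tiny_dataset):
        videos, _ = tiny_dataset

        def factory(v):
            if v == "boom":
                raise RuntimeError("synthetic failure")
            return tiny_model(variant=v, seed=7)

        table = run_ablation(videos, ["boom", "none"], _quick_cfg(),
                             model_factory=factory)
        assert np.isnan(table.loc[table.Models == "boom", "RMSE"]).all()
        assert table.loc[table.Models == "none", "error"].iloc[0] == ""

    def test_no_variants_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            run_ablation(tiny_dataset[0], [], _quick_cfg())


class TestVariantParameterOrdering:
    def test_attention_cost_ordering(self):
        counts = {v: tiny_model(variant=v, seed=0).n_parameters()
                  for v in ("none", "se", "eca", "cca", "cbam")}
        assert counts["none"] < counts["se"] <= counts["cca"]
        assert counts["none"] < counts["eca"] <= counts["cca"]
        assert counts["cca"] <= counts["cbam"]

    def test_per_block_placement_forward(self, rng):
        model = tiny_model(variant="se", seed=1, placement="per_block")
        model.eval()
        from ccanet.nn import Tensor
        out = model(Tensor(rng.normal(size=(1, 3, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 1)


class TestPlots:
    def _records(self, offset=0.0):
        return [PredictionRecord(f"v{i}", [float(i)], float(i) + offset,
                                 float(i)) for i in range(6)]

    def test_files_written_nonempty(self, tmp_path):
        recs = self._records(offset=5.0)
        p1 = error_boxplot({"m": recs}, tmp_path / "box.png")
        p2 = qq_plot(recs, tmp_path / "qq.png")
        assert p1.stat().st_size > 0 and p2.stat().st_size > 0

    def test_too_few_records_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            qq_plot(self._records()[:1], tmp_path / "qq.png")
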