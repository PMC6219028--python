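"""End-to-end pipeline configuration and runner.

``run_pipeline`` chains simulate -> extract -> select -> train -> predict ->
evaluate on phantom data, writes every artifact plus a manifest (config
hash, seed, library versions), and returns the evaluation report.  Rerunning
with the same config reproduces the report bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import MultiLevelModel, RFParams, predict, save_model, train
from .errors import ParameterError
from .evaluation import EvalReport, evaluate_model
from .features import TextureConfig, extract_all
from .phantom import PhantomSpec, generate_dataset
from .pipeline_io import save_feature_table, save_frame, save_json, save_labels, save_mask
from .selection import SelectionResult, fit_pca_selector

log = logging.getLogger("ivus_texturekit")


@dataclass(frozen=True)
class RunConfig:
    """Defaults reproduce the method's stated settings: 5x5 windows (3x3 for
    LBP), GLCM d=1 at 135 degrees, 100 trees of depth 10, FT-max threshold."""

    out_dir: str = "runs/default"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_train: int = 5
    n_test: int = 2
    texture: TextureConfig = field(default_factory=TextureConfig)
    variance_target: float = 0.95
    k_per_net: tuple[int, int, int] = (21, 15, 18)
    rf: RFParams = field(default_factory=RFParams)
    threshold_percentile: float = 100.0
    max_train_pixels_per_net: int | None = 40_000
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(
            self,
            seed=seed,
            phantom=replace(self.phantom, seed=seed),
            rf=replace(self.rf, seed=seed),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_per_net"] = list(self.k_per_net)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            d["phantom"] = PhantomSpec(**d["phantom"])
        if "texture" in d:
            d["texture"] = TextureConfig(**d["texture"])
        if "rf" in d:
            d["rf"] = RFParams(**d["rf"])
        if "k_per_net" in d:
            d["k_per_net"] = tuple(d["k_per_net"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def extract_frames(
    triples, config: TextureConfig, tag: str = ""
) -> pd.DataFrame:
    """Concatenate per-frame feature tables, tagging rows with a frame id."""
    tables = []
    for i, (frame, mask, labels) in enumerate(triples):
        t0 = time.perf_counter()
        df = extract_all(frame, mask, labels, config)
        df.insert(0, "frame", i)
        tables.append(df)
        log.info("extract %s frame %d: %d pixels in %.1fs", tag, i, len(df), time.perf_counter() - t0)
    return pd.concat(tables, ignore_index=True)


def fit_selections(
    train_table: pd.DataFrame,
    variance_target: float,
    k_per_net: tuple[int, int, int],
    threshold: float,
) -> dict[int, SelectionResult]:
    """Per-net PCA selection on each net's own training pool.

    Raw intensity is guaranteed a slot in the two leaf nets (FT-vs-FFT and
    NC-vs-DC): the cascade is intensity-based by design and the leaf tasks
    separate tissues that differ foremost in brightness, while net 1 sees
    only pixels the threshold has already confined to a narrow band.
    """
    labels = train_table["label"]
    pools = {
        1: train_table[train_table["intensity"] <= threshold],
        2: train_table[labels.isin(("FT", "FFT"))],
        3: train_table[labels.isin(("NC", "DC"))],
    }
    forced = {1: (), 2: ("intensity",), 3: ("intensity",)}
    return {
        net_id: fit_pca_selector(
            pool,
            variance_target=variance_target,
            k=k_per_net[net_id - 1],
            net_id=net_id,
            always_include=forced[net_id],
        )
        for net_id, pool in pools.items()
    }


def run_pipeline(config: RunConfig, write_artifacts: bool = True) -> EvalReport:
    out = Path(config.out_dir)
    if write_artifacts:
        out.mkdir(parents=True, exist_ok=True)

    stages: dict[str, float] = {}

    def timed(name):
        t0 = time.perf_counter()

        def done():
            stages[name] = time.perf_counter() - t0
            log.info("stage %s: %.1fs", name, stages[name])

        return done

    end = timed("simulate")
    n_total = config.n_train + config.n_test
    triples = generate_dataset(config.phantom, n_total, seed=config.seed)
    train_triples, test_triples = triples[: config.n_train], triples[config.n_train :]
    if write_artifacts:
        for i, (frame, mask, labels) in enumerate(triples):
            split = "train" if i < config.n_train else "test"
            save_frame(frame, out / f"{split}_frame_{i:03d}.png")
            save_mask(mask, out / f"{split}_mask_{i:03d}.png")
            save_labels(labels, out / f"{split}_labels_{i:03d}.png")
    end()

    end = timed("extract")
    train_table = extract_frames(train_triples, config.texture, "train")
    test_table = extract_frames(test_triples, config.texture, "test")
    if write_artifacts:
        save_feature_table(train_table, out / "features_train.csv")
        save_feature_table(test_table, out / "features_test.csv")
    end()

    end = timed("select+train")
    from .classifier import _threshold_from_values
    import numpy as np

    thr = _threshold_from_values(
        train_table.loc[train_table["label"] == "FT", "intensity"].to_numpy(np.float64),
        config.threshold_percentile,
    )
    selections = fit_selections(train_table, config.variance_target, config.k_per_net, thr)
    model = train(
        train_table,
        selections,
        rf_params=config.rf,
        threshold_percentile=config.threshold_percentile,
        max_train_pixels_per_net=config.max_train_pixels_per_net,
    )
    if write_artifacts:
        save_model(model, out / "model")
    end()

    end = timed("predict+evaluate")
    routed = predict(model, test_table)
    report = evaluate_model(model, test_table)
    if write_artifacts:
        routed.to_frame(test_table).to_csv(out / "predictions_test.csv", index=False)
        save_json(report.to_dict(), out / "report.json")
    end()

    if write_artifacts:
        import numpy as _np
        import sklearn

        save_json(
            {
                "config": config.to_dict(),
                "config_sha256": config.digest(),
                "seed": config.seed,
                "stage_seconds": stages,
                "versions": {
                    "ivus_texturekit": __version__,
                    "numpy": _np.__version__,
                    "sklearn": sklearn.__version__,
                    "pandas": pd.__version__,
                },
            },
            out / "manifest.json",
        )
    return report
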