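"""End-to-end desk-scale experiment: phantoms -> sampling -> training -> evaluation.

``run_pipeline`` wires every stage together under one seed: generate a
phantom cohort, split it, draw difficulty-weighted training voxels, extract
patch pairs, train the two-branch network, segment the held-out phantoms by
slice propagation, and write per-case metrics. Everything written to the run
directory is regenerable from the config and seed alone.

Configs are plain dataclasses, loadable from YAML; every section mirrors one
module's config type. The functions here (plus the scripts in ``examples/``)
are the package's operational surface — there is no shell command.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .metrics import evaluate_cohort
from .model import CFCNN, ModelConfig, TrainConfig, save_checkpoint, train
from .patches import PatchSpec, patch_arrays
from .phantoms import PhantomConfig, generate_cohort
from .sampling import sample_cohort
from .segmentation import CfcnnVoxelClassifier, segment

logger = logging.getLogger("cfcnn")


@dataclass(frozen=True)
class CohortSpec:
    n_train: int = 20
    n_val: int = 2
    n_test: int = 8
    kind_mix: dict = field(
        default_factory=lambda: {"isolated": 0.5, "juxtapleural": 0.25, "ggo": 0.25}
    )


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    cohort: CohortSpec = CohortSpec()
    phantom: PhantomConfig = PhantomConfig()
    patches: PatchSpec = PatchSpec()
    model: ModelConfig = ModelConfig.tiny()
    train: TrainConfig = TrainConfig(max_epochs=8, early_stop_patience=3)
    sampling_fraction: float = 0.40
    threshold: float = 0.5

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sections = {
            "cohort": CohortSpec,
            "phantom": PhantomConfig,
            "patches": PatchSpec,
            "model": ModelConfig,
            "train": TrainConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sections:
                if not isinstance(value, dict):
                    raise ConfigError(f"section {key!r} must be a mapping")
                if key == "model" and "conv_filters" in value:
                    value["conv_filters"] = tuple(
                        tuple(p) for p in value["conv_filters"]
                    )
                for tup in ("center", "shape", "spacing", "axis_ratios"):
                    if key == "phantom" and tup in value:
                        value[tup] = tuple(value[tup])
                kwargs[key] = sections[key](**value)
            elif key in ("seed", "sampling_fraction", "threshold"):
                kwargs[key] = value
            else:
                raise ConfigError(f"unknown config section {key!r}")
        return ExperimentConfig(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _derive_seed(base: int, label: str) -> int:
    # zlib.crc32 is stable across processes (str hash is salted per run)
    import zlib

    tag = zlib.crc32(label.encode())
    return int(np.random.SeedSequence([base, tag]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: ExperimentConfig, out_dir) -> Path:
    """Run every stage and return the run directory.

    Writes ``config.yaml``, ``history.json``, ``model.npz``, ``metrics.csv``
    (per-case rows), ``summary.csv`` (mean/sd) and ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        config.to_yaml(out / "config.yaml")
        c = config.cohort
        n_total = c.n_train + c.n_val + c.n_test
        logger.info("stage=phantoms n=%d seed=%d", n_total, config.seed)
        cohort = generate_cohort(
            n_total, c.kind_mix, config.phantom, seed=_derive_seed(config.seed, "cohort")
        )
        train_ph = cohort[: c.n_train]
        val_ph = cohort[c.n_train : c.n_train + c.n_val]
        test_ph = cohort[c.n_train + c.n_val :]

        logger.info("stage=sampling fraction=%.2f", config.sampling_fraction)
        sset = sample_cohort(
            train_ph, config.sampling_fraction, seed=_derive_seed(config.seed, "sampling")
        )
        by_volume = {ph.volume.volume_id: ph for ph in train_ph}
        x3_parts, x2_parts, y_parts = [], [], []
        for vol_id in sorted({vid for vid, _, _ in sset.samples}):
            coords = [c_ for vid, c_, _ in sset.samples if vid == vol_id]
            labels = [lab for vid, _, lab in sset.samples if vid == vol_id]
            x3, x2 = patch_arrays(by_volume[vol_id].volume, coords, config.patches)
            x3_parts.append(x3)
            x2_parts.append(x2)
            y_parts.append(np.array(labels))
        x3 = np.concatenate(x3_parts)
        x2 = np.concatenate(x2_parts)
        y = np.concatenate(y_parts)
        logger.info("stage=train n_samples=%d", len(y))

        model = CFCNN(config.model, seed=_derive_seed(config.seed, "model"))
        tcfg = TrainConfig(
            **{**vars(config.train), "seed": _derive_seed(config.seed, "train")}
        )
        history = train(model, (x3, x2, y), val_ph, tcfg, threshold=config.threshold)
        (out / "history.json").write_text(json.dumps(history, indent=1))
        save_checkpoint(model, out / "model.npz", tcfg)

        logger.info("stage=segment n_test=%d", len(test_ph))
        clf = CfcnnVoxelClassifier(model, config.patches)
        results, gts, spacings = [], [], []
        for ph in test_ph:
            results.append(segment(clf, ph.volume, ph.start_box, config.threshold))
            gts.append(ph.mask)
            spacings.append(ph.volume.spacing)
        table, summary = evaluate_cohort(results, gts, spacings)
        table.insert(1, "volume_id", [ph.volume.volume_id for ph in test_ph])
        table.to_csv(out / "metrics.csv", index=False)
        summary.to_csv(out / "summary.csv")
        logger.info(
            "done mean_dsc=%.4f wall=%.1fs", table["dsc"].mean(), time.time() - t0
        )
        return out
    except Exception:
        logger.exception("pipeline failed; partial outputs kept in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
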