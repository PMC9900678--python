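"""End-to-end experiment orchestration.

One experiment = generate a dataset for a layout, train the network,
reconstruct the test split with both the network and the Tikhonov-Newton
baseline, and evaluate both with the same metric suite.  Every stage derives
its randomness from the experiment's global seed and is logged to a
machine-readable JSON file.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .datasets import Dataset, DatasetManifest, generate_dataset, load_dataset
from .forward import AcquisitionConfig
from .inverse import TikhonovNewton
from .mesh import build_mesh
from .metrics import aggregate, evaluate_split, save_report
from .optics import OpticalProperties
from .periodic_net import PeriodicNet, count_parameters
from .phantoms import PhantomSpec


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    n_sources: int = 16
    n_samples: int = 1000
    epochs: int = 20
    seed: int = 0
    noise_level: float = 0.15
    tr_lambda: float | None = None
    tr_max_iter: int = 10
    tr_samples: int = 3  # TR baseline is slow; invert this many test samples
    out_dir: str = "experiment_out"

    def manifest(self) -> DatasetManifest:
        return DatasetManifest(
            total=self.n_samples, n_sources=self.n_sources, seed=self.seed
        )

    def acquisition(self) -> AcquisitionConfig:
        return AcquisitionConfig(
            n_sources=self.n_sources, noise_level=self.noise_level
        )


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    dataset_path: str
    checkpoint_path: str | None
    network_report: object  # DataFrame
    tr_report: object | None
    param_counts: dict
    log: list = field(default_factory=list)
    status: str = "ok"


def _log(result: ExperimentResult, stage: str, t0: float, **extra) -> None:
    result.log.append(
        {"stage": stage, "seconds": round(time.time() - t0, 2), **extra}
    )


def reconstruct_tr_samples(
    ds: Dataset, acq: AcquisitionConfig, indices, lam, max_iter
) -> list[np.ndarray]:
    """Tikhonov-Newton reconstructions of selected samples, as (2,64,64) stacks."""
    outs = []
    for idx in indices:
        bg = OpticalProperties(
            float(ds.meta["bg_mu_a"][idx]), float(ds.meta["bg_mu_s_prime"][idx])
        )
        spec = PhantomSpec(float(ds.meta["diameter"][idx]),
                           float(ds.meta["frequency_mhz"][idx]), bg)
        mesh = build_mesh(spec, spec.diameter / 12.0, layout_m=acq.n_sources)
        tn = TikhonovNewton(lam=lam, max_iter=max_iter)
        img = tn.reconstruct(
            ds.boundary_data(idx), mesh, acq, bg, spec.frequency_mhz
        )
        outs.append(img.stack())
    return outs


def run_experiment(cfg: ExperimentConfig, progress: bool = False) -> ExperimentResult:
    """Generate -> train -> evaluate (network) and reconstruct -> evaluate (TR)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset_path = out / f"data_{cfg.n_sources}x{cfg.n_sources - 1}.h5"
    acq = cfg.acquisition()
    result = ExperimentResult(cfg, str(dataset_path), None, None, None, {})

    try:
        t0 = time.time()
        generate_dataset(cfg.manifest(), acq, dataset_path, progress=progress)
        _log(result, "generate", t0, samples=cfg.n_samples)
        ds = load_dataset(dataset_path)

        t0 = time.time()
        net = PeriodicNet(
            m=cfg.n_sources, epochs=cfg.epochs, seed=cfg.seed, verbose=progress
        )
        net.fit(ds.inputs("train"), ds.targets("train"),
                ds.inputs("val"), ds.targets("val"))
        ckpt = out / "model.npz"
        net.save(ckpt)
        result.checkpoint_path = str(ckpt)
        _log(result, "train", t0, final_loss=net.history_["train_loss"][-1])

        result.param_counts = asdict(count_parameters(net))

        t0 = time.time()
        pred = net.predict(ds.inputs("test"))
        result.network_report = evaluate_split(
            list(pred), list(ds.targets("test")), label="periodic-net"
        )
        save_report(result.network_report, out / "network_metrics.csv",
                    out / "network_metrics.json")
        _log(result, "evaluate_network", t0)

        if cfg.tr_samples > 0:
            t0 = time.time()
            test_idx = ds.indices("test")[: cfg.tr_samples]
            tr_out = reconstruct_tr_samples(
                ds, acq, test_idx, cfg.tr_lambda, cfg.tr_max_iter
            )
            gts = [ds.ground_truth[i] for i in test_idx]
            result.tr_report = evaluate_split(tr_out, gts, label="tikhonov-newton")
            save_report(result.tr_report, out / "tr_metrics.csv",
                        out / "tr_metrics.json")
            _log(result, "evaluate_tr", t0, samples=len(test_idx))
    except Exception as exc:  # keep partial results
        result.status = f"failed: {exc!r}"

    with open(out / "experiment_log.json", "w") as fh:
        json.dump(
            {
                "config": asdict(cfg),
                "status": result.status,
                "stages": result.log,
                "param_counts": result.param_counts,
                "network_aggregate": aggregate(result.network_report)
                if result.network_report is not None
                else None,
            },
            fh,
            indent=2,
        )
    return result
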