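"""Synthetic FD-DOT dataset assembly.

Each sample is a random circular phantom: its noisy boundary data (stored in
physical units), its 64x64 ground-truth property rasters (physical units),
and its sampling metadata.  Min-max normalization statistics are computed on
the training split only and stored for reuse; splits follow an 85/10/5
train/validation/test division with largest-remainder rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .forward import AcquisitionConfig, BoundaryData, simulate_boundary_data
from .phantoms import GRID, SamplingRanges, rasterize, sample_spec

SPLIT_NAMES = ("train", "val", "test")


def largest_remainder(total: int, fractions) -> list[int]:
    """Integer apportionment of ``total`` by the largest-remainder rule."""
    quotas = [total * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    short = total - sum(counts)
    order = np.argsort([c - q for c, q in zip(counts, quotas)])
    for i in order[:short]:
        counts[i] += 1
    return counts


@dataclass(frozen=True)
class DatasetManifest:
    """What to generate: size, splits, class balance, layout, seed."""

    total: int = 1000
    n_sources: int = 16
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.85, 0.10, 0.05)
    one_to_two_ratio: tuple[int, int] = (44, 55)
    ranges: SamplingRanges = field(default_factory=SamplingRanges)
    mesh_divisions: int = 16  # target edge = diameter / mesh_divisions

    def split_counts(self) -> list[int]:
        return largest_remainder(self.total, self.split_fractions)

    def class_counts(self) -> list[int]:
        a, b = self.one_to_two_ratio
        return largest_remainder(self.total, (a / (a + b), b / (a + b)))


def generate_dataset(
    manifest: DatasetManifest, acq: AcquisitionConfig, path, progress: bool = False
) -> None:
    """Sample phantoms, run the forward solver, and write one HDF5 file.

    Fully reproducible from ``manifest.seed``: phantom geometry, noise and
    the split/class assignment all derive from it.  A phantom whose forward
    solve fails is skipped and a replacement drawn.
    """
    if acq.n_sources != manifest.n_sources:
        raise ValueError("manifest and acquisition layout disagree")
    m = manifest.n_sources
    n = m - 1
    total = manifest.total
    rng = np.random.default_rng(manifest.seed)

    n_one, n_two = manifest.class_counts()
    classes = np.array([1] * n_one + [2] * n_two)
    rng.shuffle(classes)
    split_id = np.concatenate(
        [np.full(c, s) for s, c in enumerate(manifest.split_counts())]
    )
    rng.shuffle(split_id)

    amp = np.empty((total, m, n))
    pha = np.empty((total, m, n))
    gt = np.empty((total, 2, GRID, GRID))
    meta = {
        "diameter": np.empty(total),
        "frequency_mhz": np.empty(total),
        "bg_mu_a": np.empty(total),
        "bg_mu_s_prime": np.empty(total),
        "n_inclusions": classes.astype(np.int64),
        "split": split_id.astype(np.int64),
        "sample_seed": np.empty(total, dtype=np.int64),
    }

    for s in range(total):
        for _attempt in range(20):
            sample_seed = int(rng.integers(0, 2**31 - 1))
            try:
                spec = sample_spec(sample_seed, int(classes[s]), manifest.ranges)
                edge = spec.diameter / manifest.mesh_divisions
                data, _mesh = simulate_boundary_data(
                    spec, acq, edge, noise_seed=sample_seed + 1
                )
                break
            except Exception:  # geometry/solver failure: draw a replacement
                continue
        else:
            raise RuntimeError(f"sample {s}: forward solve kept failing")
        amp[s], pha[s] = data.amplitude, data.phase
        gt[s] = rasterize(spec).stack()
        meta["diameter"][s] = spec.diameter
        meta["frequency_mhz"][s] = spec.frequency_mhz
        meta["bg_mu_a"][s] = spec.background.mu_a
        meta["bg_mu_s_prime"][s] = spec.background.mu_s_prime
        meta["sample_seed"][s] = sample_seed
        if progress and (s + 1) % 100 == 0:
            print(f"  generated {s + 1}/{total}")

    train = split_id == 0
    stats = {
        "amplitude": (float(amp[train].min()), float(amp[train].max())),
        "phase": (float(pha[train].min()), float(pha[train].max())),
        "target_mu_a": (float(gt[train, 0].min()), float(gt[train, 0].max())),
        "target_mu_s_prime": (float(gt[train, 1].min()), float(gt[train, 1].max())),
    }

    with h5py.File(path, "w") as fh:
        fh.attrs.update(
            {
                "m": m,
                "n": n,
                "total": total,
                "seed": manifest.seed,
                "noise_level": acq.noise_level,
                "mesh_divisions": manifest.mesh_divisions,
            }
        )
        b = fh.create_group("boundary")
        b.create_dataset("amplitude", data=amp)
        b.create_dataset("phase", data=pha)
        fh.create_dataset("ground_truth", data=gt)
        g = fh.create_group("spec")
        for k, v in meta.items():
            g.create_dataset(k, data=v)
        ns = fh.create_group("norm_stats")
        for k, (lo, hi) in stats.items():
            ns.create_dataset(k, data=np.array([lo, hi]))


@dataclass
class Dataset:
    """In-memory view of a generated dataset file."""

    amplitude: np.ndarray  # (S, m, n) physical, noisy
    phase: np.ndarray
    ground_truth: np.ndarray  # (S, 2, 64, 64) physical units
    split: np.ndarray  # 0 train / 1 val / 2 test
    meta: dict
    norm_stats: dict
    attrs: dict

    @property
    def m(self) -> int:
        return int(self.attrs["m"])

    def indices(self, split: str) -> np.ndarray:
        return np.nonzero(self.split == SPLIT_NAMES.index(split))[0]

    def inputs(self, split: str | None = None) -> np.ndarray:
        """Normalized (S, 2, m, n) network inputs (train-split min-max, clipped)."""
        idx = slice(None) if split is None else self.indices(split)
        out = np.empty((np.shape(self.amplitude[idx])[0], 2) + self.amplitude.shape[1:])
        for c, (arr, key) in enumerate(
            ((self.amplitude, "amplitude"), (self.phase, "phase"))
        ):
            lo, hi = self.norm_stats[key]
            out[:, c] = np.clip((arr[idx] - lo) / (hi - lo), 0.0, 1.0)
        return out

    def targets(self, split: str | None = None) -> np.ndarray:
        """Normalized (S, 2, 64, 64) training targets (train-split min-max)."""
        idx = slice(None) if split is None else self.indices(split)
        out = np.empty_like(self.ground_truth[idx])
        for c, key in enumerate(("target_mu_a", "target_mu_s_prime")):
            lo, hi = self.norm_stats[key]
            out[:, c] = (self.ground_truth[idx, c] - lo) / (hi - lo)
        return out

    def denormalize_targets(self, y: np.ndarray) -> np.ndarray:
        """Map normalized predictions back to physical units."""
        out = np.empty_like(y)
        for c, key in enumerate(("target_mu_a", "target_mu_s_prime")):
            lo, hi = self.norm_stats[key]
            out[:, c] = y[:, c] * (hi - lo) + lo
        return out

    def boundary_data(self, index: int) -> BoundaryData:
        return BoundaryData(self.amplitude[index], self.phase[index], noisy=True)


def load_dataset(path) -> Dataset:
    with h5py.File(path, "r") as fh:
        return Dataset(
            amplitude=fh["boundary/amplitude"][:],
            phase=fh["boundary/phase"][:],
            ground_truth=fh["ground_truth"][:],
            split=fh["spec/split"][:],
            meta={k: fh["spec"][k][:] for k in fh["spec"]},
            norm_stats={k: tuple(fh["norm_stats"][k][:]) for k in fh["norm_stats"]},
            attrs=dict(fh.attrs),
        )
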