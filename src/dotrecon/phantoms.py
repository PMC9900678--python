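"""Random circular-phantom specifications and ground-truth rasters.

Phantoms are disks (60-150 mm diameter) with one or two disjoint circular
inclusions of elevated absorption/scattering, probed at a modulation
frequency in the 10-100 MHz band.  Ground truth is rasterized on a 64x64
grid spanning the phantom's bounding square.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .optics import OpticalProperties

GRID = 64


class SamplingError(RuntimeError):
    """Raised when rejection sampling cannot place the requested inclusions."""


@dataclass(frozen=True)
class Inclusion:
    """One circular inclusion: center (mm, phantom-centred coords), radius (mm), properties."""

    center: tuple[float, float]
    radius: float
    props: OpticalProperties


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one simulated phantom."""

    diameter: float
    frequency_mhz: float
    background: OpticalProperties
    inclusions: tuple[Inclusion, ...] = ()
    seed: int | None = None

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def validate(self) -> None:
        if not (self.diameter > 0):
            raise ValueError("diameter must be positive")
        if self.frequency_mhz < 0:
            raise ValueError("frequency must be nonnegative")
        R = self.radius
        for a, inc in enumerate(self.inclusions):
            if np.hypot(*inc.center) + inc.radius >= R:
                raise ValueError(f"inclusion {a} not strictly inside the phantom")
            for b in range(a + 1, len(self.inclusions)):
                o = self.inclusions[b]
                d = np.hypot(inc.center[0] - o.center[0], inc.center[1] - o.center[1])
                if d <= inc.radius + o.radius:
                    raise ValueError(f"inclusions {a} and {b} are not disjoint")


@dataclass(frozen=True)
class SamplingRanges:
    """Uniform sampling ranges for random phantoms.

    Defaults are the study conditions: diameters 60-150 mm, modulation
    frequencies 10-100 MHz, background mu_a in 0.005-0.03 mm^-1 and
    mu_s' in 0.05-3 mm^-1.  Inclusion radii span 2.5-15 mm (clamped so the
    disk fits with a 2 mm margin) and inclusion properties are the background
    scaled by an independent 1.2-4x contrast per coefficient.
    """

    diameter: tuple[float, float] = (60.0, 150.0)
    frequency_mhz: tuple[float, float] = (10.0, 100.0)
    mu_a: tuple[float, float] = (0.005, 0.03)
    mu_s_prime: tuple[float, float] = (0.05, 3.0)
    inclusion_radius: tuple[float, float] = (2.5, 15.0)
    contrast: tuple[float, float] = (1.2, 4.0)
    margin: float = 2.0


def sample_spec(
    rng: int | np.random.Generator,
    n_inclusions: int,
    ranges: SamplingRanges | None = None,
    max_attempts: int = 1000,
) -> PhantomSpec:
    """Draw one random phantom specification.

    Geometry is rejection-sampled until the inclusions are mutually disjoint;
    after ``max_attempts`` failures a :class:`SamplingError` is raised.
    """
    if n_inclusions not in (0, 1, 2):
        raise ValueError("n_inclusions must be 0, 1 or 2")
    r = ranges or SamplingRanges()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng

    diameter = gen.uniform(*r.diameter)
    R = diameter / 2.0
    frequency = gen.uniform(*r.frequency_mhz)
    bg = OpticalProperties(gen.uniform(*r.mu_a), gen.uniform(*r.mu_s_prime))

    r_hi_fit = R - r.margin - 0.5  # leave room for a nonempty center region
    lo = min(r.inclusion_radius[0], r_hi_fit)
    hi = min(r.inclusion_radius[1], r_hi_fit)

    for _ in range(max_attempts):
        incs: list[Inclusion] = []
        for _k in range(n_inclusions):
            rad = gen.uniform(lo, hi)
            c_max = R - r.margin - rad
            # uniform over the admissible disk of centres
            rho = c_max * np.sqrt(gen.uniform())
            theta = gen.uniform(0.0, 2.0 * np.pi)
            props = bg.scaled(gen.uniform(*r.contrast), gen.uniform(*r.contrast))
            incs.append(Inclusion((rho * np.cos(theta), rho * np.sin(theta)), rad, props))
        ok = True
        for a in range(len(incs)):
            for b in range(a + 1, len(incs)):
                d = np.hypot(
                    incs[a].center[0] - incs[b].center[0],
                    incs[a].center[1] - incs[b].center[1],
                )
                if d <= incs[a].radius + incs[b].radius + 1.0:  # 1 mm separation
                    ok = False
        if ok:
            return PhantomSpec(diameter, frequency, bg, tuple(incs), seed=seed)
    raise SamplingError(f"could not place {n_inclusions} disjoint inclusions")


@dataclass
class PropertyImage:
    """Pair of 64x64 optical-property rasters on the phantom bounding square.

    ``mu_a`` and ``mu_s_prime`` are in physical units (mm^-1); pixels outside
    the phantom circle are zero and flagged off in ``mask``.
    """

    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    pixel_size: float
    mask: np.ndarray = field(repr=False)

    def stack(self) -> np.ndarray:
        """(2, 64, 64) array, channel 0 = mu_a, channel 1 = mu_s'."""
        return np.stack([self.mu_a, self.mu_s_prime])


def rasterize(spec: PhantomSpec, grid: int = GRID) -> PropertyImage:
    """Rasterize ground truth by pixel-centre region membership.

    The raster covers the bounding square exactly: ``pixel_size =
    diameter/grid`` with pixel centres at ``-R + (i + 1/2) * pixel_size``.
    """
    R = spec.radius
    px = spec.diameter / grid
    coords = -R + (np.arange(grid) + 0.5) * px
    X, Y = np.meshgrid(coords, coords, indexing="xy")
    mask = X**2 + Y**2 <= R**2

    mu_a = np.where(mask, spec.background.mu_a, 0.0)
    mu_s = np.where(mask, spec.background.mu_s_prime, 0.0)
    for inc in spec.inclusions:
        inside = (X - inc.center[0]) ** 2 + (Y - inc.center[1]) ** 2 <= inc.radius**2
        mu_a = np.where(inside, inc.props.mu_a, mu_a)
        mu_s = np.where(inside, inc.props.mu_s_prime, mu_s)
    return PropertyImage(mu_a, mu_s, px, mask)


def homogeneous_like(spec: PhantomSpec) -> PhantomSpec:
    """The same phantom with its inclusions removed (homogeneous background)."""
    return replace(spec, inclusions=())
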