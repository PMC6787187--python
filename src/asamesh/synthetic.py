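"""Synthetic inputs: seeded vessel scenes with ground truth, and analytic
mechanical oracles.

The vessel-scene generator emulates the three-channel content of a stained
cross-section: a ``green`` channel of lumen disks (endothelial marker), a
``red`` channel filling the lumina flagged as blood-perfused, and an
``sma`` channel of perimeter annuli on the lumina flagged as
perivascular-covered.  Placement is hard-core (no overlapping lumina) so
connected-component counting is unambiguous, and every statistic the
quantification module measures is recorded as ground truth at generation
time.  Default scene parameters mirror the in-vivo measurement context the
statistics come from: ~220 vessels per mm^2, ~50% perfusion and ~65% PVC
coverage.

The mechanical oracle solves the homogeneous (spatially uniform) isotropic
contraction of the active material in closed scalar form, providing an
independent check of the finite-element solver on a pillar-free domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from skimage.draw import disk as draw_disk

from .errors import PlacementError
from .geometry import PillarLayout, build_square_layout
from .imagequant import QuantImage
from .mechanics import ACTIVE_PRESSURE, MaterialParams


@dataclass(frozen=True)
class VesselSceneSpec:
    """Parameters of one synthetic vessel scene (all randomness from seed)."""

    roi_mm: tuple[float, float] = (1.0, 1.0)
    pixel_size_um: float = 2.0
    n_vessels: int = 220
    radius_mean_um: float = 8.0
    radius_sigma: float = 0.0  # sigma of ln(radius); 0 = monodisperse
    perfused_fraction: float = 0.504
    pvc_fraction: float = 0.65
    ring_px: int = 2
    margin_px: int = 3
    noise: float = 0.0  # gaussian noise sigma relative to unit signal
    blur_sigma_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.perfused_fraction <= 1.0):
            raise ValueError("perfused_fraction must lie in [0, 1]")
        if not (0.0 <= self.pvc_fraction <= 1.0):
            raise ValueError("pvc_fraction must lie in [0, 1]")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (int(round(self.roi_mm[1] * 1000.0 / self.pixel_size_um)),
                int(round(self.roi_mm[0] * 1000.0 / self.pixel_size_um)))


@dataclass
class GroundTruth:
    """Per-vessel plant record plus the exact statistics of the drawn masks."""

    centers_px: np.ndarray  # (n, 2) row, col
    radii_px: np.ndarray
    perfused: np.ndarray  # bool flags
    pvc: np.ndarray  # bool flags
    n_vessels: int
    density_mm2: float
    area_fraction_pct: float
    perfused_pixel_pct: float
    perfused_count_pct: float
    pvc_count_pct: float


def generate_vessel_image(spec: VesselSceneSpec) -> tuple[QuantImage, GroundTruth]:
    """Draw a seeded vessel scene and its ground truth.

    Raises :class:`PlacementError` when hard-core placement cannot fit a
    vessel within 10^4 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    n = spec.n_vessels

    if spec.radius_sigma > 0:
        radii_um = rng.lognormal(np.log(spec.radius_mean_um), spec.radius_sigma, n)
    else:
        radii_um = np.full(n, float(spec.radius_mean_um))
    radii_px = np.maximum(radii_um / spec.pixel_size_um, 1.0)

    centers = np.empty((n, 2))
    pad = spec.ring_px + spec.margin_px
    for i in range(n):
        r = radii_px[i]
        placed = False
        for _ in range(10_000):
            c = rng.uniform([r + pad, r + pad],
                            [shape[0] - r - pad, shape[1] - r - pad])
            if i == 0:
                placed = True
                break
            d = np.linalg.norm(centers[:i] - c, axis=1)
            if np.all(d > radii_px[:i] + r + 2 * spec.ring_px + spec.margin_px):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place vessel {i} of {n} after 10^4 hard-core attempts"
            )
        centers[i] = c

    k_perf = int(round(spec.perfused_fraction * n))
    k_pvc = int(round(spec.pvc_fraction * n))
    order = rng.permutation(n)
    perfused = np.zeros(n, dtype=bool)
    perfused[order[:k_perf]] = True
    order2 = rng.permutation(n)
    pvc = np.zeros(n, dtype=bool)
    pvc[order2[:k_pvc]] = True

    green = np.zeros(shape, dtype=bool)
    red = np.zeros(shape, dtype=bool)
    sma = np.zeros(shape, dtype=bool)
    for i in range(n):
        rr, cc = draw_disk(tuple(centers[i]), radii_px[i], shape=shape)
        green[rr, cc] = True
        if perfused[i]:
            red[rr, cc] = True
        if pvc[i]:
            rr2, cc2 = draw_disk(tuple(centers[i]), radii_px[i] + spec.ring_px,
                                 shape=shape)
            ring = np.zeros(shape, dtype=bool)
            ring[rr2, cc2] = True
            ring[rr, cc] = False
            sma |= ring

    roi_mm2 = spec.roi_mm[0] * spec.roi_mm[1]
    g_area = float(green.sum())
    truth = GroundTruth(
        centers_px=centers, radii_px=radii_px, perfused=perfused, pvc=pvc,
        n_vessels=n,
        density_mm2=n / roi_mm2,
        area_fraction_pct=100.0 * g_area / green.size,
        perfused_pixel_pct=(100.0 * float((green & red).sum()) / g_area
                            if g_area else np.nan),
        perfused_count_pct=100.0 * k_perf / n if n else np.nan,
        pvc_count_pct=100.0 * k_pvc / n if n else np.nan,
    )

    if spec.noise > 0 or spec.blur_sigma_px > 0:
        channels = {}
        for name, mask in (("green", green), ("red", red), ("sma", sma)):
            img = mask.astype(float)
            if spec.blur_sigma_px > 0:
                img = gaussian_filter(img, spec.blur_sigma_px)
            if spec.noise > 0:
                img = img + rng.normal(0.0, spec.noise, shape)
            channels[name] = img
    else:
        channels = {"green": green, "red": red, "sma": sma}

    image = QuantImage(channels=channels, pixel_size=spec.pixel_size_um)
    return image, truth


def homogeneous_contraction_oracle(mat: MaterialParams, eta: float) -> float:
    """Isotropic stretch of a freely contracting homogeneous tissue.

    Solves the scalar stress-free equilibrium

        mu (lbar^2 - 1) / lbar^3 + 3 lam ln(lbar) / lbar^3 + eta beta = 0

    for lbar in (0, 1] by bracketed root finding (active_pressure mode).
    In as_printed mode the undeformed state is the equilibrium, so 1 is
    returned exactly.
    """
    if mat.active_mode != ACTIVE_PRESSURE:
        return 1.0
    if eta == 0:
        return 1.0

    def f(lb):
        return (mat.mu * (lb * lb - 1.0) + 3.0 * mat.lam * np.log(lb)) / lb**3 \
            + eta * mat.beta

    return float(brentq(f, 1e-3, 1.0, xtol=1e-12, rtol=1e-14, maxiter=200))


@dataclass
class BenchmarkSuite:
    """Canonical deterministic fixtures for solver validation."""

    layout_4x4: PillarLayout
    layout_2x2: PillarLayout
    square_free: PillarLayout  # pillar-free square domain
    material: MaterialParams


def make_benchmark_suite(out_dir: str | Path | None = None) -> BenchmarkSuite:
    """Build the canonical fixtures: 4x4 and 2x2 layouts (d = 400 um,
    interval 200 um) and a pillar-free 1000 um square, with the calibrated
    material parameters.  If ``out_dir`` is given, matching TOML config
    files are written there."""
    layout44 = build_square_layout(4, 4, 400.0, 200.0)
    layout22 = build_square_layout(2, 2, 400.0, 200.0)
    free = PillarLayout(centers=np.zeros((0, 2)), radius=200.0, height=200.0,
                        substrate_bounds=(0.0, 0.0, 1000.0, 1000.0),
                        lattice_kind="custom")
    mat = MaterialParams()
    suite = BenchmarkSuite(layout_4x4=layout44, layout_2x2=layout22,
                           square_free=free, material=mat)
    if out_dir is not None:
        from .config import default_config_toml

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "benchmark_4x4.toml").write_text(default_config_toml(4, 4))
        (out / "benchmark_2x2.toml").write_text(default_config_toml(2, 2))
    return suite
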