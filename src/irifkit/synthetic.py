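"""Synthetic confocal stacks and SMLM point patterns with ground truth.

The image model deliberately keeps only the structure the downstream
detectors are sensitive to: nuclei are homogeneous ellipsoids in the
counterstain channel, repair foci are additive 3D Gaussian blobs in the two
signal channels (anisotropic: one in-plane sigma, one axial sigma), and
noise is Poisson shot noise plus Gaussian read noise. Optics-accurate PSF
simulation and fluorophore photokinetics are out of scope.

Degree of colocalization between the two signal channels is a controllable
dial: each focus renders its channel-B blob displaced from its channel-A
blob by ``channel_offset_um`` along x (offset 0 = perfect colocalization).

The default stack geometry mirrors the acquisition this package targets:
50 optical sections at 0.3 µm z-spacing with ~0.065 µm xy pixel pitch.

Point patterns for the nanoscale analysis follow a Neyman--Scott
construction: cluster centres uniform in a rectangle, offspring scattered
around them with an isotropic Gaussian, plus a uniform background
component; ``background_fraction = 1`` degenerates to complete spatial
randomness (CSR).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from irifkit.stack_io import OrteMatrix, VolumeStack

CHANNELS = ("dapi", "chA", "chB")

#: linear xy enlargement of G2 nuclei relative to G1 (G2 cells have ~2N->4N
#: DNA content and visibly larger nuclei)
G2_XY_SCALE = 1.3

#: G2 cells carry roughly twice the radiation-induced focus count of G1 cells
G2_COUNT_FACTOR = 2.0


@dataclass(frozen=True)
class StackGeometry:
    """Shape and voxel sizes of a rendered stack."""

    shape: tuple[int, int, int] = (50, 128, 128)  # (z, y, x)
    voxel_size: tuple[float, float, float] = (0.3, 0.065, 0.065)  # µm

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("stack geometry must be strictly positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))


@dataclass(frozen=True)
class NoiseModel:
    """Poisson shot noise on the rendered intensity plus Gaussian read noise."""

    shot: bool = True
    read_sigma: float = 3.0

    def apply(self, signal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = signal
        if self.shot:
            out = rng.poisson(np.clip(out, 0.0, None)).astype(float)
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return out


NOISELESS = NoiseModel(shot=False, read_sigma=0.0)


@dataclass(frozen=True)
class NucleusSpec:
    """An ellipsoidal nucleus.

    ``center`` is in voxel coordinates (z, y, x); ``semi_axes`` in µm per
    axis (z, y, x). ``base_intensity`` maps channel name to the homogeneous
    intensity rendered inside the nucleus.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    base_intensity: dict[str, float] = field(
        default_factory=lambda: {"dapi": 400.0, "chA": 40.0, "chB": 40.0}
    )
    cycle_phase: str = "G1"

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be strictly positive")
        if self.cycle_phase not in ("G1", "G2"):
            raise ValueError(f"cycle_phase must be G1 or G2, got {self.cycle_phase!r}")


@dataclass(frozen=True)
class FocusSpec:
    """A repair focus rendered as a 3D Gaussian blob in both signal channels.

    ``center`` is in voxel coordinates (z, y, x) and must lie inside the
    nucleus identified by ``nucleus_id`` (1-based). ``channel_offset_um``
    displaces the channel-B blob along +x.
    """

    center: tuple[float, float, float]
    nucleus_id: int
    sigma_xy_um: float = 0.25
    sigma_z_um: float = 0.35
    amplitude_chA: float = 200.0
    amplitude_chB: float = 200.0
    channel_offset_um: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_xy_um <= 0 or self.sigma_z_um <= 0:
            raise ValueError("focus sigma must be > 0")
        if self.channel_offset_um < 0:
            raise ValueError("channel_offset_um must be >= 0")


@dataclass(frozen=True)
class PointPatternSpec:
    """Neyman--Scott cluster pattern in a 2D rectangle (nm)."""

    region: tuple[float, float] = (3000.0, 3000.0)  # (width, height) nm
    n_clusters: int = 30
    offspring_per_cluster: int = 40
    cluster_sigma_nm: float = 25.0
    background_fraction: float = 0.1
    seed: int = 0
    channel: str = "gH2AX"

    def __post_init__(self) -> None:
        if self.region[0] * self.region[1] <= 0:
            raise ValueError("region area must be > 0")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if self.cluster_sigma_nm <= 0:
            raise ValueError("cluster_sigma_nm must be > 0")


# ---------------------------------------------------------------------------
# rendering


def ellipsoid_mask(spec: NucleusSpec, geometry: StackGeometry) -> np.ndarray:
    """Analytic boolean mask of the nucleus ellipsoid (the segmentation oracle)."""
    zz, yy, xx = np.indices(geometry.shape, dtype=float)
    dz, dy, dx = geometry.voxel_size
    cz, cy, cx = spec.center
    az, ay, ax = spec.semi_axes
    q = (
        ((zz - cz) * dz / az) ** 2
        + ((yy - cy) * dy / ay) ** 2
        + ((xx - cx) * dx / ax) ** 2
    )
    return q <= 1.0


def point_in_nucleus(point: tuple[float, float, float], spec: NucleusSpec,
                     geometry: StackGeometry) -> bool:
    dz, dy, dx = geometry.voxel_size
    cz, cy, cx = spec.center
    az, ay, ax = spec.semi_axes
    pz, py, px = point
    return (
        ((pz - cz) * dz / az) ** 2
        + ((py - cy) * dy / ay) ** 2
        + ((px - cx) * dx / ax) ** 2
    ) <= 1.0


def _render_blob(volume: np.ndarray, center: tuple[float, float, float],
                 sigma_vox: tuple[float, float, float], amplitude: float) -> None:
    """Add an anisotropic Gaussian blob in-place, windowed to ±4 sigma."""
    shape = volume.shape
    lo = [max(0, int(np.floor(c - 4 * s))) for c, s in zip(center, sigma_vox)]
    hi = [min(n, int(np.ceil(c + 4 * s)) + 1) for n, c, s in zip(shape, center, sigma_vox)]
    if any(a >= b for a, b in zip(lo, hi)):
        return
    grids = np.meshgrid(
        *[np.arange(a, b, dtype=float) for a, b in zip(lo, hi)], indexing="ij"
    )
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sigma_vox))
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-0.5 * q)


def generate_nucleus_stack(
    nuclei: list[NucleusSpec],
    foci: list[FocusSpec],
    geometry: StackGeometry = StackGeometry(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
) -> tuple[VolumeStack, pd.DataFrame]:
    """Render a 3-channel stack (counterstain, channel A, channel B).

    Every focus must reference an existing nucleus and lie inside its
    ellipsoid; a violating focus is rejected with an error naming its index.
    Returns the stack and a ground-truth table with one row per focus
    (positions both in voxels and µm).
    """
    rng = np.random.default_rng(seed)
    for i, f in enumerate(foci):
        if not 1 <= f.nucleus_id <= len(nuclei):
            raise ValueError(f"focus {i}: nucleus_id {f.nucleus_id} does not exist")
        if not point_in_nucleus(f.center, nuclei[f.nucleus_id - 1], geometry):
            raise ValueError(f"focus {i}: center {f.center} outside nucleus {f.nucleus_id}")

    channels = {name: np.zeros(geometry.shape, dtype=float) for name in CHANNELS}
    for spec in nuclei:
        mask = ellipsoid_mask(spec, geometry)
        for name in CHANNELS:
            channels[name][mask] += spec.base_intensity.get(name, 0.0)

    dz, dy, dx = geometry.voxel_size
    rows = []
    for i, f in enumerate(foci):
        sigma_vox = (f.sigma_z_um / dz, f.sigma_xy_um / dy, f.sigma_xy_um / dx)
        _render_blob(channels["chA"], f.center, sigma_vox, f.amplitude_chA)
        center_b = (f.center[0], f.center[1], f.center[2] + f.channel_offset_um / dx)
        _render_blob(channels["chB"], center_b, sigma_vox, f.amplitude_chB)
        cz, cy, cx = f.center
        rows.append(
            {
                "focus_id": i + 1,
                "nucleus_id": f.nucleus_id,
                "z_vox": cz, "y_vox": cy, "x_vox": cx,
                "z_um": (cz + 0.5) * dz, "y_um": (cy + 0.5) * dy, "x_um": (cx + 0.5) * dx,
                "sigma_xy_um": f.sigma_xy_um, "sigma_z_um": f.sigma_z_um,
                "amplitude_chA": f.amplitude_chA, "amplitude_chB": f.amplitude_chB,
                "channel_offset_um": f.channel_offset_um,
                "phase": nuclei[f.nucleus_id - 1].cycle_phase,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "focus_id", "nucleus_id", "z_vox", "y_vox", "x_vox", "z_um", "y_um",
            "x_um", "sigma_xy_um", "sigma_z_um", "amplitude_chA", "amplitude_chB",
            "channel_offset_um", "phase",
        ],
    )
    data = np.stack([noise.apply(channels[name], rng) for name in CHANNELS])
    stack = VolumeStack(data=data, voxel_size=geometry.voxel_size, channel_names=CHANNELS)
    return stack, truth


def sample_focus_centers(
    nucleus: NucleusSpec,
    n: int,
    rng: np.random.Generator,
    geometry: StackGeometry = StackGeometry(),
    min_separation_um: float = 0.0,
    margin: float = 0.75,
    max_tries: int = 20000,
) -> list[tuple[float, float, float]]:
    """Rejection-sample *n* focus centres inside a shrunk copy of the nucleus.

    ``margin`` scales the semi-axes so blobs stay clear of the nuclear rim;
    ``min_separation_um`` enforces a pairwise physical distance.
    """
    inner = replace(nucleus, semi_axes=tuple(a * margin for a in nucleus.semi_axes))
    dz, dy, dx = geometry.voxel_size
    cz, cy, cx = nucleus.center
    az, ay, ax = inner.semi_axes
    centers: list[tuple[float, float, float]] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        u = rng.uniform(-1.0, 1.0, size=3)
        if (u ** 2).sum() > 1.0:
            continue
        cand = (cz + u[0] * az / dz, cy + u[1] * ay / dy, cx + u[2] * ax / dx)
        if min_separation_um > 0:
            ok = all(
                np.hypot(
                    np.hypot((cand[0] - c[0]) * dz, (cand[1] - c[1]) * dy),
                    (cand[2] - c[2]) * dx,
                )
                >= min_separation_um
                for c in centers
            )
            if not ok:
                continue
        centers.append(cand)
    if len(centers) < n:
        raise RuntimeError(
            f"could not place {n} foci at separation {min_separation_um} µm "
            f"inside the nucleus after {max_tries} tries"
        )
    return centers


# ---------------------------------------------------------------------------
# populations


def _nucleus_for_phase(phase: str, geometry: StackGeometry, rng: np.random.Generator) -> NucleusSpec:
    nz, ny, nx = geometry.shape
    semi_g1 = (2.2, 2.9, 2.9)  # µm, SkBr3-like nucleus fitting the field of view
    scale = (1.0, G2_XY_SCALE, G2_XY_SCALE) if phase == "G2" else (1.0, 1.0, 1.0)
    semi = tuple(a * s for a, s in zip(semi_g1, scale))
    jitter = rng.uniform(-2.0, 2.0, size=3)
    center = (nz / 2 - 0.5 + jitter[0], ny / 2 - 0.5 + jitter[1], nx / 2 - 0.5 + jitter[2])
    return NucleusSpec(center=center, semi_axes=semi, cycle_phase=phase)


def generate_population(
    n_cells: int,
    dose: float,
    focus_rate_per_Gy: float = 5.0,
    g2_fraction: float = 0.3,
    background_rate: float = 0.5,
    seed: int = 0,
    geometry: StackGeometry = StackGeometry(),
) -> tuple[list[tuple[NucleusSpec, list[FocusSpec]]], pd.DataFrame]:
    """Simulate a mixed G1/G2 cell population (one nucleus per stack).

    Per-cell focus counts are Poisson with mean
    ``background_rate + dose * focus_rate_per_Gy`` for G1 cells and twice
    that for G2 cells, whose nuclei are also enlarged in xy. Returns the
    per-cell specs (render each with :func:`generate_nucleus_stack`) and
    the ground-truth table (cell id, phase, count).
    """
    if dose < 0 or focus_rate_per_Gy < 0 or background_rate < 0:
        raise ValueError("dose and rates must be >= 0")
    if not 0.0 <= g2_fraction <= 1.0:
        raise ValueError(f"g2_fraction must be in [0, 1], got {g2_fraction}")
    rng = np.random.default_rng(seed)
    mean_g1 = background_rate + dose * focus_rate_per_Gy
    cells = []
    rows = []
    for cell_id in range(1, n_cells + 1):
        phase = "G2" if rng.random() < g2_fraction else "G1"
        mean = mean_g1 * (G2_COUNT_FACTOR if phase == "G2" else 1.0)
        count = int(rng.poisson(mean))
        nucleus = _nucleus_for_phase(phase, geometry, rng)
        centers = sample_focus_centers(nucleus, count, rng, geometry, min_separation_um=0.4)
        foci = [FocusSpec(center=c, nucleus_id=1) for c in centers]
        cells.append((nucleus, foci))
        rows.append({"cell_id": cell_id, "phase": phase, "n_foci": count, "mean": mean})
    truth = pd.DataFrame(rows, columns=["cell_id", "phase", "n_foci", "mean"])
    return cells, truth


def generate_benchmark_population(
    n_cells: int,
    n_foci: int,
    min_separation_um: float = 1.0,
    seed: int = 0,
    geometry: StackGeometry = StackGeometry(),
    channel_offset_um: float = 0.0,
) -> list[tuple[NucleusSpec, list[FocusSpec]]]:
    """Cells with a fixed, well-separated focus count (detector benchmark)."""
    rng = np.random.default_rng(seed)
    cells = []
    for _ in range(n_cells):
        nucleus = _nucleus_for_phase("G1", geometry, rng)
        centers = sample_focus_centers(
            nucleus, n_foci, rng, geometry, min_separation_um=min_separation_um
        )
        foci = [
            FocusSpec(center=c, nucleus_id=1, channel_offset_um=channel_offset_um)
            for c in centers
        ]
        cells.append((nucleus, foci))
    return cells


# ---------------------------------------------------------------------------
# SMLM point patterns


def generate_smlm_pattern(spec: PointPatternSpec) -> OrteMatrix:
    """Draw a Neyman--Scott (or CSR, if ``background_fraction = 1``) pattern.

    The total localization count is ``n_clusters * offspring_per_cluster``;
    a ``background_fraction`` share of it is re-assigned to the uniform
    background component. Offspring may scatter slightly beyond the region
    boundary; the region constrains cluster centres and background points.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.region
    n_total = spec.n_clusters * spec.offspring_per_cluster
    n_bg = int(round(spec.background_fraction * n_total))
    n_clustered = n_total - n_bg

    pts = []
    if n_clustered > 0:
        centers = rng.uniform([0, 0], [w, h], size=(spec.n_clusters, 2))
        alloc = rng.multinomial(n_clustered, np.full(spec.n_clusters, 1.0 / spec.n_clusters))
        for center, k in zip(centers, alloc):
            if k:
                pts.append(center + rng.normal(0.0, spec.cluster_sigma_nm, size=(k, 2)))
    if n_bg > 0:
        pts.append(rng.uniform([0, 0], [w, h], size=(n_bg, 2)))
    xy = np.concatenate(pts, axis=0) if pts else np.empty((0, 2))

    precision = np.clip(rng.normal(10.0, 1.5, size=len(xy)), 2.0, None)
    df = pd.DataFrame(
        {
            "x_nm": xy[:, 0],
            "y_nm": xy[:, 1],
            "z_section": np.zeros(len(xy), dtype=int),
            "frame": rng.integers(0, 2000, size=len(xy)),
            "precision_nm": precision,
            "channel": spec.channel,
        }
    )
    return OrteMatrix(df=df)
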