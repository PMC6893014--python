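"""Shared domain types for the telomere 3D quantification pipeline.

Conventions used throughout the package:

* Image arrays are ordered ``(z, y, x)`` — Z is the slowest axis, matching
  the page order of multi-page TIFF stacks.
* Physical coordinates are in micrometres, with the origin at the stack
  corner and the centre of voxel ``(i, j, k)`` at ``((i + 0.5) * dz,
  (j + 0.5) * dy, (k + 0.5) * dx)``.  Indices are 0-based.
* Intensities are camera counts (integer on raw stacks, floating point on
  corrected/restored stacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel size in micrometres.

    Defaults are the acquisition sampling of the reference system: 108 nm
    laterally (camera pixel size) and 100 nm axially (z-step).
    """

    dx: float = 0.108
    dy: float = 0.108
    dz: float = 0.100

    def __post_init__(self) -> None:
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel spacing must be positive")

    @property
    def zyx(self) -> tuple[float, float, float]:
        return (self.dz, self.dy, self.dx)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in µm³."""
        return self.dx * self.dy * self.dz


@dataclass(frozen=True)
class OpticsModel:
    """Point-spread-function description of the wide-field system.

    The PSF is modelled as a separable anisotropic Gaussian.  The default
    full widths at half maximum are the theoretical lateral (220 nm) and
    axial (660 nm) resolutions of a 1.4 NA oil objective at 647 nm
    emission, i.e. a 3x elongation along Z.
    """

    lateral_fwhm: float = 220.0  # nm
    axial_fwhm: float = 660.0  # nm
    emission_wavelength: float = 647.0  # nm
    numerical_aperture: float = 1.4

    def __post_init__(self) -> None:
        if self.lateral_fwhm <= 0 or self.axial_fwhm <= 0:
            raise ValueError("PSF FWHMs must be positive")

    @property
    def axial_ratio(self) -> float:
        return self.axial_fwhm / self.lateral_fwhm

    def sigmas_um(self) -> tuple[float, float, float]:
        """Gaussian sigmas (z, y, x) in µm."""
        s_lat = self.lateral_fwhm * FWHM_TO_SIGMA * 1e-3
        s_ax = self.axial_fwhm * FWHM_TO_SIGMA * 1e-3
        return (s_ax, s_lat, s_lat)


@dataclass(frozen=True)
class CameraModel:
    """Detector model: bit depth, dark offset, read noise, gain, vignetting.

    ``vignetting_strength`` is the fractional fall-off of the illumination
    field far from the optical axis; ``vignetting_sigma`` is the Gaussian
    width of the field in µm.  A 12-bit readout (0..4095) is the default;
    the dark offset defaults to 6 counts.
    """

    bit_depth: int = 12
    dark_offset: float = 6.0
    read_noise_sd: float = 1.0
    photon_gain: float = 1.0  # counts per detected photon
    vignetting_strength: float = 0.3
    vignetting_sigma: float = 20.0  # µm

    def __post_init__(self) -> None:
        if not (0 <= self.vignetting_strength < 1):
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.bit_depth < 1:
            raise ValueError("bit_depth must be >= 1")

    @property
    def max_gray(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class NucleusSpec:
    """Ground-truth description of one simulated interphase nucleus.

    A diploid human G1 nucleus carries 92 telomeres (2 per end of 46
    chromosomes), hence the default ``n_telomeres``.  Telomere lengths are
    drawn from ``telomere_length_dist`` (kb); emitted flux is proportional
    to length.  ``cluster_fraction`` of the telomeres are placed in
    sub-resolution pairs separated by ``cluster_distance``.
    ``dna_content_scale`` is 1 for G1 and 2 for G2 DNA content.
    """

    n_telomeres: int = 92
    telomere_length_dist: tuple[float, float, str] = (5.3, 1.6, "lognormal")
    cluster_fraction: float = 0.0
    cluster_distance: float = 0.1  # µm, sub-resolution
    nucleus_semi_axes: tuple[float, float, float] = (7.0, 5.0, 1.2)  # µm (x, y, z)
    min_separation: float = 0.5  # µm between distinct emitter sites
    dna_content_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_telomeres < 0:
            raise ValueError("n_telomeres must be >= 0")
        if not (0 <= self.cluster_fraction <= 1):
            raise ValueError("cluster_fraction must be in [0, 1]")

    @property
    def n_paired(self) -> int:
        """Number of telomeres placed in pairs (rounded to an even count)."""
        return 2 * int(round(self.cluster_fraction * self.n_telomeres / 2.0))


TRUTH_COLUMNS = ["nucleus_id", "telomere_id", "x_um", "y_um", "z_um", "length_kb", "cluster_id"]


@dataclass
class GroundTruth:
    """Simulator-emitted truth table.

    ``telomeres`` has one row per telomere with columns
    ``nucleus_id, telomere_id, x_um, y_um, z_um, length_kb, cluster_id``
    (``cluster_id == 0`` means unclustered).  ``nucleus`` carries
    nucleus-level facts (id, phase label, total length in kb).
    """

    telomeres: pd.DataFrame
    nucleus: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TRUTH_COLUMNS if c not in self.telomeres.columns]
        if missing:
            raise ValueError(f"ground-truth table missing columns: {missing}")

    @property
    def positions_um(self) -> np.ndarray:
        """(n, 3) array of (z, y, x) positions in µm."""
        return self.telomeres[["z_um", "y_um", "x_um"]].to_numpy(float)

    @property
    def n_sites(self) -> int:
        """Number of distinct emitter sites (a clustered pair is one site)."""
        t = self.telomeres
        n_unclustered = int((t["cluster_id"] == 0).sum())
        n_pairs = t.loc[t["cluster_id"] > 0, "cluster_id"].nunique()
        return n_unclustered + int(n_pairs)


@dataclass
class ImageStack:
    """A 3D voxel array with physical spacing and acquisition metadata."""

    data: np.ndarray
    spacing: VoxelSpacing = field(default_factory=VoxelSpacing)
    bit_depth: int | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack expects a 3D array, got {self.data.ndim}D")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def physical_extent(self) -> tuple[float, float, float]:
        """Stack extent (z, y, x) in µm."""
        nz, ny, nx = self.data.shape
        return (nz * self.spacing.dz, ny * self.spacing.dy, nx * self.spacing.dx)

    def index_to_um(self, zyx_index: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel indices to µm (voxel-centre rule)."""
        return (np.asarray(zyx_index, float) + 0.5) * np.array(self.spacing.zyx)

    def um_to_index(self, zyx_um: np.ndarray) -> np.ndarray:
        """Convert µm coordinates to fractional voxel indices."""
        return np.asarray(zyx_um, float) / np.array(self.spacing.zyx) - 0.5


@dataclass(frozen=True)
class ExpectedKaryotype:
    """Expected telomere complement from a metaphase-spread count."""

    n_chromosomes: int = 46
    telomeres_per_chromosome_end: int = 1

    @property
    def expected_telomeres(self) -> int:
        """Telomeres per G1 cell: two chromosome ends per chromosome."""
        return 2 * self.n_chromosomes * self.telomeres_per_chromosome_end


@dataclass
class Spot3D:
    """One detected 3D telomere focus (ellipsoidal spot model)."""

    centroid_um: tuple[float, float, float]  # (z, y, x)
    lateral_radius_um: float
    axial_radius_um: float
    intensity_sum: float
    intensity_mean: float
    intensity_max: float
    volume_um3: float
    quality: float


@dataclass
class CellRecord:
    """One segmented nucleus with its DNA-content cell-cycle gate."""

    nucleus_id: int
    mask: np.ndarray | None
    nucleus_volume_um3: float
    integrated_dna: float
    phase_gate: str = "ungated"  # one of {"G1", "S/G2", "excluded", "ungated"}


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministically split one seed into ``n`` independent generators.

    A single ``SeedSequence(seed)`` is spawned ``n`` ways; this is the one
    splitting rule used everywhere a stage needs several streams.
    """
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def model_to_dict(obj: Any) -> dict[str, Any]:
    """Serializable dict view of any of the frozen parameter dataclasses."""
    return asdict(obj)
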