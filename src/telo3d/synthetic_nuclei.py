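"""Synthetic wide-field microscope: nuclei with known telomere content.

The study's readouts (telomere count, intensity-sum length proxy, spot
volume, clustering deficit) are validated here by parameter recovery:
every image this module emits comes with an exact ground truth, so each
pipeline stage can be tested against what was actually rendered.

Physical model
--------------
* Telomeres are sub-resolution point emitters; each emits a total flux of
  ``photons_per_kb * length_kb`` photons, i.e. brightness is proportional
  to telomere length (the qFISH assumption of uniform probe hybridisation).
* The PSF is a separable anisotropic Gaussian with FWHMs
  (lateral, lateral, 3x lateral) — see :class:`~telo3d.models.OpticsModel`.
  Emitters are integrated exactly over voxels (per-axis erf differences),
  so the noise-free render conserves flux to numerical precision.
* Illumination is vignetted by a centred Gaussian field (brightest on the
  optical axis, falling toward the edges).
* The camera applies Poisson shot noise to the expected photon count, a
  gain, a dark offset, additive Gaussian read noise, then quantises and
  clips to the bit depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erf

from .models import (
    CameraModel,
    GroundTruth,
    ImageStack,
    NucleusSpec,
    OpticsModel,
    VoxelSpacing,
    TRUTH_COLUMNS,
    spawn_rngs,
)

DEFAULT_SHAPE = (41, 256, 256)  # (z, y, x): 41 z-steps, full camera crop

# Flux calibration of the simulated staining: photons emitted per kb of
# telomere repeat at the reference exposure.  Chosen so a median ~5 kb
# telomere peaks at a few hundred counts above offset on a 12-bit scale.
PHOTONS_PER_KB = 2000.0

# DNA-stain brightness: expected photons per voxel inside a G1 nucleus.
DNA_PHOTONS_PER_VOXEL = 60.0


class PlacementError(RuntimeError):
    """Raised when emitter placement cannot satisfy the separation constraint."""


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def vignetting_field(shape_yx: tuple[int, int], spacing: VoxelSpacing,
                     camera: CameraModel) -> np.ndarray:
    """Relative illumination across the field of view.

    Gaussian profile centred on the image centre with value 1 on axis,
    falling to ``1 - vignetting_strength`` far from it.
    """
    ny, nx = shape_yx
    y = (np.arange(ny) + 0.5) * spacing.dy - ny * spacing.dy / 2.0
    x = (np.arange(nx) + 0.5) * spacing.dx - nx * spacing.dx / 2.0
    r2 = y[:, None] ** 2 + x[None, :] ** 2
    s = camera.vignetting_strength
    if s == 0:
        return np.ones(shape_yx)
    return (1.0 - s) + s * np.exp(-r2 / (2.0 * camera.vignetting_sigma**2))


def _axis_weights(n: int, d: float, mu: float, sigma: float,
                  half_width: float) -> tuple[int, np.ndarray]:
    """Exact Gaussian mass per voxel along one axis.

    Voxel ``i`` spans ``[i*d, (i+1)*d]``; returns the first covered index
    and the erf-difference weights over a ±half_width window.
    """
    lo = max(0, int(np.floor((mu - half_width) / d)))
    hi = min(n, int(np.ceil((mu + half_width) / d)) + 1)
    if hi <= lo:
        return lo, np.zeros(0)
    edges = np.arange(lo, hi + 1) * d
    c = erf((edges - mu) / (sigma * np.sqrt(2.0)))
    return lo, 0.5 * np.diff(c)


def render_emitters(shape: tuple[int, int, int], positions_um: np.ndarray,
                    fluxes: np.ndarray, optics: OpticsModel,
                    spacing: VoxelSpacing) -> np.ndarray:
    """Render point emitters through the Gaussian PSF onto a voxel grid.

    Parameters
    ----------
    positions_um : (n, 3) array of (z, y, x) emitter positions in µm.
    fluxes : total photons per emitter.

    Returns the expected-photon image (float64, no noise, no vignetting).
    """
    img = np.zeros(shape, dtype=np.float64)
    positions_um = np.atleast_2d(np.asarray(positions_um, float))
    fluxes = np.atleast_1d(np.asarray(fluxes, float))
    sig = optics.sigmas_um()
    spac = (spacing.dz, spacing.dy, spacing.dx)
    half = tuple(6.5 * s + d for s, d in zip(sig, spac))
    for pos, flux in zip(positions_um, fluxes):
        w = []
        los = []
        for ax in range(3):
            lo, weights = _axis_weights(shape[ax], spac[ax], pos[ax], sig[ax], half[ax])
            los.append(lo)
            w.append(weights)
        if any(len(x) == 0 for x in w):
            continue
        kernel = flux * w[0][:, None, None] * w[1][None, :, None] * w[2][None, None, :]
        img[los[0]:los[0] + len(w[0]),
            los[1]:los[1] + len(w[1]),
            los[2]:los[2] + len(w[2])] += kernel
    return img


def apply_camera(expected_photons: np.ndarray, camera: CameraModel,
                 rng: np.random.Generator | None, noise: bool = True) -> np.ndarray:
    """Detect an expected-photon image: shot noise, gain, offset, read noise.

    With ``noise=False`` the analog mean image (float, unquantised) is
    returned: ``gain * expected + dark_offset``.
    """
    if not noise:
        return camera.photon_gain * expected_photons + camera.dark_offset
    if rng is None:
        raise ValueError("an rng is required when noise is enabled")
    photons = rng.poisson(np.clip(expected_photons, 0, None)).astype(np.float64)
    counts = (camera.photon_gain * photons + camera.dark_offset
              + rng.normal(0.0, camera.read_noise_sd, expected_photons.shape))
    return np.clip(np.rint(counts), 0, camera.max_gray).astype(np.uint16)


# ---------------------------------------------------------------------------
# emitter placement
# ---------------------------------------------------------------------------

def _sample_in_ellipsoid(rng: np.random.Generator, semi_axes_zyx: np.ndarray,
                         centre_zyx: np.ndarray, n: int) -> np.ndarray:
    """Uniform points inside an axis-aligned ellipsoid (z, y, x in µm)."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return centre_zyx + v * r[:, None] * semi_axes_zyx


def place_telomeres(spec: NucleusSpec, stack_extent_zyx: tuple[float, float, float],
                    optics: OpticsModel, rng: np.random.Generator,
                    max_attempts: int = 400, max_restarts: int = 10) -> pd.DataFrame:
    """Place telomere emitters inside the nucleus with separation constraints.

    Distinct emitter *sites* are kept at least ``min_separation`` apart; a
    clustered pair shares a site, its two members separated by
    ``cluster_distance``.  Returns a truth table (without lengths).
    """
    extent = np.asarray(stack_extent_zyx, float)
    centre = extent / 2.0
    semi = np.array([spec.nucleus_semi_axes[2], spec.nucleus_semi_axes[1],
                     spec.nucleus_semi_axes[0]])  # to (z, y, x)
    ax_fwhm_um = optics.axial_fwhm * 1e-3
    if centre[0] - semi[0] < ax_fwhm_um or centre[0] + semi[0] > extent[0] - ax_fwhm_um:
        raise ValueError(
            "nucleus does not fit in the stack with a one-axial-FWHM margin in Z; "
            "increase the number of z-steps or shrink nucleus_semi_axes")
    if np.any(semi[1:] >= centre[1:]):
        raise ValueError("nucleus semi-axes exceed the lateral field of view")

    n_paired = spec.n_paired
    n_pairs = n_paired // 2
    n_single = spec.n_telomeres - n_paired
    n_sites = n_single + n_pairs

    for _ in range(max_restarts):
        sites: list[np.ndarray] = []
        ok = True
        for _ in range(n_sites):
            placed = False
            for _ in range(max_attempts):
                p = _sample_in_ellipsoid(rng, semi, centre, 1)[0]
                if sites and np.min(np.linalg.norm(np.array(sites) - p, axis=1)) < spec.min_separation:
                    continue
                sites.append(p)
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            break
    else:
        raise PlacementError(
            f"could not place {n_sites} emitter sites with min_separation="
            f"{spec.min_separation} µm inside nucleus semi-axes "
            f"{spec.nucleus_semi_axes} µm")

    rows = []
    tid = 1
    # singles first, then pairs (cluster_id 1..n_pairs)
    for i in range(n_single):
        z, y, x = sites[i]
        rows.append((tid, x, y, z, 0))
        tid += 1
    for ci in range(n_pairs):
        anchor = sites[n_single + ci]
        for _ in range(200):
            d = rng.normal(size=3)
            d = d / np.linalg.norm(d) * spec.cluster_distance
            partner = anchor + d
            if np.sum(((partner - centre) / semi) ** 2) <= 1.0:
                break
        else:
            partner = anchor  # degenerate but within truth invariants
        for p in (anchor, partner):
            z, y, x = p
            rows.append((tid, x, y, z, ci + 1))
            tid += 1
    df = pd.DataFrame(rows, columns=["telomere_id", "x_um", "y_um", "z_um", "cluster_id"])
    return df


def _draw_lengths(dist: tuple[float, float, str], n: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw telomere lengths in kb from (mean, sd, family)."""
    mean, sd, family = dist
    if n == 0:
        return np.zeros(0)
    if family == "fixed" or sd == 0:
        return np.full(n, float(mean))
    if family == "lognormal":
        s2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - s2 / 2.0
        return rng.lognormal(mu, np.sqrt(s2), n)
    if family == "normal":
        x = rng.normal(mean, sd, n)
        # redraw non-physical lengths
        bad = x <= 0.2
        while np.any(bad):
            x[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = x <= 0.2
        return x
    raise ValueError(f"unknown length distribution family: {family!r}")


# ---------------------------------------------------------------------------
# top-level simulators
# ---------------------------------------------------------------------------

def simulate_nucleus(spec: NucleusSpec, optics: OpticsModel, camera: CameraModel,
                     spacing: VoxelSpacing, seed: int,
                     shape: tuple[int, int, int] = DEFAULT_SHAPE,
                     photons_per_kb: float = PHOTONS_PER_KB,
                     noise: bool = True, vignetting: bool = True,
                     nucleus_id: int = 0,
                     ) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Simulate one two-channel z-stack of an interphase nucleus.

    Returns the telomere-probe channel, the DNA-stain channel and the
    ground truth.  With ``noise=False`` the channels are analog means
    (float, dark offset added but neither noise nor quantisation), which
    is what flux-conservation and linearity checks rely on.
    """
    rng_place, rng_len, rng_noise_t, rng_noise_d = spawn_rngs(seed, 4)
    extent = (shape[0] * spacing.dz, shape[1] * spacing.dy, shape[2] * spacing.dx)

    truth_df = place_telomeres(spec, extent, optics, rng_place)
    lengths = _draw_lengths(spec.telomere_length_dist, len(truth_df), rng_len)
    truth_df = truth_df.assign(length_kb=lengths, nucleus_id=nucleus_id)[TRUTH_COLUMNS]

    expected = render_emitters(
        shape, truth_df[["z_um", "y_um", "x_um"]].to_numpy(float),
        photons_per_kb * truth_df["length_kb"].to_numpy(float), optics, spacing)
    vfield = vignetting_field(shape[1:], spacing, camera) if vignetting else np.ones(shape[1:])
    telo = apply_camera(expected * vfield[None, :, :], camera, rng_noise_t, noise)

    dna_expected = _dna_channel(spec, shape, spacing, extent)
    dna = apply_camera(dna_expected * vfield[None, :, :], camera, rng_noise_d, noise)

    phase = "G2" if spec.dna_content_scale >= 1.5 else "G1"
    truth = GroundTruth(
        telomeres=truth_df,
        nucleus={
            "nucleus_id": nucleus_id,
            "phase": phase,
            "total_length_kb": float(truth_df["length_kb"].sum()),
            "dna_content_scale": spec.dna_content_scale,
            "semi_axes_um": tuple(spec.nucleus_semi_axes),
        },
    )
    meta = {"channel": "telomere", "noise": noise, "vignetting": vignetting,
            "photons_per_kb": photons_per_kb, "seed": seed}
    telo_stack = ImageStack(telo, spacing, camera.bit_depth, meta)
    dna_stack = ImageStack(dna, spacing, camera.bit_depth,
                           {**meta, "channel": "dna"})
    return telo_stack, dna_stack, truth


def _dna_channel(spec: NucleusSpec, shape, spacing: VoxelSpacing, extent) -> np.ndarray:
    """Smooth ellipsoidal DNA-stain photon image, scaled by DNA content."""
    centre = np.asarray(extent) / 2.0
    semi = np.array([spec.nucleus_semi_axes[2], spec.nucleus_semi_axes[1],
                     spec.nucleus_semi_axes[0]])
    z = (np.arange(shape[0]) + 0.5) * spacing.dz
    y = (np.arange(shape[1]) + 0.5) * spacing.dy
    x = (np.arange(shape[2]) + 0.5) * spacing.dx
    q = (((z[:, None, None] - centre[0]) / semi[0]) ** 2
         + ((y[None, :, None] - centre[1]) / semi[1]) ** 2
         + ((x[None, None, :] - centre[2]) / semi[2]) ** 2)
    interior = (q <= 1.0).astype(np.float64)
    sigma_vox = [0.3 / d for d in spacing.zyx]  # 0.3 µm chromatin-edge softness
    smooth = ndimage.gaussian_filter(interior, sigma_vox)
    return DNA_PHOTONS_PER_VOXEL * spec.dna_content_scale * smooth


def simulate_calibration_frames(camera: CameraModel, n_dark: int,
                                shape: tuple[int, int], seed: int,
                                spacing: VoxelSpacing | None = None,
                                flat_level: float = 2000.0,
                                noise: bool = True,
                                ) -> tuple[list[np.ndarray], np.ndarray]:
    """Simulate dark frames and a flat-field image.

    Dark frames are offset + read noise (shutter closed).  The flat field
    images a uniform fluorescent target emitting ``flat_level`` expected
    photons per pixel through the vignetted illumination, so it is
    brightest at the centre of the field.
    """
    if n_dark < 1:
        raise ValueError("n_dark must be >= 1")
    if len(shape) != 2 or min(shape) < 1:
        raise ValueError(f"invalid frame shape: {shape}")
    spacing = spacing or VoxelSpacing()
    rngs = spawn_rngs(seed, n_dark + 1)
    zeros = np.zeros(shape)
    darks = [apply_camera(zeros, camera, rngs[i], noise) for i in range(n_dark)]
    vfield = vignetting_field(shape, spacing, camera)
    flat = apply_camera(flat_level * vfield, camera, rngs[n_dark], noise)
    return darks, flat


def simulate_beads(n_beads: int, bead_diameter: float, optics: OpticsModel,
                   camera: CameraModel, spacing: VoxelSpacing, seed: int,
                   shape: tuple[int, int, int] = (41, 128, 128),
                   flux: float = 20000.0, min_separation: float = 2.0,
                   noise: bool = True) -> tuple[ImageStack, GroundTruth]:
    """Simulate a field of sub-resolution calibration beads.

    ``bead_diameter`` is in nm and must be below the lateral FWHM so that
    each bead images as one PSF (the 100 nm TetraSpeck regime).
    """
    if bead_diameter >= optics.lateral_fwhm:
        raise ValueError("beads must be sub-resolution (diameter < lateral FWHM)")
    rng_place, rng_noise = spawn_rngs(seed, 2)
    extent = np.array([shape[0] * spacing.dz, shape[1] * spacing.dy,
                       shape[2] * spacing.dx])
    margin = np.array([6.0 * s for s in optics.sigmas_um()]) + 0.2
    if np.any(extent - 2 * margin <= 0):
        raise ValueError("stack too small for the PSF support")
    positions: list[np.ndarray] = []
    for _ in range(n_beads):
        for _ in range(500):
            p = margin + rng_place.random(3) * (extent - 2 * margin)
            if not positions or np.min(
                    np.linalg.norm(np.array(positions) - p, axis=1)) >= min_separation:
                positions.append(p)
                break
        else:
            raise PlacementError(
                f"could not place {n_beads} beads {min_separation} µm apart")
    pos = np.array(positions)
    expected = render_emitters(shape, pos, np.full(n_beads, flux), optics, spacing)
    img = apply_camera(expected, camera, rng_noise, noise)
    truth_df = pd.DataFrame({
        "nucleus_id": 0,
        "telomere_id": np.arange(1, n_beads + 1),
        "x_um": pos[:, 2], "y_um": pos[:, 1], "z_um": pos[:, 0],
        "length_kb": np.nan,
        "cluster_id": 0,
    })
    truth = GroundTruth(truth_df, {"nucleus_id": 0, "phase": "bead",
                                   "total_length_kb": 0.0, "flux_photons": flux})
    return ImageStack(img, spacing, camera.bit_depth,
                      {"channel": "beads", "noise": noise, "seed": seed}), truth
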