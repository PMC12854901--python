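"""Synthetic agroinfiltrated-nucleus scenes with known phase-separation truth.

Each scene is a dark background plus an ellipsoidal nucleus whose voxels sit at
the dilute-phase concentration C_dil, with non-overlapping spherical
condensates at the dense-phase concentration C_den. Given a target condensate
volume fraction φ, a partition coefficient pc = C_den / C_dil and the mean
nuclear concentration C_tot, the two phase concentrations follow from mass
balance::

    C_tot = φ · C_den + (1 − φ) · C_dil,   C_den = pc · C_dil

so ``C_dil = C_tot / (φ·pc + 1 − φ)``.

A detector offset (``background_level``) is added everywhere, a smooth
multiplicative texture field emulates within-phase intensity heterogeneity,
and an optional isotropic Gaussian PSF and detector noise are applied last.
Ground truth always refers to the pre-blur, pre-noise geometry and to the
nominal mass-balance concentrations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .core import PlacementError, VolumetricImage

__all__ = [
    "SceneParams",
    "SyntheticGroundTruth",
    "ThermoSeriesSpec",
    "generate_scene",
    "generate_series",
    "generate_two_channel_scene",
    "generate_frap_series",
]


class SceneParams(BaseModel):
    """Generating parameters for one synthetic nucleus stack.

    Lengths are μm, intensities are a.u.; ``grid_shape`` and ``voxel_size``
    are ordered (z, y, x).
    """

    model_config = {"frozen": True}

    grid_shape: tuple[int, int, int] = (24, 128, 128)
    voxel_size: tuple[float, float, float] = (0.2, 0.08, 0.08)
    nucleus_axes: tuple[float, float, float] = (2.0, 4.2, 4.2)
    c_tot: float = Field(default=100.0, gt=0)
    partition_coefficient: float = Field(default=10.0, ge=1.0)
    volume_fraction: float = Field(default=0.05, ge=0.0, le=0.5)
    n_condensates: int = Field(default=4, ge=0)
    condensate_radius_mean: float = Field(default=0.9, gt=0)
    condensate_radius_sd: float = Field(default=0.2, ge=0)
    background_level: float = Field(default=20.0, ge=0)
    psf_sigma: float = Field(default=0.0, ge=0)
    noise_model: Literal["none", "gaussian", "poisson"] = "gaussian"
    noise_sigma: float = Field(default=4.0, ge=0)
    noise_gain: float = Field(default=1.0, gt=0)
    heterogeneity: float = Field(default=0.10, ge=0, lt=1)
    background_heterogeneity: float = Field(default=0.40, ge=0, lt=1)
    heterogeneity_length: float = Field(default=0.3, gt=0)
    placement_attempts: int = Field(default=10_000, ge=1)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "SceneParams":
        extent = [n * v for n, v in zip(self.grid_shape, self.voxel_size)]
        for ax, (a, e) in enumerate(zip(self.nucleus_axes, extent)):
            if 2 * a > e:
                raise ValueError(
                    f"nucleus axis {ax} (semi-axis {a} μm) does not fit in the "
                    f"grid extent {e} μm"
                )
        return self

    @property
    def nucleus_volume(self) -> float:
        """Analytic ellipsoid volume, μm³."""
        a, b, c = self.nucleus_axes
        return 4.0 / 3.0 * math.pi * a * b * c


@dataclass
class SyntheticGroundTruth:
    """True masks and generating concentrations of a simulated scene.

    ``true_c_dil``/``true_c_den`` are the nominal mass-balance values (the
    texture field fluctuates around them); ``true_c_tot`` is the voxel mean of
    the nominal phase pattern over the nucleus, i.e. the mass-balance mean
    after voxel discretisation. All concentrations exclude ``background_level``.
    """

    nucleus_mask: np.ndarray
    condensate_mask: np.ndarray
    condensate_labels: np.ndarray
    true_c_dil: float
    true_c_den: float
    true_c_tot: float
    true_volume_fraction: float
    per_object_volumes: list[float]
    params: SceneParams

    @property
    def n_condensates(self) -> int:
        return len(self.per_object_volumes)


def _voxel_centers(params: SceneParams):
    """Physical (z, y, x) coordinates of voxel centers, origin at grid center."""
    axes = []
    for n, v in zip(params.grid_shape, params.voxel_size):
        axes.append((np.arange(n) + 0.5) * v - n * v / 2.0)
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _nucleus_mask(params: SceneParams) -> np.ndarray:
    zz, yy, xx = _voxel_centers(params)
    az, ay, ax = params.nucleus_axes
    return (zz / az) ** 2 + (yy / ay) ** 2 + (xx / ax) ** 2 <= 1.0


def _draw_radii(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Radii with the requested spread, rescaled so the total analytic sphere
    volume matches ``volume_fraction`` of the analytic nucleus volume."""
    n = params.n_condensates
    r = rng.normal(params.condensate_radius_mean, params.condensate_radius_sd, size=n)
    r = np.clip(r, 0.25 * params.condensate_radius_mean, None)
    target = params.volume_fraction * params.nucleus_volume
    total = (4.0 / 3.0 * math.pi * r**3).sum()
    return r * (target / total) ** (1.0 / 3.0)


def _place_condensates(
    params: SceneParams, radii: np.ndarray, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Rejection-sample non-overlapping sphere centers fully inside the nucleus.

    Spheres are placed largest-first; a sphere of radius r is fully contained
    if its center lies inside the ellipsoid with semi-axes shrunk by r. A
    one-voxel-diagonal separation margin keeps voxelized spheres from touching
    under 26-connectivity, so ground-truth labels remain distinct objects.
    """
    order = np.argsort(radii)[::-1]
    axes = np.array(params.nucleus_axes)
    margin = float(np.linalg.norm(params.voxel_size))
    placed: list[tuple[np.ndarray, float]] = []
    attempts = 0
    for i in order:
        r = float(radii[i])
        shrunk = axes - r
        if np.any(shrunk <= 0):
            raise PlacementError(
                f"condensate radius {r:.3f} μm exceeds a nucleus semi-axis "
                f"{tuple(axes)}; placed {len(placed)} of {len(radii)}"
            )
        while True:
            attempts += 1
            if attempts > params.placement_attempts:
                raise PlacementError(
                    f"placed {len(placed)} of {len(radii)} condensates within "
                    f"{params.placement_attempts} attempts (nucleus too crowded)"
                )
            c = rng.uniform(-shrunk, shrunk)
            if ((c / shrunk) ** 2).sum() > 1.0:
                continue
            if any(np.linalg.norm(c - cj) <= r + rj + margin for cj, rj in placed):
                continue
            placed.append((c, r))
            break
    return placed


def _label_spheres(params: SceneParams, spheres) -> np.ndarray:
    labels = np.zeros(params.grid_shape, dtype=np.int32)
    vs = np.array(params.voxel_size)
    half = np.array(params.grid_shape) * vs / 2.0
    for lab, (c, r) in enumerate(spheres, start=1):
        lo = np.maximum(np.floor((c - r + half) / vs).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((c + r + half) / vs).astype(int) + 1, params.grid_shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        coords = [
            (np.arange(l, h) + 0.5) * v - hw
            for l, h, v, hw in zip(lo, hi, vs, half)
        ]
        zz, yy, xx = np.meshgrid(*coords, indexing="ij", sparse=True)
        inside = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
        labels[sub][inside] = lab
    return labels


def _texture_field(
    params: SceneParams, rng: np.random.Generator, amplitude: float
) -> np.ndarray:
    """Smooth unit-mean multiplicative texture emulating within-phase
    heterogeneity (expression gradients, nucleoplasmic structure) or, at
    larger amplitude, the uneven autofluorescent background of plant tissue.

    The field is drawn even when ``amplitude`` is 0 so that toggling texture
    does not shift the generator's downstream random stream.
    """
    sigma_vox = [params.heterogeneity_length / v for v in params.voxel_size]
    g = ndimage.gaussian_filter(rng.standard_normal(params.grid_shape), sigma=sigma_vox)
    if amplitude == 0:
        return np.ones(params.grid_shape)
    sd = g.std()
    if sd > 0:
        g /= sd
    return np.clip(1.0 + amplitude * g, 0.2, None)


def _apply_noise(img: np.ndarray, params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_model == "gaussian" and params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, img.shape)
    elif params.noise_model == "poisson":
        img = rng.poisson(img / params.noise_gain).astype(float) * params.noise_gain
    return np.clip(img, 0.0, None)


def generate_scene(params: SceneParams) -> tuple[VolumetricImage, SyntheticGroundTruth]:
    """Render one synthetic nucleus stack with its ground truth.

    Identical ``params`` (including ``rng_seed``) produce bit-identical output.
    """
    rng = np.random.default_rng(params.rng_seed)
    nucleus = _nucleus_mask(params)

    phi = params.volume_fraction
    if params.n_condensates > 0 and phi > 0:
        radii = _draw_radii(params, rng)
        spheres = _place_condensates(params, radii, rng)
        labels = _label_spheres(params, spheres)
    else:
        phi = 0.0
        labels = np.zeros(params.grid_shape, dtype=np.int32)
    cond = labels > 0
    labels[~nucleus] = 0  # guard: labels must be inside the nucleus
    cond &= nucleus

    pc = params.partition_coefficient
    c_dil = params.c_tot / (phi * pc + (1.0 - phi))
    c_den = pc * c_dil

    signal = np.zeros(params.grid_shape)
    signal[nucleus] = c_dil
    signal[cond] = c_den

    n_nuc = int(nucleus.sum())
    phi_vox = float(cond.sum()) / n_nuc if n_nuc else 0.0
    true_c_tot = phi_vox * c_den + (1.0 - phi_vox) * c_dil

    voxvol = math.prod(params.voxel_size)
    counts = np.bincount(labels.ravel())[1:]
    per_object = [float(c) * voxvol for c in counts if c > 0]

    img = params.background_level * _texture_field(
        params, rng, params.background_heterogeneity
    ) + signal * _texture_field(params, rng, params.heterogeneity)
    if params.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=[params.psf_sigma / v for v in params.voxel_size])
    img = _apply_noise(img, params, rng)

    gt = SyntheticGroundTruth(
        nucleus_mask=nucleus,
        condensate_mask=cond,
        condensate_labels=labels,
        true_c_dil=c_dil,
        true_c_den=c_den,
        true_c_tot=true_c_tot,
        true_volume_fraction=phi_vox,
        per_object_volumes=per_object,
        params=params,
    )
    return VolumetricImage(img, params.voxel_size, channel="mClover3"), gt


class ThermoSeriesSpec(BaseModel):
    """A cross-image series with prescribed phase thermodynamics.

    ``binary`` mode emulates simple two-phase coexistence: above the saturation
    concentration ``c_sat`` the dilute phase is pinned at C_dil = c_sat and the
    dense phase at ``c_den_binary``; only the volume fraction
    φ = (C_tot − c_sat)/(C_den − c_sat) grows. Below c_sat no condensates form
    and all signal is dilute. ``multicomponent`` mode makes both phases climb
    linearly with C_tot (heterotypic interactions shift the tie-lines):
    C_dil = dil_intercept + dil_slope·C_tot, C_den = den_intercept +
    den_slope·C_tot.

    Condensate number and mean volume both grow with φ: the per-droplet target
    volume scales as sqrt(φ/φ_ref) and the droplet count follows from
    φ·V_nucleus, emulating joint nucleation and growth.
    """

    model_config = {"frozen": True}

    n_images: int = Field(default=42, ge=2)
    c_tot_range: tuple[float, float] = (70.0, 200.0)
    mode: Literal["binary", "multicomponent"] = "multicomponent"
    # binary-mode law
    c_sat: float = Field(default=60.0, gt=0)
    c_den_binary: float = Field(default=800.0, gt=0)
    # multicomponent-mode law
    dil_intercept: float = 20.0
    dil_slope: float = Field(default=0.3, gt=0)
    den_intercept: float = 300.0
    den_slope: float = Field(default=2.5, gt=0)
    # droplet size/number law
    reference_droplet_radius: float = Field(default=1.0, gt=0)
    reference_volume_fraction: float = Field(default=0.06, gt=0)
    radius_spread: float = Field(default=0.15, ge=0)
    base_scene: SceneParams = SceneParams()
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ThermoSeriesSpec":
        lo, hi = self.c_tot_range
        if not lo < hi:
            raise ValueError(f"invalid c_tot_range {self.c_tot_range}: min must be < max")
        hi_dil, hi_den = self.phase_law(hi)
        phi_hi = (hi - hi_dil) / (hi_den - hi_dil)
        if phi_hi > 0.5:
            raise ValueError(
                f"volume fraction {phi_hi:.2f} at c_tot={hi} exceeds 0.5; "
                "adjust the thermodynamic law or the range"
            )
        return self

    def phase_law(self, c_tot: float) -> tuple[float, float]:
        """Nominal (C_dil, C_den) at a given C_tot under this spec's mode."""
        if self.mode == "binary":
            if c_tot <= self.c_sat:
                return c_tot, self.c_den_binary
            return self.c_sat, self.c_den_binary
        return (
            self.dil_intercept + self.dil_slope * c_tot,
            self.den_intercept + self.den_slope * c_tot,
        )


def _series_scene_params(spec: ThermoSeriesSpec, c_tot: float, seed: int) -> SceneParams:
    c_dil, c_den = spec.phase_law(c_tot)
    phi = max(0.0, (c_tot - c_dil) / (c_den - c_dil))
    base = spec.base_scene
    if phi <= 0:
        return base.model_copy(
            update=dict(c_tot=c_tot, volume_fraction=0.0, n_condensates=0, rng_seed=seed)
        )
    v_ref = 4.0 / 3.0 * math.pi * spec.reference_droplet_radius**3
    v = v_ref * math.sqrt(phi / spec.reference_volume_fraction)
    n = max(1, round(phi * base.nucleus_volume / v))
    r_mean = (3.0 * (phi * base.nucleus_volume / n) / (4.0 * math.pi)) ** (1.0 / 3.0)
    return base.model_copy(
        update=dict(
            c_tot=c_tot,
            volume_fraction=phi,
            partition_coefficient=c_den / c_dil,
            n_condensates=n,
            condensate_radius_mean=r_mean,
            condensate_radius_sd=spec.radius_spread * r_mean,
            rng_seed=seed,
        )
    )


def generate_series(
    spec: ThermoSeriesSpec,
) -> list[tuple[VolumetricImage, SyntheticGroundTruth]]:
    """Generate a concentration series ordered by increasing C_tot."""
    c_tots = np.linspace(*spec.c_tot_range, spec.n_images)
    seeds = [
        int(ss.generate_state(1)[0] % 2**31)
        for ss in np.random.SeedSequence(spec.rng_seed).spawn(spec.n_images)
    ]
    return [
        generate_scene(_series_scene_params(spec, float(c), s))
        for c, s in zip(c_tots, seeds)
    ]


def generate_two_channel_scene(
    params: SceneParams,
    coloc_mode: Literal["identical", "independent", "partial"] = "identical",
    rho: Optional[float] = None,
) -> tuple[VolumetricImage, VolumetricImage, SyntheticGroundTruth]:
    """A two-channel scene with controlled between-channel correlation.

    ``identical``: channel 2 is a copy of channel 1 (r = 1 exactly).
    ``independent``: channel 2 is the same scene re-rendered with a
    decorrelated seed (shared geometry still correlates the channels unless
    the scene is noise-dominated).
    ``partial``: channel 2 mixes channel 1 with an independent positive noise
    field, with the mixing weight solved by bisection so the realized whole-
    grid Pearson correlation is within 1e-3 of ``rho``.
    """
    img1, gt = generate_scene(params)
    if coloc_mode == "identical":
        img2 = img1.with_data(img1.data.copy())
    elif coloc_mode == "independent":
        seed2 = int(np.random.SeedSequence(params.rng_seed).spawn(2)[1].generate_state(1)[0] % 2**31)
        img2, _ = generate_scene(params.model_copy(update={"rng_seed": seed2}))
    elif coloc_mode == "partial":
        if rho is None or not -1.0 < rho < 1.0:
            raise ValueError(f"partial mode requires rho in (-1, 1), got {rho}")
        img2 = img1.with_data(_partial_channel(img1.data, rho, params.rng_seed))
    else:
        raise ValueError(f"unknown coloc_mode {coloc_mode!r}")
    img2.channel = "mCherry"
    return img1, img2, gt


def _partial_channel(d1: np.ndarray, rho: float, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    m, v = d1.mean(), d1.var()
    if v == 0:
        raise ZeroDivisionError("cannot build a partially correlated channel from a constant image")
    # gamma noise matched to the image's mean/variance: positive, image-like
    shape = m**2 / v
    noise = rng.gamma(shape, v / m, size=d1.shape)
    base = d1 if rho >= 0 else (d1.max() - d1)

    def corr(alpha: float) -> float:
        mix = alpha * base + (1.0 - alpha) * noise
        return float(np.corrcoef(mix.ravel(), d1.ravel())[0, 1])

    lo, hi = 0.0, 1.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if abs(corr(mid)) < abs(rho):
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    return alpha * base + (1.0 - alpha) * noise


def generate_frap_series(
    n_timepoints: int = 75,
    pre_bleach_level: float = 100.0,
    bleach_depth: float = 0.8,
    recovery_rate: float = 0.1,
    mobile_fraction: float = 0.8,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
    n_prebleach: int = 5,
) -> np.ndarray:
    """Mean-intensity FRAP trace: plateau, instantaneous bleach, exponential
    recovery toward ``floor + mobile_fraction · (1 − floor)`` of the
    pre-bleach level, where ``floor = 1 − bleach_depth``.

    Defaults mirror a 5 pre- + 70 post-bleach acquisition.
    """
    if recovery_rate < 0:
        raise ValueError(f"recovery_rate must be >= 0, got {recovery_rate}")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError(f"mobile_fraction must be in [0, 1], got {mobile_fraction}")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError(f"bleach_depth must be in (0, 1], got {bleach_depth}")
    if n_timepoints <= n_prebleach + 1:
        raise ValueError("need at least two post-bleach frames")
    rng = np.random.default_rng(rng_seed)
    floor = 1.0 - bleach_depth
    t = np.arange(n_timepoints - n_prebleach, dtype=float)
    post = floor + mobile_fraction * (1.0 - floor) * (1.0 - np.exp(-recovery_rate * t))
    trace = pre_bleach_level * np.concatenate([np.ones(n_prebleach), post])
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, trace.shape)
    return np.clip(trace, 0.0, None)
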