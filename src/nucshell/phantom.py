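"""Synthetic 3D nuclear phantoms with voxel-level ground truth.

The generator emulates the data regime of super-resolution confocal
Z-stacks of nuclear-envelope (SUN2) staining: anisotropic voxels
(0.21 x 0.05 x 0.05 µm in Z, Y, X), ovoid nuclei rendered as (optionally
fold-perturbed) ellipsoids, a centre-to-periphery radial intensity
gradient, punctate staining modelled as point emitters blurred by an
anisotropic Gaussian PSF, Poisson photon noise plus additive Gaussian read
noise, and optional border-touching distractor objects for testing the
border-clearing stage.

Two presets instantiate the two morphological regimes the pipeline is
meant to distinguish:

* ``mcf10a_like`` — flat, disc-shaped nuclei (Z semi-axis well below XY),
  regular outline, moderate puncta;
* ``mda231_like`` — taller nuclei with an irregular, folded outline and
  brighter, denser puncta.

Both carry a peripheral-enrichment intensity profile (a band peaked near
normalized depth 0.1, i.e. just inside the envelope), giving a roughly
two-fold RO-6/RO-1 contrast by construction.

Ground truth (mask, normalized depth, noiseless intensity, layer labels
for any K, true RO means and folds) is derived from the configuration
before noise is applied, using the same distance transform and binning
rule as the analysis pipeline, so recovery can be scored voxel for voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, ValidationError
from .io import VolumeImage
from .segment import LabelMask
from .shells import assign_shells, distance_transform

__all__ = [
    "NucleusSpec",
    "RadialProfileSpec",
    "flat_profile",
    "linear_profile",
    "step_profile",
    "band_profile",
    "SpeckleSpec",
    "NoiseSpec",
    "DistractorSpec",
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "mcf10a_like",
    "mda231_like",
    "phantom_batch",
]

REFERENCE_SPACING_UM = (0.21, 0.05, 0.05)


@dataclass(frozen=True)
class NucleusSpec:
    """One ellipsoidal nucleus, optionally with angular fold perturbation.

    ``fold_amplitude`` modulates the ellipsoidal radius by a low-order
    angular harmonic (relative amplitude in [0, 1]); ``fold_phase`` rotates
    the harmonic so different nuclei fold differently.
    """

    centre_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    rotation_deg: float = 0.0  # about the Z axis
    fold_amplitude: float = 0.0
    fold_phase: float = 0.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValidationError(f"semi-axes must be > 0, got {self.semi_axes_um}")
        if not (0 <= self.fold_amplitude <= 1):
            raise ValidationError("fold_amplitude must be in [0, 1]")


@dataclass(frozen=True)
class RadialProfileSpec:
    """Generating intensity as a function of normalized depth nd in (0, 1].

    nd = 1 at the nuclear centre, nd -> 0 at the envelope (matching the
    analysis convention where layer 1 is the centre).

    kinds: ``flat(v)``; ``linear(v_centre, v_edge)``; ``step(v_in, v_out,
    depth_break)`` with v_in inside (nd > break); ``band(v_base, v_peak,
    centre_depth, width)`` — a Gaussian bump of peak value v_peak on a
    v_base pedestal, centred at centre_depth.
    """

    kind: str
    params: tuple[float, ...]

    def __call__(self, nd: np.ndarray) -> np.ndarray:
        nd = np.asarray(nd, dtype=np.float64)
        if self.kind == "flat":
            (v,) = self.params
            return np.full_like(nd, v)
        if self.kind == "linear":
            v_centre, v_edge = self.params
            return v_edge + (v_centre - v_edge) * nd
        if self.kind == "step":
            v_in, v_out, depth_break = self.params
            return np.where(nd > depth_break, v_in, v_out)
        if self.kind == "band":
            v_base, v_peak, centre_depth, width = self.params
            bump = np.exp(-0.5 * ((nd - centre_depth) / width) ** 2)
            return v_base + (v_peak - v_base) * bump
        raise ValidationError(f"unknown radial profile kind {self.kind!r}")


def flat_profile(v: float) -> RadialProfileSpec:
    return RadialProfileSpec("flat", (v,))


def linear_profile(v_centre: float, v_edge: float) -> RadialProfileSpec:
    return RadialProfileSpec("linear", (v_centre, v_edge))


def step_profile(v_in: float, v_out: float, depth_break: float) -> RadialProfileSpec:
    return RadialProfileSpec("step", (v_in, v_out, depth_break))


def band_profile(
    v_base: float, v_peak: float, centre_depth: float = 0.1, width: float = 0.3
) -> RadialProfileSpec:
    """Peripheral-enrichment band: a Gaussian bump over a pedestal.

    The default width (0.3 in normalized-depth units) produces a profile
    that rises progressively from the nuclear centre to a near-plateau over
    the outer half — the shape envelope staining shows after optical blur —
    rather than an abrupt rim spike.
    """
    return RadialProfileSpec("band", (v_base, v_peak, centre_depth, width))


@dataclass(frozen=True)
class SpeckleSpec:
    """Punctate staining: point emitters blurred by an anisotropic PSF.

    density is puncta per µm³ of nuclear volume; amplitude is the
    approximate peak intensity added by an isolated punctum; psf_sigma_um
    defaults correspond to ~400 nm axial / ~140 nm lateral FWHM.
    """

    density_per_um3: float = 0.0
    amplitude: float = 0.0
    psf_sigma_um: tuple[float, float, float] = (0.17, 0.06, 0.06)

    def __post_init__(self) -> None:
        if self.density_per_um3 < 0 or self.amplitude < 0:
            raise ValidationError("speckle density and amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Poisson photon noise on scaled signal plus additive Gaussian read noise.

    The Poisson step draws counts ~ Poisson(intensity * poisson_scale) and
    divides by the scale, so poisson_scale is photons per intensity unit;
    0 disables it. Both set to 0 give exact, noise-free volumes.
    """

    poisson_scale: float = 0.0
    gaussian_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.poisson_scale < 0 or self.gaussian_sd < 0:
            raise ValidationError("noise parameters must be >= 0")


@dataclass(frozen=True)
class DistractorSpec:
    """A border-touching blob (partial cell, debris) for border-clearing tests.

    Rendered as an ellipsoid allowed to extend outside the grid; intensity
    comparable to nuclear signal so it survives thresholding.
    """

    centre_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    intensity: float = 120.0


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of a synthetic stack; identical config + seed gives
    bit-identical volumes."""

    shape: tuple[int, int, int]
    spacing_um: tuple[float, float, float] = REFERENCE_SPACING_UM
    nuclei: tuple[NucleusSpec, ...] = ()
    radial_profile: RadialProfileSpec = field(default_factory=lambda: flat_profile(100.0))
    speckle: SpeckleSpec = field(default_factory=SpeckleSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    background_level: float = 10.0
    distractors: tuple[DistractorSpec, ...] = ()
    metric_mode: str = "physical"
    seed: int = 0
    condition: str = ""
    source_id: str = "phantom"

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 2 for n in self.shape):
            raise ValidationError(f"shape must be 3 axes of >= 2 voxels, got {self.shape}")
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")
        object.__setattr__(self, "nuclei", tuple(self.nuclei))
        object.__setattr__(self, "distractors", tuple(self.distractors))


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth derived from the configuration before noise.

    ``nd`` is the true normalized depth per foreground voxel (0 outside);
    ``noiseless`` includes the speckle field but no noise. Layer labels,
    layer means, RO means and folds for any K are computed on demand with
    the same distance metric and binning rule the pipeline uses.
    """

    config: PhantomConfig
    mask: np.ndarray  # true nucleus labels (distractors excluded)
    nd: np.ndarray
    noiseless: np.ndarray

    def label_mask(self) -> LabelMask:
        return LabelMask(self.mask, self.config.spacing_um)

    def layer_assignment(self, K: int) -> np.ndarray:
        labels = self.label_mask()
        dmap = distance_transform(labels, self.config.metric_mode)
        return assign_shells(dmap, labels, K).layer

    def layer_means(self, K: int) -> np.ndarray:
        """True per-layer means of the noiseless intensity, averaged over nuclei."""
        layer = self.layer_assignment(K)
        per_nucleus = []
        for nucleus_id in np.unique(self.mask[self.mask > 0]):
            sel = self.mask == nucleus_id
            counts = np.bincount(layer[sel], minlength=K + 1)[1:]
            sums = np.bincount(layer[sel], weights=self.noiseless[sel], minlength=K + 1)[1:]
            with np.errstate(invalid="ignore"):
                per_nucleus.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
        return np.nanmean(np.vstack(per_nucleus), axis=0)

    def ro_means(self, K: int = 24, ro_size: int = 4) -> np.ndarray:
        """True per-RO means (voxel-weighted within each nucleus, then averaged)."""
        layer = self.layer_assignment(K)
        n_ro = K // ro_size
        ro_of_layer = np.concatenate([[0], (np.arange(1, K + 1) - 1) // ro_size + 1])
        ro_grid = ro_of_layer[layer]
        per_nucleus = []
        for nucleus_id in np.unique(self.mask[self.mask > 0]):
            sel = self.mask == nucleus_id
            counts = np.bincount(ro_grid[sel], minlength=n_ro + 1)[1:]
            sums = np.bincount(ro_grid[sel], weights=self.noiseless[sel], minlength=n_ro + 1)[1:]
            with np.errstate(invalid="ignore"):
                per_nucleus.append(np.where(counts > 0, sums / np.maximum(counts, 1), np.nan))
        return np.nanmean(np.vstack(per_nucleus), axis=0)

    def fold(self, K: int = 24, ro_size: int = 4) -> float:
        """True RO-last / RO-first fold of the noiseless intensity."""
        ro = self.ro_means(K, ro_size)
        return float(ro[-1] / ro[0])


def _coordinate_grids(shape, spacing_um):
    axes = [np.arange(n) * d for n, d in zip(shape, spacing_um)]
    return np.meshgrid(*axes, indexing="ij")


def _render_ellipsoid(grids, spec: NucleusSpec) -> np.ndarray:
    """Boolean mask of a (possibly folded, Z-rotated) ellipsoid."""
    zz, yy, xx = grids
    pz = zz - spec.centre_um[0]
    py = yy - spec.centre_um[1]
    px = xx - spec.centre_um[2]
    if spec.rotation_deg:
        th = np.deg2rad(spec.rotation_deg)
        px, py = px * np.cos(th) + py * np.sin(th), -px * np.sin(th) + py * np.cos(th)
    az, ay, ax = spec.semi_axes_um
    rho = np.sqrt((pz / az) ** 2 + (py / ay) ** 2 + (px / ax) ** 2)
    if spec.fold_amplitude == 0:
        return rho <= 1.0
    # low-order angular harmonic of the surface radius: reproduces smooth
    # nuclear folds/indentations with two parameters
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sqrt(px**2 + py**2 + pz**2)
        theta = np.arccos(np.clip(np.where(r > 0, pz / np.maximum(r, 1e-12), 1.0), -1, 1))
        phi = np.arctan2(py, px)
    modulation = (
        0.6 * np.cos(3 * phi + spec.fold_phase) * np.sin(theta) ** 2
        + 0.4 * np.cos(2 * theta + 0.5 * spec.fold_phase)
    )
    return rho <= 1.0 + spec.fold_amplitude * modulation


def generate_phantom(config: PhantomConfig) -> tuple[VolumeImage, PhantomTruth]:
    """Render a phantom stack and its ground truth.

    Nuclei must fit inside the grid and not overlap; distractors may touch
    or cross the lateral borders. Truth (mask, depth, noiseless intensity)
    is populated before noise is applied.
    """
    if not config.nuclei:
        raise ConfigurationError("phantom needs at least one nucleus")
    grids = _coordinate_grids(config.shape, config.spacing_um)
    mask = np.zeros(config.shape, dtype=np.int32)
    for idx, spec in enumerate(config.nuclei, start=1):
        nucleus = _render_ellipsoid(grids, spec)
        if not nucleus.any():
            raise ConfigurationError(f"nucleus {idx} renders to zero voxels")
        if (mask[nucleus] > 0).any():
            raise ConfigurationError(f"nucleus {idx} overlaps an earlier nucleus")
        border = (
            nucleus[:, 0, :].any() or nucleus[:, -1, :].any()
            or nucleus[:, :, 0].any() or nucleus[:, :, -1].any()
        )
        if border:
            raise ConfigurationError(
                f"nucleus {idx} touches a lateral border; use a DistractorSpec for that"
            )
        mask[nucleus] = idx

    labels = LabelMask(mask, config.spacing_um)
    dmap = distance_transform(labels, config.metric_mode)
    nd = np.zeros(config.shape, dtype=np.float64)
    for nucleus_id in labels.ids:
        sel = mask == nucleus_id
        d_max = dmap.dist[sel].max()
        nd[sel] = dmap.dist[sel] / d_max

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    fg = mask > 0
    noiseless = np.full(config.shape, float(config.background_level))
    noiseless[fg] = config.radial_profile(nd[fg])

    if config.speckle.density_per_um3 > 0 and config.speckle.amplitude > 0:
        voxel_vol = float(np.prod(config.spacing_um))
        fg_idx = np.flatnonzero(fg.ravel())
        n_puncta = rng.poisson(config.speckle.density_per_um3 * voxel_vol * fg_idx.size)
        if n_puncta > 0:
            chosen = rng.choice(fg_idx, size=n_puncta, replace=True)
            sigma_vox = [s / d for s, d in zip(config.speckle.psf_sigma_um, config.spacing_um)]
            # impulse height chosen so an isolated smoothed punctum peaks at
            # roughly `amplitude`
            kernel_peak = float(np.prod([1.0 / (np.sqrt(2 * np.pi) * max(s, 1e-6)) for s in sigma_vox]))
            impulses = np.zeros(config.shape, dtype=np.float64).ravel()
            np.add.at(impulses, chosen, config.speckle.amplitude / max(kernel_peak, 1e-12))
            speckle_field = ndimage.gaussian_filter(
                impulses.reshape(config.shape), sigma=sigma_vox, mode="constant"
            )
            speckle_field[~fg] = 0.0  # envelope staining stays nuclear
            noiseless = noiseless + speckle_field

    for d in config.distractors:
        blob = _render_ellipsoid(grids, NucleusSpec(d.centre_um, d.semi_axes_um))
        noiseless[blob & ~fg] = d.intensity

    truth = PhantomTruth(config=config, mask=mask, nd=nd, noiseless=noiseless.copy())

    noisy = noiseless
    if config.noise.poisson_scale > 0:
        noisy = rng.poisson(noisy * config.noise.poisson_scale) / config.noise.poisson_scale
    if config.noise.gaussian_sd > 0:
        noisy = noisy + rng.normal(0.0, config.noise.gaussian_sd, size=config.shape)
    noisy = np.clip(noisy, 0.0, None).astype(np.float32)

    img = VolumeImage(
        noisy, config.spacing_um, condition=config.condition, source_id=config.source_id
    )
    return img, truth


# ---------------------------------------------------------------------------
# Presets: the two nuclear morphology regimes
# ---------------------------------------------------------------------------

_MCF10A_SHAPE = (24, 192, 192)
_MDA231_SHAPE = (32, 176, 176)

# nucleus-to-nucleus variability in overall staining brightness
# (coefficient of variation of a lognormal multiplicative factor)
_BRIGHTNESS_CV = 0.10


def _scale_profile(profile: RadialProfileSpec, factor: float) -> RadialProfileSpec:
    """Scale a profile's intensity parameters, leaving its geometry alone."""
    p = profile.params
    if profile.kind in ("flat", "linear"):
        return RadialProfileSpec(profile.kind, tuple(v * factor for v in p))
    if profile.kind == "step":
        return RadialProfileSpec("step", (p[0] * factor, p[1] * factor, p[2]))
    if profile.kind == "band":
        return RadialProfileSpec("band", (p[0] * factor, p[1] * factor, p[2], p[3]))
    raise ValidationError(f"unknown radial profile kind {profile.kind!r}")


def _preset(
    seed: int,
    shape: tuple[int, int, int],
    semi_axes_um: tuple[float, float, float],
    fold_amplitude: float,
    speckle: SpeckleSpec,
    profile: RadialProfileSpec,
    condition: str,
    source_id: str,
    noise: NoiseSpec,
    distractors: tuple[DistractorSpec, ...] = (),
) -> tuple[VolumeImage, PhantomTruth]:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # ±5% per-axis size jitter and ~10% lognormal brightness jitter:
    # nucleus-to-nucleus variability in size and staining efficiency
    jitter = rng.uniform(0.95, 1.05, size=3)
    axes = tuple(a * j for a, j in zip(semi_axes_um, jitter))
    brightness = float(rng.lognormal(mean=0.0, sigma=_BRIGHTNESS_CV))
    centre = tuple((n - 1) * d / 2 for n, d in zip(shape, REFERENCE_SPACING_UM))
    nucleus = NucleusSpec(
        centre_um=centre,
        semi_axes_um=axes,
        rotation_deg=float(rng.uniform(0, 180)),
        fold_amplitude=fold_amplitude,
        fold_phase=float(rng.uniform(0, 2 * np.pi)),
    )
    config = PhantomConfig(
        shape=shape,
        spacing_um=REFERENCE_SPACING_UM,
        nuclei=(nucleus,),
        radial_profile=_scale_profile(profile, brightness),
        speckle=speckle,
        noise=noise,
        background_level=10.0,
        distractors=distractors,
        seed=int(rng.integers(0, 2**31 - 1)),
        condition=condition,
        source_id=source_id,
    )
    return generate_phantom(config)


def mcf10a_like(
    seed: int,
    condition: str = "minusDTT",
    source_id: str | None = None,
    profile: RadialProfileSpec | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[VolumeImage, PhantomTruth]:
    """Flat, disc-like nucleus (Z semi-axis << XY), regular outline.

    Peripheral-enrichment band profile peaked near nd = 0.1, ~2.5-fold
    edge contrast over the pedestal by construction.
    """
    return _preset(
        seed,
        _MCF10A_SHAPE,
        semi_axes_um=(1.6, 4.0, 4.0),
        fold_amplitude=0.0,
        speckle=SpeckleSpec(density_per_um3=0.3, amplitude=80.0),
        profile=profile or band_profile(100.0, 260.0),
        condition=condition,
        source_id=source_id or f"mcf10a_{seed}",
        noise=noise or NoiseSpec(poisson_scale=0.5, gaussian_sd=2.0),
    )


def mda231_like(
    seed: int,
    condition: str = "minusDTT",
    source_id: str | None = None,
    profile: RadialProfileSpec | None = None,
    noise: NoiseSpec | None = None,
) -> tuple[VolumeImage, PhantomTruth]:
    """Taller, irregular nucleus with surface folds and brighter puncta."""
    return _preset(
        seed,
        _MDA231_SHAPE,
        semi_axes_um=(2.4, 3.6, 3.4),
        fold_amplitude=0.15,
        speckle=SpeckleSpec(density_per_um3=0.4, amplitude=140.0),
        profile=profile or band_profile(110.0, 300.0),
        condition=condition,
        source_id=source_id or f"mda231_{seed}",
        noise=noise or NoiseSpec(poisson_scale=0.5, gaussian_sd=2.0),
    )


def phantom_batch(
    preset: Callable[..., tuple[VolumeImage, PhantomTruth]],
    n: int,
    seed: int,
    **kwargs,
) -> list[tuple[VolumeImage, PhantomTruth]]:
    """n phantoms with independent per-phantom streams spawned from one seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
        out.append(preset(child_seed, **{"source_id": None, **kwargs}))
    return out
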