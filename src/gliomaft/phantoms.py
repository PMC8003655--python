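"""Synthetic multi-facility brain phantoms with tumors.

Generates skull-free 4-channel (T1, T2, FLAIR, GdT1) volumes containing
a three-compartment tumor (necrotic core / enhancing rim / edema, BraTS
label codes 1 / 4 / 2) inside an ellipsoidal "brain" with smooth
low-frequency internal texture. A :class:`FacilitySpec` then emulates one
facility's acquisition characteristics by a fixed sequence of intensity
transforms:

    scale/offset -> gamma -> multiplicative bias field ->
    slice-thickness degradation -> additive Gaussian noise

The order is part of the contract (the transforms do not commute).
Intensities are generated on a normalized [0, 1]-ish scale and are
strictly positive inside the brain, so the pointwise gamma power is
well defined. Labels are never touched by facility transforms.

Channel contrast follows the usual glioma appearance: tumor and edema
hyperintense on T2/FLAIR, enhancing rim bright on GdT1, necrotic core
dark on T1 and GdT1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .volio import Volume4Ch

__all__ = [
    "FacilitySpec",
    "TumorParams",
    "TumorSampler",
    "PhantomCase",
    "make_base_phantom",
    "apply_facility_transform",
    "generate_facility_dataset",
    "load_facility_specs",
    "DEFAULT_METADATA_LABELS",
]

#: Arbitrary diagnosis-like strata attached to generated cases so that
#: group-by machinery downstream has something to group on.
DEFAULT_METADATA_LABELS = ("astrocytoma", "oligodendroglioma", "glioblastoma")

# Noise-free per-channel mean intensities (normalized units). Contrasts are
# deliberately modest — comparable to the texture and facility-noise scales —
# so that segmentation is a genuine learning problem rather than a threshold,
# and acquisition differences can measurably degrade an unadapted model.
_TISSUE = {"T1": 0.55, "T2": 0.45, "FLAIR": 0.48, "GdT1": 0.50}
_EDEMA = {"T1": 0.48, "T2": 0.55, "FLAIR": 0.58, "GdT1": 0.50}
_RIM = {"T1": 0.51, "T2": 0.57, "FLAIR": 0.57, "GdT1": 0.62}
_CORE = {"T1": 0.42, "T2": 0.60, "FLAIR": 0.53, "GdT1": 0.42}
_CHANNELS = ("T1", "T2", "FLAIR", "GdT1")

# Two-scale internal texture: a fine component (local tissue heterogeneity)
# plus a strong coarse component (anatomical intensity gradients). The coarse
# component spreads absolute intensity levels across the brain, which is what
# makes nonlinear acquisition effects (gamma) spatially non-uniform after
# per-case normalization.
_TEXTURE_FINE_AMPLITUDE = 0.05
_TEXTURE_FINE_SIGMA = 2.0
_TEXTURE_COARSE_AMPLITUDE = 0.12
_TEXTURE_COARSE_SIGMA = 6.0
_BRAIN_FRACTION = 0.42  # brain semi-axis as a fraction of each dimension


@dataclass(frozen=True)
class FacilitySpec:
    """Acquisition characteristics of one simulated facility (domain).

    ``intensity_scale`` / ``intensity_offset`` may be scalars or
    per-channel length-4 sequences. ``slice_thickness_factor`` k >= 1
    block-averages groups of k slices along z and replicates them back,
    emulating thick-slice acquisition (with 1 mm base spacing, k in 3-9
    covers the 3.3-9 mm slice-thickness range seen across real scanners).
    """

    facility_id: str
    intensity_scale: float | tuple = 1.0
    intensity_offset: float | tuple = 0.0
    gamma: float = 1.0
    bias_field_amplitude: float = 0.0
    noise_sigma: float = 0.0
    slice_thickness_factor: int = 1
    rng_seed_offset: int = 0

    def __post_init__(self):
        scale = np.atleast_1d(np.asarray(self.intensity_scale, dtype=float))
        if np.any(scale <= 0):
            raise ValueError("intensity_scale must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be nonnegative")
        if int(self.slice_thickness_factor) < 1 or self.slice_thickness_factor != int(self.slice_thickness_factor):
            raise ValueError("slice_thickness_factor must be an integer >= 1")

    def _per_channel(self, value) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=np.float32))
        if arr.size == 1:
            arr = np.repeat(arr, 4)
        if arr.size != 4:
            raise ValueError("per-channel parameter must be scalar or length 4")
        return arr.reshape(4, 1, 1, 1)


@dataclass(frozen=True)
class TumorParams:
    """Geometry of one tumor: concentric ellipsoidal compartments.

    ``radii`` are the semi-axes (voxels) of the outer edge of the
    enhancing rim; the necrotic core ends ``rim_width`` inside it and
    edema extends ``edema_width`` beyond it. ``radii == 0`` yields an
    empty tumor.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    rim_width: float = 1.2
    edema_width: float | None = None

    def __post_init__(self):
        if self.edema_width is None:
            object.__setattr__(self, "edema_width", self.rim_width)
        if self.rim_width < 0 or self.edema_width < 0:
            raise ValueError("rim_width and edema_width must be nonnegative")
        if any(r < 0 for r in self.radii):
            raise ValueError("radii must be nonnegative")


@dataclass
class PhantomCase:
    """One synthetic case: volume, sub-region labels, and metadata."""

    volume: Volume4Ch
    labels: np.ndarray
    facility_id: str = ""
    metadata_label: str = ""
    tumor_volume_ml: float = 0.0

    def __post_init__(self):
        if self.labels.shape != self.volume.shape:
            raise ValueError("labels shape does not match volume shape")

    @property
    def case_id(self) -> str:
        return self.volume.identifier


def _ellipsoid_field(shape, center, radii) -> np.ndarray:
    """Normalized squared ellipsoidal distance (<= 1 means inside)."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, radii):
        if r <= 0:
            return np.full(shape, np.inf)
        acc = acc + ((g - c) / r) ** 2
    return acc


def _tumor_labels(shape, tumor: TumorParams, brain_mask: np.ndarray) -> np.ndarray:
    labels = np.zeros(shape, dtype=np.int16)
    if all(r == 0 for r in tumor.radii):
        return labels
    outer = _ellipsoid_field(shape, tumor.center, tumor.radii) <= 1.0
    core_radii = tuple(max(r - tumor.rim_width, 0.0) for r in tumor.radii)
    core = _ellipsoid_field(shape, tumor.center, core_radii) <= 1.0
    edema_radii = tuple(r + tumor.edema_width for r in tumor.radii)
    edema = _ellipsoid_field(shape, tumor.center, edema_radii) <= 1.0
    labels[edema & brain_mask] = 2
    labels[outer & brain_mask] = 4
    labels[core & brain_mask] = 1
    return labels


def make_base_phantom(
    shape: tuple[int, int, int],
    tumor_params: TumorParams,
    seed: int,
    spacing=(1.0, 1.0, 1.0),
    identifier: str = "",
    metadata_label: str = "",
) -> PhantomCase:
    """Generate one skull-free phantom with a three-compartment tumor.

    Deterministic given ``(shape, tumor_params, seed)``. Voxels outside
    the brain ellipsoid are exactly zero; inside they are strictly
    positive.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError(f"shape must be 3 integers, each >= 8; got {shape}")

    brain_center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple(_BRAIN_FRACTION * s for s in shape)
    # conservative containment: per-axis interval check of the edema extent
    if any(r > 0 for r in tumor_params.radii):
        for ax, (c, r) in enumerate(zip(tumor_params.center, tumor_params.radii)):
            extent = r + tumor_params.edema_width
            if abs(c - brain_center[ax]) + extent > brain_radii[ax]:
                raise ValueError(
                    f"tumor radius {r} (+edema {tumor_params.edema_width}) along axis {ax} "
                    f"does not fit inside the brain ellipsoid (semi-axis {brain_radii[ax]:.1f})"
                )

    brain_mask = _ellipsoid_field(shape, brain_center, brain_radii) <= 1.0
    labels = _tumor_labels(shape, tumor_params, brain_mask)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    data = np.zeros((4,) + shape, dtype=np.float32)
    for c, name in enumerate(_CHANNELS):
        base = np.full(shape, _TISSUE[name], dtype=np.float32)
        base[labels == 2] = _EDEMA[name]
        base[labels == 4] = _RIM[name]
        base[labels == 1] = _CORE[name]
        texture = np.zeros(shape, dtype=np.float32)
        for amp, sigma in (
            (_TEXTURE_FINE_AMPLITUDE, _TEXTURE_FINE_SIGMA),
            (_TEXTURE_COARSE_AMPLITUDE, _TEXTURE_COARSE_SIGMA),
        ):
            f = gaussian_filter(rng.standard_normal(shape).astype(np.float32), sigma)
            fstd = f.std()
            if fstd > 0:
                texture += f * (amp / fstd)
        ch = np.clip(base + texture, 0.05, None)
        ch[~brain_mask] = 0.0
        data[c] = ch

    vol = Volume4Ch(data, spacing=spacing, identifier=identifier)
    tumor_ml = float((labels != 0).sum()) * vol.voxel_volume_mm3 / 1000.0
    return PhantomCase(
        volume=vol,
        labels=labels,
        metadata_label=metadata_label,
        tumor_volume_ml=tumor_ml,
    )


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """1 + amplitude * P(x, y, z) with P a degree-<=2 polynomial, max|P| = 1.

    One independent field per channel: each MR sequence is a separate
    acquisition with its own coil/shim state, so inhomogeneity is not
    shared across channels.
    """
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * x, y * y, z * z, x * y, x * z, y * z]
    fields = np.empty((4,) + tuple(shape), dtype=np.float32)
    for c in range(4):
        coef = rng.uniform(-1.0, 1.0, size=len(terms))
        p = sum(cf * t for cf, t in zip(coef, terms))
        peak = np.abs(p).max()
        if peak > 0:
            p /= peak
        fields[c] = 1.0 + amplitude * p
    return fields


def _slab_average_z(data: np.ndarray, factor: int) -> np.ndarray:
    """Block-average groups of ``factor`` slices along z, replicate back."""
    nz = data.shape[-1]
    out = np.empty_like(data)
    for start in range(0, nz, factor):
        stop = min(start + factor, nz)
        mean = data[..., start:stop].mean(axis=-1, keepdims=True)
        out[..., start:stop] = mean
    return out


def apply_facility_transform(case: PhantomCase, spec: FacilitySpec, seed: int) -> PhantomCase:
    """Apply one facility's acquisition transform to a phantom case.

    Labels are unchanged. Intensity stages run in the fixed order
    scale/offset -> gamma -> bias -> slice thickness -> noise; stages at
    their identity value are skipped, so an all-identity spec returns a
    bit-identical copy. Deterministic given ``(spec, seed)``: the bias
    and noise draws use independent substreams so that skipping one
    stage does not change the other.
    """
    ss = np.random.SeedSequence([int(seed), int(spec.rng_seed_offset), 1031])
    bias_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    data = case.volume.data.astype(np.float32).copy()
    support = np.any(case.volume.data != 0, axis=0)

    scale = spec._per_channel(spec.intensity_scale)
    offset = spec._per_channel(spec.intensity_offset)
    if np.any(scale != 1.0) or np.any(offset != 0.0):
        data = np.where(support[None], data * scale + offset, data)

    if spec.gamma != 1.0:
        inside = data[:, support]
        if inside.min() <= 0:
            raise ValueError(
                "gamma transform requires strictly positive in-brain intensities; "
                "shift intensities before applying gamma"
            )
        data[:, support] = inside ** np.float32(spec.gamma)

    if spec.bias_field_amplitude > 0:
        data *= _bias_field(case.volume.shape, spec.bias_field_amplitude, bias_rng)

    k = int(spec.slice_thickness_factor)
    if k > 1:
        data = _slab_average_z(data, k)

    if spec.noise_sigma > 0:
        noise = noise_rng.normal(0.0, spec.noise_sigma, size=data.shape).astype(np.float32)
        data[:, support] += noise[:, support]

    data[:, ~support] = 0.0

    vol = Volume4Ch(data, spacing=case.volume.spacing, identifier=case.volume.identifier)
    return PhantomCase(
        volume=vol,
        labels=case.labels.copy(),
        facility_id=spec.facility_id,
        metadata_label=case.metadata_label,
        tumor_volume_ml=case.tumor_volume_ml,
    )


@dataclass(frozen=True)
class TumorSampler:
    """Distribution over tumor geometries for dataset generation.

    Radii are drawn uniformly from ``radius_range`` (spherical tumors
    by default); the center is jittered uniformly within
    ``center_jitter`` voxels of the brain center on each axis. Samples
    are clipped so the tumor always satisfies the containment check.
    """

    radius_range: tuple[float, float] = (3.5, 6.0)
    rim_width: float = 1.2
    edema_width: float = 1.8
    center_jitter: float = 3.0

    def sample(self, rng: np.random.Generator, shape) -> TumorParams:
        lo, hi = self.radius_range
        r = float(rng.uniform(lo, hi))
        # clamp so the edema shell always fits inside the brain ellipsoid
        r_max = _BRAIN_FRACTION * min(shape) - self.edema_width - 0.5
        r = min(r, max(r_max, 0.0))
        center = []
        for s in shape:
            c = (s - 1) / 2.0
            brain_r = _BRAIN_FRACTION * s
            max_off = max(brain_r - (r + self.edema_width), 0.0)
            jit = min(self.center_jitter, max_off)
            center.append(c + float(rng.uniform(-jit, jit)))
        return TumorParams(
            center=tuple(center),
            radii=(r, r, r),
            rim_width=self.rim_width,
            edema_width=self.edema_width,
        )


@dataclass(frozen=True)
class EmptyTumorSampler:
    """Sampler that always yields an empty tumor (for degenerate tests)."""

    def sample(self, rng, shape) -> TumorParams:
        c = tuple((s - 1) / 2.0 for s in shape)
        return TumorParams(center=c, radii=(0.0, 0.0, 0.0))


def generate_facility_dataset(
    spec: FacilitySpec,
    n_cases: int,
    shape,
    tumor_sampler: TumorSampler | None = None,
    seed: int = 0,
    spacing=(1.0, 1.0, 1.0),
    metadata_labels=DEFAULT_METADATA_LABELS,
    id_prefix: str | None = None,
) -> list[PhantomCase]:
    """Generate ``n_cases`` facility-transformed phantoms.

    Per-case seeds derive deterministically from
    ``(seed, case index, spec.rng_seed_offset)``, so datasets are
    reproducible and cases are independent draws.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    sampler = tumor_sampler if tumor_sampler is not None else TumorSampler()
    prefix = id_prefix if id_prefix is not None else spec.facility_id
    cases = []
    for i in range(n_cases):
        ss = np.random.SeedSequence([int(seed), i, int(spec.rng_seed_offset), 7177])
        tumor_seed, phantom_seed, transform_seed = ss.generate_state(3) >> 1  # keep < 2**31
        rng = np.random.default_rng(int(tumor_seed))
        tumor = sampler.sample(rng, shape)
        label = metadata_labels[int(rng.integers(len(metadata_labels)))] if metadata_labels else ""
        base = make_base_phantom(
            shape,
            tumor,
            seed=int(phantom_seed),
            spacing=spacing,
            identifier=f"{prefix}_{i:03d}",
            metadata_label=label,
        )
        cases.append(apply_facility_transform(base, spec, seed=int(transform_seed)))
    return cases


def load_facility_specs(path) -> dict[str, FacilitySpec]:
    """Read facility specs from YAML: mapping facility_id -> parameters."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = {}
    for fid, params in raw.items():
        params = dict(params or {})
        params["facility_id"] = str(fid)
        if "intensity_scale" in params and isinstance(params["intensity_scale"], list):
            params["intensity_scale"] = tuple(params["intensity_scale"])
        if "intensity_offset" in params and isinstance(params["intensity_offset"], list):
            params["intensity_offset"] = tuple(params["intensity_offset"])
        specs[str(fid)] = FacilitySpec(**params)
    return specs
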