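"""Synthetic digital head phantom.

Generates a concentric-layer adult head (air / scalp fat / soft tissue /
skull / CSF / grey matter / white matter) on a regular grid together with
every raw input the downstream pipeline needs: a pseudo T1-weighted render,
pseudo Dixon water/fat channels, the true 511 keV attenuation map, an
FDG-like emission map, a pCASL control/label time series and a 13-region
ROI atlas.  Everything is a pure function of (parameters, seed), so the
whole pipeline is testable without scanner data.

Layer boundaries are built from the Euclidean distance to the scalp
surface, so each shell has uniform thickness in mm regardless of the head's
ellipsoidal shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image import Image3D

__all__ = [
    "TissueSpec",
    "Phantom",
    "ASLSeries",
    "default_tissue_specs",
    "build_head_phantom",
    "render_t1",
    "render_dixon",
    "render_emission",
    "render_asl_series",
    "ROI_NAMES",
]

# label codes, ordered inside-out along a ray from the head centre:
# wm -> gm -> csf -> skull -> soft tissue -> fat -> air
AIR, SCALP_FAT, SOFT_TISSUE, SKULL, CSF, GM, WM = 0, 1, 2, 3, 4, 5, 6
LABEL_NAMES = {
    AIR: "air",
    SCALP_FAT: "scalp_fat",
    SOFT_TISSUE: "soft_tissue",
    SKULL: "skull",
    CSF: "csf",
    GM: "gm",
    WM: "wm",
}
BRAIN_LABELS = (CSF, GM, WM)

#: the thirteen evaluation regions; geometric sectors stand in for anatomy
ROI_NAMES = [
    "frontal", "parietal", "temporal", "occipital", "cingulate", "insula",
    "cerebellum",
    "caudate", "putamen", "globus_pallidus", "thalamus", "hippocampus",
    "amygdala",
]


@dataclass(frozen=True)
class TissueSpec:
    """Physical properties of one tissue class.

    mu_511 is the linear attenuation coefficient at 511 keV in cm^-1;
    perfusion is in ml/100 g/min; t1_intensity and emission are in
    arbitrary units.
    """

    name: str
    t1_intensity: float
    fat_fraction: float
    mu_511: float
    emission: float
    perfusion: float

    def __post_init__(self):
        if self.mu_511 < 0:
            raise ValueError(f"{self.name}: mu_511 must be >= 0")
        if not 0.0 <= self.fat_fraction <= 1.0:
            raise ValueError(f"{self.name}: fat_fraction must be in [0, 1]")
        if self.emission < 0 or self.perfusion < 0:
            raise ValueError(f"{self.name}: emission and perfusion must be >= 0")


def default_tissue_specs() -> dict[int, TissueSpec]:
    """Default per-tissue properties.

    Attenuation coefficients follow the 511 keV segmentation convention:
    air 0, fat 0.086, soft tissue (and all brain tissue) 0.10, cortical
    bone 0.143 cm^-1.  T1 intensities are ordered bone < CSF < GM < WM
    ~= fat, the contrast that makes skull dark on T1 and invisible to
    Dixon.  GM perfusion defaults to 43.82 ml/100 g/min (a healthy-adult
    group mean) with WM at half that; emission contrast is an FDG-like
    GM:WM = 3:1.
    """
    return {
        AIR: TissueSpec("air", 0.0, 0.0, 0.0, 0.0, 0.0),
        SCALP_FAT: TissueSpec("scalp_fat", 0.95, 0.90, 0.086, 0.1, 0.0),
        SOFT_TISSUE: TissueSpec("soft_tissue", 0.70, 0.10, 0.10, 0.3, 0.0),
        SKULL: TissueSpec("skull", 0.15, 0.0, 0.143, 0.05, 0.0),
        CSF: TissueSpec("csf", 0.35, 0.0, 0.10, 0.1, 0.0),
        GM: TissueSpec("gm", 0.55, 0.0, 0.10, 3.0, 43.82),
        WM: TissueSpec("wm", 0.85, 0.0, 0.10, 1.0, 21.9),
    }


@dataclass
class Phantom:
    """Tissue-label volume plus per-tissue property table and ROI atlas."""

    labels: Image3D
    specs: dict[int, TissueSpec]
    roi_atlas: Image3D
    roi_names: dict[int, str]

    def __post_init__(self):
        lab = self.labels.data
        present = set(np.unique(lab).tolist())
        missing = present - set(self.specs)
        if missing:
            raise ValueError(f"labels without a TissueSpec: {sorted(missing)}")
        names = [s.name for s in self.specs.values()]
        if len(names) != len(set(names)):
            raise ValueError("tissue names must be unique")
        if not self.labels.same_grid(self.roi_atlas):
            raise ValueError("roi_atlas must share the phantom grid")
        brain = np.isin(lab, BRAIN_LABELS)
        if np.any((self.roi_atlas.data != 0) & ~brain):
            raise ValueError("roi_atlas nonzero outside brain tissue")

    def property_map(self, attr: str) -> Image3D:
        """Voxelwise map of one TissueSpec attribute (e.g. 'mu_511')."""
        lut = np.zeros(max(self.specs) + 1)
        for code, spec in self.specs.items():
            lut[code] = getattr(spec, attr)
        return self.labels.with_data(lut[self.labels.data])

    def mask(self, *label_codes: int) -> Image3D:
        return self.labels.with_data(
            np.isin(self.labels.data, label_codes).astype(np.uint8))

    @property
    def brain_mask(self) -> Image3D:
        return self.mask(*BRAIN_LABELS)

    def spec_table(self) -> list[dict]:
        """Serializable property table (used by the YAML writer)."""
        return [
            {"code": code, **vars(spec)} for code, spec in sorted(self.specs.items())
        ]


@dataclass
class ASLSeries:
    """Alternating control/label pCASL frames plus quantification constants.

    Frames are ordered control, label, control, label, ...; all model
    constants are in SI-ish units (seconds; partition coefficient in ml/g).
    """

    volumes: list
    m0: Image3D
    label_duration: float = 1.5
    post_label_delay: float = 1.2
    labeling_efficiency: float = 0.85 * 0.75**2
    blood_t1: float = 1.65
    partition_coefficient: float = 0.9

    def __post_init__(self):
        if len(self.volumes) % 2 != 0 or len(self.volumes) == 0:
            raise ValueError("ASL series needs an even, nonzero frame count")
        for p in ("label_duration", "post_label_delay", "labeling_efficiency",
                  "blood_t1", "partition_coefficient"):
            if getattr(self, p) <= 0:
                raise ValueError(f"{p} must be > 0")

    @property
    def n_pairs(self) -> int:
        return len(self.volumes) // 2

    def constants(self) -> dict[str, float]:
        return {
            "label_duration": self.label_duration,
            "post_label_delay": self.post_label_delay,
            "labeling_efficiency": self.labeling_efficiency,
            "blood_t1": self.blood_t1,
            "partition_coefficient": self.partition_coefficient,
        }


def _head_distance_mm(shape, spacing, semi_axes, centre):
    """Distance (mm) into the head from the scalp surface; 0 outside."""
    coords = [
        (np.arange(n) - c) * s for n, s, c in zip(shape, spacing, centre)
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt(
        (x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2 + (z / semi_axes[2]) ** 2
    )
    head = rho <= 1.0
    dist = ndimage.distance_transform_edt(head, sampling=spacing)
    return head, dist, (x, y, z)


def build_head_phantom(
    grid_shape=(128, 128, 128),
    spacing=2.0,
    skull_thickness=7.0,
    seed=0,
    semi_axes=None,
    fat_mm=3.0,
    soft_mm=4.0,
    csf_rim_mm=2.0,
    gm_shell_mm=5.0,
    specs=None,
) -> Phantom:
    """Build the concentric head phantom.

    The scalp surface is an ellipsoid; successive shells (scalp fat, soft
    tissue, skull of the requested thickness, subarachnoid CSF, a GM shell,
    a WM core with CSF ventricles) are carved by distance-to-surface bands,
    so the skull's measured thickness matches ``skull_thickness`` to within
    one voxel everywhere.  ``seed`` jitters the head's semi-axes by up to
    2% and the ventricle placement, giving distinct but statistically
    identical subjects.
    """
    grid_shape = tuple(int(n) for n in np.broadcast_to(grid_shape, (3,)))
    spacing = tuple(float(s) for s in np.broadcast_to(spacing, (3,)))
    if not 2.0 <= skull_thickness <= 12.0:
        raise ValueError("skull_thickness must be within [2, 12] mm")
    rng = np.random.default_rng(seed)

    fov = np.asarray(grid_shape) * np.asarray(spacing)
    if semi_axes is None:
        semi_axes = np.array([80.0, 95.0, 85.0])
    semi_axes = np.asarray(semi_axes, float) * (1.0 + 0.02 * rng.uniform(-1, 1, 3))
    # keep an air margin so every layer (and outside air) fits in the grid
    margin = np.maximum(4.0 * np.asarray(spacing), 8.0)
    semi_axes = np.minimum(semi_axes, fov / 2.0 - margin)

    depth_to_wm = fat_mm + soft_mm + skull_thickness + csf_rim_mm + gm_shell_mm
    if depth_to_wm >= semi_axes.min():
        raise ValueError(
            f"skull_thickness {skull_thickness} mm leaves no room for brain "
            f"inside semi-axes {np.round(semi_axes, 1)} mm"
        )

    centre = (np.asarray(grid_shape) - 1) / 2.0
    head, dist, (x, y, z) = _head_distance_mm(grid_shape, spacing, semi_axes, centre)

    lab = np.zeros(grid_shape, dtype=np.int16)
    b0 = fat_mm
    b1 = b0 + soft_mm
    b2 = b1 + skull_thickness
    b3 = b2 + csf_rim_mm
    b4 = b3 + gm_shell_mm
    lab[head & (dist <= b0)] = SCALP_FAT
    lab[head & (dist > b0) & (dist <= b1)] = SOFT_TISSUE
    lab[head & (dist > b1) & (dist <= b2)] = SKULL
    lab[head & (dist > b2) & (dist <= b3)] = CSF
    lab[head & (dist > b3) & (dist <= b4)] = GM
    lab[head & (dist > b4)] = WM
    if not np.any(lab == WM):
        raise ValueError("geometry error: no white-matter core at this grid")

    # lateral-ventricle pair: CSF ellipsoids inside the WM core
    for sign in (-1.0, 1.0):
        cx = sign * (12.0 + 2.0 * rng.uniform(-1, 1))
        cy = 2.0 * rng.uniform(-1, 1)
        vent = (
            ((x - cx) / 8.0) ** 2 + ((y - cy) / 20.0) ** 2 + (z / 8.0) ** 2
        ) <= 1.0
        lab[vent & (lab == WM)] = CSF

    labels = Image3D(lab, spacing=spacing)
    atlas, roi_names = _build_roi_atlas(lab, x, y, z, semi_axes)
    return Phantom(
        labels=labels,
        specs=specs if specs is not None else default_tissue_specs(),
        roi_atlas=labels.with_data(atlas),
        roi_names=roi_names,
    )


def _build_roi_atlas(lab, x, y, z, semi_axes):
    """Partition the brain into 13 named geometric regions.

    Deep brain (normalised radius < 0.4) is split into six azimuthal
    sectors named after the deep-grey structures; the remainder is split
    into a bottom 'cerebellum' cap plus six cortical sectors.  The names
    mirror the conventional a-priori ROI list for FDG brain studies; the
    geometry is deliberately schematic.
    """
    brain = np.isin(lab, BRAIN_LABELS)
    r = np.sqrt(
        (x / semi_axes[0]) ** 2 + (y / semi_axes[1]) ** 2 + (z / semi_axes[2]) ** 2
    )
    azimuth = np.arctan2(y, x)  # [-pi, pi)
    sector = np.floor((azimuth + np.pi) / (2 * np.pi) * 6).astype(int).clip(0, 5)

    atlas = np.zeros(lab.shape, dtype=np.int16)
    cortical_names = ["frontal", "parietal", "temporal", "occipital",
                      "cingulate", "insula"]
    deep_names = ["caudate", "putamen", "globus_pallidus", "thalamus",
                  "hippocampus", "amygdala"]
    codes = {name: i + 1 for i, name in enumerate(ROI_NAMES)}

    deep = brain & (r < 0.4)
    cerebellum = brain & (r >= 0.4) & (z < -0.45 * semi_axes[2])
    cortical = brain & (r >= 0.4) & ~cerebellum
    for s, name in enumerate(deep_names):
        atlas[deep & (sector == s)] = codes[name]
    atlas[cerebellum] = codes["cerebellum"]
    for s, name in enumerate(cortical_names):
        atlas[cortical & (sector == s)] = codes[name]
    return atlas, {v: k for k, v in codes.items()}


def _bias_field(shape, amplitude, rng):
    """Smooth multiplicative bias: 1 + amplitude * (2nd-order polynomial
    normalised to unit max magnitude)."""
    if amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(-1, 1, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coef = rng.uniform(-1, 1, len(terms))
    poly = sum(c * t for c, t in zip(coef, terms))
    peak = np.abs(poly).max()
    if peak > 0:
        poly = poly / peak
    return 1.0 + amplitude * poly


def render_t1(phantom: Phantom, noise_sd=0.05, bias_amplitude=0.10, seed=0) -> Image3D:
    """Pseudo T1-weighted render.

    Voxel intensity = tissue t1_intensity x smooth multiplicative bias
    field (2nd-order polynomial, amplitude +/- ``bias_amplitude``) plus
    Gaussian noise with SD = ``noise_sd`` x the tissue's mean intensity.
    """
    if noise_sd < 0 or bias_amplitude < 0:
        raise ValueError("noise_sd and bias_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    mean = phantom.property_map("t1_intensity").data
    bias = _bias_field(mean.shape, bias_amplitude, rng)
    noise = rng.standard_normal(mean.shape) * (noise_sd * mean)
    return phantom.labels.with_data(mean * bias + noise)


def render_dixon(phantom: Phantom, noise_sd=0.05, seed=0):
    """Pseudo Dixon water/fat channel pair.

    The per-tissue signal is split water = (1 - fat_fraction) x signal,
    fat = fat_fraction x signal.  Skull carries low signal in both
    channels, which is why a Dixon-only attenuation map cannot see bone.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    signal = phantom.property_map("t1_intensity").data
    ff = phantom.property_map("fat_fraction").data
    water = signal * (1.0 - ff)
    fat = signal * ff
    scale = noise_sd * signal
    water = water + rng.standard_normal(signal.shape) * scale
    fat = fat + rng.standard_normal(signal.shape) * scale
    return phantom.labels.with_data(water), phantom.labels.with_data(fat)


def render_emission(phantom: Phantom) -> Image3D:
    """FDG-like activity map: exactly spec.emission per voxel (noise enters
    later, in projection space, as Poisson counts)."""
    return phantom.property_map("emission")


def true_mumap_image(phantom: Phantom) -> Image3D:
    """Ground-truth 511 keV attenuation map in cm^-1."""
    return phantom.property_map("mu_511")


def render_asl_series(
    phantom: Phantom,
    n_pairs=64,
    noise_sd=0.01,
    params: ASLSeries | None = None,
    seed=0,
    m0_scale=100.0,
) -> ASLSeries:
    """Render a pCASL control/label series.

    Control frames are the M0 baseline plus Gaussian noise; label frames
    subtract the perfusion-weighted signal dM predicted by the same
    single-compartment model the quantifier inverts, so a noiseless series
    round-trips exactly.  Noise SD is ``noise_sd`` x the mean head M0 per
    frame; M0 itself is rendered noiselessly as m0_scale x t1_intensity.
    """
    from .aslquant import delta_m_from_cbf  # shared forward model

    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    defaults = params if params is not None else ASLSeries(
        volumes=[phantom.labels, phantom.labels], m0=phantom.labels)
    consts = defaults.constants()

    m0 = phantom.labels.with_data(
        m0_scale * phantom.property_map("t1_intensity").data)
    cbf = phantom.property_map("perfusion").data
    dm = delta_m_from_cbf(cbf, m0.data, **consts)

    head = phantom.labels.data != AIR
    sd = noise_sd * (m0.data[head].mean() if head.any() else 1.0)
    baseline = np.asarray(m0.data, np.float32)
    labelled = np.asarray(m0.data - dm, np.float32)
    frames = []
    for _ in range(n_pairs):
        # float32 frames: a 64-pair whole-head series stays desk-sized
        noise_c = (rng.standard_normal(baseline.shape) * sd).astype(np.float32)
        noise_l = (rng.standard_normal(baseline.shape) * sd).astype(np.float32)
        frames.append(m0.with_data(baseline + noise_c))
        frames.append(m0.with_data(labelled + noise_l))
    return ASLSeries(volumes=frames, m0=m0, **consts)
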