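"""Synthetic multi-modal brain phantoms with ground-truth lesion masks.

Each phantom subject mimics the structure of a sub-acute stroke segmentation
dataset: four co-registered modality volumes (T1, T2, FLAIR, DWI) on a 1 mm
grid plus an expert-style binary lesion mask.  Geometry is deliberately
simple — nested ellipsoids for CSF shell, GM band and WM core, plus one
spherical lesion — which is enough to exercise windowed neighborhood
features and tissue-interface failure modes without real anatomy.

Intensities follow the Gaussian tissue model the downstream clustering
assumes: every voxel of class ``c`` in modality ``m`` draws from
``Normal(class_means[c, m], class_sds[c, m])``, with mean/sd >= 3 everywhere
(the signal-to-noise regime in which MRI noise is approximately Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volumes_io import MultiModalVolume

# Label codes in truth volumes.
BACKGROUND, CSF, GM, WM, LESION = 0, 1, 2, 3, 4
CLASS_NAMES = {CSF: "csf", GM: "gm", WM: "wm", LESION: "lesion"}
#: Row order of class_means / class_sds matrices.
CLASS_ORDER = (CSF, GM, WM, LESION)
#: Column order of class_means / class_sds matrices.
MODALITY_ORDER = ("t1", "t2", "flair", "dwi")

# Brain ellipsoid semi-axes as fractions of brain_radius_mm (x, y, z), and
# the normalized radii of the WM core and GM band outer surfaces.  The CSF
# shell fills the remainder out to the brain surface.
AXIS_RATIOS = (1.0, 0.85, 0.8)
WM_FRACTION = 0.80
GM_FRACTION = 0.95

MIN_SNR = 3.0


@dataclass
class PhantomSpec:
    """Parameters of a phantom cohort; defaults come from :func:`default_spec`.

    ``lesion_radius_mm`` may be a scalar (same lesion size for every subject)
    or a sequence of length ``n_subjects`` (one size per subject, supporting
    lesion-size-versus-performance analyses).  ``lesion_center`` is in mm
    relative to the volume center.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    class_means: np.ndarray = field(default_factory=lambda: _DEFAULT_MEANS.copy())
    class_sds: np.ndarray = field(default_factory=lambda: _DEFAULT_SDS.copy())
    lesion_radius_mm: float | tuple[float, ...] = 11.0
    lesion_center: tuple[float, float, float] = (6.0, 4.0, 3.0)
    brain_radius_mm: float = 25.0
    seed: int = 0
    n_subjects: int = 1

    def lesion_radii(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.lesion_radius_mm, dtype=float))
        if r.size == 1:
            r = np.repeat(r, self.n_subjects)
        if r.size != self.n_subjects:
            raise ValueError(
                f"lesion_radius_mm has {r.size} entries for {self.n_subjects} subjects"
            )
        return r

    def validate(self) -> None:
        means = np.asarray(self.class_means, dtype=float)
        sds = np.asarray(self.class_sds, dtype=float)
        if means.shape != (4, 4) or sds.shape != (4, 4):
            raise ValueError("class_means and class_sds must be 4 classes x 4 modalities")
        if np.any(sds <= 0):
            raise ValueError("every class_sds entry must be > 0")
        snr = means / sds
        if np.any(snr < MIN_SNR):
            worst = float(snr.min())
            raise ValueError(
                f"class mean/sd ratio {worst:.3g} below {MIN_SNR}: outside the "
                "Gaussian-noise regime this phantom models"
            )
        if any(n <= 0 for n in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError(f"grid_shape must be 3 positive ints, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.brain_radius_mm <= 0:
            raise ValueError("brain_radius_mm must be positive")
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        radii = self.lesion_radii()
        if np.any(radii <= 0):
            raise ValueError("lesion_radius_mm must be positive")
        semi = np.array(AXIS_RATIOS) * self.brain_radius_mm
        c = np.asarray(self.lesion_center, dtype=float)
        # Conservative containment test: normalized center radius plus the
        # sphere radius measured against the smallest semi-axis.
        for r in radii:
            reach = float(np.sqrt(np.sum((c / semi) ** 2))) + float(r) / float(semi.min())
            if reach > 1.0:
                raise ValueError(
                    f"lesion sphere (radius {r} mm at {tuple(c)}) escapes the "
                    f"brain ellipsoid (containment measure {reach:.3f} > 1)"
                )


# Class-by-modality intensity means (rows CSF, GM, WM, LESION; columns T1,
# T2, FLAIR, DWI; arbitrary units).  The contrast pattern is qualitative MRI:
# CSF bright on T2 and suppressed (dark) on FLAIR, WM brightest on T1, the
# lesion hyperintense on FLAIR and DWI.
_DEFAULT_MEANS = np.array(
    [
        #  T1    T2  FLAIR  DWI
        [30.0, 95.0, 20.0, 25.0],  # CSF
        [60.0, 70.0, 55.0, 50.0],  # GM
        [80.0, 55.0, 45.0, 45.0],  # WM
        [55.0, 85.0, 90.0, 95.0],  # LESION
    ]
)
_DEFAULT_SDS = np.full((4, 4), 5.0)


@dataclass
class PhantomSubject:
    """One generated subject: volumes, full truth labels, and the lesion mask."""

    volumes: MultiModalVolume
    truth_labels: np.ndarray
    lesion_mask: np.ndarray
    lesion_radius_mm: float


def default_spec(n_subjects: int = 10, seed: int = 0) -> PhantomSpec:
    """The documented default cohort: 64^3 voxels at 1 mm, well-separated classes.

    Class contrasts satisfy mean/sd >= 3 in every cell and a between-class
    gap of at least 4 pooled sds in at least one modality for every class
    pair, with the lesion hyperintense on FLAIR and DWI.

    Default lesion radii span 10.5-11.0 mm, about twice the 5 mm half-width
    of the neighborhood-statistics window.  That ratio matters: windowed
    features mix intensities across the lesion surface, and lesions much
    smaller than ~2x the window half-width (or much larger, where the
    contaminated inner shell gains mass) are genuinely harder to isolate —
    see the methods documentation.  Real sub-acute stroke lesions are large
    relative to a 5 mm window, so the default models that regime; pass an
    explicit ``lesion_radius_mm`` sequence to study other sizes.
    """
    if n_subjects == 1:
        radii: float | tuple[float, ...] = 11.0
    else:
        radii = tuple(np.linspace(10.5, 11.0, n_subjects))
    spec = PhantomSpec(n_subjects=n_subjects, seed=seed, lesion_radius_mm=radii)
    spec.validate()
    return spec


def size_sweep_spec(n_subjects: int = 10, seed: int = 0,
                    radius_range_mm: tuple[float, float] = (5.0, 11.0)) -> PhantomSpec:
    """A cohort whose lesion radii sweep a range, for size-vs-performance studies.

    The default sweep (5-11 mm, about 0.5-5.6 cm^3) spans an order of
    magnitude in lesion volume, deliberately crossing into the small-lesion
    regime where windowed features blur the lesion boundary.
    """
    lo, hi = radius_range_mm
    radii = tuple(np.linspace(lo, hi, n_subjects))
    spec = PhantomSpec(n_subjects=n_subjects, seed=seed, lesion_radius_mm=radii)
    spec.validate()
    return spec


def _grid_coords_mm(grid_shape, voxel_size_mm):
    """Voxel-center coordinates in mm relative to the geometric volume center."""
    axes = [
        (np.arange(n, dtype=float) - (n - 1) / 2.0) * voxel_size_mm
        for n in grid_shape
    ]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_truth(spec: PhantomSpec, lesion_radius_mm: float) -> np.ndarray:
    """Label volume from the analytic geometry (no randomness).

    A voxel belongs to the brain when its normalized ellipsoid radius
    ``r = sqrt(sum((x_i / a_i)^2))`` is <= 1; WM core is ``r <= 0.8``, GM band
    ``0.8 < r <= 0.95``, CSF shell the rest.  The lesion sphere overwrites
    whatever tissue it covers (but never background).
    """
    xs, ys, zs = _grid_coords_mm(spec.grid_shape, spec.voxel_size_mm)
    semi = np.array(AXIS_RATIOS) * spec.brain_radius_mm
    r = np.sqrt((xs / semi[0]) ** 2 + (ys / semi[1]) ** 2 + (zs / semi[2]) ** 2)
    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[r <= 1.0] = CSF
    labels[r <= GM_FRACTION] = GM
    labels[r <= WM_FRACTION] = WM
    cx, cy, cz = spec.lesion_center
    dist2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
    sphere = dist2 <= lesion_radius_mm**2
    labels[sphere & (labels != BACKGROUND)] = LESION
    return labels


def _draw_intensities(labels: np.ndarray, spec: PhantomSpec, rng: np.random.Generator):
    means = np.asarray(spec.class_means, dtype=float)
    sds = np.asarray(spec.class_sds, dtype=float)
    vols = {m: np.zeros(labels.shape, dtype=np.float64) for m in MODALITY_ORDER}
    for row, cls in enumerate(CLASS_ORDER):
        idx = labels == cls
        n = int(idx.sum())
        if n == 0:
            continue
        for col, m in enumerate(MODALITY_ORDER):
            vols[m][idx] = rng.normal(means[row, col], sds[row, col], size=n)
    return vols


def make_phantom(spec: PhantomSpec) -> list[PhantomSubject]:
    """Generate ``spec.n_subjects`` subjects, fully reproducible from ``spec.seed``.

    Per-subject random streams are spawned from one seed sequence, so the
    cohort is bit-identical across calls with the same spec and independent
    of ``n_subjects`` order.
    """
    spec.validate()
    radii = spec.lesion_radii()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    subjects = []
    for i in range(spec.n_subjects):
        rng = np.random.default_rng(children[i])
        labels = rasterize_truth(spec, radii[i])
        vols = _draw_intensities(labels, spec, rng)
        mmv = MultiModalVolume(
            t1=vols["t1"],
            t2=vols["t2"],
            flair=vols["flair"],
            dwi=vols["dwi"],
            brain_mask=labels != BACKGROUND,
            voxel_size_mm=(spec.voxel_size_mm,) * 3,
            subject_id=f"phantom{i:03d}",
        )
        subjects.append(
            PhantomSubject(
                volumes=mmv,
                truth_labels=labels,
                lesion_mask=labels == LESION,
                lesion_radius_mm=float(radii[i]),
            )
        )
    return subjects
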