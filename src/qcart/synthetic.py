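"""Synthetic condyle phantoms for the relaxometry and histology pipelines.

No imaging data were deposited with the study, so every analysis here runs
on phantoms that emulate the statistical structure the pipeline assumes: a
stylized femoral-condyle cross-section (half-disc of epiphyseal cartilage
under an articular rim, with an elliptical ischemic lesion that never
involves the avascular articular cartilage), piecewise-constant ground-truth
relaxation times and safranin-O optical densities per compartment, Rician
noise for magnitude MRI frames and Poisson counting noise for transmission
microscopy.

Ground-truth compartment values default to the published per-ROI means of
the goat cohort (see :mod:`qcart.datasets`), so a noiseless phantom run of
the full pipeline must return exactly those numbers — the central
forward/inverse consistency property the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import datasets
from .histology import TransmissionImage
from .protocols import AcquisitionProtocol
from .relaxometry import ImageSeries

__all__ = [
    "PhantomSpec",
    "Phantom",
    "make_phantom",
    "simulate_series",
    "simulate_section",
    "make_cohort",
    "SyntheticSpecimen",
    "relaxation_truth_ms",
    "LABELS",
]

#: Compartment labels of the phantom ROI image.
LABELS = {"background": 0, "articular": 1, "viable": 2, "necrotic": 3}

#: Default frame amplitude (arbitrary magnitude units).
DEFAULT_AMPLITUDE = 1000.0


def relaxation_truth_ms(week: int) -> dict[str, dict[str, float]]:
    """Published per-ROI relaxation means for one cohort week, all in ms.

    T1 is converted from seconds; the week-3 T2 entry is absent (the
    measurement was invalid for that specimen).
    """
    out: dict[str, dict[str, float]] = {}
    for roi, params in datasets.RELAXATION_STATS[week].items():
        for param, (mean, _sd) in params.items():
            value = mean * 1000.0 if param == "T1" else mean
            out.setdefault(param, {})[roi] = value
    return out


def od_truth(week: int) -> dict[str, float]:
    """Published OD means per compartment; the articular rim reuses the
    viable value (articular cartilage is excluded from the OD statistics)."""
    viable = datasets.OD_STATS[week]["viable"][0]
    necrotic = datasets.OD_STATS[week]["necrotic"][0]
    return {"articular": viable, "viable": viable, "necrotic": necrotic}


@dataclass
class PhantomSpec:
    """Geometry + ground truth + noise settings of one phantom.

    The condyle is a half-disc seated on the bottom edge of the image:
    an articular band of ``articular_thickness_px`` along the curved
    surface, epiphyseal cartilage inside it, and an elliptical lesion
    (``lesion_center``/``lesion_axes_px``, rows x cols) that must lie
    entirely inside the epiphyseal compartment.

    ``truth`` maps parameter -> {articular, viable, necrotic} relaxation
    time in ms; ``od`` maps compartment -> optical density.
    """

    shape: tuple[int, int] = (256, 256)
    condyle_radius_px: float | None = None  # None -> 0.45 * min(shape)
    articular_thickness_px: float = 12.0
    lesion_center: tuple[float, float] | None = None
    lesion_axes_px: tuple[float, float] = (20.0, 30.0)
    truth: dict[str, dict[str, float]] = field(default_factory=dict)
    od: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.0
    amplitude: float = DEFAULT_AMPLITUDE
    pixel_size_um: float = 160.0
    seed: int | None = None

    @classmethod
    def for_week(
        cls,
        week: int,
        shape: tuple[int, int] = (256, 256),
        noise_sigma: float = 0.0,
        seed: int | None = None,
    ) -> "PhantomSpec":
        """Cohort phantom for one harvest week, geometry scaled to ``shape``."""
        scale = min(shape) / 256.0
        return cls(
            shape=shape,
            articular_thickness_px=max(2.0, 12.0 * scale),
            lesion_axes_px=(max(3.0, 20.0 * scale), max(4.0, 30.0 * scale)),
            truth=relaxation_truth_ms(week),
            od=od_truth(week),
            noise_sigma=noise_sigma,
            seed=seed,
        )

    def radius(self) -> float:
        return self.condyle_radius_px if self.condyle_radius_px is not None else 0.45 * min(self.shape)


@dataclass
class Phantom:
    """Realized phantom: ROI labels plus per-parameter truth maps."""

    labels: np.ndarray
    truth_maps: dict[str, np.ndarray]  # parameter -> per-pixel T (ms), NaN in background
    od_map: np.ndarray | None
    spec: PhantomSpec

    def compartment(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterize a phantom spec into label and truth images.

    Raises if the lesion ellipse is not fully contained in the epiphyseal
    compartment (lesions never involve the overlying articular cartilage).
    """
    h, w = spec.shape
    radius = spec.radius()
    if radius + 1 > min(h, w):
        raise ValueError("condyle radius does not fit the image")
    cy, cx = float(h - 1), w / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dist = np.hypot(yy - cy, xx - cx)
    condyle = dist <= radius
    articular = condyle & (dist > radius - spec.articular_thickness_px)
    epiphyseal = condyle & ~articular

    labels = np.zeros((h, w), dtype=np.int16)
    labels[articular] = LABELS["articular"]
    labels[epiphyseal] = LABELS["viable"]

    ry, rx = spec.lesion_axes_px
    if ry > 0 and rx > 0:
        if spec.lesion_center is None:
            ly, lx = cy - 0.45 * radius, cx
        else:
            ly, lx = spec.lesion_center
        lesion = ((yy - ly) / ry) ** 2 + ((xx - lx) / rx) ** 2 <= 1.0
        if np.any(lesion & ~epiphyseal):
            raise ValueError("lesion extends outside the epiphyseal compartment")
        labels[lesion] = LABELS["necrotic"]

    for truth in spec.truth.values():
        if any(v <= 0 for v in truth.values()):
            raise ValueError("all ground-truth values must be positive")

    truth_maps = {}
    for param, by_roi in spec.truth.items():
        tm = np.full((h, w), np.nan)
        for roi, value in by_roi.items():
            tm[labels == LABELS[roi]] = value
        truth_maps[param] = tm

    od_map = None
    if spec.od:
        od_map = np.zeros((h, w))
        for roi, value in spec.od.items():
            od_map[labels == LABELS[roi]] = value
    return Phantom(labels=labels, truth_maps=truth_maps, od_map=od_map, spec=spec)


def _rician(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (signal + N(0, sigma)) + i N(0, sigma)."""
    if sigma == 0:
        return signal.copy()
    return np.hypot(signal + rng.normal(0.0, sigma, signal.shape),
                    rng.normal(0.0, sigma, signal.shape))


def simulate_series(
    phantom: Phantom,
    protocol: AcquisitionProtocol,
    noise_sigma: float | None = None,
    seed: int | None = None,
    amplitude: float | None = None,
) -> ImageSeries:
    """Forward-model a magnitude image series for one preparation.

    Frames follow ``A*(1 - 2*exp(-TI/T1))`` (magnitude) or ``A*exp(-t/T)``
    over the phantom's truth map at the protocol's own time points, with
    Rician noise of standard deviation ``noise_sigma`` per channel.
    Identical seeds give bit-identical series.
    """
    if protocol.name not in phantom.truth_maps:
        raise ValueError(f"phantom has no ground-truth map for {protocol.name}")
    sigma = phantom.spec.noise_sigma if noise_sigma is None else noise_sigma
    amp = phantom.spec.amplitude if amplitude is None else amplitude
    from .protocols import build_time_axis

    times = build_time_axis(protocol)
    tmap = phantom.truth_maps[protocol.name]
    tissue = phantom.labels > 0
    safe_t = np.where(tissue, tmap, 1.0)
    frames = np.empty((times.size, *phantom.labels.shape))
    for i, t in enumerate(times):
        if protocol.model == "INVERSION_RECOVERY":
            s = np.abs(amp * (1.0 - 2.0 * np.exp(-t / safe_t)))
        else:
            s = amp * np.exp(-t / safe_t)
        frames[i] = np.where(tissue, s, 0.0)
    rng = np.random.default_rng(phantom.spec.seed if seed is None else seed)
    frames = _rician(frames, sigma, rng)
    return ImageSeries(frames=frames, times_ms=times,
                       pixel_size_um=phantom.spec.pixel_size_um, protocol=protocol)


def simulate_section(
    phantom: Phantom,
    seed: int | None = None,
    photon_budget: float = 2.0e4,
    exposure_sample_s: float = 10.0,
    exposure_reference_s: float = 1.0,
    dark_counts: float = 100.0,
    poisson: bool = True,
) -> tuple[TransmissionImage, TransmissionImage]:
    """Forward-model a stained-section sample/reference transmission pair.

    The reference (sample-free glass) transmits ``photon_budget`` counts/s
    per pixel; the sample attenuates it by ``10**(-OD_true)`` (Beer-Lambert).
    Both images accumulate counts over their own exposure (the sample gets a
    longer one, emulating exposure compensation for the dense stain), with
    Poisson shot noise and a constant dark offset.
    """
    if phantom.od_map is None:
        raise ValueError("phantom has no OD ground truth")
    if photon_budget <= 0:
        raise ValueError("photon budget must be positive")
    rng = np.random.default_rng(phantom.spec.seed if seed is None else seed)
    ref_expect = np.full(phantom.od_map.shape, photon_budget * exposure_reference_s)
    sam_expect = photon_budget * exposure_sample_s * 10.0 ** (-phantom.od_map)
    if poisson:
        ref_counts = rng.poisson(ref_expect).astype(float)
        sam_counts = rng.poisson(sam_expect).astype(float)
    else:
        ref_counts, sam_counts = ref_expect.copy(), sam_expect.copy()
    sample = TransmissionImage(counts=sam_counts + dark_counts,
                               exposure_s=exposure_sample_s,
                               background=dark_counts, wavelength_nm=530.0)
    reference = TransmissionImage(counts=ref_counts + dark_counts,
                                  exposure_s=exposure_reference_s,
                                  background=dark_counts, wavelength_nm=530.0)
    return sample, reference


@dataclass
class SyntheticSpecimen:
    """One phantom animal of the synthetic cohort, ready for the pipeline."""

    week: int
    lesion_class: str
    phantom: Phantom
    protocols: dict[str, AcquisitionProtocol]
    histological_necrosis: bool = True


def make_cohort(
    seed: int | None = None,
    shape: tuple[int, int] = (128, 128),
    noise_sigma: float = 0.0,
) -> list[SyntheticSpecimen]:
    """The six-specimen synthetic cohort.

    Large-incision phantoms at weeks 3, 5, 9 and small-incision phantoms at
    weeks 4, 6, 10; ground truth from the published per-ROI means.  The
    week-3 specimen has no T2 series (the measurement was invalid) and the
    week-6 specimen is flagged as lacking histologically evident necrosis.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(datasets.COHORT_WEEKS))
    all_protocols = datasets.cohort_protocols()
    cohort = []
    for week, child in zip(datasets.COHORT_WEEKS, child_seeds):
        spec = PhantomSpec.for_week(week, shape=shape, noise_sigma=noise_sigma,
                                    seed=int(child % (2**31)))
        phantom = make_phantom(spec)
        protocols = {
            name: proto for name, proto in all_protocols.items()
            if name in phantom.truth_maps
        }
        cohort.append(
            SyntheticSpecimen(
                week=week,
                lesion_class=datasets.lesion_class(week),
                phantom=phantom,
                protocols=protocols,
                histological_necrosis=(week != datasets.WEEK_WITHOUT_NECROSIS),
            )
        )
    return cohort
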