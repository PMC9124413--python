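"""Synthetic SPECT-like phantoms and LDS-like histograms.

The phantom emulates a cylindrical capnoperitoneum (a can of roughly
4.0 x 10.5 cm coated inside with a thin agar layer) imaged along its
axis: the default grid is 250 slices of 92 x 92 voxels with a cylinder of
radius 40 voxels spanning 210 slices.  Three canonical deposition
patterns stand in for the three ways a tracer ends up distributed after
intraperitoneal administration:

``film``
    Aerosol deposition — a uniform coat on every inner surface of the
    cavity, modelled as the cylinder's boundary shell (lateral wall plus
    end caps, 2 voxels thick by default).
``pool``
    Liquid instilled into an inflated cavity pooling under gravity — an
    ellipsoidal blob in the gravitationally lowest part of the cylinder
    (rows increase downward).
``depot``
    A focal liquid depot at the injection site — a single 3D Gaussian
    focus (sigma = 3 voxels).

The expected (pre-noise) field is scaled so its sum equals the requested
total counts exactly; Poisson counting noise, the standard model for
nuclear imaging, is applied voxelwise on request.  No detector blur or
reconstruction smoothing is simulated, so synthetic TVE values are
comparable between patterns (ordinally) but not to scanner data
numerically.

Everything is deterministic per seed; replicate seeds are derived from a
single base seed via ``numpy``'s ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from aerodist.granulometry import BinnedSizeData, DropletDistribution, bin_distribution
from aerodist.imaging_io import VoxelVolume

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_group",
    "generate_lds_histogram",
    "write_dicom_fixture",
]

PATTERNS = ("film", "pool", "depot")


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic capnoperitoneum volume.

    Parameters
    ----------
    shape
        (n_slices, n_rows, n_cols); slices index the cylinder axis.
    pattern
        One of ``film``, ``pool``, ``depot``.
    cylinder_radius, axial_extent
        Cavity geometry in voxels; defaults emulate a ~4.0 x 10.5 cm can
        on a 250 x 92 x 92 grid.
    total_expected_counts
        Sum of the expected (pre-noise) intensity field.
    noise
        ``poisson`` (voxelwise counting noise) or ``none``.
    seed
        Seed for the noise draw; irrelevant when noise is ``none``.
    shell_thickness
        Film-coat thickness in voxels (1-2 voxels emulates the 1-2 mm
        agar layer of the physical phantom).
    pool_fraction
        Fraction of the cylinder height occupied by the dependent pool.
    depot_sigma
        Standard deviation (voxels) of the focal-depot Gaussian.
    """

    shape: Tuple[int, int, int] = (250, 92, 92)
    pattern: str = "film"
    cylinder_radius: Optional[float] = None
    axial_extent: Optional[int] = None
    total_expected_counts: float = 1e6
    noise: str = "poisson"
    seed: int = 0
    shell_thickness: float = 2.0
    pool_fraction: float = 0.2
    depot_sigma: float = 3.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or len(self.shape) != 3:
            raise ValueError("shape must be three positive integers")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; choose from {PATTERNS}")
        if self.total_expected_counts <= 0:
            raise ValueError("total_expected_counts must be positive")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        # geometry defaults scale with the grid so that the canonical
        # 250 x 92 x 92 stack gets a radius-40, 210-slice cylinder
        if self.cylinder_radius is None:
            object.__setattr__(self, "cylinder_radius", round(0.435 * min(self.shape[1:])))
        if self.axial_extent is None:
            object.__setattr__(self, "axial_extent", round(0.84 * self.shape[0]))
        if self.axial_extent > self.shape[0]:
            raise ValueError("axial_extent exceeds the slice count")


def _cylinder_masks(spec: PhantomSpec):
    """Boolean interior mask of the cylinder and supporting coordinates."""
    n_slices, n_rows, n_cols = spec.shape
    z0 = (n_slices - spec.axial_extent) // 2
    z1 = z0 + spec.axial_extent
    rows = np.arange(n_rows) - (n_rows - 1) / 2.0
    cols = np.arange(n_cols) - (n_cols - 1) / 2.0
    r2 = rows[:, None] ** 2 + cols[None, :] ** 2
    inside_xs = r2 <= spec.cylinder_radius**2
    axial = np.zeros(n_slices, dtype=bool)
    axial[z0:z1] = True
    return axial, inside_xs, np.sqrt(r2), (z0, z1), rows


def _expected_field(spec: PhantomSpec) -> np.ndarray:
    n_slices, n_rows, n_cols = spec.shape
    axial, inside_xs, radius_map, (z0, z1), rows = _cylinder_masks(spec)
    field_ = np.zeros(spec.shape, dtype=float)

    if spec.pattern == "film":
        # lateral wall: a ring of shell_thickness voxels just inside the radius
        ring = inside_xs & (radius_map >= spec.cylinder_radius - spec.shell_thickness)
        field_[axial] = ring[None, :, :]
        # end caps: full discs on the first/last shell_thickness slices
        cap = max(1, int(round(spec.shell_thickness)))
        field_[z0 : z0 + cap] = inside_xs[None, :, :]
        field_[z1 - cap : z1] = inside_xs[None, :, :]
    elif spec.pattern == "pool":
        # dependent ellipsoid: centred at the bottom band of the cylinder,
        # vertical semi-axis spanning pool_fraction of the diameter
        semi_v = spec.pool_fraction * spec.cylinder_radius  # vertical (rows)
        centre_row = spec.cylinder_radius - semi_v  # depth below axis centre
        depth = spec.cylinder_radius - semi_v  # chord level
        semi_h = np.sqrt(max(spec.cylinder_radius**2 - depth**2, 1.0))  # cols
        # a liquid bolus pools compactly near the injection site; it does
        # not run the full length of the cavity
        semi_a = 0.15 * spec.axial_extent  # slices
        zc = (z0 + z1 - 1) / 2.0
        z = np.arange(n_slices) - zc
        r = np.arange(n_rows) - (n_rows - 1) / 2.0 - centre_row
        c = np.arange(n_cols) - (n_cols - 1) / 2.0
        ell = (
            (z[:, None, None] / semi_a) ** 2
            + (r[None, :, None] / semi_v) ** 2
            + (c[None, None, :] / semi_h) ** 2
        ) <= 1.0
        field_[ell & axial[:, None, None] & inside_xs[None, :, :]] = 1.0
    else:  # depot
        zc = (z0 + z1 - 1) / 2.0
        rc = (n_rows - 1) / 2.0 + 0.5 * spec.cylinder_radius  # below centre
        cc = (n_cols - 1) / 2.0
        z = np.arange(n_slices)
        r = np.arange(n_rows)
        c = np.arange(n_cols)
        d2 = (
            (z[:, None, None] - zc) ** 2
            + (r[None, :, None] - rc) ** 2
            + (c[None, None, :] - cc) ** 2
        )
        g = np.exp(-d2 / (2.0 * spec.depot_sigma**2))
        # compact support: a liquid depot ends, Gaussian tails do not --
        # truncate at 3 sigma so distant voxels carry no expectation
        g[d2 > (3.0 * spec.depot_sigma) ** 2] = 0.0
        field_ = g * (axial[:, None, None] & inside_xs[None, :, :])

    total = field_.sum()
    if total <= 0:
        raise ValueError("degenerate geometry: empty expected field")
    return field_ * (spec.total_expected_counts / total)


def generate_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Generate one phantom volume from its full specification.

    The expected field sums exactly (to float precision) to
    ``total_expected_counts``; with ``noise='poisson'`` each voxel is an
    independent Poisson draw with that expectation, seeded by
    ``spec.seed``.
    """
    expected = _expected_field(spec)
    if spec.noise == "poisson":
        rng = np.random.default_rng(spec.seed)
        data = rng.poisson(expected).astype(float)
    else:
        data = expected
    return VoxelVolume(data=data, slice_axis=0)


def generate_group(spec: PhantomSpec, n_replicates: int, base_seed: int) -> List[VoxelVolume]:
    """Generate ``n_replicates`` phantoms sharing one expected field.

    Replicate seeds are spawned deterministically from ``base_seed``, so
    two calls with the same arguments return identical lists.  Each
    replicate is the analog of one animal.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(base_seed).generate_state(n_replicates) % (2**31)
    volumes = []
    for s in seeds:
        rep = PhantomSpec(
            shape=spec.shape,
            pattern=spec.pattern,
            cylinder_radius=spec.cylinder_radius,
            axial_extent=spec.axial_extent,
            total_expected_counts=spec.total_expected_counts,
            noise=spec.noise,
            seed=int(s),
            shell_thickness=spec.shell_thickness,
            pool_fraction=spec.pool_fraction,
            depot_sigma=spec.depot_sigma,
        )
        volumes.append(generate_phantom(rep))
    return volumes


def generate_lds_histogram(
    dist: DropletDistribution, bin_edges, noise_cv: float = 0.0, seed: int = 0
) -> BinnedSizeData:
    """Simulate an instrument-reported size histogram.

    The analytic binned fractions are perturbed by multiplicative
    lognormal noise with coefficient of variation ``noise_cv`` and
    renormalized — a stand-in for run-to-run instrument variability.
    ``noise_cv=0`` returns the analytic histogram exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    clean = bin_distribution(dist, bin_edges)
    if noise_cv == 0:
        return clean
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    factors = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=clean.n_bins))
    return BinnedSizeData(bin_edges=clean.bin_edges, volume_fractions=clean.volume_fractions * factors)


def write_dicom_fixture(
    volume: VoxelVolume,
    directory,
    rescale_slope: Optional[float] = None,
    rescale_intercept: float = 0.0,
) -> List[Path]:
    """Write a volume as one single-frame DICOM file per slice.

    Values are stored as 16-bit integers with rescale slope/intercept
    chosen (or given) so that ``stored * slope + intercept`` reproduces
    the voxel values; files carry consistent series metadata and instance
    numbering and are loadable by :func:`aerodist.imaging_io.load_dicom_series`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data = volume.slices_first()
    vmax = float(data.max())
    if rescale_slope is None:
        rescale_slope = 1.0 if vmax <= 65535 else vmax / 65535.0
    stored = np.round((data - rescale_intercept) / rescale_slope)
    if stored.min() < 0 or stored.max() > 65535:
        raise ValueError("values do not fit 16-bit storage with this rescale")
    stored = stored.astype(np.uint16)

    series_uid = generate_uid(entropy_srcs=["aerodist-fixture"])
    study_uid = generate_uid(entropy_srcs=["aerodist-study"])
    st, pr, pc = volume.voxel_spacing if volume.voxel_spacing else (1.0, 1.0, 1.0)
    paths = []
    for i in range(stored.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[f"aerodist-{i}"])
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.Modality = "NM"
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "AERODIST"
        ds.InstanceNumber = i + 1
        ds.ImagePositionPatient = [0.0, 0.0, float(i) * st]
        ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
        ds.PixelSpacing = [pr, pc]
        ds.SliceThickness = st
        ds.Rows, ds.Columns = stored.shape[1], stored.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.PixelData = stored[i].tobytes()
        path = directory / f"slice_{i:04d}.dcm"
        ds.save_as(path, enforce_file_format=True)
        paths.append(path)
    return paths
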