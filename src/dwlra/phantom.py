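"""Synthetic free-breathing liver DW-MRI phantom.

Emulates a multi-b-value protocol with separately stored repeats: 3
b-values (100/500/900 s/mm^2), 3 diffusion gradient directions, 4 repeat
acquisitions, interleaved slice order (all odd-index slices acquired in
one temporal block, then all even-index slices), anisotropic voxels.
Tissue is piecewise-constant in D (units of 1e-5 mm^2/s) and S0: a liver
background around D = 100, a low-diffusion lesion, a vessel, and one
bright high-D fluid blob (gallbladder analogue) that should appear as a
high-S0/high-D cluster on an S0-vs-ADC scatter plot.

Motion model
------------
Respiration is a single-frequency cycle.  Each parity group of each
acquisition is assigned an acquisition time; the true rigid shift is

    shift(t) = A * (1 + sin(2 pi t / T)) / 2 * u  (+ optional jitter),

a one-sided excursion from the end-expiration rest position,

rounded to integers (the matching search space is integer shifts) and
clipped to +-3 px in-plane and +-2 slices.  ``u`` is a unit 3-vector, so
the true shifts lie on a line through the origin in shift space --- the
structure the constrained-movement-space step of the alignment exploits.
Acquisition times advance by a fixed fraction of the cycle per
acquisition, with a separate phase offset between the odd and even slice
blocks: that offset is what produces the odd-even interleave artefact
seen in coronal views.

Noise is Rician: the magnitude of (S + n1, n2) with n1, n2 independent
Gaussians of standard deviation sigma, giving the noise floor that the
eta*sigma^2 term of the ADC fit corrects for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_volumes import DWSeries

__all__ = [
    "Region",
    "PhantomSpec",
    "GroundTruth",
    "make_maps",
    "simulate_acquisition",
    "average_protocol_a",
]

_IN_PLANE_LIMIT = 3
_SLICE_LIMIT = 2


@dataclass
class Region:
    """Ellipsoidal tissue region: center/semi-axes in voxel units.

    ``tilt`` displaces the in-plane center linearly with slice index
    (px per slice), so structures run obliquely through the volume and
    adjacent slices are genuinely distinguishable --- as vessels and
    the liver dome are in vivo.
    """

    center: tuple          # (row, col, slice)
    semi_axes: tuple       # (a_row, a_col, a_slice)
    D: float               # 1e-5 mm^2/s
    S0: float              # signal units
    tilt: tuple = (0.0, 0.0)   # (d_row/d_slice, d_col/d_slice)

    def mask(self, shape) -> np.ndarray:
        nr, nc, ns = shape
        r, c, s = np.ogrid[:nr, :nc, :ns]
        ar, ac, asl = self.semi_axes
        cr, cc, cs = self.center
        tr, tc = self.tilt
        return (((r - cr - tr * (s - cs)) / ar) ** 2
                + ((c - cc - tc * (s - cs)) / ac) ** 2
                + ((s - cs) / asl) ** 2) <= 1.0


def _default_regions(grid):
    nr, nc, ns = grid
    cz = ns / 2 - 0.5
    return [
        # liver background: large ellipsoid, D ~ 100e-5 mm^2/s; slight
        # tilt mimics the dome moving across slices
        Region((nr * 0.5, nc * 0.5, cz), (nr * 0.42, nc * 0.42, ns * 0.48),
               D=100.0, S0=100.0, tilt=(0.3, 0.2)),
        # low-diffusion lesion
        Region((nr * 0.35, nc * 0.6, cz), (nr * 0.08, nc * 0.08, ns * 0.2),
               D=60.0, S0=85.0, tilt=(0.35, 0.25)),
        # vessel: elongated, moderate D, dark S0, running obliquely
        Region((nr * 0.62, nc * 0.32, cz), (nr * 0.04, nc * 0.16, ns * 0.3),
               D=150.0, S0=60.0, tilt=(-0.3, 0.35)),
        # gallbladder analogue: bright fluid, high D
        Region((nr * 0.68, nc * 0.68, cz), (nr * 0.1, nc * 0.1, ns * 0.25),
               D=250.0, S0=180.0, tilt=(0.3, -0.3)),
    ]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic acquisition.

    Defaults describe the emulated protocol: b = (100, 500, 900) s/mm^2,
    3 gradient directions, 4 repeats, interleaved slices, respiratory
    shifts up to 3 px in-plane / 2 slices through-plane along a fixed
    3D direction, Rician noise.  The 64 x 64 x 12 grid is a reduced
    field of view for fast computation; the acquired-resolution voxel
    size (3 x 3 x 5 mm) is kept.
    """

    grid: tuple = (64, 64, 12)
    b_values: tuple = (100.0, 500.0, 900.0)
    n_repeats: int = 4
    directions: tuple = ("-x", "y", "z")
    regions: list = None
    voxel_size: tuple = (3.0, 3.0, 5.0)
    motion_line_direction: tuple = (2.0, 1.0, 1.5)   # normalised internally
    motion_amplitude: float = 3.5                    # px along the line
    cycle_step: float = 0.37       # cycle fraction advanced per acquisition
    phase_offset: float = 0.31     # even-block phase lag (cycle fraction)
    jitter: float = 0.0            # std of isotropic shift jitter (px)
    noise_sigma: float = 5.0       # Rician channel sigma, signal units
    subpixel: bool = False         # apply true shifts with interpolation
    seed: int = 0

    def __post_init__(self):
        if self.regions is None:
            self.regions = _default_regions(self.grid)
        if len(self.grid) != 3 or min(self.grid) < 3:
            raise ValueError(f"degenerate grid {self.grid}")
        if not self.regions:
            raise ValueError("regions must be non-empty")
        if any(r.D < 0 for r in self.regions):
            raise ValueError("all D must be >= 0")
        u = np.asarray(self.motion_line_direction, dtype=float)
        self.motion_line_direction = tuple(u / np.linalg.norm(u))

    @property
    def limits(self):
        return (_IN_PLANE_LIMIT, _IN_PLANE_LIMIT, _SLICE_LIMIT)


@dataclass
class GroundTruth:
    """Truth record for one simulated series."""

    adc_map: np.ndarray                 # (nr, nc, ns), 1e-5 mm^2/s
    s0_map: np.ndarray
    shift_table: dict                   # (b, direction, repeat, parity) -> (dr, dc, ds)
    noise_sigma: float
    motion_line_direction: tuple = field(default=None)

    def relative_shifts(self, reference_key):
        """Shift table re-expressed relative to one parity group (the
        motion the aligner actually has to recover)."""
        ref = np.asarray(self.shift_table[reference_key])
        return {k: tuple(np.asarray(v) - ref) for k, v in self.shift_table.items()}


def make_maps(spec: PhantomSpec):
    """Build piecewise-constant ground-truth D and S0 maps.

    Overlapping regions resolve last-wins, so list the background first.
    """
    shape = spec.grid
    adc = np.zeros(shape)
    s0 = np.zeros(shape)
    for reg in spec.regions:
        m = reg.mask(shape)
        adc[m] = reg.D
        s0[m] = reg.S0
    return adc, s0


def _translate3d(vol: np.ndarray, shift, subpixel=False) -> np.ndarray:
    """Shift volume content by (d_row, d_col, d_slice) with edge replication."""
    from scipy import ndimage
    order = 1 if subpixel else 0
    return ndimage.shift(vol, shift, order=order, mode="nearest", prefilter=False)


def _true_shift(spec: PhantomSpec, t: float, rng) -> np.ndarray:
    # one-sided excursion from the end-expiration baseline: liver motion
    # is a displacement away from a rest position, not symmetric about
    # it; this also keeps shifts *relative to any reference acquisition*
    # within the matching limits
    u = np.asarray(spec.motion_line_direction)
    s = spec.motion_amplitude * 0.5 * (1.0 + np.sin(2 * np.pi * t))
    shift = s * u
    if spec.jitter > 0:
        shift = shift + rng.normal(0.0, spec.jitter, size=3)
    return shift


def simulate_acquisition(spec: PhantomSpec):
    """Simulate the full series; returns (DWSeries, GroundTruth).

    For every (b, direction, repeat): the noiseless signal is
    S0 * exp(-b * D * 1e-5) per voxel; each parity group of slices gets
    one rigid shift from the respiratory cycle; Rician noise is then
    applied voxelwise.  The same seed yields a bit-identical series.
    """
    rng = np.random.default_rng(spec.seed)
    adc, s0 = make_maps(spec)
    lo = -np.asarray(spec.limits)
    hi = np.asarray(spec.limits)

    volumes = {}
    shift_table = {}
    acq_index = 0
    for b in spec.b_values:
        signal = s0 * np.exp(-b * adc * 1e-5)
        for direction in spec.directions:
            for repeat in range(1, spec.n_repeats + 1):
                t0 = acq_index * spec.cycle_step
                acq_index += 1
                vol = np.empty(spec.grid)
                for parity, t in (("odd", t0), ("even", t0 + spec.phase_offset)):
                    shift = _true_shift(spec, t, rng)
                    if not spec.subpixel:
                        shift = np.round(shift)
                    shift = np.clip(shift, lo, hi)
                    moved = _translate3d(signal, shift, subpixel=spec.subpixel)
                    # parity of the 0-based slice index: "odd" group is
                    # slice_index % 2 == 1
                    idx = slice(1, None, 2) if parity == "odd" else slice(0, None, 2)
                    vol[:, :, idx] = moved[:, :, idx]
                    key = (b, direction, repeat, parity)
                    shift_table[key] = tuple(
                        float(x) if spec.subpixel else int(x) for x in shift)
                if spec.noise_sigma > 0:
                    n1 = rng.normal(0.0, spec.noise_sigma, size=vol.shape)
                    n2 = rng.normal(0.0, spec.noise_sigma, size=vol.shape)
                    vol = np.hypot(vol + n1, n2)
                volumes[(b, direction, repeat)] = vol

    series = DWSeries(volumes=volumes, voxel_size=spec.voxel_size,
                      interleaved=True, odd_first=True)
    truth = GroundTruth(adc_map=adc, s0_map=s0, shift_table=shift_table,
                        noise_sigma=spec.noise_sigma,
                        motion_line_direction=spec.motion_line_direction)
    return series, truth


def average_protocol_a(series: DWSeries) -> dict:
    """Voxelwise mean over all (direction, repeat) pairs for each b-value.

    Plain averaging of the separately stored acquisitions emulates the
    on-scanner averaged protocol; with 3 directions and 4 repeats each
    output volume is the mean of 12.
    """
    out = {}
    for b in series.b_values:
        stack = [series.volume(b, d, r)
                 for d in series.directions for r in series.repeats]
        out[b] = np.mean(stack, axis=0)
    return out
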