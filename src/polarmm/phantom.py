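"""Synthetic fibrous-tissue phantoms built by composing pure optical elements.

Each pixel is assembled as depolarizer . retarder(delta, theta) .
diattenuator(D, theta), scaled by a transmittance field, with air lacunae
at near-zero transmittance. Group presets encode the normal-vs-injured
contrast (high retardance / low diattenuation / narrow orientation spread
for healthy fibers, the reverse for injured ones) with intermediate
treatment levels. The generator replaces unavailable tissue scans with a
ground-truthed stand-in; photon-transport Monte Carlo through scatterer
suspensions is deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import reduce

import numpy as np
from scipy.ndimage import gaussian_filter

from .mm_core import MuellerImage, RankDeficientError, StokesSet

__all__ = [
    "GroupPreset",
    "PhantomGroundTruth",
    "PRESETS",
    "element_mm",
    "linear_retarder",
    "linear_diattenuator",
    "depolarizer",
    "compose_elements",
    "generate_phantom",
    "simulate_measurement",
    "default_generator_states",
    "default_analyzer_matrix",
]


# ---------------------------------------------------------------------------
# pure-element constructors (m11 = 1, Stokes basis I,Q,U,V, horizontal = +Q)


def linear_retarder(delta, theta_deg) -> np.ndarray:
    """Linear retarder, retardance ``delta`` (rad), fast axis ``theta_deg``.

    Broadcasts over array-valued parameters; returns (..., 4, 4).
    """
    delta = np.asarray(delta, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(2 * th), np.sin(2 * th)
    cd, sd = np.cos(delta), np.sin(delta)
    shape = np.broadcast_shapes(delta.shape, th.shape)
    m = np.zeros(shape + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = c**2 + s**2 * cd
    m[..., 1, 2] = s * c * (1 - cd)
    m[..., 1, 3] = -s * sd
    m[..., 2, 1] = s * c * (1 - cd)
    m[..., 2, 2] = s**2 + c**2 * cd
    m[..., 2, 3] = c * sd
    m[..., 3, 1] = s * sd
    m[..., 3, 2] = -c * sd
    m[..., 3, 3] = cd
    return m


def linear_diattenuator(d, theta_deg) -> np.ndarray:
    """Normalized linear diattenuator, diattenuation ``d``, axis ``theta_deg``."""
    d = np.asarray(d, dtype=float)
    th = np.radians(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(2 * th), np.sin(2 * th)
    k = np.sqrt(np.clip(1 - d**2, 0.0, None))
    shape = np.broadcast_shapes(d.shape, th.shape)
    m = np.zeros(shape + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 0, 1] = d * c
    m[..., 0, 2] = d * s
    m[..., 1, 0] = d * c
    m[..., 2, 0] = d * s
    m[..., 1, 1] = c**2 + k * s**2
    m[..., 1, 2] = c * s * (1 - k)
    m[..., 2, 1] = c * s * (1 - k)
    m[..., 2, 2] = s**2 + k * c**2
    m[..., 3, 3] = k
    return m


def depolarizer(a, b=None, c=None) -> np.ndarray:
    """Diagonal depolarizer diag(1, a, b, c); broadcasts over arrays."""
    if b is None and c is None and np.ndim(a) >= 1 and np.shape(a)[-1] == 3:
        a, b, c = np.moveaxis(np.asarray(a, dtype=float), -1, 0)
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    shape = np.broadcast_shapes(a.shape, b.shape, c.shape)
    m = np.zeros(shape + (4, 4))
    m[..., 0, 0] = 1.0
    m[..., 1, 1] = a
    m[..., 2, 2] = b
    m[..., 3, 3] = c
    return m


def element_mm(kind: str, **params) -> np.ndarray:
    """Validated scalar constructor for a pure optical element.

    kind='retarder' (delta in [0, pi], theta_deg in [0, 180)),
    kind='diattenuator' (d in [0, 1], theta_deg in [0, 180)),
    kind='depolarizer' (a, b, c in [0, 1]).
    """
    if kind == "retarder":
        delta, theta = params["delta"], params.get("theta_deg", 0.0)
        if not 0.0 <= delta <= math.pi:
            raise ValueError(f"retardance must lie in [0, pi], got {delta}")
        if not 0.0 <= theta < 180.0:
            raise ValueError(f"axis must lie in [0, 180) degrees, got {theta}")
        return linear_retarder(delta, theta)
    if kind == "diattenuator":
        d, theta = params["d"], params.get("theta_deg", 0.0)
        if not 0.0 <= d <= 1.0:
            raise ValueError(f"diattenuation must lie in [0, 1], got {d}")
        if not 0.0 <= theta < 180.0:
            raise ValueError(f"axis must lie in [0, 180) degrees, got {theta}")
        return linear_diattenuator(d, theta)
    if kind == "depolarizer":
        abc = tuple(params.get(k, 1.0) for k in ("a", "b", "c"))
        if any(not 0.0 <= v <= 1.0 for v in abc):
            raise ValueError(f"depolarization factors must lie in [0, 1], got {abc}")
        return depolarizer(*abc)
    raise ValueError(f"unknown element kind {kind!r}")


def compose_elements(matrices) -> np.ndarray:
    """Left-to-right matrix product of element matrices."""
    mats = list(matrices)
    if not mats:
        raise ValueError("need at least one matrix")
    return reduce(np.matmul, mats)


# ---------------------------------------------------------------------------
# group presets


@dataclass(frozen=True)
class GroupPreset:
    """Effective-optics parameters of one experimental group.

    ``delta_mean`` may be given directly or derived from birefringence:
    delta = 2*pi*dn*thickness_um*1000 / wavelength_nm.
    """

    name: str
    delta_mean: float | None = None
    delta_sd: float = 0.0
    diat_mean: float = 0.0
    diat_sd: float = 0.0
    orient_mean_deg: float = 90.0
    orient_sd_deg: float = 5.0
    depol_diag: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fiber_fill_fraction: float = 1.0
    noise_sigma: float = 0.0
    dn: float | None = None
    thickness_um: float | None = None
    wavelength_nm: float = 633.0

    def __post_init__(self) -> None:
        if self.dn is not None and self.thickness_um is not None:
            derived = 2 * math.pi * self.dn * self.thickness_um * 1000.0 / self.wavelength_nm
            if self.delta_mean is None:
                object.__setattr__(self, "delta_mean", derived)
            elif not math.isclose(self.delta_mean, derived, rel_tol=1e-9):
                raise ValueError(
                    f"delta_mean={self.delta_mean} inconsistent with "
                    f"2*pi*dn*thickness/lambda={derived}"
                )
        if self.delta_mean is None:
            raise ValueError("give delta_mean, or both dn and thickness_um")
        if not 0.0 <= self.delta_mean <= math.pi:
            raise ValueError("delta_mean must lie in [0, pi]")
        if self.orient_sd_deg < 0:
            raise ValueError("orient_sd_deg must be >= 0")
        if not 0.0 <= self.diat_mean < 1.0 or self.diat_mean + 3 * self.diat_sd >= 1.0:
            raise ValueError("need diat_mean in [0,1) and diat_mean + 3*diat_sd < 1")
        if any(not 0.0 < v <= 1.0 for v in self.depol_diag):
            raise ValueError("depol_diag factors must lie in (0, 1]")
        if not 0.0 < self.fiber_fill_fraction <= 1.0:
            raise ValueError("fiber_fill_fraction must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @classmethod
    def from_birefringence(cls, name: str, dn: float, thickness_um: float, **kw) -> "GroupPreset":
        return cls(name=name, dn=dn, thickness_um=thickness_um, **kw)


# Designed group contrast: healthy = high retardance, low diattenuation,
# narrow orientation spread, weak depolarization; injured model = the
# reverse; treatment levels graded so medium sits nearest normal, then
# high, with low and positive barely distinguishable from the model.
PRESETS: dict[str, GroupPreset] = {
    p.name: p
    for p in [
        GroupPreset(
            "normal", delta_mean=1.00, delta_sd=0.08, diat_mean=0.050, diat_sd=0.010,
            orient_sd_deg=5.0, depol_diag=(0.95, 0.95, 0.90),
            fiber_fill_fraction=0.90, noise_sigma=0.005,
        ),
        GroupPreset(
            "model", delta_mean=0.40, delta_sd=0.15, diat_mean=0.150, diat_sd=0.030,
            orient_sd_deg=35.0, depol_diag=(0.80, 0.80, 0.70),
            fiber_fill_fraction=0.70, noise_sigma=0.005,
        ),
        GroupPreset(
            "low", delta_mean=0.45, delta_sd=0.14, diat_mean=0.140, diat_sd=0.028,
            orient_sd_deg=30.0, depol_diag=(0.82, 0.82, 0.72),
            fiber_fill_fraction=0.72, noise_sigma=0.005,
        ),
        GroupPreset(
            "medium", delta_mean=1.20, delta_sd=0.07, diat_mean=0.045, diat_sd=0.010,
            orient_sd_deg=6.0, depol_diag=(0.945, 0.945, 0.895),
            fiber_fill_fraction=0.88, noise_sigma=0.005,
        ),
        GroupPreset(
            "high", delta_mean=0.75, delta_sd=0.11, diat_mean=0.090, diat_sd=0.018,
            orient_sd_deg=16.0, depol_diag=(0.88, 0.88, 0.80),
            fiber_fill_fraction=0.80, noise_sigma=0.005,
        ),
        GroupPreset(
            "positive", delta_mean=0.44, delta_sd=0.14, diat_mean=0.142, diat_sd=0.028,
            orient_sd_deg=31.0, depol_diag=(0.82, 0.82, 0.72),
            fiber_fill_fraction=0.71, noise_sigma=0.005,
        ),
    ]
}


@dataclass
class PhantomGroundTruth:
    """Per-pixel fields a phantom was built from (recovery-test oracle)."""

    delta_map: np.ndarray
    diat_map: np.ndarray
    orient_map: np.ndarray
    depol_map: np.ndarray  # (H, W, 3)
    air_mask: np.ndarray
    tau_map: np.ndarray


# ---------------------------------------------------------------------------
# phantom generation


def _smooth_unit_field(rng: np.random.Generator, shape, smooth_px: float) -> np.ndarray:
    """iid normal field, optionally smoothed and rescaled back to unit SD."""
    f = rng.standard_normal(shape)
    if smooth_px > 0:
        f = gaussian_filter(f, smooth_px, mode="reflect")
        sd = f.std()
        if sd > 0:
            f = f / sd
    return f


def generate_phantom(
    preset: GroupPreset,
    height: int,
    width: int,
    seed,
    smooth_px: float = 5.0,
    tau: float = 0.8,
    tau_jitter: float = 0.0,
    air_transmittance: float = 1e-4,
) -> tuple[MuellerImage, PhantomGroundTruth]:
    """Build one Mueller image with known ground truth.

    delta and D are spatially smoothed clipped Gaussian fields; the fiber
    orientation is an axial wrapped-normal field smoothed through the
    doubled-angle embedding (spatial smoothing shrinks the pointwise
    dispersion slightly, identically across presets). Air lacunae occupy a
    1 - fiber_fill_fraction area fraction at near-zero transmittance.
    Identical seeds give bit-identical outputs.
    """
    rng = np.random.default_rng(seed)
    shape = (height, width)

    delta = np.clip(
        preset.delta_mean + preset.delta_sd * _smooth_unit_field(rng, shape, smooth_px),
        0.0,
        math.pi,
    )
    diat = np.clip(
        preset.diat_mean + preset.diat_sd * _smooth_unit_field(rng, shape, smooth_px),
        0.0,
        0.999,
    )
    orient = preset.orient_mean_deg + preset.orient_sd_deg * rng.standard_normal(shape)
    if smooth_px > 0 and preset.orient_sd_deg > 0:
        two = np.radians(2 * orient)
        cs = gaussian_filter(np.cos(two), smooth_px, mode="reflect")
        sn = gaussian_filter(np.sin(two), smooth_px, mode="reflect")
        orient = np.degrees(np.arctan2(sn, cs)) / 2.0
    orient = np.mod(orient, 180.0)

    blob = rng.standard_normal(shape)
    if preset.fiber_fill_fraction < 1.0:
        blob = gaussian_filter(blob, max(smooth_px, 1.0) * 2, mode="reflect")
        air = blob > np.quantile(blob, preset.fiber_fill_fraction)
    else:
        air = np.zeros(shape, dtype=bool)

    tau_map = np.full(shape, float(tau))
    jitter_field = rng.standard_normal(shape)  # drawn unconditionally for stream stability
    if tau_jitter > 0:
        if smooth_px > 0:
            jitter_field = gaussian_filter(jitter_field, smooth_px, mode="reflect")
            sd = jitter_field.std()
            if sd > 0:
                jitter_field = jitter_field / sd
        tau_map = np.clip(tau + tau_jitter * jitter_field, 0.05, 1.0)
    tau_map[air] = air_transmittance

    dep = np.broadcast_to(np.asarray(preset.depol_diag, dtype=float), shape + (3,)).copy()
    m = compose_elements(
        [depolarizer(dep), linear_retarder(delta, orient), linear_diattenuator(diat, orient)]
    )
    m[air] = np.eye(4)
    m = m * tau_map[..., None, None]

    gt = PhantomGroundTruth(
        delta_map=delta, diat_map=diat, orient_map=orient, depol_map=dep,
        air_mask=air, tau_map=tau_map,
    )
    return MuellerImage(m, normalized=False, wavelength_nm=preset.wavelength_nm), gt


# ---------------------------------------------------------------------------
# measurement simulation


def default_generator_states(angles_deg=(-45.0, 0.0, 30.0, 60.0)) -> StokesSet:
    """Generator set: fixed 0-deg polarizer then a quarter-wave plate at given angles.

    The default four angles keep the 4x4 state matrix well conditioned.
    """
    s0 = np.array([1.0, 1.0, 0.0, 0.0])
    states = np.stack([linear_retarder(math.pi / 2, a) @ s0 for a in angles_deg])
    return StokesSet(states, role="generator")


def default_analyzer_matrix() -> np.ndarray:
    """Intensity projection matrix of an ideal four-channel Stokes analyzer.

    Rows measure I_0, I_45, I_RCP and I_90 (each 0.5*(S0 + component)),
    an invertible map from Stokes space to four detector intensities.
    """
    return 0.5 * np.array(
        [
            [1, 1, 0, 0],
            [1, 0, 1, 0],
            [1, 0, 0, 1],
            [1, -1, 0, 0],
        ],
        dtype=float,
    )


def simulate_measurement(
    image: MuellerImage,
    generator: StokesSet | None = None,
    analyzer: np.ndarray | None = None,
    noise_sigma: float = 0.0,
    seed=None,
    n_frames: int = 1,
) -> np.ndarray:
    """Propagate generator states through the sample; return S_out per state.

    Output shape (N, H, W, 4). With ``noise_sigma`` > 0, additive Gaussian
    noise (std = noise_sigma * incident S0) perturbs the analyzer
    intensities before Stokes assembly; ``n_frames`` noisy frames are
    averaged. Feeding the result to :func:`~polarmm.mm_core.reconstruct_mm`
    closes the measurement loop.
    """
    if generator is None:
        generator = default_generator_states()
    generator.validate()
    if analyzer is None:
        analyzer = default_analyzer_matrix()
    analyzer = np.asarray(analyzer, dtype=float)

    s_true = np.einsum("hwij,nj->nhwi", image.elements, generator.states)
    if noise_sigma <= 0:
        return s_true
    rng = np.random.default_rng(seed)
    y = np.einsum("ai,nhwi->nhwa", analyzer, s_true)
    scale = noise_sigma * generator.states[:, 0][:, None, None, None]
    # averaging n_frames i.i.d. frames reduces the effective noise by 1/sqrt(n_frames)
    y = y + rng.normal(size=(n_frames,) + y.shape).mean(axis=0) * scale
    return np.einsum("ia,nhwa->nhwi", np.linalg.inv(analyzer), y)
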