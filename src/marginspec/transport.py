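"""Weighted-photon Monte Carlo forward model with similarity scaling.

The probe-measured diffuse reflectance for arbitrary (μa, μs′) is predicted
from a small set of *baseline* transport simulations run once at μa = 0 over a
grid of reference μs′ values. Each baseline stores per-collected-photon exit
weights and path lengths; reflectance at arbitrary absorption follows by
Beer–Lambert path-length weighting, R(μa) = Σ_i w_i·exp(−μa·L_i), and linear
interpolation in μs′ between baselines. This is the standard scaled
(lookup-table) Monte Carlo construction: fast enough to sit inside a
nonlinear least-squares inversion, with the transport physics paid for once.

Geometry: one channel of the multi-channel probe — a core of 19 hexagonally
packed 200 μm illumination fibers with 4 collection fibers at the core
corners, NA 0.22, pressed against a semi-infinite homogeneous medium through
a rigid window. Azimuthal symmetry is exploited for variance reduction: the
four discrete collection fibers are represented as an annulus at the corner
radius, and collected weights carry the fiber-to-annulus area fraction.
Channels are 10 mm apart (no cross-talk), so one channel is simulated and
reused for all eight.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .spectral import (
    ChromophoreSet,
    ExtinctionBasis,
    ScatteringModel,
    WavelengthGrid,
    compose_mua,
    musp_curve,
)

__all__ = [
    "ProbeGeometry",
    "TransportConfig",
    "PhotonTable",
    "run_baseline",
    "scaled_reflectance",
    "ReflectanceLookup",
    "simulate_spectrum",
    "diffusion_reflectance",
]


class NoPhotonsCollectedError(RuntimeError):
    """No photons reached a collection fiber; increase n_photons."""


class ExtrapolationError(ValueError):
    """Requested μs′ lies outside the baseline grid hull."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Multi-channel fiber-optic probe geometry (one channel simulated)."""

    n_channels: int = 8
    illumination_fibers_per_channel: int = 19
    collection_fibers_per_channel: int = 4
    fiber_diameter_um: float = 200.0
    numerical_aperture: float = 0.22
    channel_array: tuple[int, int] = (4, 2)
    channel_pitch_mm: float = 10.0
    grid_pitch_mm: float = 5.0

    def __post_init__(self) -> None:
        if min(
            self.n_channels,
            self.illumination_fibers_per_channel,
            self.collection_fibers_per_channel,
        ) <= 0:
            raise ValueError("fiber/channel counts must be positive")
        if min(self.channel_pitch_mm, self.grid_pitch_mm, self.fiber_diameter_um) <= 0:
            raise ValueError("pitch and fiber diameter must be positive")

    @property
    def fiber_radius_cm(self) -> float:
        return self.fiber_diameter_um * 1e-4 / 2.0

    @property
    def core_radius_cm(self) -> float:
        """Radius of the hexagonally packed 19-fiber illumination core.

        Two rings around the central fiber: outermost fiber centers at twice
        the fiber diameter, plus one fiber radius.
        """
        return 2.0 * self.fiber_diameter_um * 1e-4 + self.fiber_radius_cm

    @property
    def collection_radius_cm(self) -> float:
        """Center radius of the corner collection fibers (just outside core)."""
        return self.core_radius_cm + self.fiber_radius_cm

    def geometry_hash(self) -> str:
        key = repr(self).encode()
        return hashlib.sha1(key).hexdigest()[:12]


@dataclass(frozen=True)
class TransportConfig:
    """Monte Carlo run configuration.

    ``musp_ref_grid`` is the grid of baseline reduced scattering values
    (cm⁻¹); the kernel converts to μs via μs = μs′/(1−g). Refractive indices:
    tissue 1.37, rigid window 1.49 (typical soft-tissue / acrylic values).
    """

    n_photons: int = 400_000
    seed: int = 0
    g: float = 0.9
    n_tissue: float = 1.37
    n_window: float = 1.49
    musp_ref_grid: tuple[float, ...] = (2.0, 4.5, 7.5, 11.0, 16.5, 25.0)
    max_path_cm: float = 3.0
    kill_depth_cm: float = 0.8
    roulette_weight: float = 1e-4
    depth_bin_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.g < 1.0):
            raise ValueError("anisotropy g must lie in [0, 1)")
        if self.n_photons < 1:
            raise ValueError("n_photons must be positive")
        if any(m <= 0 for m in self.musp_ref_grid):
            raise ValueError("baseline musp grid must be positive")

    @property
    def n_depth_bins(self) -> int:
        return int(round(self.kill_depth_cm / (self.depth_bin_mm / 10.0)))


@njit(cache=True, fastmath=True)
def _fresnel_unpolarized(cos_i: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, incidence from the denser medium.

    ``n_rel`` = n_outside / n_inside (< 1 when leaving tissue into window).
    """
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = sin_i2 / (n_rel * n_rel)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (cos_i - n_rel * cos_t) / (cos_i + n_rel * cos_t)
    rp = (cos_t - n_rel * cos_i) / (cos_t + n_rel * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline='always')
def _deposit(depth_acc, z0, z1, seg_len, dz_bin, n_bins):
    """Distribute a path segment's length across 1-D depth bins."""
    if seg_len <= 0.0:
        return
    lo = z0 if z0 < z1 else z1
    hi = z1 if z1 > z0 else z0
    if hi - lo < 1e-12:
        k = int(lo / dz_bin)
        if k >= n_bins:
            k = n_bins - 1
        if k < 0:
            k = 0
        depth_acc[k] += seg_len
        return
    scale = seg_len / (hi - lo)
    k0 = int(lo / dz_bin)
    k1 = int(hi / dz_bin)
    if k0 < 0:
        k0 = 0
    if k1 >= n_bins:
        k1 = n_bins - 1
    if k0 >= n_bins:
        k0 = n_bins - 1
    for k in range(k0, k1 + 1):
        blo = k * dz_bin
        bhi = blo + dz_bin
        a = lo if lo > blo else blo
        b = hi if hi < bhi else bhi
        if k == n_bins - 1 and hi > bhi:
            b = hi  # overflow depth lumped into the last bin
        if b > a:
            depth_acc[k] += (b - a) * scale


@njit(cache=True, fastmath=True)
def _transport_kernel(
    seed,
    n_photons,
    mus,
    g,
    cos_launch_min,
    sin_accept_max,
    n_rel_exit,
    src_radius,
    ann_r_in,
    ann_r_out,
    area_frac,
    max_path,
    kill_depth,
    w_roulette,
    dz_bin,
    n_bins,
    max_records,
    track_depth,
):
    np.random.seed(seed)
    rec_w = np.zeros(max_records)
    rec_path = np.zeros(max_records)
    rec_nscat = np.zeros(max_records, dtype=np.int64)
    rec_fiber = np.zeros(max_records, dtype=np.int64)
    nb = n_bins if track_depth else 1
    rec_depth = np.zeros((max_records, nb), dtype=np.float32)
    depth_acc = np.zeros(nb)
    n_rec = 0
    overflow = 0

    for _ in range(n_photons):
        # launch: uniform over the illumination core, direction uniform in
        # solid angle within the fiber acceptance cone (refracted into tissue)
        r = src_radius * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = r * np.cos(phi)
        y = r * np.sin(phi)
        z = 0.0
        cos_t = cos_launch_min + (1.0 - cos_launch_min) * np.random.random()
        sin_t = np.sqrt(1.0 - cos_t * cos_t)
        psi = 2.0 * np.pi * np.random.random()
        ux = sin_t * np.cos(psi)
        uy = sin_t * np.sin(psi)
        uz = cos_t  # +z into the tissue
        w = 1.0
        path = 0.0
        nscat = 0
        if track_depth:
            depth_acc[:] = 0.0

        while True:
            s = -np.log(np.random.random() + 1e-300) / mus
            # boundary crossing?
            if uz < 0.0 and z + s * uz < 0.0:
                s_b = -z / uz
                x += s_b * ux
                y += s_b * uy
                if track_depth:
                    _deposit(depth_acc, z, 0.0, s_b, dz_bin, n_bins)
                path += s_b
                z = 0.0
                cos_i = -uz
                rf = _fresnel_unpolarized(cos_i, n_rel_exit)
                if rf < 1.0:
                    w_exit = w * (1.0 - rf)
                    sin_i = np.sqrt(1.0 - cos_i * cos_i)
                    rho = np.sqrt(x * x + y * y)
                    if (
                        sin_i <= sin_accept_max
                        and ann_r_in <= rho <= ann_r_out
                    ):
                        if n_rec < max_records:
                            rec_w[n_rec] = w_exit * area_frac
                            rec_path[n_rec] = path
                            rec_nscat[n_rec] = nscat
                            az = np.arctan2(y, x)
                            if az < 0.0:
                                az += 2.0 * np.pi
                            rec_fiber[n_rec] = int(az / (0.5 * np.pi)) % 4
                            if track_depth:
                                for k in range(nb):
                                    rec_depth[n_rec, k] = depth_acc[k]
                            n_rec += 1
                        else:
                            overflow += 1
                    w *= rf
                    if w <= 0.0:
                        break
                uz = -uz  # internal reflection of the remainder
                if w < w_roulette:
                    if np.random.random() < 0.1:
                        w *= 10.0
                    else:
                        break
                continue

            z_new = z + s * uz
            x += s * ux
            y += s * uy
            if track_depth:
                _deposit(depth_acc, z, z_new, s, dz_bin, n_bins)
            path += s
            z = z_new
            if z > kill_depth or path > max_path:
                break

            # Henyey-Greenstein scatter
            if g == 0.0:
                cos_s = 2.0 * np.random.random() - 1.0
            else:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                cos_s = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                if cos_s > 1.0:
                    cos_s = 1.0
                elif cos_s < -1.0:
                    cos_s = -1.0
            sin_s = np.sqrt(1.0 - cos_s * cos_s)
            psi = 2.0 * np.pi * np.random.random()
            cos_p = np.cos(psi)
            sin_p = np.sin(psi)
            if abs(uz) > 0.99999:
                ux = sin_s * cos_p
                uy = sin_s * sin_p
                uz = cos_s * (1.0 if uz >= 0.0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                ux_new = sin_s * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_s
                uy_new = sin_s * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_s
                uz_new = -sin_s * cos_p * den + uz * cos_s
                ux, uy, uz = ux_new, uy_new, uz_new
            norm = np.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm
            nscat += 1

    return rec_w[:n_rec], rec_path[:n_rec], rec_nscat[:n_rec], rec_fiber[:n_rec], rec_depth[:n_rec], overflow


@dataclass
class PhotonTable:
    """Per-photon collection records from one baseline (μa = 0) simulation."""

    weights: np.ndarray
    path_cm: np.ndarray
    n_scatter: np.ndarray
    fiber_id: np.ndarray
    depth_path: np.ndarray  # (n_records, n_depth_bins), cm of path per bin
    depth_bin_cm: float
    musp_ref: float
    mus_ref: float
    g: float
    seed: int
    n_photons: int
    geometry_hash: str

    def __post_init__(self) -> None:
        if self.weights.size == 0:
            raise NoPhotonsCollectedError(
                "baseline simulation collected zero photons; increase n_photons"
            )
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("collected weights must lie in (0, 1]")
        if np.any(self.path_cm <= 0):
            raise ValueError("collected path lengths must be positive")

    @property
    def collected_fraction(self) -> float:
        """Baseline (μa = 0) reflectance: total collected weight per photon."""
        return float(self.weights.sum() / self.n_photons)

    def reflectance(self, mua: float | np.ndarray) -> float | np.ndarray:
        """Beer–Lambert re-weighting of this table at absorption ``mua``."""
        mua_arr = np.atleast_1d(np.asarray(mua, dtype=float))
        r = np.exp(-np.outer(mua_arr, self.path_cm)) @ self.weights / self.n_photons
        return float(r[0]) if np.isscalar(mua) or np.ndim(mua) == 0 else r

    def depth_bins_mm(self) -> np.ndarray:
        """Centers of the depth bins in mm."""
        nb = self.depth_path.shape[1]
        return (np.arange(nb) + 0.5) * self.depth_bin_cm * 10.0


def run_baseline(
    geometry: ProbeGeometry,
    config: TransportConfig,
    musp_ref: float,
    seed: int | None = None,
    track_depth: bool = False,
) -> PhotonTable:
    """Run one μa = 0 baseline simulation at reduced scattering ``musp_ref``.

    ``track_depth`` enables per-collected-photon depth-binned path length
    bookkeeping (needed by the sensing-depth analysis; costs extra time and
    memory, so reflectance-only baselines leave it off).
    """
    if musp_ref <= 0:
        raise ValueError("musp_ref must be positive")
    if geometry.core_radius_cm <= 0:
        raise ValueError("degenerate probe geometry")
    seed = config.seed if seed is None else seed
    mus = musp_ref / (1.0 - config.g)
    sin_accept = geometry.numerical_aperture / config.n_tissue
    cos_launch_min = np.sqrt(max(0.0, 1.0 - sin_accept**2))
    fr = geometry.fiber_radius_cm
    r_col = geometry.collection_radius_cm
    ann_in, ann_out = r_col - fr, r_col + fr
    area_frac = (
        geometry.collection_fibers_per_channel * np.pi * fr**2
        / (np.pi * (ann_out**2 - ann_in**2))
    )
    n_rel_exit = config.n_window / config.n_tissue
    dz = config.depth_bin_mm / 10.0
    max_records = max(1000, config.n_photons // 40)
    w, p, ns, fid, dpth, overflow = _transport_kernel(
        seed % (2**31 - 1),
        config.n_photons,
        mus,
        config.g,
        cos_launch_min,
        sin_accept,
        n_rel_exit,
        geometry.core_radius_cm,
        ann_in,
        ann_out,
        area_frac,
        config.max_path_cm,
        config.kill_depth_cm,
        config.roulette_weight,
        dz,
        config.n_depth_bins,
        max_records,
        track_depth,
    )
    if overflow > 0:
        raise RuntimeError(
            f"photon record buffer overflowed ({overflow} dropped); "
            "raise max_records"
        )
    return PhotonTable(
        weights=w,
        path_cm=p,
        n_scatter=ns,
        fiber_id=fid,
        depth_path=dpth,
        depth_bin_cm=dz,
        musp_ref=musp_ref,
        mus_ref=mus,
        g=config.g,
        seed=seed,
        n_photons=config.n_photons,
        geometry_hash=geometry.geometry_hash(),
    )


class ReflectanceLookup:
    """Baseline-table set supporting R(μa, μs′) for arbitrary arguments.

    Path lengths are binned (geometric bins shared across tables) so that a
    reflectance evaluation is one small matrix product — cheap enough for the
    inner loop of a spectral inversion. Binned and per-photon evaluations
    agree to well under the Monte Carlo noise floor.
    """

    def __init__(self, tables: list[PhotonTable], n_path_bins: int = 160):
        if len(tables) < 2:
            raise ValueError("need at least two baseline tables for interpolation")
        tables = sorted(tables, key=lambda t: t.musp_ref)
        self.tables = tables
        self.musp_grid = np.array([t.musp_ref for t in tables])
        if np.any(np.diff(self.musp_grid) <= 0):
            raise ValueError("duplicate musp_ref values in baseline set")
        lmin = min(t.path_cm.min() for t in tables)
        lmax = max(t.path_cm.max() for t in tables)
        edges = np.geomspace(max(lmin, 1e-4) * 0.999, lmax * 1.001, n_path_bins + 1)
        # weight-preserving binning: weighted mean path within each bin
        self.path_centers = np.sqrt(edges[:-1] * edges[1:])
        self.bin_weights = np.zeros((n_path_bins, len(tables)))
        centers = self.path_centers.copy()
        wsum_l = np.zeros(n_path_bins)
        for j, t in enumerate(tables):
            idx = np.clip(np.digitize(t.path_cm, edges) - 1, 0, n_path_bins - 1)
            np.add.at(self.bin_weights[:, j], idx, t.weights / t.n_photons)
            np.add.at(wsum_l, idx, t.weights * t.path_cm)
        tot_w = self.bin_weights.sum(axis=1)
        nz = tot_w > 0
        # recentre populated bins at their weight-averaged path length
        wsum = np.zeros(n_path_bins)
        for j, t in enumerate(tables):
            idx = np.clip(np.digitize(t.path_cm, edges) - 1, 0, n_path_bins - 1)
            np.add.at(wsum, idx, t.weights)
        centers[nz] = wsum_l[nz] / wsum[nz]
        self.path_centers = centers

    @property
    def musp_span(self) -> tuple[float, float]:
        return float(self.musp_grid[0]), float(self.musp_grid[-1])

    def reflectance(self, mua, musp) -> np.ndarray:
        """R for paired arrays (or scalars) of μa and μs′ [cm⁻¹]."""
        mua_arr = np.atleast_1d(np.asarray(mua, dtype=float))
        musp_arr = np.atleast_1d(np.asarray(musp, dtype=float))
        mua_arr, musp_arr = np.broadcast_arrays(mua_arr, musp_arr)
        lo, hi = self.musp_span
        if np.any(musp_arr < lo - 1e-9) or np.any(musp_arr > hi + 1e-9):
            raise ExtrapolationError(
                f"musp outside baseline hull [{lo}, {hi}] cm^-1"
            )
        if np.any(mua_arr < 0):
            raise ValueError("mua must be >= 0")
        # (n_eval, n_bins) attenuation matrix, then per-table reflectance
        att = np.exp(-np.multiply.outer(mua_arr.ravel(), self.path_centers))
        r_tables = att @ self.bin_weights  # (n_eval, n_tables)
        j = np.clip(
            np.searchsorted(self.musp_grid, musp_arr.ravel()) - 1,
            0,
            len(self.musp_grid) - 2,
        )
        m0 = self.musp_grid[j]
        m1 = self.musp_grid[j + 1]
        f = np.clip((musp_arr.ravel() - m0) / (m1 - m0), 0.0, 1.0)
        rows = np.arange(r_tables.shape[0])
        out = (1.0 - f) * r_tables[rows, j] + f * r_tables[rows, j + 1]
        if np.isscalar(mua) and np.isscalar(musp):
            return float(out[0])
        return out.reshape(mua_arr.shape)


def scaled_reflectance(table, mua, musp):
    """Reflectance at (μa, μs′) from stored baseline photon records.

    ``table`` may be a single :class:`PhotonTable` (μs′ must then match the
    table's own reference) or a :class:`ReflectanceLookup` spanning a μs′
    grid.
    """
    if isinstance(table, ReflectanceLookup):
        return table.reflectance(mua, musp)
    if isinstance(table, PhotonTable):
        if np.any(np.abs(np.asarray(musp, float) - table.musp_ref) > 1e-9):
            raise ExtrapolationError(
                "single baseline table cannot interpolate in musp; "
                "build a ReflectanceLookup over a musp grid"
            )
        return table.reflectance(mua)
    raise TypeError("table must be a PhotonTable or ReflectanceLookup")


_DEFAULT_LOOKUP_CACHE: dict[tuple, ReflectanceLookup] = {}


def build_lookup(
    geometry: ProbeGeometry | None = None,
    config: TransportConfig | None = None,
) -> ReflectanceLookup:
    """Build (and memoize, per process) the baseline lookup for a config."""
    geometry = geometry or ProbeGeometry()
    config = config or TransportConfig()
    key = (geometry.geometry_hash(), config.seed, config.n_photons, config.musp_ref_grid)
    if key not in _DEFAULT_LOOKUP_CACHE:
        tables = [
            run_baseline(geometry, config, m, seed=config.seed + 7919 * i)
            for i, m in enumerate(config.musp_ref_grid)
        ]
        _DEFAULT_LOOKUP_CACHE[key] = ReflectanceLookup(tables)
    return _DEFAULT_LOOKUP_CACHE[key]


def simulate_spectrum(
    c: ChromophoreSet,
    s: ScatteringModel,
    basis: ExtinctionBasis,
    grid: WavelengthGrid,
    lookup: ReflectanceLookup,
) -> np.ndarray:
    """Forward-model reflectance spectrum on ``grid``: one value per λ."""
    mua = compose_mua(c, basis, grid)
    musp = musp_curve(s, grid)
    return lookup.reflectance(mua, musp)


def diffusion_reflectance(
    mua, musp, n_rel: float = 1.37 / 1.49
) -> float | np.ndarray:
    """Closed-form total diffuse reflectance of a semi-infinite medium.

    Standard diffusion-dipole result with an extrapolated boundary: the
    point-source dipole solution integrated over the exit surface,

        R = (a′/2)·[exp(−μ_eff·z0) + exp(−μ_eff·(z0 + 2·z_b))],

    with a′ = μs′/(μa+μs′), z0 = 1/(μa+μs′), μ_eff = √(3μa(μa+μs′)),
    z_b = 2AD, and A the internal-reflection boundary coefficient. Used as an
    independent physics oracle for the Monte Carlo model, not as part of the
    fitted pipeline.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(musp <= 0):
        raise ValueError("musp must be positive")
    mut = mua + musp
    ap = musp / mut
    mueff = np.sqrt(3.0 * mua * mut)
    z0 = 1.0 / mut
    # Groenhuis/Egan-Hilgeman empirical internal-reflection parameter
    rd = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    a_coef = (1.0 + rd) / (1.0 - rd)
    d = 1.0 / (3.0 * mut)
    zb = 2.0 * a_coef * d
    r = 0.5 * ap * (np.exp(-mueff * z0) + np.exp(-mueff * (z0 + 2.0 * zb)))
    return float(r) if r.ndim == 0 else r


def diffusion_reflectance_radial(
    mua, musp, rho_cm: float, n_rel: float = 1.37 / 1.49
) -> float | np.ndarray:
    """Diffusion-dipole reflectance at source-detector separation ``rho_cm``.

    The standard extrapolated-boundary dipole (isotropic source at
    z0 = 1/μt′, image source at −(z0 + 2z_b)):

        R(ρ) = (a′/4π)·Σ_± z_±(μ_eff + 1/r_±)·exp(−μ_eff·r_±)/r_±².

    Used as the geometry-matched physics oracle for the probe's Monte Carlo
    reflectance (the probe collects at sub-millimeter separations, where the
    *total* reflectance closed form has much longer effective paths).
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(musp <= 0) or rho_cm <= 0:
        raise ValueError("musp and rho must be positive")
    mut = mua + musp
    ap = musp / mut
    mueff = np.sqrt(3.0 * mua * mut)
    z0 = 1.0 / mut
    rd = -1.440 * n_rel**-2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    a_coef = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * a_coef / (3.0 * mut)
    r1 = np.sqrt(z0**2 + rho_cm**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho_cm**2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    r = ap / (4.0 * np.pi) * (term1 + term2)
    return float(r) if r.ndim == 0 else r
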