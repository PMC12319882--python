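"""Ground-truth phantoms: a folded gyrus, its SAF sheet, retinotopy and fMRI.

The phantom emulates the inferior cuneal gyrus at the V1-V2 interface: a
single fold (two cortical banks meeting at a rounded crown) extruded along
the anterior-posterior (A-P, +y) axis.  The white-surface cross-section is
a "tent" - two straight banks of slope ``a`` joined by a circular crown of
radius R - and the sub-cortical U/V-fibres are the inward offset of that
curve at a fixed depth, one fibre per A-P station, so every generated
streamline has an analytically known arc length and apex angle.

Retinotopy follows the in vivo layout: eccentricity increases linearly
along the A-P axis (default 3 deg -> 6.9 deg, the experimentally stimulated
range) and polar angle varies linearly with cross-fold arc length.
Phase-encoded fMRI responses are sinusoids at the stimulus frequency whose
phase encodes eccentricity, plus Gaussian noise.

Degradation knobs emulate tractography error rather than rigid motion:
``jitter_sd`` displaces the V1-end of each fibre along the A-P axis with a
linear ramp (full displacement at the V1 termination, none at the V2 end),
decoupling the V1-end retinotopy from the fibre's position, and
``crowding_sd`` perturbs the V1 arm's cross-fold extent (the fibre keeps
following the offset curve, so lengths and apex angles stay analytic),
decoupling the V1-end polar angle from the mirrored V2-end position and
emulating the tight cross-fold packing that degrades polar-angle order more
than eccentricity order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import (
    CorticalLabel,
    SurfaceMesh,
    Tractogram,
    ValidationError,
    VertexScalarMap,
)
from .retinotopy import FMRITimeSeries

__all__ = [
    "FoldConfig",
    "FibreConfig",
    "RetinotopyConfig",
    "FMRIConfig",
    "SceneConfig",
    "SyntheticScene",
    "solve_fold_geometry",
    "make_gyrus_mesh",
    "make_saf_streamlines",
    "make_retinotopy_fields",
    "make_fmri_timeseries",
    "make_scene",
    "make_bundle_streamlines",
    "make_fibre_cloud",
]


@dataclass
class FoldConfig:
    """Geometry of the single-fold gyrus."""

    crown_radius: float = 2.0  # mm; rounding of the crown (smaller = sharper)
    half_width: float = 9.0  # mm; cross-fold half extent
    extent_ap: float = 18.0  # mm along the A-P axis
    cortical_thickness: float = 2.0  # mm, white -> pial offset
    mesh_step: float = 0.5  # mm grid resolution

    def __post_init__(self) -> None:
        for name in ("crown_radius", "half_width", "extent_ap", "cortical_thickness", "mesh_step"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"fold.{name} must be > 0")


@dataclass
class FibreConfig:
    """The planted SAF population."""

    count: int = 200
    apex_angle: float = 140.0  # deg, target measured bending angle
    mean_length: float = 12.0  # mm arc length
    length_sd: float = 2.0  # mm, per-fibre spread (clipped to +-2 sd)
    depth: float = 0.5  # mm below the white surface
    jitter_sd: float = 0.0  # mm, V1-endward ramped A-P displacement
    crowding_sd: float = 0.5  # mm, rigid cross-fold translation per fibre
    point_step: float = 0.2  # mm sampling along each fibre

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError("fibres.count must be >= 1")
        if not 0 < self.apex_angle < 180:
            raise ValidationError("fibres.apex_angle must be in (0, 180) deg")
        for name in ("mean_length", "depth", "point_step"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"fibres.{name} must be > 0")
        if self.length_sd < 0 or self.jitter_sd < 0 or self.crowding_sd < 0:
            raise ValidationError("spreads must be >= 0")


@dataclass
class RetinotopyConfig:
    """Linear retinotopic gradients on the phantom cortex."""

    ecc_range: tuple[float, float] = (3.0, 6.9)  # deg along A-P
    polar_range: tuple[float, float] = (180.0, 270.0)  # deg across the fold

    def __post_init__(self) -> None:
        if self.ecc_range[0] < 0 or self.ecc_range[1] <= self.ecc_range[0]:
            raise ValidationError("ecc_range must be increasing and non-negative")


@dataclass
class FMRIConfig:
    """Phase-encoded fMRI response model."""

    stimulus_frequency: int = 8  # cycles per run
    n_samples: int = 128
    tr: float = 2.0  # s
    amplitude: float = 1.0
    noise_sd: float = 0.2
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.stimulus_frequency < 1:
            raise ValidationError("stimulus_frequency must be >= 1")
        if self.n_samples < 4 * self.stimulus_frequency:
            raise ValidationError("need >= 4 samples per stimulus cycle")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValidationError("amplitude and noise_sd must be >= 0")


@dataclass
class SceneConfig:
    fold: FoldConfig = field(default_factory=FoldConfig)
    fibres: FibreConfig = field(default_factory=FibreConfig)
    retinotopy: RetinotopyConfig = field(default_factory=RetinotopyConfig)
    fmri: FMRIConfig = field(default_factory=FMRIConfig)
    seed: int = 0
    ap_margin: float = 2.0  # mm free margin at both A-P ends
    n_ecc_bands: int = 6
    n_polar_bands: int = 15

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        for key, sub in (
            ("fold", FoldConfig),
            ("fibres", FibreConfig),
            ("retinotopy", RetinotopyConfig),
            ("fmri", FMRIConfig),
        ):
            if key in d and isinstance(d[key], dict):
                val = dict(d[key])
                for k, v in val.items():
                    if isinstance(v, list):
                        val[k] = tuple(v)
                d[key] = sub(**val)
        return cls(**d)


@dataclass
class FoldGeometry:
    """Solved continuous geometry shared by mesh and fibres."""

    slope: float  # bank slope a
    crown_radius: float  # R (white surface)
    depth: float  # fibre depth d
    x_end: float  # fibre endpoint |x| for the mean-length fibre
    centre_z: float  # crown circle centre (on the z axis)

    @property
    def fibre_radius(self) -> float:
        return self.crown_radius - self.depth

    def white_z(self, x: np.ndarray) -> np.ndarray:
        """White-surface height at cross-fold coordinate x (crown near z=0)."""
        return self._offset_z(np.asarray(x, dtype=float), 0.0)

    def fibre_z(self, x: np.ndarray) -> np.ndarray:
        return self._offset_z(np.asarray(x, dtype=float), self.depth)

    def _offset_z(self, x: np.ndarray, d: float) -> np.ndarray:
        a = self.slope
        r = self.crown_radius - d
        x_t = a * r / np.sqrt(1 + a * a)
        cap = self.centre_z + np.sqrt(np.maximum(r * r - x * x, 0.0))
        arm = -a * np.abs(x) - d * np.sqrt(1 + a * a)
        return np.where(np.abs(x) < x_t, cap, arm)

    def fibre_arc(
        self, x_neg: float, x_pos: float, step: float
    ) -> tuple[np.ndarray, np.ndarray, float]:
        """Uniform-arc-length samples (x, z) of the fibre cross-section from
        ``-x_neg`` to ``+x_pos`` (arms may be asymmetric), plus the exact
        total arc length."""
        a, r = self.slope, self.fibre_radius
        rt = np.sqrt(1 + a * a)
        x_t = a * r / rt
        alpha = np.arctan(a)
        s_arm1 = (x_neg - x_t) * rt
        s_arm2 = (x_pos - x_t) * rt
        s_cap = 2 * alpha * r
        total = s_arm1 + s_cap + s_arm2
        s = np.arange(0.0, total, step)
        if total - s[-1] > 1e-9:
            s = np.concatenate([s, [total]])
        else:
            s[-1] = total
        x = np.empty_like(s)
        z = np.empty_like(s)
        m1 = s <= s_arm1
        x[m1] = -x_neg + s[m1] / rt
        z[m1] = -a * np.abs(x[m1]) - self.depth * rt
        m2 = (s > s_arm1) & (s < s_arm1 + s_cap)
        psi = (s[m2] - s_arm1) / r - alpha
        x[m2] = r * np.sin(psi)
        z[m2] = self.centre_z + r * np.cos(psi)
        m3 = s >= s_arm1 + s_cap
        x[m3] = x_t + (s[m3] - s_arm1 - s_cap) / rt
        z[m3] = -a * np.abs(x[m3]) - self.depth * rt
        return x, z, float(total)

    def apex_angle(self, x_neg: float, x_pos: float | None = None) -> float:
        """Analytic apex-to-endpoints angle (deg) of the continuous fibre."""
        a, r = self.slope, self.fibre_radius
        if x_pos is None:
            x_pos = x_neg
        delta = r * (np.sqrt(1 + a * a) - 1)
        half1 = np.arctan2(x_neg, a * x_neg - delta)
        half2 = np.arctan2(x_pos, a * x_pos - delta)
        return float(np.degrees(half1 + half2))

    def arc_length_asym(self, x_neg: float, x_pos: float) -> float:
        a, r = self.slope, self.fibre_radius
        rt = np.sqrt(1 + a * a)
        x_t = a * r / rt
        return float((x_neg - x_t) * rt + (x_pos - x_t) * rt + 2 * np.arctan(a) * r)

    def arc_length_for_xend(self, x_end: float) -> float:
        a, r = self.slope, self.fibre_radius
        rt = np.sqrt(1 + a * a)
        x_t = a * r / rt
        return float(2 * (x_end - x_t) * rt + 2 * np.arctan(a) * r)

    def xend_for_arc_length(self, length: float) -> float:
        a, r = self.slope, self.fibre_radius
        rt = np.sqrt(1 + a * a)
        x_t = a * r / rt
        return float(x_t + (length / 2 - np.arctan(a) * r) / rt)


def solve_fold_geometry(fold: FoldConfig, fibres: FibreConfig) -> FoldGeometry:
    """Solve the bank slope so the mean-length fibre measures the target angle.

    The measured bending angle (apex -> endpoints) of a tent fibre with a
    rounded crown is slightly wider than the asymptotic arm angle; the slope
    is solved numerically so the two coincide for the mean-length fibre.
    """
    theta = np.radians(fibres.apex_angle)
    r_f = fold.crown_radius - fibres.depth
    if r_f <= 0:
        raise ValidationError("fibre depth >= crown radius: no white matter left")
    target = 1.0 / np.tan(theta / 2.0)

    a = max(target, 1e-4)
    x_end = fibres.mean_length / 2.0
    for _ in range(60):
        rt = np.sqrt(1 + a * a)
        x_t = a * r_f / rt
        x_end = x_t + (fibres.mean_length / 2 - np.arctan(a) * r_f) / rt
        if x_end <= x_t:
            raise ValidationError("mean_length too short for this crown radius")

        def g(aa: float, xe: float = x_end) -> float:
            return aa * xe - r_f * (np.sqrt(1 + aa * aa) - 1) - xe * target

        try:
            a_new = brentq(g, 1e-6, 50.0, xtol=1e-12)
        except ValueError as exc:
            raise ValidationError(
                "apex angle unreachable: fibres too short for this crown radius"
            ) from exc
        if abs(a_new - a) < 1e-12:
            a = a_new
            break
        a = a_new
    centre_z = -fold.crown_radius * np.sqrt(1 + a * a)
    geom = FoldGeometry(
        slope=a,
        crown_radius=fold.crown_radius,
        depth=fibres.depth,
        x_end=x_end,
        centre_z=centre_z,
    )
    if x_end + 1.0 > fold.half_width:
        raise ValidationError(
            f"fibre extent {x_end:.1f} mm does not fit half_width {fold.half_width} mm"
        )
    return geom


def make_gyrus_mesh(cfg: SceneConfig) -> tuple[SurfaceMesh, SurfaceMesh]:
    """White and pial meshes of the extruded single-fold gyrus.

    Pial is the white surface offset outward (upward) along vertex normals by
    the cortical thickness; the crown is convex so the offset cannot fold.
    """
    geom = solve_fold_geometry(cfg.fold, cfg.fibres)
    f = cfg.fold
    nx = int(round(2 * f.half_width / f.mesh_step)) + 1
    ny = int(round(f.extent_ap / f.mesh_step)) + 1
    xs = np.linspace(-f.half_width, f.half_width, nx)
    ys = np.linspace(0.0, f.extent_ap, ny)
    X, Y = np.meshgrid(xs, ys, indexing="xy")  # rows j over y
    Z = np.broadcast_to(geom.white_z(xs), X.shape)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    tris = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            v00 = j * nx + i
            v10 = v00 + 1
            v01 = v00 + nx
            v11 = v01 + 1
            tris.append([v00, v10, v11])
            tris.append([v00, v11, v01])
    triangles = np.array(tris, dtype=np.int64)
    white = SurfaceMesh(vertices, triangles, role="white")

    normals = white.vertex_normals()
    pial = SurfaceMesh(vertices + f.cortical_thickness * normals, triangles, role="pial")
    # outward offset of this convex-crowned fold cannot fold over, but guard
    # against pathological configs by checking no triangle flipped
    from ._mesh import triangle_normals

    nw, _ = triangle_normals(white.vertices, white.triangles)
    np_, _ = triangle_normals(pial.vertices, pial.triangles)
    if np.any(np.einsum("ij,ij->i", nw, np_) <= 0):
        raise ValidationError("cortical thickness causes the pial offset to self-intersect")
    return white, pial


def _nearest_bank_vertex(white: SurfaceMesh, points: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Index (into ``bank``) of the nearest bank vertex for each point."""
    from scipy.spatial import cKDTree

    tree = cKDTree(white.vertices[bank])
    _, j = tree.query(points)
    return j


def make_saf_streamlines(
    cfg: SceneConfig, white: SurfaceMesh
) -> tuple[Tractogram, pd.DataFrame]:
    """The planted U/V-fibre sheet plus its ground-truth manifest.

    One fibre per A-P station (evenly spaced inside the margins), running at
    the configured depth below the white surface from the V1 bank (x < 0)
    across the crown to the V2 bank.  The manifest records, per fibre, the
    analytic arc length and apex angle of the continuous geometry, the seed
    retinotopy at the (unjittered) V1 termination, and the eccentricity /
    polar-angle band the V1 termination falls in (band of its nearest V1
    surface vertex, mirroring termination-based clustering).
    """
    geom = solve_fold_geometry(cfg.fold, cfg.fibres)
    fib = cfg.fibres
    rng = np.random.default_rng(cfg.seed)
    Y = cfg.fold.extent_ap
    y_lo, y_hi = cfg.ap_margin, Y - cfg.ap_margin
    stations = y_lo + (np.arange(fib.count) + 0.5) / fib.count * (y_hi - y_lo)

    lengths = np.clip(
        rng.normal(fib.mean_length, fib.length_sd, fib.count),
        fib.mean_length - 2 * fib.length_sd,
        fib.mean_length + 2 * fib.length_sd,
    )
    min_len = geom.arc_length_for_xend(
        geom.slope * geom.fibre_radius / np.sqrt(1 + geom.slope**2) + 0.5
    )
    max_len = geom.arc_length_for_xend(cfg.fold.half_width - 1.0)
    lengths = np.clip(lengths, min_len, max_len)

    jitter = rng.normal(0.0, fib.jitter_sd, fib.count) if fib.jitter_sd else np.zeros(fib.count)
    crowd = rng.normal(0.0, fib.crowding_sd, fib.count) if fib.crowding_sd else np.zeros(fib.count)
    flip = rng.random(fib.count) < 0.5

    ecc0, ecc1 = cfg.retinotopy.ecc_range
    pol0, pol1 = cfg.retinotopy.polar_range
    cross = _cross_arc_interpolator(cfg, geom)

    streamlines: list[np.ndarray] = []
    records = []
    bank = np.flatnonzero(white.vertices[:, 0] < 0)  # V1 bank vertices
    bank_coords = white.vertices[bank]
    y_band_w = (Y - 0.0) / cfg.n_ecc_bands
    x_lo, x_hi = bank_coords[:, 0].min(), bank_coords[:, 0].max()
    x_band_w = (x_hi - x_lo) / cfg.n_polar_bands

    x_t = geom.slope * geom.fibre_radius / np.sqrt(1 + geom.slope**2)
    v1_ends = np.empty((fib.count, 3))
    for k in range(fib.count):
        x_end = geom.xend_for_arc_length(lengths[k])
        # crowding misplaces the V1 termination along the cross-fold curve
        x_neg = float(np.clip(x_end + crowd[k], x_t + 0.5, cfg.fold.half_width - 1.0))
        x, z, total = geom.fibre_arc(x_neg, x_end, fib.point_step)
        s = np.linspace(0.0, 1.0, len(x))
        ramp = 1.0 - s  # 1 at the V1 end, 0 at the V2 end
        pts = np.column_stack([x, stations[k] + jitter[k] * ramp, z])
        v1_ends[k] = pts[0]
        if flip[k]:
            pts = pts[::-1]
        streamlines.append(pts)

        true_angle = geom.apex_angle(x_neg, x_end)
        seed_ecc = ecc0 + (ecc1 - ecc0) * stations[k] / Y
        seed_pol = pol0 + (pol1 - pol0) * cross(-x_neg)
        records.append(
            {
                "index": k,
                "y_station": stations[k],
                "x_end": x_end,
                "x_end_v1": x_neg,
                "true_length": total,
                "true_apex_angle": true_angle,
                "seed_eccentricity": seed_ecc,
                "seed_polar_angle": seed_pol,
                "depth": fib.depth,
                "reversed": bool(flip[k]),
                "jitter_y": jitter[k],
                "crowding_x": crowd[k],
            }
        )

    near = _nearest_bank_vertex(white, v1_ends, bank)
    near_xy = bank_coords[near]
    manifest = pd.DataFrame.from_records(records)
    manifest["ecc_band"] = np.clip(
        (near_xy[:, 1] / y_band_w).astype(int), 0, cfg.n_ecc_bands - 1
    )
    manifest["polar_band"] = np.clip(
        ((near_xy[:, 0] - x_lo) / x_band_w).astype(int), 0, cfg.n_polar_bands - 1
    )
    return Tractogram(streamlines, provenance={"generator": "safsheet-phantom"}), manifest


def _cross_arc_interpolator(cfg: SceneConfig, geom: FoldGeometry):
    """Normalised cross-fold arc-length coordinate s(x) in [0, 1] on white."""
    xs = np.linspace(-cfg.fold.half_width, cfg.fold.half_width, 4001)
    zs = geom.white_z(xs)
    seg = np.sqrt(np.diff(xs) ** 2 + np.diff(zs) ** 2)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    cum /= cum[-1]

    def interp(x):
        return np.interp(x, xs, cum)

    return interp


def make_retinotopy_fields(
    cfg: SceneConfig, mesh: SurfaceMesh
) -> tuple[VertexScalarMap, VertexScalarMap]:
    """Eccentricity linear along A-P; polar angle linear in cross-fold arc."""
    geom = solve_fold_geometry(cfg.fold, cfg.fibres)
    ecc0, ecc1 = cfg.retinotopy.ecc_range
    pol0, pol1 = cfg.retinotopy.polar_range
    y = mesh.vertices[:, 1]
    ecc = ecc0 + (ecc1 - ecc0) * y / cfg.fold.extent_ap
    cross = _cross_arc_interpolator(cfg, geom)
    pol = np.mod(pol0 + (pol1 - pol0) * cross(mesh.vertices[:, 0]), 360.0)
    return (
        VertexScalarMap(ecc, kind="eccentricity"),
        VertexScalarMap(pol, kind="polar_angle"),
    )


def analytic_noise_free_snr(n_samples: int) -> float:
    """SNR of a pure integer-frequency sinusoid under the spectral SNR
    statistic: one non-zero bin among the T/2 non-DC one-sided bins."""
    nb = n_samples // 2
    return nb / np.sqrt(nb - 1)


def make_fmri_timeseries(
    cfg: SceneConfig,
    ecc_map: VertexScalarMap,
    mesh: SurfaceMesh,
) -> tuple[FMRITimeSeries, np.ndarray]:
    """Phase-encoded responses: phase proportional to eccentricity.

    Returns the time series and the per-vertex true phase (radians).
    """
    fm = cfg.fmri
    rng = np.random.default_rng(cfg.seed + 1)
    ecc0, ecc1 = cfg.retinotopy.ecc_range
    phase = 2 * np.pi * (ecc_map.values - ecc0) / (ecc1 - ecc0)
    t = np.arange(fm.n_samples)
    arg = 2 * np.pi * fm.stimulus_frequency * t[None, :] / fm.n_samples + phase[:, None]
    samples = fm.baseline + fm.amplitude * np.sin(arg)
    if fm.noise_sd > 0:
        samples = samples + rng.normal(0.0, fm.noise_sd, samples.shape)
    return (
        FMRITimeSeries(samples, stimulus_frequency=fm.stimulus_frequency, tr=fm.tr),
        phase,
    )


@dataclass
class SyntheticScene:
    """A complete phantom bundle plus ground truth."""

    config: SceneConfig
    white: SurfaceMesh
    pial: SurfaceMesh
    tractogram: Tractogram
    manifest: pd.DataFrame
    eccentricity: VertexScalarMap
    polar_angle: VertexScalarMap
    v1: CorticalLabel
    v2: CorticalLabel
    timeseries: FMRITimeSeries | None = None
    true_phase: np.ndarray | None = None

    def true_axis_variances(self) -> np.ndarray:
        """Pooled-point variances along the canonical scene axes (y, x, z)."""
        pts = np.vstack(list(self.tractogram))
        v = pts.var(axis=0)
        return np.array([v[1], v[0], v[2]])


def make_scene(cfg: SceneConfig | None = None, with_fmri: bool = True) -> SyntheticScene:
    """Generate the full phantom: meshes, fibres, maps, labels, time series."""
    cfg = cfg or SceneConfig()
    white, pial = make_gyrus_mesh(cfg)
    tract, manifest = make_saf_streamlines(cfg, white)
    ecc, pol = make_retinotopy_fields(cfg, white)
    x = white.vertices[:, 0]
    v1 = CorticalLabel("V1", vertex_indices=np.flatnonzero(x < 0))
    v2 = CorticalLabel("V2", vertex_indices=np.flatnonzero(x >= 0))
    ts = phase = None
    if with_fmri:
        ts, phase = make_fmri_timeseries(cfg, ecc, white)
    return SyntheticScene(
        config=cfg,
        white=white,
        pial=pial,
        tractogram=tract,
        manifest=manifest,
        eccentricity=ecc,
        polar_angle=pol,
        v1=v1,
        v2=v2,
        timeseries=ts,
        true_phase=phase,
    )


def make_bundle_streamlines(
    n_fibres: int = 100,
    length: float = 20.0,
    cross_sd: float = 1.0,
    step: float = 0.5,
    seed: int = 0,
) -> Tractogram:
    """A cylinder-bundle phantom: straight fibres along +y with a tight,
    isotropic Gaussian cross-section (one long axis, two small comparable
    ones)."""
    rng = np.random.default_rng(seed)
    centres = rng.normal(0.0, cross_sd, size=(n_fibres, 2))
    ys = np.arange(0.0, length + step / 2, step)
    streamlines = [
        np.column_stack([np.full_like(ys, cx), ys, np.full_like(ys, cz)])
        for cx, cz in centres
    ]
    return Tractogram(streamlines, provenance={"generator": "safsheet-bundle"})


def make_fibre_cloud(
    variances: tuple[float, float, float] = (25.0, 9.0, 1.0),
    n_fibres: int = 200,
    n_points: int = 50,
    rotation: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[Tractogram, dict]:
    """Gaussian streamline cloud with exactly known generating variances.

    Points are drawn i.i.d. N(0, diag(variances)); each fibre's points are
    sorted along the first axis so they form a valid polyline.  An optional
    rotation matrix maps the generating axes into world space; the manifest
    records the generating variances and axes.
    """
    rng = np.random.default_rng(seed)
    sd = np.sqrt(np.asarray(variances, dtype=float))
    R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
    streamlines = []
    for _ in range(n_fibres):
        pts = rng.normal(0.0, 1.0, size=(n_points, 3)) * sd
        pts = pts[np.argsort(pts[:, 0])]
        streamlines.append(pts @ R.T)
    # points transform as p = R x, so the generating axes are R's columns
    manifest = {"variances": tuple(float(v) for v in variances), "axes": R.copy()}
    return Tractogram(streamlines, provenance={"generator": "safsheet-cloud"}), manifest
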