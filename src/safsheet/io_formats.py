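"""Domain types and file I/O for SAF sheet analysis.

All world coordinates are RAS millimetres.  Tractograms travel as TCK,
surfaces and per-vertex scalar maps as GIFTI (with a plain-text fallback:
OFF meshes and one-value-per-line maps), voxel labels as NIfTI, and
per-streamline reports as TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as _NibTractogram
from nibabel.streamlines.tck import TckFile

from ._mesh import triangle_normals, vertex_adjacency, vertex_normals

__all__ = [
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "Streamline",
    "Tractogram",
    "SurfaceMesh",
    "VertexScalarMap",
    "CorticalLabel",
    "read_tractogram",
    "write_tractogram",
    "read_surface",
    "read_vertex_map",
    "read_surface_and_maps",
    "write_surface",
    "write_vertex_map",
    "read_label_volume",
    "write_label_volume",
    "write_report",
    "read_report",
]

MAP_KINDS = ("eccentricity", "polar_angle", "snr")


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Data violate a structural invariant."""


class ConfigurationError(ValueError):
    """Inconsistent or unknown configuration value."""


# a streamline is an (N, 3) float array of RAS mm positions, N >= 2
Streamline = np.ndarray


def validate_streamline(points: np.ndarray, index: int | None = None) -> np.ndarray:
    """Check one streamline: >= 2 points, finite, no zero-length segments."""
    pts = np.asarray(points, dtype=float)
    where = "" if index is None else f" (streamline {index})"
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"streamline must be an (N, 3) array{where}")
    if len(pts) < 2:
        raise ValidationError(f"streamline needs at least 2 points{where}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError(f"non-finite streamline coordinate{where}")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValidationError(f"repeated consecutive point in streamline{where}")
    return pts


@dataclass
class Tractogram:
    """An ordered collection of streamlines in world (RAS, mm) coordinates."""

    streamlines: list[Streamline]
    space: str = "RAS"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.streamlines = [
            validate_streamline(s, i) for i, s in enumerate(self.streamlines)
        ]

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def subset(self, keep: Sequence[int] | np.ndarray) -> "Tractogram":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return Tractogram(
            [self.streamlines[i] for i in keep],
            space=self.space,
            provenance=dict(self.provenance),
        )


@dataclass
class SurfaceMesh:
    """A triangulated cortical surface (white or pial), vertices in RAS mm."""

    vertices: np.ndarray
    triangles: np.ndarray
    role: str = "white"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValidationError("triangles must be (F, 3)")
        if len(self.triangles) and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValidationError("triangle vertex index out of range")
        _, areas = triangle_normals(self.vertices, self.triangles)
        if np.any(areas <= 0):
            bad = np.flatnonzero(areas <= 0)
            raise ValidationError(f"degenerate zero-area triangles: {bad[:5].tolist()}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def vertex_normals(self) -> np.ndarray:
        return vertex_normals(self.vertices, self.triangles)

    def vertex_adjacency(self) -> list[np.ndarray]:
        return vertex_adjacency(self.triangles, self.n_vertices)

    def is_winding_consistent(self) -> bool:
        import trimesh

        tm = trimesh.Trimesh(self.vertices, self.triangles, process=False)
        return bool(tm.is_winding_consistent)


def wrap_polar_angle(values: np.ndarray) -> np.ndarray:
    """Wrap polar-angle degrees onto the principal interval [0, 360)."""
    out = np.mod(values, 360.0)
    return out * (out != 360.0)  # float rounding can yield exactly 360.0


@dataclass
class VertexScalarMap:
    """One scalar per mesh vertex: eccentricity (deg), polar angle (deg) or SNR.

    ``valid`` flags which vertices carry a trustworthy value; invalid ones are
    excluded from smoothing neighbourhoods and from endpoint means.
    """

    values: np.ndarray
    kind: str
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ConfigurationError(
                f"unknown map kind {self.kind!r}; expected one of {MAP_KINDS}"
            )
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).ravel()
            if len(self.valid) != len(self.values):
                raise ValidationError("valid mask length differs from values")
        finite = self.values[self.valid]
        if not np.all(np.isfinite(finite)):
            raise ValidationError("non-finite value flagged as valid")
        if self.kind == "polar_angle":
            out = (self.values < 0) | (self.values >= 360.0)
            if np.any(out & self.valid):
                warnings.warn(
                    "polar angle outside [0, 360) wrapped on load", stacklevel=2
                )
                self.values = wrap_polar_angle(self.values)
        elif np.any(finite < 0):
            raise ValidationError(f"{self.kind} map must be non-negative")

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "VertexScalarMap":
        return VertexScalarMap(self.values.copy(), self.kind, self.valid.copy())


@dataclass
class CorticalLabel:
    """A named cortical region as surface vertex indices and/or a voxel mask.

    Voxel labels carry an affine (voxel index -> RAS mm world).  Surface
    labels are authoritative for endpoint projection; voxel labels are the
    ones subject to V1/V2 overlap resolution.
    """

    name: str
    vertex_indices: np.ndarray | None = None
    voxels: np.ndarray | None = None  # (K, 3) integer voxel indices
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.vertex_indices is not None:
            idx = np.asarray(self.vertex_indices, dtype=np.int64).ravel()
            if len(np.unique(idx)) != len(idx):
                raise ValidationError(f"duplicate vertex indices in label {self.name}")
            if len(idx) and idx.min() < 0:
                raise ValidationError(f"negative vertex index in label {self.name}")
            self.vertex_indices = idx
        if self.voxels is not None:
            vox = np.asarray(self.voxels, dtype=np.int64)
            if vox.ndim != 2 or vox.shape[1] != 3:
                raise ValidationError("voxels must be (K, 3) integer indices")
            self.voxels = np.unique(vox, axis=0)
            if self.affine is None:
                raise ValidationError(f"voxel label {self.name} needs an affine")
            self.affine = np.asarray(self.affine, dtype=float)
            if self.affine.shape != (4, 4):
                raise ValidationError("affine must be 4x4")
        if self.vertex_indices is None and self.voxels is None:
            raise ValidationError(f"label {self.name} is empty of both carriers")

    def voxel_set(self) -> set[tuple[int, int, int]]:
        if self.voxels is None:
            return set()
        return {(int(a), int(b), int(c)) for a, b, c in self.voxels}

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world mm to nearest voxel indices (round-to-nearest)."""
        if self.affine is None:
            raise ValidationError(f"label {self.name} has no affine")
        inv = np.linalg.inv(self.affine)
        ijk = points @ inv[:3, :3].T + inv[:3, 3]
        return np.rint(ijk).astype(np.int64)

    def contains_world(self, points: np.ndarray, mesh: SurfaceMesh | None = None,
                       tolerance: float = 1.0) -> np.ndarray:
        """Membership of world points in this label.

        Voxel labels: round-to-nearest voxel after world->voxel mapping.
        Surface-only labels: nearest labelled vertex within ``tolerance`` mm.
        """
        points = np.atleast_2d(points)
        if self.voxels is not None:
            ijk = self.world_to_voxel(points)
            members = self.voxel_set()
            return np.array([tuple(r) in members for r in ijk], dtype=bool)
        if mesh is None:
            raise ConfigurationError(
                f"surface label {self.name} needs its mesh for point membership"
            )
        from scipy.spatial import cKDTree

        labelled = mesh.vertices[self.vertex_indices]
        d, _ = cKDTree(labelled).query(points)
        return d <= tolerance


# ---------------------------------------------------------------------------
# tractogram I/O (TCK)
# ---------------------------------------------------------------------------

def read_tractogram(path: str | Path) -> Tractogram:
    """Load a TCK tractogram; streamlines come back in world RAS mm."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        tck = nib.streamlines.load(str(path))
    except Exception as exc:  # nibabel raises assorted header errors
        raise FormatError(f"could not parse {path} as TCK: {exc}") from exc
    if not isinstance(tck, TckFile):
        raise FormatError(f"{path} is not a TCK file")
    provenance = {
        k: v for k, v in tck.header.items() if isinstance(v, (str, int, float))
    }
    streamlines = [np.asarray(s, dtype=float) for s in tck.streamlines]
    return Tractogram(streamlines, space="RAS", provenance=provenance)


def write_tractogram(t: Tractogram, path: str | Path) -> None:
    """Write a tractogram to TCK, readable by standard streamline toolkits."""
    for i, s in enumerate(t.streamlines):
        validate_streamline(s, i)
    nt = _NibTractogram(
        [np.asarray(s, dtype=np.float32) for s in t.streamlines],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nt, str(path))


# ---------------------------------------------------------------------------
# surface + vertex-map I/O (GIFTI, with plain-text fallback)
# ---------------------------------------------------------------------------

def read_surface(path: str | Path, role: str = "white") -> SurfaceMesh:
    """Read a surface mesh from GIFTI (.gii) or text OFF (.off)."""
    path = Path(path)
    if path.suffix == ".off":
        return _read_off(path, role)
    img = nib.load(str(path))
    if not isinstance(img, nib.gifti.GiftiImage):
        raise FormatError(f"{path} is not a GIFTI surface")
    pts = tris = None
    for arr in img.darrays:
        intent = nib.nifti1.intent_codes.label.get(arr.intent, arr.intent)
        if intent == "pointset":
            pts = arr.data
        elif intent == "triangle":
            tris = arr.data
    if pts is None or tris is None:
        raise FormatError(f"{path} lacks pointset/triangle arrays")
    return SurfaceMesh(np.asarray(pts, float), np.asarray(tris, np.int64), role=role)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".off":
        _write_off(mesh, path)
        return
    da_pts = nib.gifti.GiftiDataArray(
        mesh.vertices.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
    )
    da_tri = nib.gifti.GiftiDataArray(
        mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[da_pts, da_tri]), str(path))


def _read_off(path: Path, role: str) -> SurfaceMesh:
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines or lines[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    nv, nf, _ = (int(x) for x in lines[1].split())
    verts = np.array([[float(x) for x in ln.split()] for ln in lines[2:2 + nv]])
    faces = []
    for ln in lines[2 + nv:2 + nv + nf]:
        parts = [int(x) for x in ln.split()]
        if parts[0] != 3:
            raise FormatError(f"{path}: non-triangular face")
        faces.append(parts[1:4])
    return SurfaceMesh(verts, np.array(faces, dtype=np.int64), role=role)


def _write_off(mesh: SurfaceMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def read_vertex_map(path: str | Path, kind: str, mesh: SurfaceMesh | None = None) -> VertexScalarMap:
    """Read a per-vertex scalar map from GIFTI .func/.shape or plain text."""
    path = Path(path)
    if path.suffix in (".txt", ".csv"):
        values = np.loadtxt(path, dtype=float, ndmin=1)
    else:
        img = nib.load(str(path))
        if not isinstance(img, nib.gifti.GiftiImage) or not img.darrays:
            raise FormatError(f"{path} is not a GIFTI scalar map")
        values = np.asarray(img.darrays[0].data, dtype=float).ravel()
    vmap = VertexScalarMap(values, kind)
    if mesh is not None and len(vmap) != mesh.n_vertices:
        raise ValidationError(
            f"map {path.name} has {len(vmap)} values for {mesh.n_vertices} vertices"
        )
    return vmap


def write_vertex_map(vmap: VertexScalarMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".txt", ".csv"):
        np.savetxt(path, vmap.values, fmt="%.9g")
        return
    da = nib.gifti.GiftiDataArray(
        vmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
    )
    nib.save(nib.gifti.GiftiImage(darrays=[da]), str(path))


def read_surface_and_maps(
    surf_path: str | Path,
    map_paths: Mapping[str, str | Path],
    role: str = "white",
) -> tuple[SurfaceMesh, dict[str, VertexScalarMap]]:
    """Read a mesh and bind named scalar maps to it (vertex counts must match).

    ``map_paths`` maps a kind from {eccentricity, polar_angle, snr} to a file.
    """
    mesh = read_surface(surf_path, role=role)
    maps: dict[str, VertexScalarMap] = {}
    for kind, p in map_paths.items():
        maps[kind] = read_vertex_map(p, kind, mesh=mesh)
    return mesh, maps


# ---------------------------------------------------------------------------
# voxel labels (NIfTI)
# ---------------------------------------------------------------------------

def read_label_volume(path: str | Path, name: str) -> CorticalLabel:
    """Read a binary NIfTI mask as a voxel label (affine: voxel -> RAS mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    voxels = np.argwhere(data > 0)
    return CorticalLabel(name=name, voxels=voxels, affine=img.affine)


def write_label_volume(label: CorticalLabel, shape: tuple[int, int, int], path: str | Path) -> None:
    if label.voxels is None:
        raise ValidationError(f"label {label.name} has no voxel carrier")
    data = np.zeros(shape, dtype=np.uint8)
    data[tuple(label.voxels.T)] = 1
    nib.save(nib.Nifti1Image(data, label.affine), str(path))


# ---------------------------------------------------------------------------
# reports (TSV)
# ---------------------------------------------------------------------------

def write_report(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> None:
    """Write per-streamline or group records as a TSV with a documented header.

    Rows keep streamline-index order when an ``index`` column is present.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty and df.columns.empty:
        raise ValidationError("refusing to write a report with no schema")
    if "index" in df.columns:
        df = df.sort_values("index", kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
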