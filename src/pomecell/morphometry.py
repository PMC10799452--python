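"""Morphometric quantification of parenchyma tissue volumes.

Sample-level parameters (porosity, cell/pore/stone-cell densities, specific
surface areas, anisotropy, Euler number of the pore network) and per-object
parameters (volume, surface area, length, width, equivalent spherical
diameter, sphericity, SSA, anisotropy) are computed from binary masks and
instance-label volumes with isotropic voxel size.  Distribution statistics
(mean, SD, mode, IQR, skewness, excess kurtosis) condense each per-object
parameter into the flat per-sample parameter vector used for downstream
multivariate statistics.

Numerical choices
-----------------
* Surface areas come from a marching-cubes boundary mesh whose vertices are
  relaxed by shrink-free Taubin smoothing (10 iterations).  Voxel-face
  counting overestimates a sphere's area by ~50% and raw marching cubes by
  ~9%; the smoothed mesh is within ~2% for a radius-20 ball and within ~5%
  of the closed form for a cube, the two shapes used as oracles.
* Sample-level anisotropy uses the mean-intercept-length (MIL) fabric
  tensor estimated over >=128 uniformly distributed directions; object-level
  anisotropy uses the voxel-coordinate covariance tensor.  Both report
  1 - lambda_min/lambda_max (0 = isotropic).
* Euler characteristic uses 26-connectivity for the foreground.
* Kurtosis is reported as excess kurtosis (Fisher g2).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import measure

__all__ = [
    "SampleMorphometrics",
    "DistributionStats",
    "surface_area",
    "specific_surface_area",
    "euler_number",
    "anisotropy_mil",
    "anisotropy_object",
    "sample_level",
    "object_level",
    "distribution_stats",
    "assemble_parameter_vector",
]

#: per-object parameters that enter the distribution statistics
OBJECT_PARAMS = (
    "volume",
    "surface_area",
    "length",
    "width",
    "esd",
    "sphericity",
    "ssa",
    "anisotropy",
)
STAT_NAMES = ("mean", "sd", "mode", "iqr", "skewness", "kurtosis")


@dataclass
class SampleMorphometrics:
    """Sample-level tissue parameters.

    Densities are per mm^3, volume fractions in percent, specific surface
    areas in 1/mm; anisotropy is dimensionless and the Euler number refers
    to the pore network.
    """

    cell_density: float
    pore_density: float
    stone_cell_density: float
    stone_cell_volume_fraction: float
    vascular_volume_fraction: float
    porosity: float
    matrix_ssa: float
    pore_ssa: float
    matrix_anisotropy: float
    pore_anisotropy: float
    euler_number: int

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


@dataclass
class DistributionStats:
    mean: float
    sd: float
    mode: float
    iqr: float
    skewness: float
    kurtosis: float


# ---------------------------------------------------------------------------
# surface geometry


def _boundary_mesh(mask: np.ndarray, voxel_size: float = 1.0, smooth_iters: int = 10):
    """Taubin-smoothed marching-cubes mesh of a binary mask's boundary.

    The mask is zero-padded by one voxel so surfaces at the array border are
    closed.
    """
    padded = np.pad(np.asarray(mask, bool), 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, 0.5)
    mesh = trimesh.Trimesh(vertices=verts * voxel_size, faces=faces, process=False)
    if smooth_iters > 0:
        trimesh.smoothing.filter_taubin(mesh, iterations=smooth_iters)
    return mesh


def surface_area(mask: np.ndarray, voxel_size: float = 1.0, smooth_iters: int = 10) -> float:
    """Boundary surface area of a binary mask (units of voxel_size squared)."""
    if not np.any(mask):
        raise ValueError("empty mask has no surface")
    return float(_boundary_mesh(mask, voxel_size, smooth_iters).area)


def specific_surface_area(mask: np.ndarray, voxel_size: float = 1.0) -> float:
    """Surface area divided by phase volume, units 1/voxel_size-unit."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    volume = mask.sum() * voxel_size**3
    return surface_area(mask, voxel_size) / volume


def euler_number(mask: np.ndarray) -> int:
    """3D Euler characteristic (26-connected foreground).

    chi = components - tunnels + cavities: a ball gives 1, a torus 0, a
    hollow shell 2; a well-connected pore network is strongly negative.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        return 0
    return int(measure.euler_number(mask, connectivity=3))


# ---------------------------------------------------------------------------
# anisotropy


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.stack([z, r * np.cos(phi), r * np.sin(phi)], axis=1)


def anisotropy_mil(mask: np.ndarray, n_dirs: int = 128) -> float:
    """Degree of anisotropy from the mean-intercept-length fabric tensor.

    MIL along direction u is 2 V / S(u) with S(u) the boundary area
    projected onto u (sum over mesh faces of |n_f . u| A_f).  The fabric
    tensor M is fitted by least squares to 1/MIL(u)^2 = u^T M u over
    ``n_dirs`` uniformly distributed directions; the principal MILs are
    1/sqrt(eigenvalues) and the returned degree is 1 - MIL_min/MIL_max.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 10:
        raise ValueError("too few voxels for a fabric tensor")
    mesh = _boundary_mesh(mask)
    normals = mesh.face_normals
    areas = mesh.area_faces
    volume = mask.sum()
    dirs = _fibonacci_sphere(max(n_dirs, 128))
    proj = np.abs(dirs @ normals.T) @ areas  # S(u)
    mil = 2.0 * volume / proj
    # least-squares fit of the symmetric tensor M in 1/MIL^2 = u'Mu
    u = dirs
    design = np.column_stack(
        [
            u[:, 0] ** 2,
            u[:, 1] ** 2,
            u[:, 2] ** 2,
            2 * u[:, 0] * u[:, 1],
            2 * u[:, 0] * u[:, 2],
            2 * u[:, 1] * u[:, 2],
        ]
    )
    coef, *_ = np.linalg.lstsq(design, 1.0 / mil**2, rcond=None)
    m = np.array(
        [
            [coef[0], coef[3], coef[4]],
            [coef[3], coef[1], coef[5]],
            [coef[4], coef[5], coef[2]],
        ]
    )
    eig = np.linalg.eigvalsh(m)
    eig = np.clip(eig, 1e-12, None)
    principal_mil = 1.0 / np.sqrt(eig)
    return float(1.0 - principal_mil.min() / principal_mil.max())


def anisotropy_object(coords: np.ndarray) -> float:
    """1 - lambda_min/lambda_max of the voxel-coordinate covariance tensor.

    ``coords`` is an (n, 3) array of voxel coordinates.  Raises for
    degenerate (coplanar or near-coplanar) objects.
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 10:
        raise ValueError("too few voxels for covariance anisotropy")
    cov = np.cov(coords.T)
    eig = np.linalg.eigvalsh(cov)
    if eig[-1] <= 0 or eig[0] / eig[-1] < 1e-8:
        raise ValueError("degenerate (coplanar) object")
    return float(1.0 - eig[0] / eig[-1])


# ---------------------------------------------------------------------------
# sample level


def sample_level(masks, pore_labels: np.ndarray, cell_labels: np.ndarray,
                 voxel_size: float) -> SampleMorphometrics:
    """Sample-level morphometric parameters of one tissue volume.

    Parameters
    ----------
    masks : TissueMasks-like
        Object with boolean ``cell_matrix``, ``pore``, ``stone`` and
        ``vascular`` attributes of identical shape.
    pore_labels, cell_labels : ndarray of int
        Instance labels of pores and cells (0 = background).
    voxel_size : float
        Isotropic voxel edge in micrometres.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    matrix = np.asarray(masks.cell_matrix, bool)
    pore = np.asarray(masks.pore, bool)
    stone = np.asarray(masks.stone, bool)
    vasc = np.asarray(masks.vascular, bool)
    n_total = matrix.size
    if not (matrix.any() or pore.any()):
        raise ValueError("empty sample")
    volume_mm3 = n_total * voxel_size**3 * 1e-9

    n_cells = int(np.count_nonzero(np.unique(cell_labels)))
    n_pores = int(np.count_nonzero(np.unique(pore_labels)))
    n_stone = int(ndi.label(stone, structure=np.ones((3, 3, 3)))[1]) if stone.any() else 0

    # SSA in 1/mm: area(um^2)/volume(um^3) * 1000
    matrix_ssa = specific_surface_area(matrix, voxel_size) * 1e3 if matrix.any() else 0.0
    pore_ssa = specific_surface_area(pore, voxel_size) * 1e3 if pore.any() else 0.0

    return SampleMorphometrics(
        cell_density=n_cells / volume_mm3,
        pore_density=n_pores / volume_mm3,
        stone_cell_density=n_stone / volume_mm3,
        stone_cell_volume_fraction=100.0 * stone.sum() / n_total,
        vascular_volume_fraction=100.0 * vasc.sum() / n_total,
        porosity=100.0 * pore.sum() / n_total,
        matrix_ssa=matrix_ssa,
        pore_ssa=pore_ssa,
        matrix_anisotropy=anisotropy_mil(matrix) if matrix.any() else 0.0,
        pore_anisotropy=anisotropy_mil(pore) if pore.sum() >= 10 else 0.0,
        euler_number=euler_number(pore),
    )


# ---------------------------------------------------------------------------
# object level


def object_level(labels: np.ndarray, voxel_size: float = 1.0) -> pd.DataFrame:
    """Per-object morphometric table for an instance-label volume.

    Columns: label, volume (um^3), surface_area (um^2), length, width,
    esd (um), sphericity, ssa (1/um), anisotropy, touches_border.  Length
    and width are the largest and smallest extents of the bounding box
    oriented along the object's principal axes.  Objects too small for a
    covariance tensor get NaN anisotropy.
    """
    labels = np.asarray(labels)
    if labels.max() < 1:
        raise ValueError("no labels present")
    slices = ndi.find_objects(labels)
    rows = []
    shape = labels.shape
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        crop = labels[sl] == lab
        n = int(crop.sum())
        volume = n * voxel_size**3
        try:
            area = surface_area(crop, voxel_size)
        except (ValueError, RuntimeError):
            area = np.nan
        esd = (6.0 * volume / np.pi) ** (1.0 / 3.0)
        sph = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area if area else np.nan
        coords = np.argwhere(crop).astype(float)
        centered = coords - coords.mean(axis=0)
        if n >= 10:
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            extents = np.ptp(centered @ vt.T, axis=0) + 1.0
            length, width = float(extents.max()) * voxel_size, float(extents.min()) * voxel_size
            try:
                aniso = anisotropy_object(coords)
            except ValueError:
                aniso = np.nan
        else:
            ext = np.ptp(coords, axis=0) + 1.0
            length, width = float(ext.max()) * voxel_size, float(ext.min()) * voxel_size
            aniso = np.nan
        touches = any(
            s.start == 0 or s.stop == dim for s, dim in zip(sl, shape)
        )
        rows.append(
            dict(
                label=lab,
                volume=volume,
                surface_area=area,
                length=length,
                width=width,
                esd=esd,
                sphericity=sph,
                ssa=area / volume if area else np.nan,
                anisotropy=aniso,
                touches_border=touches,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution statistics and the per-sample parameter vector


def distribution_stats(values) -> DistributionStats:
    """Mean, SD, mode, IQR, skewness and excess kurtosis of a sample.

    The mode is the midpoint of the densest histogram bin with
    Freedman-Diaconis bin widths (falling back to Sturges when the IQR
    vanishes); quantiles use linear interpolation; skewness is Fisher g1 and
    kurtosis excess g2.
    """
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need at least 4 values for distribution statistics")
    q1, q3 = np.percentile(v, [25, 75])
    try:
        hist, edges = np.histogram(v, bins="fd")
    except (ValueError, MemoryError):
        hist, edges = np.histogram(v, bins="sturges")
    if hist.size == 0 or not np.isfinite(edges).all():
        hist, edges = np.histogram(v, bins="sturges")
    k = int(np.argmax(hist))
    return DistributionStats(
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        mode=float(0.5 * (edges[k] + edges[k + 1])),
        iqr=float(q3 - q1),
        skewness=float(sps.skew(v, bias=True)),
        kurtosis=float(sps.kurtosis(v, fisher=True, bias=True)),
    )


def assemble_parameter_vector(
    sample: SampleMorphometrics,
    cell_table: pd.DataFrame | None,
    pore_table: pd.DataFrame | None,
) -> pd.Series:
    """Flat named parameter vector for one sample.

    Concatenates the sample-level parameters with, for every per-object
    parameter of cells and pores, its mean, SD, mode, IQR, skewness and
    excess kurtosis.  Border-touching objects are excluded from the
    statistics (their truncated shapes bias the size metrics).  The schema
    is fixed, so every sample in a batch yields a vector of identical
    length and naming.
    """
    out = {}
    for name, value in asdict(sample).items():
        out[name] = value
    for kind, table in (("cell", cell_table), ("pore", pore_table)):
        if table is None or len(table) == 0:
            raise ValueError(f"missing {kind} object table")
        interior = table.loc[~table["touches_border"]] if "touches_border" in table else table
        if len(interior) < 4:
            interior = table  # tiny volumes: keep all rather than fail
        for param in OBJECT_PARAMS:
            values = interior[param].to_numpy()
            try:
                stats = distribution_stats(values)
            except ValueError:
                # fewer than 4 finite values (e.g. anisotropy of tiny
                # objects): keep the schema, report NaN statistics
                stats = DistributionStats(*([np.nan] * 6))
            for stat in STAT_NAMES:
                out[f"{kind}_{param}_{stat}"] = getattr(stats, stat)
    series = pd.Series(out)
    assert series.index.is_unique
    return series
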