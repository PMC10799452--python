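"""Synthetic 3D parenchyma tissue phantoms.

Generates instance-labelled cell packings with controllable porosity,
cell density, stone-cell clusters and vascular strands, then renders them
as a registered pair of grayscale volumes emulating a conventional and a
contrast-enhanced micro-CT scan of fruit flesh:

* **apple-like** tissue: high porosity (~16-27%), few large pores formed by
  deleting whole cells (lysigenous pore formation), clustered cells;
* **pear-like** tissue: low porosity (~3-5%), many small connected pore
  channels along the edges where three or more cells meet (schizogenous
  pore formation), optionally with stone-cell clusters (brachysclereids)
  and vascular strands.

Cells are Voronoi regions of jittered-grid seed points, which reproduces
the polyhedral space-filling geometry of parenchyma.  The grayscale model
is deliberately simple (per-phase intensity levels plus additive Gaussian
noise): in a conventional scan the cell-to-cell interfaces carry *no*
intensity contrast — only cell-to-pore interfaces are visible — while the
contrast-enhanced rendering adds bright cell walls and contrast-agent
filled pores.  That is exactly the contrast relationship the downstream
segmentation stages depend on.

All randomness flows from ``PhantomConfig.seed`` through named generators;
identical configs give bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

__all__ = [
    "PhantomConfig",
    "TissueMasks",
    "Phantom",
    "apple_config",
    "pear_config",
    "generate_cell_labels",
    "carve_pores",
    "add_structures",
    "render",
    "generate_phantom",
]

# rendered intensity levels (8-bit grayscale)
LEVELS_CONVENTIONAL = {"pore": 30.0, "matrix": 150.0, "vascular": 170.0, "stone": 230.0}
LEVELS_CONTRAST = {"cell": 150.0, "wall": 240.0, "pore": 240.0, "vascular": 240.0, "stone": 230.0}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic tissue sample.

    Densities are per mm^3 of sample volume, the voxel size is in
    micrometres, and ``target_porosity`` is a volume fraction in [0, 1).
    ``anisotropy_stretch`` scales the Voronoi metric per axis (values > 1
    elongate cells along that axis).  ``pore_connectivity`` (pear style
    only) is the fraction of the cell-edge network opened into pore
    channels: 1.0 gives a fully connected network, smaller values leave
    isolated channel segments.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 24.0
    style: str = "apple"
    target_cell_density: float = 200.0
    target_porosity: float = 0.19
    anisotropy_stretch: tuple[float, float, float] = (1.0, 1.0, 1.0)
    stone_cell_density: float = 0.0
    stone_cluster_radius: float = 80.0
    vascular_strand_count: int = 0
    pore_connectivity: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.style not in ("apple", "pear"):
            raise ValueError(f"unknown style {self.style!r}")
        if not (0.0 <= self.target_porosity < 1.0):
            raise ValueError("target_porosity must be in [0, 1)")
        if min(self.shape) < 32:
            raise ValueError("shape entries must be >= 32")
        if self.target_cell_density < 0 or self.stone_cell_density < 0:
            raise ValueError("densities must be non-negative")
        if any(s < 1.0 for s in self.anisotropy_stretch):
            raise ValueError("anisotropy_stretch factors must be >= 1")

    @property
    def volume_mm3(self) -> float:
        return float(np.prod(self.shape)) * self.voxel_size**3 * 1e-9

    def replace(self, **kw) -> "PhantomConfig":
        return dataclasses.replace(self, **kw)


def apple_config(**kw) -> PhantomConfig:
    """Apple-like defaults: high porosity, large lysigenous pores."""
    base = dict(style="apple", target_porosity=0.19, target_cell_density=200.0,
                voxel_size=24.0)
    base.update(kw)
    return PhantomConfig(**base)


def pear_config(**kw) -> PhantomConfig:
    """Pear-like defaults: low porosity, dense small cells, stone clusters."""
    base = dict(style="pear", target_porosity=0.045, target_cell_density=650.0,
                voxel_size=16.0, stone_cell_density=2.0, stone_cluster_radius=80.0)
    base.update(kw)
    return PhantomConfig(**base)


@dataclass
class TissueMasks:
    """Mutually exclusive semantic masks of one sample."""

    cell_matrix: np.ndarray
    pore: np.ndarray
    stone: np.ndarray
    vascular: np.ndarray

    def copy(self) -> "TissueMasks":
        return TissueMasks(*(m.copy() for m in
                             (self.cell_matrix, self.pore, self.stone, self.vascular)))

    def validate(self) -> None:
        total = (self.cell_matrix.astype(int) + self.pore.astype(int)
                 + self.stone.astype(int) + self.vascular.astype(int))
        if total.max() > 1:
            raise ValueError("semantic masks overlap")


@dataclass
class Phantom:
    """A complete synthetic sample: labels, masks and both renderings."""

    cell_labels: np.ndarray
    masks: TissueMasks
    conventional: np.ndarray
    contrast_enhanced: np.ndarray
    config: PhantomConfig
    n_pore_components: int = 0
    #: pores as constructed: deleted cells (apple) / 26-connected components (pear)
    n_pores_constructed: int = 0


def _rng(config: PhantomConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed % (2**31), stage]))


def _seed_points(config: PhantomConfig, n: int) -> np.ndarray:
    """Jittered-grid seed points, exactly ``n`` of them, inside the volume."""
    rng = _rng(config, 1)
    shape = np.asarray(config.shape, float)
    cell_edge = (shape.prod() / n) ** (1.0 / 3.0)
    grid = np.maximum(1, np.round(shape / cell_edge).astype(int))
    while grid.prod() < n:
        grid[np.argmin(grid * cell_edge / shape)] += 1
    pitch = shape / grid
    idx = np.stack(np.meshgrid(*[np.arange(g) for g in grid], indexing="ij"), -1).reshape(-1, 3)
    centers = (idx + 0.5) * pitch
    jitter = rng.uniform(-0.45, 0.45, size=centers.shape) * pitch
    pts = centers + jitter
    order = rng.permutation(len(pts))[:n]
    return np.clip(pts[order], 0.5, shape - 0.5)


def generate_cell_labels(config: PhantomConfig, _density: float | None = None) -> np.ndarray:
    """Space-filling Voronoi cell labels 1..N from jittered-grid seeds.

    N = round(target_cell_density x physical volume in mm^3).  The
    ``anisotropy_stretch`` factors scale coordinates before tessellation so
    cells elongate along stretched axes.  Deterministic for a given config.
    """
    density = config.target_cell_density if _density is None else _density
    n = int(round(density * config.volume_mm3))
    if n < 2:
        raise ValueError(f"too few cells: density {density}/mm^3 in "
                         f"{config.volume_mm3:.4g} mm^3 yields {n} seeds")
    pts = _seed_points(config, n)
    stretch = np.asarray(config.anisotropy_stretch, float)
    tree = cKDTree(pts / stretch)
    coords = np.stack(np.meshgrid(*[np.arange(s) + 0.5 for s in config.shape],
                                  indexing="ij"), -1).reshape(-1, 3)
    _, nearest = tree.query(coords / stretch, workers=-1)
    return (nearest.astype(np.int32) + 1).reshape(config.shape)


def _wall_mask(labels: np.ndarray) -> np.ndarray:
    """One-voxel-thick walls: voxels with a 26-neighbour of greater label."""
    dil = ndi.grey_dilation(labels, size=(3, 3, 3))
    return dil != labels


def _face_map(labels: np.ndarray):
    """Inter-cell wall voxels and the id of the cell-pair face each belongs to.

    Walls are one voxel thick and one-sided: a voxel belongs to the wall
    when some 26-neighbour carries a greater label.  Its face id encodes
    the voxel's own label and the greatest neighbouring label, so the wall
    network partitions into the individual cell-to-cell contact faces.
    A one-voxel-thick channel still disconnects the two cells it separates
    under 26-connectivity.
    """
    dil = ndi.grey_dilation(labels, size=(3, 3, 3))
    wall = dil != labels
    face_id = labels.astype(np.int64) * (int(labels.max()) + 1) + dil
    return wall, np.where(wall, face_id, 0)


def carve_pores(labels: np.ndarray, config: PhantomConfig) -> TissueMasks:
    """Carve the intercellular pore space into a cell packing.

    apple style
        whole cells are deleted at random and adjacent deletions merge into
        large cavities (lysigenous pores).
    pear style
        the channels along cell edges (junctions of >= 3 cells) are opened
        into thin connected pores (schizogenous pores); the fraction of the
        edge network that is opened is ``config.pore_connectivity``.

    The achieved voxel porosity must fall within +-10% relative of
    ``target_porosity`` or a ValueError reports the achieved value.
    """
    shape = labels.shape
    n_total = labels.size
    target = config.target_porosity
    empty = np.zeros(shape, bool)
    if target == 0:
        return TissueMasks(cell_matrix=np.ones(shape, bool), pore=empty.copy(),
                           stone=empty.copy(), vascular=empty.copy())

    if config.style == "apple":
        # lysigenous carving: delete whole cells, preferring cells whose
        # neighbours are intact so pores stay mostly cell-sized and the
        # pore density tracks the deletion count (adjacent deletions still
        # merge when the porosity target demands them)
        rng = _rng(config, 2)
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        sizes = dict(zip(ids.tolist(), counts.tolist()))
        dil = ndi.grey_dilation(labels, size=(3, 3, 3))
        pair_mask = dil != labels
        neigh: dict[int, set] = {int(i): set() for i in ids}
        for a, b in set(zip(labels[pair_mask].tolist(), dil[pair_mask].tolist())):
            if a > 0 and b > 0:
                neigh[a].add(b)
                neigh[b].add(a)
        goal = target * n_total
        deleted: set[int] = set()
        removed = 0
        order = [int(i) for i in ids[rng.permutation(len(ids))]]
        for isolated_pass in (True, False):
            for i in order:
                if removed >= goal:
                    break
                if i in deleted:
                    continue
                if isolated_pass and neigh[i] & deleted:
                    continue
                if abs(removed + sizes[i] - goal) < abs(removed - goal):
                    deleted.add(i)
                    removed += sizes[i]
        lut = np.zeros(int(labels.max()) + 1, bool)
        lut[list(deleted)] = True
        pore = lut[labels]
    else:
        # schizogenous carving: open whole cell-contact faces into thin
        # channels until the porosity target is met.  pore_connectivity
        # steers how the opened faces are chosen: 1.0 grows one connected
        # complex of adjoining faces (well-connected network, many loops),
        # small values scatter isolated faces.
        wall, face_id = _face_map(labels)
        rng = _rng(config, 2)
        ids, inverse, counts = np.unique(face_id[wall], return_inverse=True,
                                         return_counts=True)
        n_faces = len(ids)
        if n_faces == 0:
            raise ValueError("no inter-cell faces available to carve pores")
        cell_a = ids // (int(labels.max()) + 1)
        cell_b = ids % (int(labels.max()) + 1)
        # faces sharing a cell are adjacent; grow vs. scatter per connectivity
        from collections import defaultdict
        by_cell = defaultdict(list)
        for f in range(n_faces):
            by_cell[int(cell_a[f])].append(f)
            by_cell[int(cell_b[f])].append(f)
        quota = int(round(target * n_total))
        opened = np.zeros(n_faces, bool)
        frontier: list[int] = []
        total = 0
        order = rng.permutation(n_faces)
        oi = 0
        while total < quota:
            grow = frontier and rng.random() < config.pore_connectivity
            if grow:
                f = frontier.pop(int(rng.integers(len(frontier))))
            else:
                while oi < n_faces and opened[order[oi]]:
                    oi += 1
                if oi >= n_faces:
                    break
                f = int(order[oi])
            if opened[f]:
                continue
            opened[f] = True
            total += int(counts[f])
            for c in (int(cell_a[f]), int(cell_b[f])):
                frontier.extend(g for g in by_cell[c] if not opened[g])
        open_vox = opened[inverse]
        pore = np.zeros(shape, bool)
        pore[wall] = open_vox

    achieved = pore.sum() / n_total
    if target > 0 and abs(achieved - target) > 0.10 * target:
        raise ValueError(
            f"porosity target {target:.3f} unreachable at this resolution; "
            f"achieved {achieved:.3f}")
    return TissueMasks(cell_matrix=~pore, pore=pore, stone=empty.copy(),
                       vascular=empty.copy())


def _warp_outward(arrays: list[np.ndarray], center: np.ndarray, radius: float,
                  influence: float, shape) -> None:
    """Push content radially outward around ``center`` (in place).

    Content originally at radius s is displayed at r where
    s = influence * (r - radius)/(influence - radius): a solid blob of
    ``radius`` is opened up and the surrounding cells are squeezed
    against their neighbours.
    """
    lo = np.maximum(np.floor(center - influence).astype(int), 0)
    hi = np.minimum(np.ceil(center + influence).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    pos = np.stack(grids, -1).astype(float) + 0.5
    rel = pos - center
    r = np.linalg.norm(rel, axis=-1)
    inside = (r < influence) & (r > 1e-9)
    src_r = influence * np.clip(r - radius, 0.0, None) / (influence - radius)
    scale = np.where(inside, src_r / np.maximum(r, 1e-9), 1.0)
    src = center + rel * scale[..., None] - 0.5
    src_idx = tuple(np.clip(np.round(src[..., i]).astype(int), 0, shape[i] - 1)
                    for i in range(3))
    region = tuple(slice(a, b) for a, b in zip(lo, hi))
    for arr in arrays:
        vals = arr[src_idx]
        block = arr[region]
        block[inside] = vals[inside]
        arr[region] = block


def add_structures(masks: TissueMasks, labels: np.ndarray,
                   config: PhantomConfig) -> tuple[TissueMasks, np.ndarray]:
    """Add stone-cell clusters and vascular strands to a phantom.

    Stone clusters are solid spherical blobs (count = round(density x
    volume)) that displace the surrounding cells through a local outward
    warp of the label map.  Vascular strands are smooth tubes along the
    z axis.  Both are recorded in their own masks; cell labels are cleared
    where structures sit.  Raises if the structures would swallow more than
    half of the pore space.
    """
    masks = masks.copy()
    labels = labels.copy()
    shape = np.asarray(labels.shape)
    rng = _rng(config, 3)
    pore_before = int(masks.pore.sum())

    n_stone = int(round(config.stone_cell_density * config.volume_mm3))
    if n_stone > 0:
        if config.style != "pear":
            raise ValueError("stone-cell clusters are a pear-style feature")
        radius = config.stone_cluster_radius / config.voxel_size
        influence = 2.2 * radius
        centers = []
        tries = 0
        while len(centers) < n_stone and tries < 1000:
            tries += 1
            c = rng.uniform(influence, shape - influence)
            if all(np.linalg.norm(c - o) > 2.2 * radius for o in centers):
                centers.append(c)
        if len(centers) < n_stone:
            raise ValueError("could not place requested stone clusters")
        for c in centers:
            _warp_outward([labels, masks.pore], c, radius, influence, tuple(shape))
            grids = np.meshgrid(*[np.arange(s) + 0.5 for s in shape], indexing="ij")
            r = np.sqrt(sum((g - ci) ** 2 for g, ci in zip(grids, c)))
            blob = r <= radius
            masks.stone |= blob
        masks.pore &= ~masks.stone
        labels[masks.stone] = 0

    if config.vascular_strand_count > 0:
        rv = max(2.0, 50.0 / config.voxel_size)
        nz = shape[0]
        yy, xx = np.meshgrid(np.arange(shape[1]) + 0.5, np.arange(shape[2]) + 0.5,
                             indexing="ij")
        for _ in range(config.vascular_strand_count):
            start = rng.uniform(2 * rv, shape[1:] - 2 * rv)
            steps = rng.normal(0, 0.6, size=(nz, 2))
            path = start + np.cumsum(steps, axis=0)
            path = ndi.gaussian_filter1d(path, sigma=4.0, axis=0)
            path = np.clip(path, rv + 1, shape[1:] - rv - 1)
            for z in range(nz):
                disk = (yy - path[z, 0]) ** 2 + (xx - path[z, 1]) ** 2 <= rv**2
                masks.vascular[z] |= disk
        masks.vascular &= ~masks.stone
        masks.pore &= ~masks.vascular
        labels[masks.vascular] = 0

    if pore_before > 0:
        lost = pore_before - int(masks.pore.sum())
        if lost > 0.5 * pore_before:
            raise ValueError("structures overlap more than 50% of the pore space")
    masks.cell_matrix = ~(masks.pore | masks.stone | masks.vascular)
    return masks, labels


def render(masks: TissueMasks, labels: np.ndarray,
           config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render the conventional and contrast-enhanced grayscale volumes.

    ``labels`` are the wall-free cell labels: wall voxels are the part of
    the cell matrix carrying no label.  Conventional rendering shows no
    contrast at cell-to-cell interfaces (walls get the matrix intensity);
    the contrast-enhanced rendering shows bright walls and bright
    contrast-agent filled pores.  Additive Gaussian noise with
    ``config.noise_sd`` is applied to both, and intensities are clipped to
    [0, 255].
    """
    wall = masks.cell_matrix & (labels == 0)
    conv = np.full(labels.shape, LEVELS_CONVENTIONAL["matrix"], np.float32)
    conv[masks.pore] = LEVELS_CONVENTIONAL["pore"]
    conv[masks.vascular] = LEVELS_CONVENTIONAL["vascular"]
    conv[masks.stone] = LEVELS_CONVENTIONAL["stone"]

    ce = np.full(labels.shape, LEVELS_CONTRAST["cell"], np.float32)
    ce[wall] = LEVELS_CONTRAST["wall"]
    ce[masks.pore] = LEVELS_CONTRAST["pore"]
    ce[masks.vascular] = LEVELS_CONTRAST["vascular"]
    ce[masks.stone] = LEVELS_CONTRAST["stone"]

    if config.noise_sd > 0:
        rng = _rng(config, 4)
        conv = conv + rng.normal(0, config.noise_sd, conv.shape).astype(np.float32)
        ce = ce + rng.normal(0, config.noise_sd, ce.shape).astype(np.float32)
    return np.clip(conv, 0, 255), np.clip(ce, 0, 255)


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate a complete phantom from a config.

    For apple-style tissue the seed count is inflated by
    1/(1 - target_porosity) before whole-cell deletion so that the number
    of *surviving* cells matches the configured cell density.
    """
    density = config.target_cell_density
    if config.style == "apple" and config.target_porosity > 0:
        density = density / (1.0 - config.target_porosity)
    full_labels = generate_cell_labels(config, _density=density)
    masks = carve_pores(full_labels, config)
    if config.style == "apple":
        n_constructed = int(np.unique(full_labels[masks.pore]).size)
    else:
        n_constructed = int(ndi.label(masks.pore, structure=np.ones((3, 3, 3)))[1])
    masks, full_labels = add_structures(masks, full_labels, config)
    full_labels[~masks.cell_matrix] = 0

    wall = _wall_mask(full_labels) & masks.cell_matrix
    gt = full_labels.copy()
    gt[wall] = 0
    # consecutive labels 1..N over surviving cells
    ids = np.unique(gt)
    ids = ids[ids > 0]
    remap = np.zeros(int(full_labels.max()) + 1, np.int32)
    remap[ids] = np.arange(1, len(ids) + 1, dtype=np.int32)
    gt = remap[gt]

    conv, ce = render(masks, gt, config)
    masks.validate()
    n_pores = int(ndi.label(masks.pore, structure=np.ones((3, 3, 3)))[1])
    return Phantom(cell_labels=gt, masks=masks, conventional=conv,
                   contrast_enhanced=ce, config=config, n_pore_components=n_pores,
                   n_pores_constructed=n_constructed)
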