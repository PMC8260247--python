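"""Region geometry on a synthetic voxel grid.

Analyses operate on an isotropic 3-D grid with unit voxel spacing.  A
:class:`RegionLayout` holds named spherical regions (targets, whose voxels
are candidates for selection, and seeds, which supply the distal
connectivity criterion), each tagged with a stimulus category, plus a
gray-matter mask restricting which voxels are eligible for analysis.
Voxels outside the gray mask stand in for white matter / CSF and feed the
global-signal nuisance regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TARGET = "target"
SEED = "seed"

#: Minimum voxel count demanded of every target region.
MIN_TARGET_VOXELS = 300


@dataclass(frozen=True)
class RegionSpec:
    """Sphere specification: center (voxel coords), radius (voxels)."""

    name: str
    center: tuple[int, int, int]
    radius: float
    role: str  # "target" | "seed"
    category: str


@dataclass
class RegionLayout:
    """Named voxel regions plus a gray-matter mask on a common grid.

    ``regions`` maps region name to a sorted 1-D array of flat voxel
    indices (C order on ``grid_dims``).  ``gray_mask`` is a boolean grid
    of analysis-eligible voxels.
    """

    grid_dims: tuple[int, int, int]
    regions: dict[str, np.ndarray]
    roles: dict[str, str]
    categories: dict[str, str]
    gray_mask: np.ndarray
    specs: list[RegionSpec] = field(default_factory=list)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_dims))

    def region_coords(self, name: str) -> np.ndarray:
        return np.column_stack(np.unravel_index(self.regions[name], self.grid_dims))

    def target_regions(self) -> list[str]:
        return [r for r in self.regions if self.roles[r] == TARGET]

    def seed_regions_for(self, target: str) -> list[str]:
        """All other same-category regions: the distal seeds of ``target``.

        Mirrors seeding a target region from every other region sharing
        its category preference (the sibling target region plus any
        dedicated seed regions).
        """
        cat = self.categories[target]
        return [r for r in self.regions if r != target and self.categories[r] == cat]

    def gray_indices(self) -> np.ndarray:
        return np.flatnonzero(self.gray_mask.ravel())

    def nongray_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.gray_mask.ravel())


def sphere_indices(
    grid_dims: tuple[int, int, int], center: tuple[int, int, int], radius: float
) -> np.ndarray:
    """Flat indices of lattice points within Euclidean ``radius`` of ``center``."""
    cx, cy, cz = center
    r = int(np.floor(radius))
    xs = np.arange(max(0, cx - r), min(grid_dims[0], cx + r + 1))
    ys = np.arange(max(0, cy - r), min(grid_dims[1], cy + r + 1))
    zs = np.arange(max(0, cz - r), min(grid_dims[2], cz + r + 1))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    keep = d2 <= radius**2
    flat = np.ravel_multi_index((gx[keep], gy[keep], gz[keep]), grid_dims)
    return np.sort(flat)


def make_layout(
    grid_dims: tuple[int, int, int],
    region_specs: list[RegionSpec],
    gray_border: int = 1,
) -> RegionLayout:
    """Build a :class:`RegionLayout` from spherical region specs.

    The gray mask is the grid interior (a border shell of ``gray_border``
    voxels is non-gray and supplies the global-signal proxy).

    Raises
    ------
    ValueError
        If a region leaves the grid, a target region resolves to
        ``MIN_TARGET_VOXELS`` or fewer voxels, or two same-category
        regions overlap (selection must never draw a voxel that also
        serves as its own seed).
    """
    grid_dims = tuple(int(d) for d in grid_dims)
    regions: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}
    categories: dict[str, str] = {}
    for spec in region_specs:
        if spec.name in regions:
            raise ValueError(f"duplicate region name {spec.name!r}")
        if spec.role not in (TARGET, SEED):
            raise ValueError(f"region {spec.name!r}: unknown role {spec.role!r}")
        lo = np.array(spec.center) - spec.radius
        hi = np.array(spec.center) + spec.radius
        if (lo < 0).any() or (hi > np.array(grid_dims) - 1).any():
            raise ValueError(f"region {spec.name!r} extends outside the grid")
        idx = sphere_indices(grid_dims, spec.center, spec.radius)
        if spec.role == TARGET and idx.size <= MIN_TARGET_VOXELS:
            raise ValueError(
                f"target region {spec.name!r} has {idx.size} voxels; "
                f"more than {MIN_TARGET_VOXELS} required"
            )
        regions[spec.name] = idx
        roles[spec.name] = spec.role
        categories[spec.name] = spec.category

    names = list(regions)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if categories[a] == categories[b]:
                if np.intersect1d(regions[a], regions[b], assume_unique=True).size:
                    raise ValueError(
                        f"same-category regions {a!r} and {b!r} overlap"
                    )

    gray = np.zeros(grid_dims, dtype=bool)
    b = gray_border
    gray[b : grid_dims[0] - b, b : grid_dims[1] - b, b : grid_dims[2] - b] = True
    return RegionLayout(
        grid_dims=grid_dims,
        regions=regions,
        roles=roles,
        categories=categories,
        gray_mask=gray,
        specs=list(region_specs),
    )


def six_region_layout() -> RegionLayout:
    """Three-category layout mirroring the six-target-region study geometry.

    Two target spheres (radius 5, 515 voxels) per category — standing in
    for the tool- (MFus/PMTG-like), face- (FFA/OFA-like) and
    place-preferring (PPA/OPA-like) regions — plus one dedicated distal
    seed sphere per category.  Each target is seeded from every other
    same-category region.
    """
    dims = (24, 24, 24)
    specs = [
        RegionSpec("tool_A", (6, 6, 6), 5.0, TARGET, "tools"),
        RegionSpec("tool_B", (17, 6, 6), 5.0, TARGET, "tools"),
        RegionSpec("face_A", (6, 17, 6), 5.0, TARGET, "faces"),
        RegionSpec("face_B", (17, 17, 6), 5.0, TARGET, "faces"),
        RegionSpec("place_A", (6, 6, 17), 5.0, TARGET, "places"),
        RegionSpec("place_B", (17, 6, 17), 5.0, TARGET, "places"),
        RegionSpec("tool_seed", (6, 17, 17), 3.0, SEED, "tools"),
        RegionSpec("face_seed", (17, 17, 17), 3.0, SEED, "faces"),
        RegionSpec("place_seed", (12, 12, 12), 3.0, SEED, "places"),
    ]
    return make_layout(dims, specs)


def two_region_layout(radius: float = 5.0) -> RegionLayout:
    """Reduced single-category layout: two targets plus one distal seed.

    Used for calibration studies where the full six-region geometry is
    unnecessary; supports the two decoding comparisons of one category.
    """
    dims = (36, 14, 14)
    specs = [
        RegionSpec("tool_A", (6, 7, 7), radius, TARGET, "tools"),
        RegionSpec("tool_B", (17, 7, 7), radius, TARGET, "tools"),
        RegionSpec("tool_seed", (28, 7, 7), 3.0, SEED, "tools"),
    ]
    return make_layout(dims, specs)


def compact_two_region_layout() -> RegionLayout:
    """Minimal single-category layout (radius-4.5 targets, 389 voxels).

    The smallest geometry satisfying the >300-voxel target invariant;
    used for replicate-heavy calibration studies (e.g. type-I error
    rates over many null cohorts).
    """
    dims = (28, 12, 12)
    specs = [
        RegionSpec("tool_A", (5, 5, 5), 4.5, TARGET, "tools"),
        RegionSpec("tool_B", (15, 5, 5), 4.5, TARGET, "tools"),
        RegionSpec("tool_seed", (23, 5, 5), 3.0, SEED, "tools"),
    ]
    return make_layout(dims, specs)


def compact_searchlight_layout() -> RegionLayout:
    """Minimal single-target layout for searchlight calibration studies."""
    dims = (16, 13, 13)
    specs = [RegionSpec("tool_A", (6, 6, 6), 5.0, TARGET, "tools")]
    return make_layout(dims, specs)


def searchlight_layout() -> RegionLayout:
    """Small single-target layout for whole-grid searchlight studies.

    Sized so that part of the gray matter lies beyond the reach of any
    searchlight overlapping the coupled seed region, leaving genuinely
    "bad seed" territory.
    """
    dims = (24, 14, 14)
    specs = [
        RegionSpec("tool_A", (6, 7, 7), 5.0, TARGET, "tools"),
        RegionSpec("tool_seed", (17, 7, 7), 3.0, SEED, "tools"),
    ]
    return make_layout(dims, specs)
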