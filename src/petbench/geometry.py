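"""Detector-ring geometry of the modelled scanner.

The scanner is a cylindrical ring of ``n_sectors`` sectors. Each sector
holds ``n_modules_axial`` modules stacked axially; each module holds
``n_blocks_per_module`` blocks stacked transaxially; each block carries a
``block_crystals_transaxial x block_crystals_axial`` crystal array.

With the defaults (34 sectors, 4 modules, 4 blocks, 4 x 9 crystals of
5.3 mm axial x 3.95 mm transaxial x 25 mm depth) this gives 19 584
crystals in 36 rings of 544 crystals each, a ~19 cm axial FOV and a
~70 cm transaxial FOV once the minimum-sector-difference coincidence
acceptance (4 sectors) is applied.

Indexing convention (0-based everywhere)::

    flat_id = ((sector*n_modules + module)*n_blocks + block)*cpb
              + crystal_a*block_crystals_transaxial + crystal_t
    ring            = module*block_crystals_axial + crystal_a
    transaxial_pos  = sector*crystals_per_sector_t
                      + block*block_crystals_transaxial + crystal_t

where ``cpb`` is the number of crystals per block.  The 9-crystal block
axis is taken axial and the 4-crystal axis transaxial (4 blocks stacked
transaxially per module): this is the only assignment consistent with a
~20 cm axial FOV, 544 crystals per ring and 272 sinogram projections.

``ring_radius`` is the radius of the crystal *front faces*; crystal
centres sit on a cylinder of radius ``ring_radius + crystal_depth/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

__all__ = [
    "ScannerConfig",
    "CrystalIndex",
    "ScannerGeometry",
    "build_scanner",
    "crystal_lookup",
    "lor_accepted",
    "default_scanner_config",
]

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class ScannerConfig:
    """Scanner hierarchy counts, crystal dimensions (mm) and acceptance."""

    n_sectors: int = 34
    n_modules_axial: int = 4
    n_blocks_per_module: int = 4
    block_crystals_transaxial: int = 4
    block_crystals_axial: int = 9
    crystal_axial_mm: float = 5.3
    crystal_transaxial_mm: float = 3.95
    crystal_depth_mm: float = 25.0
    ring_radius_mm: float = 372.0
    crystal_gap_mm: float = 0.0
    block_gap_mm: float = 0.0
    module_gap_mm: float = 0.0
    min_sector_difference: int = 4
    lead_shielding: bool = False
    plastic_cover: bool = False

    def __post_init__(self) -> None:
        counts = {
            "n_sectors": self.n_sectors,
            "n_modules_axial": self.n_modules_axial,
            "n_blocks_per_module": self.n_blocks_per_module,
            "block_crystals_transaxial": self.block_crystals_transaxial,
            "block_crystals_axial": self.block_crystals_axial,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        lengths = {
            "crystal_axial_mm": self.crystal_axial_mm,
            "crystal_transaxial_mm": self.crystal_transaxial_mm,
            "crystal_depth_mm": self.crystal_depth_mm,
            "ring_radius_mm": self.ring_radius_mm,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value!r}")
        for name in ("crystal_gap_mm", "block_gap_mm", "module_gap_mm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.min_sector_difference < 0:
            raise ConfigurationError("min_sector_difference must be >= 0")
        if not self.min_sector_difference < self.n_sectors / 2:
            raise ConfigurationError(
                f"min_sector_difference ({self.min_sector_difference}) must be "
                f"< n_sectors/2 ({self.n_sectors / 2}): the ring cannot close"
            )
        # the transaxial crystal arc must fit within the sector's angular slot
        if self.sector_arc_mm > self.sector_pitch_rad * self.ring_radius_mm + 1e-9:
            raise ConfigurationError(
                "transaxial crystal arc exceeds the sector angular pitch; "
                "increase ring_radius_mm or reduce crystal sizes/gaps"
            )

    # -- derived counts -------------------------------------------------
    @property
    def crystals_per_block(self) -> int:
        return self.block_crystals_transaxial * self.block_crystals_axial

    @property
    def crystals_per_sector_t(self) -> int:
        """Transaxial crystals per sector (blocks are stacked transaxially)."""
        return self.n_blocks_per_module * self.block_crystals_transaxial

    @property
    def crystals_per_ring(self) -> int:
        return self.n_sectors * self.crystals_per_sector_t

    @property
    def n_rings(self) -> int:
        return self.n_modules_axial * self.block_crystals_axial

    @property
    def n_crystals(self) -> int:
        return self.crystals_per_ring * self.n_rings

    # -- derived transaxial layout --------------------------------------
    @property
    def sector_pitch_rad(self) -> float:
        return 2.0 * np.pi / self.n_sectors

    @property
    def transaxial_pitch_mm(self) -> float:
        """Arc length allotted to one crystal at the front-face radius."""
        return self.crystal_transaxial_mm + self.crystal_gap_mm

    @property
    def sector_arc_mm(self) -> float:
        """Arc spanned by the crystals of one sector (incl. block gaps)."""
        nb = self.n_blocks_per_module
        return (
            nb * self.block_crystals_transaxial * self.transaxial_pitch_mm
            + (nb - 1) * self.block_gap_mm
        )

    # -- derived axial layout -------------------------------------------
    @property
    def axial_pitch_mm(self) -> float:
        return self.crystal_axial_mm + self.crystal_gap_mm

    @property
    def axial_extent_mm(self) -> float:
        return (
            self.n_rings * self.axial_pitch_mm
            + (self.n_modules_axial - 1) * self.module_gap_mm
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScannerConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def default_scanner_config() -> ScannerConfig:
    """The bundled default scanner configuration."""
    return ScannerConfig.from_yaml(_DATA_DIR / "scanner_default.yaml")


@dataclass(frozen=True)
class CrystalIndex:
    """Full index tuple of one crystal."""

    sector: int
    module: int
    block: int
    crystal_t: int
    crystal_a: int
    flat_id: int
    ring: int
    transaxial_pos: int


class ScannerGeometry:
    """Crystal positions and index arithmetic for a :class:`ScannerConfig`.

    Attributes
    ----------
    crystal_centres : (n_crystals, 3) array, mm
        Centres on the cylinder of radius ``ring_radius + depth/2``.
    crystal_normals : (n_crystals, 3) array
        Inward-pointing unit face normals.
    """

    def __init__(self, config: ScannerConfig):
        self.config = config
        c = config
        flat = np.arange(c.n_crystals)
        self.sector, rem = np.divmod(flat, c.n_modules_axial * c.n_blocks_per_module * c.crystals_per_block)
        module_rem, rem = np.divmod(rem, c.n_blocks_per_module * c.crystals_per_block)
        self.module = module_rem
        self.block, rem = np.divmod(rem, c.crystals_per_block)
        self.crystal_a, self.crystal_t = np.divmod(rem, c.block_crystals_transaxial)
        self.ring = self.module * c.block_crystals_axial + self.crystal_a
        self.transaxial_pos = (
            self.sector * c.crystals_per_sector_t
            + self.block * c.block_crystals_transaxial
            + self.crystal_t
        )
        # inverse map (ring, transaxial_pos) -> flat_id
        self._flat_from_rp = np.empty((c.n_rings, c.crystals_per_ring), dtype=np.int64)
        self._flat_from_rp[self.ring, self.transaxial_pos] = flat

        self.phi = self._phi_of_tpos(self.transaxial_pos.astype(float))
        self.z = self._z_of_ring(self.ring.astype(float))
        r_centre = c.ring_radius_mm + c.crystal_depth_mm / 2.0
        self.crystal_centres = np.column_stack(
            [r_centre * np.cos(self.phi), r_centre * np.sin(self.phi), self.z]
        )
        self.crystal_normals = np.column_stack(
            [-np.cos(self.phi), -np.sin(self.phi), np.zeros_like(self.phi)]
        )
        self.axial_extent_mm = c.axial_extent_mm
        # widest accepted LOR: between crystals of sectors exactly
        # min_sector_difference apart
        self.transaxial_fov_mm = (
            2.0
            * c.ring_radius_mm
            * np.cos(c.min_sector_difference * c.sector_pitch_rad / 2.0)
        )

    # -- layout helpers --------------------------------------------------
    def _phi_of_tpos(self, tpos: np.ndarray) -> np.ndarray:
        """Azimuth (rad) of a (possibly fractional) transaxial position."""
        c = self.config
        n_t = c.crystals_per_sector_t
        sector = np.floor_divide(tpos, n_t)
        k = tpos - sector * n_t
        block = np.floor_divide(k, c.block_crystals_transaxial)
        arc = (
            block * (c.block_crystals_transaxial * c.transaxial_pitch_mm + c.block_gap_mm)
            + (k - block * c.block_crystals_transaxial + 0.5) * c.transaxial_pitch_mm
        )
        return sector * c.sector_pitch_rad + (arc - c.sector_arc_mm / 2.0) / c.ring_radius_mm

    def _z_of_ring(self, ring: np.ndarray) -> np.ndarray:
        c = self.config
        module = np.floor_divide(ring, c.block_crystals_axial)
        z = (ring + 0.5) * c.axial_pitch_mm + module * c.module_gap_mm
        return z - c.axial_extent_mm / 2.0

    # -- index arithmetic -------------------------------------------------
    def _check_flat(self, flat_id) -> None:
        flat = np.asarray(flat_id)
        if np.any(flat < 0) or np.any(flat >= self.config.n_crystals):
            raise IndexError(
                f"flat_id out of range [0, {self.config.n_crystals}): {flat_id}"
            )

    def flat_to_index(self, flat_id: int) -> CrystalIndex:
        self._check_flat(flat_id)
        i = int(flat_id)
        return CrystalIndex(
            sector=int(self.sector[i]),
            module=int(self.module[i]),
            block=int(self.block[i]),
            crystal_t=int(self.crystal_t[i]),
            crystal_a=int(self.crystal_a[i]),
            flat_id=i,
            ring=int(self.ring[i]),
            transaxial_pos=int(self.transaxial_pos[i]),
        )

    def index_to_flat(self, sector: int, module: int, block: int, crystal_t: int, crystal_a: int) -> int:
        c = self.config
        return (
            (sector * c.n_modules_axial + module) * c.n_blocks_per_module + block
        ) * c.crystals_per_block + crystal_a * c.block_crystals_transaxial + crystal_t

    def flat_from_ring_pos(self, ring, transaxial_pos):
        return self._flat_from_rp[ring, transaxial_pos]

    # -- detection mapping (used by the transport stage) ------------------
    def crystal_at(self, phi: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Map front-face cylinder coordinates to flat crystal ids.

        Returns -1 where (phi, z) falls in a gap or outside the axial
        extent.  Vectorised.
        """
        c = self.config
        phi = np.mod(np.asarray(phi, dtype=float), 2 * np.pi)
        z = np.asarray(z, dtype=float)
        out = np.full(phi.shape, -1, dtype=np.int64)

        sector = np.round(phi / c.sector_pitch_rad).astype(np.int64) % c.n_sectors
        dphi = phi - sector * c.sector_pitch_rad
        dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
        u = dphi * c.ring_radius_mm + c.sector_arc_mm / 2.0  # arc within sector
        block_pitch = c.block_crystals_transaxial * c.transaxial_pitch_mm + c.block_gap_mm
        block = np.floor_divide(u, block_pitch).astype(np.int64)
        in_sector = (u >= 0) & (block >= 0) & (block < c.n_blocks_per_module)
        v = u - block * block_pitch
        ct = np.floor_divide(v, c.transaxial_pitch_mm).astype(np.int64)
        in_block = (v >= 0) & (ct < c.block_crystals_transaxial)
        # crystal occupies the centre crystal_transaxial_mm of its pitch slot
        w = v - ct * c.transaxial_pitch_mm
        in_crystal_t = np.abs(w - c.transaxial_pitch_mm / 2.0) <= c.crystal_transaxial_mm / 2.0

        zz = z + c.axial_extent_mm / 2.0
        module_pitch = c.block_crystals_axial * c.axial_pitch_mm + c.module_gap_mm
        module = np.floor_divide(zz, module_pitch).astype(np.int64)
        in_axial = (zz >= 0) & (module >= 0) & (module < c.n_modules_axial)
        za = zz - module * module_pitch
        ca = np.floor_divide(za, c.axial_pitch_mm).astype(np.int64)
        in_module = (za >= 0) & (ca < c.block_crystals_axial)
        wa = za - ca * c.axial_pitch_mm
        in_crystal_a = np.abs(wa - c.axial_pitch_mm / 2.0) <= c.crystal_axial_mm / 2.0

        ok = in_sector & in_block & in_crystal_t & in_axial & in_module & in_crystal_a
        if np.any(ok):
            flat = (
                (sector[ok] * c.n_modules_axial + module[ok]) * c.n_blocks_per_module
                + block[ok]
            ) * c.crystals_per_block + ca[ok] * c.block_crystals_transaxial + ct[ok]
            out[ok] = flat
        return out

    # -- LOR acceptance ----------------------------------------------------
    def sector_distance(self, id_a, id_b) -> np.ndarray:
        sa = self.sector[np.asarray(id_a)]
        sb = self.sector[np.asarray(id_b)]
        d = np.abs(sa - sb)
        return np.minimum(d, self.config.n_sectors - d)

    def lor_accepted(self, id_a, id_b) -> np.ndarray | bool:
        """True where the crystal pair satisfies the sector-difference rule."""
        a = np.asarray(id_a)
        b = np.asarray(id_b)
        self._check_flat(a)
        self._check_flat(b)
        ok = (a != b) & (self.sector_distance(a, b) >= self.config.min_sector_difference)
        if ok.ndim == 0:
            return bool(ok)
        return ok


def build_scanner(config: ScannerConfig | None = None) -> ScannerGeometry:
    """Build the crystal map for *config* (default: bundled scanner)."""
    if config is None:
        config = default_scanner_config()
    return ScannerGeometry(config)


def crystal_lookup(geometry: ScannerGeometry, flat_id: int) -> tuple[CrystalIndex, np.ndarray]:
    """Full index tuple and 3D centre (mm) of one crystal."""
    idx = geometry.flat_to_index(flat_id)
    return idx, geometry.crystal_centres[idx.flat_id]


def lor_accepted(geometry: ScannerGeometry, id_a, id_b):
    return geometry.lor_accepted(id_a, id_b)
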