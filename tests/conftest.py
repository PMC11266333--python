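import numpy as np
import pytest

from petbench.geometry import ScannerConfig, ScannerGeometry, build_scanner


@pytest.fixture(scope="session")
def geometry() -> ScannerGeometry:
    """The bundled full-size scanner."""
    return build_scanner()


@pytest.fixture(scope="session")
def small_geometry() -> ScannerGeometry:
    """A reduced ring (192 crystals, 6 rings of 32) for exhaustive tests."""
    cfg = ScannerConfig(
        n_sectors=8, n_modules_axial=2, n_blocks_per_module=2,
        block_crystals_transaxial=2, block_crystals_axial=3,
        crystal_axial_mm=5.3, crystal_transaxial_mm=3.95, crystal_depth_mm=25.0,
        ring_radius_mm=120.0, min_sector_difference=2,
    )
    return build_scanner(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
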