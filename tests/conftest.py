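import numpy as np
import pytest

from aggrequant import PixelCalibration, SegmentationParams


@pytest.fixture
def calib_um():
    """1.5 µm/px, 0.5 h frame interval — the live-imaging default."""
    return PixelCalibration(1.5, 0.5, "um", "h")


@pytest.fixture
def seg_params():
    return SegmentationParams()


@pytest.fixture
def disc_roi():
    """Factory for a single disc-footprint label image."""
    def _make(radius_nm: float, pixel_nm: float) -> np.ndarray:
        r_px = radius_nm / pixel_nm
        n = 2 * int(np.ceil(r_px)) + 5
        yy, xx = np.mgrid[:n, :n]
        c = n // 2
        return (((yy - c) ** 2 + (xx - c) ** 2) <= r_px ** 2).astype(np.uint16)
    return _make


@pytest.fixture
def blob_image():
    """Factory for frames with Gaussian blobs on an optional ramp."""
    def _make(shape, centers, amplitude=1000.0, sigma_px=2.0, ramp=0.0):
        yy, xx = np.mgrid[:shape[0], :shape[1]]
        img = ramp * xx / max(shape[1] - 1, 1)
        for cy, cx in centers:
            img = img + amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px ** 2))
        return img
    return _make
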