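import numpy as np
import pytest

from cd31quant.imageio import ImageMeta, LabelMap, TissueClass
from cd31quant.morphometry import VesselInstance
from cd31quant.synthetic import SynthConfig


def make_instance(mask: np.ndarray, offset=(0, 0)) -> VesselInstance:
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    flat = (rr + offset[0]) * 10_000 + (cc + offset[1])
    return VesselInstance(mask=mask, offset_rc=tuple(offset), area_px=int(mask.sum()),
                          first_pixel_flat=int(flat.min()))


def disk_mask(shape, center, radius):
    yy, xx = np.indices(shape)
    return ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) <= radius**2


def labelmap_of(codes: np.ndarray, pixel_size_um: float = 1.0) -> LabelMap:
    codes = np.asarray(codes, dtype=np.uint8)
    meta = ImageMeta(pixel_size_um, width_px=codes.shape[1], height_px=codes.shape[0])
    return LabelMap(codes, meta)


def stroma_canvas(shape) -> np.ndarray:
    return np.full(shape, int(TissueClass.STROMA), dtype=np.uint8)


@pytest.fixture(scope="session")
def toy_synth_config() -> SynthConfig:
    """Scaled-down scene used for fast pipeline tests: 96 px canvas, three
    small vessels plus one adipose vacuole, one lymphocyte cluster and one
    leukocyte on stroma."""
    return SynthConfig(
        canvas_px=96,
        n_vessels=3,
        n_tumour_nests=0,
        n_adipose=1,
        n_lymphocyte_clusters=1,
        n_leukocytes=1,
        vessel_outer_radius_px=(5.0, 9.0),
        vessel_wall_px=(2.0, 3.5),
        vessel_elongation=(1.0, 2.0),
        adipose_radius_px=(5.0, 8.0),
        lymph_radius_px=(5.0, 8.0),
        leukocyte_radius_px=(1.5, 2.5),
    )
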