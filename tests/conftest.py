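import numpy as np
import pytest
from skimage import draw

from micromorph.mask_io import CellRecord


def disk_mask(radius: int, pad: int = 10) -> np.ndarray:
    side = 2 * (radius + pad)
    m = np.zeros((side, side), dtype=bool)
    rr, cc = draw.disk((side // 2, side // 2), radius)
    m[rr, cc] = True
    return m


def as_cell(mask: np.ndarray, cell_id: str = "cell",
            image_shape=None) -> CellRecord:
    """Wrap a full-canvas mask as a CellRecord cropped to its bbox."""
    mask = np.asarray(mask, dtype=bool)
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    crop = mask[bbox[0]:bbox[2], bbox[1]:bbox[3]]
    coords = np.argwhere(mask)
    return CellRecord(
        cell_id=cell_id,
        mask=crop,
        bbox=bbox,
        centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
        image_id="img",
        group="G0",
        image_shape=image_shape or mask.shape,
    )


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic mixed-archetype scene shared across tests."""
    from micromorph.synthgen import SceneSpec, make_scene

    spec = SceneSpec(
        n_cells={"amoeboid": 3, "reactive": 3, "ramified": 3},
        canvas=(900, 900),
        seed=42,
        image_id="scene42",
        group="G0",
        lateral_mm=0.72,
    )
    return make_scene(spec)
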