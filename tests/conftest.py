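import numpy as np
import pytest

from seedscan.features import assemble_table
from seedscan.morphometry import MeasurementRecord
from seedscan.pipeline import measure_image
from seedscan.scanio import ScanImage
from seedscan.segmentation import label_particles
from seedscan.synthgen import SimulationConfig, generate_dataset


def mask_to_image(mask: np.ndarray, dpi: float = 600.0, tag: str = "") -> ScanImage:
    """Dark seeds (0) on a white platen (255)."""
    px = np.where(np.asarray(mask, bool), 0, 255).astype(np.uint8)
    return ScanImage(pixels=px, dpi=dpi, source_tag=tag)


def single_particle(mask: np.ndarray):
    parts = label_particles(mask, min_area_mm2=0.0, pixel_size_mm=1.0)
    assert len(parts) == 1
    return parts[0]


@pytest.fixture
def img_factory():
    return mask_to_image


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SimulationConfig(
        n_seeds=150, rng_seed=7, canvas_px=(1200, 1200), seeds_per_scan=(4, 10)
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    import pandas as pd

    frames = []
    for image, _meta in small_dataset.scans:
        df = measure_image(image, threshold="none")
        if not df.empty:
            frames.append(df)
    feats = pd.concat(frames, ignore_index=True)
    records = [
        MeasurementRecord(**{k: (None if pd.isna(v) else v) for k, v in row.items()})
        for row in feats.to_dict(orient="records")
    ]
    return assemble_table(records)


def make_record(**overrides) -> MeasurementRecord:
    """A fully-populated plausible measurement row for table tests."""
    base = dict(
        Area=0.5, X=1.0, Y=1.0, XM=1.0, YM=1.0, Perim=3.0, BX=0.5, BY=0.5,
        Width=1.2, Height=0.6, Major=1.1, Minor=0.55, Angle=10.0, Circ=0.7,
        Feret=1.2, IntDen=0.0, Median=0.0, Skew=None, Kurt=None, RawIntDen=0.0,
        FeretX=10.0, FeretY=12.0, FeretAngle=15.0, MinFeret=0.5, AR=2.0,
        Round=0.5, Solidity=0.9,
        tag="S01_T01_2019-10-01_TSHE_filled_rep1.tif",
    )
    base.update(overrides)
    return MeasurementRecord(**base)
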