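"""Synthetic winged-seed scans with ground truth.

Generates binary flatbed-scanner-like images of conifer-style seeds so the
whole pipeline — segmentation, morphometry, classification, consensus — is
testable without any external data.  Each species template is an ellipse
body fused with a superellipse wing lobe; damage removes a circular bite.
Every physical batch is rendered twice with fresh rotations, mirrorings and
placements, emulating replicate scans of rearranged seeds.

All randomness flows from one seeded generator; per-batch substreams are
derived deterministically so datasets regenerate bit-identically.
"""

from __future__ import annotations

import datetime as _dt
import math
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .scanio import ScanImage, ScanMetadata, format_tag, pixel_size_mm, write_scan

__all__ = [
    "SpeciesTemplate",
    "SiteSpec",
    "SimulationConfig",
    "default_templates",
    "default_sites",
    "sample_seed_spec",
    "sample_silhouette",
    "rasterize_seed",
    "render_scan",
    "generate_dataset",
    "write_dataset",
]


@dataclass
class SpeciesTemplate:
    name: str
    body_length_mm: float  # median of the lognormal body length
    body_length_sigma: float = 0.10  # log-scale sd
    aspect_mean: float = 2.0
    aspect_sd: float = 0.12
    wing_fraction: float = 0.8  # wing length as a fraction of body length
    wing_asymmetry: float = 0.1  # lateral wing offset, fraction of body width
    damage_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.body_length_mm <= 0:
            raise ValueError("body_length_mm must be positive")
        if not 0 <= self.wing_fraction <= 3:
            raise ValueError("wing_fraction must be in [0, 3]")
        if not 0 <= self.damage_prob <= 1:
            raise ValueError("damage_prob must be in [0, 1]")


@dataclass
class SiteSpec:
    name: str
    species_weights: Dict[str, float]
    size_shift: float = 1.0  # multiplicative size modifier at this site


@dataclass
class SimulationConfig:
    templates: List[SpeciesTemplate] = field(default_factory=lambda: default_templates())
    sites: List[SiteSpec] = field(default_factory=lambda: default_sites())
    seeds_per_scan: Tuple[int, int] = (5, 18)
    n_seeds: int = 600  # total physical seeds across all batches
    debris_rate: float = 4.0  # mean sub-threshold specks per scan
    dpi: float = 600.0
    canvas_px: Tuple[int, int] = (1500, 1500)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.templates) < 2:
            raise ValueError("need at least 2 species templates")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")


def default_templates() -> List[SpeciesTemplate]:
    """Six conifer-like templates; the last two are deliberately confusable."""
    return [
        SpeciesTemplate("ABAM", 5.9, 0.09, 2.00, 0.12, 0.90, 0.15, 0.10),
        SpeciesTemplate("CANO", 3.0, 0.10, 1.25, 0.08, 0.25, 0.05, 0.05),
        SpeciesTemplate("PSME", 4.5, 0.09, 1.70, 0.10, 0.75, 0.12, 0.10),
        SpeciesTemplate("THPL", 2.55, 0.09, 3.10, 0.15, 0.20, 0.05, 0.10),
        SpeciesTemplate("TSHE", 2.45, 0.11, 1.85, 0.12, 1.00, 0.10, 0.12),
        SpeciesTemplate("TSME", 2.65, 0.11, 1.85, 0.12, 1.05, 0.10, 0.12),
    ]


def default_sites() -> List[SiteSpec]:
    return [
        SiteSpec("S01", {"ABAM": 1, "CANO": 1, "PSME": 2, "THPL": 2, "TSHE": 2, "TSME": 0.3}, 0.95),
        SiteSpec("S02", {"ABAM": 2, "CANO": 1, "PSME": 1, "THPL": 1, "TSHE": 1, "TSME": 1}, 1.00),
        SiteSpec("S03", {"ABAM": 1, "CANO": 2, "PSME": 0.5, "THPL": 1, "TSHE": 0.3, "TSME": 2}, 1.06),
    ]


@dataclass
class SeedSpec:
    """Physical parameters of one sampled seed (persist across replicates)."""

    species: str
    body_len_px: float
    body_wid_px: float
    wing_len_px: float
    wing_wid_px: float
    wing_offset_px: float
    bite_angle: Optional[float] = None  # body-frame damage, None = undamaged
    bite_radius_px: float = 0.0


def sample_seed_spec(
    template: SpeciesTemplate,
    rng: np.random.Generator,
    size_shift: float = 1.0,
    dpi: float = 600.0,
) -> SeedSpec:
    cal = pixel_size_mm(dpi)
    length_mm = template.body_length_mm * size_shift * math.exp(
        rng.normal(0.0, template.body_length_sigma)
    )
    aspect = max(1.05, rng.normal(template.aspect_mean, template.aspect_sd))
    body_len = length_mm / cal
    body_wid = body_len / aspect
    wing_len = template.wing_fraction * body_len
    wing_wid = 0.75 * body_wid
    offset = template.wing_asymmetry * body_wid * rng.normal(1.0, 0.3)
    damaged = rng.random() < template.damage_prob
    return SeedSpec(
        species=template.name,
        body_len_px=body_len,
        body_wid_px=body_wid,
        wing_len_px=wing_len,
        wing_wid_px=wing_wid,
        wing_offset_px=offset,
        # bite stays away from the +x wing junction so damage cannot detach
        # the wing in a pose-dependent way
        bite_angle=float(rng.uniform(math.pi / 4, 7 * math.pi / 4)) if damaged else None,
        bite_radius_px=0.2 * body_len if damaged else 0.0,
    )


def rasterize_seed(
    spec: SeedSpec, angle_deg: float, mirror: bool = False
) -> np.ndarray:
    """Rasterize one seed at a pose; a pixel is set when its center falls
    inside the (rotated, optionally mirrored) silhouette."""
    a_b = spec.body_len_px / 2.0
    b_b = spec.body_wid_px / 2.0
    a_w = spec.wing_len_px / 2.0
    b_w = spec.wing_wid_px / 2.0
    # wing lobe overlaps the body tip by 20% of its length
    wing_cx = a_b + a_w - 0.4 * a_w
    wing_cy = spec.wing_offset_px

    radius = max(a_b, b_b, wing_cx + a_w, abs(wing_cy) + b_w) + 2
    half = int(math.ceil(radius))
    coords = np.arange(-half, half + 1) + 0.5
    xx, yy = np.meshgrid(coords, coords)

    th = math.radians(angle_deg)
    u = math.cos(th) * xx + math.sin(th) * yy
    v = -math.sin(th) * xx + math.cos(th) * yy
    if mirror:
        v = -v

    inside_body = (u / a_b) ** 2 + (v / b_b) ** 2 <= 1.0
    ne = 2.5  # superellipse exponent: blunt-tipped wing
    if a_w > 0 and b_w > 0:
        inside_wing = (
            np.abs((u - wing_cx) / a_w) ** ne + np.abs((v - wing_cy) / b_w) ** ne
            <= 1.0
        )
    else:
        inside_wing = np.zeros_like(inside_body)
    mask = inside_body | inside_wing

    if spec.bite_angle is not None and spec.bite_radius_px > 0:
        bx = a_b * math.cos(spec.bite_angle)
        by = b_b * math.sin(spec.bite_angle)
        bite = (u - bx) ** 2 + (v - by) ** 2 <= spec.bite_radius_px ** 2
        mask &= ~bite

    # a bite can sever a sliver; a real broken-off fragment would be lost,
    # so keep only the largest connected piece
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        return np.zeros((1, 1), dtype=bool)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    rr, cc = np.nonzero(mask)
    return mask[rr.min() : rr.max() + 1, cc.min() : cc.max() + 1]


def sample_silhouette(
    template: SpeciesTemplate,
    rng: np.random.Generator,
    size_shift: float = 1.0,
    dpi: float = 600.0,
) -> tuple[np.ndarray, str]:
    """Sample a seed and rasterize it at a random pose: (mask, label)."""
    spec = sample_seed_spec(template, rng, size_shift=size_shift, dpi=dpi)
    angle = float(rng.uniform(0, 180))
    mirror = bool(rng.random() < 0.5)
    return rasterize_seed(spec, angle, mirror), spec.species


_GAP_STRUCT = np.ones((3, 3), dtype=bool)


def _place(
    occupancy: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    max_attempts: int = 300,
) -> tuple[int, int]:
    H, W = occupancy.shape
    h, w = mask.shape
    if h > H or w > W:
        raise RuntimeError("silhouette larger than canvas; enlarge canvas_px")
    grown = ndimage.binary_dilation(mask, structure=_GAP_STRUCT, iterations=2)
    for _ in range(max_attempts):
        r0 = int(rng.integers(0, H - h + 1))
        c0 = int(rng.integers(0, W - w + 1))
        if not occupancy[r0 : r0 + h, c0 : c0 + w][grown].any():
            occupancy[r0 : r0 + h, c0 : c0 + w] |= grown
            return r0, c0
    raise RuntimeError(
        f"could not place a {h}x{w} silhouette after {max_attempts} attempts; "
        "use a larger canvas or fewer seeds per scan"
    )


def render_scan(
    silhouettes: Sequence[tuple[np.ndarray, str]],
    config: SimulationConfig,
    rng: np.random.Generator,
    source_tag: str = "",
) -> tuple[ScanImage, pd.DataFrame]:
    """Place silhouettes on a white canvas without overlap (>= 2 px gaps),
    sprinkle sub-threshold debris, and return the binary scan plus a truth
    table whose rows follow segmentation's particle ordering
    (top-to-bottom then left-to-right by bounding-box origin)."""
    H, W = config.canvas_px
    canvas = np.full((H, W), 255, dtype=np.uint8)
    occupancy = np.zeros((H, W), dtype=bool)

    placed = []
    for mask, label in silhouettes:
        r0, c0 = _place(occupancy, mask, rng)
        canvas[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]][mask] = 0
        placed.append((r0, c0, label))

    n_debris = int(rng.poisson(config.debris_rate))
    yy, xx = np.mgrid[-3:4, -3:4]
    for _ in range(n_debris):
        rad = float(rng.uniform(0.8, 2.5))
        speck = (xx ** 2 + yy ** 2) <= rad ** 2
        try:
            r0, c0 = _place(occupancy, speck, rng, max_attempts=50)
        except RuntimeError:
            continue
        canvas[r0 : r0 + 7, c0 : c0 + 7][speck] = 0

    placed.sort(key=lambda t: (t[0], t[1]))
    truth = pd.DataFrame(
        {
            "label_id": range(1, len(placed) + 1),
            "species": [lab for _, _, lab in placed],
            "tag": source_tag,
        }
    )
    image = ScanImage(pixels=canvas, dpi=config.dpi, source_tag=source_tag)
    return image, truth


@dataclass
class Dataset:
    scans: List[tuple[ScanImage, ScanMetadata]]
    truth: pd.DataFrame  # tag, label_id, species per particle


def generate_dataset(config: SimulationConfig) -> Dataset:
    """Simulate batches until ``config.n_seeds`` physical seeds exist, each
    batch rendered as two replicate scans of the same sampled seeds."""
    root = np.random.default_rng(config.rng_seed)
    templates = {t.name: t for t in config.templates}
    scans: List[tuple[ScanImage, ScanMetadata]] = []
    truth_parts: List[pd.DataFrame] = []

    total = 0
    batch_no = 0
    base_date = _dt.date(2019, 10, 1)
    while total < config.n_seeds:
        batch_no += 1
        rng = np.random.default_rng([config.rng_seed, batch_no])
        site = config.sites[int(rng.integers(0, len(config.sites)))]
        names = sorted(site.species_weights)
        w = np.array([site.species_weights[s] for s in names], dtype=float)
        species = names[int(rng.choice(len(names), p=w / w.sum()))]
        template = templates[species]

        lo, hi = config.seeds_per_scan
        n = int(rng.integers(lo, hi + 1))
        n = min(n, config.n_seeds - total) or 1
        total += n
        specs = [
            sample_seed_spec(template, rng, site.size_shift, config.dpi)
            for _ in range(n)
        ]

        meta_base = ScanMetadata(
            site=site.name,
            trap_id=f"T{batch_no:03d}",
            collection_date=base_date + _dt.timedelta(days=batch_no % 30),
            species_label=species,
            fill_status="filled",
            replicate_index=1,
        )
        for rep in (1, 2):
            meta = replace(meta_base, replicate_index=rep)
            tag = format_tag(meta)
            meta.source_tag = tag
            sils = [
                (
                    rasterize_seed(
                        s,
                        float(rng.uniform(0, 180)),
                        bool(rng.random() < 0.5),
                    ),
                    s.species,
                )
                for s in specs
            ]
            image, truth = render_scan(sils, config, rng, source_tag=tag)
            scans.append((image, meta))
            truth_parts.append(truth)

    truth = pd.concat(truth_parts, ignore_index=True)
    return Dataset(scans=scans, truth=truth)


def write_dataset(dataset: Dataset, out_dir: str) -> pd.DataFrame:
    """Write scans as TIFFs named by the tag grammar plus truth.csv."""
    os.makedirs(out_dir, exist_ok=True)
    for image, meta in dataset.scans:
        write_scan(image, os.path.join(out_dir, meta.source_tag))
    truth_path = os.path.join(out_dir, "truth.csv")
    dataset.truth.to_csv(truth_path, index=False)
    return dataset.truth
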