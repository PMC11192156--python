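"""Feature-table assembly and train/test splitting.

The classifier consumes one row per particle: the 25 retained measurements
(Skew and Kurt are dropped for their frequent missing values) plus the
categorical Site parsed from the file-name tag — 26 predictors in the
default configuration.  Bookkeeping columns (tag, trap, replicate, fill)
ride along but are never used for prediction.
"""

from __future__ import annotations

import logging
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .morphometry import MEASUREMENT_COLUMNS, MeasurementRecord
from .scanio import ScanMetadata, parse_tag

__all__ = [
    "PREDICTOR_MEASUREMENTS",
    "POSITIONAL_PREDICTORS",
    "default_predictors",
    "assemble_table",
    "split_train_test",
]

log = logging.getLogger(__name__)

# Measurements excluded from prediction (frequently missing on binary scans).
EXCLUDED_MEASUREMENTS = ("Skew", "Kurt")

PREDICTOR_MEASUREMENTS: List[str] = [
    c for c in MEASUREMENT_COLUMNS if c not in EXCLUDED_MEASUREMENTS
]

# Position-dependent predictors; retained by default, excludable via config.
POSITIONAL_PREDICTORS = ("X", "Y", "XM", "YM", "BX", "BY", "FeretX", "FeretY")

BOOKKEEPING_COLUMNS = ["tag", "trap_id", "replicate_index", "fill_status", "batch_id"]
RESPONSE_COLUMN = "Species"


def default_predictors(include_positional: bool = True) -> List[str]:
    """Predictor column names: retained measurements + Site."""
    cols = [
        c
        for c in PREDICTOR_MEASUREMENTS
        if include_positional or c not in POSITIONAL_PREDICTORS
    ]
    return cols + ["Site"]


def assemble_table(
    records: Sequence[MeasurementRecord],
    metadata: Optional[Iterable[ScanMetadata]] = None,
    tag_mode: str = "strict",
    include_positional: bool = True,
) -> pd.DataFrame:
    """Join measurements with tag metadata into the model's feature table.

    Metadata is looked up by source tag (parsed from each record's ``tag``
    when not supplied).  Rows with any missing predictor are dropped with a
    logged count; an all-rows-dropped table is an error.
    """
    if not records:
        raise ValueError("no measurement records to assemble")
    meta_by_tag = {}
    if metadata is not None:
        meta_by_tag = {m.source_tag: m for m in metadata}

    rows = []
    for rec in records:
        d = rec.to_dict()
        tag = d["tag"]
        meta = meta_by_tag.get(tag)
        if meta is None:
            meta = parse_tag(tag, mode=tag_mode)
        d["Site"] = meta.site
        d[RESPONSE_COLUMN] = meta.species_label
        d["trap_id"] = meta.trap_id
        d["replicate_index"] = meta.replicate_index
        d["fill_status"] = meta.fill_status
        d["batch_id"] = meta.batch_id
        rows.append(d)
    df = pd.DataFrame(rows)

    predictors = default_predictors(include_positional)
    n0 = len(df)
    df = df.dropna(subset=[c for c in predictors if c in df.columns])
    dropped = n0 - len(df)
    if dropped:
        log.warning("dropped %d rows with missing predictor values", dropped)
    if df.empty:
        raise ValueError("all rows dropped: every record had missing predictors")

    ordered = predictors + [RESPONSE_COLUMN] + BOOKKEEPING_COLUMNS
    df = df[[c for c in ordered if c in df.columns]]
    return df.reset_index(drop=True)


def split_train_test(
    table: pd.DataFrame,
    train_fraction: float = 0.8,
    rng_seed: int = 0,
    group_by_batch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified per-species train/test split.

    Per species, train size = round(train_fraction * n).  With
    ``group_by_batch`` both replicate scans of a physical batch land on the
    same side (slightly looser stratification, no replicate leakage).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if RESPONSE_COLUMN not in table or table[RESPONSE_COLUMN].isna().any():
        raise ValueError("split requires species labels on every row")
    rng = np.random.default_rng(rng_seed)

    train_idx: list = []
    test_idx: list = []
    for species in sorted(table[RESPONSE_COLUMN].unique()):
        sub = table.index[table[RESPONSE_COLUMN] == species].to_numpy()
        if len(sub) < 2:
            raise ValueError(
                f"species {species!r} has fewer than 2 rows; cannot split"
            )
        n_train = int(round(train_fraction * len(sub)))
        n_train = min(max(n_train, 1), len(sub) - 1)
        if group_by_batch:
            batches = sorted(table.loc[sub, "batch_id"].unique())
            order = rng.permutation(len(batches))
            taken = 0
            train_batches = set()
            for k in order:
                if taken >= n_train:
                    break
                b = batches[k]
                train_batches.add(b)
                taken += int((table.loc[sub, "batch_id"] == b).sum())
            mask = table.loc[sub, "batch_id"].isin(train_batches).to_numpy()
            train_idx.extend(sub[mask])
            test_idx.extend(sub[~mask])
        else:
            perm = rng.permutation(len(sub))
            train_idx.extend(sub[perm[:n_train]])
            test_idx.extend(sub[perm[n_train:]])

    train = table.loc[sorted(train_idx)].reset_index(drop=True)
    test = table.loc[sorted(test_idx)].reset_index(drop=True)
    return train, test
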