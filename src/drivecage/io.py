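"""CSV and manifest input/output for cage and cross datasets.

Formats are plain UTF-8 comma-separated tables with a required header.
Cage tables have one row per (cage, generation); cross tables one row
per replicate cross.  Reads validate the count invariants and name the
offending row on failure.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Sequence

import pandas as pd
import yaml

from .crosses import CrossTally
from .inference import CageDataset, PhenotypeCounts

__all__ = [
    "CAGE_COLUMNS",
    "CROSS_COLUMNS",
    "write_cage_csv",
    "read_cage_csv",
    "write_cross_csv",
    "read_cross_csv",
    "write_manifest",
    "read_manifest",
]

CAGE_COLUMNS = [
    "cage_id",
    "ratio",
    "generation",
    "gfp_black",
    "gfp_white",
    "nogfp_black",
    "nogfp_white",
    "nogfp_mosaic",
    "total",
]

CROSS_COLUMNS = [
    "replicate",
    "lineage",
    "n",
    "gfp_pos",
    "nogfp_black",
    "nogfp_white",
    "nogfp_mosaic",
]


def write_cage_csv(datasets: Sequence[CageDataset], path) -> None:
    rows = []
    for ds in datasets:
        for c in ds.counts:
            rows.append(
                {
                    "cage_id": ds.cage_id,
                    "ratio": ds.ratio,
                    "generation": c.generation,
                    "gfp_black": c.gfp_black,
                    "gfp_white": c.gfp_white,
                    "nogfp_black": c.nogfp_black,
                    "nogfp_white": c.nogfp_white,
                    "nogfp_mosaic": c.nogfp_mosaic,
                    "total": c.total,
                }
            )
    pd.DataFrame(rows, columns=CAGE_COLUMNS).to_csv(path, index=False)


def read_cage_csv(path) -> List[CageDataset]:
    df = pd.read_csv(path)
    required = [c for c in CAGE_COLUMNS if c != "nogfp_mosaic"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cage CSV {path}: missing columns {missing}")
    if "nogfp_mosaic" not in df.columns:
        warnings.warn(f"cage CSV {path}: no nogfp_mosaic column, assuming zeros")
        df["nogfp_mosaic"] = 0
    datasets = []
    for (cage_id, ratio), grp in df.groupby(["cage_id", "ratio"], sort=False):
        counts = []
        for idx, row in grp.sort_values("generation").iterrows():
            try:
                counts.append(
                    PhenotypeCounts(
                        generation=int(row["generation"]),
                        gfp_black=int(row["gfp_black"]),
                        gfp_white=int(row["gfp_white"]),
                        nogfp_black=int(row["nogfp_black"]),
                        nogfp_white=int(row["nogfp_white"]),
                        nogfp_mosaic=int(row["nogfp_mosaic"]),
                        total=int(row["total"]),
                    )
                )
            except ValueError as err:
                raise ValueError(f"cage CSV {path}, row {idx}: {err}") from None
        datasets.append(CageDataset(cage_id=str(cage_id), ratio=str(ratio), counts=counts))
    return datasets


def write_cross_csv(tallies: Sequence[CrossTally], path) -> None:
    rows = [
        {
            "replicate": t.replicate,
            "lineage": t.lineage,
            "n": t.n,
            "gfp_pos": t.gfp_pos,
            "nogfp_black": t.nogfp_black,
            "nogfp_white": t.nogfp_white,
            "nogfp_mosaic": t.nogfp_mosaic,
        }
        for t in tallies
    ]
    pd.DataFrame(rows, columns=CROSS_COLUMNS).to_csv(path, index=False)


def read_cross_csv(path) -> List[CrossTally]:
    df = pd.read_csv(path)
    required = ["replicate", "lineage", "n", "gfp_pos"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cross CSV {path}: missing columns {missing}")
    for col in ("nogfp_black", "nogfp_white", "nogfp_mosaic"):
        if col not in df.columns:
            warnings.warn(f"cross CSV {path}: no {col} column, assuming zeros")
            df[col] = 0
    tallies = []
    for idx, row in df.iterrows():
        try:
            tallies.append(
                CrossTally(
                    n=int(row["n"]),
                    gfp_pos=int(row["gfp_pos"]),
                    nogfp_black=int(row["nogfp_black"]),
                    nogfp_white=int(row["nogfp_white"]),
                    nogfp_mosaic=int(row["nogfp_mosaic"]),
                    replicate=str(row["replicate"]),
                    lineage=str(row["lineage"]),
                )
            )
        except ValueError as err:
            raise ValueError(f"cross CSV {path}, row {idx}: {err}") from None
    return tallies


def write_manifest(manifest: Dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))


def read_manifest(path) -> Dict:
    return yaml.safe_load(Path(path).read_text())
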