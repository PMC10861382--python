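"""Reading/writing twin item-response CSVs and pipeline configuration.

Dialect: UTF-8, comma-separated, header required. Columns ``family_id``,
``zygosity`` (MZ/DZ), ``twin`` (1/2), then ``item_1..item_I`` holding
1-based integer categories; an empty field is a missing response. Families
in which every response of both twins is missing are excluded on read (the
analysis has nothing to condition on for them) with a logged count.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import MISSING, ItemResponseTable, LatentTwinSample

logger = logging.getLogger("twinaxe")

__all__ = [
    "read_twin_csv",
    "write_twin_csv",
    "write_truth_csv",
    "PipelineConfig",
]


class TwinCsvError(ValueError):
    """Validation failure with the offending rows listed."""


def write_twin_csv(table: ItemResponseTable, path) -> None:
    df = table.to_frame()
    item_cols = [c for c in df.columns if c.startswith("item_")]
    df[item_cols] = df[item_cols].astype("Int64")
    df.to_csv(path, index=False)


def read_twin_csv(path, n_categories=None) -> ItemResponseTable:
    """Parse and validate a twin CSV into an :class:`ItemResponseTable`.

    ``n_categories`` declares per-item category counts K_i; when omitted it
    is inferred as the highest observed category per item (at least 2).
    Raises :class:`TwinCsvError` on unknown zygosity codes, out-of-range
    categories, or duplicated (family, twin) keys, listing offending rows.
    """
    df = pd.read_csv(path)
    required = {"family_id", "zygosity", "twin"}
    if not required <= set(df.columns):
        raise TwinCsvError(f"missing required columns {required - set(df.columns)}")
    item_cols = sorted(
        (c for c in df.columns if c.startswith("item_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not item_cols:
        raise TwinCsvError("no item_<i> columns found")

    bad = df[~df["zygosity"].isin(["MZ", "DZ"])]
    if len(bad):
        raise TwinCsvError(f"unknown zygosity codes in rows {bad.index.tolist()}")
    dup = df.duplicated(subset=["family_id", "twin"], keep=False)
    if dup.any():
        raise TwinCsvError(
            f"duplicated family/twin keys in rows {df.index[dup].tolist()}"
        )
    counts = df.groupby("family_id")["twin"].agg(["count"])
    bad_fams = counts[counts["count"] != 2].index.tolist()
    if bad_fams:
        raise TwinCsvError(f"families without exactly two twins: {bad_fams}")

    df = df.sort_values(["family_id", "twin"], kind="stable").reset_index(drop=True)
    raw = df[item_cols].to_numpy(dtype=float)
    if n_categories is None:
        with np.errstate(invalid="ignore"):
            ks = tuple(
                int(max(np.nanmax(col), 2)) if not np.all(np.isnan(col)) else 2
                for col in raw.T
            )
    else:
        ks = tuple(int(k) for k in n_categories)
        if len(ks) != len(item_cols):
            raise TwinCsvError("n_categories length disagrees with item columns")

    resp = np.where(np.isnan(raw), float(MISSING), raw - 1.0)
    out_of_range = (resp >= np.asarray(ks)[None, :]) | (
        (resp < 0) & (resp != MISSING)
    ) | (np.mod(np.where(np.isnan(raw), 0.0, raw), 1) != 0)
    if out_of_range.any():
        rows = sorted(set(np.where(out_of_range)[0].tolist()))
        raise TwinCsvError(f"category out of range / non-integer in rows {rows}")

    fam_ids = df["family_id"].to_numpy()[0::2]
    zyg = df["zygosity"].to_numpy(dtype=object)[0::2]
    zyg2 = df["zygosity"].to_numpy(dtype=object)[1::2]
    if not np.all(zyg == zyg2):
        raise TwinCsvError("co-twins disagree on zygosity")
    resp = resp.astype(np.int64)

    all_missing = (resp == MISSING).reshape(fam_ids.size, -1).all(axis=1)
    if all_missing.any():
        logger.info(
            "excluded %d families with missing data on all items",
            int(all_missing.sum()),
        )
        keep = ~all_missing
        fam_ids, zyg = fam_ids[keep], zyg[keep]
        resp = resp.reshape(-1, 2, len(item_cols))[keep].reshape(-1, len(item_cols))

    return ItemResponseTable(
        family_id=fam_ids, zygosity=zyg, responses=resp, n_categories=ks
    )


def write_truth_csv(latents: LatentTwinSample, path) -> None:
    """Companion file with the generating latent values (for recovery tests)."""
    n = latents.n_individuals
    pd.DataFrame(
        {
            "family_id": np.repeat(np.arange(n // 2), 2),
            "zygosity": np.repeat(latents.zygosity, 2),
            "twin": np.tile([1, 2], n // 2),
            "A": latents.A,
            "C": latents.C,
            "D": latents.D,
            "E": latents.E,
            "theta": latents.theta,
        }
    ).to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Declarative description of a full simulate -> fit -> report run.

    Round-trips losslessly through JSON or YAML (``to_file``/``from_file``).
    """

    out_dir: str
    seed: int = 0
    input_csv: str | None = None
    simulate: dict | None = None
    irt_models: list = field(default_factory=lambda: ["PCM", "GPCM", "GRM"])
    genetic_models: list = field(
        default_factory=lambda: [
            {"flavour": "AE", "interaction": False},
            {"flavour": "AE", "interaction": True},
            {"flavour": "ACE", "interaction": False},
            {"flavour": "ACE", "interaction": True},
        ]
    )
    sampler: dict = field(
        default_factory=lambda: {
            "n_chains": 2,
            "burn_in": 5000,
            "n_iter": 10000,
            "thin": 1,
        }
    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
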