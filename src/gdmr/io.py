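"""File formats and schemas: FASTA, pyrogram CSV, phenotype CSV, BED, config.

All CSV is comma-separated, UTF-8, header row, '.' decimal.  Percentages are
carried as percent (0-100) throughout, never fractions.  BED output is
0-based half-open.  Sampling dates are ordered categorical labels
(birth, 1m, 2m, 3m, 4m), not calendar dates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .assay_sim import Pyrogram
from .genome_scan import SiteMap

PYROGRAM_COLUMNS = ["sample_id", "run_id", "reaction", "dispensation_index", "base", "height"]
PHENOTYPE_REQUIRED = ["animal", "breed", "sex", "gdmr"]


class SchemaError(ValueError):
    """CSV schema violation, naming the offending columns/rows."""


def pyrograms_to_frame(pyrograms: Iterable[Pyrogram]) -> pd.DataFrame:
    """Long-format table: one row per dispensation per reaction per sample."""
    rows = []
    for p in pyrograms:
        for i, (base, height) in enumerate(zip(p.dispensation, p.peaks), start=1):
            rows.append(
                {
                    "sample_id": p.sample_id,
                    "run_id": p.run_id,
                    "reaction": p.reaction,
                    "dispensation_index": i,
                    "base": base,
                    "height": height,
                }
            )
    return pd.DataFrame(rows, columns=PYROGRAM_COLUMNS)


def frame_to_pyrograms(frame: pd.DataFrame) -> dict[str, Pyrogram]:
    """Rebuild one sample's pyrograms keyed by reaction from long rows."""
    out: dict[str, Pyrogram] = {}
    for reaction, group in frame.groupby("reaction", sort=True):
        g = group.sort_values("dispensation_index")
        idx = g["dispensation_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise SchemaError(
                f"reaction {reaction!r}: dispensation indices must be 1..n, got {idx[:8]}"
            )
        out[str(reaction)] = Pyrogram(
            sample_id=str(g["sample_id"].iloc[0]),
            run_id=str(g["run_id"].iloc[0]),
            reaction=str(reaction),
            dispensation="".join(g["base"].astype(str)),
            peaks=g["height"].to_numpy(dtype=float),
        )
    return out


def write_pyrograms_csv(pyrograms: Iterable[Pyrogram], path: str | Path) -> None:
    pyrograms_to_frame(pyrograms).to_csv(path, index=False)


def read_pyrograms_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(PYROGRAM_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"pyrogram CSV lacks columns: {sorted(missing)}")
    bad = frame.index[~np.isfinite(frame["height"])].tolist()
    if bad:
        raise SchemaError(f"non-numeric peak heights at rows {bad[:5]}")
    return frame


def write_phenotypes_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path, *, required: list[str] | None = None) -> pd.DataFrame:
    frame = pd.read_csv(path)
    req = PHENOTYPE_REQUIRED if required is None else required
    missing = [c for c in req if c not in frame.columns]
    if missing:
        raise SchemaError(f"phenotype CSV lacks columns: {missing}")
    return frame


def write_bed(maps: Iterable[SiteMap], path: str | Path) -> None:
    """0-based half-open BED of motif occurrences (name column = motif)."""
    with open(path, "w") as fh:
        for m in maps:
            for motif, positions in m.positions.items():
                for pos in positions:
                    fh.write(f"{m.contig_id}\t{pos}\t{pos + len(motif)}\t{motif}\n")


def write_fasta(records: dict[str, str], path: str | Path, *, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config file must be a key-value mapping")
    return cfg


def dump_config(cfg: dict, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(cfg, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
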