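"""Round-trip readers/writers for the pipeline's plain-text formats.

Counts and metadata travel as TSV, peaks as BED6 (0-based half-open, native
convention), enhancer tables as TSV, gene-set collections as GMT.  Result
tables are TSV with a leading comment line carrying the config hash so runs
are traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BED_COLUMNS, CountMatrix, EnhancerDB, PeakSet


def write_counts(cm: CountMatrix, path) -> None:
    df = cm.counts.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_counts(path, meta: pd.DataFrame) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    for j, col in enumerate(df.columns):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values != np.floor(values))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-integer count at row {i + 2} (gene {df.index[i]}), "
                f"column {j + 2} ({col})"
            )
    return CountMatrix(df.astype(np.int64), meta)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col="sample")
    for col in ("condition", "dataset"):
        if col not in meta.columns:
            raise ValueError(f"{path}: metadata lacks required column '{col}'")
    return meta


def write_bed(peaks: PeakSet, path) -> None:
    peaks.df[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path, label: str = "") -> PeakSet:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: BED line has fewer than 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((fields[0], start, end, name, score, strand))
    return PeakSet(pd.DataFrame(rows, columns=BED_COLUMNS), label=label)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    out = annotation.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col="gene")
    required = {"chrom", "start", "end", "strand", "tss"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: annotation lacks columns {sorted(missing)}")
    return ann


def write_enhancers(db: EnhancerDB, path) -> None:
    merged = db.associations.merge(
        db.enhancers.reset_index(), on="enhancer_id", how="left"
    )[["chrom", "start", "end", "enhancer_id", "enhancer_score", "gene", "association_score"]]
    merged.to_csv(path, sep="\t", index=False)


def read_enhancers(path) -> EnhancerDB:
    df = pd.read_csv(path, sep="\t")
    enh = (
        df[["enhancer_id", "chrom", "start", "end", "enhancer_score"]]
        .drop_duplicates("enhancer_id")
        .set_index("enhancer_id")
    )
    assoc = df[["enhancer_id", "gene", "association_score"]].reset_index(drop=True)
    return EnhancerDB(enh, assoc)


def write_gmt(sets: dict[str, tuple[str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in sets.items():
            fh.write("\t".join([term_id, name, *genes]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, name, >=1 gene")
            term_id = fields[0]
            if term_id in sets:
                raise ValueError(f"{path}:{ln}: duplicate term id {term_id!r}")
            sets[term_id] = (fields[1], fields[2:])
    return sets


def config_hash(config) -> str:
    payload = json.dumps(repr(config), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_result_table(df: pd.DataFrame, path, cfg_hash: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_result_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (set, frozenset)):
        return sorted(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
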