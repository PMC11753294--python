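"""Core in-memory containers shared across the pipeline.

Counts travel as a genes x samples integer DataFrame with per-sample
metadata (case/control condition label and originating dataset).  Genomic
intervals are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_LABELS = ("case", "control")


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix plus per-sample metadata.

    Parameters
    ----------
    counts
        genes x samples DataFrame of non-negative integers; index = gene ids,
        columns = sample ids.
    meta
        sample-indexed DataFrame with at least ``condition`` (``case`` or
        ``control``) and ``dataset`` columns, aligned with ``counts.columns``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if not set(self.counts.columns) <= set(self.meta.index):
            missing = set(self.counts.columns) - set(self.meta.index)
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        self.meta = self.meta.loc[self.counts.columns]
        for col in ("condition", "dataset"):
            if col not in self.meta.columns:
                raise ValueError(f"sample metadata lacks '{col}' column")
        bad = set(self.meta["condition"]) - set(GROUP_LABELS)
        if bad:
            raise ValueError(f"condition labels must be case/control, got {bad}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples], self.meta.loc[samples])

    def subset_genes(self, genes) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.meta)

    def condition_mask(self, label: str) -> np.ndarray:
        return (self.meta["condition"] == label).to_numpy()


def concat_count_matrices(matrices: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate datasets sharing the same gene universe."""
    genes = matrices[0].genes
    for m in matrices[1:]:
        if not genes.equals(m.genes):
            raise ValueError("datasets do not share a gene universe")
    counts = pd.concat([m.counts for m in matrices], axis=1)
    meta = pd.concat([m.meta for m in matrices], axis=0)
    return CountMatrix(counts, meta)


BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class PeakSet:
    """Genomic intervals (0-based half-open) with optional scores."""

    df: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[BED_COLUMNS]
        if len(df):
            if (df["start"] >= df["end"]).any():
                raise ValueError("peak intervals require start < end")
            if (df["start"] < 0).any():
                raise ValueError("negative peak coordinates")
        df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class EnhancerDB:
    """Enhancer intervals with scores and enhancer-gene association rows.

    ``enhancers``: enhancer_id-indexed DataFrame (chrom, start, end,
    enhancer_score).  ``associations``: rows (enhancer_id, gene,
    association_score).
    """

    enhancers: pd.DataFrame
    associations: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.associations):
            orphan = set(self.associations["enhancer_id"]) - set(self.enhancers.index)
            if orphan:
                raise ValueError(f"associations reference unknown enhancers: {sorted(orphan)[:5]}")
            if (self.associations["association_score"] < 0).any():
                raise ValueError("association scores must be >= 0")
        if len(self.enhancers) and (self.enhancers["enhancer_score"] < 0).any():
            raise ValueError("enhancer scores must be >= 0")


@dataclass
class SignatureSet:
    """Per-condition direction-signed gene signature with provenance."""

    condition: str
    directions: dict[str, int]
    provenance: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)
    excluded_discordant: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = set(self.directions) & self.excluded_discordant
        if overlap:
            raise ValueError(f"genes both retained and excluded: {sorted(overlap)[:5]}")
        bad = {g for g, d in self.directions.items() if d not in (-1, 1)}
        if bad:
            raise ValueError("signature directions must be +1/-1")

    @property
    def genes(self) -> set[str]:
        return set(self.directions)

    def tally(self) -> dict[str, int]:
        up = sum(1 for d in self.directions.values() if d == 1)
        return {
            "genes": len(self.directions),
            "up": up,
            "down": len(self.directions) - up,
            "excluded_discordant": len(self.excluded_discordant),
        }


@dataclass
class CommonSignature:
    """Cross-condition intersection of two signatures."""

    common: set[str]
    concordant: dict[str, int]
    discordant: set[str]

    def __post_init__(self) -> None:
        if set(self.concordant) | self.discordant != self.common:
            raise ValueError("concordant and discordant must partition common")
        if set(self.concordant) & self.discordant:
            raise ValueError("concordant and discordant overlap")

    def tally(self) -> dict[str, int]:
        up = sum(1 for d in self.concordant.values() if d == 1)
        return {
            "common": len(self.common),
            "concordant": len(self.concordant),
            "discordant": len(self.discordant),
            "concordant_up": up,
            "concordant_down": len(self.concordant) - up,
        }
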