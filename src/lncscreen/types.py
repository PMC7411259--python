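"""Shared domain containers.

Coordinates are 0-based half-open throughout; file writers convert to the
1-based conventions of their formats at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BIOTYPES = ("coding", "lncRNA")
STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene: identifier, biotype, and genomic interval.

    ``exons`` is an optional tuple of (start, end) intervals inside the gene
    body; genes without an exon list are treated as single-exon downstream.
    """

    id: str
    biotype: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.id}")
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r} for {self.id}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.id}"
            )
        if self.exons is not None:
            for s, e in self.exons:
                if not (self.start <= s < e <= self.end):
                    raise ValueError(
                        f"exon [{s}, {e}) outside gene body of {self.id}"
                    )

    @property
    def five_prime(self) -> int:
        """5' end position (start on '+', end on '-')."""
        return self.start if self.strand == "+" else self.end

    def exon_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exons, with the whole body standing in when none are annotated."""
        if self.exons:
            return tuple(sorted(self.exons))
        return ((self.start, self.end),)

    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        exons = self.exon_intervals()
        return tuple(
            (a_end, b_start)
            for (_, a_end), (b_start, _) in zip(exons, exons[1:])
            if a_end < b_start
        )


@dataclass
class CountMatrix:
    """Integer gene x sample count table with per-sample timepoint labels."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame  # indexed by sample id, column "timepoint"

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            raise ValueError("duplicated gene ids in count matrix")
        if c.columns.duplicated().any():
            raise ValueError("duplicated sample ids in count matrix")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
            self.counts = c.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "timepoint" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'timepoint' column")
        missing = set(c.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"sample_meta missing samples: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def timepoints(self) -> list[str]:
        """Timepoint labels in first-appearance (sample sheet) order."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(str(self.sample_meta.loc[s, "timepoint"]), None)
        return list(seen)

    def samples_for(self, timepoint: str) -> list[str]:
        return [
            s
            for s in self.sample_ids
            if str(self.sample_meta.loc[s, "timepoint"]) == str(timepoint)
        ]


@dataclass
class ContrastResult:
    """Per-gene statistics for one time contrast plus the screened sets.

    ``table`` is indexed by gene id with columns base_mean, log2fc, p, fdr,
    direction. Genes untestable in this contrast (zero counts on both sides)
    carry NaN p/fdr and direction "ns"; they are excluded from the BH
    denominator.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame

    @property
    def name(self) -> str:
        return f"{self.contrast[0]}_vs_{self.contrast[1]}"

    @property
    def up(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "up"])

    @property
    def down(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["direction"] == "down"])


@dataclass(frozen=True)
class CommonSet:
    """Direction-consistent intersection across all contrasts.

    ``mixed`` holds genes significant everywhere but with inconsistent
    direction; the three sets are pairwise disjoint and partition the set of
    everywhere-significant genes.
    """

    common_up: frozenset[str]
    common_down: frozenset[str]
    mixed: frozenset[str]
    venn_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.common_up & self.common_down
            or self.common_up & self.mixed
            or self.common_down & self.mixed
        ):
            raise ValueError("common_up/common_down/mixed must be disjoint")


@dataclass
class GeneSetCollection:
    """Named gene sets over an explicit background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    kind: str = "term"  # "term" | "tf_targets"

    def __post_init__(self) -> None:
        self.sets = {str(k): frozenset(v) for k, v in self.sets.items()}
        self.universe = frozenset(self.universe)

    def restricted(self) -> "GeneSetCollection":
        """Collection with every set intersected with the universe."""
        return GeneSetCollection(
            {k: v & self.universe for k, v in self.sets.items()},
            self.universe,
            self.kind,
        )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class Module:
    """A dense subnetwork found by the MCODE-style procedure."""

    members: frozenset[str]
    seed: str
    density: float
    score: float

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("module seed must be a member")
        if not (0.0 <= self.density <= 1.0):
            raise ValueError("density must lie in [0, 1]")


def as_feature_frame(features: Iterable[GeneFeature]) -> pd.DataFrame:
    """Tabular view of a feature list (one row per gene, indexed by id)."""
    rows = [
        (f.id, f.biotype, f.chrom, f.strand, f.start, f.end)
        for f in features
    ]
    return pd.DataFrame(
        rows, columns=["id", "biotype", "chrom", "strand", "start", "end"]
    ).set_index("id")
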