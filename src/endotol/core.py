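"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere; BED is the native convention
and any 1-based input is converted at parse time. Probe and gene identifiers
are opaque, case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) with optional strand and name."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +,-,., got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PWM:
    """Position weight matrix with log-odds scoring.

    Counts are stored row-per-base in A,C,G,T order. Scoring uses
    log2((count + pseudocount) / (column_total + 4 * pseudocount)) minus
    log2(background) per column.
    """

    def __init__(
        self,
        name: str,
        counts: np.ndarray,
        pseudocount: float = 0.25,
        background: Iterable[float] = (0.25, 0.25, 0.25, 0.25),
    ) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix (A,C,G,T rows)")
        if counts.shape[1] < 1:
            raise ValueError("PWM must have at least one column")
        if (counts < 0).any():
            raise ValueError("PWM counts must be non-negative")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        background = np.asarray(list(background), dtype=float)
        if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be 4 probabilities summing to 1")
        self.name = name
        self.counts = counts
        self.pseudocount = float(pseudocount)
        self.background = background

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x L matrix of per-base log2 odds against the background."""
        col_tot = self.counts.sum(axis=0) + 4 * self.pseudocount
        probs = (self.counts + self.pseudocount) / col_tot
        return np.log2(probs) - np.log2(self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PWM({self.name!r}, L={self.length})"


class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, per-set unique genes."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self.sets: dict[str, tuple[str, ...]] = {}
        self.descriptions: dict[str, str] = {}
        for name, genes in sets.items():
            seen: dict[str, None] = {}
            for g in genes:
                if not g:
                    raise ValueError(f"empty gene id in set {name!r}")
                seen.setdefault(g, None)
            if not seen:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = tuple(seen)
            self.descriptions[name] = (descriptions or {}).get(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class SampleSheet:
    """Sample metadata: unique sample ids, condition label, donor id."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample", "condition", "donor")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.frame["sample"].duplicated().any():
            dups = self.frame["sample"][self.frame["sample"].duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dups))}")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.frame["sample"].astype(str))

    def subset(self, conditions: Iterable[str]) -> "SampleSheet":
        keep = self.frame["condition"].isin(list(conditions))
        if not keep.any():
            raise ValueError(f"no samples with conditions {list(conditions)}")
        return SampleSheet(self.frame.loc[keep].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)
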