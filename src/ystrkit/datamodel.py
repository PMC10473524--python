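"""In-memory haplotype data model.

A :class:`HaplotypeTable` holds one row per male with a population label and
one cell per panel locus.  Cell values:

* ``float``            — a repeat count at a single-copy locus (microvariants
                         carry a fractional part, e.g. ``17.2``);
* ``None``             — missing / deleted allele;
* ``tuple of floats``  — at a multi-copy locus (DYS385): the unphased pair,
                         sorted ascending; at a single-copy locus: a
                         duplication record (>= 2 observed alleles), kept
                         verbatim so the duplicated-haplotype filter can act
                         on it.

Missingness is an explicit ``None``, never a sentinel number; the "99" /
blank / "NA" input codes are translated at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ystrkit.panels import KitPanel

#: fractional parts allowed for microvariant repeat counts
ALLOWED_MICROVARIANT_FRACTIONS = (0.0, 0.1, 0.2, 0.3)

MISSING_TOKENS = {"99", "99.0", "", "na", "nan", "?"}


def validate_allele(value: float, *, where: str = "") -> float:
    """Validate a repeat count: non-negative, one decimal place, fractional
    part one of the STR microvariant conventions (.1/.2/.3)."""
    v = round(float(value), 1)
    if v < 0:
        raise ValueError(f"negative repeat count {value!r} {where}".strip())
    frac = round(v - int(v), 1)
    if frac not in ALLOWED_MICROVARIANT_FRACTIONS:
        raise ValueError(
            f"allele {value!r} {where}: fractional part .{int(frac * 10)} is not a "
            f"recognised microvariant (.1/.2/.3)".strip()
        )
    return v


def is_microvariant(value: float | None) -> bool:
    """True for a repeat count with an incomplete repeat unit (e.g. 17.2)."""
    if value is None:
        return False
    return abs(round(value) - value) > 1e-9


@dataclass(frozen=True)
class FilterReport:
    """Accounting for the duplicated-allele haplotype filter."""

    n_input: int
    n_removed_duplicated: int
    n_retained: int
    removed_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_duplicated + self.n_retained:
            raise ValueError("filter report counts do not add up")


class HaplotypeTable:
    """Samples x loci matrix of Y-STR repeat counts with population labels."""

    def __init__(
        self,
        sample_ids: list[str],
        populations: list[str],
        alleles: pd.DataFrame,
        panel: KitPanel,
        metadata: pd.DataFrame | None = None,
    ) -> None:
        if not (len(sample_ids) == len(populations) == len(alleles)):
            raise ValueError("sample_ids, populations and allele matrix disagree in length")
        if tuple(alleles.columns) != tuple(panel.loci):
            raise ValueError(
                f"allele columns {tuple(alleles.columns)} do not match panel loci {panel.loci}"
            )
        self.sample_ids = list(sample_ids)
        self.populations = list(populations)
        self.alleles = alleles.reset_index(drop=True)
        self.panel = panel
        #: optional per-sample annotations (e.g. a stored haplogroup column)
        self.metadata = (
            metadata.reset_index(drop=True)
            if metadata is not None
            else pd.DataFrame(index=range(len(sample_ids)))
        )

    # -- basic protocol ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __repr__(self) -> str:
        return (
            f"HaplotypeTable(n={len(self)}, panel={self.panel.name!r}, "
            f"populations={sorted(set(self.populations))})"
        )

    def copy(self) -> "HaplotypeTable":
        return HaplotypeTable(
            list(self.sample_ids),
            list(self.populations),
            self.alleles.copy(),
            self.panel,
            self.metadata.copy(),
        )

    def equal_alleles(self, other: "HaplotypeTable") -> bool:
        """Cell-wise equality of the allele matrices (missing == missing)."""
        if self.alleles.shape != other.alleles.shape:
            return False
        return all(
            a == b or (a is None and b is None)
            for a, b in zip(
                self.alleles.to_numpy().ravel(), other.alleles.to_numpy().ravel()
            )
        )

    # -- row selection -----------------------------------------------------

    def take(self, idx: list[int]) -> "HaplotypeTable":
        return HaplotypeTable(
            [self.sample_ids[i] for i in idx],
            [self.populations[i] for i in idx],
            self.alleles.iloc[idx].reset_index(drop=True),
            self.panel,
            self.metadata.iloc[idx].reset_index(drop=True),
        )

    def by_population(self) -> dict[str, "HaplotypeTable"]:
        """Split into per-population tables, preserving row order."""
        out: dict[str, HaplotypeTable] = {}
        for pop in dict.fromkeys(self.populations):
            idx = [i for i, p in enumerate(self.populations) if p == pop]
            out[pop] = self.take(idx)
        return out

    # -- completeness and numeric views --------------------------------------

    def has_duplication(self, row: int) -> bool:
        """True if any single-copy locus of ``row`` carries >= 2 alleles."""
        for locus in self.panel.loci:
            if locus in self.panel.multi_copy:
                continue
            if isinstance(self.alleles.at[row, locus], tuple):
                return True
        return False

    def complete_rows(self, loci: tuple[str, ...] | None = None) -> list[int]:
        """Indices of rows with no missing allele at ``loci`` (default: all)."""
        loci = loci or self.panel.loci
        sub = self.alleles[list(loci)]
        return [i for i in range(len(self)) if not any(v is None for v in sub.iloc[i])]

    def haplotype_tuples(
        self, loci: tuple[str, ...] | None = None
    ) -> list[tuple | None]:
        """Per-row haplotype identity: tuple over ``loci`` with the DYS385
        pair kept as a sorted sub-tuple; ``None`` where any allele is missing."""
        loci = loci or self.panel.loci
        out: list[tuple | None] = []
        for i in range(len(self)):
            vals = []
            ok = True
            for locus in loci:
                v = self.alleles.at[i, locus]
                if v is None:
                    ok = False
                    break
                vals.append(v)
            out.append(tuple(vals) if ok else None)
        return out

    def integer_matrix(self, loci: tuple[str, ...]) -> tuple[np.ndarray, list[int]]:
        """Complete rows as an integer repeat-count matrix over single-copy
        ``loci`` (microvariants rounded half away from zero).

        Returns ``(matrix, row_indices)``; rows with missing data or a
        duplication at any requested locus are dropped.
        """
        for locus in loci:
            if locus in self.panel.multi_copy:
                raise ValueError(
                    f"{locus} is multi-copy; per-copy differences are ill-defined"
                )
        rows, kept = [], []
        for i in range(len(self)):
            vals = []
            ok = True
            for locus in loci:
                v = self.alleles.at[i, locus]
                if v is None or isinstance(v, tuple):
                    ok = False
                    break
                vals.append(round_half_away(v))
            if ok:
                rows.append(vals)
                kept.append(i)
        return np.asarray(rows, dtype=np.int64).reshape(len(kept), len(loci)), kept


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (17.5 -> 18, -0.5 -> -1)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x != 0 else 0
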