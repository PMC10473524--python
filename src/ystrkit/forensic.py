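"""Forensic and population-genetic summary statistics for Y-STR data.

Per-locus quantities are computed from the allele frequency spectrum:
gene diversity GD = 1 - sum(p_i^2), its n/(n-1) unbiased variant,
polymorphism information content (PIC), and the locus match probability
sum(p_i^2).  Per-haplotype quantities follow Nei's unbiased haplotype
diversity HD = n (1 - sum(p_i^2)) / (n - 1) with p_i the haplotype
frequencies by the counting method, the match probability MP = sum(p_i^2),
the discrimination capacity DC = h/n with h the number of different
haplotypes, and the haplotype match probability HMP = 1 - HD.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from ystrkit.datamodel import HaplotypeTable
from ystrkit.io import subset_kit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FreqSpectrum:
    """Allele frequency spectrum of one locus (alleles sorted ascending)."""

    locus: str
    counts: dict[float, int]
    n: int = field(init=False)
    frequencies: dict[float, float] = field(init=False)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError(f"locus {self.locus}: no observations")
        ordered = dict(sorted(self.counts.items()))
        object.__setattr__(self, "counts", ordered)
        n = sum(ordered.values())
        object.__setattr__(self, "n", n)
        object.__setattr__(
            self, "frequencies", {a: c / n for a, c in ordered.items()}
        )

    @property
    def n_alleles(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LocusDiversity:
    locus: str
    GD: float
    GD_corrected: float | None
    PIC: float
    MP_locus: float
    n_alleles: int


@dataclass(frozen=True)
class ForensicSummary:
    n: int
    h_distinct: int
    h_unique: int
    HD: float
    MP: float
    DC: float
    HMP: float
    n_excluded_incomplete: int = 0

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "h_distinct": self.h_distinct,
            "h_unique": self.h_unique,
            "HD": self.HD,
            "MP": self.MP,
            "DC": self.DC,
            "DC_percent": 100.0 * self.DC,
            "HMP": self.HMP,
            "n_excluded_incomplete": self.n_excluded_incomplete,
        }


def allele_frequencies(table: HaplotypeTable, locus: str) -> FreqSpectrum:
    """Allele frequency spectrum of one locus.

    Missing alleles are excluded; each multi-copy (DYS385) male contributes
    two observations.  Duplication records at single-copy loci are excluded
    (they should have been filtered upstream).
    """
    if locus not in table.panel.loci:
        raise KeyError(f"locus {locus!r} not in panel {table.panel.name!r}")
    counts: Counter[float] = Counter()
    multi = locus in table.panel.multi_copy
    for v in table.alleles[locus]:
        if v is None:
            continue
        if isinstance(v, tuple):
            if multi:
                counts.update(v)
            # single-copy duplication record: skip
        else:
            counts[v] += 1
    if not counts:
        raise ValueError(f"locus {locus}: no observations")
    return FreqSpectrum(locus, dict(counts))


def gene_diversity(spec: FreqSpectrum, corrected: bool = False) -> LocusDiversity:
    """Locus diversity summary from a frequency spectrum.

    GD is the plain 1 - sum(p^2); ``corrected`` adds the n/(n-1) unbiased
    scaling as a separate field.  PIC = 1 - sum(p^2) - (sum(p^2))^2 + sum(p^4).
    """
    p = list(spec.frequencies.values())
    sum_p2 = sum(x * x for x in p)
    sum_p4 = sum(x**4 for x in p)
    gd = 1.0 - sum_p2
    gd_corr = None
    if corrected:
        if spec.n < 2:
            raise ValueError(f"locus {spec.locus}: n/(n-1) correction needs n >= 2")
        gd_corr = spec.n / (spec.n - 1) * gd
    pic = 1.0 - sum_p2 - sum_p2 * sum_p2 + sum_p4
    return LocusDiversity(
        locus=spec.locus,
        GD=gd,
        GD_corrected=gd_corr,
        PIC=pic,
        MP_locus=sum_p2,
        n_alleles=spec.n_alleles,
    )


def locus_diversity_table(table: HaplotypeTable, corrected: bool = False) -> list[LocusDiversity]:
    """Per-locus diversity summaries for every panel locus."""
    return [
        gene_diversity(allele_frequencies(table, locus), corrected=corrected)
        for locus in table.panel.loci
    ]


def haplotype_summary(table: HaplotypeTable) -> ForensicSummary:
    """Haplotype-level forensic summary over complete profiles.

    Haplotype identity is the tuple of alleles over every panel locus, with
    the DYS385 pair compared as a sorted pair.  Rows with a missing allele
    (or an unfiltered duplication record) are excluded with a logged count:
    forensic haplotype counting requires complete profiles.
    """
    haps = [h for h in table.haplotype_tuples() if h is not None]
    n_excluded = len(table) - len(haps)
    if n_excluded:
        logger.info("haplotype_summary: excluded %d incomplete profiles", n_excluded)
    n = len(haps)
    if n < 2:
        raise ValueError(f"need >= 2 complete profiles, have {n}")
    counts = Counter(haps)
    mp = sum((c / n) ** 2 for c in counts.values())
    hd = n * (1.0 - mp) / (n - 1)
    h_distinct = len(counts)
    return ForensicSummary(
        n=n,
        h_distinct=h_distinct,
        h_unique=sum(1 for c in counts.values() if c == 1),
        HD=hd,
        MP=mp,
        DC=h_distinct / n,
        HMP=1.0 - hd,
        n_excluded_incomplete=n_excluded,
    )


def kit_comparison(
    table: HaplotypeTable, subset: tuple[str, ...]
) -> tuple[ForensicSummary, ForensicSummary]:
    """Forensic summaries for the full panel and a locus subset on the same rows.

    Used to quantify what a reduced kit (e.g. Yfiler17) loses relative to
    the full panel: the subset can only merge haplotypes, so its distinct
    count, HD and DC are bounded by the full panel's.
    """
    full = haplotype_summary(table)
    reduced = haplotype_summary(subset_kit(table, subset))
    return full, reduced
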