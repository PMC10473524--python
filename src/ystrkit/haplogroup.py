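"""Bayesian haplogroup prediction from Y-STR haplotypes.

A Y haplogroup is a SNP-defined paternal lineage; because Y-STR alleles
drift within lineages, the haplogroup of a male can be predicted from his
STR haplotype given per-haplogroup allele frequency tables.  The score of
haplogroup g for haplotype x is

    score_g = prior_g * prod_l f_{g,l}(x_l)

and the reported probability is the posterior 100 * score_g / sum(scores).
A goodness-of-fit ("fitness") score guards against confidently assigning a
haplotype that fits every candidate poorly: it is defined here as 100 times
the geometric mean over loci of the allele's frequency relative to the
modal allele of that haplogroup,

    fitness_g = 100 * (prod_l f_{g,l}(x_l) / max_a f_{g,l}(a)) ** (1/L).

A haplotype is assigned to the top haplogroup only when the posterior
probability and the fitness both clear their thresholds (defaults 85 and
15); otherwise it is reported as UNPREDICTED.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ystrkit.datamodel import HaplotypeTable, is_microvariant

logger = logging.getLogger(__name__)

UNPREDICTED = "UNPREDICTED"


def synthetic_frequency_table_path() -> Path:
    """Path of the bundled SYNTHETIC haplogroup frequency fixture.

    Five haplogroups x fifteen loci of invented allele frequency profiles
    for tests and demos; it does not reproduce any real reference database.
    """
    return Path(__file__).parent / "data" / "synthetic_haplogroup_freqs.csv"

#: loci excluded from prediction by default: DYS533 for lack of reference
#: allele-frequency data; DYS543 is accepted in configs for interoperability
#: although it is not a PowerPlex Y23 locus (DYS643 is the Y23-specific
#: marker most often also absent from reference tables and can be added).
DEFAULT_EXCLUDED_LOCI = ("DYS533", "DYS543")

DEFAULT_THRESHOLDS = (85.0, 15.0)  # (min posterior %, min fitness)


@dataclass(frozen=True)
class HaplogroupFrequencyTable:
    """Per-haplogroup, per-locus allele frequency distributions with priors.

    ``smoothing`` is the pseudo-frequency mass reserved for alleles unseen
    in a (haplogroup, locus) distribution; each distribution is renormalised
    so that seen alleles plus the unseen bucket sum to one.  A single unseen
    allele therefore down-weights, but never zeroes out, a haplogroup.
    """

    haplogroups: tuple[str, ...]
    distributions: dict[tuple[str, str], dict[float, float]]
    priors: dict[str, float]
    smoothing: float = 0.001
    loci: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.smoothing <= 0:
            raise ValueError("smoothing must be > 0")
        loci = tuple(dict.fromkeys(l for _, l in self.distributions))
        object.__setattr__(self, "loci", loci)
        for hg in self.haplogroups:
            if not any(h == hg for h, _ in self.distributions):
                raise ValueError(f"haplogroup {hg!r} has no loci")
        total_prior = sum(self.priors.values())
        if total_prior <= 0:
            raise ValueError("priors must have positive mass")
        object.__setattr__(
            self, "priors", {h: p / total_prior for h, p in self.priors.items()}
        )

    def frequency(self, haplogroup: str, locus: str, allele: float) -> float:
        """Smoothed, normalised frequency of ``allele``; unseen alleles get
        the smoothing mass.  Microvariants absent from the table fall back to
        the rounded integer allele (logged)."""
        dist = self.distributions[(haplogroup, locus)]
        total = sum(dist.values()) + self.smoothing
        if allele in dist:
            return dist[allele] / total
        if is_microvariant(allele):
            fallback = float(round(allele))
            if fallback in dist:
                logger.info(
                    "microvariant %.1f at %s absent from %s table; using integer allele %g",
                    allele,
                    locus,
                    haplogroup,
                    fallback,
                )
                return dist[fallback] / total
        return self.smoothing / total

    def modal_frequency(self, haplogroup: str, locus: str) -> float:
        dist = self.distributions[(haplogroup, locus)]
        total = sum(dist.values()) + self.smoothing
        return max(dist.values()) / total


def load_frequency_table(
    path: str | Path,
    priors: str | Path = "uniform",
    smoothing: float = 0.001,
) -> HaplogroupFrequencyTable:
    """Load a long-format frequency CSV (haplogroup, locus, allele, frequency).

    ``priors`` is ``"uniform"`` or a path to a two-column CSV
    (haplogroup, weight), e.g. weights attuned to a regional reference
    population.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"haplogroup", "locus", "allele", "frequency"}
    if not required <= set(df.columns):
        raise ValueError(f"frequency table needs columns {sorted(required)}")
    if (df["frequency"] < 0).any():
        bad = df[df["frequency"] < 0].iloc[0]
        raise ValueError(
            f"negative frequency for {bad['haplogroup']}/{bad['locus']}/{bad['allele']}"
        )
    dists: dict[tuple[str, str], dict[float, float]] = {}
    for (hg, locus), grp in df.groupby(["haplogroup", "locus"]):
        dists[(str(hg), str(locus))] = dict(
            zip(grp["allele"].astype(float), grp["frequency"].astype(float))
        )
    haplogroups = tuple(dict.fromkeys(str(h) for h in df["haplogroup"]))
    if isinstance(priors, (str, Path)) and str(priors) == "uniform":
        prior_map = {h: 1.0 for h in haplogroups}
    else:
        pdf = pd.read_csv(priors)
        prior_map = dict(
            zip(pdf.iloc[:, 0].astype(str), pdf.iloc[:, 1].astype(float))
        )
        missing = set(haplogroups) - set(prior_map)
        if missing:
            raise ValueError(f"priors file lacks haplogroups: {sorted(missing)}")
    return HaplogroupFrequencyTable(haplogroups, dists, prior_map, smoothing)


@dataclass(frozen=True)
class HaplogroupPrediction:
    best: str
    probability: float  # posterior % of the best haplogroup
    fitness: float  # goodness-of-fit score of the best haplogroup
    per_haplogroup: dict[str, float]  # posterior %, sums to 100
    loci_used: int


def predict_haplogroup(
    haplotype: dict[str, float],
    ft: HaplogroupFrequencyTable,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    exclude_loci: tuple[str, ...] = DEFAULT_EXCLUDED_LOCI,
) -> HaplogroupPrediction:
    """Predict the haplogroup of one haplotype (map locus -> repeat count).

    Multi-copy loci (tuple values), excluded loci, missing alleles and loci
    absent from the frequency table are dropped; at least one usable locus
    must remain.
    """
    loci = [
        l
        for l in ft.loci
        if l not in exclude_loci
        and l in haplotype
        and haplotype[l] is not None
        and not isinstance(haplotype[l], tuple)
    ]
    if not loci:
        raise ValueError("no usable loci overlap between haplotype and frequency table")
    log_scores: dict[str, float] = {}
    log_fit: dict[str, float] = {}
    for hg in ft.haplogroups:
        ls = math.log(ft.priors[hg]) if ft.priors[hg] > 0 else -math.inf
        lf = 0.0
        for locus in loci:
            f = ft.frequency(hg, locus, float(haplotype[locus]))
            ls += math.log(f)
            lf += math.log(f / ft.modal_frequency(hg, locus))
        log_scores[hg] = ls
        log_fit[hg] = lf
    top = max(log_scores.values())
    weights = {h: math.exp(s - top) for h, s in log_scores.items()}
    z = sum(weights.values())
    posterior = {h: 100.0 * w / z for h, w in weights.items()}
    best = max(posterior, key=lambda h: (posterior[h], h))
    fitness = 100.0 * math.exp(log_fit[best] / len(loci))
    prob = posterior[best]
    assigned = best if (prob > thresholds[0] and fitness > thresholds[1]) else UNPREDICTED
    return HaplogroupPrediction(assigned, prob, fitness, posterior, len(loci))


def batch_predict(
    table: HaplotypeTable,
    ft: HaplogroupFrequencyTable,
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    exclude_loci: tuple[str, ...] = DEFAULT_EXCLUDED_LOCI,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict every row; returns (per-sample predictions, tally summary).

    Rows that fail (e.g. no usable loci) are reported with best=UNPREDICTED
    and a note, never fatally.
    """
    records = []
    for i in range(len(table)):
        hap = {l: table.alleles.at[i, l] for l in table.panel.loci}
        try:
            pred = predict_haplogroup(hap, ft, thresholds, exclude_loci)
            records.append(
                {
                    "SampleID": table.sample_ids[i],
                    "Population": table.populations[i],
                    "Haplogroup": pred.best,
                    "Probability": pred.probability,
                    "Fitness": pred.fitness,
                    "LociUsed": pred.loci_used,
                    "Note": "",
                }
            )
        except ValueError as exc:
            records.append(
                {
                    "SampleID": table.sample_ids[i],
                    "Population": table.populations[i],
                    "Haplogroup": UNPREDICTED,
                    "Probability": float("nan"),
                    "Fitness": float("nan"),
                    "LociUsed": 0,
                    "Note": str(exc),
                }
            )
    preds = pd.DataFrame(records)
    summary = haplogroup_tally(preds["Haplogroup"].tolist() if len(preds) else [])
    return preds, summary


def haplogroup_tally(labels: list[str]) -> pd.DataFrame:
    """Counts and percentages per haplogroup label (UNPREDICTED included)."""
    counts = Counter(labels)
    n = sum(counts.values())
    rows = [
        {"Haplogroup": hg, "Count": c, "Percent": 100.0 * c / n if n else 0.0}
        for hg, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["Haplogroup", "Count", "Percent"])


def microvariant_crosstab(
    table: HaplotypeTable, locus: str, haplogroup_labels: list[str]
) -> pd.DataFrame:
    """Cross-tabulate microvariant carriers at ``locus`` by haplogroup.

    A carrier is a male whose allele at ``locus`` has a fractional repeat
    (e.g. 17.2 at DYS458).  Returns counts and the percentage of carriers in
    each haplogroup; empty when no carriers exist.
    """
    if locus not in table.panel.loci:
        raise KeyError(f"locus {locus!r} not in panel")
    if len(haplogroup_labels) != len(table):
        raise ValueError("haplogroup labels must align with table rows")
    carriers: Counter[str] = Counter()
    for i in range(len(table)):
        v = table.alleles.at[i, locus]
        vals = v if isinstance(v, tuple) else (v,)
        if any(is_microvariant(x) for x in vals if x is not None):
            carriers[haplogroup_labels[i]] += 1
    total = sum(carriers.values())
    rows = [
        {"Haplogroup": hg, "Carriers": c, "PercentOfCarriers": 100.0 * c / total}
        for hg, c in sorted(carriers.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["Haplogroup", "Carriers", "PercentOfCarriers"])
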