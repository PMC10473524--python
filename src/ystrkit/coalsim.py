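"""Structured-coalescent simulation of Y-STR haplotypes.

Because the Y chromosome does not recombine, every locus of a male shares
ONE genealogy; the simulator draws a single structured-coalescent tree per
replicate and drops independent stepwise mutations on it per locus.  Time
is measured in mutational units (1/mu generations), so the per-locus
mutation rate is exactly 1 and the parameters match Migrate-style scaling:
Theta_i = 2 N_i mu per deme and M[i][j] = m/mu, the backward-in-time rate
at which a lineage currently in deme i jumps to deme j.

Four gene-flow model topologies are supported:

* ``unidirectional_flow`` — demes of unbounded age coupled by one-way
  migration (no common-ancestor event; the migration graph must still let
  every lineage reach a common deme);
* ``divergence_only``     — isolated demes merging into one ancestral deme
  at time tau;
* ``divergence_plus_migration`` — migration active until the merge at tau;
* ``panmixia``            — all samples drawn from a single deme
  (migration ignored; deme labels kept for bookkeeping).

Mutations follow the strict single-step model: each mutation shifts the
repeat count by +/-1 with probability 1/2 (alleles reflected at 1).
``bayes_factor_rank`` provides the model-comparison arithmetic on log
marginal likelihoods computed elsewhere (log Bayes factor = difference of
log marginal likelihoods).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ystrkit.datamodel import HaplotypeTable
from ystrkit.panels import KitPanel

MODELS = (
    "unidirectional_flow",
    "divergence_only",
    "divergence_plus_migration",
    "panmixia",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated Y-STR study."""

    sample_sizes: tuple[int, ...]
    theta: tuple[float, ...]
    model: str = "panmixia"
    migration: tuple[tuple[float, ...], ...] | None = None
    divergence_time: float | None = None
    ancestral_theta: float | None = None
    loci: tuple[str, ...] = tuple(f"L{i + 1}" for i in range(17))
    root_alleles: tuple[int, ...] = ()
    deme_names: tuple[str, ...] = ()
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        d = len(self.sample_sizes)
        if len(self.theta) != d:
            raise ValueError("theta must have one entry per deme")
        if any(t <= 0 for t in self.theta):
            raise ValueError("Theta must be > 0 in every deme")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.migration is not None:
            M = np.asarray(self.migration, dtype=float)
            if M.shape != (d, d):
                raise ValueError("migration matrix must be d x d")
            if (M < 0).any() or np.diag(M).any():
                raise ValueError("migration rates must be >= 0 with a zero diagonal")
        if self.model in ("divergence_only", "divergence_plus_migration"):
            if self.divergence_time is None or self.divergence_time <= 0:
                raise ValueError(f"model {self.model!r} needs divergence_time > 0")
        if not self.root_alleles:
            object.__setattr__(self, "root_alleles", (14,) * len(self.loci))
        if len(self.root_alleles) != len(self.loci):
            raise ValueError("root_alleles must align with loci")
        if not self.deme_names:
            object.__setattr__(
                self, "deme_names", tuple(f"deme{i}" for i in range(d))
            )
        if len(self.deme_names) != d:
            raise ValueError("deme_names must align with sample_sizes")

    @property
    def n_demes(self) -> int:
        return len(self.sample_sizes)

    def migration_matrix(self) -> np.ndarray:
        if self.model in ("panmixia", "divergence_only") or self.migration is None:
            return np.zeros((self.n_demes, self.n_demes))
        return np.asarray(self.migration, dtype=float)

    def validate_coalescible(self) -> None:
        """Fail fast for configurations that can never fully coalesce."""
        if self.model != "unidirectional_flow":
            return
        M = self.migration_matrix()
        d = self.n_demes
        sampled = [i for i in range(d) if self.sample_sizes[i] > 0]
        reach = [{i} for i in range(d)]
        for _ in range(d):
            for i in range(d):
                for j in range(d):
                    if M[i, j] > 0:
                        reach[i] |= reach[j]
        if not any(all(t in reach[s] for s in sampled) for t in range(d)):
            raise ValueError(
                "lineages cannot reach a common deme: no divergence event and "
                "the migration graph has no deme reachable from every sampled deme"
            )

    def to_dict(self) -> dict:
        return {
            "sample_sizes": list(self.sample_sizes),
            "theta": list(self.theta),
            "model": self.model,
            "migration": [list(r) for r in self.migration] if self.migration else None,
            "divergence_time": self.divergence_time,
            "ancestral_theta": self.ancestral_theta,
            "loci": list(self.loci),
            "root_alleles": list(self.root_alleles),
            "deme_names": list(self.deme_names),
            "replicates": self.replicates,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("sample_sizes", "theta", "loci", "root_alleles", "deme_names"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        if d.get("migration") is not None:
            d["migration"] = tuple(tuple(r) for r in d["migration"])
        return cls(**{k: v for k, v in d.items() if v is not None})


@dataclass
class Genealogy:
    """A single coalescent tree: 2n-1 nodes, tips 0..n-1 at time 0."""

    parent: np.ndarray  # parent index, -1 at the root
    time: np.ndarray  # node times in mutational units
    tip_deme: np.ndarray  # deme index per tip
    n_migrations: int

    @property
    def n_tips(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def tmrca(self) -> float:
        return float(self.time[-1])


def simulate_genealogy(config: SimConfig, rng: np.random.Generator) -> Genealogy:
    """Draw one structured-coalescent genealogy under the configured model.

    Backward in time, with k_i lineages in deme i each unordered pair
    coalesces at rate 2/Theta_i and each lineage migrates i->j at rate
    M[i][j]; under the divergence models every lineage moves to the
    ancestral deme at time tau (Theta = ``ancestral_theta`` or the mean of
    the deme Thetas from then on).
    """
    config.validate_coalescible()
    d = config.n_demes
    n = sum(config.sample_sizes)
    if config.model == "panmixia":
        theta = [float(config.theta[0])]
        lineages: list[list[int]] = [list(range(n))]
        M = np.zeros((1, 1))
    else:
        theta = [float(t) for t in config.theta]
        lineages = []
        nid = 0
        for i in range(d):
            lineages.append(list(range(nid, nid + config.sample_sizes[i])))
            nid += config.sample_sizes[i]
        M = config.migration_matrix()

    tip_deme = np.concatenate(
        [np.full(sz, i, dtype=np.int64) for i, sz in enumerate(config.sample_sizes)]
    )
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    times = np.zeros(2 * n - 1)
    tau = (
        config.divergence_time
        if config.model in ("divergence_only", "divergence_plus_migration")
        else None
    )
    merged = tau is None
    t = 0.0
    next_node = n
    n_migrations = 0
    while sum(len(l) for l in lineages) > 1:
        coal = [len(l) * (len(l) - 1) / th for l, th in zip(lineages, theta)]
        mig = (
            np.array(
                [
                    [len(lineages[i]) * M[i, j] for j in range(len(lineages))]
                    for i in range(len(lineages))
                ]
            )
            if M.any()  # zeroed once demes merge at tau
            else None
        )
        total = sum(coal) + (mig.sum() if mig is not None else 0.0)
        if total > 0.0:
            dt = rng.exponential(1.0 / total)
            if merged or t + dt < tau:
                t += dt
                u = rng.uniform(0.0, total)
                acc = 0.0
                done = False
                for i, c in enumerate(coal):
                    acc += c
                    if u < acc:
                        k = len(lineages[i])
                        a, b = rng.choice(k, size=2, replace=False)
                        la, lb = lineages[i][int(a)], lineages[i][int(b)]
                        parent[la] = parent[lb] = next_node
                        times[next_node] = t
                        lineages[i] = [x for x in lineages[i] if x not in (la, lb)]
                        lineages[i].append(next_node)
                        next_node += 1
                        done = True
                        break
                if not done and mig is not None:
                    u -= sum(coal)
                    flat = mig.ravel().cumsum()
                    idx = int(np.searchsorted(flat, u, side="right"))
                    i, j = divmod(idx, len(lineages))
                    k = rng.integers(len(lineages[i]))
                    lineages[j].append(lineages[i].pop(int(k)))
                    n_migrations += 1
                continue
        elif merged:  # unreachable given validate_coalescible
            raise RuntimeError("no events possible; genealogy cannot complete")
        # reached tau: merge every lineage into the ancestral deme
        t = tau
        anc_theta = config.ancestral_theta or float(np.mean(config.theta))
        lineages = [[x for l in lineages for x in l]]
        theta = [anc_theta]
        merged = True
        M = np.zeros((1, 1))
    return Genealogy(parent, times, tip_deme, n_migrations)


def drop_mutations(
    g: Genealogy, config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place stepwise mutations on the shared genealogy for every locus.

    Per locus, mutations arrive as a Poisson process of rate 1 per unit
    branch length (time is in 1/mu units) and each shifts the repeat count
    by +/-1 with probability 1/2.  Returns ``(tip_alleles, mutation_counts)``
    of shapes (n_tips, n_loci) and (n_loci,).  Tip alleles are reflected at
    repeat count 1 (rare under sane Theta).
    """
    n_nodes = len(g.parent)
    n = g.n_tips
    L = len(config.loci)
    branch = np.where(g.parent >= 0, g.time[g.parent] - g.time, 0.0)
    nmut = rng.poisson(branch[:, None], size=(n_nodes, L))
    net = 2 * rng.binomial(nmut, 0.5) - nmut
    alleles = np.zeros((n_nodes, L), dtype=np.int64)
    alleles[-1] = np.asarray(config.root_alleles, dtype=np.int64)
    order = np.argsort(g.time)[::-1]  # root first; every parent precedes its children
    for node in order:
        p = g.parent[node]
        if p >= 0:
            alleles[node] = alleles[p] + net[node]
    tips = alleles[:n]
    under = tips < 1
    while under.any():
        tips[under] = 2 - tips[under]
        under = tips < 1
    return tips, nmut.sum(axis=0)


@dataclass(frozen=True)
class SimTruth:
    """Generative truth of one simulated dataset, for recovery tests."""

    config: dict
    tmrca: float
    n_migrations: int
    mutation_counts: tuple[int, ...]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "tmrca": self.tmrca,
                    "n_migrations": self.n_migrations,
                    "mutation_counts": list(self.mutation_counts),
                },
                indent=2,
            )
        )


def sim_panel(config: SimConfig) -> KitPanel:
    return KitPanel(name="simulated", loci=tuple(config.loci))


def simulate_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypeTable, SimTruth]:
    """Simulate one replicate as a standard :class:`HaplotypeTable`.

    Reproducible: the same config (including seed) yields an identical
    table.  Deme names become population labels.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    g = simulate_genealogy(config, rng)
    tips, mut_counts = drop_mutations(g, config, rng)
    panel = sim_panel(config)
    alleles = pd.DataFrame(
        [[float(v) for v in row] for row in tips],
        columns=list(panel.loci),
        dtype=object,
    )
    sample_ids = [f"S{i + 1:04d}" for i in range(tips.shape[0])]
    populations = [config.deme_names[d] for d in g.tip_deme]
    table = HaplotypeTable(sample_ids, populations, alleles, panel)
    truth = SimTruth(
        config=config.to_dict(),
        tmrca=g.tmrca,
        n_migrations=g.n_migrations,
        mutation_counts=tuple(int(c) for c in mut_counts),
    )
    return table, truth


def simulate_replicates(config: SimConfig, rng: np.random.Generator):
    """Yield ``(tip_alleles, tip_demes, genealogy)`` per replicate.

    Lean array path for Monte-Carlo studies (no DataFrame overhead)."""
    for _ in range(config.replicates):
        g = simulate_genealogy(config, rng)
        tips, _ = drop_mutations(g, config, rng)
        yield tips, g.tip_deme, g


# ---------------------------------------------------------------------------
# post-hoc corruption operators (exercise IO and filtering paths)


def inject_missing(table: HaplotypeTable, prob: float, seed: int) -> HaplotypeTable:
    """Set each allele cell to missing with probability ``prob`` (seeded)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for i in range(len(out)):
        for locus in out.panel.loci:
            if rng.random() < prob:
                out.alleles.at[i, locus] = None
    return out


def inject_duplications(table: HaplotypeTable, prob: float, seed: int) -> HaplotypeTable:
    """Give each haplotype, with probability ``prob``, a duplicated allele at
    one random single-copy locus (seeded).

    Models the locus-duplication artefacts that
    :func:`ystrkit.io.filter_duplicated_alleles` removes: the cell becomes a
    record of two alleles one repeat apart.
    """
    rng = np.random.default_rng(seed)
    single = [l for l in table.panel.loci if l not in table.panel.multi_copy]
    if not single:
        raise ValueError("panel has no single-copy loci to duplicate")
    out = table.copy()
    for i in range(len(out)):
        if rng.random() >= prob:
            continue
        locus = single[int(rng.integers(len(single)))]
        v = out.alleles.at[i, locus]
        if isinstance(v, float):
            out.alleles.at[i, locus] = (v, v + 1.0)
    return out


def inject_microvariants(
    table: HaplotypeTable, prob: float, seed: int, fraction: float = 0.2
) -> HaplotypeTable:
    """Turn integer alleles into microvariants (e.g. 17 -> 17.2) with
    probability ``prob`` per cell (seeded)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for i in range(len(out)):
        for locus in out.panel.loci:
            v = out.alleles.at[i, locus]
            if isinstance(v, float) and rng.random() < prob:
                out.alleles.at[i, locus] = round(v + fraction, 1)
    return out


# ---------------------------------------------------------------------------
# Bayes-factor model ranking


def bayes_factor_rank(models: dict[str, float]) -> list[dict]:
    """Rank gene-flow models/routes by log marginal likelihood.

    Returns a list sorted best-first with ``log_bf`` = log(ml_best) -
    log(ml_model) >= 0 (0 for the best model); ties are ordered by name.
    """
    if len(models) < 2:
        raise ValueError("need >= 2 models to compare")
    for name, lml in models.items():
        if not np.isfinite(lml):
            raise ValueError(f"model {name!r} has non-finite log marginal likelihood")
    best = max(models.values())
    ranked = sorted(models.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        {"model": name, "log_ml": float(lml), "log_bf": float(best - lml), "rank": r + 1}
        for r, (name, lml) in enumerate(ranked)
    ]
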