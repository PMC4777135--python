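"""Synthetic open-pollinated (OP) family test data.

Emulates the structure of a conifer OP progeny trial: unrelated founder
dams, each producing a family of wind-pollinated offspring that is
conventionally *assumed* to consist of maternal half-sibs, planted in a
randomized complete block design.  Two contamination mechanisms break
the half-sib assumption the way real OP families do:

* ``selfing_rate`` — an offspring is produced by selfing the dam;
* ``repeated_sire_rate`` — an offspring shares its sire with the
  previous sibling, creating hidden full-sibs.

Phenotypes are generated under the additive + dominance +
additive×additive variance structure the multi-kernel mixed models
estimate, plus replication (block), replication×family and residual
effects.  Genetic effect sizes are rescaled *post hoc* so the realized
variance of each genetic component equals its target exactly, which
makes parameter-recovery experiments sharp.

Defaults mirror a single-site spruce trial: 214 OP families of ~8
offspring over 6 blocks, several thousand SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .kernels import ConfigurationError, GenotypeMatrix, AlleleFrequencyVector

__all__ = [
    "SimulationConfig",
    "TruthSet",
    "SimulatedDataset",
    "simulate_founders",
    "simulate_op_progeny",
    "simulate_phenotypes",
    "simulate_dataset",
]

GENETIC_TERMS = ("additive", "dominance", "add_x_add")
DESIGN_TERMS = ("replication", "rep_x_family", "residual")


def _default_variance_targets() -> dict[str, float]:
    # roughly the proportions seen in conifer height trials:
    # h2 ~ 0.25 with modest block and plot effects
    return {
        "additive": 1.0,
        "dominance": 0.0,
        "add_x_add": 0.0,
        "replication": 0.25,
        "rep_x_family": 1.0,
        "residual": 3.0,
    }


@dataclass
class SimulationConfig:
    """Parameters of the OP-family generator.

    ``pollen_pool_size`` candidate sires exist per family; a "fresh"
    pollen draw picks a not-yet-used candidate while any remain, so with
    zero contamination and a pool at least as large as the family, all
    sibs are true maternal half-sibs.
    """

    n_parents: int = 214
    n_families: int = 214
    offspring_per_family: int = 8
    n_blocks: int = 6
    n_loci: int = 3000
    maf_range: tuple[float, float] = (0.05, 0.5)
    pollen_pool_size: int = 20
    selfing_rate: float = 0.05
    repeated_sire_rate: float = 0.10
    variance_targets: dict[str, float] = field(default_factory=_default_variance_targets)
    n_dominance_loci: int = 300
    n_epistatic_pairs: int = 2000
    trait_name: str = "trait"
    trait_mean: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families > self.n_parents:
            raise ConfigurationError("n_families cannot exceed n_parents")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be at least 1")
        if self.offspring_per_family < 1:
            raise ConfigurationError("offspring_per_family must be at least 1")
        if self.n_blocks < 1:
            raise ConfigurationError("n_blocks must be at least 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for rate in (self.selfing_rate, self.repeated_sire_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError("rates must be probabilities in [0, 1]")
        if self.pollen_pool_size < 1 and self.selfing_rate < 1.0:
            raise ConfigurationError(
                "pollen_pool_size must be positive unless selfing_rate is 1"
            )
        targets = dict(_default_variance_targets())
        targets.update(self.variance_targets)
        unknown = set(targets) - set(GENETIC_TERMS) - set(DESIGN_TERMS)
        if unknown:
            raise ConfigurationError(f"unknown variance targets {sorted(unknown)}")
        if any(v < 0 for v in targets.values()):
            raise ConfigurationError("variance targets must be non-negative")
        self.variance_targets = targets

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, salt]))


@dataclass
class TruthSet:
    """Ground truth recorded by the generator for recovery experiments."""

    true_pedigree: pd.DataFrame  # id, dam, sire (actual sire, may equal dam)
    true_breeding_value: pd.Series | None = None
    true_dominance_deviation: pd.Series | None = None
    true_epistatic_value: pd.Series | None = None
    realized_variances: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    founders: GenotypeMatrix
    founder_frequencies: AlleleFrequencyVector
    genotypes: GenotypeMatrix  # progeny only
    phenotypes: pd.DataFrame  # id, family, block, <trait>
    assumed_pedigree: pd.DataFrame  # id, dam, sire='' (half-sib assumption)
    truth: TruthSet


# ---------------------------------------------------------------------------

def _hwe_genotypes(rng: np.random.Generator, n: int, p: np.ndarray) -> np.ndarray:
    return rng.binomial(2, p[None, :], size=(n, p.size)).astype(float)


def simulate_founders(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, AlleleFrequencyVector]:
    """Draw an unrelated founder panel in HWE.

    Founders comprise ``n_parents`` dams plus a per-family pollen pool
    of ``pollen_pool_size`` candidate sires.  Each locus gets a founder
    allele frequency drawn uniformly from ``maf_range``; dosages are
    binomial(2, p) per individual.
    """
    rng = config.rng(salt=1)
    lo, hi = config.maf_range
    p = rng.uniform(lo, hi, size=config.n_loci)
    dam_ids = [f"D{i+1:04d}" for i in range(config.n_parents)]
    sire_ids = [
        f"S{f+1:04d}_{j+1:03d}"
        for f in range(config.n_families)
        for j in range(config.pollen_pool_size)
    ]
    ids = dam_ids + sire_ids
    dosages = _hwe_genotypes(rng, len(ids), p)
    loci = [f"L{i+1:05d}" for i in range(config.n_loci)]
    founders = GenotypeMatrix(ids, loci, dosages)
    freqs = AlleleFrequencyVector(loci, p)
    return founders, freqs


def _gametes(rng: np.random.Generator, parents: np.ndarray) -> np.ndarray:
    """One transmitted allele per locus per row, Mendelian, loci unlinked."""
    het = parents == 1.0
    allele = (parents == 2.0).astype(float)
    allele[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    return allele


def simulate_op_progeny(
    founders: GenotypeMatrix, config: SimulationConfig
) -> tuple[GenotypeMatrix, TruthSet]:
    """Mate dams to wind-borne pollen, with hidden-relatedness contamination.

    Per offspring the sire is (a) the dam itself with probability
    ``selfing_rate``, else (b) the previous sibling's sire with
    probability ``repeated_sire_rate``, else (c) a fresh draw from the
    family's pollen pool.  The true pedigree records actual sires; the
    half-sib *assumption* (sire unknown) lives in the assumed pedigree.
    """
    rng = config.rng(salt=2)
    pos = {s: i for i, s in enumerate(founders.sample_ids)}
    dam_ids = [f"D{i+1:04d}" for i in range(config.n_parents)]
    ped_rows: list[tuple[str, str, str]] = []
    dam_of: list[int] = []
    sire_of: list[int] = []
    for f in range(config.n_families):
        dam = dam_ids[f]
        pool = [f"S{f+1:04d}_{j+1:03d}" for j in range(config.pollen_pool_size)]
        unused = list(pool)
        prev_sire: str | None = None
        for j in range(config.offspring_per_family):
            if rng.random() < config.selfing_rate:
                sire = dam
            elif prev_sire is not None and rng.random() < config.repeated_sire_rate:
                sire = prev_sire
            else:
                if unused:
                    k = int(rng.integers(len(unused)))
                    sire = unused.pop(k)
                else:
                    sire = pool[int(rng.integers(len(pool)))]
            prev_sire = sire
            child = f"F{f+1:04d}_{j+1:03d}"
            ped_rows.append((child, dam, sire))
            dam_of.append(pos[dam])
            sire_of.append(pos[sire])
    dam_g = founders.dosages[np.array(dam_of)]
    sire_g = founders.dosages[np.array(sire_of)]
    dosages = _gametes(rng, dam_g) + _gametes(rng, sire_g)
    progeny = GenotypeMatrix(
        [r[0] for r in ped_rows], founders.locus_ids, dosages
    )
    truth = TruthSet(
        true_pedigree=pd.DataFrame(ped_rows, columns=["id", "dam", "sire"])
    )
    return progeny, truth


def _rescale(values: np.ndarray, target: float) -> np.ndarray:
    """Scale to exact sample variance ``target`` (zeros if target is 0)."""
    if target <= 0.0:
        return np.zeros_like(values)
    sd = values.std(ddof=1)
    if sd == 0.0:
        raise ConfigurationError(
            "cannot rescale a constant genetic-value vector to positive variance"
        )
    centered = values - values.mean()
    return centered * np.sqrt(target) / sd


def simulate_phenotypes(
    progeny: GenotypeMatrix,
    truth: TruthSet,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthSet]:
    """Layer genetic values and design effects onto the progeny.

    Additive values are linear in centered dosages; dominance values are
    heterozygote effects at ``n_dominance_loci`` random loci; epistatic
    values are products of centered dosages at ``n_epistatic_pairs``
    random locus pairs.  Each genetic component is rescaled so its
    realized variance equals the target exactly.  Families are spread
    round-robin across blocks.
    """
    rng = config.rng(salt=3)
    targets = config.variance_targets
    n = progeny.n_samples
    M = progeny.dosages
    Zc = M - M.mean(axis=0)

    alpha = rng.normal(size=progeny.n_loci)
    a = _rescale(Zc @ alpha, targets["additive"])

    n_dom = min(config.n_dominance_loci, progeny.n_loci)
    dom_loci = rng.choice(progeny.n_loci, size=n_dom, replace=False)
    het = (M[:, dom_loci] == 1.0).astype(float)
    het -= het.mean(axis=0)
    d = _rescale(het @ rng.normal(size=n_dom), targets["dominance"])

    pairs = rng.integers(0, progeny.n_loci, size=(config.n_epistatic_pairs, 2))
    prod = Zc[:, pairs[:, 0]] * Zc[:, pairs[:, 1]]
    aa = _rescale(prod @ rng.normal(size=config.n_epistatic_pairs), targets["add_x_add"])

    fam = truth.true_pedigree.set_index("id").loc[progeny.sample_ids, "dam"]
    # round-robin block allocation within family, family-specific offset
    # so block totals stay balanced
    blocks = np.empty(n, dtype=int)
    start = 0
    for _, idx in pd.Series(range(n), index=fam.values).groupby(level=0, sort=False):
        k = idx.values
        blocks[k] = (start + np.arange(k.size)) % config.n_blocks
        start += k.size
    block_labels = np.array([f"B{b+1}" for b in blocks])

    block_eff = rng.normal(0.0, np.sqrt(targets["replication"]), size=config.n_blocks)
    cells = pd.unique(pd.Series(block_labels) + "|" + fam.values)
    cell_eff = dict(
        zip(cells, rng.normal(0.0, np.sqrt(targets["rep_x_family"]), size=len(cells)))
    )
    rxf = np.array([cell_eff[b + "|" + f] for b, f in zip(block_labels, fam.values)])
    resid = rng.normal(0.0, np.sqrt(targets["residual"]), size=n)

    y = config.trait_mean + a + d + aa + block_eff[blocks] + rxf + resid
    phen = pd.DataFrame(
        {
            "id": progeny.sample_ids,
            "family": fam.values,
            "block": block_labels,
            config.trait_name: y,
        }
    )
    ids = pd.Index(progeny.sample_ids)
    truth.true_breeding_value = pd.Series(a, index=ids, name="true_breeding_value")
    truth.true_dominance_deviation = pd.Series(
        d, index=ids, name="true_dominance_deviation"
    )
    truth.true_epistatic_value = pd.Series(aa, index=ids, name="true_epistatic_value")
    truth.realized_variances = {
        "additive": float(np.var(a, ddof=1)),
        "dominance": float(np.var(d, ddof=1)),
        "add_x_add": float(np.var(aa, ddof=1)),
        "replication": targets["replication"],
        "rep_x_family": targets["rep_x_family"],
        "residual": targets["residual"],
    }
    return phen, truth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: founders → OP progeny → phenotypes."""
    founders, freqs = simulate_founders(config)
    progeny, truth = simulate_op_progeny(founders, config)
    phen, truth = simulate_phenotypes(progeny, truth, config)
    # half-sib assumption: dams known founders, sires unknown
    dams = pd.DataFrame(
        {"id": sorted(set(truth.true_pedigree["dam"])), "dam": "", "sire": ""}
    )
    offspring = truth.true_pedigree[["id", "dam"]].copy()
    offspring["sire"] = ""
    assumed = pd.concat([dams, offspring], ignore_index=True)
    return SimulatedDataset(
        config=config,
        founders=founders,
        founder_frequencies=freqs,
        genotypes=progeny,
        phenotypes=phen,
        assumed_pedigree=assumed,
        truth=truth,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["maf_range"] = list(d["maf_range"])
    return d
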