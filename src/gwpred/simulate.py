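"""QTLMAS2010-style quantitative-trait simulator.

Generates a multi-generation pedigree, drops founder haplotypes down it with
recombination (gene dropping), and builds a continuous trait from a mixed
QTL architecture:

* 2 additive major genes and 28 random minor genes whose effects are drawn
  from a truncated normal distribution;
* 3 maternally imprinted genes — the maternal copy is silenced, so only the
  paternally inherited allele contributes;
* 2 epistatic pairs with no individual (marginal) effects — the interaction
  term is the product of centered allele codes, residualized against both
  single-locus codings so its sample correlation with each locus is exactly
  zero;
* one dominance, one over-dominance and one under-dominance locus.

Founder haplotypes are sampled from a small ancestral pool, which induces
linkage disequilibrium that decays with map distance as recombination breaks
ancestral segments. Meiosis uses a Haldane-type model: the chance of a
crossover between adjacent markers at map distance d Morgans is
0.5 * (1 - exp(-2d)).

The environmental variance is calibrated per replicate so that the realized
narrow-sense heritability — Var(additive component) / Var(phenotype), with
the non-additive components counted only in the denominator — hits the
configured target (default 0.45). At the default scale of 3,226 individuals
the realized value fluctuates by well under 0.01 around the target.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; identical configs give identical output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import GenotypeMatrix, write_genotypes, write_phenotypes

logger = logging.getLogger("gwpred")

__all__ = [
    "ArchitectureSpec",
    "SimConfig",
    "QTL",
    "EpistaticPair",
    "DominanceLocus",
    "QTLArchitecture",
    "SimOutput",
    "simulate_pedigree",
    "simulate_genotypes",
    "assign_architecture",
    "simulate_phenotypes",
    "simulate",
    "export",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Counts and effect-size knobs for the trait architecture.

    Effect-size defaults are scale choices, not estimates: minor effects are
    truncated normal (mean 0, sd 1, bounds +-2) and the controlled major
    classes get fixed magnitudes a few times the minor sd, keeping the
    non-additive variance small enough that the narrow-sense heritability
    target stays reachable.
    """

    n_additive_major: int = 2
    n_imprinted: int = 3
    n_epistatic_pairs: int = 2
    n_minor: int = 28
    major_effect_size: float = 3.0
    imprinted_effect_size: float = 2.0
    epistatic_effect_size: float = 2.0
    minor_mean: float = 0.0
    minor_sd: float = 1.0
    minor_bounds: tuple[float, float] = (-2.0, 2.0)
    # (type, additive value a, heterozygote value d); genotype-value maps are
    # {0:0, 1:d, 2:a} for dominance and {0:0, 1:d, 2:0} for over/under
    dominance_loci: tuple[tuple[str, float, float], ...] = (
        ("dominance", 2.0, 2.0),
        ("overdominance", 0.0, 1.5),
        ("underdominance", 0.0, -1.5),
    )
    min_maf: float = 0.05

    @property
    def n_qtl(self) -> int:
        return (
            self.n_additive_major
            + self.n_imprinted
            + 2 * self.n_epistatic_pairs
            + self.n_minor
        )

    @property
    def n_special_loci(self) -> int:
        return self.n_qtl + len(self.dominance_loci)


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 3,226 individuals in 5 generations, 10,000
    markers on 10 one-Morgan chromosomes, founder pool of 20 haplotypes,
    37-QTL architecture plus 3 dominance-class loci, target h^2 = 0.45."""

    generation_sizes: tuple[int, ...] = (100, 626, 800, 800, 900)
    n_offspring_per_mating: int = 2
    n_markers: int = 10_000
    n_chromosomes: int = 10
    chrom_length_morgans: float = 1.0
    founder_haplotype_pool: int = 20
    architecture: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    target_h2: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_h2 < 1.0:
            raise ValueError("target_h2 must be in (0, 1)")
        if len(self.generation_sizes) < 1 or any(
            s < 1 for s in self.generation_sizes
        ):
            raise ValueError("generation_sizes must be positive")
        if self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one marker and one chromosome")
        if self.founder_haplotype_pool < 2:
            raise ValueError("founder pool needs at least 2 haplotypes")

    @property
    def n_founders(self) -> int:
        return self.generation_sizes[0]

    @property
    def n_generations(self) -> int:
        return len(self.generation_sizes)

    @property
    def n_individuals(self) -> int:
        return int(sum(self.generation_sizes))


@dataclass(frozen=True)
class QTL:
    index: int  # 0-based marker column
    kind: str  # additive_major | minor | imprinted
    effect: float


@dataclass(frozen=True)
class EpistaticPair:
    index_a: int
    index_b: int
    effect: float


@dataclass(frozen=True)
class DominanceLocus:
    index: int
    kind: str  # dominance | overdominance | underdominance
    a: float
    d: float


@dataclass
class QTLArchitecture:
    """Realized architecture: marker columns chosen and effects drawn."""

    additive: list[QTL]
    imprinted: list[QTL]
    epistatic_pairs: list[EpistaticPair]
    dominance: list[DominanceLocus]

    def all_indices(self) -> list[int]:
        idx = [q.index for q in self.additive + self.imprinted]
        for pr in self.epistatic_pairs:
            idx += [pr.index_a, pr.index_b]
        idx += [d.index for d in self.dominance]
        return idx


@dataclass
class SimOutput:
    genotypes: GenotypeMatrix
    paternal_alleles: np.ndarray  # n x p, allele inherited from the sire
    phenotypes: np.ndarray
    pedigree: pd.DataFrame
    architecture: QTLArchitecture
    components: dict[str, np.ndarray]  # additive/imprinted/epistatic/dominance
    residual: np.ndarray
    realized_h2: float


# ---------------------------------------------------------------------------
# Pedigree

def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Random-mating pedigree; parents drawn from the previous generation.

    Returns columns (individual, sire, dam, generation), 1-based individual
    numbers, 0 for unknown (founder) parents. Matings produce
    ``n_offspring_per_mating`` full sibs; no selfing (sire != dam).
    """
    rows = []
    next_id = 1
    prev_gen_ids: list[int] = []
    for g, size in enumerate(cfg.generation_sizes, start=1):
        ids = list(range(next_id, next_id + size))
        next_id += size
        if g == 1:
            for i in ids:
                rows.append((i, 0, 0, g))
        else:
            if len(prev_gen_ids) < 2:
                raise ValueError(
                    f"generation {g - 1} has fewer than 2 individuals; no matings possible"
                )
            fam = max(1, cfg.n_offspring_per_mating)
            n_matings = -(-size // fam)  # ceil
            prev = np.asarray(prev_gen_ids)
            sires = prev[rng.integers(0, prev.size, n_matings)]
            dams = prev[rng.integers(0, prev.size, n_matings)]
            clash = sires == dams
            while clash.any():  # redraw dams to forbid selfing
                dams[clash] = prev[rng.integers(0, prev.size, int(clash.sum()))]
                clash = sires == dams
            for k, i in enumerate(ids):
                m = k // fam
                rows.append((i, int(sires[m]), int(dams[m]), g))
        prev_gen_ids = ids
    return pd.DataFrame(rows, columns=["individual", "sire", "dam", "generation"])


# ---------------------------------------------------------------------------
# Gene dropping

def _switch_probabilities(cfg: SimConfig) -> np.ndarray:
    """Per-marker probability that a gamete switches parental haplotype
    before this marker; 0.5 at each chromosome start (independent segments),
    Haldane 0.5*(1-exp(-2d)) between adjacent markers within a chromosome."""
    base = cfg.n_markers // cfg.n_chromosomes
    sizes = [base + (1 if c < cfg.n_markers % cfg.n_chromosomes else 0)
             for c in range(cfg.n_chromosomes)]
    probs = np.empty(cfg.n_markers)
    pos = 0
    for mc in sizes:
        if mc == 0:
            continue
        d = cfg.chrom_length_morgans / max(mc - 1, 1)
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        probs[pos] = 0.5
        probs[pos + 1 : pos + mc] = r
        pos += mc
    return probs


def _gametes(
    parent_haps: np.ndarray, switch_prob: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per parent row. ``parent_haps`` is (B, 2, m)."""
    B, _, m = parent_haps.shape
    switches = rng.random((B, m)) < switch_prob
    parity = np.cumsum(switches, axis=1) & 1  # 0 -> haplotype 0, 1 -> haplotype 1
    return np.where(parity == 0, parent_haps[:, 0, :], parent_haps[:, 1, :])


def simulate_genotypes(
    cfg: SimConfig, pedigree: pd.DataFrame, rng: np.random.Generator
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Drop founder-pool haplotypes down the pedigree with recombination.

    Founder haplotypes are drawn (with replacement) from a pool of
    ``founder_haplotype_pool`` ancestral haplotypes whose allele frequencies
    are uniform on (0.1, 0.9); the finite pool induces LD along chromosomes.
    Returns the 0/1/2 code matrix and the matrix of paternally inherited
    alleles (parental-origin tracking for imprinting).
    """
    n = len(pedigree)
    m = cfg.n_markers
    freq = rng.uniform(0.1, 0.9, m)
    pool = (rng.random((cfg.founder_haplotype_pool, m)) < freq).astype(np.int8)
    switch_prob = _switch_probabilities(cfg)

    haps = np.zeros((n, 2, m), dtype=np.int8)  # slot 0 = paternal
    gen = pedigree["generation"].to_numpy()
    sire = pedigree["sire"].to_numpy()
    dam = pedigree["dam"].to_numpy()
    founders = np.flatnonzero(gen == 1)
    draw = rng.integers(0, cfg.founder_haplotype_pool, (founders.size, 2))
    haps[founders, 0, :] = pool[draw[:, 0]]
    haps[founders, 1, :] = pool[draw[:, 1]]

    for g in range(2, cfg.n_generations + 1):
        kids = np.flatnonzero(gen == g)
        s_rows = sire[kids] - 1  # ids are 1-based
        d_rows = dam[kids] - 1
        haps[kids, 0, :] = _gametes(haps[s_rows], switch_prob, rng)
        haps[kids, 1, :] = _gametes(haps[d_rows], switch_prob, rng)

    codes = haps.sum(axis=1, dtype=np.int8)
    gmat = GenotypeMatrix(
        codes,
        individual_ids=[str(i) for i in pedigree["individual"]],
        marker_ids=[f"M{j + 1}" for j in range(m)],
    )
    return gmat, haps[:, 0, :].copy()


# ---------------------------------------------------------------------------
# Architecture

def assign_architecture(
    cfg: SimConfig, genotypes: GenotypeMatrix, rng: np.random.Generator
) -> QTLArchitecture:
    """Pick distinct polymorphic marker columns and draw the QTL effects.

    All chosen loci have MAF >= ``min_maf`` so every QTL class segregates.
    Controlled classes (majors, imprinted, epistatic, dominance) use fixed
    magnitudes with random sign; minor effects come from the truncated
    normal spec.
    """
    spec = cfg.architecture
    f = genotypes.allele_frequencies()
    candidates = np.flatnonzero(np.minimum(f, 1 - f) >= spec.min_maf)
    need = spec.n_special_loci
    if candidates.size < need:
        raise ValueError(
            f"only {candidates.size} markers with MAF >= {spec.min_maf}; "
            f"need {need} for the architecture"
        )
    chosen = rng.choice(candidates, size=need, replace=False)
    it = iter(chosen)

    def take(k):
        return [int(next(it)) for _ in range(k)]

    sign = lambda: float(rng.choice([-1.0, 1.0]))
    additive = [
        QTL(i, "additive_major", sign() * spec.major_effect_size)
        for i in take(spec.n_additive_major)
    ]
    lo = (spec.minor_bounds[0] - spec.minor_mean) / spec.minor_sd
    hi = (spec.minor_bounds[1] - spec.minor_mean) / spec.minor_sd
    minor_eff = stats.truncnorm.rvs(
        lo, hi, loc=spec.minor_mean, scale=spec.minor_sd,
        size=spec.n_minor, random_state=rng,
    )
    additive += [QTL(i, "minor", float(e)) for i, e in zip(take(spec.n_minor), minor_eff)]
    imprinted = [
        QTL(i, "imprinted", sign() * spec.imprinted_effect_size)
        for i in take(spec.n_imprinted)
    ]
    pairs = [
        EpistaticPair(*take(2), effect=sign() * spec.epistatic_effect_size)
        for _ in range(spec.n_epistatic_pairs)
    ]
    dominance = [
        DominanceLocus(i, kind, a, d)
        for (kind, a, d), i in zip(spec.dominance_loci, take(len(spec.dominance_loci)))
    ]
    arch = QTLArchitecture(additive, imprinted, pairs, dominance)
    assert len(set(arch.all_indices())) == need
    return arch


# ---------------------------------------------------------------------------
# Phenotypes

def _epistatic_component(
    pairs: list[EpistaticPair], codes: np.ndarray
) -> np.ndarray:
    """Interactions with no individual effects.

    Each pair contributes the product of its centered allele codes; the
    products are then residualized against [1, codes of every epistatic
    locus], so the summed component has exactly zero sample correlation with
    each constituent single-locus coding — the realized-sample analogue of
    "epistatic genes with no individual effects".
    """
    n = codes.shape[0]
    if not pairs:
        return np.zeros(n)
    loci = [i for pr in pairs for i in (pr.index_a, pr.index_b)]
    D = np.column_stack([np.ones(n)] + [codes[:, i] for i in loci])
    comp = np.zeros(n)
    for pr in pairs:
        x1, x2 = codes[:, pr.index_a], codes[:, pr.index_b]
        comp += pr.effect * (x1 - x1.mean()) * (x2 - x2.mean())
    coef, *_ = np.linalg.lstsq(D, comp, rcond=None)
    return comp - D @ coef


_DOM_MAPS = {
    "dominance": lambda a, d: np.array([0.0, d, a]),
    "overdominance": lambda a, d: np.array([0.0, d, 0.0]),
    "underdominance": lambda a, d: np.array([0.0, d, 0.0]),
}


def simulate_phenotypes(
    cfg: SimConfig,
    genotypes: GenotypeMatrix,
    paternal_alleles: np.ndarray,
    arch: QTLArchitecture,
    rng: np.random.Generator,
) -> SimOutput:
    """Build the trait from its genetic components plus calibrated noise.

    The residual variance is set so that Var(additive)/Var(phenotype)
    equals ``target_h2`` in expectation, where the additive component is the
    sum over major and minor QTLs of effect * code; imprinted, epistatic and
    dominance components count only toward total variance (narrow sense).
    """
    codes = genotypes.codes.astype(float)
    n = genotypes.n_individuals

    additive = np.zeros(n)
    for q in arch.additive:
        additive += q.effect * codes[:, q.index]
    imprinted = np.zeros(n)
    for q in arch.imprinted:
        imprinted += q.effect * paternal_alleles[:, q.index].astype(float)
    epistatic = _epistatic_component(arch.epistatic_pairs, codes)
    dominance = np.zeros(n)
    for dl in arch.dominance:
        table = _DOM_MAPS[dl.kind](dl.a, dl.d)
        dominance += table[genotypes.codes[:, dl.index]]

    genetic = additive + imprinted + epistatic + dominance
    var_a = float(np.var(additive))
    if var_a == 0:
        raise ValueError("zero additive variance — cannot calibrate heritability")
    sigma2_e = var_a / cfg.target_h2 - float(np.var(genetic))
    if sigma2_e <= 0:
        raise ValueError(
            "non-additive variance too large to reach the target narrow-sense "
            f"heritability {cfg.target_h2}"
        )
    residual = rng.normal(0.0, np.sqrt(sigma2_e), n)
    y = genetic + residual
    realized_h2 = var_a / float(np.var(y))
    logger.info("simulated phenotypes: realized h2 = %.4f", realized_h2)
    return SimOutput(
        genotypes=genotypes,
        paternal_alleles=paternal_alleles,
        phenotypes=y,
        pedigree=None,  # filled by simulate()
        architecture=arch,
        components={
            "additive": additive,
            "imprinted": imprinted,
            "epistatic": epistatic,
            "dominance": dominance,
        },
        residual=residual,
        realized_h2=realized_h2,
    )


def simulate(cfg: SimConfig) -> SimOutput:
    """Full run: pedigree -> gene dropping -> architecture -> phenotypes."""
    rng = np.random.default_rng(cfg.seed)
    ped = simulate_pedigree(cfg, rng)
    gmat, paternal = simulate_genotypes(cfg, ped, rng)
    arch = assign_architecture(cfg, gmat, rng)
    out = simulate_phenotypes(cfg, gmat, paternal, arch, rng)
    out.pedigree = ped
    return out


# ---------------------------------------------------------------------------
# Export

def export(sim: SimOutput, path: str | Path) -> None:
    """Write genotypes/phenotypes in the data_io delimited layout plus truth
    files (per-QTL effects, per-individual components) for recovery tests."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    write_genotypes(sim.genotypes, path / "genotypes.txt")
    write_phenotypes(sim.phenotypes, path / "phenotypes.txt")

    rows = []
    for q in sim.architecture.additive + sim.architecture.imprinted:
        rows.append({"index": q.index, "kind": q.kind, "effect": q.effect,
                     "partner": "", "a": "", "d": ""})
    for pr in sim.architecture.epistatic_pairs:
        rows.append({"index": pr.index_a, "kind": "epistatic", "effect": pr.effect,
                     "partner": pr.index_b, "a": "", "d": ""})
    for dl in sim.architecture.dominance:
        rows.append({"index": dl.index, "kind": dl.kind, "effect": "",
                     "partner": "", "a": dl.a, "d": dl.d})
    pd.DataFrame(rows).to_csv(path / "truth_effects.csv", index=False)

    comp = pd.DataFrame(
        {"individual": sim.genotypes.individual_ids, **sim.components,
         "residual": sim.residual, "phenotype": sim.phenotypes}
    )
    comp.to_csv(path / "truth_components.csv", index=False)
    if sim.pedigree is not None:
        sim.pedigree.to_csv(path / "pedigree.csv", index=False)
    with open(path / "summary.json", "w") as fh:
        json.dump(
            {
                "n_individuals": sim.genotypes.n_individuals,
                "n_markers": sim.genotypes.n_markers,
                "realized_h2": sim.realized_h2,
            },
            fh,
            indent=2,
        )
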