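"""Simulation of experimental-cross genotypes and discrete phenotypes.

Genotypes are generated chromosome by chromosome as a first-order Markov chain
over loci: the genotype at the first locus is a fair draw between the two
parental classes, and the class switches between adjacent loci with probability
equal to the Haldane recombination fraction of the inter-locus distance
(doubled for recombinant inbred lines, r* = 2r/(1+2r); two independent gamete
chains for an F2).  Phenotypes are drawn from the chosen GLM family with mean
g^{-1}(mu0 + sum_j x_ij b_j) computed from the *true* QTL genotypes, which are
stored alongside the marker data but withheld from the mapper.

``ten_qtl_scenario`` builds the standard benchmark used throughout the test
suite: a backcross of six 100 cM chromosomes, 11 evenly spaced markers each,
and ten QTLs with fixed positions and effects spanning large (2.0) to small
(-0.22) values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import Chromosome, GeneticMap, cumulative_position, map_distance_to_recomb
from .glmfam import GLMFamily, make_family

__all__ = [
    "QTL",
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
    "simulate_null",
    "ten_qtl_scenario",
    "TRUE_GENOME_POSITIONS",
    "TRUE_EFFECTS",
]

DESIGNS = ("backcross", "DH", "RIL", "F2")

# the 10-QTL benchmark: genome-wide positions (cM) and additive effects
TRUE_GENOME_POSITIONS = (23.0, 56.0, 148.0, 193.0, 267.0, 332.0, 390.0, 478.0, 522.0, 574.0)
TRUE_EFFECTS = (1.5, 2.0, 0.72, 1.1, -0.22, 0.70, -0.65, 1.25, 0.35, -0.80)


@dataclass(frozen=True)
class QTL:
    chrom: str
    pos_cM: float
    additive: float
    dominance: float | None = None


@dataclass(frozen=True)
class SimulationSpec:
    design: str
    gmap: GeneticMap
    qtls: tuple
    family_name: str = "binomial"
    link_name: str | None = None
    mu0: float = 0.0
    n: int = 200
    binomial_trials: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.design not in DESIGNS:
            raise ValueError(f"design must be one of {DESIGNS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.binomial_trials < 1:
            raise ValueError("binomial_trials must be >= 1")
        for q in self.qtls:
            chrom = self.gmap.chromosome(q.chrom)
            lo, hi = chrom.marker_pos_cM[0], chrom.marker_pos_cM[-1]
            if not (lo <= q.pos_cM <= hi):
                raise ValueError(f"QTL at {q.chrom}:{q.pos_cM} outside chromosome span")
            if q.dominance is not None and self.design != "F2":
                raise ValueError("dominance effects are only meaningful for an F2 design")

    @property
    def family(self) -> GLMFamily:
        return make_family(self.family_name, self.link_name)

    def qtl_genome_positions(self):
        return np.array(
            [cumulative_position(self.gmap, q.chrom, q.pos_cM) for q in self.qtls]
        )


@dataclass
class SimulatedDataset:
    spec: SimulationSpec
    marker_genotypes: np.ndarray  # n x m coded matrix
    qtl_genotypes: np.ndarray     # n x q coded (additive coding), truth
    phenotypes: np.ndarray
    qtl_dom_genotypes: np.ndarray | None = None


def _switch_prob(d_cM, design):
    r = map_distance_to_recomb(d_cM)
    if design == "RIL":
        r = 2.0 * r / (1.0 + 2.0 * r)
    return r


def _simulate_chain(rng, n, positions, design):
    """Markov chain of parental-class states (0/1) at the given positions.

    F2 individuals are two independent gamete chains; the returned matrix then
    holds allele counts in {0, 1, 2}.
    """
    n_gametes = 2 if design == "F2" else 1
    L = len(positions)
    out = np.zeros((n, L), dtype=np.int8)
    for _ in range(n_gametes):
        states = np.zeros((n, L), dtype=np.int8)
        states[:, 0] = rng.random(n) < 0.5
        for k in range(1, L):
            r = _switch_prob(positions[k] - positions[k - 1], design)
            flip = rng.random(n) < r
            states[:, k] = np.where(flip, 1 - states[:, k - 1], states[:, k - 1])
        out += states
    return out


def simulate_genotypes(spec: SimulationSpec, rng=None):
    """Simulate linked genotypes at all markers and all QTL positions.

    Returns ``(marker_genotypes, qtl_add, qtl_dom)``.  Backcross/DH/RIL
    genotypes are coded +1/-1 for the two classes; F2 additive codes are
    +1/0/-1 for QQ/Qq/qq with the dominance indicator 1 for the heterozygote.
    ``qtl_dom`` is None outside the F2 design.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n
    marker_cols = []
    qtl_add_cols = {}
    qtl_dom_cols = {}
    qtl_by_chrom = {}
    for qi, q in enumerate(spec.qtls):
        qtl_by_chrom.setdefault(q.chrom, []).append((qi, q.pos_cM))
    for chrom in spec.gmap.chromosomes:
        mpos = chrom.marker_pos_cM
        extra = qtl_by_chrom.get(chrom.name, [])
        allpos = np.concatenate([mpos, [p for _, p in extra]])
        order = np.argsort(allpos, kind="stable")
        states = _simulate_chain(rng, n, allpos[order], spec.design)
        inv = np.empty_like(order)
        inv[order] = np.arange(order.size)
        if spec.design == "F2":
            add = states.astype(np.int8) - 1  # counts 0/1/2 -> -1/0/+1
        else:
            add = (2 * states - 1).astype(np.int8)  # 0/1 -> -1/+1
        marker_cols.append(add[:, inv[: mpos.size]])
        for j, (qi, _) in enumerate(extra):
            col = add[:, inv[mpos.size + j]]
            qtl_add_cols[qi] = col
            if spec.design == "F2":
                qtl_dom_cols[qi] = (states[:, inv[mpos.size + j]] == 1).astype(np.int8)
    marker_geno = np.hstack(marker_cols) if marker_cols else np.zeros((n, 0), dtype=np.int8)
    nq = len(spec.qtls)
    qtl_add = np.zeros((n, nq), dtype=np.int8)
    for qi in range(nq):
        qtl_add[:, qi] = qtl_add_cols[qi]
    qtl_dom = None
    if spec.design == "F2":
        qtl_dom = np.zeros((n, nq), dtype=np.int8)
        for qi in range(nq):
            qtl_dom[:, qi] = qtl_dom_cols[qi]
    return marker_geno, qtl_add, qtl_dom


def simulate_phenotypes(qtl_genotypes, spec: SimulationSpec, rng=None, qtl_dom_genotypes=None):
    """Draw phenotypes from the family distribution at the model mean.

    The linear predictor is eta_i = mu0 + sum_j x_ij b_j (+ dominance terms for
    an F2); the mean is g^{-1}(eta).  Binomial phenotypes are returned as
    success proportions out of ``binomial_trials``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    fam = spec.family
    n = qtl_genotypes.shape[0] if len(spec.qtls) else spec.n
    eta = np.full(n, float(spec.mu0))
    if len(spec.qtls):
        b = np.array([q.additive for q in spec.qtls])
        eta = eta + qtl_genotypes @ b
        if spec.design == "F2" and any(q.dominance is not None for q in spec.qtls):
            d = np.array([q.dominance or 0.0 for q in spec.qtls])
            if qtl_dom_genotypes is None:
                raise ValueError("dominance effects specified but no dominance genotypes given")
            eta = eta + qtl_dom_genotypes @ d
    mu_raw = fam._link.inverse(eta)
    if fam.family_name == "poisson" and np.any(mu_raw < 0):
        bad = int(np.flatnonzero(mu_raw < 0)[0])
        raise ValueError(
            f"mean {mu_raw[bad]:.4g} for individual {bad} is outside the Poisson mean "
            f"domain under the {fam.link_name} link"
        )
    if fam.family_name == "binomial" and np.any((mu_raw < 0) | (mu_raw > 1)):
        bad = int(np.flatnonzero((mu_raw < 0) | (mu_raw > 1))[0])
        raise ValueError(
            f"mean {mu_raw[bad]:.4g} for individual {bad} is outside [0, 1] under the "
            f"{fam.link_name} link"
        )
    mu = fam.clip_mean(mu_raw)
    if fam.family_name == "gaussian":
        return mu + rng.standard_normal(n)
    if fam.family_name == "poisson":
        return rng.poisson(mu).astype(float)
    counts = rng.binomial(spec.binomial_trials, mu)
    return counts / float(spec.binomial_trials)


def simulate_dataset(spec: SimulationSpec, seed=None) -> SimulatedDataset:
    """Genotypes + phenotypes for one replicate; ``seed`` overrides the spec's."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    marker_geno, qtl_add, qtl_dom = simulate_genotypes(spec, rng)
    y = simulate_phenotypes(qtl_add, spec, rng, qtl_dom_genotypes=qtl_dom)
    return SimulatedDataset(
        spec=spec,
        marker_genotypes=marker_geno,
        qtl_genotypes=qtl_add,
        phenotypes=y,
        qtl_dom_genotypes=qtl_dom,
    )


def simulate_null(gmap, design, family_name, n, seed, link_name=None, mu0=0.0,
                  binomial_trials=1) -> SimulatedDataset:
    """A dataset with all genetic effects zero (the threshold null model)."""
    spec = SimulationSpec(
        design=design,
        gmap=gmap,
        qtls=(),
        family_name=family_name,
        link_name=link_name,
        mu0=mu0,
        n=n,
        binomial_trials=binomial_trials,
        seed=seed,
    )
    return simulate_dataset(spec)


def standard_map(n_chrom=6, length_cM=100.0, n_markers=11) -> GeneticMap:
    """Evenly spaced markers: the benchmark genome (6 x 100 cM, 11 markers)."""
    chroms = []
    for c in range(n_chrom):
        pos = np.linspace(0.0, length_cM, n_markers)
        names = tuple(f"M{c + 1}_{k + 1}" for k in range(n_markers))
        chroms.append(Chromosome(name=f"chr{c + 1}", marker_names=names, marker_pos_cM=pos))
    return GeneticMap(chromosomes=tuple(chroms))


def ten_qtl_scenario(trait: str, n: int, seed: int = 0) -> SimulationSpec:
    """The 10-QTL backcross benchmark scenario.

    ``trait`` is "binary" (binomial/logit) or "poisson" (Poisson/log); the ten
    QTLs sit at genome positions 23..574 cM with effects from 2.0 down to
    -0.22, population mean zero.
    """
    trait = trait.lower()
    if trait not in ("binary", "poisson"):
        raise ValueError("trait must be 'binary' or 'poisson'")
    gmap = standard_map()
    qtls = []
    for gpos, eff in zip(TRUE_GENOME_POSITIONS, TRUE_EFFECTS):
        ci = int(gpos // 100)
        qtls.append(QTL(chrom=f"chr{ci + 1}", pos_cM=gpos - 100.0 * ci, additive=eff))
    family = "binomial" if trait == "binary" else "poisson"
    link = "logit" if trait == "binary" else "log"
    return SimulationSpec(
        design="backcross",
        gmap=gmap,
        qtls=tuple(qtls),
        family_name=family,
        link_name=link,
        mu0=0.0,
        n=n,
        binomial_trials=1,
        seed=seed,
    )


def replicate_seed(base_seed: int, replicate: int) -> np.random.Generator:
    """Independent, reproducible generator for a numbered replicate."""
    return np.random.default_rng([int(base_seed), int(replicate)])
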