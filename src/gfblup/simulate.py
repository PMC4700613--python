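"""Synthetic livestock genotypes and two-component phenotype simulation.

The generator emulates a commercial pig breeding population: founder
haplotypes with blocky linkage disequilibrium (first-order Markov
dependence between adjacent markers via a latent AR(1) Gaussian copula),
dropped with recombination through a multi-generation nested half-sib
pedigree, yielding highly related individuals in discrete cohorts.

Phenotypes follow the two-component model

    y = g1 + g2 + e

where g1 ~ N(0, G1 sigma_g1^2) is driven by a 100-marker causal feature
set C1, g2 ~ N(0, G2 sigma_g2^2) by the remaining 900 causal markers C2,
and e is independent noise, with the total phenotypic variance fixed at
sigma_P^2 = 100.  The variance split is controlled by the genomic
heritability h^2 = (sigma_g1^2 + sigma_g2^2)/sigma_P^2 and the causal
feature share h_f^2 = sigma_g1^2/(sigma_g1^2 + sigma_g2^2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureSet
from .io_qc import GenotypeMatrix
from .kinship import center_scale

__all__ = [
    "PopulationStructure",
    "SimScenario",
    "SimDataset",
    "simulate_genotypes",
    "select_causal",
    "variance_split",
    "simulate_phenotypes",
    "make_dilution_and_null_sets",
    "scenario_grid",
    "simulate_dataset",
    "DILUTION_GRID",
    "NULL_SIZES",
]

DILUTION_GRID = tuple(range(100, 2001, 100))
NULL_SIZES = (100, 500, 1000, 5000)


@dataclass(frozen=True)
class PopulationStructure:
    """Parameters of the synthetic population and marker map.

    Defaults emulate a closed nucleus herd: 5 discrete generations of
    nested half-sib families (25 sires each mated to 10 dams, 2 offspring
    per dam), founder minor-allele frequencies uniform on (0.05, 0.5),
    latent adjacent-marker correlation 0.7, markers spaced 60 kb apart on
    18 autosomes with recombination at 1 cM/Mb.
    """

    generations: int = 5
    n_sires: int = 25
    n_dams_per_sire: int = 10
    n_offspring_per_dam: int = 2
    rho: float = 0.7
    founder_maf: tuple[float, float] = (0.05, 0.5)
    n_chrom: int = 18
    marker_spacing_bp: int = 60_000
    recomb_rate_per_bp: float = 1e-8

    def __post_init__(self) -> None:
        if self.generations < 1 or self.n_sires < 1 or self.n_dams_per_sire < 1:
            raise ValueError("pedigree dimensions must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        lo, hi = self.founder_maf
        if not 0.0 < lo < hi <= 0.5:
            raise ValueError("founder MAF bounds must satisfy 0 < lo < hi <= 0.5")


@dataclass(frozen=True)
class SimScenario:
    """One point of the factorial simulation grid."""

    h2: float = 0.2
    h2_f: float = 0.2
    dilution: int = 0
    causal_model: str = "cluster"
    n_obs: int = 3000
    n_markers: int = 5000
    sigma_P2: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 < 1.0 or not 0.0 <= self.h2_f <= 1.0:
            raise ValueError("h2 and h2_f must lie in [0, 1)")
        if self.dilution < 0 or self.sigma_P2 <= 0:
            raise ValueError("invalid dilution or phenotypic variance")
        if self.causal_model not in ("random", "cluster"):
            raise ValueError(f"unknown causal model {self.causal_model!r}")


@dataclass
class SimDataset:
    """One realized dataset with known truth."""

    genotypes: GenotypeMatrix
    y: np.ndarray
    C1: FeatureSet
    C2: FeatureSet
    truth: dict
    scenario: SimScenario
    diluted_sets: dict[int, FeatureSet] = field(default_factory=dict)
    null_sets: list[FeatureSet] = field(default_factory=list)


def _marker_map(m: int, structure: PopulationStructure):
    sizes = np.full(structure.n_chrom, m // structure.n_chrom)
    sizes[: m % structure.n_chrom] += 1
    sizes = sizes[sizes > 0]
    chrom = np.concatenate(
        [np.full(s, str(c + 1), dtype=object) for c, s in enumerate(sizes)]
    )
    pos = np.concatenate(
        [structure.marker_spacing_bp * np.arange(1, s + 1) for s in sizes]
    )
    new_chrom = np.ones(m, dtype=bool)
    new_chrom[1:] = chrom[1:] != chrom[:-1]
    return chrom, pos.astype(np.int64), new_chrom


def _founder_haplotypes(n_hap, m, structure, thresholds, new_chrom, rng):
    """Latent AR(1) Gaussian copula haplotypes (first-order Markov LD)."""
    rho = np.full(m, structure.rho)
    rho[new_chrom] = 0.0  # chain restarts at chromosome boundaries
    innov = np.sqrt(1.0 - rho**2)
    eps = rng.standard_normal((n_hap, m))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    for j in range(1, m):
        z[:, j] = rho[j] * z[:, j - 1] + innov[j] * eps[:, j]
    return (z < thresholds).astype(np.int8)


def _meiosis(hap_pairs, r, rng):
    """One gamete per individual from its two haplotypes, with crossovers.

    ``hap_pairs`` has shape (n, 2, m); ``r`` is the per-interval
    recombination probability (0.5 at chromosome boundaries).
    """
    n, _, m = hap_pairs.shape
    switch = rng.random((n, m)) < r
    switch[:, 0] = rng.random(n) < 0.5  # random starting haplotype
    chooser = np.cumsum(switch, axis=1) % 2
    return np.take_along_axis(
        hap_pairs, chooser[:, None, :], axis=1
    )[:, 0, :]


def simulate_genotypes(
    n: int,
    m: int,
    structure: PopulationStructure | None = None,
    seed=None,
) -> GenotypeMatrix:
    """Simulate an n x m allele-count panel with LD and family structure.

    Founder haplotypes carry first-order Markov dependence between
    adjacent markers; offspring are produced through ``generations``
    rounds of nested half-sib matings with recombination.  If the stated
    family sizes produce fewer than ``n`` offspring, litter size is
    scaled up, and the most recent ``n`` individuals are returned (their
    cohort labels are kept in ``meta``).  The same seed reproduces the
    same panel.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    structure = structure or PopulationStructure()
    rng = np.random.default_rng(seed)
    chrom, pos, new_chrom = _marker_map(m, structure)

    per_gen = structure.n_sires * structure.n_dams_per_sire
    n_off = structure.n_offspring_per_dam
    if structure.generations * per_gen * n_off < n:
        n_off = int(np.ceil(n / (structure.generations * per_gen)))

    freqs = rng.uniform(*structure.founder_maf, size=m)
    thresholds = stats.norm.ppf(freqs)
    n_parents = structure.n_sires + per_gen  # sires plus dams
    haps = _founder_haplotypes(2 * n_parents, m, structure, thresholds, new_chrom, rng)
    parents = haps.reshape(n_parents, 2, m)

    r = structure.recomb_rate_per_bp * np.diff(pos, prepend=pos[0]).astype(float)
    r[new_chrom] = 0.5
    r = np.clip(r, 0.0, 0.5)

    counts_list, cohorts = [], []
    for gen in range(1, structure.generations + 1):
        order = rng.permutation(n_parents)
        sires = parents[order[: structure.n_sires]]
        dams = parents[order[structure.n_sires : n_parents]]
        n_children = per_gen * n_off
        sire_of = np.repeat(np.arange(structure.n_sires), structure.n_dams_per_sire * n_off)
        dam_of = np.repeat(np.arange(per_gen), n_off)
        paternal = _meiosis(sires[sire_of], r, rng)
        maternal = _meiosis(dams[dam_of], r, rng)
        children = np.stack([paternal, maternal], axis=1)
        counts_list.append(paternal + maternal)
        cohorts.append(np.full(n_children, gen))
        if n_children >= n_parents:
            parents = children[rng.permutation(n_children)[:n_parents]]
        else:
            parents = children

    counts = np.concatenate(counts_list, axis=0)
    cohort = np.concatenate(cohorts)
    if counts.shape[0] < n:
        raise ValueError("pedigree structure produced fewer individuals than n")
    counts, cohort = counts[-n:], cohort[-n:]
    samples = np.array([f"id{i:05d}" for i in range(n)], dtype=object)
    meta = pd.DataFrame({"cohort": cohort}, index=samples)
    return GenotypeMatrix(
        counts=counts.astype(np.int8),
        samples=samples,
        markers=np.array([f"snp{j:05d}" for j in range(m)], dtype=object),
        chrom=chrom,
        pos=pos,
        meta=meta,
    )


def select_causal(
    m: int,
    model: str = "cluster",
    n_c1: int = 100,
    n_c2: int = 900,
    n_regions: int = 20,
    region_span: int = 50,
    seed=None,
) -> tuple[FeatureSet, FeatureSet]:
    """Draw the causal feature set C1 and the remaining causal set C2.

    ``random`` samples both sets uniformly without replacement.
    ``cluster`` places C1 inside ``n_regions`` non-overlapping regions of
    ``region_span`` adjacent markers (``n_c1 / n_regions`` causal markers
    per region); C2 is uniform over the remaining markers.
    """
    rng = np.random.default_rng(seed)
    if m < n_c1 + n_c2:
        raise ValueError("panel too small for the requested causal sets")
    if model == "random":
        perm = rng.permutation(m)
        c1, c2 = perm[:n_c1], perm[n_c1 : n_c1 + n_c2]
    elif model == "cluster":
        n_blocks = m // region_span
        if n_blocks < n_regions:
            raise ValueError(
                f"cannot place {n_regions} non-overlapping regions of "
                f"{region_span} markers in {m}"
            )
        per_region, extra = divmod(n_c1, n_regions)
        blocks = rng.choice(n_blocks, size=n_regions, replace=False)
        picks = []
        for b, block in enumerate(blocks):
            k = per_region + (1 if b < extra else 0)
            within = rng.choice(region_span, size=k, replace=False)
            picks.append(block * region_span + within)
        c1 = np.concatenate(picks)
        pool = np.setdiff1d(np.arange(m), c1)
        c2 = rng.choice(pool, size=n_c2, replace=False)
    else:
        raise ValueError(f"unknown causal model {model!r}")
    return (
        FeatureSet(name="C1", indices=c1, provenance="custom"),
        FeatureSet(name="C2", indices=c2, provenance="custom"),
    )


def variance_split(h2: float, h2_f: float, sigma_P2: float = 100.0):
    """Split total phenotypic variance into (sigma_g1^2, sigma_g2^2, sigma_e^2)."""
    if not 0.0 <= h2 <= 1.0 or not 0.0 <= h2_f <= 1.0 or sigma_P2 <= 0:
        raise ValueError("invalid variance-split arguments")
    sg1 = h2 * h2_f * sigma_P2
    sg2 = h2 * (1.0 - h2_f) * sigma_P2
    se = (1.0 - h2) * sigma_P2
    return sg1, sg2, se


def simulate_phenotypes(
    g: GenotypeMatrix,
    C1: FeatureSet,
    C2: FeatureSet,
    scenario: SimScenario,
    rng=None,
    w=None,
) -> SimDataset:
    """Simulate y = g1 + g2 + e on a genotype panel with known truth.

    The genomic components are sampled exactly from their singular
    covariances via the factor form: with W_k the centered/scaled columns
    of causal set k, ``g_k = sigma_gk / sqrt(m_k) * W_k z`` with z
    standard normal has covariance ``sigma_gk^2 G_k`` by construction, so
    no eigendecomposition or PSD projection is needed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(scenario.seed if rng is None else rng)
    w = center_scale(g) if w is None else w
    sg1, sg2, se = variance_split(scenario.h2, scenario.h2_f, scenario.sigma_P2)
    n = g.n_samples

    def component(fset, sigma2):
        if sigma2 == 0.0:
            return np.zeros(n)
        Wk = w.W[:, fset.indices]
        z = rng.standard_normal(fset.n_markers)
        return np.sqrt(sigma2 / fset.n_markers) * (Wk @ z)

    g1 = component(C1, sg1)
    g2 = component(C2, sg2)
    e = np.sqrt(se) * rng.standard_normal(n)
    y = g1 + g2 + e
    return SimDataset(
        genotypes=g,
        y=y,
        C1=C1,
        C2=C2,
        truth={
            "g1": g1,
            "g2": g2,
            "e": e,
            "sigma_g1": sg1,
            "sigma_g2": sg2,
            "sigma_e": se,
        },
        scenario=scenario,
    )


def make_dilution_and_null_sets(
    C1: FeatureSet,
    C2: FeatureSet,
    m: int,
    dilution_grid=DILUTION_GRID,
    null_sizes=NULL_SIZES,
    n_null: int = 50,
    mode: str = "genomewide",
    seed=None,
):
    """Diluted causal sets (C1 plus k non-causal markers) and null sets.

    ``mode='genomewide'`` samples dilution markers uniformly among
    non-causal markers; ``mode='flanking'`` adds the non-causal markers
    closest (in marker order) to C1, emulating expanding windows around
    causal clusters.  Null sets of each requested size are sampled among
    non-causal markers, ``n_null`` per size.
    """
    rng = np.random.default_rng(seed)
    causal = np.union1d(C1.indices, C2.indices)
    pool = np.setdiff1d(np.arange(m), causal)
    diluted: dict[int, FeatureSet] = {}
    if mode == "flanking":
        dist = np.min(np.abs(pool[:, None] - C1.indices[None, :]), axis=1)
        ranked = pool[np.argsort(dist, kind="stable")]
    elif mode != "genomewide":
        raise ValueError(f"unknown dilution mode {mode!r}")
    for k in sorted(set(dilution_grid)):
        if k > pool.size:
            raise ValueError(
                f"dilution {k} exceeds the {pool.size} available non-causal markers"
            )
        extra = ranked[:k] if mode == "flanking" else rng.choice(pool, size=k, replace=False)
        diluted[k] = FeatureSet(
            name=f"C1+{k}",
            indices=np.concatenate([C1.indices, extra]),
            provenance="custom",
        )
    null_sets = []
    for size in null_sizes:
        if size > pool.size:
            raise ValueError(
                f"null-set size {size} exceeds the {pool.size} available "
                "non-causal markers"
            )
        for i in range(n_null):
            null_sets.append(
                FeatureSet(
                    name=f"null_{size}_{i}",
                    indices=rng.choice(pool, size=size, replace=False),
                    provenance="custom",
                )
            )
    return diluted, null_sets


def scenario_grid(
    n_obs=(1000, 2000, 3000),
    h2=(0.1, 0.2, 0.3),
    h2_f=(0.1, 0.2, 0.3, 0.5),
    causal_model=("random", "cluster"),
    n_markers: int = 5000,
    sigma_P2: float = 100.0,
    base_seed: int = 0,
) -> list[SimScenario]:
    """The full factorial grid (3 x 3 x 4 x 2 = 72 cells at defaults)."""
    grid = []
    for i, (n, h, hf, model) in enumerate(
        itertools.product(n_obs, h2, h2_f, causal_model)
    ):
        grid.append(
            SimScenario(
                h2=h,
                h2_f=hf,
                causal_model=model,
                n_obs=n,
                n_markers=n_markers,
                sigma_P2=sigma_P2,
                seed=base_seed + i,
            )
        )
    return grid


def simulate_dataset(
    scenario: SimScenario,
    structure: PopulationStructure | None = None,
    qc: bool = True,
    with_sets: bool = False,
    n_null: int = 50,
) -> SimDataset:
    """Generate one complete dataset for a scenario.

    Simulates genotypes, optionally applies the default quality-control
    filters, draws causal sets under the scenario's causal model, and
    simulates phenotypes.  ``with_sets`` additionally builds the diluted
    and null marker sets for the scenario's dilution level.
    """
    from .io_qc import qc_filter

    rng = np.random.default_rng(scenario.seed)
    g = simulate_genotypes(
        scenario.n_obs, scenario.n_markers, structure=structure,
        seed=rng.integers(2**31),
    )
    if qc:
        g, _ = qc_filter(g)
    C1, C2 = select_causal(
        g.n_markers, model=scenario.causal_model, seed=rng.integers(2**31)
    )
    ds = simulate_phenotypes(g, C1, C2, scenario, rng=rng)
    if with_sets:
        grid = (scenario.dilution,) if scenario.dilution > 0 else ()
        sizes = [s for s in NULL_SIZES if s <= g.n_markers - 1000]
        ds.diluted_sets, ds.null_sets = make_dilution_and_null_sets(
            C1, C2, g.n_markers, dilution_grid=grid, null_sizes=sizes,
            n_null=n_null, seed=rng.integers(2**31),
        )
    return ds
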