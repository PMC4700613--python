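"""Validation and experiment aggregation: generation-gapped train/validation
splits, bootstrap predictive ability, and power / false-positive-rate /
bias experiments over the simulation grid.

The power pipeline wires the other modules together: simulate a panel,
fit GBLUP, back-solve per-marker t statistics, and run the
cyclic-rotation set test on diluted causal sets (power) and on non-causal
sets (false-positive rate).  Within one scenario cell the genotype panel
and its eigendecomposition are held fixed across phenotype replicates —
mirroring a study design in which the genotypes are a fixed resource —
which reduces each replicate to O(n m) work.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .features import FeatureSet
from .io_qc import GenotypeMatrix, qc_filter
from .kinship import ScaledGenotypes, build_grm, center_scale
from .marker_stats import MarkerEffects, gblup_marker_stats
from .mixed_model import RemlError, fit_reml, make_gblup_spec
from .permtest import cyclic_permutation_test
from .simulate import (
    PopulationStructure,
    SimScenario,
    make_dilution_and_null_sets,
    select_causal,
    simulate_genotypes,
    simulate_phenotypes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationResult",
    "PowerTable",
    "PanelContext",
    "split_train_validation",
    "bootstrap_predictive_ability",
    "max_predictive_correlation",
    "prepare_panel",
    "fit_gblup_replicate",
    "run_power_experiment",
]


def max_predictive_correlation(h2: float) -> float:
    """Upper bound on the phenotype/genomic-value correlation: sqrt(h^2)."""
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must lie in [0, 1]")
    return float(np.sqrt(h2))


@dataclass
class ValidationResult:
    """Bootstrap predictive ability of one model."""

    model: str
    mean_correlation: float
    se: float
    n_boot: int
    boot_fraction: float
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.mean_correlation <= 1.0:
            raise ValueError("mean correlation outside [-1, 1]")
        if self.se < 0:
            raise ValueError("negative standard error")


def split_train_validation(cohorts, train_max, val_min, gap: int = 1):
    """Index split by cohort with a generation gap.

    Training animals have cohort <= ``train_max``; validation animals have
    cohort >= ``val_min``; the boundaries must leave at least ``gap``
    cohorts out entirely (``val_min > train_max + gap``).
    """
    cohorts = np.asarray(pd.Series(cohorts).to_numpy())
    if not val_min > train_max + gap:
        raise ValueError(
            f"validation boundary {val_min} must exceed training boundary "
            f"{train_max} by more than the gap ({gap})"
        )
    train = np.flatnonzero(cohorts <= train_max)
    val = np.flatnonzero(cohorts >= val_min)
    if train.size == 0 or val.size == 0:
        raise ValueError("empty training or validation side")
    return train, val


def bootstrap_predictive_ability(
    y_val,
    g_hat_val,
    frac: float = 0.2,
    n_boot: int = 100,
    seed=None,
    model: str = "model",
) -> ValidationResult:
    """Predictive ability as the mean correlation over bootstrap subsamples.

    Each repeat draws ``floor(frac * n)`` validation animals without
    replacement and records the Pearson correlation between phenotype and
    total genomic value; draws in which either vector is constant are
    skipped (and counted).
    """
    y_val = np.asarray(y_val, dtype=float).ravel()
    g_hat_val = np.asarray(g_hat_val, dtype=float).ravel()
    if y_val.size != g_hat_val.size:
        raise ValueError("vectors not aligned")
    if y_val.size < 10:
        raise ValueError("validation set too small")
    k = int(np.floor(frac * y_val.size))
    if k < 2:
        raise ValueError("bootstrap fraction leaves fewer than 2 animals")
    rng = np.random.default_rng(seed)
    cors, skipped = [], 0
    for _ in range(n_boot):
        idx = rng.choice(y_val.size, size=k, replace=False)
        a, b = y_val[idx], g_hat_val[idx]
        if a.std() == 0.0 or b.std() == 0.0:
            skipped += 1
            continue
        cors.append(np.corrcoef(a, b)[0, 1])
    if not cors:
        raise ValueError("every bootstrap draw was degenerate (constant vector)")
    if skipped:
        logger.info("bootstrap: skipped %d degenerate draws", skipped)
    cors = np.asarray(cors)
    return ValidationResult(
        model=model,
        mean_correlation=float(cors.mean()),
        se=float(cors.std(ddof=1) / np.sqrt(cors.size)) if cors.size > 1 else 0.0,
        n_boot=n_boot,
        boot_fraction=frac,
        n_skipped=skipped,
    )


# ---------------------------------------------------------------------------
# power / false-positive-rate pipeline


@dataclass
class PanelContext:
    """A fixed genotype panel with the factorizations reused across
    phenotype replicates: GRM eigenpairs and the rotated marker matrix."""

    genotypes: GenotypeMatrix
    w: ScaledGenotypes
    G: np.ndarray
    eig: tuple
    Wt: np.ndarray

    @property
    def n_markers(self) -> int:
        return self.w.n_markers


def prepare_panel(
    n: int,
    m: int,
    structure: PopulationStructure | None = None,
    seed=None,
    qc: bool = True,
) -> PanelContext:
    """Simulate, QC and factorize one genotype panel."""
    g = simulate_genotypes(n, m, structure=structure, seed=seed)
    if qc:
        g, _ = qc_filter(g)
    w = center_scale(g)
    G = build_grm(w)
    d, U = sla.eigh(G.values)
    return PanelContext(
        genotypes=g, w=w, G=G.values, eig=(np.maximum(d, 0.0), U), Wt=U.T @ w.W
    )


def fit_gblup_replicate(ctx: PanelContext, y) -> tuple[MarkerEffects, object, object]:
    """Fit GBLUP on a panel and back-solve marker statistics."""
    spec = make_gblup_spec(y, ctx.G, eig=ctx.eig)
    v = fit_reml(spec)
    me = gblup_marker_stats(ctx.w, spec, v, Wt=ctx.Wt)
    return me, spec, v


@dataclass
class PowerTable:
    """Tidy per-cell power and false-positive-rate estimates."""

    table: pd.DataFrame
    alpha: float
    n_permutations: int

    def __post_init__(self) -> None:
        for col in ("power", "fpr"):
            if col in self.table and not self.table[col].dropna().between(0, 1).all():
                raise ValueError(f"{col} outside [0, 1]")


def run_power_experiment(
    grid,
    alpha: float = 0.05,
    n_perm: int = 200,
    n_replicates: int = 10,
    dilution_grid=(0,),
    null_sizes=(100, 500, 1000),
    n_null_sets: int = 1,
    seed=None,
    structure: PopulationStructure | None = None,
    statistic: str = "t_sum",
    min_success: float = 0.5,
    panels_per_cell: int = 1,
) -> PowerTable:
    """Estimate set-test power and false-positive rate over scenario cells.

    For every :class:`~gfblup.simulate.SimScenario` in ``grid`` and every
    replicate: draw causal sets under the scenario's causal model,
    simulate phenotypes, fit GBLUP, back-solve marker t statistics, and
    run the rotation test on each diluted causal set (C1 plus ``k``
    non-causal markers for ``k`` in ``dilution_grid``) and on ``n_null_sets``
    non-causal sets per size in ``null_sizes``.  Power is the fraction of
    causal-set tests with empirical p <= ``alpha``; the false-positive
    rate is the same fraction over null sets.  Replicates whose REML fit
    fails are logged and skipped; a cell with fewer than
    ``min_success * n_replicates`` successes is flagged incomplete.
    ``panels_per_cell`` panels are simulated per cell and replicates are
    spread across them.
    """
    if not grid:
        raise ValueError("empty scenario grid")
    rng = np.random.default_rng(seed)
    rows = []
    for scenario in grid:
        cell_rng = np.random.default_rng(rng.integers(2**31))
        hits = {k: 0 for k in dilution_grid}
        tests = {k: 0 for k in dilution_grid}
        null_hits = null_tests = 0
        n_ok = 0
        reps_per_panel = int(np.ceil(n_replicates / panels_per_cell))
        rep = 0
        for _ in range(panels_per_cell):
            if rep >= n_replicates:
                break
            ctx = prepare_panel(
                scenario.n_obs,
                scenario.n_markers,
                structure=structure,
                seed=cell_rng.integers(2**31),
            )
            for _ in range(reps_per_panel):
                if rep >= n_replicates:
                    break
                rep += 1
                C1, C2 = select_causal(
                    ctx.n_markers,
                    model=scenario.causal_model,
                    seed=cell_rng.integers(2**31),
                )
                ds = simulate_phenotypes(
                    ctx.genotypes, C1, C2, scenario, rng=cell_rng, w=ctx.w
                )
                try:
                    me, spec, v = fit_gblup_replicate(ctx, ds.y)
                except (RemlError, np.linalg.LinAlgError) as exc:
                    logger.warning("replicate skipped, REML failure: %s", exc)
                    continue
                n_ok += 1
                sizes = [s for s in null_sizes if s <= ctx.n_markers - 1001]
                diluted, nulls = make_dilution_and_null_sets(
                    C1,
                    C2,
                    ctx.n_markers,
                    dilution_grid=[k for k in dilution_grid if k > 0],
                    null_sizes=sizes,
                    n_null=n_null_sets,
                    seed=cell_rng.integers(2**31),
                )
                if 0 in dilution_grid:
                    diluted[0] = C1
                for k, fset in diluted.items():
                    res = cyclic_permutation_test(
                        me.t, fset, n_perm=n_perm, statistic=statistic,
                        seed=cell_rng.integers(2**31),
                    )
                    tests[k] += 1
                    hits[k] += res.p_empirical <= alpha
                for fset in nulls:
                    res = cyclic_permutation_test(
                        me.t, fset, n_perm=n_perm, statistic=statistic,
                        seed=cell_rng.integers(2**31),
                    )
                    null_tests += 1
                    null_hits += res.p_empirical <= alpha
        complete = n_ok >= min_success * n_replicates
        for k in dilution_grid:
            rows.append(
                {
                    "n_obs": scenario.n_obs,
                    "h2": scenario.h2,
                    "h2_f": scenario.h2_f,
                    "causal_model": scenario.causal_model,
                    "dilution": k,
                    "power": hits[k] / tests[k] if tests[k] else np.nan,
                    "fpr": null_hits / null_tests if null_tests else np.nan,
                    "n_replicates": n_ok,
                    "complete": complete,
                }
            )
    return PowerTable(table=pd.DataFrame(rows), alpha=alpha, n_permutations=n_perm)
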