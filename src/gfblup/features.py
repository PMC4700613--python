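"""Genomic feature construction: marker sets that define G_f.

Three feature classes are supported:

* single-marker sets — all markers below a p-value cutoff, over a grid of
  decreasing cutoffs (nested sets);
* block sets — the genome partitioned into runs of physically adjacent
  markers (50 by default) within chromosomes, each block tested with the
  rotation set test, and blocks below a cutoff unioned into the feature;
* QTL sets — markers within a fixed half-window (250 kb by default) of
  each QTL midpoint, grouped by trait category, with sets spanning fewer
  than three markers dropped, plus a "rest" set (markers in no QTL
  window) and an "all" set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import QtlRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSet",
    "FeatureClass",
    "single_marker_sets",
    "block_sets",
    "genome_blocks",
    "qtl_feature_sets",
    "write_feature_sets",
    "read_feature_sets",
]


@dataclass(frozen=True)
class FeatureSet:
    """A named set of marker indices (positions in the genome-ordered panel)."""

    name: str
    indices: np.ndarray
    provenance: str = "custom"

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        if idx.size and idx.min() < 0:
            raise ValueError("negative marker index")
        object.__setattr__(self, "indices", idx)

    @property
    def n_markers(self) -> int:
        return int(self.indices.size)

    def complement(self, m: int, name: str | None = None) -> "FeatureSet":
        """All panel markers not in this set (the G_r marker set)."""
        mask = np.ones(m, dtype=bool)
        mask[self.indices] = False
        return FeatureSet(
            name=name or f"{self.name}_rest",
            indices=np.flatnonzero(mask),
            provenance="rest",
        )


@dataclass
class FeatureClass:
    """A named collection of feature sets of one construction kind."""

    kind: str
    sets: dict[str, FeatureSet] = field(default_factory=dict)

    def add(self, fset: FeatureSet) -> None:
        if fset.name in self.sets:
            raise ValueError(f"duplicate feature set name {fset.name!r}")
        self.sets[fset.name] = fset

    def __iter__(self):
        return iter(self.sets.values())

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> FeatureSet:
        return self.sets[name]


DEFAULT_CUTOFFS = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1)


def single_marker_sets(me, cutoffs=DEFAULT_CUTOFFS) -> FeatureClass:
    """One feature set per p-value cutoff: markers with p below the cutoff.

    Sets are nested across the cutoff grid.  Cutoffs yielding an empty set
    are omitted with a logged notice.
    """
    cutoffs = sorted(cutoffs)
    if any(not 0.0 < c <= 1.0 for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1]")
    fc = FeatureClass(kind="single_marker")
    p = np.asarray(me.p, dtype=float)
    for c in cutoffs:
        idx = np.flatnonzero(p < c)
        if idx.size == 0:
            logger.info("single-marker cutoff %g yields an empty set; omitted", c)
            continue
        fc.add(FeatureSet(name=f"p<{c:g}", indices=idx, provenance="single_marker"))
    return fc


def genome_blocks(chrom, block_size: int = 50) -> list[np.ndarray]:
    """Partition genome-ordered markers into runs of ``block_size``
    physically adjacent markers within chromosomes; a final short run on a
    chromosome is kept as its own block."""
    chrom = np.asarray(chrom)
    blocks: list[np.ndarray] = []
    start = 0
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        for lo in range(0, idx.size, block_size):
            blocks.append(idx[lo : lo + block_size])
    return blocks


def block_sets(
    chrom,
    tester,
    block_size: int = 50,
    cutoffs=DEFAULT_CUTOFFS,
) -> FeatureClass:
    """Feature sets from adjacent-marker blocks selected by the set test.

    Each block of ``block_size`` adjacent markers is tested with
    ``tester`` (a callable mapping a :class:`FeatureSet` to a result with
    a ``p_empirical`` attribute — normally the cyclic-rotation test bound
    to the per-marker statistics).  Per cutoff, the feature is the union
    of markers in blocks whose empirical p falls below the cutoff.
    """
    cutoffs = sorted(cutoffs)
    blocks = genome_blocks(chrom, block_size=block_size)
    block_p = np.empty(len(blocks))
    for b, idx in enumerate(blocks):
        block_p[b] = tester(
            FeatureSet(name=f"block{b}", indices=idx, provenance="block")
        ).p_empirical
    fc = FeatureClass(kind="block")
    for c in cutoffs:
        chosen = [blocks[b] for b in np.flatnonzero(block_p < c)]
        if not chosen:
            logger.info("block cutoff %g yields an empty set; omitted", c)
            continue
        fc.add(
            FeatureSet(
                name=f"blocks_p<{c:g}",
                indices=np.concatenate(chosen),
                provenance="block",
            )
        )
    return fc


def qtl_feature_sets(
    records: list[QtlRecord],
    chrom,
    pos,
    half_window_bp: int = 250_000,
    min_snps: int = 3,
) -> FeatureClass:
    """Trait-wise QTL feature sets from standardized midpoint windows.

    Every QTL interval is reduced to its midpoint and expanded to
    ``half_window_bp`` on each side (inclusive at both ends, 1-based bp).
    A trait's set is the union of its windows' markers, counted once.
    Trait sets spanning fewer than ``min_snps`` markers are dropped.  A
    ``rest`` set (markers in no QTL window of any trait, dropped or not)
    and an ``all`` set complete the class.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    m = pos.size
    known = set(chrom.tolist())
    by_trait: dict[str, list[np.ndarray]] = {}
    covered = np.zeros(m, dtype=bool)
    for rec in records:
        if rec.chromosome not in known:
            logger.warning(
                "QTL record for %r on unknown chromosome %r skipped",
                rec.trait,
                rec.chromosome,
            )
            continue
        mid = rec.midpoint
        hit = (chrom == rec.chromosome) & (pos >= mid - half_window_bp) & (
            pos <= mid + half_window_bp
        )
        idx = np.flatnonzero(hit)
        by_trait.setdefault(rec.trait, []).append(idx)
        covered[idx] = True

    fc = FeatureClass(kind="qtl")
    for trait in sorted(by_trait):
        idx = np.unique(np.concatenate(by_trait[trait]))
        if idx.size < min_snps:
            logger.info(
                "QTL set %r spans %d SNPs (< %d); dropped", trait, idx.size, min_snps
            )
            continue
        fc.add(FeatureSet(name=trait, indices=idx, provenance="qtl"))
    fc.add(FeatureSet(name="rest", indices=np.flatnonzero(~covered), provenance="rest"))
    fc.add(FeatureSet(name="all", indices=np.arange(m), provenance="all"))
    return fc


def write_feature_sets(fc: FeatureClass, path, markers=None) -> None:
    """Serialize as a two-column TSV (set name, marker), GMT-like grouping."""
    rows = []
    for fset in fc:
        for j in fset.indices:
            rows.append((fset.name, markers[j] if markers is not None else j))
    pd.DataFrame(rows, columns=["set", "marker"]).to_csv(path, sep="\t", index=False)


def read_feature_sets(path, markers=None, kind: str = "custom") -> FeatureClass:
    """Read the two-column TSV written by :func:`write_feature_sets`.

    With ``markers`` given, the file's marker column holds identifiers to
    be looked up; otherwise it holds integer indices."""
    df = pd.read_csv(path, sep="\t")
    fc = FeatureClass(kind=kind)
    if markers is not None:
        lookup = {mk: j for j, mk in enumerate(markers)}
        df["idx"] = df["marker"].map(lookup)
        if df["idx"].isna().any():
            missing = df.loc[df["idx"].isna(), "marker"].iloc[0]
            raise KeyError(f"marker {missing!r} not in panel")
    else:
        df["idx"] = df["marker"].astype(int)
    for name, grp in df.groupby("set", sort=False):
        fc.add(FeatureSet(name=str(name), indices=grp["idx"].to_numpy(int), provenance=kind))
    return fc
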