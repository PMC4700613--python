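"""Genotype, pedigree, phenotype and QTL-record input with quality control.

Genotypes are held as allele counts in {0, 1, 2} (count of the designated
allele, normally the minor allele) with ``-1`` marking missing calls.
Quality control follows the usual SNP-chip editing pipeline: sample call
rate first, then per-marker call rate, minor allele frequency,
Hardy-Weinberg equilibrium and a mapped-position requirement, and finally
re-orientation of the counted allele to the within-sample minor allele.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "QcReport",
    "QtlRecord",
    "RemovalReason",
    "load_genotypes",
    "load_phenotypes",
    "load_pedigree",
    "load_qtl_records",
    "qc_filter",
    "hwe_chisq",
    "write_genotypes",
]


class RemovalReason(str, Enum):
    SAMPLE_CALL_RATE = "sample_call_rate"
    CALL_RATE = "call_rate"
    MAF = "maf"
    HWE = "hwe"
    UNMAPPED = "unmapped"


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed under the named format."""


class EmptyPanelError(ValueError):
    """Raised when quality control removes every marker."""


@dataclass
class GenotypeMatrix:
    """An ``n x m`` panel of allele counts with a marker map.

    Parameters
    ----------
    counts
        Integer matrix of shape ``(n_samples, n_markers)`` with values in
        ``{0, 1, 2}`` and :data:`MISSING` (-1) for no-calls.
    samples, markers
        Unique ordered identifiers.
    chrom, pos
        Per-marker chromosome label and 1-based bp position.  Markers with
        ``pos < 0`` are treated as unmapped.
    alleles
        Optional per-marker ``(counted, other)`` allele labels.
    meta
        Optional per-sample table (e.g. a ``cohort`` column with the birth
        generation, used for train/validation splitting).
    """

    counts: np.ndarray
    samples: np.ndarray
    markers: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray | None = None
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.samples = np.asarray(self.samples, dtype=object)
        self.markers = np.asarray(self.markers, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_markers(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        n, m = self.counts.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise ValueError("identifier lengths do not match counts shape")
        if len(set(self.samples)) != n:
            raise ValueError("duplicated sample identifiers")
        if len(set(self.markers)) != m:
            raise ValueError("duplicated marker identifiers")
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("marker map length does not match marker count")
        bad = ~np.isin(self.counts, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"allele count out of range at sample {self.samples[i]!r}, "
                f"marker {self.markers[j]!r}: {self.counts[i, j]}"
            )

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Return a copy restricted to the given sample/marker indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            counts=self.counts[np.ix_(si, mi)].copy(),
            samples=self.samples[si],
            markers=self.markers[mi],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            alleles=None if self.alleles is None else self.alleles[mi],
            meta=None if self.meta is None else self.meta.iloc[si],
        )

    def sample_call_rate(self) -> np.ndarray:
        return (self.counts != MISSING).mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        return (self.counts != MISSING).mean(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele among non-missing calls."""
        obs = self.counts != MISSING
        called = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(obs, self.counts, 0).sum(axis=0) / (2.0 * called)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)


@dataclass
class QcReport:
    """Record of every sample/marker removed during quality control."""

    removed_markers: list[tuple[str, RemovalReason]] = field(default_factory=list)
    removed_samples: list[tuple[str, RemovalReason]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("marker", i, r.value) for i, r in self.removed_markers]
        rows += [("sample", i, r.value) for i, r in self.removed_samples]
        return pd.DataFrame(rows, columns=["kind", "id", "reason"])


@dataclass(frozen=True)
class QtlRecord:
    """One QTL database record: a trait label and a bp interval."""

    trait: str
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"QTL record for {self.trait!r}: start_bp {self.start_bp} "
                f"> end_bp {self.end_bp}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start_bp + self.end_bp) // 2


# ---------------------------------------------------------------------------
# loading


def _load_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicated sample identifiers in table")
    if df.columns.duplicated().any():
        raise ValueError("duplicated marker identifiers in table")
    counts = df.to_numpy()
    counts = np.where(pd.isna(counts), MISSING, counts).astype(np.int8)
    m = counts.shape[1]
    return GenotypeMatrix(
        counts=counts,
        samples=df.index.astype(str).to_numpy(),
        markers=df.columns.astype(str).to_numpy(),
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1),
    )


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    rows, ids, chroms, poss, alleles = [], [], [], [], []
    for i, var in enumerate(vcf):
        gt = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 3=hom alt, 2=unknown
        counts = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(counts.astype(np.int8))
        ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
        alleles.append((var.ALT[0] if var.ALT else ".", var.REF))
    if not rows:
        raise GenotypeFormatError(f"no variant records in {path}")
    return GenotypeMatrix(
        counts=np.column_stack(rows) if len(rows) > 1 else rows[0][:, None],
        samples=samples,
        markers=np.array(ids, dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss),
        alleles=np.array(alleles, dtype=object),
    )


_PLINK_CODES = np.array([2, MISSING, 1, 0], dtype=np.int8)  # 2-bit codes, ALT->counted


def _load_plink(prefix) -> GenotypeMatrix:
    # Minimal reader for the binary PLINK trio (no dedicated reader is
    # available in this environment).  SNP-major .bed assumed.
    prefix = str(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not Path(prefix + ext).exists():
            raise GenotypeFormatError(f"missing {prefix + ext}")
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tolist() != [0x6C, 0x1B, 0x01]:
        raise GenotypeFormatError("not a SNP-major PLINK .bed file")
    bytes_per = (n + 3) // 4
    body = raw[3:].reshape(m, bytes_per)
    codes = np.zeros((m, bytes_per * 4), dtype=np.int8)
    for shift in range(4):
        codes[:, shift::4] = _PLINK_CODES[(body >> (2 * shift)) & 0b11]
    counts = codes[:, :n].T.copy()
    # .bim allele 1 (A1) is the counted allele in PLINK's coding
    return GenotypeMatrix(
        counts=counts,
        samples=fam[1].astype(str).to_numpy(),
        markers=bim[1].astype(str).to_numpy(),
        chrom=bim[0].astype(str).to_numpy(),
        pos=bim[3].to_numpy(),
        alleles=bim[[4, 5]].astype(str).to_numpy(),
    )


def load_genotypes(path, format: str = "table", map_path=None) -> GenotypeMatrix:
    """Read a genotype panel.

    Parameters
    ----------
    path
        File path (for ``plink``, the shared prefix of .bed/.bim/.fam).
    format
        One of ``table`` (headered TSV, samples x markers), ``vcf``
        (diploid GT field), ``plink``.
    map_path
        Optional marker-map TSV with columns ``marker``, ``chrom``, ``pos``;
        applied on top of whatever map the main file provides (the table
        format carries no positions of its own).
    """
    loaders = {"table": _load_table, "vcf": _load_vcf, "plink": _load_plink}
    if format not in loaders:
        raise ValueError(f"unknown genotype format {format!r}")
    try:
        g = loaders[format](path)
    except (pd.errors.ParserError, UnicodeDecodeError, OSError) as exc:
        raise GenotypeFormatError(f"cannot parse {path} as {format}: {exc}") from exc
    if map_path is not None:
        mp = pd.read_csv(map_path, sep="\t", dtype={"chrom": str}).set_index("marker")
        mp = mp.reindex(np.asarray(g.markers, dtype=str))
        g.chrom = mp["chrom"].fillna("0").astype(object).to_numpy()
        g.pos = mp["pos"].fillna(-1).to_numpy(dtype=np.int64)
    return g


def write_genotypes(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write a panel as a headered TSV (and optionally its map)."""
    df = pd.DataFrame(g.counts, index=g.samples, columns=g.markers)
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    if map_path is not None:
        pd.DataFrame(
            {"marker": g.markers, "chrom": g.chrom, "pos": g.pos}
        ).to_csv(map_path, sep="\t", index=False)


def load_phenotypes(path, id_col: str = "id", value_col: str = "phenotype") -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={id_col: str})
    return df.set_index(id_col)[value_col]


def load_pedigree(path) -> list[tuple[str, str | None, str | None]]:
    """Read a pedigree TSV with columns id, sire, dam ('0'/empty = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("0")
    out = []
    for _, row in df.iterrows():
        sire = None if row["sire"] in ("0", "") else row["sire"]
        dam = None if row["dam"] in ("0", "") else row["dam"]
        out.append((row["id"], sire, dam))
    return out


def load_qtl_records(path) -> list[QtlRecord]:
    """Read QTL records from a TSV with columns trait, chromosome, start_bp, end_bp."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    if df.empty:
        return []
    return [
        QtlRecord(
            trait=str(r.trait),
            chromosome=str(r.chromosome),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# quality control


def hwe_chisq(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Upper-tail p-value of the 1-df chi-square goodness-of-fit test of
    Hardy-Weinberg genotype proportions at the sample allele frequency.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("no genotype calls: HWE test undefined")
    p = (2 * n_AA + n_Aa) / (2 * n)
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    if p in (0.0, 1.0):
        return 1.0  # monomorphic: fits trivially (and is caught by the MAF filter)
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(g: GenotypeMatrix) -> np.ndarray:
    c = g.counts
    n_AA = (c == 0).sum(axis=0)
    n_Aa = (c == 1).sum(axis=0)
    n_aa = (c == 2).sum(axis=0)
    return np.array(
        [hwe_chisq(a, b, d) for a, b, d in zip(n_AA, n_Aa, n_aa)]
    )


def qc_filter(
    g: GenotypeMatrix,
    snp_call_rate: float = 0.90,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-7,
    sample_call_rate: float = 0.80,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply panel quality control and re-orient counts to the minor allele.

    Samples failing the sample call-rate threshold are dropped first, so
    that near-empty samples do not distort per-marker statistics.  Then
    markers are kept only if call rate > ``snp_call_rate``, minor allele
    frequency > ``maf_min``, HWE p > ``hwe_p_min``, and the marker has a
    mapped position.  Finally the counted allele is flipped, where needed,
    to the minor allele in the retained samples (frequency ties keep the
    file's coding).  Missing calls are retained as the sentinel; downstream
    centering/scaling imputes them at the marker mean.
    """
    report = QcReport(
        thresholds={
            "snp_call_rate": snp_call_rate,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
            "sample_call_rate": sample_call_rate,
        }
    )
    scr = g.sample_call_rate()
    keep_s = scr > sample_call_rate
    for sid in g.samples[~keep_s]:
        report.removed_samples.append((sid, RemovalReason.SAMPLE_CALL_RATE))
    g = g.subset(sample_idx=np.flatnonzero(keep_s))

    mapped = g.pos >= 0
    cr_ok = g.marker_call_rate() > snp_call_rate
    maf_ok = g.maf() > maf_min
    hwe_ok = _hwe_pvalues(g) > hwe_p_min
    keep_m = mapped & cr_ok & maf_ok & hwe_ok
    # report the first failing reason per marker, in filter order
    for j in np.flatnonzero(~keep_m):
        if not mapped[j]:
            reason = RemovalReason.UNMAPPED
        elif not cr_ok[j]:
            reason = RemovalReason.CALL_RATE
        elif not maf_ok[j]:
            reason = RemovalReason.MAF
        else:
            reason = RemovalReason.HWE
        report.removed_markers.append((g.markers[j], reason))
    if not keep_m.any():
        raise EmptyPanelError("quality control removed every marker")
    g = g.subset(marker_idx=np.flatnonzero(keep_m))

    # orient to within-sample minor allele; ties (p == 0.5) keep file coding
    flip = g.allele_freq() > 0.5
    if flip.any():
        cols = g.counts[:, flip]
        obs = cols != MISSING
        g.counts[:, flip] = np.where(obs, 2 - cols, MISSING)
        if g.alleles is not None:
            g.alleles[flip] = g.alleles[flip][:, ::-1]
    return g, report
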