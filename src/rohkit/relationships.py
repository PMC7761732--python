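"""Pedigree, SNP-based and ROH-based relationship matrices, and the
comparison of the inbreeding coefficients they imply.

* :func:`pedigree_a_matrix` -- the numerator relationship matrix A by the
  tabular (recursive) method: founders are unrelated and non-inbred;
  a(i,j) = 0.5 [a(j, sire_i) + a(j, dam_i)] for previously processed j,
  a(i,i) = 1 + 0.5 a(sire_i, dam_i).  The diagonal is 1 + F with F the
  pedigree inbreeding coefficient; unknown parents contribute 0 (treated
  as unrelated founders).

* :func:`vanraden_g` -- the genomic relationship matrix
  G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the genotype matrix centred by
  twice the sample allele frequencies.  Missing genotypes are mean-imputed
  (replaced by 2 p_j) before centring, which leaves their Z entries at
  exactly zero.

* :func:`roh_relationship` -- a relationship matrix from ROH sharing: the
  numerator for a pair is the total length of their overlapping ROH;
  the scale is the population sum over distinct overlap regions of
  (region frequency x region length), so longer and more widely shared
  runs carry proportionally more weight and the statistic is
  dimensionless and symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, Pedigree, StructuralError
from .runs_detection import RunSet

__all__ = [
    "RelationshipMatrix",
    "InbreedingComparison",
    "pedigree_a_matrix",
    "vanraden_g",
    "roh_relationship",
    "compare_inbreeding",
]


@dataclass
class RelationshipMatrix:
    """Square symmetric animal x animal matrix with labelled axes."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "A" | "G" | "ROH"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise StructuralError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise StructuralError("relationship matrix is not symmetric")

    def inbreeding(self) -> pd.Series:
        """Diagonal minus one (meaningful for kind='A': F = a_ii - 1)."""
        return pd.Series(np.diag(self.values) - 1.0,
                         index=pd.Index(self.labels, name="animal"), name="F")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="animal")

    def to_long_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tvalue\n")
            for a, row in zip(self.labels, self.values):
                for b, v in zip(self.labels, row):
                    fh.write(f"{a}\t{b}\t{v:.10g}\n")

    def reorder(self, labels: Sequence[str]) -> "RelationshipMatrix":
        idx = [self.labels.index(l) for l in labels]
        return RelationshipMatrix(list(labels),
                                  self.values[np.ix_(idx, idx)], self.kind)


def pedigree_a_matrix(pedigree: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Requires the pedigree in topological order (guaranteed by
    :class:`~rohkit.genotype_io.Pedigree`); unknown parents are treated as
    unrelated, non-inbred founders.
    """
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    if np.any(sire >= np.arange(n)) or np.any(dam >= np.arange(n)):
        raise StructuralError("pedigree order violates the sort contract")
    a = np.zeros((n, n))
    for i in range(n):
        si, di = sire[i], dam[i]
        row = np.zeros(i)
        if si >= 0:
            row += a[si, :i]
        if di >= 0:
            row += a[di, :i]
        a[i, :i] = a[:i, i] = 0.5 * row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return RelationshipMatrix(pedigree.animals, a, "A")


def vanraden_g(genotypes: GenotypeMatrix) -> RelationshipMatrix:
    """Genomic relationship matrix from centred genotype dosages.

    Frequencies come from the analysed sample; monomorphic SNPs contribute
    zero to both numerator and scale.  Missing calls are mean-imputed.
    """
    if genotypes.n_samples < 2:
        raise StructuralError("G needs at least two animals")
    vals = genotypes.values.astype(float)
    nonmiss = genotypes.values != MISSING
    n = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(nonmiss, vals, 0.0).sum(axis=0) / (2 * n),
                     0.0)
    vals = np.where(nonmiss, vals, 2 * p[None, :])
    z = vals - 2 * p[None, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise StructuralError("all SNPs monomorphic: zero VanRaden scale")
    g = (z @ z.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against float noise
    return RelationshipMatrix(list(genotypes.samples), g, "G")


def roh_relationship(runsets: RunSet | Sequence[RunSet],
                     denominator: str = "population") -> RelationshipMatrix:
    """ROH-overlap relationship matrix.

    ``runsets`` is either one RunSet covering all animals or a sequence of
    per-animal RunSets from the same panel and parameters (checked via
    provenance; mixing provenances raises).

    numerator(i, j): total bp of pairwise intersection of i's and j's runs
    (numerator(i, i) = total run length of i).  With
    ``denominator="population"`` (default) every entry is scaled by
    sum over distinct overlap regions of (carrier frequency x length),
    where overlap regions are maximal intervals of constant carrier count;
    with ``denominator="pair"`` each entry (i, j) is scaled by that sum
    restricted to regions carried by i or j.
    """
    if denominator not in ("population", "pair"):
        raise ValueError("denominator must be 'population' or 'pair'")
    if isinstance(runsets, RunSet):
        runset = runsets
    else:
        runsets = list(runsets)
        if not runsets:
            raise StructuralError("no RunSets given")
        keys = {(rs.provenance.get("panel_hash"),
                 str(rs.provenance.get("params"))) for rs in runsets}
        if len(keys) > 1:
            raise StructuralError(
                "RunSets come from different panels or parameters")
        runset = RunSet(
            pd.concat([rs.df for rs in runsets], ignore_index=True),
            dict(runsets[0].provenance,
                 samples=sorted({s for rs in runsets for s in rs.samples})),
        )
    animals = runset.samples or sorted(runset.df["animal"].unique())
    index = {a: k for k, a in enumerate(animals)}
    n = len(animals)
    numer = np.zeros((n, n))
    denom_pop = 0.0
    cover_sum = np.zeros(n)  # per-animal sum of freq-weighted covered length

    for _, grp in runset.df.groupby("chrom", sort=False):
        # sweep line over run boundaries: elementary intervals with a
        # constant carrier set
        starts = grp["start_bp"].to_numpy(dtype=np.int64)
        ends = grp["end_bp"].to_numpy(dtype=np.int64)  # treat [start, end)
        who = np.array([index[a] for a in grp["animal"]], dtype=np.int64)
        cuts = np.unique(np.concatenate([starts, ends]))
        if cuts.size < 2:
            continue
        lengths = np.diff(cuts).astype(float)
        # carrier matrix: elementary interval x animal
        cov = np.zeros((cuts.size - 1, n))
        lo = np.searchsorted(cuts, starts, side="left")
        hi = np.searchsorted(cuts, ends, side="left")
        for a_i, l_i, h_i in zip(who, lo, hi):
            cov[l_i:h_i, a_i] = 1.0
        numer += cov.T @ (cov * lengths[:, None])
        carriers = cov.sum(axis=1)
        w = lengths * carriers / n
        denom_pop += float(w.sum())
        cover_sum += cov.T @ w

    if denominator == "population":
        if denom_pop <= 0:
            raise StructuralError("no ROH in any animal: zero denominator")
        values = numer / denom_pop
    else:
        pair_denom = cover_sum[:, None] + cover_sum[None, :] - \
            _pair_shared(runset, animals, n)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(pair_denom > 0, numer / pair_denom, 0.0)
        values = (values + values.T) / 2.0
    return RelationshipMatrix(animals, values, "ROH")


def _pair_shared(runset: RunSet, animals: list[str], n: int) -> np.ndarray:
    """Freq-weighted length of regions carried by both i and j (the
    inclusion-exclusion term of the per-pair denominator)."""
    index = {a: k for k, a in enumerate(animals)}
    shared = np.zeros((n, n))
    for _, grp in runset.df.groupby("chrom", sort=False):
        starts = grp["start_bp"].to_numpy(dtype=np.int64)
        ends = grp["end_bp"].to_numpy(dtype=np.int64)
        who = np.array([index[a] for a in grp["animal"]], dtype=np.int64)
        cuts = np.unique(np.concatenate([starts, ends]))
        if cuts.size < 2:
            continue
        lengths = np.diff(cuts).astype(float)
        cov = np.zeros((cuts.size - 1, n))
        lo = np.searchsorted(cuts, starts, side="left")
        hi = np.searchsorted(cuts, ends, side="left")
        for a_i, l_i, h_i in zip(who, lo, hi):
            cov[l_i:h_i, a_i] = 1.0
        carriers = cov.sum(axis=1)
        w = lengths * carriers / n
        shared += cov.T @ (cov * w[:, None])
    return shared


@dataclass
class InbreedingComparison:
    """Joined inbreeding coefficients and their correlation matrices."""

    table: pd.DataFrame      # per animal: f_ped, fis, froh_total, froh bins
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    excluded: list[str]

    @property
    def n(self) -> int:
        return len(self.table)


def compare_inbreeding(f_ped: pd.Series | None, fis_table: pd.DataFrame,
                       froh_table: pd.DataFrame) -> InbreedingComparison:
    """Inner-join pedigree F, FIS and FROH (total + per length bin) on
    animal id and compute Pearson and Spearman correlation matrices.

    ``f_ped`` may be None (no pedigree available), in which case the
    comparison covers the genomic coefficients only.  Fewer than three
    joined animals raises.
    """
    pieces = {"fis": fis_table["fis"]}
    for c in froh_table.columns:
        pieces[c] = froh_table[c]
    if f_ped is not None:
        pieces = {"f_ped": f_ped, **pieces}
    df = pd.DataFrame(pieces).dropna()
    all_ids = set().union(*(set(s.index) for s in pieces.values()))
    excluded = sorted(all_ids - set(df.index))
    if len(df) < 3:
        raise StructuralError(
            f"only {len(df)} animals with every coefficient; need >= 3")
    return InbreedingComparison(
        table=df,
        pearson=df.corr(method="pearson"),
        spearman=df.corr(method="spearman"),
        excluded=excluded,
    )
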