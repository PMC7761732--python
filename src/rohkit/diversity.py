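"""Per-SNP diversity statistics and the excess-homozygosity inbreeding
coefficient FIS.

Per SNP: counted-allele frequency *p*, minor allele frequency
``maf = min(p, 1-p)``, observed heterozygosity HO (fraction of
heterozygous calls among non-missing calls) and expected heterozygosity
HE = 2p(1-p).  HE is reported without a sample-size correction; the
unbiased variant 2p(1-p)·n/(n-1) is exposed as an extra column.

Per animal, FIS follows the method-of-moments estimator on genotype
counts: with O(hom) the observed number of homozygous calls and E(hom)
the expected number under Hardy-Weinberg,

    E(hom) = sum over the animal's non-missing SNPs j of
             [1 - 2 p_j (1 - p_j) * n_j / (n_j - 1)],
    FIS    = (O(hom) - E(hom)) / (N - E(hom)),

where n_j is the number of non-missing genotypes at SNP j and N the
animal's non-missing call count.  The n/(n-1) factor is the finite-sample
correction of the expected heterozygosity.  Negative values indicate
lower-than-average homozygosity.  Allele frequencies are always computed
from the analysed sample itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, StructuralError

__all__ = ["SnpStats", "FisTable", "snp_stats", "fis"]


@dataclass
class SnpStats:
    """Per-SNP statistics plus panel-wide means/SDs."""

    table: pd.DataFrame  # columns p, maf, ho, he, he_unbiased, n_nonmissing
    summary: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class FisTable:
    """Per-animal FIS; ``fis`` is NaN where undefined (N == E(hom))."""

    table: pd.DataFrame  # index animal: n_nonmissing, o_hom, e_hom, fis

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="animal")


def _freqs(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counted-allele frequency and non-missing count per SNP."""
    nonmiss = values != MISSING
    n = nonmiss.sum(axis=0)
    dose = np.where(nonmiss, values, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, dose / (2.0 * n), np.nan)
    return p, n


def snp_stats(genotypes: GenotypeMatrix) -> SnpStats:
    """Compute per-SNP p, MAF, HO and HE, and their panel means.

    SNPs with no non-missing call get NaN statistics and are reported in
    ``summary["n_snps_no_calls"]`` rather than raising.
    """
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise StructuralError("empty genotype matrix")
    vals = genotypes.values
    p, n = _freqs(vals)
    nonmiss = vals != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n > 0, (vals == 1).sum(axis=0) / n, np.nan)
    he = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        he_unbiased = np.where(n > 1, he * n / (n - 1.0), np.nan)
    maf = np.minimum(p, 1.0 - p)
    table = pd.DataFrame({
        "p": p, "maf": maf, "ho": ho, "he": he,
        "he_unbiased": he_unbiased, "n_nonmissing": n,
    })
    ok = n > 0
    summary = {
        "mean_ho": float(np.nanmean(ho[ok])),
        "sd_ho": float(np.nanstd(ho[ok])),
        "mean_he": float(np.nanmean(he[ok])),
        "sd_he": float(np.nanstd(he[ok])),
        "mean_maf": float(np.nanmean(maf[ok])),
        "sd_maf": float(np.nanstd(maf[ok])),
        "n_snps": int(genotypes.n_snps),
        "n_snps_no_calls": int((~ok).sum()),
    }
    return SnpStats(table, summary)


def fis(genotypes: GenotypeMatrix) -> FisTable:
    """Per-animal method-of-moments inbreeding coefficient (see module
    docstring).  SNPs with fewer than two non-missing genotypes are
    excluded from every animal's sums."""
    if genotypes.n_samples < 2:
        raise StructuralError("FIS needs at least two samples")
    vals = genotypes.values
    p, n = _freqs(vals)
    usable = n >= 2
    n_excluded = int((~usable).sum())
    if n_excluded:
        import logging
        logging.getLogger(__name__).warning(
            "%d SNPs with fewer than 2 calls excluded from FIS", n_excluded)
    # expected-homozygosity term per SNP, with the n/(n-1) correction
    with np.errstate(invalid="ignore", divide="ignore"):
        term = 1.0 - 2.0 * p * (1.0 - p) * n / (n - 1.0)
    term = np.where(usable, term, 0.0)

    nonmiss = (vals != MISSING) & usable[None, :]
    o_hom = (((vals == 0) | (vals == 2)) & usable[None, :]).sum(axis=1)
    e_hom = nonmiss @ term
    n_nm = nonmiss.sum(axis=1)
    denom = n_nm - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (o_hom - e_hom) / denom, np.nan)
    table = pd.DataFrame({
        "n_nonmissing": n_nm, "o_hom": o_hom, "e_hom": e_hom, "fis": f,
    }, index=pd.Index(genotypes.samples, name="animal"))
    return FisTable(table)
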