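"""Reading, writing and quality control of SNP-chip genotype data.

The on-disk formats are the PLINK text formats: a 4-column MAP file
(chromosome, SNP id, genetic position in cM, physical position in bp) and a
PED file (six mandatory columns followed by two allele columns per SNP).
Genotypes are held in memory as an animals x SNPs matrix of counted-allele
dosages in {0, 1, 2} with ``MISSING`` (-1) as the missing sentinel.

Quality control follows the usual SNP-chip workflow for a single-breed
panel: non-autosomal markers are dropped, then low call-rate SNPs, then
high-missingness animals.  No MAF filter is applied -- rare alleles are
informative for homozygosity detection and removing them would bias run
calling in a single-population study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: Missing-genotype sentinel used throughout the package.
MISSING: int = -1

#: Chromosome labels excluded by the default autosome filter.
DEFAULT_EXCLUDED_CHROMS = frozenset({"X", "Y", "MT", "0"})


class ParseError(ValueError):
    """Malformed input file (names the offending line where possible)."""


class StructuralError(ValueError):
    """Inconsistent dimensions or broken cross-file structure."""


def chrom_sort_key(label: str):
    """Sort key placing numeric chromosome labels first, in numeric order."""
    try:
        return (0, int(label), "")
    except (TypeError, ValueError):
        return (1, 0, str(label))


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class MarkerMap:
    """Ordered SNP metadata defining the genome coordinate system.

    ``table`` has columns ``snp_id``, ``chrom`` (opaque string label),
    ``cm`` (genetic position, preserved but unused) and ``pos_bp``
    (1-based physical position).  Rows are sorted by (chromosome, position)
    and positions are strictly increasing within each chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["snp_id", "chrom", "cm", "pos_bp"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise StructuralError(f"marker map lacks columns {missing}")
        self.table = self.table[required].reset_index(drop=True)
        self.table["chrom"] = self.table["chrom"].astype(str)
        self.table["pos_bp"] = self.table["pos_bp"].astype(np.int64)
        if self.table["snp_id"].duplicated().any():
            dup = self.table.loc[self.table["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise StructuralError(f"duplicate SNP id {dup!r} in marker map")
        for chrom, idx in self.chrom_blocks():
            pos = self.table["pos_bp"].to_numpy()[idx]
            if np.any(np.diff(pos) <= 0):
                raise StructuralError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def positions(self) -> np.ndarray:
        return self.table["pos_bp"].to_numpy()

    @property
    def chroms(self) -> list[str]:
        """Chromosome labels in map order (unique, order-preserving)."""
        seen: dict[str, None] = {}
        for c in self.table["chrom"]:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_blocks(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chromosome, row-index array) in map order."""
        chroms = self.table["chrom"].to_numpy()
        for c in self.chroms:
            yield c, np.flatnonzero(chroms == c)

    def covered_length_mb(self) -> float:
        """Total genome span covered by the panel: sum over chromosomes of
        (last SNP - first SNP) in Mb.  Default LAUTO for FROH."""
        total = 0
        for _, idx in self.chrom_blocks():
            pos = self.table["pos_bp"].to_numpy()[idx]
            total += int(pos[-1] - pos[0])
        return total / 1e6

    def subset(self, rows: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.table.iloc[rows].reset_index(drop=True))


@dataclass
class GenotypeMatrix:
    """Animals x SNPs counted-allele dosages, aligned to a :class:`MarkerMap`."""

    samples: list[str]
    values: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2:
            raise StructuralError("genotype matrix must be 2-dimensional")
        if self.values.shape[0] != len(self.samples):
            raise StructuralError(
                f"{len(self.samples)} sample ids but {self.values.shape[0]} rows"
            )
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise StructuralError(
                f"invalid genotype code {int(self.values[i, j])} at "
                f"sample {self.samples[i]!r}, SNP column {j}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.values == MISSING

    def subset(self, sample_rows: np.ndarray | None = None,
               snp_cols: np.ndarray | None = None) -> "GenotypeMatrix":
        vals = self.values
        samples = self.samples
        if sample_rows is not None:
            vals = vals[sample_rows]
            samples = [samples[i] for i in np.atleast_1d(sample_rows)]
        if snp_cols is not None:
            vals = vals[:, snp_cols]
        return GenotypeMatrix(list(samples), vals.copy())


@dataclass
class Pedigree:
    """Animal-sire-dam records, stored in an order where parents precede
    offspring.  Unknown parents are ``None`` (founders)."""

    table: pd.DataFrame  # columns animal, sire, dam (+ optional extras)

    def __post_init__(self) -> None:
        for c in ("animal", "sire", "dam"):
            if c not in self.table.columns:
                raise StructuralError(f"pedigree lacks column {c!r}")
        self.table = self.table.reset_index(drop=True)
        if self.table["animal"].duplicated().any():
            dup = self.table.loc[self.table["animal"].duplicated(), "animal"].iloc[0]
            raise StructuralError(f"duplicate pedigree record for {dup!r}")
        pos = {a: i for i, a in enumerate(self.table["animal"])}
        for i, (a, s, d) in enumerate(
            self.table[["animal", "sire", "dam"]].itertuples(index=False)
        ):
            for p in (s, d):
                if p is not None and (p not in pos or pos[p] >= i):
                    raise StructuralError(
                        f"parent {p!r} of {a!r} does not precede it; "
                        "pedigree must be topologically sorted"
                    )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def animals(self) -> list[str]:
        return list(self.table["animal"])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire and dam per animal, -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.table["animal"])}
        sire = np.array([pos.get(s, -1) if s is not None else -1
                         for s in self.table["sire"]], dtype=np.int64)
        dam = np.array([pos.get(d, -1) if d is not None else -1
                        for d in self.table["dam"]], dtype=np.int64)
        return sire, dam


@dataclass
class QcReport:
    """Counts removed at each QC step, in execution order."""

    n_snps_in: int
    n_samples_in: int
    n_snps_nonautosomal: int
    n_snps_low_call_rate: int
    n_samples_high_missing: int
    n_snps_out: int
    n_samples_out: int
    snp_call_rate_threshold: float
    sample_missing_threshold: float
    removed_samples: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# PED/MAP reading and writing
# ---------------------------------------------------------------------------


def _read_map_table(map_path: str | Path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise ParseError(
                    f"{map_path}, line {lineno}: expected 4 columns, got {len(tok)}"
                )
            rows.append((tok[1], tok[0], float(tok[2]), int(tok[3])))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "cm", "pos_bp"])


def read_ped_map(ped_path: str | Path,
                 map_path: str | Path) -> tuple[GenotypeMatrix, MarkerMap]:
    """Read PLINK text PED/MAP into a genotype matrix and marker map.

    Alleles are recoded per SNP as counts of the first allele symbol
    encountered in file order (a deterministic, file-defined choice); the
    allele pair ``0 0`` (or any pair containing ``0``) becomes MISSING.
    SNP columns are reordered to follow the map sorted by (chromosome,
    position).
    """
    raw_map = _read_map_table(map_path)
    n_snps = len(raw_map)

    samples: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) < 6 or (len(tok) - 6) % 2 != 0:
                raise ParseError(
                    f"{ped_path}, line {lineno}: ragged row "
                    f"({len(tok)} fields; expected 6 + 2 alleles per SNP)"
                )
            if (len(tok) - 6) // 2 != n_snps:
                raise StructuralError(
                    f"{ped_path}, line {lineno}: {(len(tok) - 6) // 2} SNPs "
                    f"but MAP file has {n_snps}"
                )
            samples.append(tok[1])
            allele_rows.append(np.array(tok[6:], dtype="U8"))

    n_samples = len(samples)
    if n_samples:
        alleles = np.stack(allele_rows).reshape(n_samples, n_snps, 2)
        geno = _recode_alleles(alleles, ped_path)
    else:
        geno = np.zeros((0, n_snps), dtype=np.int8)

    order = sorted(
        range(n_snps),
        key=lambda i: (chrom_sort_key(raw_map["chrom"].iat[i]),
                       raw_map["pos_bp"].iat[i]),
    )
    order = np.asarray(order, dtype=np.int64)
    marker_map = MarkerMap(raw_map.iloc[order].reset_index(drop=True))
    return GenotypeMatrix(samples, geno[:, order]), marker_map


def _recode_alleles(alleles: np.ndarray, ped_path) -> np.ndarray:
    """(n_samples, n_snps, 2) allele symbols -> dosage codes."""
    n_samples, n_snps, _ = alleles.shape
    # per-SNP alleles in encounter order: sample-major, first then second
    per_snp = alleles.transpose(1, 0, 2).reshape(n_snps, n_samples * 2)
    observed = per_snp != "0"
    has_call = observed.any(axis=1)
    first_idx = np.argmax(observed, axis=1)
    counted = np.take_along_axis(per_snp, first_idx[:, None], axis=1)[:, 0]
    counted = np.where(has_call, counted, "?")
    other_mask = observed & (per_snp != counted[:, None])
    has_other = other_mask.any(axis=1)
    other_idx = np.argmax(other_mask, axis=1)
    other = np.take_along_axis(per_snp, other_idx[:, None], axis=1)[:, 0]
    other = np.where(has_other, other, counted)
    extra = observed & (per_snp != counted[:, None]) & (per_snp != other[:, None])
    if extra.any():
        j = int(np.argwhere(extra.any(axis=1))[0, 0])
        raise ParseError(
            f"{ped_path}: SNP column {j} has more than two allele symbols"
        )
    miss = (alleles == "0").any(axis=2)
    geno = (alleles == counted[None, :, None]).sum(axis=2).astype(np.int8)
    geno[miss] = MISSING
    return geno


def write_ped_map(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                  ped_path: str | Path, map_path: str | Path,
                  family_id: str = "FAM") -> None:
    """Write PLINK text PED/MAP.  The counted allele is written as ``A``,
    the other as ``B``; heterozygotes are written ``A B``; MISSING as
    ``0 0``.  The result is re-readable by :func:`read_ped_map` (identical
    up to per-SNP allele relabelling; write-read-write is a fixpoint)."""
    if genotypes.n_snps != marker_map.n_snps:
        raise StructuralError(
            f"{genotypes.n_snps} genotype columns vs {marker_map.n_snps} map rows"
        )
    with open(map_path, "w") as fh:
        for row in marker_map.table.itertuples(index=False):
            cm = int(row.cm) if float(row.cm).is_integer() else row.cm
            fh.write(f"{row.chrom}\t{row.snp_id}\t{cm}\t{row.pos_bp}\n")
    pair = {2: "A A", 1: "A B", 0: "B B", MISSING: "0 0"}
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(genotypes.samples):
            fields = [family_id, sample, "0", "0", "0", "-9"]
            fields.extend(pair[int(g)] for g in genotypes.values[i])
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# pedigree reading
# ---------------------------------------------------------------------------

_UNKNOWN_TOKENS = {"0", "", "NA", "na", ".", "nan", "None"}
_HEADER_TOKENS = {"animal", "id", "iid", "sample", "individual"}


def _normalise_parent(tok: str | None) -> str | None:
    if tok is None or str(tok) in _UNKNOWN_TOKENS:
        return None
    return str(tok)


def topological_sort(records: Sequence[tuple[str, str | None, str | None]]
                     ) -> list[tuple[str, str | None, str | None]]:
    """Kahn's algorithm, stable with respect to input order.

    Raises :class:`StructuralError` listing one cycle if the parent
    relation is cyclic (e.g. an animal among its own ancestors).
    """
    rec = {a: (s, d) for a, s, d in records}
    order_hint = {a: i for i, (a, _, _) in enumerate(records)}
    children: dict[str, list[str]] = {a: [] for a in rec}
    indeg = {a: 0 for a in rec}
    for a, (s, d) in rec.items():
        for p in {p for p in (s, d) if p is not None}:
            children[p].append(a)
            indeg[a] += 1
    ready = sorted((a for a, k in indeg.items() if k == 0), key=order_hint.get)
    out: list[tuple[str, str | None, str | None]] = []
    import heapq

    heap = [(order_hint[a], a) for a in ready]
    heapq.heapify(heap)
    while heap:
        _, a = heapq.heappop(heap)
        s, d = rec[a]
        out.append((a, s, d))
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (order_hint[c], c))
    if len(out) < len(rec):
        remaining = {a for a in rec if indeg[a] > 0}
        start = next(iter(sorted(remaining, key=order_hint.get)))
        cycle = [start]
        node = start
        while True:
            s, d = rec[node]
            node = next(p for p in (s, d) if p in remaining)
            if node in cycle:
                cycle.append(node)
                break
            cycle.append(node)
        raise StructuralError(
            "pedigree contains a cycle: " + " -> ".join(cycle)
        )
    return out


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a 3-column animal/sire/dam file (whitespace- or comma-separated).

    ``0`` or an empty field denotes an unknown parent.  Parents named but
    lacking their own record are added as founders.  The result is
    topologically sorted (parents before offspring).
    """
    text = Path(path).read_text()
    sep = "," if ("," in text.splitlines()[0] if text.splitlines() else False) else None
    records: list[tuple[str, str | None, str | None]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        tok = [t.strip() for t in (line.split(sep) if sep else line.split())]
        tok = [t for t in tok if t != ""] if sep is None else tok
        if not tok or not any(tok):
            continue
        if lineno == 1 and tok[0].lower() in _HEADER_TOKENS:
            continue
        if len(tok) < 3:
            raise ParseError(f"{path}, line {lineno}: expected 3 columns")
        records.append((tok[0], _normalise_parent(tok[1]), _normalise_parent(tok[2])))
    return pedigree_from_records(records)


def pedigree_from_records(
    records: Iterable[tuple[str, str | None, str | None]]
) -> Pedigree:
    """Build a sorted :class:`Pedigree`, adding founder records for any
    parent that has no record of its own."""
    records = list(records)
    known = {a for a, _, _ in records}
    implicit = []
    for _, s, d in records:
        for p in (s, d):
            if p is not None and p not in known:
                implicit.append((p, None, None))
                known.add(p)
    ordered = topological_sort(implicit + records)
    return Pedigree(pd.DataFrame(ordered, columns=["animal", "sire", "dam"]))


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    df = pedigree.table[["animal", "sire", "dam"]].copy()
    for c in ("sire", "dam"):
        df[c] = [p if p is not None else "0" for p in df[c]]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


def apply_qc(genotypes: GenotypeMatrix, marker_map: MarkerMap,
             min_snp_call_rate: float = 0.95,
             max_sample_missing: float = 0.15,
             drop_nonautosomal: bool = True,
             excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
             ) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Apply the standard QC cascade, in fixed order.

    1. drop SNPs on excluded (sex/unplaced) chromosome labels;
    2. drop SNPs with call rate below ``min_snp_call_rate`` (keep at
       exactly the threshold);
    3. drop animals with missing fraction strictly above
       ``max_sample_missing`` (an animal at exactly the threshold is kept).

    No MAF filter is applied.
    """
    if not (0 <= min_snp_call_rate <= 1 and 0 <= max_sample_missing <= 1):
        raise ValueError("QC thresholds must lie in [0, 1]")
    if genotypes.n_snps != marker_map.n_snps:
        raise StructuralError("genotypes and map have different SNP counts")

    n_snps_in, n_samples_in = genotypes.n_snps, genotypes.n_samples

    chroms = marker_map.table["chrom"].to_numpy()
    if drop_nonautosomal:
        keep_auto = ~np.isin(chroms, list(excluded_chroms))
    else:
        keep_auto = np.ones(n_snps_in, dtype=bool)
    n_nonauto = int((~keep_auto).sum())

    vals = genotypes.values[:, keep_auto]
    nonmiss = vals != MISSING
    if n_samples_in > 0:
        call_rate = nonmiss.mean(axis=0)
    else:
        call_rate = np.ones(vals.shape[1])
    keep_snp = call_rate >= min_snp_call_rate
    n_lowcall = int((~keep_snp).sum())

    snp_cols = np.flatnonzero(keep_auto)[keep_snp]
    if snp_cols.size == 0:
        raise StructuralError("QC removed every SNP; no panel left to analyse")

    vals = genotypes.values[:, snp_cols]
    miss_frac = (vals == MISSING).mean(axis=1) if vals.shape[1] else np.zeros(n_samples_in)
    keep_sample = miss_frac <= max_sample_missing  # strictly ">" removed
    removed_samples = [s for s, k in zip(genotypes.samples, keep_sample) if not k]

    out_g = GenotypeMatrix(
        [s for s, k in zip(genotypes.samples, keep_sample) if k],
        vals[keep_sample].copy(),
    )
    out_m = marker_map.subset(snp_cols)
    report = QcReport(
        n_snps_in=n_snps_in,
        n_samples_in=n_samples_in,
        n_snps_nonautosomal=n_nonauto,
        n_snps_low_call_rate=n_lowcall,
        n_samples_high_missing=len(removed_samples),
        n_snps_out=out_g.n_snps,
        n_samples_out=out_g.n_samples,
        snp_call_rate_threshold=min_snp_call_rate,
        sample_missing_threshold=max_sample_missing,
        removed_samples=removed_samples,
    )
    return out_g, out_m, report
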