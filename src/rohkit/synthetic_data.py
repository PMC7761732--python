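"""Gene-drop simulation of SNP genotypes with known autozygosity.

Founder haplotypes are drawn from per-SNP allele frequencies and dropped
through a pedigree with recombination.  Crossovers are placed as a Poisson
process along each chromosome (Haldane model, no interference) at a fixed
cM/Mb rate, so autozygous tract lengths follow the classical exponential
expectation: segments inherited from a common ancestor ``g`` generations
back have mean length 100/(2g) cM.  Each transmitted chromosome carries its
founder-haplotype origin labels, so the simulator knows exactly which
genome segments are identical by descent; the :class:`TruthTrack` records
those segments and the true autozygous fraction per animal, against which
run detectors and inbreeding estimators can be validated.

The default configuration emulates a small two-herd beef-cattle population
genotyped on a medium-density (~50k) array: 29 autosomes of 87.6 Mb
(~2540 Mb total), 1700 SNPs per chromosome, a shallow 4-generation pedigree
of ~150 animals, modest genotyping error and missingness.

The module also provides :func:`plant_runs`, a deterministic fixture
builder that embeds known homozygous or heterozygous runs (with a stated
number of blemishes) in an alternating het/hom background, for oracle
testing of the run detectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    StructuralError,
    pedigree_from_records,
)

__all__ = [
    "SimulationConfig",
    "TruthTrack",
    "PlantedRun",
    "simulate_pedigree",
    "gene_drop",
    "plant_runs",
    "truth_track_from_bed",
]


@dataclass
class SimulationConfig:
    """Parameters of the pedigree + gene-drop simulation.

    Defaults describe the study conditions this package is exercised
    under: a ~150-head, 4-generation, two-family-farm cattle population on
    a ~49k-SNP autosomal panel spanning ~2540 Mb, at 1 cM/Mb.
    """

    n_founders: int = 30
    n_generations: int = 4
    offspring_per_mating: int = 2
    mating_design: str = "random"  # random | circular | full_sib_loop
    n_chrom: int = 29
    snps_per_chrom: int = 1700
    chrom_length_mb: float = 87.6
    founder_maf_low: float = 0.05
    founder_maf_high: float = 0.5
    cm_per_mb: float = 1.0
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.005
    seed: int = 0
    two_herds: bool = False
    inbred_founders: bool = False  # founders carry two copies of one haplotype

    def __post_init__(self) -> None:
        if self.mating_design not in ("random", "circular", "full_sib_loop"):
            raise ValueError(f"unknown mating design {self.mating_design!r}")
        for name in ("genotyping_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0 < self.founder_maf_low <= self.founder_maf_high <= 0.5):
            raise ValueError("founder MAF bounds must satisfy 0 < low <= high <= 0.5")
        if self.n_founders < 2 or self.n_founders % 2:
            raise ValueError("n_founders must be even (paired matings) and >= 2")
        if self.mating_design == "full_sib_loop" and self.offspring_per_mating < 2:
            raise ValueError("full_sib_loop needs >= 2 offspring per mating")
        if min(self.n_chrom, self.snps_per_chrom) < 1 or self.chrom_length_mb <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    @property
    def chrom_length_bp(self) -> int:
        return int(round(self.chrom_length_mb * 1e6))


@dataclass
class TruthTrack:
    """True autozygous (IBD) segments per animal, at recombination-breakpoint
    resolution.  ``segments`` columns: animal, chrom, start_bp, end_bp
    (1-based, inclusive).  ``fraction`` is the exact autozygous genome
    fraction per animal (sum of segment lengths / total genome length)."""

    segments: pd.DataFrame
    fraction: pd.Series
    chrom_lengths: dict[str, int]

    @property
    def genome_length_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def segments_for(self, animal: str) -> pd.DataFrame:
        return self.segments[self.segments["animal"] == animal]

    def to_bed(self, path: str | Path) -> None:
        """Write segments as BED (0-based, half-open), one row per segment,
        name column = animal id."""
        with open(path, "w") as fh:
            for row in self.segments.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t{row.animal}\n"
                )


def truth_track_from_bed(path: str | Path,
                         chrom_lengths: dict[str, int]) -> TruthTrack:
    """Inverse of :meth:`TruthTrack.to_bed` (BED 0-based half-open back to
    1-based inclusive)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            rows.append((tok[3], tok[0], int(tok[1]) + 1, int(tok[2])))
    seg = pd.DataFrame(rows, columns=["animal", "chrom", "start_bp", "end_bp"])
    total = sum(chrom_lengths.values())
    lengths = seg["end_bp"] - seg["start_bp"] + 1
    frac = lengths.groupby(seg["animal"]).sum() / total
    frac.name = "fraction"
    return TruthTrack(seg, frac, chrom_lengths)


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig) -> Pedigree:
    """Simulate a pedigree of ``n_generations`` discrete generations on top
    of ``n_founders`` founders.

    Designs:

    * ``random`` -- each generation, n_founders/2 matings pair a random
      sire and dam from the previous generation (with replacement), each
      producing ``offspring_per_mating`` offspring;
    * ``circular`` -- deterministic rotational pairing (male i x female
      i+1), the classical scheme for minimising inbreeding accumulation;
    * ``full_sib_loop`` -- founder pairs start independent full-sib lines:
      every later generation mates two full sibs, so pedigree inbreeding
      follows the textbook recursion (F = 0.25 after one sib mating,
      0.375 after two, ...).

    With ``two_herds`` the founders are split into two clusters mated
    within herd except for occasionally shared sires, mimicking two farms
    connected only through common sires (a ``herd`` column is added).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    records: list[tuple[str, str | None, str | None]] = []
    meta: dict[str, tuple[int, str, int]] = {}  # animal -> (generation, sex, herd)

    founders = [f"FND{i:04d}" for i in range(config.n_founders)]
    half = config.n_founders // 2
    for i, a in enumerate(founders):
        records.append((a, None, None))
        herd = int(config.two_herds and i >= half)
        meta[a] = (0, "M" if i % 2 == 0 else "F", herd)

    def split_by_sex(animals: list[str]) -> tuple[list[str], list[str]]:
        males = [a for a in animals if meta[a][1] == "M"]
        females = [a for a in animals if meta[a][1] == "F"]
        return males, females

    prev = founders
    counter = 0
    for g in range(1, config.n_generations + 1):
        current: list[str] = []
        matings: list[tuple[str, str]] = []
        if config.mating_design == "full_sib_loop":
            if g == 1:
                matings = [(founders[2 * k], founders[2 * k + 1])
                           for k in range(half)]
            else:
                # one sib pair per family line of the previous generation
                fams: dict[tuple[str | None, str | None], list[str]] = {}
                rec = {a: (s, d) for a, s, d in records}
                for a in prev:
                    fams.setdefault(rec[a], []).append(a)
                matings = [(sibs[0], sibs[1]) for sibs in fams.values()
                           if len(sibs) >= 2]
        elif config.mating_design == "circular":
            males, females = split_by_sex(prev)
            n = min(len(males), len(females))
            matings = [(males[k], females[(k + 1) % n]) for k in range(n)]
        else:  # random
            herds = [0, 1] if config.two_herds else [0]
            for herd in herds:
                pool = [a for a in prev if meta[a][2] == herd] \
                    if config.two_herds else prev
                males, females = split_by_sex(pool)
                other = [a for a in prev if meta[a][2] != herd and meta[a][1] == "M"]
                n_matings = max(1, len(pool) // 2)
                for _ in range(n_matings):
                    if config.two_herds and other and rng.random() < 0.2:
                        sire = other[rng.integers(len(other))]  # shared sire
                    else:
                        sire = males[rng.integers(len(males))]
                    dam = females[rng.integers(len(females))]
                    matings.append((sire, dam))
        for sire, dam in matings:
            herd = meta[dam][2]
            for c in range(config.offspring_per_mating):
                a = f"G{g}A{counter:04d}"
                counter += 1
                records.append((a, sire, dam))
                meta[a] = (g, "M" if c % 2 == 0 else "F", herd)
                current.append(a)
        prev = current if current else prev

    ped = pedigree_from_records(records)
    ped.table["generation"] = [meta[a][0] for a in ped.table["animal"]]
    ped.table["sex"] = [meta[a][1] for a in ped.table["animal"]]
    if config.two_herds:
        ped.table["herd"] = [meta[a][2] for a in ped.table["animal"]]
    return ped


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

# A haplotype for one chromosome: SNP alleles plus founder-origin intervals
# [(start_bp, end_bp, origin_id)], half-open 0-based bp covering [0, L).
_Hap = tuple[np.ndarray, list[tuple[int, int, int]]]


def _slice_intervals(iv: list[tuple[int, int, int]], lo: int, hi: int
                     ) -> list[tuple[int, int, int]]:
    out = []
    for s, e, o in iv:
        if e <= lo or s >= hi:
            continue
        out.append((max(s, lo), min(e, hi), o))
    return out


def _meiosis(hap_a: _Hap, hap_b: _Hap, length_bp: int, snp_pos0: np.ndarray,
             morgans: float, rng: np.random.Generator) -> _Hap:
    """One gamete from a parent's two haplotypes, Haldane crossovers."""
    n_xo = rng.poisson(morgans)
    xo = np.sort(rng.integers(1, length_bp, size=n_xo)) if n_xo else \
        np.empty(0, dtype=np.int64)
    start = int(rng.integers(0, 2))
    phase = (start + np.searchsorted(xo, snp_pos0, side="right")) % 2
    alleles = np.where(phase == 0, hap_a[0], hap_b[0]).astype(np.int8)
    cuts = [0, *xo.tolist(), length_bp]
    origins: list[tuple[int, int, int]] = []
    for k in range(len(cuts) - 1):
        lo, hi = cuts[k], cuts[k + 1]
        if hi <= lo:
            continue
        source = hap_a if (start + k) % 2 == 0 else hap_b
        origins.extend(_slice_intervals(source[1], lo, hi))
    # compact adjacent pieces with the same origin
    merged: list[tuple[int, int, int]] = []
    for s, e, o in origins:
        if merged and merged[-1][2] == o and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, o)
        else:
            merged.append((s, e, o))
    return alleles, merged


def _autozygous_intervals(iv_a: list[tuple[int, int, int]],
                          iv_b: list[tuple[int, int, int]]
                          ) -> list[tuple[int, int]]:
    """Intervals where the two haplotypes descend from the same founder
    haplotype; contiguous autozygous pieces are merged."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(iv_a) and j < len(iv_b):
        a_s, a_e, a_o = iv_a[i]
        b_s, b_e, b_o = iv_b[j]
        lo, hi = max(a_s, b_s), min(a_e, b_e)
        if hi > lo and a_o == b_o:
            if out and out[-1][1] == lo:
                out[-1] = (out[-1][0], hi)
            else:
                out.append((lo, hi))
        if a_e <= b_e:
            i += 1
        else:
            j += 1
    return out


def gene_drop(pedigree: Pedigree, config: SimulationConfig
              ) -> tuple[GenotypeMatrix, MarkerMap, TruthTrack]:
    """Drop founder haplotypes through ``pedigree`` with recombination.

    Returns genotypes (with genotyping error and missingness applied),
    the marker map, and the exact IBD truth track.  Any parent recorded as
    unknown receives a fresh, unrelated founder haplotype.  Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    L = config.chrom_length_bp
    n_snps_c = config.snps_per_chrom
    chroms = [str(c + 1) for c in range(config.n_chrom)]
    morgans = config.chrom_length_mb * config.cm_per_mb / 100.0

    # SNPs land at sorted uniform random positions (0-based internally,
    # 1-based in the map): array spacing is irregular, as on real chips
    pos_by_chrom: list[np.ndarray] = []
    for _ in chroms:
        pos = np.unique(rng.integers(0, L, size=n_snps_c))
        while pos.size < n_snps_c:  # rare collisions: top up
            extra = rng.integers(0, L, size=n_snps_c - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        pos_by_chrom.append(pos.astype(np.int64))

    map_rows = []
    for c, snp_pos0 in zip(chroms, pos_by_chrom):
        for k, p0 in enumerate(snp_pos0):
            map_rows.append((f"snp{c}_{k:05d}", c,
                             p0 / 1e6 * config.cm_per_mb, int(p0) + 1))
    marker_map = MarkerMap(
        pd.DataFrame(map_rows, columns=["snp_id", "chrom", "cm", "pos_bp"])
    )

    # per-chromosome counted-allele founder frequencies
    freqs = [rng.uniform(config.founder_maf_low, config.founder_maf_high,
                         size=n_snps_c) for _ in chroms]

    origin_counter = 0

    def founder_pair() -> list[tuple[_Hap, _Hap]]:
        nonlocal origin_counter
        haps = []
        for ci in range(config.n_chrom):
            a1 = (rng.random(n_snps_c) < freqs[ci]).astype(np.int8)
            o1 = origin_counter
            origin_counter += 1
            if config.inbred_founders:
                hap1: _Hap = (a1, [(0, L, o1)])
                haps.append((hap1, (a1.copy(), [(0, L, o1)])))
            else:
                a2 = (rng.random(n_snps_c) < freqs[ci]).astype(np.int8)
                o2 = origin_counter
                origin_counter += 1
                haps.append(((a1, [(0, L, o1)]), (a2, [(0, L, o2)])))
        return haps

    sire_idx, dam_idx = pedigree.parent_indices()
    animals = pedigree.animals
    haplos: list[list[tuple[_Hap, _Hap]]] = []
    for i, _animal in enumerate(animals):
        si, di = sire_idx[i], dam_idx[i]
        if si < 0 and di < 0:
            haplos.append(founder_pair())
            continue
        pat_src = haplos[si] if si >= 0 else founder_pair()
        mat_src = haplos[di] if di >= 0 else founder_pair()
        per_chrom = []
        for ci in range(config.n_chrom):
            gam_p = _meiosis(pat_src[ci][0], pat_src[ci][1], L,
                             pos_by_chrom[ci], morgans, rng)
            gam_m = _meiosis(mat_src[ci][0], mat_src[ci][1], L,
                             pos_by_chrom[ci], morgans, rng)
            per_chrom.append((gam_p, gam_m))
        haplos.append(per_chrom)

    n_animals = len(animals)
    geno = np.empty((n_animals, config.n_chrom * n_snps_c), dtype=np.int8)
    seg_rows = []
    auto_bp = np.zeros(n_animals, dtype=np.int64)
    for i, animal in enumerate(animals):
        for ci, chrom in enumerate(chroms):
            (ap, ivp), (am, ivm) = haplos[i][ci]
            geno[i, ci * n_snps_c:(ci + 1) * n_snps_c] = ap + am
            for lo, hi in _autozygous_intervals(ivp, ivm):
                seg_rows.append((animal, chrom, lo + 1, hi))
                auto_bp[i] += hi - lo

    # missingness first: a masked call cannot also carry an error
    miss = rng.random(geno.shape) < config.missing_rate
    err = (rng.random(geno.shape) < config.genotyping_error_rate) & ~miss
    if err.any():
        flip_to = rng.integers(0, 2, size=geno.shape) * 2  # 0 or 2, for hets
        new = np.where(geno == 1, flip_to, 1).astype(np.int8)
        geno = np.where(err, new, geno).astype(np.int8)
    geno[miss] = MISSING

    segments = pd.DataFrame(
        seg_rows, columns=["animal", "chrom", "start_bp", "end_bp"]
    )
    fraction = pd.Series(auto_bp / (config.n_chrom * L), index=animals,
                         name="fraction")
    truth = TruthTrack(segments, fraction, {c: L for c in chroms})
    return GenotypeMatrix(list(animals), geno), marker_map, truth


# ---------------------------------------------------------------------------
# planted-run fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedRun:
    """Specification of one run to embed in a fixture genotype matrix."""

    animal: int
    chrom: str
    start_bp: int
    end_bp: int
    kind: str  # "hom" | "het"
    n_opposite: int = 0
    n_missing: int = 0


def plant_runs(n_animals: int, marker_map: MarkerMap,
               run_specs: Sequence[PlantedRun | tuple],
               background: str = "alternating") -> GenotypeMatrix:
    """Build a genotype matrix with exactly the specified runs.

    The background alternates heterozygous / homozygous calls so that no
    accidental run of either kind can satisfy realistic minimum-SNP
    thresholds.  Inside each spec window genotypes are forced to the
    target state, except ``n_opposite`` opposite-state and ``n_missing``
    missing calls placed at deterministic, evenly spaced interior
    positions (window endpoints always carry the target state).  The SNPs
    immediately flanking each window are forced to the opposite state so
    the planted run cannot silently extend into the background.
    """
    if background != "alternating":
        raise ValueError("only the 'alternating' background is implemented")
    specs = [s if isinstance(s, PlantedRun) else PlantedRun(*s) for s in run_specs]
    n_snps = marker_map.n_snps
    idx_in_chrom: dict[str, np.ndarray] = dict(marker_map.chrom_blocks())
    pos = marker_map.positions

    base = np.where(np.arange(n_snps) % 2 == 0, 1, 2).astype(np.int8)
    geno = np.tile(base, (n_animals, 1))

    claimed: dict[int, list[tuple[int, int]]] = {}
    for spec in specs:
        if spec.kind not in ("hom", "het"):
            raise ValueError(f"unknown run kind {spec.kind!r}")
        if not 0 <= spec.animal < n_animals:
            raise StructuralError(f"animal index {spec.animal} out of range")
        rows = idx_in_chrom.get(spec.chrom)
        if rows is None:
            raise StructuralError(f"chromosome {spec.chrom!r} not in map")
        inside = rows[(pos[rows] >= spec.start_bp) & (pos[rows] <= spec.end_bp)]
        m = inside.size
        blemishes = spec.n_opposite + spec.n_missing
        if m < blemishes + 2:
            raise ValueError(
                f"window holds {m} SNPs; needs >= {blemishes + 2} for "
                f"{blemishes} blemishes plus target-state endpoints"
            )
        for lo, hi in claimed.get(spec.animal, []):
            if not (spec.end_bp < lo or spec.start_bp > hi):
                raise ValueError(
                    f"overlapping run specs for animal {spec.animal} "
                    f"on chromosome {spec.chrom}"
                )
        claimed.setdefault(spec.animal, []).append((spec.start_bp, spec.end_bp))

        target, opposite = (2, 1) if spec.kind == "hom" else (1, 2)
        geno[spec.animal, inside] = target
        # evenly spaced interior blemish slots
        slots = [int(np.floor((k + 1) * (m - 1) / (blemishes + 1)))
                 for k in range(blemishes)]
        slots = sorted(set(np.clip(slots, 1, m - 2)))
        if len(slots) < blemishes:  # collisions in tiny windows: pack left
            slots = list(range(1, blemishes + 1))
        for k, s in enumerate(slots):
            geno[spec.animal, inside[s]] = opposite if k < spec.n_opposite \
                else MISSING
        # opposite-state walls flanking the window
        j0 = int(np.searchsorted(rows, inside[0]))
        if j0 > 0:
            geno[spec.animal, rows[j0 - 1]] = opposite
        j1 = int(np.searchsorted(rows, inside[-1]))
        if j1 + 1 < rows.size:
            geno[spec.animal, rows[j1 + 1]] = opposite

    samples = [f"S{i:03d}" for i in range(n_animals)]
    return GenotypeMatrix(samples, geno)
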