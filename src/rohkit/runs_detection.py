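"""Detection of runs of homozygosity (ROH) and heterozygosity-rich regions
(ROHet) in individual SNP-chip genomes.

Two detectors are provided:

* :func:`detect_roh_sliding` -- the sliding-window method: a fixed-size
  window is slid SNP-by-SNP along each chromosome; a window is *eligible*
  if it contains at most ``max_het`` heterozygous and ``max_missing``
  missing calls; each SNP is scored by the proportion of windows covering
  it that are eligible, and SNPs reaching ``window_hit_proportion`` become
  candidates.  Maximal candidate stretches, split at large inter-SNP gaps,
  are emitted as ROH if they meet the SNP-count, length, density and
  per-run blemish constraints.  The low default hit proportion (0.05)
  deliberately lets SNPs at the edges of a true homozygous segment be
  called, as long as windows are large enough that a window is unlikely to
  be homozygous by chance.  A consequence of window scoring is that runs
  shorter than the window itself cannot be called.

* :func:`detect_runs_consecutive` -- the window-free consecutive method:
  SNPs are scanned left to right, extending the current segment until
  adding the next SNP would exceed the allowed opposite-state calls, the
  allowed missing calls, or the maximum gap; segments are trimmed so both
  endpoints carry the target state.  With ``target="het"`` this detects
  heterozygosity-rich regions.

Defaults reproduce a standard 50k-array cattle configuration: ROH of at
least 30 SNPs and 2 Mb with one het and one missing call allowed; ROHet of
at least 15 SNPs and 250 kb with up to three homozygous and two missing
calls allowed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "RohParams",
    "ConsecutiveParams",
    "Run",
    "RunSet",
    "detect_roh_sliding",
    "detect_runs_consecutive",
    "verify_counts",
    "panel_hash",
]


@dataclass(frozen=True)
class RohParams:
    """Sliding-window ROH detection parameters (base scenario defaults)."""

    window_snps: int = 50
    window_hit_proportion: float = 0.05
    min_snps: int = 30
    min_length_mb: float = 2.0
    max_gap_kb: float = 1000.0
    density_kb_per_snp: float = 100.0
    max_het: int = 1
    max_missing: int = 1
    window_only: bool = False  # blemish limits at window level only

    def __post_init__(self) -> None:
        if not 0 < self.window_hit_proportion <= 1:
            raise ValueError("window_hit_proportion must lie in (0, 1]")
        for name in ("window_snps", "min_snps", "min_length_mb", "max_gap_kb",
                     "density_kb_per_snp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het < 0 or self.max_missing < 0:
            raise ValueError("blemish allowances must be non-negative")


@dataclass(frozen=True)
class ConsecutiveParams:
    """Consecutive-method parameters (ROHet defaults)."""

    target: Literal["het", "hom"] = "het"
    min_snps: int = 15
    min_length_kb: float = 250.0
    max_gap_kb: float = 1000.0
    max_opposite: int = 3
    max_missing: int = 2

    def __post_init__(self) -> None:
        if self.target not in ("het", "hom"):
            raise ValueError(f"target must be 'het' or 'hom', got {self.target!r}")
        if self.min_snps <= 0 or self.min_length_kb <= 0 or self.max_gap_kb <= 0:
            raise ValueError("min_snps, min_length_kb, max_gap_kb must be positive")
        if self.max_opposite < 0 or self.max_missing < 0:
            raise ValueError("blemish allowances must be non-negative")


@dataclass(frozen=True)
class Run:
    """One detected run in one animal."""

    animal: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_hom: int
    n_missing: int
    kind: str  # "ROH" | "ROHet"

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


_RUN_COLUMNS = ["animal", "chrom", "start_bp", "end_bp", "length_bp",
                "n_snps", "n_het", "n_hom", "n_missing", "kind"]


@dataclass
class RunSet:
    """A collection of runs plus provenance (parameters and panel hash)."""

    df: pd.DataFrame
    provenance: dict

    def __post_init__(self) -> None:
        if list(self.df.columns) != _RUN_COLUMNS:
            self.df = self.df.reindex(columns=_RUN_COLUMNS)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(self.provenance.get("samples", []))

    def total_length_bp(self) -> pd.Series:
        """Per-animal total run length (animals without runs absent)."""
        return self.df.groupby("animal")["length_bp"].sum()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# provenance: " + json.dumps(self.provenance,
                                                   sort_keys=True) + "\n")
            out = self.df.copy()
            out["length_kb"] = out.pop("length_bp") / 1000.0
            out = out[["animal", "chrom", "start_bp", "end_bp", "length_kb",
                       "n_snps", "n_het", "n_missing", "kind"]]
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RunSet":
        provenance: dict = {}
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# provenance:"):
                provenance = json.loads(first.split(":", 1)[1])
                df = pd.read_csv(fh, sep="\t", dtype={"chrom": str,
                                                      "animal": str})
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t", dtype={"chrom": str,
                                                      "animal": str})
        df["length_bp"] = (df.pop("length_kb") * 1000).round().astype(np.int64)
        df["n_hom"] = df["n_snps"] - df["n_het"] - df["n_missing"]
        return cls(df, provenance)

    def to_bed(self, path: str | Path) -> None:
        """BED export, 0-based half-open, name = animal."""
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.start_bp - 1}\t{row.end_bp}\t"
                         f"{row.animal}\n")


def panel_hash(genotypes: GenotypeMatrix, marker_map: MarkerMap) -> str:
    """Hash identifying the (samples, SNP panel, genotypes) a RunSet came
    from; used as a provenance check before combining RunSets."""
    h = hashlib.sha256()
    h.update("\x00".join(genotypes.samples).encode())
    h.update("\x00".join(marker_map.table["snp_id"]).encode())
    h.update(marker_map.positions.tobytes())
    h.update(np.ascontiguousarray(genotypes.values).tobytes())
    return h.hexdigest()[:16]


def _provenance(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                params, kind: str) -> dict:
    return {
        "kind": kind,
        "params": asdict(params),
        "panel_hash": panel_hash(genotypes, marker_map),
        "samples": list(genotypes.samples),
    }


def _finish(rows: list[tuple], genotypes, marker_map, params, kind) -> RunSet:
    df = pd.DataFrame(rows, columns=["animal", "chrom", "start_bp", "end_bp",
                                     "n_snps", "n_het", "n_hom", "n_missing"])
    df["length_bp"] = df["end_bp"] - df["start_bp"]
    df["kind"] = kind
    df = df[_RUN_COLUMNS]
    df = df.sort_values(["animal", "chrom", "start_bp"],
                        key=lambda s: s if s.name != "chrom"
                        else s.map(lambda c: f"{int(c):09d}" if str(c).isdigit()
                                   else str(c))).reset_index(drop=True)
    return RunSet(df, _provenance(genotypes, marker_map, params, kind))


# ---------------------------------------------------------------------------
# sliding-window method
# ---------------------------------------------------------------------------


def detect_roh_sliding(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                       params: RohParams = RohParams()) -> RunSet:
    """Detect ROH with the sliding-window method (see module docstring)."""
    if genotypes.n_snps != marker_map.n_snps:
        raise StructuralError("genotypes and map have different SNP counts")
    W = params.window_snps
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_mb * 1e6
    rows: list[tuple] = []
    pos_all = marker_map.positions
    blocks = list(marker_map.chrom_blocks())
    warned: set[str] = set()
    for a, animal in enumerate(genotypes.samples):
        g_row = genotypes.values[a]
        for chrom, idx in blocks:
            n = idx.size
            if n < W:
                if chrom not in warned:
                    logger.warning(
                        "chromosome %s has %d SNPs < window of %d; skipped",
                        chrom, n, W)
                    warned.add(chrom)
                continue
            g = g_row[idx]
            pos = pos_all[idx]
            het = (g == 1).astype(np.int64)
            mis = (g == MISSING).astype(np.int64)
            ch = np.concatenate(([0], np.cumsum(het)))
            cm = np.concatenate(([0], np.cumsum(mis)))
            n_win = n - W + 1
            w_het = ch[W:] - ch[:-W]
            w_mis = cm[W:] - cm[:-W]
            eligible = ((w_het <= params.max_het) &
                        (w_mis <= params.max_missing)).astype(np.int64)
            ce = np.concatenate(([0], np.cumsum(eligible)))
            i_arr = np.arange(n)
            w_lo = np.maximum(0, i_arr - W + 1)
            w_hi = np.minimum(i_arr, n_win - 1)
            total = w_hi - w_lo + 1
            elig_count = ce[w_hi + 1] - ce[w_lo]
            candidate = elig_count >= params.window_hit_proportion * total
            het_b = het.astype(bool)
            mis_b = mis.astype(bool)
            for stretch in _candidate_segments(candidate, pos, max_gap_bp):
                if params.window_only:
                    pieces = [stretch]
                else:
                    pieces = _best_partition(
                        *stretch, het_b, mis_b, pos,
                        params.max_het, params.max_missing,
                        params.min_snps, min_len_bp)
                for s, e in pieces:
                    n_snps = e - s + 1
                    length = pos[e] - pos[s]
                    if n_snps < params.min_snps or length < min_len_bp:
                        continue
                    if length / 1000.0 / n_snps > params.density_kb_per_snp:
                        continue
                    n_het = int(ch[e + 1] - ch[s])
                    n_mis = int(cm[e + 1] - cm[s])
                    rows.append((animal, chrom, int(pos[s]), int(pos[e]),
                                 n_snps, n_het, n_snps - n_het - n_mis, n_mis))
    return _finish(rows, genotypes, marker_map, params, "ROH")


def _best_partition(s: int, e: int, het: np.ndarray, mis: np.ndarray,
                    pos: np.ndarray, max_het: int, max_missing: int,
                    min_snps: int, min_len_bp: float
                    ) -> list[tuple[int, int]]:
    """Disjoint sub-segments of a candidate stretch, each holding at most
    ``max_het`` heterozygous and ``max_missing`` missing calls, bounded
    by homozygous non-missing SNPs and no shorter than ``min_snps`` /
    ``min_len_bp``, chosen to maximise the total covered length (ties:
    fewer segments, then leftmost starts).

    Candidate stretches routinely absorb heterozygous SNPs just beyond
    the edges of a true homozygous segment (window scoring deliberately
    calls edge SNPs) and can bridge two autozygous segments across a
    blemished interval; enforcing the per-run blemish limits by outright
    rejection would then lose whole runs, while any one-directional
    trimming rule mishandles one of the two situations.  The
    maximum-coverage partition handles both, is deterministic, and keeps
    the emitted length monotone in the blemish allowances.  Solved by
    dynamic programming with a sliding-window maximum over feasible
    segment starts (all feasibility bounds are monotone in the segment
    end, so two pointers suffice).
    """
    n = e - s + 1
    h = het[s:e + 1]
    ms = mis[s:e + 1]
    hom = ~(h | ms)
    p = pos[s:e + 1]
    hc = np.concatenate(([0], np.cumsum(h)))
    mc = np.concatenate(([0], np.cumsum(ms)))
    # f[k]: (covered bp, -pieces) achievable within the first k SNPs
    f: list[tuple[int, int]] = [(0, 0)] * (n + 1)
    choice = [-1] * n
    from collections import deque
    dq: deque = deque()  # (key, start): key = (f[start] cov - pos, -pieces)
    lo = 0          # smallest start within the blemish budgets
    next_push = 0   # starts become eligible once the piece is long enough
    for i in range(n):
        while hc[i + 1] - hc[lo] > max_het or mc[i + 1] - mc[lo] > max_missing:
            lo += 1
        # a piece [s0, i] needs >= min_snps SNPs and >= min_len_bp span
        hi = i - min_snps + 1
        while next_push <= hi and p[i] - p[next_push] >= min_len_bp:
            s0 = next_push
            if hom[s0]:
                key = (f[s0][0] - int(p[s0]), f[s0][1])
                while dq and dq[-1][0] < key:
                    dq.pop()
                dq.append((key, s0))
            next_push += 1
        while dq and dq[0][1] < lo:
            dq.popleft()
        f[i + 1] = f[i]
        if hom[i] and dq:
            key, s0 = dq[0]
            cand = (key[0] + int(p[i]), key[1] - 1)
            if cand > f[i]:
                f[i + 1] = cand
                choice[i] = s0
    pieces: list[tuple[int, int]] = []
    i = n - 1
    while i >= 0:
        if choice[i] == -1:
            i -= 1
        else:
            pieces.append((s + choice[i], s + i))
            i = choice[i] - 1
    pieces.reverse()
    return pieces


def _candidate_segments(candidate: np.ndarray, pos: np.ndarray,
                        max_gap_bp: float):
    """Maximal stretches of candidate SNPs, split at gaps > max_gap_bp."""
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(
        (np.diff(idx) > 1) | (np.diff(pos[idx]) > max_gap_bp)
    )
    start = 0
    for b in breaks:
        yield int(idx[start]), int(idx[b])
        start = b + 1
    yield int(idx[start]), int(idx[-1])


# ---------------------------------------------------------------------------
# consecutive method
# ---------------------------------------------------------------------------

_TARGET, _OPPOSITE, _MISS = 0, 1, 2


def _states(g: np.ndarray, target: str) -> np.ndarray:
    st = np.full(g.shape, _OPPOSITE, dtype=np.int8)
    het = g == 1
    if target == "het":
        st[het] = _TARGET
    else:
        st[(g == 0) | (g == 2)] = _TARGET
    st[g == MISSING] = _MISS
    return st


def detect_runs_consecutive(genotypes: GenotypeMatrix, marker_map: MarkerMap,
                            params: ConsecutiveParams = ConsecutiveParams()
                            ) -> RunSet:
    """Detect runs with the consecutive (window-free) method.

    Scanning is left-to-right per animal and chromosome.  A segment starts
    at a target-state SNP and is extended until the next SNP would exceed
    ``max_opposite`` opposite-state calls, exceed ``max_missing`` missing
    calls, or lie more than ``max_gap_kb`` beyond its predecessor.  At a
    break the segment is emitted (if long enough after trimming to
    target-state endpoints) and scanning restarts from the breaking SNP.
    """
    if genotypes.n_snps != marker_map.n_snps:
        raise StructuralError("genotypes and map have different SNP counts")
    max_gap_bp = params.max_gap_kb * 1000.0
    min_len_bp = params.min_length_kb * 1000.0
    kind = "ROHet" if params.target == "het" else "ROH"
    rows: list[tuple] = []
    pos_all = marker_map.positions
    blocks = list(marker_map.chrom_blocks())
    for a, animal in enumerate(genotypes.samples):
        g_row = genotypes.values[a]
        for chrom, idx in blocks:
            g = g_row[idx]
            pos = pos_all[idx]
            st = _states(g, params.target)
            rows.extend(
                _scan_chromosome(animal, chrom, st, pos, params,
                                 max_gap_bp, min_len_bp)
            )
    return _finish(rows, genotypes, marker_map, params, kind)


def _scan_chromosome(animal, chrom, st, pos, params, max_gap_bp, min_len_bp):
    n = st.size
    out = []
    start = None
    n_opp = n_mis = 0

    def emit(a: int, b: int) -> None:
        # trim to target-state endpoints
        while a <= b and st[a] != _TARGET:
            a += 1
        while b >= a and st[b] != _TARGET:
            b -= 1
        if a > b:
            return
        n_snps = b - a + 1
        length = pos[b] - pos[a]
        if n_snps < params.min_snps or length < min_len_bp:
            return
        seg = st[a:b + 1]
        k_opp = int((seg == _OPPOSITE).sum())
        k_mis = int((seg == _MISS).sum())
        if params.target == "het":
            n_het, n_hom = n_snps - k_opp - k_mis, k_opp
        else:
            n_het, n_hom = k_opp, n_snps - k_opp - k_mis
        out.append((animal, chrom, int(pos[a]), int(pos[b]),
                    n_snps, n_het, n_hom, k_mis))

    for i in range(n):
        if start is not None and pos[i] - pos[i - 1] > max_gap_bp:
            emit(start, i - 1)
            start, n_opp, n_mis = None, 0, 0
        s = st[i]
        if start is None:
            if s == _TARGET:
                start = i
            continue
        if s == _TARGET:
            continue
        if s == _OPPOSITE:
            if n_opp + 1 > params.max_opposite:
                emit(start, i - 1)
                start, n_opp, n_mis = None, 0, 0
            else:
                n_opp += 1
        else:
            if n_mis + 1 > params.max_missing:
                emit(start, i - 1)
                start, n_opp, n_mis = None, 0, 0
            else:
                n_mis += 1
    if start is not None:
        emit(start, n - 1)
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def verify_counts(runset: RunSet, genotypes: GenotypeMatrix,
                  marker_map: MarkerMap) -> None:
    """Re-count het/hom/missing calls inside every run against the genotype
    matrix; raise :class:`StructuralError` on any mismatch.  Also checks
    that runs of one animal on one chromosome do not overlap."""
    sample_row = {s: i for i, s in enumerate(genotypes.samples)}
    pos = marker_map.positions
    blocks = dict(marker_map.chrom_blocks())
    for (animal, chrom), grp in runset.df.groupby(["animal", "chrom"],
                                                  sort=False):
        grp = grp.sort_values("start_bp")
        if (grp["start_bp"].to_numpy()[1:] <= grp["end_bp"].to_numpy()[:-1]).any():
            raise StructuralError(
                f"overlapping runs for {animal} on chromosome {chrom}")
        idx = blocks.get(str(chrom))
        if idx is None:
            raise StructuralError(f"run on unknown chromosome {chrom!r}")
        row = sample_row[animal]
        for run in grp.itertuples(index=False):
            inside = idx[(pos[idx] >= run.start_bp) & (pos[idx] <= run.end_bp)]
            g = genotypes.values[row, inside]
            n_het = int((g == 1).sum())
            n_mis = int((g == MISSING).sum())
            n_hom = int(((g == 0) | (g == 2)).sum())
            if (inside.size, n_het, n_hom, n_mis) != (
                    run.n_snps, run.n_het, run.n_hom, run.n_missing):
                raise StructuralError(
                    f"run counts for {animal} {chrom}:{run.start_bp}-"
                    f"{run.end_bp} do not match the genotype matrix"
                )
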