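"""Unit scoring, unit-preserving positional permutation, and P-values.

The summary statistic of a CNA unit u(k, L) is the grand mean of its
thresholded block over all N samples and L probes (zeros of unaltered
samples included), so it jointly encodes amplitude and recurrence
frequency::

    U_{k,L} = (1 / (L N)) sum_n sum_{l=k}^{k+L-1} S[n, l]

Significance is assessed against a positional permutation null that
preserves the correlation structure within each sample: every maximal
contiguous nonzero run of a sample row -- the sample's CNA segment, which
the already-defined CNA units partition -- is copied intact to a uniformly
random start position (whole genome or its own chromosome, depending on
scope), rows independently.  A row's runs are placed at mutually disjoint
positions by default (sequential rejection in random order), so every
observed unit is retained intact in every permuted dataset; an "overwrite"
collision mode (later placements clobber earlier ones) is available for
comparison.

For each permuted dataset the maximum U score over all windows of each
observed unit length is recorded; the empirical P-value of an observed unit
is the right-tail rank of its score among those per-length maxima (left
tail for deletions).  Taking the maximum over window positions makes the
P-values family-wise adjusted by construction.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numba import njit

from .core_units import (
    AMPLIFICATION,
    CNAUnit,
    ConfigurationError,
    SignedMatrix,
)

GENOME = "genome"
CHROMOSOME = "chromosome"
SCOPES = (GENOME, CHROMOSOME)

REJECT = "reject"
OVERWRITE = "overwrite"
COLLISION_MODES = (REJECT, OVERWRITE)

#: relocation atom modes: each sample's maximal contiguous segments ("runs")
#: or per-(unit, row) value blocks ("units")
RUNS = "runs"
UNITS = "units"
ATOM_MODES = (RUNS, UNITS)

#: attempts per segment before the non-overlap placement falls back to an
#: additive placement at the last drawn position
REJECTION_MAX_TRIES = 100

#: overwrite-mode permutation plans are drawn in fixed-size chunks from one
#: generator so that increasing T never reshuffles earlier permutations
PLAN_CHUNK = 32

#: relative guard band for Eq.-4 tie counting (see docs/methods.md)
TIE_REL_TOL = 1e-9


@dataclasses.dataclass
class NullDistribution:
    """Per-length permutation extrema of the sliding-window U score.

    ``extrema[(L, chrom)]`` holds the T per-permutation maxima (amplification)
    or minima (deletion) of the U score over all L-wide windows in the given
    chromosome; ``chrom`` is None under genome scope.
    """

    extrema: dict[tuple[int, str | None], np.ndarray]
    T: int
    scope: str
    tail: str

    def vector(self, unit: CNAUnit) -> np.ndarray:
        key = (unit.L, unit.chromosome if self.scope == CHROMOSOME else None)
        return self.extrema[key]


@dataclasses.dataclass(frozen=True)
class SCACall:
    """A CNA unit with its U score, P-value and calling iteration."""

    unit: CNAUnit
    score: float
    pvalue: float
    tail: str
    iteration: int


# ---------------------------------------------------------------------------
# scores and P-values
# ---------------------------------------------------------------------------

def unit_score(S: SignedMatrix, k: int, L: int) -> float:
    """Grand mean of the (N x L) block of S starting at probe k."""
    if k < 0 or L < 1 or k + L > S.n_probes:
        raise ConfigurationError(f"unit (k={k}, L={L}) outside the matrix")
    return float(S.values[:, k:k + L].mean())


def max_window_score(Xp: np.ndarray,
                     L: int,
                     chrom_blocks: Sequence[tuple[str, int, int]] | None = None,
                     ) -> float:
    """Maximum U score over every L-wide window of a (permuted) matrix.

    Windows never cross chromosome boundaries; with no annotation the whole
    matrix is one span.  This is the plain-numpy reference used for
    validation; Algorithm 1 runs an equivalent compiled scan.
    """
    Xp = np.asarray(Xp, dtype=np.float64)
    n, m = Xp.shape
    if not (1 <= L <= m):
        raise ConfigurationError(f"window length {L} outside [1, {m}]")
    if chrom_blocks is None:
        chrom_blocks = [("*", 0, m)]
    cs = np.concatenate([[0.0], np.cumsum(Xp.sum(axis=0))])
    best = -np.inf
    for _, lo, hi in chrom_blocks:
        if hi - lo < L:
            continue
        w = cs[lo + L:hi + 1] - cs[lo:hi - L + 1]
        best = max(best, float(w.max()))
    if not np.isfinite(best):
        raise ConfigurationError(f"no chromosome can hold a window of length {L}")
    return best / (L * n)


def unit_pvalue(U_obs: float, extrema: np.ndarray, tail: str = AMPLIFICATION) -> float:
    """Empirical tail probability of an observed U score.

    Amplification: P = (1 + #{t : max_t >= U}) / (T + 1); deletion reverses
    the inequality against per-permutation minima.  Ties count as
    exceedances; a tiny relative guard band keeps structural ties (a unit
    reproducing its own window in a permutation) stable under float
    round-off.
    """
    m = np.asarray(extrema, dtype=np.float64)
    if m.size == 0:
        raise ConfigurationError("empty permutation extrema vector")
    tol = TIE_REL_TOL * max(1.0, abs(U_obs))
    if tail == AMPLIFICATION:
        c = int(np.count_nonzero(m >= U_obs - tol))
    else:
        c = int(np.count_nonzero(m <= U_obs + tol))
    return (1 + c) / (m.size + 1)


# ---------------------------------------------------------------------------
# relocation atoms: per-sample contiguous segments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _SegmentSet:
    """Per-row maximal contiguous nonzero runs of a signed matrix.

    A row's run is one sample's CNA segment: the permutation relocates these
    runs intact, preserving within-sample correlation structure exactly;
    every observed CNA unit is contained in (a union of) such runs and is
    therefore retained in each permuted dataset.
    """

    row_ptr: np.ndarray      # (N+1,) segment index ranges per row
    seg_row: np.ndarray      # (S,)
    seg_len: np.ndarray      # (S,)
    seg_vptr: np.ndarray     # (S,) offsets into seg_vals
    seg_vals: np.ndarray     # flat float64 values
    seg_chrom: np.ndarray    # (S,) chromosome block index of the run
    n_rows: int
    n_probes: int


def _build_segments(values: np.ndarray,
                    chrom_blocks: Sequence[tuple[str, int, int]]) -> _SegmentSet:
    n, m = values.shape
    rows: list[int] = []
    lens: list[int] = []
    chroms: list[int] = []
    vals: list[np.ndarray] = []
    for nrow in range(n):
        nz = values[nrow] != 0.0
        for ci, (_, lo, hi) in enumerate(chrom_blocks):
            x = nz[lo:hi].astype(np.int8)
            d = np.diff(np.concatenate([[0], x, [0]]))
            starts = np.flatnonzero(d == 1)
            stops = np.flatnonzero(d == -1)
            for s, e in zip(starts, stops):
                rows.append(nrow)
                lens.append(int(e - s))
                chroms.append(ci)
                vals.append(values[nrow, lo + s:lo + e])
    seg_row = np.asarray(rows, dtype=np.int64)
    seg_len = np.asarray(lens, dtype=np.int64)
    seg_chrom = np.asarray(chroms, dtype=np.int64)
    seg_vals = (np.concatenate(vals) if vals else np.empty(0, np.float64))
    seg_vptr = (np.concatenate([[0], np.cumsum(seg_len)])[:-1].astype(np.int64)
                if seg_len.size else np.empty(0, np.int64))
    # rows were scanned in order, so segments are already row-grouped
    row_ptr = np.searchsorted(seg_row, np.arange(n + 1)).astype(np.int64)
    return _SegmentSet(row_ptr, seg_row, seg_len, seg_vptr,
                       np.ascontiguousarray(seg_vals, dtype=np.float64),
                       seg_chrom, n, m)


def _build_unit_segments(values: np.ndarray,
                         units: Sequence[CNAUnit],
                         chrom_blocks: Sequence[tuple[str, int, int]]
                         ) -> _SegmentSet:
    """Relocation atoms as per-(unit, row) value blocks: for every observed
    unit, each sample-row with any signal in the unit contributes its full
    L-length block (internal zeros included) as one atom."""
    chrom_index = {name: i for i, (name, _, _) in enumerate(chrom_blocks)}
    n, m = values.shape
    rows: list[np.ndarray] = []
    lens: list[np.ndarray] = []
    chroms: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    for u in units:
        block = values[:, u.k:u.stop]
        nz = np.flatnonzero(np.any(block != 0.0, axis=1))
        if nz.size == 0:
            continue
        rows.append(nz)
        lens.append(np.full(nz.size, u.L, dtype=np.int64))
        chroms.append(np.full(nz.size, chrom_index[u.chromosome], dtype=np.int64))
        vals.append(block[nz].ravel())
    if rows:
        seg_row = np.concatenate(rows)
        seg_len = np.concatenate(lens)
        seg_chrom = np.concatenate(chroms)
    else:
        seg_row = np.empty(0, dtype=np.int64)
        seg_len = np.empty(0, dtype=np.int64)
        seg_chrom = np.empty(0, dtype=np.int64)
    order = np.argsort(seg_row, kind="stable")
    seg_row_sorted = seg_row[order]
    seg_len_sorted = seg_len[order]
    seg_chrom = seg_chrom[order]
    if seg_len.size:
        vptr_unsorted = np.concatenate([[0], np.cumsum(seg_len)])[:-1]
        flat = np.concatenate(vals)
        seg_vptr = np.concatenate([[0], np.cumsum(seg_len_sorted)])[:-1].astype(np.int64)
        within = (np.arange(int(seg_len_sorted.sum()), dtype=np.int64)
                  - np.repeat(seg_vptr, seg_len_sorted))
        seg_vals = flat[np.repeat(vptr_unsorted[order], seg_len_sorted) + within]
    else:
        seg_vptr = np.empty(0, np.int64)
        seg_vals = np.empty(0, np.float64)
    row_ptr = np.searchsorted(seg_row_sorted, np.arange(n + 1)).astype(np.int64)
    return _SegmentSet(row_ptr, seg_row_sorted, seg_len_sorted.astype(np.int64),
                       seg_vptr, np.ascontiguousarray(seg_vals, dtype=np.float64),
                       seg_chrom, n, m)


def _chrom_bound_arrays(chrom_blocks: Sequence[tuple[str, int, int]]
                        ) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[1] for b in chrom_blocks], dtype=np.int64)
    hi = np.array([b[2] for b in chrom_blocks], dtype=np.int64)
    return lo, hi


def _placement_domain(segs: _SegmentSet, chrom_lo: np.ndarray,
                      chrom_hi: np.ndarray, scope: str):
    """Precompute the valid-start structure consumed by the kernels.

    Chromosome scope: each segment draws uniformly among the starts inside
    its own chromosome.  Genome scope: uniform among all starts (in any
    chromosome) where the segment fits entirely.
    """
    if scope == CHROMOSOME:
        lo = chrom_lo[segs.seg_chrom]
        nvalid = (chrom_hi[segs.seg_chrom] - lo) - segs.seg_len + 1
        if segs.seg_len.size and np.any(nvalid <= 0):
            j = int(np.argmax(nvalid <= 0))
            raise ConfigurationError(
                f"unit of length {segs.seg_len[j]} longer than its chromosome")
        dlen = np.zeros(segs.seg_len.size, dtype=np.int64)
        cum = np.zeros((1, chrom_lo.size), dtype=np.int64)
        totals = np.zeros(1, dtype=np.int64)
        return lo.astype(np.int64), nvalid.astype(np.int64), dlen, cum, totals
    distinct = np.unique(segs.seg_len) if segs.seg_len.size else np.array([1])
    cum = np.empty((distinct.size, chrom_lo.size), dtype=np.int64)
    totals = np.empty(distinct.size, dtype=np.int64)
    for d, L in enumerate(distinct):
        counts = np.clip(chrom_hi - chrom_lo - L + 1, 0, None)
        cum[d] = np.cumsum(counts)
        totals[d] = cum[d, -1]
        if totals[d] <= 0:
            raise ConfigurationError(
                f"unit of length {L} longer than every chromosome")
    dlen = np.searchsorted(distinct, segs.seg_len).astype(np.int64)
    lo = np.zeros(segs.seg_len.size, dtype=np.int64)
    nvalid = np.ones(segs.seg_len.size, dtype=np.int64)
    return lo, nvalid, dlen, cum, totals


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _scan_windows(cs, chrom_lo, chrom_hi, key_len, key_chrom, n_samples, out_row):
    """Max window sum / (L N) per key; key_chrom = -1 means genome-wide."""
    for ki in range(key_len.shape[0]):
        L = key_len[ki]
        c = key_chrom[ki]
        best = -1.0e300
        if c >= 0:
            c0, c1 = c, c + 1
        else:
            c0, c1 = 0, chrom_lo.shape[0]
        for cc in range(c0, c1):
            lo = chrom_lo[cc]
            hi = chrom_hi[cc]
            for s in range(lo, hi - L + 1):
                w = cs[s + L] - cs[s]
                if w > best:
                    best = w
        out_row[ki] = best / (L * n_samples)


@njit(cache=True)
def _reject_kernel(seeds, row_ptr, seg_len, seg_vptr, seg_vals,
                   seg_lo, seg_nvalid, genome, dlen_idx, cum_counts, totals,
                   chrom_lo, chrom_hi, key_len, key_chrom,
                   M, n_samples, max_tries, out_maxima, record, out_starts):
    """Non-overlapping placement null: per permutation, each row's segments
    are placed in random order at uniformly drawn starts, redrawing on
    collision (bounded tries; rare exhaustion falls back to an additive
    placement so no mass is ever lost)."""
    B = seeds.shape[0]
    n_rows = row_ptr.shape[0] - 1
    colsum = np.zeros(M)
    cs = np.empty(M + 1)
    occ = np.full(M, -1, dtype=np.int64)
    maxseg = 0
    for n in range(n_rows):
        c = row_ptr[n + 1] - row_ptr[n]
        if c > maxseg:
            maxseg = c
    order = np.empty(max(maxseg, 1), dtype=np.int64)
    epoch = 0
    for t in range(B):
        np.random.seed(seeds[t])
        for m in range(M):
            colsum[m] = 0.0
        for n in range(n_rows):
            a = row_ptr[n]
            b = row_ptr[n + 1]
            k = b - a
            if k == 0:
                continue
            epoch += 1
            for i in range(k):
                order[i] = a + i
            for i in range(k - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                tmp = order[i]
                order[i] = order[j]
                order[j] = tmp
            for i in range(k):
                sj = order[i]
                L = seg_len[sj]
                vp = seg_vptr[sj]
                s = -1
                for _attempt in range(max_tries):
                    if genome:
                        d = dlen_idx[sj]
                        u = np.random.randint(0, totals[d])
                        cc = 0
                        while u >= cum_counts[d, cc]:
                            cc += 1
                        prev = cum_counts[d, cc - 1] if cc > 0 else 0
                        s = chrom_lo[cc] + (u - prev)
                    else:
                        s = seg_lo[sj] + np.random.randint(0, seg_nvalid[sj])
                    free = True
                    for x in range(L):
                        if occ[s + x] == epoch:
                            free = False
                            break
                    if free:
                        break
                for x in range(L):
                    colsum[s + x] += seg_vals[vp + x]
                    occ[s + x] = epoch
                if record:
                    out_starts[t, sj] = s
        cs[0] = 0.0
        for m in range(M):
            cs[m + 1] = cs[m] + colsum[m]
        _scan_windows(cs, chrom_lo, chrom_hi, key_len, key_chrom, n_samples,
                      out_maxima[t])


@njit(cache=True)
def _overwrite_kernel(starts, order, row_ptr, seg_len, seg_vptr, seg_vals,
                      chrom_lo, chrom_hi, key_len, key_chrom, M, n_samples,
                      out):
    """Plan-based overwrite-collision null: segments placed at precomputed
    starts in the given per-row order, later placements overwriting."""
    B = starts.shape[0]
    n_rows = row_ptr.shape[0] - 1
    colsum = np.zeros(M)
    rowbuf = np.zeros(M)
    cs = np.empty(M + 1)
    for t in range(B):
        for m in range(M):
            colsum[m] = 0.0
        for n in range(n_rows):
            a = row_ptr[n]
            b = row_ptr[n + 1]
            if a == b:
                continue
            for q in range(a, b):
                j = order[t, q]
                s = starts[t, j]
                L = seg_len[j]
                vp = seg_vptr[j]
                for x in range(L):
                    rowbuf[s + x] = seg_vals[vp + x]
            # collect-and-zero: overlapping spans contribute once because the
            # first visit zeroes the shared cells
            for q in range(a, b):
                j = order[t, q]
                s = starts[t, j]
                L = seg_len[j]
                for x in range(L):
                    colsum[s + x] += rowbuf[s + x]
                    rowbuf[s + x] = 0.0
        cs[0] = 0.0
        for m in range(M):
            cs[m + 1] = cs[m] + colsum[m]
        _scan_windows(cs, chrom_lo, chrom_hi, key_len, key_chrom, n_samples,
                      out[t])


# ---------------------------------------------------------------------------
# plan drawing (overwrite mode) and plan application
# ---------------------------------------------------------------------------

def _draw_plan(segs: _SegmentSet,
               chrom_lo: np.ndarray,
               chrom_hi: np.ndarray,
               scope: str,
               rng: np.random.Generator,
               B: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw B overwrite-mode placement plans: a random start per segment plus
    a random per-row placement order."""
    S = segs.seg_len.size
    starts = np.empty((B, S), dtype=np.int64)
    if S:
        seg_lo, seg_nvalid, dlen, cum, totals = _placement_domain(
            segs, chrom_lo, chrom_hi, scope)
        if scope == CHROMOSOME:
            starts[:] = seg_lo + rng.integers(0, seg_nvalid, size=(B, S))
        else:
            u = rng.integers(0, totals[dlen], size=(B, S))
            counts = np.diff(np.concatenate([np.zeros((cum.shape[0], 1),
                                                      dtype=np.int64), cum],
                                            axis=1), axis=1)
            for d in range(totals.size):
                cols = np.flatnonzero(dlen == d)
                if cols.size == 0:
                    continue
                ci = np.searchsorted(cum[d], u[:, cols], side="right")
                prev = cum[d][ci] - counts[d][ci]
                starts[:, cols] = chrom_lo[ci] + (u[:, cols] - prev)
    ordr = np.empty((B, S), dtype=np.int64)
    for n in range(segs.n_rows):
        a, b = int(segs.row_ptr[n]), int(segs.row_ptr[n + 1])
        if b == a:
            continue
        if b - a == 1:
            ordr[:, a] = a
        else:
            tiled = np.tile(np.arange(a, b, dtype=np.int64), (B, 1))
            ordr[:, a:b] = rng.permuted(tiled, axis=1)
    return starts, ordr


def _apply_starts(segs: _SegmentSet, starts: np.ndarray,
                  order: np.ndarray | None = None,
                  overwrite: bool = False) -> np.ndarray:
    """Materialise one placement as a full permuted matrix (numpy)."""
    out = np.zeros((segs.n_rows, segs.n_probes))
    for n in range(segs.n_rows):
        a, b = int(segs.row_ptr[n]), int(segs.row_ptr[n + 1])
        idx = order[a:b] if order is not None else range(a, b)
        for j in idx:
            j = int(j)
            s = int(starts[j])
            L = int(segs.seg_len[j])
            vp = int(segs.seg_vptr[j])
            if overwrite:
                out[n, s:s + L] = segs.seg_vals[vp:vp + L]
            else:
                out[n, s:s + L] += segs.seg_vals[vp:vp + L]
    return out


def _reject_starts(segs: _SegmentSet, chrom_lo: np.ndarray, chrom_hi: np.ndarray,
                   scope: str, seeds: np.ndarray) -> np.ndarray:
    """Run the rejection kernel for the given per-permutation seeds and
    return the chosen starts, shape (len(seeds), n_segments)."""
    seg_lo, seg_nvalid, dlen, cum, totals = _placement_domain(
        segs, chrom_lo, chrom_hi, scope)
    B = seeds.size
    out_starts = np.full((B, max(segs.seg_len.size, 1)), -1, dtype=np.int64)
    dummy_keys = np.empty(0, dtype=np.int64)
    out_max = np.empty((B, 0), dtype=np.float64)
    _reject_kernel(seeds.astype(np.int64), segs.row_ptr, segs.seg_len,
                   segs.seg_vptr, segs.seg_vals, seg_lo, seg_nvalid,
                   scope == GENOME, dlen, cum, totals, chrom_lo, chrom_hi,
                   dummy_keys, dummy_keys, segs.n_probes, segs.n_rows,
                   REJECTION_MAX_TRIES, out_max, True, out_starts)
    return out_starts[:, :segs.seg_len.size]


def permute_within_row(S: SignedMatrix,
                       units: Sequence[CNAUnit],
                       rng: np.random.Generator,
                       scope: str = CHROMOSOME,
                       collision: str = REJECT) -> np.ndarray:
    """One unit-preserving positional permutation of a signed matrix.

    Each sample row's maximal contiguous nonzero runs -- the sample's CNA
    segments, which the observed ``units`` partition -- are copied intact
    (values and internal order preserved) to uniformly random start
    positions within the permitted span; rows are permuted independently
    and a row's runs are placed in random order.  Default collision mode
    keeps a row's runs disjoint, so every observed unit is retained intact
    in the permuted matrix; ``collision="overwrite"`` lets later placements
    clobber earlier ones instead.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"unknown scope {scope!r}")
    if collision not in COLLISION_MODES:
        raise ConfigurationError(f"unknown collision mode {collision!r}")
    del units  # scoring elements; the relocation atoms come from the matrix
    segs = _build_segments(S.values, S.chrom_blocks)
    chrom_lo, chrom_hi = _chrom_bound_arrays(S.chrom_blocks)
    if segs.seg_len.size == 0:
        return np.zeros_like(S.values)
    if collision == OVERWRITE:
        starts, order = _draw_plan(segs, chrom_lo, chrom_hi, scope, rng, 1)
        return _apply_starts(segs, starts[0], order[0], overwrite=True)
    seeds = rng.integers(0, 2 ** 32, size=1, dtype=np.int64)
    starts = _reject_starts(segs, chrom_lo, chrom_hi, scope, seeds)
    return _apply_starts(segs, starts[0])


# ---------------------------------------------------------------------------
# null construction and Algorithm 1
# ---------------------------------------------------------------------------

def _null_keys(units: Sequence[CNAUnit], scope: str
               ) -> list[tuple[int, str | None]]:
    if scope == CHROMOSOME:
        keys = {(u.L, u.chromosome) for u in units}
    else:
        keys = {(u.L, None) for u in units}
    return sorted(keys, key=lambda k: (k[0], str(k[1])))


def build_null_distribution(S: SignedMatrix,
                            score_units: Sequence[CNAUnit],
                            T: int,
                            scope: str,
                            rng: np.random.Generator,
                            collision: str = REJECT,
                            placed_units: Sequence[CNAUnit] | None = None
                            ) -> NullDistribution:
    """Permutation null for the lengths of ``score_units``, built by
    relocating the (possibly masked) matrix S's atoms: the per-sample
    contiguous segments by default, or per-(unit, row) blocks when
    ``placed_units`` is given.

    For deletion matrices the extrema are per-permutation window minima.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"unknown scope {scope!r}")
    if collision not in COLLISION_MODES:
        raise ConfigurationError(f"unknown collision mode {collision!r}")
    if T < 1:
        raise ConfigurationError("need at least one permutation")
    sign = 1.0 if S.tail == AMPLIFICATION else -1.0
    blocks = S.chrom_blocks
    keys = _null_keys(score_units, scope)
    chrom_index = {name: i for i, (name, _, _) in enumerate(blocks)}
    key_len = np.array([k[0] for k in keys], dtype=np.int64)
    key_chrom = np.array(
        [chrom_index[k[1]] if k[1] is not None else -1 for k in keys],
        dtype=np.int64)
    for L, chrom in keys:
        spans = ([hi - lo for name, lo, hi in blocks if name == chrom]
                 if chrom is not None else [hi - lo for _, lo, hi in blocks])
        if not spans or L > max(spans):
            raise ConfigurationError(
                f"unit of length {L} longer than the permitted span "
                f"({'chromosome ' + str(chrom) if chrom else 'every chromosome'})")
    if placed_units is None:
        segs = _build_segments(sign * S.values, blocks)
    else:
        segs = _build_unit_segments(sign * S.values, placed_units, blocks)
    chrom_lo, chrom_hi = _chrom_bound_arrays(blocks)
    out = np.empty((T, len(keys)), dtype=np.float64)
    if collision == REJECT:
        seg_lo, seg_nvalid, dlen, cum, totals = _placement_domain(
            segs, chrom_lo, chrom_hi, scope)
        seeds = rng.integers(0, 2 ** 32, size=T, dtype=np.int64)
        dummy = np.full((1, 1), -1, dtype=np.int64)
        _reject_kernel(seeds, segs.row_ptr, segs.seg_len, segs.seg_vptr,
                       segs.seg_vals, seg_lo, seg_nvalid, scope == GENOME,
                       dlen, cum, totals, chrom_lo, chrom_hi, key_len,
                       key_chrom, segs.n_probes, segs.n_rows,
                       REJECTION_MAX_TRIES, out, False, dummy)
    else:
        done = 0
        while done < T:
            b = min(PLAN_CHUNK, T - done)
            starts, order = _draw_plan(segs, chrom_lo, chrom_hi, scope, rng, b)
            _overwrite_kernel(starts, order, segs.row_ptr, segs.seg_len,
                              segs.seg_vptr, segs.seg_vals, chrom_lo, chrom_hi,
                              key_len, key_chrom, segs.n_probes, segs.n_rows,
                              out[done:done + b])
            done += b
    extrema = {key: sign * out[:, i] for i, key in enumerate(keys)}
    return NullDistribution(extrema=extrema, T=T, scope=scope, tail=S.tail)


def run_algorithm1(S: SignedMatrix,
                   units: Sequence[CNAUnit],
                   T: int,
                   scope: str = CHROMOSOME,
                   rng: np.random.Generator | int | None = None,
                   iteration: int = 1,
                   collision: str = REJECT,
                   atoms: str = RUNS
                   ) -> tuple[list[SCACall], NullDistribution]:
    """Score every observed unit against the unit-preserving permutation null.

    Returns one candidate call per unit (with its length-adaptive,
    multiplicity-adjusted P-value) plus the null distribution used.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    units = list(units)
    if not units:
        return [], NullDistribution({}, T, scope, S.tail)
    if atoms not in ATOM_MODES:
        raise ConfigurationError(f"unknown atom mode {atoms!r}")
    null = build_null_distribution(
        S, units, T, scope, rng, collision,
        placed_units=units if atoms == UNITS else None)
    calls = []
    for u in units:
        score = unit_score(S, u.k, u.L)
        p = unit_pvalue(score, null.vector(u), S.tail)
        calls.append(SCACall(unit=u, score=score, pvalue=p, tail=S.tail,
                             iteration=iteration))
    return calls, null
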