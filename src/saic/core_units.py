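"""Containers and CNA-unit decomposition for multi-sample copy-number data.

The input is a samples x probes matrix of segmented log2 copy-number ratios
(log2 of observed copies over the diploid baseline of 2).  Amplifications and
deletions are analysed separately: the matrix is split into two *signed*
matrices by thresholding, probes altered in at least one sample become *CNA
probes*, maximal runs of CNA probes form *CNA regions*, and each region is
partitioned into *CNA units* -- runs of consecutive probes whose adjacent
cross-sample Pearson correlations all reach a threshold ``theta_rho``.  The
CNA unit is the atomic element that is scored and permuted downstream.
"""

from __future__ import annotations

import dataclasses
import functools
from typing import Iterable, Sequence

import numpy as np

AMPLIFICATION = "amplification"
DELETION = "deletion"
TAILS = (AMPLIFICATION, DELETION)


class SaicError(Exception):
    """Base class for errors raised by this package."""


class DataQualityError(SaicError):
    """Input data violates a contract (non-finite values, bad shapes...)."""


class ConfigurationError(SaicError):
    """A parameter combination is invalid or infeasible."""


def chromosome_sort_key(name: str) -> tuple:
    """Natural chromosome ordering: 1..22, then X, Y, then anything else.

    Accepts names with or without a ``chr`` prefix.
    """
    s = str(name)
    core = s[3:] if s.lower().startswith("chr") else s
    if core.isdigit():
        return (0, int(core), "")
    if core.upper() == "X":
        return (1, 0, "")
    if core.upper() == "Y":
        return (1, 1, "")
    return (2, 0, core)


@dataclasses.dataclass
class CopyNumberMatrix:
    """Samples x probes log2-ratio matrix with ordered probe annotation.

    Parameters
    ----------
    values
        ``(N, M)`` float array of segmented log2 ratios, N samples, M probes.
    samples
        N sample identifiers.
    probe_ids, chromosomes, positions
        Per-probe annotation, length M.  Probes must be sorted by
        (chromosome in natural order, position) with strictly increasing
        positions within each chromosome.
    """

    values: np.ndarray
    samples: list[str]
    probe_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.values.ndim != 2:
            raise DataQualityError("values must be a 2-D samples x probes array")
        n, m = self.values.shape
        if n < 2:
            raise DataQualityError(f"need at least 2 samples, got {n}")
        if m < 1:
            raise DataQualityError("need at least 1 probe")
        if len(self.samples) != n:
            raise DataQualityError("sample list does not match matrix rows")
        for arr, what in ((self.probe_ids, "probe_ids"),
                          (self.chromosomes, "chromosomes"),
                          (self.positions, "positions")):
            if len(arr) != m:
                raise DataQualityError(f"{what} length != number of probes")
        keys = [chromosome_sort_key(c) for c in self.chromosomes]
        for i in range(1, m):
            if keys[i] < keys[i - 1]:
                raise DataQualityError(
                    f"probes not sorted by chromosome at index {i} "
                    f"({self.chromosomes[i - 1]} -> {self.chromosomes[i]})")
            if keys[i] == keys[i - 1] and self.positions[i] <= self.positions[i - 1]:
                raise DataQualityError(
                    f"positions not strictly increasing within chromosome "
                    f"{self.chromosomes[i]} at probe {self.probe_ids[i]}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @functools.cached_property
    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous probe-index ranges per chromosome: (name, lo, hi)."""
        blocks: list[tuple[str, int, int]] = []
        lo = 0
        for i in range(1, self.n_probes + 1):
            if i == self.n_probes or self.chromosomes[i] != self.chromosomes[lo]:
                blocks.append((str(self.chromosomes[lo]), lo, i))
                lo = i
        return blocks

    def select_chromosomes(self, names: Iterable[str]) -> "CopyNumberMatrix":
        """Return the sub-matrix restricted to the given chromosomes."""
        wanted = {str(c) for c in names}
        mask = np.array([str(c) in wanted for c in self.chromosomes])
        if not mask.any():
            raise ConfigurationError(f"no probes on chromosomes {sorted(wanted)}")
        return CopyNumberMatrix(
            values=self.values[:, mask],
            samples=list(self.samples),
            probe_ids=self.probe_ids[mask],
            chromosomes=self.chromosomes[mask],
            positions=self.positions[mask],
        )


@dataclasses.dataclass
class SignedMatrix:
    """One tail (amplification or deletion) of the thresholded matrix.

    ``values`` has the same shape as the source matrix; entries failing the
    tail's indicator are zero.  Amplification keeps entries >= theta_amp > 0,
    deletion keeps entries <= theta_del < 0.
    """

    values: np.ndarray
    tail: str
    theta_amplification: float
    theta_deletion: float
    matrix: CopyNumberMatrix

    def __post_init__(self) -> None:
        if self.tail not in TAILS:
            raise ConfigurationError(f"unknown tail {self.tail!r}")

    @property
    def threshold(self) -> float:
        return (self.theta_amplification if self.tail == AMPLIFICATION
                else self.theta_deletion)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    @property
    def chrom_blocks(self) -> list[tuple[str, int, int]]:
        return self.matrix.chrom_blocks

    def copy(self) -> "SignedMatrix":
        return dataclasses.replace(self, values=self.values.copy())


@dataclasses.dataclass(frozen=True)
class CNAUnit:
    """A maximal run of correlated consecutive CNA probes u(k, L).

    ``k`` is the 0-based start probe index, ``L`` the length in probes; all
    probes of a unit lie on one chromosome.
    """

    k: int
    L: int
    chromosome: str

    @property
    def stop(self) -> int:
        """Exclusive end index."""
        return self.k + self.L

    def probes(self) -> range:
        return range(self.k, self.stop)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def threshold_matrix(X: CopyNumberMatrix,
                     theta_amplification: float,
                     theta_deletion: float) -> tuple[SignedMatrix, SignedMatrix]:
    """Split a log2-ratio matrix into amplification and deletion matrices.

    Entry-wise: the amplification matrix keeps x where x >= theta_amp, the
    deletion matrix keeps x where x <= theta_del; everything else is zero.
    The two nonzero supports are disjoint because theta_amp > 0 > theta_del.
    """
    if not (theta_amplification > 0 > theta_deletion):
        raise ConfigurationError(
            f"need theta_amplification > 0 > theta_deletion, got "
            f"{theta_amplification} and {theta_deletion}")
    bad = ~np.isfinite(X.values)
    if bad.any():
        n, m = np.argwhere(bad)[0]
        raise DataQualityError(
            f"non-finite log2 ratio for sample {X.samples[n]!r} at probe "
            f"{X.probe_ids[m]!r}")
    amp = np.where(X.values >= theta_amplification, X.values, 0.0)
    dele = np.where(X.values <= theta_deletion, X.values, 0.0)
    return (
        SignedMatrix(amp, AMPLIFICATION, theta_amplification, theta_deletion, X),
        SignedMatrix(dele, DELETION, theta_amplification, theta_deletion, X),
    )


def find_cna_probes(S: SignedMatrix) -> np.ndarray:
    """Boolean mask of probes altered in at least one sample."""
    return np.any(S.values != 0.0, axis=0)


def merge_cna_regions(mask: np.ndarray,
                      chromosomes: Sequence[str]) -> list[tuple[int, int]]:
    """Merge consecutive CNA probes into regions, never crossing chromosomes.

    Returns ``(start, length)`` intervals in probe index space, ordered by
    start.
    """
    mask = np.asarray(mask, dtype=bool)
    m = len(mask)
    if len(chromosomes) != m:
        raise DataQualityError("mask and chromosome annotation length differ")
    regions: list[tuple[int, int]] = []
    start = None
    for i in range(m):
        boundary = i > 0 and chromosomes[i] != chromosomes[i - 1]
        if start is not None and (not mask[i] or boundary):
            regions.append((start, i - start))
            start = None
        if mask[i] and start is None:
            start = i
    if start is not None:
        regions.append((start, m - start))
    return regions


def probe_correlation(S: SignedMatrix, i: int, j: int) -> float:
    """Pearson correlation of probes i and j across samples (ddof = 1).

    Computed on the signed (thresholded) values, zeros included: the zeros
    of unaltered samples carry the recurrence-frequency signal.  Returns NaN
    when either probe has zero variance across samples; an undefined
    correlation is interpreted as a breakpoint by the unit decomposition.
    """
    if i == j:
        raise ConfigurationError("probe_correlation requires i != j")
    x = S.values[:, i]
    y = S.values[:, j]
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((dx * dy).sum() / denom, -1.0, 1.0))


def _adjacent_correlations(values: np.ndarray) -> np.ndarray:
    """Pearson correlation of each adjacent column pair; NaN where undefined.

    Vectorised over the window ``values`` of shape (N, W); returns (W-1,).
    """
    d = values - values.mean(axis=0)
    ss = np.einsum("nm,nm->m", d, d)
    cov = np.einsum("nm,nm->m", d[:, :-1], d[:, 1:])
    denom = np.sqrt(ss[:-1] * ss[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0.0, cov / denom, np.nan)
    return np.clip(rho, -1.0, 1.0)


def split_into_units(region: tuple[int, int],
                     S: SignedMatrix,
                     theta_rho: float) -> list[CNAUnit]:
    """Partition a CNA region into correlation-coherent CNA units.

    A breakpoint is declared between adjacent probes (i, i+1) whenever their
    cross-sample correlation is below ``theta_rho`` or undefined; the region
    is cut after every breakpoint.  The result is a gapless, non-overlapping
    partition of the region.
    """
    if not (0.0 < theta_rho < 1.0):
        raise ConfigurationError(f"theta_rho must be in (0, 1), got {theta_rho}")
    start, length = region
    chrom = str(S.matrix.chromosomes[start])
    if length == 1:
        return [CNAUnit(start, 1, chrom)]
    rho = _adjacent_correlations(S.values[:, start:start + length])
    # NaN comparisons are False, so undefined correlations break as required.
    keep = rho >= theta_rho
    units: list[CNAUnit] = []
    k = start
    for off, ok in enumerate(keep):
        if not ok:
            cut = start + off + 1
            units.append(CNAUnit(k, cut - k, chrom))
            k = cut
    units.append(CNAUnit(k, start + length - k, chrom))
    return units


def build_units(X: CopyNumberMatrix,
                theta_amplification: float,
                theta_deletion: float,
                theta_rho: float) -> dict[str, tuple[SignedMatrix, list[CNAUnit]]]:
    """Threshold the matrix and decompose each tail into CNA units.

    Returns ``{tail: (signed_matrix, units)}``; for each tail the units
    partition exactly the set of that tail's CNA probes.
    """
    amp, dele = threshold_matrix(X, theta_amplification, theta_deletion)
    out: dict[str, tuple[SignedMatrix, list[CNAUnit]]] = {}
    for S in (amp, dele):
        mask = find_cna_probes(S)
        units: list[CNAUnit] = []
        for region in merge_cna_regions(mask, X.chromosomes):
            units.extend(split_into_units(region, S, theta_rho))
        out[S.tail] = (S, units)
    return out
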