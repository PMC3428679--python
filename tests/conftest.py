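"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from saic import CNAUnit, CopyNumberMatrix, make_matrix
from saic.core_units import AMPLIFICATION, DELETION


# ---------------------------------------------------------------------------
# engineered fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def region_unit_matrix() -> CopyNumberMatrix:
    """3 samples x 16 probes with amplification CNA probes at 1-10 and 14-16
    (1-based): the first region splits into units of lengths 3, 4, 3 (perfect
    within-unit correlation, negative correlation across the two internal
    breakpoints), the second region is a single 3-probe unit."""
    a = np.array([0.5, 0.9, 0.0])   # unit 1: probes 1-3
    b = np.array([0.0, 0.5, 0.9])   # unit 2: probes 4-7 (corr(a, b) < 0)
    c = np.array([0.9, 0.0, 0.5])   # unit 3: probes 8-10 (corr(b, c) < 0)
    d = np.array([0.6, 0.6, 0.3])   # unit 4: probes 14-16
    cols = [a, a, a, b, b, b, b, c, c, c,
            np.zeros(3), np.zeros(3), np.zeros(3), d, d, d]
    return make_matrix(np.column_stack(cols))


FIGURE_UNITS_1BASED = [(1, 3), (4, 4), (8, 3), (14, 3)]


def planted_matrix(rng: np.random.Generator, N: int = 12, M: int = 300,
                   amp_span: tuple[int, int] = (100, 140),
                   del_span: tuple[int, int] | None = (200, 230),
                   carriers: int = 9) -> np.ndarray:
    """Sporadic background plus strongly recurrent planted region(s)."""
    X = np.zeros((N, M))
    for n in range(N):
        L = int(rng.integers(8, 20))
        s = int(rng.integers(0, M - L))
        X[n, s:s + L] = rng.choice([0.8, -0.8])
    X[:carriers, amp_span[0]:amp_span[1]] = 1.1 + 0.1 * rng.random(carriers)[:, None]
    if del_span is not None:
        X[:carriers, del_span[0]:del_span[1]] = -1.0 - 0.1 * rng.random(carriers)[:, None]
    return X


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------

def oracle_units(values: np.ndarray, chromosomes, theta_amp: float,
                 theta_del: float, theta_rho: float) -> dict[str, list[CNAUnit]]:
    """Direct re-derivation of the unit decomposition by explicit loops."""
    out: dict[str, list[CNAUnit]] = {}
    n, m = values.shape
    for tail, keep in ((AMPLIFICATION, values >= theta_amp),
                       (DELETION, values <= theta_del)):
        S = np.where(keep, values, 0.0)
        mask = [any(S[i, j] != 0 for i in range(n)) for j in range(m)]
        units: list[CNAUnit] = []
        j = 0
        while j < m:
            if not mask[j]:
                j += 1
                continue
            e = j
            while (e + 1 < m and mask[e + 1]
                   and chromosomes[e + 1] == chromosomes[e]):
                e += 1
            start = j
            for i in range(j, e):
                x, y = S[:, i], S[:, i + 1]
                sx, sy = x.std(ddof=1), y.std(ddof=1)
                if sx == 0 or sy == 0:
                    rho = np.nan
                else:
                    rho = float(np.corrcoef(x, y)[0, 1])
                if not (rho >= theta_rho):
                    units.append(CNAUnit(start, i + 1 - start,
                                         str(chromosomes[start])))
                    start = i + 1
            units.append(CNAUnit(start, e + 1 - start, str(chromosomes[start])))
            j = e + 1
        out[tail] = units
    return out


def oracle_max_window(Xp: np.ndarray, L: int, chrom_blocks=None) -> float:
    """Exhaustive window enumeration with plain np.mean."""
    n, m = Xp.shape
    if chrom_blocks is None:
        chrom_blocks = [("*", 0, m)]
    best = -np.inf
    for _, lo, hi in chrom_blocks:
        for s in range(lo, hi - L + 1):
            best = max(best, float(np.mean(Xp[:, s:s + L])))
    return best


def oracle_pvalue(u_obs: float, extrema, tail: str) -> float:
    """Direct Eq.-4 count with the same tie guard as the implementation."""
    tol = 1e-9 * max(1.0, abs(u_obs))
    if tail == AMPLIFICATION:
        c = sum(1 for x in extrema if x >= u_obs - tol)
    else:
        c = sum(1 for x in extrema if x <= u_obs + tol)
    return (1 + c) / (len(extrema) + 1)


def two_region_matrix(rng, N=20, M=800, weak_carriers=7):
    """A dominant recurrent amplification plus a weaker one, in sporadic
    background: the configuration that motivates iterative re-estimation."""
    X = np.zeros((N, M))
    for n in range(N):
        for _ in range(3):
            L = int(rng.integers(10, 30))
            s = int(rng.integers(0, M - L))
            X[n, s:s + L] = 0.8
    X[:18, 100:180] = 1.6            # dominant: 18/20 carriers, strong
    X[:weak_carriers, 400:460] = 0.55  # weak: borderline against iter-1 null
    return X
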