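"""Synthetic copy-number data generators and evaluation metrics.

Three dataset families with definitive ground truth:

* **null** -- no recurrent aberrations: each sample carries its own
  independently placed sporadic CNA units (optionally positionally clumped
  within the sample), so any cross-sample positional concentration is pure
  chance.  Used to estimate the family-wise error rate (FWER).
* **power** -- a contamination-mixture cohort: every probe's signal is a
  mixture of tumor and normal genomes with per-sample normal-cell fraction
  lambda ~ N(mu, sigma) truncated to [0, 1]; each sample carries one
  sporadic deletion (0-1 copies) and one sporadic amplification (3-8
  copies), and each dataset plants one recurrent deletion and one recurrent
  amplification interval carried by a Bernoulli(omega) subset of samples.
  Used to estimate detection power.
* **roc** -- a noisy genome with per-sample background CNAs, uniform
  contamination, tiered Gaussian noise and four planted recurrent regions,
  with probe-level truth labels.  Used for probe-level ROC analysis.

Observed copies c = lambda * 2 + (1 - lambda) * tumor_copy are reported as
log2(c / 2); a homozygous deletion in a pure tumor (c = 0) is floored at a
small positive copy count before the log.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .core_units import (
    AMPLIFICATION,
    DELETION,
    TAILS,
    ConfigurationError,
    CopyNumberMatrix,
)
from .iterative import IterativeResult, SAICParams, run_algorithm2

#: thresholds used throughout the simulation studies (focal-CNA defaults of
#: the upstream segmentation tooling): theta_amp/theta_del = +/-0.1 log2
#: units, adjacent-correlation threshold 0.75
def simulation_params(permutations: int = 1000, alpha: float = 0.05,
                      seed: int = 0, **kw) -> SAICParams:
    return SAICParams(theta_amp=0.1, theta_del=-0.1, theta_rho=0.75,
                      permutations=permutations, alpha=alpha, seed=seed, **kw)


@dataclasses.dataclass(frozen=True)
class TruthRegion:
    """A planted recurrent interval: probe span [start, start+length), tail."""

    start: int
    length: int
    tail: str

    @property
    def stop(self) -> int:
        return self.start + self.length


def mix_with_normal(tumor_copy: float, lam: float, floor: float = 0.05) -> float:
    """Log2 ratio of a tumor/normal mixture: c = 2*lam + (1-lam)*copy.

    ``lam`` is the normal-cell fraction; copies below ``floor`` are floored
    before the log so a homozygous deletion stays finite but strongly
    negative.
    """
    if not (0.0 <= lam <= 1.0):
        raise ConfigurationError(f"lambda must be in [0, 1], got {lam}")
    if tumor_copy < 0:
        raise ConfigurationError("tumor copy number cannot be negative")
    c = lam * 2.0 + (1.0 - lam) * tumor_copy
    return float(np.log2(max(c, floor) / 2.0))


def _probe_grid(M: int, chromosome: str = "1") -> dict:
    return dict(
        probe_ids=np.array([f"p{i + 1}" for i in range(M)], dtype=object),
        chromosomes=np.full(M, chromosome, dtype=object),
        positions=np.arange(1, M + 1, dtype=np.int64),
    )


def make_matrix(values: np.ndarray, chromosome: str = "1") -> CopyNumberMatrix:
    """Wrap a plain (N, M) array as a single-chromosome CopyNumberMatrix
    with unit-spaced positions -- convenient for simulations and tests."""
    values = np.asarray(values, dtype=np.float64)
    n, m = values.shape
    return CopyNumberMatrix(values=values,
                            samples=[f"s{i + 1}" for i in range(n)],
                            **_probe_grid(m, chromosome))


_as_matrix = make_matrix


def _draw_copy(rng: np.random.Generator, tail: str,
               del_copies: tuple[int, int], amp_copies: tuple[int, int]) -> int:
    lo, hi = del_copies if tail == DELETION else amp_copies
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# null / FWER model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NullSimConfig:
    """Null-model settings: per-sample sporadic units only.

    ``clump_fraction`` places that fraction of each sample's units inside
    one random window of ``clump_window_fraction`` of the span, inducing
    within-sample positional clustering while remaining null across samples.
    """

    N: int = 20
    M: int = 1000
    units_per_sample: tuple[int, int] = (2, 10)
    unit_length: tuple[int, int] = (10, 50)
    clump_fraction: float = 0.0
    clump_window_fraction: float = 0.1
    lam_range: tuple[float, float] = (0.2, 0.8)
    del_copies: tuple[int, int] = (0, 1)
    amp_copies: tuple[int, int] = (3, 8)
    noise_sd: float = 0.0   #: segmented input is piecewise constant; see docs
    copy_floor: float = 0.05

    def validate(self) -> None:
        if not (0.0 <= self.clump_fraction < 1.0):
            raise ConfigurationError("clump_fraction must be in [0, 1)")
        if self.unit_length[1] > self.M:
            raise ConfigurationError("sporadic unit longer than the genome")


def simulate_null_dataset(cfg: NullSimConfig,
                          rng: np.random.Generator) -> CopyNumberMatrix:
    """One dataset with sporadic, independently placed CNA units only.

    Each sample's units occupy disjoint spans (sequential rejection),
    mirroring the disjointness of observed CNA units; clumped units go into
    one random window sized max(clump_window_fraction * M, 1.3x their total
    length), grown if disjoint packing fails.
    """
    cfg.validate()
    X = np.zeros((cfg.N, cfg.M))
    lam = rng.uniform(*cfg.lam_range, size=cfg.N)
    for n in range(cfg.N):
        k = int(rng.integers(cfg.units_per_sample[0],
                             cfg.units_per_sample[1] + 1))
        lens = rng.integers(cfg.unit_length[0], cfg.unit_length[1] + 1, size=k)
        tails = np.where(rng.random(k) < 0.5, AMPLIFICATION, DELETION)
        n_clumped = int(round(cfg.clump_fraction * k))
        window = None
        if n_clumped:
            W = min(cfg.M, max(int(cfg.clump_window_fraction * cfg.M),
                               int(np.ceil(1.3 * lens[:n_clumped].sum())),
                               int(lens.max())))
            w0 = int(rng.integers(0, cfg.M - W + 1))
            window = (w0, w0 + W)
        occupied: list[tuple[int, int]] = []
        for i in range(k):
            L = int(lens[i])
            if i < n_clumped:
                span = None
                win = window
                while span is None:
                    try:
                        span = _place_disjoint(rng, cfg.M, L, occupied, 200, win)
                    except ConfigurationError:
                        if win[1] - win[0] >= cfg.M:
                            span = _place_disjoint(rng, cfg.M, L, occupied,
                                                   200, fallback=True)
                            break
                        # grow the clump window rather than dropping the unit
                        w0, w1 = win
                        grow = max(1, (w1 - w0) // 2)
                        win = (max(0, w0 - grow // 2),
                               min(cfg.M, w1 + grow))
            else:
                span = _place_disjoint(rng, cfg.M, L, occupied, 200,
                                       fallback=True)
            occupied.append(span)
            copy = _draw_copy(rng, str(tails[i]), cfg.del_copies, cfg.amp_copies)
            X[n, span[0]:span[1]] = mix_with_normal(copy, lam[n], cfg.copy_floor)
    if cfg.noise_sd > 0:
        X += rng.normal(0.0, cfg.noise_sd, size=X.shape)
    return _as_matrix(X)


# ---------------------------------------------------------------------------
# power model (contamination mixture)
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PowerSimConfig:
    """Power-model settings: sporadic + recurrent regions under contamination.

    ``omega`` is the recurrence frequency; ``mu_lambda``/``sigma_lambda``
    parameterise the per-sample normal-cell fraction (truncated normal on
    [0, 1]).  All region lengths are drawn uniformly from ``region_length``.
    """

    N: int = 60
    M: int = 5000
    omega: float = 0.2
    mu_lambda: float = 0.6
    sigma_lambda: float = 0.15
    region_length: tuple[int, int] = (150, 250)
    del_copies: tuple[int, int] = (0, 1)
    amp_copies: tuple[int, int] = (3, 8)
    copy_floor: float = 0.05
    max_placement_tries: int = 1000

    def validate(self) -> None:
        if not (0.0 <= self.omega <= 1.0):
            raise ConfigurationError("omega must be in [0, 1]")
        if not (0.0 <= self.mu_lambda <= 1.0):
            raise ConfigurationError("mu_lambda must be in [0, 1]")
        if self.sigma_lambda <= 0:
            raise ConfigurationError("sigma_lambda must be > 0")
        if 2 * self.region_length[1] > self.M:
            raise ConfigurationError("regions cannot fit disjointly")


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float,
                      size: int) -> np.ndarray:
    a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=size,
                               random_state=rng)


def _place_disjoint(rng: np.random.Generator, M: int, length: int,
                    occupied: list[tuple[int, int]], tries: int,
                    window: tuple[int, int] | None = None,
                    fallback: bool = False) -> tuple[int, int]:
    lo_w, hi_w = window if window is not None else (0, M)
    s = int(rng.integers(lo_w, hi_w - length + 1))
    for _ in range(tries):
        if all(s + length <= lo or s >= hi for lo, hi in occupied):
            return s, s + length
        s = int(rng.integers(lo_w, hi_w - length + 1))
    if fallback:
        # dense configuration: accept an overlapping placement
        return s, s + length
    raise ConfigurationError(
        f"could not place a {length}-probe interval disjointly after {tries} tries")


def simulate_power_dataset(cfg: PowerSimConfig, rng: np.random.Generator
                           ) -> tuple[CopyNumberMatrix, list[TruthRegion]]:
    """One power-model dataset plus its two recurrent truth intervals."""
    cfg.validate()
    lo, hi = cfg.region_length
    truth: list[TruthRegion] = []
    occupied: list[tuple[int, int]] = []
    for tail in (DELETION, AMPLIFICATION):
        L = int(rng.integers(lo, hi + 1))
        span = _place_disjoint(rng, cfg.M, L, occupied, cfg.max_placement_tries)
        occupied.append(span)
        truth.append(TruthRegion(span[0], L, tail))
    lam = _truncated_normal(rng, cfg.mu_lambda, cfg.sigma_lambda, cfg.N)
    carriers = {t: rng.random(cfg.N) < cfg.omega for t in TAILS}
    X = np.zeros((cfg.N, cfg.M))
    for n in range(cfg.N):
        taken = list(occupied)
        for tail in (DELETION, AMPLIFICATION):
            L = int(rng.integers(lo, hi + 1))
            span = _place_disjoint(rng, cfg.M, L, taken, cfg.max_placement_tries)
            taken.append(span)
            copy = _draw_copy(rng, tail, cfg.del_copies, cfg.amp_copies)
            X[n, span[0]:span[1]] = mix_with_normal(copy, lam[n], cfg.copy_floor)
        for region in truth:
            if carriers[region.tail][n]:
                copy = _draw_copy(rng, region.tail, cfg.del_copies, cfg.amp_copies)
                X[n, region.start:region.stop] = mix_with_normal(
                    copy, lam[n], cfg.copy_floor)
    return _as_matrix(X), truth


# ---------------------------------------------------------------------------
# ROC model
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RocSimConfig:
    """ROC-model settings: planted recurrent regions in a noisy background.

    Truth regions: amplifications of (length, copy) = (30, 3), (20, 4),
    (10, 5) and one deletion of length 20 with per-carrier copies in {0, 1},
    each at frequency ``omega * beta_omega`` and with lengths scaled by
    ``beta_length``.  Every sample also carries 2-10 background CNAs and
    zero-mean Gaussian noise with a per-sample sd tier.
    """

    N: int = 50
    M: int = 5000
    lam_range: tuple[float, float] = (0.2, 0.8)
    noise_tiers: tuple[tuple[float, float], ...] = ((0.2, 0.4), (0.4, 0.6),
                                                    (0.6, 0.8))
    background_count: tuple[int, int] = (2, 10)
    background_length: tuple[int, int] = (10, 50)
    amp_truth: tuple[tuple[int, int], ...] = ((30, 3), (20, 4), (10, 5))
    del_truth_length: int = 20
    del_copies: tuple[int, int] = (0, 1)
    amp_copies: tuple[int, int] = (3, 8)
    omega: float = 0.1
    beta_length: float = 1.0
    beta_omega: float = 1.0
    copy_floor: float = 0.05
    max_placement_tries: int = 1000

    def validate(self) -> None:
        freq = self.omega * self.beta_omega
        if not (0.0 < freq <= 1.0):
            raise ConfigurationError("omega * beta_omega must be in (0, 1]")
        if self.beta_length <= 0:
            raise ConfigurationError("beta_length must be > 0")


def simulate_roc_dataset(cfg: RocSimConfig, rng: np.random.Generator
                         ) -> tuple[CopyNumberMatrix, dict[str, np.ndarray]]:
    """One ROC-model dataset plus probe-level truth label masks per tail."""
    cfg.validate()
    freq = cfg.omega * cfg.beta_omega
    truth: list[tuple[TruthRegion, int | None]] = []
    occupied: list[tuple[int, int]] = []
    for base_len, copy in cfg.amp_truth:
        L = max(1, int(round(base_len * cfg.beta_length)))
        span = _place_disjoint(rng, cfg.M, L, occupied, cfg.max_placement_tries)
        occupied.append(span)
        truth.append((TruthRegion(span[0], L, AMPLIFICATION), copy))
    L = max(1, int(round(cfg.del_truth_length * cfg.beta_length)))
    span = _place_disjoint(rng, cfg.M, L, occupied, cfg.max_placement_tries)
    occupied.append(span)
    truth.append((TruthRegion(span[0], L, DELETION), None))

    lam = rng.uniform(*cfg.lam_range, size=cfg.N)
    X = np.zeros((cfg.N, cfg.M))
    for n in range(cfg.N):
        # background CNAs first (disjoint within the sample); planted
        # recurrent signal overwrites them in carrier samples
        k = int(rng.integers(cfg.background_count[0],
                             cfg.background_count[1] + 1))
        taken: list[tuple[int, int]] = []
        for _ in range(k):
            bl = int(rng.integers(cfg.background_length[0],
                                  cfg.background_length[1] + 1))
            span = _place_disjoint(rng, cfg.M, bl, taken,
                                   cfg.max_placement_tries)
            taken.append(span)
            tail = AMPLIFICATION if rng.random() < 0.5 else DELETION
            copy = _draw_copy(rng, tail, cfg.del_copies, cfg.amp_copies)
            X[n, span[0]:span[1]] = mix_with_normal(copy, lam[n], cfg.copy_floor)
        for region, fixed_copy in truth:
            if rng.random() < freq:
                copy = (fixed_copy if fixed_copy is not None
                        else _draw_copy(rng, DELETION, cfg.del_copies,
                                        cfg.amp_copies))
                X[n, region.start:region.stop] = mix_with_normal(
                    copy, lam[n], cfg.copy_floor)
        tier = cfg.noise_tiers[int(rng.integers(0, len(cfg.noise_tiers)))]
        sigma = float(rng.uniform(*tier))
        X[n] += rng.normal(0.0, sigma, size=cfg.M)
    labels = {t: np.zeros(cfg.M, dtype=bool) for t in TAILS}
    for region, _ in truth:
        labels[region.tail][region.start:region.stop] = True
    return _as_matrix(X), labels


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------

def _rep_seed(seed: int, rep: int) -> int:
    """Deterministic 31-bit per-replicate seed for the detection procedure."""
    return int(np.random.SeedSequence((seed, rep)).generate_state(1)[0]
               & 0x7FFFFFFF)


def _rep_rng(seed: int, rep: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, rep, stream)))


def estimate_fwer(cfg: NullSimConfig, params: SAICParams, replicates: int,
                  seed: int = 0) -> float:
    """Fraction of null datasets on which the procedure makes >= 1 call."""
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    hits = 0
    for rep in range(replicates):
        X = simulate_null_dataset(cfg, _rep_rng(seed, rep, 1))
        p = dataclasses.replace(params, seed=_rep_seed(seed, rep))
        hits += bool(run_algorithm2(X, p).calls)
    return hits / replicates


def _detected(result: IterativeResult, region: TruthRegion) -> bool:
    """>= 1 probe overlap between a matching-tail call and the truth region."""
    return any(c.tail == region.tail
               and c.unit.k < region.stop and region.start < c.unit.stop
               for c in result.calls)


def _boundary_error(result: IterativeResult, region: TruthRegion) -> float | None:
    """Mean absolute start/end error (probes) of the merged overlapping calls."""
    spans = [(c.unit.k, c.unit.stop) for c in result.calls
             if c.tail == region.tail
             and c.unit.k < region.stop and region.start < c.unit.stop]
    if not spans:
        return None
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    return 0.5 * (abs(lo - region.start) + abs(hi - region.stop))


@dataclasses.dataclass
class PowerEstimate:
    amplification: float
    deletion: float
    combined: float
    boundary_error_probes: float  #: mean over detected regions; NaN if none


def estimate_power(cfg: PowerSimConfig, params: SAICParams, replicates: int,
                   seed: int = 0) -> PowerEstimate:
    """Per-tail and combined recurrent-region detection rates.

    A truth interval counts as detected when at least one called SCA of the
    matching tail overlaps it by >= 1 probe; combined power is the mean of
    the two per-tail rates.  Boundary accuracy of detected regions is
    reported alongside but not thresholded.
    """
    if replicates < 1:
        raise ConfigurationError("need at least one replicate")
    hits = {t: 0 for t in TAILS}
    errors: list[float] = []
    for rep in range(replicates):
        X, truth = simulate_power_dataset(cfg, _rep_rng(seed, rep, 2))
        p = dataclasses.replace(params, seed=_rep_seed(seed, rep))
        result = run_algorithm2(X, p)
        for region in truth:
            if _detected(result, region):
                hits[region.tail] += 1
                err = _boundary_error(result, region)
                if err is not None:
                    errors.append(err)
    amp = hits[AMPLIFICATION] / replicates
    dele = hits[DELETION] / replicates
    return PowerEstimate(
        amplification=amp, deletion=dele, combined=0.5 * (amp + dele),
        boundary_error_probes=float(np.mean(errors)) if errors else float("nan"))


def _probe_pvalues(result: IterativeResult, tail: str, M: int) -> np.ndarray:
    """Per-probe P-value: the covering unit's final P (probes outside any
    unit can never be called and get P > 1)."""
    p = np.full(M, 1.1)
    for c in result.candidates[tail]:
        p[c.unit.k:c.unit.stop] = c.pvalue
    return p


def _staircase(scores: np.ndarray, labels: np.ndarray,
               thresholds: np.ndarray, smaller_is_stronger: bool
               ) -> list[tuple[float, float]]:
    pos = labels.sum()
    neg = labels.size - pos
    pts = [(0.0, 0.0)]
    for thr in thresholds:
        called = scores <= thr if smaller_is_stronger else scores >= thr
        tpr = float((called & labels).sum() / pos) if pos else 0.0
        fpr = float((called & ~labels).sum() / neg) if neg else 0.0
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    pts.sort()
    return pts


def partial_auc(points: Sequence[tuple[float, float]], fpr_cap: float = 0.2
                ) -> float:
    """Trapezoidal area under an ROC staircase over FPR in [0, fpr_cap]."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    grid = np.unique(np.clip(np.append(fpr, [0.0, fpr_cap]), 0.0, fpr_cap))
    interp = np.interp(grid, fpr, tpr)
    return float(np.trapezoid(interp, grid))


def roc_curve(cfg: RocSimConfig, params: SAICParams,
              alpha_grid: Sequence[float], replicates: int, seed: int = 0
              ) -> dict[str, list[tuple[float, float]]]:
    """Probe-level (FPR, TPR) points per tail, averaged over replicates.

    A probe is called at level alpha when a unit covering it has final
    P <= alpha (matching tail).
    """
    grid = np.sort(np.asarray(alpha_grid, dtype=float))
    sums = {t: np.zeros((grid.size, 2)) for t in TAILS}
    for rep in range(replicates):
        X, labels = simulate_roc_dataset(cfg, _rep_rng(seed, rep, 3))
        p = dataclasses.replace(params, seed=_rep_seed(seed, rep))
        result = run_algorithm2(X, p)
        for tail in TAILS:
            probs = _probe_pvalues(result, tail, cfg.M)
            pts = _staircase(probs, labels[tail], grid, True)[1:-1]
            sums[tail] += np.asarray(pts)
    out = {}
    for tail in TAILS:
        avg = sums[tail] / replicates
        pts = [(0.0, 0.0)] + [tuple(row) for row in avg] + [(1.0, 1.0)]
        pts.sort()
        out[tail] = pts
    return out


def frequency_baseline_points(X: CopyNumberMatrix, tail: str, theta: float,
                              labels: np.ndarray) -> list[tuple[float, float]]:
    """ROC staircase of the frequency-only statistic: the fraction of
    samples beyond the threshold at each probe, swept over its levels."""
    if tail == AMPLIFICATION:
        freq = (X.values >= theta).mean(axis=0)
    else:
        freq = (X.values <= theta).mean(axis=0)
    thresholds = np.unique(freq)[::-1]
    return _staircase(freq, labels, thresholds, smaller_is_stronger=False)


def compare_roc_with_frequency_baseline(cfg: RocSimConfig, params: SAICParams,
                                        replicates: int, seed: int = 0,
                                        fpr_cap: float = 0.2
                                        ) -> dict[str, object]:
    """Per-replicate partial-AUC comparison of the detector against the
    internal frequency-only baseline, pooled over both tails."""
    T = params.permutations
    alpha_grid = np.arange(1, T + 2) / (T + 1)  # every achievable P level
    wins = 0
    saic_auc: list[float] = []
    base_auc: list[float] = []
    for rep in range(replicates):
        X, labels = simulate_roc_dataset(cfg, _rep_rng(seed, rep, 3))
        p = dataclasses.replace(params, seed=_rep_seed(seed, rep))
        result = run_algorithm2(X, p)
        s_tot = b_tot = 0.0
        for tail in TAILS:
            probs = _probe_pvalues(result, tail, cfg.M)
            pts = _staircase(probs, labels[tail], alpha_grid, True)
            s_tot += partial_auc(pts, fpr_cap)
            theta = params.theta_amp if tail == AMPLIFICATION else params.theta_del
            b_tot += partial_auc(
                frequency_baseline_points(X, tail, theta, labels[tail]), fpr_cap)
        saic_auc.append(s_tot / 2)
        base_auc.append(b_tot / 2)
        wins += s_tot > b_tot
    return {"win_fraction": wins / replicates,
            "saic_partial_auc": saic_auc,
            "baseline_partial_auc": base_auc}
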