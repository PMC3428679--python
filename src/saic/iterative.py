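"""Iterative SCA detection with an SCA-exclusive permutation null.

A single round of the permutation test is conservative when true recurrent
aberrations are present: their relocated segments inflate the null maxima
and hide weaker recurrent signal.  The iterative procedure therefore (1)
runs the permutation test, (2) calls units significant at the per-iteration
level ``alpha' = alpha / (1 + alpha)``, (3) masks the called units to zero
and repeats until no new call appears, and finally re-computes the P-values
of every call under the *truth-converging* null -- the permutation null of
the fully masked data, in which only presumed-sporadic signal remains.

The per-iteration level alpha' makes the cumulative false-positive rate of
the whole loop equal the targeted alpha: calls at iteration r are
conditional on (false) calls at every earlier iteration, so the FPR is the
geometric series sum_r alpha'^r = alpha' / (1 - alpha') = alpha.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np

from .core_units import (
    TAILS,
    CNAUnit,
    ConfigurationError,
    CopyNumberMatrix,
    SignedMatrix,
    build_units,
)
from .significance import (
    ATOM_MODES,
    CHROMOSOME,
    COLLISION_MODES,
    SCOPES,
    NullDistribution,
    SCACall,
    build_null_distribution,
    run_algorithm1,
    unit_pvalue,
)

logger = logging.getLogger("saic")


def significance_threshold(alpha: float) -> float:
    """Per-iteration significance level alpha' = alpha / (1 + alpha).

    Inverse of the geometric-series FPR identity alpha'/(1 - alpha') = alpha.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    return alpha / (1.0 + alpha)


def mask_scas(S: SignedMatrix, detected: Sequence[CNAUnit]) -> SignedMatrix:
    """Zero the probe columns of the detected units across all samples."""
    out = S.copy()
    for u in detected:
        out.values[:, u.k:u.stop] = 0.0
    return out


@dataclasses.dataclass
class SAICParams:
    """Tunable parameters of the full detection procedure.

    Thresholds are in log2-ratio units.  ``permutations`` is the number T of
    positional permutations per null estimate; ``alpha`` the targeted
    family-wise false-positive rate; ``scope`` controls whether units are
    relocated (and window maxima taken) genome-wide or per chromosome.
    """

    theta_amp: float = 0.263
    theta_del: float = -0.322
    theta_rho: float = 0.95
    permutations: int = 1000
    alpha: float = 0.05
    scope: str = CHROMOSOME
    seed: int = 0
    max_iterations: int = 50
    collision: str = "reject"
    atoms: str = "runs"

    def validate(self) -> None:
        if not (self.theta_amp > 0 > self.theta_del):
            raise ConfigurationError("need theta_amp > 0 > theta_del")
        if not (0.0 < self.theta_rho < 1.0):
            raise ConfigurationError("theta_rho must be in (0, 1)")
        if self.permutations < 1:
            raise ConfigurationError("permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.scope not in SCOPES:
            raise ConfigurationError(f"unknown scope {self.scope!r}")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if self.collision not in COLLISION_MODES:
            raise ConfigurationError(f"unknown collision mode {self.collision!r}")
        if self.atoms not in ATOM_MODES:
            raise ConfigurationError(f"unknown atom mode {self.atoms!r}")


@dataclasses.dataclass
class IterativeResult:
    """Outcome of the iterative procedure.

    ``calls`` hold the final (truth-converging-null) P-values; the iteration
    field records when each unit was called.  ``candidates`` maps each tail
    to one entry per observed unit carrying its most up-to-date P-value
    (called units: the final re-calculated one; others: the value from the
    last iteration's null).  ``iteration_pvalues`` keeps the raw per-
    iteration P-value tables for diagnostics.
    """

    calls: list[SCACall]
    iterations_run: int
    alpha: float
    alpha_prime: float
    final_null: dict[str, NullDistribution]
    candidates: dict[str, list[SCACall]]
    units: dict[str, list[CNAUnit]]
    iteration_pvalues: dict[str, list[dict[CNAUnit, float]]]


def _tail_rng(seed: int, iteration: int) -> np.random.Generator:
    # shared across tails on purpose: deletion runs the amplification code
    # path on the negated matrix, so identical streams give exact sign
    # symmetry between the two branches
    return np.random.default_rng(np.random.SeedSequence((seed, iteration)))


def _run_tail(S: SignedMatrix,
              units: list[CNAUnit],
              params: SAICParams,
              alpha_prime: float,
              ) -> tuple[list[SCACall], NullDistribution, list[SCACall],
                         list[dict[CNAUnit, float]], int]:
    T = params.permutations
    calls: list[SCACall] = []
    history: list[dict[CNAUnit, float]] = []
    last_cands: dict[CNAUnit, SCACall] = {}
    S_work = S
    active = list(units)
    r = 0
    null = NullDistribution({}, T, params.scope, S.tail)
    while True:
        r += 1
        cands, null = run_algorithm1(S_work, active, T, params.scope,
                                     rng=_tail_rng(params.seed, r), iteration=r,
                                     collision=params.collision,
                                     atoms=params.atoms)
        history.append({c.unit: c.pvalue for c in cands})
        last_cands.update({c.unit: c for c in cands})
        new = [c for c in cands if c.pvalue <= alpha_prime]
        logger.info("%s iteration %d: %d unit(s) called", S.tail, r, len(new))
        if not new:
            break
        calls.extend(new)
        S_work = mask_scas(S_work, [c.unit for c in new])
        called = {c.unit for c in new}
        active = [u for u in active if u not in called]
        if r >= params.max_iterations:
            logger.warning("%s: max_iterations=%d reached with calls still "
                           "appearing; stopping", S.tail, params.max_iterations)
            break
    # truth-converging null: fresh permutations of the fully masked data,
    # evaluated at the lengths of the called units
    if calls:
        final_null = build_null_distribution(
            S_work, [c.unit for c in calls], T, params.scope,
            _tail_rng(params.seed, r + 1), collision=params.collision,
            placed_units=active if params.atoms == "units" else None)
        recalced = []
        for c in calls:
            p = unit_pvalue(c.score, final_null.vector(c.unit), S.tail)
            recalced.append(dataclasses.replace(c, pvalue=p))
        calls = recalced
    else:
        final_null = null
    final_by_unit = {c.unit: c for c in calls}
    candidates = [final_by_unit.get(u, last_cands[u]) for u in units]
    return calls, final_null, candidates, history, r


def run_algorithm2(X: CopyNumberMatrix, params: SAICParams) -> IterativeResult:
    """Full iterative SCA detection on both tails of a log2-ratio matrix.

    Amplification and deletion branches run independently (no cross-tail
    multiplicity correction).  The call set is decided at alpha' during the
    iterations and is not re-thresholded after the final P-value
    re-calculation: each call is conditional on the calls before it.
    """
    params.validate()
    alpha_prime = significance_threshold(params.alpha)
    decomp = build_units(X, params.theta_amp, params.theta_del, params.theta_rho)
    all_calls: list[SCACall] = []
    final_null: dict[str, NullDistribution] = {}
    candidates: dict[str, list[SCACall]] = {}
    units_out: dict[str, list[CNAUnit]] = {}
    histories: dict[str, list[dict[CNAUnit, float]]] = {}
    iterations = 0
    for tail in TAILS:
        S, units = decomp[tail]
        units_out[tail] = units
        if not units:
            final_null[tail] = NullDistribution({}, params.permutations,
                                                params.scope, tail)
            candidates[tail] = []
            histories[tail] = []
            continue
        calls, null, cands, history, r = _run_tail(S, units, params, alpha_prime)
        all_calls.extend(calls)
        final_null[tail] = null
        candidates[tail] = cands
        histories[tail] = history
        iterations = max(iterations, r)
    return IterativeResult(
        calls=all_calls,
        iterations_run=iterations,
        alpha=params.alpha,
        alpha_prime=alpha_prime,
        final_null=final_null,
        candidates=candidates,
        units=units_out,
        iteration_pvalues=histories,
    )
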