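"""Ensemble model of duplex melting via a no-slip partition function.

The partition function Q sums Boltzmann factors exp(-dG/RT) over all pairing
states (the unpaired state contributes exactly 1).  Left/right partial sums
Q_L,i and Q_R,i are built by recursion from the 5' and 3' ends and satisfy
two exact identities that pin the implementation:

* sum_i Q_L,i = Q - 1                        (decomposition by rightmost pair)
* Q_L,i * Q_R,i = total weight of all structures containing pair i,
  with initiation (and the symmetry term) counted exactly once.

Conditional per-pair probabilities, the probability of at least one pair at
total strand concentration C_T (bimolecular mass balance), model
fraction-paired curves and predicted melting temperatures follow.

All energy-dependent internals are vectorized over temperature arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.optimize import bisect

from .errors import NoTransitionError, NumericalError, ValidationError
from .thermo_model import (
    CELSIUS_OFFSET,
    DS_SYM,
    MAX_LOOP,
    NNParamSet,
    DuplexSequence,
    R_GAS,
    canonical_stack,
)


@dataclass
class PartitionResult:
    """Partition function and left/right partial sums at one or many temperatures.

    ``Q`` has the temperature shape; ``QL``/``QR`` have shape (L,) + temperature
    shape.  ``temperature`` is in kelvin.
    """

    Q: np.ndarray
    QL: np.ndarray
    QR: np.ndarray
    temperature: np.ndarray
    self_complementary: bool


@dataclass
class ModelCurve:
    """Predicted fraction of maximal pairs on a temperature grid (deg C)."""

    temperatures: np.ndarray
    fractions: np.ndarray
    strand_concentration: float
    duplex_id: str = ""


def _as_temp_array(T):
    arr = np.atleast_1d(np.asarray(T, dtype=float))
    if np.any(arr <= 0):
        raise ValidationError("temperatures must be positive kelvin")
    return arr


def compute_partition(
    seq: DuplexSequence, params: NNParamSet, T
) -> PartitionResult:
    """Partition function of a duplex at kelvin temperature(s) T.

    Q includes the unpaired state with weight exactly 1.  Initiation and, for
    self-complementary duplexes, the fixed symmetry term are folded into the
    5'-start weight of the left recursion so the Q_L*Q_R factorization counts
    them once.
    """
    T_arr = _as_temp_array(T)
    scalar = np.isscalar(T) or np.asarray(T).ndim == 0
    L = seq.length
    top = seq.top_strand
    RT = R_GAS * T_arr
    dg = params.delta_g_arrays(T_arr)

    def boltz(g):
        # clip the exponent so single factors stay finite; genuine overflow of
        # accumulated products is still caught below
        return np.exp(np.clip(-np.asarray(g) / RT, None, 700.0))

    # Helix-end factor per position (terminal A-U term, or 1 for G-C pairs).
    e = [boltz(dg["terminal_AU"]) if top[i] in "AU" else np.ones_like(T_arr) for i in range(L)]
    # Stack weight between positions i-1 and i (0-based i >= 1).
    w_stack = [None] + [boltz(dg[canonical_stack(top[i - 1 : i + 1])]) for i in range(1, L)]
    w_loop = {g: boltz(dg[f"loop_{g}"]) for g in range(1, MAX_LOOP + 1)}

    dg_init = dg["initiation"].copy()
    if seq.self_complementary:
        dg_init += -T_arr * DS_SYM / 1000.0
    w_init = boltz(dg_init)

    # A[i]: weight of configs on 1..i with i paired, everything included
    # except the right-side helix-end term at i (undetermined until we know
    # what follows).  B[i] is the mirror from the 3' end, without initiation
    # and without the left-side end term at i.
    with np.errstate(over="ignore"):  # overflow detected via the finite check
        A = [None] * L
        for i in range(L):
            tot = w_init * e[i]
            if i >= 1:
                tot = tot + A[i - 1] * w_stack[i]
            for g in range(1, min(MAX_LOOP, i - 1) + 1):
                k = i - 1 - g
                tot = tot + A[k] * e[k] * w_loop[g] * e[i]
            A[i] = tot

        B = [None] * L
        for i in range(L - 1, -1, -1):
            tot = e[i].copy()
            if i <= L - 2:
                tot = tot + B[i + 1] * w_stack[i + 1]
            for g in range(1, min(MAX_LOOP, L - i - 2) + 1):
                m = i + 1 + g
                tot = tot + B[m] * e[m] * w_loop[g] * e[i]
            B[i] = tot

        QL = np.stack([A[i] * e[i] for i in range(L)])
        QR = np.stack([B[i] / e[i] for i in range(L)])
        Q = 1.0 + QL.sum(axis=0)

    if not (np.all(np.isfinite(Q)) and np.all(np.isfinite(QR))):
        raise NumericalError(
            "partition function overflowed; rescale energies or restrict the "
            "temperature range"
        )
    if scalar:
        return PartitionResult(Q[0], QL[:, 0], QR[:, 0], T_arr[0], seq.self_complementary)
    return PartitionResult(Q, QL, QR, T_arr, seq.self_complementary)


def pair_probabilities(result: PartitionResult) -> np.ndarray:
    """Conditional probability P_i,bp of each pair given >= 1 pair formed."""
    denom = np.asarray(result.Q) - 1.0
    if np.any(denom <= 0.0):
        raise NumericalError("Q is numerically 1: conditional pair probabilities undefined")
    return result.QL * result.QR / denom


def prob_any_pair(Q, C_T: float, self_complementary: bool) -> np.ndarray | float:
    """Probability that a strand is in a duplex with >= 1 pair, at C_T mol/L.

    Bimolecular mass balance with ensemble association constant K = Q - 1:
    two distinct strands each at C_T/2 for non-self-complementary duplexes,
    one species at C_T for self-complementary ones.  Evaluated in the
    rationalized form (conjugate multiplied through), which is free of
    catastrophic cancellation and reproduces the series limits
    P -> x/2 (non-self-complementary) and P -> 2x (self-complementary)
    as x = (Q-1)*C_T -> 0.
    """
    Q_arr = np.asarray(Q, dtype=float)
    if np.any(Q_arr < 1.0):
        raise ValidationError("Q must be >= 1")
    if C_T <= 0:
        raise ValidationError("strand concentration must be positive")
    x = (Q_arr - 1.0) * C_T
    with np.errstate(over="ignore"):
        if self_complementary:
            out = 4.0 * x / (1.0 + 4.0 * x + np.sqrt(1.0 + 8.0 * x))
        else:
            out = x / (1.0 + x + np.sqrt(1.0 + 2.0 * x))
    if np.any(out < -1e-12) or np.any(out > 1.0 + 1e-12):
        raise NumericalError("probability of pairing left [0, 1]")
    return out if np.ndim(Q) else float(out)


def _two_state_log_k(seq: DuplexSequence, params: NNParamSet, T_arr: np.ndarray) -> np.ndarray:
    """log of the whole-duplex (fully paired only) equilibrium constant."""
    from .thermo_model import decompose_duplex

    counts = decompose_duplex(seq)
    dg = params.delta_g_arrays(T_arr)
    total = sum(n * dg[f] for f, n in counts.items())
    if seq.self_complementary:
        total = total + (-T_arr * DS_SYM / 1000.0)
    return -total / (R_GAS * T_arr)


def fraction_paired(
    seq: DuplexSequence,
    params: NNParamSet,
    T,
    C_T: float,
    two_state: bool = False,
):
    """Model fraction of maximal base pairs X at kelvin temperature(s) T.

    X = P_bp * (sum_i P_i,bp) / L.  With ``two_state=True`` only the fully
    paired structure is allowed (every P_i,bp = 1), giving the classical
    van't Hoff sigmoid.
    """
    T_arr = _as_temp_array(T)
    scalar = np.ndim(T) == 0
    if two_state:
        K = np.exp(_two_state_log_k(seq, params, T_arr))
        X = prob_any_pair(1.0 + K, C_T, seq.self_complementary)
        X = np.asarray(X)
    else:
        res = compute_partition(seq, params, T_arr)
        qm1 = res.Q - 1.0
        sum_qlqr = (res.QL * res.QR).sum(axis=0)
        p_bp = prob_any_pair(res.Q, C_T, seq.self_complementary)
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_p = np.where(qm1 > 0.0, sum_qlqr / np.where(qm1 > 0, qm1, 1.0), 0.0)
        X = np.asarray(p_bp) * mean_p / seq.length
    return float(X[0]) if scalar else X


def predict_curve(
    seq: DuplexSequence,
    params: NNParamSet,
    C_T: float,
    temperatures_c: Sequence[float],
    two_state: bool = False,
) -> ModelCurve:
    """Predicted fraction-paired curve on a Celsius grid."""
    grid = np.asarray(temperatures_c, dtype=float)
    if grid.size == 0:
        raise ValidationError("temperature grid is empty")
    X = fraction_paired(seq, params, grid + CELSIUS_OFFSET, C_T, two_state=two_state)
    return ModelCurve(grid, np.atleast_1d(X), C_T, seq.duplex_id)


def predict_tm(
    seq: DuplexSequence,
    params: NNParamSet,
    C_T: float,
    low_c: float = 0.0,
    high_c: float = 110.0,
    two_state: bool = False,
    xtol: float = 1e-3,
) -> float:
    """Melting temperature (deg C) where X = 0.5, by scan + bisection.

    Robust to flat tails: an initial 1 deg C scan locates the first bracketing
    interval by increasing temperature, then bisection refines to ``xtol``.
    """
    grid = np.arange(low_c, high_c + 1e-9, 1.0)
    X = fraction_paired(seq, params, grid + CELSIUS_OFFSET, C_T, two_state=two_state)
    f = np.asarray(X) - 0.5
    hits = np.nonzero(f == 0.0)[0]
    if hits.size:
        return float(grid[hits[0]])
    sign_change = np.nonzero(f[:-1] * f[1:] < 0.0)[0]
    if sign_change.size == 0:
        raise NoTransitionError(
            f"model curve never crosses 0.5 in [{low_c}, {high_c}] deg C "
            f"(duplex {seq.duplex_id!r}, C_T={C_T:g})"
        )
    if sign_change.size > 1:
        warnings.warn(
            f"multiple 0.5 crossings for duplex {seq.duplex_id!r}; using the first",
            stacklevel=2,
        )
    a, b = grid[sign_change[0]], grid[sign_change[0] + 1]

    def g(t_c: float) -> float:
        return fraction_paired(seq, params, t_c + CELSIUS_OFFSET, C_T, two_state=two_state) - 0.5

    return float(bisect(g, a, b, xtol=xtol))


def fraction_paired_profile(
    seq: DuplexSequence, params: NNParamSet, T_arr: np.ndarray
) -> Dict[str, np.ndarray]:
    """Concentration-independent pieces of Eq-4-style curves on a kelvin grid.

    Returns ``Q`` and ``mean_p`` (= sum_i P_i,bp / L) so that curves at many
    strand concentrations of the same duplex reuse one recursion pass:
    X(C_T) = prob_any_pair(Q, C_T, sc) * mean_p.
    """
    res = compute_partition(seq, params, T_arr)
    qm1 = res.Q - 1.0
    sum_qlqr = (res.QL * res.QR).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_p = np.where(qm1 > 0.0, sum_qlqr / np.where(qm1 > 0, qm1, 1.0), 0.0) / seq.length
    return {"Q": res.Q, "mean_p": mean_p}
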