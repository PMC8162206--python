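"""Autoregressive modelling of multi-sinusoid series.

An AR(p) model expresses each sample as a linear combination of the previous
``p`` samples plus a stochastic term,

    x[t] = a0 + a1*x[t-1] + ... + ap*x[t-p] + eps[t],

with ``a_j`` multiplying lag ``j`` throughout this module. Stacking the
recurrence over a record of length ``L`` gives an overdetermined linear
system whose least-squares solution — the pseudo-inverse solution
``a = (A^T A)^-1 A^T b`` for a full-column-rank design — identifies the
coefficients. A noiseless sum of K sinusoids (none at DC or Nyquist)
satisfies an exact recurrence of order 2K whose characteristic roots are the
conjugate pairs ``exp(+-i*2*pi*f/fs)`` on the unit circle, so the fitted
model extrapolates such a series indefinitely; this is what makes the
extended-spectrum super-resolution pipeline work.

The same linear neuron can instead be trained iteratively by full-batch
gradient descent on the mean squared error (the classical adaptive-linear-
neuron / back-propagation route); :func:`fit_ar_bp` provides it for
comparison with the closed-form solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter, lfiltic

from .types import (
    ArspecError,
    ConvergenceError,
    DivergenceWarning,
    RankDeficientError,
    SignalRecord,
)

__all__ = [
    "ARModel",
    "DesignSystem",
    "build_design_system",
    "fit_ar_lms",
    "fit_ar_bp",
    "extrapolate",
    "characteristic_roots",
    "implied_frequencies",
    "select_order",
]

#: Root-modulus threshold above which extrapolation warns about divergence.
ROOT_MODULUS_GUARD = 1.0 + 1e-6


@dataclass
class ARModel:
    """Fitted AR(p) model: order, optional intercept, lag coefficients.

    ``coefficients[j-1]`` multiplies lag ``j`` (i.e. ``x[t-j]``);
    ``intercept`` is 0 when the fit excluded it. ``training_rss`` is the sum
    of squared one-step residuals over the training rows.
    """

    order: int
    coefficients: np.ndarray
    intercept: float = 0.0
    training_rss: float = 0.0

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coefficients, dtype=float)
        if self.order < 1 or coeffs.shape != (self.order,):
            raise ArspecError(
                f"coefficient sequence must have length order={self.order}"
            )
        if not np.all(np.isfinite(coeffs)) or not np.isfinite(self.intercept):
            raise ArspecError("model parameters must be finite")
        if self.training_rss < 0:
            raise ArspecError("training_rss must be >= 0")
        self.coefficients = coeffs


@dataclass
class DesignSystem:
    """Lagged design matrix and targets for the stacked AR recurrence.

    Row ``r`` (0-based) holds ``[x[p+r-1], x[p+r-2], ..., x[r]]`` — column
    ``j`` is lag ``j+1`` — and the target is ``b[r] = x[p+r]``. With an
    intercept a constant-1 column is appended at index ``p``. Requiring
    ``L >= 2p`` keeps the system square-or-overdetermined.
    """

    matrix: np.ndarray
    target: np.ndarray
    order: int
    include_intercept: bool = False


def build_design_system(
    signal: SignalRecord, p: int, include_intercept: bool = False
) -> DesignSystem:
    """Stack the AR(p) recurrence over a record into matrix form."""
    if p < 1:
        raise ArspecError("order p must be >= 1")
    L = signal.L
    if L < 2 * p:
        raise ArspecError(
            f"signal of length {L} too short for order {p}: need L >= 2p = {2 * p}"
        )
    x = signal.samples
    m = L - p
    # column j (0-based) holds lag j+1: A[r, j] = x[p + r - 1 - j]
    idx = (p - 1 - np.arange(p))[None, :] + np.arange(m)[:, None]
    A = x[idx]
    if include_intercept:
        A = np.hstack([A, np.ones((m, 1))])
    b = x[p:]
    return DesignSystem(A, b, order=p, include_intercept=include_intercept)


def _split_solution(w: np.ndarray, p: int, include_intercept: bool) -> tuple[np.ndarray, float]:
    if include_intercept:
        return w[:p], float(w[p])
    return w, 0.0


def fit_ar_lms(
    signal: SignalRecord, p: int, include_intercept: bool = False
) -> ARModel:
    """Closed-form least-squares (pseudo-inverse) AR fit.

    Returns the minimiser of ``||A a - b||^2`` over the lagged design
    system; for a full-column-rank design this equals the pseudo-inverse
    solution ``(A^T A)^-1 A^T b``. Solved by an orthogonal factorisation
    (LAPACK least squares) rather than forming the normal equations, which
    is mathematically equivalent but better conditioned. Rank-deficient
    designs are rejected: the pseudo-inverse derivation assumes full column
    rank, and a silent minimum-norm answer would hide a degenerate input.
    """
    sys = build_design_system(signal, p, include_intercept)
    A, b = sys.matrix, sys.target
    ncols = A.shape[1]
    rank = np.linalg.matrix_rank(A)
    if rank < ncols:
        raise RankDeficientError(
            f"design matrix has rank {rank} < {ncols} columns; the signal does "
            f"not determine a unique AR({p}) model (e.g. all-zero or degenerate input)"
        )
    w, _res, _rank, _sv = np.linalg.lstsq(A, b, rcond=None)
    rss = float(np.sum((A @ w - b) ** 2))
    coeffs, intercept = _split_solution(w, p, include_intercept)
    return ARModel(order=p, coefficients=coeffs, intercept=intercept, training_rss=rss)


def fit_ar_bp(
    signal: SignalRecord,
    p: int,
    learning_rate: float = 0.01,
    epochs: int = 200,
    init: str = "zeros",
    seed: int = 0,
    include_intercept: bool = False,
) -> ARModel:
    """Iterative adaptive-linear-neuron fit by full-batch gradient descent.

    Minimises the mean squared error over the design rows with the update
    ``w <- w + lr * (2/m) * A^T (b - A w)``, ``m = L - p``. Deterministic
    given ``init`` and ``seed`` (no sample shuffling). Provided as the
    back-propagation alternative to :func:`fit_ar_lms`; it approaches the
    same minimiser but, at a finite epoch budget, its residual coefficient
    error makes long-horizon extrapolation markedly worse.

    Raises
    ------
    ConvergenceError
        If the loss ever exceeds 1e6 times the initial loss (divergence).
    """
    if learning_rate <= 0:
        raise ArspecError("learning_rate must be positive")
    if epochs < 0:
        raise ArspecError("epochs must be >= 0")
    sys = build_design_system(signal, p, include_intercept)
    A, b = sys.matrix, sys.target
    m, ncols = A.shape
    if init == "zeros":
        w = np.zeros(ncols)
    elif init == "random":
        w = np.random.default_rng(seed).normal(0.0, 0.1, size=ncols)
    else:
        raise ArspecError(f"unknown init {init!r}: expected 'zeros' or 'random'")
    resid = b - A @ w
    initial_loss = float(np.mean(resid**2))
    guard = 1e6 * max(initial_loss, np.finfo(float).tiny)
    for epoch in range(epochs):
        w = w + learning_rate * (2.0 / m) * (A.T @ resid)
        resid = b - A @ w
        loss = float(np.mean(resid**2))
        if not np.isfinite(loss) or loss > guard:
            raise ConvergenceError(
                f"gradient-descent training diverged at epoch {epoch + 1}: "
                f"loss {loss:.3g} exceeds 1e6 x initial loss {initial_loss:.3g}; "
                f"reduce learning_rate"
            )
    rss = float(np.sum(resid**2))
    coeffs, intercept = _split_solution(w, p, include_intercept)
    return ARModel(order=p, coefficients=coeffs, intercept=intercept, training_rss=rss)


def characteristic_roots(model: ARModel) -> np.ndarray:
    """Roots of ``z^p - a1 z^(p-1) - ... - ap`` (with multiplicity).

    Each sinusoid in an exactly-fitted noiseless mixture contributes a
    conjugate pair ``exp(+-i 2 pi f / fs)`` of modulus 1; moduli above 1
    signal an extrapolation that grows without bound.
    """
    poly = np.concatenate(([1.0], -model.coefficients))
    roots = np.roots(poly)
    if roots.size != model.order:  # leading coefficient is 1, cannot happen
        raise ArspecError("unexpected root count")
    return roots


def implied_frequencies(model: ARModel, fs: float) -> np.ndarray:
    """Frequencies ``fs * |arg z| / (2 pi)`` implied by the roots, sorted."""
    roots = characteristic_roots(model)
    freqs = fs * np.abs(np.angle(roots)) / (2.0 * np.pi)
    return np.sort(freqs)


def extrapolate(model: ARModel, signal: SignalRecord, n_extra: int) -> SignalRecord:
    """Predict ``n_extra`` samples beyond the record by the AR recurrence.

    The stochastic term is set to zero, so prediction ``L + k`` is
    ``a0 + sum_j a_j x[L + k - j]`` applied recursively; the recursion is
    run as an all-pole filter driven by the constant intercept. The first
    ``L`` output samples equal the input bit-for-bit, and the prediction
    depends only on the last ``p`` samples of the seed record. A warning is
    emitted (but extrapolation proceeds — growing transients can be a
    legitimate model) when any characteristic-root modulus exceeds
    ``1 + 1e-6``.
    """
    if n_extra < 0:
        raise ArspecError("n_extra must be >= 0")
    p = model.order
    if signal.L < p:
        raise ArspecError(f"need at least p={p} seed samples, got {signal.L}")
    moduli = np.abs(characteristic_roots(model))
    if np.any(moduli > ROOT_MODULUS_GUARD):
        warnings.warn(
            f"AR model has characteristic root modulus {moduli.max():.6g} > 1; "
            f"extrapolation may diverge",
            DivergenceWarning,
            stacklevel=2,
        )
    x = signal.samples
    if n_extra == 0:
        return SignalRecord(x.copy(), signal.fs)
    a_poly = np.concatenate(([1.0], -model.coefficients))
    # past outputs, most recent first, initialise the filter state
    zi = lfiltic([1.0], a_poly, x[-1 : -p - 1 : -1])
    drive = np.full(int(n_extra), model.intercept)
    pred, _zf = lfilter([1.0], a_poly, drive, zi=zi)
    return SignalRecord(np.concatenate([x, pred]), signal.fs)


def select_order(
    signal: SignalRecord,
    max_order: int,
    include_intercept: bool = False,
    rel_tol: float = 1e-10,
) -> int:
    """Smallest order whose training RSS falls below ``rel_tol * sum(x^2)``.

    A sweep utility for when the tone count is unknown: a noiseless mixture
    of K sinusoids is matched exactly at order 2K. Returns ``max_order``
    when no order meets the tolerance (e.g. noisy data).
    """
    energy = float(np.sum(signal.samples**2))
    best = None
    for p in range(1, max_order + 1):
        if signal.L < 2 * p:
            break
        try:
            model = fit_ar_lms(signal, p, include_intercept)
        except RankDeficientError:
            continue
        if model.training_rss <= rel_tol * energy:
            return p
        best = p
    if best is None:
        raise ArspecError("no admissible order: signal too short or degenerate")
    return best
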