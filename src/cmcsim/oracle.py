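"""Analytic ground truth for the stochastic threshold rule.

Every neuron update in the circuit has the same form: a signed sum of
uniformly scaled random drives is compared against a depolarisation
threshold,

    sum_i a_i * X_i  -  sum_j b_j * Y_j  >  DT,      X, Y ~ iid U[0, 1)

with one independent draw per active synaptic term.  This module computes the
exact firing probability of that comparison: closed forms for up to two
active terms, numeric convolution of the box densities otherwise.  It also
derives the stationary one-sample DCN firing probability for homogeneous
parameters by exhaustive enumeration over the Boolean states of the upstream
neurons, with the Golgi feedback resolved by fixed-point iteration.  Nothing
here touches the simulator's sampling code, so it can serve as an independent
oracle for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThresholdProblem",
    "firing_probability",
    "single_draw_probability",
    "mc_firing_probability",
    "dcn_marginal",
]


def single_draw_probability(net_weight: float, threshold: float) -> float:
    """Exact P(X * w > DT) for one shared draw X ~ U[0, 1).

    This is the firing rule of the comparator equations, where a single
    uniform variate multiplies the signed sum ``w`` of the active weights;
    a non-positive net weight can never beat a non-negative threshold.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if net_weight <= 0:
        return 0.0
    return float(np.clip(1.0 - threshold / net_weight, 0.0, 1.0))

_CONV_POINTS = 20_000  # grid size for the >2-term numeric convolution


@dataclass(frozen=True)
class ThresholdProblem:
    """Active synaptic terms feeding one threshold comparison.

    ``excitatory`` and ``inhibitory`` hold the synaptic strengths (SyS) of the
    currently *active* terms only; inactive presynaptic neurons contribute
    nothing and appear nowhere.
    """

    excitatory: tuple[float, ...] = field(default_factory=tuple)
    inhibitory: tuple[float, ...] = field(default_factory=tuple)
    threshold: float = 0.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "excitatory", tuple(float(w) for w in self.excitatory))
        object.__setattr__(self, "inhibitory", tuple(float(w) for w in self.inhibitory))
        if any(w < 0 for w in self.excitatory + self.inhibitory):
            raise ValueError("synaptic strengths must be >= 0")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


def _p_sum_two_gt(a: float, b: float, d: float) -> float:
    """P(aX + bY > d) for X, Y ~ U[0,1), a, b > 0."""
    if a < b:
        a, b = b, a
    if d <= 0:
        return 1.0
    if d >= a + b:
        return 0.0
    if d <= b:
        return 1.0 - d * d / (2.0 * a * b)
    if d <= a:
        return 1.0 - (2.0 * d - b) / (2.0 * a)
    return (a + b - d) ** 2 / (2.0 * a * b)


def _p_diff_gt(a: float, b: float, d: float) -> float:
    """P(aX - bY > d) for X, Y ~ U[0,1), a, b > 0."""
    if d >= a:
        return 0.0
    if d <= -b:
        return 1.0
    if d >= 0:
        c = a - d
        if c >= b:
            return (2.0 * c - b) / (2.0 * a)
        return c * c / (2.0 * a * b)
    # d < 0: complement of the mirrored problem bY - aX > -d (ties measure 0)
    return 1.0 - _p_diff_gt(b, a, -d)


def _p_convolution_gt(exc: Sequence[float], inh: Sequence[float], d: float) -> float:
    """Numeric convolution of the box densities for >= 3 active terms."""
    lo = -sum(inh)
    hi = sum(exc)
    span = hi - lo
    h = span / _CONV_POINTS
    dens: np.ndarray | None = None
    for w in list(exc) + [-v for v in inh]:
        width = abs(w)
        m = max(int(round(width / h)), 2)
        box = np.full(m + 1, 1.0 / width)
        box[0] *= 0.5
        box[-1] *= 0.5  # trapezoidal end-weights
        dens = box if dens is None else np.convolve(dens, box) * h
    assert dens is not None
    x = lo + h * np.arange(dens.size)
    mask = x > d
    if not mask.any():
        return 0.0
    # trapezoid over the tail, splitting the cell containing d
    p = float(np.trapezoid(dens[mask], x[mask]))
    i = int(np.argmax(mask))
    if i > 0:
        x0, x1 = x[i - 1], x[i]
        f_d = dens[i - 1] + (dens[i] - dens[i - 1]) * (d - x0) / (x1 - x0)
        p += 0.5 * (f_d + dens[i]) * (x1 - d)
    return min(max(p, 0.0), 1.0)


def firing_probability(problem: ThresholdProblem) -> float:
    """Exact P(sum a_i X_i - sum b_j Y_j > DT)."""
    exc = [w for w in problem.excitatory if w > 0]
    inh = [w for w in problem.inhibitory if w > 0]
    d = problem.threshold
    k = len(exc) + len(inh)
    if k == 0:
        return 1.0 if 0.0 > d else 0.0
    if k == 1:
        if exc:
            a = exc[0]
            return float(np.clip(1.0 - d / a, 0.0, 1.0))
        b = inh[0]
        # -bY > d with d >= 0 is impossible
        return 0.0 if d >= 0 else float(np.clip(-d / b, 0.0, 1.0))
    if k == 2:
        if len(exc) == 2:
            return _p_sum_two_gt(exc[0], exc[1], d)
        if len(exc) == 1:
            return _p_diff_gt(exc[0], inh[0], d)
        return 0.0 if d >= 0 else 1.0 - _p_sum_two_gt(inh[0], inh[1], -d)
    return _p_convolution_gt(exc, inh, d)


def mc_firing_probability(
    problem: ThresholdProblem, n_draws: int, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Brute-force Monte-Carlo estimate and its binomial standard error."""
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total = np.zeros(n_draws)
    for w in problem.excitatory:
        total += w * rng.random(n_draws)
    for w in problem.inhibitory:
        total -= w * rng.random(n_draws)
    p = float(np.mean(total > problem.threshold))
    se = float(np.sqrt(max(p * (1.0 - p), 1.0 / n_draws) / n_draws))
    return p, se


# --------------------------------------------------------------------------
# stationary DCN marginal for homogeneous parameters


def _scalar(value) -> float:
    arr = np.asarray(value, dtype=float).ravel()
    if arr.size > 1 and not np.all(arr == arr[0]):
        raise ValueError("dcn_marginal requires homogeneous parameters")
    return float(arr[0])


def _extract(params) -> tuple[dict[str, float], dict[str, float]]:
    if params is None:
        from .cmc_core import CIRCUIT_SYNAPSES, CIRCUIT_NEURONS

        return {s: 1.5 for s in CIRCUIT_SYNAPSES}, {m: 0.15 for m in CIRCUIT_NEURONS}
    sys_map = {k: _scalar(v) for k, v in params.sys.items()}
    dt_map = {k: _scalar(v) for k, v in params.dt.items()}
    return sys_map, dt_map


def dcn_marginal(
    mf_prob: float,
    cf_prob: float,
    params=None,
    *,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> float:
    """Stationary per-sample DCN firing probability.

    ``params`` may be a homogeneous :class:`~cmcsim.cmc_core.SynapticParams`
    (or any object with scalar-valued ``sys``/``dt`` mappings); ``None`` uses
    the defaults SyS = 1.5, DT = 0.15.  The Golgi cell feeds back onto the
    granule cell with one sample of delay; its stationary firing probability
    is found by fixed-point iteration, after which the DCN marginal follows by
    total probability over the Boolean states of every upstream neuron.
    """
    if not (0.0 <= mf_prob <= 1.0 and 0.0 <= cf_prob <= 1.0):
        raise ValueError("afferent probabilities must lie in [0, 1]")
    sys_map, dt_map = _extract(params)

    def fp(exc: list[float], inh: list[float], dt: float) -> float:
        return firing_probability(ThresholdProblem(tuple(exc), tuple(inh), dt))

    def p_granule(m: int, g_prev: int) -> float:
        exc = [sys_map["mf_granule"]] if m else []
        inh = [sys_map["golgi_granule"]] if g_prev else []
        return fp(exc, inh, dt_map["granule"])

    p_golgi_given_gr1 = fp([sys_map["granule_golgi"]], [], dt_map["golgi"])

    # stationary Golgi marginal: golgi_{t-1} independent of mossy_t
    p_g = 0.0
    for _ in range(max_iter):
        p_gr = sum(
            (mf_prob if m else 1 - mf_prob)
            * (p_g if g else 1 - p_g)
            * p_granule(m, g)
            for m in (0, 1)
            for g in (0, 1)
        )
        p_g_new = p_gr * p_golgi_given_gr1
        if abs(p_g_new - p_g) < tol:
            p_g = p_g_new
            break
        p_g = p_g_new
    else:
        raise RuntimeError("Golgi fixed-point iteration failed to converge")

    p_ii_given_gr1 = fp([sys_map["granule_ii"]], [], dt_map["ii"])

    total = 0.0
    for m in (0, 1):
        w_m = mf_prob if m else 1 - mf_prob
        if w_m == 0:
            continue
        p_gr_m = sum((p_g if g else 1 - p_g) * p_granule(m, g) for g in (0, 1))
        for c in (0, 1):
            w_c = cf_prob if c else 1 - cf_prob
            if w_c == 0:
                continue
            for gr in (0, 1):
                w_gr = p_gr_m if gr else 1 - p_gr_m
                if w_gr == 0:
                    continue
                p_ii = p_ii_given_gr1 if gr else 0.0
                for ii in (0, 1):
                    w_ii = p_ii if ii else 1 - p_ii
                    if w_ii == 0:
                        continue
                    exc_pk = ([sys_map["granule_purkinje"]] if gr else []) + (
                        [sys_map["cf_purkinje"]] if c else []
                    )
                    inh_pk = [sys_map["ii_purkinje"]] if ii else []
                    p_pk = fp(exc_pk, inh_pk, dt_map["purkinje"])
                    for pk in (0, 1):
                        w_pk = p_pk if pk else 1 - p_pk
                        if w_pk == 0:
                            continue
                        exc_dcn = ([sys_map["mf_dcn"]] if m else []) + (
                            [sys_map["cf_dcn"]] if c else []
                        )
                        inh_dcn = [sys_map["purkinje_dcn"]] if pk else []
                        p_dcn = fp(exc_dcn, inh_dcn, dt_map["dcn"])
                        total += w_m * w_c * w_gr * w_ii * w_pk * p_dcn
    return total
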