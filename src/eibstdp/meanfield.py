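"""Slow-learning mean-field theory of the STDP dynamics.

In the limit of a slow learning rate the stochastic weight updates are
replaced by their expectation over the spike statistics at fixed weights.
For the delayed linear Poisson neuron (rate = e + sum wE.xE - sum wI.xI,
evaluated a delay d after the inputs) with instantaneous input
correlations, the drift of an inhibitory weight is

    dw_i/dt = lam * r * [ (1-w_i)^mu * (nu*tau - K(d) * (C w)_i)
                          - alpha * w_i^mu * nu*tau ],

with presynaptic rate r, postsynaptic rate nu = e + r*sum(wE) - r*sum(wI),
STDP filter integral tau and the filter evaluated at the causal delay
K(d); excitatory weights obey the same expression with the sign of the
correlation term flipped (an excitatory spike *raises* the probability of
a subsequent postsynaptic spike - positive feedback - while an inhibitory
spike lowers it - negative feedback).  C is the input correlation matrix;
under isotropy the uniform vector is an eigenvector of C with eigenvalue
C1 and a homogeneous fixed point exists.  Its stability decomposes into a
uniform block (1x1 or 2x2) plus one eigenvalue per non-uniform eigenvector
of each correlation matrix.

For a single inhibitory synapse onto a nonlinear (integrate-and-fire)
cell, the linear-response closure replaces the correlation term with the
measured dip Gamma(s) in the conditional postsynaptic rate after an
inhibitory spike:

    dw/dt = lam * r * [ (1-w)^mu * (nu*tau - w*GammaBar)
                        - alpha * w^mu * nu*tau ],

where GammaBar = int_0^inf K(s) Gamma(s) ds is the overlap of the STDP
filter with the fitted dip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from .plasticity import STDPRule

__all__ = [
    "GammaKernel",
    "PopulationModel",
    "MeanFieldModel",
    "FixedPointResult",
    "RateFloorError",
    "kernel_overlap",
    "drift_single",
    "fixed_point_single",
    "drift_population",
    "homogeneous_fixed_point",
    "fixed_point_inh_mu1_closed_form",
    "stability_spectrum",
    "integrate_population",
]


class RateFloorError(ValueError):
    """The net input to the postsynaptic cell is non-positive.

    A neuron with net inhibitory input will not fire, so there is no
    learning and the linearised theory does not apply in this region.
    """


@dataclass(frozen=True)
class GammaKernel:
    """Linear-response dip of the postsynaptic conditional rate.

    ``Gamma(s) = amplitude * exp(-(s - latency)/decay_tau)`` for
    ``s >= latency`` and 0 before; ``s`` is the time since an inhibitory
    presynaptic spike.  ``amplitude`` is the rate dip per unit synaptic
    weight (spikes/s), so the dip for a synapse of weight w is
    ``w * Gamma(s)``.
    """

    amplitude: float         # spikes/s per unit weight
    decay_tau: float         # ms
    latency: float = 0.0     # ms
    fit_residual: float | None = None  # RMS residual when fitted from an STA

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.latency < 0:
            raise ValueError("latency must be non-negative")

    def __call__(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        out = self.amplitude * np.exp(-(s - self.latency) / self.decay_tau)
        return np.where(s >= self.latency, out, 0.0)


def kernel_overlap(rule: STDPRule, gamma: GammaKernel) -> float:
    """Overlap integral ``int_0^inf K(s) Gamma(s) ds`` (dimensionless).

    ``K`` is the STDP temporal filter of ``rule`` (lags in ms); the
    integral is taken in seconds so the result multiplies rates directly.
    A closed form is used when both kernels are exponentials, adaptive
    quadrature (relative tolerance 1e-8) otherwise.
    """
    if gamma.amplitude == 0.0:
        return 0.0
    if rule.kernel == "exp":
        tau_s = rule.tau / 1000.0
        tg_s = gamma.decay_tau / 1000.0
        return (
            gamma.amplitude
            * np.exp(-gamma.latency / rule.tau)
            * tau_s * tg_s / (tau_s + tg_s)
        )
    upper = gamma.latency + 40.0 * max(rule.tau, gamma.decay_tau)
    val, err = integrate.quad(
        lambda s: float(rule.temporal_filter(s)) * float(gamma(s)),
        gamma.latency, upper, epsrel=1e-8, limit=200,
    )
    if not np.isfinite(val):
        raise ValueError("divergent kernel overlap")
    return val / 1000.0  # ms -> s


# ---------------------------------------------------------------------------
# single synapse, linear-response closure
# ---------------------------------------------------------------------------

def drift_single(
    w: float,
    rule: STDPRule,
    pre_rate: float,
    post_rate: float,
    gamma: GammaKernel,
) -> float:
    """Mean drift dw/dt (per second) of a single inhibitory weight."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("w must lie in [0, 1]")
    tau_s = rule.tau / 1000.0
    gbar = kernel_overlap(rule, gamma)
    nu_tau = post_rate * tau_s
    return rule.learning_rate * pre_rate * (
        (1.0 - w) ** rule.mu * (nu_tau - w * gbar)
        - rule.alpha * w ** rule.mu * nu_tau
    )


@dataclass
class FixedPointResult:
    """A solved fixed point plus diagnostics.

    ``weights`` maps population name ('inh'/'exc'/'single') to the
    homogeneous weight.  ``boundary`` flags a fixed point pinned at 0 or 1
    (no interior sign change).  ``eigenvalues``/``labels`` are filled in by
    :func:`stability_spectrum`.
    """

    weights: dict
    residual: float
    stable: bool | None = None
    boundary: bool = False
    post_rate: float | None = None
    eigenvalues: np.ndarray | None = None
    labels: np.ndarray | None = None

    @property
    def classification(self) -> str:
        if self.stable is None:
            return "unknown"
        return "stable" if self.stable else "unstable"


def fixed_point_single(
    rule: STDPRule,
    pre_rate: float,
    post_rate: float,
    gamma: GammaKernel,
    grid: int = 1000,
    tol: float = 1e-10,
) -> FixedPointResult:
    """Fixed point of the single-synapse drift by bracketed bisection.

    Scans a uniform grid on [0, 1] for a sign change and bisects; when the
    drift does not change sign the appropriate boundary (0 or 1) is
    returned with ``boundary=True``.  Stability is the sign of the drift
    derivative at the root.
    """
    f = lambda w: drift_single(w, rule, pre_rate, post_rate, gamma)
    ws = np.linspace(0.0, 1.0, grid + 1)
    vals = np.array([f(w) for w in ws])
    idx = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
    if idx.size == 0:
        w_star = 1.0 if vals[-1] > 0 else 0.0
        return FixedPointResult(
            weights={"single": w_star}, residual=abs(float(vals[-1 if w_star else 0])),
            stable=True, boundary=True, post_rate=post_rate,
        )
    i = idx[0]
    w_star = optimize.bisect(f, ws[i], ws[i + 1], xtol=tol)
    h = 1e-6
    slope = (f(min(w_star + h, 1.0)) - f(max(w_star - h, 0.0))) / (
        min(w_star + h, 1.0) - max(w_star - h, 0.0)
    )
    return FixedPointResult(
        weights={"single": float(w_star)}, residual=abs(f(w_star)),
        stable=slope < 0, boundary=False, post_rate=post_rate,
    )


# ---------------------------------------------------------------------------
# populations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationModel:
    """One presynaptic population entering the mean-field equations."""

    n: int
    rule: STDPRule
    corr: np.ndarray | None = None   # (n, n) correlation matrix; identity if None

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("population size must be positive")
        c = self.corr
        if c is not None:
            c = np.asarray(c, dtype=float)
            if c.shape != (self.n, self.n):
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(c, c.T):
                raise ValueError("correlation matrix must be symmetric")
            if np.linalg.eigvalsh(c).min() < -1e-10 * self.n:
                raise ValueError("correlation matrix must be positive semidefinite")
            object.__setattr__(self, "corr", c)

    @property
    def corr_matrix(self) -> np.ndarray:
        return np.eye(self.n) if self.corr is None else self.corr

    @property
    def c1(self) -> float:
        """Eigenvalue of the correlation matrix in the uniform direction."""
        rows = self.corr_matrix.sum(axis=1)
        if not np.allclose(rows, rows[0], atol=1e-8 * self.n):
            raise ValueError(
                "population is not isotropic: the uniform vector is not an "
                "eigenvector of the correlation matrix"
            )
        return float(rows[0])


@dataclass(frozen=True)
class MeanFieldModel:
    """Inputs of the population drift equations.

    ``drive`` is the constant excitatory drive e (spikes/s); ``rate`` the
    common presynaptic rate.  ``bin_width_ms`` optionally applies the
    finite-bin corrections of the discrete simulations (trace integrals
    become geometric sums, the delay snaps to the bin grid, and the
    count-correlation term picks up the Bernoulli 1-q factor); leave
    ``None`` for the continuous-time theory.
    """

    rate: float
    drive: float = 0.0
    inh: PopulationModel | None = None
    exc: PopulationModel | None = None
    delay_ms: float = 0.1
    bin_width_ms: float | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("presynaptic rate must be positive")
        if self.drive < 0:
            raise ValueError("drive must be non-negative")
        if self.inh is None and self.exc is None:
            raise ValueError("at least one population required")

    # effective filter integral (s) and filter-at-delay for one rule
    def _tau_eff(self, rule: STDPRule) -> float:
        if self.bin_width_ms is None:
            return rule.tau / 1000.0
        dt = self.bin_width_ms
        return dt / 1000.0 / np.expm1(dt / rule.tau)

    def _k_delay(self, rule: STDPRule) -> float:
        if self.bin_width_ms is None:
            return float(np.exp(-self.delay_ms / rule.tau))
        dt = self.bin_width_ms
        d = max(1, int(round(self.delay_ms / dt)))
        q = self.rate * dt / 1000.0
        return float(np.exp(-d * dt / rule.tau)) * (1.0 - q)

    def post_rate(self, w_inh=None, w_exc=None) -> float:
        nu = self.drive
        if w_exc is not None:
            nu += self.rate * float(np.sum(w_exc))
        if w_inh is not None:
            nu += -self.rate * float(np.sum(w_inh))
        return nu


def _pop_drift(
    w: np.ndarray, pop: PopulationModel, nu: float, model: MeanFieldModel, sign: float
) -> np.ndarray:
    rule = pop.rule
    tau = model._tau_eff(rule)
    kd = model._k_delay(rule)
    cw = pop.corr_matrix @ w
    return rule.learning_rate * model.rate * (
        (1.0 - w) ** rule.mu * (nu * tau + sign * kd * cw)
        - rule.alpha * w ** rule.mu * nu * tau
    )


def drift_population(
    model: MeanFieldModel,
    w_inh: np.ndarray | None = None,
    w_exc: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Mean drift (per second) of every synaptic weight.

    Returns ``(dw_inh, dw_exc)`` matching the populations present in the
    model.  Raises :class:`RateFloorError` when the net input at the
    evaluation point is non-positive (the linear closure is invalid
    there).
    """
    if (model.inh is None) != (w_inh is None) or (model.exc is None) != (w_exc is None):
        raise ValueError("weights must match the populations of the model")
    nu = model.post_rate(w_inh, w_exc)
    if nu <= 0:
        raise RateFloorError(
            f"net input {nu:g} spikes/s <= 0: rate floor engaged"
        )
    d_inh = d_exc = None
    if model.inh is not None:
        w = np.asarray(w_inh, dtype=float)
        d_inh = _pop_drift(w, model.inh, nu, model, sign=-1.0)
    if model.exc is not None:
        w = np.asarray(w_exc, dtype=float)
        d_exc = _pop_drift(w, model.exc, nu, model, sign=+1.0)
    return d_inh, d_exc


def _homog_drift_inh(w: float, nu: float, pop: PopulationModel, model) -> float:
    rule = pop.rule
    tau = model._tau_eff(rule)
    kd = model._k_delay(rule)
    return (1.0 - w) ** rule.mu * (nu * tau - kd * pop.c1 * w) - rule.alpha * (
        w ** rule.mu
    ) * nu * tau


def _homog_drift_exc(w: float, nu: float, pop: PopulationModel, model) -> float:
    rule = pop.rule
    tau = model._tau_eff(rule)
    kd = model._k_delay(rule)
    return (1.0 - w) ** rule.mu * (nu * tau + kd * pop.c1 * w) - rule.alpha * (
        w ** rule.mu
    ) * nu * tau


def _bracketed_root(f, lo: float, hi: float, grid: int = 1000) -> float | None:
    ws = np.linspace(lo, hi, grid + 1)
    prev = f(ws[0])
    for k in range(1, len(ws)):
        cur = f(ws[k])
        if np.isfinite(prev) and np.isfinite(cur) and prev * cur < 0:
            return float(optimize.brentq(f, ws[k - 1], ws[k], xtol=1e-12))
        prev = cur
    return None


def homogeneous_fixed_point(model: MeanFieldModel) -> FixedPointResult:
    """Homogeneous fixed point w-bar (scalar or E/I pair).

    The root is found by a bracket scan plus Brent's method inside the
    admissible region where the net postsynaptic input is positive; the
    second, net-inhibitory root of the scalar fixed-point equation is
    unphysical (a neuron with net inhibitory input will not fire) and is
    rejected by construction.
    """
    r = model.rate
    eps = 1e-12

    if model.exc is None:
        pop = model.inh
        if model.drive <= 0:
            raise ValueError("inhibitory-only model requires positive drive e")
        # admissible w: nu(w) = e - N r w > 0
        w_hi = min(1.0 - eps, (model.drive / (r * pop.n)) * (1 - 1e-9))
        f = lambda w: _homog_drift_inh(w, model.post_rate(np.full(pop.n, w)), pop, model)
        w_star = _bracketed_root(f, eps, w_hi)
        if w_star is None:
            # drift one-signed on the admissible interval -> boundary point
            w_b = w_hi if f(w_hi * 0.999999) > 0 else 0.0
            return FixedPointResult(
                weights={"inh": w_b}, residual=abs(f(max(w_b, eps))),
                boundary=True, post_rate=model.post_rate(np.full(pop.n, w_b)),
            )
        nu = model.post_rate(np.full(pop.n, w_star))
        return FixedPointResult(
            weights={"inh": float(w_star)}, residual=abs(f(w_star)),
            boundary=False, post_rate=nu,
        )

    if model.inh is None:
        pop = model.exc
        f = lambda w: _homog_drift_exc(w, model.post_rate(None, np.full(pop.n, w)), pop, model)
        w_star = _bracketed_root(f, eps, 1.0 - eps)
        if w_star is None:
            w_b = 1.0 if f(0.5) > 0 else 0.0
            return FixedPointResult(
                weights={"exc": w_b}, residual=abs(f(min(max(w_b, eps), 1 - eps))),
                boundary=True, post_rate=model.post_rate(None, np.full(pop.n, w_b)),
            )
        return FixedPointResult(
            weights={"exc": float(w_star)}, residual=abs(f(w_star)),
            boundary=False, post_rate=model.post_rate(None, np.full(pop.n, w_star)),
        )

    # joint model: nest the inhibitory scalar solve inside the excitatory one
    inh, exc = model.inh, model.exc

    def wi_of_we(we: float) -> float | None:
        def g(wi: float) -> float:
            nu = model.post_rate(np.full(inh.n, wi), np.full(exc.n, we))
            if nu <= 0:
                return -1.0  # net-inhibitory: drift ill-defined, treat as depressed
            return _homog_drift_inh(wi, nu, inh, model)

        wi = _bracketed_root(g, 1e-12, 1.0 - 1e-12)
        return wi

    def fe(we: float) -> float:
        wi = wi_of_we(we)
        if wi is None:
            return np.nan
        nu = model.post_rate(np.full(inh.n, wi), np.full(exc.n, we))
        if nu <= 0:
            return np.nan
        return _homog_drift_exc(we, nu, exc, model)

    we_star = _bracketed_root(fe, 1e-9, 1.0 - 1e-9, grid=400)
    boundary = False
    if we_star is None:
        # excitation saturates (positive feedback) or collapses
        vals = [fe(x) for x in np.linspace(0.05, 0.95, 19)]
        finite = [v for v in vals if np.isfinite(v)]
        we_star = 1.0 if (finite and finite[-1] > 0) else 0.0
        we_eval = min(max(we_star, 1e-9), 1 - 1e-9)
        boundary = True
    else:
        we_eval = we_star
    wi_star = wi_of_we(we_eval)
    if wi_star is None:
        raise RateFloorError(
            "no admissible inhibitory root: net input non-positive everywhere"
        )
    nu = model.post_rate(np.full(inh.n, wi_star), np.full(exc.n, we_eval))
    res = abs(_homog_drift_inh(wi_star, nu, inh, model))
    if not boundary:
        res = max(res, abs(_homog_drift_exc(we_star, nu, exc, model)))
    return FixedPointResult(
        weights={"exc": float(we_star), "inh": float(wi_star)},
        residual=float(res), boundary=boundary, post_rate=nu,
    )


def fixed_point_inh_mu1_closed_form(model: MeanFieldModel) -> float:
    """Closed-form homogeneous inhibitory fixed point for mu = 1.

    At mu = 1 the scalar fixed-point equation
    ``(1-w)(nu(w) tau - K C1 w) = alpha w nu(w) tau`` with
    ``nu(w) = e - N r w`` is a quadratic in w:

        [(1+alpha) tau N r + K C1] w^2
        - [tau (N r + e (1+alpha)) + K C1] w + tau e = 0.

    The physical root is the one inside (0, 1) with positive net input.
    Serves as an algebraic cross-check of the numerical solver.
    """
    if model.exc is not None or model.inh is None:
        raise ValueError("closed form applies to the inhibitory-only model")
    pop = model.inh
    rule = pop.rule
    if rule.mu != 1.0:
        raise ValueError("closed form requires mu = 1")
    tau = model._tau_eff(rule)
    kd = model._k_delay(rule)
    e, nr, c1, al = model.drive, model.rate * pop.n, pop.c1, rule.alpha
    a = (1.0 + al) * tau * nr + kd * c1
    b = -(tau * (nr + e * (1.0 + al)) + kd * c1)
    c = tau * e
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real root")
    for w in sorted(((-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a))):
        if 0.0 < w < 1.0 and e - nr * w > 0:
            return float(w)
    raise ValueError("no admissible root in (0, 1)")


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def _het_eigs(pop: PopulationModel) -> np.ndarray:
    """Non-uniform eigenvalues of the correlation matrix (n-1 values)."""
    eigs = np.linalg.eigvalsh(pop.corr_matrix)
    c1 = pop.c1
    k = int(np.argmin(np.abs(eigs - c1)))
    return np.delete(eigs, k)


def _het_rate(w: float, nu: float, pop: PopulationModel, model, sign: float, c_k: float) -> float:
    """Eigenvalue of the stability matrix along a non-uniform direction."""
    rule = pop.rule
    tau = model._tau_eff(rule)
    kd = model._k_delay(rule)
    mu, al = rule.mu, rule.alpha
    term = sign * (1.0 - w) ** mu * kd * c_k
    if mu > 0:
        term -= mu * (1.0 - w) ** (mu - 1.0) * (nu * tau + sign * kd * pop.c1 * w)
        term -= al * mu * w ** (mu - 1.0) * nu * tau
    return rule.learning_rate * model.rate * term


def _nu_coupling(w: float, pop: PopulationModel, model, dnu: float) -> float:
    """d(drift)/d(nu) * dnu for the uniform block."""
    rule = pop.rule
    tau = model._tau_eff(rule)
    return rule.learning_rate * model.rate * tau * dnu * (
        (1.0 - w) ** rule.mu - rule.alpha * w ** rule.mu
    )


def stability_spectrum(
    fp: FixedPointResult, model: MeanFieldModel
) -> FixedPointResult:
    """Labelled eigenvalues of the stability matrix at a homogeneous point.

    The matrix is assembled analytically from the spectra of the input
    correlation matrices: fluctuations along non-uniform eigenvectors of C
    decouple (labels ``het-I`` / ``het-E``), and the uniform directions
    couple through the shared postsynaptic rate (label ``uniform``).
    Eigenvalues are relaxation rates in 1/s; the result is stored on (and
    returned as) the fixed-point object.
    """
    if fp.residual > 1e-6:
        raise ValueError("fixed point residual too large for a stability analysis")
    nu = fp.post_rate
    labels: list[str] = []
    eigs: list[float] = []
    r = model.rate

    wi = fp.weights.get("inh")
    we = fp.weights.get("exc")
    for pop, w, sign, tag in (
        (model.inh, wi, -1.0, "het-I"),
        (model.exc, we, +1.0, "het-E"),
    ):
        if pop is None:
            continue
        for c_k in _het_eigs(pop):
            labels.append(tag)
            eigs.append(_het_rate(w, nu, pop, model, sign, c_k))

    # uniform block
    blocks = []
    if model.exc is not None:
        blocks.append(("exc", model.exc, we, +1.0))
    if model.inh is not None:
        blocks.append(("inh", model.inh, wi, -1.0))
    m = len(blocks)
    J = np.zeros((m, m))
    for a, (_, pa, wa, sa) in enumerate(blocks):
        for b, (_, pb, _, sb) in enumerate(blocks):
            dnu = r * pb.n * (1.0 if sb > 0 else -1.0)
            J[a, b] = _nu_coupling(wa, pa, model, dnu)
            if a == b:
                J[a, b] += _het_rate(wa, nu, pa, model, sa, pa.c1)
    for ev in np.linalg.eigvals(J):
        labels.append("uniform")
        eigs.append(float(np.real(ev)))

    fp.labels = np.asarray(labels)
    fp.eigenvalues = np.asarray(eigs)
    fp.stable = bool(np.max(fp.eigenvalues) < 0)
    return fp


def integrate_population(
    model: MeanFieldModel,
    w_inh0: np.ndarray | None,
    w_exc0: np.ndarray | None,
    t_end: float,
    n_eval: int = 50,
):
    """Integrate the population drift ODE (scipy ``solve_ivp``, LSODA).

    Weights are clipped to [0, 1] inside the right-hand side, mirroring
    the hard bounds of the stochastic updates.  Returns the solver result;
    ``y`` stacks inhibitory then excitatory weights.
    """
    ni = 0 if model.inh is None else model.inh.n
    parts = []
    if w_inh0 is not None:
        parts.append(np.asarray(w_inh0, float))
    if w_exc0 is not None:
        parts.append(np.asarray(w_exc0, float))
    y0 = np.concatenate(parts)

    def rhs(_t, y):
        y = np.clip(y, 0.0, 1.0)
        wi = y[:ni] if model.inh is not None else None
        we = y[ni:] if model.exc is not None else None
        di, de = drift_population(model, wi, we)
        out = []
        if di is not None:
            out.append(di)
        if de is not None:
            out.append(de)
        return np.concatenate(out)

    return integrate.solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_eval), rtol=1e-8, atol=1e-10,
    )
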