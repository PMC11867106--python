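"""Log-likelihoods of lineage-through-time data under birth-death models.

All routines return natural-log densities, with combinatorial factors
computed through ``lgamma`` so that trees with tens of thousands of tips
are handled without under- or overflow.  Data that are impossible under a
model (an age outside its admissible epoch, a zero birth rate with
observed speciations, ...) yield ``-inf`` rather than an exception, so
that numerical optimizers may probe boundary regions freely.

Conditioning matters and is always an explicit caller choice: the joint
density of ages and tip count given the stem age, the density given stem
age and n, and the density given root age and n are different objects,
and the two-epoch likelihood conditions on the per-epoch speciation
counts (I, J).  Each returned value carries a conditioning tag.

The labelled-history factor
---------------------------
The joint Yule density of ages and tip count carries the factor (n-1)!
from the rank-ordering of speciation events.  We include the same factor
in the generalized (time-varying-rate) likelihoods, so that the Yule
model is an exact special case of the GBDP likelihood and the
constant-rate model an exact special case of the two-epoch one; the
congruence identities are unaffected because the factor is shared by the
GBDP and its congruent generalized Yule process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .models import LTTData, ModelError, RateModel, TwoEpochData, TwoEpochModel
from . import transitions as tr

__all__ = [
    "LogLikelihood",
    "yule_joint_loglik",
    "yule_prob_n_given_stem",
    "yule_log_prob_n_given_stem",
    "yule_prob_n_given_root",
    "yule_log_prob_n_given_root",
    "yule_prob_n_given_root_convolution",
    "yule_loglik_given_stem",
    "yule_loglik_given_root",
    "truncated_exp_logpdf",
    "gbdp_loglik",
    "gyp_loglik",
    "bdp_loglik_conditioned",
    "bdp_joint_loglik",
    "label_switch_check",
    "two_epoch_loglik",
    "massext_p1star",
    "massext_log_p1star",
    "massext_p1star_series",
    "massext_loglik",
]

_NEG_INF = float("-inf")


@dataclass(frozen=True)
class LogLikelihood:
    """A log-density value together with its conditioning scheme."""

    value: float
    conditioning: str

    def __float__(self) -> float:
        return float(self.value)

    def __repr__(self) -> str:  # compact, value first
        return f"LogLikelihood({self.value:.10g}, {self.conditioning!r})"


def _lfact(k: int) -> float:
    return math.lgamma(k + 1)


# ---------------------------------------------------------------------------
# Yule process
# ---------------------------------------------------------------------------

def yule_joint_loglik(data: LTTData, lam: float) -> LogLikelihood:
    """Joint log-density of node ages and tip count given the stem age.

    For a pure-birth process started with one lineage at the stem age t0,
    ``f(t, n | t0) = (n-1)! lam^{n-1} exp(-lam * (t0 + sum_i t_i))``.
    """
    if data.stem_age is None:
        raise ModelError("joint Yule likelihood requires a stem age")
    if lam < 0:
        raise ValueError("rate must be non-negative")
    t0 = data.stem_age
    n = data.n
    if data.ages.size and data.ages[0] >= t0:
        return LogLikelihood(_NEG_INF, "joint_with_n")
    if n == 1:
        return LogLikelihood(-lam * t0, "joint_with_n")
    if lam == 0.0:
        return LogLikelihood(_NEG_INF, "joint_with_n")
    value = _lfact(n - 1) + (n - 1) * math.log(lam) - lam * (t0 + data.ages.sum())
    return LogLikelihood(value, "joint_with_n")


def yule_log_prob_n_given_stem(n: int, t0: float, lam: float) -> float:
    """log Pr(n tips | stem age t0) under the Yule process.

    Marginalizing the ages out of the joint density recovers the
    single-lineage descendant-count law, so this is the same geometric
    distribution as :func:`bdphylo.transitions.yule_log_pn`.
    """
    return tr.yule_log_pn(n, t0, lam)


def yule_prob_n_given_stem(n: int, t0: float, lam: float) -> float:
    return math.exp(yule_log_prob_n_given_stem(n, t0, lam))


def yule_log_prob_n_given_root(n: int, t1: float, lam: float) -> float:
    """log Pr(n tips | root age t1), Yule: (n-1) e^{-2 lam t1} (1-e^{-lam t1})^{n-2}.

    The root's two daughter lineages leave i and n-i descendants; summing
    the convolution over i gives this closed form.
    """
    if n < 2:
        raise ValueError("a root requires at least two descendant lineages")
    if t1 < 0 or lam < 0:
        raise ValueError("invalid age or rate")
    x = lam * t1
    if x == 0.0:
        return 0.0 if n == 2 else _NEG_INF
    out = math.log(n - 1) - 2.0 * x
    if n > 2:
        out += (n - 2) * math.log(-math.expm1(-x))
    return out


def yule_prob_n_given_root(n: int, t1: float, lam: float) -> float:
    return math.exp(yule_log_prob_n_given_root(n, t1, lam))


def yule_prob_n_given_root_convolution(n: int, t1: float, lam: float) -> float:
    """Brute-force convolution sum_{i=1}^{n-1} p_i(t1) p_{n-i}(t1)."""
    if n < 2:
        raise ValueError("a root requires at least two descendant lineages")
    return float(
        sum(tr.yule_pn(i, t1, lam) * tr.yule_pn(n - i, t1, lam) for i in range(1, n))
    )


def truncated_exp_logpdf(x, t0: float, lam: float):
    """log-pdf of the per-age kernel: Exp(lam) truncated to [0, t0].

    The stem-and-n conditioned Yule density is the joint order-statistics
    density of n-1 i.i.d. draws from this kernel.
    """
    x = np.asarray(x, dtype=float)
    if lam <= 0 or t0 <= 0:
        raise ValueError("lam and t0 must be positive")
    logZ = math.log(-math.expm1(-lam * t0))
    out = np.where(
        (x >= 0) & (x <= t0), math.log(lam) - lam * x - logZ, _NEG_INF
    )
    return out if out.ndim else float(out)


def _yule_stem_route_conditioned(data: LTTData, lam: float) -> float:
    """Stem-conditioned density as joint minus log Pr(n | t0)."""
    joint = yule_joint_loglik(data, lam).value
    if joint == _NEG_INF:
        return _NEG_INF
    return joint - yule_log_prob_n_given_stem(data.n, data.stem_age, lam)


def _yule_stem_route_orderstats(data: LTTData, lam: float) -> float:
    """Stem-conditioned density as (n-1)! times i.i.d. kernel densities."""
    t0 = data.stem_age
    if data.ages.size and data.ages[0] >= t0:
        return _NEG_INF
    if data.n == 1:
        return 0.0
    if lam == 0.0:
        return _NEG_INF
    return float(_lfact(data.n - 1) + truncated_exp_logpdf(data.ages, t0, lam).sum())


def yule_loglik_given_stem(data: LTTData, lam: float, route: str = "auto") -> LogLikelihood:
    """Log-density of the node ages given the stem age and tip count.

    Two algebraically equal routes exist: dividing the joint density by
    Pr(n | t0) (``route="conditioned"``), or the order-statistics product
    of truncated-exponential kernels (``route="orderstats"``).  The
    default computes both and checks their agreement.
    """
    if data.stem_age is None:
        raise ModelError("stem-conditioned likelihood requires a stem age")
    if route == "conditioned":
        value = _yule_stem_route_conditioned(data, lam)
    elif route == "orderstats":
        value = _yule_stem_route_orderstats(data, lam)
    elif route == "auto":
        a = _yule_stem_route_conditioned(data, lam)
        b = _yule_stem_route_orderstats(data, lam)
        if math.isfinite(a) and abs(a - b) > 1e-9 * max(1.0, abs(a)):
            raise AssertionError(f"stem-conditioning routes disagree: {a} vs {b}")
        value = b
    else:
        raise ValueError(f"unknown route {route!r}")
    return LogLikelihood(value, "given_stem_n")


def yule_loglik_given_root(data: LTTData, lam: float) -> LogLikelihood:
    """Log-density of the node ages given the root age and tip count.

    ``(n-2)! lam^{n-1} e^{-lam sum_i t_i} / [e^{-2 lam t1} (1-e^{-lam t1})^{n-2}]``
    where t1 is the oldest node age.  The root age is registered with a
    rate-density factor, matching the stem-conditioned form with the stem
    replaced by the root; for n = 2 the empty product over younger nodes
    contributes nothing beyond the root-age factor.
    """
    if data.n < 2:
        raise ModelError("root-conditioned likelihood needs at least 2 tips")
    if lam <= 0:
        return LogLikelihood(_NEG_INF, "given_root_n")
    n = data.n
    t1 = data.root_age
    # (n-1)! lam^{n-1} e^{-lam sum} / Pr(n|t1); the (n-1) in Pr(n|t1)
    # reduces the factorial to (n-2)!
    value = (
        _lfact(n - 1)
        + (n - 1) * math.log(lam)
        - lam * data.ages.sum()
        - yule_log_prob_n_given_root(n, t1, lam)
    )
    return LogLikelihood(value, "given_root_n")


# ---------------------------------------------------------------------------
# generalized birth-death and generalized Yule processes
# ---------------------------------------------------------------------------

def gbdp_loglik(
    data: LTTData, model: RateModel, conditioning: str = "survival"
) -> LogLikelihood:
    """GBDP log-likelihood of LTT data with a stem age.

    The joint density of ages and tip count is
    ``log f = log (n-1)! + log p1(t0) + sum_i [log lam(t_i) + log p1(t_i)]``
    with p1 the sampled single-descendant probability of the model
    (``conditioning="none"``).  The default ``conditioning="survival"``
    divides by the probability 1 - p0(t0) that the stem lineage leaves
    any sampled descendant at all — the event without which there is no
    tree to observe.  Only the survival-conditioned likelihood is shared
    exactly with the congruent pulled-rate pure-birth process (for which
    the conditioning is vacuous); the joint forms differ across congruent
    models by precisely this stem survival factor.
    """
    if data.stem_age is None:
        raise ModelError("GBDP likelihood requires a stem age")
    if conditioning not in ("survival", "none"):
        raise ValueError(f"unknown conditioning {conditioning!r}")
    t0 = data.stem_age
    tag = "joint_with_n" if conditioning == "none" else "joint_with_n_given_survival"
    if data.ages.size and data.ages[0] >= t0:
        return LogLikelihood(_NEG_INF, tag)
    value = _lfact(data.n - 1) + tr.gbdp_log_p1(t0, model)
    if conditioning == "survival":
        p0 = tr.gbdp_p0(t0, model)
        if p0 >= 1.0:
            return LogLikelihood(_NEG_INF, tag)
        value -= math.log1p(-p0)
    for t in data.ages:
        lam_t = float(model.birth(float(t)))
        if lam_t <= 0.0:
            return LogLikelihood(_NEG_INF, tag)
        value += math.log(lam_t) + tr.gbdp_log_p1(float(t), model)
    return LogLikelihood(float(value), tag)


class _QuadCumulative:
    """Cumulative integral of a rate callable with per-age caching."""

    def __init__(self, fn):
        self.fn = fn
        self._cache: dict[float, float] = {0.0: 0.0}

    def __call__(self, t: float) -> float:
        t = float(t)
        if t not in self._cache:
            val, _ = quad(self.fn, 0.0, t, epsabs=1e-12, epsrel=1e-10, limit=200)
            self._cache[t] = val
        return self._cache[t]


def gyp_loglik(data: LTTData, pulled_rate) -> LogLikelihood:
    """Generalized-Yule log-likelihood for a time-varying birth rate.

    ``log f = log (n-1)! - Lambda(t0) + sum_i [log lam_p(t_i) - Lambda(t_i)]``
    where Lambda is the cumulative of the rate.  ``pulled_rate`` may be a
    :class:`bdphylo.congruence.PulledRate`, a plain callable of age
    (cumulative computed by quadrature), or a scalar constant rate.
    """
    if data.stem_age is None:
        raise ModelError("GYP likelihood requires a stem age")
    if np.isscalar(pulled_rate):
        lam = float(pulled_rate)
        rate = lambda t: lam  # noqa: E731
        cumulative = lambda t: lam * t  # noqa: E731
    elif hasattr(pulled_rate, "rate") and hasattr(pulled_rate, "cumulative"):
        rate, cumulative = pulled_rate.rate, pulled_rate.cumulative
    elif callable(pulled_rate):
        rate, cumulative = pulled_rate, _QuadCumulative(pulled_rate)
    else:
        raise TypeError("pulled_rate must be scalar, callable or PulledRate")

    t0 = data.stem_age
    if data.ages.size and data.ages[0] >= t0:
        return LogLikelihood(_NEG_INF, "joint_with_n")
    value = _lfact(data.n - 1) - float(cumulative(t0))
    for t in data.ages:
        r = float(rate(float(t)))
        if r <= 0.0:
            return LogLikelihood(_NEG_INF, "joint_with_n")
        value += math.log(r) - float(cumulative(float(t)))
    return LogLikelihood(float(value), "joint_with_n")


# ---------------------------------------------------------------------------
# constant-rate BDP likelihoods and the label-switching symmetry
# ---------------------------------------------------------------------------

def bdp_joint_loglik(data: LTTData, lam: float, mu: float) -> LogLikelihood:
    """Joint (unconditioned) constant-rate BDP log-likelihood, rho = 1."""
    return gbdp_loglik(data, _const_model(lam, mu))


def _const_model(lam: float, mu: float) -> RateModel:
    from .models import make_constant_model

    return make_constant_model(lam, mu, 1.0)


def bdp_loglik_conditioned(
    data: LTTData, lam: float, mu: float, conditioning: str = "stem"
) -> LogLikelihood:
    """Constant-rate BDP (rho = 1) log-density conditioned on tip count.

    ``conditioning="stem"`` divides the stem-started joint density by
    Pr(n | t0); ``conditioning="root"`` uses the root-started process
    (two lineages at the root age t1, hence a p1(t1)^2 factor and no
    rate density at t1) divided by Pr(n | t1) = sum_k p_k(t1) p_{n-k}(t1).
    Both conditioned densities are invariant under swapping lam and mu
    (label-switching non-identifiability): p1(t) is itself swap-symmetric
    and the lam^{k} factors cancel against the descendant-count law in
    the denominator.  The unconditioned joint density is not invariant.
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    n = data.n
    if conditioning == "stem":
        if data.stem_age is None:
            raise ModelError("stem conditioning requires a stem age")
        t0 = data.stem_age
        if data.ages.size and data.ages[0] >= t0:
            return LogLikelihood(_NEG_INF, "given_stem_n")
        if lam == 0.0 and n > 1:
            return LogLikelihood(_NEG_INF, "given_stem_n")
        core = sum(
            math.log(i * lam) + tr.bdp_log_p1(float(t), lam, mu)
            for i, t in enumerate(data.ages, start=1)
        )
        pn = tr.bdp_pn(n, t0, lam, mu)
        if pn <= 0.0:
            return LogLikelihood(_NEG_INF, "given_stem_n")
        value = core + tr.bdp_log_p1(t0, lam, mu) - math.log(pn)
        return LogLikelihood(float(value), "given_stem_n")
    if conditioning == "root":
        if n < 2:
            raise ModelError("root conditioning needs at least 2 tips")
        if lam == 0.0 and n > 2:
            return LogLikelihood(_NEG_INF, "given_root_n")
        t1 = data.root_age
        core = 2.0 * tr.bdp_log_p1(t1, lam, mu)
        for i, t in enumerate(data.ages[1:], start=2):
            core += math.log(i * lam) + tr.bdp_log_p1(float(t), lam, mu)
        pr = sum(
            tr.bdp_pn(k, t1, lam, mu) * tr.bdp_pn(n - k, t1, lam, mu)
            for k in range(1, n)
        )
        if pr <= 0.0:
            return LogLikelihood(_NEG_INF, "given_root_n")
        return LogLikelihood(float(core - math.log(pr)), "given_root_n")
    raise ValueError(f"unknown conditioning {conditioning!r}")


def label_switch_check(
    data: LTTData, lam: float, mu: float, conditioning: str = "stem"
) -> float:
    """|conditioned loglik(lam, mu) - conditioned loglik(mu, lam)|.

    The conditioned constant-rate BDP likelihood is invariant when the
    birth and death rates are swapped, so this deviation should vanish to
    numerical precision; it quantifies the label-switching
    non-identifiability of the constant-rate model.
    """
    a = bdp_loglik_conditioned(data, lam, mu, conditioning).value
    b = bdp_loglik_conditioned(data, mu, lam, conditioning).value
    if a == b:  # covers the symmetric point and -inf == -inf
        return 0.0
    return abs(a - b)


# ---------------------------------------------------------------------------
# two-epoch Yule process
# ---------------------------------------------------------------------------

def _check_epoch_bounds(data: TwoEpochData, model: TwoEpochModel) -> bool:
    ok_old = (data.old_ages > model.T).all() and (
        data.old_ages.size == 0 or data.old_ages[0] < model.t0
    )
    ok_young = data.young_ages.size == 0 or data.young_ages[0] <= model.T
    return bool(ok_old and ok_young)


def two_epoch_loglik(
    data: TwoEpochData, model: TwoEpochModel, form: str = "kernel"
) -> LogLikelihood:
    """Two-rate Yule log-likelihood, conditioned on the epoch counts I, J.

    ``form="kernel"`` drops the data-only combinatorial constant:
    ``I log lam0 + J log lam1 + T I (lam0 - lam1) - lam0 sum t_i^0 -
    lam1 sum t_j^1``; ``form="full"`` adds ``log (I+J)!``.  Maximum
    likelihood estimates are invariant to the choice.
    """
    if model.survival_p != 1.0:
        raise ModelError("use massext_loglik for models with survival_p < 1")
    if form not in ("kernel", "full"):
        raise ValueError(f"unknown form {form!r}")
    lam0, lam1, T = model.lambda0, model.lambda1, model.T
    if lam0 <= 0 or lam1 <= 0 or not _check_epoch_bounds(data, model):
        return LogLikelihood(_NEG_INF, "epoch_counts")
    I, J = data.I, data.J
    value = (
        I * math.log(lam0)
        + J * math.log(lam1)
        + T * I * (lam0 - lam1)
        - lam0 * data.old_ages.sum()
        - lam1 * data.young_ages.sum()
    )
    if form == "full":
        value += _lfact(I + J)
    return LogLikelihood(float(value), "epoch_counts")


# ---------------------------------------------------------------------------
# mass-extinction epoch model
# ---------------------------------------------------------------------------

def massext_log_p1star(t: float, model: TwoEpochModel) -> float:
    """log p1*(t): single-sampled-descendant probability across the event.

    For a lineage arising in the old epoch at age t > T, average over the
    number m of its descendants just before the mass extinction (geometric
    with the old-epoch Yule law at elapsed time t - T), exactly one of
    which survives the event (probability m p (1-p)^{m-1}) and leaves one
    descendant at present (e^{-lam1 T}).  The series sums to

        p1*(t) = p x e^{-lam1 T} / (p + x (1 - p))^2,   x = e^{-lam0 (t-T)},

    which equals the closed form written with e^{lam0 t} and e^{lam0 T}
    factors after multiplying numerator and denominator by e^{-2 lam0 t};
    at p = 1 and lam0 = lam1 = lam it reduces to e^{-lam t}.
    """
    if t <= model.T:
        raise ModelError("p1* applies to lineages arising before the event (t > T)")
    p = model.survival_p
    logx = -model.lambda0 * (t - model.T)
    x = math.exp(logx)
    return math.log(p) + logx - model.lambda1 * model.T - 2.0 * math.log(p + x * (1.0 - p))


def massext_p1star(t: float, model: TwoEpochModel) -> float:
    return math.exp(massext_log_p1star(t, model))


def massext_p1star_series(t: float, model: TwoEpochModel, tail: float = 1e-14) -> float:
    """p1*(t) by explicit summation over the pre-event descendant count m.

    Terms are x(1-x)^{m-1} * m p (1-p)^{m-1} * e^{-lam1 T} with
    x = e^{-lam0 (t-T)}; the sum is truncated once the geometric tail
    bound drops below ``tail``.  Independent oracle for the closed form.
    """
    if t <= model.T:
        raise ModelError("p1* applies to lineages arising before the event (t > T)")
    p = model.survival_p
    x = math.exp(-model.lambda0 * (t - model.T))
    fac = math.exp(-model.lambda1 * model.T) * p * x
    q = (1.0 - x) * (1.0 - p)
    total = 0.0
    m = 1
    term = fac
    while True:
        total += term
        # tail bound: fac * sum_{k>m} k q^{k-1} <= fac * q^m (m(1-q)+1)/(1-q)^2
        bound = fac * q**m * (m * (1.0 - q) + 1.0) / (1.0 - q) ** 2
        if bound < tail or m > 100_000:
            return total
        m += 1
        term = fac * m * q ** (m - 1)


def massext_loglik(
    data: TwoEpochData, model: TwoEpochModel, form: str = "full"
) -> LogLikelihood:
    """Two-epoch Yule log-likelihood with a mass extinction at age T.

    ``sum_i [log(i lam0) + log p1*(t_i^0)] + sum_j [log((I+j) lam1) -
    lam1 t_j^1]``, conditioned on the epoch counts.  As the survival
    probability p -> 1 this reduces continuously to the plain two-epoch
    likelihood (``form="full"``); ``form="kernel"`` drops the log (I+J)!
    constant to match the kernel form of :func:`two_epoch_loglik`.
    """
    if form not in ("kernel", "full"):
        raise ValueError(f"unknown form {form!r}")
    lam0, lam1 = model.lambda0, model.lambda1
    if lam0 <= 0 or lam1 <= 0 or not _check_epoch_bounds(data, model):
        return LogLikelihood(_NEG_INF, "epoch_counts")
    I, J = data.I, data.J
    value = I * math.log(lam0) + J * math.log(lam1) - lam1 * data.young_ages.sum()
    for t in data.old_ages:
        value += massext_log_p1star(float(t), model)
    if form == "full":
        value += _lfact(I + J)
    return LogLikelihood(float(value), "epoch_counts")
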