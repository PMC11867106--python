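"""Diversification models and the data containers shared by the whole package.

Time convention
---------------
Every public API in this package measures time as *age*: the present is 0
and age increases into the past.  A birth-death process that "starts" with
one lineage at the stem age ``t0`` runs forward in real time, but all rate
functions, transition probabilities and likelihoods are written as
functions of age.  All node ages are therefore non-negative and the stem
age is at least the root age.

Rates are per-lineage event intensities (events per lineage per unit
time).  Time is unitless; in worked examples we use millions of years.

Rate functions may be constant, piecewise-constant in age (a
multiple-change-point model) or tabulated (arbitrary callables of age).
For piecewise-constant models every cumulative integral used downstream is
computed exactly as a sum of closed-form per-piece terms; tabulated models
fall back to dense Simpson grids with spline interpolation.

A change point at age ``c`` is interpreted so that the *younger* piece
applies at age exactly ``c`` and the older piece applies for ages just
above ``c``.  Tied node ages (a measure-zero event under every model here)
are kept in input order by stable sorting, and an age exactly equal to an
epoch boundary ``T`` is assigned to the young epoch, consistently with the
change-point convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.integrate import cumulative_simpson

__all__ = [
    "ModelError",
    "RateModel",
    "LTTData",
    "TwoEpochData",
    "TwoEpochModel",
    "make_constant_model",
    "make_piecewise_model",
    "make_tabulated_model",
    "partition_ltt",
    "model_to_dict",
    "model_from_dict",
]


class ModelError(ValueError):
    """Invalid model specification or data container."""


# ---------------------------------------------------------------------------
# numerically careful primitives
# ---------------------------------------------------------------------------

def _log_exprel(r: float, w: float) -> float:
    """log of (e^{r w} - 1) / r, the integral of e^{r s} over [0, w].

    Stable for r of either sign and for |r w| << 1, where the value
    approaches w.
    """
    if w == 0.0:
        return -math.inf
    x = r * w
    if abs(x) < 1e-12:
        return math.log(w) + x / 2.0
    if x > 0:
        # e^{x}(1 - e^{-x}) / r
        return x + math.log1p(-math.exp(-x)) - math.log(r)
    # (1 - e^{x}) / (-r)
    return math.log(-math.expm1(x)) - math.log(-r)


def _sorted_desc(values: Iterable[float]) -> np.ndarray:
    a = np.asarray(list(values), dtype=float)
    if a.ndim != 1:
        raise ModelError("ages must be a 1-d sequence")
    order = np.argsort(-a, kind="stable")
    return a[order]


# ---------------------------------------------------------------------------
# rate models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateModel:
    """A diversification model: birth rate, death rate and sampling fraction.

    Parameters
    ----------
    kind:
        ``"constant"``, ``"piecewise_constant"`` or ``"tabulated"``.
    rho:
        Probability that an extant lineage is sampled at present, in (0, 1].
    lambdas, mus:
        Per-piece birth and death rates, youngest piece first
        (``lambdas[0]`` applies on ``[0, change_points[0])``); a single
        entry for constant models.
    change_points:
        Strictly increasing ages separating the pieces; empty for constant
        models.
    birth_fn, death_fn:
        Callables of age for tabulated models.
    """

    kind: str
    rho: float
    lambdas: tuple = ()
    mus: tuple = ()
    change_points: tuple = ()
    birth_fn: Callable[[float], float] | None = None
    death_fn: Callable[[float], float] | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    # -- validation ---------------------------------------------------------
    def __post_init__(self) -> None:
        if self.kind not in ("constant", "piecewise_constant", "tabulated"):
            raise ModelError(f"unknown model kind {self.kind!r}")
        if not (0.0 < self.rho <= 1.0):
            raise ModelError(f"sampling fraction rho={self.rho} outside (0, 1]")
        if self.kind == "tabulated":
            if self.birth_fn is None or self.death_fn is None:
                raise ModelError("tabulated model needs birth_fn and death_fn")
            return
        lams, mus, cps = self.lambdas, self.mus, self.change_points
        if len(lams) != len(mus) or len(lams) != len(cps) + 1:
            raise ModelError(
                "need len(lambdas) == len(mus) == len(change_points) + 1; "
                f"got {len(lams)}, {len(mus)}, {len(cps)}"
            )
        if any((not math.isfinite(x)) or x < 0 for x in lams + mus):
            raise ModelError("rates must be finite and non-negative")
        if any(not math.isfinite(c) or c <= 0 for c in cps):
            raise ModelError("change points must be finite and positive")
        if any(b <= a for a, b in zip(cps, cps[1:])):
            raise ModelError("change points must be strictly increasing")

    # -- point evaluation ---------------------------------------------------
    def _piece_index(self, t: float) -> int:
        # side="left": an age exactly at a change point takes the young piece
        return int(np.searchsorted(np.asarray(self.change_points), t, side="left"))

    def birth(self, t):
        """Birth rate lambda(t) at age t (scalar or array)."""
        if self.kind == "tabulated":
            return self.birth_fn(t)
        if np.ndim(t) == 0:
            return self.lambdas[self._piece_index(float(t))]
        idx = np.searchsorted(np.asarray(self.change_points), np.asarray(t), side="left")
        return np.asarray(self.lambdas)[idx]

    def death(self, t):
        """Death rate mu(t) at age t (scalar or array)."""
        if self.kind == "tabulated":
            return self.death_fn(t)
        if np.ndim(t) == 0:
            return self.mus[self._piece_index(float(t))]
        idx = np.searchsorted(np.asarray(self.change_points), np.asarray(t), side="left")
        return np.asarray(self.mus)[idx]

    @property
    def is_constant(self) -> bool:
        return self.kind == "constant" or (
            self.kind == "piecewise_constant" and len(self.lambdas) == 1
        )

    @property
    def constant_rates(self) -> tuple[float, float]:
        if not self.is_constant:
            raise ModelError("model is not constant-rate")
        return float(self.lambdas[0]), float(self.mus[0])

    # -- exact piecewise integration ---------------------------------------
    def _pieces(self, t: float):
        """Yield (width, lam, mu) for the pieces covering [0, t]."""
        if t < 0:
            raise ModelError("ages must be non-negative")
        lo = 0.0
        for c, lam, mu in zip(self.change_points, self.lambdas, self.mus):
            if t <= c:
                yield (t - lo, lam, mu)
                return
            yield (c - lo, lam, mu)
            lo = c
        yield (t - lo, self.lambdas[-1], self.mus[-1])

    def cum_birth(self, t: float) -> float:
        """Integral of lambda(s) over [0, t]."""
        if self.kind == "tabulated":
            return self._tab(t)["L"]
        return float(sum(w * lam for w, lam, _ in self._pieces(float(t))))

    def cum_death(self, t: float) -> float:
        """Integral of mu(s) over [0, t]."""
        if self.kind == "tabulated":
            return self._tab(t)["M"]
        return float(sum(w * mu for w, _, mu in self._pieces(float(t))))

    def net_growth(self, t: float) -> float:
        """R(t) = integral of lambda(s) - mu(s) over [0, t]."""
        if self.kind == "tabulated":
            tab = self._tab(t)
            return tab["L"] - tab["M"]
        return float(sum(w * (lam - mu) for w, lam, mu in self._pieces(float(t))))

    def log_growth_integral(self, t: float) -> float:
        """log of G(t) = integral of lambda(s) e^{R(s)} over [0, t].

        Exact per-piece accumulation in log space for (piecewise-)constant
        models; spline-interpolated Simpson grid for tabulated ones.
        """
        if self.kind == "tabulated":
            return self._tab(t)["logG"]
        acc = -math.inf
        R = 0.0
        for w, lam, mu in self._pieces(float(t)):
            if w <= 0.0:
                continue
            r = lam - mu
            if lam > 0.0:
                term = math.log(lam) + R + _log_exprel(r, w)
                acc = np.logaddexp(acc, term)
            R += r * w
        return float(acc)

    def log_death_integral(self, t: float) -> float:
        """log of K(t) = integral of mu(s) e^{R(s)} over [0, t].

        Together with G this carries the complete-sampling (Kendall)
        forms of the transition probabilities: 1 + G = e^R + K.
        """
        if self.kind == "tabulated":
            return self._tab(t)["logK"]
        acc = -math.inf
        R = 0.0
        for w, lam, mu in self._pieces(float(t)):
            if w <= 0.0:
                continue
            r = lam - mu
            if mu > 0.0:
                term = math.log(mu) + R + _log_exprel(r, w)
                acc = np.logaddexp(acc, term)
            R += r * w
        return float(acc)

    # -- tabulated-model grid cache ----------------------------------------
    def _tab(self, t: float) -> dict:
        """Cumulative integrals for tabulated models, from a cached grid.

        Builds a dense Simpson grid on [0, t_max] (t_max grows on demand)
        and interpolates each cumulative with a cubic spline; accurate to
        roughly 1e-9 relative for smooth rate functions.
        """
        from scipy.interpolate import CubicSpline

        t = float(t)
        if t < 0:
            raise ModelError("ages must be non-negative")
        if t == 0.0:
            return {"L": 0.0, "M": 0.0, "logG": -math.inf, "logK": -math.inf}
        cache = self._cache
        if "t_max" not in cache or t > cache["t_max"]:
            t_max = max(t * 1.05, 1e-6)
            n = 8193
            grid = np.linspace(0.0, t_max, n)
            lam = np.asarray(self.birth_fn(grid), dtype=float) * np.ones(n)
            mu = np.asarray(self.death_fn(grid), dtype=float) * np.ones(n)
            if (lam < 0).any() or (mu < 0).any():
                raise ModelError("tabulated rates must be non-negative")
            L = np.concatenate([[0.0], cumulative_simpson(lam, x=grid)])
            M = np.concatenate([[0.0], cumulative_simpson(mu, x=grid)])
            R = L - M
            shift = R.max()
            G = np.concatenate(
                [[0.0], cumulative_simpson(lam * np.exp(R - shift), x=grid)]
            )
            K = np.concatenate(
                [[0.0], cumulative_simpson(mu * np.exp(R - shift), x=grid)]
            )
            cache["t_max"] = t_max
            cache["L"] = CubicSpline(grid, L)
            cache["M"] = CubicSpline(grid, M)
            cache["G"] = CubicSpline(grid, G)
            cache["K"] = CubicSpline(grid, K)
            cache["shift"] = shift
        G = float(cache["G"](t))
        K = float(cache["K"](t))
        return {
            "L": float(cache["L"](t)),
            "M": float(cache["M"](t)),
            "logG": (math.log(G) + cache["shift"]) if G > 0 else -math.inf,
            "logK": (math.log(K) + cache["shift"]) if K > 0 else -math.inf,
        }


def make_constant_model(lam: float, mu: float, rho: float = 1.0) -> RateModel:
    """Constant-rate birth-death model with sampling fraction rho."""
    return RateModel(kind="constant", rho=float(rho), lambdas=(float(lam),),
                     mus=(float(mu),), change_points=())


def make_piecewise_model(
    change_points: Sequence[float],
    lambdas: Sequence[float],
    mus: Sequence[float],
    rho: float = 1.0,
) -> RateModel:
    """Piecewise-constant rate model; youngest piece listed first.

    ``change_points`` are strictly increasing ages; ``lambdas[k]`` and
    ``mus[k]`` apply between ``change_points[k-1]`` and
    ``change_points[k]`` (with 0 and infinity at the ends).  With zero
    change points this degenerates to a constant model.
    """
    cps = tuple(float(c) for c in change_points)
    kind = "piecewise_constant" if cps else "constant"
    return RateModel(
        kind=kind,
        rho=float(rho),
        lambdas=tuple(float(x) for x in lambdas),
        mus=tuple(float(x) for x in mus),
        change_points=cps,
    )


def make_tabulated_model(
    birth: Callable[[float], float],
    death: Callable[[float], float],
    rho: float = 1.0,
) -> RateModel:
    """Rate model from arbitrary (vectorizable) callables of age."""
    return RateModel(kind="tabulated", rho=float(rho), birth_fn=birth, death_fn=death)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LTTData:
    """Rank-ordered speciation ages of a reconstructed tree.

    ``ages`` holds the internal-node ages t1 > t2 > ... > t_{n-1} (sorted
    descending on construction, stable for ties); a tree with n tips has
    n - 1 of them.  ``stem_age`` is the optional age t0 at which the
    process started with a single lineage and must exceed the root age t1.
    These ages are the sufficient statistic for every likelihood in this
    package: the tree topology carries no extra information when rates
    vary only through time.
    """

    ages: np.ndarray
    stem_age: float | None = None

    def __post_init__(self) -> None:
        a = _sorted_desc(np.atleast_1d(np.asarray(self.ages, dtype=float)))
        if a.size and (a <= 0).any():
            raise ModelError("node ages must be strictly positive")
        object.__setattr__(self, "ages", a)
        if self.stem_age is not None:
            t0 = float(self.stem_age)
            if not math.isfinite(t0) or t0 <= 0:
                raise ModelError("stem age must be positive and finite")
            if a.size and t0 <= a[0]:
                raise ModelError("stem age must exceed the root age")
            object.__setattr__(self, "stem_age", t0)

    @property
    def n(self) -> int:
        """Number of tips."""
        return int(self.ages.size) + 1

    @property
    def root_age(self) -> float:
        if self.ages.size == 0:
            raise ModelError("no internal nodes: root age undefined")
        return float(self.ages[0])


@dataclass(frozen=True)
class TwoEpochData:
    """LTT ages split at a change point into old- and young-epoch sets.

    ``old_ages`` (count I) lie above the change point, ``young_ages``
    (count J) at or below it.
    """

    old_ages: np.ndarray
    young_ages: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "old_ages", _sorted_desc(np.atleast_1d(np.asarray(self.old_ages, dtype=float))))
        object.__setattr__(self, "young_ages", _sorted_desc(np.atleast_1d(np.asarray(self.young_ages, dtype=float))))
        if (self.old_ages <= 0).any() or (self.young_ages <= 0).any():
            raise ModelError("node ages must be strictly positive")

    @property
    def I(self) -> int:  # noqa: E743 - field name from the two-epoch model
        return int(self.old_ages.size)

    @property
    def J(self) -> int:
        return int(self.young_ages.size)

    @property
    def n(self) -> int:
        """Tip count of the underlying tree."""
        return self.I + self.J + 1

    def pooled(self, stem_age: float | None = None) -> LTTData:
        return LTTData(np.concatenate([self.old_ages, self.young_ages]), stem_age)


def partition_ltt(data: LTTData, T: float) -> TwoEpochData:
    """Split LTT ages at the change point T.

    Ages strictly above T belong to the old epoch, ages at or below T to
    the young epoch, so I + J = n - 1 always.
    """
    T = float(T)
    if T <= 0:
        raise ModelError("change point T must be positive")
    old = data.ages[data.ages > T]
    young = data.ages[data.ages <= T]
    return TwoEpochData(old_ages=old, young_ages=young)


@dataclass(frozen=True)
class TwoEpochModel:
    """Pure-birth model with one rate shift and an optional mass extinction.

    The process starts at stem age ``t0`` with birth rate ``lambda0``,
    switches to ``lambda1`` at age ``T`` and, if ``survival_p`` < 1, every
    lineage alive at age T survives the instantaneous mass extinction
    independently with probability ``survival_p``.
    """

    lambda0: float
    lambda1: float
    T: float
    t0: float
    survival_p: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t0 > self.T > 0):
            raise ModelError("need stem age t0 > change point T > 0")
        if self.lambda0 <= 0 or self.lambda1 <= 0:
            raise ModelError("epoch birth rates must be positive")
        if not (0.0 < self.survival_p <= 1.0):
            raise ModelError("survival probability must be in (0, 1]")

    def to_rate_model(self) -> RateModel:
        """Piecewise-constant pure-birth model with the same rates.

        The mass extinction (if any) is not representable as a rate
        function and is dropped here; forward simulation handles it as a
        discrete event.
        """
        return make_piecewise_model(
            [self.T], [self.lambda1, self.lambda0], [0.0, 0.0], rho=1.0
        )


# ---------------------------------------------------------------------------
# config round-trip
# ---------------------------------------------------------------------------

def model_to_dict(model: RateModel) -> dict:
    """JSON-serializable model specification (not for tabulated models)."""
    if model.kind == "tabulated":
        raise ModelError("tabulated models cannot be serialized to config")
    return {
        "kind": model.kind,
        "rho": model.rho,
        "lambdas": list(model.lambdas),
        "mus": list(model.mus),
        "change_points": list(model.change_points),
    }


def model_from_dict(spec: dict) -> RateModel:
    kind = spec.get("kind")
    if kind == "constant":
        return make_constant_model(spec["lambdas"][0], spec["mus"][0], spec.get("rho", 1.0))
    if kind == "piecewise_constant":
        return make_piecewise_model(
            spec["change_points"], spec["lambdas"], spec["mus"], spec.get("rho", 1.0)
        )
    raise ModelError(f"cannot build model of kind {kind!r} from config")
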