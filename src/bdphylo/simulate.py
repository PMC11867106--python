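"""Simulators for birth-death trees and lineage-through-time data.

Two complementary routes are provided:

* the order-statistics samplers draw the n - 1 node ages of a
  reconstructed tree conditioned on the tip count and stem age directly,
  as i.i.d. draws from the per-age kernel (a truncated exponential for
  the Yule process, lam(x) p1(x) normalized numerically for birth-death
  models), rank-ordered;

* the forward simulator runs the process event by event from a single
  lineage at the stem age down to the present (exact per-piece
  exponential waiting times for piecewise-constant rates, thinning
  against a rate bound for tabulated ones), applies the optional mass
  extinction and present-day rho-sampling, and prunes the complete event
  history to the reconstructed tree of sampled survivors.

Both are exact samplers of the same laws and are cross-validated against
each other in the test-suite.  A single seeded generator drives each
simulation and the seed is recorded in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .models import LTTData, ModelError, RateModel, TwoEpochModel
from . import transitions as tr

__all__ = [
    "SimulatedTree",
    "sample_yule_order_stats",
    "sample_bdp_order_stats",
    "sample_gbdp_order_stats",
    "simulate_forward",
    "forward_conditional_on_n",
    "prune_to_reconstructed",
    "ltt_from_tree",
    "tree_from_ltt",
]

#: relative ultrametricity tolerance for imported trees
ULTRAMETRIC_RTOL = 1e-6


# ---------------------------------------------------------------------------
# order-statistics samplers
# ---------------------------------------------------------------------------

def sample_yule_order_stats(n: int, t0: float, lam: float, seed=None) -> LTTData:
    """Node ages of a Yule tree conditioned on n tips and stem age t0.

    The n - 1 ages are i.i.d. truncated-exponential draws on [0, t0]
    (inverse-CDF sampling), rank-ordered.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if t0 <= 0 or lam <= 0:
        raise ValueError("t0 and lam must be positive")
    rng = np.random.default_rng(seed)
    u = rng.random(n - 1)
    # F(x) = (1 - e^{-lam x}) / (1 - e^{-lam t0})
    ages = -np.log1p(u * np.expm1(-lam * t0)) / lam
    return LTTData(ages, stem_age=t0)


def sample_gbdp_order_stats(
    n: int, t0: float, model: RateModel, seed=None, grid_size: int = 2049
) -> LTTData:
    """Node ages of a GBDP reconstructed tree given n sampled tips and t0.

    The per-age kernel is proportional to lam(x) p1(x) on [0, t0]; it is
    tabulated on a uniform grid, normalized by the trapezoid rule and
    sampled by inverse CDF on the monotone interpolant.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if t0 <= 0:
        raise ValueError("t0 must be positive")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, t0, grid_size)
    lam = np.asarray(model.birth(x), dtype=float) * np.ones(grid_size)
    dens = lam * np.array([tr.gbdp_p1(float(xi), model) for xi in x])
    if not np.any(dens > 0):
        raise ModelError("degenerate kernel: lam(x) p1(x) vanishes on [0, t0]")
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(x))])
    cdf /= cdf[-1]
    u = rng.random(n - 1)
    ages = np.interp(u, cdf, x)
    return LTTData(ages, stem_age=t0)


def sample_bdp_order_stats(
    n: int, t0: float, lam: float, mu: float, rho: float = 1.0, seed=None
) -> LTTData:
    """Constant-rate BDP version of :func:`sample_gbdp_order_stats`.

    With mu = 0 and rho = 1 the kernel is the truncated exponential of
    the Yule sampler.
    """
    from .models import make_constant_model

    return sample_gbdp_order_stats(n, t0, make_constant_model(lam, mu, rho), seed=seed)


# ---------------------------------------------------------------------------
# forward event simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTree:
    """Complete event history of one forward birth-death simulation.

    Lineage k arose at ``birth_age[k]`` by splitting off ``parent[k]``
    (the founding lineage has parent -1 and birth age t0).
    ``death_age[k]`` is NaN for lineages alive at present;
    ``sampled[k]`` marks present-day lineages kept by rho-sampling.
    ``events`` is the time-ordered (age-descending) list of
    (age, kind, lineage id) with kind in {"birth", "death",
    "mass_extinction_death", "mass_extinction_survival"}.
    """

    t0: float
    seed: object
    parent: np.ndarray
    birth_age: np.ndarray
    death_age: np.ndarray
    sampled: np.ndarray
    events: list = field(repr=False)

    @property
    def n_lineages(self) -> int:
        return int(self.parent.size)

    @property
    def n_sampled(self) -> int:
        return int(self.sampled.sum())

    @property
    def extinct(self) -> bool:
        """True when no lineage survives to be sampled (empty reconstruction)."""
        return self.n_sampled == 0

    def tip_count_law_sample(self) -> int:
        """Number of sampled present-day lineages (0 when extinct)."""
        return self.n_sampled

    # -- reconstruction (records-based, O(total lineages)) ------------------
    def _sampled_descendant_flags(self) -> np.ndarray:
        samp = self.sampled.copy()
        for k in range(self.parent.size - 1, 0, -1):
            if samp[k]:
                samp[self.parent[k]] = True
        return samp

    def _children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.parent.size)]
        for k in range(1, self.parent.size):
            kids[self.parent[k]].append(k)  # appended in descending birth age
        return kids

    def reconstructed_ltt(self) -> LTTData:
        """Node ages of the reconstructed tree of sampled survivors.

        A birth event appears in the reconstructed tree exactly when both
        the new lineage and the continuing side of its parent (restricted
        to younger events) retain a sampled descendant.
        """
        if self.extinct:
            raise ModelError("no sampled survivors: reconstructed tree is empty")
        samp = self._sampled_descendant_flags()
        kids = self._children()
        ages: list[float] = []
        for i in range(self.parent.size):
            own = bool(self.sampled[i])
            for j in reversed(kids[i]):  # youngest birth first
                if samp[j] and own:
                    ages.append(float(self.birth_age[j]))
                own = own or bool(samp[j])
        return LTTData(np.asarray(ages), stem_age=self.t0)

    def full_tree(self) -> dendropy.Tree:
        """The complete simulated tree, including extinct lineages."""
        n = self.parent.size
        keep = np.ones(n, dtype=bool)
        tip_age = np.where(np.isnan(self.death_age), 0.0, self.death_age)
        return _records_to_tree(self, keep=keep, tip_keep=keep, tip_age=tip_age)


def _segments(model, t0: float):
    """(hi, lo, lam, mu) age segments with constant rates, oldest first."""
    if isinstance(model, TwoEpochModel):
        return [(t0, model.T, model.lambda0, 0.0), (model.T, 0.0, model.lambda1, 0.0)]
    if model.kind == "tabulated":
        return None
    edges = [c for c in model.change_points if c < t0]
    hi = t0
    segs = []
    for c in reversed(edges):
        idx = model._piece_index((hi + c) / 2.0)
        segs.append((hi, c, model.lambdas[idx], model.mus[idx]))
        hi = c
    idx = model._piece_index(hi / 2.0)
    segs.append((hi, 0.0, model.lambdas[idx], model.mus[idx]))
    return segs


def simulate_forward(
    model: RateModel | TwoEpochModel,
    t0: float | None = None,
    seed=None,
    max_lineages: int = 1_000_000,
) -> SimulatedTree:
    """Exact forward simulation from one lineage at age t0 to the present.

    Piecewise-constant rates use per-segment exponential waiting times
    (memorylessness makes restarting at segment boundaries exact);
    tabulated rates use thinning against a grid-based bound.  For a
    :class:`TwoEpochModel` with survival_p < 1 every lineage alive at age
    T survives the mass extinction independently with that probability.
    Present-day lineages are then sampled with probability rho.

    Total extinction is not an error: the result has ``extinct = True``
    and an empty reconstruction.
    """
    if isinstance(model, TwoEpochModel):
        if t0 is None:
            t0 = model.t0
        rho = 1.0
        mass_ext = (model.T, model.survival_p) if model.survival_p < 1.0 else None
    else:
        if t0 is None:
            raise ValueError("t0 is required for RateModel simulations")
        rho = model.rho
        mass_ext = None
    if t0 <= 0:
        raise ValueError("t0 must be positive")

    rng = np.random.default_rng(seed)
    parent = [-1]
    birth_age = [float(t0)]
    death_age = [math.nan]
    alive = [0]
    events: list = []

    def do_birth(age: float) -> None:
        k = len(parent)
        i = alive[int(rng.integers(len(alive)))]
        parent.append(i)
        birth_age.append(age)
        death_age.append(math.nan)
        alive.append(k)
        events.append((age, "birth", k))
        if len(parent) > max_lineages:
            raise RuntimeError(f"simulation exceeded {max_lineages} lineages")

    def do_death(age: float) -> None:
        j = int(rng.integers(len(alive)))
        i = alive[j]
        alive[j] = alive[-1]
        alive.pop()
        death_age[i] = age
        events.append((age, "death", i))

    segs = _segments(model, t0)
    if segs is not None:
        for hi, lo, lam, mu in segs:
            age = hi
            total_rate = lam + mu
            while alive:
                if total_rate <= 0.0:
                    break
                w = rng.exponential(1.0 / (len(alive) * total_rate))
                if age - w <= lo:
                    break
                age -= w
                if rng.random() < lam / total_rate:
                    do_birth(age)
                else:
                    do_death(age)
            if not alive:
                break
            if mass_ext is not None and lo == mass_ext[0]:
                T, p = mass_ext
                survivors = []
                for i in alive:
                    if rng.random() < p:
                        survivors.append(i)
                        events.append((T, "mass_extinction_survival", i))
                    else:
                        death_age[i] = T
                        events.append((T, "mass_extinction_death", i))
                alive = survivors
                if not alive:
                    break
    else:
        # tabulated rates: thinning against a grid bound
        grid = np.linspace(0.0, t0, 4097)
        per_lineage_bound = 1.05 * float(
            np.max(np.asarray(model.birth_fn(grid)) + np.asarray(model.death_fn(grid)))
        )
        age = t0
        while alive and age > 0.0:
            bound = len(alive) * per_lineage_bound
            age -= rng.exponential(1.0 / bound)
            if age <= 0.0:
                break
            lam = float(model.birth(age))
            mu = float(model.death(age))
            if lam + mu > per_lineage_bound:
                raise RuntimeError("thinning bound violated: rate function too rough")
            u = rng.random() * per_lineage_bound
            if u < lam:
                do_birth(age)
            elif u < lam + mu:
                do_death(age)

    sampled = np.zeros(len(parent), dtype=bool)
    for i in alive:
        if rho >= 1.0 or rng.random() < rho:
            sampled[i] = True
    return SimulatedTree(
        t0=float(t0),
        seed=seed,
        parent=np.asarray(parent, dtype=np.int64),
        birth_age=np.asarray(birth_age, dtype=float),
        death_age=np.asarray(death_age, dtype=float),
        sampled=sampled,
        events=events,
    )


def forward_conditional_on_n(
    model,
    t0: float,
    n: int,
    size: int,
    seed=None,
    max_attempts: int = 1_000_000,
):
    """Rejection-sample forward simulations with exactly n sampled tips.

    Returns (list of LTTData, acceptance rate).  Raises RuntimeError if
    ``max_attempts`` forward simulations do not yield ``size`` accepted
    replicates.
    """
    rng = np.random.default_rng(seed)
    out: list[LTTData] = []
    attempts = 0
    while len(out) < size:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"rejection sampling: {len(out)}/{size} accepted in {attempts} attempts"
            )
        attempts += 1
        sim = simulate_forward(model, t0=t0, seed=rng)
        if sim.n_sampled == n:
            out.append(sim.reconstructed_ltt())
    return out, len(out) / attempts


# ---------------------------------------------------------------------------
# pruning and tree conversion
# ---------------------------------------------------------------------------

def _records_to_tree(
    sim: SimulatedTree, keep: np.ndarray, tip_keep: np.ndarray, tip_age: np.ndarray
) -> dendropy.Tree:
    """Build a dendropy tree from lineage records.

    ``keep[k]`` marks lineages whose subtree is retained; ``tip_keep[k]``
    marks lineages whose own tip (at ``tip_age[k]``) is a leaf of the
    output.  A kept lineage without a kept tip is suppressed as a unary
    pass-through: its subtree starts at its first kept child.  Iterative
    (no recursion) so very large trees are safe.
    """
    kids = sim._children()
    taxa = dendropy.TaxonNamespace()
    rep: dict[int, dendropy.Node] = {}
    for i in range(sim.parent.size - 1, -1, -1):
        if not keep[i]:
            continue
        cur = None
        if tip_keep[i]:
            cur = dendropy.Node()
            cur.age = float(tip_age[i])
            cur.taxon = taxa.new_taxon(label=f"T{i}")
        for j in reversed(kids[i]):  # youngest birth first
            sub = rep.get(j)
            if sub is None:
                continue
            if cur is None:
                cur = sub  # unary vertex suppressed
                continue
            joint = dendropy.Node()
            joint.age = float(sim.birth_age[j])
            joint.add_child(cur)
            joint.add_child(sub)
            cur = joint
        if cur is None:
            raise AssertionError("kept lineage with no kept tip or child")
        rep[i] = cur
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = rep[0]
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
        else:
            nd.edge.length = sim.t0 - nd.age
    tree.stem_age = sim.t0
    return tree


def prune_to_reconstructed(sim: SimulatedTree) -> dendropy.Tree | None:
    """Reconstructed tree of the sampled survivors (None if extinct).

    Removes every lineage without a sampled descendant and suppresses the
    resulting unary vertices; internal-node ages of the result are the
    subset of birth ages ancestral to at least two sampled tips.  The
    operation is idempotent: the reconstructed tree prunes to itself.
    """
    if sim.extinct:
        return None
    samp = sim._sampled_descendant_flags()
    tip_age = np.zeros(sim.parent.size)
    return _records_to_tree(sim, keep=samp, tip_keep=sim.sampled, tip_age=tip_age)


def ltt_from_tree(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> LTTData:
    """Rank-ordered internal-node ages of an ultrametric binary tree.

    Node ages are computed from root-to-tip path lengths; the tree must
    be ultrametric within ``rtol`` times its height and strictly binary.
    The stem age is taken from a root edge length when present.
    """
    depths: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            if nd.edge.length is None:
                raise ModelError("tree has missing branch lengths")
            depths[nd] = depths[nd.parent_node] + float(nd.edge.length)
    leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
    height = max(leaf_depths)
    if height <= 0:
        raise ModelError("tree has zero height")
    worst = max(abs(d - height) for d in leaf_depths)
    if worst > rtol * height:
        raise ModelError(
            f"tree is not ultrametric: tip depth deviation {worst:.3g} "
            f"exceeds {rtol:.1g} x height"
        )
    ages = []
    for nd in tree.preorder_internal_node_iter():
        nkids = len(nd.child_nodes())
        if nkids != 2:
            raise ModelError(f"tree is not binary: a node has {nkids} children")
        ages.append(height - depths[nd])
    stem = getattr(tree, "stem_age", None)
    if stem is None and tree.seed_node.edge.length:
        stem = height + float(tree.seed_node.edge.length)
    return LTTData(np.asarray(ages), stem_age=stem)


def tree_from_ltt(data: LTTData, seed=None) -> dendropy.Tree:
    """A uniformly random labelled history with the given node ages.

    Under every model in this package all topologies with the same ranked
    ages are equally likely, so attaching each successive speciation to a
    uniformly chosen extant lineage inverts :func:`ltt_from_tree` exactly
    (the recovered ages equal the input ages).
    """
    if data.ages.size == 0:
        raise ModelError("need at least one node age")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    root.age = float(data.ages[0])

    def split(parent: dendropy.Node) -> list[dendropy.Node]:
        out = [dendropy.Node(), dendropy.Node()]
        for c in out:
            parent.add_child(c)
        return out

    # active: unresolved lineages (pending child slots extending to present)
    active = split(root)
    for age in data.ages[1:]:
        node = active[int(rng.integers(len(active)))]
        node.age = float(age)
        active.remove(node)
        active.extend(split(node))
    for k, tip in enumerate(active):
        tip.age = 0.0
        tip.taxon = taxa.new_taxon(label=f"T{k}")
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.parent_node.age - nd.age
    if data.stem_age is not None:
        tree.seed_node.edge.length = data.stem_age - root.age
        tree.stem_age = data.stem_age
    return tree
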