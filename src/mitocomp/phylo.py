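"""Distance, likelihood and dating machinery for concatenated-PCG phylogenetics.

Implements Kimura two-parameter distances, 13-gene supermatrix concatenation,
neighbor joining, Felsenstein-pruning log-likelihoods under JC/K2P/HKY/GTR
(optionally with discrete-gamma rate variation), BIC model ranking with
branch-length optimization, and a relative-rate divergence dater that rescales
relative node heights to absolute ages under point or interval calibrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
TRANSITIONS = {frozenset("AG"), frozenset("CT")}

# ---------------------------------------------------------------------------
# K2P distances


@dataclass
class K2PResult:
    """Kimura two-parameter distance between two aligned sequences.

    ``P`` and ``Q`` are the transition and transversion proportions over
    pairwise-comparable sites; ``d = -1/2 ln((1-2P-Q) sqrt(1-2Q))`` in
    substitutions/site; ``valid`` is False on saturation (non-positive log
    argument), with P and Q still reported.  ``se`` is the delta-method
    standard error.
    """

    P: float
    Q: float
    d: float | None
    valid: bool
    n_sites: int
    se: float | None = None

    @property
    def percent(self) -> float | None:
        return None if self.d is None else 100.0 * self.d


def k2p_distance(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance with pairwise deletion of gap/N sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    n = ts = tv = 0
    for x, y in zip(seq_a, seq_b):
        if x not in _BASE_INDEX or y not in _BASE_INDEX:
            continue
        n += 1
        if x != y:
            if frozenset((x, y)) in TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P=P, Q=Q, d=None, valid=False, n_sites=n)
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    c1, c2 = 1 / w1, 1 / w2
    c3 = (c1 + c2) / 2
    var = (c1 * c1 * P + c3 * c3 * Q - (c1 * P + c3 * Q) ** 2) / n
    return K2PResult(P=P, Q=Q, d=d, valid=True, n_sites=n,
                     se=math.sqrt(max(var, 0.0)))


def k2p_matrix(seqs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise K2P distance matrix over a set of aligned sequences."""
    labels = list(seqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = k2p_distance(seqs[labels[i]], seqs[labels[j]])
            if not res.valid:
                raise ValueError(
                    f"saturated pair {labels[i]}/{labels[j]}: K2P undefined")
            D[i, j] = D[j, i] = res.d
    return D, labels


# ---------------------------------------------------------------------------
# Concatenation


def concatenate_pcgs(gene_seqs: dict[str, dict[str, str]],
                     gene_order: list[str],
                     ) -> tuple[dict[str, str], dict[str, tuple[int, int]]]:
    """Column-concatenate per-gene alignments into a supermatrix.

    ``gene_seqs`` maps gene -> {taxon: aligned sequence}.  Every gene must be
    present for every taxon (no auto-gapping); the returned partition map
    records each gene's 1-based inclusive column span.
    """
    taxa: list[str] = []
    for g in gene_order:
        for t in gene_seqs.get(g, {}):
            if t not in taxa:
                taxa.append(t)
    missing = [(t, g) for g in gene_order for t in taxa
               if t not in gene_seqs.get(g, {})]
    if missing:
        raise ValueError(f"missing taxon/gene combinations: {missing}")
    spans: dict[str, tuple[int, int]] = {}
    parts = {t: [] for t in taxa}
    at = 0
    for g in gene_order:
        lens = {len(s) for s in gene_seqs[g].values()}
        if len(lens) != 1:
            raise ValueError(f"gene {g}: unequal aligned lengths {lens}")
        glen = lens.pop()
        spans[g] = (at + 1, at + glen)
        at += glen
        for t in taxa:
            parts[t].append(gene_seqs[g][t])
    return {t: "".join(v) for t, v in parts.items()}, spans


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    Exact on additive matrices; negative branch lengths are clamped to zero
    with a warning.  Returns an unrooted dendropy tree.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T) or (D < 0).any():
        raise ValueError("distance matrix must be square, symmetric, >= 0")

    def clamp(x: float) -> float:
        if x < 0:
            if x < -1e-9:
                warnings.warn(f"negative NJ branch length {x:.6g} clamped to 0",
                              stacklevel=3)
            return 0.0
        return x

    nodes = [f"{lab}" for lab in labels]  # newick fragments
    idx = list(range(n))
    D = D.copy()
    active = list(range(n))
    frags = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        a, b = np.unravel_index(np.argmin(Qm), Qm.shape)
        i, j = active[a], active[b]
        dij = D[i, j]
        li_raw = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        li = clamp(li_raw)
        lj = clamp(dij - li_raw)
        new = D.shape[0]
        drow = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[new, :new], D[:new, new] = drow, drow
        D[new, new] = 0.0
        frags[new] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [new]
    i, j, k = active
    li = clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lj = clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lk = clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    newick = (f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g},"
              f"{frags[k]}:{lk:.10g});")
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Substitution models


@dataclass
class SubstitutionModel:
    """Time-reversible nucleotide model, optionally with discrete-gamma rates.

    ``exchangeabilities`` order: AC, AG, AT, CG, CT, GT.  The rate matrix is
    normalized to one expected substitution per site per unit branch length.
    """

    name: str
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    exchangeabilities: np.ndarray = field(
        default_factory=lambda: np.ones(6))
    gamma_alpha: float | None = None
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-8):
            raise ValueError("base frequencies must sum to 1")
        if (self.exchangeabilities <= 0).any():
            raise ValueError("exchangeabilities must be positive")

    @property
    def n_free_params(self) -> int:
        base = {"JC": 0, "K2P": 1, "HKY": 4, "GTR": 8}[self.base_name]
        return base + (1 if self.gamma_alpha is not None else 0)

    @property
    def base_name(self) -> str:
        return self.name.split("+")[0]

    def rate_matrix(self) -> np.ndarray:
        s = self.exchangeabilities
        pi = self.freqs
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        Q = np.zeros((4, 4))
        for (i, j), sij in zip(pairs, s):
            Q[i, j] = sij * pi[j]
            Q[j, i] = sij * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        return Q / mu

    def rate_categories(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) of the discrete-gamma mixture (mean-per-category)."""
        if getattr(self, "_rate_cache", None) is not None:
            return self._rate_cache
        if self.gamma_alpha is None:
            self._rate_cache = (np.array([1.0]), np.array([1.0]))
        else:
            a, k = self.gamma_alpha, self.gamma_categories
            edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1 / a)
            upper = gamma_dist.cdf(edges, a + 1, scale=1 / a)
            self._rate_cache = (k * np.diff(upper), np.full(k, 1 / k))
        return self._rate_cache

    def spectral(self):
        """Cached symmetric eigendecomposition of the (reversible) rate
        matrix, so P(t) = D^{-1/2} V exp(wt) V' D^{1/2} avoids one expm per
        branch."""
        if getattr(self, "_spec_cache", None) is None:
            Q = self.rate_matrix()
            sq = np.sqrt(self.freqs)
            B = Q * (sq[:, None] / sq[None, :])
            B = 0.5 * (B + B.T)
            w, V = np.linalg.eigh(B)
            left = V.T * sq[None, :]      # V' D^{1/2}
            right = V / sq[:, None]       # D^{-1/2} V
            self._spec_cache = (w, right, left)
        return self._spec_cache

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        if t * rate <= 0:
            return np.eye(4)
        w, right, left = self.spectral()
        P = (right * np.exp(w * t * rate)) @ left
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=1, keepdims=True)


def jc_model(gamma_alpha: float | None = None) -> SubstitutionModel:
    return SubstitutionModel("JC" + ("+G" if gamma_alpha else ""),
                             gamma_alpha=gamma_alpha)


def k2p_model(kappa: float = 2.0,
              gamma_alpha: float | None = None) -> SubstitutionModel:
    ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return SubstitutionModel("K2P" + ("+G" if gamma_alpha else ""),
                             exchangeabilities=ex, gamma_alpha=gamma_alpha)


def hky_model(kappa: float, freqs, gamma_alpha: float | None = None
              ) -> SubstitutionModel:
    ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    return SubstitutionModel("HKY" + ("+G" if gamma_alpha else ""),
                             freqs=np.asarray(freqs), exchangeabilities=ex,
                             gamma_alpha=gamma_alpha)


def gtr_model(exchangeabilities, freqs,
              gamma_alpha: float | None = None) -> SubstitutionModel:
    return SubstitutionModel("GTR" + ("+G" if gamma_alpha else ""),
                             freqs=np.asarray(freqs),
                             exchangeabilities=np.asarray(exchangeabilities),
                             gamma_alpha=gamma_alpha)


# ---------------------------------------------------------------------------
# Pruning likelihood


def _encode_alignment(alignment: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    taxa = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows differ in length")
    L = lengths.pop()
    if L == 0:
        raise ValueError("zero-length alignment")
    M = np.zeros((len(taxa), L), dtype=np.int8)
    for r, t in enumerate(taxa):
        M[r] = [_BASE_INDEX.get(c, -1) for c in alignment[t].upper()]
    return M, taxa


def _site_patterns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    patterns, counts = np.unique(M, axis=1, return_counts=True)
    return patterns, counts


class PruningEngine:
    """Reusable Felsenstein-pruning evaluator for one (tree, alignment) pair.

    Encodes the alignment and compresses site patterns once; the tree is
    flattened to postorder index arrays so repeated likelihood evaluations
    (model fitting, branch-length optimization) cost only the small
    per-branch matrix products.
    """

    def __init__(self, tree: dendropy.Tree, alignment: dict[str, str]):
        M, taxa = _encode_alignment(alignment)
        tip_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        if tip_labels != set(taxa):
            raise ValueError("tree tips do not match alignment taxa")
        self.patterns, self.counts = _site_patterns(M)
        self.n_sites = int(self.counts.sum())
        npat = self.patterns.shape[1]
        row_of = {t: r for r, t in enumerate(taxa)}

        self._nodes = list(tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(self._nodes)}
        self.children: list[list[int]] = []
        self.leaf_partials: dict[int, np.ndarray] = {}
        bl = []
        self.edge_of_node: list[int | None] = []
        self._edges = []
        for node in self._nodes:
            self.children.append([index[id(c)] for c in node.child_nodes()])
            if node.is_leaf():
                states = self.patterns[row_of[node.taxon.label]]
                part = np.zeros((npat, 4))
                known = states >= 0
                part[known, states[known]] = 1.0
                part[~known] = 1.0
                self.leaf_partials[index[id(node)]] = part
            if node.parent_node is not None:
                self.edge_of_node.append(len(bl))
                bl.append(node.edge.length or 0.0)
                self._edges.append(node.edge)
            else:
                self.edge_of_node.append(None)
        self.branch_lengths = np.asarray(bl)
        self.root = len(self._nodes) - 1

    @property
    def n_branches(self) -> int:
        return len(self.branch_lengths)

    def write_back(self) -> None:
        """Push the engine's branch lengths onto the dendropy edges."""
        for e, x in zip(self._edges, self.branch_lengths):
            e.length = float(x)

    def loglik(self, model: SubstitutionModel,
               bl: np.ndarray | None = None) -> float:
        if bl is None:
            bl = self.branch_lengths
        rates, weights = model.rate_categories()
        pi = model.freqs
        npat = self.patterns.shape[1]
        site_like = np.zeros(npat)
        for rate, w in zip(rates, weights):
            pmats = [model.transition_matrix(t, rate) for t in bl]
            partials: list[np.ndarray | None] = [None] * len(self._nodes)
            for i, kids in enumerate(self.children):
                if not kids:
                    partials[i] = self.leaf_partials[i]
                    continue
                part = np.ones((npat, 4))
                for c in kids:
                    part *= partials[c] @ pmats[self.edge_of_node[c]].T
                partials[i] = part
            site_like += w * (partials[self.root] @ pi)
        if (site_like <= 0).any():
            return -np.inf
        return float(self.counts @ np.log(site_like))


def loglikelihood(tree: dendropy.Tree, alignment: dict[str, str],
                  model: SubstitutionModel) -> float:
    """Felsenstein-pruning log-likelihood of an alignment on a tree.

    Gamma rate variation averages site likelihoods over the discrete
    categories; ambiguous characters (gap/N) contribute a partial vector of
    ones.  Site log-likelihoods are summed over compressed site patterns.
    """
    return PruningEngine(tree, alignment).loglik(model)


# ---------------------------------------------------------------------------
# Branch-length optimization and BIC ranking


def _optimize_engine_branches(engine: PruningEngine, model: SubstitutionModel,
                              sweeps: int = 3, max_bl: float = 10.0) -> float:
    """Coordinate-ascent branch-length optimization on an engine; returns lnL."""
    bl = engine.branch_lengths
    bl[bl < 1e-8] = 1e-8
    lnl = engine.loglik(model, bl)
    for _ in range(sweeps):
        improved = False
        for k in range(engine.n_branches):
            def neg(x, _k=k):
                bl[_k] = x
                return -engine.loglik(model, bl)
            res = minimize_scalar(neg, bounds=(0.0, max_bl), method="bounded",
                                  options={"xatol": 1e-5})
            bl[k] = float(res.x)
            if -res.fun > lnl + 1e-9:
                lnl = -res.fun
                improved = True
        if not improved:
            break
    return lnl


def optimize_branch_lengths(tree: dendropy.Tree, alignment: dict[str, str],
                            model: SubstitutionModel, sweeps: int = 3,
                            max_bl: float = 10.0) -> float:
    """Coordinate-ascent ML branch lengths in place on ``tree``; returns lnL."""
    engine = PruningEngine(tree, alignment)
    lnl = _optimize_engine_branches(engine, model, sweeps=sweeps, max_bl=max_bl)
    engine.write_back()
    return lnl


@dataclass
class ModelFit:
    model: SubstitutionModel
    lnL: float
    n_params: int
    bic: float
    converged: bool = True


def _empirical_freqs(alignment: dict[str, str]) -> np.ndarray:
    counts = np.zeros(4)
    for s in alignment.values():
        for i, b in enumerate(BASES):
            counts[i] += s.upper().count(b)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


def _fit_model(name: str, alignment: dict[str, str], tree: dendropy.Tree,
               ) -> ModelFit:
    """Fit one named model: free rate parameters by Nelder-Mead (log scale),
    branch lengths by coordinate ascent, frequencies empirical."""
    plus_g = name.endswith("+G")
    base = name.split("+")[0]
    freqs = (_empirical_freqs(alignment) if base in ("HKY", "GTR")
             else np.full(4, 0.25))

    def build(theta: np.ndarray) -> SubstitutionModel:
        vals = np.exp(theta)
        i = 0
        if base == "JC":
            ex = np.ones(6)
        elif base == "K2P" or base == "HKY":
            kappa = vals[i]; i += 1
            ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        else:  # GTR: 5 free exchangeabilities, GT fixed at 1
            ex = np.append(vals[i:i + 5], 1.0); i += 5
        alpha = vals[i] if plus_g else None
        return SubstitutionModel(name, freqs=freqs, exchangeabilities=ex,
                                 gamma_alpha=alpha)

    n_theta = {"JC": 0, "K2P": 1, "HKY": 1, "GTR": 5}[base] + int(plus_g)
    theta0 = np.zeros(n_theta)
    if plus_g:
        theta0[-1] = math.log(0.5)

    work = tree.clone(depth=1)
    engine = PruningEngine(work, alignment)
    converged = True
    model = build(theta0)
    lnl = _optimize_engine_branches(engine, model, sweeps=2)
    if n_theta:
        def neg(theta):
            return -engine.loglik(build(theta))
        res = minimize(neg, theta0, method="Nelder-Mead",
                       options={"maxiter": 120 * max(n_theta, 1),
                                "xatol": 1e-3, "fatol": 1e-4})
        converged = bool(res.success)
        model = build(res.x)
        lnl = _optimize_engine_branches(engine, model, sweeps=1)
        res = minimize(neg, res.x, method="Nelder-Mead",
                       options={"maxiter": 60 * max(n_theta, 1),
                                "xatol": 1e-3, "fatol": 1e-4})
        if -res.fun > lnl:
            model = build(res.x)
            lnl = _optimize_engine_branches(engine, model, sweeps=1)
    n_branches = engine.n_branches
    n_params = model.n_free_params + n_branches
    n_sites = engine.n_sites
    bic = n_params * math.log(n_sites) - 2 * lnl
    return ModelFit(model=model, lnL=lnl, n_params=n_params, bic=bic,
                    converged=converged)


def bic_rank(alignment: dict[str, str], tree: dendropy.Tree,
             candidate_models: list[str] | None = None) -> list[ModelFit]:
    """Rank candidate substitution models by BIC = p ln(n) - 2 lnL (ascending).

    Candidates are drawn from {JC, K2P, HKY, GTR} x {+G}; branch lengths are
    re-optimized per model.  A non-converged optimizer flags the fit but the
    model is still ranked.
    """
    if candidate_models is None:
        candidate_models = ["JC", "K2P", "HKY", "GTR",
                            "JC+G", "K2P+G", "HKY+G", "GTR+G"]
    fits = [_fit_model(name, alignment, tree) for name in candidate_models]
    return sorted(fits, key=lambda f: f.bic)


# ---------------------------------------------------------------------------
# Relative-rate dating


@dataclass(frozen=True)
class Calibration:
    """Age constraint on the MRCA of the named taxa (MYA): either a point
    ``age`` or an interval [min_age, max_age]."""

    taxa: tuple[str, ...]
    age: float | None = None
    min_age: float | None = None
    max_age: float | None = None


class CalibrationConflictError(ValueError):
    """No positive scale satisfies all point calibrations within 10%."""


@dataclass
class TimeTree:
    tree: dendropy.Tree
    scale: float
    node_ages: list[tuple[tuple[str, ...], float, float]]
    """(sorted tip labels of clade, relative height, absolute age MYA)."""

    def age_of(self, *taxa: str) -> float:
        want = set(taxa)
        best = None
        for clade, _, age in self.node_ages:
            if want <= set(clade):
                if best is None or len(clade) < len(best[0]):
                    best = (clade, age)
        if best is None:
            raise KeyError(f"no clade containing {sorted(want)}")
        return best[1]


def _relative_heights(tree: dendropy.Tree) -> None:
    """Relative node heights by recursive rate averaging, tips -> root.

    Each child lineage proposes ``height(child) + branch``; the node takes
    the mean of the proposals, so unequal descendant rates are equalized.
    Clamped to keep ages monotone along every root-to-tip path.
    """
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.rel_height = 0.0
            continue
        ests = [c.rel_height + (c.edge.length or 0.0)
                for c in node.child_nodes()]
        h = sum(ests) / len(ests)
        node.rel_height = max([h] + [c.rel_height for c in node.child_nodes()])


def reltime_date(tree: dendropy.Tree, outgroup: str,
                 calibrations: list[Calibration]) -> TimeTree:
    """Date a tree by relative rates plus calibration rescaling.

    The outgroup tip roots the topology and is then excluded from height
    estimation.  Relative heights come from recursive rate averaging; a
    single point calibration fixes the absolute scale, multiple point
    calibrations are combined by least squares (raising
    :class:`CalibrationConflictError` when no scale fits all of them within
    10%), and interval calibrations constrain the feasible scale range.
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    work = tree.clone(depth=1)
    taxon = next((t for t in work.taxon_namespace if t.label == outgroup), None)
    if taxon is None:
        raise ValueError(f"outgroup {outgroup!r} not among tree tips")
    og_node = work.find_node_with_taxon_label(outgroup)
    work.to_outgroup_position(og_node, update_bipartitions=False)
    work.prune_taxa([taxon])
    work.purge_taxon_namespace()
    _relative_heights(work)

    label_cache: dict[int, tuple[str, ...]] = {}
    for node in work.postorder_node_iter():
        if node.is_leaf():
            label_cache[id(node)] = (node.taxon.label,)
        else:
            labs: list[str] = []
            for c in node.child_nodes():
                labs.extend(label_cache[id(c)])
            label_cache[id(node)] = tuple(sorted(labs))

    def mrca_height(taxa: tuple[str, ...]) -> float:
        want = set(taxa)
        best = None
        for node in work.postorder_node_iter():
            labs = set(label_cache[id(node)])
            if want <= labs and (best is None or len(labs) < best[0]):
                best = (len(labs), node)
        if best is None:
            raise ValueError(f"calibration taxa {taxa} not in ingroup")
        node = best[1]
        if node.is_leaf():
            raise ValueError(f"calibration {taxa} resolves to a tip")
        return node.rel_height

    points = [(mrca_height(c.taxa), c.age) for c in calibrations
              if c.age is not None]
    intervals = [(mrca_height(c.taxa), c.min_age, c.max_age)
                 for c in calibrations if c.age is None]
    if points:
        num = sum(h * a for h, a in points)
        den = sum(h * h for h, a in points)
        if den <= 0:
            raise ValueError("calibrated node has zero relative height")
        scale = num / den
        for h, a in points:
            if abs(scale * h - a) > 0.10 * a:
                raise CalibrationConflictError(
                    f"no positive scale satisfies all point calibrations "
                    f"within 10% (node height {h:.4g}, age {a})")
    else:
        los = [mn / h for h, mn, _ in intervals if mn is not None and h > 0]
        his = [mx / h for h, _, mx in intervals if mx is not None and h > 0]
        lo = max(los) if los else 0.0
        hi = min(his) if his else math.inf
        if lo > hi:
            raise CalibrationConflictError(
                "interval calibrations admit no common scale")
        scale = lo if math.isinf(hi) else 0.5 * (lo + hi)
    for h, mn, mx in intervals:
        if mn is not None and scale * h < mn * 0.999:
            raise CalibrationConflictError("interval calibration violated")
        if mx is not None and scale * h > mx * 1.001:
            raise CalibrationConflictError("interval calibration violated")

    node_ages = []
    for node in work.postorder_node_iter():
        if not node.is_leaf():
            node.age_mya = scale * node.rel_height
            node_ages.append((label_cache[id(node)], node.rel_height,
                              node.age_mya))
    return TimeTree(tree=work, scale=scale, node_ages=node_ages)


def bootstrap_node_ages(alignment: dict[str, str], outgroup: str,
                        calibrations: list[Calibration],
                        replicates: int = 100, seed: int = 0) -> dict:
    """Nonparametric site bootstrap of the K2P->NJ->relative-rate pipeline.

    Resamples alignment columns with replacement, recomputes the dated tree,
    and returns per-clade age quantiles (2.5/50/97.5%) over replicates in
    which the clade is present.
    """
    rng = np.random.default_rng(seed)
    taxa = list(alignment)
    L = len(next(iter(alignment.values())))
    ages: dict[tuple[str, ...], list[float]] = {}
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        boot = {t: "".join(alignment[t][c] for c in cols) for t in taxa}
        try:
            D, labels = k2p_matrix(boot)
            tree = neighbor_joining(D, labels)
            tt = reltime_date(tree, outgroup, calibrations)
        except (ValueError, CalibrationConflictError):
            continue
        for clade, _, age in tt.node_ages:
            ages.setdefault(clade, []).append(age)
    out = {}
    for clade, vals in ages.items():
        arr = np.sort(np.asarray(vals))
        out[clade] = {
            "n": len(arr),
            "lo": float(np.quantile(arr, 0.025)),
            "median": float(np.quantile(arr, 0.5)),
            "hi": float(np.quantile(arr, 0.975)),
        }
    return out
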