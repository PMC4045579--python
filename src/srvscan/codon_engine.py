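"""Markov codon models: rate matrices, pruning likelihood, ML fitting.

The substitution process follows the Goldman–Yang/Muse–Gaut family:
instantaneous change between sense codons differing at a single
nucleotide position, proportional to the target codon's stationary
frequency, multiplied by ``kappa`` for transitions, by the synonymous
rate factor ``alpha`` (dS) for synonymous changes and by the
nonsynonymous factor ``beta`` (dN) otherwise.  ``omega = beta/alpha``
measures selection on the protein.

Site-model mixtures are handled by Felsenstein pruning with per-node
rescaling; every category's transition matrices come from one shared
eigendecomposition code path (the simulator reuses it), batched across
categories for speed.

Fitted models:

======  =====================================================
M0      single omega, constant dS
M3(k)   k discrete omega classes, constant dS
M7      omega ~ discretized Beta(p, q), constant dS
M8      discretized Beta plus a class with omega_s >= 1
DUAL    independent discrete dS and dN distributions (product grid);
        the dS distribution is constrained to mean one, which fixes
        the scale confound between dS and branch lengths
======  =====================================================

Branch lengths are in expected substitutions per codon site at the
reference rates ``alpha = beta = 1``; matrices are globally scaled so
that this reference process has unit rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp, softmax

from .codes import GeneticCode, is_transition, standard_code
from .seqio import CodonAlignment, PhyloTree, TreeNode, check_tree_matches_alignment

__all__ = [
    "CodonFrequencies",
    "CodonSubstitutionParams",
    "DiscreteRateDistribution",
    "ModelFit",
    "ParameterError",
    "DegenerateInputError",
    "build_rate_matrix",
    "log_likelihood",
    "PruningEngine",
    "fit_M0",
    "fit_M3",
    "fit_M7",
    "fit_M8",
    "fit_DUAL",
    "multistart_optimize",
    "f3x4_frequencies",
    "f61_frequencies",
    "uniform_frequencies",
]


class ParameterError(ValueError):
    """Invalid substitution-model parameters."""


class DegenerateInputError(ValueError):
    """A site has zero likelihood under every mixture category."""


# ---------------------------------------------------------------------------
# Frequencies and rate distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodonFrequencies:
    """Stationary frequencies over the sense codons of a genetic code."""

    values: np.ndarray  # length n_sense, sums to 1
    kind: str = "custom"  # F3x4 | F61 | uniform | custom

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or np.any(vals < 0) or not np.isclose(vals.sum(), 1.0):
            raise ParameterError("frequencies must be a non-negative unit-sum vector")


def uniform_frequencies(code: GeneticCode | None = None) -> CodonFrequencies:
    code = code or standard_code()
    n = code.n_sense
    return CodonFrequencies(values=np.full(n, 1.0 / n), kind="uniform")


def _position_nucleotide_counts(aln: CodonAlignment, pseudocount: float) -> np.ndarray:
    counts = np.full((3, 4), pseudocount, dtype=float)
    nuc_idx = {c: i for i, c in enumerate("ACGT")}
    for row in range(aln.n_sequences):
        seq = aln.rows[row]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) & {"N", "-"}:
                continue
            for pos, base in enumerate(codon):
                counts[pos, nuc_idx[base]] += 1
    return counts


def f3x4_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> CodonFrequencies:
    """Empirical F3x4 frequencies (position-specific nucleotide products).

    A small pseudocount keeps every sense-codon frequency strictly
    positive even when a nucleotide is unobserved at some position.
    """
    code = aln.code
    counts = _position_nucleotide_counts(aln, pseudocount)
    probs = counts / counts.sum(axis=1, keepdims=True)
    nuc_idx = {c: i for i, c in enumerate("ACGT")}
    vals = np.array(
        [
            probs[0, nuc_idx[c[0]]] * probs[1, nuc_idx[c[1]]] * probs[2, nuc_idx[c[2]]]
            for c in code.sense_codons
        ]
    )
    vals /= vals.sum()
    return CodonFrequencies(values=vals, kind="F3x4")


def f61_frequencies(aln: CodonAlignment, pseudocount: float = 0.5) -> CodonFrequencies:
    """Empirical per-codon frequencies with a pseudocount."""
    code = aln.code
    counts = np.full(code.n_sense, pseudocount, dtype=float)
    for row in range(aln.n_sequences):
        seq = aln.rows[row]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) & {"N", "-"}:
                continue
            counts[code.codon_index[codon]] += 1
    return CodonFrequencies(values=counts / counts.sum(), kind="F61")


@dataclass(frozen=True)
class DiscreteRateDistribution:
    """A discrete distribution of rate factors with category weights."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rates, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)
        if r.shape != w.shape or r.ndim != 1:
            raise ParameterError("rates and weights must be 1-d and equally long")
        if np.any(r < 0) or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ParameterError("rates must be >= 0 and weights a unit-sum vector")

    @property
    def k(self) -> int:
        return len(self.rates)

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.rates))

    @property
    def variance(self) -> float:
        mu = self.mean
        return float(np.dot(self.weights, (self.rates - mu) ** 2))

    @property
    def cv(self) -> float:
        """Coefficient of variation sd/mean (error when the mean is 0)."""
        mu = self.mean
        if mu == 0:
            raise ParameterError("CV undefined: distribution mean is 0")
        return float(np.sqrt(self.variance) / mu)

    def normalized_to_mean_one(self) -> "DiscreteRateDistribution":
        mu = self.mean
        if mu == 0:
            raise ParameterError("cannot normalize a zero-mean distribution")
        return DiscreteRateDistribution(rates=self.rates / mu, weights=self.weights)


@dataclass(frozen=True)
class CodonSubstitutionParams:
    """Parameters of one codon rate matrix (one mixture category)."""

    kappa: float
    alpha: float  # synonymous rate factor (dS)
    beta: float  # nonsynonymous rate factor (dN)
    freqs: CodonFrequencies

    def __post_init__(self):
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be >= 0")

    @property
    def omega(self) -> float:
        if self.alpha == 0:
            raise ParameterError("omega undefined when alpha = 0")
        return self.beta / self.alpha


# ---------------------------------------------------------------------------
# Rate matrix construction
# ---------------------------------------------------------------------------

_PAIR_CACHE: dict[str, tuple] = {}


def _single_change_pairs(code: GeneticCode):
    """Index arrays over codon pairs differing at exactly one position."""
    if code.name in _PAIR_CACHE:
        return _PAIR_CACHE[code.name]
    ii, jj, syn, ts = [], [], [], []
    codons = code.sense_codons
    for i, a in enumerate(codons):
        for j, b in enumerate(codons):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            syn.append(code.translate(a) == code.translate(b))
            ts.append(is_transition(*diffs[0]))
    out = (
        np.array(ii),
        np.array(jj),
        np.array(syn, dtype=bool),
        np.array(ts, dtype=bool),
    )
    _PAIR_CACHE[code.name] = out
    return out


def _rate_matrix_parts(kappa: float, pi: np.ndarray, code: GeneticCode):
    """Unscaled syn and nonsyn parts of Q plus the reference scale.

    The reference scale is the expected rate per codon site when
    ``alpha = beta = 1`` (with the given kappa and frequencies); the
    final matrix is divided by it so branch lengths are expected
    substitutions per codon site at the neutral reference.
    """
    n = len(pi)
    ii, jj, syn, ts = _single_change_pairs(code)
    vals = pi[jj] * np.where(ts, kappa, 1.0)
    syn_part = np.zeros((n, n))
    nonsyn_part = np.zeros((n, n))
    syn_part[ii[syn], jj[syn]] = vals[syn]
    nonsyn_part[ii[~syn], jj[~syn]] = vals[~syn]
    ref = syn_part + nonsyn_part
    scale = float(np.dot(pi, ref.sum(axis=1)))
    return syn_part, nonsyn_part, scale


def build_rate_matrix(params: CodonSubstitutionParams, code: GeneticCode | None = None) -> np.ndarray:
    """The scaled instantaneous rate matrix Q for one category."""
    code = code or standard_code()
    pi = params.freqs.values
    if np.any(pi <= 0):
        raise ParameterError("all codon frequencies must be strictly positive")
    syn_part, nonsyn_part, scale = _rate_matrix_parts(params.kappa, pi, code)
    q = (params.alpha * syn_part + params.beta * nonsyn_part) / scale
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _eigensystem(q: np.ndarray, pi: np.ndarray):
    """Eigendecomposition of a time-reversible Q via symmetrization."""
    sqrt_pi = np.sqrt(pi)
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    sym = 0.5 * (sym + sym.T)
    lam, u = np.linalg.eigh(sym)
    a = u / sqrt_pi[:, None]
    b = u.T * sqrt_pi[None, :]
    return lam, a, b


def transition_matrix(params: CodonSubstitutionParams, t: float, code: GeneticCode | None = None) -> np.ndarray:
    """P(t) = exp(Qt) for one category (convenience path)."""
    q = build_rate_matrix(params, code)
    lam, a, b = _eigensystem(q, params.freqs.values)
    p = (a * np.exp(lam * t)[None, :]) @ b
    return np.maximum(p, 0.0)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


class PruningEngine:
    """Felsenstein pruning over compressed site patterns.

    Gap and ``N`` characters (and codons mixing gaps with bases) are
    treated as fully missing and marginalized.  Likelihoods are
    rescaled per internal node to avoid underflow.
    """

    def __init__(
        self,
        aln: CodonAlignment,
        tree: PhyloTree,
        freqs: CodonFrequencies | None = None,
    ):
        check_tree_matches_alignment(tree, aln)
        self.aln = aln
        self.code = aln.code
        self.tree = tree
        self.freqs = freqs or f3x4_frequencies(aln)
        self.pi = self.freqs.values

        nodes = tree.postorder()
        self.nodes = nodes
        index = {id(n): i for i, n in enumerate(nodes)}
        self.children = [
            [index[id(c)] for c in n.children] for n in nodes
        ]
        self.base_lengths = np.array(
            [0.0 if n is tree.root else n.length for n in nodes]
        )
        self.is_leaf = np.array([n.is_leaf for n in nodes])
        self.root_index = index[id(tree.root)]

        # site patterns: integer state per (leaf, site); -1 = missing
        row_of = {name: r for r, name in enumerate(aln.ids)}
        leaf_ids = [i for i, n in enumerate(nodes) if n.is_leaf]
        n_sites = aln.n_codons
        states = np.empty((len(leaf_ids), n_sites), dtype=np.int64)
        for k, node_i in enumerate(leaf_ids):
            row = row_of[nodes[node_i].name]
            seq = aln.rows[row]
            for s in range(n_sites):
                codon = seq[3 * s : 3 * s + 3]
                if set(codon) & {"N", "-"}:
                    states[k, s] = -1
                else:
                    states[k, s] = self.code.codon_index[codon]
        patterns, inverse, counts = np.unique(
            states, axis=1, return_inverse=True, return_counts=True
        )
        self.pattern_counts = counts.astype(float)
        self.pattern_inverse = inverse
        self.n_patterns = patterns.shape[1]
        self.leaf_states = {
            node_i: patterns[k] for k, node_i in enumerate(leaf_ids)
        }

    # -- helpers ----------------------------------------------------------

    def tree_with_lengths(self, lengths: np.ndarray) -> PhyloTree:
        """A copy of the engine's tree with the given per-node branch lengths."""

        def _build(i: int) -> TreeNode:
            n = self.nodes[i]
            return TreeNode(
                name=n.name,
                length=0.0 if i == self.root_index else float(lengths[i]),
                children=[_build(c) for c in self.children[i]],
            )

        return PhyloTree(root=_build(self.root_index))

    def _mixture_arrays(self, mixture):
        kappas = np.array([p.kappa for p, _ in mixture])
        alphas = np.array([p.alpha for p, _ in mixture])
        betas = np.array([p.beta for p, _ in mixture])
        weights = np.array([w for _, w in mixture], dtype=float)
        if not np.isclose(weights.sum(), 1.0):
            raise ParameterError("mixture weights must sum to 1")
        return kappas, alphas, betas, weights

    def pattern_log_likelihoods(
        self,
        mixture,
        edge_lengths: np.ndarray | None = None,
        scale: float = 1.0,
    ) -> np.ndarray:
        """Log-likelihood of each compressed site pattern under the mixture."""
        kappas, alphas, betas, weights = self._mixture_arrays(mixture)
        n_cat = len(kappas)
        pi = self.pi
        n = len(pi)

        lengths = self.base_lengths if edge_lengths is None else edge_lengths
        t = np.asarray(lengths, dtype=float) * scale

        # eigendecompositions, batched over categories
        lam = np.empty((n_cat, n))
        amat = np.empty((n_cat, n, n))
        bmat = np.empty((n_cat, n, n))
        cache: dict[tuple, tuple] = {}
        for c in range(n_cat):
            key = (kappas[c], alphas[c], betas[c])
            if key not in cache:
                q = build_rate_matrix(
                    CodonSubstitutionParams(
                        kappa=kappas[c], alpha=alphas[c], beta=betas[c], freqs=self.freqs
                    ),
                    self.code,
                )
                cache[key] = _eigensystem(q, pi)
            lam[c], amat[c], bmat[c] = cache[key]

        # transition matrices for every (category, node-edge)
        explam = np.exp(lam[:, None, :] * t[None, :, None])  # (C, V, n)
        p = np.matmul(amat[:, None, :, :] * explam[:, :, None, :], bmat[:, None, :, :])
        np.maximum(p, 0.0, out=p)
        pt = np.ascontiguousarray(p.transpose(0, 1, 3, 2))  # PT[c,v] = P[c,v].T

        n_pat = self.n_patterns
        log_scale = np.zeros((n_cat, n_pat))
        partials: dict[int, np.ndarray] = {}

        for i, node in enumerate(self.nodes):
            if self.is_leaf[i]:
                continue
            part = np.ones((n_cat, n_pat, n))
            for ci in self.children[i]:
                if self.is_leaf[ci]:
                    states = self.leaf_states[ci]
                    contrib = pt[:, ci][:, np.maximum(states, 0), :]
                    if np.any(states < 0):
                        contrib[:, states < 0, :] = 1.0
                else:
                    contrib = np.matmul(partials.pop(ci), pt[:, ci])
                part *= contrib
            m = part.max(axis=2)
            safe = np.where(m > 0, m, 1.0)
            part /= safe[:, :, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(m > 0, np.log(safe), -np.inf)
            partials[i] = part

        root_part = partials[self.root_index]
        site_lik = root_part @ pi  # (C, n_pat)
        with np.errstate(divide="ignore"):
            lnl_cat = np.log(site_lik) + log_scale
            pattern_lnl = logsumexp(
                np.log(weights)[:, None] + lnl_cat, axis=0
            )
        if np.any(np.isneginf(pattern_lnl)) or np.any(np.isnan(pattern_lnl)):
            raise DegenerateInputError(
                "a site pattern has zero likelihood under every mixture category"
            )
        return pattern_lnl

    def log_likelihood(self, mixture, edge_lengths=None, scale: float = 1.0) -> float:
        pattern_lnl = self.pattern_log_likelihoods(mixture, edge_lengths, scale)
        return float(np.dot(pattern_lnl, self.pattern_counts))

    def site_log_likelihoods(self, mixture, edge_lengths=None, scale: float = 1.0) -> np.ndarray:
        """Per-site (uncompressed) log-likelihoods."""
        pattern_lnl = self.pattern_log_likelihoods(mixture, edge_lengths, scale)
        return pattern_lnl[self.pattern_inverse]


def log_likelihood(aln: CodonAlignment, tree: PhyloTree, mixture, freqs=None) -> float:
    """Mixture log-likelihood of an alignment on a tree (one-shot API)."""
    return PruningEngine(aln, tree, freqs=freqs).log_likelihood(mixture)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------


def multistart_optimize(
    objective,
    x0,
    bounds=None,
    n_restarts: int = 1,
    seed: int | None = None,
    jitter: float = 0.5,
    maxfun: int = 2000,
    free_mask=None,
):
    """Maximize ``objective`` from ``n_restarts`` jittered starts.

    The first start is ``x0`` itself; later starts add uniform noise
    of half-width ``jitter`` to every free coordinate (coordinates are
    log rates or weight logits, so this multiplies rates by roughly
    ``exp(U(-jitter, jitter))``).  Deterministic given ``seed``.
    Returns ``(best_x, best_value, restart_log)`` where the log holds
    one ``(value, success)`` pair per restart.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    x0 = np.asarray(x0, dtype=float)
    rng = np.random.default_rng(seed)
    mask = np.ones(len(x0), dtype=bool) if free_mask is None else np.asarray(free_mask)

    def neg(theta_free):
        theta = x0.copy()
        theta[mask] = theta_free
        return -objective(theta)

    sub_bounds = None
    if bounds is not None:
        sub_bounds = [b for b, m in zip(bounds, mask) if m]

    best_x, best_val, log = None, -np.inf, []
    for r in range(n_restarts):
        start = x0[mask].copy()
        if r > 0:
            start = start + rng.uniform(-jitter, jitter, size=start.shape)
            if sub_bounds is not None:
                lo = np.array([b[0] for b in sub_bounds])
                hi = np.array([b[1] for b in sub_bounds])
                start = np.clip(start, lo, hi)
        res = optimize.minimize(
            neg,
            start,
            method="L-BFGS-B",
            bounds=sub_bounds,
            options={"maxfun": maxfun, "ftol": 1e-11, "gtol": 1e-7},
        )
        log.append((-res.fun, bool(res.success)))
        if -res.fun > best_val:
            best_val = -res.fun
            best_x = res.x
    if best_x is None:
        raise RuntimeError("all optimization restarts failed")
    full = x0.copy()
    full[mask] = best_x
    return full, best_val, log


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

_LN_KAPPA_BOUNDS = (np.log(0.05), np.log(50.0))
_LN_OMEGA_BOUNDS = (np.log(1e-8), np.log(60.0))
_LN_RATE_BOUNDS = (np.log(1e-4), np.log(50.0))
_LOGIT_BOUNDS = (-12.0, 12.0)


@dataclass
class ModelFit:
    """Result of fitting one codon site-model to one family."""

    model: str
    lnL: float
    kappa: float
    syn_dist: DiscreteRateDistribution
    nonsyn_dist: DiscreteRateDistribution
    tree: PhyloTree
    freqs: CodonFrequencies
    n_restarts: int = 1
    converged: bool = True
    flags: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)
    restart_log: tuple = ()

    def __post_init__(self):
        if not np.isfinite(self.lnL):
            raise ParameterError("log-likelihood must be finite")

    @property
    def omega(self) -> float:
        """Mean omega over categories (for M0 the single estimate)."""
        syn_mean = self.syn_dist.mean
        return float(self.nonsyn_dist.mean / syn_mean)

    def mixture(self):
        """The (params, weight) mixture this fit represents."""
        out = []
        for s, ws in zip(self.syn_dist.rates, self.syn_dist.weights):
            for nrate, wn in zip(self.nonsyn_dist.rates, self.nonsyn_dist.weights):
                out.append(
                    (
                        CodonSubstitutionParams(
                            kappa=self.kappa, alpha=float(s), beta=float(nrate), freqs=self.freqs
                        ),
                        float(ws * wn),
                    )
                )
        return out

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "lnL": self.lnL,
            "kappa": self.kappa,
            "syn_rates": self.syn_dist.rates.tolist(),
            "syn_weights": self.syn_dist.weights.tolist(),
            "nonsyn_rates": self.nonsyn_dist.rates.tolist(),
            "nonsyn_weights": self.nonsyn_dist.weights.tolist(),
            "tree": self.tree.newick(),
            "frequency_model": self.freqs.kind,
            "n_restarts": self.n_restarts,
            "converged": self.converged,
            "flags": list(self.flags),
            "extras": {k: v for k, v in self.extras.items()},
            "restart_log": [list(r) for r in self.restart_log],
        }
        return json.dumps(payload, indent=1)


def _informative_flags(aln: CodonAlignment) -> tuple[str, ...]:
    if len(set(aln.rows)) < 2:
        return ("uninformative",)
    return ()


def _softmax_weights(logits: np.ndarray) -> np.ndarray:
    return softmax(np.concatenate([[0.0], logits]))


def _weights_to_logits(weights: np.ndarray) -> np.ndarray:
    logw = np.log(np.maximum(weights, 1e-10))
    return logw[1:] - logw[0]


def _collapse_flags(rates: np.ndarray, tol: float = 1e-6) -> tuple[str, ...]:
    r = np.sort(rates)
    if np.any(np.diff(r) < tol):
        return ("category-collapse",)
    return ()


def fit_M0(
    aln: CodonAlignment,
    tree: PhyloTree,
    freqs: CodonFrequencies | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    optimize_branch_lengths: bool = True,
    branch_rounds: int = 1,
) -> ModelFit:
    """Fit M0: one omega for all sites and times.

    Branch lengths are optimized as a joint scaling of the input tree
    followed by ``branch_rounds`` sweeps of per-branch refinement; the
    fitted lengths are meant to be reused (fixed) by the site-model fits.
    """
    engine = PruningEngine(aln, tree, freqs=freqs)
    flags = _informative_flags(aln)

    def theta_to_model(theta):
        kappa, omega, scale = np.exp(theta)
        mixture = [
            (CodonSubstitutionParams(kappa=kappa, alpha=1.0, beta=omega, freqs=engine.freqs), 1.0)
        ]
        return mixture, scale

    def objective(theta):
        mixture, scale = theta_to_model(theta)
        try:
            return engine.log_likelihood(mixture, scale=scale)
        except DegenerateInputError:
            return -1e12

    x0 = np.array([np.log(2.0), np.log(0.5), 0.0])
    bounds = [_LN_KAPPA_BOUNDS, _LN_OMEGA_BOUNDS, (np.log(1e-3), np.log(1e3))]
    best, best_lnl, log = multistart_optimize(
        objective, x0, bounds=bounds, n_restarts=n_restarts, seed=seed
    )
    kappa, omega, scale = np.exp(best)
    lengths = engine.base_lengths * scale

    if optimize_branch_lengths and branch_rounds > 0:
        mixture, _ = theta_to_model(best)
        for _round in range(branch_rounds):
            for i in range(len(lengths)):
                if i == engine.root_index:
                    continue

                def edge_obj(bl, i=i):
                    trial = lengths.copy()
                    trial[i] = bl
                    return -engine.log_likelihood(mixture, edge_lengths=trial)

                res = optimize.minimize_scalar(
                    edge_obj, bounds=(1e-8, 60.0), method="bounded",
                    options={"xatol": 1e-6, "maxiter": 40},
                )
                lengths[i] = res.x
        # re-polish kappa and omega at the refined branch lengths
        def obj2(theta2):
            kap, om = np.exp(theta2)
            mix = [
                (CodonSubstitutionParams(kappa=kap, alpha=1.0, beta=om, freqs=engine.freqs), 1.0)
            ]
            try:
                return engine.log_likelihood(mix, edge_lengths=lengths)
            except DegenerateInputError:
                return -1e12

        best2, best_lnl, log2 = multistart_optimize(
            obj2, np.log([kappa, omega]), bounds=bounds[:2], n_restarts=1
        )
        kappa, omega = np.exp(best2)
        log = log + log2

    fitted_tree = engine.tree_with_lengths(lengths)
    return ModelFit(
        model="M0",
        lnL=best_lnl,
        kappa=float(kappa),
        syn_dist=DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0])),
        nonsyn_dist=DiscreteRateDistribution(rates=np.array([omega]), weights=np.array([1.0])),
        tree=fitted_tree,
        freqs=engine.freqs,
        n_restarts=n_restarts,
        converged=any(s for _, s in log),
        flags=flags,
        extras={"branch_scale": float(scale)},
        restart_log=tuple(log),
    )


def fit_M3(
    aln: CodonAlignment,
    tree: PhyloTree,
    k: int = 3,
    freqs: CodonFrequencies | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    start_kappa: float = 2.0,
    start_omegas: np.ndarray | None = None,
) -> ModelFit:
    """Fit M3: k free omega classes with free proportions, constant dS.

    Branch lengths of ``tree`` (normally the M0 fit's tree) are fixed.
    With ``k=1`` the model is exactly M0 at fixed branch lengths.
    """
    engine = PruningEngine(aln, tree, freqs=freqs)
    flags = _informative_flags(aln)

    if start_omegas is None:
        start_omegas = np.geomspace(0.05, 1.5, k) if k > 1 else np.array([0.5])

    def theta_to_mixture(theta):
        kappa = np.exp(theta[0])
        omegas = np.exp(theta[1 : 1 + k])
        weights = _softmax_weights(theta[1 + k :])
        return [
            (CodonSubstitutionParams(kappa=kappa, alpha=1.0, beta=o, freqs=engine.freqs), w)
            for o, w in zip(omegas, weights)
        ]

    def objective(theta):
        try:
            return engine.log_likelihood(theta_to_mixture(theta))
        except DegenerateInputError:
            return -1e12

    x0 = np.concatenate([[np.log(start_kappa)], np.log(start_omegas), np.zeros(k - 1)])
    bounds = (
        [_LN_KAPPA_BOUNDS] + [_LN_OMEGA_BOUNDS] * k + [_LOGIT_BOUNDS] * (k - 1)
    )
    best, best_lnl, log = multistart_optimize(
        objective, x0, bounds=bounds, n_restarts=n_restarts, seed=seed
    )
    kappa = float(np.exp(best[0]))
    omegas = np.exp(best[1 : 1 + k])
    weights = _softmax_weights(best[1 + k :])
    return ModelFit(
        model="M3",
        lnL=best_lnl,
        kappa=kappa,
        syn_dist=DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0])),
        nonsyn_dist=DiscreteRateDistribution(rates=omegas, weights=weights),
        tree=tree,
        freqs=engine.freqs,
        n_restarts=n_restarts,
        converged=any(s for _, s in log),
        flags=flags + _collapse_flags(omegas),
        extras={"k": k},
        restart_log=tuple(log),
    )


def _beta_category_omegas(p: float, q: float, ncat: int) -> np.ndarray:
    """Equal-probability discretization of Beta(p, q) at quantile midpoints."""
    probs = (np.arange(ncat) + 0.5) / ncat
    return stats.beta.ppf(probs, p, q)


def fit_M7(
    aln: CodonAlignment,
    tree: PhyloTree,
    ncat: int = 10,
    freqs: CodonFrequencies | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
) -> ModelFit:
    """Fit M7: omega ~ Beta(p, q) discretized into equal-weight categories."""
    engine = PruningEngine(aln, tree, freqs=freqs)
    flags = _informative_flags(aln)
    ln_pq_bounds = (np.log(0.005), np.log(99.0))

    def theta_to_mixture(theta):
        kappa = np.exp(theta[0])
        p, q = np.exp(theta[1:3])
        omegas = _beta_category_omegas(p, q, ncat)
        w = 1.0 / ncat
        return [
            (CodonSubstitutionParams(kappa=kappa, alpha=1.0, beta=float(o), freqs=engine.freqs), w)
            for o in omegas
        ]

    def objective(theta):
        try:
            return engine.log_likelihood(theta_to_mixture(theta))
        except DegenerateInputError:
            return -1e12

    x0 = np.array([np.log(2.0), np.log(0.5), np.log(1.5)])
    bounds = [_LN_KAPPA_BOUNDS, ln_pq_bounds, ln_pq_bounds]
    best, best_lnl, log = multistart_optimize(
        objective, x0, bounds=bounds, n_restarts=n_restarts, seed=seed
    )
    kappa = float(np.exp(best[0]))
    p, q = np.exp(best[1:3])
    omegas = _beta_category_omegas(p, q, ncat)
    weights = np.full(ncat, 1.0 / ncat)
    return ModelFit(
        model="M7",
        lnL=best_lnl,
        kappa=kappa,
        syn_dist=DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0])),
        nonsyn_dist=DiscreteRateDistribution(rates=omegas, weights=weights),
        tree=tree,
        freqs=engine.freqs,
        n_restarts=n_restarts,
        converged=any(s for _, s in log),
        flags=flags,
        extras={"p": float(p), "q": float(q), "ncat": ncat},
        restart_log=tuple(log),
    )


def fit_M8(
    aln: CodonAlignment,
    tree: PhyloTree,
    ncat: int = 10,
    freqs: CodonFrequencies | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    start_from: ModelFit | None = None,
) -> ModelFit:
    """Fit M8: discretized Beta(p, q) plus an extra class with omega_s >= 1.

    ``p1`` is the proportion of sites in the extra (positive-selection)
    class.  Estimates with ``p1`` near its zero boundary are flagged;
    the chi-square calibration of the M7-vs-M8 LRT is then conservative.
    """
    engine = PruningEngine(aln, tree, freqs=freqs)
    flags = _informative_flags(aln)
    ln_pq_bounds = (np.log(0.005), np.log(99.0))

    def theta_to_mixture(theta):
        kappa = np.exp(theta[0])
        p, q = np.exp(theta[1:3])
        p1 = expit(theta[3])
        omega_s = 1.0 + np.exp(theta[4])
        omegas = _beta_category_omegas(p, q, ncat)
        w0 = (1.0 - p1) / ncat
        mixture = [
            (CodonSubstitutionParams(kappa=kappa, alpha=1.0, beta=float(o), freqs=engine.freqs), w0)
            for o in omegas
        ]
        mixture.append(
            (
                CodonSubstitutionParams(kappa=kappa, alpha=1.0, beta=float(omega_s), freqs=engine.freqs),
                float(p1),
            )
        )
        return mixture

    def objective(theta):
        try:
            return engine.log_likelihood(theta_to_mixture(theta))
        except DegenerateInputError:
            return -1e12

    if start_from is not None and start_from.model == "M7":
        x0 = np.array(
            [
                np.log(start_from.kappa),
                np.log(start_from.extras["p"]),
                np.log(start_from.extras["q"]),
                np.log(0.05 / 0.95),
                np.log(1.0),  # omega_s = 2
            ]
        )
    else:
        x0 = np.array([np.log(2.0), np.log(0.5), np.log(1.5), np.log(0.05 / 0.95), np.log(1.0)])
    bounds = [
        _LN_KAPPA_BOUNDS,
        ln_pq_bounds,
        ln_pq_bounds,
        (-12.0, 6.0),
        (-10.0, 3.5),
    ]
    best, best_lnl, log = multistart_optimize(
        objective, x0, bounds=bounds, n_restarts=n_restarts, seed=seed
    )
    kappa = float(np.exp(best[0]))
    p, q = np.exp(best[1:3])
    p1 = float(expit(best[3]))
    omega_s = float(1.0 + np.exp(best[4]))
    omegas = np.concatenate([_beta_category_omegas(p, q, ncat), [omega_s]])
    weights = np.concatenate([np.full(ncat, (1.0 - p1) / ncat), [p1]])
    boundary = ("boundary-p1",) if p1 < 1e-3 else ()
    return ModelFit(
        model="M8",
        lnL=best_lnl,
        kappa=kappa,
        syn_dist=DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0])),
        nonsyn_dist=DiscreteRateDistribution(rates=omegas, weights=weights),
        tree=tree,
        freqs=engine.freqs,
        n_restarts=n_restarts,
        converged=any(s for _, s in log),
        flags=flags + boundary,
        extras={"p": float(p), "q": float(q), "p1": p1, "omega_s": omega_s, "ncat": ncat},
        restart_log=tuple(log),
    )


def fit_DUAL(
    aln: CodonAlignment,
    tree: PhyloTree,
    k_syn: int = 3,
    k_nonsyn: int = 3,
    freqs: CodonFrequencies | None = None,
    n_restarts: int = 3,
    seed: int | None = None,
    start_from: ModelFit | None = None,
    kappa: float | None = None,
    two_stage: bool = True,
) -> ModelFit:
    """Fit the DUAL model: independent discrete dS and dN distributions.

    Site rates are drawn from the product grid of a ``k_syn``-category
    synonymous distribution (constrained to mean one) and a
    ``k_nonsyn``-category nonsynonymous distribution with absolute
    rates.  Pass a fitted M3 as ``start_from`` to seed the dN side;
    pass ``kappa`` to keep the transition/transversion ratio fixed at a
    previously estimated value instead of re-estimating it.

    With ``k_syn=1`` the model reduces exactly to M3.
    """
    engine = PruningEngine(aln, tree, freqs=freqs)
    flags = _informative_flags(aln)
    fixed_kappa = kappa is not None

    # theta layout: [ln kappa, ln r_2..r_ks, z_syn x (ks-1), ln n_1..n_kn, z_n x (kn-1)]
    n_syn_r = k_syn - 1
    n_syn_z = k_syn - 1
    i_syn_r = 1
    i_syn_z = i_syn_r + n_syn_r
    i_n_r = i_syn_z + n_syn_z
    i_n_z = i_n_r + k_nonsyn
    n_theta = i_n_z + (k_nonsyn - 1)

    def decode(theta):
        kap = kappa if fixed_kappa else float(np.exp(theta[0]))
        raw = np.concatenate([[1.0], np.exp(theta[i_syn_r:i_syn_z])])
        w_syn = _softmax_weights(theta[i_syn_z:i_n_r])
        s = raw / np.dot(w_syn, raw)  # mean-one constraint
        n_rates = np.exp(theta[i_n_r:i_n_z])
        w_n = _softmax_weights(theta[i_n_z:])
        return kap, s, w_syn, n_rates, w_n

    def theta_to_mixture(theta):
        kap, s, w_syn, n_rates, w_n = decode(theta)
        mixture = []
        for si, wsi in zip(s, w_syn):
            for nj, wnj in zip(n_rates, w_n):
                mixture.append(
                    (
                        CodonSubstitutionParams(
                            kappa=kap, alpha=float(si), beta=float(nj), freqs=engine.freqs
                        ),
                        float(wsi * wnj),
                    )
                )
        return mixture

    def objective(theta):
        try:
            return engine.log_likelihood(theta_to_mixture(theta))
        except DegenerateInputError:
            return -1e12

    # starting values
    x0 = np.zeros(n_theta)
    if start_from is not None:
        x0[0] = np.log(start_from.kappa)
        kn = min(k_nonsyn, start_from.nonsyn_dist.k)
        start_n = np.full(k_nonsyn, 0.5)
        start_n[:kn] = np.maximum(start_from.nonsyn_dist.rates[:kn], 1e-6)
        x0[i_n_r:i_n_z] = np.log(start_n)
        if start_from.nonsyn_dist.k == k_nonsyn:
            x0[i_n_z:] = _weights_to_logits(start_from.nonsyn_dist.weights)
    else:
        x0[0] = np.log(2.0)
        x0[i_n_r:i_n_z] = np.log(np.geomspace(0.05, 1.5, k_nonsyn))
    # mild initial spread on the dS side
    if n_syn_r > 0:
        x0[i_syn_r:i_syn_z] = np.log(np.geomspace(0.6, 1.6, k_syn)[1:])

    bounds = (
        [_LN_KAPPA_BOUNDS]
        + [_LN_RATE_BOUNDS] * n_syn_r
        + [_LOGIT_BOUNDS] * n_syn_z
        + [_LN_OMEGA_BOUNDS] * k_nonsyn
        + [_LOGIT_BOUNDS] * (k_nonsyn - 1)
    )

    log = []
    if two_stage and start_from is not None and k_syn > 1:
        # stage 1: optimize the dS side only, dN side frozen at the M3 start
        mask = np.zeros(n_theta, dtype=bool)
        mask[i_syn_r:i_n_r] = True
        x0, _, log1 = multistart_optimize(
            objective, x0, bounds=bounds, n_restarts=1, free_mask=mask
        )
        log.extend(log1)

    mask = np.ones(n_theta, dtype=bool)
    if fixed_kappa:
        mask[0] = False
    best, best_lnl, log2 = multistart_optimize(
        objective, x0, bounds=bounds, n_restarts=n_restarts, seed=seed, free_mask=mask
    )
    log.extend(log2)

    kap, s, w_syn, n_rates, w_n = decode(best)
    syn_dist = DiscreteRateDistribution(rates=s, weights=w_syn)
    nonsyn_dist = DiscreteRateDistribution(rates=n_rates, weights=w_n)
    return ModelFit(
        model="DUAL",
        lnL=best_lnl,
        kappa=float(kap),
        syn_dist=syn_dist,
        nonsyn_dist=nonsyn_dist,
        tree=tree,
        freqs=engine.freqs,
        n_restarts=n_restarts,
        converged=any(s_ for _, s_ in log2),
        flags=flags + _collapse_flags(s) + _collapse_flags(n_rates),
        extras={"k_syn": k_syn, "k_nonsyn": k_nonsyn, "kappa_fixed": fixed_kappa},
        restart_log=tuple(log),
    )
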