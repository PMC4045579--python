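import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from srvscan import codon_engine as ce
from srvscan import synthetic_data as sd
from srvscan.codes import is_transition, standard_code
from srvscan.seqio import alignment_from_strings, parse_newick


def make_params(kappa=2.0, alpha=1.0, beta=0.5, freqs=None):
    freqs = freqs or ce.uniform_frequencies()
    return ce.CodonSubstitutionParams(kappa=kappa, alpha=alpha, beta=beta, freqs=freqs)


def reference_rate_matrix(kappa, alpha, beta, pi, code):
    """Independent element-by-element reconstruction of the scaled Q."""
    n = len(pi)
    codons = code.sense_codons
    q = np.zeros((n, n))
    ref = np.zeros((n, n))
    for i, a in enumerate(codons):
        for j, b in enumerate(codons):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            rate = pi[j] * (kappa if is_transition(*diffs[0]) else 1.0)
            ref[i, j] = rate
            syn = code.translate(a) == code.translate(b)
            q[i, j] = rate * (alpha if syn else beta)
    scale = sum(pi[i] * ref[i].sum() for i in range(n))
    q /= scale
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class TestRateMatrix:
    def test_beta_zero_kills_nonsynonymous_rates(self, code):
        q = ce.build_rate_matrix(make_params(beta=0.0))
        codons = code.sense_codons
        for i, j in zip(*np.nonzero(q)):
            if i == j:
                continue
            assert code.translate(codons[i]) == code.translate(codons[j])

    def test_uniform_neutral_entries_equal(self, code):
        q = ce.build_rate_matrix(make_params(kappa=1.0, alpha=1.0, beta=1.0))
        off = q[~np.eye(len(q), dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_matches_reconstruction_stationarity_reversibility(self, code, rng):
        pi = rng.dirichlet(np.ones(61))
        freqs = ce.CodonFrequencies(values=pi)
        kappa, alpha, beta = 3.1, 0.8, 0.25
        q = ce.build_rate_matrix(make_params(kappa, alpha, beta, freqs))
        q_ref = reference_rate_matrix(kappa, alpha, beta, pi, code)
        assert np.allclose(q, q_ref, atol=1e-12)
        assert np.allclose(pi @ q, 0.0, atol=1e-12)
        assert np.allclose(pi[:, None] * q, (pi[:, None] * q).T, atol=1e-12)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_reference_scaling_gives_unit_rate(self):
        # at alpha=beta=1 the expected substitution rate per codon is 1
        params = make_params(kappa=2.5, alpha=1.0, beta=1.0)
        q = ce.build_rate_matrix(params)
        pi = params.freqs.values
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_frequency_rejected(self):
        vals = np.zeros(61)
        vals[0] = 1.0
        with pytest.raises(ce.ParameterError):
            ce.build_rate_matrix(make_params(freqs=ce.CodonFrequencies(values=vals)))

    @pytest.mark.parametrize("t", [0.0, 0.01, 0.5, 2.0, 10.0])
    def test_transition_matrix_is_stochastic(self, t):
        p = ce.transition_matrix(make_params(kappa=3.0, alpha=1.3, beta=0.2), t)
        assert np.all(p >= -1e-12)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_transition_matrix_matches_scipy_expm(self):
        params = make_params(kappa=2.0, alpha=0.7, beta=1.4)
        q = ce.build_rate_matrix(params)
        assert np.allclose(ce.transition_matrix(params, 0.37), expm(q * 0.37), atol=1e-10)


def brute_force_loglik(aln, tree, mixture, pi):
    """Sum over all internal-node codon assignments, site by site."""
    code = aln.code
    nodes = tree.postorder()
    row_of = {name: r for r, name in enumerate(aln.ids)}
    internals = [nd for nd in nodes if not nd.is_leaf]
    n = len(pi)
    total = 0.0
    p_cache = {}
    for params, _ in mixture:
        for node in nodes:
            if node is not tree.root:
                q = ce.build_rate_matrix(params, code)
                p_cache[(id(params), id(node))] = expm(q * node.length)
    for s in range(aln.n_codons):
        site_lik = 0.0
        for params, w in mixture:
            lik = 0.0
            for assign in itertools.product(range(n), repeat=len(internals)):
                state = {id(nd): a for nd, a in zip(internals, assign)}
                for leaf in tree.leaves():
                    codon = aln.codon(row_of[leaf.name], s)
                    state[id(leaf)] = code.codon_index[codon]
                pr = pi[state[id(tree.root)]]
                stack = [tree.root]
                while stack:
                    node = stack.pop()
                    for child in node.children:
                        pr *= p_cache[(id(params), id(child))][
                            state[id(node)], state[id(child)]
                        ]
                        stack.append(child)
                lik += pr
            site_lik += w * lik
        total += np.log(site_lik)
    return total


class TestPruningLikelihood:
    def test_identical_sequences_zero_tree(self):
        aln = alignment_from_strings(">a\nATGTTT\n>b\nATGTTT\n")
        tree = parse_newick("(a:0.0,b:0.0);")
        eng = ce.PruningEngine(aln, tree, freqs=ce.uniform_frequencies())
        lnl = eng.log_likelihood([(make_params(), 1.0)])
        assert lnl == pytest.approx(2 * np.log(1 / 61), abs=1e-10)

    def test_all_gap_site_contributes_zero(self):
        aln1 = alignment_from_strings(">a\nATG\n>b\nATG\n")
        aln2 = alignment_from_strings(">a\nATG---\n>b\nATG---\n")
        tree = parse_newick("(a:0.1,b:0.2);")
        mix = [(make_params(), 1.0)]
        lnl1 = ce.log_likelihood(aln1, tree, mix, freqs=ce.uniform_frequencies())
        lnl2 = ce.log_likelihood(aln2, tree, mix, freqs=ce.uniform_frequencies())
        assert lnl1 == pytest.approx(lnl2, abs=1e-12)

    @pytest.mark.parametrize("n_taxa", [3, 4, 5])
    def test_matches_brute_force_enumeration(self, n_taxa):
        spec = sd.SimulationSpec(n_taxa=n_taxa, n_codons=6, seed=7 + n_taxa,
                                 mean_branch_length=0.25)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        eng = ce.PruningEngine(aln, tree)
        mix = [
            (make_params(2.0, 1.0, 0.3, eng.freqs), 0.6),
            (make_params(2.0, 1.6, 1.1, eng.freqs), 0.4),
        ]
        assert eng.log_likelihood(mix) == pytest.approx(
            brute_force_loglik(aln, tree, mix, eng.freqs.values), abs=1e-8
        )

    def test_invariant_to_sequence_and_site_permutation(self, small_family):
        aln, tree, _ = small_family
        eng = ce.PruningEngine(aln, tree)
        mix = [(make_params(freqs=eng.freqs), 1.0)]
        base = eng.log_likelihood(mix)

        order = [2, 0, 3, 1]
        perm_aln = type(aln)(
            ids=tuple(aln.ids[i] for i in order),
            rows=tuple(aln.rows[i] for i in order),
            code=aln.code,
        )
        lnl_seq = ce.PruningEngine(perm_aln, tree, freqs=eng.freqs).log_likelihood(mix)
        assert lnl_seq == pytest.approx(base, abs=1e-9)

        rng = np.random.default_rng(0)
        sites = rng.permutation(aln.n_codons)
        rows = tuple(
            "".join(row[3 * s : 3 * s + 3] for s in sites) for row in aln.rows
        )
        site_aln = type(aln)(ids=aln.ids, rows=rows, code=aln.code)
        lnl_site = ce.PruningEngine(site_aln, tree, freqs=eng.freqs).log_likelihood(mix)
        assert lnl_site == pytest.approx(base, abs=1e-9)

    def test_mismatched_labels_rejected(self, small_family):
        aln, _, _ = small_family
        tree = parse_newick("(x:0.1,y:0.1,z:0.1);")
        with pytest.raises(Exception, match="mismatch"):
            ce.PruningEngine(aln, tree)


class TestFits:
    def test_m0_neutral_recovery(self):
        neutral = ce.DiscreteRateDistribution(rates=np.array([1.0]), weights=np.array([1.0]))
        spec = sd.SimulationSpec(n_taxa=6, n_codons=300, seed=11,
                                 mean_branch_length=0.1, nonsyn_dist=neutral)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        fit = ce.fit_M0(aln, tree, n_restarts=1, seed=0)
        assert abs(fit.omega - 1.0) < 0.15

    def test_m0_boundary_omega_zero(self):
        lethal = ce.DiscreteRateDistribution(rates=np.array([0.0]), weights=np.array([1.0]))
        spec = sd.SimulationSpec(n_taxa=5, n_codons=150, seed=13, nonsyn_dist=lethal)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        fit = ce.fit_M0(aln, tree, n_restarts=1, seed=0)
        assert fit.omega < 1e-3

    def test_m0_mle_beats_truth_on_grid(self, small_family):
        # optimizer-vs-grid: the fitted lnL tops a coarse 2-parameter grid
        aln, tree, truth = small_family
        fit = ce.fit_M0(aln, tree, n_restarts=1, seed=0)
        eng = ce.PruningEngine(aln, fit.tree, freqs=fit.freqs)
        for kappa in (0.5, 1.0, 2.0, 4.0, 8.0):
            for omega in (0.05, 0.2, 0.5, 1.0, 2.0):
                lnl = eng.log_likelihood(
                    [(make_params(kappa, 1.0, omega, fit.freqs), 1.0)]
                )
                assert lnl <= fit.lnL + 1e-6

    def test_m3_k1_reduces_to_m0(self, medium_family, medium_fits):
        aln, _, _ = medium_family
        m0 = medium_fits["M0"]
        # the single-category M3 likelihood at the M0 estimates is identical
        eng = ce.PruningEngine(aln, m0.tree, freqs=m0.freqs)
        lnl_as_m3 = eng.log_likelihood(m0.mixture())
        assert lnl_as_m3 == pytest.approx(m0.lnL, abs=1e-8)
        # and refitting with k=1 recovers the same optimum
        m3_k1 = ce.fit_M3(aln, m0.tree, k=1, n_restarts=1, seed=0)
        assert m3_k1.lnL == pytest.approx(m0.lnL, abs=1e-4)

    def test_m3_two_class_recovery(self):
        truth_dist = ce.DiscreteRateDistribution(
            rates=np.array([0.1, 1.5]), weights=np.array([0.7, 0.3])
        )
        spec = sd.SimulationSpec(n_taxa=8, n_codons=500, seed=21, nonsyn_dist=truth_dist)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        fit = ce.fit_M3(aln, tree, k=2, n_restarts=1, seed=0)
        est = np.sort(fit.nonsyn_dist.rates)
        assert abs(est[0] - 0.1) < 0.3
        assert abs(est[1] - 1.5) < 0.3

    def test_nesting_chain(self, medium_fits):
        tol = 1e-4
        assert medium_fits["M3"].lnL >= medium_fits["M0"].lnL - tol
        assert medium_fits["DUAL"].lnL >= medium_fits["M3"].lnL - tol

    def test_dual_k_syn_1_equals_m3(self, medium_family, medium_fits):
        aln, _, _ = medium_family
        m0, m3 = medium_fits["M0"], medium_fits["M3"]
        eng = ce.PruningEngine(aln, m0.tree, freqs=m3.freqs)
        lnl_as_dual = eng.log_likelihood(m3.mixture())
        assert lnl_as_dual == pytest.approx(m3.lnL, abs=1e-6)
        dual_k1 = ce.fit_DUAL(aln, m0.tree, k_syn=1, n_restarts=1, seed=0, start_from=m3)
        assert dual_k1.lnL == pytest.approx(m3.lnL, abs=1e-3)

    def test_dual_null_gives_no_srv_signal(self, medium_fits):
        """Constant-dS data: the extra dS spread a 3-category ML fit finds
        is statistically empty (tiny lnL gain), so the SRV LRT stays
        non-significant even when the point estimate of CV drifts off 0."""
        from srvscan.classify import classify_srv

        call, cv, test = classify_srv(medium_fits["M3"], medium_fits["DUAL"])
        assert call == "SRV-"
        assert test.p_value > 0.05
        assert cv >= 0.0

    def test_m7_m8_nesting_and_null_p1(self):
        spec = sd.SimulationSpec(n_taxa=6, n_codons=150, seed=31)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        m7 = ce.fit_M7(aln, tree, n_restarts=1, seed=0)
        m8 = ce.fit_M8(aln, tree, n_restarts=1, seed=0, start_from=m7)
        assert m8.lnL >= m7.lnL - 1e-4
        # simulated without positive selection: the M8 extra-class mass is tiny
        assert m8.extras["p1"] * aln.n_codons < 2.0

    def test_m8_recovers_planted_positive_selection(self):
        planted = ce.DiscreteRateDistribution(
            rates=np.array([0.1, 0.6, 3.0]), weights=np.array([0.5, 0.4, 0.1])
        )
        spec = sd.SimulationSpec(n_taxa=8, n_codons=400, seed=41, nonsyn_dist=planted)
        aln, truth = sd.simulate_alignment(spec)
        tree = parse_newick(truth.tree_newick)
        m7 = ce.fit_M7(aln, tree, n_restarts=1, seed=0)
        m8 = ce.fit_M8(aln, tree, n_restarts=1, seed=0, start_from=m7)
        assert m8.extras["omega_s"] > 1.0
        assert m8.lnL - m7.lnL > 2.0

    def test_uninformative_alignment_flagged(self):
        aln = alignment_from_strings(">a\nATGTTTAAA\n>b\nATGTTTAAA\n")
        tree = parse_newick("(a:0.05,b:0.05);")
        fit = ce.fit_M0(aln, tree, n_restarts=1, optimize_branch_lengths=False)
        assert "uninformative" in fit.flags


class TestMultistart:
    @staticmethod
    def bimodal(theta):
        # two Gaussian bumps; global optimum at +2, local at -2
        x = theta[0]
        return 1.0 * np.exp(-((x + 2) ** 2)) + 2.0 * np.exp(-((x - 2) ** 2))

    def test_single_restart_from_bad_basin_stays_local(self):
        x, val, _ = ce.multistart_optimize(
            self.bimodal, [-2.1], bounds=[(-6, 6)], n_restarts=1
        )
        assert x[0] == pytest.approx(-2.0, abs=0.05)

    def test_restarts_escape_to_global_optimum(self):
        x, val, log = ce.multistart_optimize(
            self.bimodal, [-2.1], bounds=[(-6, 6)], n_restarts=5, seed=4, jitter=3.0
        )
        assert x[0] == pytest.approx(2.0, abs=0.05)
        assert len(log) == 5

    def test_deterministic_given_seed(self):
        a = ce.multistart_optimize(self.bimodal, [-2.1], bounds=[(-6, 6)],
                                   n_restarts=3, seed=9, jitter=3.0)
        b = ce.multistart_optimize(self.bimodal, [-2.1], bounds=[(-6, 6)],
                                   n_restarts=3, seed=9, jitter=3.0)
        assert np.array_equal(a[0], b[0])
        assert a[1] == b[1]


class TestRecoveryScaling:
    def test_omega_rmse_shrinks_with_alignment_length(self):
        """RMSE of the M0 omega estimate at 1000 codons is below 100 codons."""
        true_omega = 0.4
        dist = ce.DiscreteRateDistribution(
            rates=np.array([true_omega]), weights=np.array([1.0])
        )
        rmse = {}
        for n_codons in (100, 1000):
            errs = []
            for rep in range(3):
                spec = sd.SimulationSpec(
                    n_taxa=6, n_codons=n_codons, seed=1000 + rep, nonsyn_dist=dist
                )
                aln, truth = sd.simulate_alignment(spec)
                tree = parse_newick(truth.tree_newick)
                fit = ce.fit_M0(aln, tree, n_restarts=1, seed=rep,
                                optimize_branch_lengths=False)
                errs.append((fit.omega - true_omega) ** 2)
            rmse[n_codons] = np.sqrt(np.mean(errs))
        assert rmse[1000] < rmse[100]
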