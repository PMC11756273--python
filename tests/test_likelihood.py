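import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from hetcheck.alignment import Alignment
from hetcheck.fixtures import FixtureSpec, generate_site_profiles, generate_tree
from hetcheck.likelihood import (
    average_site_profiles,
    compute_pmsf_profiles,
    read_site_profiles,
    site_likelihood_table,
    site_log_likelihood,
    total_log_likelihood,
    write_site_profiles,
)
from hetcheck.models import (
    ExchangeabilityMatrix,
    FrequencyProfile,
    HomogeneousModel,
    MixtureModel,
    SiteProfileModel,
    discrete_gamma_rates,
    regularize_freqs,
)
from hetcheck.simulate import SimulationRequest, simulate_alignment
from hetcheck.treeio import parse_newick


# ---------------------------------------------------------------------------
# Independent oracle: exhaustive sum over internal-node state assignments,
# with transition matrices from scipy's expm (not the package's spectral code).
# ---------------------------------------------------------------------------

def _oracle_rate_matrix(s, pi):
    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q / -(pi @ np.diag(Q))


def oracle_site_likelihood(tree, exch, pi, rate, column):
    """Sum over every assignment of states to internal nodes."""
    Q = _oracle_rate_matrix(exch.s, pi)
    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    P = {id(n): expm(Q * (float(n.edge.length) * rate)) for n in nodes if n.parent_node}
    total = 0.0
    for assign in itertools.product(range(20), repeat=len(internal)):
        state = {id(n): a for n, a in zip(internal, assign)}
        term = pi[state[id(nodes[0])]]
        for n in nodes[1:]:
            parent_state = state[id(n.parent_node)]
            if n.is_leaf():
                c = column[n.taxon.label]
                if c is None:  # gap
                    continue
                term *= P[id(n)][parent_state, c]
            else:
                term *= P[id(n)][parent_state, state[id(n)]]
        total += term
    return total


def _random_profile(seed, conc=0.5):
    return regularize_freqs(np.random.default_rng(seed).dirichlet(np.full(20, conc)))


ORACLE_TREES = [
    "(A:0.4,B:0.7,C:0.2);",
    "((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);",
    "((A:0.2,(B:0.3,C:0.1):0.2):0.1,(D:0.15,E:0.25):0.05);",
]


class TestPruningOracle:
    @pytest.mark.parametrize("newick", ORACLE_TREES)
    @pytest.mark.parametrize("exch_name", ["poisson", "lg"])
    def test_matches_exhaustive_enumeration(self, newick, exch_name):
        tree = parse_newick(newick)
        exch = getattr(ExchangeabilityMatrix, exch_name)()
        rng = np.random.default_rng(hash((newick, exch_name)) % 2**31)
        pi = _random_profile(int(rng.integers(2**31)))
        gamma = discrete_gamma_rates(0.8, 2)
        model = HomogeneousModel(exch, FrequencyProfile(pi), gamma)
        residues = "ARNDC"
        column = {t: residues[i % 5] for i, t in enumerate(tree.leaf_labels)}
        got = site_log_likelihood(tree, model, column)
        col_idx = {t: "ARNDCQEGHILKMFPSTWYV".index(c) for t, c in column.items()}
        lik = np.mean(
            [oracle_site_likelihood(tree, exch, pi, r, col_idx) for r in gamma.category_rates]
        )
        assert got == pytest.approx(np.log(lik), abs=1e-9)

    def test_mixture_matches_enumeration(self):
        tree = parse_newick(ORACLE_TREES[1])
        exch = ExchangeabilityMatrix.poisson()
        gamma = discrete_gamma_rates(1.2, 2)
        pis = [_random_profile(1), _random_profile(2)]
        weights = np.array([0.3, 0.7])
        model = MixtureModel(exch, [FrequencyProfile(p) for p in pis], weights, gamma)
        column = {"A": "A", "B": "R", "C": "A", "D": "N"}
        col_idx = {t: "ARN".index(c) for t, c in column.items()}
        got = site_log_likelihood(tree, model, column)
        lik = sum(
            w * np.mean([oracle_site_likelihood(tree, exch, p, r, col_idx)
                         for r in gamma.category_rates])
            for w, p in zip(weights, pis)
        )
        assert got == pytest.approx(np.log(lik), abs=1e-9)

    def test_gap_is_partial_information(self):
        tree = parse_newick(ORACLE_TREES[1])
        exch = ExchangeabilityMatrix.poisson()
        pi = _random_profile(9)
        model = HomogeneousModel(exch, FrequencyProfile(pi), discrete_gamma_rates(1.0, 1))
        column = {"A": "A", "B": "-", "C": "C", "D": "A"}
        col_idx = {"A": 0, "B": None, "C": 4, "D": 0}
        got = site_log_likelihood(tree, model, column)
        assert got == pytest.approx(
            np.log(oracle_site_likelihood(tree, exch, pi, 1.0, col_idx)), abs=1e-9
        )


class TestClosedFormsAndInvariances:
    def test_all_gap_column_log_likelihood_zero(self, quartet_tree, poisson_uniform_g1):
        assert site_log_likelihood(
            quartet_tree, poisson_uniform_g1, {t: "-" for t in "ABCD"}
        ) == pytest.approx(0.0, abs=1e-12)

    def test_two_leaf_same_residue_closed_form(self, poisson_uniform_g1):
        tree = parse_newick("(A:0.3,B:0.4);")
        t = 0.7
        expected = np.log((1 / 20) * (1 / 20 + (19 / 20) * np.exp(-20 * t / 19)))
        assert site_log_likelihood(
            tree, poisson_uniform_g1, {"A": "K", "B": "K"}
        ) == pytest.approx(expected, abs=1e-12)

    def test_repeated_column_scales_linearly(self, quartet_tree, gamma4):
        model = HomogeneousModel(
            ExchangeabilityMatrix.lg(), FrequencyProfile(_random_profile(4)), gamma4
        )
        aln1 = Alignment.from_sequences(list("ABCD"), ["A", "R", "A", "N"])
        aln7 = Alignment.from_sequences(list("ABCD"), ["A" * 7, "R" * 7, "A" * 7, "N" * 7])
        assert total_log_likelihood(quartet_tree, model, aln7) == pytest.approx(
            7 * total_log_likelihood(quartet_tree, model, aln1), abs=1e-8
        )

    def test_taxon_order_irrelevant(self, quartet_tree, gamma4):
        model = HomogeneousModel(
            ExchangeabilityMatrix.poisson(), FrequencyProfile(_random_profile(5)), gamma4
        )
        aln = Alignment.from_sequences(list("ABCD"), ["ARN", "RRN", "AAN", "ARD"])
        flipped = aln.subset_taxa(["D", "B", "A", "C"])
        assert total_log_likelihood(quartet_tree, model, flipped) == pytest.approx(
            total_log_likelihood(quartet_tree, model, aln), abs=1e-10
        )

    def test_root_placement_irrelevant_for_reversible_model(self, gamma4):
        # same unrooted tree written with two different root placements
        t1 = parse_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);")
        t2 = parse_newick("(C:0.15,D:0.25,(A:0.2,B:0.3):0.15);")
        model = HomogeneousModel(
            ExchangeabilityMatrix.lg(), FrequencyProfile(_random_profile(6)), gamma4
        )
        aln = Alignment.from_sequences(list("ABCD"), ["AC", "RC", "AD", "NE"])
        assert total_log_likelihood(t2, model, aln) == pytest.approx(
            total_log_likelihood(t1, model, aln), abs=1e-8
        )

    def test_column_arity_checked(self, quartet_tree, poisson_uniform_g1):
        with pytest.raises(ValueError):
            site_log_likelihood(quartet_tree, poisson_uniform_g1, {"A": "A", "B": "R"})

    def test_many_taxa_no_underflow(self, gamma4):
        tree = generate_tree(FixtureSpec(n_taxa=120, tree_style="coalescent", seed=2))
        model = HomogeneousModel(
            ExchangeabilityMatrix.poisson(), FrequencyProfile.uniform(), gamma4
        )
        aln = simulate_alignment(SimulationRequest(tree=tree, model=model, n_sites=5, seed=1))
        ll = total_log_likelihood(tree, model, aln)
        assert np.isfinite(ll) and ll < 0

    def test_likelihood_identifies_generating_tree(self):
        """On data simulated under tree T, T beats rival topologies (most seeds)."""
        wins = 0
        rivals = None
        for seed in range(5):
            truth = generate_tree(FixtureSpec(n_taxa=6, tree_style="coalescent", seed=40 + seed))
            model = HomogeneousModel(
                ExchangeabilityMatrix.poisson(),
                FrequencyProfile(_random_profile(seed)),
                discrete_gamma_rates(1.0, 2),
            )
            aln = simulate_alignment(
                SimulationRequest(tree=truth, model=model, n_sites=400, seed=seed)
            )
            rivals = [
                generate_tree(FixtureSpec(n_taxa=6, tree_style="coalescent", seed=90 + k))
                for k in range(3)
            ]
            ll_truth = total_log_likelihood(truth, model, aln)
            if all(
                ll_truth > total_log_likelihood(r, model, aln)
                for r in rivals
                if r.bipartitions() != truth.bipartitions()
            ):
                wins += 1
        assert wins >= 3


class TestPMSF:
    def _mixture(self, profiles, weights, gamma=None):
        return MixtureModel(
            ExchangeabilityMatrix.poisson(),
            [FrequencyProfile(p) for p in profiles],
            np.asarray(weights),
            gamma or discrete_gamma_rates(1.0, 4),
        )

    def test_single_class_degenerates_to_that_profile(self, quartet_tree):
        p = _random_profile(11)
        mix = self._mixture([p], [1.0])
        aln = Alignment.from_sequences(list("ABCD"), ["ARN", "RRN", "AAN", "ARD"])
        out = compute_pmsf_profiles(quartet_tree, mix, aln)
        assert np.allclose(out.site_profiles, p[None, :], atol=1e-12)

    def test_identical_classes_ignore_weights(self, quartet_tree):
        p = _random_profile(12)
        mix = self._mixture([p, p], [0.9, 0.1])
        aln = Alignment.from_sequences(list("ABCD"), ["AR", "RR", "AA", "AR"])
        out = compute_pmsf_profiles(quartet_tree, mix, aln)
        assert np.allclose(out.site_profiles, p[None, :], atol=1e-12)

    def test_strong_signal_column_posterior(self):
        """An all-alanine column on a 50-taxon tree pins the alanine-rich class."""
        tree = generate_tree(
            FixtureSpec(
                n_taxa=50,
                tree_style="coalescent",
                branch_length_distribution=("exponential", 0.05),
                seed=13,
            )
        )
        ala = np.full(20, 0.01 / 19)
        ala[0] = 0.99
        gly = np.full(20, 0.01 / 19)
        gly[7] = 0.99
        mix = self._mixture([regularize_freqs(ala), regularize_freqs(gly)], [0.5, 0.5])
        aln = Alignment.from_sequences(tree.leaf_labels, ["A"] * 50)
        table = site_likelihood_table(tree, mix, aln)
        assert table.class_posteriors[0, 0] > 0.99
        out = compute_pmsf_profiles(tree, mix, aln)
        assert np.abs(out.site_profiles[0] - regularize_freqs(ala)).sum() < 1e-2

    def test_output_is_convex_combination_of_classes(self, small_coalescent_tree, gamma4):
        profiles = [_random_profile(20 + i) for i in range(4)]
        mix = self._mixture(profiles, [0.25] * 4, gamma4)
        truth = SiteProfileModel(
            ExchangeabilityMatrix.poisson(),
            generate_site_profiles(30, "dirichlet:0.3", 7),
            gamma4,
        )
        aln = simulate_alignment(SimulationRequest(tree=small_coalescent_tree, model=truth, seed=3))
        out = compute_pmsf_profiles(small_coalescent_tree, mix, aln)
        post = site_likelihood_table(small_coalescent_tree, mix, aln).class_posteriors
        recon = post @ np.stack(profiles)
        assert np.abs(out.site_profiles - recon).max() < 1e-9
        assert np.abs(post.sum(axis=1) - 1).max() < 1e-9

    def test_pmsf_fits_heterogeneous_data_better_than_mean_profile(self, gamma4):
        wins = 0
        for seed in range(5):
            tree = generate_tree(FixtureSpec(n_taxa=15, tree_style="coalescent", seed=60 + seed))
            # data generated from sparse mixture classes; PMSF is computed
            # from that same fitted mixture, as in the two-step procedure
            classes = generate_site_profiles(8, "dirichlet:0.1", 500 + seed)
            mix = self._mixture(list(classes), [1 / 8] * 8, gamma4)
            rng = np.random.default_rng(seed)
            site_profiles = classes[rng.integers(0, 8, size=120)]
            truth = SiteProfileModel(ExchangeabilityMatrix.poisson(), site_profiles, gamma4)
            aln = simulate_alignment(SimulationRequest(tree=tree, model=truth, seed=seed))
            pmsf = compute_pmsf_profiles(tree, mix, aln)
            mean_prof = FrequencyProfile(regularize_freqs(site_profiles.mean(axis=0)))
            hom = HomogeneousModel(ExchangeabilityMatrix.poisson(), mean_prof, gamma4)
            if total_log_likelihood(tree, pmsf, aln) >= total_log_likelihood(tree, hom, aln):
                wins += 1
        assert wins >= 3


class TestSiteProfileIO:
    def test_iqtree_fs_round_trip(self, tmp_path, sparse_profiles):
        path = tmp_path / "x.sitefreq"
        write_site_profiles([sparse_profiles], path, dialect="iqtree_fs")
        back = read_site_profiles(path, dialect="iqtree_fs")
        assert len(back) == 1
        assert np.abs(back[0] - sparse_profiles).max() < 1e-12

    def test_phylobayes_blocks_round_trip(self, tmp_path):
        samples = [generate_site_profiles(3, "dirichlet:0.5", s) for s in range(2)]
        path = tmp_path / "x.siteprofiles"
        write_site_profiles(samples, path, dialect="phylobayes_ss")
        back = read_site_profiles(path, dialect="phylobayes_ss")
        assert len(back) == 2 and back[0].shape == (3, 20)
        for a, b in zip(samples, back):
            assert np.abs(a - b).max() < 1e-12
        assert np.abs(back[0].sum(axis=1) - 1).max() < 1e-9

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.sitefreq"
        path.write_text("1 " + " ".join(["0.05"] * 19) + "\n")
        with pytest.raises(ValueError, match="line 1"):
            read_site_profiles(path, dialect="iqtree_fs")

    def test_non_numeric_cell_names_line(self, tmp_path):
        good = "1 " + " ".join(["0.05"] * 20)
        bad = "2 " + " ".join(["0.05"] * 19) + " oops"
        path = tmp_path / "bad.sitefreq"
        path.write_text(good + "\n" + bad + "\n")
        with pytest.raises(ValueError, match="line 2"):
            read_site_profiles(path, dialect="iqtree_fs")

    def test_unknown_dialect_rejected(self, tmp_path):
        path = tmp_path / "x"
        path.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_site_profiles(path, dialect="nexus")


class TestAveraging:
    def test_single_sample_identity(self, sparse_profiles):
        out = average_site_profiles([sparse_profiles])
        assert np.abs(out - sparse_profiles).max() < 1e-15

    def test_two_permuted_samples_average_to_midpoint(self):
        a = generate_site_profiles(5, "dirichlet:0.5", 1)
        b = a[:, ::-1].copy()
        mean = average_site_profiles([a, b])
        assert np.allclose(mean, (a + b) / 2)
        assert np.abs(mean.sum(axis=1) - 1).max() < 1e-12

    def test_inconsistent_site_counts_rejected(self):
        a = generate_site_profiles(5, "dirichlet:0.5", 1)
        b = generate_site_profiles(6, "dirichlet:0.5", 2)
        with pytest.raises(ValueError, match="site counts"):
            average_site_profiles([a, b])

    def test_posterior_sample_mean_near_target(self):
        """CLT check: the mean of many Dirichlet draws approaches its expectation."""
        rng = np.random.default_rng(33)
        target = rng.dirichlet(np.full(20, 5.0))
        conc = 200.0
        samples = [rng.dirichlet(conc * target, size=4) for _ in range(100)]
        mean = average_site_profiles(samples)
        var = target * (1 - target) / (conc + 1)
        se = np.sqrt(var / 100)
        assert np.all(np.abs(mean - target[None, :]) <= 3 * se[None, :] + 1e-6)
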