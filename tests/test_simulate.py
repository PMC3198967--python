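"""Serial-founder simulator and T92(+G) sequence evolution."""

import io
import json

import numpy as np
import pytest
from scipy.stats import ks_2samp, spearmanr
from skbio import TreeNode

from ychap import (
    SeqSimConfig,
    SimConfig,
    SubstitutionModelParams,
    build_mjn,
    dad_statistic,
    haplotype_diversity,
    load_haplotype_table,
    pairwise_counts,
    simulate_alignment,
    simulate_founder_chain,
    t92_distance,
)
from ychap.simulate import ANCESTRAL_STATE, discrete_gamma_rates, t92_rate_matrix

#: down-scaled chain used where many replicates are needed
SMALL = dict(n_demes=6, deme_size=40, founder_size=6, generations_per_stage=25)


class TestFounderChain:
    def test_zero_rates_stay_ancestral(self):
        cfg = SimConfig(mu_mono=0, mu_tri=0, mu_penta=0, snp_rate=0, **SMALL, seed=1)
        table, history = simulate_founder_chain(cfg)
        assert table.k == 1
        assert table.n == cfg.n_demes * cfg.deme_size
        h = table.haplotypes[0]
        assert (h.penta_repeats, h.tri_repeats, h.mono_repeats) == tuple(ANCESTRAL_STATE[:3])
        assert (h.sry_snp, h.str_snp) == ("A", "A")
        assert all(
            v == {"sry_snp": 0.0, "str_snp": 0.0} for v in history["derived_freq"].values()
        )

    def test_seed_reproducibility_byte_for_byte(self, tmp_path):
        out = []
        for run in range(2):
            table, history = simulate_founder_chain(SimConfig(**SMALL, seed=42))
            p = tmp_path / f"run{run}.tsv"
            table.to_tsv(p)
            out.append((p.read_text(), json.dumps(history, sort_keys=True)))
        assert out[0] == out[1]

    def test_different_seeds_differ(self):
        t1, _ = simulate_founder_chain(SimConfig(**SMALL, seed=1))
        t2, _ = simulate_founder_chain(SimConfig(**SMALL, seed=2))
        assert (t1.ids != t2.ids) or not (t1.counts.values == t2.counts.values).all()

    def test_founders_cannot_exceed_deme(self):
        with pytest.raises(ValueError, match="founder_size"):
            SimConfig(deme_size=5, founder_size=10)

    def test_round_trip_through_full_pipeline(self, tmp_path):
        table, _ = simulate_founder_chain(SimConfig(**SMALL, seed=7))
        p = tmp_path / "sim.tsv"
        table.to_tsv(p)
        again = load_haplotype_table(p)
        assert again.ids == table.ids
        assert again.n == table.n
        # every downstream stage accepts the simulated table
        assert 0 <= haplotype_diversity(again).h < 1
        dad = dad_statistic(again, "deme01", f"deme{SMALL['n_demes']:02d}")
        assert all(v >= 0 for v in dad.differences.values())
        net = build_mjn(again)
        assert set(net.sampled) >= set()  # built without error, connected by contract

    def test_fast_motif_dominates_dad_over_replicates(self):
        # the mononucleotide's ten-fold rate advantage must show up in
        # the mean between-end-deme Dad even on the short chain; the
        # finer tri > penta separation needs the full-length chain and
        # is checked there (acceptance suite)
        dads = []
        for seed in range(40):
            table, _ = simulate_founder_chain(SimConfig(**SMALL, seed=seed))
            d = dad_statistic(table, "deme01", "deme06").differences
            dads.append([d["penta"], d["tri"], d["mono"]])
        mean = np.asarray(dads).mean(axis=0)
        assert mean[2] > mean[1] and mean[2] > mean[0]

    def test_derived_snp_cline_over_replicates(self):
        freqs = []
        for seed in range(40):
            _, history = simulate_founder_chain(SimConfig(**SMALL, seed=seed))
            freqs.append(
                [
                    history["derived_freq"][f"deme{i + 1:02d}"]["sry_snp"]
                    + history["derived_freq"][f"deme{i + 1:02d}"]["str_snp"]
                    for i in range(SMALL["n_demes"])
                ]
            )
        mean = np.asarray(freqs).mean(axis=0)
        rho, _ = spearmanr(range(len(mean)), mean)
        assert rho > 0


class TestRateMatrix:
    def test_stationarity_and_scaling(self):
        params = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281)
        q, pi = t92_rate_matrix(params)
        assert pi @ q == pytest.approx(np.zeros(4), abs=1e-12)
        assert -float(pi @ np.diag(q)) == pytest.approx(1.0)

    def test_flux_ratio_equals_ts_tv(self):
        params = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281)
        q, pi = t92_rate_matrix(params)
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        ts = sum(pi[i] * q[i, j] for i, j in transitions)
        tv = sum(
            pi[i] * q[i, j]
            for i in range(4)
            for j in range(4)
            if i != j and (i, j) not in transitions
        )
        assert ts / tv == pytest.approx(1.6281)

    def test_gamma_rates_mean_one_and_increasing(self):
        rates = discrete_gamma_rates(0.4762, 5)
        assert rates.mean() == pytest.approx(1.0)
        assert (np.diff(rates) > 0).all()


def _two_taxon_estimate(params, length, seed, n_categories=5):
    tree = TreeNode.read(io.StringIO("(x:0.05,y:0.05);"))
    cfg = SeqSimConfig(tree=tree, params=params, length=length, n_categories=n_categories, seed=seed)
    aln = simulate_alignment(cfg)
    return aln, pairwise_counts(aln.seqs[0], aln.seqs[1])


def _expected_counts(params, total_length, n_categories):
    """Analytic transition/transversion proportions for the generating
    process (mixture over discrete-gamma categories)."""
    from scipy.linalg import expm

    q, pi = t92_rate_matrix(params)
    if params.gamma_shape is None:
        rates = np.ones(1)
    else:
        rates = discrete_gamma_rates(params.gamma_shape, n_categories)
    m = sum(expm(q * total_length * r) for r in rates) / len(rates)
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    P = sum(pi[i] * m[i, j] for i, j in transitions)
    Q = sum(
        pi[i] * m[i, j] for i in range(4) for j in range(4) if i != j and (i, j) not in transitions
    )
    return P, Q


class TestSequenceSimulation:
    def test_zero_branches_identical_sequences(self):
        tree = TreeNode.read(io.StringIO("(x:0.0,y:0.0);"))
        params = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281, gamma_shape=0.4762)
        aln = simulate_alignment(SeqSimConfig(tree=tree, params=params, length=500, seed=3))
        assert aln.seqs[0] == aln.seqs[1]

    def test_negative_branch_rejected(self):
        tree = TreeNode.read(io.StringIO("(x:-0.1,y:0.0);"))
        params = SubstitutionModelParams(theta=0.5)
        with pytest.raises(ValueError, match="nonnegative"):
            SeqSimConfig(tree=tree, params=params, length=10)

    def test_t92g_estimator_recovers_generating_distance(self):
        # estimate vs the analytic expectation of the generating
        # process, within 3 delta-method standard errors
        params = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281, gamma_shape=0.4762)
        L = 50_000
        _, counts = _two_taxon_estimate(params, L, seed=17)
        P0, Q0 = _expected_counts(params, 0.1, 5)
        from ychap.seqdist import PairwiseCounts

        d_expected = t92_distance(PairwiseCounts(L, P0, Q0), params)
        d_est = t92_distance(counts, params)
        # delta-method SE via numeric gradient at the expectation
        eps = 1e-6
        dP = (
            t92_distance(PairwiseCounts(L, P0 + eps, Q0), params)
            - t92_distance(PairwiseCounts(L, P0 - eps, Q0), params)
        ) / (2 * eps)
        dQ = (
            t92_distance(PairwiseCounts(L, P0, Q0 + eps), params)
            - t92_distance(PairwiseCounts(L, P0, Q0 - eps), params)
        ) / (2 * eps)
        var = (
            dP**2 * P0 * (1 - P0) / L
            + dQ**2 * Q0 * (1 - Q0) / L
            - 2 * dP * dQ * P0 * Q0 / L
        )
        assert abs(d_est - d_expected) < 3 * np.sqrt(var)

    def test_fine_discretization_recovers_nominal_distance(self):
        # with enough rate categories the continuous-gamma correction
        # recovers the true path length 0.1 within Monte-Carlo error
        params = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281, gamma_shape=0.4762)
        ests = [
            t92_distance(_two_taxon_estimate(params, 20_000, seed=s, n_categories=32)[1], params)
            for s in range(6)
        ]
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - 0.1) < 3 * se

    def test_large_shape_indistinguishable_from_no_gamma(self):
        flat = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281)
        nearly_flat = SubstitutionModelParams(theta=0.3216, ts_tv=1.6281, gamma_shape=1e6)
        d_flat, d_near = [], []
        for s in range(25):
            _, c1 = _two_taxon_estimate(flat, 2000, seed=s)
            _, c2 = _two_taxon_estimate(nearly_flat, 2000, seed=1000 + s)
            d_flat.append(t92_distance(c1, flat))
            d_near.append(t92_distance(c2, flat))
        assert ks_2samp(d_flat, d_near).pvalue > 0.01
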