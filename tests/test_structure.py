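import numpy as np
import pytest

from epimsap import (
    McmcParams,
    StructureRun,
    align_runs,
    evanno_delta_k,
    fit_structure,
    structure_scan,
)

FAST = McmcParams(burn_in=100, n_sweeps=200, thin=2)


def _two_pop_data(seed=0, n_per=10, S=150, p_hi=0.8, p_lo=0.2):
    rng = np.random.default_rng(seed)
    pa = np.where(rng.random(S) < 0.5, p_hi, p_lo)
    pb = 1.0 - pa
    X = np.vstack(
        [rng.random((n_per, S)) < pa, rng.random((n_per, S)) < pb]
    ).astype(int)
    return X


def test_k1_matches_beta_posterior_expected_loglik():
    """With no latent structure the trace mean has an exact closed form.

    At K=1 each recorded log-likelihood is n1*log(p) + n0*log(1-p) with
    p ~ Beta(1+n1, 1+n0) per column, so its expectation follows from
    E[log p] = psi(a) - psi(a+b).
    """
    from scipy.special import digamma

    rng = np.random.default_rng(1)
    X = (rng.random((15, 80)) < 0.3).astype(int)
    run = fit_structure(X, K=1, mcmc=McmcParams(200, 800, 2), seed=2)
    assert np.allclose(run.Q, 1.0)
    n1 = X.sum(axis=0)
    n0 = X.shape[0] - n1
    ref = float(
        (
            n1 * (digamma(1 + n1) - digamma(2 + X.shape[0]))
            + n0 * (digamma(1 + n0) - digamma(2 + X.shape[0]))
        ).sum()
    )
    mc_err = 3 * run.loglik_trace.std(ddof=1) / np.sqrt(run.loglik_trace.size) + 1.0
    assert run.mean_loglik == pytest.approx(ref, abs=5 * mc_err)
    assert np.isfinite(run.loglik_trace).all()


def test_q_rows_sum_to_one_and_recovery():
    X = _two_pop_data(seed=3)
    run = fit_structure(X, K=2, mcmc=FAST, seed=4)
    np.testing.assert_allclose(run.Q.sum(axis=1), 1.0, atol=1e-9)
    assert ((run.P > 0) & (run.P < 1)).all()
    maj = run.Q.argmax(axis=1)
    # one cluster must own >= 95% of each true subpopulation's individuals
    frac = max(
        (maj[:10] == 0).mean() + (maj[10:] == 1).mean(),
        (maj[:10] == 1).mean() + (maj[10:] == 0).mean(),
    ) / 2
    assert frac >= 0.95


def test_seeded_determinism_bit_identical():
    X = _two_pop_data(seed=5, n_per=6, S=60)
    r1 = fit_structure(X, K=3, mcmc=FAST, seed=11)
    r2 = fit_structure(X, K=3, mcmc=FAST, seed=11)
    np.testing.assert_array_equal(r1.Q, r2.Q)
    np.testing.assert_array_equal(r1.P, r2.P)
    np.testing.assert_array_equal(r1.loglik_trace, r2.loglik_trace)


def test_duplicate_individuals_get_similar_memberships():
    X = _two_pop_data(seed=7, n_per=8, S=120)
    X = np.vstack([X, X[0]])  # duplicate the first individual
    run = fit_structure(X, K=2, mcmc=McmcParams(200, 600, 2), seed=8)
    assert np.abs(run.Q[0] - run.Q[-1]).max() < 0.05


def test_input_validation():
    with pytest.raises(ValueError, match="binary"):
        fit_structure(np.array([[0, 2]]), K=1, mcmc=FAST, seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        fit_structure(np.eye(3, dtype=int), K=5, mcmc=FAST, seed=0)
    with pytest.raises(ValueError, match=">= 1"):
        fit_structure(np.eye(3, dtype=int), K=0, mcmc=FAST, seed=0)


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------


def _fake_runs(mean_L: dict[int, float], offsets=(-2**-0.5, 2**-0.5)):
    """Replicate runs with per-replicate constant offsets (sd_L = 1)."""
    runs = []
    for K, m in mean_L.items():
        for c in offsets:
            runs.append(
                StructureRun(
                    K=K,
                    individual_ids=["x"],
                    Q=np.ones((1, K)) / K,
                    P=np.full((K, 1), 0.5),
                    loglik_trace=np.array([m + c]),
                    mean_loglik=m + c,
                    seed=0,
                    mcmc=FAST,
                )
            )
    return runs


def test_evanno_hand_oracle():
    """mean L = (-1000, -800, -790, -788), sd 1 -> delta_K peaks at K=2 (190)."""
    runs = _fake_runs({1: -1000.0, 2: -800.0, 3: -790.0, 4: -788.0})
    ev = evanno_delta_k(runs)
    assert ev.best_K == 2
    assert ev.table.loc[2, "delta_K"] == pytest.approx(190.0, rel=1e-9)
    assert ev.table.loc[3, "delta_K"] == pytest.approx(8.0, rel=1e-9)
    assert np.isnan(ev.table.loc[1, "delta_K"]) and np.isnan(ev.table.loc[4, "delta_K"])
    assert ev.table.loc[2, "L_prime"] == pytest.approx(200.0)


def test_evanno_linear_likelihood_zero_delta():
    runs = _fake_runs({k: -1000.0 + 50.0 * k for k in range(1, 5)})
    ev = evanno_delta_k(runs)
    interior = ev.table["delta_K"].dropna()
    assert np.allclose(interior, 0.0, atol=1e-9)


def test_evanno_flags_sd_zero_rows():
    runs = _fake_runs({1: -10.0, 2: -5.0, 3: -4.0}, offsets=(0.0, 0.0))
    with pytest.raises(ValueError, match="undefined"):
        evanno_delta_k(runs)


def test_evanno_requires_consecutive_ks():
    runs = _fake_runs({1: -10.0, 3: -5.0, 4: -4.0})
    with pytest.raises(ValueError, match="consecutive"):
        evanno_delta_k(runs)


def test_structure_scan_seeds_differ_and_derive_from_master():
    X = _two_pop_data(seed=9, n_per=4, S=30)
    runs = structure_scan(X, range(1, 3), replicates=2, mcmc=FAST, seed=42)
    seeds = [r.seed for r in runs]
    assert len(set(seeds)) == len(seeds)
    runs2 = structure_scan(X, range(1, 3), replicates=2, mcmc=FAST, seed=42)
    assert seeds == [r.seed for r in runs2]
    np.testing.assert_array_equal(runs[0].Q, runs2[0].Q)


# ---------------------------------------------------------------------------
# Run alignment
# ---------------------------------------------------------------------------


def test_align_recovers_known_permutations():
    rng = np.random.default_rng(20)
    Q = rng.dirichlet(np.ones(3), size=12)
    base = StructureRun(
        K=3, individual_ids=[f"i{k}" for k in range(12)], Q=Q,
        P=rng.random((3, 6)), loglik_trace=np.zeros(1), mean_loglik=0.0,
        seed=0, mcmc=FAST,
    )
    runs = [base]
    for _ in range(4):
        perm = rng.permutation(3)
        runs.append(
            StructureRun(
                K=3, individual_ids=base.individual_ids, Q=Q[:, perm],
                P=base.P[perm, :], loglik_trace=np.zeros(1), mean_loglik=0.0,
                seed=0, mcmc=FAST,
            )
        )
    aligned, mean_Q = align_runs(runs)
    for run in aligned:
        np.testing.assert_allclose(run.Q, Q, atol=1e-12)
        np.testing.assert_allclose(run.P, base.P, atol=1e-12)
    np.testing.assert_allclose(mean_Q, Q, atol=1e-12)


def test_align_single_run_unchanged():
    rng = np.random.default_rng(21)
    Q = rng.dirichlet(np.ones(2), size=5)
    run = StructureRun(
        K=2, individual_ids=list("abcde"), Q=Q, P=rng.random((2, 4)),
        loglik_trace=np.zeros(1), mean_loglik=0.0, seed=0, mcmc=FAST,
    )
    aligned, mean_Q = align_runs([run])
    assert aligned[0] is run
    np.testing.assert_array_equal(mean_Q, Q)


def test_align_shape_mismatch_rejected():
    rng = np.random.default_rng(22)
    mk = lambda K, n: StructureRun(
        K=K, individual_ids=[f"i{j}" for j in range(n)],
        Q=rng.dirichlet(np.ones(K), size=n), P=rng.random((K, 3)),
        loglik_trace=np.zeros(1), mean_loglik=0.0, seed=0, mcmc=FAST,
    )
    with pytest.raises(ValueError, match="differ"):
        align_runs([mk(2, 5), mk(3, 5)])
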