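import numpy as np
import pytest
from scipy import stats

from nnmelt.errors import NoTransitionError, ValidationError
from nnmelt.fitting import (
    MeltDataset,
    ThermoSummary,
    benchmark_report,
    fit_partition_model,
    fit_two_state_curve,
    fit_two_state_nn,
    jackknife,
    multistart_fit,
    paired_one_tailed_t,
    residuals,
    rmsd,
    summaries_from_params,
)
from nnmelt.melt_io import FractionCurve
from nnmelt.partition import ModelCurve, predict_curve
from nnmelt.synthetic_data import (
    SyntheticSpec,
    default_truth_params,
    fraction_dataset,
    generate_dataset,
    generate_melt,
    random_duplexes,
)
from nnmelt.thermo_model import (
    FEATURES,
    HELIX_FEATURES,
    DuplexSequence,
    R_GAS,
    decompose_duplex,
)


def small_corpus(noise_sd=0.0, seed=0, n_duplexes=6, n_conc=2, t_step=5.0):
    rng = np.random.default_rng(seed)
    spec = SyntheticSpec(
        duplexes=random_duplexes(n_duplexes, rng, require_coverage=False),
        concentrations=np.geomspace(5e-6, 2e-4, n_conc).tolist(),
        params=default_truth_params(),
        noise_sd=noise_sd,
        seed=seed,
        t_step=t_step,
    )
    return fraction_dataset(generate_dataset(spec)), spec.params


# ---------------------------------------------------------------------------
# MeltDataset / residuals
# ---------------------------------------------------------------------------


def test_dataset_validation(lit_params):
    seq = DuplexSequence("d1", "GACU")
    with pytest.raises(ValidationError, match="no curves"):
        MeltDataset([(seq, [])])
    wrong = FractionCurve("c1", "other", np.array([20.0, 40.0]), np.array([0.9, 0.1]), 1e-5)
    with pytest.raises(ValidationError, match="references duplex"):
        MeltDataset([(seq, [wrong])])


def test_residuals_zero_at_truth():
    data, truth = small_corpus()
    r = residuals(truth, data)
    assert r.shape == (data.n_points,)
    np.testing.assert_allclose(r, 0.0, atol=1e-12)


def test_residuals_three_point_hand_computation(lit_params):
    seq = DuplexSequence("d1", "GACUCAG")
    T = np.array([30.0, 45.0, 60.0])
    model = predict_curve(seq, lit_params, 1e-5, T).fractions
    obs = np.array([0.9, 0.5, 0.1])
    curve = FractionCurve("c1", "d1", T, obs, 1e-5)
    r = residuals(lit_params, MeltDataset([(seq, [curve])]))
    np.testing.assert_allclose(r, obs - model, atol=1e-14)


def test_residual_norm_is_euclidean_norm():
    data, truth = small_corpus(noise_sd=0.002, seed=3)
    fit = fit_partition_model(data, truth, max_nfev=3)
    r = residuals(fit.params, data)
    assert fit.residual_norm == pytest.approx(float(np.linalg.norm(r)), rel=1e-12)


# ---------------------------------------------------------------------------
# fit_partition_model
# ---------------------------------------------------------------------------


def test_fit_from_truth_converges_immediately():
    data, truth = small_corpus()
    fit = fit_partition_model(data, truth)
    assert fit.converged
    assert fit.residual_norm < 1e-6
    assert set(fit.per_curve_rmsd) == set(data.curve_ids())


def test_fit_recovers_perturbed_truth():
    data, truth = small_corpus(n_duplexes=8, n_conc=3)
    rng = np.random.default_rng(11)
    fit = fit_partition_model(data, truth.perturbed(rng, 0.05))
    assert fit.converged
    # features present in this small corpus are pinned by the data
    present = set()
    for seq, _ in data.entries:
        present.update(decompose_duplex(seq))
    for f in present & set(HELIX_FEATURES):
        assert fit.params.delta_g37(f) == pytest.approx(truth.delta_g37(f), abs=0.01)


def test_fit_nonconvergence_is_flagged_not_raised():
    data, truth = small_corpus()
    rng = np.random.default_rng(5)
    fit = fit_partition_model(data, truth.perturbed(rng, 0.2), max_nfev=2)
    assert not fit.converged


# ---------------------------------------------------------------------------
# multistart
# ---------------------------------------------------------------------------


def test_multistart_determinism():
    data, truth = small_corpus(n_duplexes=4)
    a = multistart_fit(data, truth, n_starts=2, seed=42, max_nfev=4)
    b = multistart_fit(data, truth, n_starts=2, seed=42, max_nfev=4)
    np.testing.assert_array_equal(a.residual_norms, b.residual_norms)
    assert a.fits[0].params == b.fits[0].params


def test_multistart_requires_two_starts():
    data, truth = small_corpus(n_duplexes=4)
    with pytest.raises(ValidationError):
        multistart_fit(data, truth, n_starts=1)


# ---------------------------------------------------------------------------
# Two-state NN regression
# ---------------------------------------------------------------------------


def test_two_state_nn_exact_recovery(lit_params, duplexes34):
    """Summaries that are exact NN sums are fit back exactly."""
    summaries = summaries_from_params(duplexes34, lit_params)
    fit = fit_two_state_nn(summaries)
    for f in HELIX_FEATURES:
        assert fit.params.dh[f] == pytest.approx(lit_params.dh[f], abs=1e-8)
        assert fit.params.ds[f] == pytest.approx(lit_params.ds[f], abs=1e-8)
        assert fit.dg37[f] == pytest.approx(lit_params.delta_g37(f), abs=1e-8)
    assert fit.residual_dg37 < 1e-10


def test_two_state_nn_design_row_matches_decomposition(lit_params):
    seq = DuplexSequence("x", "GGCUUCAA")
    s = summaries_from_params([seq], lit_params)[0]
    counts = decompose_duplex(seq)
    # reconstruct the dH observable from the counts: the design row acts on
    # the same decomposition
    assert s.dh == pytest.approx(sum(n * lit_params.dh[f] for f, n in counts.items()))


def test_two_state_nn_equal_weights_reduce_to_ols(duplexes34, lit_params, rng):
    summaries = summaries_from_params(duplexes34, lit_params)
    noisy = [
        ThermoSummary(s.seq, s.dh + rng.normal(0, 2), s.ds + rng.normal(0, 5),
                      s.dg37 + rng.normal(0, 0.2), 1.0, 1.0, 1.0)
        for s in summaries
    ]
    fit = fit_two_state_nn(noisy)
    # independent OLS with numpy on the same design
    X = np.array([
        [decompose_duplex(s.seq).get(f, 0) for f in HELIX_FEATURES] for s in noisy
    ], dtype=float)
    sym = np.array([s.seq.self_complementary for s in noisy], dtype=float)
    y = np.array([s.dh for s in noisy])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    for f, b in zip(HELIX_FEATURES, beta):
        assert fit.params.dh[f] == pytest.approx(b, abs=1e-8)


def test_two_state_nn_rank_deficiency_names_features(lit_params):
    seqs = [DuplexSequence(f"d{i}", "A" * (i + 3)) for i in range(12)]
    summaries = summaries_from_params(seqs, lit_params)
    with pytest.raises(ValidationError, match="unidentifiable"):
        fit_two_state_nn(summaries)


def test_two_state_nn_needs_enough_duplexes(lit_params):
    seqs = [DuplexSequence("a", "GACU")]
    with pytest.raises(ValidationError):
        fit_two_state_nn(summaries_from_params(seqs, lit_params))


# ---------------------------------------------------------------------------
# Two-state curve fit
# ---------------------------------------------------------------------------


def two_state_melt(seq, params, c_t, noise_sd=0.0, seed=0, t_step=0.5):
    spec = SyntheticSpec(
        duplexes=[seq], concentrations=[c_t], params=params,
        noise_sd=noise_sd, seed=seed, two_state=True, t_step=t_step,
    )
    return generate_melt(seq, params, c_t, spec)


def test_two_state_curve_exact_recovery(lit_params):
    seq = DuplexSequence("d1", "GAGGAG")
    counts = decompose_duplex(seq)
    dh_true = sum(n * lit_params.dh[f] for f, n in counts.items())
    ds_true = sum(n * lit_params.ds[f] for f, n in counts.items())
    curve = two_state_melt(seq, lit_params, 1e-4)
    fit = fit_two_state_curve(curve, self_complementary=False)
    assert fit.converged
    assert fit.dh == pytest.approx(dh_true, abs=0.02)
    assert fit.ds == pytest.approx(ds_true, abs=0.06)


def test_two_state_curve_tm_closed_form(lit_params):
    seq = DuplexSequence("d1", "GAGGAG")
    c_t = 1e-4
    curve = two_state_melt(seq, lit_params, c_t)
    fit = fit_two_state_curve(curve, self_complementary=False)
    expected = fit.dh / (fit.ds / 1000.0 + R_GAS * np.log(c_t / 4.0)) - 273.15
    assert fit.tm == pytest.approx(expected, abs=1e-9)


def test_two_state_curve_flat_raises(lit_params):
    from nnmelt.melt_io import MeltingCurve

    T = np.linspace(10, 90, 120)
    flat = MeltingCurve("c", "d", T, 0.0005 * T + 0.7, 1e-5)
    with pytest.raises(NoTransitionError):
        fit_two_state_curve(flat)


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------


def test_jackknife_identical_duplex_copies_sd_zero():
    """Copies of one synthetic duplex under different ids: every resample
    sees the same information, so parameter SD is zero."""
    rng = np.random.default_rng(0)
    base = DuplexSequence("d0", "GCACG")
    spec = SyntheticSpec(
        duplexes=[base], concentrations=[1e-5, 1e-4],
        params=default_truth_params(), noise_sd=0.0, seed=0, t_step=5.0,
    )
    synth = generate_dataset(spec)
    curves = fraction_dataset(synth).entries[0][1]
    entries = []
    for k in range(4):
        seq_k = DuplexSequence(f"d{k}", base.top_strand)
        curves_k = [
            FractionCurve(f"{c.curve_id}_{k}", seq_k.duplex_id, c.temperatures,
                          c.fractions, c.strand_concentration)
            for c in curves
        ]
        entries.append((seq_k, curves_k))
    data = MeltDataset(entries)
    jk = jackknife(data, init=spec.params, max_nfev=8)
    assert len(jk.fits) == data.n_duplexes
    for f in FEATURES:
        sd_dh, sd_ds = jk.param_sd[f]
        assert sd_dh == pytest.approx(0.0, abs=1e-9)
        assert sd_ds == pytest.approx(0.0, abs=1e-9)


def test_jackknife_resample_count_and_heldout():
    data, truth = small_corpus(n_duplexes=4)
    jk = jackknife(data, init=truth)
    assert len(jk.fits) == 4
    assert set(jk.left_out_ids) == {s.duplex_id for s, _ in data.entries}
    assert all(v >= 0 for v in jk.heldout_rmsd.values())


def test_jackknife_needs_three_duplexes():
    data, truth = small_corpus(n_duplexes=2)
    with pytest.raises(ValidationError):
        jackknife(data, init=truth)


# ---------------------------------------------------------------------------
# rmsd
# ---------------------------------------------------------------------------


def test_rmsd_identical_zero():
    T = np.linspace(10, 90, 30)
    X = np.linspace(1, 0, 30)
    obs = FractionCurve("c", "d", T, X, 1e-5)
    pred = ModelCurve(T, X.copy(), 1e-5)
    assert rmsd(obs, pred) == 0.0


def test_rmsd_constant_offset():
    T = np.linspace(10, 90, 30)
    X = np.linspace(1, 0, 30)
    pred = ModelCurve(T, X + 0.07, 1e-5)
    assert rmsd(FractionCurve("c", "d", T, X, 1e-5), pred) == pytest.approx(0.07)


def test_rmsd_hand_three_points():
    T = np.array([1.0, 2.0, 3.0])
    obs = FractionCurve("c", "d", T, np.array([0.9, 0.5, 0.1]), 1e-5)
    pred = ModelCurve(T, np.array([0.8, 0.5, 0.4]), 1e-5)
    assert rmsd(obs, pred) == pytest.approx(np.sqrt((0.01 + 0.0 + 0.09) / 3))


def test_rmsd_grid_mismatch():
    obs = FractionCurve("c", "d", np.array([1.0, 2.0]), np.array([0.5, 0.4]), 1e-5)
    pred = ModelCurve(np.array([1.0, 2.5]), np.array([0.5, 0.4]), 1e-5)
    with pytest.raises(ValidationError):
        rmsd(obs, pred)


# ---------------------------------------------------------------------------
# Paired one-tailed t-test
# ---------------------------------------------------------------------------


def test_t_all_zero_differences_undefined():
    res = paired_one_tailed_t([0.0, 0.0, 0.0, 0.0])
    assert res.undefined and not res.significant


def test_t_textbook_example_against_scipy():
    d = np.array([0.8, 0.3, -0.1, 0.6, 0.5])
    mine = paired_one_tailed_t(d)
    ref = stats.ttest_1samp(d, 0.0, alternative="greater")
    assert mine.t == pytest.approx(float(ref.statistic), rel=1e-12)
    assert mine.p == pytest.approx(float(ref.pvalue), rel=1e-12)


def test_t_one_tailed_is_half_two_tailed_for_positive_t(rng):
    d = rng.normal(0.5, 1.0, 12)
    if np.mean(d) < 0:
        d = -d
    mine = paired_one_tailed_t(d)
    two = stats.ttest_1samp(d, 0.0)
    assert mine.p == pytest.approx(float(two.pvalue) / 2.0, rel=1e-12)


# ---------------------------------------------------------------------------
# Benchmark report
# ---------------------------------------------------------------------------


def test_benchmark_set_vs_itself_zero_differences():
    data, truth = small_corpus(n_duplexes=4, t_step=8.0)
    report = benchmark_report(data, {"a": truth, "b": truth})
    diff = report.per_duplex[("a", "rmsd")] - report.per_duplex[("b", "rmsd")]
    np.testing.assert_allclose(diff.values, 0.0, atol=1e-15)
    assert (report.ttests["significant"] == False).all()  # noqa: E712


def test_benchmark_truth_beats_perturbed(rng):
    data, truth = small_corpus(n_duplexes=6, noise_sd=0.001, t_step=4.0)
    worse = truth.perturbed(rng, 0.15)
    report = benchmark_report(data, {"truth": truth, "perturbed": worse})
    assert (
        report.summary.loc[("truth", "rmsd"), "per_duplex_mean"]
        < report.summary.loc[("perturbed", "rmsd"), "per_duplex_mean"]
    )


def test_benchmark_reports_both_scopes():
    data, truth = small_corpus(n_duplexes=4, t_step=8.0)
    report = benchmark_report(data, {"a": truth, "b": truth.perturbed(np.random.default_rng(1), 0.05)})
    assert {"per_duplex", "per_melt"} == set(report.ttests["scope"].unique())
    assert "per_duplex_mean" in report.summary.columns
    assert "per_melt_mean" in report.summary.columns
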