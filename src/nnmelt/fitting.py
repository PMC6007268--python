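"""Parameter estimation and benchmarking.

The central fit minimizes the sum of squared differences between measured and
model fraction-of-maximal-pairs over every point of every melting curve, with
the 40 nearest-neighbor enthalpies/entropies as free parameters, using a
trust-region nonlinear least-squares solver.  Also here: the multistart
convergence protocol, the classical error-weighted two-state linear NN
regression, per-melt two-state curve fits, jackknife resampling, RMSD and Tm
benchmarking with paired one-tailed t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import NoTransitionError, NumericalError, ValidationError
from .melt_io import (
    BaselineFit,
    FractionCurve,
    MeltingCurve,
    fit_baselines,
    interpolate_tm,
    load_melt_curves,
    to_fraction_paired,
)
from .partition import (
    ModelCurve,
    fraction_paired_profile,
    predict_tm,
    prob_any_pair,
)
from .thermo_model import (
    CELSIUS_OFFSET,
    DS_SYM,
    FEATURES,
    HELIX_FEATURES,
    NNParamSet,
    DuplexSequence,
    R_GAS,
    T37,
    decompose_duplex,
)

# Internal optimizer scaling: dH/10 and dS*T_ref/1e4 give both parameter
# families comparable magnitude.
_H_SCALE = 10.0
_S_SCALE = 1.0e4 / T37
_N = len(FEATURES)


def _pack(params: NNParamSet) -> np.ndarray:
    x = params.to_vector()
    return np.concatenate([x[:_N] / _H_SCALE, x[_N:] / _S_SCALE])


def _unpack(x: np.ndarray) -> NNParamSet:
    return NNParamSet.from_vector(
        np.concatenate([x[:_N] * _H_SCALE, x[_N:] * _S_SCALE])
    )


@dataclass
class MeltDataset:
    """Duplexes with their fraction-paired melting curves."""

    entries: List[Tuple[DuplexSequence, List[FractionCurve]]]

    def __post_init__(self) -> None:
        ids = set()
        for seq, curves in self.entries:
            if not curves:
                raise ValidationError(f"duplex {seq.duplex_id!r} has no curves")
            if seq.duplex_id in ids:
                raise ValidationError(f"duplicate duplex_id {seq.duplex_id!r}")
            ids.add(seq.duplex_id)
            for c in curves:
                if c.duplex_id != seq.duplex_id:
                    raise ValidationError(
                        f"curve {c.curve_id!r} references duplex {c.duplex_id!r}, "
                        f"not {seq.duplex_id!r}"
                    )

    @property
    def n_duplexes(self) -> int:
        return len(self.entries)

    @property
    def n_curves(self) -> int:
        return sum(len(c) for _, c in self.entries)

    @property
    def n_points(self) -> int:
        return sum(c.temperatures.size for _, cs in self.entries for c in cs)

    def without(self, duplex_id: str) -> "MeltDataset":
        kept = [(s, c) for s, c in self.entries if s.duplex_id != duplex_id]
        if len(kept) == len(self.entries):
            raise ValidationError(f"no duplex {duplex_id!r} in dataset")
        return MeltDataset(kept)

    def curve_ids(self) -> List[str]:
        return [c.curve_id for _, cs in self.entries for c in cs]


def dataset_from_manifest(manifest_path, lower_frac: float = 0.10, upper_frac: float = 0.10) -> MeltDataset:
    """Load a manifest, fit baselines and transform every curve to fractions."""
    by_duplex: Dict[str, Tuple[DuplexSequence, List[FractionCurve]]] = {}
    for row, curve in load_melt_curves(manifest_path):
        base = fit_baselines(
            curve,
            row.lower_frac if row.lower_frac is not None else lower_frac,
            row.upper_frac if row.upper_frac is not None else upper_frac,
        )
        frac = to_fraction_paired(curve, base)
        if row.duplex_id not in by_duplex:
            by_duplex[row.duplex_id] = (DuplexSequence(row.duplex_id, row.top_strand), [])
        by_duplex[row.duplex_id][1].append(frac)
    return MeltDataset(list(by_duplex.values()))


# ---------------------------------------------------------------------------
# Residuals and the partition-function fit
# ---------------------------------------------------------------------------


def residuals(params: NNParamSet, data: MeltDataset) -> np.ndarray:
    """Per-point residuals X_melt(T) - X_model(T), dataset order then temperature.

    Curves of the same duplex share one recursion pass over their
    concatenated temperature grids (concentration only enters the bimolecular
    mass balance).
    """
    out: List[np.ndarray] = []
    for seq, curves in data.entries:
        T_all = np.concatenate([c.temperatures for c in curves]) + CELSIUS_OFFSET
        try:
            prof = fraction_paired_profile(seq, params, T_all)
        except NumericalError:
            # trial point overflowed the partition function: return a large,
            # finite penalty so trust-region search backs off smoothly
            out.append(np.full(T_all.size, 1e3))
            continue
        offset = 0
        for c in curves:
            n = c.temperatures.size
            sl = slice(offset, offset + n)
            offset += n
            p_bp = prob_any_pair(prof["Q"][sl], c.strand_concentration, seq.self_complementary)
            model = np.asarray(p_bp) * prof["mean_p"][sl]
            out.append(c.fractions - model)
    return np.concatenate(out)


@dataclass
class FitResult:
    params: NNParamSet
    residual_norm: float
    per_curve_rmsd: Dict[str, float]
    converged: bool
    n_evaluations: int
    status: int
    message: str
    seed: Optional[int] = None

    def delta_g37(self) -> Dict[str, float]:
        return {f: self.params.delta_g37(f) for f in FEATURES}


def fit_partition_model(
    data: MeltDataset,
    init: NNParamSet,
    *,
    ftol: float = 1e-10,
    xtol: float = 1e-10,
    gtol: float = 1e-8,
    max_nfev: Optional[int] = None,
    verbose: int = 0,
    segment_nfev: int = 50,
) -> FitResult:
    """Trust-region nonlinear least-squares fit of the 40 NN parameters.

    Convergence when the relative reduction of the residual norm or the step
    norm falls below 1e-10 (defaults).  Exhausting the evaluation budget
    yields a result flagged not converged rather than an exception.

    The solver is run in segments of ``segment_nfev`` function evaluations,
    restarting from the last iterate: a restart resets the trust-region
    radius, which escapes the flat plateaus that strongly perturbed starts
    land on far faster than one long run.  Results are deterministic.
    """
    if data.n_curves < 1:
        raise ValidationError("dataset has no curves")

    def fun(x: np.ndarray) -> np.ndarray:
        return residuals(_unpack(x), data)

    budget = max_nfev if max_nfev is not None else 2000
    x = _pack(init)
    total_nfev = 0
    while True:
        res = least_squares(
            fun,
            x,
            method="trf",
            ftol=ftol,
            xtol=xtol,
            gtol=gtol,
            diff_step=1e-6,
            max_nfev=min(segment_nfev, budget - total_nfev),
            verbose=verbose,
        )
        total_nfev += res.nfev
        x = res.x
        if res.status > 0 or total_nfev >= budget:
            break
    params = _unpack(res.x)
    r = res.fun
    per_curve: Dict[str, float] = {}
    offset = 0
    for seq, curves in data.entries:
        for c in curves:
            n = c.temperatures.size
            per_curve[c.curve_id] = float(np.sqrt(np.mean(r[offset : offset + n] ** 2)))
            offset += n
    return FitResult(
        params=params,
        residual_norm=float(np.linalg.norm(r)),
        per_curve_rmsd=per_curve,
        converged=bool(res.status > 0),
        n_evaluations=int(total_nfev),
        status=int(res.status),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# Multistart convergence protocol
# ---------------------------------------------------------------------------


@dataclass
class MultistartResult:
    fits: List[FitResult]
    residual_norms: np.ndarray
    dg37_spread: Dict[str, float]  # max - min of fitted dG37 across starts
    helix_dg37_spread: float
    loop_dg37_spread: float
    best_index: int
    seed: Optional[int]

    @property
    def residual_norm_spread(self) -> float:
        return float(self.residual_norms.max() - self.residual_norms.min())

    @property
    def best(self) -> FitResult:
        return self.fits[self.best_index]


def multistart_fit(
    data: MeltDataset,
    base_init: NNParamSet,
    n_starts: int = 100,
    perturb_frac: float = 0.20,
    seed: Optional[int] = None,
    **fit_kwargs,
) -> MultistartResult:
    """``n_starts`` fits from initializations uniformly perturbed by up to
    ``perturb_frac`` of each parameter's value; reports the spread of the
    residual norm and of per-feature dG37 across starts.

    A single master seed drives deterministic per-start substreams.
    """
    if n_starts < 2:
        raise ValidationError("n_starts must be >= 2")
    streams = np.random.SeedSequence(seed).spawn(n_starts)
    fits: List[FitResult] = []
    for k in range(n_starts):
        rng = np.random.default_rng(streams[k])
        init_k = base_init.perturbed(rng, perturb_frac)
        fit = fit_partition_model(data, init_k, **fit_kwargs)
        fit.seed = seed
        fits.append(fit)
    norms = np.array([f.residual_norm for f in fits])
    dg = {f: np.array([fit.params.delta_g37(f) for fit in fits]) for f in FEATURES}
    spread = {f: float(v.max() - v.min()) for f, v in dg.items()}
    return MultistartResult(
        fits=fits,
        residual_norms=norms,
        dg37_spread=spread,
        helix_dg37_spread=max(spread[f] for f in HELIX_FEATURES),
        loop_dg37_spread=max(spread[f] for f in FEATURES if f.startswith("loop_")),
        best_index=int(np.argmin(norms)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Classical two-state analyses
# ---------------------------------------------------------------------------


@dataclass
class ThermoSummary:
    """Whole-duplex two-state thermodynamics: inputs to the NN regression."""

    seq: DuplexSequence
    dh: float  # kcal/mol
    ds: float  # cal/(mol.K)
    dg37: float  # kcal/mol
    err_dh: float = 1.0
    err_ds: float = 1.0
    err_dg37: float = 1.0


def summaries_from_params(
    seqs: Sequence[DuplexSequence], params: NNParamSet
) -> List[ThermoSummary]:
    """Exact NN-sum summaries (for consistency tests and synthetic corpora)."""
    out = []
    for seq in seqs:
        counts = decompose_duplex(seq)
        dh = sum(n * params.dh[f] for f, n in counts.items())
        ds = sum(n * params.ds[f] for f, n in counts.items())
        if seq.self_complementary:
            ds += DS_SYM
        out.append(ThermoSummary(seq, dh, ds, dh - T37 * ds / 1000.0))
    return out


@dataclass
class TwoStateNNFit:
    params: NNParamSet  # from the dH and dS regressions, loops preset
    se_dh: Dict[str, float]
    se_ds: Dict[str, float]
    dg37: Dict[str, float]  # from the independent dG37 regression
    se_dg37: Dict[str, float]
    residual_dg37: float


def _weighted_lls(
    X: np.ndarray, y: np.ndarray, err: np.ndarray, feature_names: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    w = 1.0 / np.asarray(err, float) ** 2
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        # name features spanning the null space
        _, s, vt = np.linalg.svd(Xw)
        null = vt[rank:]
        bad = sorted(
            {feature_names[j] for row in null for j in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise ValidationError(f"design matrix rank-deficient; unidentifiable features: {bad}")
    beta, *_ = np.linalg.lstsq(Xw, y * sw, rcond=None)
    cov = np.linalg.inv(Xw.T @ Xw)
    return beta, np.sqrt(np.diag(cov))


def fit_two_state_nn(
    summaries: Sequence[ThermoSummary],
    loop_dh: float = 10.0,
    loop_ds: float = -1.0,
) -> TwoStateNNFit:
    """Error-weighted linear regression of NN parameters from two-state
    whole-duplex dH/dS/dG37 summaries.

    The design matrix row of each duplex is its fully-paired feature count
    vector (10 stacks + initiation + terminal_AU); the fixed symmetry entropy
    of self-complementary duplexes is subtracted from the observables before
    regression.  dH, dS and dG37 are fit separately; parameter uncertainties
    are square roots of the diagonal of the variance-covariance matrix.
    """
    names = list(HELIX_FEATURES)
    if len(summaries) < len(names):
        raise ValidationError(
            f"need at least {len(names)} duplexes to identify {len(names)} features"
        )
    X = np.zeros((len(summaries), len(names)))
    for i, s in enumerate(summaries):
        counts = decompose_duplex(s.seq)
        for j, f in enumerate(names):
            X[i, j] = counts.get(f, 0)
    sym = np.array([s.seq.self_complementary for s in summaries], dtype=float)
    y_dh = np.array([s.dh for s in summaries])
    y_ds = np.array([s.ds for s in summaries]) - sym * DS_SYM
    y_dg = np.array([s.dg37 for s in summaries]) - sym * (-T37 * DS_SYM / 1000.0)

    beta_h, se_h = _weighted_lls(X, y_dh, np.array([s.err_dh for s in summaries]), names)
    beta_s, se_s = _weighted_lls(X, y_ds, np.array([s.err_ds for s in summaries]), names)
    beta_g, se_g = _weighted_lls(X, y_dg, np.array([s.err_dg37 for s in summaries]), names)

    dh = {f: float(b) for f, b in zip(names, beta_h)}
    ds = {f: float(b) for f, b in zip(names, beta_s)}
    for n in range(1, 9):
        dh[f"loop_{n}"] = loop_dh
        ds[f"loop_{n}"] = loop_ds
    return TwoStateNNFit(
        params=NNParamSet(dh, ds),
        se_dh={f: float(v) for f, v in zip(names, se_h)},
        se_ds={f: float(v) for f, v in zip(names, se_s)},
        dg37={f: float(b) for f, b in zip(names, beta_g)},
        se_dg37={f: float(v) for f, v in zip(names, se_g)},
        residual_dg37=float(np.linalg.norm(X @ beta_g - y_dg)),
    )


@dataclass
class TwoStateCurveFit:
    dh: float
    ds: float
    tm: float  # deg C
    baselines: BaselineFit
    residual_norm: float
    converged: bool


def fit_two_state_curve(
    curve: MeltingCurve,
    self_complementary: bool = False,
    lower_frac: float = 0.10,
    upper_frac: float = 0.10,
) -> TwoStateCurveFit:
    """Nonlinear two-state fit of one absorbance melting curve.

    Model: A(T) = (1 - f(T)) * upper(T) + f(T) * lower(T) with f from the
    bimolecular two-state equilibrium at the curve's C_T.  Baselines float
    with the thermodynamics.  Returns dH, dS and the implied Tm.
    """
    from .errors import DegenerateBaselineError

    base0 = fit_baselines(curve, lower_frac, upper_frac)
    try:
        frac0 = to_fraction_paired(curve, base0)
    except DegenerateBaselineError as exc:
        raise NoTransitionError(
            f"curve {curve.curve_id!r}: no transition (baselines coincide)"
        ) from exc
    tm0_c = interpolate_tm(frac0)  # raises NoTransitionError on flat curves
    tm0 = tm0_c + CELSIUS_OFFSET
    c_t = curve.strand_concentration
    ln_ct = np.log(c_t) if self_complementary else np.log(c_t / 4.0)
    dh0 = -70.0
    ds0 = (dh0 / tm0 - R_GAS * ln_ct) * 1000.0

    T = curve.temperatures
    TK = T + CELSIUS_OFFSET
    A = curve.absorbances

    def model(x: np.ndarray) -> np.ndarray:
        dh, ds, m_u, b_u, m_l, b_l = (
            x[0] * _H_SCALE,
            x[1] * _S_SCALE,
            x[2],
            x[3],
            x[4],
            x[5],
        )
        with np.errstate(over="raise"):
            try:
                K = np.exp(-(dh - TK * ds / 1000.0) / (R_GAS * TK))
            except FloatingPointError:
                return np.full_like(A, 1e6)
        f = np.asarray(prob_any_pair(1.0 + K, c_t, self_complementary))
        return (1.0 - f) * (m_u * T + b_u) + f * (m_l * T + b_l)

    x0 = np.array(
        [
            dh0 / _H_SCALE,
            ds0 / _S_SCALE,
            base0.upper_slope,
            base0.upper_intercept,
            base0.lower_slope,
            base0.lower_intercept,
        ]
    )
    res = least_squares(lambda x: model(x) - A, x0, method="trf", ftol=1e-12, xtol=1e-12)
    dh, ds = res.x[0] * _H_SCALE, res.x[1] * _S_SCALE
    tm = dh / (ds / 1000.0 + R_GAS * ln_ct) - CELSIUS_OFFSET
    fitted_base = BaselineFit(
        res.x[4], res.x[5], res.x[2], res.x[3], base0.n_lower, base0.n_upper
    )
    return TwoStateCurveFit(
        dh=float(dh),
        ds=float(ds),
        tm=float(tm),
        baselines=fitted_base,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.status > 0),
    )


# ---------------------------------------------------------------------------
# Jackknife
# ---------------------------------------------------------------------------


@dataclass
class JackknifeResult:
    left_out_ids: List[str]
    fits: List[FitResult]
    heldout_rmsd: Dict[str, float]  # mean RMSD over the excluded duplex's curves
    param_sd: Dict[str, Tuple[float, float]]  # per feature: (sd dH, sd dS)
    dg37_sd: Dict[str, float]
    dg37_mean: Dict[str, float]
    n_converged: int


def jackknife(
    data: MeltDataset,
    fitter: Optional[Callable[[MeltDataset], FitResult]] = None,
    init: Optional[NNParamSet] = None,
    **fit_kwargs,
) -> JackknifeResult:
    """Leave-one-duplex-out resampling.

    One fit per left-out duplex; held-out RMSD is computed for the excluded
    duplex's curves under the resample's parameters.  Parameter uncertainty
    is the plain sample SD (ddof=1) across converged resamples; jackknife
    variance inflation by (n-1) is a deliberate non-default alternative.
    """
    if data.n_duplexes < 3:
        raise ValidationError("jackknife needs at least 3 duplexes")
    if fitter is None:
        if init is None:
            raise ValidationError("provide a fitter or an init parameter set")
        fitter = lambda d: fit_partition_model(d, init, **fit_kwargs)

    left_out, fits, heldout = [], [], {}
    for seq, curves in data.entries:
        sub = data.without(seq.duplex_id)
        fit = fitter(sub)
        if not fit.converged:
            warnings.warn(
                f"jackknife resample without {seq.duplex_id!r} did not converge; "
                "excluded from SD",
                stacklevel=2,
            )
        left_out.append(seq.duplex_id)
        fits.append(fit)
        r = residuals(fit.params, MeltDataset([(seq, curves)]))
        heldout[seq.duplex_id] = float(np.sqrt(np.mean(r**2)))

    ok = [f for f in fits if f.converged]
    n_ok = len(ok)
    param_sd: Dict[str, Tuple[float, float]] = {}
    dg_sd: Dict[str, float] = {}
    dg_mean: Dict[str, float] = {}
    for f in FEATURES:
        dh_vals = np.array([fit.params.dh[f] for fit in ok])
        ds_vals = np.array([fit.params.ds[f] for fit in ok])
        dg_vals = np.array([fit.params.delta_g37(f) for fit in ok])
        if n_ok >= 2:
            param_sd[f] = (float(np.std(dh_vals, ddof=1)), float(np.std(ds_vals, ddof=1)))
            dg_sd[f] = float(np.std(dg_vals, ddof=1))
        else:
            param_sd[f] = (float("nan"), float("nan"))
            dg_sd[f] = float("nan")
        dg_mean[f] = float(np.mean(dg_vals)) if n_ok else float("nan")
    return JackknifeResult(left_out, fits, heldout, param_sd, dg_sd, dg_mean, n_ok)


# ---------------------------------------------------------------------------
# Accuracy metrics and statistics
# ---------------------------------------------------------------------------


def rmsd(observed: FractionCurve, predicted: ModelCurve) -> float:
    """Root-mean-square deviation of fraction paired on matching grids."""
    if observed.temperatures.shape != predicted.temperatures.shape or not np.allclose(
        observed.temperatures, predicted.temperatures
    ):
        raise ValidationError("temperature grids do not match")
    return float(np.sqrt(np.mean((observed.fractions - predicted.fractions) ** 2)))


@dataclass
class TTestResult:
    t: float
    p: float
    n: int
    significant: bool
    undefined: bool = False


def paired_one_tailed_t(differences: Sequence[float], alpha: float = 0.05) -> TTestResult:
    """One-tailed paired t-test on per-pair accuracy differences.

    H1: mean(differences) > 0.  Computed from first principles (t = mean /
    (sd/sqrt(n)), p = upper tail of Student's t with n-1 df); zero variance
    yields an undefined, not-significant result.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValidationError("need at least 2 paired differences")
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        return TTestResult(float("nan"), float("nan"), d.size, False, undefined=True)
    t = float(np.mean(d) / (sd / np.sqrt(d.size)))
    p = float(stats.t.sf(t, d.size - 1))
    return TTestResult(t, p, d.size, p < alpha)


# ---------------------------------------------------------------------------
# Benchmark report
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkReport:
    per_duplex: pd.DataFrame  # rows: duplex; columns: (set, metric)
    per_melt: pd.DataFrame  # rows: curve; columns: (set, metric)
    summary: pd.DataFrame  # per-duplex and per-melt averages per set
    ttests: pd.DataFrame  # each set vs the reference


def benchmark_report(
    data: MeltDataset,
    param_sets: Mapping[str, NNParamSet],
    reference: Optional[str] = None,
    alpha: float = 0.05,
) -> BenchmarkReport:
    """Per-duplex and per-melt RMSD / |dTm| comparison of parameter sets.

    All sets are evaluated under the ensemble partition model (two-state sets
    should carry the loop-forbidding preset).  Paired one-tailed t-tests ask
    whether each set improves on the reference (first set by default):
    differences are reference_error - set_error, per duplex and per melt.
    """
    if not param_sets:
        raise ValidationError("no parameter sets given")
    names = list(param_sets)
    if reference is None:
        reference = names[0]
    if reference not in param_sets:
        raise ValidationError(f"reference {reference!r} not among parameter sets")

    melt_rows = []
    for seq, curves in data.entries:
        for c in curves:
            try:
                tm_exp = interpolate_tm(c)
            except NoTransitionError:
                tm_exp = np.nan
            row: Dict[str, object] = {"duplex_id": seq.duplex_id, "curve_id": c.curve_id}
            for name, params in param_sets.items():
                r = residuals(params, MeltDataset([(seq, [c])]))
                row[(name, "rmsd")] = float(np.sqrt(np.mean(r**2)))
                try:
                    tm_pred = predict_tm(seq, params, c.strand_concentration)
                    row[(name, "abs_dtm")] = (
                        abs(tm_pred - tm_exp) if np.isfinite(tm_exp) else np.nan
                    )
                except NoTransitionError:
                    row[(name, "abs_dtm")] = np.nan
            melt_rows.append(row)
    per_melt = pd.DataFrame(melt_rows).set_index(["duplex_id", "curve_id"])
    per_melt.columns = pd.MultiIndex.from_tuples(per_melt.columns)
    per_duplex = per_melt.groupby(level="duplex_id").mean()

    summary = pd.DataFrame(
        {
            "per_duplex_mean": per_duplex.mean(),
            "per_melt_mean": per_melt.mean(),
        }
    )

    rows = []
    for name in names:
        if name == reference:
            continue
        for metric in ("rmsd", "abs_dtm"):
            for scope, table in (("per_duplex", per_duplex), ("per_melt", per_melt)):
                diff = (table[(reference, metric)] - table[(name, metric)]).dropna().values
                if diff.size >= 2:
                    tt = paired_one_tailed_t(diff, alpha)
                    rows.append(
                        {
                            "set": name,
                            "vs": reference,
                            "metric": metric,
                            "scope": scope,
                            "t": tt.t,
                            "p": tt.p,
                            "n": tt.n,
                            "significant": tt.significant,
                        }
                    )
    ttests = pd.DataFrame(rows)
    return BenchmarkReport(per_duplex, per_melt, summary, ttests)
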