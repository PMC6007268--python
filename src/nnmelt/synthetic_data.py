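"""Seeded synthetic optical-melting experiments.

Stands in for undeposited raw melting data: an ensemble (or two-state)
transition placed between sloping linear baselines, sampled on a temperature
grid at multiple strand concentrations, with additive absorbance noise.
Everything is deterministic given the master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ValidationError
from .fitting import MeltDataset
from .melt_io import BaselineFit, FractionCurve, MeltingCurve, fit_baselines, to_fraction_paired
from .partition import predict_curve
from .thermo_model import STACKS, DuplexSequence, NNParamSet, decompose_duplex
from .datasets import literature_params


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic melting corpus.

    Baseline defaults slope upward with temperature (absorbance rises on
    melting) and keep the upper baseline above the lower one across the grid,
    so 10% windows are pure baseline for typical Tm between 30 and 70 deg C.
    Noise is additive on absorbance (the measured quantity).
    """

    duplexes: Sequence[DuplexSequence]
    concentrations: Sequence[float]  # mol/L total strands, shared across duplexes
    params: NNParamSet
    t_start: float = 10.0
    t_stop: float = 90.0
    t_step: float = 0.5
    upper_slope: float = 5.0e-4
    upper_intercept: float = 0.70
    lower_slope: float = 2.0e-4
    lower_intercept: float = 0.60
    noise_sd: float = 0.002
    seed: int = 0
    two_state: bool = False

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ValidationError("t_step must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if any(c <= 0 for c in self.concentrations):
            raise ValidationError("concentrations must be positive")
        if not self.duplexes or not self.concentrations:
            raise ValidationError("need at least one duplex and one concentration")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_stop + 1e-9, self.t_step)

    def baselines(self) -> BaselineFit:
        return BaselineFit(
            self.lower_slope,
            self.lower_intercept,
            self.upper_slope,
            self.upper_intercept,
            n_lower=0,
            n_upper=0,
        )


def generate_melt(
    seq: DuplexSequence,
    params: NNParamSet,
    c_t: float,
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    curve_id: str = "",
) -> MeltingCurve:
    """One synthetic absorbance curve:
    A(T) = (1-X)*upper + X*lower + noise, X from the ensemble model."""
    grid = spec.grid
    upper = spec.upper_slope * grid + spec.upper_intercept
    lower = spec.lower_slope * grid + spec.lower_intercept
    if np.any(upper <= lower):
        raise ValidationError("upper baseline crosses lower baseline inside the grid")
    X = predict_curve(seq, params, c_t, grid, two_state=spec.two_state).fractions
    A = (1.0 - X) * upper + X * lower
    if spec.noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        A = A + rng.normal(0.0, spec.noise_sd, size=A.size)
    return MeltingCurve(
        curve_id=curve_id or f"{seq.duplex_id}_ct{c_t:g}",
        duplex_id=seq.duplex_id,
        temperatures=grid.copy(),
        absorbances=A,
        strand_concentration=c_t,
    )


@dataclass
class SyntheticDataset:
    raw: List[Tuple[DuplexSequence, List[MeltingCurve]]]
    truth: NNParamSet
    spec: SyntheticSpec

    @property
    def n_curves(self) -> int:
        return sum(len(c) for _, c in self.raw)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full synthetic corpus plus the generating truth for recovery scoring.

    Warns when some Watson-Crick stack never occurs in the duplex list
    (recovery tests then cannot identify it).  Per-curve noise streams are
    spawned deterministically from the master seed.
    """
    covered = set()
    for seq in spec.duplexes:
        covered.update(f for f in decompose_duplex(seq) if "/" in f)
    missing = set(STACKS) - covered
    if missing:
        warnings.warn(
            f"stacks not represented in any duplex: {sorted(missing)}", stacklevel=2
        )
    streams = np.random.SeedSequence(spec.seed).spawn(
        len(spec.duplexes) * len(spec.concentrations)
    )
    raw: List[Tuple[DuplexSequence, List[MeltingCurve]]] = []
    k = 0
    for seq in spec.duplexes:
        curves = []
        for j, c_t in enumerate(spec.concentrations):
            rng = np.random.default_rng(streams[k])
            k += 1
            curves.append(
                generate_melt(
                    seq, spec.params, c_t, spec, rng, curve_id=f"{seq.duplex_id}_m{j}"
                )
            )
        raw.append((seq, curves))
    return SyntheticDataset(raw, spec.params, spec)


def fraction_dataset(
    synth: SyntheticDataset,
    use_true_baselines: bool = True,
    lower_frac: float = 0.10,
    upper_frac: float = 0.10,
) -> MeltDataset:
    """Transform a synthetic corpus to fraction curves.

    ``use_true_baselines=True`` applies the generating baselines (exact
    round trip, isolates thermodynamic recovery from baseline estimation);
    ``False`` exercises the full melt_io path with fitted baselines.
    """
    entries = []
    for seq, curves in synth.raw:
        fracs: List[FractionCurve] = []
        for c in curves:
            base = (
                synth.spec.baselines()
                if use_true_baselines
                else fit_baselines(c, lower_frac, upper_frac)
            )
            fracs.append(to_fraction_paired(c, base))
        entries.append((seq, fracs))
    return MeltDataset(entries)


# ---------------------------------------------------------------------------
# Corpus builders
# ---------------------------------------------------------------------------


def random_duplexes(
    n: int,
    rng: np.random.Generator,
    length_range: Tuple[int, int] = (5, 8),
    require_coverage: bool = True,
    max_attempts: int = 1000,
) -> List[DuplexSequence]:
    """``n`` random duplexes; with ``require_coverage``, resamples until all
    10 stacks occur somewhere in the list (deterministic given the rng)."""
    lo, hi = length_range
    for _ in range(max_attempts):
        seqs = []
        for i in range(n):
            L = int(rng.integers(lo, hi + 1))
            top = "".join(rng.choice(list("ACGU"), size=L))
            seqs.append(DuplexSequence(f"s{i:02d}", top))
        covered = set()
        for s in seqs:
            covered.update(f for f in decompose_duplex(s) if "/" in f)
        if not require_coverage or len(covered) == len(STACKS):
            return seqs
    raise ValidationError(
        f"could not cover all stacks with {n} duplexes of length {length_range}"
    )


def default_truth_params(loop_dh: float = 5.0, loop_ds: float = -1.0) -> NNParamSet:
    """Physically plausible generating truth: the published helix set with
    moderately unfavorable (but not forbidden) disordered-loop terms."""
    return literature_params(loop_dh=loop_dh, loop_ds=loop_ds)


def recovery_spec(
    n_duplexes: int = 30,
    n_concentrations: int = 8,
    noise_sd: float = 0.0,
    seed: int = 0,
    t_step: float = 2.5,
    params: Optional[NNParamSet] = None,
) -> SyntheticSpec:
    """Standard parameter-recovery corpus: random stack-covering duplexes,
    log-spaced strand concentrations, configurable noise and grid."""
    rng = np.random.default_rng(seed)
    duplexes = random_duplexes(n_duplexes, rng)
    concentrations = np.geomspace(2e-6, 2e-4, n_concentrations).tolist()
    return SyntheticSpec(
        duplexes=duplexes,
        concentrations=concentrations,
        params=params if params is not None else default_truth_params(),
        noise_sd=noise_sd,
        seed=seed,
        t_step=t_step,
    )
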