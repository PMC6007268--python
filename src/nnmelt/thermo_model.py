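"""Sequence and parameter data model for no-slip RNA duplexes.

A duplex is a top strand 5'->3' paired against its full reverse complement;
no register slipping is allowed, so position ``i`` of the top strand can only
pair with its partner on the bottom strand.  Helix stability is decomposed
into nearest-neighbor features: 10 Watson-Crick stacks, one intermolecular
initiation term, a terminal A-U helix-end term, and 8 symmetric disordered
internal-loop terms indexed by unpaired nucleotides per side (n = 1..8, total
loop size 2n).  Each feature carries an enthalpy (kcal/mol) and an entropy
(cal/(mol.K)), giving 40 free parameters.

This module also hosts the brute-force structure enumerator and per-structure
energy used as the independent oracle for :mod:`nnmelt.partition`.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterator, Mapping, Sequence, Tuple

import numpy as np

from .errors import ValidationError

#: Gas constant in kcal/(mol.K).
R_GAS = 1.98717e-3

#: Fixed symmetry entropy correction (-R ln 2) for self-complementary
#: duplexes, in cal/(mol.K); applied once per structure with >= 1 pair.
DS_SYM = -1.377

#: Reference temperature (37 C) used for dG37 reporting, kelvin.
T37 = 310.15

CELSIUS_OFFSET = 273.15

MAX_LOOP = 8

STACKS: Tuple[str, ...] = (
    "AA/UU", "AU/UA", "UA/AU", "CU/GA", "CA/GU",
    "GU/CA", "GA/CU", "CG/GC", "GG/CC", "GC/CG",
)
LOOP_FEATURES: Tuple[str, ...] = tuple(f"loop_{n}" for n in range(1, MAX_LOOP + 1))
HELIX_FEATURES: Tuple[str, ...] = STACKS + ("initiation", "terminal_AU")
FEATURES: Tuple[str, ...] = HELIX_FEATURES + LOOP_FEATURES

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Canonical name for each top-strand dinucleotide; total over the 16 WC
# dinucleotides, absorbing the choice of strand.
_CANONICAL_STACK = {
    "AA": "AA/UU", "UU": "AA/UU",
    "AU": "AU/UA",
    "UA": "UA/AU",
    "CU": "CU/GA", "AG": "CU/GA",
    "CA": "CA/GU", "UG": "CA/GU",
    "GU": "GU/CA", "AC": "GU/CA",
    "GA": "GA/CU", "UC": "GA/CU",
    "CG": "CG/GC",
    "GG": "GG/CC", "CC": "GG/CC",
    "GC": "GC/CG",
}


def reverse_complement(strand: str) -> str:
    """Reverse complement of an RNA string over {A,C,G,U}."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(strand))
    except KeyError as exc:
        raise ValidationError(
            f"invalid RNA base {exc.args[0]!r} in {strand!r}; expected A/C/G/U"
        ) from None


def canonical_stack(dinucleotide: str) -> str:
    """Canonical stack label for a top-strand dinucleotide (5'->3')."""
    try:
        return _CANONICAL_STACK[dinucleotide]
    except KeyError:
        raise ValidationError(f"not a Watson-Crick dinucleotide: {dinucleotide!r}") from None


@dataclass(frozen=True)
class DuplexSequence:
    """A fully complementary, no-slip RNA duplex identified by its top strand.

    Parameters
    ----------
    duplex_id:
        Caller-chosen identifier.
    top_strand:
        Top strand 5'->3' over {A,C,G,U}; the bottom strand is its reverse
        complement by construction.
    """

    duplex_id: str
    top_strand: str

    def __post_init__(self) -> None:
        if len(self.top_strand) < 2:
            raise ValidationError(
                f"duplex {self.duplex_id!r}: need at least 2 base pairs, "
                f"got {len(self.top_strand)}"
            )
        bad = set(self.top_strand) - set("ACGU")
        if bad:
            raise ValidationError(
                f"duplex {self.duplex_id!r}: invalid bases {sorted(bad)}; expected A/C/G/U"
            )

    @property
    def length(self) -> int:
        """Number of base pairs L in the fully paired duplex."""
        return len(self.top_strand)

    @property
    def bottom_strand(self) -> str:
        return reverse_complement(self.top_strand)

    @property
    def self_complementary(self) -> bool:
        return self.top_strand == self.bottom_strand


# A pairing state is a sorted tuple of 1-based paired positions.
PairingState = Tuple[int, ...]


def _loop_feature(gap: int) -> str:
    if gap > MAX_LOOP:
        raise ValidationError(
            f"internal loop of {gap} unpaired nucleotides per side exceeds "
            f"the maximum of {MAX_LOOP}"
        )
    return f"loop_{gap}"


class NNParamSet:
    """Nearest-neighbor parameter set: (dH, dS) per feature.

    dH in kcal/mol, dS in cal/(mol.K).  Holds exactly the 20 features of
    :data:`FEATURES` (40 free parameters).  Fixed constants (R, the
    self-complementary symmetry entropy) are module-level, not fitted.
    """

    __slots__ = ("dh", "ds")

    def __init__(self, dh: Mapping[str, float], ds: Mapping[str, float]):
        missing = set(FEATURES) - set(dh) | set(FEATURES) - set(ds)
        extra = (set(dh) | set(ds)) - set(FEATURES)
        if missing or extra:
            raise ValidationError(
                f"parameter set must define exactly {len(FEATURES)} features; "
                f"missing={sorted(missing)} unknown={sorted(extra)}"
            )
        self.dh: Dict[str, float] = {f: float(dh[f]) for f in FEATURES}
        self.ds: Dict[str, float] = {f: float(ds[f]) for f in FEATURES}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_pairs(cls, pairs: Mapping[str, Tuple[float, float]]) -> "NNParamSet":
        return cls({f: v[0] for f, v in pairs.items()}, {f: v[1] for f, v in pairs.items()})

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "NNParamSet":
        """Inverse of :meth:`to_vector` (dH block then dS block, FEATURES order)."""
        x = np.asarray(x, dtype=float)
        n = len(FEATURES)
        if x.shape != (2 * n,):
            raise ValidationError(f"expected parameter vector of length {2 * n}, got {x.shape}")
        return cls(dict(zip(FEATURES, x[:n])), dict(zip(FEATURES, x[n:])))

    def to_vector(self) -> np.ndarray:
        return np.array(
            [self.dh[f] for f in FEATURES] + [self.ds[f] for f in FEATURES], dtype=float
        )

    # -- energies -------------------------------------------------------------

    def delta_g(self, feature: str, T: float) -> float:
        """dG(T) = dH - T*dS/1000 in kcal/mol for one feature; T in kelvin."""
        if feature not in self.dh:
            raise ValidationError(f"unknown feature {feature!r}")
        return self.dh[feature] - T * self.ds[feature] / 1000.0

    def delta_g37(self, feature: str) -> float:
        return self.delta_g(feature, T37)

    def delta_g_arrays(self, T: np.ndarray) -> Dict[str, np.ndarray]:
        """dG(T) per feature, vectorized over a kelvin array."""
        T = np.asarray(T, dtype=float)
        return {f: self.dh[f] - T * self.ds[f] / 1000.0 for f in FEATURES}

    # -- misc -----------------------------------------------------------------

    def perturbed(self, rng: np.random.Generator, frac: float) -> "NNParamSet":
        """Each parameter multiplied by (1 + u), u ~ U(-frac, frac)."""
        x = self.to_vector()
        return NNParamSet.from_vector(x * (1.0 + rng.uniform(-frac, frac, size=x.size)))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, NNParamSet) and self.dh == other.dh and self.ds == other.ds
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NNParamSet({len(FEATURES)} features)"

    # -- parameter-table I/O ---------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the feature/dH/dS table (CSV)."""
        lines = ["feature,dH_kcal_mol,dS_cal_mol_K"]
        lines += [f"{f},{self.dh[f]:.10g},{self.ds[f]:.10g}" for f in FEATURES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        fill_loops: Tuple[float, float] | None = None,
    ) -> "NNParamSet":
        """Read a feature table (comma or tab separated, '#' comments).

        ``fill_loops=(dH, dS)`` supplies values for any loop features absent
        from the table (two-state parameter sets have no loop terms).
        """
        dh: Dict[str, float] = {}
        ds: Dict[str, float] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
            if parts[0] == "feature":
                continue
            if len(parts) < 3:
                raise ValidationError(f"{path}: line {lineno}: expected feature,dH,dS")
            feature = parts[0]
            if feature not in FEATURES:
                raise ValidationError(f"{path}: line {lineno}: unknown feature {feature!r}")
            try:
                dh[feature] = float(parts[1])
                ds[feature] = float(parts[2])
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric dH/dS for {feature!r}"
                ) from None
        if fill_loops is not None:
            for f in LOOP_FEATURES:
                dh.setdefault(f, fill_loops[0])
                ds.setdefault(f, fill_loops[1])
        return cls(dh, ds)


def with_loop_preset(
    params: NNParamSet, loop_dh: float = 10.0, loop_ds: float = -1.0
) -> NNParamSet:
    """Copy of ``params`` with every disordered-loop feature set to the given
    (dH, dS).  The default 10.0 kcal/mol / -1.0 cal/(mol.K) effectively
    forbids loop formation, which is how two-state parameter sets (that have
    no loop terms) are evaluated under the ensemble model."""
    dh = dict(params.dh)
    ds = dict(params.ds)
    for f in LOOP_FEATURES:
        dh[f] = loop_dh
        ds[f] = loop_ds
    return NNParamSet(dh, ds)


# ---------------------------------------------------------------------------
# Duplex decomposition (fully paired helix)
# ---------------------------------------------------------------------------


def decompose_duplex(seq: DuplexSequence) -> Counter:
    """Nearest-neighbor feature counts of the fully paired duplex.

    Counts each adjacent top-strand dinucleotide once (self-complementary
    duplexes counted once, not twice), one initiation per duplex, and one
    terminal_AU per duplex-terminal A-U or U-A closing pair.
    """
    top = seq.top_strand
    counts: Counter = Counter()
    for i in range(seq.length - 1):
        counts[canonical_stack(top[i : i + 2])] += 1
    counts["initiation"] = 1
    counts["terminal_AU"] = int(top[0] in "AU") + int(top[-1] in "AU")
    return counts


def feature_delta_g(params: NNParamSet, feature: str, T: float) -> float:
    """dG(T) of a single feature; thin alias kept for API symmetry."""
    return params.delta_g(feature, T)


# ---------------------------------------------------------------------------
# Pairing states: features, energy, enumeration (the oracle)
# ---------------------------------------------------------------------------


def state_features(seq: DuplexSequence, state: Sequence[int]) -> Counter:
    """Feature counts of one pairing state (1-based paired positions).

    Stacks between adjacent paired positions, loop_g for each maximal
    internal gap of g unpaired positions, one initiation, and one
    terminal_AU for every helix-terminal A-U/U-A pair (a paired position
    whose neighbor on that side is unpaired or off the end; an isolated
    A-U pair counts twice).  Frayed single-stranded ends contribute nothing.
    """
    positions = sorted(int(p) for p in state)
    if not positions:
        raise ValidationError("empty pairing state has no features (dG = 0 by convention)")
    if positions[0] < 1 or positions[-1] > seq.length or len(set(positions)) != len(positions):
        raise ValidationError(f"invalid pairing state {positions} for L={seq.length}")
    top = seq.top_strand
    paired = set(positions)
    counts: Counter = Counter()
    counts["initiation"] = 1
    for a, b in zip(positions, positions[1:]):
        gap = b - a - 1
        if gap == 0:
            counts[canonical_stack(top[a - 1 : a + 1])] += 1
        else:
            counts[_loop_feature(gap)] += 1
    for p in positions:
        if top[p - 1] in "AU":
            if p - 1 not in paired:
                counts["terminal_AU"] += 1
            if p + 1 not in paired:
                counts["terminal_AU"] += 1
    return counts


def structure_energy(
    seq: DuplexSequence, state: Sequence[int], params: NNParamSet, T: float
) -> float:
    """dG(T) of one pairing state in kcal/mol; T in kelvin.

    Adds the fixed symmetry term -T*DS_SYM/1000 once for self-complementary
    duplexes (any structure with >= 1 pair).
    """
    counts = state_features(seq, state)
    energy = sum(n * params.delta_g(f, T) for f, n in counts.items())
    if seq.self_complementary:
        energy += -T * DS_SYM / 1000.0
    return energy


def enumerate_states(seq: DuplexSequence, max_length: int = 16) -> Iterator[PairingState]:
    """All valid pairing states, including the empty one.

    Valid means every maximal internal gap between two paired positions is
    at most MAX_LOOP.  Brute-force oracle only; refuses long duplexes.
    """
    L = seq.length
    if L > max_length:
        raise ValidationError(f"enumeration limited to L <= {max_length}; got L={L}")
    for mask in itertools.product((False, True), repeat=L):
        positions = tuple(i + 1 for i, on in enumerate(mask) if on)
        if positions and max(
            (b - a - 1 for a, b in zip(positions, positions[1:])), default=0
        ) > MAX_LOOP:
            continue
        yield positions


def state_feature_matrix(seq: DuplexSequence) -> Tuple[list, np.ndarray]:
    """(states, matrix) where matrix[k, j] counts FEATURES[j] in state k.

    The empty state is excluded.  Used to vectorize the brute-force oracle
    over many parameter sets: state energies are ``matrix @ dg_vector`` plus
    the symmetry term.
    """
    states = [s for s in enumerate_states(seq) if s]
    index = {f: j for j, f in enumerate(FEATURES)}
    mat = np.zeros((len(states), len(FEATURES)))
    for k, s in enumerate(states):
        for f, n in state_features(seq, s).items():
            mat[k, index[f]] = n
    return states, mat
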