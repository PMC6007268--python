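"""Bundled reference data.

``benchmark_duplexes()`` returns the 34 Watson-Crick RNA duplexes compiled
from published optical-melting studies that this method is benchmarked on
(top strands 5'->3'; each paired with its full reverse complement; 11 are
self-complementary).

``literature_params()`` returns the standard published two-state-derived RNA
Watson-Crick nearest-neighbor dH/dS set, conventionally used both as the
comparison baseline and as the starting point for ensemble fits.  Loop
features are not part of that published set; the loader fills them with a
caller-supplied value (default: the loop-forbidding two-state preset of
10.0 kcal/mol and -1.0 cal/(mol.K)).
"""

from __future__ import annotations

from typing import List, Tuple

from .thermo_model import DuplexSequence, NNParamSet

#: (duplex_id, top strand 5'->3') for the 34 benchmark duplexes.
BENCHMARK_TOP_STRANDS: Tuple[Tuple[str, str], ...] = (
    ("d01", "GACUCAG"),
    ("d02", "GAGGAG"),
    ("d03", "GAGUGAG"),
    ("d04", "GCACG"),
    ("d05", "GCUCG"),
    ("d06", "GGCUUCAA"),
    ("d07", "GUCACUG"),
    ("d08", "GUGUCG"),
    ("d09", "UAUGCAUA"),
    ("d10", "UCAGACU"),
    ("d11", "UCAUGA"),
    ("d12", "UCGCU"),
    ("d13", "UCUAUAGA"),
    ("d14", "UGACAGU"),
    ("d15", "UGAUCA"),
    ("d16", "UGCGU"),
    ("d17", "UUCCGGAA"),
    ("d18", "UUGCGCAA"),
    ("d19", "UUGGCCAA"),
    ("d20", "UUGUACAA"),
    ("d21", "CAGUCAGU"),
    ("d22", "UCAAUUAGU"),
    ("d23", "UCACUGAGU"),
    ("d24", "UCAGUCAG"),
    ("d25", "UCAGUCAGU"),
    ("d26", "UCAUUAAGU"),
    ("d27", "CACAGCAC"),
    ("d28", "CACGGCUC"),
    ("d29", "UUAUCGAUAA"),
    ("d30", "AUCGGUA"),
    ("d31", "UUGACCAU"),
    ("d32", "AACUAGUU"),
    ("d33", "AGUAUACU"),
    ("d34", "UAGAUCUA"),
)

#: Published two-state RNA WC nearest-neighbor (dH kcal/mol, dS cal/(mol.K)).
LITERATURE_DH_DS: Tuple[Tuple[str, float, float], ...] = (
    ("AA/UU", -6.82, -19.0),
    ("AU/UA", -9.38, -26.7),
    ("UA/AU", -7.69, -20.5),
    ("CU/GA", -10.48, -27.1),
    ("CA/GU", -10.44, -26.9),
    ("GU/CA", -11.40, -29.5),
    ("GA/CU", -12.44, -32.5),
    ("CG/GC", -10.64, -26.7),
    ("GG/CC", -13.39, -32.7),
    ("GC/CG", -14.88, -36.9),
    ("initiation", 3.61, -1.5),
    ("terminal_AU", 3.72, 10.5),
)


def benchmark_duplexes() -> List[DuplexSequence]:
    """The 34 bundled benchmark duplexes as validated DuplexSequence objects."""
    return [DuplexSequence(did, top) for did, top in BENCHMARK_TOP_STRANDS]


def literature_params(loop_dh: float = 10.0, loop_ds: float = -1.0) -> NNParamSet:
    """Published two-state NN set, with loop features filled in.

    The defaults effectively forbid internal-loop formation, which is the
    convention for evaluating two-state-derived sets under the ensemble
    model; pass other values to allow loops.
    """
    dh = {f: h for f, h, _ in LITERATURE_DH_DS}
    ds = {f: s for f, _, s in LITERATURE_DH_DS}
    for n in range(1, 9):
        dh[f"loop_{n}"] = loop_dh
        ds[f"loop_{n}"] = loop_ds
    return NNParamSet(dh, ds)
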