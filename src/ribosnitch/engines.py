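"""Folding-engine abstraction: the internal model or an external package.

The scoring pipeline only needs a callable ``seq -> BasePairProbabilityMatrix``.
The internal engine (default) uses this package's own nearest-neighbor
model.  The ``vienna`` adapter delegates to the ViennaRNA Turner-parameter
implementation when its Python bindings are importable; it exists to
reproduce published absolute correlation values, which depend on the full
Turner parameter set.
"""

from __future__ import annotations

import numpy as np

from .model import EnergyModel
from .sequence import RnaSequence
from .thermo import BasePairProbabilityMatrix, partition_function


class InternalEngine:
    """Partition functions from the package's own energy model."""

    name = "internal"

    def __init__(self, model: EnergyModel | None = None) -> None:
        self.model = model or EnergyModel.default()

    def __call__(self, seq: RnaSequence) -> BasePairProbabilityMatrix:
        return partition_function(seq, self.model)


class ViennaEngine:
    """Adapter over ViennaRNA's partition function (Turner parameters)."""

    name = "vienna"

    def __init__(self) -> None:
        try:
            import RNA  # noqa: F401
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise RuntimeError(
                "the 'vienna' engine requires the ViennaRNA Python bindings "
                "(module 'RNA')"
            ) from exc
        self._rna = RNA

    def __call__(self, seq: RnaSequence) -> BasePairProbabilityMatrix:
        RNA = self._rna
        fc = RNA.fold_compound(seq.residues)
        _, dg = fc.pf()
        n = len(seq)
        bpp = np.array(fc.bpp())[1:, 1:]  # ViennaRNA returns 1-indexed upper triangle
        mat = bpp + bpp.T
        kt = fc.exp_params.kT / 1000.0  # cal -> kcal/mol; populated by fc.pf()
        log_z = -dg / kt
        z = float(np.exp(log_z)) if log_z < 700 else float("inf")
        return BasePairProbabilityMatrix(matrix=mat, z=z, log_z=log_z, sequence_id=seq.id)


def get_engine(name: str, model: EnergyModel | None = None):
    if name == "internal":
        return InternalEngine(model)
    if name == "vienna":
        return ViennaEngine()
    raise ValueError(f"unknown engine {name!r}; choose 'internal' or 'vienna'")
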