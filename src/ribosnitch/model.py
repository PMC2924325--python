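"""Nearest-neighbor energy model: parameters, tables, Boltzmann weights.

The model assigns a free energy (kcal/mol) to every nested secondary
structure by loop decomposition: each base pair closes exactly one loop
(hairpin, stacked pair, bulge, internal loop, or multiloop) and the
structure energy is the sum of loop energies; the exterior loop is free.
The same decomposition is used by the dynamic-programming recursions, the
exhaustive-enumeration oracle, and the stochastic sampler, so all engines
agree exactly on the ensemble they describe.

Parameters are loaded from a small versioned YAML file; the bundled default
set is ``params/default.yaml``.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

#: canonical base ordering used for integer encoding
BASES = "ACGU"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: canonical ordering of the six admissible pair types
PAIR_TYPES = ("AU", "UA", "GC", "CG", "GU", "UG")
PAIR_TYPE_INDEX = {p: i for i, p in enumerate(PAIR_TYPES)}

INF = 1e18


class ParameterError(ValueError):
    """Raised for malformed or inconsistent energy-parameter files."""


def _loop_table(entries: dict[int, float], min_size: int) -> np.ndarray:
    sizes = sorted(entries)
    if sizes[0] != min_size or sizes != list(range(min_size, sizes[-1] + 1)):
        raise ParameterError(
            f"loop table must cover consecutive sizes starting at {min_size}, got {sizes}"
        )
    return np.array([entries[s] for s in sizes], dtype=float)


@dataclass(frozen=True)
class EnergyModel:
    """A fully specified nearest-neighbor model for nested RNA structures.

    Attributes
    ----------
    allowed_pairs : frozenset of 2-letter pair strings (subset of the six
        canonical Watson-Crick + wobble pairs).
    stack : 6x6 array of step energies indexed by (outer pair type, inner
        pair type) in :data:`PAIR_TYPES` order; +inf marks disallowed steps.
    hairpin_tab, bulge_tab, internal_tab : tabulated loop penalties starting
        at the minimum size of each class (hairpin: ``min_hairpin_loop``,
        bulge: 1, internal: 2).
    ml_closing, ml_branch, ml_unpaired : affine multiloop coefficients.
    min_hairpin_loop : minimum number of unpaired residues in a hairpin (h).
    max_interior_loop : bulge/internal loops larger than this are disallowed
        outright (a hard model constraint, not just an extrapolated penalty).
    temperature : kelvin.  gas_constant : kcal/(mol*K).
    """

    allowed_pairs: frozenset
    stack: np.ndarray
    hairpin_tab: np.ndarray
    bulge_tab: np.ndarray
    internal_tab: np.ndarray
    ml_closing: float
    ml_branch: float
    ml_unpaired: float
    min_hairpin_loop: int
    max_interior_loop: int
    temperature: float
    gas_constant: float
    loop_extrapolation_factor: float
    source_digest: str = "unversioned"
    version: int = 0

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ParameterError("minimum hairpin loop must be >= 3")
        bad = set(self.allowed_pairs) - set(PAIR_TYPES)
        if bad:
            raise ParameterError(f"disallowed pair types in parameter file: {sorted(bad)}")
        if not np.all(np.isfinite(self.stack[self.stack < INF / 2])):
            raise ParameterError("stacking energies must be finite")

    # ------------------------------------------------------------------
    # derived quantities
    # ------------------------------------------------------------------
    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return self.gas_constant * self.temperature

    def pair_type_table(self) -> np.ndarray:
        """4x4 table mapping (base_i, base_j) to a pair-type id, -1 if unpairable."""
        tab = -np.ones((4, 4), dtype=np.int64)
        for pt, idx in PAIR_TYPE_INDEX.items():
            if pt in self.allowed_pairs:
                tab[BASE_INDEX[pt[0]], BASE_INDEX[pt[1]]] = idx
        return tab

    def _extrapolate(self, tab: np.ndarray, min_size: int, upto: int) -> np.ndarray:
        """Loop energies for sizes 0..upto; sizes below min_size get +inf."""
        out = np.full(upto + 1, INF)
        top = min_size + len(tab) - 1
        for s in range(min_size, upto + 1):
            if s <= top:
                out[s] = tab[s - min_size]
            else:
                out[s] = tab[-1] + self.loop_extrapolation_factor * self.rt * math.log(s / top)
        return out

    def loop_energy_tables(self, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(hairpin, bulge, internal) energy arrays indexed by loop size, up to n.

        Bulge/internal sizes beyond ``max_interior_loop`` are +inf (disallowed).
        """
        hp = self._extrapolate(self.hairpin_tab, self.min_hairpin_loop, max(n, self.min_hairpin_loop))
        bu = self._extrapolate(self.bulge_tab, 1, max(n, 1))
        il = self._extrapolate(self.internal_tab, 2, max(n, 2))
        bu[self.max_interior_loop + 1 :] = INF
        il[self.max_interior_loop + 1 :] = INF
        return hp, bu, il

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict, digest: str = "unversioned") -> "EnergyModel":
        try:
            allowed = frozenset(cfg["allowed_pairs"])
            stack = np.full((6, 6), INF)
            for outer, inner_map in cfg["stack"].items():
                for inner, e in inner_map.items():
                    stack[PAIR_TYPE_INDEX[outer], PAIR_TYPE_INDEX[inner]] = float(e)
            ml = cfg["multiloop"]
            return cls(
                allowed_pairs=allowed,
                stack=stack,
                hairpin_tab=_loop_table(cfg["hairpin"], int(cfg["min_hairpin_loop"])),
                bulge_tab=_loop_table(cfg["bulge"], 1),
                internal_tab=_loop_table(cfg["internal"], 2),
                ml_closing=float(ml["closing"]),
                ml_branch=float(ml["branch"]),
                ml_unpaired=float(ml["unpaired"]),
                min_hairpin_loop=int(cfg["min_hairpin_loop"]),
                max_interior_loop=int(cfg["max_interior_loop"]),
                temperature=float(cfg["temperature_kelvin"]),
                gas_constant=float(cfg["gas_constant_kcal"]),
                loop_extrapolation_factor=float(cfg["loop_extrapolation_factor"]),
                source_digest=digest,
                version=int(cfg.get("version", 0)),
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ParameterError(f"missing key in parameter file: {exc}") from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyModel":
        text = Path(path).read_text()
        digest = hashlib.sha256(text.encode()).hexdigest()[:16]
        return cls.from_dict(yaml.safe_load(text), digest=digest)

    @classmethod
    def default(cls) -> "EnergyModel":
        text = resources.files("ribosnitch.params").joinpath("default.yaml").read_text()
        digest = hashlib.sha256(text.encode()).hexdigest()[:16]
        return cls.from_dict(yaml.safe_load(text), digest=digest)

    def zero_energy_variant(self) -> "EnergyModel":
        """A copy with every energy term set to 0 (uniform ensemble).

        Useful for counting/uniform-sampling checks: every admissible
        structure then has Boltzmann weight 1 and Z equals the number of
        admissible structures.
        """
        stack = np.where(self.stack < INF / 2, 0.0, INF)
        return EnergyModel(
            allowed_pairs=self.allowed_pairs,
            stack=stack,
            hairpin_tab=np.zeros_like(self.hairpin_tab),
            bulge_tab=np.zeros_like(self.bulge_tab),
            internal_tab=np.zeros_like(self.internal_tab),
            ml_closing=0.0,
            ml_branch=0.0,
            ml_unpaired=0.0,
            min_hairpin_loop=self.min_hairpin_loop,
            max_interior_loop=self.max_interior_loop,
            temperature=self.temperature,
            gas_constant=self.gas_constant,
            loop_extrapolation_factor=0.0,
            source_digest=self.source_digest + "+zeroed",
            version=self.version,
        )


def encode_sequence(residues: str) -> np.ndarray:
    """Integer-encode residues (A=0, C=1, G=2, U=3)."""
    return np.array([BASE_INDEX[b] for b in residues], dtype=np.int64)
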