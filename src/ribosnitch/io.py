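"""File formats and run provenance: FASTA in, TSV/JSON/dot-bracket out.

All tabular output is TSV with one header row; floats are printed at six
significant digits; writes are atomic (temp file + rename).  Every run
directory gets a machine-readable manifest recording the inputs, seeds,
energy-parameter digest and package version that produced it.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .model import BASES, EnergyModel
from .scoring import MutationScanResult, SnpScore
from .sequence import RnaSequence, SequenceError, parse_mutation  # noqa: F401  (re-export)
from .structure import SecondaryStructure

FLOAT_FMT = "{:.6g}"


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a (multi-)FASTA file into RNA sequences, in file order.

    DNA is converted (T -> U); ambiguity codes are rejected with the record
    id and offending position in the message.  An empty file is an error.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        try:
            out.append(RnaSequence(id=rec.id, residues=str(rec.seq)))
        except SequenceError as exc:
            raise SequenceError(f"record {rec.id!r}: {exc}") from exc
    return out


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:  # pragma: no cover - cleanup path
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x: float) -> str:
    return FLOAT_FMT.format(float(x))


def write_scan_tsv(scan: MutationScanResult, path: str | Path) -> None:
    """Scan table: mutation, position, wild, variant, correlation, rank, p_value."""
    lines = ["mutation\tposition\twild\tvariant\tcorrelation\trank\tp_value"]
    order = np.argsort(scan.correlations, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    sorted_r = scan.correlations[order]
    # conservative tie handling: every member of a tie gets the largest rank
    ranks_sorted = np.searchsorted(sorted_r, sorted_r, side="right")
    ranks[order] = ranks_sorted
    total = len(scan.mutations)
    for mut, r, rank in zip(scan.mutations, scan.correlations, ranks):
        lines.append(
            f"{mut.label}\t{mut.position}\t{mut.wild}\t{mut.variant}\t"
            f"{_fmt(r)}\t{rank}\t{_fmt(rank / total)}"
        )
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_heatmap_tsv(scan: MutationScanResult, path: str | Path) -> None:
    """4 x n heat map, rows labelled A,C,G,U; wild-type cells printed as '.'."""
    hm = scan.heat_map()
    lines = ["base\t" + "\t".join(str(p) for p in range(1, scan.n + 1))]
    for row, base in enumerate(BASES):
        cells = ["." if np.isnan(v) else _fmt(v) for v in hm[row]]
        lines.append(base + "\t" + "\t".join(cells))
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_bppm_tsv(matrix: np.ndarray, path: str | Path, dense: bool = False) -> None:
    """Base-pair probability matrix as sparse upper-triangle or dense TSV."""
    n = matrix.shape[0]
    if dense:
        lines = ["\t".join(_fmt(matrix[i, j]) for j in range(n)) for i in range(n)]
    else:
        lines = ["i\tj\tprobability"]
        for i in range(n):
            for j in range(i + 1, n):
                if matrix[i, j] > 0:
                    lines.append(f"{i + 1}\t{j + 1}\t{_fmt(matrix[i, j])}")
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_accessibility_tsv(vectors: dict, path: str | Path) -> None:
    """Per-nucleotide paired probabilities, one column per labelled sequence."""
    labels = list(vectors)
    n = len(next(iter(vectors.values())))
    lines = ["position\t" + "\t".join(labels)]
    for pos in range(n):
        lines.append(
            f"{pos + 1}\t" + "\t".join(_fmt(vectors[lab][pos]) for lab in labels)
        )
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_projection_tsv(projections, summary, path: str | Path) -> None:
    """Pooled projection table: sequence_label, structure_index, pc1, pc2, cluster."""
    lines = ["sequence_label\tstructure_index\tpc1\tpc2\tcluster"]
    for proj in projections:
        labels = summary.assignments[proj.sequence_id]
        for idx, ((x, y), c) in enumerate(zip(proj.coordinates, labels)):
            lines.append(f"{proj.sequence_id}\t{idx}\t{_fmt(x)}\t{_fmt(y)}\t{c}")
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_occupancy_tsv(summary, path: str | Path) -> None:
    """Cluster occupancy per sequence (fractions in [0, 1])."""
    lines = ["sequence_label\t" + "\t".join(f"cluster_{c}" for c in range(summary.k))]
    for sid, frac in summary.occupancy.items():
        lines.append(sid + "\t" + "\t".join(_fmt(f) for f in frac))
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_dotbracket(entries: list[tuple[str, str, SecondaryStructure]], path: str | Path) -> None:
    """FASTA-like dot-bracket file: (>label, sequence, dot-bracket) triples."""
    lines = []
    for label, residues, struct in entries:
        lines.append(f">{label}")
        lines.append(residues)
        lines.append(struct.to_dotbracket(len(residues)))
    _atomic_write(Path(path), "\n".join(lines) + "\n")


def write_snp_score_json(score: SnpScore, sequence_id: str, path: str | Path) -> None:
    payload = {
        "sequence_id": sequence_id,
        "mutation": score.mutation.label,
        "correlation": round(score.correlation, 6),
        "rank": score.rank,
        "total_mutations": score.total,
        "p_value": round(score.p_value, 6),
    }
    _atomic_write(Path(path), json.dumps(payload, indent=2) + "\n")


def write_manifest(
    path: str | Path,
    *,
    command: str,
    inputs: dict,
    seeds: dict,
    model: EnergyModel,
    engine: str = "internal",
) -> None:
    """Run manifest: enough provenance to reproduce the output bit for bit."""
    from . import __version__

    payload = {
        "tool": "ribosnitch",
        "version": __version__,
        "command": command,
        "engine": engine,
        "energy_parameters": {
            "digest": model.source_digest,
            "version": model.version,
            "temperature_kelvin": model.temperature,
        },
        "inputs": inputs,
        "seeds": seeds,
    }
    _atomic_write(Path(path), json.dumps(payload, indent=2, sort_keys=True) + "\n")
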