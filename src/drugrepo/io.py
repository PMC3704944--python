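"""Readers and writers for every table the pipeline touches.

All tables are tab-separated with a single header line; lines starting with
``#`` are comments.  Matrices are written with drug ids as both the header
row and the first column, at full float precision so a write/read round-trip
is bit-exact.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np

from .matrix import DissimilarityMatrix, MatrixError
from .profiles import ATC2_PATTERN, DrugProfile

log = logging.getLogger(__name__)

_ATC2_RE = re.compile(ATC2_PATTERN)


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


def _rows(path: str | Path, min_cols: int, name: str) -> Iterable[tuple[int, list[str]]]:
    """Yield (line_number, fields) for data rows, skipping header/comments."""
    header_seen = False
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise FormatError(
                    f"{name}: line {lineno} has {len(fields)} column(s), "
                    f"expected at least {min_cols}"
                )
            yield lineno, fields


# ---------------------------------------------------------------------------
# fingerprints


def read_fingerprints(
    path: str | Path, format: str = "bit-table", n_bits: int = 1024
) -> dict[str, np.ndarray]:
    """Read per-drug binary fingerprints.

    ``bit-table`` rows are ``drug_id<TAB>bitstring`` with every bitstring the
    same length; ``smiles`` rows are ``drug_id<TAB>smiles`` and require RDKit,
    from which a Morgan fingerprint of ``n_bits`` bits is computed.
    """
    if format == "smiles":
        return _fingerprints_from_smiles(path, n_bits)
    if format != "bit-table":
        raise ValueError(f"unknown fingerprint format: {format!r}")
    out: dict[str, np.ndarray] = {}
    length: int | None = None
    for lineno, fields in _rows(path, 2, "fingerprints"):
        drug_id, bits = fields[0], fields[1]
        if drug_id in out:
            raise FormatError(f"fingerprints: duplicate drug_id {drug_id!r} at line {lineno}")
        if not set(bits) <= {"0", "1"}:
            raise FormatError(f"fingerprints: non-binary characters at line {lineno}")
        if length is None:
            length = len(bits)
        elif len(bits) != length:
            raise FormatError(
                f"fingerprints: ragged row at line {lineno} "
                f"(length {len(bits)}, expected {length})"
            )
        out[drug_id] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    return out


def _fingerprints_from_smiles(path: str | Path, n_bits: int) -> dict[str, np.ndarray]:
    try:
        from rdkit import Chem
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RuntimeError("SMILES input requires the optional rdkit backend") from exc
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    out: dict[str, np.ndarray] = {}
    bad: list[str] = []
    for lineno, fields in _rows(path, 2, "smiles"):
        drug_id, smiles = fields[0], fields[1]
        if drug_id in out:
            raise FormatError(f"smiles: duplicate drug_id {drug_id!r} at line {lineno}")
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            bad.append(drug_id)
            continue
        out[drug_id] = np.array(gen.GetFingerprint(mol), dtype=np.uint8)
    if bad:
        raise FormatError(f"smiles: unparseable SMILES for drug(s): {', '.join(bad)}")
    return out


def write_fingerprints(path: str | Path, fingerprints: dict[str, np.ndarray]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("drug_id\tfingerprint\n")
        for drug_id, bits in fingerprints.items():
            fh.write(f"{drug_id}\t{''.join(str(int(b)) for b in bits)}\n")


# ---------------------------------------------------------------------------
# targets and PPI network


def read_targets(path: str | Path) -> dict[str, frozenset[str]]:
    """Read the two-column drug -> target-protein table into sets."""
    out: dict[str, set[str]] = {}
    for _, fields in _rows(path, 2, "targets"):
        out.setdefault(fields[0], set()).add(fields[1])
    return {d: frozenset(t) for d, t in out.items()}


def write_targets(path: str | Path, targets: dict[str, frozenset[str]]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("drug_id\tprotein_id\n")
        for drug_id in targets:
            for protein in sorted(targets[drug_id]):
                fh.write(f"{drug_id}\t{protein}\n")


def read_ppi(path: str | Path) -> nx.Graph:
    """Read an undirected protein-protein interaction edge list.

    Self-loops are dropped (with a logged count); duplicate edges and edges
    listed in both directions collapse to one.
    """
    net = nx.Graph()
    self_loops = 0
    for _, fields in _rows(path, 2, "ppi"):
        a, b = fields[0], fields[1]
        if a == b:
            self_loops += 1
            net.add_node(a)
            continue
        net.add_edge(a, b)
    if self_loops:
        log.info("read_ppi: dropped %d self-loop(s)", self_loops)
    return net


def write_ppi(path: str | Path, net: nx.Graph) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.edges):
            fh.write(f"{a}\t{b}\n")
        isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
        for node in isolated:
            fh.write(f"{node}\t{node}\n")  # self-loop row keeps isolated nodes


# ---------------------------------------------------------------------------
# expression statistics


def read_expression_stats(
    path: str | Path, intersect_genes: bool = False
) -> dict[str, dict[str, tuple[float, int]]]:
    """Read per-drug differential-expression statistics.

    Columns: ``drug_id, gene_id, p_value, log_fc``.  The fold-change sign is
    derived as the sign of ``log_fc`` (zero maps to +1).  Every drug must
    cover the same gene universe; with ``intersect_genes`` the profiles are
    instead restricted to the genes common to all drugs.
    """
    out: dict[str, dict[str, tuple[float, int]]] = {}
    for lineno, fields in _rows(path, 4, "expr_stats"):
        drug_id, gene_id = fields[0], fields[1]
        try:
            p, log_fc = float(fields[2]), float(fields[3])
        except ValueError as exc:
            raise FormatError(f"expr_stats: non-numeric value at line {lineno}") from exc
        if not 0.0 < p <= 1.0 or math.isnan(p):
            raise FormatError(
                f"expr_stats: p-value {p} outside (0, 1] at line {lineno}"
            )
        sign = -1 if log_fc < 0 else 1
        out.setdefault(drug_id, {})[gene_id] = (p, sign)
    if not out:
        return out
    universes = {d: set(stats) for d, stats in out.items()}
    common = set.intersection(*universes.values())
    if intersect_genes:
        return {
            d: {g: s for g, s in stats.items() if g in common}
            for d, stats in out.items()
        }
    union = set.union(*universes.values())
    for drug_id, genes in universes.items():
        if genes != union:
            missing = sorted(union - genes)[:10]
            raise FormatError(
                f"expr_stats: drug {drug_id} does not cover the common gene "
                f"universe (missing e.g. {', '.join(missing)}); "
                "use intersect_genes to take the intersection"
            )
    return out


def write_expression_stats(
    path: str | Path, stats: dict[str, dict[str, tuple[float, int]]]
) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("drug_id\tgene_id\tp_value\tlog_fc\n")
        for drug_id, genes in stats.items():
            for gene_id in sorted(genes):
                p, sign = genes[gene_id]
                fh.write(f"{drug_id}\t{gene_id}\t{p:.17g}\t{float(sign):.1f}\n")


# ---------------------------------------------------------------------------
# ATC labels


def read_atc(path: str | Path) -> dict[str, str]:
    """Read drug -> ATC level-2 labels; rows failing the code regex are
    rejected with a logged warning."""
    out: dict[str, str] = {}
    for lineno, fields in _rows(path, 2, "atc"):
        drug_id, code = fields[0], fields[1]
        if not _ATC2_RE.match(code):
            log.warning("atc: line %d rejected, %r is not a level-2 code", lineno, code)
            continue
        if drug_id not in out:  # first code in file order wins
            out[drug_id] = code
        elif out[drug_id] != code:
            log.warning(
                "atc: drug %s has multiple codes; keeping %s, ignoring %s",
                drug_id, out[drug_id], code,
            )
    return out


def write_atc(path: str | Path, labels: dict[str, str]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("drug_id\tatc2\n")
        for drug_id, code in labels.items():
            fh.write(f"{drug_id}\t{code}\n")


# ---------------------------------------------------------------------------
# matrices


def write_matrix(path: str | Path, matrix: DissimilarityMatrix) -> None:
    """Write a dissimilarity matrix as TSV at full float precision."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(matrix.ids) + "\n")
        for i, drug_id in enumerate(matrix.ids):
            row = "\t".join(f"{v:.17g}" for v in matrix.values[i])
            fh.write(f"{drug_id}\t{row}\n")


def read_matrix(path: str | Path) -> DissimilarityMatrix:
    """Read a matrix written by :func:`write_matrix`; asymmetry beyond the
    dissimilarity-matrix tolerance raises an error."""
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            if len(fields) != len(header) + 1:
                raise FormatError(f"matrix: line {lineno} has wrong column count")
            ids.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
    if header is None:
        raise FormatError("matrix: empty file")
    if ids != header:
        raise FormatError("matrix: header ids and row ids disagree")
    try:
        return DissimilarityMatrix(tuple(ids), np.array(rows, dtype=float))
    except MatrixError as exc:
        raise FormatError(f"matrix: {exc}") from exc


# ---------------------------------------------------------------------------
# whole-cohort convenience


def load_cohort(directory: str | Path, intersect_genes: bool = False):
    """Load the six-file cohort layout into drug profiles plus the network.

    Returns ``(profiles, ppi)`` where ``profiles`` is a list of
    :class:`DrugProfile` over the union of drug ids seen in any table.
    """
    directory = Path(directory)
    fingerprints = read_fingerprints(directory / "fingerprints.tsv")
    targets = read_targets(directory / "targets.tsv")
    ppi = read_ppi(directory / "ppi.tsv")
    expr = read_expression_stats(directory / "expr_stats.tsv", intersect_genes)
    atc = read_atc(directory / "atc.tsv")
    drug_ids = sorted(set(fingerprints) | set(targets) | set(expr) | set(atc))
    profiles = [
        DrugProfile(
            drug_id=d,
            fingerprint=fingerprints.get(d),
            targets=targets.get(d, frozenset()),
            expr_stats=expr.get(d, {}),
            atc2=atc.get(d),
        )
        for d in drug_ids
    ]
    return profiles, ppi
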