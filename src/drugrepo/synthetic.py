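"""Self-contained synthetic drug cohorts with planted class structure.

The generator emulates the five input tables the pipeline consumes —
fingerprints, drug-target links, a protein interaction network,
differential-expression statistics and therapeutic labels — with a known
class structure planted coherently across all three evidence layers:

* each class has a fingerprint prototype; members are noisy copies;
* each class owns a connected module of proteins in a random interaction
  graph; members draw their targets from that module;
* each class owns a block of differentially expressed genes with low
  p-values and a coherent fold-change direction; all other genes get
  uniform p-values and random signs.

A controllable fraction of drugs is deliberately mislabelled: their
features come from one class while their label names another, and the
truth table records each planted event so repositioning recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import io as io_formats
from .profiles import DrugProfile


class SyntheticError(ValueError):
    """Raised when a cohort specification is infeasible."""


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the scale of a real multi-class drug screen class-wise
    (10 therapeutic classes of 12 drugs, comfortably above a min-8 class
    filter) with a desk-scale gene universe.
    """

    seed: int
    n_classes: int = 10
    drugs_per_class: int = 12
    fp_length: int = 128
    fp_prototype_density: float = 0.2
    fp_flip_rate: float = 0.05
    n_proteins: int = 300
    ppi_edge_prob: float = 0.02
    targets_per_class_module: int = 6
    n_genes: int = 1000
    de_genes_per_class: int = 30
    de_p_scale: float = 0.01
    mislabel_fraction: float = 0.0
    ppi_model: str = "erdos-renyi"  # or "barabasi-albert"

    def __post_init__(self) -> None:
        for name in ("fp_prototype_density", "fp_flip_rate", "mislabel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SyntheticError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.ppi_edge_prob <= 1.0:
            raise SyntheticError("ppi_edge_prob must lie in [0, 1]")
        if self.n_classes < 2:
            raise SyntheticError("need at least two classes")
        if self.de_genes_per_class * self.n_classes > self.n_genes:
            raise SyntheticError("not enough genes for the requested DE blocks")
        if self.targets_per_class_module * self.n_classes > self.n_proteins:
            raise SyntheticError("not enough proteins for the requested modules")
        if self.ppi_model not in ("erdos-renyi", "barabasi-albert"):
            raise SyntheticError(f"unknown ppi_model: {self.ppi_model!r}")


@dataclass(frozen=True)
class PlantedEvent:
    """A deliberately mislabelled drug: features from one class, label of
    another."""

    drug_id: str
    label_class: str
    feature_class: str


@dataclass
class Cohort:
    """A generated cohort: profiles, the interaction network, and the truth
    table of planted mislabels."""

    profiles: list[DrugProfile]
    ppi: nx.Graph
    truth: list[PlantedEvent] = field(default_factory=list)

    @property
    def drug_ids(self) -> list[str]:
        return [p.drug_id for p in self.profiles]


def _class_codes(n: int) -> list[str]:
    if n > 26:
        raise SyntheticError("at most 26 synthetic classes supported")
    return [f"{chr(ord('A') + i)}01" for i in range(n)]


def _ppi_graph(spec: CohortSpec, rng: np.random.Generator) -> nx.Graph:
    nx_seed = int(rng.integers(0, 2**31 - 1))
    names = [f"P{i:04d}" for i in range(spec.n_proteins)]
    if spec.ppi_model == "barabasi-albert":
        m = max(1, int(round(spec.ppi_edge_prob * spec.n_proteins / 2)))
        g = nx.barabasi_albert_graph(spec.n_proteins, m, seed=nx_seed)
    else:
        g = nx.fast_gnp_random_graph(spec.n_proteins, spec.ppi_edge_prob, seed=nx_seed)
    return nx.relabel_nodes(g, dict(enumerate(names)))


def _connected_module(
    net: nx.Graph, size: int, used: set[str], rng: np.random.Generator
) -> list[str]:
    """Grow a connected subgraph of ``size`` nodes avoiding ``used``.

    Randomized breadth-first expansion from random starts; separate class
    modules never share proteins, keeping within-class target distances
    shorter than between-class ones.
    """
    candidates = [n for n in net.nodes if n not in used]
    rng.shuffle(candidates)
    for start in candidates:
        module = [start]
        frontier = [
            n for n in net.neighbors(start) if n not in used
        ]
        while len(module) < size and frontier:
            nxt = frontier.pop(int(rng.integers(len(frontier))))
            if nxt in module:
                continue
            module.append(nxt)
            frontier.extend(
                n for n in net.neighbors(nxt)
                if n not in used and n not in module and n not in frontier
            )
        if len(module) == size:
            return module
    raise SyntheticError(
        f"could not place a connected {size}-protein module; "
        "increase ppi_edge_prob or n_proteins"
    )


def _uniform_open_zero(rng: np.random.Generator, size) -> np.ndarray:
    """Uniform draws on (0, 1]: p-values must be strictly positive."""
    return 1.0 - rng.random(size=size)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort with planted class structure per ``spec``.

    Deterministic given ``spec.seed``.  The truth table lists exactly the
    ``mislabel_fraction`` of drugs whose features were drawn from a class
    other than their label.
    """
    rng = np.random.default_rng(spec.seed)
    codes = _class_codes(spec.n_classes)
    net = _ppi_graph(spec, rng)

    prototypes = {
        c: (rng.random(spec.fp_length) < spec.fp_prototype_density).astype(np.uint8)
        for c in codes
    }
    # a prototype with no set bits would make the chemical layer undefined
    for c, proto in prototypes.items():
        if not proto.any():
            proto[int(rng.integers(spec.fp_length))] = 1

    used: set[str] = set()
    modules: dict[str, list[str]] = {}
    for c in codes:
        modules[c] = _connected_module(net, spec.targets_per_class_module, used, rng)
        used.update(modules[c])

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    de_blocks: dict[str, list[str]] = {}
    de_signs: dict[str, dict[str, int]] = {}
    for k, c in enumerate(codes):
        block = gene_ids[k * spec.de_genes_per_class:(k + 1) * spec.de_genes_per_class]
        de_blocks[c] = block
        de_signs[c] = {
            g: int(rng.choice([-1, 1])) for g in block
        }

    n_drugs = spec.n_classes * spec.drugs_per_class
    drug_ids = [f"d{i:03d}" for i in range(n_drugs)]
    label_of = {
        d: codes[i // spec.drugs_per_class] for i, d in enumerate(drug_ids)
    }

    n_mislabelled = int(round(spec.mislabel_fraction * n_drugs))
    planted_ids = (
        sorted(rng.choice(drug_ids, size=n_mislabelled, replace=False).tolist())
        if n_mislabelled
        else []
    )
    feature_of = dict(label_of)
    truth: list[PlantedEvent] = []
    for d in planted_ids:
        others = [c for c in codes if c != label_of[d]]
        feature_of[d] = others[int(rng.integers(len(others)))]
        truth.append(
            PlantedEvent(drug_id=d, label_class=label_of[d], feature_class=feature_of[d])
        )

    profiles: list[DrugProfile] = []
    for d in drug_ids:
        fc = feature_of[d]
        flips = rng.random(spec.fp_length) < spec.fp_flip_rate
        fingerprint = np.where(flips, 1 - prototypes[fc], prototypes[fc]).astype(np.uint8)
        if not fingerprint.any():
            fingerprint[int(rng.integers(spec.fp_length))] = 1

        module = modules[fc]
        k_targets = int(rng.integers(max(1, len(module) // 2), len(module) + 1))
        targets = frozenset(
            rng.choice(module, size=k_targets, replace=False).tolist()
        )

        p = _uniform_open_zero(rng, spec.n_genes)
        signs = rng.choice([-1, 1], size=spec.n_genes)
        expr = dict(zip(gene_ids, zip(p.tolist(), (int(s) for s in signs))))
        for g in de_blocks[fc]:
            expr[g] = (
                float(spec.de_p_scale * _uniform_open_zero(rng, None)),
                de_signs[fc][g],
            )

        profiles.append(
            DrugProfile(
                drug_id=d,
                fingerprint=fingerprint,
                targets=targets,
                expr_stats=expr,
                atc2=label_of[d],
            )
        )
    return Cohort(profiles=profiles, ppi=net, truth=truth)


COHORT_FILES = (
    "fingerprints.tsv",
    "targets.tsv",
    "ppi.tsv",
    "expr_stats.tsv",
    "atc.tsv",
    "truth.tsv",
)


def write_cohort(cohort: Cohort, outdir: str | Path, force: bool = False) -> list[Path]:
    """Write the cohort as the six standard pipeline tables.

    Refuses a non-empty ``outdir`` unless ``force`` is set.  Output is
    deterministic: same cohort, byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    existing = [p for p in outdir.iterdir() if p.name in COHORT_FILES]
    if existing and not force:
        raise FileExistsError(
            f"{outdir} already contains cohort files; pass force=True to overwrite"
        )
    io_formats.write_fingerprints(
        outdir / "fingerprints.tsv",
        {p.drug_id: p.fingerprint for p in cohort.profiles},
    )
    io_formats.write_targets(
        outdir / "targets.tsv", {p.drug_id: p.targets for p in cohort.profiles}
    )
    io_formats.write_ppi(outdir / "ppi.tsv", cohort.ppi)
    io_formats.write_expression_stats(
        outdir / "expr_stats.tsv", {p.drug_id: p.expr_stats for p in cohort.profiles}
    )
    io_formats.write_atc(
        outdir / "atc.tsv",
        {p.drug_id: p.atc2 for p in cohort.profiles if p.atc2 is not None},
    )
    with open(outdir / "truth.tsv", "wt", encoding="utf-8") as fh:
        fh.write("drug_id\tlabel_class\tfeature_class\n")
        for ev in cohort.truth:
            fh.write(f"{ev.drug_id}\t{ev.label_class}\t{ev.feature_class}\n")
    return [outdir / name for name in COHORT_FILES]
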