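"""Fusion of the three layers and class-size filtering.

The joint matrix is the elementwise mean of the expression, target and
chemical dissimilarities over the drugs common to all three layers; drugs in
therapeutic classes with too few exemplars are then removed so every class
can support cross-validated training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .matrix import DissimilarityMatrix

log = logging.getLogger(__name__)


class IntegrationError(ValueError):
    """Raised when fusion or filtering cannot produce a usable cohort."""


@dataclass(frozen=True)
class LabelledCohort:
    """A fused dissimilarity matrix together with per-drug class labels."""

    dissim: DissimilarityMatrix
    labels: dict[str, str]

    def __post_init__(self) -> None:
        missing = [d for d in self.dissim.ids if d not in self.labels]
        if missing:
            raise IntegrationError(
                f"{len(missing)} drug(s) in the matrix lack labels, e.g. {missing[:5]}"
            )

    @property
    def label_list(self) -> list[str]:
        return [self.labels[d] for d in self.dissim.ids]

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.label_list:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def integrate_layers(
    gex: DissimilarityMatrix,
    tar: DissimilarityMatrix,
    chem: DissimilarityMatrix,
) -> DissimilarityMatrix:
    """Elementwise mean of the three layers over their common drugs.

    The output is indexed by the sorted intersection of the three id sets;
    fewer than two shared drugs is an error.
    """
    common = sorted(set(gex.ids) & set(tar.ids) & set(chem.ids))
    if len(common) < 2:
        raise IntegrationError(
            f"only {len(common)} drug(s) common to all three layers"
        )
    stack = [m.submatrix(common).values for m in (gex, tar, chem)]
    return DissimilarityMatrix(tuple(common), np.mean(stack, axis=0))


def filter_by_class_size(
    cohort_or_matrix: LabelledCohort | DissimilarityMatrix,
    labels: Mapping[str, str] | None = None,
    min_size: int = 8,
) -> LabelledCohort:
    """Drop unlabelled drugs, then every class with fewer than ``min_size``
    members; the matrix becomes the corresponding principal submatrix with
    drug order preserved."""
    if isinstance(cohort_or_matrix, LabelledCohort):
        matrix, labels = cohort_or_matrix.dissim, cohort_or_matrix.labels
    else:
        matrix = cohort_or_matrix
        labels = dict(labels or {})
    labelled = [d for d in matrix.ids if d in labels]
    dropped_unlabelled = len(matrix.ids) - len(labelled)
    if dropped_unlabelled:
        log.info("filter: dropped %d unlabelled drug(s)", dropped_unlabelled)
    sizes: dict[str, int] = {}
    for d in labelled:
        sizes[labels[d]] = sizes.get(labels[d], 0) + 1
    keep = [d for d in labelled if sizes[labels[d]] >= min_size]
    if not keep:
        raise IntegrationError(f"no class has at least {min_size} member(s)")
    removed = {c for c, s in sizes.items() if s < min_size}
    if removed:
        log.info(
            "filter: removed %d class(es) below %d exemplars: %s",
            len(removed), min_size, ", ".join(sorted(removed)),
        )
    return LabelledCohort(
        dissim=matrix.submatrix(keep),
        labels={d: labels[d] for d in keep},
    )
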