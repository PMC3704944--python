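"""Per-drug data container tying the three evidence layers together."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: ATC level-2 codes: anatomical-group letter plus two-digit therapeutic
#: subgroup, e.g. ``L01`` (antineoplastic agents).
ATC2_PATTERN = r"^[A-Z][0-9]{2}$"


@dataclass
class DrugProfile:
    """One drug's fingerprint, target set, expression statistics and label.

    Attributes
    ----------
    drug_id
        Unique identifier within a cohort.
    fingerprint
        Fixed-length binary substructure fingerprint (same length for every
        drug in a cohort); ``None`` when the chemical layer is unavailable.
    targets
        Set of protein ids the drug is known to bind.
    expr_stats
        Mapping ``gene_id -> (p_value, fc_sign)`` from an upstream
        differential-expression analysis of treated-vs-control profiles.
        p-values lie in ``(0, 1]``; ``fc_sign`` is ``+1`` for over- and
        ``-1`` for under-expression.
    atc2
        ATC level-2 therapeutic-subgroup code, or ``None`` if unlabelled.
    """

    drug_id: str
    fingerprint: np.ndarray | None = None
    targets: frozenset[str] = frozenset()
    expr_stats: dict[str, tuple[float, int]] = field(default_factory=dict)
    atc2: str | None = None

    def __post_init__(self) -> None:
        if self.fingerprint is not None:
            self.fingerprint = np.asarray(self.fingerprint, dtype=np.uint8)
        self.targets = frozenset(self.targets)
        for gene, (p, sign) in self.expr_stats.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(
                    f"drug {self.drug_id}: p-value for {gene} outside (0, 1]: {p}"
                )
            if sign not in (-1, 1):
                raise ValueError(
                    f"drug {self.drug_id}: fc_sign for {gene} must be -1 or +1"
                )
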