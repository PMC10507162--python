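"""Relative qPCR quantification: primer efficiency and ΔΔCq fold changes.

The sign convention is dCq = Cq(reference gene) − Cq(gene of interest), then
ddCq = dCq − mean dCq of the control condition within the same experimental
batch, and fold change = 2^ddCq.  Note this dCq orientation is the negative
of the classical Livak ΔCt; with it, a target amplifying EARLIER than the
reference (lower Cq, more abundant) has a HIGHER dCq, so fold changes still
read as expression relative to the control condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import DomainError, QpcrRecord

DEFAULT_REFERENCE_GENE = "GAPDH"

#: Cell-purity marker genes: strong fold changes flag possible contamination
#: from astrocytes / Müller glia.  Flagged only, never dropped.
DEFAULT_MARKER_GENES = ("IBA1", "GFAP")
DEFAULT_MARKER_FOLD_THRESHOLD = 2.0


@dataclass
class FoldChangeRecord:
    sample_id: str
    group: str
    gene: str
    mean_cq: float
    dcq: float
    ddcq: float
    fold_change: float
    qc_flags: list[str] = field(default_factory=list)


def primer_efficiency(slope: float) -> tuple[float, bool]:
    """Amplification efficiency (%) from a dilution-series slope.

    E = ((2^(−1/slope)) − 1) × 100, with the slope taken from four to five
    serial 1:4 dilutions.  Returns (efficiency %, pass flag for the 90–110%
    acceptance window).
    """
    if slope == 0:
        raise DomainError("slope must be non-zero")
    eff = (2.0 ** (-1.0 / slope) - 1.0) * 100.0
    return eff, 90.0 <= eff <= 110.0


def fold_changes(
    records: list[QpcrRecord],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_group: str = "WT_naive",
    marker_genes: tuple[str, ...] = DEFAULT_MARKER_GENES,
    marker_fold_threshold: float | None = DEFAULT_MARKER_FOLD_THRESHOLD,
) -> list[FoldChangeRecord]:
    """ΔΔCq fold changes for every (sample, gene), normalized to GAPDH-like
    reference and to the control condition within each experimental batch.

    Per sample, Cq is averaged over technical replicates; dCq = reference −
    gene; ddCq subtracts the control group's mean dCq for that gene and
    batch; fold change = 2^ddCq.  Purity-marker genes whose fold change
    exceeds ``marker_fold_threshold`` get a ``contamination_marker`` QC flag
    but are never dropped.
    """
    # reference mean Cq per (sample, batch)
    ref_cq: dict[tuple[str, str], float] = {}
    for r in records:
        if r.gene == reference_gene:
            ref_cq[(r.sample_id, r.batch)] = r.mean_cq

    samples = {(r.sample_id, r.batch) for r in records}
    missing = sorted(s for s, b in samples if (s, b) not in ref_cq)
    if missing:
        raise DomainError(
            f"reference gene '{reference_gene}' missing for sample(s): {', '.join(missing)}"
        )

    # dCq per record
    dcq = {
        (r.sample_id, r.batch, r.gene): ref_cq[(r.sample_id, r.batch)] - r.mean_cq
        for r in records
    }

    # control-condition mean dCq per (batch, gene)
    control_dcq: dict[tuple[str, str], float] = {}
    for (batch, gene), values in _group_control_dcq(records, dcq, control_group).items():
        control_dcq[(batch, gene)] = float(np.mean(values))

    out: list[FoldChangeRecord] = []
    for r in records:
        key = (r.batch, r.gene)
        if key not in control_dcq:
            raise DomainError(
                f"no control-group ('{control_group}') samples for gene '{r.gene}' "
                f"in batch '{r.batch}'"
            )
        d = dcq[(r.sample_id, r.batch, r.gene)]
        dd = d - control_dcq[key]
        fold = 2.0**dd
        flags: list[str] = []
        if (
            marker_fold_threshold is not None
            and r.gene.upper() in {g.upper() for g in marker_genes}
            and fold > marker_fold_threshold
        ):
            flags.append("contamination_marker")
        out.append(FoldChangeRecord(
            sample_id=r.sample_id,
            group=r.group,
            gene=r.gene,
            mean_cq=r.mean_cq,
            dcq=d,
            ddcq=dd,
            fold_change=fold,
            qc_flags=flags,
        ))
    return out


def _group_control_dcq(
    records: list[QpcrRecord],
    dcq: dict[tuple[str, str, str], float],
    control_group: str,
) -> dict[tuple[str, str], list[float]]:
    grouped: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if r.group == control_group:
            grouped.setdefault((r.batch, r.gene), []).append(
                dcq[(r.sample_id, r.batch, r.gene)]
            )
    return grouped
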