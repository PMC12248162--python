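"""Reading, preprocessing and partitioning of assay score tables.

Input is delimited text (CSV/TSV) in the style of MaveDB score sets: one
row per variant with one or more replicate score columns, an optional
clinical/population label, an optional splice-effect score (the maximum of
the SpliceAI acceptor/donor loss and gain deltas, precomputed upstream)
and an optional author functional annotation.  Preprocessing follows the
assay-calibration conventions: replicate scores are averaged (finite
replicates only), variants whose splice score exceeds 0.5 are removed for
assays that cannot detect splice effects, and scores are partitioned into
the P/LP, B/LB, reference (gnomAD) and synonymous samples used to fit the
mixture; VUS and unlabeled variants are carried separately and never used
in fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mixture import SampleSet

__all__ = [
    "PLP",
    "BLB",
    "REF",
    "SYN",
    "VUS",
    "UNLABELED",
    "LABEL_PRECEDENCE",
    "VariantRecord",
    "AssayDataset",
    "SchemaError",
    "read_scores",
    "read_labels",
    "apply_labels",
    "write_dataset",
    "average_replicates",
    "splice_filter",
    "negate_scores",
    "build_sample_set",
]

logger = logging.getLogger("mavecal")

PLP = "PLP"
BLB = "BLB"
REF = "REF"
SYN = "SYN"
VUS = "VUS"
UNLABELED = "UNLABELED"
_LABELS = (PLP, BLB, REF, SYN, VUS, UNLABELED)

# A variant can appear in several source sets (e.g. a gnomAD variant that is
# also B/LB); bootstrap stratification needs a single label per variant.
LABEL_PRECEDENCE = (PLP, BLB, SYN, REF, VUS, UNLABELED)

_LABEL_ALIASES = {
    "PLP": PLP, "P/LP": PLP, "P": PLP, "LP": PLP, "PATHOGENIC": PLP,
    "BLB": BLB, "B/LB": BLB, "B": BLB, "LB": BLB, "BENIGN": BLB,
    "REF": REF, "GNOMAD": REF, "G": REF, "REFERENCE": REF,
    "SYN": SYN, "S": SYN, "SYNONYMOUS": SYN,
    "VUS": VUS, "UNCERTAIN": VUS,
    "UNLABELED": UNLABELED, "": UNLABELED, "NAN": UNLABELED, "NONE": UNLABELED,
}

_ANNOTATIONS = ("abnormal", "indeterminate", "normal")


class SchemaError(ValueError):
    """A mandatory column is missing or a cell cannot be parsed."""


@dataclass
class VariantRecord:
    variant_id: str
    scores: tuple[float, ...]
    label: str = UNLABELED
    splice_score: float | None = None
    author_annotation: str | None = None

    def __post_init__(self) -> None:
        finite = [s for s in self.scores if np.isfinite(s)]
        if not finite:
            raise ValueError(f"variant {self.variant_id!r} has no finite replicate score")
        if self.label not in _LABELS:
            raise ValueError(f"unknown label {self.label!r} for variant {self.variant_id!r}")
        if self.splice_score is not None and not 0.0 <= self.splice_score <= 1.0:
            raise ValueError(
                f"splice score for {self.variant_id!r} must lie in [0, 1], "
                f"got {self.splice_score}"
            )
        if self.author_annotation is not None and self.author_annotation not in _ANNOTATIONS:
            raise ValueError(f"unknown author annotation {self.author_annotation!r}")

    @property
    def mean_score(self) -> float:
        finite = [s for s in self.scores if np.isfinite(s)]
        return float(np.mean(finite))


@dataclass
class AssayDataset:
    records: list[VariantRecord]
    direction: str = "low_scores_abnormal"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.variant_id in seen:
                raise ValueError(f"duplicate variant_id {rec.variant_id!r}")
            seen.add(rec.variant_id)

    def __len__(self) -> int:
        return len(self.records)

    def by_label(self, label: str) -> list[VariantRecord]:
        return [r for r in self.records if r.label == label]


def _normalize_label(raw) -> str:
    key = str(raw).strip().upper()
    if key in _LABEL_ALIASES:
        return _LABEL_ALIASES[key]
    raise SchemaError(f"unrecognized label value {raw!r}")


def read_scores(path, mapping: dict) -> AssayDataset:
    """Parse a delimited score table into an :class:`AssayDataset`.

    ``mapping`` names the columns: ``variant_id`` (str, required),
    ``scores`` (list of replicate columns, required), and optionally
    ``label``, ``splice_score``, ``author_annotation``, plus ``delimiter``
    (auto-detected when omitted) and ``direction``.
    """
    delimiter = mapping.get("delimiter")
    df = pd.read_csv(path, sep=delimiter, engine="python", dtype=str)
    required = [mapping.get("variant_id")] + list(mapping.get("scores", []))
    if mapping.get("variant_id") is None or not mapping.get("scores"):
        raise SchemaError("column mapping must name 'variant_id' and 'scores'")
    missing = [c for c in required if c not in df.columns]
    for opt in ("label", "splice_score", "author_annotation"):
        col = mapping.get(opt)
        if col is not None and col not in df.columns:
            missing.append(col)
    if missing:
        raise SchemaError(
            f"missing columns {missing} in {path}; file has columns {list(df.columns)}"
        )

    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        row = dict(zip(df.columns, row))
        vid = str(row[mapping["variant_id"]]).strip()
        scores = []
        for col in mapping["scores"]:
            cell = row[col]
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                scores.append(np.nan)
                continue
            try:
                scores.append(float(cell))
            except ValueError as exc:
                raise SchemaError(
                    f"non-numeric score {cell!r} in column {col!r} at line {pos} of {path}"
                ) from exc
        if not any(np.isfinite(s) for s in scores):
            raise SchemaError(f"variant {vid!r} at line {pos} has no finite replicate score")
        label = _normalize_label(row[mapping["label"]]) if mapping.get("label") else UNLABELED
        splice = None
        if mapping.get("splice_score"):
            cell = row[mapping["splice_score"]]
            if cell is not None and str(cell).strip() not in ("", "nan"):
                splice = float(cell)
        annot = None
        if mapping.get("author_annotation"):
            cell = row[mapping["author_annotation"]]
            if cell is not None and str(cell).strip() not in ("", "nan"):
                annot = str(cell).strip().lower()
        records.append(
            VariantRecord(
                variant_id=vid,
                scores=tuple(scores),
                label=label,
                splice_score=splice,
                author_annotation=annot,
            )
        )
    return AssayDataset(
        records=records,
        direction=mapping.get("direction", "low_scores_abnormal"),
        metadata={"source": str(path)},
    )


def read_labels(path, mapping: dict) -> dict[str, str]:
    """Read a (variant_id, label) table; conflicts resolve by precedence.

    A variant listed under several labels keeps the highest-precedence one
    (PLP > BLB > SYN > REF); each demotion is logged.
    """
    df = pd.read_csv(path, sep=mapping.get("delimiter"), engine="python", dtype=str)
    id_col, label_col = mapping.get("variant_id"), mapping.get("label")
    if id_col not in df.columns or label_col not in df.columns:
        raise SchemaError(
            f"label file {path} must contain columns {id_col!r} and {label_col!r}; "
            f"found {list(df.columns)}"
        )
    rank = {lab: i for i, lab in enumerate(LABEL_PRECEDENCE)}
    labels: dict[str, str] = {}
    for _, row in df.iterrows():
        vid = str(row[id_col]).strip()
        label = _normalize_label(row[label_col])
        if vid in labels and labels[vid] != label:
            kept = min(labels[vid], label, key=rank.__getitem__)
            logger.info(
                "variant %s has labels %s and %s; keeping %s by precedence",
                vid, labels[vid], label, kept,
            )
            labels[vid] = kept
        else:
            labels[vid] = label
    return labels


def apply_labels(dataset: AssayDataset, labels: dict[str, str]) -> AssayDataset:
    """Attach labels from a side table to the dataset's records."""
    records = [
        replace(rec, label=labels.get(rec.variant_id, rec.label)) for rec in dataset.records
    ]
    return AssayDataset(records=records, direction=dataset.direction, metadata=dataset.metadata)


def write_dataset(dataset: AssayDataset, path) -> None:
    """Write a dataset back to CSV (replicates as score_1..score_k)."""
    n_rep = max(len(r.scores) for r in dataset.records)
    rows = []
    for rec in dataset.records:
        row = {"variant_id": rec.variant_id, "label": rec.label}
        for k in range(n_rep):
            row[f"score_{k + 1}"] = rec.scores[k] if k < len(rec.scores) else np.nan
        row["splice_score"] = rec.splice_score if rec.splice_score is not None else ""
        row["author_annotation"] = rec.author_annotation or ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def standard_mapping(n_replicates: int = 1) -> dict:
    """Column mapping matching :func:`write_dataset` output."""
    return {
        "variant_id": "variant_id",
        "scores": [f"score_{k + 1}" for k in range(n_replicates)],
        "label": "label",
        "splice_score": "splice_score",
        "author_annotation": "author_annotation",
    }


# ---------------------------------------------------------------------------
# preprocessing


def average_replicates(dataset: AssayDataset) -> AssayDataset:
    """Collapse replicate scores to their finite-only mean."""
    records = [replace(rec, scores=(rec.mean_score,)) for rec in dataset.records]
    return AssayDataset(records=records, direction=dataset.direction, metadata=dataset.metadata)


def splice_filter(dataset: AssayDataset, threshold: float = 0.5) -> AssayDataset:
    """Drop variants whose splice score strictly exceeds ``threshold``.

    Records without a splice score are retained.  Intended for assays that
    cannot detect splice-altering effects, where a pathogenic effect might
    be mediated by splicing rather than the assayed function.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("splice threshold must lie in [0, 1]")
    if all(rec.splice_score is None for rec in dataset.records):
        logger.warning("no splice scores present; splice filter is a no-op")
        return dataset
    kept, removed = [], []
    for rec in dataset.records:
        if rec.splice_score is not None and rec.splice_score > threshold:
            removed.append(rec.variant_id)
        else:
            kept.append(rec)
    for vid in removed:
        logger.info("splice filter removed variant %s", vid)
    return AssayDataset(records=kept, direction=dataset.direction, metadata=dataset.metadata)


def negate_scores(dataset: AssayDataset) -> AssayDataset:
    """Flip score orientation (high-scores-abnormal -> low-scores-abnormal)."""
    records = [
        replace(rec, scores=tuple(-s for s in rec.scores)) for rec in dataset.records
    ]
    new_direction = (
        "low_scores_abnormal"
        if dataset.direction == "high_scores_abnormal"
        else "high_scores_abnormal"
    )
    return AssayDataset(records=records, direction=new_direction, metadata=dataset.metadata)


def build_sample_set(dataset: AssayDataset) -> SampleSet:
    """Partition averaged scores by label into the fitting samples.

    P/LP, B/LB and reference scores are mandatory; synonymous scores are
    included when present.  VUS and unlabeled variants are never part of
    the fit and stay on the dataset for downstream evidence assignment.
    """
    def scores_for(label: str) -> np.ndarray:
        return np.array([rec.mean_score for rec in dataset.by_label(label)])

    for label, name in ((PLP, "P/LP"), (BLB, "B/LB"), (REF, "reference")):
        if not dataset.by_label(label):
            raise ValueError(f"dataset has no {name} ({label}) records; cannot fit")
    syn = scores_for(SYN)
    return SampleSet(
        scores_plp=scores_for(PLP),
        scores_blb=scores_for(BLB),
        scores_ref=scores_for(REF),
        scores_syn=syn if syn.size else None,
    )
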