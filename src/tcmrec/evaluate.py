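"""Ontology-rollup prescription matching and time-sliced evaluation.

Two prescriptions are compared after rolling every drug up to its
first-category ancestor: a recommended drug counts as correct whenever it
shares a first category with some drug in the physician's order, which is
how within-category herb substitution between physicians is absorbed.
Counts are, by default, micro-aggregated (summed over patients before the
ratio) and reported per evaluation time slice:

    precision = TP / (TP + FP)        recall = TP / (TP + FN)

with the convention that an empty denominator scores 1.0 (an empty
recommendation against an empty order is perfect, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .embed import EmbeddingModel, vectorize
from .features import PatientRecord, extract_tokens
from .model import PrescriptionTransformer
from .ontology import DrugOntology

__all__ = ["MatchCounts", "match_counts", "precision_recall",
           "evaluate_timeline", "predict_record", "render_table",
           "TIME_SLICE_LABELS"]

TIME_SLICE_LABELS = {0.0: "Admission", 24.0: "In 24 hours", 48.0: "In 48 hours",
                     72.0: "In 3 days", 168.0: "In 1 week"}


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_counts(
    onto: DrugOntology,
    predicted: set[str],
    reference: set[str],
    level: str = "category1",
) -> MatchCounts:
    """TP/FP/FN between two prescriptions after rollup to `level`."""
    pred = onto.rollup(predicted, level=level)
    ref = onto.rollup(reference, level=level)
    return MatchCounts(tp=len(pred & ref), fp=len(pred - ref), fn=len(ref - pred))


def precision_recall(c: MatchCounts) -> tuple[float, float]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 1.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else 1.0
    return precision, recall


def predict_record(
    model: PrescriptionTransformer,
    record: PatientRecord,
    embedding: EmbeddingModel,
    label_categories: list[str],
    cutoff_hours: float,
    threshold: float | None = None,
    include_prior_orders: bool = True,
) -> set[str]:
    """End-to-end single-record prediction: tokens at the cutoff ->
    embedding matrix -> forward -> threshold decoding -> category ids."""
    seq = extract_tokens(record, cutoff_hours, include_prior_orders=include_prior_orders)
    em = vectorize(seq, embedding, model.cfg.max_num_tokens)
    sets = model.predict_sets(em.values[None], em.mask[None], threshold)
    return {label_categories[i] for i in sets[0]}


def evaluate_timeline(
    model: PrescriptionTransformer,
    records: list[PatientRecord],
    onto: DrugOntology,
    embedding: EmbeddingModel,
    label_categories: list[str],
    cutoffs: tuple[float, ...] = (0.0, 24.0, 48.0, 72.0, 168.0),
    threshold: float | None = None,
    agg: str = "micro",
    level: str = "category1",
    include_prior_orders: bool = True,
) -> pd.DataFrame:
    """Precision/recall per evaluation time slice.

    For each cutoff, each record's tokens are truncated at the cutoff,
    vectorized, classified, decoded, and matched against the reference order
    issued at that cutoff.  Records lacking a reference order at a cutoff are
    skipped for that slice (and counted in the ``n_skipped`` column).
    """
    if agg not in ("micro", "macro"):
        raise ValueError("agg must be 'micro' or 'macro'")
    rows = []
    for cutoff in cutoffs:
        total = MatchCounts()
        per_patient: list[tuple[float, float]] = []
        n_used = n_skipped = 0
        # vectorize all records at this cutoff, then classify in one batch
        used, X, M, refs = [], [], [], []
        for r in records:
            order = r.order_at(cutoff)
            if order is None:
                n_skipped += 1
                continue
            seq = extract_tokens(r, cutoff, include_prior_orders=include_prior_orders)
            em = vectorize(seq, embedding, model.cfg.max_num_tokens)
            used.append(r)
            X.append(em.values)
            M.append(em.mask)
            refs.append(set(order.drug_ids))
        if used:
            sets = model.predict_sets(np.stack(X), np.stack(M), threshold)
            for pred_idx, ref in zip(sets, refs):
                predicted = {label_categories[i] for i in pred_idx}
                c = match_counts(onto, predicted, ref, level=level)
                total = total + c
                per_patient.append(precision_recall(c))
                n_used += 1
        if agg == "micro":
            precision, recall = precision_recall(total)
        else:
            precision = float(np.mean([p for p, _ in per_patient])) if per_patient else 1.0
            recall = float(np.mean([r for _, r in per_patient])) if per_patient else 1.0
        rows.append({
            "cutoff_hours": cutoff,
            "time": TIME_SLICE_LABELS.get(cutoff, f"{cutoff:g}h"),
            "precision": precision, "recall": recall,
            "tp": total.tp, "fp": total.fp, "fn": total.fn,
            "n_patients": n_used, "n_skipped": n_skipped,
        })
    return pd.DataFrame(rows)


def render_table(train: pd.DataFrame | None, test: pd.DataFrame) -> str:
    """Text table in the familiar layout: rows are time slices, column pairs
    are training/test precision and recall rates in percent."""
    lines = []
    if train is not None:
        header = (f"{'Time':<14}{'Train precision (%)':>21}{'Train recall (%)':>18}"
                  f"{'Test precision (%)':>20}{'Test recall (%)':>17}")
        lines.append(header)
        lines.append("-" * len(header))
        for (_, tr), (_, te) in zip(train.iterrows(), test.iterrows()):
            lines.append(
                f"{te['time']:<14}{100 * tr['precision']:>21.2f}"
                f"{100 * tr['recall']:>18.2f}{100 * te['precision']:>20.2f}"
                f"{100 * te['recall']:>17.2f}"
            )
    else:
        header = f"{'Time':<14}{'Precision (%)':>15}{'Recall (%)':>13}"
        lines.append(header)
        lines.append("-" * len(header))
        for _, te in test.iterrows():
            lines.append(
                f"{te['time']:<14}{100 * te['precision']:>15.2f}"
                f"{100 * te['recall']:>13.2f}"
            )
    return "\n".join(lines)
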