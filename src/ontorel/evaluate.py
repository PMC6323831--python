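"""SemEval-style scoring for relation extraction.

Two tasks are scored over the same instance universe (keyed by document,
sentence and unordered entity pair):

* **detection** — positive vs negative only;
* **classification** — a true positive additionally requires the exact
  interaction type; a positive pair predicted positive with the wrong
  type counts as a false positive for the predicted type *and* a false
  negative for the gold type.  Precision/recall/F1 are micro-averaged
  over the four positive types.

A per-document-type breakdown and a multi-system overlap (Venn)
partition are also provided.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

from .corpus import CandidatePair, Document

__all__ = [
    "Metrics",
    "EvaluationReport",
    "OverlapPartition",
    "UniverseMismatchError",
    "score",
    "score_by_subset",
    "overlap_analysis",
]


class UniverseMismatchError(Exception):
    def __init__(self, missing_in_pred, missing_in_gold):
        self.missing_in_pred = sorted(map(str, missing_in_pred))
        self.missing_in_gold = sorted(map(str, missing_in_gold))
        super().__init__(
            f"gold and predictions cover different instances; "
            f"{len(self.missing_in_pred)} gold-only, {len(self.missing_in_gold)} prediction-only"
        )


@dataclass(frozen=True)
class Metrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


@dataclass
class EvaluationReport:
    detection: Metrics
    classification: Metrics
    per_subset: dict[str, "EvaluationReport"] = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {
            "detection": self.detection.as_dict(),
            "classification": self.classification.as_dict(),
        }
        if self.per_subset:
            out["per_subset"] = {k: v.as_dict() for k, v in self.per_subset.items()}
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def table(self) -> str:
        rows = [("", "P", "R", "F1")]
        for name, m in (("detection", self.detection), ("classification", self.classification)):
            rows.append((name, f"{m.precision:.4f}", f"{m.recall:.4f}", f"{m.f1:.4f}"))
        for sub, rep in sorted(self.per_subset.items()):
            for name, m in (("detection", rep.detection), ("classification", rep.classification)):
                rows.append((f"{sub}/{name}", f"{m.precision:.4f}", f"{m.recall:.4f}", f"{m.f1:.4f}"))
        w = [max(len(r[i]) for r in rows) for i in range(4)]
        return "\n".join("  ".join(c.ljust(w[i]) for i, c in enumerate(r)) for r in rows)


def score(
    gold: Sequence[CandidatePair], predicted: Sequence[CandidatePair]
) -> EvaluationReport:
    """Score predictions against gold over an identical instance universe."""
    g = {p.key: p for p in gold}
    q = {p.key: p for p in predicted}
    if g.keys() != q.keys():
        raise UniverseMismatchError(g.keys() - q.keys(), q.keys() - g.keys())
    det_tp = det_fp = det_fn = 0
    cls_tp = cls_fp = cls_fn = 0
    for key, gp in g.items():
        pp = q[key]
        if pp.is_positive and gp.is_positive:
            det_tp += 1
            if pp.label == gp.label:
                cls_tp += 1
            else:
                cls_fp += 1
                cls_fn += 1
        elif pp.is_positive:
            det_fp += 1
            cls_fp += 1
        elif gp.is_positive:
            det_fn += 1
            cls_fn += 1
    return EvaluationReport(
        detection=Metrics(det_tp, det_fp, det_fn),
        classification=Metrics(cls_tp, cls_fp, cls_fn),
    )


def score_by_subset(
    gold: Sequence[CandidatePair],
    predicted: Sequence[CandidatePair],
    documents: Sequence[Document],
) -> EvaluationReport:
    """Pooled report plus independent metrics per document source type."""
    source_of = {d.id: d.source_type for d in documents}
    report = score(gold, predicted)
    subsets = sorted({source_of.get(p.doc_id, "other") for p in gold})
    for sub in subsets:
        gsub = [p for p in gold if source_of.get(p.doc_id, "other") == sub]
        keys = {p.key for p in gsub}
        psub = [p for p in predicted if p.key in keys]
        report.per_subset[sub] = score(gsub, psub)
    return report


@dataclass
class OverlapPartition:
    """Region counts of the membership lattice of gold + system sets."""

    set_names: tuple[str, ...]  # gold first
    regions: dict[frozenset, int]
    unique_true_positives: dict[str, int]
    global_false_negatives: int

    def region(self, *names: str) -> int:
        """Count of items belonging to exactly the named sets."""
        return self.regions.get(frozenset(names), 0)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["region", "count"])
            for key in sorted(self.regions, key=lambda k: (len(k), sorted(k))):
                w.writerow(["&".join(sorted(key)), self.regions[key]])

    def marginal(self, name: str) -> int:
        """Total size of one set, recovered from the region counts."""
        return sum(c for k, c in self.regions.items() if name in k)


def overlap_analysis(
    gold: set[Hashable], systems: Mapping[str, set[Hashable]]
) -> OverlapPartition:
    """Partition gold + predicted-positive sets into Venn regions.

    Also reports, per system, the true positives found by that system
    alone, and the gold pairs found by no system (global false
    negatives).
    """
    if not 1 <= len(systems) <= 4:
        raise ValueError("between 1 and 4 systems are supported")
    sets = {"gold": set(gold), **{k: set(v) for k, v in systems.items()}}
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for item in universe:
        member = frozenset(name for name, s in sets.items() if item in s)
        regions[member] = regions.get(member, 0) + 1
    unique_tp = {
        name: len(sets["gold"] & sets[name] - set().union(
            *(sets[o] for o in systems if o != name), set()
        ))
        for name in systems
    }
    global_fn = len(sets["gold"] - set().union(*(sets[n] for n in systems)))
    return OverlapPartition(
        set_names=("gold",) + tuple(systems),
        regions=regions,
        unique_true_positives=unique_tp,
        global_false_negatives=global_fn,
    )
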