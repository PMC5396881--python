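"""ROC validation of ranked candidate terms against gold-standard labels.

Terms are ranked by their enrichment p-value (smaller ranks higher); the
ROC curve plots sensitivity against one minus specificity over all score
thresholds, tied scores moving together (Mann–Whitney tie convention, so
the trapezoidal area equals the pairwise rank statistic exactly).  Curve
points come from scikit-learn with no threshold dropping; the area is a
trapezoid integral.  A frequency-cutoff sweep re-restricts the ranking
to terms whose group A count exceeds each cutoff and recomputes the
curve, mirroring the sensitivity analysis over cutoffs 1–6.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "LabeledRanking",
    "roc_curve",
    "auc",
    "roc_auc",
    "cutoff_sweep",
    "read_labels_tsv",
    "write_roc_tsv",
]


@dataclass
class LabeledRanking:
    """Terms with a ranking score and a 0/1 gold-standard label.

    ``smaller_is_better=True`` (the default) suits p-values: smaller
    scores rank higher.
    """

    terms: list[str]
    scores: np.ndarray
    labels: np.ndarray
    smaller_is_better: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.terms) == len(self.scores) == len(self.labels)):
            raise ValueError("terms, scores and labels must have equal length")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")

    @classmethod
    def from_entries(
        cls,
        entries: Iterable[tuple[str, float, int]],
        smaller_is_better: bool = True,
    ) -> "LabeledRanking":
        entries = list(entries)
        return cls(
            terms=[e[0] for e in entries],
            scores=np.array([e[1] for e in entries], dtype=float),
            labels=np.array([e[2] for e in entries], dtype=int),
            smaller_is_better=smaller_is_better,
        )

    @classmethod
    def from_results(
        cls, results: Iterable, labels: Mapping[str, int]
    ) -> "LabeledRanking":
        """Rank enrichment results by p-value against a term -> label map.

        Terms without a label are skipped (gold standards rarely cover
        every candidate).
        """
        from ._text import norm_term

        label_map = {norm_term(k): int(v) for k, v in labels.items()}
        entries = [
            (r.term, r.p_value, label_map[norm_term(r.term)])
            for r in results
            if norm_term(r.term) in label_map
        ]
        return cls.from_entries(entries, smaller_is_better=True)

    def _oriented_scores(self) -> np.ndarray:
        return -self.scores if self.smaller_is_better else self.scores


def roc_curve(ranking: LabeledRanking) -> np.ndarray:
    """ROC points, one per distinct threshold, endpoints (0,0) and (1,1).

    Raises :class:`ValueError` naming the missing class when all labels
    are identical (the curve is undefined).
    """
    pos = int(ranking.labels.sum())
    neg = len(ranking.labels) - pos
    if pos == 0 or neg == 0:
        missing = "positive (1)" if pos == 0 else "negative (0)"
        raise ValueError(f"ROC undefined: no {missing} labels in the ranking")
    fpr, tpr, _ = _sk_roc_curve(
        ranking.labels, ranking._oriented_scores(), drop_intermediate=False
    )
    return np.column_stack([fpr, tpr])


def auc(points: np.ndarray) -> float:
    """Trapezoidal area under ROC points sorted by false-positive rate."""
    points = np.asarray(points, dtype=float)
    fpr, tpr = points[:, 0], points[:, 1]
    if np.any(np.diff(fpr) < 0):
        raise ValueError("points must be sorted by ascending fpr")
    return float(np.trapezoid(tpr, fpr))


def roc_auc(ranking: LabeledRanking) -> float:
    return auc(roc_curve(ranking))


def cutoff_sweep(
    ranking: LabeledRanking,
    counts: Mapping[str, int],
    cutoffs: Sequence[int],
) -> dict[int, tuple[np.ndarray | None, float | None]]:
    """Recompute the ROC after restricting to terms with count > cutoff.

    A cutoff whose restriction leaves one label class empty (or no terms
    at all) is reported as ``(None, None)``; the sweep continues.
    """
    from ._text import norm_term

    count_map = {norm_term(k): int(v) for k, v in counts.items()}
    out: dict[int, tuple[np.ndarray | None, float | None]] = {}
    for cutoff in cutoffs:
        keep = [
            i for i, t in enumerate(ranking.terms)
            if count_map.get(norm_term(t), 0) > cutoff
        ]
        if not keep:
            out[cutoff] = (None, None)
            continue
        sub = LabeledRanking(
            terms=[ranking.terms[i] for i in keep],
            scores=ranking.scores[keep],
            labels=ranking.labels[keep],
            smaller_is_better=ranking.smaller_is_better,
        )
        try:
            pts = roc_curve(sub)
        except ValueError:
            out[cutoff] = (None, None)
            continue
        out[cutoff] = (pts, auc(pts))
    return out


def read_labels_tsv(source) -> dict[str, int]:
    """Read a gold-label TSV (columns: term, 0/1 label; optional header)."""
    if hasattr(source, "read"):
        handle = source
    elif isinstance(source, (str, Path)) and "\n" not in str(source) and Path(source).exists():
        handle = Path(source).open("r", encoding="utf-8")
    else:
        handle = io.StringIO(str(source))
    labels: dict[str, int] = {}
    for row in csv.reader(handle, delimiter="\t"):
        if not row or row[0].startswith("#"):
            continue
        if row[1].strip() not in ("0", "1"):
            if not labels:  # header row
                continue
            raise ValueError(f"label must be 0/1, got {row[1]!r} for {row[0]!r}")
        labels[row[0].strip()] = int(row[1])
    return labels


def write_roc_tsv(points: np.ndarray, dest, header_comment: str | None = None) -> None:
    own = not hasattr(dest, "write")
    handle = Path(dest).open("w", encoding="utf-8") if own else dest
    try:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        handle.write("fpr\ttpr\n")
        for fpr, tpr in np.asarray(points):
            handle.write(f"{fpr:.10g}\t{tpr:.10g}\n")
    finally:
        if own:
            handle.close()
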