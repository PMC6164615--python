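"""Disorder annotations, benchmark filters, ratio balancing, CV and metrics.

Disordered regions are exchanged between two equivalent representations:
1-based inclusive ``(start, end)`` intervals (the form used in structure
annotations and figure captions) and per-residue label strings over
{O, D}.  Residue-level performance uses D as the positive class and is
summarized by sensitivity, specificity, balanced accuracy
(ACC = (Sn + Sp) / 2) and Matthews correlation — the standard choices when
ordered residues vastly outnumber disordered ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from .crf import ALPHABET, LabeledSequence, ObservationSequence

__all__ = [
    "Interval",
    "ProteinRecord",
    "ConfusionCounts",
    "Metrics",
    "FoldAssignment",
    "canonicalize_intervals",
    "intervals_to_labels",
    "labels_to_intervals",
    "confusion_counts",
    "metrics",
    "apply_benchmark_filters",
    "subsample_ordered_residues",
    "kfold_split",
    "ratio_curve_experiment",
    "read_interval_table",
    "write_interval_table",
]

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised for inconsistent disorder annotations."""


@dataclass
class ProteinRecord:
    """A benchmark entry: sequence plus disorder annotation and optional metadata."""

    id: str
    sequence: str
    disorder_intervals: list[Interval] = field(default_factory=list)
    resolution: float | None = None  # X-ray resolution, Angstrom
    source: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def labels(self) -> str:
        return intervals_to_labels(self.disorder_intervals, self.length)


def canonicalize_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping or touching 1-based inclusive intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if s > e:
            raise AnnotationError(f"invalid interval ({s}, {e}): start > end")
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intervals_to_labels(intervals: Iterable[Interval], length: int) -> str:
    """Per-residue label string: D inside any interval, O elsewhere."""
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        if not (1 <= s <= e <= length):
            raise AnnotationError(f"interval ({s}, {e}) outside 1..{length}")
        mask[s - 1 : e] = True
    return "".join("D" if m else "O" for m in mask)


def labels_to_intervals(labels: str) -> list[Interval]:
    """Maximal runs of D as 1-based inclusive intervals (inverse of intervals_to_labels)."""
    out: list[Interval] = []
    start = None
    for i, c in enumerate(labels, start=1):
        if c == "D":
            if start is None:
                start = i
        else:
            if start is not None:
                out.append((start, i - 1))
                start = None
    if start is not None:
        out.append((start, len(labels)))
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    """Residue-level confusion counts with D as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise AnnotationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def confusion_counts(truth: str, prediction: str) -> ConfusionCounts:
    if len(truth) != len(prediction):
        raise AnnotationError(
            f"truth length {len(truth)} != prediction length {len(prediction)}"
        )
    t = np.frombuffer(truth.encode(), dtype="S1") == b"D"
    p = np.frombuffer(prediction.encode(), dtype="S1") == b"D"
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


@dataclass(frozen=True)
class Metrics:
    sn: float
    sp: float
    acc: float
    mcc: float


def metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, balanced accuracy and Matthews correlation.

    ACC is the mean of Sn and Sp (balanced accuracy), not raw accuracy.  A
    zero MCC denominator yields MCC = 0 with a warning; an absent class
    makes Sn or Sp NaN with a warning.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if tp + fn == 0:
        warnings.warn("no disordered residues in truth: Sn undefined")
        sn = math.nan
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no ordered residues in truth: Sp undefined")
        sp = math.nan
    else:
        sp = tn / (tn + fp)
    acc = (sn + sp) / 2
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    return Metrics(sn=sn, sp=sp, acc=acc, mcc=mcc)


def apply_benchmark_filters(
    records: Sequence[ProteinRecord],
    max_resolution: float = 2.0,
    min_length: int = 30,
    log: list[str] | None = None,
) -> list[ProteinRecord]:
    """Keep X-ray entries with resolution <= 2 A, length >= 30 and >= 1 IDR.

    Both boundaries are inclusive.  Records without a resolution value are
    excluded with a logged reason.
    """
    kept: list[ProteinRecord] = []
    for rec in records:
        if rec.resolution is None:
            reason = "missing resolution"
        elif rec.resolution > max_resolution:
            reason = f"resolution {rec.resolution} > {max_resolution}"
        elif rec.length < min_length:
            reason = f"length {rec.length} < {min_length}"
        elif not canonicalize_intervals(rec.disorder_intervals):
            reason = "no disordered region"
        else:
            kept.append(rec)
            continue
        if log is not None:
            log.append(f"{rec.id}: dropped ({reason})")
    return kept


def _label_counts(data: Sequence[LabeledSequence]) -> tuple[int, int]:
    d = sum(seq.labels.count("D") for seq in data)
    o = sum(seq.labels.count("O") for seq in data)
    return d, o


def subsample_ordered_residues(
    data: Sequence[LabeledSequence], ratio_d_to_o: float, seed: int
) -> list[LabeledSequence]:
    """Randomly excise ordered residues until the global D:O ratio is ~1:m.

    Each excised residue splits its chain at the excision point, so the
    resulting subsequences only contain genuinely adjacent residue pairs.
    Disordered residues are never removed.  Deterministic given ``seed``.
    """
    m = float(ratio_d_to_o)
    if m < 1:
        raise AnnotationError("ratio must be at least 1 (one O per D)")
    n_d, n_o = _label_counts(data)
    if n_d == 0 or n_o == 0:
        raise AnnotationError("dataset must contain both ordered and disordered residues")
    n_remove = int(round(n_o - m * n_d))
    if n_remove <= 0:
        warnings.warn(
            f"requested ratio 1:{m} already exceeded (D:O = {n_d}:{n_o}); dataset unchanged"
        )
        return list(data)

    # global uniform choice among all ordered residue positions
    positions = [
        (si, pi)
        for si, seq in enumerate(data)
        for pi, lab in enumerate(seq.labels)
        if lab == "O"
    ]
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positions), size=n_remove, replace=False)
    removed_by_seq: dict[int, set[int]] = {}
    for c in chosen:
        si, pi = positions[c]
        removed_by_seq.setdefault(si, set()).add(pi)

    out: list[LabeledSequence] = []
    for si, seq in enumerate(data):
        removed = removed_by_seq.get(si)
        if not removed:
            out.append(seq)
            continue
        L = seq.observation.length
        part = 0
        start = 0
        for pos in range(L + 1):
            if pos == L or pos in removed:
                if pos > start:
                    obs = ObservationSequence(
                        f"{seq.observation.sequence_id}/part{part}",
                        seq.observation.features[start:pos],
                    )
                    out.append(LabeledSequence(obs, seq.labels[start:pos]))
                    part += 1
                start = pos + 1
    return out


@dataclass(frozen=True)
class FoldAssignment:
    """Protein-level k-fold partition, reproducible from its seed."""

    assignment: dict[str, int]
    k: int
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [pid for pid, f in self.assignment.items() if f == fold]


def kfold_split(ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle protein ids and deal them into k folds whose sizes differ by <= 1."""
    if k < 2:
        raise AnnotationError("k must be at least 2")
    if k > len(ids):
        raise AnnotationError(f"k = {k} exceeds number of proteins ({len(ids)})")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    return FoldAssignment({pid: i % k for i, pid in enumerate(order)}, k=k, seed=seed)


class Trainer(Protocol):
    """Any train/predict pair usable in the ratio experiment."""

    def train(self, data: Sequence[LabeledSequence]): ...

    def predict(self, model, obs: ObservationSequence) -> str: ...


def ratio_curve_experiment(
    data: Sequence[LabeledSequence],
    ratios: Sequence[float],
    trainer: Trainer,
    seed: int = 0,
    k: int = 5,
) -> pd.DataFrame:
    """Residue-pooled k-fold CV metrics after balancing training folds to each D:O ratio.

    For each ratio 1:m, every CV training split is subsampled to that ratio
    (test folds are left untouched), the trainer is fit, and confusion counts
    are pooled over all residues of all test folds.
    """
    ids = [seq.observation.sequence_id for seq in data]
    if len(set(ids)) != len(ids):
        raise AnnotationError("duplicate sequence ids in dataset")
    folds = kfold_split(ids, k=k, seed=seed)
    rows = []
    for ratio in ratios:
        pooled = ConfusionCounts(0, 0, 0, 0)
        for fold in range(k):
            test = [s for s in data if folds.assignment[s.observation.sequence_id] == fold]
            train_part = [s for s in data if folds.assignment[s.observation.sequence_id] != fold]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                balanced = subsample_ordered_residues(train_part, ratio, seed=seed + fold)
            model = trainer.train(balanced)
            for s in test:
                pred = trainer.predict(model, s.observation)
                pooled = pooled + confusion_counts(s.labels, pred)
        mets = metrics(pooled)
        rows.append(
            {"ratio": ratio, "Sn": mets.sn, "Sp": mets.sp, "ACC": mets.acc, "MCC": mets.mcc}
        )
    return pd.DataFrame(rows)


def read_interval_table(path) -> dict[str, list[Interval]]:
    """Read a tab-separated ``id  start  end`` interval file (1-based inclusive)."""
    out: dict[str, list[Interval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise AnnotationError(f"{path}: line {lineno}: expected 'id start end'")
            pid, s, e = parts
            out.setdefault(pid, []).append((int(s), int(e)))
    return {pid: canonicalize_intervals(ivs) for pid, ivs in out.items()}


def write_interval_table(intervals_by_id: dict[str, list[Interval]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# id\tstart\tend (1-based inclusive)\n")
        for pid in sorted(intervals_by_id):
            for s, e in intervals_by_id[pid]:
                fh.write(f"{pid}\t{s}\t{e}\n")
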