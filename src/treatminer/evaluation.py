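"""Precision/recall/F1 evaluation stratified by co-occurrence frequency.

Gold standards are anchored on one drug or one disease (every gold pair
contains the anchor), because exhaustive manual curation of treatment
pairs is only feasible one entity at a time.  Recall is reported at
minimum co-occurrence-frequency cutoffs: a pattern-based extractor can
only find a pair in sentences where the pair co-occurs, so rare pairs are
structurally hard and recall rises with the cutoff.  Precision is computed
once on all extracted pairs and is cutoff-invariant by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from treatminer.pattern_miner import DrugDiseasePair
from treatminer.tagger import CooccurrenceIndex


class UndefinedMetricError(ValueError):
    """Raised when a ratio's denominator is empty (0/0 is not a score)."""


@dataclass(frozen=True)
class GoldStandard:
    """Manually curated true pairs, all containing one anchor entity."""

    anchor_type: str  # "DRUG" | "DISEASE"
    anchor_term: str
    pairs: frozenset[DrugDiseasePair]

    def __post_init__(self) -> None:
        for p in self.pairs:
            side = p.drug if self.anchor_type == "DRUG" else p.disease
            if side != self.anchor_term:
                raise ValueError(
                    f"gold pair {p} does not contain anchor {self.anchor_type}={self.anchor_term!r}"
                )

    def restrict(self, extracted: Iterable[DrugDiseasePair]) -> set[DrugDiseasePair]:
        """Keep only the extracted pairs containing this gold standard's anchor."""
        if self.anchor_type == "DRUG":
            return {p for p in extracted if p.drug == self.anchor_term}
        return {p for p in extracted if p.disease == self.anchor_term}


@dataclass(frozen=True)
class EvalRow:
    cutoff: int
    precision: float
    recall: float | None
    f1: float | None
    n_extracted: int
    n_gold_at_cutoff: int
    n_true_positive: int


@dataclass(frozen=True)
class EvalReport:
    rows: tuple[EvalRow, ...]


def precision_recall(
    extracted: set[DrugDiseasePair], gold: set[DrugDiseasePair]
) -> tuple[float, float]:
    """P = |E ∩ G| / |E|, R = |E ∩ G| / |G|; empty denominators are errors."""
    if not extracted:
        raise UndefinedMetricError("precision undefined: no extracted pairs")
    if not gold:
        raise UndefinedMetricError("recall undefined: empty gold standard")
    tp = len(extracted & gold)
    return tp / len(extracted), tp / len(gold)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; (0, 0) -> 0 by convention."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must be in [0, 1]")
    if precision == 0.0 and recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def round3(x: float) -> float:
    """Round half away from zero at 3 decimals (display convention)."""
    q = Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    return float(q)


def evaluate_at_cutoffs(
    extracted: Iterable[DrugDiseasePair],
    gold: GoldStandard,
    freq: CooccurrenceIndex,
    cutoffs: Sequence[int],
) -> EvalReport:
    """One report row per minimum-frequency cutoff.

    At cutoff c the gold subset is the gold pairs with co-occurrence
    frequency >= c (a pair absent from the index has frequency 0) and
    recall is computed against it.  Precision is computed once on all
    extracted pairs (restricted to the anchor) against the full gold set
    and repeated on every row.  An empty gold subset yields a row with an
    undefined-recall marker (None), not a zero.
    """
    if list(cutoffs) != sorted(cutoffs) or (cutoffs and cutoffs[0] < 1):
        raise ValueError("cutoffs must be ascending integers >= 1")
    extracted_anchor = gold.restrict(extracted)
    precision, _ = precision_recall(extracted_anchor, set(gold.pairs))
    rows = []
    for c in cutoffs:
        gold_c = {g for g in gold.pairs if freq.get(g) >= c}
        tp = len(extracted_anchor & gold_c)
        if gold_c:
            recall = tp / len(gold_c)
            f1 = f1_score(precision, recall)
        else:
            recall = None
            f1 = None
        rows.append(
            EvalRow(
                cutoff=c,
                precision=precision,
                recall=recall,
                f1=f1,
                n_extracted=len(extracted_anchor),
                n_gold_at_cutoff=len(gold_c),
                n_true_positive=tp,
            )
        )
    return EvalReport(tuple(rows))


# -- TSV interfaces ---------------------------------------------------------

def load_gold_tsv(path, anchor_type: str, anchor_term: str) -> GoldStandard:
    from treatminer.corpus_io import load_pairs_tsv

    pairs = frozenset(DrugDiseasePair(d, z) for d, z in load_pairs_tsv(path))
    return GoldStandard(anchor_type, anchor_term, pairs)


def write_report_tsv(report: EvalReport, path) -> None:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{round3(x):.3f}"

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cutoff\tprecision\trecall\tf1\tn_extracted\tn_gold_at_cutoff\tn_true_positive\n")
        for r in report.rows:
            fh.write(
                f"{r.cutoff}\t{fmt(r.precision)}\t{fmt(r.recall)}\t{fmt(r.f1)}\t"
                f"{r.n_extracted}\t{r.n_gold_at_cutoff}\t{r.n_true_positive}\n"
            )
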