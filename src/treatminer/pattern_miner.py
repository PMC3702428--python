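"""Inter-entity pattern extraction, ranking and selection.

A *pattern* is the verbatim text between a drug mention and a disease
mention in one sentence, tagged with its orientation (which entity type
comes first).  Patterns observed with many distinct known treatment pairs
(seeds from a clinical-trials registry) tend to be treatment-specific
("in the treatment of"), while patterns observed mostly outside the seed
set tend to express other relations ("-induced", an adverse effect).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

from treatminer.tagger import TaggedSentence

Orientation = Literal["DRUG_FIRST", "DISEASE_FIRST"]

DRUG_FIRST: Orientation = "DRUG_FIRST"
DISEASE_FIRST: Orientation = "DISEASE_FIRST"


@dataclass(frozen=True, order=True)
class DrugDiseasePair:
    """A canonicalized (generic drug, disease) pair, both case-folded."""

    drug: str
    disease: str


def _normalize_infix(text: str) -> str:
    return " ".join(text.split()).casefold()


@dataclass(frozen=True, order=True)
class Pattern:
    """An orientation-tagged, normalized infix.

    The infix is case-folded, outer whitespace trimmed and inner whitespace
    collapsed; it may be empty (adjacent mentions).  Equality is
    (orientation, infix) equality.
    """

    orientation: Orientation
    infix: str

    def __post_init__(self) -> None:
        if "\t" in self.infix or "\n" in self.infix:
            raise ValueError("pattern infix must not contain tabs or newlines")

    @classmethod
    def from_text(cls, orientation: Orientation, raw_infix: str) -> "Pattern":
        return cls(orientation, _normalize_infix(raw_infix))


@dataclass(frozen=True)
class PatternObservation:
    pattern: Pattern
    pair: DrugDiseasePair
    doc_id: str
    sentence_index: int


@dataclass(frozen=True)
class PatternStat:
    pattern: Pattern
    seed_pair_count: int
    total_pair_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.seed_pair_count <= self.total_pair_count:
            raise ValueError("0 <= seed_pair_count <= total_pair_count violated")


def extract_pattern_observations(tagged: TaggedSentence) -> list[PatternObservation]:
    """One observation per (drug mention, disease mention) pair in the sentence.

    The infix is the verbatim text strictly between the two mention spans
    (whatever its length, and keeping any intervening mention's surface text),
    normalized per ``Pattern``.  Duplicate (pattern, pair) observations
    within one sentence are deduplicated.  A sentence lacking one of the two
    entity types yields an empty list.
    """
    drugs = [m for m in tagged.mentions if m.entity_type == "DRUG"]
    diseases = [m for m in tagged.mentions if m.entity_type == "DISEASE"]
    text = tagged.sentence.text
    seen: set[tuple[Pattern, DrugDiseasePair]] = set()
    out: list[PatternObservation] = []
    for d in drugs:
        for z in diseases:
            if d.start < z.start:
                orientation, infix = DRUG_FIRST, text[d.end : z.start]
            else:
                orientation, infix = DISEASE_FIRST, text[z.end : d.start]
            pattern = Pattern.from_text(orientation, infix)
            pair = DrugDiseasePair(d.term, z.term)
            key = (pattern, pair)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                PatternObservation(
                    pattern, pair, tagged.sentence.doc_id, tagged.sentence.sentence_index
                )
            )
    return out


def aggregate_pattern_stats(
    observations: Iterable[PatternObservation],
    seeds: set[DrugDiseasePair],
) -> list[PatternStat]:
    """Exact per-pattern distinct-pair counts, overall and within the seed set."""
    pairs_by_pattern: dict[Pattern, set[DrugDiseasePair]] = {}
    for obs in observations:
        pairs_by_pattern.setdefault(obs.pattern, set()).add(obs.pair)
    return [
        PatternStat(p, len(pairs & seeds), len(pairs))
        for p, pairs in pairs_by_pattern.items()
    ]


def rank_patterns(stats: Iterable[PatternStat]) -> list[PatternStat]:
    """Total deterministic order: descending seed-pair count, then descending
    total-pair count, then ascending (orientation, infix)."""
    return sorted(
        stats,
        key=lambda s: (-s.seed_pair_count, -s.total_pair_count, s.pattern.orientation, s.pattern.infix),
    )


#: The shipped default curation: 17 drug-first treatment-specific infixes.
DEFAULT_TREATMENT_INFIXES: tuple[str, ...] = (
    "in",
    "in the treatment of",
    "for",
    "in patients with",
    "for the treatment of",
    "treatment of",
    "therapy for",
    "therapy in",
    "for treatment of",
    "against",
    "in the management of",
    "therapy of",
    "treatment for",
    "treatment in",
    "in a patient with",
    "in treatment of",
    "in children with",
)


def default_treatment_patterns() -> set[Pattern]:
    """The package's default curated treatment-specific pattern set.

    Loaded from the shipped ``patterns_default.tsv``; all are DRUG_FIRST —
    disease-first patterns ("DISEASE with DRUG") are far less specific to
    treatment and are excluded from the default curation.
    """
    text = resources.files("treatminer").joinpath("data/patterns_default.tsv").read_text("utf-8")
    patterns: set[Pattern] = set()
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        orientation, infix = line.split("\t")
        patterns.add(Pattern(orientation, infix))  # type: ignore[arg-type]
    return patterns


def select_patterns(
    ranked: Sequence[PatternStat],
    explicit: Iterable[Pattern] | None = None,
    top_k: int | None = None,
) -> set[Pattern]:
    """Return the curated pattern set.

    Priority: an explicit list wins; otherwise the first ``top_k`` of the
    ranked statistics; otherwise the shipped default curation.  An explicit
    pattern absent from the ranked list is still selectable (a warning is
    the caller's concern via logging here).
    """
    import logging

    logger = logging.getLogger(__name__)
    if explicit is not None:
        selected = set(explicit)
        ranked_patterns = {s.pattern for s in ranked}
        for p in selected - ranked_patterns:
            logger.warning("selected pattern %r not present in ranked list", p)
        return selected
    if top_k is not None:
        return {s.pattern for s in ranked[:top_k]}
    return default_treatment_patterns()


# -- pattern stats TSV ------------------------------------------------------

def write_pattern_stats_tsv(ranked: Sequence[PatternStat], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("orientation\tinfix\tseed_pair_count\ttotal_pair_count\trank\n")
        for rank, s in enumerate(ranked, start=1):
            fh.write(
                f"{s.pattern.orientation}\t{s.pattern.infix}\t"
                f"{s.seed_pair_count}\t{s.total_pair_count}\t{rank}\n"
            )


def load_patterns_tsv(path) -> set[Pattern]:
    """Read patterns from a TSV whose first two columns are orientation, infix."""
    patterns: set[Pattern] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["orientation", "infix"]:
            raise ValueError(f"pattern TSV {path!s} must start with orientation, infix columns")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            patterns.add(Pattern(fields[0], fields[1]))  # type: ignore[arg-type]
    return patterns
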