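"""Correlation of extracted treatment pairs with drug annotations.

If the extracted drug-disease pairs carry real therapeutic signal, then
drugs that treat the same diseases should tend to share target genes and
ATC (Anatomical Therapeutic Chemical) classification codes.  This module
computes, for every unordered drug-drug pair, the number of shared
diseases / target genes / ATC codes, and reports the mean shared gene
(or ATC) count among pairs whose shared-disease count meets increasing
thresholds.  A rising curve is the enrichment signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

AssociationKind = Literal["GENE", "ATC", "DISEASE"]

#: ATC code prefix lengths per hierarchy level (1=anatomical group ... 5=substance).
_ATC_LEVEL_PREFIX = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class AssociationTable:
    """drug -> set of associated items (disease terms, gene symbols or ATC codes)."""

    kind: AssociationKind
    mapping: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for drug, items in self.mapping.items():
            if drug != drug.casefold():
                raise ValueError(f"drug {drug!r} is not case-folded")
            if not items:
                raise ValueError(f"drug {drug!r} has an empty item set")

    @classmethod
    def from_pairs(cls, kind: AssociationKind, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        mapping: dict[str, set[str]] = {}
        for drug, item in pairs:
            mapping.setdefault(drug.casefold(), set()).add(item)
        return cls(kind, {d: frozenset(s) for d, s in mapping.items()})

    def truncate_atc(self, level: int) -> "AssociationTable":
        """Collapse ATC codes to a hierarchy level (1-5) before intersecting."""
        if self.kind != "ATC":
            raise ValueError("truncate_atc applies to ATC tables only")
        n = _ATC_LEVEL_PREFIX[level]
        return AssociationTable(
            "ATC", {d: frozenset(c[:n] for c in items) for d, items in self.mapping.items()}
        )


@dataclass(frozen=True)
class SharedProfileRow:
    """Shared-item counts for one unordered drug pair (drug_a < drug_b)."""

    drug_a: str
    drug_b: str
    shared_diseases: int
    shared_genes: int
    shared_atc: int

    def __post_init__(self) -> None:
        if self.drug_a >= self.drug_b:
            raise ValueError("rows must satisfy drug_a < drug_b (unordered uniqueness)")


def disease_table_from_pairs(pairs) -> AssociationTable:
    """Build the drug->disease profile from (drug, disease) treatment pairs."""
    return AssociationTable.from_pairs("DISEASE", ((p.drug, p.disease) for p in pairs))


def shared_profile(
    diseases: AssociationTable,
    genes: AssociationTable,
    atc: AssociationTable,
    atc_level: int | None = None,
) -> list[SharedProfileRow]:
    """One row per unordered drug pair in the analysis universe.

    The universe is restricted to drugs that have a disease profile AND at
    least one gene or ATC annotation (drugs absent from the annotation
    sources say nothing about enrichment).  A drug missing from one
    annotation table contributes an empty set there.
    """
    if atc_level is not None:
        atc = atc.truncate_atc(atc_level)
    universe = sorted(
        set(diseases.mapping) & (set(genes.mapping) | set(atc.mapping))
    )
    if len(universe) < 2:
        raise ValueError("analysis universe must contain at least 2 drugs")
    empty: frozenset[str] = frozenset()
    rows = []
    for a, b in combinations(universe, 2):
        rows.append(
            SharedProfileRow(
                drug_a=a,
                drug_b=b,
                shared_diseases=len(diseases.mapping[a] & diseases.mapping[b]),
                shared_genes=len(genes.mapping.get(a, empty) & genes.mapping.get(b, empty)),
                shared_atc=len(atc.mapping.get(a, empty) & atc.mapping.get(b, empty)),
            )
        )
    return rows


def mean_shared_by_threshold(
    rows: Sequence[SharedProfileRow],
    item: Literal["GENES", "ATC"],
    thresholds: Sequence[int],
) -> list[tuple[int, int, float | None]]:
    """(threshold, n_pairs, mean shared item count) per shared-disease threshold.

    Threshold t selects the rows with shared_diseases >= t (t=0 is all
    pairs).  An empty selection yields an undefined marker (None), never a
    zero — no pairs is not the same as no sharing.
    """
    if list(thresholds) != sorted(thresholds) or (thresholds and thresholds[0] < 0):
        raise ValueError("thresholds must be ascending integers >= 0")
    attr = "shared_genes" if item == "GENES" else "shared_atc"
    out: list[tuple[int, int, float | None]] = []
    for t in thresholds:
        selected = [getattr(r, attr) for r in rows if r.shared_diseases >= t]
        if selected:
            out.append((t, len(selected), sum(selected) / len(selected)))
        else:
            out.append((t, 0, None))
    return out


# -- TSV interfaces ---------------------------------------------------------

def load_association_tsv(path, kind: AssociationKind) -> AssociationTable:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "drug" not in header or "item" not in header:
            raise ValueError(f"association TSV {path!s} must have columns drug, item")
        d_i, i_i = header.index("drug"), header.index("item")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            pairs.append((fields[d_i], fields[i_i]))
    return AssociationTable.from_pairs(kind, pairs)


def write_mean_shared_tsv(table: Sequence[tuple[int, int, float | None]], path) -> None:
    from treatminer.evaluation import round3

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("threshold\tn_pairs\tmean_shared\n")
        for t, n, mean in table:
            fh.write(f"{t}\t{n}\t{'NA' if mean is None else f'{round3(mean):.3f}'}\n")
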