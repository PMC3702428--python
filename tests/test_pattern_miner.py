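"""Pattern extraction, aggregation, ranking and selection."""

from __future__ import annotations

import random

import pytest

from treatminer.corpus_io import SentenceRecord
from treatminer.lexicon import Lexicon
from treatminer.pattern_miner import (
    DEFAULT_TREATMENT_INFIXES,
    DISEASE_FIRST,
    DRUG_FIRST,
    DrugDiseasePair,
    Pattern,
    PatternObservation,
    PatternStat,
    aggregate_pattern_stats,
    default_treatment_patterns,
    extract_pattern_observations,
    rank_patterns,
    select_patterns,
)
from treatminer.tagger import tag_sentence


DRUGS = Lexicon("DRUG", frozenset({"irinotecan", "tamoxifen", "gabapentin"}))
DISEASES = Lexicon(
    "DISEASE",
    frozenset({"small cell carcinoma", "breast cancer", "endometrial cancer", "tinnitus"}),
)


def observe(text, doc_id="1"):
    s = SentenceRecord(doc_id, 0, text)
    return extract_pattern_observations(tag_sentence(s, DRUGS, DISEASES))


class TestExtractObservations:
    def test_drug_first_treatment_pattern(self):
        obs = observe("Role of irinotecan in the treatment of small cell carcinoma")
        assert obs == [
            PatternObservation(
                Pattern(DRUG_FIRST, "in the treatment of"),
                DrugDiseasePair("irinotecan", "small cell carcinoma"),
                "1", 0,
            )
        ]

    def test_disease_first_pattern(self):
        obs = observe("Seventeen women with breast cancer were treated with tamoxifen (20 mg, twice a day)")
        assert obs == [
            PatternObservation(
                Pattern(DISEASE_FIRST, "were treated with"),
                DrugDiseasePair("tamoxifen", "breast cancer"),
                "1", 0,
            )
        ]

    def test_hyphenated_side_effect_pattern(self):
        obs = observe("Tamoxifen-induced endometrial cancer")
        assert obs == [
            PatternObservation(
                Pattern(DRUG_FIRST, "-induced"),
                DrugDiseasePair("tamoxifen", "endometrial cancer"),
                "1", 0,
            )
        ]

    def test_missing_entity_type_yields_empty(self):
        assert observe("tamoxifen alone") == []
        assert observe("breast cancer alone") == []

    def test_all_ordered_pairs_emitted(self):
        obs = observe("gabapentin for tinnitus and tamoxifen for breast cancer")
        patterns = {(o.pattern, o.pair) for o in obs}
        # 2 drugs x 2 diseases, orientation per precedence
        assert patterns == {
            (Pattern(DRUG_FIRST, "for"), DrugDiseasePair("gabapentin", "tinnitus")),
            (Pattern(DRUG_FIRST, "for"), DrugDiseasePair("tamoxifen", "breast cancer")),
            (
                Pattern(DRUG_FIRST, "for tinnitus and tamoxifen for"),
                DrugDiseasePair("gabapentin", "breast cancer"),
            ),
            (Pattern(DISEASE_FIRST, "and"), DrugDiseasePair("tamoxifen", "tinnitus")),
        }

    def test_infix_normalization_case_and_whitespace(self):
        obs = observe("Irinotecan  IN THE   TREATMENT OF small cell carcinoma")
        assert obs[0].pattern == Pattern(DRUG_FIRST, "in the treatment of")

    def test_empty_infix_for_adjacent_mentions(self):
        obs = observe("tamoxifen breast cancer")
        assert obs[0].pattern == Pattern(DRUG_FIRST, "")

    def test_reconstruction_invariant(self, world):
        """The normalized infix equals the normalized between-span slice."""
        from treatminer.tagger import tag_corpus

        for ts in tag_corpus(world["sentences"][:60], world["drugs"], world["diseases"], world["synonyms"]):
            text = ts.sentence.text
            for obs in extract_pattern_observations(ts):
                witnesses = []
                for d in ts.mentions:
                    for z in ts.mentions:
                        if d.entity_type != "DRUG" or z.entity_type != "DISEASE":
                            continue
                        if (d.term, z.term) != (obs.pair.drug, obs.pair.disease):
                            continue
                        if d.start < z.start:
                            infix, orientation = text[d.end:z.start], "DRUG_FIRST"
                        else:
                            infix, orientation = text[z.end:d.start], "DISEASE_FIRST"
                        witnesses.append(Pattern.from_text(orientation, infix))
                assert obs.pattern in witnesses, (text, obs)


class TestAggregateStats:
    def test_direct_count(self):
        p = Pattern(DRUG_FIRST, "for")
        pairs = [DrugDiseasePair("a", "x"), DrugDiseasePair("b", "y"), DrugDiseasePair("c", "z")]
        obs = [PatternObservation(p, pair, "d", 0) for pair in pairs]
        seeds = set(pairs[:2])
        (stat,) = aggregate_pattern_stats(obs, seeds)
        assert (stat.seed_pair_count, stat.total_pair_count) == (2, 3)

    def test_empty(self):
        assert aggregate_pattern_stats([], set()) == []

    def test_matches_brute_force_tally(self):
        """Aggregation equals an independent nested-loop tally on 600 observations."""
        rng = random.Random(17)
        patterns = [Pattern(DRUG_FIRST, f"p{i}") for i in range(8)]
        pairs = [DrugDiseasePair(f"d{i}", f"z{j}") for i in range(6) for j in range(6)]
        seeds = set(rng.sample(pairs, 12))
        obs = [
            PatternObservation(rng.choice(patterns), rng.choice(pairs), f"doc{k}", 0)
            for k in range(600)
        ]
        stats = {s.pattern: s for s in aggregate_pattern_stats(obs, seeds)}
        for pattern in patterns:
            distinct = {o.pair for o in obs if o.pattern == pattern}
            if not distinct:
                assert pattern not in stats
                continue
            assert stats[pattern].total_pair_count == len(distinct)
            assert stats[pattern].seed_pair_count == len([p for p in distinct if p in seeds])

    def test_order_invariance_and_seed_monotonicity(self):
        rng = random.Random(3)
        patterns = [Pattern(DRUG_FIRST, f"p{i}") for i in range(3)]
        pairs = [DrugDiseasePair(f"d{i}", "z") for i in range(10)]
        obs = [PatternObservation(rng.choice(patterns), rng.choice(pairs), "d", 0) for _ in range(50)]
        seeds_small, seeds_big = set(pairs[:3]), set(pairs[:7])
        shuffled = obs[:]
        rng.shuffle(shuffled)
        assert sorted(aggregate_pattern_stats(obs, seeds_small), key=repr) == sorted(
            aggregate_pattern_stats(shuffled, seeds_small), key=repr
        )
        small = {s.pattern: s.seed_pair_count for s in aggregate_pattern_stats(obs, seeds_small)}
        big = {s.pattern: s.seed_pair_count for s in aggregate_pattern_stats(obs, seeds_big)}
        assert all(small[p] <= big[p] for p in small)


class TestRankAndSelect:
    def make_stats(self, triples):
        return [
            PatternStat(Pattern(DRUG_FIRST, infix), seed, total)
            for infix, seed, total in triples
        ]

    def test_rank_matches_sort_oracle(self):
        stats = self.make_stats(
            [("a", 5, 9), ("b", 3, 10), ("c", 3, 4), ("d", 1, 1), ("e", 3, 10)]
        )
        ranked = rank_patterns(stats)
        oracle = sorted(
            stats,
            key=lambda s: (-s.seed_pair_count, -s.total_pair_count,
                           s.pattern.orientation, s.pattern.infix),
        )
        assert ranked == oracle
        assert [s.pattern.infix for s in ranked] == ["a", "b", "e", "c", "d"]

    def test_single_pattern(self):
        stats = self.make_stats([("only", 2, 2)])
        assert rank_patterns(stats) == stats

    def test_all_equal_counts_lexicographic(self):
        stats = self.make_stats([("c", 1, 1), ("a", 1, 1), ("b", 1, 1)])
        assert [s.pattern.infix for s in rank_patterns(stats)] == ["a", "b", "c"]

    def test_default_selection_is_the_17_curated_patterns(self):
        selected = select_patterns([])
        assert selected == default_treatment_patterns()
        assert len(selected) == 17
        assert all(p.orientation == DRUG_FIRST for p in selected)
        assert {p.infix for p in selected} == set(DEFAULT_TREATMENT_INFIXES)
        assert "in the treatment of" in {p.infix for p in selected}

    def test_explicit_selection(self, caplog):
        wanted = {Pattern(DRUG_FIRST, "for"), Pattern(DRUG_FIRST, "unseen")}
        got = select_patterns(self.make_stats([("for", 1, 1)]), explicit=wanted)
        assert got == wanted
        assert any("unseen" in m for m in caplog.messages)

    def test_top_k_selection(self):
        ranked = rank_patterns(self.make_stats([("a", 5, 5), ("b", 4, 4), ("c", 3, 3), ("d", 2, 2)]))
        assert select_patterns(ranked, top_k=3) == {
            Pattern(DRUG_FIRST, "a"), Pattern(DRUG_FIRST, "b"), Pattern(DRUG_FIRST, "c")
        }


class TestPatternInvariants:
    def test_infix_rejects_tabs_and_newlines(self):
        with pytest.raises(ValueError):
            Pattern(DRUG_FIRST, "a\tb")

    def test_planted_seed_pair_count_is_exact(self, world):
        """On the fixture, each planted pattern's seed count equals the number
        of planted seed pairs assigned to it."""
        from treatminer.tagger import tag_corpus

        truth = world["truth"]
        obs = [
            o
            for ts in tag_corpus(world["sentences"], world["drugs"], world["diseases"], world["synonyms"])
            for o in extract_pattern_observations(ts)
        ]
        stats = {s.pattern: s for s in aggregate_pattern_stats(obs, set(truth.seed_pairs))}
        for pattern in truth.selected_patterns:
            expected_pairs = {p for pt, p, _ in truth.planted_links if pt == pattern}
            expected_seeds = expected_pairs & set(truth.seed_pairs)
            assert stats[pattern].total_pair_count == len(expected_pairs)
            assert stats[pattern].seed_pair_count == len(expected_seeds)
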