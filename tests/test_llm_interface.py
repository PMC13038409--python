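"""Completion contract, cache record/replay, and the mock oracle."""

import json
from dataclasses import replace

import numpy as np
import pytest

from nerprompt import (
    PRESETS,
    CachingClient,
    LLMConfig,
    MockBackend,
    MockOracleConfig,
    ReplayMissError,
    ResponseCache,
    Sentence,
    decode,
    mock_annotate,
)
from nerprompt.llm_interface import label_space_for, max_jaccard_relevance


class TestConfig:
    def test_presets_carry_published_sampling_settings(self):
        assert (PRESETS["gpt"].temperature, PRESETS["gpt"].top_p) == (0.2, 0.1)
        assert (PRESETS["llama3"].temperature, PRESETS["llama3"].top_p) == (0.5, 0.95)
        assert (PRESETS["gpt-oss"].temperature, PRESETS["gpt-oss"].top_p) == (1.0, 1.0)

    def test_invalid_sampling_rejected(self):
        with pytest.raises(ValueError):
            LLMConfig(top_p=1.5)
        with pytest.raises(ValueError):
            LLMConfig(temperature=-0.1)


class CountingBackend:
    def __init__(self, response="[]"):
        self.calls = 0
        self.response = response

    def complete(self, prompt, config):
        self.calls += 1
        return self.response


class TestCachingClient:
    def test_record_mode_caches_identical_requests(self):
        backend = CountingBackend('["a-O"]')
        client = CachingClient(backend, mode="record")
        cfg = LLMConfig()
        r1 = client.complete("p", cfg)
        r2 = client.complete("p", cfg)
        assert r1 == r2 == '["a-O"]'
        assert backend.calls == 1

    def test_replay_miss_raises(self):
        client = CachingClient(None, cache=ResponseCache(), mode="replay")
        with pytest.raises(ReplayMissError):
            client.complete("unseen", LLMConfig())

    def test_record_then_replay_roundtrip(self, tmp_path):
        path = tmp_path / "cache.json"
        backend = CountingBackend('["x-O"]')
        rec = CachingClient(backend, ResponseCache(path), mode="record")
        out = rec.complete("prompt", LLMConfig())
        rec.cache.save()
        rep = CachingClient(None, ResponseCache(path), mode="replay")
        assert rep.complete("prompt", LLMConfig()) == out
        assert backend.calls == 1

    def test_config_distinguishes_cache_entries(self):
        backend = CountingBackend()
        client = CachingClient(backend, mode="record")
        client.complete("p", LLMConfig(model_name="a"))
        client.complete("p", LLMConfig(model_name="b"))
        assert backend.calls == 2


def make_gold(tokens, labels):
    return Sentence("g", tuple(tokens), tuple(labels))


class TestMockAnnotate:
    GOLD = make_gold(
        ["the", "pain", "was", "bad"], ["O", "B-X", "O", "O"]
    )
    SPACE = label_space_for(["X"])

    def test_perfect_oracle_reproduces_gold(self):
        cfg = MockOracleConfig(base_accuracy=1.0, relevance_gain=0.0, seed=1)
        items = mock_annotate([], self.GOLD, cfg, self.SPACE)
        res = decode(items, self.GOLD.tokens)
        assert res.labels == self.GOLD.labels
        assert res.n_repairs == 0

    def test_relevance_clamps_probability_to_one(self):
        cfg = MockOracleConfig(base_accuracy=0.0, relevance_gain=1.0, seed=2)
        identical_example = list(self.GOLD.tokens)  # rel = 1
        items = mock_annotate([identical_example], self.GOLD, cfg, self.SPACE)
        assert decode(items, self.GOLD.tokens).labels == self.GOLD.labels

    @pytest.mark.parametrize(
        "rel_example,expected_acc",
        [(None, 0.5), ("identical", 0.9)],
    )
    def test_token_accuracy_matches_binomial_expectation(self, rel_example, expected_acc):
        """Mean raw-label accuracy over 2000 seeded trials ≈ p0 + alpha·rel (±0.03).

        Raw emitted labels are compared (before IOB2 repair, which can
        coincidentally restore a corrupted tag and bias the estimate).
        """
        from nerprompt.codec import split_item

        examples = [] if rel_example is None else [list(self.GOLD.tokens)]
        correct = total = 0
        for seed in range(2000):
            cfg = MockOracleConfig(base_accuracy=0.5, relevance_gain=0.4, seed=seed)
            items = mock_annotate(examples, self.GOLD, cfg, self.SPACE)
            labels = [split_item(it)[1] for it in items]
            correct += sum(a == b for a, b in zip(labels, self.GOLD.labels))
            total += len(labels)
        assert abs(correct / total - expected_acc) < 0.03

    def test_accuracy_monotone_in_relevance(self):
        """E[accuracy] non-decreasing in example overlap when alpha > 0."""
        gold = make_gold([f"t{i}" for i in range(8)], ["O"] * 8)
        space = label_space_for(["X"])
        accs = []
        for n_shared in (0, 4, 8):
            example = [f"t{i}" for i in range(n_shared)] + [
                f"z{i}" for i in range(8 - n_shared)
            ]
            correct = 0
            for seed in range(500):
                cfg = MockOracleConfig(base_accuracy=0.3, relevance_gain=0.6, seed=seed)
                items = mock_annotate([example], gold, cfg, space)
                labels = decode(items, gold.tokens).labels
                correct += sum(a == b for a, b in zip(labels, gold.labels))
            accs.append(correct)
        assert accs[0] <= accs[1] <= accs[2]

    def test_format_noise_exercises_repair(self):
        cfg = MockOracleConfig(base_accuracy=1.0, format_noise=0.5, seed=3)
        n_repaired = 0
        for seed in range(50):
            items = mock_annotate([], self.GOLD, replace(cfg, seed=seed), self.SPACE)
            if decode(items, self.GOLD.tokens).n_repairs > 0:
                n_repaired += 1
        assert n_repaired > 25  # format noise at 0.5 mangles most outputs

    def test_max_jaccard_relevance(self):
        sets = [frozenset({"a", "b"}), frozenset({"a", "b", "c", "d"})]
        assert max_jaccard_relevance(sets, ["A", "b"]) == 1.0
        assert max_jaccard_relevance([], ["a"]) == 0.0

    def test_invalid_oracle_config_rejected(self):
        with pytest.raises(ValueError):
            MockOracleConfig(base_accuracy=1.5)
        with pytest.raises(ValueError):
            MockOracleConfig(relevance_gain=-0.1)


class TestMockBackend:
    def test_parses_structured_prompt_and_answers_json(self, synthetic_corpus):
        from nerprompt import baseline_components, build_prompt, select_static_examples

        backend = MockBackend(MockOracleConfig(base_accuracy=1.0, seed=0))
        backend.register(synthetic_corpus)
        comps = baseline_components(sorted(synthetic_corpus.entity_types))
        comps = comps.with_examples(select_static_examples(synthetic_corpus, 2, 0))
        target = synthetic_corpus[10]
        response = backend.complete(build_prompt(comps, target), LLMConfig())
        items = json.loads(response)
        assert decode(items, target.tokens).labels == target.labels

    def test_unknown_input_rejected(self):
        backend = MockBackend(MockOracleConfig())
        with pytest.raises(ValueError, match="no gold"):
            backend.complete('## Input\nInput: ["zz"]\nOutput:', LLMConfig())

    def test_fixed_seed_byte_identical_responses(self, synthetic_corpus):
        from nerprompt import baseline_components, build_prompt

        comps = baseline_components(sorted(synthetic_corpus.entity_types))
        prompt = build_prompt(comps, synthetic_corpus[0])
        responses = set()
        for _ in range(3):
            backend = MockBackend(MockOracleConfig(base_accuracy=0.5, seed=9))
            backend.register(synthetic_corpus)
            responses.add(backend.complete(prompt, LLMConfig()))
        assert len(responses) == 1
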