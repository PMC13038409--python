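"""Experiment orchestration: static ablation, dynamic shots, pool size.

Three designs are provided, mirroring the standard evaluation protocol
for few-shot prompting studies:

* **Static component ablation** — the baseline prompt (BP) against
  BP + one optional component at a time and BP + all components, with
  in-context examples redrawn randomly per run and results averaged over
  the runs (default 4).
* **Dynamic shot comparison** — per retrieval engine and shot count, the
  example slot is filled by top-n retrieval; a random-example arm is the
  static comparator, redrawn per run.
* **Retrieval pool-size ablation** — dynamic prompting with the index
  restricted to seeded subsamples of the training set (50/100/200/ALL),
  averaged over independent subsampling runs (default 2).

Every run is reduced to a tidy long-format table (condition, run,
metric, value) plus a :class:`RunLedger` holding the full config
snapshot, per-run reports and request hashes, so any table regenerates
bit-identically from its ledger with the mock backend (or a recorded
response cache) and the same seeds.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .codec import decode, extract_output_items
from .corpus_io import Corpus, Sentence, high_frequency_instances
from .evaluation import (
    EvalReport,
    PredictionRecord,
    aggregate_runs,
    record_from_labels,
    score_strict,
)
from .llm_interface import (
    Backend,
    CachingClient,
    LLMConfig,
    MockBackend,
    MockOracleConfig,
    ResponseCache,
    request_key,
)
from .prompt_builder import (
    PromptComponents,
    build_dynamic_prompt,
    build_prompt,
    select_static_examples,
)
from .retrieval import EncoderContract, build_index, subsample_pool

#: optional components toggled by each ablation condition
CONDITIONS: dict[str, tuple[str, ...]] = {
    "BP": (),
    "BP+dataset_desc": ("dataset_description",),
    "BP+high_freq": ("high_freq_lexicon",),
    "BP+background": ("background_knowledge",),
    "BP+feedback": ("error_feedback",),
    "BP+All": (
        "dataset_description",
        "high_freq_lexicon",
        "background_knowledge",
        "error_feedback",
    ),
}

#: a client factory maps a run seed to a (client, sampling config) pair
ClientFactory = Callable[[int], tuple[Backend, LLMConfig]]


def mock_client_factory(
    oracle: MockOracleConfig,
    corpora: Sequence[Corpus],
    cache: ResponseCache | None = None,
    mode: str = "record",
) -> ClientFactory:
    """Per-seed mock clients sharing one response cache.

    The run seed becomes the oracle seed and is folded into the model
    name, so cached responses from different runs never collide.
    """

    def factory(seed: int) -> tuple[Backend, LLMConfig]:
        backend = MockBackend(replace(oracle, seed=seed))
        for corpus in corpora:
            backend.register(corpus)
        client = CachingClient(backend, cache=cache, mode=mode)
        config = LLMConfig(model_name=f"mock-s{seed}")
        return client, config

    return factory


@dataclass
class RunLedger:
    """Everything needed to audit and regenerate one experiment table."""

    kind: str
    config: dict
    table: list[dict] = field(default_factory=list)
    request_hashes: list[str] = field(default_factory=list)
    started_at: float = field(default_factory=time.time)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "kind": self.kind,
                    "config": self.config,
                    "table": self.table,
                    "request_hashes": self.request_hashes,
                    "started_at": self.started_at,
                },
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunLedger":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(d["kind"], d["config"], d["table"], d["request_hashes"], d["started_at"])


# ---------------------------------------------------------------------------
# Core annotation loop
# ---------------------------------------------------------------------------

def annotate_sentences(
    sentences: Sequence[Sentence],
    prompt_for: Callable[[Sentence], str],
    client: Backend,
    config: LLMConfig,
    hashes: list[str] | None = None,
) -> list[PredictionRecord]:
    """Prompt → complete → extract → decode → record, per sentence."""
    records = []
    for s in sentences:
        prompt = prompt_for(s)
        if hashes is not None:
            hashes.append(request_key(prompt, config))
        response = client.complete(prompt, config)
        items = extract_output_items(response)
        result = decode(items, s.tokens)
        records.append(record_from_labels(s, result.labels, result.n_repairs))
    return records


def _condition_components(
    full: PromptComponents, condition: str, train: Corpus
) -> PromptComponents:
    """Mask the optional blocks of ``full`` down to one ablation condition."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    keep = CONDITIONS[condition]
    fields = {
        "dataset_description": None,
        "high_freq_lexicon": None,
        "background_knowledge": None,
        "error_feedback": None,
    }
    for name in keep:
        value = getattr(full, name)
        if value is None and name == "high_freq_lexicon":
            value = high_frequency_instances(train)
        if value is None:
            raise ValueError(
                f"condition {condition!r} needs component {name!r}, which is unset"
            )
        fields[name] = value
    return replace(full, **fields)


def _tidy(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["condition", "run", "metric", "value"])


def _append_report(rows: list[dict], condition: str, run, report: EvalReport) -> None:
    for metric in ("precision", "recall", "f1"):
        rows.append(
            {
                "condition": condition,
                "run": run,
                "metric": metric,
                "value": getattr(report, metric),
            }
        )


def _check_self_consistency(rows: list[dict]) -> None:
    # every "mean" cell must equal the mean of its stored per-run values
    df = _tidy(rows)
    per_run = df[df["run"] != "mean"]
    means = df[df["run"] == "mean"]
    for _, row in means.iterrows():
        vals = per_run[
            (per_run["condition"] == row["condition"])
            & (per_run["metric"] == row["metric"])
        ]["value"]
        if abs(vals.mean() - row["value"]) > 1e-12:
            raise AssertionError(
                f"ledger self-consistency violated for {row['condition']}"
            )


# ---------------------------------------------------------------------------
# Experiment designs
# ---------------------------------------------------------------------------

def run_static_ablation(
    train: Corpus,
    test: Corpus,
    components: PromptComponents,
    clients: ClientFactory,
    conditions: Sequence[str] = tuple(CONDITIONS),
    runs: int = 4,
    seeds: Sequence[int] | None = None,
    k: int = 5,
    strategy: str = "per_label",
) -> tuple[pd.DataFrame, RunLedger]:
    """Static prompt component ablation, averaged over random example draws.

    ``components`` carries the full set of optional block texts; each
    condition masks it down (``high_freq_lexicon`` is computed from the
    training set when unset).  In-context examples are redrawn per run
    with that run's seed and results are the arithmetic mean over runs.
    """
    seeds = list(seeds) if seeds is not None else list(range(runs))
    if len(seeds) != runs:
        raise ValueError("need one seed per run")
    ledger = RunLedger(
        kind="static_ablation",
        config={
            "conditions": list(conditions),
            "runs": runs,
            "seeds": seeds,
            "k": k,
            "strategy": strategy,
        },
    )
    rows: list[dict] = []
    for condition in conditions:
        cond_components = _condition_components(components, condition, train)
        reports = []
        for run_i, seed in enumerate(seeds):
            client, config = clients(seed)
            examples = select_static_examples(train, k, seed, strategy, components.mode)
            cc = cond_components.with_examples(examples)
            records = annotate_sentences(
                test,
                lambda s: build_prompt(cc, s),
                client,
                config,
                ledger.request_hashes,
            )
            report = score_strict(records)
            reports.append(report)
            _append_report(rows, condition, run_i, report)
        _append_report(rows, condition, "mean", aggregate_runs(reports))
    _check_self_consistency(rows)
    df = _tidy(rows)
    ledger.table = df.to_dict("records")
    return df, ledger


def run_dynamic(
    train: Corpus,
    test: Corpus,
    components: PromptComponents,
    clients: ClientFactory,
    engines: Sequence[str] = ("tfidf",),
    shots: Sequence[int] = (5, 10, 20),
    runs: int = 4,
    seeds: Sequence[int] | None = None,
    encoder: EncoderContract | None = None,
    include_random_arm: bool = True,
    pool: Corpus | None = None,
) -> tuple[pd.DataFrame, RunLedger]:
    """Dynamic prompting per engine × shot count, with a random-example arm.

    Engine arms fill the example slot by top-n retrieval from the (full
    or subsampled) training pool; the ``random`` arm is the static
    comparator whose examples are redrawn uniformly per run.  Shot count
    is the total number of in-context examples.
    """
    seeds = list(seeds) if seeds is not None else list(range(runs))
    if len(seeds) != runs:
        raise ValueError("need one seed per run")
    pool = pool if pool is not None else train
    ledger = RunLedger(
        kind="dynamic",
        config={
            "engines": list(engines),
            "shots": list(shots),
            "runs": runs,
            "seeds": seeds,
            "pool_size": len(pool),
            "random_arm": include_random_arm,
        },
    )
    indices = {engine: build_index(pool, engine, encoder) for engine in engines}
    arms = list(engines) + (["random"] if include_random_arm else [])
    rows: list[dict] = []
    for shot in shots:
        for arm in arms:
            reports = []
            for run_i, seed in enumerate(seeds):
                client, config = clients(seed)
                if arm == "random":
                    examples = select_static_examples(
                        pool, min(shot, len(pool)), seed, "uniform", components.mode
                    )
                    cc = components.with_examples(examples)
                    prompt_for = lambda s, cc=cc: build_prompt(cc, s)
                else:
                    index = indices[arm]
                    prompt_for = lambda s, idx=index, n=shot: build_dynamic_prompt(
                        components, idx, s, n
                    )
                records = annotate_sentences(
                    test, prompt_for, client, config, ledger.request_hashes
                )
                report = score_strict(records)
                reports.append(report)
                _append_report(rows, f"{arm}@{shot}", run_i, report)
            _append_report(rows, f"{arm}@{shot}", "mean", aggregate_runs(reports))
    _check_self_consistency(rows)
    df = _tidy(rows)
    ledger.table = df.to_dict("records")
    return df, ledger


def run_pool_ablation(
    train: Corpus,
    test: Corpus,
    components: PromptComponents,
    clients: ClientFactory,
    pool_sizes: Sequence[int | None] = (50, 100, 200, None),
    subsample_runs: int = 2,
    shots: Sequence[int] = (5, 10),
    engines: Sequence[str] = ("tfidf", "dual_encoder"),
    runs: int = 4,
    seeds: Sequence[int] | None = None,
    encoder: EncoderContract | None = None,
    subsample_seed_base: int = 1000,
) -> tuple[pd.DataFrame, RunLedger]:
    """Dynamic prompting with the retrieval pool restricted in size.

    For each pool size, ``subsample_runs`` independent seeded subsamples
    of the training set are indexed and the dynamic design is run on
    each; reported cells are the mean over subsample runs.  ``None``
    means ALL (the full training set), which reduces exactly to
    :func:`run_dynamic` on the full pool under the same seeds.
    """
    seeds = list(seeds) if seeds is not None else list(range(runs))
    ledger = RunLedger(
        kind="pool_ablation",
        config={
            "pool_sizes": ["ALL" if s is None else s for s in pool_sizes],
            "subsample_runs": subsample_runs,
            "shots": list(shots),
            "engines": list(engines),
            "runs": runs,
            "seeds": seeds,
            "subsample_seed_base": subsample_seed_base,
        },
    )
    rows: list[dict] = []
    for size in pool_sizes:
        size_name = "ALL" if size is None else str(size)
        sub_tables = []
        for sub_i in range(subsample_runs):
            pool = subsample_pool(train, size, subsample_seed_base + sub_i)
            df_sub, led_sub = run_dynamic(
                train,
                test,
                components,
                clients,
                engines=engines,
                shots=shots,
                runs=runs,
                seeds=seeds,
                encoder=encoder,
                include_random_arm=False,
                pool=pool,
            )
            ledger.request_hashes.extend(led_sub.request_hashes)
            sub = df_sub[df_sub["run"] == "mean"].copy()
            sub["subsample"] = sub_i
            sub_tables.append(sub)
            for _, row in sub.iterrows():
                rows.append(
                    {
                        "condition": f"pool{size_name}/{row['condition']}",
                        "run": f"sub{sub_i}",
                        "metric": row["metric"],
                        "value": row["value"],
                    }
                )
        merged = pd.concat(sub_tables)
        means = merged.groupby(["condition", "metric"], sort=False)["value"].mean()
        for (cond, metric), value in means.items():
            rows.append(
                {
                    "condition": f"pool{size_name}/{cond}",
                    "run": "mean",
                    "metric": metric,
                    "value": value,
                }
            )
    df = _tidy(rows)
    ledger.table = df.to_dict("records")
    return df, ledger


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------

def rerun_from_ledger(
    ledger: RunLedger,
    train: Corpus,
    test: Corpus,
    components: PromptComponents,
    clients: ClientFactory,
    encoder: EncoderContract | None = None,
) -> pd.DataFrame:
    """Regenerate an experiment table from its ledger's config snapshot.

    With the mock backend (or a recorded cache in replay mode) and the
    seeds stored in the ledger, the regenerated table is bit-identical
    to the original.
    """
    cfg = ledger.config
    if ledger.kind == "static_ablation":
        df, _ = run_static_ablation(
            train,
            test,
            components,
            clients,
            conditions=cfg["conditions"],
            runs=cfg["runs"],
            seeds=cfg["seeds"],
            k=cfg["k"],
            strategy=cfg["strategy"],
        )
    elif ledger.kind == "dynamic":
        df, _ = run_dynamic(
            train,
            test,
            components,
            clients,
            engines=cfg["engines"],
            shots=cfg["shots"],
            runs=cfg["runs"],
            seeds=cfg["seeds"],
            encoder=encoder,
            include_random_arm=cfg["random_arm"],
        )
    elif ledger.kind == "pool_ablation":
        df, _ = run_pool_ablation(
            train,
            test,
            components,
            clients,
            pool_sizes=[None if s == "ALL" else int(s) for s in cfg["pool_sizes"]],
            subsample_runs=cfg["subsample_runs"],
            shots=cfg["shots"],
            engines=cfg["engines"],
            runs=cfg["runs"],
            seeds=cfg["seeds"],
            encoder=encoder,
            subsample_seed_base=cfg["subsample_seed_base"],
        )
    else:
        raise ValueError(f"unknown ledger kind {ledger.kind!r}")
    return df
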