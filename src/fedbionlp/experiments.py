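"""The three experimental designs, composed from the library modules.

* ``comparison`` — centralized vs FedAvg vs single-client learning on an IID
  k-fold split of one synthetic source, scored on a global test set under
  both matching schemes.
* ``scale`` — FedAvg on the *same* training set re-partitioned into k = 2..10
  clients (total data volume fixed), tracking F1 as the federation grows.
* ``heterogeneity`` — two low-overlap synthetic sources as non-IID clients;
  FedAvg against FedProx across a mu sweep, plus an IID control split of the
  pooled data.

Every design repeats with seeds ``base, base+1, ...`` and reports the mean
and sample standard deviation per cell.  A re-run from the same config and
base seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .corpus_io import Corpus, dedup_split
from .evaluation import evaluate_ner, format_mean_sd, summarize_repeats
from .federation import (
    ClientState,
    FedConfig,
    run_centralized,
    run_federated,
    run_single_client,
)
from .models import LinearTagger, TaggerModel, build_vocab
from .partitioning import scale_series, split_by_source, split_iid
from .synthetic import GenConfig, generate_ner, make_sources

__all__ = [
    "ExperimentConfig",
    "load_config",
    "config_hash",
    "run_comparison",
    "run_scale",
    "run_heterogeneity",
    "run_experiment",
    "bio_tag_list",
]

SCHEMES = ("lenient", "strict")


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale defaults for the synthetic study conditions."""

    design: str = "comparison"
    # generator
    n_sentences: int = 1250  # single-source designs, before dedup/split
    n_per_source: int = 700  # heterogeneity design, per source
    tag_noise_rate: float = 0.05
    overlap: float = 0.2  # cross-source vocabulary overlap (non-IID)
    # model
    model_family: str = "linear"  # "linear" | "rnn_crf"
    emb_dim: int = 16
    hidden: int = 16
    # design specifics
    k: int = 10
    k_values: tuple[int, ...] = (2, 4, 6, 8, 10)
    mu_values: tuple[float, ...] = (1.0, 0.5, 0.1, 0.01, 0.001)
    repeats: int = 3
    fed: FedConfig = field(
        default_factory=lambda: FedConfig(
            rounds=15, local_epochs=1, batch_size=32, learning_rate=0.05,
            optimizer="adam", scheduler="linear_warmup",
        )
    )

    def __post_init__(self) -> None:
        if self.design not in ("comparison", "scale", "heterogeneity"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.design == "scale" and not self.k_values:
            raise ValueError("scale design requires k_values")
        if self.design == "heterogeneity" and not self.mu_values:
            raise ValueError("heterogeneity design requires mu_values")
        if self.model_family not in ("linear", "rnn_crf"):
            raise ValueError(f"unknown model_family {self.model_family!r}")


_FED_FIELDS = {f.name for f in dataclasses.fields(FedConfig)}
_EXP_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)} - {"fed"}


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a flat YAML mapping; keys route to FedConfig or ExperimentConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must hold a flat mapping")
    fed_kw, exp_kw = {}, {}
    for key, value in raw.items():
        if key in _FED_FIELDS:
            fed_kw[key] = value
        elif key in _EXP_FIELDS:
            if key in ("k_values",):
                value = tuple(int(v) for v in value)
            elif key in ("mu_values",):
                value = tuple(float(v) for v in value)
            exp_kw[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return ExperimentConfig(fed=FedConfig(**fed_kw), **exp_kw)


def config_hash(cfg: ExperimentConfig) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def bio_tag_list(entity_types: Sequence[str]) -> list[str]:
    """Deterministic tag inventory: O first, then B-/I- per sorted type."""
    tags = ["O"]
    for etype in sorted(entity_types):
        tags += [f"B-{etype}", f"I-{etype}"]
    return tags


def _tagger_factory(cfg: ExperimentConfig, vocab: dict[str, int], tags: list[str]):
    if cfg.model_family == "linear":
        return lambda seed: LinearTagger(vocab, tags, seed=seed)
    return lambda seed: TaggerModel(
        vocab, tags, emb_dim=cfg.emb_dim, hidden=cfg.hidden, seed=seed
    )


def _gen_split(cfg: ExperimentConfig, seed: int, overlap: float = 1.0):
    """One synthetic source, generated and preprocessed like a real corpus."""
    source = make_sources(1, overlap, seed)[0]
    corpus = generate_ner(
        source,
        GenConfig(
            n_sentences=cfg.n_sentences, tag_noise_rate=cfg.tag_noise_rate, seed=seed
        ),
    )
    return dedup_split(corpus, seed=seed)


def _scores(model, test: Corpus) -> dict[str, float]:
    return {s: evaluate_ner(model, test, scheme=s).macro_f1 for s in SCHEMES}


def _summarize(rows: list[dict], keys: list[str]) -> pd.DataFrame:
    """Collapse per-repeat rows into mean ± sd cells per (keys, scheme)."""
    df = pd.DataFrame(rows)
    out = []
    for group, grp in df.groupby(keys, sort=False, dropna=False):
        rec = dict(zip(keys, group if isinstance(group, tuple) else (group,)))
        for s in SCHEMES:
            mean, sd = summarize_repeats(list(grp[s]))
            rec[f"{s}_mean"] = mean
            rec[f"{s}_sd"] = sd
            rec[f"{s}"] = format_mean_sd(mean, sd)
        rec["n_repeats"] = len(grp)
        out.append(rec)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Designs


def run_comparison(cfg: ExperimentConfig, base_seed: int = 0) -> pd.DataFrame:
    """Centralized vs FedAvg vs single-client on an IID k-fold split."""
    rows = []
    for rep in range(cfg.repeats):
        seed = base_seed + rep
        train, dev, test = _gen_split(cfg, seed)
        tags = bio_tag_list(train.type_inventory)
        vocab = build_vocab([train])
        factory = _tagger_factory(cfg, vocab, tags)
        fed = replace(cfg.fed, seed=seed)
        clients = split_iid(train, cfg.k, seed)

        model = factory(seed)
        w, _ = run_centralized(train, factory, fed)
        model.set_params(w)
        rows.append({"method": "centralized", "seed": seed, **_scores(model, test)})

        w, _ = run_federated(clients, factory, fed)
        model.set_params(w)
        rows.append({"method": "fedavg", "seed": seed, **_scores(model, test)})

        # Single-client learning: client-local vocabulary, scores averaged
        # unweighted across clients ("Single (avg)").
        per_client = {s: [] for s in SCHEMES}
        for client in clients:
            local_vocab = build_vocab([client.train])
            local_factory = _tagger_factory(cfg, local_vocab, tags)
            w_c, _ = run_centralized(client.train, local_factory, fed)
            local_model = local_factory(seed)
            local_model.set_params(w_c)
            for s, v in _scores(local_model, test).items():
                per_client[s].append(v)
        rows.append(
            {
                "method": "single",
                "seed": seed,
                **{s: float(pd.Series(v).mean()) for s, v in per_client.items()},
            }
        )
    table = _summarize(rows, ["method"])
    table.attrs["config_hash"] = config_hash(cfg)
    table.attrs["seeds"] = list(range(base_seed, base_seed + cfg.repeats))
    return table


def run_scale(cfg: ExperimentConfig, base_seed: int = 0) -> pd.DataFrame:
    """FedAvg F1 as the same data volume is spread over more clients."""
    rows = []
    volumes = set()
    for rep in range(cfg.repeats):
        seed = base_seed + rep
        train, dev, test = _gen_split(cfg, seed)
        tags = bio_tag_list(train.type_inventory)
        vocab = build_vocab([train])
        factory = _tagger_factory(cfg, vocab, tags)
        fed = replace(cfg.fed, seed=seed)
        series = scale_series(train, cfg.k_values, seed)
        for k, clients in series.items():
            volumes.add(sum(c.n_k for c in clients))
            w, _ = run_federated(clients, factory, fed)
            model = factory(seed)
            model.set_params(w)
            rows.append({"k": k, "seed": seed, **_scores(model, test)})
    if len(volumes) != 1:
        raise AssertionError(f"total training volume varied across k: {volumes}")
    table = _summarize(rows, ["k"])
    table.attrs["config_hash"] = config_hash(cfg)
    table.attrs["seeds"] = list(range(base_seed, base_seed + cfg.repeats))
    table.attrs["total_volume"] = volumes.pop()
    return table


def run_heterogeneity(cfg: ExperimentConfig, base_seed: int = 0) -> pd.DataFrame:
    """FedAvg vs the FedProx mu sweep on two low-overlap sources + IID control."""
    rows = []
    for rep in range(cfg.repeats):
        seed = base_seed + rep
        sources = make_sources(2, cfg.overlap, seed)
        trains, tests = [], []
        for i, source in enumerate(sources):
            corpus = generate_ner(
                source,
                GenConfig(
                    n_sentences=cfg.n_per_source,
                    tag_noise_rate=cfg.tag_noise_rate,
                    seed=seed + 7919 * i,
                ),
            )
            tr, _, te = dedup_split(corpus, seed=seed)
            trains.append(tr)
            tests.append(te)
        global_test = trains[0].with_records(
            tests[0].records + tests[1].records, "test"
        )
        pooled = trains[0].with_records(trains[0].records + trains[1].records, "train")
        tags = bio_tag_list(pooled.type_inventory)
        vocab = build_vocab(trains)
        factory = _tagger_factory(cfg, vocab, tags)
        fed = replace(cfg.fed, seed=seed)
        noniid_clients = split_by_source(trains)
        iid_clients = split_iid(pooled, len(sources), seed)

        def _run(clients, fedcfg, method, mu, setting):
            w, _ = run_federated(clients, factory, fedcfg)
            model = factory(seed)
            model.set_params(w)
            rows.append(
                {
                    "method": method,
                    "mu": mu,
                    "setting": setting,
                    "seed": seed,
                    **_scores(model, global_test),
                }
            )

        for setting, clients in (("noniid", noniid_clients), ("iid", iid_clients)):
            _run(clients, replace(fed, algorithm="fedavg", mu=0.0), "fedavg", None, setting)
            for mu in cfg.mu_values:
                _run(
                    clients,
                    replace(fed, algorithm="fedprox", mu=float(mu)),
                    "fedprox",
                    float(mu),
                    setting,
                )
    table = _summarize(rows, ["setting", "method", "mu"])
    table.attrs["config_hash"] = config_hash(cfg)
    table.attrs["seeds"] = list(range(base_seed, base_seed + cfg.repeats))
    return table


_DESIGNS = {
    "comparison": run_comparison,
    "scale": run_scale,
    "heterogeneity": run_heterogeneity,
}


def run_experiment(cfg: ExperimentConfig, base_seed: int = 0) -> pd.DataFrame:
    return _DESIGNS[cfg.design](cfg, base_seed)


def write_results(table: pd.DataFrame, out_dir: str | Path, name: str) -> None:
    """CSV table plus JSON metadata (config hash, seeds, extras)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(out_dir / f"{name}.csv", index=False)
    meta = {k: v for k, v in table.attrs.items()}
    with open(out_dir / f"{name}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, default=str)
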