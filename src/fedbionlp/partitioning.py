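"""Client dataset construction: IID k-fold splits, source-based non-IID
splits, and the fixed-total-volume scale series.

Partitioning always operates on sentences / instances, never documents, and
only ever on training data — dev and test sets stay global so every training
regime is scored on the same held-out material.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Corpus, CorpusError
from .federation import ClientState

__all__ = [
    "split_iid",
    "split_by_source",
    "scale_series",
    "write_manifest",
    "read_manifest",
]


def split_iid(corpus: Corpus, k: int, seed: int) -> list[ClientState]:
    """Shuffle with ``seed`` and deal records round-robin to ``k`` clients.

    Client sizes differ by at most one; clients are disjoint and their union
    is the input corpus.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(corpus):
        raise ValueError(f"k={k} exceeds corpus size {len(corpus)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    clients = []
    for i in range(k):
        idx = tuple(int(j) for j in order[i::k])
        clients.append(
            ClientState(
                client_id=f"client_{i}",
                train=corpus.with_records([corpus.records[j] for j in idx]),
                record_indices=idx,
            )
        )
    return clients


def split_by_source(corpora: Sequence[Corpus]) -> list[ClientState]:
    """One client per source corpus; the federation's label inventory is the union."""
    if len(corpora) < 2:
        raise ValueError("split_by_source requires >= 2 source corpora")
    tasks = {c.task for c in corpora}
    if len(tasks) != 1:
        raise CorpusError(f"mixed tasks {tasks}")
    source_ids = [_single_source(c) for c in corpora]
    if len(set(source_ids)) != len(source_ids):
        raise ValueError(f"duplicate source_id among {source_ids}")
    union = frozenset().union(*(c.type_inventory for c in corpora))
    clients = []
    for sid, corpus in zip(source_ids, corpora):
        clients.append(
            ClientState(
                client_id=sid,
                train=Corpus(
                    task=corpus.task,
                    records=corpus.records,
                    type_inventory=union,
                    split_name=corpus.split_name,
                ),
            )
        )
    return clients


def _single_source(corpus: Corpus) -> str:
    sources = {rec.source_id for rec in corpus}
    if len(sources) != 1:
        raise CorpusError(f"corpus mixes sources {sorted(sources)}")
    return next(iter(sources))


def scale_series(
    corpus: Corpus, k_values: Sequence[int], seed: int
) -> dict[int, list[ClientState]]:
    """Re-partition the *same* record set for each k (total volume constant)."""
    return {k: split_iid(corpus, k, seed) for k in k_values}


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(clients: Sequence[ClientState], path: str | Path) -> None:
    """CSV mapping each record's position in the parent corpus to its client."""
    rows = []
    for client in clients:
        if client.record_indices is None:
            raise ValueError(
                f"client {client.client_id!r} carries no record indices"
            )
        rows.extend(
            {"record_index": i, "client_id": client.client_id}
            for i in client.record_indices
        )
    pd.DataFrame(rows).sort_values("record_index").to_csv(path, index=False)


def read_manifest(corpus: Corpus, path: str | Path) -> list[ClientState]:
    """Rebuild a partition from a manifest produced by :func:`write_manifest`."""
    df = pd.read_csv(path)
    clients = []
    for cid, grp in df.groupby("client_id", sort=True):
        idx = tuple(int(i) for i in grp["record_index"])
        clients.append(
            ClientState(
                client_id=str(cid),
                train=corpus.with_records([corpus.records[i] for i in idx]),
                record_indices=idx,
            )
        )
    return clients
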