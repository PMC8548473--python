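"""Per-session bipartite networks of roots and inflected patterns.

Every recording session yields two networks per dyad, one per speaker
stratum (CS and CDS).  Nodes are the roots and inflected patterns that
carry at least one token in that session; edges are the attested
wordforms (root x inflected-pattern combinations).  A dyad recorded in
47 sessions therefore yields 94 networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np
import pandas as pd

from . import inventory as inv
from .corpus import SPEAKERS, CorpusTable


class EmptyStratumError(ValueError):
    """Raised when an operation requires a non-empty participant stratum."""


def _pattern_labels(df: pd.DataFrame) -> pd.Series:
    """Vectorized inflected-pattern node labels from the coded columns."""
    parts = df["binyan"].str.cat(df["temporal"], sep=".")
    for col in ("person", "gender", "number"):  # label order: person, gender, number
        extra = df[col].astype(str)
        parts = parts.str.cat(extra.where(extra == "", "." + extra), na_rep="")
    return parts


@dataclass(frozen=True)
class NodeRegistry:
    """All roots / patterns a participant ever used, in stable sorted order."""

    dyad_id: str
    speaker: str
    roots: tuple[str, ...]
    patterns: tuple[str, ...]


@dataclass
class BipartiteNetwork:
    """One participant's root x pattern network at one recording.

    ``edges`` maps (root, pattern) to a token count; in binary mode the
    adjacency is 0/1 and ``m`` is the number of distinct wordform links.
    An empty stratum produces an explicitly empty network (``n == 0``),
    flagged via :attr:`is_empty`, never silently skipped.
    """

    dyad_id: str
    speaker: str
    session_index: int
    age_days: int
    root_nodes: tuple[str, ...]
    pattern_nodes: tuple[str, ...]
    edges: dict[tuple[str, str], int]
    mode: str = "binary"

    @property
    def n(self) -> int:
        return len(self.root_nodes) + len(self.pattern_nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def is_empty(self) -> bool:
        return self.n == 0

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.root_nodes + self.pattern_nodes

    def adjacency(self) -> tuple[np.ndarray, tuple[str, ...], tuple[str, ...]]:
        """Root x pattern block adjacency (binary or token-weighted)."""
        ri = {r: i for i, r in enumerate(self.root_nodes)}
        pi = {p: i for i, p in enumerate(self.pattern_nodes)}
        A = np.zeros((len(ri), len(pi)))
        for (r, p), w in self.edges.items():
            A[ri[r], pi[p]] = w if self.mode == "weighted" else 1.0
        return A, self.root_nodes, self.pattern_nodes

    def full_adjacency(self) -> tuple[np.ndarray, tuple[str, ...]]:
        """Symmetric (n x n) adjacency over roots followed by patterns."""
        B, roots, patterns = self.adjacency()
        nr, npat = B.shape
        A = np.zeros((nr + npat, nr + npat))
        A[:nr, nr:] = B
        A[nr:, :nr] = B.T
        return A, roots + patterns

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(self.root_nodes, bipartite="root")
        G.add_nodes_from(self.pattern_nodes, bipartite="pattern")
        for (r, p), w in self.edges.items():
            G.add_edge(r, p, weight=w if self.mode == "weighted" else 1)
        return G

    def adjacency_json(self) -> str:
        """JSON dump of the block adjacency for cross-language checks."""
        import json

        A, roots, patterns = self.adjacency()
        return json.dumps(
            {
                "dyad_id": self.dyad_id,
                "speaker": self.speaker,
                "session_index": self.session_index,
                "mode": self.mode,
                "roots": list(roots),
                "patterns": list(patterns),
                "adjacency": A.tolist(),
            }
        )

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {
                "dyad_id": self.dyad_id,
                "session_index": self.session_index,
                "speaker": self.speaker,
                "root": r,
                "pattern": p,
                "weight": w if self.mode == "weighted" else 1,
            }
            for (r, p), w in sorted(self.edges.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["dyad_id", "session_index", "speaker", "root", "pattern", "weight"],
        )


@dataclass
class NetworkSeries:
    """Ordered per-(session, speaker) networks for one dyad."""

    dyad_id: str
    networks: dict[tuple[int, str], BipartiteNetwork]
    ages: dict[int, int]

    @property
    def sessions(self) -> list[int]:
        return sorted(self.ages)

    @property
    def speakers(self) -> list[str]:
        return sorted({spk for _, spk in self.networks}, reverse=True)  # CS, CDS

    def __len__(self) -> int:
        return len(self.networks)

    def get(self, session_index: int, speaker: str) -> BipartiteNetwork:
        return self.networks[(session_index, speaker)]


def _stratum(table: CorpusTable, dyad_id: str, speaker: str) -> pd.DataFrame:
    df = table.df
    return df[(df["dyad_id"] == dyad_id) & (df["speaker"] == speaker)]


def build_registry(table: CorpusTable, dyad_id: str, speaker: str) -> NodeRegistry:
    """Union of all roots / inflected patterns a participant ever used."""
    df = _stratum(table, dyad_id, speaker)
    if df.empty:
        raise EmptyStratumError(f"no tokens for ({dyad_id!r}, {speaker!r})")
    return NodeRegistry(
        dyad_id=dyad_id,
        speaker=speaker,
        roots=tuple(sorted(df["root"].unique())),
        patterns=tuple(sorted(_pattern_labels(df).unique())),
    )


def build_session_network(
    table: CorpusTable,
    dyad_id: str,
    speaker: str,
    session_index: int,
    mode: str = "binary",
    age_days: Optional[int] = None,
) -> BipartiteNetwork:
    """Bipartite network of one (participant, session) stratum.

    Nodes are constructs with at least one token in the session; an empty
    stratum yields an explicitly empty, flagged network.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    df = _stratum(table, dyad_id, speaker)
    df = df[df["session_index"] == session_index]
    if df.empty:
        return BipartiteNetwork(
            dyad_id, speaker, session_index, int(age_days or 0), (), (), {}, mode
        )
    pats = _pattern_labels(df)
    counts = (
        pd.DataFrame({"root": df["root"], "pattern": pats, "count": df["count"]})
        .groupby(["root", "pattern"], sort=True)["count"]
        .sum()
    )
    edges = {(r, p): int(c) for (r, p), c in counts.items()}
    return BipartiteNetwork(
        dyad_id=dyad_id,
        speaker=speaker,
        session_index=session_index,
        age_days=int(df["age_days"].iloc[0]),
        root_nodes=tuple(sorted({r for r, _ in edges})),
        pattern_nodes=tuple(sorted({p for _, p in edges})),
        edges=edges,
        mode=mode,
    )


def build_network_series(
    table: CorpusTable, dyad_id: str, mode: str = "binary"
) -> NetworkSeries:
    """One network per (session, speaker) stratum of a dyad.

    Sessions where one speaker is silent still get an (empty, flagged)
    network so the time series keeps its index.
    """
    df = table.df[table.df["dyad_id"] == dyad_id]
    if df.empty:
        raise EmptyStratumError(f"dyad {dyad_id!r} not present")
    ages = df.groupby("session_index")["age_days"].first().astype(int).to_dict()
    speakers = [s for s in SPEAKERS if (df["speaker"] == s).any()]
    networks = {}
    for sess in sorted(ages):
        for spk in speakers:
            networks[(sess, spk)] = build_session_network(
                table, dyad_id, spk, sess, mode=mode, age_days=ages[sess]
            )
    return NetworkSeries(dyad_id=dyad_id, networks=networks, ages=ages)
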