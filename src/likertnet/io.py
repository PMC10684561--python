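"""Reading and writing the pipeline's standard artifacts.

Ratings travel as a single CSV with a ``condition`` column, a
``participant_id`` column, and one column per item; networks as
edge-list CSV (each undirected edge once, endpoints in lexicographic
order) or GraphML; partitions and core assignments as two-column CSV.

Participants with any missing item response are excluded at read time
and the exclusion is logged, mirroring the usual complete-case rule for
questionnaire batteries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .community import Partition
from .synthetic import RatingsTable

logger = logging.getLogger(__name__)

__all__ = ["ItemLexicon", "read_ratings", "write_ratings", "write_network",
           "read_network", "write_partition", "read_partition"]

# Short adjective labels for a 75-item aesthetic-emotion battery.  This
# synthetic default lexicon covers the adjectives conventionally used for
# aesthetic-emotion items (being moved, fascination, beauty, negative
# affect, ...) and is meant for demos and generated data, not as a
# reproduction of any published instrument's wording.
DEFAULT_ADJECTIVES = [
    "moved", "deeply_moved", "touched", "sentimental", "longing", "nostalgic",
    "meaning", "awe", "sublime", "wonder", "fascinated", "absorbed", "engaged",
    "gripped", "captivated", "interest", "curious", "intrigued", "surprised",
    "astonished", "impressed", "inspired", "enchanted", "spiritual", "solemn",
    "beauty", "perfection", "liking", "pleasant", "delight", "happy", "joy",
    "cheerful", "amused", "playful", "humor", "content", "relaxed", "calm",
    "serene", "relieved", "hopeful", "grateful", "admiration", "pride",
    "energized", "motivated", "enthusiastic", "thrilled", "exhilarated",
    "invigorated", "vital", "chills", "goosebumps", "excited", "agitated",
    "tense", "anxious", "worried", "scared", "shocked", "unsettled",
    "uncomfortable", "unpleasant", "dislike", "distaste", "repelled",
    "disgusted", "irritated", "angry", "oppressive", "depressed", "sad",
    "melancholic", "bored",
]


@dataclass(frozen=True)
class ItemLexicon:
    """Bijection between long item statements and short adjective labels."""

    long_to_short: dict

    def __post_init__(self):
        shorts = list(self.long_to_short.values())
        if len(set(shorts)) != len(shorts):
            raise ValueError("short labels are not unique")

    @classmethod
    def default(cls) -> "ItemLexicon":
        """A synthetic 75-entry lexicon: 'It filled me with X' -> 'X'."""
        return cls({f"It filled me with {a.replace('_', ' ')}": a for a in DEFAULT_ADJECTIVES})

    @property
    def short_to_long(self) -> dict:
        return {s: l for l, s in self.long_to_short.items()}

    @property
    def short_labels(self) -> list:
        return list(self.long_to_short.values())

    def __len__(self) -> int:
        return len(self.long_to_short)


def read_ratings(path, condition_col: str = "condition",
                 participant_col: str = "participant_id",
                 likert_levels: int = 5, column_map: dict | None = None) -> dict[str, RatingsTable]:
    """Read a ratings CSV into one RatingsTable per condition.

    ``column_map`` optionally renames raw CSV columns to canonical item
    labels.  Rows with any missing item response are dropped (counted in
    the log); out-of-range or non-integer ratings raise with the
    offending row and column named.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns=column_map)
    if condition_col not in raw.columns:
        raise ValueError(f"missing condition column {condition_col!r}")
    if participant_col not in raw.columns:
        raise ValueError(f"missing participant column {participant_col!r}")
    item_cols = [c for c in raw.columns if c not in (condition_col, participant_col)]
    if len(item_cols) < 2:
        raise ValueError("need at least 2 item columns")

    out: dict[str, RatingsTable] = {}
    for cond, grp in raw.groupby(condition_col, sort=False):
        if grp[participant_col].duplicated().any():
            dup = grp.loc[grp[participant_col].duplicated(), participant_col].iloc[0]
            raise ValueError(f"duplicate participant id {dup!r} in condition {cond!r}")
        items = grp[item_cols]
        complete = items.notna().all(axis=1)
        n_excluded = int((~complete).sum())
        if n_excluded:
            logger.info("condition %s: excluded %d participant(s) with missing items",
                        cond, n_excluded)
        kept = grp.loc[complete]
        values = kept[item_cols].to_numpy(dtype=float)
        if not np.array_equal(values, np.round(values)):
            r, c = np.argwhere(values != np.round(values))[0]
            raise ValueError(
                f"non-integer rating at participant {kept[participant_col].iloc[r]!r}, "
                f"item {item_cols[c]!r}")
        bad = (values < 1) | (values > likert_levels)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"rating {values[r, c]:g} outside [1, {likert_levels}] at participant "
                f"{kept[participant_col].iloc[r]!r}, item {item_cols[c]!r}")
        frame = pd.DataFrame(values.astype(int), columns=item_cols,
                             index=kept[participant_col].tolist())
        table = RatingsTable(str(cond), frame, likert_levels)
        out[str(cond)] = table
    return out


def write_ratings(tables: dict[str, RatingsTable], path) -> None:
    """Write per-condition tables back to the single-CSV schema."""
    frames = []
    for cond, t in tables.items():
        f = t.data.copy()
        f.insert(0, "participant_id", t.data.index)
        f.insert(0, "condition", cond)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_network(net: nx.Graph, path, fmt: str | None = None) -> None:
    """Write an undirected network as edge-list CSV or GraphML.

    The format is inferred from the extension unless ``fmt`` is given.
    Edge-list rows are (source_label, target_label, weight) with
    source < target lexicographically and each edge written once.
    """
    if net.number_of_edges() == 0:
        raise ValueError("refusing to write a network with no edges")
    path = str(path)
    if fmt is None:
        fmt = "graphml" if path.endswith(".graphml") else "edgelist" if path.endswith(".csv") else None
    if fmt == "edgelist":
        rows = []
        for u, v, d in net.edges(data=True):
            a, b = sorted((str(u), str(v)))
            rows.append({"source_label": a, "target_label": b,
                         "weight": float(d.get("weight", 1.0))})
        rows.sort(key=lambda r: (r["source_label"], r["target_label"]))
        pd.DataFrame(rows).to_csv(path, index=False)
    elif fmt == "graphml":
        clean = net.copy()
        for key in [k for k, val in clean.graph.items() if val is None]:
            del clean.graph[key]
        nx.write_graphml(clean, path)
    else:
        raise ValueError(f"unknown network format {fmt!r} for {path}")


def read_network(path, fmt: str | None = None) -> nx.Graph:
    path = str(path)
    if fmt is None:
        fmt = "graphml" if path.endswith(".graphml") else "edgelist"
    if fmt == "graphml":
        return nx.read_graphml(path)
    frame = pd.read_csv(path)
    G = nx.Graph()
    for _, row in frame.iterrows():
        G.add_edge(row["source_label"], row["target_label"], weight=float(row["weight"]))
    return G


def write_partition(partition: Partition, path) -> None:
    pd.DataFrame({"item": list(partition.labels),
                  "community_id": list(partition.labels.values())}).to_csv(path, index=False)


def read_partition(path) -> Partition:
    frame = pd.read_csv(path)
    return Partition.from_ids(frame["item"], frame["community_id"], source=str(path))
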