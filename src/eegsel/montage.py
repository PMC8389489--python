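"""Electrode montages: 2-D scalp layouts and their adjacency graphs.

A :class:`Montage` couples projected 2-D electrode positions (standard
10-20/10-10 layout, azimuthal-equidistant projection) with an unweighted
adjacency graph over the channels.  Adjacency is defined by Delaunay
triangulation of the layout, pruned of edges longer than 1.8x the median
Delaunay edge length; this yields a connected, anatomically plausible
neighborhood structure on irregular scalp layouts where simple
nearest-distance thresholds do not.

Two montages ship with the package:

``standard_1020_32``
    The 32 scalp channels of a Biosemi/10-20 EEG cap (DEAP channel set).
``emotiv_epoc_14``
    The 14 channels of the Emotiv EPOC headset (DREAMER channel set).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import Delaunay

__all__ = ["Montage", "load_montage", "BUILTIN_MONTAGES"]

BUILTIN_MONTAGES = ("standard_1020_32", "emotiv_epoc_14")

#: Prune Delaunay edges longer than this multiple of the median edge length.
_PRUNE_FACTOR = 1.8


@dataclass(frozen=True)
class Montage:
    """2-D electrode layout plus unweighted adjacency over scalp channels."""

    names: tuple[str, ...]
    positions: np.ndarray  # (C, 2)
    graph: nx.Graph = field(compare=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValueError(f"duplicate channel names in montage: {dupes}")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def subset(self, names: list[str] | tuple[str, ...]) -> "Montage":
        """Montage restricted to ``names`` (adjacency rebuilt from positions)."""
        for n in names:
            if n not in self.names:
                raise KeyError(f"channel {n!r} not in montage")
        idx = [self.index(n) for n in names]
        return _build(tuple(names), self.positions[idx])

    def distances(self) -> np.ndarray:
        """Euclidean distance matrix between layout positions."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.linalg.norm(d, axis=-1)


def _adjacency(names: tuple[str, ...], xy: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(names)
    n = len(names)
    if n < 3:
        for i, j in itertools.combinations(range(n), 2):
            g.add_edge(names[i], names[j])
        return g
    tri = Delaunay(xy)
    edges = set()
    for simplex in tri.simplices:
        for i, j in itertools.combinations(simplex, 2):
            edges.add((min(i, j), max(i, j)))
    lengths = {e: float(np.linalg.norm(xy[e[0]] - xy[e[1]])) for e in edges}
    cutoff = _PRUNE_FACTOR * float(np.median(list(lengths.values())))
    pruned = nx.Graph()
    pruned.add_nodes_from(names)
    for (i, j), L in lengths.items():
        if L <= cutoff:
            pruned.add_edge(names[i], names[j])
    if nx.is_connected(pruned):
        return pruned
    # pruning disconnected the scalp: fall back to the full triangulation
    for i, j in edges:
        g.add_edge(names[i], names[j])
    return g


def _build(names: tuple[str, ...], xy: np.ndarray) -> Montage:
    return Montage(names=names, positions=np.asarray(xy, dtype=float),
                   graph=_adjacency(names, np.asarray(xy, dtype=float)))


def _read_table(path_or_text) -> tuple[tuple[str, ...], np.ndarray]:
    lines = [ln.strip() for ln in str(path_or_text).splitlines() if ln.strip()]
    if not lines or lines[0].split("\t")[0].lower() != "name":
        raise ValueError("montage table must start with a 'name\\tx\\ty' header")
    names, xs, ys = [], [], []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise ValueError(f"malformed montage row: {ln!r}")
        names.append(parts[0])
        xs.append(float(parts[1]))
        ys.append(float(parts[2]))
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate channel names in montage file: {dupes}")
    return tuple(names), np.column_stack([xs, ys])


def load_montage(name: str) -> Montage:
    """Load a montage by built-in name or ``custom:<path>``.

    Parameters
    ----------
    name
        One of ``standard_1020_32``, ``emotiv_epoc_14``, or ``custom:<path>``
        pointing to a tab-separated ``name  x  y`` table.
    """
    if name in BUILTIN_MONTAGES:
        text = (resources.files("eegsel.data") / f"{name}.tsv").read_text()
    elif name.startswith("custom:"):
        text = Path(name[len("custom:"):]).read_text()
    else:
        raise ValueError(
            f"unknown montage {name!r}; expected one of {BUILTIN_MONTAGES} or 'custom:<path>'"
        )
    names, xy = _read_table(text)
    return _build(names, xy)
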