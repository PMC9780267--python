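"""Molecular networking from MS/MS fragment similarity.

Nodes are spectra; an edge connects two spectra whose fragment patterns are
similar under the modified cosine score; clusters ("regions") are the
connected components of the thresholded graph.  Structurally related
glycosides — which share aglycone product ions and glycosyl-loss ladders —
fall into the same region.

Scores on unit-intensity spectra reduce to n_matched / sqrt(n_a * n_b),
which is how scores on the packaged reference library (no recorded
intensities) should be read.

The modified cosine optionally matches peak pairs offset by the precursor
mass difference.  For pure homologous glycan ladders this *by design* links
analog series across aglycone classes (the ladders align peak-for-peak at
the precursor offset), so class-region extraction defaults to the unshifted
score; pass ``precursor_shift=True`` to ``build_network`` for analog
networking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .spectra import Spectrum

__all__ = [
    "modified_cosine",
    "SimilarityEdge",
    "MolecularNetwork",
    "build_network",
    "export_graphml",
    "read_graphml",
]


def _greedy_score(
    a: Spectrum, b: Spectrum, frag_tol: float, precursor_shift: bool
) -> tuple[float, int]:
    ma, ia = a.mzs, a.intensities
    mb, ib = b.mzs, b.intensities
    delta = b.precursor_mz - a.precursor_mz
    candidates: list[tuple[float, float, int, int]] = []  # (product, |dm|, i, j)
    seen: set[tuple[int, int]] = set()
    for i, mza in enumerate(ma):
        for j, mzb in enumerate(mb):
            dm = mzb - mza
            direct = abs(dm) <= frag_tol
            shifted = precursor_shift and abs(dm - delta) <= frag_tol
            if direct or shifted:
                if (i, j) in seen:
                    continue
                seen.add((i, j))
                err = abs(dm) if direct else abs(dm - delta)
                candidates.append((ia[i] * ib[j], err, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    total = 0.0
    n_matched = 0
    for product, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        total += product
        n_matched += 1
    norm2 = sum(x * x for x in ia) * sum(x * x for x in ib)
    return total / math.sqrt(norm2), n_matched


def modified_cosine(
    a: Spectrum,
    b: Spectrum,
    frag_tol: float = 0.02,
    precursor_shift: bool = True,
) -> tuple[float, int]:
    """Modified cosine similarity between two spectra.

    Peaks are greedily matched one-to-one, highest intensity product first;
    a pair may match directly (|dm| <= frag_tol) or, when
    ``precursor_shift`` is set, at an offset equal to the precursor mass
    difference.  Returns (score in [0, 1], number of matched peak pairs).
    Empty spectra score (0.0, 0).  Exactly symmetric in its arguments.
    """
    if not a.peaks or not b.peaks:
        return 0.0, 0
    # canonical argument order guarantees bit-identical symmetry
    if (b.precursor_mz, str(b.id)) < (a.precursor_mz, str(a.id)):
        a, b = b, a
    return _greedy_score(a, b, frag_tol, precursor_shift)


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity edge between two spectrum ids."""

    id_a: str
    id_b: str
    score: float
    n_matched_peaks: int


@dataclass
class MolecularNetwork:
    """Weighted spectral-similarity graph with its connected components."""

    graph: nx.Graph
    clusters: list[list[str]]
    params: dict = field(default_factory=dict)

    @property
    def edges(self) -> list[SimilarityEdge]:
        return [
            SimilarityEdge(u, v, d["score"], d["n_matched"])
            for u, v, d in self.graph.edges(data=True)
        ]


def build_network(
    spectra: Sequence[Spectrum],
    frag_tol: float = 0.02,
    score_threshold: float = 0.7,
    min_matched: int = 3,
    top_k: int = 10,
    precursor_shift: bool = False,
) -> MolecularNetwork:
    """All-pairs modified-cosine network with mutual top-k edge filtering.

    Edges require score >= *score_threshold* and at least *min_matched*
    matched peaks; each node then retains an edge only if it ranks within
    that node's *top_k* strongest on both endpoints.  Clusters are the
    connected components (singletons allowed).  Deterministic.
    """
    if not spectra:
        raise ValueError("need at least one spectrum")
    ids = [s.id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique within a network")
    graph = nx.Graph()
    for s in spectra:
        attrs = {"precursor_mz": s.precursor_mz, "n_peaks": len(s)}
        if s.rt is not None:
            attrs["rt"] = s.rt
        label = s.metadata.get("class", s.metadata.get("class_label"))
        if label is not None:
            attrs["class_label"] = str(label)
        graph.add_node(s.id, **attrs)

    raw: list[tuple[str, str, float, int]] = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, n_matched = modified_cosine(
                spectra[i], spectra[j], frag_tol, precursor_shift
            )
            if score >= score_threshold and n_matched >= min_matched:
                raw.append((ids[i], ids[j], score, n_matched))

    # mutual top-k: keep an edge only if it is within the top_k strongest
    # incident edges of both endpoints
    rank: dict[str, list[tuple[float, str]]] = {u: [] for u in ids}
    for u, v, score, _ in raw:
        rank[u].append((score, v))
        rank[v].append((score, u))
    keep: dict[str, set[str]] = {}
    for u, incident in rank.items():
        incident.sort(key=lambda t: (-t[0], t[1]))
        keep[u] = {v for _, v in incident[:top_k]}
    for u, v, score, n_matched in raw:
        if v in keep[u] and u in keep[v]:
            graph.add_edge(u, v, score=score, n_matched=n_matched)

    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return MolecularNetwork(
        graph=graph,
        clusters=components,
        params={
            "frag_tol": frag_tol,
            "score_threshold": score_threshold,
            "min_matched": min_matched,
            "top_k": top_k,
            "precursor_shift": precursor_shift,
        },
    )


def export_graphml(net: MolecularNetwork, path: str | Path) -> Path:
    """Write the network as GraphML (losslessly re-importable)."""
    path = Path(path)
    nx.write_graphml(net.graph, path)
    return path


def read_graphml(path: str | Path) -> MolecularNetwork:
    """Re-import a GraphML network written by :func:`export_graphml`."""
    graph = nx.read_graphml(str(path))
    components = [sorted(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return MolecularNetwork(graph=graph, clusters=components)
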