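"""Molecular networking: consensus clustering, modified cosine, graph export.

The modified cosine treats two MS/MS spectra as vectors of square-root
intensities and counts a fragment pair as matchable when the two m/z agree
within the fragment tolerance either directly or after shifting one
spectrum by the precursor-mass difference — the shift is what lets two
structurally related compounds differing by a single modification still
align their common substructure fragments.  Matching is one-to-one and
greedy by descending weight product; the greedy score is a lower bound on
the optimal assignment and coincides with it whenever matches are
unambiguous (verified against an exhaustive oracle in the tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = ["ScoringParams", "ConsensusSpectrum", "cosine_score", "cluster_spectra",
           "build_network", "constellations", "library_match", "export_network"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoringParams:
    """Networking parameters; defaults follow common molecular-networking practice."""

    parent_tol: float = 0.01        # Da, precursor tolerance
    fragment_tol: float = 0.5       # Da, fragment-matching tolerance
    min_cosine: float = 0.7         # edge / cluster-membership threshold
    min_cluster_size: int = 4       # consensus nodes need this many member scans
    library_min_score: float = 0.5  # spectral-library hit threshold
    library_min_matched: int = 2    # minimum matched fragment peaks for a hit
    intensity_power: float = 0.5    # weight = intensity ** power
    top_k: int | None = None        # optional neighbour pruning (off by default)

    def __post_init__(self) -> None:
        if self.parent_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        for thr in (self.min_cosine, self.library_min_score):
            if not 0 <= thr <= 1:
                raise ValueError("cosine thresholds must lie in [0, 1]")


@dataclass
class ConsensusSpectrum:
    """Merged representative of a cluster of replicate scans."""

    id: str
    member_ids: list[str]
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    strains_observed: set[str] = field(default_factory=set)
    rt: float = 0.0
    group: str = ""        # filled in by tag classification
    annotation: str = ""   # filled in by library matching

    @property
    def size(self) -> int:
        return len(self.member_ids)

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def _normalized_weights(intensity: np.ndarray, power: float) -> np.ndarray:
    w = np.power(np.asarray(intensity, dtype=float), power)
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def cosine_score(a, b, p: ScoringParams = ScoringParams(), shifted: bool = True):
    """Modified cosine between two spectra (or consensus spectra).

    Returns ``(score, matched_peaks)`` with score in [0, 1].  With
    ``shifted=False`` only direct m/z matches are allowed (plain cosine).
    """
    if a.mz.size == 0 or b.mz.size == 0:
        raise ValueError("cannot score a spectrum without peaks")
    wa = _normalized_weights(a.intensity, p.intensity_power)
    wb = _normalized_weights(b.intensity, p.intensity_power)
    delta = a.precursor_mz - b.precursor_mz
    candidates: dict[tuple[int, int], float] = {}
    for offset in ([0.0, delta] if shifted else [0.0]):
        # b's fragments shifted by the precursor difference may match a's.
        j0 = 0
        for i, mza in enumerate(a.mz):
            for j, mzb in enumerate(b.mz):
                if abs(mza - (mzb + offset)) <= p.fragment_tol:
                    prod = wa[i] * wb[j]
                    key = (i, j)
                    if prod > candidates.get(key, -1.0):
                        candidates[key] = prod
    # Greedy one-to-one assignment, largest product first; index order breaks ties.
    order = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    score = 0.0
    matched = 0
    for (i, j), prod in order:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        score += prod
        matched += 1
    return min(score, 1.0), matched


def _merge_peaks(mz: np.ndarray, intensity: np.ndarray, tol: float):
    """Tolerance-merge a concatenated peak list: intensity-weighted centroids."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    out_mz, out_int = [], []
    i = 0
    n = mz.size
    while i < n:
        j = i + 1
        while j < n and mz[j] - mz[i] <= tol:
            j += 1
        seg_mz, seg_int = mz[i:j], intensity[i:j]
        total = seg_int.sum()
        centroid = float((seg_mz * seg_int).sum() / total) if total > 0 else float(seg_mz.mean())
        out_mz.append(centroid)
        out_int.append(float(total))
        i = j
    return np.array(out_mz), np.array(out_int)


def cluster_spectra(spectra: Sequence[Spectrum], p: ScoringParams = ScoringParams()) -> list[ConsensusSpectrum]:
    """Greedy single-pass consensus clustering of replicate scans.

    Spectra are sorted by precursor m/z; a scan joins the open cluster when
    its precursor lies within ``parent_tol`` of the cluster's median
    precursor and its plain cosine to the running consensus reaches
    ``min_cosine``.  Clusters smaller than ``min_cluster_size`` are
    discarded.  The pass is order-deterministic after sorting.
    """
    if not spectra:
        raise ValueError("no spectra to cluster")
    ordered = sorted(spectra, key=lambda s: (s.precursor_mz, s.id))
    clusters: list[list[Spectrum]] = []
    consensi: list[ConsensusSpectrum] = []

    def _consensus(members: list[Spectrum], cid: str) -> ConsensusSpectrum:
        mz = np.concatenate([m.mz for m in members])
        inten = np.concatenate([m.intensity for m in members])
        cmz, cint = _merge_peaks(mz, inten, p.fragment_tol)
        return ConsensusSpectrum(
            id=cid,
            member_ids=[m.id for m in members],
            precursor_mz=float(np.median([m.precursor_mz for m in members])),
            mz=cmz,
            intensity=cint,
            strains_observed={m.strain for m in members if m.strain},
            rt=float(np.mean([m.rt for m in members])),
        )

    current: list[Spectrum] = []
    current_consensus: ConsensusSpectrum | None = None
    for s in ordered:
        if current:
            median_prec = float(np.median([m.precursor_mz for m in current]))
            if abs(s.precursor_mz - median_prec) <= p.parent_tol:
                sc, _ = cosine_score(s, current_consensus, p, shifted=False)
                if sc >= p.min_cosine:
                    current.append(s)
                    current_consensus = _consensus(current, current_consensus.id)
                    continue
        if current:
            clusters.append(current)
        current = [s]
        current_consensus = _consensus(current, f"N{len(clusters) + 1}")
    if current:
        clusters.append(current)

    kept = 0
    for members in clusters:
        if len(members) >= p.min_cluster_size:
            kept += 1
            consensi.append(_consensus(members, f"N{kept}"))
    if not consensi:
        log.warning("no cluster reached the minimum size of %d", p.min_cluster_size)
    return consensi


def build_network(nodes: Sequence[ConsensusSpectrum], p: ScoringParams = ScoringParams()) -> nx.Graph:
    """All-pairs modified-cosine graph with edges at ``score >= min_cosine``."""
    if not nodes:
        raise ValueError("network needs at least one node")
    g = nx.Graph()
    for n in nodes:
        g.add_node(
            n.id,
            precursor_mz=round(n.precursor_mz, 6),
            size=n.size,
            strains=",".join(sorted(n.strains_observed)),
            group=n.group,
            annotation=n.annotation,
        )
    scored = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            sc, matched = cosine_score(nodes[i], nodes[j], p, shifted=True)
            if sc >= p.min_cosine:
                scored.append((nodes[i].id, nodes[j].id, sc, matched))
    if p.top_k is not None:
        # Keep an edge only if it ranks within each endpoint's top_k neighbours.
        by_node: dict[str, list[tuple[float, str]]] = {}
        for u, v, sc, _ in scored:
            by_node.setdefault(u, []).append((sc, v))
            by_node.setdefault(v, []).append((sc, u))
        keep = {}
        for node, nbrs in by_node.items():
            nbrs.sort(key=lambda t: (-t[0], t[1]))
            keep[node] = {v for _, v in nbrs[: p.top_k]}
        scored = [e for e in scored if e[1] in keep.get(e[0], set()) and e[0] in keep.get(e[1], set())]
    for u, v, sc, matched in scored:
        g.add_edge(u, v, cosine=round(sc, 6), matched_peaks=matched)
    return g


def constellations(g: nx.Graph) -> list[set[str]]:
    """Connected components ("constellations"), largest first; singletons included."""
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def library_match(
    node: ConsensusSpectrum | Spectrum,
    library: Sequence[Spectrum],
    p: ScoringParams = ScoringParams(),
) -> list[tuple[Spectrum, float, int]]:
    """Match one node against an annotated spectral library.

    Returns ``(entry, score, matched_peaks)`` for every library entry with
    score >= library_min_score and at least library_min_matched matched
    fragment peaks, best score first.
    """
    if not library:
        raise ValueError("spectral library is empty")
    hits = []
    for entry in library:
        sc, matched = cosine_score(node, entry, p, shifted=False)
        if sc >= p.library_min_score and matched >= p.library_min_matched:
            hits.append((entry, sc, matched))
    hits.sort(key=lambda h: (-h[1], h[0].id))
    return hits


def export_network(g: nx.Graph, basepath: str | Path) -> dict[str, Path]:
    """Write GraphML plus node/edge TSV tables next to *basepath*."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "graphml": base.with_suffix(".graphml"),
        "nodes": base.parent / (base.name + ".nodes.tsv"),
        "edges": base.parent / (base.name + ".edges.tsv"),
    }
    nx.write_graphml(g, paths["graphml"])
    nodes = pd.DataFrame(
        [{"id": n, **attrs} for n, attrs in sorted(g.nodes(data=True))]
    )
    nodes.to_csv(paths["nodes"], sep="\t", index=False)
    edges = pd.DataFrame(
        [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in sorted(g.edges(data=True))
        ],
        columns=["source", "target", "cosine", "matched_peaks"],
    )
    edges.to_csv(paths["edges"], sep="\t", index=False)
    for kind, path in paths.items():
        log.info("wrote %s export to %s", kind, path)
    return paths
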