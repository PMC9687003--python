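"""Parasegment labelling and PSB / -1 / +1 interface classification.

Parasegmental boundaries (PSBs) sit at the anterior border of each
*engrailed*-expressing stripe.  Given the set of expressing cells in a frame,
stripes are the connected components of expressing cells in the adjacency
graph, ordered along AP; each stripe seeds a parasegment that extends
posteriorly to the next stripe.  A cell's AP rank is its graph distance (in
AP-neighbour steps) from the stripe.  PSB interfaces separate an expressing
cell from its non-expressing anterior AP neighbour; the -1 and +1 control
interfaces are the columns of AP interfaces one cell diameter anterior and
posterior of the PSBs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .mesh import CellFrame, Interface, TissueTimeSeries

log = logging.getLogger(__name__)

__all__ = [
    "ParasegmentMap",
    "label_parasegments",
    "find_psb_interfaces",
    "find_offset_interfaces",
    "classify_frame_interfaces",
    "propagate_labels",
    "interfaces_to_table",
]


@dataclass
class ParasegmentMap:
    """Per-frame cell labelling: parasegment index and AP rank within it."""

    parasegment: dict[int, int] = field(default_factory=dict)
    ap_rank: dict[int, int] = field(default_factory=dict)
    stripes: list[set[int]] = field(default_factory=list)  # AP-ordered member sets

    def __contains__(self, cell_id: int) -> bool:
        return cell_id in self.parasegment


def _ap_digraph(frame: CellFrame) -> nx.DiGraph:
    """Directed AP-neighbour graph: edge a -> b means b is the posterior neighbour."""
    cent = frame.centroids()
    g = nx.DiGraph()
    g.add_nodes_from(frame.cells)
    for a, b in frame.ap_neighbours():
        if cent[a][0] <= cent[b][0]:
            g.add_edge(a, b)
        else:
            g.add_edge(b, a)
    return g


def label_parasegments(frame: CellFrame, expressing: set[int],
                       trailing: str = "include") -> ParasegmentMap:
    """Label cells by parasegment from the expressing-cell stripes of one frame.

    Stripes are connected components of expressing cells; parasegment k is
    stripe k plus the cells posterior of it up to (not including) stripe k+1.
    Cells anterior to the first stripe stay unlabelled (out of range); with
    ``trailing="exclude"`` cells posterior to the last stripe do too, while
    the default assigns them to the last parasegment.  AP rank is the BFS
    depth from the stripe along posterior AP-neighbour steps.
    """
    if trailing not in ("include", "exclude"):
        raise ValueError("trailing must be 'include' or 'exclude'")
    pmap = ParasegmentMap()
    expressing = expressing & set(frame.cells)
    if not expressing:
        log.warning("no expressing cells: empty parasegment map")
        return pmap
    adj = frame.adjacency()
    cent = frame.centroids()
    comps = list(nx.connected_components(adj.subgraph(expressing)))
    comps.sort(key=lambda comp: float(np.mean([cent[c][0] for c in comp])))
    pmap.stripes = [set(c) for c in comps]

    dg = _ap_digraph(frame)
    # multi-source BFS posterior-ward; later stripes block earlier ones
    for k, stripe in enumerate(pmap.stripes):
        for c in stripe:
            pmap.parasegment[c] = k
            pmap.ap_rank[c] = 0
    frontier = [(c, k) for k, stripe in enumerate(pmap.stripes) for c in stripe]
    rank = dict.fromkeys(pmap.parasegment, 0)
    while frontier:
        nxt = []
        for c, k in frontier:
            for nb in dg.successors(c):
                if nb in pmap.parasegment or nb in expressing:
                    continue
                pmap.parasegment[nb] = k
                rank[nb] = rank[c] + 1
                pmap.ap_rank[nb] = rank[nb]
                nxt.append((nb, k))
        frontier = nxt
    if trailing == "exclude":
        last = len(pmap.stripes) - 1
        drop = [c for c, k in pmap.parasegment.items()
                if k == last and c not in pmap.stripes[last]]
        for c in drop:
            del pmap.parasegment[c]
            del pmap.ap_rank[c]
    return pmap


def find_psb_interfaces(frame: CellFrame, pmap: ParasegmentMap,
                        expressing: set[int] | None = None) -> list[Interface]:
    """AP interfaces between an expressing cell and a non-expressing anterior neighbour."""
    expressing = set().union(*pmap.stripes) if expressing is None else expressing
    dg = _ap_digraph(frame)
    itfs = {(i.cell_a, i.cell_b): i for i in frame.interfaces()}
    out = []
    for a, b in dg.edges:  # a anterior of b
        if b in expressing and a not in expressing:
            key = (a, b) if a < b else (b, a)
            if key in itfs:
                out.append(itfs[key])
    return out


def find_offset_interfaces(frame: CellFrame, pmap: ParasegmentMap, offset: int,
                           psb: list[Interface] | None = None,
                           expressing: set[int] | None = None) -> list[Interface]:
    """Control interfaces one cell diameter anterior (-1) or posterior (+1) of PSBs.

    -1 interfaces are AP edges between the non-expressing PSB partner and its
    own anterior AP neighbours; +1 interfaces are AP edges between the
    posterior end of the stripe and the first non-expressing cell behind it.
    Boundaries inside parasegments narrower than two ranks yield no offset
    interface (logged).
    """
    if offset not in (-1, 1):
        raise ValueError("offset must be -1 or +1")
    expressing = set().union(*pmap.stripes) if expressing is None else expressing
    if psb is None:
        psb = find_psb_interfaces(frame, pmap, expressing)
    dg = _ap_digraph(frame)
    cent = frame.centroids()
    itfs = {(i.cell_a, i.cell_b): i for i in frame.interfaces()}
    psb_pairs = {(i.cell_a, i.cell_b) for i in psb}
    out, seen = [], set()
    for pa, pb in psb_pairs:
        ant, post = (pa, pb) if cent[pa][0] <= cent[pb][0] else (pb, pa)
        if offset == -1:
            found = False
            for nb in dg.predecessors(ant):
                key = (nb, ant) if nb < ant else (ant, nb)
                if key in itfs and key not in seen and key not in psb_pairs:
                    seen.add(key)
                    out.append(itfs[key])
                    found = True
            if not found:
                log.warning("no -1 interface anterior of PSB pair (%d, %d)", pa, pb)
        else:
            # walk to the posterior end of the stripe, then one step further
            tail, guard = post, 0
            while guard < 1000:
                guard += 1
                nxt = [nb for nb in dg.successors(tail) if nb in expressing]
                if not nxt:
                    break
                tail = min(nxt, key=lambda n: cent[n][0])
            found = False
            for nb in dg.successors(tail):
                if nb in expressing:
                    continue
                if nb in pmap and tail in pmap and pmap.parasegment[nb] != pmap.parasegment[tail]:
                    continue  # must stay within the same parasegment
                key = (nb, tail) if nb < tail else (tail, nb)
                if key in itfs and key not in seen and key not in psb_pairs:
                    seen.add(key)
                    out.append(itfs[key])
                    found = True
            if not found:
                log.warning("no +1 interface posterior of PSB pair (%d, %d)", pa, pb)
    return out


def classify_frame_interfaces(frame: CellFrame, expressing: set[int],
                              trailing: str = "include") -> pd.DataFrame:
    """One-frame classification: every interface labelled psb/minus1/plus1/other.

    Classes partition the edges; an edge qualifying for two classes (possible
    only in degenerate two-cell-wide parasegments) is demoted to "other" with
    a warning.
    """
    pmap = label_parasegments(frame, expressing, trailing=trailing)
    rows = []
    classes: dict[tuple[int, int], str] = {}
    if pmap.stripes:
        psb = find_psb_interfaces(frame, pmap, expressing)
        minus1 = find_offset_interfaces(frame, pmap, -1, psb=psb, expressing=expressing)
        plus1 = find_offset_interfaces(frame, pmap, +1, psb=psb, expressing=expressing)
        for group, name in ((psb, "psb"), (minus1, "minus1"), (plus1, "plus1")):
            for itf in group:
                key = (itf.cell_a, itf.cell_b)
                if key in classes and classes[key] != name:
                    log.warning("interface %s claimed as both %s and %s; set to other",
                                key, classes[key], name)
                    classes[key] = "other"
                else:
                    classes[key] = name
    for itf in frame.interfaces():
        key = (itf.cell_a, itf.cell_b)
        rows.append({
            "frame": frame.index, "time_min": frame.time_min,
            "cell_a": itf.cell_a, "cell_b": itf.cell_b,
            "cls": classes.get(key, "other"),
            "x1": itf.p1[0], "y1": itf.p1[1], "x2": itf.p2[0], "y2": itf.p2[1],
            "theta_deg": itf.theta,
        })
    return pd.DataFrame(rows)


def propagate_labels(series: TissueTimeSeries,
                     reference: dict[int, ParasegmentMap]) -> dict[int, dict[int, int]]:
    """Propagate parasegment labels from reference frames to every frame.

    Cell identities are persistent, so a cell's label is constant over its
    track.  Conflicting labels across reference frames resolve by majority
    vote, ties by the earliest reference frame.  Returns a per-frame mapping
    cell_id -> parasegment for cells present in that frame; cells never seen
    at a reference frame stay unlabelled.
    """
    votes: dict[int, dict[int, list[int]]] = {}
    for ref_idx in sorted(reference):
        for cid, ps in reference[ref_idx].parasegment.items():
            votes.setdefault(cid, {}).setdefault(ps, []).append(ref_idx)
    label: dict[int, int] = {}
    for cid, by_ps in votes.items():
        best = max(by_ps.items(), key=lambda kv: (len(kv[1]), -min(kv[1])))
        label[cid] = best[0]
    return {f.index: {cid: label[cid] for cid in f.cells if cid in label}
            for f in series.frames}


def interfaces_to_table(series: TissueTimeSeries, expressing_by_frame: dict[int, set[int]],
                        trailing: str = "include") -> pd.DataFrame:
    """Classify interfaces in every frame; tidy long table over time."""
    tables = []
    for frame in series.frames:
        expressing = expressing_by_frame.get(frame.index, set())
        tables.append(classify_frame_interfaces(frame, expressing, trailing=trailing))
    return pd.concat(tables, ignore_index=True)
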