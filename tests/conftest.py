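"""Shared fixtures: hand-written format fixtures, graph builders, and the
independent brute-force fragment oracle used to validate edge-cut
enumeration."""

from __future__ import annotations

import base64
import itertools
import struct
import zlib

import pytest
from hypothesis import settings

from pnpmatch.fragmentation import PNPEdge, PNPGraph, PNPVertex

settings.register_profile("pnpmatch", derandomize=True, deadline=None)
settings.load_profile("pnpmatch")


GLYCINE_V3000 = """glycine
  test

  0  0  0  0  0  0  0  0  0  0999 V3000
M  V30 BEGIN CTAB
M  V30 COUNTS 5 4 0 0 0
M  V30 BEGIN ATOM
M  V30 1 N 0.0 0.0 0.0 0
M  V30 2 C 1.0 0.0 0.0 0
M  V30 3 C 2.0 0.0 0.0 0
M  V30 4 O 3.0 0.5 0.0 0
M  V30 5 O 2.0 -1.0 0.0 0
M  V30 END ATOM
M  V30 BEGIN BOND
M  V30 1 1 1 2
M  V30 2 1 2 3
M  V30 3 2 3 4
M  V30 4 1 3 5
M  V30 END BOND
M  V30 END CTAB
M  END
"""


@pytest.fixture
def glycine_v3000() -> str:
    return GLYCINE_V3000


def make_graph(n_vertices: int, edges: list[tuple[int, int]],
               masses: list[float] | None = None) -> PNPGraph:
    """Bare PNP graph for graph-level tests (no underlying molecule)."""
    if masses is None:
        masses = [100.0 + 7.0 * i for i in range(n_vertices)]
    vertices = [
        PNPVertex(index=i, atom_indices=frozenset([i]), mass=masses[i],
                  label=f"v{i}")
        for i in range(n_vertices)
    ]
    pedges = [
        PNPEdge(index=k, bond=None, vertex_a=u, vertex_b=v)
        for k, (u, v) in enumerate(edges)
    ]
    return PNPGraph(vertices=vertices, edges=pedges)


def path_graph(n: int) -> PNPGraph:
    return make_graph(n, [(i, i + 1) for i in range(n - 1)])


def cycle_graph(n: int) -> PNPGraph:
    return make_graph(n, [(i, (i + 1) % n) for i in range(n)])


def brute_force_fragments(g: PNPGraph) -> dict[frozenset, set[frozenset]]:
    """All-subsets/all-cuts oracle, independent of the enumeration path.

    A proper nonempty vertex subset S is a fragment iff some 1- or 2-edge
    cut leaves S as a connected component: the cut must cover every edge
    crossing S's boundary, and S must stay connected after removing any
    cut edge internal to S. Returns {vertex set: set of generating cuts}.
    """
    verts = [v.index for v in g.vertices]
    edges = {e.index: (e.vertex_a, e.vertex_b) for e in g.edges}

    def connected(sub: frozenset, removed: frozenset) -> bool:
        if not sub:
            return False
        adj = {v: set() for v in sub}
        for ei, (u, v) in edges.items():
            if ei not in removed and u in sub and v in sub and u != v:
                adj[u].add(v)
                adj[v].add(u)
        seen, stack = set(), [next(iter(sub))]
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj[x] - seen)
        return seen == set(sub)

    cuts = [frozenset([i]) for i in edges]
    cuts += [frozenset(p) for p in itertools.combinations(sorted(edges), 2)]

    result: dict[frozenset, set[frozenset]] = {}
    for r in range(1, len(verts)):
        for combo in itertools.combinations(verts, r):
            s = frozenset(combo)
            boundary = {
                ei for ei, (u, v) in edges.items() if (u in s) != (v in s)
            }
            if len(boundary) > 2 or not connected(s, frozenset()):
                continue
            generating = {
                cut for cut in cuts
                if boundary <= cut and connected(s, cut)
            }
            if generating:
                result[s] = generating
    return result


def mzxml_document(scans: list[dict], compression: str = "none",
                   precision: int = 64) -> bytes:
    """Minimal mzXML 3.2 document with base64-encoded peak arrays.

    Each scan dict: num, ms_level, peaks [(mz, intensity)], and optionally
    precursor_mz / precursor_charge.
    """
    fmt = {64: ">d", 32: ">f"}[precision]
    body = []
    for scan in scans:
        raw = b"".join(
            struct.pack(fmt, value)
            for mz, inten in scan["peaks"]
            for value in (mz, inten)
        )
        if compression == "zlib":
            raw = zlib.compress(raw)
        encoded = base64.b64encode(raw).decode()
        precursor = ""
        if scan.get("precursor_mz") is not None:
            precursor = (
                f'<precursorMz precursorCharge="{scan.get("precursor_charge", 1)}">'
                f'{scan["precursor_mz"]}</precursorMz>'
            )
        body.append(
            f'<scan num="{scan["num"]}" msLevel="{scan["ms_level"]}" '
            f'peaksCount="{len(scan["peaks"])}">{precursor}'
            f'<peaks compressionType="{compression}" compressedLen="{len(raw)}" '
            f'precision="{precision}" byteOrder="network" '
            f'contentType="m/z-int">{encoded}</peaks></scan>'
        )
    doc = (
        '<?xml version="1.0" encoding="ISO-8859-1"?>'
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">'
        f'<msRun scanCount="{len(scans)}">{"".join(body)}</msRun></mzXML>'
    )
    return doc.encode()
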