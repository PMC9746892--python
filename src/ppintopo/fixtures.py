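"""Deterministic synthetic inputs: analytic graphs, random-model graphs and
MITAB files seeded with known anomalies.

Analytic families (star, clique, path, cycle) have closed-form topological
measures and anchor the exact tests; the random families — Barabási–Albert
preferential attachment, Erdős–Rényi, Watts–Strogatz — emulate the
scale-free / homogeneous / small-world regimes discussed throughout network
biology.  All generators are bit-reproducible: the same spec always yields
the same edge list, with zero-padded node labels ``n0000`` ….

:func:`make_mitab_fixture` writes a synthetic IntAct-style MITAB 2.7 file
whose anomalies (duplicate rows, reversed-pair repetitions, self-loops,
non-protein interactors, non-human taxa, missing confidence scores) are
injected in known numbers; the accompanying manifest states the exact
post-cleaning N, L and anomaly counts, so the whole parse→clean pipeline is
testable end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import PPINetwork

__all__ = ["FixtureSpec", "make_graph", "make_mitab_fixture"]

FAMILIES = (
    "star",
    "clique",
    "path",
    "cycle",
    "barabasi_albert",
    "erdos_renyi",
    "watts_strogatz",
)


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible graph-fixture request: family, size parameters, seed.

    Parameters by family: ``star(n)`` (n leaves), ``clique(n)``, ``path(n)``,
    ``cycle(n)``; ``barabasi_albert(n, m)``; ``erdos_renyi(n, p)``;
    ``watts_strogatz(n, k, p)``.  The seed only matters for the random
    families.
    """

    family: str
    params: tuple[tuple[str, float], ...]
    seed: int = 0

    @classmethod
    def make(cls, family: str, seed: int = 0, **params: float) -> "FixtureSpec":
        return cls(family=family, params=tuple(sorted(params.items())), seed=seed)

    def param_dict(self) -> dict[str, float]:
        return dict(self.params)


def _label(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def _labels(count: int) -> list[str]:
    width = max(4, len(str(max(count - 1, 0))))
    return [_label(i, width) for i in range(count)]


def _ba_edges(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Preferential attachment via the repeated-nodes urn (bit-reproducible)."""
    if m < 1 or n <= m:
        raise ValueError("Barabási–Albert requires m >= 1 and n > m")
    edges: list[tuple[int, int]] = []
    urn: list[int] = []
    targets = list(range(m))  # the first arriving node links to all seeds
    for new in range(m, n):
        for t in targets:
            edges.append((t, new))
        urn.extend(targets)
        urn.extend([new] * m)
        if new + 1 < n:
            chosen: set[int] = set()
            while len(chosen) < m:
                chosen.add(urn[int(rng.integers(len(urn)))])
            targets = sorted(chosen)
    return edges


def _er_edges(n: int, p: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    if not (0.0 <= p <= 1.0) or n < 2:
        raise ValueError("Erdős–Rényi requires n >= 2 and p in [0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.random(len(iu)) < p
    return list(zip(iu[keep].tolist(), ju[keep].tolist()))


def _ws_edges(n: int, k: int, p: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    if k % 2 or k < 2 or k >= n:
        raise ValueError("Watts–Strogatz requires even k with 2 <= k < n")
    if not (0.0 <= p <= 1.0):
        raise ValueError("rewiring probability must lie in [0, 1]")
    edge_set: set[tuple[int, int]] = set()
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            edge_set.add((min(i, j), max(i, j)))
    edges = sorted(edge_set)
    for idx, (u, v) in enumerate(edges):
        if rng.random() < p:
            # rewire the far end, avoiding self-loops and existing edges
            for _ in range(n):
                w = int(rng.integers(n))
                cand = (min(u, w), max(u, w))
                if w != u and cand not in edge_set:
                    edge_set.discard((u, v))
                    edge_set.add(cand)
                    edges[idx] = cand
                    break
    return sorted(edge_set)


def make_graph(spec: FixtureSpec) -> PPINetwork:
    """Materialize a fixture graph with deterministic ``n000…`` labels."""
    if spec.family not in FAMILIES:
        raise ValueError(f"unknown family {spec.family!r}; expected one of {FAMILIES}")
    p = spec.param_dict()
    rng = np.random.default_rng(spec.seed)

    if spec.family == "star":
        n = int(p["n"])
        if n < 1:
            raise ValueError("star requires n >= 1 leaves")
        labels = _labels(n + 1)
        edges = [(labels[0], labels[i]) for i in range(1, n + 1)]
    elif spec.family == "clique":
        n = int(p["n"])
        if n < 2:
            raise ValueError("clique requires n >= 2")
        labels = _labels(n)
        edges = [(labels[i], labels[j]) for i in range(n) for j in range(i + 1, n)]
    elif spec.family == "path":
        n = int(p["n"])
        if n < 2:
            raise ValueError("path requires n >= 2")
        labels = _labels(n)
        edges = [(labels[i], labels[i + 1]) for i in range(n - 1)]
    elif spec.family == "cycle":
        n = int(p["n"])
        if n < 3:
            raise ValueError("cycle requires n >= 3")
        labels = _labels(n)
        edges = [(labels[i], labels[(i + 1) % n]) for i in range(n)]
    else:
        n = int(p["n"])
        labels = _labels(n)
        if spec.family == "barabasi_albert":
            raw = _ba_edges(n, int(p["m"]), rng)
        elif spec.family == "erdos_renyi":
            raw = _er_edges(n, float(p["p"]), rng)
        else:
            raw = _ws_edges(n, int(p["k"]), float(p["p"]), rng)
        edges = [(labels[u], labels[v]) for u, v in raw]

    return PPINetwork.from_edges(edges)


# ---------------------------------------------------------------------------
# synthetic MITAB fixtures


@dataclass
class MitabManifest:
    """Ground truth for a synthetic MITAB file (what cleaning must recover)."""

    n_records: int
    n_base_edges: int
    n_duplicate_records: int
    n_reversed_repetitions: int
    n_self_loop_records: int
    expected_n: int
    expected_l: int
    n_non_protein_interactors: int
    n_non_human_interactors: int
    n_missing_scores: int
    seed: int
    accessions: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.__dict__, handle, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "MitabManifest":
        with open(path, encoding="utf-8") as handle:
            return cls(**json.load(handle))


_YEAST_TWO_HYBRID = 'psi-mi:"MI:0018"(two hybrid)'
_COIP = 'psi-mi:"MI:0019"(coimmunoprecipitation)'
_METHOD_CYCLE = (
    _YEAST_TWO_HYBRID,
    _COIP,
    'psi-mi:"MI:0676"(tandem affinity purification)',
    'psi-mi:"MI:0096"(pull down)',
)


def _mitab_line(
    id_a: str,
    id_b: str,
    interaction_id: str,
    score: float | None,
    type_a: str = "protein",
    type_b: str = "protein",
    taxid_a: int = 9606,
    taxid_b: int = 9606,
    method: str = _YEAST_TWO_HYBRID,
    publication: str = "pubmed:32296183",
) -> str:
    tax_name = {9606: "human", 10090: "mouse"}
    cols = ["-"] * 42
    cols[0] = f"uniprotkb:{id_a}"
    cols[1] = f"uniprotkb:{id_b}"
    cols[6] = method
    cols[8] = publication
    cols[9] = f"taxid:{taxid_a}({tax_name.get(taxid_a, 'other')})"
    cols[10] = f"taxid:{taxid_b}({tax_name.get(taxid_b, 'other')})"
    cols[13] = f"intact:{interaction_id}"
    if score is not None:
        cols[14] = f"intact-miscore:{score:.2f}"
    cols[20] = f'psi-mi:"MI:0326"({type_a})'
    cols[21] = f'psi-mi:"MI:0326"({type_b})'
    return "\t".join(cols)


def make_mitab_fixture(
    n_edges: int,
    path: str | Path,
    duplicates: bool = False,
    reversed_pairs: bool = False,
    n_self_loops: int = 0,
    n_non_protein: int = 0,
    n_non_human: int = 0,
    n_missing_scores: int = 0,
    varied_metadata: bool = False,
    seed: int = 0,
) -> MitabManifest:
    """Write a synthetic MITAB 2.7 file with known anomalies and its manifest.

    The base network is a random connected graph on UniProt-style accessions
    (``P00001`` …): a random spanning tree plus random extra edges, so after
    cleaning the largest component is the whole graph and the expected N and
    L are exact.  Anomaly injection: ``duplicates`` repeats every base record
    once verbatim; ``reversed_pairs`` re-records half the base edges (every
    second one) with the interactors swapped; ``n_self_loops`` self-loop
    records reuse existing accessions; ``n_non_protein`` / ``n_non_human``
    relabel the A-interactor of that many base records (metadata only, the
    network shape is unchanged); ``n_missing_scores`` drops the confidence
    field of that many records.  With ``varied_metadata`` every base record
    gets its own publication id and the detection method cycles through four
    techniques (a bias-free metadata profile); by default all records share
    one publication and one method, emulating a single-experiment dataset.
    A JSON manifest with the exact expected counts is written next to the
    file (``<path>.manifest.json``).
    """
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    rng = np.random.default_rng(seed)

    # connected base graph: spanning tree on n_nodes = n_edges * 2 // 3 + 2,
    # then random extra edges up to n_edges
    n_nodes = max(2, (2 * n_edges) // 3 + 2)
    n_nodes = min(n_nodes, n_edges + 1)
    accessions = [f"P{i + 1:05d}" for i in range(n_nodes)]
    edges: list[tuple[str, str]] = []
    edge_set: set[tuple[str, str]] = set()
    for i in range(1, n_nodes):
        j = int(rng.integers(i))
        pair = tuple(sorted((accessions[i], accessions[j])))
        edges.append(pair)
        edge_set.add(pair)
    while len(edges) < n_edges:
        i, j = rng.integers(n_nodes), rng.integers(n_nodes)
        if i == j:
            continue
        pair = tuple(sorted((accessions[int(i)], accessions[int(j)])))
        if pair in edge_set:
            continue
        edges.append(pair)
        edge_set.add(pair)

    if n_non_protein > n_edges or n_non_human > n_edges or n_missing_scores > n_edges:
        raise ValueError("anomaly counts cannot exceed the number of base records")

    lines: list[str] = []
    counter = 0

    def _next_id() -> str:
        nonlocal counter
        counter += 1
        return f"EBI-{counter:07d}"

    # base records, with metadata anomalies folded onto the first ones
    non_protein_ids: set[str] = set()
    non_human_ids: set[str] = set()
    for idx, (a, b) in enumerate(edges):
        score = None if idx < n_missing_scores else round(0.3 + 0.6 * rng.random(), 2)
        type_a = "small molecule" if idx < n_non_protein else "protein"
        taxid_a = 10090 if idx < n_non_human else 9606
        if idx < n_non_protein:
            non_protein_ids.add(a)
        if idx < n_non_human:
            non_human_ids.add(a)
        method = _METHOD_CYCLE[idx % 4] if varied_metadata else _YEAST_TWO_HYBRID
        pub = f"pubmed:{20000000 + idx}" if varied_metadata else "pubmed:32296183"
        lines.append(
            _mitab_line(a, b, _next_id(), score, type_a=type_a, taxid_a=taxid_a,
                        method=method, publication=pub)
        )
        if duplicates:
            lines.append(
                _mitab_line(a, b, _next_id(), score, type_a=type_a, taxid_a=taxid_a,
                            method=method, publication=pub)
            )
        if reversed_pairs and idx % 2 == 0:
            lines.append(_mitab_line(b, a, _next_id(), score, method=_COIP, publication=pub))

    n_rev = (n_edges + 1) // 2 if reversed_pairs else 0
    for s in range(n_self_loops):
        node = accessions[s % n_nodes]
        lines.append(_mitab_line(node, node, _next_id(), 0.9))

    path = Path(path)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("#ID(s) interactor A\t" + "\t".join(["..."] * 41) + "\n")
        for line in lines:
            handle.write(line + "\n")

    manifest = MitabManifest(
        n_records=len(lines),
        n_base_edges=n_edges,
        n_duplicate_records=n_edges if duplicates else 0,
        n_reversed_repetitions=n_rev,
        n_self_loop_records=n_self_loops,
        expected_n=n_nodes,
        expected_l=n_edges,
        n_non_protein_interactors=len(non_protein_ids),
        n_non_human_interactors=len(non_human_ids),
        n_missing_scores=n_missing_scores,
        seed=seed,
        accessions=accessions,
    )
    manifest.to_json(path.with_suffix(path.suffix + ".manifest.json"))
    return manifest
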