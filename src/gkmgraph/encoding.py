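"""Encoding a DNA sequence into a sequence feature graph.

A sequence of length L is slid over with a window of k bases, yielding the
L−k+1 contiguous k-mers. With a gap distance d ≥ 2, additional gapped matches
are enumerated: k informative bases where, at one internal junction, the next
informative base sits d positions downstream of its predecessor (d−1 skipped
positions; written e.g. GT**A for k=3, d=3). Gapped matches are collapsed onto
the node identity of their informative bases, so they augment node counts —
making the features robust to small sequence variation — without enlarging
the node set.

The resulting graph G = (n, e) has one node per k-mer (feature = occurrence
frequency over all valid counted windows) and an undirected edge between
k-mers that occur as consecutive windows (weight = number of co-occurrences).
Windows containing N are excluded from node and edge counting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gkmgraph.sequence_io import LabeledSequence

logger = logging.getLogger(__name__)

_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class EncoderConfig:
    """Parameters of the sequence-to-graph encoder.

    k is the number of informative bases per window; d is the positional
    distance between the two informative bases flanking the gap (d = 1 means
    contiguous windows only). ``count_mode`` selects raw counts or relative
    frequencies; ``node_universe`` is "full" (all 4^k k-mers, lexicographic)
    or "observed" (only k-mers seen in the sequence).
    """

    k: int = 3
    d: int = 3
    count_mode: str = "relative"
    node_universe: str = "full"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.k > 8:
            raise ValueError(f"k must be <= 8 (4^k node explosion), got {self.k}")
        if self.d < 1:
            raise ValueError(f"d must be >= 1, got {self.d}")
        if self.count_mode not in ("relative", "raw"):
            raise ValueError(f"count_mode must be 'relative' or 'raw', got {self.count_mode!r}")
        if self.node_universe not in ("full", "observed"):
            raise ValueError(f"node_universe must be 'full' or 'observed', got {self.node_universe!r}")


@dataclass
class SequenceFeatureGraph:
    """Per-sequence graph over the k-mer universe.

    ``kmer_labels`` fixes the canonical node order; ``node_features`` holds one
    frequency per node; ``edges`` maps an index pair (i <= j) to a positive
    weight; ``n_windows`` is the contiguous window count max(0, L−k+1).
    """

    kmer_labels: list[str]
    node_features: np.ndarray
    edges: dict[tuple[int, int], float]
    n_windows: int
    sequence_id: str = ""
    label: int | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.kmer_labels)

    def adjacency_matrix(self, use_edge_weights: bool = True) -> np.ndarray:
        """Dense symmetric adjacency; unit entries when weights are disabled."""
        a = np.zeros((self.n_nodes, self.n_nodes))
        for (i, j), w in self.edges.items():
            v = w if use_edge_weights else 1.0
            a[i, j] += v
            if i != j:
                a[j, i] += v
        return a

    def degrees(self, use_edge_weights: bool = True) -> np.ndarray:
        return self.adjacency_matrix(use_edge_weights).sum(axis=1)

    def normalized_adjacency(self, use_edge_weights: bool = True) -> np.ndarray:
        """D^{-1/2} A D^{-1/2} with zero rows/columns for isolated nodes."""
        a = self.adjacency_matrix(use_edge_weights)
        d = a.sum(axis=1)
        with np.errstate(divide="ignore"):
            inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
        return inv_sqrt[:, None] * a * inv_sqrt[None, :]


def full_kmer_universe(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product(_ALPHABET, repeat=k)]


def _is_valid_window(w: str) -> bool:
    return all(b in _BASE_INDEX for b in w)


def extract_contiguous_kmers(bases: str, k: int) -> list[str]:
    """The max(0, L−k+1) contiguous windows of length k, left to right.

    Windows containing N are emitted verbatim; downstream counting skips them.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [bases[i : i + k] for i in range(len(bases) - k + 1)]


def extract_gapped_kmers(bases: str, k: int, d: int) -> list[str]:
    """Gapped matches: k informative bases with one internal gap of d−1 positions.

    For each junction j (after the j-th informative base, 1 <= j <= k−1) and
    each start offset, the informative positions are j contiguous bases, then
    a base d positions downstream of its predecessor, then the remaining bases
    contiguous; each match spans k + d − 1 sequence positions. The returned
    label is the k informative bases only (the gap position is not encoded).
    Matches containing N are excluded. d = 1 returns [] (contiguous windows
    are handled separately).
    """
    if k < 2:
        raise ValueError(f"gapped extraction requires k >= 2, got {k}")
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if d == 1:
        return []
    span = k + d - 1
    out: list[str] = []
    for junction in range(1, k):
        # informative offsets within the span: 0..junction-1, then shifted by the gap
        offsets = list(range(junction)) + [junction - 1 + d + t for t in range(k - junction)]
        for start in range(len(bases) - span + 1):
            match = "".join(bases[start + o] for o in offsets)
            if _is_valid_window(match):
                out.append(match)
    return out


def count_node_frequencies(windows: list[str], config: EncoderConfig) -> np.ndarray:
    """Per-node occurrence features over the configured k-mer universe.

    Raw mode returns counts; relative mode divides by the number of valid
    counted windows (contiguous and gapped pooled). Windows containing N are
    skipped; a window of the wrong length is an error. In "observed" universe
    mode the vector covers the sorted set of k-mers present in ``windows``.
    """
    for w in windows:
        if len(w) != config.k:
            raise ValueError(f"window {w!r} has length {len(w)}, expected k={config.k}")
    valid = [w for w in windows if _is_valid_window(w)]
    if config.node_universe == "full":
        labels = full_kmer_universe(config.k)
    else:
        labels = sorted(set(valid))
    index = {kmer: i for i, kmer in enumerate(labels)}
    counts = np.zeros(len(labels))
    for w in valid:
        counts[index[w]] += 1.0
    if config.count_mode == "relative" and valid:
        counts /= len(valid)
    return counts


def count_adjacency(windows: list[str]) -> dict[tuple[str, str], float]:
    """Undirected co-occurrence weights of consecutive contiguous windows.

    Each consecutive pair with both windows valid increments the weight of the
    edge between their k-mer identities (keys sorted lexicographically;
    self-loops allowed). Total weight equals the number of valid pairs.
    """
    edges: dict[tuple[str, str], float] = {}
    for a, b in zip(windows, windows[1:]):
        if _is_valid_window(a) and _is_valid_window(b):
            key = (a, b) if a <= b else (b, a)
            edges[key] = edges.get(key, 0.0) + 1.0
    return edges


def build_sequence_feature_graph(
    seq: LabeledSequence, config: EncoderConfig
) -> SequenceFeatureGraph:
    """Encode one labeled sequence as a sequence feature graph.

    Node features pool contiguous and gapped window counts; edges come from
    contiguous-window adjacency only (gapped matches have no well-defined
    successor). Sequences shorter than k + d − 1 may yield empty graphs; a
    warning is logged when no window fits at all.
    """
    contiguous = extract_contiguous_kmers(seq.bases, config.k)
    gapped = (
        extract_gapped_kmers(seq.bases, config.k, config.d)
        if config.d >= 2 and config.k >= 2
        else []
    )
    pooled = contiguous + gapped
    if not contiguous:
        logger.warning(
            "sequence %s (length %d) is shorter than k=%d: empty graph",
            seq.id, len(seq.bases), config.k,
        )

    node_features = count_node_frequencies(pooled, config)
    if config.node_universe == "full":
        labels = full_kmer_universe(config.k)
    else:
        labels = sorted({w for w in pooled if _is_valid_window(w)})
    index = {kmer: i for i, kmer in enumerate(labels)}

    edges = {
        (index[a], index[b]): w for (a, b), w in count_adjacency(contiguous).items()
    }
    return SequenceFeatureGraph(
        kmer_labels=labels,
        node_features=node_features,
        edges=edges,
        n_windows=max(0, len(seq.bases) - config.k + 1),
        sequence_id=seq.id,
        label=seq.label,
    )


def render_gapped_pattern(k: int, d: int, junction: int) -> str:
    """Wildcard rendering of a gapped window, e.g. (k=3, d=3, junction=2) -> 'NN**N'.

    ``junction`` counts informative bases before the gap (1 <= junction <= k−1);
    the gap holds d−1 wildcard positions. Informative slots print as 'N'.
    """
    if not 1 <= junction <= k - 1:
        raise ValueError(f"junction must be in [1, {k - 1}], got {junction}")
    return "N" * junction + "*" * (d - 1) + "N" * (k - junction)


def render_gapped_match(bases: str, d: int, junction: int) -> str:
    """Render the informative bases of one gapped match with its wildcards.

    ``bases`` are the k informative bases; e.g. ('GTA', d=3, junction=2) ->
    'GT**A', the canonical written form of a gapped 3-mer with a 2-position gap.
    """
    k = len(bases)
    if not 1 <= junction <= k - 1:
        raise ValueError(f"junction must be in [1, {k - 1}], got {junction}")
    return bases[:junction] + "*" * (d - 1) + bases[junction:]


def write_graph_tsv(graph: SequenceFeatureGraph, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Serialize one graph as a node table (kmer, feature) and an edge list."""
    with open(nodes_path, "w") as fh:
        fh.write("kmer\tfeature\n")
        for kmer, feat in zip(graph.kmer_labels, graph.node_features):
            fh.write(f"{kmer}\t{feat:.10g}\n")
    with open(edges_path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for (i, j), w in sorted(graph.edges.items()):
            fh.write(f"{graph.kmer_labels[i]}\t{graph.kmer_labels[j]}\t{w:.10g}\n")
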