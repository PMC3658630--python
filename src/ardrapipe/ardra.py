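"""In-silico ARDRA (amplified ribosomal DNA restriction analysis).

The wet-lab workflow this module reproduces computationally: PCR-amplify the
16S rRNA gene with universal primers, digest the amplicon with a 4-cutter
restriction enzyme (HaeIII, recognising GGCC and cutting bluntly GG^CC), run
the fragments on a polyacrylamide gel, and group clones whose band patterns
match into OTU families via Dice similarity and UPGMA clustering.

Here the gel is modelled directly from fragment lengths: fragments shorter
than a detection floor are invisible, and fragments whose lengths are closer
than a tolerance on the log10 scale co-migrate into a single band.  Band
patterns are presence/absence sets; intensity is not modelled.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .synthetic_data import FORWARD_PRIMER, REVERSE_PRIMER

__all__ = [
    "AmpliconNotFoundError",
    "PrimerPair",
    "FragmentSet",
    "BandPattern",
    "DistanceMatrix",
    "Dendrogram",
    "DendrogramNode",
    "OTUAssignment",
    "DEFAULT_PRIMERS",
    "iupac_to_regex",
    "reverse_complement",
    "find_amplicon",
    "digest",
    "to_band_pattern",
    "dice_similarity",
    "distance_matrix_from_patterns",
    "upgma",
    "assign_otus",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class AmpliconNotFoundError(ValueError):
    """No valid forward/reverse primer pair found in a template."""


@dataclass(frozen=True)
class PrimerPair:
    """A PCR primer pair; both primers written 5'->3' on their own strand."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, p in (("forward", self.forward), ("reverse", self.reverse)):
            if not p:
                raise ValueError(f"{name} primer is empty")
            bad = set(p.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC symbols {bad}")


DEFAULT_PRIMERS = PrimerPair(forward=FORWARD_PRIMER, reverse=REVERSE_PRIMER)


def reverse_complement(seq: str) -> str:
    """Reverse complement, honouring IUPAC degeneracy codes."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq.upper()))


def iupac_to_regex(primer: str) -> str:
    """Compile an IUPAC-degenerate primer into a character-class regex."""
    parts = []
    for c in primer.upper():
        opts = IUPAC[c]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def find_amplicon(sequence: str, primers: PrimerPair = DEFAULT_PRIMERS) -> str:
    """Extract the primer-bounded amplicon from a template.

    The forward primer is matched directly (5'-most match wins, mimicking the
    dominant PCR product); the reverse primer is matched as its reverse
    complement on the given strand, taking the first site that starts at or
    after the end of the forward site.  The returned amplicon includes both
    primer-binding sites.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("template sequence must be over {A,C,G,T}")
    fwd = re.search(iupac_to_regex(primers.forward), seq)
    rev_pat = re.compile(iupac_to_regex(reverse_complement(primers.reverse)))
    if fwd is None:
        raise AmpliconNotFoundError("forward primer site not found")
    rev = rev_pat.search(seq, fwd.end())
    if rev is None:
        if rev_pat.search(seq) is not None:
            raise AmpliconNotFoundError(
                "reverse primer site lies before the forward site")
        raise AmpliconNotFoundError("reverse primer site not found")
    return seq[fwd.start():rev.end()]


@dataclass(frozen=True)
class FragmentSet:
    """Restriction fragments of one amplicon, in 5'->3' order."""

    parent_len: int
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(l < 1 for l in self.fragment_lengths):
            raise ValueError("all fragment lengths must be >= 1")
        if sum(self.fragment_lengths) != self.parent_len:
            raise ValueError("fragment lengths must sum to the parent length")


def digest(sequence: str, recognition_site: str = "GGCC",
           cut_offset: int = 2) -> FragmentSet:
    """Digest a sequence at every occurrence of a restriction site.

    ``cut_offset`` is the position within the site after which the cut is
    made (HaeIII: GG^CC, offset 2).  Overlapping site occurrences are all
    honoured (the scan advances one base at a time).  Fragment lengths sum
    to the input length by construction.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot digest an empty sequence")
    site = recognition_site.upper()
    if set(site) - set("ACGT"):
        raise ValueError("recognition site must be non-degenerate (A/C/G/T)")
    if not 0 <= cut_offset <= len(site):
        raise ValueError(
            f"cut_offset must be in [0, {len(site)}], got {cut_offset}")
    cuts = sorted({
        i + cut_offset
        for i in range(len(seq) - len(site) + 1)
        if seq.startswith(site, i)
        if 0 < i + cut_offset < len(seq)
    })
    bounds = [0, *cuts, len(seq)]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return FragmentSet(parent_len=len(seq), fragment_lengths=frags)


@dataclass(frozen=True)
class BandPattern:
    """Presence/absence band fingerprint of one digested clone.

    Bands are identified by the smallest fragment length in their log10 bin,
    so identical fragment sets always yield identical patterns.  The gel
    parameters travel with the pattern; patterns produced under different
    parameters are not comparable.
    """

    bands: frozenset[int]
    min_detectable_len: int = 60
    log_tolerance: float = 0.01

    @property
    def params(self) -> tuple[int, float]:
        return (self.min_detectable_len, self.log_tolerance)


def to_band_pattern(fragments: FragmentSet, min_detectable_len: int = 60,
                    log_tolerance: float = 0.01) -> BandPattern:
    """Model the gel lane: drop undetectable fragments, merge co-migrants.

    Fragments shorter than ``min_detectable_len`` run off / are invisible.
    Remaining lengths are binned greedily in ascending order on the log10
    scale: a fragment joins the current band while its log10 length is
    within ``log_tolerance`` of the band's anchor (smallest member).  An
    empty pattern is legal.
    """
    if log_tolerance <= 0:
        raise ValueError(f"log_tolerance must be > 0, got {log_tolerance}")
    visible = sorted(l for l in fragments.fragment_lengths
                     if l >= min_detectable_len)
    bands: set[int] = set()
    anchor: int | None = None
    for l in visible:
        if anchor is None or np.log10(l) - np.log10(anchor) > log_tolerance:
            anchor = l
            bands.add(anchor)
    return BandPattern(bands=frozenset(bands),
                       min_detectable_len=min_detectable_len,
                       log_tolerance=log_tolerance)


def dice_similarity(p1: BandPattern, p2: BandPattern) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|) between two band patterns.

    Two empty patterns (no detectable bands at all) are defined as identical
    (similarity 1) with a warning, since there is no signal to compare.
    """
    if p1.params != p2.params:
        raise ValueError("band patterns built with different gel parameters")
    if not p1.bands and not p2.bands:
        warnings.warn("comparing two empty band patterns; defining "
                      "similarity as 1.0", stacklevel=2)
        return 1.0
    shared = len(p1.bands & p2.bands)
    return 2.0 * shared / (len(p1.bands) + len(p2.bands))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix (1 - Dice similarity) over labelled items."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        ia, ib = self.labels.index(a), self.labels.index(b)
        return float(self.values[ia, ib])


def distance_matrix_from_patterns(
        patterns: Mapping[str, BandPattern]) -> DistanceMatrix:
    """Pairwise 1 - Dice distances, labels sorted lexicographically."""
    labels = tuple(sorted(patterns))
    n = len(labels)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = 1.0 - dice_similarity(patterns[labels[i]],
                                                      patterns[labels[j]])
    return DistanceMatrix(labels=labels, values=v)


@dataclass
class DendrogramNode:
    """A node of a rooted UPGMA tree; leaves have height 0."""

    height: float
    label: str | None = None            # leaf label
    children: tuple["DendrogramNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Dendrogram:
    """Ultrametric UPGMA dendrogram over labelled leaves."""

    root: DendrogramNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def to_newick(self) -> str:
        """Newick string with branch lengths = height differences, so
        leaf-to-leaf patristic distance equals twice the join height."""
        def fmt(node: DendrogramNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        if self.root.is_leaf:
            return f"{self.root.label}:0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def cut(self, height: float) -> list[list[str]]:
        """Clusters obtained by cutting the tree at the given height: members
        of any subtree whose root height is <= height (plus tolerance)."""
        clusters: list[list[str]] = []

        def walk(node: DendrogramNode) -> None:
            if node.height <= height + 1e-12:
                clusters.append(node.leaves())
            else:
                for c in node.children:
                    walk(c)

        walk(self.root)
        return clusters


def upgma(d: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    At each step the closest pair of clusters is merged at height
    distance/2; the distance from the merged cluster to any other is the
    size-weighted mean of the members' distances (equivalently, the mean of
    all original pairwise distances across the two clusters).  Ties are
    broken by the lexicographically smallest pair of cluster labels, where a
    cluster is labelled by its smallest member label.
    """
    n = len(d.labels)
    if n < 2:
        raise ValueError("UPGMA needs at least 2 leaves")
    # cluster id -> (label, size, node); label = smallest member leaf label
    clusters: dict[str, tuple[int, DendrogramNode]] = {
        lab: (1, DendrogramNode(height=0.0, label=lab)) for lab in d.labels
    }
    dist: dict[frozenset[str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((d.labels[i], d.labels[j]))] = float(
                d.values[i, j])

    while len(clusters) > 1:
        best = min(
            ((dist[frozenset((a, b))], a, b)
             for i, a in enumerate(sorted(clusters))
             for b in sorted(clusters)[i + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dmin, a, b = best
        sa, node_a = clusters.pop(a)
        sb, node_b = clusters.pop(b)
        new_label = min(a, b)
        new_node = DendrogramNode(height=dmin / 2.0,
                                  children=(node_a, node_b))
        for other in clusters:
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((new_label, other))] = (sa * da + sb * db) / (sa + sb)
        dist.pop(frozenset((a, b)), None)
        clusters[new_label] = (sa + sb, new_node)

    (_, root), = clusters.values()
    return Dendrogram(root=root)


@dataclass(frozen=True)
class OTUAssignment:
    """Clone -> OTU map with the mode and threshold that produced it."""

    assignments: Mapping[str, str]
    mode: str
    threshold: float

    def otus(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for clone, otu in self.assignments.items():
            out.setdefault(otu, []).append(clone)
        for members in out.values():
            members.sort()
        return out

    @property
    def n_otus(self) -> int:
        return len(set(self.assignments.values()))


def _name_otus(groups: Iterable[Iterable[str]], mode: str,
               threshold: float) -> OTUAssignment:
    ordered = sorted((sorted(g) for g in groups), key=lambda g: g[0])
    width = max(2, len(str(len(ordered))))
    assignments = {
        clone: f"OTU{i + 1:0{width}d}"
        for i, members in enumerate(ordered) for clone in members
    }
    return OTUAssignment(assignments=assignments, mode=mode,
                         threshold=threshold)


def assign_otus(patterns: Mapping[str, BandPattern], mode: str = "exact",
                threshold: float = 1.0) -> OTUAssignment:
    """Group clones into OTU families from their band patterns.

    ``exact`` mode (default, parameter-free): an OTU is an equivalence class
    of identical band sets — the in-silico analogue of calling two gel lanes
    the same pattern.  ``cut`` mode: build the UPGMA dendrogram on 1 - Dice
    distances and cut it at height (1 - threshold)/2; each cluster is an
    OTU.  OTU ids are assigned deterministically, ordered by each family's
    smallest clone id.
    """
    if not patterns:
        raise ValueError("no band patterns to assign")
    params = {p.params for p in patterns.values()}
    if len(params) > 1:
        raise ValueError("band patterns built with different gel parameters")
    if mode == "exact":
        groups: dict[frozenset[int], list[str]] = {}
        for clone, pat in patterns.items():
            groups.setdefault(pat.bands, []).append(clone)
        return _name_otus(groups.values(), mode, threshold)
    if mode == "cut":
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {threshold}")
        if len(patterns) == 1:
            return _name_otus([list(patterns)], mode, threshold)
        dm = distance_matrix_from_patterns(patterns)
        tree = upgma(dm)
        return _name_otus(tree.cut((1.0 - threshold) / 2.0), mode, threshold)
    raise ValueError(f"unknown OTU mode {mode!r} (expected 'exact' or 'cut')")
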