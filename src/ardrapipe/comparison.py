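"""Between-library comparisons: Sorensen similarity, Venn tallies of shared
OTUs, class-level composition profiles and trends along the gut axis.

The Sorensen index Cs = 2j/(a+b) is incidence-based: j is the number of OTUs
present in both libraries, a and b the library richness values.  It is
reported in percent (100 = identical OTU membership, 0 = no OTU in common).
Sorensen is not a metric — no triangle inequality is implied or checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import OTUTable

__all__ = [
    "sorensen",
    "sorensen_matrix",
    "venn_counts",
    "class_composition",
    "axis_trend",
    "TrendSummary",
    "split_library_label",
]


def split_library_label(label: str) -> tuple[str, str]:
    """Split a ``"<fish>|<compartment>"`` library label."""
    fish, _, comp = label.partition("|")
    if not comp:
        raise ValueError(f"library label {label!r} is not 'fish|compartment'")
    return fish, comp


def sorensen(otus_a: Iterable[str], otus_b: Iterable[str],
             percent: bool = True) -> float:
    """Sorensen similarity Cs = 2j/(a+b) between two OTU incidence sets."""
    a, b = set(otus_a), set(otus_b)
    if not a and not b:
        raise ValueError("Sorensen similarity is undefined for two empty sets")
    cs = 2.0 * len(a & b) / (len(a) + len(b))
    return 100.0 * cs if percent else cs


def sorensen_matrix(table: OTUTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise Sorensen similarities between the table's libraries.

    Returns ``(cs_percent, shared_j)``: a symmetric percent matrix with a
    diagonal of 100, and the integer matrix of shared-OTU counts j.
    """
    libs = table.libraries
    inc = {lib: table.incidence(lib) for lib in libs}
    cs = pd.DataFrame(100.0, index=libs, columns=libs)
    j = pd.DataFrame(0, index=libs, columns=libs, dtype=int)
    for lib in libs:
        j.loc[lib, lib] = len(inc[lib])
    for a, b in combinations(libs, 2):
        shared = len(inc[a] & inc[b])
        val = sorensen(inc[a], inc[b])
        cs.loc[a, b] = cs.loc[b, a] = val
        j.loc[a, b] = j.loc[b, a] = shared
    return cs, j


def venn_counts(sets: Mapping[str, Iterable[str]]) -> dict[str, int]:
    """Exact Venn region counts for 2 or 3 labelled OTU sets.

    Regions are keyed by their membership signature, e.g. ``"IB"`` (only in
    IB), ``"IB&MI"``, ``"IB&MI&PI"``.  Region counts partition the union.
    """
    labels = list(sets)
    if len(labels) not in (2, 3):
        raise ValueError(f"venn_counts supports 2 or 3 sets, got {len(labels)}")
    as_sets = {k: set(v) for k, v in sets.items()}
    universe = set().union(*as_sets.values())
    out: dict[str, int] = {}
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            out["&".join(combo)] = 0
    for item in universe:
        membership = [lab for lab in labels if item in as_sets[lab]]
        out["&".join(membership)] += 1
    return out


def class_composition(table: OTUTable,
                      taxonomy: Mapping[str, str]) -> pd.DataFrame:
    """Percent of clones per bacterial class in every library.

    ``taxonomy`` maps OTU id -> class label (``"unclassified"`` is a valid
    label).  Classes absent from a library are reported as 0; per-library
    percentages sum to 100.
    """
    missing = [o for o in table.otu_ids if o not in taxonomy]
    if missing:
        raise KeyError(f"OTUs missing from the taxonomy map: {missing}")
    classes = sorted({taxonomy[o] for o in table.otu_ids})
    rows = {}
    for lib in table.libraries:
        row = table.counts.loc[lib]
        total = row.sum()
        per_class = {cls: 0.0 for cls in classes}
        for otu, n in row.items():
            per_class[taxonomy[otu]] += float(n)
        rows[lib] = {cls: 100.0 * v / total for cls, v in per_class.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")[classes]
    df.index.name = "library"
    return df


@dataclass(frozen=True)
class TrendSummary:
    """Per-fish abundance trajectory of one class along the gut axis."""

    class_label: str
    compartment_order: tuple[str, ...]
    values: pd.DataFrame            # fish x compartment, percent
    nonincreasing: dict[str, bool]  # per fish, monotone weak
    nondecreasing: dict[str, bool]
    strictly_decreasing: dict[str, bool]
    strictly_increasing: dict[str, bool]

    @property
    def all_nonincreasing(self) -> bool:
        return all(self.nonincreasing.values())

    @property
    def all_nondecreasing(self) -> bool:
        return all(self.nondecreasing.values())


def axis_trend(profile: pd.DataFrame, class_label: str,
               compartment_order: Sequence[str] = ("IB", "MI", "PI"),
               ) -> TrendSummary:
    """Order one class's abundances along the gut axis and flag monotonicity.

    ``profile`` is the output of :func:`class_composition` (libraries x
    classes, percent).  Every fish must have a value for every compartment
    in ``compartment_order``.  Weak flags allow ties; strict flags do not.
    A constant trajectory is weakly monotone in both directions.
    """
    if class_label not in profile.columns:
        raise KeyError(f"class {class_label!r} not in the profile")
    comp_order = tuple(compartment_order)
    cells: dict[str, dict[str, float]] = {}
    for lib in profile.index:
        fish, comp = split_library_label(lib)
        cells.setdefault(fish, {})[comp] = float(profile.loc[lib, class_label])
    for fish, comps in cells.items():
        missing = [c for c in comp_order if c not in comps]
        if missing:
            raise ValueError(
                f"fish {fish!r} is missing compartments {missing}")
    fish_ids = sorted(cells)
    values = pd.DataFrame(
        [[cells[f][c] for c in comp_order] for f in fish_ids],
        index=fish_ids, columns=list(comp_order))
    values.index.name = "fish"
    diffs = {f: np.diff(values.loc[f].values) for f in fish_ids}
    return TrendSummary(
        class_label=class_label,
        compartment_order=comp_order,
        values=values,
        nonincreasing={f: bool((d <= 0).all()) for f, d in diffs.items()},
        nondecreasing={f: bool((d >= 0).all()) for f, d in diffs.items()},
        strictly_decreasing={f: bool((d < 0).all()) for f, d in diffs.items()},
        strictly_increasing={f: bool((d > 0).all()) for f, d in diffs.items()},
    )
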