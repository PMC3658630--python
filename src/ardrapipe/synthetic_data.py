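"""Synthetic clone-library generator.

Builds ground-truth bacterial communities laid out on a fish x gut-compartment
grid, gives every taxon a 16S-like reference sequence carrying the universal
primer-binding sites, and draws clone libraries from each community by
multinomial sampling.  The generator emulates the sampling design of a small
clone-library survey of the zebrafish intestine: three fish, three gut
compartments (intestinal bulb IB, mid-intestine MI, posterior intestine PI),
roughly 63 clones per library, and class-level composition gradients along
the proximal-distal axis (one class rising, one falling).

Everything downstream of this module (amplicon extraction, digestion, OTU
calling, diversity statistics) can therefore be exercised end-to-end with a
known ground truth and no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "TaxonProfile",
    "Community",
    "StudyDesign",
    "CloneLibrary",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "DEFAULT_COMPARTMENTS",
    "DEFAULT_GRADIENT",
    "generate_community",
    "generate_reference_sequences",
    "sample_clone_library",
    "generate_gradient_study",
    "sample_study",
    "default_gut_design",
]

#: Universal bacterial 16S primers; forward 27f and the ~1.5 kb reverse
#: primer, both written 5'->3' on their own strand (IUPAC codes allowed).
FORWARD_PRIMER = "AGAGTTTGATCMTGGCTCAG"
REVERSE_PRIMER = "TACGGYTACCTTGTTACGACTT"

#: Proximal -> distal order of the gut compartments.
DEFAULT_COMPARTMENTS = ("IB", "MI", "PI")

#: Class-level abundance trajectories (IB, MI, PI) for the default
#: gradient study: Bacilli falling and Gammaproteobacteria rising along the
#: gut axis, the two dominant contrasting classes of the study design.
DEFAULT_GRADIENT: dict[str, tuple[float, float, float]] = {
    "Bacilli": (0.50, 0.20, 0.03),
    "Gammaproteobacteria": (0.17, 0.40, 0.87),
}

#: Minor classes that absorb the abundance not claimed by the gradient spec.
DEFAULT_BACKGROUND_CLASSES = (
    "Actinobacteria",
    "Alphaproteobacteria",
    "Betaproteobacteria",
    "Fusobacteria",
)

# Fixed realization of degenerate primer bases used when *embedding* primer
# sites into reference sequences (M -> A, Y -> C).  Amplicon finding still
# matches the full degenerate pattern.
_DEGENERACY_REALIZATION = {"M": "A", "Y": "C", "R": "A", "W": "A", "S": "C",
                          "K": "G", "B": "C", "D": "A", "H": "A", "V": "A",
                          "N": "A"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _realize(primer: str) -> str:
    """Replace IUPAC degeneracies with one fixed unambiguous base."""
    return "".join(_DEGENERACY_REALIZATION.get(c, c) for c in primer)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TaxonProfile:
    """One ground-truth taxon: identity, class membership, abundance and
    (optionally) its reference sequence."""

    taxon_id: str
    class_label: str
    rel_abundance: float
    ref_sequence: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rel_abundance <= 1.0:
            raise ValueError(
                f"rel_abundance must be in [0, 1], got {self.rel_abundance}"
            )


@dataclass(frozen=True)
class Community:
    """An ordered collection of taxa whose relative abundances sum to one."""

    taxa: tuple[TaxonProfile, ...]

    def __post_init__(self) -> None:
        ids = [t.taxon_id for t in self.taxa]
        if len(ids) != len(set(ids)):
            raise ValueError("taxon_ids must be unique within a community")
        if self.taxa:
            total = sum(t.rel_abundance for t in self.taxa)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"abundances must sum to 1, got {total!r}")

    @property
    def abundances(self) -> np.ndarray:
        return np.array([t.rel_abundance for t in self.taxa])

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(t.taxon_id for t in self.taxa)

    def class_composition(self) -> dict[str, float]:
        """True relative abundance per class label."""
        out: dict[str, float] = {}
        for t in self.taxa:
            out[t.class_label] = out.get(t.class_label, 0.0) + t.rel_abundance
        return out


@dataclass(frozen=True)
class CloneLibrary:
    """Clones sampled from one (fish, compartment) community.

    ``clones`` is an ordered tuple of ``(clone_id, true_taxon_id, sequence)``.
    """

    fish_id: str
    compartment: str
    clones: tuple[tuple[str, str, str], ...]

    def __len__(self) -> int:
        return len(self.clones)


@dataclass(frozen=True)
class StudyDesign:
    """Fish x compartment grid of ground-truth communities.

    Compartment order is meaningful (proximal -> distal).
    """

    fish_ids: tuple[str, ...]
    compartments: tuple[str, ...]
    communities: Mapping[tuple[str, str], Community]
    library_sizes: Mapping[tuple[str, str], int]
    seed: int

    def __post_init__(self) -> None:
        for fish in self.fish_ids:
            for comp in self.compartments:
                if (fish, comp) not in self.communities:
                    raise ValueError(f"missing community for cell {(fish, comp)}")
                if (fish, comp) not in self.library_sizes:
                    raise ValueError(f"missing library size for cell {(fish, comp)}")

    def cells(self) -> list[tuple[str, str]]:
        return [(f, c) for f in self.fish_ids for c in self.compartments]


def _allocate_counts(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Largest-remainder allocation of ``total`` items to keys by fraction."""
    ssum = sum(fractions.values())
    if abs(ssum - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {ssum!r}")
    keys = list(fractions)
    raw = {k: fractions[k] * total for k in keys}
    counts = {k: int(math.floor(raw[k])) for k in keys}
    leftover = total - sum(counts.values())
    # distribute by largest fractional part, ties broken by input order
    order = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), keys.index(k)))
    for k in order[:leftover]:
        counts[k] += 1
    return counts


def _abundance_weights(s: int, model: str, rng: np.random.Generator, *,
                       k: float = 0.5, mu: float = 0.0,
                       sigma: float = 1.0) -> np.ndarray:
    if model == "geometric":
        if not 0.0 < k <= 1.0:
            raise ValueError(f"geometric ratio k must be in (0, 1], got {k}")
        w = k ** np.arange(s)
    elif model in ("lognormal", "log-normal"):
        if sigma < 0:
            raise ValueError(f"lognormal sigma must be >= 0, got {sigma}")
        w = np.sort(rng.lognormal(mean=mu, sigma=sigma, size=s))[::-1]
    elif model == "uniform":
        w = np.ones(s)
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    return w / w.sum()


def generate_community(s_true: int, abundance_model: str = "geometric", *,
                       k: float = 0.5, mu: float = 0.0, sigma: float = 1.0,
                       class_assignment: Mapping[str, float] | None = None,
                       taxon_prefix: str = "T", seed: int = 0) -> Community:
    """Draw a ground-truth community of ``s_true`` taxa.

    Parameters
    ----------
    s_true
        Number of taxa (true richness).
    abundance_model
        ``"geometric"`` (ranked series ``k**i``, the default because clone
        libraries in small gut surveys tend to be dominated by one taxon per
        class), ``"lognormal"`` (skewed species-abundance distribution with
        parameters ``mu``/``sigma``) or ``"uniform"``.
    class_assignment
        Mapping class label -> fraction of taxa; fractions must sum to 1.
        Defaults to a single ``"Unclassified"`` class.
    seed
        Seed for the abundance draw; the output is deterministic in
        (parameters, seed).
    """
    if s_true < 1:
        raise ValueError(f"s_true must be >= 1, got {s_true}")
    rng = np.random.default_rng(seed)
    weights = _abundance_weights(s_true, abundance_model, rng,
                                 k=k, mu=mu, sigma=sigma)
    if class_assignment is None:
        class_assignment = {"Unclassified": 1.0}
    counts = _allocate_counts(class_assignment, s_true)
    labels: list[str] = []
    for cls in class_assignment:
        labels.extend([cls] * counts[cls])
    width = max(2, len(str(s_true)))
    taxa = tuple(
        TaxonProfile(taxon_id=f"{taxon_prefix}{i + 1:0{width}d}",
                     class_label=labels[i], rel_abundance=float(weights[i]))
        for i in range(s_true)
    )
    return Community(taxa=taxa)


def _mutation_rate(divergence: float) -> float:
    """Per-site mutation probability giving the requested expected *pairwise*
    divergence between two sequences mutated independently from one ancestor.

    Two independently mutated copies differ at a site with probability
    ``2m(1-m) + (2/3)m**2``; solving for ``m`` yields the rate used here.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1], got {divergence}")
    if divergence == 0.0:
        return 0.0
    disc = 4.0 - (16.0 / 3.0) * divergence
    if disc < 0:  # pairwise divergence beyond what independent mutation can reach
        return 1.0
    return (2.0 - math.sqrt(disc)) / (8.0 / 3.0)


def generate_reference_sequences(community: Community, amplicon_len: int = 1445,
                                 between_taxon_divergence: float = 0.10,
                                 seed: int = 0) -> Community:
    """Attach 16S-like reference sequences to every taxon of a community.

    Each sequence is ``amplicon_len`` long and consists of the forward primer
    (degenerate positions fixed to one realization), a taxon-specific core
    evolved from a common random ancestor, and the reverse-complemented
    reverse primer site.  The per-site mutation rate is calibrated so that
    two taxa differ at ~``between_taxon_divergence`` of the core positions.
    """
    fwd = _realize(FORWARD_PRIMER)
    rev_site = _revcomp(_realize(REVERSE_PRIMER))
    core_len = amplicon_len - len(fwd) - len(rev_site)
    if core_len < 1:
        raise ValueError(
            f"amplicon_len={amplicon_len} too short to host both primers "
            f"({len(fwd)} + {len(rev_site)} bp) plus a core"
        )
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, 4, size=core_len)
    m = _mutation_rate(between_taxon_divergence)
    taxa = []
    for t in community.taxa:
        core = ancestor.copy()
        if m > 0:
            hit = rng.random(core_len) < m
            # substitute to one of the three *other* bases
            core[hit] = (core[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        core_str = _BASES[core].tobytes().decode("ascii")
        taxa.append(replace(t, ref_sequence=fwd + core_str + rev_site))
    return Community(taxa=tuple(taxa))


def sample_clone_library(community: Community, n_clones: int, fish_id: str,
                         compartment: str, seed: int = 0) -> CloneLibrary:
    """Draw ``n_clones`` clones i.i.d. from the community abundance vector.

    Each clone copies its taxon's reference sequence verbatim (no PCR error
    model).  Reproducible for a fixed seed.
    """
    if not community.taxa:
        raise ValueError("cannot sample from an empty community")
    if n_clones < 0:
        raise ValueError(f"n_clones must be >= 0, got {n_clones}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(community.taxa), size=n_clones,
                     p=community.abundances)
    clones = []
    for i, j in enumerate(idx):
        t = community.taxa[int(j)]
        clone_id = f"{fish_id}_{compartment}_c{i + 1:03d}"
        clones.append((clone_id, t.taxon_id, t.ref_sequence or ""))
    return CloneLibrary(fish_id=fish_id, compartment=compartment,
                        clones=tuple(clones))


def generate_gradient_study(
    fish_ids: Sequence[str] = ("F1", "F2", "F3"),
    gradient_spec: Mapping[str, Sequence[float]] | None = None,
    s_true: int = 63,
    library_sizes: int | Mapping[tuple[str, str], int] = 63,
    seed: int = 0,
    *,
    compartments: Sequence[str] = DEFAULT_COMPARTMENTS,
    background_classes: Sequence[str] = DEFAULT_BACKGROUND_CLASSES,
    jitter_sigma: float = 0.1,
    within_class_k: float = 0.5,
    amplicon_len: int = 1445,
    between_taxon_divergence: float = 0.10,
) -> StudyDesign:
    """Build a fish x compartment study whose class compositions follow a
    per-compartment trajectory.

    ``gradient_spec`` maps class label -> one abundance value per compartment
    (defaults to :data:`DEFAULT_GRADIENT`).  Per compartment the specified
    values must sum to <= 1; the remainder is split equally among
    ``background_classes`` (held flat along the axis).  All cells share one
    taxon pool (with reference sequences generated once), so OTUs are
    comparable across libraries; only the class weights change.

    Fish-to-fish variability is modelled as one log-normal multiplicative
    factor per (fish, class), applied to the whole trajectory of that class
    and renormalized per compartment.  Because the factor is shared across
    compartments, it rescales but never reorders a class's trajectory within
    a fish.
    """
    fish_ids = tuple(fish_ids)
    compartments = tuple(compartments)
    if gradient_spec is None:
        gradient_spec = DEFAULT_GRADIENT
    gradient_spec = {c: tuple(float(v) for v in traj)
                     for c, traj in gradient_spec.items()}
    for cls, traj in gradient_spec.items():
        if len(traj) != len(compartments):
            raise ValueError(
                f"trajectory for {cls!r} has {len(traj)} values, "
                f"expected one per compartment ({len(compartments)})"
            )
    for ci, comp in enumerate(compartments):
        total = sum(traj[ci] for traj in gradient_spec.values())
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"gradient trajectories sum to {total} > 1 in compartment {comp}"
            )
    if jitter_sigma < 0:
        raise ValueError(f"jitter_sigma must be >= 0, got {jitter_sigma}")

    all_classes = list(gradient_spec) + [c for c in background_classes
                                         if c not in gradient_spec]
    # class trajectories incl. background remainder split equally
    n_bg = len(all_classes) - len(gradient_spec)
    traj: dict[str, list[float]] = {c: list(gradient_spec[c]) for c in gradient_spec}
    for c in all_classes[len(gradient_spec):]:
        traj[c] = []
    for ci in range(len(compartments)):
        remainder = 1.0 - sum(gradient_spec[c][ci] for c in gradient_spec)
        for c in all_classes[len(gradient_spec):]:
            traj[c].append(remainder / n_bg if n_bg else 0.0)

    # one shared taxon pool: taxa split equally across classes, geometric
    # ranked abundances within each class
    class_fracs = {c: 1.0 / len(all_classes) for c in all_classes}
    # fix float drift so fractions sum to exactly 1
    class_fracs[all_classes[-1]] = 1.0 - sum(
        class_fracs[c] for c in all_classes[:-1])
    n_per_class = _allocate_counts(class_fracs, s_true)

    ss = np.random.SeedSequence(seed)
    seq_seed, jitter_seed = ss.spawn(2)

    width = max(2, len(str(s_true)))
    taxa: list[TaxonProfile] = []
    within: dict[str, np.ndarray] = {}
    i = 0
    for cls in all_classes:
        n = n_per_class[cls]
        if n == 0:
            within[cls] = np.array([])
            continue
        w = within_class_k ** np.arange(n)
        within[cls] = w / w.sum()
        for j in range(n):
            taxa.append(TaxonProfile(taxon_id=f"T{i + 1:0{width}d}",
                                     class_label=cls, rel_abundance=0.0))
            i += 1

    # reference sequences generated once on a flat placeholder community
    flat = Community(tuple(
        replace(t, rel_abundance=1.0 / len(taxa)) for t in taxa))
    flat = generate_reference_sequences(
        flat, amplicon_len=amplicon_len,
        between_taxon_divergence=between_taxon_divergence,
        seed=int(seq_seed.generate_state(1)[0] % (2 ** 31)))
    pool = flat.taxa

    jit_rng = np.random.default_rng(jitter_seed)
    jitter = {
        (fish, cls): float(jit_rng.lognormal(0.0, jitter_sigma))
        if jitter_sigma > 0 else 1.0
        for fish in fish_ids for cls in all_classes
    }

    communities: dict[tuple[str, str], Community] = {}
    for fish in fish_ids:
        for ci, comp in enumerate(compartments):
            cw = np.array([traj[c][ci] * jitter[(fish, c)] for c in all_classes])
            if cw.sum() <= 0:
                raise ValueError(f"all class weights zero in cell {(fish, comp)}")
            cw = cw / cw.sum()
            ab: list[float] = []
            for cls_idx, cls in enumerate(all_classes):
                ab.extend(cw[cls_idx] * within[cls])
            ab_arr = np.array(ab)
            ab_arr = ab_arr / ab_arr.sum()
            communities[(fish, comp)] = Community(tuple(
                replace(t, rel_abundance=float(a))
                for t, a in zip(pool, ab_arr)))

    if isinstance(library_sizes, int):
        sizes = {(f, c): library_sizes for f in fish_ids for c in compartments}
    else:
        sizes = dict(library_sizes)
    return StudyDesign(fish_ids=fish_ids, compartments=compartments,
                       communities=communities, library_sizes=sizes, seed=seed)


def sample_study(design: StudyDesign) -> list[CloneLibrary]:
    """Sample one clone library per cell of the design.

    Per-cell seeds are spawned deterministically from the design seed, so the
    whole study is a pure function of (design parameters, seed).
    """
    ss = np.random.SeedSequence(design.seed).spawn(1)[0]
    cell_seeds = ss.spawn(len(design.cells()))
    out = []
    for (fish, comp), cs in zip(design.cells(), cell_seeds):
        out.append(sample_clone_library(
            design.communities[(fish, comp)],
            design.library_sizes[(fish, comp)],
            fish, comp, seed=int(cs.generate_state(1)[0] % (2 ** 31))))
    return out


def default_gut_design(seed: int = 0, **overrides) -> StudyDesign:
    """The default study: 3 fish x (IB, MI, PI) x 63 clones, 63 taxa, with
    Bacilli falling and Gammaproteobacteria rising along the gut axis."""
    return generate_gradient_study(seed=seed, **overrides)
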