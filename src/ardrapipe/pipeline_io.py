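"""Pipeline orchestration, file formats and configuration.

File conventions
----------------
* Clones travel as FASTA; the header encodes
  ``fish|compartment|clone_id|true_taxon_id`` ("|"-separated; the taxon
  field may be absent for real data of unknown origin).
* Every table is TSV (tab-separated, header row, UTF-8, "." decimal).
* Dendrograms are written as Newick with branch lengths equal to UPGMA
  height differences, so leaf-to-leaf patristic distance is twice the join
  height.
* Configuration is a flat-ish YAML file; the fully resolved configuration
  (all defaults filled in) is serialized into the output directory so every
  run is auditable and regenerable.

The end-to-end run is a pure function of (config, seed): simulate (optional)
-> amplicon extraction -> digestion -> band patterns -> OTU assignment ->
diversity -> comparisons -> repeated-measures statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .ardra import (PrimerPair, DEFAULT_PRIMERS, Dendrogram, assign_otus,
                    digest, distance_matrix_from_patterns, find_amplicon,
                    to_band_pattern, upgma)
from .comparison import (axis_trend, class_composition, sorensen_matrix,
                         split_library_label, venn_counts, TrendSummary)
from .diversity import OTUTable, diversity_report, rarefaction_curve
from .group_stats import arcsine_sqrt, rm_anova_with_tukey, AnovaResult
from .synthetic_data import (CloneLibrary, StudyDesign, generate_gradient_study,
                             sample_study, DEFAULT_GRADIENT)

__all__ = [
    "CloneRecord",
    "PipelineConfig",
    "RunReport",
    "read_clone_fasta",
    "write_clone_fasta",
    "read_otu_table",
    "write_otu_table",
    "write_newick",
    "run_pipeline",
]

log = logging.getLogger("ardrapipe")


@dataclass(frozen=True)
class CloneRecord:
    clone_id: str
    fish_id: str
    compartment: str
    sequence: str
    true_taxon_id: str | None = None

    @property
    def library(self) -> str:
        return f"{self.fish_id}|{self.compartment}"


def read_clone_fasta(path: str | Path) -> list[CloneRecord]:
    """Read clones from FASTA with ``fish|compartment|clone_id[|taxon]``
    headers.  Raises on an empty file, malformed headers or duplicate clone
    ids."""
    path = Path(path)
    records = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        parts = rec.description.split("|")
        if len(parts) < 3:
            raise ValueError(
                f"{path}: record {i + 1} ({rec.id!r}): header must be "
                "'fish|compartment|clone_id[|taxon]'")
        fish, comp, clone_id = parts[0], parts[1], parts[2]
        taxon = parts[3] if len(parts) > 3 else None
        if clone_id in seen:
            raise ValueError(f"{path}: duplicate clone id {clone_id!r}")
        seen.add(clone_id)
        records.append(CloneRecord(clone_id=clone_id, fish_id=fish,
                                   compartment=comp,
                                   sequence=str(rec.seq).upper(),
                                   true_taxon_id=taxon))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_clone_fasta(libraries: list[CloneLibrary] | list[CloneRecord],
                      path: str | Path) -> None:
    """Write clones as FASTA using the "|"-delimited header convention."""
    recs = []
    for item in libraries:
        if isinstance(item, CloneLibrary):
            for clone_id, taxon, seq in item.clones:
                header = f"{item.fish_id}|{item.compartment}|{clone_id}|{taxon}"
                recs.append(SeqRecord(Seq(seq), id=header, description=""))
        else:
            header = f"{item.fish_id}|{item.compartment}|{item.clone_id}"
            if item.true_taxon_id:
                header += f"|{item.true_taxon_id}"
            recs.append(SeqRecord(Seq(item.sequence), id=header,
                                  description=""))
    SeqIO.write(recs, str(path), "fasta")


def write_otu_table(table: OTUTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_otu_table(path: str | Path) -> OTUTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return OTUTable(counts=df)


def write_newick(dendrogram: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dendrogram.to_newick() + "\n")


# ---------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Synthetic study block; present when no input FASTA/table is given."""

    fish_ids: tuple[str, ...] = ("F1", "F2", "F3")
    s_true: int = 63
    clones_per_library: int = 63
    gradient: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {k: tuple(v)
                                 for k, v in DEFAULT_GRADIENT.items()})
    jitter_sigma: float = 0.1
    within_class_k: float = 0.5
    amplicon_len: int = 1445
    between_taxon_divergence: float = 0.10


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; every field has a default.

    Exactly one clone source must be present: an input FASTA, an input OTU
    table, or the simulation block (the default).
    """

    input_fasta: str | None = None
    input_otu_table: str | None = None
    taxonomy_tsv: str | None = None
    out_dir: str = "ardra_out"
    seed: int = 0
    # ARDRA parameters
    recognition_site: str = "GGCC"
    cut_offset: int = 2
    min_detectable_len: int = 60
    log_tolerance: float = 0.01
    otu_mode: str = "exact"
    otu_threshold: float = 1.0
    # diversity parameters
    chao_variant: str = "classic"
    evenness_base: float = math.e
    # group statistics
    alpha: float = 0.05
    proportion_transform: str = "none"   # "none" | "arcsine"
    simulation: SimulationConfig | None = field(
        default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        sources = [self.input_fasta is not None,
                   self.input_otu_table is not None,
                   self.simulation is not None]
        if not any(sources):
            raise ValueError("config needs an input path or a simulation block")
        if self.proportion_transform not in ("none", "arcsine"):
            raise ValueError(
                f"unknown proportion_transform {self.proportion_transform!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", "default")
        cfg = cls(**raw, simulation=None) if sim is None else cls(
            **raw, simulation=SimulationConfig() if sim == "default"
            else SimulationConfig(**{
                k: (tuple(v) if k == "fish_ids" else
                    {c: tuple(t) for c, t in v.items()} if k == "gradient"
                    else v)
                for k, v in sim.items()}))
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        # YAML-friendly plain types
        if d.get("simulation"):
            sim = d["simulation"]
            sim["fish_ids"] = list(sim["fish_ids"])
            sim["gradient"] = {k: list(v) for k, v in sim["gradient"].items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# run report

@dataclass
class RunReport:
    """All tables produced by one pipeline run, plus provenance."""

    otu_table: OTUTable
    clone_otus: pd.DataFrame
    diversity: pd.DataFrame
    rarefaction: pd.DataFrame
    sorensen_pct: pd.DataFrame
    sorensen_shared: pd.DataFrame
    venn_compartments: dict[str, int] | None
    venn_fish: dict[str, int] | None
    composition: pd.DataFrame
    trends: dict[str, TrendSummary]
    anova: dict[str, AnovaResult]
    provenance: dict[str, Any]

    def within_fish_sorensen(self) -> pd.DataFrame:
        """Long table of Sorensen values between compartments of one fish."""
        rows = []
        libs = list(self.sorensen_pct.index)
        for i, a in enumerate(libs):
            fa, ca = split_library_label(a)
            for b in libs[i + 1:]:
                fb, cb = split_library_label(b)
                if fa == fb:
                    rows.append({"fish": fa, "pair": f"{ca}-{cb}",
                                 "comp_a": ca, "comp_b": cb,
                                 "cs_pct": float(self.sorensen_pct.loc[a, b]),
                                 "shared_j": int(self.sorensen_shared.loc[a, b])})
        return pd.DataFrame(rows)

    def between_fish_sorensen(self) -> pd.DataFrame:
        """Long table of Sorensen values for the same compartment of two fish."""
        rows = []
        libs = list(self.sorensen_pct.index)
        for i, a in enumerate(libs):
            fa, ca = split_library_label(a)
            for b in libs[i + 1:]:
                fb, cb = split_library_label(b)
                if fa != fb and ca == cb:
                    rows.append({"compartment": ca, "pair": f"{fa}-{fb}",
                                 "cs_pct": float(self.sorensen_pct.loc[a, b]),
                                 "shared_j": int(self.sorensen_shared.loc[a, b])})
        return pd.DataFrame(rows)


def _process_clones(records: list[CloneRecord], config: PipelineConfig,
                    primers: PrimerPair = DEFAULT_PRIMERS):
    """Amplicon -> digest -> band pattern for every clone.

    Identical sequences share one computation (clones of one taxon are
    verbatim copies), which keeps large simulated studies cheap.
    """
    cache: dict[str, tuple] = {}
    patterns = {}
    fragments = {}
    for rec in records:
        if rec.sequence not in cache:
            try:
                amp = find_amplicon(rec.sequence, primers)
                frag = digest(amp, config.recognition_site, config.cut_offset)
                pat = to_band_pattern(frag, config.min_detectable_len,
                                      config.log_tolerance)
            except ValueError as err:
                raise RuntimeError(
                    f"ARDRA stage failed for clone {rec.clone_id!r} "
                    f"(library {rec.library}): {err}") from err
            cache[rec.sequence] = (frag, pat)
        frag, pat = cache[rec.sequence]
        fragments[rec.clone_id] = frag
        patterns[rec.clone_id] = pat
    return patterns, fragments


def _otu_taxonomy(clone_otus: pd.DataFrame,
                  taxon_classes: Mapping[str, str] | None) -> dict[str, str]:
    """Class label per OTU: majority class of its member clones' true taxa
    (ties broken alphabetically); "unclassified" when no taxonomy is known."""
    out: dict[str, str] = {}
    for otu, group in clone_otus.groupby("otu"):
        if taxon_classes is None or group["true_taxon"].isna().all():
            out[str(otu)] = "unclassified"
            continue
        classes = [taxon_classes.get(t, "unclassified")
                   for t in group["true_taxon"].dropna()]
        vc = pd.Series(classes).value_counts()
        top = vc[vc == vc.max()].index.sort_values()[0]
        out[str(otu)] = str(top)
    return out


def run_pipeline(config: PipelineConfig, write: bool = True) -> RunReport:
    """Execute the full analysis and (optionally) write every artifact.

    Returns a :class:`RunReport`; with ``write=True`` all tables are also
    written as TSV under ``config.out_dir`` together with the resolved
    configuration, the clone FASTA (for simulated runs) and the OTU-level
    UPGMA dendrogram as Newick.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "resolved_config.yaml")
    log.info("pipeline start: config hash %s, seed %d",
             config.content_hash(), config.seed)

    taxon_classes: dict[str, str] | None = None
    design: StudyDesign | None = None

    if config.input_otu_table is not None:
        records = None
        table = read_otu_table(config.input_otu_table)
        clone_otus = pd.DataFrame(
            columns=["clone_id", "library", "otu", "true_taxon"])
    else:
        if config.simulation is not None and config.input_fasta is None:
            sim = config.simulation
            design = generate_gradient_study(
                fish_ids=sim.fish_ids,
                gradient_spec=sim.gradient,
                s_true=sim.s_true,
                library_sizes=sim.clones_per_library,
                seed=config.seed,
                jitter_sigma=sim.jitter_sigma,
                within_class_k=sim.within_class_k,
                amplicon_len=sim.amplicon_len,
                between_taxon_divergence=sim.between_taxon_divergence,
            )
            libraries = sample_study(design)
            records = [
                CloneRecord(clone_id=cid, fish_id=lib.fish_id,
                            compartment=lib.compartment, sequence=seq,
                            true_taxon_id=taxon)
                for lib in libraries for cid, taxon, seq in lib.clones
            ]
            any_comm = next(iter(design.communities.values()))
            taxon_classes = {t.taxon_id: t.class_label for t in any_comm.taxa}
            if write:
                write_clone_fasta(libraries, out / "clones.fasta")
                _write_ground_truth(design, out / "ground_truth.tsv")
        else:
            records = read_clone_fasta(config.input_fasta)
            if config.taxonomy_tsv:
                tax = pd.read_csv(config.taxonomy_tsv, sep="\t")
                taxon_classes = dict(zip(tax.iloc[:, 0].astype(str),
                                         tax.iloc[:, 1].astype(str)))

        patterns, fragments = _process_clones(records, config)
        assignment = assign_otus(patterns, mode=config.otu_mode,
                                 threshold=config.otu_threshold)
        clone_otus = pd.DataFrame({
            "clone_id": [r.clone_id for r in records],
            "library": [r.library for r in records],
            "otu": [assignment.assignments[r.clone_id] for r in records],
            "true_taxon": [r.true_taxon_id for r in records],
        })
        table = OTUTable.from_assignments(
            assignment.assignments,
            {r.clone_id: r.library for r in records})
        if write:
            clone_otus.to_csv(out / "clone_otus.tsv", sep="\t", index=False)
            frag_rows = pd.DataFrame({
                "clone_id": list(fragments),
                "fragment_lengths": [
                    ",".join(map(str, fragments[c].fragment_lengths))
                    for c in fragments],
            })
            frag_rows.to_csv(out / "fragments.tsv", sep="\t", index=False)
            # dendrogram over one representative pattern per OTU (identical
            # patterns would join at height 0 anyway)
            reps = {}
            for otu, members in assignment.otus().items():
                reps[otu] = patterns[members[0]]
            if len(reps) >= 2:
                tree = upgma(distance_matrix_from_patterns(reps))
                write_newick(tree, out / "otu_dendrogram.nwk")

    # ----- diversity -----
    div = diversity_report(table, chao_variant=config.chao_variant,
                           evenness_base=config.evenness_base)
    rare_frames = []
    for lib in table.libraries:
        curve = rarefaction_curve(table.library_counts(lib))
        curve.insert(0, "library", lib)
        rare_frames.append(curve)
    rarefaction = pd.concat(rare_frames, ignore_index=True)

    # ----- comparisons -----
    cs, shared = sorensen_matrix(table)
    fish_ids = sorted({split_library_label(l)[0] for l in table.libraries})
    comps = sorted({split_library_label(l)[1] for l in table.libraries})
    venn_comp = venn_fish = None
    if 2 <= len(comps) <= 3:
        pooled = {
            c: set().union(*(table.incidence(l) for l in table.libraries
                             if split_library_label(l)[1] == c))
            for c in comps
        }
        venn_comp = venn_counts(pooled)
    if 2 <= len(fish_ids) <= 3:
        pooled = {
            f: set().union(*(table.incidence(l) for l in table.libraries
                             if split_library_label(l)[0] == f))
            for f in fish_ids
        }
        venn_fish = venn_counts(pooled)

    taxonomy = _otu_taxonomy(clone_otus, taxon_classes) if len(clone_otus) \
        else {o: "unclassified" for o in table.otu_ids}
    composition = class_composition(table, taxonomy)

    comp_order = [c for c in ("IB", "MI", "PI") if c in comps] or comps
    trends: dict[str, TrendSummary] = {}
    complete = all(
        f"{f}|{c}" in set(table.libraries) for f in fish_ids for c in comp_order)
    if complete:
        for cls in composition.columns:
            trends[cls] = axis_trend(composition, cls, comp_order)

    # ----- group statistics -----
    anova: dict[str, AnovaResult] = {}
    if complete and len(fish_ids) >= 2 and len(comp_order) >= 2:
        def wide(series: pd.Series) -> pd.DataFrame:
            data = [[series[f"{f}|{c}"] for c in comp_order] for f in fish_ids]
            return pd.DataFrame(data, index=fish_ids, columns=comp_order)

        for metric in ("S_obs", "coverage_pct", "shannon_H",
                       "simpson_recip", "evenness_E"):
            m = div[metric]
            if m.isna().any():
                continue
            anova[metric] = rm_anova_with_tukey(wide(m), comp_order,
                                                alpha=config.alpha)
        for cls in composition.columns:
            vals = wide(composition[cls])
            if config.proportion_transform == "arcsine":
                vals = pd.DataFrame(arcsine_sqrt(vals.values),
                                    index=vals.index, columns=vals.columns)
            anova[f"class:{cls}"] = rm_anova_with_tukey(vals, comp_order,
                                                        alpha=config.alpha)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "n_libraries": len(table.libraries),
        "n_clones": int(table.counts.values.sum()),
        "n_otus": len(table.otu_ids),
        "sphericity_correction": "none",
        "evenness_base": config.evenness_base,
        "chao_variant": config.chao_variant,
        "proportion_transform": config.proportion_transform,
    }
    report = RunReport(
        otu_table=table, clone_otus=clone_otus, diversity=div,
        rarefaction=rarefaction, sorensen_pct=cs, sorensen_shared=shared,
        venn_compartments=venn_comp, venn_fish=venn_fish,
        composition=composition, trends=trends, anova=anova,
        provenance=provenance)

    if write:
        write_otu_table(table, out / "otu_table.tsv")
        div.to_csv(out / "diversity.tsv", sep="\t")
        rarefaction.to_csv(out / "rarefaction.tsv", sep="\t", index=False)
        cs.to_csv(out / "sorensen_pct.tsv", sep="\t")
        shared.to_csv(out / "sorensen_shared.tsv", sep="\t")
        composition.to_csv(out / "composition.tsv", sep="\t")
        for name, venn in (("venn_compartments", venn_comp),
                           ("venn_fish", venn_fish)):
            if venn is not None:
                pd.Series(venn, name="n_otus").rename_axis("region").to_csv(
                    out / f"{name}.tsv", sep="\t")
        if trends:
            trend_rows = []
            for cls, tr in trends.items():
                for fish in tr.values.index:
                    row = {"class": cls, "fish": fish}
                    row.update({c: tr.values.loc[fish, c]
                                for c in tr.compartment_order})
                    row["nonincreasing"] = tr.nonincreasing[fish]
                    row["nondecreasing"] = tr.nondecreasing[fish]
                    trend_rows.append(row)
            pd.DataFrame(trend_rows).to_csv(out / "trends.tsv", sep="\t",
                                            index=False)
        if anova:
            stat_rows = []
            for resp, res in anova.items():
                row = {"response": resp, "F": res.F,
                       "df_treatment": res.df_treatment,
                       "df_error": res.df_error, "p": res.p}
                if res.letters:
                    for lev, letter in res.letters.items():
                        row[f"letters_{lev}"] = letter
                stat_rows.append(row)
            pd.DataFrame(stat_rows).to_csv(out / "anova.tsv", sep="\t",
                                           index=False)
        pd.Series(provenance).rename_axis("key").to_frame("value").to_csv(
            out / "provenance.tsv", sep="\t")
    log.info("pipeline done: %d libraries, %d OTUs",
             len(table.libraries), len(table.otu_ids))
    return report


def _write_ground_truth(design: StudyDesign, path: Path) -> None:
    any_comm = next(iter(design.communities.values()))
    rows = []
    for i, taxon in enumerate(any_comm.taxa):
        row = {"taxon_id": taxon.taxon_id, "class_label": taxon.class_label}
        for cell in design.cells():
            comm = design.communities[cell]
            row[f"{cell[0]}|{cell[1]}"] = comm.taxa[i].rel_abundance
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
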