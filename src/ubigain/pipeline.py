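"""End-to-end orchestration: sites -> screening -> dating -> window -> report.

A run is driven by one config (YAML file or :class:`RunConfig`) naming the
site tables, the alignment directory, the tree and clade config, and every
threshold. It writes a master per-site TSV, a per-branch gain summary, the
window reports, and a JSON manifest embedding the full config, input file
digests, and the per-stage funnel counts. The funnel is asserted monotone on
every run (input sites >= non-redundant >= mapped >= retained), and a rerun
with identical config and inputs is bit-identical.

The manual-curation stage of the original procedure is replaced by the
parameterized filters plus explicit force-keep / force-drop lists, so any
hand decision can be reproduced and audited.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alignments import (
    OrthologAlignment,
    SpeciesTree,
    default_species_tree,
    load_species_tree,
    parse_alignment_fasta,
    residue_profile,
)
from .screening import (
    DISCARDED,
    RETAINED,
    ScreenConfig,
    SiteCall,
    build_reference_index,
    map_site,
    screen_site,
)
from .sites_io import ModKind, ModSite, deduplicate, parse_site_table
from .timing import GainSummary, infer_origin_clade, tabulate_gains
from .window import (
    DEFAULT_CONSERVED_MIN_FRACTION,
    WindowReport,
    acetylation_overlap,
    classify_calls,
)

logger = logging.getLogger(__name__)

STAGES = ("screen", "time", "classify", "all")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    site_tables: list[dict] = field(default_factory=list)  # {path, source}
    alignments_dir: str = ""
    out_dir: str = "ubigain_out"
    tree_newick: str | None = None
    clade_config: str | None = None
    acetylation_table: str | None = None
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    conserved_min_fraction: float = DEFAULT_CONSERVED_MIN_FRACTION
    species_regex: str = r"^(\S+)"
    force_keep: list[str] = field(default_factory=list)  # "protein_id:position"
    force_drop: list[str] = field(default_factory=list)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        screen = ScreenConfig(**raw.pop("screen", {}))
        return cls(screen=screen, **raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunResult:
    manifest: dict
    calls: list[SiteCall]
    summary: GainSummary | None
    window_reports: dict[tuple[str, int], WindowReport]
    out_dir: Path


class FunnelError(AssertionError):
    """The per-stage counts violated the monotone-funnel invariant."""


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_alignments(cfg: RunConfig) -> dict[str, OrthologAlignment]:
    aln_dir = Path(cfg.alignments_dir)
    files = sorted(
        p for p in aln_dir.iterdir() if p.suffix in (".fa", ".fasta", ".mfa")
    )
    alignments: dict[str, OrthologAlignment] = {}
    for p in files:
        aln = parse_alignment_fasta(p, species_regex=cfg.species_regex)
        alignments[aln.gene_id] = aln
    return alignments


def _find_gene(
    site: ModSite, alignments: dict[str, OrthologAlignment]
) -> tuple[OrthologAlignment | None, str | None]:
    """Locate the alignment for a site: by accession, else unique peptide match."""
    aln = alignments.get(site.protein_id)
    if aln is not None:
        return aln, None
    hits = [a for a in alignments.values() if map_site(site, a).ok]
    if len(hits) == 1:
        return hits[0], "GENE_BY_PEPTIDE"
    if len(hits) > 1:
        return None, "AMBIGUOUS_GENE"
    return None, None


def run(config: RunConfig | str | Path, through: str = "all") -> RunResult:
    """Execute the pipeline up to *through* ('screen', 'time', 'classify', 'all')."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; expected one of {STAGES}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.tree_newick and config.clade_config:
        tree = load_species_tree(config.tree_newick, config.clade_config)
    else:
        tree = default_species_tree()

    all_sites: list[ModSite] = []
    rejected_rows = 0
    input_paths: list[str] = []
    for entry in config.site_tables:
        path, source = entry["path"], entry.get("source")
        sites, diags = parse_site_table(path, ModKind.UBIQUITYLATION, source)
        all_sites.extend(sites)
        rejected_rows += len(diags)
        input_paths.append(path)
    nonredundant, conflicts = deduplicate(all_sites)

    alignments = _load_alignments(config)
    ref_index = build_reference_index(alignments.values())

    force_keep = set(config.force_keep)
    force_drop = set(config.force_drop)
    calls: list[SiteCall] = []
    for site in nonredundant:
        aln, gene_flag = _find_gene(site, alignments)
        call = screen_site(site, aln, tree, config.screen, ref_index)
        if gene_flag:
            call.flags.append(gene_flag)
        key = f"{site.protein_id}:{site.position}"
        if key in force_drop:
            if call.retained:
                call.status = DISCARDED
            call.flags.append("CURATED_DROP")
        elif key in force_keep and not call.retained and call.column is not None:
            call.flags.extend(f"OVERRIDDEN:{r}" for r in call.reasons)
            call.reasons = []
            call.status = RETAINED
            call.flags.append("CURATED_KEEP")
        calls.append(call)

    retained = [c for c in calls if c.retained]
    summary: GainSummary | None = None
    window_reports: dict[tuple[str, int], WindowReport] = {}
    if through in ("time", "classify", "all"):
        for call in retained:
            aln = alignments[call.gene_id]
            profile = residue_profile(aln, call.column, tree)
            origin = infer_origin_clade(profile, tree)
            call.origin_clade = origin.clade
            call.consistent_clades = list(origin.consistent_clades)
            call.ambiguous_origin = origin.ambiguous
            call.homoplasy_species = list(origin.homoplasy_species)
        summary = tabulate_gains(retained, tree)
    if through in ("classify", "all"):
        window_reports = classify_calls(
            retained, alignments, tree,
            conserved_min_fraction=config.conserved_min_fraction,
            radius=config.screen.window_radius,
        )
    acet_count = 0
    if through == "all" and config.acetylation_table:
        acet_raw, _ = parse_site_table(
            config.acetylation_table, ModKind.ACETYLATION, "acet"
        )
        acet_sites, _ = deduplicate(acet_raw)
        acetylation_overlap(calls, acet_sites)
        acet_count = sum(1 for c in retained if c.acetylated_too)
        input_paths.append(config.acetylation_table)

    counts = {
        "input_sites": len(all_sites),
        "rejected_rows": rejected_rows,
        "peptide_conflicts": len(conflicts),
        "nonredundant_sites": len(nonredundant),
        "mapped_sites": sum(1 for c in calls if c.column is not None),
        "genes_with_mappings": len(
            {c.gene_id for c in calls if c.column is not None}
        ),
        "retained_sites": len(retained),
        "retained_genes": len({c.gene_id for c in retained}),
        "acetylation_overlaps": acet_count,
    }
    if summary is not None:
        counts["gains_by_clade"] = summary.counts_by_clade
    if through in ("classify", "all"):
        counts["window_classes"] = {
            cls: sum(1 for c in retained if c.window_class == cls)
            for cls in ("new", "additional", "shifted")
        }
    _assert_funnel(counts)

    manifest = {
        "tool": "ubigain",
        "version": __version__,
        "stage": through,
        "seed": config.seed,
        "config": config.snapshot(),
        "ladder": [c.name for c in tree.ladder],
        "input_digests": {p: _sha256(p) for p in sorted(set(input_paths))},
        "counts": counts,
    }
    _write_outputs(out_dir, manifest, calls, summary, window_reports, tree)
    return RunResult(manifest, calls, summary, window_reports, out_dir)


def _assert_funnel(counts: dict) -> None:
    funnel = [
        counts["input_sites"],
        counts["nonredundant_sites"],
        counts["mapped_sites"],
        counts["retained_sites"],
    ]
    if any(a < b for a, b in zip(funnel, funnel[1:])):
        raise FunnelError(f"funnel counts increased along the pipeline: {funnel}")
    by_clade = counts.get("gains_by_clade")
    if by_clade is not None and sum(by_clade.values()) != counts["retained_sites"]:
        raise FunnelError("per-branch gains do not sum to the retained total")
    classes = counts.get("window_classes")
    if classes is not None and sum(classes.values()) != counts["retained_sites"]:
        raise FunnelError("window classes do not partition the retained set")


def calls_frame(calls: list[SiteCall]) -> pd.DataFrame:
    """Master per-site table (alignment columns reported 1-based)."""
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id or "" for c in calls],
            "protein_id": [c.site.protein_id for c in calls],
            "position": [c.site.position for c in calls],
            "corrected_position": [c.corrected_position or "" for c in calls],
            "peptide": [c.site.peptide for c in calls],
            "column": [c.column + 1 if c.column is not None else "" for c in calls],
            "status": [c.status for c in calls],
            "reasons": [",".join(c.reasons) for c in calls],
            "flags": [",".join(c.flags) for c in calls],
            "origin_clade": [c.origin_clade or "" for c in calls],
            "consistent_clades": [",".join(c.consistent_clades) for c in calls],
            "ambiguous_origin": [c.ambiguous_origin for c in calls],
            "homoplasy_species": [",".join(c.homoplasy_species) for c in calls],
            "window_class": [c.window_class or "" for c in calls],
            "acetylated_too": [c.acetylated_too for c in calls],
            "sources": [",".join(sorted(c.site.sources)) for c in calls],
        }
    )


def _write_outputs(
    out_dir: Path,
    manifest: dict,
    calls: list[SiteCall],
    summary: GainSummary | None,
    window_reports: dict[tuple[str, int], WindowReport],
    tree: SpeciesTree,
) -> None:
    frame = calls_frame(calls)
    frame.to_csv(out_dir / "site_calls.tsv", sep="\t", index=False)
    if summary is not None:
        with open(out_dir / "gain_summary.tsv", "w") as fh:
            fh.write("clade\tgains\n")
            for clade in tree.ladder:
                fh.write(f"{clade.name}\t{summary.counts_by_clade[clade.name]}\n")
    if window_reports:
        with open(out_dir / "window_reports.tsv", "w") as fh:
            fh.write(
                "protein_id\tposition\tclassification\toffsets_with_reference_K\t"
                "conservation\tloss_offsets\tclipped\n"
            )
            for (pid, pos), rep in sorted(window_reports.items()):
                cons = ";".join(
                    f"{o}:{rep.conservation[o]:.3f}" for o in sorted(rep.conservation)
                )
                loss = ",".join(str(o) for o in sorted(rep.loss_pattern) if rep.loss_pattern[o])
                refk = ",".join(str(o) for o in rep.offsets_with_reference_K)
                fh.write(
                    f"{pid}\t{pos}\t{rep.classification}\t{refk}\t{cons}\t{loss}\t"
                    f"{rep.clipped}\n"
                )
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def render_report(manifest: dict, frame: pd.DataFrame) -> str:
    """Human-readable run summary: funnel, per-branch table, human-specific list."""
    counts = manifest["counts"]
    lines = [
        f"ubigain {manifest['version']} — run report",
        "",
        "Funnel",
        f"  input site records       {counts['input_sites']}",
        f"  non-redundant sites      {counts['nonredundant_sites']}",
        f"  mapped into alignments   {counts['mapped_sites']} "
        f"(in {counts['genes_with_mappings']} genes)",
        f"  retained after screening {counts['retained_sites']} "
        f"(in {counts['retained_genes']} genes)",
    ]
    by_clade = counts.get("gains_by_clade")
    if by_clade:
        lines += ["", "Gains per human-lineage branch (smallest clade first)"]
        order = manifest.get("ladder") or list(by_clade)
        for name in order:
            lines.append(f"  {name:<20} {by_clade[name]}")
    classes = counts.get("window_classes")
    if classes:
        lines += [
            "",
            "Window classes: "
            + ", ".join(f"{k}={v}" for k, v in classes.items()),
        ]
    if "acetylation_overlaps" in counts:
        lines.append(f"Acetylation overlaps among retained sites: {counts['acetylation_overlaps']}")
    retained = frame[frame["status"] == RETAINED]
    human = retained[retained["origin_clade"] == "human"]
    if len(human):
        lines += ["", "Human-specific gains"]
        for _, row in human.iterrows():
            lines.append(
                f"  {row['protein_id']:<16} {row['peptide']:<13} {row['position']}"
            )
    return "\n".join(lines) + "\n"
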