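"""Species-tree-aware simulator with planted lysine gains and confounders.

Generates gap-free orthologous protein alignments evolved down the mammal
tree, with one lysine gain planted on a chosen human-lineage branch: the
ancestral residue at the planted column is drawn from {Q, E, R} (the
ancestral states observed at real gained sites) and every species inside the
planted clade — and only those — carries 'K' there. Matching PTM site
tables and a full ground-truth table are emitted, so the entire pipeline is
testable with no external data.

Confounder patterns reproduce the failure modes the screen must catch, and
the window-analysis classes it must recognise:

none                clean gain; expected retained, window class 'new'.
euarchontoglires_K  mouse carries an aligned K; expected discarded with
                    exactly EUARCHONTOGLIRES_K.
nearby_conserved_K  a universally conserved K two residues upstream;
                    retained, class 'additional'.
ancestral_K_shift   a K one residue upstream conserved in every species
                    outside the planted clade but lost within it; retained,
                    class 'shifted'.
many_nonprimate_K   ten non-Euarchontoglires outgroup species carry an
                    aligned K; expected discarded with MANY_NONPRIMATE_K.
low_conservation    the surrounding window is scrambled in all non-human
                    rows; expected discarded with LOW_CONSERVATION.

The simulation is indel-free: screening and dating are column-based, and a
gap-free alignment keeps the ground-truth bookkeeping exact. Gap handling is
exercised by hand-written fixtures instead. Substitutions are uniform over
the other 19 residues, Poisson(rate x branch length x sites) per edge;
branch lengths default to 1 where the newick supplies none.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignments import (
    OrthologAlignment,
    SpeciesTree,
    default_species_tree,
    write_clade_config,
    write_newick,
)
from .screening import DISCARDED, RETAINED
from .sites_io import ModSite, write_site_table
from .window import ADDITIONAL, NEW, SHIFTED

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_K_CODE = AA20.index("K")

#: ancestral residues observed at real gained sites
ANCESTRAL_CHOICES = "QER"

CONFOUNDERS = (
    "none",
    "euarchontoglires_K",
    "nearby_conserved_K",
    "ancestral_K_shift",
    "many_nonprimate_K",
    "low_conservation",
)

#: offset (in residues) of the confounder column relative to the planted site
CONFOUNDER_OFFSETS = {"nearby_conserved_K": -2, "ancestral_K_shift": -1}

#: outgroup species given an aligned K under many_nonprimate_K (10 of the 26
#: non-primates, i.e. a 0.385 lysine fraction — well above the 0.2 default cap)
MANY_NONPRIMATE_SPECIES = (
    "canFam2", "felCat3", "equCab2", "bosTau4", "turTru1",
    "vicPac1", "pteVam1", "myoLuc1", "loxAfr3", "proCap1",
)

#: per-residue scramble probability for the low_conservation confounder
SCRAMBLE_PROB = 0.7


@dataclass(frozen=True)
class SimConfig:
    """One simulation regime; every field participates in the ground truth."""

    tree: SpeciesTree = field(default_factory=default_species_tree)
    n_genes: int = 50
    seq_length: int = 120
    substitution_rate: float = 0.01
    planted_branch: str = "human"
    confounder: str = "none"
    missing_species: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_length < 13:
            raise ValueError("seq_length must be >= 13")
        if self.substitution_rate < 0:
            raise ValueError("substitution_rate must be >= 0")
        if self.planted_branch not in {c.name for c in self.tree.ladder}:
            raise ValueError(f"unknown planted_branch {self.planted_branch!r}")
        if self.confounder not in CONFOUNDERS:
            raise ValueError(f"unknown confounder {self.confounder!r}")
        if self.tree.reference_species in self.missing_species:
            raise ValueError("the reference species cannot be masked")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one simulated gene."""

    gene_id: str
    planted_column: int  # 0-based; equals position-1 (gap-free alignment)
    planted_branch: str
    planted_window_class: str
    expected_screen_status: str
    ancestral_residue: str
    confounder: str


def _evolve_leaves(
    cfg: SimConfig, rng: np.random.Generator, root: np.ndarray
) -> dict[str, np.ndarray]:
    """Evolve the root sequence down the tree; return leaf sequences by species."""
    L = root.size
    seqs: dict[int, np.ndarray] = {}
    leaves: dict[str, np.ndarray] = {}
    for node in cfg.tree.tree.preorder_node_iter():
        if node.parent_node is None:
            seq = root.copy()
        else:
            seq = seqs[id(node.parent_node)].copy()
            blen = node.edge.length if node.edge.length is not None else 1.0
            n_sub = rng.poisson(cfg.substitution_rate * blen * L)
            if n_sub:
                positions = rng.integers(0, L, size=int(n_sub))
                draws = rng.integers(0, 19, size=int(n_sub))
                for p, d in zip(positions, draws):
                    # uniform over the 19 residues other than the current one
                    seq[p] = d if d < seq[p] else d + 1
        seqs[id(node)] = seq
        if node.is_leaf():
            leaves[node.taxon.label] = seq
    return leaves


def simulate_gene(
    cfg: SimConfig, gene_index: int, gene_id: str | None = None
) -> tuple[OrthologAlignment, ModSite, SyntheticTruth]:
    """Simulate one gene alignment with a planted gain; reproducible from seed."""
    if gene_id is None:
        gene_id = f"g{gene_index:04d}"
    rng = np.random.default_rng([cfg.seed, gene_index])
    L = cfg.seq_length
    # keep the full 13-mer and the confounder offsets inside the sequence
    planted = int(rng.integers(8, L - 8))
    ancestral = ANCESTRAL_CHOICES[int(rng.integers(0, len(ANCESTRAL_CHOICES)))]
    shifted_residue = ANCESTRAL_CHOICES[int(rng.integers(0, len(ANCESTRAL_CHOICES)))]

    root = rng.integers(0, 20, size=L)
    # keep the classification window free of ancestral background lysines so
    # the planted window class is the ground truth; confounder columns are
    # overwritten below with their own K patterns
    for col in range(planted - 5, planted + 6):
        while root[col] == _K_CODE:
            root[col] = rng.integers(0, 20)
    leaves = _evolve_leaves(cfg, rng, root)

    clade_members = cfg.tree.clade(cfg.planted_branch).members
    code = {c: i for i, c in enumerate(AA20)}
    for species, seq in leaves.items():
        seq[planted] = _K_CODE if species in clade_members else code[ancestral]

    conf_col = planted + CONFOUNDER_OFFSETS.get(cfg.confounder, 0)
    if cfg.confounder == "nearby_conserved_K":
        for seq in leaves.values():
            seq[conf_col] = _K_CODE
    elif cfg.confounder == "ancestral_K_shift":
        for species, seq in leaves.items():
            seq[conf_col] = (
                code[shifted_residue] if species in clade_members else _K_CODE
            )
    elif cfg.confounder == "euarchontoglires_K":
        leaves["mm9"][planted] = _K_CODE
    elif cfg.confounder == "many_nonprimate_K":
        for species in MANY_NONPRIMATE_SPECIES:
            leaves[species][planted] = _K_CODE
    elif cfg.confounder == "low_conservation":
        ref_sp = cfg.tree.reference_species
        lo, hi = max(0, planted - 10), min(L, planted + 11)
        for species in sorted(leaves):
            if species == ref_sp:
                continue
            seq = leaves[species]
            for col in range(lo, hi):
                if col == planted:
                    continue
                if rng.random() < SCRAMBLE_PROB:
                    seq[col] = rng.integers(0, 20)

    order = [
        t.label
        for t in cfg.tree.tree.taxon_namespace
        if t.label not in cfg.missing_species
    ]
    rows = {sp: "".join(AA20[c] for c in leaves[sp]) for sp in order}
    aln = OrthologAlignment(
        gene_id=gene_id, rows=rows, reference_species=cfg.tree.reference_species
    )

    position = planted + 1  # gap-free: column + 1
    peptide = rows[cfg.tree.reference_species][planted - 6 : planted + 7]
    site = ModSite(
        protein_id=gene_id,
        position=position,
        peptide=peptide,
        sources=frozenset({"sim"}),
    )

    expected_status = (
        DISCARDED
        if cfg.confounder in ("euarchontoglires_K", "many_nonprimate_K", "low_conservation")
        else RETAINED
    )
    window_class = {
        "nearby_conserved_K": ADDITIONAL,
        "ancestral_K_shift": SHIFTED,
    }.get(cfg.confounder, NEW)
    truth = SyntheticTruth(
        gene_id=gene_id,
        planted_column=planted,
        planted_branch=cfg.planted_branch,
        planted_window_class=window_class,
        expected_screen_status=expected_status,
        ancestral_residue=ancestral,
        confounder=cfg.confounder,
    )
    return aln, site, truth


def write_alignment_fasta(aln: OrthologAlignment, path: str | Path) -> None:
    """Write one alignment in the dialect the pipeline consumes."""
    with open(path, "w") as fh:
        for species, row in aln.rows.items():
            fh.write(f">{species} {aln.gene_id}\n{row}\n")


def simulate_dataset(
    cfgs: list[SimConfig], out_dir: str | Path
) -> dict[str, Path]:
    """Simulate every gene of every config and write the full input bundle.

    Emits ``sites.tsv``, ``alignments/<gene>.fa``, ``truth.tsv``,
    ``tree.nwk`` and ``clades.yaml`` under *out_dir* — exactly the dialects
    the pipeline reads. Identical configs (including seeds) produce
    byte-identical files.
    """
    out_dir = Path(out_dir)
    aln_dir = out_dir / "alignments"
    aln_dir.mkdir(parents=True, exist_ok=True)
    sites: list[ModSite] = []
    truths: list[SyntheticTruth] = []
    for ci, cfg in enumerate(cfgs):
        for gi in range(cfg.n_genes):
            gene_id = f"g{ci:02d}_{gi:04d}"
            aln, site, truth = simulate_gene(cfg, gi, gene_id=gene_id)
            write_alignment_fasta(aln, aln_dir / f"{gene_id}.fa")
            sites.append(site)
            truths.append(truth)
    paths = {
        "sites": out_dir / "sites.tsv",
        "alignments": aln_dir,
        "truth": out_dir / "truth.tsv",
        "tree": out_dir / "tree.nwk",
        "clades": out_dir / "clades.yaml",
    }
    write_site_table(sites, paths["sites"])
    with open(paths["truth"], "w") as fh:
        fh.write(
            "gene_id\tplanted_column\tplanted_branch\tplanted_window_class\t"
            "expected_screen_status\tancestral_residue\tconfounder\n"
        )
        for t in truths:
            fh.write(
                f"{t.gene_id}\t{t.planted_column}\t{t.planted_branch}\t"
                f"{t.planted_window_class}\t{t.expected_screen_status}\t"
                f"{t.ancestral_residue}\t{t.confounder}\n"
            )
    tree = cfgs[0].tree if cfgs else default_species_tree()
    write_newick(tree, paths["tree"])
    write_clade_config(tree, paths["clades"])
    return paths
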