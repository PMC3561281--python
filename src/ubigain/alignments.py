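"""Orthologous protein alignments and the mammalian species tree.

Per-gene protein alignments follow the multiz-derived dialect: one FASTA
record per species, the species (assembly) code as the first header token,
'-' for alignment gaps, 'X' for unknown residues, '*' for stop codons. The
human row is the coordinate reference: modified-site positions are 1-based
indices into the ungapped human sequence, alignment columns are 0-based.

'X', '*', '-' and species absent from a file are all treated as MISSING
data: a residue that is not observed can neither support nor veto a lysine
call (draft-quality genomes must not create false gains or losses).

The species tree carries two layers of clade structure used throughout:

* a major-clade tag per species (pri / eua / lau / afr / xen / met / pro),
  where ``eua`` denotes the *non-primate* Euarchontoglires that act as the
  critical outgroup for calling primate-lineage gains;
* the human-lineage clade ladder — the strictly nested clades
  human < human+chimpanzee < African great apes < great apes < apes <
  catarrhines < simians < haplorhines < primates — each corresponding to a
  datable branch.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: sentinel for absent residue data in a column profile
MISSING = None

#: residue characters that carry no information
NON_RESIDUE_CHARS = frozenset("-X*")

REFERENCE_SPECIES = "hg19"

#: (assembly code, common name, major-clade tag) for the 37-taxon mammal set
SPECIES_TABLE: tuple[tuple[str, str, str], ...] = (
    ("hg19", "human", "pri"),
    ("panTro2", "chimpanzee", "pri"),
    ("gorGor1", "gorilla", "pri"),
    ("ponAbe2", "orangutan", "pri"),
    ("nomLeu1", "gibbon", "pri"),
    ("rheMac2", "rhesus", "pri"),
    ("papHam1", "baboon", "pri"),
    ("calJac1", "marmoset", "pri"),
    ("tarSyr1", "tarsier", "pri"),
    ("micMur1", "mouse_lemur", "pri"),
    ("otoGar1", "bushbaby", "pri"),
    ("tupBel1", "treeshrew", "eua"),
    ("mm9", "mouse", "eua"),
    ("rn4", "rat", "eua"),
    ("dipOrd1", "kangaroo_rat", "eua"),
    ("cavPor3", "guinea_pig", "eua"),
    ("speTri1", "squirrel", "eua"),
    ("oryCun2", "rabbit", "eua"),
    ("ochPri2", "pika", "eua"),
    ("canFam2", "dog", "lau"),
    ("felCat3", "cat", "lau"),
    ("equCab2", "horse", "lau"),
    ("bosTau4", "cow", "lau"),
    ("turTru1", "dolphin", "lau"),
    ("vicPac1", "alpaca", "lau"),
    ("pteVam1", "megabat", "lau"),
    ("myoLuc1", "microbat", "lau"),
    ("eriEur1", "hedgehog", "lau"),
    ("sorAra1", "shrew", "lau"),
    ("loxAfr3", "elephant", "afr"),
    ("proCap1", "rock_hyrax", "afr"),
    ("echTel1", "tenrec", "afr"),
    ("dasNov2", "armadillo", "xen"),
    ("choHof1", "sloth", "xen"),
    ("monDom5", "opossum", "met"),
    ("macEug1", "wallaby", "met"),
    ("ornAna1", "platypus", "pro"),
)

#: ladder step name -> species added relative to the previous (smaller) step
LADDER_STEPS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("human", ("hg19",)),
    ("human-chimpanzee", ("panTro2",)),
    ("african-great-apes", ("gorGor1",)),
    ("great-apes", ("ponAbe2",)),
    ("apes", ("nomLeu1",)),
    ("catarrhines", ("rheMac2", "papHam1")),
    ("simians", ("calJac1",)),
    ("haplorhines", ("tarSyr1",)),
    ("primates", ("micMur1", "otoGar1")),
)

DEFAULT_NEWICK = (
    "(((((((((((((hg19,panTro2),gorGor1),ponAbe2),nomLeu1),(rheMac2,papHam1)),"
    "calJac1),tarSyr1),(micMur1,otoGar1)),tupBel1),"
    "(((mm9,rn4),dipOrd1),(cavPor3,speTri1),(oryCun2,ochPri2))),"
    "(((canFam2,felCat3),(equCab2,(bosTau4,turTru1,vicPac1)),(pteVam1,myoLuc1)),"
    "(eriEur1,sorAra1))),"
    "((((loxAfr3,proCap1),echTel1),(dasNov2,choHof1)),(monDom5,macEug1))),"
    "ornAna1);"
)


class AlignmentFormatError(ValueError):
    """A per-gene alignment file violates the expected dialect."""


class CladeConfigError(ValueError):
    """The species-tree / clade configuration is internally inconsistent."""


@dataclass(frozen=True)
class Clade:
    """A named clade with its member-species set."""

    name: str
    members: frozenset[str]


@dataclass
class SpeciesTree:
    """Rooted species topology plus major-clade tags and the dating ladder."""

    tree: dendropy.Tree
    major_clade: dict[str, str]
    ladder: list[Clade]
    reference_species: str = REFERENCE_SPECIES

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.major_clade)

    @property
    def primates(self) -> frozenset[str]:
        return frozenset(s for s, tag in self.major_clade.items() if tag == "pri")

    def clade(self, name: str) -> Clade:
        for c in self.ladder:
            if c.name == name:
                return c
        raise KeyError(f"no ladder clade named {name!r}")

    def leaf_set(self) -> frozenset[str]:
        return frozenset(t.label for t in self.tree.taxon_namespace)

    def is_monophyletic(self, members: frozenset[str]) -> bool:
        """True iff *members* is exactly the leaf set under some tree node."""
        if not members:
            return False
        mrca = self.tree.mrca(taxon_labels=sorted(members))
        under = frozenset(leaf.taxon.label for leaf in mrca.leaf_iter())
        return under == members

    def validate(self) -> None:
        """Check all structural invariants; raise CladeConfigError on violation."""
        leaves = self.leaf_set()
        untagged = leaves - self.species
        if untagged:
            raise CladeConfigError(f"tree species without a major-clade tag: {sorted(untagged)}")
        if self.reference_species not in leaves:
            raise CladeConfigError(f"reference species {self.reference_species!r} not in tree")
        prev: frozenset[str] = frozenset()
        for clade in self.ladder:
            stray = clade.members - leaves
            if stray:
                raise CladeConfigError(
                    f"ladder clade {clade.name!r} lists species not in the tree: {sorted(stray)}"
                )
            if self.reference_species not in clade.members:
                raise CladeConfigError(
                    f"ladder clade {clade.name!r} does not contain the reference species"
                )
            if prev and not (prev < clade.members):
                raise CladeConfigError(
                    f"ladder clade {clade.name!r} is not a strict superset of its predecessor"
                )
            if not self.is_monophyletic(clade.members):
                raise CladeConfigError(f"ladder clade {clade.name!r} is not monophyletic")
            prev = clade.members
        if self.ladder and self.ladder[-1].members != self.primates:
            raise CladeConfigError(
                "the top ladder clade must equal the set of species tagged 'pri'"
            )


@dataclass(frozen=True)
class ColumnProfile:
    """The per-species residue observed at one alignment column.

    Values are single uppercase letters, or :data:`MISSING` (``None``) for
    gaps, unknown residues, stop codons, and species absent from the file.
    """

    column: int
    residue_by_species: Mapping[str, str | None]

    def residue(self, species: str) -> str | None:
        return self.residue_by_species.get(species, MISSING)


@dataclass
class OrthologAlignment:
    """One per-gene protein alignment over the species set.

    ``rows`` maps species code to the aligned sequence; all rows have equal
    length. The reference (human) row defines the coordinate system.
    ``audit_log`` records replaced rows so curation steps stay traceable.
    """

    gene_id: str
    rows: dict[str, str]
    reference_species: str = REFERENCE_SPECIES
    audit_log: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.gene_id}: ragged alignment, row lengths {sorted(lengths)}"
            )
        if self.reference_species not in self.rows:
            raise AlignmentFormatError(
                f"{self.gene_id}: reference row {self.reference_species!r} absent"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_species]

    @property
    def ungapped_reference(self) -> str:
        return self.reference_row.replace("-", "")

    @property
    def reference_length(self) -> int:
        return len(self.ungapped_reference)


def parse_alignment_fasta(
    path: str | Path,
    gene_id: str | None = None,
    species_regex: str = r"^(\S+)",
    reference_species: str = REFERENCE_SPECIES,
) -> OrthologAlignment:
    """Read one per-gene alignment FASTA into an :class:`OrthologAlignment`.

    The species code is extracted from each record header by *species_regex*
    (first capture group; default: the first whitespace-delimited token).
    A species appearing twice in one file is an error — that is a corrupt
    input, distinct from multi-copy human genes which are handled during
    screening.
    """
    path = Path(path)
    if gene_id is None:
        gene_id = path.stem
    pattern = re.compile(species_regex)
    rows: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        m = pattern.search(record.description)
        if not m:
            raise AlignmentFormatError(
                f"{path}: header {record.description!r} does not match species regex"
            )
        code = m.group(1)
        if code in rows:
            raise AlignmentFormatError(f"{path}: duplicate species {code!r}")
        rows[code] = str(record.seq).upper()
    if not rows:
        raise AlignmentFormatError(f"{path}: empty alignment file")
    return OrthologAlignment(gene_id=gene_id, rows=rows, reference_species=reference_species)


def column_of_position(aln: OrthologAlignment, position: int) -> int:
    """0-based alignment column holding the *position*-th reference residue."""
    if position < 1:
        raise IndexError(f"position {position} < 1")
    seen = 0
    for col, ch in enumerate(aln.reference_row):
        if ch != "-":
            seen += 1
            if seen == position:
                return col
    raise IndexError(
        f"{aln.gene_id}: position {position} beyond reference length {aln.reference_length}"
    )


def position_of_column(aln: OrthologAlignment, column: int) -> int:
    """1-based reference position of the residue at alignment *column*."""
    row = aln.reference_row
    if not (0 <= column < len(row)):
        raise IndexError(f"column {column} out of range")
    if row[column] == "-":
        raise IndexError(f"{aln.gene_id}: reference row is gapped at column {column}")
    return sum(1 for ch in row[: column + 1] if ch != "-")


def residue_profile(
    aln: OrthologAlignment, column: int, tree: SpeciesTree | None = None
) -> ColumnProfile:
    """Observed residues at one column; gaps/'X'/'*'/absent species are MISSING.

    When *tree* is given, species present in the tree but absent from the
    alignment file get explicit MISSING entries, so downstream filters see a
    complete species roster.
    """
    if not (0 <= column < aln.length):
        raise IndexError(f"column {column} out of range for {aln.gene_id}")
    profile: dict[str, str | None] = {}
    roster: Iterable[str] = aln.rows
    if tree is not None:
        roster = list(aln.rows) + sorted(tree.species - set(aln.rows))
    for species in roster:
        row = aln.rows.get(species)
        if row is None:
            profile[species] = MISSING
            continue
        ch = row[column].upper()
        profile[species] = MISSING if ch in NON_RESIDUE_CHARS else ch
    return ColumnProfile(column=column, residue_by_species=profile)


def replace_sequence(
    aln: OrthologAlignment, species: str, new_row: str
) -> OrthologAlignment:
    """Return a copy of *aln* with one row replaced (or added), audit-logged.

    Replacing a low-quality row with a curated sequence, or adding a species
    missing from the original alignment set (e.g. gibbon augmentation), both
    go through here; the previous row, when present, is retained in the
    audit log.
    """
    if len(new_row) != aln.length:
        raise AlignmentFormatError(
            f"{aln.gene_id}: replacement row for {species!r} has length "
            f"{len(new_row)}, alignment length is {aln.length}"
        )
    rows = dict(aln.rows)
    audit = list(aln.audit_log)
    if species in rows:
        audit.append((species, rows[species]))
    else:
        audit.append((species, ""))
    rows[species] = new_row.upper()
    return OrthologAlignment(
        gene_id=aln.gene_id,
        rows=rows,
        reference_species=aln.reference_species,
        audit_log=audit,
    )


# ---------------------------------------------------------------------------
# species tree construction and (de)serialization


def _build_species_tree(
    newick: str,
    major_clade: Mapping[str, str],
    ladder_steps: Iterable[tuple[str, Iterable[str]]],
    reference_species: str = REFERENCE_SPECIES,
) -> SpeciesTree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    cumulative: set[str] = set()
    ladder: list[Clade] = []
    for name, added in ladder_steps:
        cumulative |= set(added)
        ladder.append(Clade(name=name, members=frozenset(cumulative)))
    st = SpeciesTree(
        tree=tree,
        major_clade=dict(major_clade),
        ladder=ladder,
        reference_species=reference_species,
    )
    st.validate()
    return st


def default_species_tree() -> SpeciesTree:
    """The built-in 37-taxon mammal tree with the 9-step human-lineage ladder."""
    return _build_species_tree(
        DEFAULT_NEWICK,
        {code: tag for code, _, tag in SPECIES_TABLE},
        LADDER_STEPS,
    )


def load_species_tree(
    newick_path: str | Path, clades_path: str | Path
) -> SpeciesTree:
    """Load a species tree from a newick file plus a YAML/JSON clade config.

    The config must provide ``major_clades`` (species code -> tag) and
    ``ladder`` (ordered list of ``{name, members}``, smallest clade first;
    members are cumulative full member lists). All structural invariants are
    verified at load time; a violation raises :class:`CladeConfigError`
    naming the offending clade.
    """
    with open(clades_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "major_clades" not in cfg or "ladder" not in cfg:
        raise CladeConfigError(
            f"{clades_path}: config must define 'major_clades' and 'ladder'"
        )
    tree = dendropy.Tree.get(
        path=str(newick_path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    ladder = [
        Clade(name=step["name"], members=frozenset(step["members"]))
        for step in cfg["ladder"]
    ]
    st = SpeciesTree(
        tree=tree,
        major_clade=dict(cfg["major_clades"]),
        ladder=ladder,
        reference_species=cfg.get("reference_species", REFERENCE_SPECIES),
    )
    st.validate()
    return st


def write_clade_config(tree: SpeciesTree, path: str | Path) -> None:
    """Serialize the clade layer of *tree* to the YAML dialect load_species_tree reads."""
    cfg = {
        "reference_species": tree.reference_species,
        "major_clades": dict(sorted(tree.major_clade.items())),
        "ladder": [
            {"name": c.name, "members": sorted(c.members)} for c in tree.ladder
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_newick(tree: SpeciesTree, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.tree.as_string(schema="newick", suppress_rooting=True))


def common_names() -> dict[str, str]:
    """Assembly code -> common species name for the built-in species set."""
    return {code: name for code, name, _ in SPECIES_TABLE}
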