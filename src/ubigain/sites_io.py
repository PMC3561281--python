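"""Reading, validation, and deduplication of PTM site tables.

Large-scale diGly-remnant proteomics experiments report modified lysines as
(protein accession, 1-based residue position, 13-mer peptide with the modified
lysine at the center). Multiple experiments overlap heavily, so downstream
analysis starts from a non-redundant union keyed on (protein, position,
modification kind).

Positions are taken on the coordinate system of the accession as given;
no cross-mapping between accession namespaces (IPI / UniProt / RefSeq) is
attempted here.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: the 20 standard amino acids plus 'X' for unknown residues
AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: maximum peptide length (the conventional diGly 13-mer)
MAX_PEPTIDE_LEN = 13


class ModKind(str, enum.Enum):
    """Kind of lysine modification carried by a site record."""

    UBIQUITYLATION = "ubiquitylation"
    ACETYLATION = "acetylation"


class SiteTableFormatError(ValueError):
    """The site table as a whole is malformed (e.g. a required column is absent)."""


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected input row with the reason it was rejected."""

    line: int  # 1-based data-row number (header excluded)
    message: str


@dataclass(frozen=True)
class PeptideConflict:
    """Two records agree on (protein, position, kind) but disagree on peptide."""

    protein_id: str
    position: int
    kept: str
    discarded: str


@dataclass(frozen=True)
class ModSite:
    """One experimentally observed modified lysine.

    The peptide is the (up to) 13-mer context with the modified lysine at the
    center; peptides shorter than 13 arise only from symmetric truncation at a
    protein terminus, so the length is always odd and the center residue is
    always 'K'.
    """

    protein_id: str
    position: int
    peptide: str
    sources: frozenset[str] = field(default_factory=frozenset)
    mod_kind: ModKind = ModKind.UBIQUITYLATION

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        pep = self.peptide
        if not pep or len(pep) > MAX_PEPTIDE_LEN or len(pep) % 2 == 0:
            raise ValueError(
                f"peptide must have odd length <= {MAX_PEPTIDE_LEN}, got {pep!r}"
            )
        bad = set(pep) - AA_LETTERS
        if bad:
            raise ValueError(f"peptide {pep!r} contains non-amino-acid letters {bad}")
        if pep[len(pep) // 2] != "K":
            raise ValueError(f"center residue of {pep!r} is not 'K'")

    @property
    def key(self) -> tuple[str, int, ModKind]:
        return (self.protein_id, self.position, self.mod_kind)

    @property
    def flank(self) -> int:
        """Number of residues on each side of the central lysine."""
        return len(self.peptide) // 2


REQUIRED_COLUMNS = ("protein_id", "position", "peptide")


def parse_site_table(
    path: str | Path,
    mod_kind: ModKind = ModKind.UBIQUITYLATION,
    source_label: str | None = None,
) -> tuple[list[ModSite], list[RowDiagnostic]]:
    """Read a TSV site table into validated :class:`ModSite` records.

    Required columns: ``protein_id``, ``position``, ``peptide``. An optional
    ``source`` column (single label) or ``sources`` column (comma-joined)
    overrides *source_label*. Rows violating the site invariants (non-integer
    position, center residue not K, ...) are rejected individually and
    reported in the returned diagnostics list, never silently dropped.

    Returns
    -------
    (sites, diagnostics)
        The valid records in file order, and one diagnostic per rejected row.

    Raises
    ------
    SiteTableFormatError
        If a required column is missing or the file is unreadable as TSV.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SiteTableFormatError(f"cannot read site table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SiteTableFormatError(
            f"site table {path} is missing required column(s) {missing}"
        )

    sites: list[ModSite] = []
    diagnostics: list[RowDiagnostic] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        raw_pos = getattr(row, "position")
        try:
            position = int(raw_pos)
        except (TypeError, ValueError):
            diagnostics.append(RowDiagnostic(i, f"non-integer position {raw_pos!r}"))
            continue
        if "sources" in frame.columns and getattr(row, "sources"):
            sources = frozenset(
                s.strip() for s in getattr(row, "sources").split(",") if s.strip()
            )
        elif "source" in frame.columns and getattr(row, "source"):
            sources = frozenset({getattr(row, "source").strip()})
        elif source_label is not None:
            sources = frozenset({source_label})
        else:
            sources = frozenset()
        try:
            site = ModSite(
                protein_id=getattr(row, "protein_id").strip(),
                position=position,
                peptide=getattr(row, "peptide").strip().upper(),
                sources=sources,
                mod_kind=mod_kind,
            )
        except ValueError as exc:
            diagnostics.append(RowDiagnostic(i, str(exc)))
            continue
        sites.append(site)
    for diag in diagnostics:
        logger.warning("%s row %d rejected: %s", path, diag.line, diag.message)
    return sites, diagnostics


def deduplicate(
    sites: Iterable[ModSite],
) -> tuple[list[ModSite], list[PeptideConflict]]:
    """Collapse repeated observations of the same site across experiments.

    One record is kept per (protein_id, position, mod_kind); its ``sources``
    set is the union over all contributing records. If two records for the
    same key carry different peptides, the longer peptide wins and the
    conflict is reported. Output is sorted by protein_id then position, so
    deduplication is deterministic and idempotent.
    """
    merged: dict[tuple[str, int, ModKind], ModSite] = {}
    conflicts: list[PeptideConflict] = []
    for site in sites:
        prev = merged.get(site.key)
        if prev is None:
            merged[site.key] = site
            continue
        sources = prev.sources | site.sources
        if site.peptide != prev.peptide:
            keep, drop = (
                (site, prev) if len(site.peptide) > len(prev.peptide) else (prev, site)
            )
            conflicts.append(
                PeptideConflict(site.protein_id, site.position, keep.peptide, drop.peptide)
            )
            merged[site.key] = replace(keep, sources=sources)
        else:
            merged[site.key] = replace(prev, sources=sources)
    out = sorted(merged.values(), key=lambda s: (s.protein_id, s.position, s.mod_kind.value))
    for c in conflicts:
        logger.warning(
            "peptide conflict at %s:%d — kept %r, discarded %r",
            c.protein_id, c.position, c.kept, c.discarded,
        )
    return out, conflicts


def write_site_table(sites: Sequence[ModSite], path: str | Path) -> None:
    """Write sites back out in the input TSV dialect plus a ``sources`` column."""
    frame = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in sites],
            "position": [s.position for s in sites],
            "peptide": [s.peptide for s in sites],
            "sources": [",".join(sorted(s.sources)) for s in sites],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
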