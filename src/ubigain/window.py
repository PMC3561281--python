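"""±5-residue window analysis: new, additional, or shifted target sites.

Ubiquitylation sites can migrate a few residues without loss of function, so
a newly gained lysine may not be a genuinely new target. For each retained
gain the window of ±5 reference residues around the site (gap columns
skipped — offsets are counted in human residues, not alignment columns) is
scanned for alternative lysines:

new         no offset carries a conserved ancestral lysine — the gain
            created a genuinely new modification target.
additional  a conserved ancestral lysine coexists and is still present in
            the human row — the protein acquired an additional target.
shifted     a conserved ancestral lysine is absent from the human row; when
            it is absent throughout the origin clade, the target migrated as
            the novel lysine appeared.

"Conserved" means the fraction of non-missing non-primate species carrying
a lysine at the offset's column is at least ``conserved_min_fraction``
(default 0.75). The classes are disjoint: additional takes precedence over
shifted when both patterns co-occur.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .alignments import MISSING, OrthologAlignment, SpeciesTree, column_of_position, position_of_column, residue_profile
from .screening import SiteCall
from .sites_io import ModSite

logger = logging.getLogger(__name__)

NEW = "new"
ADDITIONAL = "additional"
SHIFTED = "shifted"

DEFAULT_CONSERVED_MIN_FRACTION = 0.75


@dataclass(frozen=True)
class WindowReport:
    """Per-offset evidence and the resulting class for one retained site."""

    offsets_with_reference_K: tuple[int, ...]
    conservation: dict[int, float]  # offset -> non-primate K fraction
    loss_pattern: dict[int, bool]  # offset -> conserved K absent in origin clade
    classification: str
    clipped: bool = False


def window_report(
    aln: OrthologAlignment,
    column: int,
    origin_clade: str,
    tree: SpeciesTree,
    conserved_min_fraction: float = DEFAULT_CONSERVED_MIN_FRACTION,
    radius: int = 5,
) -> WindowReport:
    """Classify one retained gain from its ±*radius* residue window.

    Offsets beyond a protein terminus are dropped and the report flagged as
    clipped. The per-offset loss-pattern map records the strict test that an
    ancestrally conserved lysine is absent from every non-missing member of
    the origin clade.
    """
    pos = position_of_column(aln, column)
    ref = aln.ungapped_reference
    clade_members = tree.clade(origin_clade).members
    nonpri = [s for s, tag in tree.major_clade.items() if tag != "pri"]

    offsets = [o for o in range(-radius, radius + 1) if o != 0]
    usable = [o for o in offsets if 1 <= pos + o <= len(ref)]
    clipped = len(usable) < len(offsets)

    ref_k: list[int] = []
    conservation: dict[int, float] = {}
    loss_pattern: dict[int, bool] = {}
    for off in usable:
        p = pos + off
        col = column_of_position(aln, p)
        prof = residue_profile(aln, col, tree)
        if ref[p - 1] == "K":
            ref_k.append(off)
        observed = [s for s in nonpri if prof.residue(s) is not MISSING]
        frac = (
            sum(1 for s in observed if prof.residue(s) == "K") / len(observed)
            if observed
            else 0.0
        )
        conservation[off] = frac
        clade_observed = [s for s in clade_members if prof.residue(s) is not MISSING]
        absent_in_clade = bool(clade_observed) and all(
            prof.residue(s) != "K" for s in clade_observed
        )
        loss_pattern[off] = frac >= conserved_min_fraction and absent_in_clade

    conserved = [o for o in usable if conservation[o] >= conserved_min_fraction]
    if not conserved:
        classification = NEW
    elif any(o in ref_k for o in conserved):
        classification = ADDITIONAL
    else:
        classification = SHIFTED
    return WindowReport(
        offsets_with_reference_K=tuple(ref_k),
        conservation=conservation,
        loss_pattern=loss_pattern,
        classification=classification,
        clipped=clipped,
    )


def classify_calls(
    calls: Sequence[SiteCall],
    alignments: dict[str, OrthologAlignment],
    tree: SpeciesTree,
    conserved_min_fraction: float = DEFAULT_CONSERVED_MIN_FRACTION,
    radius: int = 5,
) -> dict[tuple[str, int], WindowReport]:
    """Run the window analysis over all retained, dated calls in place.

    Sets ``window_class`` on each call and returns the full reports keyed by
    (protein_id, position) for TSV export.
    """
    reports: dict[tuple[str, int], WindowReport] = {}
    for call in calls:
        if not call.retained or call.origin_clade is None or call.column is None:
            continue
        rep = window_report(
            alignments[call.gene_id],
            call.column,
            call.origin_clade,
            tree,
            conserved_min_fraction=conserved_min_fraction,
            radius=radius,
        )
        call.window_class = rep.classification
        reports[(call.site.protein_id, call.site.position)] = rep
    return reports


def acetylation_overlap(
    ubi_calls: Sequence[SiteCall], acet_sites: Iterable[ModSite]
) -> list[SiteCall]:
    """Mark ubiquitylation calls whose lysine is also an acetylation target.

    The match is exact on (protein_id, position) in the input coordinate
    system; neighbouring positions never count. The acetylation set should
    be deduplicated first.
    """
    acet_keys = {(s.protein_id, s.position) for s in acet_sites}
    for call in ubi_calls:
        call.acetylated_too = (call.site.protein_id, call.site.position) in acet_keys
    return list(ubi_calls)
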