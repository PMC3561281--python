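"""Shared fixtures: the default species tree and hand-built alignment patterns.

The pattern fixtures reconstruct the canonical per-gene situations — a
human-specific gain in a conserved region (ERCC2-style), a great-ape gain
with the gibbon row missing plus a conserved lysine two residues upstream
(BIRC2-style), an ape-clade gain whose ancestral lysine at -1 was lost in
the gaining clade (LRPPRC-style), and a great-ape gain with the gibbon
observed (PML-style) — as fully synthetic alignments over the 37-species
set, conserved everywhere except the columns of interest.
"""

from __future__ import annotations

import pytest

from ubigain import ModSite, OrthologAlignment, default_species_tree

# 19 letters, deliberately lysine-free so backgrounds never add K columns
BACKGROUND = "ACDEFGHILMNPQRSTVWY"


@pytest.fixture(scope="session")
def tree():
    return default_species_tree()


@pytest.fixture(scope="session")
def species_order(tree):
    return [t.label for t in tree.tree.taxon_namespace]


@pytest.fixture
def make_aln(species_order):
    """Build a gap-free alignment, conserved except for explicit overrides.

    ``overrides`` maps 1-based positions to ``{species_or_'default': residue}``.
    """

    def _make(gene_id="gene", length=40, overrides=None, absent=()):
        base = (BACKGROUND * (length // len(BACKGROUND) + 1))[:length]
        rows = {}
        for sp in species_order:
            if sp in absent:
                continue
            row = list(base)
            for pos, spec in (overrides or {}).items():
                row[pos - 1] = spec.get(sp, spec.get("default", base[pos - 1]))
            rows[sp] = "".join(row)
        return OrthologAlignment(gene_id=gene_id, rows=rows)

    return _make


def peptide_at(aln: OrthologAlignment, position: int) -> str:
    """The reference 13-mer centered on *position* (symmetric truncation)."""
    ref = aln.ungapped_reference
    flank = min(6, position - 1, len(ref) - position)
    return ref[position - 1 - flank : position + flank]


@pytest.fixture
def ercc2(tree, make_aln):
    """Human-specific gain at 701 in a conserved region; other mammals Q/R."""
    pep = "ESEETLKRIEQIA"
    ov = {695 + i: {"default": c} for i, c in enumerate(pep)}
    ov[701] = {
        "default": "Q",
        "hg19": "K",
        "canFam2": "R",
        "bosTau4": "R",
        "monDom5": "R",
    }
    aln = make_aln("ERCC2", 710, ov)
    site = ModSite("ERCC2", 701, pep, frozenset({"Kim"}))
    return aln, site


@pytest.fixture
def birc2(tree, make_aln):
    """Great-ape gain at 448, gibbon missing, conserved K at the -2 offset."""
    great_apes = tree.clade("great-apes").members
    ov = {
        446: {"default": "K"},
        448: {"default": "Q", **{sp: "K" for sp in great_apes}},
    }
    aln = make_aln("BIRC2", 460, ov, absent=("nomLeu1",))
    site = ModSite("BIRC2", 448, peptide_at(aln, 448), frozenset({"Kim"}))
    return aln, site


@pytest.fixture
def lrpprc(tree, make_aln):
    """Ape-clade gain at 613; ancestral K at -1 conserved outside, lost inside."""
    apes = tree.clade("apes").members
    ov = {
        612: {"default": "K", **{sp: "R" for sp in apes}},
        613: {"default": "E", **{sp: "K" for sp in apes}},
    }
    aln = make_aln("LRPPRC", 625, ov)
    site = ModSite("LRPPRC", 613, peptide_at(aln, 613), frozenset({"Wagner"}))
    return aln, site


@pytest.fixture
def pml(tree, make_aln):
    """Great-ape gain at 394 with the gibbon row present (non-K)."""
    great_apes = tree.clade("great-apes").members
    ov = {394: {"default": "Q", **{sp: "K" for sp in great_apes}}}
    aln = make_aln("PML", 400, ov)
    site = ModSite("PML", 394, peptide_at(aln, 394), frozenset({"Kim"}))
    return aln, site
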