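"""Species-paired co-alignments for complex-structure prediction.

A per-chain MSA (:class:`SpeciesTaggedMSA`) carries one taxon-tagged homolog
row per species.  Receptor and ligand MSAs are trimmed to the delimitations
of interest and then concatenated row-wise into a :class:`CoAlignment` in
one of three evolutionary-information modes:

``mixed``
    homologs from the same species are joined into one paired row; homologs
    whose species is absent from the other block are appended unpaired, with
    gaps in place of the missing partner.
``unpaired``
    no species joining at all: every homolog contributes one row with gaps
    outside its own block.
``no_ligand_msa``
    the receptor side is built as in ``mixed`` but the ligand block carries
    only the query sequence — no evolutionary information on the peptide.

Homomeric (and heteromeric) receptors are handled by repeating (or listing)
receptor MSAs; copies of the same MSA are filled simultaneously, pairing
each homolog with itself across subunits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .formats_io import ChainSequence, Region

MODES = ("mixed", "unpaired", "no_ligand_msa")


@dataclass
class SpeciesTaggedMSA:
    """A query-anchored match-state alignment with taxon-tagged rows."""

    query: ChainSequence
    rows: list  # list[(taxon_key, gapped match-state string)]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        width = len(self.query.sequence)
        taxa = [t for t, _ in self.rows]
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon keys must be unique")
        for taxon, row in self.rows:
            if len(row) != width:
                raise ValueError(
                    f"row for taxon {taxon!r} has width {len(row)} != {width}"
                )

    @property
    def width(self) -> int:
        return len(self.query.sequence)

    @property
    def taxa(self) -> set:
        return {t for t, _ in self.rows}

    def row_for(self, taxon: str) -> str:
        return next(r for t, r in self.rows if t == taxon)


def trim_msa(msa: SpeciesTaggedMSA, region: Region) -> SpeciesTaggedMSA:
    """Restrict an MSA to ``region`` columns; all-gap rows are dropped."""
    region.validate_on(msa.width)
    lo, hi = region.start - 1, region.end
    query = ChainSequence(
        source_id=msa.query.source_id,
        chain_label=msa.query.chain_label,
        sequence=msa.query.sequence[lo:hi],
        first_residue_number=msa.query.first_residue_number + lo,
    )
    rows = []
    for taxon, row in msa.rows:
        piece = row[lo:hi]
        if set(piece) != {"-"}:
            rows.append((taxon, piece))
    prov = dict(msa.provenance)
    prov["trimmed_to"] = (region.start, region.end)
    return SpeciesTaggedMSA(query=query, rows=rows, provenance=prov)


@dataclass(frozen=True)
class Block:
    """One column span of a co-alignment, tied back to its source chain."""

    role: str  # "receptor" | "ligand"
    region: Region  # in the source chain's coordinates
    col_start: int  # 1-based inclusive within the co-alignment
    col_end: int
    msa_index: int  # index of the distinct source MSA (copies share it)


@dataclass
class CoAlignment:
    """A concatenated receptor+ligand alignment ready for a predictor."""

    mode: str
    blocks: list  # list[Block]
    rows: list  # list[(joined gapped string, paired flag)], query excluded
    query_row: str
    row_taxa: list = field(default_factory=list)  # parallel to rows

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        w = self.width
        if "-" in self.query_row:
            raise ValueError("query row must be gap-free")
        for row, _ in self.rows:
            if len(row) != w:
                raise ValueError("ragged co-alignment row")

    @property
    def width(self) -> int:
        return len(self.query_row)

    def ligand_block(self) -> Block:
        return next(b for b in self.blocks if b.role == "ligand")

    def block_slice(self, block: Block) -> slice:
        return slice(block.col_start - 1, block.col_end)


def homomer_block(receptor_msa: SpeciesTaggedMSA, copies: int) -> list:
    """The receptor MSA repeated ``copies`` times, as a co-alignment input.

    Each copy is filled with the same homolog row, i.e. every species is
    paired with itself across subunits.
    """
    if copies < 1:
        raise ValueError(f"copies must be >= 1, got {copies}")
    return [receptor_msa] * copies


def _distinct_msas(msas: list) -> tuple[list, list]:
    """Group identical MSA objects: (distinct msas, per-input distinct index)."""
    distinct: list = []
    index = []
    for m in msas:
        for i, d in enumerate(distinct):
            if d is m:
                index.append(i)
                break
        else:
            distinct.append(m)
            index.append(len(distinct) - 1)
    return distinct, index


def build_coalignment(
    receptor_msas: list,
    ligand_msa: SpeciesTaggedMSA | None,
    mode: str = "mixed",
) -> CoAlignment:
    """Concatenate receptor and ligand MSAs into a co-alignment.

    ``receptor_msas`` lists one MSA per receptor subunit; repeat the same
    object for homomeric copies (see :func:`homomer_block`). Paired rows are
    ordered by ascending taxon key; unpaired rows follow, receptor blocks
    first in input order, then the ligand block.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if not receptor_msas:
        raise ValueError("at least one receptor MSA is required")
    if ligand_msa is None or (mode != "no_ligand_msa" and ligand_msa is None):
        raise ValueError("a ligand MSA is required")
    if not ligand_msa.rows and mode in ("mixed", "unpaired"):
        # allowed: pairing degenerates, every receptor homolog is unpaired
        pass

    all_msas = list(receptor_msas) + [ligand_msa]
    roles = ["receptor"] * len(receptor_msas) + ["ligand"]
    distinct, didx = _distinct_msas(all_msas)
    ligand_d = didx[-1]

    # column layout
    blocks = []
    col = 1
    for i, (msa, role) in enumerate(zip(all_msas, roles)):
        w = msa.width
        r0 = msa.query.first_residue_number
        blocks.append(
            Block(
                role=role,
                region=Region(r0, r0 + w - 1),
                col_start=col,
                col_end=col + w - 1,
                msa_index=didx[i],
            )
        )
        col += w
    width = col - 1
    query_row = "".join(m.query.sequence for m in all_msas)

    ligand_in_pairing = mode != "no_ligand_msa"
    pairing_members = set(didx[:-1]) | ({ligand_d} if ligand_in_pairing else set())

    def joined(fill: dict) -> str:
        # fill: distinct msa index -> row string (or None for gaps)
        parts = []
        for i, msa in enumerate(all_msas):
            row = fill.get(didx[i])
            parts.append(row if row is not None else "-" * msa.width)
        return "".join(parts)

    rows: list = []
    taxa_out: list = []
    paired_taxa: set = set()
    if mode in ("mixed", "no_ligand_msa"):
        common = None
        for d in sorted(pairing_members):
            taxa = distinct[d].taxa
            common = taxa if common is None else (common & taxa)
        common = common or set()
        for taxon in sorted(common):
            fill = {d: distinct[d].row_for(taxon) for d in pairing_members}
            if not ligand_in_pairing:
                fill[ligand_d] = None
            # a row is "paired" only when it has content on both sides
            rows.append((joined(fill), ligand_in_pairing))
            taxa_out.append(taxon)
        paired_taxa = common

    if mode == "unpaired":
        emit_from = list(range(len(distinct)))
    else:
        emit_from = sorted(pairing_members)

    for d in emit_from:
        if mode == "no_ligand_msa" and d == ligand_d:
            continue
        for taxon, row in distinct[d].rows:
            if mode != "unpaired" and taxon in paired_taxa:
                continue
            fill = {d: row}
            if mode == "no_ligand_msa":
                fill.setdefault(ligand_d, None)
            rows.append((joined(fill), False))
            taxa_out.append(taxon)

    return CoAlignment(
        mode=mode, blocks=blocks, rows=rows, query_row=query_row, row_taxa=taxa_out
    )


def count_report(coaln: CoAlignment) -> dict:
    """Row accounting for a co-alignment (query counted separately)."""
    n_paired = sum(1 for _, paired in coaln.rows if paired)
    lig = coaln.ligand_block()
    lsl = coaln.block_slice(lig)
    n_unp_rec = 0
    n_unp_lig = 0
    for row, paired in coaln.rows:
        if paired:
            continue
        if set(row[lsl]) == {"-"}:
            n_unp_rec += 1
        else:
            n_unp_lig += 1
    return {
        "n_rows": len(coaln.rows) + 1,
        "n_paired": n_paired,
        "n_unpaired_receptor": n_unp_rec,
        "n_unpaired_ligand": n_unp_lig,
        "width": coaln.width,
    }


def write_coalignment_a3m(coaln: CoAlignment, path, query_name: str = "query") -> None:
    """Emit a concatenated A3M (joined query first) plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{query_name}\n{coaln.query_row}\n")
        for i, (row, paired) in enumerate(coaln.rows):
            taxon = coaln.row_taxa[i] if coaln.row_taxa else str(i)
            tag = "paired" if paired else "unpaired"
            fh.write(f">row{i}_{taxon} {tag}\n{row}\n")
    sidecar = {
        "mode": coaln.mode,
        "width": coaln.width,
        "blocks": [
            {
                "role": b.role,
                "region": [b.region.start, b.region.end],
                "columns": [b.col_start, b.col_end],
                "msa_index": b.msa_index,
            }
            for b in coaln.blocks
        ],
        "rows": [
            {"taxon": t, "paired": p}
            for t, (_, p) in zip(coaln.row_taxa, coaln.rows)
        ],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
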