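"""Readers and writers for the external formats the pipeline touches.

Sequences travel as :class:`ChainSequence`, residue intervals as
:class:`Region` (1-based inclusive everywhere in the library; the 0-based
half-open convention appears only in the BED-like fragment export), and
structures as :class:`StructureRecord` (heavy atoms only, with explicit
receptor/ligand role labels).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
from Bio import SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class InputError(ValueError):
    """Raised when a syntactically valid input cannot be used."""


@dataclass(frozen=True)
class ChainSequence:
    """One protein chain: an accession, a chain label and its sequence.

    ``first_residue_number`` carries the author numbering of position 1 so
    that delimitations given in author coordinates can be converted to the
    1-based internal convention.
    """

    source_id: str
    chain_label: str
    sequence: str
    first_residue_number: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"empty sequence for {self.source_id}")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            pos = min(i for i, c in enumerate(self.sequence) if c in bad) + 1
            raise FormatError(
                f"illegal residue letter {sorted(bad)[0]!r} in record "
                f"{self.source_id!r} at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive residue interval in parent-sequence coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def validate_on(self, parent_length: int) -> None:
        if self.end > parent_length:
            raise ValueError(
                f"region ({self.start}, {self.end}) exceeds parent length "
                f"{parent_length}"
            )

    def intersection_length(self, other: "Region") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "Region") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class ResidueRecord:
    """One residue: author number, 3-letter name, heavy atoms with coords."""

    number: int
    name: str
    atoms: dict  # atom name -> np.ndarray shape (3,)

    def backbone(self) -> dict:
        return {a: self.atoms[a] for a in BACKBONE_ATOMS if a in self.atoms}


@dataclass
class StructureRecord:
    """A two-role complex: per-chain residue lists plus receptor/ligand labels."""

    chains: dict  # chain label -> list[ResidueRecord]
    roles: dict  # chain label -> "receptor" | "ligand"

    def __post_init__(self) -> None:
        ligands = [c for c, r in self.roles.items() if r == "ligand"]
        if len(ligands) != 1:
            raise InputError(
                f"exactly one ligand chain required, got {ligands!r}"
            )

    @property
    def ligand_chain(self) -> str:
        return next(c for c, r in self.roles.items() if r == "ligand")

    @property
    def receptor_chains(self) -> list:
        return [c for c, r in self.roles.items() if r == "receptor"]

    def chain_residues(self, label: str) -> list:
        return self.chains[label]


def read_fasta(path) -> list[ChainSequence]:
    """Read a FASTA file into :class:`ChainSequence` records.

    Sequences are uppercased; ``*`` and whitespace are stripped. An empty
    file or an illegal residue letter raises :class:`FormatError`.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace("*", "").replace(" ", "").upper()
        records.append(ChainSequence(source_id=rec.id, chain_label=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


_OX_RE = re.compile(r"\bOX=(\d+)")


def default_taxon_extractor(header: str) -> str:
    """Taxon key from a UniProt-style header.

    Prefers the ``OX=<digits>`` tag; otherwise falls back to the token after
    the last underscore of the identifier (e.g. ``sp|P12345|NAME_HUMAN`` ->
    ``HUMAN``). Returns the whole identifier when neither applies.
    """
    m = _OX_RE.search(header)
    if m:
        return m.group(1)
    ident = header.split()[0]
    if "_" in ident:
        return ident.rsplit("_", 1)[1]
    return ident


def make_regex_taxon_extractor(pattern: str) -> Callable[[str], str]:
    """A taxon extractor pulling group 1 of ``pattern`` from the header."""
    rx = re.compile(pattern)

    def _extract(header: str) -> str:
        m = rx.search(header)
        if m is None:
            raise FormatError(f"taxon pattern {pattern!r} not found in {header!r}")
        return m.group(1)

    return _extract


def _parse_a3m_records(path: Path):
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                continue
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:]
                chunks = []
            elif header is not None:
                chunks.append(line.strip())
    if header is not None:
        yield header, "".join(chunks)


def read_a3m(path, taxon_extractor: Callable[[str], str] | None = None):
    """Read an A3M alignment into a species-tagged MSA.

    The first record is the query; lowercase letters in later rows are
    insertions relative to the query and are dropped from the match-state
    matrix (but counted in provenance). Rows sharing a taxon key keep only
    the first occurrence.
    """
    from .msa_coalign import SpeciesTaggedMSA  # deferred: avoids cycle

    if taxon_extractor is None:
        taxon_extractor = default_taxon_extractor
    path = Path(path)
    records = list(_parse_a3m_records(path))
    if not records:
        raise FormatError(f"no records in {path}")
    q_header, q_seq = records[0]
    if any(c.islower() for c in q_seq):
        raise FormatError(f"query row of {path} contains lowercase (insertion) states")
    if "-" in q_seq:
        raise FormatError(f"query row of {path} contains gaps")
    query = ChainSequence(source_id=q_header.split()[0], chain_label=q_header.split()[0], sequence=q_seq.upper())
    width = len(q_seq)

    rows = []
    seen: set[str] = set()
    n_insertions = 0
    for header, raw in records[1:]:
        match = "".join(c for c in raw if not c.islower())
        n_insertions += sum(1 for c in raw if c.islower())
        if len(match) != width:
            raise FormatError(
                f"row {header!r}: match-state length {len(match)} != query length {width}"
            )
        taxon = taxon_extractor(header)
        if taxon in seen:
            continue
        seen.add(taxon)
        rows.append((taxon, match.upper()))
    return SpeciesTaggedMSA(
        query=query,
        rows=rows,
        provenance={"source": str(path), "insertions_dropped": n_insertions},
    )


def _pick_altloc(atoms: Sequence[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy, ties broken alphabetically by altloc
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path, role_map: Mapping[str, str] | None = None) -> StructureRecord:
    """Read a PDB or mmCIF complex into a :class:`StructureRecord`.

    Hydrogens are dropped; alternative locations resolve to the highest
    occupancy (alphabetical on ties). Unless ``role_map`` assigns roles
    explicitly, the shortest polymer chain becomes the ligand and every
    other chain a receptor; a length tie makes the roles unresolvable.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains: dict[str, list[ResidueRecord]] = {}
    for chain in model:
        residues = []
        for res in chain:
            if res.is_water():
                continue
            groups: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element == gemmi.Element("H") or atom.element == gemmi.Element("D"):
                    continue
                groups.setdefault(atom.name, []).append(atom)
            atoms = {}
            for name, group in groups.items():
                a = _pick_altloc(group)
                atoms[name] = np.array([a.pos.x, a.pos.y, a.pos.z])
            if atoms:
                residues.append(ResidueRecord(number=res.seqid.num, name=res.name, atoms=atoms))
        if residues:
            chains[chain.name] = residues
    if len(chains) < 2:
        raise InputError(f"{path} has {len(chains)} polymer chain(s); a complex needs >= 2")

    if role_map is not None:
        roles = dict(role_map)
        unknown = set(roles) - set(chains)
        if unknown:
            raise InputError(f"role map names unknown chains {sorted(unknown)}")
        for label in chains:
            roles.setdefault(label, "receptor")
    else:
        lengths = {label: len(res) for label, res in chains.items()}
        min_len = min(lengths.values())
        shortest = sorted(label for label, n in lengths.items() if n == min_len)
        if len(shortest) > 1:
            raise InputError(
                f"chains {shortest} tie at length {min_len}; pass an explicit "
                "role map to assign receptor/ligand roles"
            )
        roles = {label: ("ligand" if label == shortest[0] else "receptor") for label in chains}
    return StructureRecord(chains=chains, roles=roles)


SCORE_COLUMNS = [
    "case_id",
    "protocol",
    "run_index",
    "model_index",
    "plddt",
    "ptm",
    "iptm",
    "confidence",
    "fnat",
    "irmsd",
    "lrmsd",
    "dockq",
    "capri_class",
]


def write_score_table(records: Iterable[Mapping], path) -> None:
    """Write per-model score records as CSV with a stable column order.

    Records must share a schema; metric columns are optional but must be
    present in either all or none of the records.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to write")
    keysets = {tuple(sorted(r.keys())) for r in records}
    if len(keysets) > 1:
        raise ValueError("records have mixed schemas")
    df = pd.DataFrame.from_records(records)
    cols = [c for c in SCORE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.12g")


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
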