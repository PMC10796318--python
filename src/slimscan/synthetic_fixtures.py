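"""Seed-reproducible synthetic inputs for exercising the whole pipeline.

Nothing here imitates real predictor output distributions; the fixtures are
geometric and combinatorial controls.  The toy complex is a two-helix
receptor with a groove holding an extended peptide (N, CA, C, O, CB atoms,
ideal 3.8 A CA-CA spacing) — enough heavy atoms for every interface metric
without a rotamer library.  Decoys rigidly displace the peptide so that
larger perturbations give strictly larger ligand RMSD.  MSA pairs carry a
controlled number of shared taxa; ELM-style tables and MM-align-style text
are generated with controlled corruption for the filtering logic.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .formats_io import ChainSequence, Region, ResidueRecord, StructureRecord
from .msa_coalign import SpeciesTaggedMSA
from .quality_eval import ReferenceComplex

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


@dataclass
class FixtureSpec:
    seed: int = 0
    receptor_size: int = 40  # residues, split over the two groove helices
    peptide_length: int = 12
    decoy_perturbations: list = field(default_factory=list)  # (rot deg, trans A)
    n_receptor_homologs: int = 8
    n_ligand_homologs: int = 6
    n_shared_taxa: int = 4

    def __post_init__(self) -> None:
        if self.receptor_size < 20:
            raise ValueError("receptor must have >= 20 residues")
        if not (6 <= self.peptide_length <= 39):
            raise ValueError("peptide length must be in [6, 39]")
        for rot, trans in self.decoy_perturbations:
            if rot < 0 or trans < 0:
                raise ValueError("perturbation magnitudes must be >= 0")


def _random_sequence(rng, n: int) -> str:
    return "".join(rng.choice(list(AA20)) for _ in range(n))


def _residue(number: int, letter: str, ca: np.ndarray, axis: np.ndarray,
             radial: np.ndarray) -> ResidueRecord:
    """A reduced residue: backbone placed by simple offsets from the CA."""
    perp = np.cross(axis, radial)
    atoms = {
        "N": ca - 1.2 * axis + 0.4 * perp,
        "CA": ca,
        "C": ca + 1.2 * axis - 0.4 * perp,
        "O": ca + 1.4 * axis + 0.8 * perp,
        "CB": ca + 1.5 * radial,
    }
    return ResidueRecord(number=number, name=AA3.get(letter, "ALA"), atoms=atoms)


def _helix(sequence: str, origin: np.ndarray, start_number: int = 1,
           phase: float = 0.0) -> list:
    """Ideal alpha-helical CA trace along +z (2.3 A radius, 1.5 A rise)."""
    residues = []
    axis = np.array([0.0, 0.0, 1.0])
    for i, letter in enumerate(sequence):
        ang = phase + np.deg2rad(100.0) * i
        radial = np.array([np.cos(ang), np.sin(ang), 0.0])
        ca = origin + 2.3 * radial + np.array([0.0, 0.0, 1.5 * i])
        residues.append(_residue(start_number + i, letter, ca, axis, radial))
    return residues


def _strand(sequence: str, origin: np.ndarray, start_number: int = 1) -> list:
    """Extended chain along +z, 3.8 A CA-CA, CB pointing away from the groove."""
    residues = []
    axis = np.array([0.0, 0.0, 1.0])
    radial = np.array([1.0, 0.0, 0.0])
    for i, letter in enumerate(sequence):
        ca = origin + np.array([0.0, 0.0, 3.8 * i])
        residues.append(_residue(start_number + i, letter, ca, axis, radial))
    return residues


def make_toy_complex(spec: FixtureSpec, workdir=None):
    """A two-helix receptor with a peptide lying in its groove.

    Returns ``(ReferenceComplex, {"pdb": path})``; the PDB is written only
    when ``workdir`` is given. The peptide is centered along the groove and
    makes at least 5 native contacts at 5 A by construction.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = spec.receptor_size // 2
    n2 = spec.receptor_size - n1
    rec_seq = _random_sequence(rng, spec.receptor_size)
    pep_seq = _random_sequence(rng, spec.peptide_length)

    helix1 = _helix(rec_seq[:n1], np.array([0.0, 0.0, 0.0]), start_number=1)
    helix2 = _helix(
        rec_seq[n1:], np.array([0.0, 7.6, 0.0]), start_number=n1 + 1,
        phase=np.pi,
    )
    # center the peptide along the groove between the two helices
    groove_len = 1.5 * (min(n1, n2) - 1)
    pep_len = 3.8 * (spec.peptide_length - 1)
    z0 = max(0.0, (groove_len - pep_len) / 2.0)
    peptide = _strand(pep_seq, np.array([4.4, 3.8, z0]), start_number=1)

    structure = StructureRecord(
        chains={"A": helix1 + helix2, "B": peptide},
        roles={"A": "receptor", "B": "ligand"},
    )
    ref = ReferenceComplex(
        structure=structure,
        receptor_region=Region(1, spec.receptor_size),
        ligand_region=Region(1, spec.peptide_length),
    )
    files = {}
    if workdir is not None:
        path = Path(workdir) / f"toy_complex_seed{spec.seed}.synthetic.pdb"
        write_pdb(structure, path)
        files["pdb"] = path
    return ref, files


def structure_to_gemmi(record: StructureRecord, name: str = "toy") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model("1")
    for label, residues in record.chains.items():
        chain = gemmi.Chain(label)
        for res in residues:
            r = gemmi.Residue()
            r.name = res.name
            r.seqid = gemmi.SeqId(res.number, " ")
            for atom_name, xyz in res.atoms.items():
                a = gemmi.Atom()
                a.name = atom_name
                a.element = gemmi.Element(atom_name[0])
                a.pos = gemmi.Position(*xyz)
                a.occ = 1.0
                r.add_atom(a)
            chain.add_residue(r)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(record: StructureRecord, path) -> None:
    structure_to_gemmi(record).write_pdb(str(path))


def _rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def transform_ligand(record: StructureRecord, rotation_deg: float = 0.0,
                     translation: np.ndarray | float = 0.0,
                     axis=(0.0, 1.0, 0.0),
                     direction=(0.0, 0.0, 1.0)) -> StructureRecord:
    """Rigidly move the ligand chain: rotate about its centroid, then translate.

    A scalar ``translation`` moves along ``direction`` (default: along the
    groove, +z), so the ligand RMSD of the result equals the scalar exactly
    when the rotation is zero.
    """
    out = copy.deepcopy(record)
    lig = out.ligand_chain
    residues = out.chains[lig]
    coords = np.array([xyz for r in residues for xyz in r.atoms.values()])
    centroid = coords.mean(axis=0)
    R = _rotation_matrix(np.asarray(axis, dtype=float), rotation_deg)
    if np.isscalar(translation):
        t = float(translation) * np.asarray(direction, dtype=float)
    else:
        t = np.asarray(translation, dtype=float)
    for res in residues:
        for name in res.atoms:
            res.atoms[name] = R @ (res.atoms[name] - centroid) + centroid + t
    return out


def displace_ligand(record: StructureRecord, magnitude: float, rng) -> StructureRecord:
    """Slide the ligand ``magnitude`` A along the groove, with a tiny rng jitter.

    The fixed displacement axis keeps model quality a monotone function of
    the magnitude; the sub-0.1 A jitter makes each pose seed-dependent.
    """
    t = magnitude * np.array([0.0, 0.0, 1.0]) + rng.normal(0.0, 0.03, size=3)
    return transform_ligand(record, translation=t)


# Default ladder spanning all four peptide-quality classes on the toy groove
DEFAULT_DECOY_LADDER = [(0.0, 0.0), (0.0, 1.0), (0.0, 2.0), (0.0, 4.0), (0.0, 50.0)]


def make_decoys(ref: ReferenceComplex, magnitudes=None) -> list:
    """Rigid-ligand decoys of a reference, one per (rotation, translation).

    Translations slide the peptide along the groove axis, so a ladder of
    strictly increasing translation magnitudes (at zero rotation) gives
    strictly increasing ligand RMSD; the default ladder starts at the
    zero-perturbation decoy and ends far outside the interface.
    """
    if magnitudes is None:
        magnitudes = DEFAULT_DECOY_LADDER
    return [
        transform_ligand(ref.structure, rotation_deg=rot, translation=trans)
        for rot, trans in magnitudes
    ]


def make_msa_pair(n_receptor: int, n_ligand: int, n_shared_taxa: int,
                  seed: int = 0, receptor_length: int = 60,
                  ligand_length: int = 24, mutation_rate: float = 0.35):
    """Receptor and ligand MSAs with exactly ``n_shared_taxa`` common taxa."""
    if n_shared_taxa > min(n_receptor, n_ligand):
        raise ValueError("shared taxa cannot exceed either homolog count")
    rng = np.random.default_rng(seed)

    def build(tag: str, query_len: int, n_rows: int, taxa: list):
        query = ChainSequence(f"{tag}_query", tag, _random_sequence(rng, query_len))
        rows = []
        for taxon in taxa:
            row = [
                (rng.choice(list(AA20)) if rng.random() < mutation_rate else c)
                for c in query.sequence
            ]
            # a few gap columns, never all of them
            n_gaps = int(rng.integers(0, max(1, query_len // 10)))
            for pos in rng.choice(query_len, size=n_gaps, replace=False):
                row[pos] = "-"
            rows.append((taxon, "".join(row)))
        return SpeciesTaggedMSA(query=query, rows=rows, provenance={"seed": seed})

    shared = [f"tax{9000 + i}" for i in range(n_shared_taxa)]
    rec_only = [f"tax{1000 + i}" for i in range(n_receptor - n_shared_taxa)]
    lig_only = [f"tax{5000 + i}" for i in range(n_ligand - n_shared_taxa)]
    receptor = build("receptor", receptor_length, n_receptor, shared + rec_only)
    ligand = build("ligand", ligand_length, n_ligand, shared + lig_only)
    return receptor, ligand


def make_elm_table(n_per_category: int, categories: list, n_no_pdb: int = 0,
                   n_multi_motif: int = 0, n_short_motif: int = 0,
                   seed: int = 0, path=None):
    """An ELM-style motif table with controlled corruption.

    ``n_no_pdb`` entries lose their PDB references and a disjoint
    ``n_multi_motif`` entries are marked as carrying a second motif of the
    same type; ``n_short_motif`` entries (from the clean remainder) get
    motifs shorter than 5 residues. Returns the entry list; also writes the
    TSV dialect of :mod:`slimscan.dataset_prep` when ``path`` is given.
    """
    from .dataset_prep import ELM_TSV_COLUMNS, ElmEntry

    if not categories:
        raise ValueError("at least one category required")
    rng = np.random.default_rng(seed)
    total = n_per_category * len(categories)
    if n_no_pdb + n_multi_motif > total:
        raise ValueError("corruption counts exceed table size")
    corrupt = rng.permutation(total)
    no_pdb_idx = set(corrupt[:n_no_pdb].tolist())
    multi_idx = set(corrupt[n_no_pdb : n_no_pdb + n_multi_motif].tolist())
    clean = [i for i in corrupt[n_no_pdb + n_multi_motif :].tolist()]
    short_idx = set(clean[:n_short_motif])

    entries = []
    i = 0
    for cat in categories:
        for k in range(n_per_category):
            ligand_length = int(rng.integers(80, 400))
            mlen = 3 if i in short_idx else int(rng.integers(5, 16))
            start = int(rng.integers(1, ligand_length - mlen + 1))
            entries.append(
                ElmEntry(
                    entry_id=f"{cat}_{k:04d}",
                    elm_type=cat,
                    elm_class="LIG" if rng.random() < 0.7 else "DOC",
                    motif=Region(start, start + mlen - 1),
                    ligand_length=ligand_length,
                    receptor_domain=Region(1, int(rng.integers(60, 200))),
                    has_pubmed=True,
                    pdb_refs=[] if i in no_pdb_idx else [f"{rng.integers(1, 9)}XX{k % 10}"],
                    motif_count_in_ligand=2 if i in multi_idx else 1,
                )
            )
            i += 1
    if path is not None:
        import pandas as pd

        rows = []
        for e in entries:
            rows.append(
                {
                    "entry_id": e.entry_id,
                    "elm_type": e.elm_type,
                    "elm_class": e.elm_class,
                    "ligand_acc": f"P{abs(hash(e.entry_id)) % 100000:05d}",
                    "ligand_length": e.ligand_length,
                    "motif_start": e.motif.start,
                    "motif_end": e.motif.end,
                    "receptor_acc": "Q00001",
                    "domain_start": e.receptor_domain.start,
                    "domain_end": e.receptor_domain.end,
                    "pubmed_ids": "12345678" if e.has_pubmed else "",
                    "pdb_refs": ";".join(e.pdb_refs),
                    "motif_count": e.motif_count_in_ligand,
                }
            )
        pd.DataFrame(rows, columns=ELM_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    return entries


MMALIGN_TEMPLATE = """\
 ********************************************************************
 * MM-align (Version 20191021): complex structure alignment         *
 ********************************************************************

Name of Structure_1: model1.pdb
Name of Structure_2: model2.pdb
Length of Structure_1: {len1} residues
Length of Structure_2: {len2} residues

Aligned length= {aligned}, RMSD= {rmsd:.2f}, Seq_ID=n_identical/n_aligned= 0.310
TM-score= {tm1:.5f} (normalized by length of Structure_1)
TM-score= {tm2:.5f} (normalized by length of Structure_2)
TM-score= {tma:.5f} (normalized by average length of two structures)

(":" denotes residue pairs of d < 5.0 Angstrom, "." denotes other aligned residues)
{seq1}
{marks}
{seq2}
"""


def make_mmalign_output(tm_scores, marks: str, seq1: str | None = None,
                        seq2: str | None = None, rmsd: float = 2.1) -> str:
    """MM-align-shaped stdout text (option -a layout) for parser tests."""
    tm1, tm2, tma = tm_scores
    n = len(marks)
    if seq1 is None:
        seq1 = "A" * n
    if seq2 is None:
        seq2 = "A" * n
    return MMALIGN_TEMPLATE.format(
        len1=n, len2=n, aligned=n, rmsd=rmsd, tm1=tm1, tm2=tm2, tma=tma,
        seq1=seq1, marks=marks, seq2=seq2,
    )
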