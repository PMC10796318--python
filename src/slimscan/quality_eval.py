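"""Model-vs-reference quality metrics for protein-peptide complexes.

A predicted complex is compared to its experimental reference on the
residues common to both (the model is conceptually cut to the reference
delimitations first).  The metrics are the protein-peptide CAPRI set:

fnat
    fraction of native receptor-ligand residue contacts (any heavy-atom
    pair within 5.0 A) reproduced by the model;
iRMSD
    backbone RMSD over the interface residues (reference residues with a
    heavy atom within 10.0 A of the other chain) after superposing on those
    residues;
L-RMSD
    ligand backbone RMSD after superposing on the receptor backbone;
DockQ
    (fnat + 1/(1+(iRMSD/1.5)^2) + 1/(1+(L-RMSD/8.5)^2)) / 3;
CAPRI class
    Incorrect < Acceptable < Medium < High from threshold rules on
    (fnat, L-RMSD, iRMSD).

FRIR (fraction of native interface residues recalled) and FRNNAT (fraction
of model contacts that are non-native) are reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.spatial import cKDTree

from .formats_io import BACKBONE_ATOMS, InputError, Region, StructureRecord

CONTACT_CUTOFF = 5.0  # A, heavy atoms, fnat/FRNNAT
INTERFACE_CUTOFF = 10.0  # A, heavy atoms, interface residue selection
DOCKQ_D1 = 1.5  # A, iRMSD scaling
DOCKQ_D2 = 8.5  # A, L-RMSD scaling


class CapriClass(IntEnum):
    """Ordered protein-peptide model quality classes."""

    Incorrect = 0
    Acceptable = 1
    Medium = 2
    High = 3

    def __str__(self) -> str:  # for CSV output
        return self.name


@dataclass
class QualityMetrics:
    fnat: float
    irmsd: float
    lrmsd: float
    dockq: float
    capri_class: CapriClass
    frir: float
    frnnat: float
    n_common_residues: int


@dataclass
class ReferenceComplex:
    """An experimental reference plus the model<->reference residue mapping.

    ``mapping`` (chain label -> {model residue number -> reference residue
    number}) defaults to the identity on shared residue numbers.
    """

    structure: StructureRecord
    receptor_region: Region | None = None
    ligand_region: Region | None = None
    mapping: dict | None = None

    def map_residue(self, chain: str, number: int) -> int:
        if self.mapping is None or chain not in self.mapping:
            return number
        return self.mapping[chain].get(number, None)


def superpose(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid-body fit of ``mobile`` onto ``target`` (Kabsch).

    Returns ``(rotation (3,3), translation (3,), rmsd)`` with a proper
    rotation (det = +1). Degenerate (collinear or near-collinear) point sets
    are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("paired (n, 3) coordinate sets required")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need >= 3 paired atoms, got {n}")
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    P = mobile - mc
    Q = target - tc
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear sets leave the rotation about the line undetermined
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tc - R @ mc
    moved = (R @ mobile.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))
    return R, t, rmsd


def _chain_atoms(structure: StructureRecord, label: str):
    """(coords (n,3), parallel residue numbers) over heavy atoms of a chain."""
    coords, numbers = [], []
    for res in structure.chain_residues(label):
        for xyz in res.atoms.values():
            coords.append(xyz)
            numbers.append(res.number)
    return np.asarray(coords), np.asarray(numbers)


def _residue_pairs_within(structure: StructureRecord, rec_label: str,
                          lig_label: str, cutoff: float) -> set:
    rc, rn = _chain_atoms(structure, rec_label)
    lc, ln = _chain_atoms(structure, lig_label)
    pairs = set()
    if len(rc) == 0 or len(lc) == 0:
        return pairs
    tree = cKDTree(rc)
    for hits, lnum in zip(tree.query_ball_point(lc, cutoff), ln):
        for h in hits:
            pairs.add((int(rn[h]), int(lnum)))
    return pairs


def native_contacts(ref: ReferenceComplex, cutoff: float = CONTACT_CUTOFF) -> set:
    """All (receptor residue, ligand residue) pairs with heavy atoms <= cutoff.

    For multi-chain receptors the receptor residue is ``(chain, number)``;
    single-receptor complexes use the bare number.
    """
    st = ref.structure
    lig = st.ligand_chain
    out = set()
    multi = len(st.receptor_chains) > 1
    for rec in st.receptor_chains:
        for rnum, lnum in _residue_pairs_within(st, rec, lig, cutoff):
            out.add(((rec, rnum) if multi else rnum, lnum))
    return out


def classify_capri(fnat: float, lrmsd: float, irmsd: float) -> CapriClass:
    """CAPRI protein-peptide class from (fnat, L-RMSD, iRMSD).

    Lower bounds of the printed fnat intervals are inclusive; the shared
    endpoints resolve in favor of the higher class.
    """
    if not (0.0 <= fnat <= 1.0):
        raise ValueError(f"fnat must be in [0, 1], got {fnat}")
    if lrmsd < 0 or irmsd < 0:
        raise ValueError("RMSDs must be >= 0")
    if fnat >= 0.8 and (lrmsd <= 1.0 or irmsd <= 0.5):
        return CapriClass.High
    if (0.5 <= fnat < 0.8 and (lrmsd <= 2.0 or irmsd <= 1.0)) or (
        fnat >= 0.8 and lrmsd > 1.0 and irmsd > 0.5
    ):
        return CapriClass.Medium
    if (0.2 <= fnat < 0.5 and (lrmsd <= 4.0 or irmsd <= 2.0)) or (
        fnat >= 0.5 and lrmsd > 2.0 and irmsd > 1.0
    ):
        return CapriClass.Acceptable
    return CapriClass.Incorrect


def dockq_score(fnat: float, irmsd: float, lrmsd: float) -> float:
    return (
        fnat
        + 1.0 / (1.0 + (irmsd / DOCKQ_D1) ** 2)
        + 1.0 / (1.0 + (lrmsd / DOCKQ_D2) ** 2)
    ) / 3.0


def _paired_backbone(model_res: dict, ref_res: dict, numbers) -> tuple:
    """Paired backbone coordinate arrays over shared residues/atoms."""
    m, r = [], []
    for num in numbers:
        mres = model_res.get(num)
        rres = ref_res.get(num)
        if mres is None or rres is None:
            continue
        for atom in BACKBONE_ATOMS:
            if atom in mres.atoms and atom in rres.atoms:
                m.append(mres.atoms[atom])
                r.append(rres.atoms[atom])
    return np.asarray(m), np.asarray(r)


def _by_number(residues) -> dict:
    return {res.number: res for res in residues}


def _interface_residue_keys(structure: StructureRecord, cutoff: float) -> set:
    """(chain, residue number) keys of residues near the other role's chain."""
    st = structure
    lig = st.ligand_chain
    keys = set()
    for rec in st.receptor_chains:
        pairs = _residue_pairs_within(st, rec, lig, cutoff)
        for rnum, lnum in pairs:
            keys.add((rec, rnum))
            keys.add((lig, lnum))
    return keys


def evaluate_model(model: StructureRecord, ref: ReferenceComplex,
                   irmsd_interface: str = "10A") -> QualityMetrics:
    """All quality metrics for one model against one reference.

    ``irmsd_interface`` selects whether the iRMSD residue set is the 10 A
    interface ("10A", default) or the residues of the 5 A native contacts
    ("contact").
    """
    st = ref.structure
    if set(model.roles.items()) != set(st.roles.items()):
        # same chain labels/roles required; residue mapping handles numbering
        common_labels = set(model.chains) & set(st.chains)
        if not common_labels:
            raise InputError("model and reference share no chain labels")
    lig = st.ligand_chain

    # common residue mapping, per chain, by residue number
    model_res = {c: _by_number(model.chain_residues(c)) for c in model.chains}
    ref_res = {c: _by_number(st.chain_residues(c)) for c in st.chains}
    common = {
        c: sorted(set(model_res[c]) & set(ref_res[c]))
        for c in set(model_res) & set(ref_res)
    }
    n_common = sum(len(v) for v in common.values())
    if not common.get(lig):
        raise InputError("no common ligand residues between model and reference")

    # restrict both structures to the common mapping ("cut to delimitations")
    def cut(struc: StructureRecord) -> StructureRecord:
        chains = {
            c: [r for r in struc.chain_residues(c) if r.number in set(common[c])]
            for c in common
        }
        return StructureRecord(chains=chains, roles={c: st.roles[c] for c in common})

    model_c = cut(model)
    ref_c = cut(st)

    native = native_contacts(ReferenceComplex(structure=ref_c))
    model_contacts = native_contacts(ReferenceComplex(structure=model_c))
    if native:
        fnat = len(model_contacts & native) / len(native)
    else:
        fnat = float("nan")
    frnnat = (
        len(model_contacts - native) / len(model_contacts) if model_contacts else 0.0
    )

    # L-RMSD: fit on receptor backbone, measure ligand backbone
    rec_m, rec_r = [], []
    for c in st.receptor_chains:
        if c not in common:
            continue
        m, r = _paired_backbone(model_res[c], ref_res[c], common[c])
        if len(m):
            rec_m.append(m)
            rec_r.append(r)
    if not rec_m:
        raise InputError("no mapped receptor backbone atoms")
    rec_m = np.vstack(rec_m)
    rec_r = np.vstack(rec_r)
    if len(rec_m) < 3:
        raise InputError(f"need >= 3 mapped receptor backbone atoms, got {len(rec_m)}")
    R, t, _ = superpose(rec_m, rec_r)
    lig_m, lig_r = _paired_backbone(model_res[lig], ref_res[lig], common[lig])
    if len(lig_m) == 0:
        raise InputError("no mapped ligand backbone atoms")
    moved = (R @ lig_m.T).T + t
    lrmsd = float(np.sqrt(np.mean(np.sum((moved - lig_r) ** 2, axis=1))))

    # iRMSD: fit and measure on interface backbone
    if irmsd_interface == "contact":
        iface_keys = _interface_residue_keys(ref_c, CONTACT_CUTOFF)
    else:
        iface_keys = _interface_residue_keys(ref_c, INTERFACE_CUTOFF)
    im, ir = [], []
    for c in common:
        nums = [n for n in common[c] if (c, n) in iface_keys]
        m, r = _paired_backbone(model_res[c], ref_res[c], nums)
        if len(m):
            im.append(m)
            ir.append(r)
    if im and sum(len(x) for x in im) >= 3:
        _, _, irmsd = superpose(np.vstack(im), np.vstack(ir))
    else:
        irmsd = float("inf")

    if np.isnan(fnat):
        capri = CapriClass.Incorrect
        dockq = 0.0
        fnat_out = 0.0
        frir = 0.0
    else:
        capri = classify_capri(fnat, lrmsd, irmsd)
        dockq = dockq_score(fnat, irmsd, lrmsd)
        fnat_out = fnat
        native_iface = _interface_residue_keys(ref_c, INTERFACE_CUTOFF)
        model_iface = _interface_residue_keys(model_c, INTERFACE_CUTOFF)
        frir = (
            len(native_iface & model_iface) / len(native_iface)
            if native_iface
            else 0.0
        )
    return QualityMetrics(
        fnat=fnat_out,
        irmsd=irmsd,
        lrmsd=lrmsd,
        dockq=dockq,
        capri_class=capri,
        frir=frir,
        frnnat=frnnat,
        n_common_residues=n_common,
    )


def choose_reference(model: StructureRecord, candidate_refs) -> tuple:
    """Evaluate against every candidate reference and keep the DockQ maximizer.

    Candidates may include homologous references and symmetry-alternative
    copies of the same reference; all are scored, the best is returned as
    ``(reference, metrics)``.
    """
    candidates = list(candidate_refs)
    if not candidates:
        raise ValueError("at least one candidate reference required")
    best = None
    errors = []
    for ref in candidates:
        try:
            metrics = evaluate_model(model, ref)
        except (InputError, ValueError) as exc:
            errors.append(str(exc))
            continue
        if best is None or metrics.dockq > best[1].dockq:
            best = (ref, metrics)
    if best is None:
        raise InputError(
            "no candidate reference could be mapped: " + "; ".join(errors)
        )
    return best
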