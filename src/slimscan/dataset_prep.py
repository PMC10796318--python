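"""Benchmark construction logic: redundancy filters and ELM-table preparation.

Candidate receptor-peptide complexes are screened against structures that a
predictor may have trained on, in two stages: a sequence filter (a receptor
homolog at >= 30% identity bound to a partner in the same region) and a
structural filter on interface similarity (MM-align TM-score > 0.5, counted
only when at least 5 consecutive ligand residues aligned within 5.0 A).
MM-align itself is external; only its text output is parsed here.

ELM-style motif tables are reduced to the evaluable set: LIG/DOC classes
with a PubMed reference and defined delimitations, a reference PDB
structure, and a unique motif of the type in the ligand; motifs shorter
than 5 residues are extended to 5.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
import pandas as pd

from .formats_io import FormatError, Region
from .fragmenter import extend_motif

SEQ_IDENTITY_THRESHOLD = 30.0  # percent
TM_THRESHOLD = 0.5
MIN_CONSECUTIVE_LIGAND_RUN = 5
MIN_MOTIF_LENGTH = 5


@dataclass
class RedundancyVerdict:
    candidate_id: str
    decision: str  # kept | discarded_sequence | discarded_structure
    best_tm: float | None = None
    longest_run: int | None = None

    def __post_init__(self) -> None:
        if self.decision == "discarded_structure":
            assert self.best_tm is not None and self.best_tm > TM_THRESHOLD
            assert (
                self.longest_run is not None
                and self.longest_run >= MIN_CONSECUTIVE_LIGAND_RUN
            )


@dataclass
class ElmEntry:
    """One receptor/ligand pair from an ELM-style motif table."""

    entry_id: str
    elm_type: str  # category, e.g. LIG_LIR_Gen_1
    elm_class: str  # LIG | DOC | other
    motif: Region | None
    ligand_length: int
    receptor_domain: Region | None = None
    has_pubmed: bool = True
    pdb_refs: list = field(default_factory=list)
    motif_count_in_ligand: int = 1

    def __post_init__(self) -> None:
        if not self.elm_type:
            raise ValueError("category string must be non-empty")
        if self.motif is not None:
            self.motif.validate_on(self.ligand_length)


def sequence_redundancy(
    candidate_id: str,
    prior_hits: list,
    threshold: float = SEQ_IDENTITY_THRESHOLD,
) -> RedundancyVerdict:
    """Sequence-level filter against previously released receptor homologs.

    ``prior_hits`` carries ``(identity_percent, same_region)`` pairs for
    homologs of the receptor released before the training cutoff; the
    candidate is discarded iff any hit reaches the identity threshold while
    binding a partner in the same receptor region.
    """
    for identity, same_region in prior_hits:
        if identity >= threshold and same_region:
            return RedundancyVerdict(candidate_id, "discarded_sequence")
    return RedundancyVerdict(candidate_id, "kept")


@dataclass
class MMAlignResult:
    tm_scores: tuple  # the three printed TM-scores
    alignment_marks: str  # ':' / '.' / ' ' per aligned column
    tm_max: float
    longest_run: int  # longest run of ':' marks


def longest_colon_run(marks: str) -> int:
    best = cur = 0
    for c in marks:
        cur = cur + 1 if c == ":" else 0
        best = max(best, cur)
    return best


_TM_RE = re.compile(r"^TM-score=\s*([0-9.]+)")


def parse_mmalign(text: str) -> MMAlignResult:
    """Parse MM-align (-a option) stdout: three TM-scores and the marks line.

    The marks line sits between the two aligned sequences, two lines below
    the comment explaining that ':' denotes residue pairs closer than 5 A.
    """
    lines = text.splitlines()
    scores = []
    for line in lines:
        m = _TM_RE.match(line.strip())
        if m:
            scores.append(float(m.group(1)))
    if len(scores) < 3:
        raise FormatError(
            f"expected 3 TM-score lines (option -a), found {len(scores)}"
        )
    marks = None
    for i, line in enumerate(lines):
        if '":" denotes' in line:
            if i + 2 >= len(lines):
                raise FormatError(
                    f"truncated alignment block after line {i + 1}"
                )
            marks = lines[i + 2]
            break
    if marks is None:
        raise FormatError("no alignment annotation block found")
    tms = tuple(scores[:3])
    return MMAlignResult(
        tm_scores=tms,
        alignment_marks=marks,
        tm_max=max(tms),
        longest_run=longest_colon_run(marks),
    )


def structure_redundancy(
    tm_max: float,
    longest_run: int,
    tm_threshold: float = TM_THRESHOLD,
    run_threshold: int = MIN_CONSECUTIVE_LIGAND_RUN,
) -> bool:
    """Interface redundancy rule: TM above threshold AND a long ligand run.

    An interface whose best TM-score exceeds the threshold still does not
    count as redundant unless the aligner matched at least ``run_threshold``
    consecutive ligand residues within 5 A.
    """
    return tm_max > tm_threshold and longest_run >= run_threshold


def judge_candidate(
    candidate_id: str, tm_max: float, longest_run: int
) -> RedundancyVerdict:
    if structure_redundancy(tm_max, longest_run):
        return RedundancyVerdict(
            candidate_id, "discarded_structure", best_tm=tm_max, longest_run=longest_run
        )
    return RedundancyVerdict(
        candidate_id, "kept", best_tm=tm_max, longest_run=longest_run
    )


ELM_EXCLUSIONS = (
    "wrong_class",
    "no_pubmed",
    "no_delimitation",
    "no_pdb",
    "multi_motif",
)


def filter_elm(entries: list) -> tuple:
    """Reduce an ELM-style table to the evaluable receptor/ligand pairs.

    Filters, in order: ELM class must be LIG or DOC; a PubMed reference and
    defined delimitations are required; entries without any reference PDB
    structure are dropped; ligands carrying multiple motifs of the same type
    are dropped. Motifs shorter than 5 residues are extended symmetrically
    to 5 (clamped at chain ends). Returns ``(evaluable entries, tally)``
    where the tally partitions the input.
    """
    tally = {k: 0 for k in ELM_EXCLUSIONS}
    kept = []
    for e in entries:
        if e.elm_class not in ("LIG", "DOC"):
            tally["wrong_class"] += 1
            continue
        if not e.has_pubmed:
            tally["no_pubmed"] += 1
            continue
        if e.motif is None:
            tally["no_delimitation"] += 1
            continue
        if not e.pdb_refs:
            tally["no_pdb"] += 1
            continue
        if e.motif_count_in_ligand > 1:
            tally["multi_motif"] += 1
            continue
        motif = e.motif
        if len(motif) < MIN_MOTIF_LENGTH:
            motif = extend_motif(
                motif, e.ligand_length, MIN_MOTIF_LENGTH - len(motif)
            )
        kept.append(
            ElmEntry(
                entry_id=e.entry_id,
                elm_type=e.elm_type,
                elm_class=e.elm_class,
                motif=motif,
                ligand_length=e.ligand_length,
                receptor_domain=e.receptor_domain,
                has_pubmed=e.has_pubmed,
                pdb_refs=list(e.pdb_refs),
                motif_count_in_ligand=e.motif_count_in_ligand,
            )
        )
    tally["kept"] = len(kept)
    assert sum(tally.values()) == len(entries)
    return kept, tally


ELM_TSV_COLUMNS = [
    "entry_id",
    "elm_type",
    "elm_class",
    "ligand_acc",
    "ligand_length",
    "motif_start",
    "motif_end",
    "receptor_acc",
    "domain_start",
    "domain_end",
    "pubmed_ids",
    "pdb_refs",
    "motif_count",
]


def read_elm_table(path) -> list:
    """Read the tab-separated ELM-style table written by the fixture maker."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(ELM_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"ELM table lacks columns {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        motif = None
        if row["motif_start"] and row["motif_end"]:
            motif = Region(int(row["motif_start"]), int(row["motif_end"]))
        domain = None
        if row["domain_start"] and row["domain_end"]:
            domain = Region(int(row["domain_start"]), int(row["domain_end"]))
        entries.append(
            ElmEntry(
                entry_id=row["entry_id"],
                elm_type=row["elm_type"],
                elm_class=row["elm_class"],
                motif=motif,
                ligand_length=int(row["ligand_length"]),
                receptor_domain=domain,
                has_pubmed=bool(row["pubmed_ids"]),
                pdb_refs=[p for p in row["pdb_refs"].split(";") if p],
                motif_count_in_ligand=int(row["motif_count"] or 1),
            )
        )
    return entries


def write_verdicts(verdicts: list, path) -> None:
    pd.DataFrame(
        [
            {
                "candidate_id": v.candidate_id,
                "decision": v.decision,
                "best_tm": v.best_tm,
                "longest_run": v.longest_run,
            }
            for v in verdicts
        ]
    ).to_csv(path, index=False)
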