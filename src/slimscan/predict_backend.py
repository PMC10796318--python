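"""Contract between the pipeline and a complex-structure predictor.

Any backend maps (co-alignment, seed) to a fixed number of scored models
per run.  Two backends ship here: a command-building adapter for an
AlphaFold2-Multimer-style engine run through ColabFold (it only writes
inputs, assembles the command line and parses score files — inference
itself is external), and a deterministic mock whose interface confidence
decays with the distance between the scanned fragment and a planted motif,
for end-to-end testing without a GPU.

Scores follow the predictor conventions: per-residue pLDDT in [0, 100],
pTM and ipTM in [0, 1], and the model confidence score
``0.2 * pTM + 0.8 * ipTM``.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .formats_io import StructureRecord
from .msa_coalign import CoAlignment, write_coalignment_a3m

logger = logging.getLogger(__name__)

CONFIDENCE_PTM_WEIGHT = 0.2
CONFIDENCE_IPTM_WEIGHT = 0.8


def confidence_score(ptm: float, iptm: float) -> float:
    """Model confidence: a 20:80 weighted combination of pTM and ipTM."""
    if not (0.0 <= ptm <= 1.0) or not (0.0 <= iptm <= 1.0):
        raise ValueError(f"ptm/iptm must be in [0, 1], got ({ptm}, {iptm})")
    return CONFIDENCE_PTM_WEIGHT * ptm + CONFIDENCE_IPTM_WEIGHT * iptm


@dataclass
class PredictedModel:
    """One predicted complex with its confidence scores."""

    structure: StructureRecord | None
    plddt: np.ndarray  # per-residue, [0, 100]
    ptm: float
    iptm: float
    confidence: float
    protocol: str
    run_index: int
    model_index: int
    seed: int

    def __post_init__(self) -> None:
        if self.run_index < 0 or self.model_index < 0:
            raise ValueError("indices must be non-negative")
        expected = confidence_score(self.ptm, self.iptm)
        if abs(self.confidence - expected) > 1e-9:
            raise ValueError(
                f"confidence {self.confidence} != 0.2*ptm + 0.8*iptm = {expected}"
            )
        if np.any(self.plddt < 0) or np.any(self.plddt > 100):
            raise ValueError("pLDDT values must be in [0, 100]")


class BackendError(RuntimeError):
    pass


def protocol_seed(base_seed: int, protocol: str, run_index: int) -> int:
    """Stable per-run seed: base + crc32(protocol)*10007 + run, mod 2^31."""
    return (base_seed + zlib.crc32(protocol.encode()) * 10007 + run_index) % (2**31)


def run_protocol(
    coaln: CoAlignment,
    backend,
    protocol: str = "default",
    n_runs: int = 5,
    models_per_run: int = 5,
    base_seed: int = 0,
) -> list:
    """Run ``n_runs`` independent predictor runs of ``models_per_run`` models.

    A failing run is skipped with a warning; all runs failing is an error.
    No relaxation is applied to the returned models.
    """
    models: list = []
    failures = 0
    for r in range(n_runs):
        seed = protocol_seed(base_seed, protocol, r)
        try:
            run_models = backend.predict(coaln, seed=seed, n_models=models_per_run)
        except Exception as exc:  # noqa: BLE001 - backend is third-party code
            failures += 1
            logger.warning("run %d of protocol %s failed: %s", r, protocol, exc)
            continue
        for m, model in enumerate(run_models):
            model.protocol = protocol
            model.run_index = r
            model.model_index = m
            model.seed = seed
            models.append(model)
    if failures == n_runs:
        raise BackendError(f"all {n_runs} runs of protocol {protocol!r} failed")
    return models


class MockBackend:
    """Deterministic stand-in predictor with an optional planted motif.

    When ``planted=(motif, max_iptm)`` is given, the ipTM of a scanned
    fragment decays exponentially with the sequence gap between the
    co-alignment's ligand block and the motif; a fragment overlapping the
    motif attains ``max_iptm`` exactly (first model of the run pinned at the
    ceiling). When a ``reference`` toy complex is supplied, each model also
    carries coordinates: the reference ligand rigidly displaced by an amount
    that shrinks monotonically as the confidence grows, so model quality
    correlates with confidence by construction.
    """

    decay_scale = 120.0  # residues
    jitter_width = 0.25
    noise_sd = 0.01

    def __init__(self, planted=None, reference=None, base_iptm: float = 0.35):
        self.planted = planted
        self.reference = reference
        self.base_iptm = base_iptm

    def _base_iptm(self, coaln: CoAlignment) -> float:
        if self.planted is None:
            return self.base_iptm
        motif, max_iptm = self.planted
        lig = coaln.ligand_block().region
        gap = max(motif.start - lig.end, lig.start - motif.end, 0)
        return max_iptm * float(np.exp(-gap / self.decay_scale))

    def _structure(self, confidence: float, rng) -> StructureRecord | None:
        if self.reference is None:
            return None
        from .synthetic_fixtures import displace_ligand

        translation = max(0.0, (0.82 - confidence)) * 60.0
        return displace_ligand(self.reference.structure, translation, rng)

    def predict(self, coaln: CoAlignment, seed: int, n_models: int = 5) -> list:
        rng = np.random.default_rng(seed)
        base = self._base_iptm(coaln)
        models = []
        for m in range(n_models):
            if m == 0:
                iptm = base
            else:
                jitter = rng.uniform(0.0, self.jitter_width)
                noise = rng.normal(0.0, self.noise_sd)
                # the planted ceiling caps every model of the fragment
                iptm = float(np.clip(base * (1.0 - jitter) + noise, 0.0, base))
            ptm = float(np.clip(iptm + rng.uniform(-0.05, 0.1), 0.0, 1.0))
            conf = confidence_score(ptm, iptm)
            n_res = coaln.width
            plddt = np.clip(
                55.0 + 40.0 * iptm + rng.normal(0.0, 3.0, size=n_res), 0.0, 100.0
            )
            models.append(
                PredictedModel(
                    structure=self._structure(conf, rng),
                    plddt=plddt,
                    ptm=ptm,
                    iptm=iptm,
                    confidence=conf,
                    protocol="mock",
                    run_index=0,
                    model_index=m,
                    seed=seed,
                )
            )
        return models


@dataclass
class ColabFoldAdapter:
    """Builds inputs and command lines for a ColabFold-style engine.

    The adapter never bundles model weights or runs inference; it writes the
    concatenated A3M exactly as :mod:`slimscan.msa_coalign` emits it,
    assembles the command (3 recycles, chosen multimer parameter tag, no
    relaxation), and parses the engine's JSON score files and PDB models.
    """

    model_type: str = "alphafold2_multimer_v2"
    num_recycle: int = 3
    num_models: int = 5

    def write_input(self, coaln: CoAlignment, workdir, name: str = "query") -> Path:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        a3m = workdir / f"{name}.a3m"
        write_coalignment_a3m(coaln, a3m, query_name=name)
        return a3m

    def build_command(self, a3m_path, outdir, seed: int) -> list:
        return [
            "colabfold_batch",
            "--model-type", self.model_type,
            "--num-recycle", str(self.num_recycle),
            "--num-models", str(self.num_models),
            "--random-seed", str(seed),
            str(a3m_path),
            str(outdir),
        ]

    @staticmethod
    def parse_scores(path) -> dict:
        """Parse an engine JSON score file (keys: ptm, iptm, plddt)."""
        data = json.loads(Path(path).read_text())
        for key in ("ptm", "iptm", "plddt"):
            if key not in data:
                raise BackendError(f"score file {path} lacks key {key!r}")
        return {
            "ptm": float(data["ptm"]),
            "iptm": float(data["iptm"]),
            "plddt": np.asarray(data["plddt"], dtype=float),
        }
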