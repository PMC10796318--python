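"""Model selection, fragment ranking, protocol pooling and success rates.

Per case, the best model of a 25-model protocol pool is the one with the
highest model confidence score (highest ipTM in fragment-scan mode, where
the interface matters more than the fold of the fragment itself).  Pooling
the models of several protocols and re-ranking by confidence gives the
combined protocol.  A case counts as a success when the best model reaches
CAPRI class Acceptable or better; benchmark-level rates are reported as
percentages to one decimal, either plainly or by repeated stratified
sampling (one case drawn per category per iteration) when categories are
unbalanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats_io import Region
from .fragmenter import overlaps_motif
from .quality_eval import CapriClass

SELECT_KEYS = ("confidence", "iptm")


@dataclass
class CaseSummary:
    case_id: str
    per_protocol_best: dict  # protocol -> (PredictedModel, QualityMetrics|None)
    combined_best: tuple | None = None  # (PredictedModel, QualityMetrics|None)


@dataclass
class SuccessSummary:
    n_cases: int
    class_counts: dict  # CapriClass -> int
    success_rate: float  # percent, >= Acceptable
    stratified_mean: float | None = None
    stratified_sd: float | None = None


@dataclass
class ScanVerdict:
    """Outcome of ranking scan fragments by their best ipTM."""

    ranked: list  # [(Region, best_iptm)] descending by iptm
    top_fragment: Region
    success: bool | None  # None when no motif annotation was given
    best_overlapping: tuple | None  # (Region, iptm) of highest-ipTM overlap
    best_non_overlapping: tuple | None


def select_best(models: list, key: str = "confidence"):
    """Argmax of ``key``; ties resolve to the lower (run, model) indices."""
    if not models:
        raise ValueError("empty model pool")
    if key not in SELECT_KEYS:
        raise ValueError(f"key must be one of {SELECT_KEYS}, got {key!r}")
    return min(
        models, key=lambda m: (-getattr(m, key), m.run_index, m.model_index)
    )


def pool_protocols(per_protocol_pools: dict) -> list:
    """Concatenate per-protocol model pools, keeping protocol labels."""
    if len(per_protocol_pools) < 2:
        raise ValueError("pooling needs >= 2 protocols")
    combined: list = []
    for protocol, pool in per_protocol_pools.items():
        if not pool:
            logging.getLogger(__name__).warning(
                "protocol %s contributed no models to the pool", protocol
            )
            continue
        combined.extend(pool)
    return combined


def rank_scan(fragment_results: list, motif: Region | None = None) -> ScanVerdict:
    """Rank scanned fragments by best ipTM; judge against a known motif.

    ``fragment_results`` is a list of ``(Region, best_iptm)``. With a motif
    annotation, the verdict is a success iff the top-ranked fragment
    overlaps it; of several overlapping fragments only the highest-ipTM one
    is reported.
    """
    ranked = sorted(fragment_results, key=lambda fr: (-fr[1], fr[0].start))
    top_fragment = ranked[0][0]
    if motif is None:
        return ScanVerdict(ranked, top_fragment, None, None, None)
    overlapping = [fr for fr in ranked if overlaps_motif(fr[0], motif)[0]]
    non_overlapping = [fr for fr in ranked if not overlaps_motif(fr[0], motif)[0]]
    return ScanVerdict(
        ranked=ranked,
        top_fragment=top_fragment,
        success=bool(overlaps_motif(top_fragment, motif)[0]),
        best_overlapping=overlapping[0] if overlapping else None,
        best_non_overlapping=non_overlapping[0] if non_overlapping else None,
    )


def success_rate(capri_classes: list) -> SuccessSummary:
    """Fraction of cases whose best model is Acceptable or better, as %."""
    if not capri_classes:
        raise ValueError("no cases")
    counts = {cls: 0 for cls in CapriClass}
    for c in capri_classes:
        counts[CapriClass(c)] += 1
    n = len(capri_classes)
    ok = sum(v for cls, v in counts.items() if cls >= CapriClass.Acceptable)
    return SuccessSummary(
        n_cases=n,
        class_counts=counts,
        success_rate=round(100.0 * ok / n, 1),
    )


def stratified_success(
    cases_by_category: dict, n_iter: int = 1000, seed: int = 0
) -> tuple:
    """Repeated stratified sampling of the success rate, in percent.

    Each iteration draws one case uniformly from every category and scores
    the fraction of drawn cases that succeeded; the mean and standard
    deviation over ``n_iter`` iterations are returned.
    ``cases_by_category`` maps category -> list of booleans (case success).
    """
    if not cases_by_category:
        raise ValueError("no categories")
    for cat, cases in cases_by_category.items():
        if not cases:
            raise ValueError(f"category {cat!r} is empty")
    rng = np.random.default_rng(seed)
    cats = sorted(cases_by_category)
    arrays = [np.asarray(cases_by_category[c], dtype=float) for c in cats]
    rates = np.empty(n_iter)
    for i in range(n_iter):
        drawn = [a[rng.integers(len(a))] for a in arrays]
        rates[i] = np.mean(drawn)
    return float(np.mean(rates) * 100.0), float(np.std(rates) * 100.0)


@dataclass
class CrossPartnerReport:
    scores: pd.DataFrame  # receptors x ligands, confidence scores
    cognate: dict  # receptor -> cognate ligand id
    cognate_top: dict  # receptor -> True/False/None (None = tie)
    n_discriminated: int
    promiscuous_ligands: list


def cross_partner_matrix(
    receptor_coalns: dict,
    ligand_ids: list,
    backend_factory,
    cognate: dict,
    clusters: dict | None = None,
    n_runs: int = 1,
    models_per_run: int = 5,
    base_seed: int = 0,
) -> CrossPartnerReport:
    """Confidence matrix of every receptor against candidate ligands.

    ``receptor_coalns`` maps receptor id -> {ligand id -> CoAlignment}
    (built in the no-ligand-MSA mode so the peptide carries no evolutionary
    information). ``clusters`` maps ligand id -> conformation cluster;
    candidates are restricted to the cognate's cluster. A receptor
    discriminates when its cognate ligand's score is the strict maximum of
    its row; exact ties are reported but not counted.
    """
    from .predict_backend import run_protocol

    for rid in receptor_coalns:
        if rid not in cognate:
            raise ValueError(f"receptor {rid!r} has no cognate ligand in the set")
    rows = {}
    for rid, per_ligand in receptor_coalns.items():
        if clusters is not None:
            cluster = clusters[cognate[rid]]
            candidates = [l for l in ligand_ids if clusters.get(l) == cluster]
        else:
            candidates = list(ligand_ids)
        scores = {}
        for lid in candidates:
            if lid not in per_ligand:
                continue
            backend = backend_factory(rid, lid)
            models = run_protocol(
                per_ligand[lid],
                backend,
                protocol=f"{rid}:{lid}",
                n_runs=n_runs,
                models_per_run=models_per_run,
                base_seed=base_seed,
            )
            scores[lid] = select_best(models, key="confidence").confidence
        rows[rid] = scores
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=ligand_ids)

    cognate_top = {}
    for rid, scores in rows.items():
        cog = cognate[rid]
        if cog not in scores:
            cognate_top[rid] = False
            continue
        others = [v for l, v in scores.items() if l != cog]
        if not others or scores[cog] > max(others):
            cognate_top[rid] = True
        elif scores[cog] == max(others):
            cognate_top[rid] = None  # tie: not counted as discrimination
        else:
            cognate_top[rid] = False
    n_ok = sum(1 for v in cognate_top.values() if v is True)

    # promiscuous ligand flagging: robust (MAD) outliers among column means
    col_means = df.mean(axis=0, skipna=True).dropna()
    promiscuous: list = []
    if len(col_means) >= 3:
        med = float(col_means.median())
        mad = float((col_means - med).abs().median())
        scale = max(mad, 1e-12)
        for lid, m in col_means.items():
            if (m - med) / scale * 0.6745 > 3.5:
                promiscuous.append(lid)
    return CrossPartnerReport(
        scores=df,
        cognate=dict(cognate),
        cognate_top=cognate_top,
        n_discriminated=n_ok,
        promiscuous_ligands=promiscuous,
    )


def replicate_from_score_table(df: pd.DataFrame, select_key: str = "confidence") -> dict:
    """Recompute per-case best models and success rates from a score table.

    ``df`` must carry columns case_id, protocol, run_index, model_index,
    ptm, iptm, confidence and capri_class (as produced by
    :func:`slimscan.formats_io.write_score_table`, or a deposited per-model
    score table with the same column roles). Returns per-protocol and
    combined success summaries plus class counts of the selected models.
    """
    required = {"case_id", "protocol", select_key, "capri_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"score table lacks columns {sorted(missing)}")
    df = df.copy()
    if df["capri_class"].dtype == object:
        df["capri_class"] = df["capri_class"].map(lambda s: CapriClass[s])

    def best_rows(group):
        order = [-group[select_key].to_numpy()]
        for col in ("run_index", "model_index"):
            if col in group.columns:
                order.append(group[col].to_numpy())
        idx = np.lexsort(order[::-1])
        return group.iloc[idx[0]]

    out: dict = {"per_protocol": {}, "combined": None}
    for protocol, g in df.groupby("protocol"):
        picks = g.groupby("case_id", group_keys=False).apply(
            best_rows, include_groups=False
        )
        out["per_protocol"][protocol] = success_rate(list(picks["capri_class"]))
    picks = df.groupby("case_id", group_keys=False).apply(
        best_rows, include_groups=False
    )
    out["combined"] = success_rate(list(picks["capri_class"]))
    return out
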