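"""Context-specific kinase-substrate discovery (GSK3-style pipeline).

GSK3 phosphorylates serines/threonines that carry a pre-existing "priming"
phosphosite downstream: canonically four residues after the target, with
known substrates at gaps of three or five. The substrate motif is therefore
pS/T-X(2-4)-pS/T, i.e. a priming phospho-S/T at downstream offsets 3-5 from
the target residue. A phosphopeptide is called a putative substrate when it
is (1) significantly down-regulated by acute GSK3 inhibition
(adj. p < 0.05, log2 inhibitor/basal < -0.58) and (2) at least one of its
localized sites matches the motif with priming evidence — either the
priming position was itself detected phosphorylated in the study's own
data, or it is annotated as a phosphosite in the reference database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import IntensityTable, KinaseAnnotationSet, parse_sites
from .regulation import ALPHA, FC_THRESHOLD


@dataclass
class MotifSpec:
    """Priming-motif geometry: downstream offsets where a phospho-S/T primes
    the target (defaults 3..5, canonical gap 4)."""

    target_residues: frozenset = frozenset({"S", "T"})
    priming_residues: frozenset = frozenset({"S", "T"})
    gap_min: int = 3
    gap_max: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.gap_min <= self.gap_max):
            raise ValueError("need 0 < gap_min <= gap_max")


@dataclass
class PhosphoEvidence:
    """Observed / database phosphosite positions per protein accession.

    ``own``: (accession -> set of 1-based positions) seen phosphorylated in
    this study's data; ``database``: positions annotated in the reference
    phosphosite database. Evidence tags prefer own data.
    """

    own: dict[str, set[int]] = field(default_factory=dict)
    database: dict[str, set[int]] = field(default_factory=dict)

    def source_at(self, accession: str, position: int) -> str:
        if position in self.own.get(accession, set()):
            return "own_data"
        if position in self.database.get(accession, set()):
            return "database"
        return "none"


def evidence_from_study(
    table: IntensityTable,
    annotations: KinaseAnnotationSet | None = None,
) -> PhosphoEvidence:
    """Collect priming evidence: every localized site in the table is own-data
    evidence; every annotated substrate site in the database table is
    database evidence."""
    own: dict[str, set[int]] = {}
    for _, row in table.annotations.iterrows():
        acc = row.get("protein_accession")
        sites = row.get("site_positions")
        if not isinstance(sites, str) or not sites:
            continue
        for _, pos in parse_sites(sites):
            own.setdefault(acc, set()).add(pos)
    db: dict[str, set[int]] = {}
    if annotations is not None:
        for _, rec in annotations.records.iterrows():
            res_pos = parse_sites(rec["site"])
            for _, pos in res_pos:
                db.setdefault(rec["substrate_accession"], set()).add(pos)
    return PhosphoEvidence(own=own, database=db)


def inhibitor_response_filter(
    results: pd.DataFrame,
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> set[str]:
    """Features significantly down-regulated by the inhibitor:
    adj. p < alpha and log2 inhibitor/basal < -fc."""
    mask = (results["p_adj"] < alpha) & (results["log2fc"] < -fc)
    return set(results.loc[mask.fillna(False), "feature_id"])


def motif_match(
    site_position: int,
    sequence_window: str,
    accession: str,
    evidence: PhosphoEvidence,
    spec: MotifSpec = MotifSpec(),
) -> tuple[bool, str]:
    """Does a target site carry priming phospho-evidence at offsets 3-5?

    The window is centered on the target residue; downstream offsets beyond
    the window edge simply cannot match (short windows are evaluated over
    the positions available). Returns ``(matched, evidence_source)`` with
    the source preferring own-data over database evidence.
    """
    center = len(sequence_window) // 2
    if sequence_window[center] not in spec.target_residues:
        return False, "none"
    best = "none"
    for gap in range(spec.gap_min, spec.gap_max + 1):
        idx = center + gap
        if idx >= len(sequence_window):
            continue
        if sequence_window[idx] not in spec.priming_residues:
            continue
        source = evidence.source_at(accession, site_position + gap)
        if source == "own_data":
            return True, "own_data"
        if source == "database":
            best = "database"
    return best != "none", best


def discover_substrates(
    inhibitor_results: pd.DataFrame,
    table: IntensityTable,
    evidence: PhosphoEvidence,
    spec: MotifSpec = MotifSpec(),
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Intersect the inhibitor-response filter with the priming motif.

    Each localized site of a multi-site peptidoform is evaluated
    independently; the peptidoform qualifies if any site matches (the
    matching site is recorded). Output row order follows sorted feature_id,
    independent of input order.
    """
    down = inhibitor_response_filter(inhibitor_results, fc=fc, alpha=alpha)
    rows = []
    for fid in sorted(table.feature_ids.astype(str)):
        row = table.annotations.loc[fid]
        acc = row.get("protein_accession")
        window = row.get("sequence_window")
        sites_spec = row.get("site_positions")
        if not isinstance(sites_spec, str) or not sites_spec \
                or not isinstance(window, str) or not window:
            continue
        is_down = fid in down
        matched_any = False
        match_site = ""
        prime_src = "none"
        for res, pos in parse_sites(sites_spec):
            ok, src = motif_match(pos, window, acc, evidence, spec)
            if ok and not matched_any:
                matched_any, match_site, prime_src = True, f"{res}{pos}", src
            elif ok and src == "own_data" and prime_src != "own_data":
                match_site, prime_src = f"{res}{pos}", src
        rows.append((fid, acc, row.get("gene"), sites_spec, match_site,
                     is_down, matched_any, prime_src,
                     bool(is_down and matched_any)))
    calls = pd.DataFrame(rows, columns=[
        "feature_id", "protein_accession", "gene", "site_positions",
        "matched_site", "inhibitor_down", "motif_match", "priming_evidence",
        "putative_substrate"])
    return calls


def substrate_summary(calls: pd.DataFrame) -> dict[str, int]:
    """Counts of qualifying peptidoforms, unique sites, and proteins."""
    hits = calls[calls["putative_substrate"]]
    sites = set(zip(hits["protein_accession"], hits["matched_site"]))
    return {
        "n_peptides": int(len(hits)),
        "n_sites": len(sites),
        "n_proteins": int(hits["protein_accession"].nunique()),
    }
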