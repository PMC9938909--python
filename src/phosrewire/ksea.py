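"""Kinase substrate enrichment analysis (KSEA) with a permutation null.

A *signature* assigns each quantified phosphopeptide a score — a log2
INS/BAS fold change within one group, a log2 Model/CTRL fold change within
one treatment state, or a control-normalized insulin response (model minus
control). For a kinase with annotated substrates among the scored features,
the enrichment score is the signed maximum deviation of an unweighted
GSEA-style running sum over the score-ranked universe: +1/N_hit at each
substrate, -1/N_miss elsewhere. Significance comes from an empirical
permutation null in which substrate sets of the same size are drawn
uniformly from the universe; the reported p carries the add-one correction
(1 + exceedances)/(n_perm + 1), so the smallest attainable p is
1/(n_perm + 1) rather than zero.

Because the statistic is rank-based it is invariant under any strictly
monotone transform of the scores. Ranking ties are broken by feature id so
that permutation p-values are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import IntensityTable, KinaseAnnotationSet, parse_sites


@dataclass
class Signature:
    """feature_id -> score mapping with explicit semantics."""

    scores: pd.Series
    semantics: str  # e.g. "INS/BAS:CTRL", "Model/CTRL:INS:DEX", "ctrl_norm:DEX"

    def __post_init__(self) -> None:
        if not self.semantics:
            raise ValueError("signature semantics tag is mandatory")
        if not np.isfinite(self.scores.to_numpy(float)).all():
            raise ValueError("signature scores must be finite")


@dataclass
class KseaResult:
    kinase: str
    signature: str
    n_substrates: int
    es: float
    p_emp: float        # directional: sign-matched null exceedances
    p_two_sided: float  # |ES| tail; uniform on its grid under the null
    n_perm: int

    @property
    def direction(self) -> int:
        return int(np.sign(self.es))


def build_signature(
    table: IntensityTable,
    semantics: str,
    group: str | None = None,
    control: str = "CTRL",
    treatments: tuple[str, str] = ("BAS", "INS"),
    state: str | None = None,
) -> Signature:
    """Construct a fold-change signature from a preprocessed table.

    semantics:
      - ``"ins_bas"``: mean(INS) - mean(BAS) within ``group``.
      - ``"model_ctrl"``: mean(group) - mean(control) within treatment
        ``state``.
      - ``"ctrl_norm"``: the group's INS/BAS response minus the control's
        (control's own signature is identically zero).

    Features whose score cannot be computed (no quantified values on a
    side) are omitted from the signature.
    """
    vals = table.values

    def _mean(g: str, t: str) -> pd.Series:
        cols = table.samples_of(g, t)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            return vals[cols].mean(axis=1, skipna=True)

    t_bas, t_ins = treatments
    if semantics == "ins_bas":
        if group is None:
            raise ValueError("ins_bas semantics needs a group")
        score = _mean(group, t_ins) - _mean(group, t_bas)
        tag = f"INS/BAS:{group}"
    elif semantics == "model_ctrl":
        if group is None or state is None:
            raise ValueError("model_ctrl semantics needs group and state")
        score = _mean(group, state) - _mean(control, state)
        tag = f"Model/CTRL:{state}:{group}"
    elif semantics == "ctrl_norm":
        if group is None:
            raise ValueError("ctrl_norm semantics needs a group")
        score = (_mean(group, t_ins) - _mean(group, t_bas)) - (
            _mean(control, t_ins) - _mean(control, t_bas))
        tag = f"ctrl_norm:{group}"
    else:
        raise ValueError(f"unknown signature semantics {semantics!r}")
    score = score.dropna()
    return Signature(scores=score, semantics=tag)


def _ranked_membership(signature: Signature, substrate_ids: set[str]) -> np.ndarray:
    """Boolean hit vector over the universe ranked by decreasing score,
    ties broken by feature_id (stable, reproducible)."""
    s = signature.scores
    order = sorted(s.index, key=lambda f: (-s[f], str(f)))
    return np.array([f in substrate_ids for f in order], bool)


def _es_from_hits(hits: np.ndarray) -> float:
    n = len(hits)
    n_hit = int(hits.sum())
    n_miss = n - n_hit
    if n_hit == 0:
        raise ValueError("empty substrate set")
    if n_miss == 0:
        return 1.0  # all hits: running sum climbs monotonically to 1
    steps = np.where(hits, 1.0 / n_hit, -1.0 / n_miss)
    run = np.cumsum(steps)
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def ksea_score(signature: Signature, substrate_ids: set[str]) -> float:
    """Signed maximum deviation of the unweighted running sum."""
    substrate_ids = set(substrate_ids) & set(signature.scores.index)
    if not substrate_ids:
        raise ValueError("no substrates in the signature universe")
    return _es_from_hits(_ranked_membership(signature, substrate_ids))


def _null_es(n_universe: int, n_hit: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random same-size substrate sets."""
    n_miss = n_universe - n_hit
    if n_miss == 0:
        return np.ones(n_perm)
    # random hit positions per permutation via partial argsort of random keys
    keys = rng.random((n_perm, n_universe))
    idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
    steps = np.full((n_perm, n_universe), -1.0 / n_miss)
    np.put_along_axis(steps, idx, 1.0 / n_hit, axis=1)
    run = np.cumsum(steps, axis=1)
    flat = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), flat]


def ksea_permutation_p(
    signature: Signature,
    substrate_ids: set[str],
    n_perm: int = 1000,
    seed: int = 0,
    kinase: str = "",
) -> KseaResult:
    """Empirical permutation p for the enrichment of one substrate set.

    p_emp = (1 + #{null: |es_null| >= |es_obs| and same sign}) / (n_perm + 1)
    is the directional p of the observed enrichment direction (sub-uniform
    under the null because the direction is chosen by the data); p_two_sided
    drops the sign match and is uniform on its grid under the null.
    """
    substrate_ids = set(substrate_ids) & set(signature.scores.index)
    if not substrate_ids:
        raise ValueError("no substrates in the signature universe")
    hits = _ranked_membership(signature, substrate_ids)
    es = _es_from_hits(hits)
    n = len(hits)
    n_hit = int(hits.sum())
    rng = np.random.default_rng(seed)
    null = _null_es(n, n_hit, n_perm, rng)
    abs_exceed = np.abs(null) >= abs(es)
    p2 = (1.0 + int(abs_exceed.sum())) / (n_perm + 1)
    if es == 0.0:
        p = 1.0
    else:
        sign_matched = np.sign(null) == np.sign(es)
        p = (1.0 + int(np.sum(sign_matched & abs_exceed))) / (n_perm + 1)
    return KseaResult(kinase=kinase, signature=signature.semantics,
                      n_substrates=n_hit, es=es, p_emp=float(p),
                      p_two_sided=float(p2), n_perm=n_perm)


def map_substrates(
    table: IntensityTable,
    annotations: KinaseAnnotationSet,
) -> dict[str, set[str]]:
    """kinase -> feature_ids whose (accession, any localized site) is annotated.

    A multi-site peptidoform matches a kinase if ANY of its localized sites
    is an annotated substrate site of that kinase.
    """
    site_index: dict[tuple[str, str], set[str]] = {}
    for fid, row in table.annotations.iterrows():
        acc = row.get("protein_accession")
        sites = row.get("site_positions")
        if not isinstance(sites, str) or not sites:
            continue
        for res, pos in parse_sites(sites):
            site_index.setdefault((acc, f"{res}{pos}"), set()).add(fid)
    mapped: dict[str, set[str]] = {}
    for kinase in annotations.kinases():
        feats: set[str] = set()
        for acc, site in annotations.substrates_of(kinase):
            feats |= site_index.get((acc, site), set())
        if feats:
            mapped[kinase] = feats
    return mapped


def batch_ksea(
    signatures: list[Signature],
    table: IntensityTable,
    annotations: KinaseAnnotationSet,
    min_substrates: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    exclude_on_any: bool = True,
) -> pd.DataFrame:
    """KSEA of every mapped kinase against every signature.

    Kinases whose quantified substrate count falls below ``min_substrates``
    in any signature are excluded entirely (set ``exclude_on_any=False`` to
    drop them only from the failing signatures). Results are sorted by
    kinase then signature.
    """
    substrate_map = map_substrates(table, annotations)
    counts = {
        (k, sig.semantics): len(set(feats) & set(sig.scores.index))
        for k, feats in substrate_map.items() for sig in signatures
    }
    rows = []
    for k_i, (kinase, feats) in enumerate(sorted(substrate_map.items())):
        per_sig = [counts[(kinase, sig.semantics)] for sig in signatures]
        if exclude_on_any and any(c < min_substrates for c in per_sig):
            continue
        for sig, c in zip(signatures, per_sig):
            if c < min_substrates or c == 0:
                continue
            res = ksea_permutation_p(
                sig, feats, n_perm=n_perm,
                seed=np.random.SeedSequence([seed, k_i]).generate_state(1)[0] % (2**31),
                kinase=kinase)
            rows.append((res.kinase, res.signature, res.n_substrates,
                         res.es, res.p_emp, res.p_two_sided, res.n_perm,
                         res.direction))
    return pd.DataFrame(rows, columns=["kinase", "signature", "n_substrates",
                                       "es", "p_emp", "p_two_sided", "n_perm",
                                       "direction"])


def ksea_wide(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Heatmap-ready kinase x signature ES matrix with a significance mask."""
    es = results.pivot(index="kinase", columns="signature", values="es")
    sig = results.pivot(index="kinase", columns="signature", values="p_emp") < alpha
    return es.join(sig.add_suffix(":significant"))
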