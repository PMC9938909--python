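"""Cross-model comparison of insulin responses and rewiring classification.

Insulin resistance can rewire phosphorylation signaling in two directions:
a site that responds to insulin in healthy control cells can lose that
response in a resistance model (*defective* phosphorylation), or a site
silent in control cells can acquire a response (*emergent* phosphorylation).

The workflow per feature:

1. Build per-group *insulin response* vectors: INS replicate intensities
   minus the group's BAS median (the BAS median is treated as known and BAS
   replicates do not enter the ANOVA).
2. Compare response vectors across groups by one-way ANOVA, BH-adjust the
   ANOVA p across features, and run Dunnett many-to-one post-hoc contrasts
   (model vs control) on the significant features; Dunnett family-wise p is
   then BH-adjusted across features within each model.
3. Classify each (feature, model): defective if the model response differs
   significantly from control and falls inside the fold-change threshold in
   the control direction; emergent if the model response is significant,
   exceeds the threshold, and the feature is unregulated in control.
4. Attribute defects to the basal or insulin-stimulated state by re-running
   ANOVA + Dunnett separately on the BAS and on the INS intensities of
   control plus the defective models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IntensityTable
from .dunnett import dunnett_contrasts
from .regulation import ALPHA, FC_THRESHOLD, bh_adjust

_DUNNETT_MIN_PER_ARM = 2


def insulin_response_vectors(
    table: IntensityTable,
    group: str,
    treatments: tuple[str, str] = ("BAS", "INS"),
) -> pd.DataFrame:
    """Per-replicate insulin responses: INS values minus the group BAS median.

    Rows are features, columns the group's INS samples; a row is all-NaN
    when the feature has fewer than two quantifications in either arm.
    """
    t_bas, t_ins = treatments
    bas = table.values[table.samples_of(group, t_bas)]
    ins = table.values[table.samples_of(group, t_ins)]
    ok = (bas.notna().sum(axis=1) >= _DUNNETT_MIN_PER_ARM) & (
        ins.notna().sum(axis=1) >= _DUNNETT_MIN_PER_ARM
    )
    resp = ins.sub(bas.median(axis=1, skipna=True), axis=0)
    resp[~ok] = np.nan
    return resp


def anova_insulin_response(responses: dict[str, np.ndarray]) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA over per-group response vectors.

    Returns ``(F, df_between, df_within, p)``. Groups must each carry >= 2
    finite values.
    """
    groups = []
    for name, vals in responses.items():
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            raise ValueError(f"group {name!r} has < 2 finite responses")
        groups.append(v)
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    k = len(groups)
    n = sum(len(g) for g in groups)
    f, p = stats.f_oneway(*groups)
    if not np.isfinite(f):  # all values identical across groups
        f, p = 0.0, 1.0
    return float(f), k - 1, n - k, float(p)


@dataclass
class RewiringCall:
    """Per-(feature, model) rewiring verdict."""

    feature_id: str
    model: str
    defective: bool = False
    emergent: bool = False
    defect_mode: set[str] = field(default_factory=set)
    dunnett_p_adj: float = np.nan
    model_log2fc: float = np.nan

    def __post_init__(self) -> None:
        assert not (self.defective and self.emergent), (
            "defective and emergent are mutually exclusive by construction"
        )


def classify_defective_contrast(
    ctrl_label: str,
    model_log2fc: float,
    dunnett_p_adj: float,
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> bool:
    """Defective: control-regulated feature whose model response is
    significantly different from control and inside the threshold in the
    control direction."""
    if ctrl_label not in {"up", "down"}:
        return False
    if not (dunnett_p_adj < alpha):
        return False
    if np.isnan(model_log2fc):
        return False
    if ctrl_label == "up":
        return model_log2fc < fc
    return model_log2fc > -fc


def classify_emergent_contrast(
    ctrl_p_adj: float,
    ctrl_log2fc: float,
    model_log2fc: float,
    dunnett_p_adj: float,
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> bool:
    """Emergent: a feature that did not respond in control
    (p_adj >= alpha AND |log2fc| <= fc) whose model response is beyond the
    threshold and significantly different from control."""
    if np.isnan(ctrl_p_adj) or np.isnan(ctrl_log2fc):
        return False
    if ctrl_p_adj < alpha or abs(ctrl_log2fc) > fc:
        return False
    if np.isnan(model_log2fc) or np.isnan(dunnett_p_adj):
        return False
    return abs(model_log2fc) > fc and dunnett_p_adj < alpha


def classify_mouse_mode(
    chow: pd.Series,
    hfd: pd.Series,
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> tuple[bool, bool]:
    """Per-diet rule used when only two diets are compared directly.

    ``chow`` / ``hfd`` are rows of regulation results (log2fc, p_adj,
    label). Defective: regulated in CHOW but magnitude lost in HFD
    (direction-matched). Emergent: regulated in HFD while unregulated in
    CHOW. Returns ``(defective, emergent)``.
    """
    defective = False
    if chow["label"] == "up":
        defective = bool(hfd["log2fc"] < fc)
    elif chow["label"] == "down":
        defective = bool(hfd["log2fc"] > -fc)
    hfd_regulated = (hfd["p_adj"] < alpha) and (abs(hfd["log2fc"]) > fc)
    chow_unregulated = (chow["p_adj"] >= alpha) and (abs(chow["log2fc"]) <= fc)
    emergent = bool(hfd_regulated and chow_unregulated
                    and not np.isnan(chow["p_adj"]))
    return defective, emergent


def compare_models(
    table: IntensityTable,
    ctrl_calls: pd.DataFrame,
    control: str = "CTRL",
    models: list[str] | None = None,
    treatments: tuple[str, str] = ("BAS", "INS"),
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """ANOVA + Dunnett comparison of insulin responses, with classification.

    ``ctrl_calls`` is the labeled regulation-result frame for the control
    group (from :func:`phosrewire.regulation.call_regulated`). Returns a long
    frame with one row per (feature, model): the model's own response
    magnitude, the Dunnett p (family-wise, then BH across features within the
    model), and the defective/emergent flags.
    """
    if models is None:
        models = [g for g in table.design["group"].unique() if g != control]
    responses = {g: insulin_response_vectors(table, g, treatments)
                 for g in [control, *models]}
    # dense per-feature response arrays (NaN rows already mark untestable)
    clean: dict[str, list[np.ndarray]] = {}
    for g in [control, *models]:
        arr = responses[g].to_numpy()
        clean[g] = [row[np.isfinite(row)] for row in arr]

    fids = list(table.feature_ids)
    anova_rows = []
    for i, fid in enumerate(fids):
        ctrl_resp = clean[control][i]
        model_resp = {m: clean[m][i] for m in models if len(clean[m][i]) >= 2}
        if len(ctrl_resp) < 2 or not model_resp:
            anova_rows.append((fid, np.nan, np.nan))
            continue
        try:
            f, _, _, p = anova_insulin_response(
                {control: ctrl_resp, **model_resp})
        except ValueError:
            anova_rows.append((fid, np.nan, np.nan))
            continue
        anova_rows.append((fid, f, p))

    anova = pd.DataFrame(anova_rows, columns=["feature_id", "F", "p_raw"]
                         ).set_index("feature_id")
    anova["p_adj"] = bh_adjust(anova["p_raw"].to_numpy())
    anova_padj = anova["p_adj"].to_numpy()

    rows = []
    for i, fid in enumerate(fids):
        ctrl_resp = clean[control][i]
        padj = anova_padj[i]
        tested = {}
        if np.isfinite(padj) and padj < alpha and len(ctrl_resp) >= 2:
            model_resp = {m: clean[m][i] for m in models
                          if len(clean[m][i]) >= 2}
            if model_resp and np.ptp(np.concatenate(
                    [ctrl_resp, *model_resp.values()])) > 0:
                res = dunnett_contrasts(list(model_resp.values()), ctrl_resp)
                for j, m in enumerate(model_resp):
                    tested[m] = (res["estimates"][j], res["p_adj"][j])
        for m in models:
            resp_m = clean[m][i]
            model_fc = float(np.mean(resp_m)) if len(resp_m) else np.nan
            est, p_dunnett = tested.get(m, (np.nan, np.nan))
            rows.append((fid, m, model_fc, p_dunnett))

    calls = pd.DataFrame(rows, columns=["feature_id", "model",
                                        "model_log2fc", "dunnett_p"])
    # BH across features within each model
    calls["dunnett_p_adj"] = np.nan
    for m in models:
        sel = calls["model"] == m
        calls.loc[sel, "dunnett_p_adj"] = bh_adjust(
            calls.loc[sel, "dunnett_p"].to_numpy())

    labels = ctrl_calls["label"]
    calls["ctrl_label"] = calls["feature_id"].map(labels).fillna("untested")
    calls["ctrl_p_adj"] = calls["feature_id"].map(ctrl_calls["p_adj"])
    calls["ctrl_log2fc"] = calls["feature_id"].map(ctrl_calls["log2fc"])
    calls["defective"] = [
        classify_defective_contrast(lab, mfc, dp, fc, alpha)
        for lab, mfc, dp in zip(calls["ctrl_label"], calls["model_log2fc"],
                                calls["dunnett_p_adj"])
    ]
    calls["emergent"] = [
        classify_emergent_contrast(cp, cf, mfc, dp, fc, alpha)
        for cp, cf, mfc, dp in zip(calls["ctrl_p_adj"], calls["ctrl_log2fc"],
                                   calls["model_log2fc"],
                                   calls["dunnett_p_adj"])
    ]
    assert not (calls["defective"] & calls["emergent"]).any()
    calls["anova_p_adj"] = calls["feature_id"].map(anova["p_adj"])
    return calls


def attribute_defect(
    table: IntensityTable,
    calls: pd.DataFrame,
    ctrl_calls: pd.DataFrame,
    control: str = "CTRL",
    treatments: tuple[str, str] = ("BAS", "INS"),
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Attribute each defect to the basal or insulin-stimulated state.

    For every defective feature, ANOVA + Dunnett are run twice over control
    plus the defective models only — once on BAS intensities, once on INS —
    with BH on the ANOVA p across features and BH on Dunnett p within each
    model. For a control-up feature the defect is an *insulin defect* when
    the model's INS level sits significantly below control by more than the
    threshold, and a *basal defect* when the model's BAS level sits
    significantly above control; both directions invert for control-down
    features. A defect matching neither is *unattributed*.
    """
    t_bas, t_ins = treatments
    defective = calls[calls["defective"]]
    per_feature = defective.groupby("feature_id")["model"].apply(list)

    state_cols = {
        t_bas: {g: table.samples_of(g, t_bas) for g in table.design["group"].unique()},
        t_ins: {g: table.samples_of(g, t_ins) for g in table.design["group"].unique()},
    }

    # first pass: ANOVA per (feature, state) over CTRL + defective models
    records = []
    for fid, models in per_feature.items():
        for state in (t_bas, t_ins):
            arrays = {}
            for g in [control, *models]:
                v = table.values.loc[fid, state_cols[state][g]].dropna().to_numpy()
                if len(v) >= 2:
                    arrays[g] = v
            if control not in arrays or len(arrays) < 2:
                records.append((fid, state, np.nan, None))
                continue
            try:
                _, _, _, p = anova_insulin_response(arrays)
            except ValueError:
                records.append((fid, state, np.nan, None))
                continue
            records.append((fid, state, p, arrays))

    anova_p = pd.DataFrame(
        [(f, s, p) for f, s, p, _ in records],
        columns=["feature_id", "state", "p_raw"],
    )
    anova_p["p_adj"] = bh_adjust(anova_p["p_raw"].to_numpy())
    sig = {
        (f, s): padj < alpha
        for f, s, padj in zip(anova_p["feature_id"], anova_p["state"],
                              anova_p["p_adj"])
        if np.isfinite(padj)
    }

    # second pass: Dunnett on significant (feature, state)
    contrast_rows = []
    for fid, state, p, arrays in records:
        if arrays is None or not sig.get((fid, state), False):
            continue
        models_here = [g for g in arrays if g != control]
        if np.ptp(np.concatenate(list(arrays.values()))) == 0:
            continue
        res = dunnett_contrasts([arrays[m] for m in models_here],
                                arrays[control])
        for i, m in enumerate(models_here):
            contrast_rows.append((fid, m, state, res["estimates"][i],
                                  res["p_adj"][i]))
    contrasts = pd.DataFrame(
        contrast_rows,
        columns=["feature_id", "model", "state", "estimate", "p_dunnett"])
    if len(contrasts):
        contrasts["p_adj"] = np.nan
        for m in contrasts["model"].unique():
            sel = contrasts["model"] == m
            contrasts.loc[sel, "p_adj"] = bh_adjust(
                contrasts.loc[sel, "p_dunnett"].to_numpy())
    lookup = {
        (f, m, s): (est, padj)
        for f, m, s, est, padj in zip(
            contrasts.get("feature_id", []), contrasts.get("model", []),
            contrasts.get("state", []), contrasts.get("estimate", []),
            contrasts.get("p_adj", []))
    } if len(contrasts) else {}

    labels = ctrl_calls["label"]
    out_rows = []
    for _, row in defective.iterrows():
        fid, m = row["feature_id"], row["model"]
        direction = labels.get(fid)
        sign = 1.0 if direction == "up" else -1.0
        modes = set()
        ins = lookup.get((fid, m, t_ins))
        # insulin defect: model INS below CTRL INS for a CTRL-up feature
        if ins is not None and ins[1] < alpha and sign * ins[0] < -fc:
            modes.add("insulin_defect")
        bas = lookup.get((fid, m, t_bas))
        # basal defect: model BAS above CTRL BAS for a CTRL-up feature
        if bas is not None and bas[1] < alpha and sign * bas[0] > fc:
            modes.add("basal_defect")
        if not modes:
            modes = {"unattributed"}
        out_rows.append((fid, m, ";".join(sorted(modes))))
    return pd.DataFrame(out_rows,
                        columns=["feature_id", "model", "defect_mode"])


def defect_bias_tests(
    calls: pd.DataFrame,
    ctrl_calls: pd.DataFrame,
    pathway_membership: set[str] | None = None,
    max_k: int = 5,
) -> pd.DataFrame:
    """One-sided Fisher's exact tests for biases in which sites go defective.

    Two families: (1) for each k, whether features defective in >= k models
    are enriched for control-down (dephosphorylation) direction; (2) whether
    membership in a core-pathway protein set makes a regulated feature less
    likely to be defective. p-values are BH-adjusted across the k family.
    """
    regulated = ctrl_calls[ctrl_calls["label"].isin(["up", "down"])]
    n_def_models = calls[calls["defective"]].groupby("feature_id").size()
    rows = []
    for k in range(1, max_k + 1):
        def_k = set(n_def_models[n_def_models >= k].index)
        is_def = regulated["feature_id"].isin(def_k)
        is_down = regulated["label"] == "down"
        tab = np.array([
            [int((is_def & is_down).sum()), int((is_def & ~is_down).sum())],
            [int((~is_def & is_down).sum()), int((~is_def & ~is_down).sum())],
        ])
        odds, p = stats.fisher_exact(tab, alternative="greater")
        a, b = tab[0]
        c, d = tab[1]
        rate_def = a / (a + b) if a + b else np.nan
        rate_not = c / (c + d) if c + d else np.nan
        rel = rate_def / rate_not if rate_not else np.nan
        rows.append(("down_bias", k, odds, rel, p))
    bias = pd.DataFrame(rows, columns=["test", "k", "odds_ratio",
                                       "relative_ratio", "p_raw"])
    bias["p_adj"] = bh_adjust(bias["p_raw"].to_numpy())

    if pathway_membership is not None:
        def_any = set(n_def_models[n_def_models >= 1].index)
        in_path = regulated["feature_id"].isin(pathway_membership)
        is_def = regulated["feature_id"].isin(def_any)
        tab = np.array([
            [int((in_path & ~is_def).sum()), int((in_path & is_def).sum())],
            [int((~in_path & ~is_def).sum()), int((~in_path & is_def).sum())],
        ])
        odds, p = stats.fisher_exact(tab, alternative="greater")
        extra = pd.DataFrame(
            [("core_pathway_protected", 1, odds, np.nan, p, p)],
            columns=["test", "k", "odds_ratio", "relative_ratio",
                     "p_raw", "p_adj"])
        bias = pd.concat([bias, extra], ignore_index=True)
    return bias


def summarize_calls(calls: pd.DataFrame, ctrl_calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of regulated / defective / emergent per model and per-k overlap."""
    rows = []
    n_reg = int(ctrl_calls["label"].isin(["up", "down"]).sum())
    for m, sub in calls.groupby("model"):
        rows.append((m, n_reg, int(sub["defective"].sum()),
                     int(sub["emergent"].sum())))
    summary = pd.DataFrame(rows, columns=["model", "n_regulated_ctrl",
                                          "n_defective", "n_emergent"])
    return summary
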