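"""Ground-truth synthetic studies for end-to-end pipeline validation.

The generator emulates the shapes of the four study designs the pipeline
targets — an adipocyte insulin-resistance phosphoproteome (control with six
replicates per treatment, five resistance models with four), a matched
proteome, a mouse adipose phosphoproteome (three diets, twelve replicates),
and an acute kinase-inhibitor phosphoproteome (two arms of four) — with
planted, fully known structure:

* log2 intensities = feature baseline ``N(22, 2^2)`` + condition effects +
  replicate noise ``N(0, 0.35^2)``;
* insulin-regulated features respond in every group (+1.5 up, -1.0 down by
  default); *defective* features lose that response in designated models
  (insulin mode: the INS shift is removed; basal mode: the BAS level is
  raised to the INS level); *emergent* features respond only in a model;
* kinase blocks shift their substrates' insulin response coherently, the
  minimal mechanism substrate-enrichment analysis can detect;
* inhibitor-study substrates are down-shifted under the inhibitor and carry
  a priming S/T at downstream offset +4 of their sequence window (with
  database or own-data evidence), while every decoy window carries no S/T
  at offsets 3-5;
* missingness is left-censored (missing-not-at-random):
  ``P(missing) = logistic((threshold - value) * steepness)``, plus an
  optional completely-at-random fraction.

Everything is a pure function of the configuration and seed: the same seed
reproduces the bundle bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import IntensityTable, KinaseAnnotationSet

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NON_ST = np.array(list("ACDEFGHIKLMNPQVWY"))
_WINDOW = 15


@dataclass
class KinaseBlock:
    """A planted kinase: n substrates sharing an insulin-response shift."""

    name: str
    n_substrates: int
    ins_shift: float


@dataclass
class GskBlock:
    """Planted inhibitor-responsive substrates with priming-motif windows.

    The down-shift models strong dephosphorylation of direct substrates
    under a potent inhibitor (canonical substrates lose well over
    four-fold); -2.5 log2 units is a six-fold drop.
    """

    n_substrates: int = 60
    down_shift: float = -2.5
    priming_own_frac: float = 0.5  # fraction whose priming site is itself observed


@dataclass
class SimConfig:
    study: str = "cell_ir"
    n_features: int = 2000
    groups: dict[str, tuple[int, int]] = field(default_factory=dict)
    treatments: tuple[str, str] = ("BAS", "INS")
    control: str = "CTRL"
    baseline_mean: float = 22.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.35
    frac_regulated_up: float = 0.10
    frac_regulated_down: float = 0.07
    effect_up: float = 1.5
    effect_down: float = -1.0
    frac_defective: dict[str, float] = field(default_factory=dict)
    defect_mode_mix: float = 0.6  # probability a defect is insulin-mode
    frac_emergent: float = 0.02
    emergent_effect: float = 1.5
    kinase_blocks: list[KinaseBlock] = field(default_factory=list)
    gsk3: GskBlock | None = None
    censor_threshold: float = 19.0
    censor_steepness: float = 0.8
    mcar_rate: float = 0.0
    raw_scale: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.frac_regulated_up, self.frac_regulated_down,
                     self.frac_emergent, *self.frac_defective.values()):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.frac_regulated_up + self.frac_regulated_down > 1.0:
            raise ValueError("regulated fractions sum above 1")
        n_kinase = sum(b.n_substrates for b in self.kinase_blocks)
        n_gsk = self.gsk3.n_substrates if self.gsk3 else 0
        n_planted = (int(self.n_features * (self.frac_regulated_up
                                            + self.frac_regulated_down))
                     + n_kinase + n_gsk)
        if n_planted > self.n_features:
            raise ValueError("planted structure exceeds n_features")
        for g, (n0, n1) in self.groups.items():
            if n0 < 2 or n1 < 2:
                raise ValueError(f"group {g}: replicate counts must be >= 2")


def default_config(study: str, seed: int = 0, **overrides) -> SimConfig:
    """Study-shaped default configurations (the simulated trial designs)."""
    if study == "cell_ir":
        cfg = SimConfig(
            study=study, seed=seed,
            groups={"CTRL": (6, 6), "CI": (4, 4), "DEX": (4, 4),
                    "TNF": (4, 4), "MPQ": (4, 4), "AA": (4, 4)},
            treatments=("BAS", "INS"), control="CTRL",
            frac_defective={m: 0.3 for m in ("CI", "DEX", "TNF", "MPQ", "AA")},
            kinase_blocks=[KinaseBlock("AKT1", 40, 1.0),
                           KinaseBlock("CSNK2A1", 40, 0.0)],
        )
    elif study == "proteome":
        cfg = SimConfig(
            study=study, seed=seed,
            groups={"CTRL": (6, 6), "CI": (4, 4), "DEX": (4, 4),
                    "TNF": (4, 4), "MPQ": (4, 4), "AA": (4, 4)},
            treatments=("BAS", "INS"), control="CTRL",
            frac_regulated_up=0.02, frac_regulated_down=0.02,
            frac_defective={}, frac_emergent=0.0,
        )
    elif study == "mouse":
        cfg = SimConfig(
            study=study, seed=seed,
            groups={"CHOW": (12, 12), "HFD": (12, 12), "REV": (12, 12)},
            treatments=("BAS", "INS"), control="CHOW",
            frac_defective={"HFD": 0.4, "REV": 0.05},
            censor_threshold=18.5,
        )
    elif study == "gsk3i":
        cfg = SimConfig(
            study=study, seed=seed,
            groups={"ADIPO": (4, 4)},
            treatments=("Basal", "GSK3i"), control="ADIPO",
            frac_regulated_up=0.02, frac_regulated_down=0.02,
            frac_defective={}, frac_emergent=0.0,
            gsk3=GskBlock(),
        )
    else:
        raise ValueError(f"unknown study kind {study!r}")
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.__post_init__()
    return cfg


def recovery_benchmark_config(seed: int = 0, n_features: int = 2000) -> SimConfig:
    """Planted-recovery benchmark: the defective class is a *full loss* of a
    +1.5 log2 insulin response in the designated model, and the emergent
    class is its mirror image — a +/-1.5 response gained only in the model,
    planted at the same expected per-model prevalence as the defects."""
    frac_up = 0.15
    frac_def = 0.3
    n_kinase = 80
    n_reg = frac_up * n_features
    n_null = n_features - n_reg - n_kinase
    frac_emergent = frac_def * n_reg / n_null
    return SimConfig(
        study="cell_ir", seed=seed, n_features=n_features,
        groups={"CTRL": (6, 6), "CI": (4, 4), "DEX": (4, 4),
                "TNF": (4, 4), "MPQ": (4, 4), "AA": (4, 4)},
        treatments=("BAS", "INS"), control="CTRL",
        frac_regulated_up=frac_up, frac_regulated_down=0.0,
        effect_up=1.5,
        frac_defective={m: frac_def for m in ("CI", "DEX", "TNF", "MPQ", "AA")},
        defect_mode_mix=1.0,  # pure insulin-mode losses
        frac_emergent=frac_emergent, emergent_effect=1.5,
        kinase_blocks=[KinaseBlock("AKT1", 40, 1.0),
                       KinaseBlock("CSNK2A1", 40, 0.0)],
    )


@dataclass
class GroundTruth:
    """Planted labels: what the pipeline should recover."""

    features: pd.DataFrame   # index feature_id: regulated, kinase, gsk3_substrate, true_effect
    defective: pd.DataFrame  # feature_id, model, mode
    emergent: pd.DataFrame   # feature_id, model, effect

    def regulated_ids(self) -> set[str]:
        return set(self.features.index[self.features["regulated"] != "none"])

    def defective_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.defective["feature_id"], self.defective["model"]))

    def emergent_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.emergent["feature_id"], self.emergent["model"]))

    def substrate_ids(self) -> set[str]:
        return set(self.features.index[self.features["gsk3_substrate"]])


@dataclass
class SimBundle:
    table: IntensityTable
    truth: GroundTruth
    annotations: KinaseAnnotationSet
    config: SimConfig


def _random_window(rng: np.random.Generator, center_res: str) -> list[str]:
    win = list(rng.choice(_AA, size=_WINDOW))
    win[_WINDOW // 2] = center_res
    return win


def generate_study(config: SimConfig) -> SimBundle:
    """Simulate one study: intensity table, ground truth, kinase annotations."""
    rng = np.random.default_rng(config.seed)
    n = config.n_features
    fids = [f"pep{i:05d}" for i in range(n)]

    # ---- design -----------------------------------------------------------
    sample_rows = []
    for g, (n0, n1) in config.groups.items():
        for t, nt in zip(config.treatments, (n0, n1)):
            for r in range(1, nt + 1):
                sample_rows.append((f"{g}_{t}_{r}", g, t, r))
    design = pd.DataFrame(sample_rows, columns=["sample_id", "group",
                                                "treatment", "replicate"]
                          ).set_index("sample_id")
    samples = design.index.tolist()
    grp = design["group"].to_numpy()
    trt = design["treatment"].to_numpy()
    t_stim = config.treatments[1]
    models = [g for g in config.groups if g != config.control]

    # ---- feature classes --------------------------------------------------
    n_up = int(round(n * config.frac_regulated_up))
    n_down = int(round(n * config.frac_regulated_down))
    perm = rng.permutation(n)
    up_idx = perm[:n_up]
    down_idx = perm[n_up:n_up + n_down]
    pool = list(perm[n_up + n_down:])  # unregulated pool, consumed by blocks

    regulated = np.array(["none"] * n, dtype=object)
    regulated[up_idx] = "up"
    regulated[down_idx] = "down"
    effect = np.zeros(n)
    effect[up_idx] = config.effect_up
    effect[down_idx] = config.effect_down

    kinase_of = np.array([""] * n, dtype=object)
    kinase_shifted = np.zeros(n, bool)
    for block in config.kinase_blocks:
        if block.ins_shift == 0:
            # null kinase: substrates must be exchangeable with the whole
            # universe (drawing them from the unregulated pool only would
            # plant a spurious depletion signal)
            free = np.array([i for i in range(n) if not kinase_of[i]], int)
            take = list(rng.choice(free, size=block.n_substrates, replace=False))
        else:
            take, pool = pool[:block.n_substrates], pool[block.n_substrates:]
        kinase_of[take] = block.name
        effect[np.array(take, int)] += block.ins_shift
        if abs(block.ins_shift) > 0:
            kinase_shifted[np.array(take, int)] = True
            regulated[np.array(take, int)] = "up" if block.ins_shift > 0 else "down"

    gsk3_sub = np.zeros(n, bool)
    if config.gsk3 is not None:
        take, pool = pool[:config.gsk3.n_substrates], pool[config.gsk3.n_substrates:]
        take = np.array(take, int)
        gsk3_sub[take] = True
        effect[take] += config.gsk3.down_shift
        regulated[take] = "down" if config.gsk3.down_shift < 0 else "up"

    # defects among regulated (not kinase-block, not inhibitor substrates)
    defect_rows, emergent_rows = [], []
    defect_map: dict[tuple[int, str], str] = {}
    emergent_map: dict[tuple[int, str], float] = {}
    plain_reg = [i for i in range(n)
                 if regulated[i] != "none" and not kinase_shifted[i]
                 and not gsk3_sub[i]]
    for m in models:
        frac = config.frac_defective.get(m, 0.0)
        if frac <= 0:
            continue
        for i in plain_reg:
            if rng.random() < frac:
                mode = ("insulin" if rng.random() < config.defect_mode_mix
                        else "basal")
                defect_map[(i, m)] = mode
                defect_rows.append((fids[i], m, mode))
    null_idx = [i for i in range(n)
                if regulated[i] == "none" and not kinase_shifted[i]
                and not gsk3_sub[i]]
    for m in models:
        if config.frac_emergent <= 0:
            continue
        for i in null_idx:
            if rng.random() < config.frac_emergent:
                e = config.emergent_effect * (1 if rng.random() < 0.5 else -1)
                emergent_map[(i, m)] = e
                emergent_rows.append((fids[i], m, e))

    # ---- intensity matrix -------------------------------------------------
    base = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    values = base[:, None] + rng.normal(0.0, config.noise_sd,
                                        size=(n, len(samples)))
    stim = trt == t_stim
    for g in config.groups:
        g_stim = (grp == g) & stim
        g_bas = (grp == g) & ~stim
        add_stim = effect.copy()
        add_bas = np.zeros(n)
        if g != config.control:
            for i in range(n):
                mode = defect_map.get((i, g))
                if mode == "insulin":
                    add_stim[i] -= effect[i]      # response removed
                elif mode == "basal":
                    add_bas[i] += effect[i]       # basal raised to stimulated level
                e = emergent_map.get((i, g))
                if e is not None:
                    add_stim[i] += e
        values[:, g_stim] += add_stim[:, None]
        values[:, g_bas] += add_bas[:, None]

    # ---- left-censored missingness ---------------------------------------
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(-(config.censor_threshold - values)
                                     * config.censor_steepness))
    miss = rng.random(values.shape) < p_miss
    if config.mcar_rate > 0:
        miss |= rng.random(values.shape) < config.mcar_rate
    values = np.where(miss, np.nan, values)

    # ---- annotations and sequence windows --------------------------------
    positions = rng.integers(20, 800, size=n)
    res_choices = rng.choice(np.array(["S", "T", "Y"]), size=n,
                             p=[0.8, 0.15, 0.05])
    anno_rows = []
    kin_records: list[tuple[str, str, str]] = []
    own_prime = (rng.random(n) < (config.gsk3.priming_own_frac
                                  if config.gsk3 else 0.0))
    decoy_trap = rng.random(n) < 0.3  # decoys with S/T + evidence at offset 6
    c = _WINDOW // 2
    for i in range(n):
        acc = f"P{i:05d}"
        gene = f"GENE{i}"
        pos = int(positions[i])
        res = res_choices[i]
        if gsk3_sub[i]:
            res = "S" if res == "Y" else res
            win = _random_window(rng, res)
            # no accidental priming except the planted +4
            for off in (3, 5):
                win[c + off] = str(rng.choice(_NON_ST))
            win[c + 4] = "S"
            if own_prime[i]:
                sites = f"{res}{pos};S{pos + 4}"
                mult = 2
            else:
                sites = f"{res}{pos}"
                mult = 1
                kin_records.append(("CK2", acc, f"S{pos + 4}"))
            kin_records.append(("GSK3", acc, f"{res}{pos}"))
        else:
            win = _random_window(rng, res)
            for off in (3, 4, 5):  # decoys never carry a motif-range S/T
                if win[c + off] in "ST":
                    win[c + off] = str(rng.choice(_NON_ST))
            if config.gsk3 is not None and decoy_trap[i]:
                win[c + 6] = "S"
                kin_records.append(("CK2", acc, f"S{pos + 6}"))
            sites = f"{res}{pos}"
            mult = 1
        if kinase_of[i]:
            kin_records.append((kinase_of[i], acc, f"{res}{pos}"))
        anno_rows.append((fids[i], acc, gene, sites, mult, "".join(win)))

    # background annotations so un-planted kinases exist in the database
    bg_idx = rng.choice(null_idx, size=min(len(null_idx), 30), replace=False)
    for i in bg_idx:
        kin_records.append(("MAPK1", f"P{i:05d}",
                            f"{res_choices[i]}{int(positions[i])}"))

    annotations = pd.DataFrame(anno_rows, columns=[
        "feature_id", "protein_accession", "gene", "site_positions",
        "multiplicity", "sequence_window"]).set_index("feature_id")
    kin_df = pd.DataFrame(sorted(set(kin_records)),
                          columns=["kinase", "substrate_accession", "site"])
    kin_set = KinaseAnnotationSet(records=kin_df)

    out_values = pd.DataFrame(
        np.power(2.0, values) if config.raw_scale else values,
        index=pd.Index(fids, name="feature_id"), columns=samples)
    table = IntensityTable(
        values=out_values, annotations=annotations, design=design,
        scale_state="raw" if config.raw_scale else "log2_norm")

    truth = GroundTruth(
        features=pd.DataFrame(
            {"regulated": regulated, "kinase": kinase_of,
             "gsk3_substrate": gsk3_sub, "true_effect": effect},
            index=pd.Index(fids, name="feature_id")),
        defective=pd.DataFrame(defect_rows,
                               columns=["feature_id", "model", "mode"]),
        emergent=pd.DataFrame(emergent_rows,
                              columns=["feature_id", "model", "effect"]),
    )
    return SimBundle(table=table, truth=truth, annotations=kin_set,
                     config=config)


def truth_metrics(predicted: set, actual: set) -> dict[str, float]:
    """Confusion-matrix metrics of a predicted label set against truth.

    FDR is reported as 0 (with ``fdr_defined=False``) when nothing was
    called, so downstream aggregation never divides by zero silently.
    """
    predicted, actual = set(predicted), set(actual)
    tp = len(predicted & actual)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    sens = tp / (tp + fn) if (tp + fn) else 0.0
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "sensitivity": sens,
        "fdr": fdr,
        "fdr_defined": bool(tp + fp),
    }


def config_to_dict(config: SimConfig) -> dict:
    """YAML/JSON-serializable view of a configuration."""
    d = asdict(config)
    d["groups"] = {g: list(v) for g, v in config.groups.items()}
    d["treatments"] = list(config.treatments)
    return d
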