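"""Data model and TSV/GMT parsing for phosphoproteomic intensity tables.

The central container is :class:`IntensityTable`: a features x samples matrix
of intensities (``NaN`` marks a missing quantification) together with
per-feature annotations (protein accession, gene, localized phosphosites,
sequence window) and a sample design (group, treatment, replicate). Files are
plain tab-separated text emulating MaxQuant/Spectronaut site-level exports.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ordered annotation columns expected in an intensity TSV before the sample
#: columns begin.
ANNOTATION_COLUMNS = [
    "feature_id",
    "protein_accession",
    "gene",
    "site_positions",
    "multiplicity",
    "sequence_window",
]

DESIGN_COLUMNS = ["sample_id", "group", "treatment", "replicate"]

#: Forward-only progression of the intensity matrix scale.
SCALE_STATES = ["raw", "log2", "log2_norm", "imputed"]

_SITE_RE = re.compile(r"^([STY])(\d+)$")


class ValidationError(ValueError):
    """Raised when a table, design, or annotation set violates its contract."""


def parse_sites(spec: str) -> list[tuple[str, int]]:
    """Parse ``"S641;S645"`` into ``[("S", 641), ("S", 645)]`` (1-based)."""
    sites = []
    for tok in str(spec).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        m = _SITE_RE.match(tok)
        if m is None:
            raise ValidationError(f"malformed site token {tok!r}")
        sites.append((m.group(1), int(m.group(2))))
    if sites != sorted(sites, key=lambda rs: rs[1]):
        raise ValidationError(f"site positions not ascending in {spec!r}")
    return sites


def format_sites(sites: Iterable[tuple[str, int]]) -> str:
    return ";".join(f"{r}{p}" for r, p in sites)


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c != "sample_id" and c not in design.columns]
    if missing:
        raise ValidationError(f"design lacks columns {missing}")
    if design.index.duplicated().any():
        dupes = design.index[design.index.duplicated()].tolist()
        raise ValidationError(f"duplicate sample ids in design: {dupes}")
    treatments = sorted(design["treatment"].unique())
    if len(treatments) != 2:
        raise ValidationError(
            f"design must have exactly one two-level treatment factor, got {treatments}"
        )
    cell_sizes = design.groupby(["group", "treatment"], observed=True).size()
    if (cell_sizes < 1).any():
        raise ValidationError("every (group, treatment) cell needs >= 1 sample")
    if (design["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate numbers must be positive")


def validate_annotations(annotations: pd.DataFrame) -> None:
    if annotations.index.duplicated().any():
        dupes = annotations.index[annotations.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature_id: {dupes}")
    for fid, row in annotations.iterrows():
        win = row.get("sequence_window")
        if isinstance(win, str) and win:
            if len(win) % 2 != 1:
                raise ValidationError(f"{fid}: sequence window length must be odd")
            if win[len(win) // 2] not in "STY":
                raise ValidationError(f"{fid}: window center must be S/T/Y, got {win}")
        sites = row.get("site_positions")
        if isinstance(sites, str) and sites:
            parse_sites(sites)
        mult = row.get("multiplicity")
        if pd.notna(mult) and int(mult) < 1:
            raise ValidationError(f"{fid}: multiplicity must be >= 1")


@dataclass
class IntensityTable:
    """Intensity matrix plus row annotations and sample design.

    Parameters
    ----------
    values
        Features x samples DataFrame; ``NaN`` encodes a missing
        quantification (distinct from an observed zero on the raw scale,
        which is rejected at log-transform time).
    annotations
        Indexed by ``feature_id``, aligned with ``values.index``.
    design
        Indexed by ``sample_id``, aligned with ``values.columns``.
    scale_state
        One of ``raw | log2 | log2_norm | imputed``; transitions only move
        forward through that list.
    imputed
        Boolean mask, same shape as ``values``; True where a cell was filled
        by imputation rather than observed.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame
    design: pd.DataFrame
    scale_state: str = "raw"
    imputed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scale_state not in SCALE_STATES:
            raise ValidationError(f"unknown scale_state {self.scale_state!r}")
        if not self.values.index.equals(self.annotations.index):
            raise ValidationError("values rows do not match annotation feature_ids")
        if not self.values.columns.equals(self.design.index):
            raise ValidationError("values columns do not match design sample_ids")
        validate_design(self.design)
        validate_annotations(self.annotations)
        if self.imputed is not None and self.imputed.shape != self.values.shape:
            raise ValidationError("imputation mask shape mismatch")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, group: str, treatment: str | None = None) -> list[str]:
        """Sample ids of one group, optionally restricted to a treatment."""
        mask = self.design["group"] == group
        if treatment is not None:
            mask &= self.design["treatment"] == treatment
        return self.design.index[mask].tolist()

    def advance_scale(self, new_state: str) -> None:
        if SCALE_STATES.index(new_state) < SCALE_STATES.index(self.scale_state):
            raise ValidationError(
                f"scale_state may only move forward ({self.scale_state} -> {new_state})"
            )
        self.scale_state = new_state

    def copy(self) -> "IntensityTable":
        return replace(
            self,
            values=self.values.copy(),
            annotations=self.annotations.copy(),
            design=self.design.copy(),
            imputed=None if self.imputed is None else self.imputed.copy(),
        )

    def subset(self, feature_ids: Iterable[str]) -> "IntensityTable":
        have = set(self.values.index)
        idx = pd.Index([f for f in feature_ids if f in have],
                       name=self.values.index.name)
        return replace(
            self,
            values=self.values.loc[idx],
            annotations=self.annotations.loc[idx],
            design=self.design,
            imputed=None if self.imputed is None else self.imputed.loc[idx],
        )


@dataclass
class KinaseAnnotationSet:
    """Kinase -> (substrate accession, site) records, isoform-merged.

    ``records`` has columns ``kinase, substrate_accession, site`` with the
    site written residue-letter + 1-based position (``S641``). After
    construction no kinase name equals a key of the merge map and records are
    unique.
    """

    records: pd.DataFrame
    merge_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.records["kinase"]) & set(self.merge_map)
        if bad:
            raise ValidationError(f"unmerged isoform names remain: {sorted(bad)}")
        if self.records.duplicated().any():
            raise ValidationError("duplicate kinase-substrate-site records")

    def kinases(self) -> list[str]:
        return sorted(self.records["kinase"].unique())

    def substrates_of(self, kinase: str) -> set[tuple[str, str]]:
        sub = self.records[self.records["kinase"] == kinase]
        return set(zip(sub["substrate_accession"], sub["site"]))


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with a source tag."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(members) != len(set(members)):
                raise ValidationError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# file IO


def load_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design file lacks columns {missing}")
    design = design.set_index("sample_id")
    validate_design(design)
    return design


def load_intensity_table(
    path: str | Path,
    design_path: str | Path,
    missing: str = "zero",
) -> IntensityTable:
    """Read an intensity TSV plus its sample design.

    ``missing`` selects the export dialect: ``"zero"`` treats 0 as a missing
    quantification (MaxQuant LFQ convention), ``"empty"`` treats only empty
    cells / ``NaN`` as missing and keeps zeros as observed values.
    """
    if missing not in {"zero", "empty"}:
        raise ValueError("missing dialect must be 'zero' or 'empty'")
    design = load_design(design_path)
    raw = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    anno_cols = [c for c in ANNOTATION_COLUMNS if c in raw.columns]
    if "feature_id" not in anno_cols:
        raise ValidationError("intensity file lacks a feature_id column")
    sample_cols = [c for c in raw.columns if c not in anno_cols]

    unknown = sorted(set(sample_cols) - set(design.index))
    absent = sorted(set(design.index) - set(sample_cols))
    if unknown or absent:
        raise ValidationError(
            f"sample ids disagree with design (not in design: {unknown}; "
            f"missing from table: {absent})"
        )

    annotations = raw[anno_cols].set_index("feature_id")
    if annotations.index.duplicated().any():
        dupes = annotations.index[annotations.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature_id in {path}: {dupes}")
    values = raw.set_index("feature_id")[list(design.index)].astype(float)
    if missing == "zero":
        values = values.mask(values == 0.0)
    return IntensityTable(values=values, annotations=annotations, design=design)


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    """Write the canonical TSV dialect (missing cells left empty)."""
    out = table.annotations.copy()
    out.insert(0, "feature_id", table.annotations.index)
    out = pd.concat([out.reset_index(drop=True),
                     table.values.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.reset_index().to_csv(path, sep="\t", index=False)


def load_kinase_annotations(
    path: str | Path,
    merge_map: Mapping[str, str] | None = None,
) -> KinaseAnnotationSet:
    """Read a kinase/substrate-accession/site TSV, merging kinase isoforms.

    Isoform merging collapses e.g. Gsk3a and Gsk3b records onto a single
    GSK3 entry; records made identical by merging are deduplicated.
    """
    merge_map = dict(merge_map or {})
    rec = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["kinase", "substrate_accession", "site"]
    missing_cols = [c for c in needed if c not in rec.columns]
    if missing_cols:
        raise ValidationError(f"kinase annotation file lacks columns {missing_cols}")
    rec = rec[needed].copy()
    rec["kinase"] = rec["kinase"].map(lambda k: merge_map.get(k, k))
    rec = rec.drop_duplicates().reset_index(drop=True)
    return KinaseAnnotationSet(records=rec, merge_map=merge_map)


def write_kinase_annotations(annotations: KinaseAnnotationSet, path: str | Path) -> None:
    annotations.records.to_csv(path, sep="\t", index=False)


def load_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Read a GMT file: one set per line as name, description, members."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: GMT line with <3 fields skipped", path, lineno)
                continue
            name, desc, *members = fields
            members = [m for m in members if m]
            uniq = list(dict.fromkeys(members))
            if len(uniq) != len(members):
                logger.warning("%s:%d: duplicate members in %s deduplicated",
                               path, lineno, name)
            sets[name] = uniq
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             source=source or str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result DataFrames as ``<name>.tsv`` with stable column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, na_rep="NA")
        written.append(p)
    return written
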