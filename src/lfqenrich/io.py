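"""Reading and writing the tabular formats the pipeline touches.

Input is a MaxQuant-style protein-groups table (tab-separated, one row per
protein group, per-sample ``LFQ intensity <sample>`` columns, ``+``-flagged
decoy/contaminant columns) together with a sample-design table binding each
intensity column to fraction × preparation × replicate.  Parsing never drops
rows: identification-level filtering is an explicit downstream step.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import Fraction, Prep, SampleDescriptor, validate_design

RAW = "raw"
LOG2 = "log2"

# MaxQuant column dialect
_COL_PROTEIN = "Majority protein IDs"
_COL_GENE = "Gene names"
_COL_REVERSE = "Reverse"
_COL_CONTAMINANT = "Potential contaminant"
_COL_ONLY_SITE = "Only identified by site"
_COL_UNIQUE = "Peptide counts (unique)"
_LFQ_PREFIX = "LFQ intensity "


class DesignError(ValueError):
    """A sample-design table does not match the intensity table."""


class FormatError(ValueError):
    """A table violates the expected tabular dialect."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein group with its QC flags."""

    protein_id: str
    gene_name: str = ""
    is_reverse: bool = False
    is_contaminant: bool = False
    is_only_by_site: bool = False
    unique_peptides: int = 1

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if self.unique_peptides < 0:
            raise ValueError("unique_peptides must be non-negative")


@dataclass
class IntensityTable:
    """Proteins × samples intensity matrix with an explicit missingness mask.

    ``values`` holds raw LFQ intensities (``scale == "raw"``) or their base-2
    logarithms (``scale == "log2"``); cells where ``mask`` is False are
    missing and any placeholder value there is meaningless.  The scale moves
    raw → log2 exactly once.
    """

    records: list[ProteinRecord]
    design: list[SampleDescriptor]
    values: np.ndarray
    mask: np.ndarray
    scale: str = RAW

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")
        if self.values.shape != (len(self.records), len(self.design)):
            raise ValueError("matrix shape must be records × design")
        if self.scale not in (RAW, LOG2):
            raise ValueError(f"unknown scale {self.scale!r}")
        ids = [r.protein_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate protein_id in table")
        validate_design(self.design)

    @property
    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    @property
    def n_proteins(self) -> int:
        return len(self.records)

    @property
    def conditions(self) -> list[tuple[Fraction, Prep]]:
        seen: list[tuple[Fraction, Prep]] = []
        for d in self.design:
            if d.condition not in seen:
                seen.append(d.condition)
        return seen

    def condition_columns(self, fraction: Fraction, prep: Prep) -> np.ndarray:
        """Column indices of all samples of one fraction × prep condition."""
        idx = [
            i
            for i, d in enumerate(self.design)
            if d.fraction == fraction and d.prep == prep
        ]
        return np.asarray(idx, dtype=int)

    def observed_counts(self, fraction: Fraction, prep: Prep) -> np.ndarray:
        """Per-protein number of observed values in one condition."""
        cols = self.condition_columns(fraction, prep)
        return self.mask[:, cols].sum(axis=1)

    def subset_rows(self, index: np.ndarray) -> "IntensityTable":
        index = np.asarray(index)
        return IntensityTable(
            records=[self.records[i] for i in index],
            design=list(self.design),
            values=self.values[index].copy(),
            mask=self.mask[index].copy(),
            scale=self.scale,
        )

    def copy(self) -> "IntensityTable":
        return IntensityTable(
            records=list(self.records),
            design=list(self.design),
            values=self.values.copy(),
            mask=self.mask.copy(),
            scale=self.scale,
        )


@dataclass
class AnalysisConfig:
    """Tunable parameters of the differential-enrichment analysis.

    min_quantified_per_condition
        Minimum observed values a protein needs in at least one condition to
        survive the quantified-value filter; also the quantification
        threshold of the presence/absence rule.
    fc_threshold_raw
        Raw-scale fold-change gate applied before testing (1.3 by default).
    fdr_level
        Adjusted-p cutoff for calling a protein significantly enriched.
    absent_rule_min_controls
        Number of distinct control fractions a protein must be absent from
        (while quantified in MBR+) to enter the enriched set via the
        presence/absence branch.
    pi0_method
        Estimator for the proportion of true nulls: ``"mean2x"`` (robust
        min(1, 2·mean p)) or ``"storey"`` (λ = 0.5 tail estimator).
    imputation_mode
        ``"draw"`` imputes by a seeded random draw from the conditional
        normal; ``"mean"`` uses the conditional mean (deterministic).
    """

    min_quantified_per_condition: int = 2
    fc_threshold_raw: float = 1.3
    fdr_level: float = 0.05
    absent_rule_min_controls: int = 1
    pi0_method: str = "mean2x"
    imputation_mode: str = "draw"
    seed: int = 0
    min_unique_peptides: int = 1

    def __post_init__(self) -> None:
        if self.fc_threshold_raw <= 1:
            raise ValueError("fc_threshold_raw must be > 1")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        for name in ("min_quantified_per_condition", "absent_rule_min_controls",
                     "min_unique_peptides"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pi0_method not in ("mean2x", "storey"):
            raise ValueError(f"unknown pi0_method {self.pi0_method!r}")
        if self.imputation_mode not in ("draw", "mean"):
            raise ValueError(f"unknown imputation_mode {self.imputation_mode!r}")

    @property
    def log2_fc_threshold(self) -> float:
        return float(np.log2(self.fc_threshold_raw))

    def digest(self) -> str:
        """Stable hash of the configuration, written into output headers."""
        payload = json.dumps(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)


def read_design(path: str | Path) -> list[SampleDescriptor]:
    """Read a tab-separated design table (sample_id, fraction, prep, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "fraction", "prep", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"design table missing columns: {sorted(missing)}")
    design = []
    for row in df.itertuples(index=False):
        try:
            design.append(
                SampleDescriptor(
                    sample_id=row.sample_id,
                    fraction=Fraction(row.fraction),
                    prep=Prep(row.prep),
                    replicate=int(row.replicate),
                )
            )
        except ValueError as exc:
            raise FormatError(f"bad design row {tuple(row)}: {exc}") from exc
    validate_design(design)
    return design


def _parse_unique_peptides(value) -> int:
    # MaxQuant reports semicolon-separated counts per member of the group;
    # the leading entry refers to the majority protein.
    if pd.isna(value):
        return 0
    first = str(value).split(";")[0].strip()
    return int(first) if first else 0


def read_protein_groups(
    path: str | Path, design: list[SampleDescriptor] | str | Path
) -> IntensityTable:
    """Parse a protein-groups table into an IntensityTable at raw scale.

    Intensity cells equal to 0 or empty are recorded as missing in the mask
    (log2 of zero is undefined and unquantified proteins are encoded as zero
    by the upstream quantification software).  Flagged rows are retained.
    """
    if not isinstance(design, list):
        design = read_design(design)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if _COL_PROTEIN not in df.columns:
        raise FormatError(f"missing column {_COL_PROTEIN!r}")

    lfq_cols = []
    for d in design:
        col = _LFQ_PREFIX + d.sample_id
        if col not in df.columns:
            raise DesignError(f"design sample {d.sample_id!r} has no column {col!r}")
        lfq_cols.append(col)

    def flag(col: str) -> np.ndarray:
        if col not in df.columns:
            return np.zeros(len(df), dtype=bool)
        return (df[col].fillna("") == "+").to_numpy()

    reverse = flag(_COL_REVERSE)
    contaminant = flag(_COL_CONTAMINANT)
    only_site = flag(_COL_ONLY_SITE)
    genes = df[_COL_GENE].fillna("") if _COL_GENE in df.columns else [""] * len(df)
    uniques = (
        df[_COL_UNIQUE].map(_parse_unique_peptides)
        if _COL_UNIQUE in df.columns
        else pd.Series([1] * len(df))
    )

    records = []
    seen: set[str] = set()
    for i, pid in enumerate(df[_COL_PROTEIN]):
        pid = str(pid)
        if pid in seen:
            raise FormatError(f"duplicate protein_id {pid!r}")
        seen.add(pid)
        records.append(
            ProteinRecord(
                protein_id=pid,
                gene_name=str(list(genes)[i]),
                is_reverse=bool(reverse[i]),
                is_contaminant=bool(contaminant[i]),
                is_only_by_site=bool(only_site[i]),
                unique_peptides=int(list(uniques)[i]),
            )
        )

    n, p = len(df), len(design)
    values = np.zeros((n, p))
    mask = np.zeros((n, p), dtype=bool)
    for j, col in enumerate(lfq_cols):
        raw = df[col]
        for i, cell in enumerate(raw):
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                v = float(cell)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric intensity at row {i}, column {col!r}: {cell!r}"
                ) from exc
            if v != 0.0:
                values[i, j] = v
                mask[i, j] = True
    return IntensityTable(records=records, design=design, values=values, mask=mask,
                          scale=RAW)


def write_protein_groups(table: IntensityTable, path: str | Path) -> None:
    """Write an IntensityTable back to the protein-groups dialect.

    Missing cells are encoded as 0 (raw scale required), so a round trip
    through :func:`read_protein_groups` reproduces values, mask and design.
    """
    if table.scale != RAW:
        raise ValueError("only raw-scale tables can be written as protein groups")
    data: dict[str, object] = {
        _COL_PROTEIN: [r.protein_id for r in table.records],
        _COL_GENE: [r.gene_name for r in table.records],
        _COL_REVERSE: ["+" if r.is_reverse else "" for r in table.records],
        _COL_CONTAMINANT: ["+" if r.is_contaminant else "" for r in table.records],
        _COL_ONLY_SITE: ["+" if r.is_only_by_site else "" for r in table.records],
        _COL_UNIQUE: [r.unique_peptides for r in table.records],
    }
    filled = np.where(table.mask, table.values, 0.0)
    for j, d in enumerate(table.design):
        data[_LFQ_PREFIX + d.sample_id] = filled[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_design(design: list[SampleDescriptor], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [d.sample_id for d in design],
            "fraction": [d.fraction.value for d in design],
            "prep": [d.prep.value for d in design],
            "replicate": [d.replicate for d in design],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cluster_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column protein → functional-cluster table (multi-label)."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"malformed cluster-annotation row {lineno}: {line!r}")
            mapping.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    if not mapping:
        warnings.warn("cluster annotation file is empty", stacklevel=2)
    return mapping


def read_protein_list(path: str | Path) -> list[str]:
    """Read a one-identifier-per-line protein list (blank lines ignored)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def _write_tsv(df: pd.DataFrame, path: Path, header_line: str) -> None:
    with open(path, "w") as fh:
        fh.write(header_line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def write_results(results, out_dir: str | Path) -> list[Path]:
    """Write all result tables of a pipeline run as tab-separated files.

    Each file starts with a ``#`` metadata line carrying the config digest
    and seed, so identical inputs and configuration reproduce byte-identical
    files.  Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = f"# config={results.config.digest()} seed={results.config.seed}"
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        _write_tsv(df, path, header)
        written.append(path)

    for label, comp in results.comparisons.items():
        emit(comp.table, f"comparison_{label}.tsv")
    emit(results.merged, "merged_volcano.tsv")
    emit(results.merged[results.merged["enriched"]], "enriched_set.tsv")
    emit(results.upset, "upset_counts.tsv")
    if results.clusters is not None:
        emit(results.clusters, "cluster_enrichment.tsv")
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(results.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written.append(manifest_path)
    return written
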