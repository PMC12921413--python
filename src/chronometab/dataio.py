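"""Tabular I/O and design validation for two-group circadian metabolomics.

The study design modelled here is a metabolite abundance matrix (metabolites
in rows, samples in columns) collected from two light-treatment groups (LD =
normal 12:12 light/dark, LL = continuous light) at several Zeitgeber times
(ZT, hours after lights-on) with a handful of replicate animals per
(group, ZT) cell.  Abundances are non-negative intensities in arbitrary
units; missing values are encoded explicitly (empty cell or "NA"), never as
silent zeros.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

GROUPS = ("LD", "LL")
META_COLUMNS = ("sample_id", "group", "zt", "replicate")
NA_MARKERS = ("", "NA", "NaN", "nan")


@dataclass
class AnalysisConfig:
    """Analysis thresholds and switches.

    Defaults follow the screening conventions of the study design: rhythm
    screen at p < 0.05, global differential screen at FC > 1.2 & p < 0.05,
    timepoint screen at VIP > 1.5 & p < 0.05, enrichment at FDR < 0.05.
    """

    period: float = 24.0
    alpha_rhythm: float = 0.05
    fc_threshold: float = 1.2
    vip_threshold: float = 1.5
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    seed: int = 0
    # preprocessing switches (the source protocol is silent on both)
    log_transform: bool = False
    autoscale: bool = True
    # rhythm-screen options
    lag_step: float | None = None  # None -> timepoint spacing
    across_metabolite_fdr: bool = False
    exact_null_limit: int = 25
    n_permutations: int = 1000

    def __post_init__(self) -> None:
        for name in ("period", "alpha_rhythm", "fc_threshold", "vip_threshold",
                     "p_threshold", "fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.lag_step is not None and self.lag_step <= 0:
            raise ValueError("lag_step must be > 0 when given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key:value YAML file overriding the defaults."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MetaboliteTable:
    """Abundance matrix (metabolites x samples) joined to sample metadata.

    ``meta`` is indexed by sample_id with columns group, zt, replicate and is
    row-aligned with the columns of ``abundance``.
    """

    abundance: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            dups = self.abundance.index[self.abundance.index.duplicated()].unique()
            raise ValueError(f"duplicate metabolite IDs: {list(dups)}")
        if list(self.abundance.columns) != list(self.meta.index):
            raise ValueError("abundance columns and metadata rows are not aligned")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(self.meta["group"].unique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.meta["zt"].unique())

    def subset(self, group: str | None = None, zt: float | None = None) -> "MetaboliteTable":
        mask = pd.Series(True, index=self.meta.index)
        if group is not None:
            mask &= self.meta["group"] == group
        if zt is not None:
            mask &= np.isclose(self.meta["zt"], zt)
        meta = self.meta.loc[mask]
        return MetaboliteTable(self.abundance.loc[:, meta.index], meta)

    def values_for(self, metabolite_id: str, group: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, zt_hours) for one metabolite, optionally one group."""
        sub = self.subset(group=group) if group is not None else self
        return (sub.abundance.loc[metabolite_id].to_numpy(float),
                sub.meta["zt"].to_numpy(float))


@dataclass
class DesignSummary:
    groups: list[str]
    timepoints: dict[str, list[float]]
    replicates: dict[tuple[str, float], int]
    n_samples: int
    comparison_enabled: bool
    warnings: list[str] = field(default_factory=list)


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata is missing required columns: {sorted(missing)}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample IDs in metadata: {dups}")
    bad_groups = set(meta["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}; expected {GROUPS}")
    meta["zt"] = pd.to_numeric(meta["zt"], errors="raise").astype(float)
    if (meta["zt"] < 0).any() or not np.isfinite(meta["zt"]).all():
        raise ValueError("zt values must be finite and non-negative")
    meta["replicate"] = meta["replicate"].astype(int)
    if (meta["replicate"] < 1).any():
        raise ValueError("replicate indices must be positive integers")
    meta = meta.sort_values(["group", "zt", "replicate"], kind="mergesort")
    return meta.set_index("sample_id")


def read_metabolite_table(table_path: str | Path, meta_path: str | Path) -> MetaboliteTable:
    """Read an abundance CSV (first column = metabolite ID, header = sample
    IDs) plus a long metadata CSV, validate, and normalize sample order to
    (group, zt, replicate).

    Missing abundances may be encoded as empty cells or "NA"; any other
    non-numeric cell is a hard error reported with its coordinates.
    """
    meta = _normalize_meta(pd.read_csv(meta_path))
    raw = pd.read_csv(table_path, index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = raw.index[raw.index.duplicated()].unique()
        raise ValueError(f"duplicate metabolite ID(s) in table: {list(dups)}")

    unmet = [c for c in raw.columns if c not in meta.index]
    if unmet:
        raise ValueError(f"sample column(s) absent from metadata: {unmet}")
    extra = [s for s in meta.index if s not in raw.columns]
    if extra:
        warnings.warn(f"metadata rows without table columns dropped: {extra}")
        meta = meta.drop(index=extra)

    values = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
    for col in raw.columns:
        cells = raw[col].str.strip()
        is_na = cells.isin(NA_MARKERS)
        parsed = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = parsed.isna() & ~is_na
        if bad.any():
            row = raw.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric cell at metabolite '{row}', sample '{col}': "
                f"{cells[bad].iloc[0]!r}")
        # numpy's strtod is correctly rounded (to_numeric's fast path is not),
        # which is what makes write->read bitwise exact
        out = np.full(len(cells), np.nan)
        out[(~is_na).to_numpy()] = cells[~is_na].to_numpy().astype(float)
        values[col] = out
    values = values.loc[:, meta.index]  # normalize column order
    return MetaboliteTable(values, meta)


def write_metabolite_table(table: MetaboliteTable, table_path: str | Path,
                           meta_path: str | Path) -> None:
    """Write the abundance/metadata CSV pair. Floats use shortest
    round-trip repr, so write->read preserves values bit for bit."""
    out = table.abundance.copy()
    out.index.name = out.index.name or "metabolite_id"
    out.to_csv(table_path)
    table.meta.reset_index().to_csv(meta_path, index=False)


def validate_design(table: MetaboliteTable, config: AnalysisConfig) -> DesignSummary:
    """Check the sampling design against what the analysis needs.

    Hard errors: any group with fewer than 3 distinct timepoints (the
    harmonic model is unidentifiable), zt outside [0, period).  A single
    group only produces a warning and disables the rhythm comparison.
    """
    meta = table.meta
    if (meta["zt"] >= config.period).any():
        raise ValueError("zt values must be < period")
    notes: list[str] = []
    groups = sorted(meta["group"].unique())
    tps = {g: sorted(meta.loc[meta["group"] == g, "zt"].unique()) for g in groups}
    for g, t in tps.items():
        if len(t) < 3:
            raise ValueError(
                f"group {g} has only {len(t)} distinct timepoints; "
                "harmonic model unidentifiable (need >= 3)")
    reps = {(g, z): int(((meta["group"] == g) & (meta["zt"] == z)).sum())
            for g in groups for z in tps[g]}
    for cell, n in reps.items():
        if n < 1:
            raise ValueError(f"design cell {cell} has no samples")
        if n < 2:
            notes.append(f"cell {cell} has a single replicate; "
                         "interaction inference may be weak")
    comparison = len(groups) == 2
    if not comparison:
        notes.append("single group present: rhythm comparison disabled, "
                     "detection-only mode")
    return DesignSummary(groups=groups, timepoints=tps, replicates=reps,
                         n_samples=len(meta), comparison_enabled=comparison,
                         warnings=notes)
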