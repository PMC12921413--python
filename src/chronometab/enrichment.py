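"""Metabolite-set over-representation analysis with BH-FDR control.

The test is the one-sided hypergeometric upper tail: with a background of N
mappable metabolites, a pathway of size K and a hit set of size n sharing k
members, p = P(X >= k) for X ~ Hypergeom(N, K, n).  The background defaults
to the measured-and-mappable panel (standard practice for targeted panels),
not a whole reference database.  Raw p-values are adjusted across the tested
pathways with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .dataio import AnalysisConfig


@dataclass
class PathwayMap:
    pathways: dict[str, frozenset]
    names: dict[str, str]
    background: frozenset

    def __post_init__(self) -> None:
        for pid, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {pid} is empty")
            orphans = members - self.background
            if orphans:
                raise ValueError(
                    f"pathway {pid} has members outside the background: "
                    f"{sorted(orphans)[:5]}")


def load_pathway_map(map_path: str | Path,
                     background_path: str | Path | None = None) -> PathwayMap:
    """Read a pathway membership TSV: columns (pathway_id, [name,] metabolite),
    one row per member.  The background is read from a one-ID-per-line file,
    defaulting to the union of all pathway members."""
    df = pd.read_csv(map_path, sep="\t", dtype=str)
    if df.shape[1] == 2:
        df.columns = ["pathway_id", "metabolite"]
        df["name"] = df["pathway_id"]
    elif df.shape[1] >= 3:
        df = df.iloc[:, :3]
        df.columns = ["pathway_id", "name", "metabolite"]
    else:
        raise ValueError("pathway map needs >= 2 columns")
    pathways = {pid: frozenset(g["metabolite"]) for pid, g in df.groupby("pathway_id")}
    names = {pid: g["name"].iloc[0] for pid, g in df.groupby("pathway_id")}
    if background_path is not None:
        background = frozenset(
            line.strip() for line in Path(background_path).read_text().splitlines()
            if line.strip())
    else:
        background = frozenset().union(*pathways.values())
    return PathwayMap(pathways=pathways, names=names, background=background)


def load_toy_pathway_map() -> PathwayMap:
    """The small bundled demonstration map (KEGG-style pathways over named
    metabolites, including the core rhythm-disrupted set)."""
    pkg = resources.files("chronometab") / "data"
    return load_pathway_map(str(pkg / "toy_pathways.tsv"),
                            str(pkg / "toy_background.txt"))


def ora_test(hits, pathway, background) -> float:
    """One-sided hypergeometric upper-tail p for pathway over-representation."""
    hits, pathway, background = set(hits), set(pathway), set(background)
    if not background:
        raise ValueError("empty background")
    for label, s in (("hits", hits), ("pathway", pathway)):
        orphans = s - background
        if orphans:
            raise ValueError(f"{label} not in background: {sorted(orphans)[:10]}")
    N, K, n = len(background), len(pathway), len(hits)
    k = len(hits & pathway)
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(hits, pathway_map: PathwayMap,
           config: AnalysisConfig | None = None) -> pd.DataFrame:
    """ORA of a hit set against every pathway, BH-adjusted across pathways.

    Rows are sorted by raw p with a deterministic pathway_id tie-break;
    significant <=> FDR < fdr_threshold.
    """
    config = config or AnalysisConfig()
    hits = set(hits)
    rows = []
    for pid in sorted(pathway_map.pathways):
        members = pathway_map.pathways[pid]
        p = ora_test(hits, members, pathway_map.background)
        rows.append(dict(pathway_id=pid, name=pathway_map.names[pid],
                         k=len(hits & members), K=len(members), n=len(hits),
                         N=len(pathway_map.background), p=p))
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < config.fdr_threshold
    return df.sort_values(["p", "pathway_id"], kind="mergesort").reset_index(drop=True)
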