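"""Input/output plumbing: data bundles, trait configuration, report tables.

All tabular files are CSV with a header row and the line identifier in the
first column. Genotypic rows are always reindexed to phenotype row order by
identifier, never trusted to arrive in matching positional order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grm import RelationshipMatrix, center_scale_markers, compute_grm

__all__ = [
    "TraitSpec",
    "DataBundle",
    "load_bundle",
    "thresholds_from_rules",
    "write_selection_report",
]


@dataclass
class TraitSpec:
    """Per-trait selection configuration.

    ``direction`` states whether breeding progress means raising or lowering
    the trait. The truncation threshold is either an empirical quantile of
    the observed phenotypes (``quantile`` in (0,1)) or a fixed value on the
    phenotype scale (``fixed``); exactly one must be given.
    """

    name: str
    direction: str = "increase"
    quantile: float | None = None
    fixed: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("increase", "decrease"):
            raise ValueError(f"direction must be increase/decrease, got {self.direction!r}")
        if (self.quantile is None) == (self.fixed is None):
            raise ValueError(f"trait {self.name!r}: give exactly one of quantile or fixed")
        if self.quantile is not None and not (0.0 < self.quantile < 1.0):
            raise ValueError(f"trait {self.name!r}: quantile must lie strictly in (0,1)")


@dataclass
class DataBundle:
    """Phenotypes plus genomic information for one population."""

    phenotypes: pd.DataFrame                 # n×t, indexed by line id
    relationship: RelationshipMatrix | None = None
    markers: pd.DataFrame | None = None      # n×p, indexed by line id

    @property
    def n(self) -> int:
        return self.phenotypes.shape[0]

    @property
    def t(self) -> int:
        return self.phenotypes.shape[1]

    @property
    def line_ids(self) -> list[str]:
        return list(self.phenotypes.index.astype(str))

    @property
    def traits(self) -> list[str]:
        return list(self.phenotypes.columns)

    def grm(self) -> RelationshipMatrix:
        """The relationship matrix, computed from markers if not supplied."""
        if self.relationship is not None:
            return self.relationship
        if self.markers is None:
            raise ValueError("bundle has neither a relationship matrix nor markers")
        return compute_grm(center_scale_markers(self.markers.to_numpy()))

    def __post_init__(self) -> None:
        ph = self.phenotypes
        if ph.index.has_duplicates:
            dup = ph.index[ph.index.duplicated()][0]
            raise ValueError(f"duplicate line identifier {dup!r} in phenotypes")
        if ph.isna().any().any():
            r, c = np.argwhere(ph.isna().to_numpy())[0]
            raise ValueError(
                f"missing phenotype at line {ph.index[r]!r}, trait {ph.columns[c]!r}; "
                "complete records are required"
            )
        if self.relationship is not None and self.relationship.n != self.n:
            raise ValueError(
                f"relationship matrix is {self.relationship.n}×{self.relationship.n} "
                f"but phenotypes have {self.n} lines"
            )
        if self.markers is not None and self.markers.shape[0] != self.n:
            raise ValueError(
                f"marker matrix has {self.markers.shape[0]} rows "
                f"but phenotypes have {self.n} lines"
            )


def load_bundle(
    phenotype_path: str | Path,
    genotype_path: str | Path,
    genotype_kind: str = "grm",
) -> DataBundle:
    """Read a phenotype CSV and a genotype CSV (markers or GRM) into a bundle.

    Both files carry the line identifier in the first column; the genotype
    rows (and, for a GRM, columns) are reindexed to phenotype order.
    """
    if genotype_kind not in ("markers", "grm"):
        raise ValueError(f"genotype_kind must be 'markers' or 'grm', got {genotype_kind!r}")
    ph = pd.read_csv(phenotype_path, index_col=0)
    ph.index = ph.index.astype(str)
    geno = pd.read_csv(genotype_path, index_col=0)
    geno.index = geno.index.astype(str)

    missing = ph.index.difference(geno.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} phenotyped lines absent from genotype file "
            f"(first: {missing[0]!r}); files have {ph.shape[0]} vs {geno.shape[0]} rows"
        )
    if genotype_kind == "grm":
        geno.columns = geno.columns.astype(str)
        if geno.shape[0] != geno.shape[1]:
            raise ValueError(f"GRM file must be square, got {geno.shape}")
        sub = geno.loc[ph.index, ph.index]
        rel = RelationshipMatrix(values=sub.to_numpy(dtype=float), provenance="supplied")
        return DataBundle(phenotypes=ph, relationship=rel)
    sub = geno.loc[ph.index]
    return DataBundle(phenotypes=ph, markers=sub)


def thresholds_from_rules(
    phenotypes: pd.DataFrame, specs: Sequence[TraitSpec]
) -> np.ndarray:
    """Build the truncation vector yc from per-trait rules.

    Quantile rules use linear interpolation of the order statistics
    (numpy's default, "type 7"); fixed rules pass through unchanged.
    """
    if len(specs) != phenotypes.shape[1]:
        raise ValueError(
            f"{len(specs)} trait specs for {phenotypes.shape[1]} phenotype columns"
        )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be unique within a configuration")
    yc = np.empty(len(specs))
    for j, spec in enumerate(specs):
        col = phenotypes[spec.name].to_numpy(dtype=float)
        if spec.fixed is not None:
            yc[j] = spec.fixed
        else:
            yc[j] = np.quantile(col, spec.quantile, method="linear")
    return yc


# fixed column layout of the selection report CSV
_REPORT_META = ["line", "loss", "pel_raw", "pel_std", "rank", "selected", "mc_se"]


def write_selection_report(results: Iterable, path: str | Path) -> pd.DataFrame:
    """Write ranked PEL results to CSV, one row per line per loss function.

    Columns: line id, per-trait GEBV posterior mean (``gebv_<trait>``) and
    posterior variance (``pvar_<trait>``), raw and standardized PEL, rank,
    selected flag, and the Monte-Carlo standard error of the PEL estimate.
    Returns the frame that was written.
    """
    rows = []
    for r in results:
        row = {
            "line": r.line_id,
            "loss": r.loss_kind,
            "pel_raw": r.pel_raw,
            "pel_std": r.pel_std,
            "rank": r.rank,
            "selected": r.selected,
            "mc_se": r.mc_se,
        }
        for trait, m, v in zip(r.traits, r.gebv_mean, r.gebv_var):
            row[f"gebv_{trait}"] = m
            row[f"pvar_{trait}"] = v
        rows.append(row)
    if rows:
        frame = pd.DataFrame(rows)
    else:
        frame = pd.DataFrame(columns=_REPORT_META)
    frame.to_csv(path, index=False, float_format="%.10g")
    return frame
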