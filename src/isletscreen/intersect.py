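"""Cross-assay hit intersection: thresholded gene sets and exact Venn regions.

Differential-expression hits (upregulated under immune challenge) are
intersected with screen-enriched knockouts to find genes supported by both
the transcriptional and the functional readout.  Thresholds are strict
inequalities (log2FC > 1, adjusted p < 0.05 for DE; L > 1 for the screen),
so boundary rows are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import pandas as pd

from .errors import DataValidationError


@dataclass(frozen=True)
class HitSet:
    """A named set of gene symbols (whitespace-stripped, case-sensitive)."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "HitSet":
        return cls(name=name, genes=frozenset(str(g).strip() for g in genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class VennResult:
    """Exact membership regions over 2-4 input sets.

    ``regions`` maps a membership pattern — a tuple of booleans, one per
    input set in order — to the sorted list of genes with exactly that
    membership.  The all-False pattern is absent; regions partition the
    union of the inputs.
    """

    set_names: list[str]
    regions: dict[tuple[bool, ...], list[str]] = field(repr=False)

    def count(self, pattern: tuple[bool, ...]) -> int:
        return len(self.regions.get(pattern, []))

    def region(self, *names: str) -> list[str]:
        """Genes in exactly the named sets and no others."""
        unknown = set(names) - set(self.set_names)
        if unknown:
            raise DataValidationError(f"unknown set names {sorted(unknown)}")
        pattern = tuple(n in names for n in self.set_names)
        return self.regions.get(pattern, [])

    @property
    def union_size(self) -> int:
        return sum(len(g) for g in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pattern in sorted(self.regions, reverse=True):
            genes = self.regions[pattern]
            rows.append(
                {
                    "region": "&".join(
                        n for n, inside in zip(self.set_names, pattern) if inside
                    ),
                    "pattern": "".join("1" if b else "0" for b in pattern),
                    "count": len(genes),
                    "genes": ",".join(genes),
                }
            )
        return pd.DataFrame(rows, columns=["region", "pattern", "count", "genes"])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "set_names": self.set_names,
            "union_size": self.union_size,
            "regions": [
                {
                    "pattern": "".join("1" if b else "0" for b in pattern),
                    "sets": [n for n, inside in zip(self.set_names, pattern) if inside],
                    "count": len(genes),
                    "genes": genes,
                }
                for pattern, genes in sorted(self.regions.items(), reverse=True)
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table TSV with columns gene, log2fc, padj."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise DataValidationError(f"{path}: DE table missing columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate genes in DE table")
    bad = df["padj"].astype(float)
    if ((bad < 0) | (bad > 1)).any():
        raise DataValidationError(f"{path}: padj outside [0, 1]")
    return df


def filter_de_up(
    table: pd.DataFrame,
    name: str = "DE_up",
    lfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> HitSet:
    """Significantly upregulated genes: log2fc > lfc_min AND padj < padj_max.

    Both inequalities are strict; rows exactly at a threshold are dropped.
    """
    missing = {"gene", "log2fc", "padj"} - set(table.columns)
    if missing:
        raise DataValidationError(f"DE table missing columns {sorted(missing)}")
    keep = (table["log2fc"].astype(float) > lfc_min) & (
        table["padj"].astype(float) < padj_max
    )
    return HitSet.from_iterable(name, table.loc[keep, "gene"])


def filter_screen_enriched(
    ranked_results: pd.DataFrame,
    name: str = "screen",
    lfc_min: float = 1.0,
    q_max: float | None = None,
) -> HitSet:
    """Positively enriched screen hits: L_g > lfc_min (optionally q < q_max).

    The q cutoff is off by default — positive enrichment alone defines the
    screen circle of the intersection.
    """
    if not {"gene", "log2fc"} <= set(ranked_results.columns):
        raise DataValidationError("ranked results need columns gene and log2fc")
    keep = ranked_results["log2fc"].astype(float) > lfc_min
    if q_max is not None:
        if "q" not in ranked_results.columns:
            raise DataValidationError("q cutoff requested but results have no q column")
        keep &= ranked_results["q"].astype(float) < q_max
    return HitSet.from_iterable(name, ranked_results.loc[keep, "gene"])


def venn(sets: list[HitSet]) -> VennResult:
    """Partition the union of 2-4 hit sets into exact membership regions."""
    if not 2 <= len(sets) <= 4:
        raise DataValidationError(f"venn needs 2-4 sets, got {len(sets)}")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise DataValidationError(f"duplicate set names: {names}")
    union = frozenset().union(*(s.genes for s in sets))
    regions: dict[tuple[bool, ...], list[str]] = {}
    for pattern in product([True, False], repeat=len(sets)):
        if not any(pattern):
            continue
        genes = sorted(
            g
            for g in union
            if all((g in s.genes) == inside for s, inside in zip(sets, pattern))
        )
        regions[pattern] = genes
    return VennResult(set_names=names, regions=regions)


def merge_de_tables(tables: list[pd.DataFrame], mode: str = "union") -> pd.DataFrame:
    """Combine per-cell-type DE tables into one before thresholding.

    ``union``: a gene passes if it passes the thresholds in *any* table
    (the most significant row is kept).  ``intersection``: the gene must be
    present in every table; the least significant row is kept, so it must
    pass everywhere.
    """
    if not tables:
        raise DataValidationError("no DE tables to merge")
    if mode not in ("union", "intersection"):
        raise DataValidationError(f"unknown merge mode {mode!r}")
    stacked = pd.concat(tables, ignore_index=True)
    if mode == "union":
        # keep, per gene, the row with max log2fc then min padj
        stacked = stacked.sort_values(
            ["gene", "log2fc", "padj"], ascending=[True, False, True], kind="mergesort"
        )
        return stacked.drop_duplicates("gene", keep="first").reset_index(drop=True)
    counts = stacked["gene"].value_counts()
    everywhere = counts[counts == len(tables)].index
    stacked = stacked[stacked["gene"].isin(everywhere)]
    stacked = stacked.sort_values(
        ["gene", "log2fc", "padj"], ascending=[True, True, False], kind="mergesort"
    )
    return stacked.drop_duplicates("gene", keep="first").reset_index(drop=True)
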