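"""File formats for the screen: library, count matrix, sample sheet, FASTQ counting.

All tabular formats are UTF-8 TSV; lines starting with ``#`` are comments.
Readers validate strictly and raise :class:`DataValidationError` rather than
coercing — a screen analysis should never silently repair its inputs.
Counts are kept per mouse sample and never pre-pooled; pooling across mice
happens only inside the statistics.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .errors import DataValidationError
from .library import SPACER_LEN, LibraryDesign

CONDITIONS = ("control", "hPi")


# ---------------------------------------------------------------------------
# Count table + sample sheet


@dataclass
class GuideCountTable:
    """Integer guide-by-sample count matrix with per-sample metadata.

    ``counts``: DataFrame indexed by guide_id, one column per sample_id,
    non-negative integers.  ``samples``: DataFrame with columns
    ``sample_id``, ``condition`` (control / hPi) and ``mouse_id``, one row
    per count column, same order.
    """

    counts: pd.DataFrame = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        c, s = self.counts, self.samples
        required = {"sample_id", "condition", "mouse_id"}
        if not required <= set(s.columns):
            raise DataValidationError(
                f"sample sheet missing columns: {sorted(required - set(s.columns))}"
            )
        if s["sample_id"].duplicated().any():
            raise DataValidationError("duplicate sample_ids in sample sheet")
        if c.index.duplicated().any():
            raise DataValidationError("duplicate guide_ids in count table")
        bad = set(s["condition"]) - set(CONDITIONS)
        if bad:
            raise DataValidationError(
                f"unknown conditions {sorted(bad)}; expected {CONDITIONS}"
            )
        if list(c.columns) != list(s["sample_id"]):
            missing = set(s["sample_id"]) - set(c.columns)
            extra = set(c.columns) - set(s["sample_id"])
            if missing or extra:
                raise DataValidationError(
                    f"count columns and sample sheet disagree: "
                    f"missing from counts {sorted(missing)}, "
                    f"not in sheet {sorted(extra)}"
                )
            self.counts = c = c[list(s["sample_id"])]
        if not all(np.issubdtype(dt, np.integer) for dt in c.dtypes):
            frac = c.to_numpy(dtype=float)
            if not np.all(np.isfinite(frac)) or np.any(frac != np.round(frac)):
                raise DataValidationError("count table contains non-integer cells")
            self.counts = c = c.round().astype(np.int64)
        if (c.to_numpy() < 0).any():
            raise DataValidationError("count table contains negative entries")

    # -- accessors -------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    def samples_for(self, condition: str) -> list[str]:
        if condition not in CONDITIONS:
            raise DataValidationError(f"unknown condition {condition!r}")
        s = self.samples
        return list(s.loc[s["condition"] == condition, "sample_id"])

    def check_library(self, library: LibraryDesign) -> None:
        """Require every library guide to have a count row."""
        missing = library.guide_ids.difference(self.counts.index)
        if len(missing):
            raise DataValidationError(
                f"{len(missing)} library guides missing from count table, "
                f"e.g. {list(missing[:5])}"
            )


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kw)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet TSV: sample_id, condition, mouse_id [, fastq]."""
    df = _read_tsv(path)
    required = {"sample_id", "condition", "mouse_id"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"{path}: sample sheet missing columns {sorted(required - set(df.columns))}"
        )
    if df["sample_id"].duplicated().any():
        raise DataValidationError(f"{path}: duplicate sample_ids")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise DataValidationError(
            f"{path}: unknown conditions {sorted(bad)}; expected {CONDITIONS}"
        )
    return df


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Library TSV


def read_library(path: str | Path) -> LibraryDesign:
    """Read a library TSV with columns guide_id, gene, class, spacer.

    Empty / missing ``gene`` denotes a control guide.  Raises
    :class:`DataValidationError` naming the offending row on duplicate ids,
    malformed spacers or unknown classes.
    """
    df = _read_tsv(path)
    required = {"guide_id", "gene", "class", "spacer"}
    if not required <= set(df.columns):
        raise DataValidationError(
            f"{path}: library missing columns {sorted(required - set(df.columns))}"
        )
    df = df[["guide_id", "spacer", "gene", "class"]].copy()
    df["gene"] = df["gene"].replace("", pd.NA)
    try:
        return LibraryDesign(df)
    except DataValidationError as e:
        raise DataValidationError(f"{path}: {e}") from e


def write_library(library: LibraryDesign, path: str | Path) -> None:
    out = library.table[["guide_id", "gene", "class", "spacer"]].copy()
    out["gene"] = out["gene"].fillna("")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix TSV


def read_counts(path: str | Path, sample_sheet: pd.DataFrame) -> GuideCountTable:
    """Read a count matrix TSV (first column guide_id) against a sample sheet."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "guide_id":
        raise DataValidationError(f"{path}: first column must be guide_id")
    df = df.set_index("guide_id")
    sheet_samples = set(sample_sheet["sample_id"])
    table_samples = set(df.columns)
    if sheet_samples - table_samples:
        raise DataValidationError(
            f"{path}: samples in sheet missing from table: "
            f"{sorted(sheet_samples - table_samples)}"
        )
    if table_samples - sheet_samples:
        raise DataValidationError(
            f"{path}: samples in table missing from sheet: "
            f"{sorted(table_samples - sheet_samples)}"
        )
    try:
        return GuideCountTable(df, sample_sheet)
    except DataValidationError as e:
        raise DataValidationError(f"{path}: {e}") from e


def write_counts(table: GuideCountTable, path: str | Path) -> None:
    table.counts.rename_axis("guide_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Ground-truth effects TSV (simulator output / recovery-test input)


def read_effects(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"gene", "theta"} <= set(df.columns):
        raise DataValidationError(f"{path}: effects table needs columns gene, theta")
    theta = df.set_index("gene")["theta"].astype(float)
    if (theta <= 0).any():
        raise DataValidationError(f"{path}: theta must be > 0")
    return theta.to_dict()


def write_effects(theta: dict[str, float], path: str | Path) -> None:
    pd.DataFrame({"gene": list(theta), "theta": list(theta.values())}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# FASTQ spacer counting


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_guides_from_fastq(
    fastq_path: str | Path,
    library: LibraryDesign,
    search_window: tuple[int, int],
    revcomp: bool = False,
) -> tuple[pd.Series, int]:
    """Count reads per guide by exact 20-mer spacer match.

    Each read is scanned at offsets ``search_window[0]..search_window[1]``
    (inclusive); a read is assigned to a guide iff exactly one library
    spacer matches at some offset.  Reads matching spacers of two or more
    guides are left unassigned, as are reads with no exact match — there is
    no mismatch tolerance.  With ``revcomp`` the reverse complement of each
    read is scanned as well.

    Returns ``(counts, n_unassigned)`` with
    ``counts.sum() + n_unassigned == number of reads``.
    """
    lo, hi = search_window
    if lo < 0 or hi < lo:
        raise DataValidationError(f"invalid search window {search_window}")
    spacer_to_guide = dict(zip(library.table["spacer"], library.table["guide_id"]))
    counts = pd.Series(0, index=library.guide_ids, dtype=np.int64)
    n_unassigned = 0
    n_records = 0
    with _open_text(fastq_path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                n_records += 1
                seqs = [str(rec.seq).upper()]
                if revcomp:
                    seqs.append(reverse_complement(seqs[0]))
                hits: set[str] = set()
                for seq in seqs:
                    last = min(hi, len(seq) - SPACER_LEN)
                    for p in range(lo, last + 1):
                        g = spacer_to_guide.get(seq[p : p + SPACER_LEN])
                        if g is not None:
                            hits.add(g)
                if len(hits) == 1:
                    counts[hits.pop()] += 1
                else:
                    n_unassigned += 1
        except ValueError as e:
            raise DataValidationError(
                f"{fastq_path}: malformed FASTQ near record {n_records + 1}: {e}"
            ) from e
    return counts, n_unassigned


def count_samples_from_fastq(
    sample_sheet: pd.DataFrame,
    library: LibraryDesign,
    search_window: tuple[int, int],
    revcomp: bool = False,
    base_dir: str | Path | None = None,
) -> tuple[GuideCountTable, pd.Series]:
    """Build a GuideCountTable by counting every FASTQ in a sample sheet.

    The sheet must carry a ``fastq`` column.  Returns the table plus a
    per-sample Series of unassigned read counts.
    """
    if "fastq" not in sample_sheet.columns:
        raise DataValidationError("sample sheet has no fastq column")
    cols: dict[str, pd.Series] = {}
    unassigned: dict[str, int] = {}
    for row in sample_sheet.itertuples(index=False):
        path = Path(row.fastq)
        if base_dir is not None and not path.is_absolute():
            path = Path(base_dir) / path
        counts, n_un = count_guides_from_fastq(path, library, search_window, revcomp)
        cols[row.sample_id] = counts
        unassigned[row.sample_id] = n_un
    counts_df = pd.DataFrame(cols)
    return GuideCountTable(counts_df, sample_sheet), pd.Series(unassigned)
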