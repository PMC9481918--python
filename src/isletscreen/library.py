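"""Guide library design: targeting guides grouped by gene plus control guides.

A pooled knockout library in the Brunello style carries ~4 spacers per
protein-coding gene together with two classes of internal controls:
non-targeting spacers with no genomic match and spacers aimed at gene-free
intergenic loci.  Control guides are the screen's model-free null — every
normalization and empirical-null step downstream anchors on them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DataValidationError

GUIDE_CLASSES = ("targeting", "non_targeting", "intergenic")
CONTROL_CLASSES = ("non_targeting", "intergenic")
SPACER_LEN = 20
_BASES = np.array(list("ACGT"))


@dataclass
class LibraryDesign:
    """The guide pool: one row per guide with id, spacer, gene and class.

    ``table`` columns: ``guide_id``, ``spacer`` (20-nt uppercase DNA),
    ``gene`` (NA for controls), ``class`` (one of :data:`GUIDE_CLASSES`).
    Validated on construction; invalid tables raise
    :class:`~isletscreen.errors.DataValidationError`.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if "gene" in self.table.columns:
            # normalize any null-like (None, NaN) to pd.NA for stable round trips
            gene = self.table["gene"].astype("object")
            gene[gene.isna()] = pd.NA
            self.table["gene"] = gene
        self._validate()

    def _validate(self) -> None:
        t = self.table
        required = {"guide_id", "spacer", "gene", "class"}
        missing = required - set(t.columns)
        if missing:
            raise DataValidationError(f"library table missing columns: {sorted(missing)}")
        if t["guide_id"].duplicated().any():
            dups = t.loc[t["guide_id"].duplicated(), "guide_id"].unique()[:5]
            raise DataValidationError(f"duplicate guide_ids: {list(dups)}")
        if t["spacer"].duplicated().any():
            dups = t.loc[t["spacer"].duplicated(), "spacer"].unique()[:5]
            raise DataValidationError(f"duplicate spacers: {list(dups)}")
        bad_class = ~t["class"].isin(GUIDE_CLASSES)
        if bad_class.any():
            i = int(np.flatnonzero(bad_class)[0])
            raise DataValidationError(
                f"unknown guide class {t['class'].iloc[i]!r} at row {i} "
                f"(guide {t['guide_id'].iloc[i]!r}); expected one of {GUIDE_CLASSES}"
            )
        valid = t["spacer"].str.fullmatch(f"[ACGT]{{{SPACER_LEN}}}", na=False)
        if not valid.all():
            i = int(np.flatnonzero(~valid)[0])
            raise DataValidationError(
                f"malformed spacer {t['spacer'].iloc[i]!r} at row {i} "
                f"(guide {t['guide_id'].iloc[i]!r}): must be {SPACER_LEN} bases of ACGT"
            )
        targeting = t["class"] == "targeting"
        if t.loc[targeting, "gene"].isna().any():
            i = int(np.flatnonzero(targeting & t["gene"].isna())[0])
            raise DataValidationError(
                f"targeting guide {t['guide_id'].iloc[i]!r} at row {i} has no gene"
            )
        if t.loc[~targeting, "gene"].notna().any():
            i = int(np.flatnonzero(~targeting & t["gene"].notna())[0])
            raise DataValidationError(
                f"control guide {t['guide_id'].iloc[i]!r} at row {i} must have empty gene"
            )

    # -- accessors -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    @property
    def guide_ids(self) -> pd.Index:
        return pd.Index(self.table["guide_id"])

    @property
    def targeting_ids(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["class"] == "targeting", "guide_id"])

    @property
    def nt_ids(self) -> pd.Index:
        """Non-targeting control guide ids."""
        t = self.table
        return pd.Index(t.loc[t["class"] == "non_targeting", "guide_id"])

    @property
    def intergenic_ids(self) -> pd.Index:
        t = self.table
        return pd.Index(t.loc[t["class"] == "intergenic", "guide_id"])

    @property
    def control_ids(self) -> pd.Index:
        """All control guides (non-targeting + intergenic)."""
        t = self.table
        return pd.Index(t.loc[t["class"].isin(CONTROL_CLASSES), "guide_id"])

    @property
    def genes(self) -> pd.Index:
        """Unique targeted genes, in first-appearance order."""
        t = self.table
        return pd.Index(t.loc[t["class"] == "targeting", "gene"].unique())

    def guides_for_gene(self, gene: str) -> pd.Index:
        t = self.table
        ids = t.loc[t["gene"] == gene, "guide_id"]
        if ids.empty:
            raise DataValidationError(f"gene {gene!r} not in library")
        return pd.Index(ids)

    def gene_of_guide(self) -> pd.Series:
        """Series guide_id -> gene (NaN for controls)."""
        return self.table.set_index("guide_id")["gene"]


def _random_spacers(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` distinct uniform 20-mers over ACGT."""
    if n > 4**SPACER_LEN:
        raise ConfigError(f"cannot draw {n} distinct {SPACER_LEN}-mers")
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        chunk = _BASES[rng.integers(0, 4, size=(n - len(out), SPACER_LEN))]
        for s in ("".join(row) for row in chunk):
            if s not in seen:
                seen.add(s)
                out.append(s)
    return np.array(out)


def build_library(
    n_genes: int,
    guides_per_gene: int = 4,
    n_nt: int = 941,
    n_intergenic: int = 59,
    seed: int | np.random.SeedSequence = 0,
) -> LibraryDesign:
    """Construct a uniform Brunello-like library.

    ``n_genes * guides_per_gene`` targeting guides (gene symbols ``G000001``…)
    plus ``n_nt`` non-targeting and ``n_intergenic`` intergenic controls.
    Spacers are drawn uniformly without replacement from the 4^20 space;
    deterministic for a fixed ``seed``.  Unlike the real library, every gene
    gets exactly ``guides_per_gene`` guides.
    """
    if n_genes < 1 or guides_per_gene < 1:
        raise ConfigError("n_genes and guides_per_gene must be >= 1")
    if n_nt < 0 or n_intergenic < 0:
        raise ConfigError("control guide counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_targeting = n_genes * guides_per_gene
    n_total = n_targeting + n_nt + n_intergenic
    spacers = _random_spacers(n_total, rng)

    width = max(6, len(str(n_genes)))
    genes = np.repeat([f"G{i + 1:0{width}d}" for i in range(n_genes)], guides_per_gene)
    guide_ids = [
        f"{genes[i]}_sg{i % guides_per_gene + 1}" for i in range(n_targeting)
    ]
    guide_ids += [f"NT_{i + 1:04d}" for i in range(n_nt)]
    guide_ids += [f"IG_{i + 1:04d}" for i in range(n_intergenic)]
    table = pd.DataFrame(
        {
            "guide_id": guide_ids,
            "spacer": spacers,
            "gene": list(genes) + [pd.NA] * (n_nt + n_intergenic),
            "class": ["targeting"] * n_targeting
            + ["non_targeting"] * n_nt
            + ["intergenic"] * n_intergenic,
        }
    )
    return LibraryDesign(table)
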