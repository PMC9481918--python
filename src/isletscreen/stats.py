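"""Gene-level enrichment statistics for the two-arm graft screen.

The screen compares guide abundance in immune-challenged (hPi) grafts
against unchallenged control grafts.  Because rejection depletes *all*
cells in hPi mice, every comparison is anchored on the non-targeting (NT)
control guides: the gene statistic is

    L_g = log2[(sum counts of g's guides in hPi + pc) / (sum NT counts in hPi + pc)]
        - log2[(sum counts of g's guides in ctrl + pc) / (sum NT counts in ctrl + pc)]

with raw counts pooled over the mice of each condition and pseudocount
``pc`` (default 1).  Positive L_g: the knockout is enriched under immune
attack, i.e. protective.  Significance comes from an empirical null built
by drawing pseudo-genes from the control guides themselves, followed by
Benjamini-Hochberg adjustment; per-guide negative-binomial fits across
mouse replicates provide model predictions for guide-level inspection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigError, DataValidationError, StatisticalError
from .io import GuideCountTable
from .library import LibraryDesign

logger = logging.getLogger(__name__)

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Normalization


def control_size_factors(table: GuideCountTable, control_guide_ids) -> pd.Series:
    """Median-of-ratios size factors computed over control guides only.

    For each control guide with nonzero counts in every sample, the ratio
    of its count to its geometric mean across samples is formed; each
    sample's factor is the median ratio, rescaled so the factors'
    geometric mean is 1.  If every control guide has a zero somewhere, the
    estimate falls back to total-control-count ratios (with a warning);
    an all-zero control total in any sample is an error.
    """
    control_guide_ids = pd.Index(control_guide_ids)
    missing = control_guide_ids.difference(table.counts.index)
    if len(missing):
        raise DataValidationError(f"control guides missing from table: {list(missing[:5])}")
    if len(control_guide_ids) < 2:
        raise StatisticalError("need >= 2 control guides for size factors")
    sub = table.counts.loc[control_guide_ids].to_numpy(dtype=float)
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise StatisticalError(f"zero total control counts in samples {bad}")
    all_pos = (sub > 0).all(axis=1)
    if all_pos.any():
        logmat = np.log(sub[all_pos])
        log_geo = logmat.mean(axis=1, keepdims=True)
        f = np.exp(np.median(logmat - log_geo, axis=0))
    else:
        logger.warning(
            "every control guide has a zero count in some sample; "
            "falling back to total-control-count size factors"
        )
        f = totals
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=table.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# Gene statistic


def _pooled(table: GuideCountTable) -> tuple[pd.Series, pd.Series]:
    """Raw counts pooled (summed) across the mice of each condition."""
    hpi = table.counts[table.samples_for("hPi")].sum(axis=1)
    ctrl = table.counts[table.samples_for("control")].sum(axis=1)
    if hpi.empty or len(table.samples_for("hPi")) == 0 or len(table.samples_for("control")) == 0:
        raise DataValidationError("both conditions need >= 1 sample")
    return hpi, ctrl


def gene_log2fc(
    table: GuideCountTable,
    library: LibraryDesign,
    gene: str,
    pseudocount: float = 1.0,
    reference_ids=None,
    method: str = "sum",
) -> float:
    """Gene-level log2 fold change L_g for one gene (see module docstring).

    ``reference_ids`` defaults to the library's non-targeting guides.
    ``method='sum'`` integrates the gene's guides by summing raw counts
    before forming ratios; ``method='median'`` instead takes the median of
    per-guide log2 fold changes (robust alternative).
    """
    guides = library.guides_for_gene(gene).intersection(table.counts.index)
    if guides.empty:
        raise DataValidationError(f"gene {gene!r} has no guides in the count table")
    if reference_ids is None:
        reference_ids = library.nt_ids
    reference_ids = pd.Index(reference_ids).intersection(table.counts.index)
    if reference_ids.empty:
        raise DataValidationError("no reference (NT) guides present in the count table")
    hpi, ctrl = _pooled(table)
    pc = float(pseudocount)
    ref_h = hpi[reference_ids].sum()
    ref_c = ctrl[reference_ids].sum()
    if method == "sum":
        g_h = hpi[guides].sum()
        g_c = ctrl[guides].sum()
        return float(
            np.log2((g_h + pc) / (ref_h + pc)) - np.log2((g_c + pc) / (ref_c + pc))
        )
    if method == "median":
        per_guide = np.log2((hpi[guides] + pc) / (ref_h + pc)) - np.log2(
            (ctrl[guides] + pc) / (ref_c + pc)
        )
        return float(np.median(per_guide))
    raise ConfigError(f"unknown integration method {method!r}")


def gene_log2fc_all(
    table: GuideCountTable,
    library: LibraryDesign,
    pseudocount: float = 1.0,
    reference_ids=None,
    method: str = "sum",
) -> pd.DataFrame:
    """Vectorized L_g for every targeted gene with >= 1 guide in the table.

    Returns a DataFrame indexed by gene with columns ``log2fc`` and
    ``n_guides`` (guides actually summed, after any upstream filtering).
    """
    if reference_ids is None:
        reference_ids = library.nt_ids
    reference_ids = pd.Index(reference_ids).intersection(table.counts.index)
    if reference_ids.empty:
        raise DataValidationError("no reference (NT) guides present in the count table")
    hpi, ctrl = _pooled(table)
    pc = float(pseudocount)
    ref_h = hpi[reference_ids].sum()
    ref_c = ctrl[reference_ids].sum()

    gene_map = library.gene_of_guide()
    present = table.counts.index.intersection(gene_map.dropna().index)
    genes_of_present = gene_map[present]
    if method == "sum":
        g_h = hpi[present].groupby(genes_of_present).sum()
        g_c = ctrl[present].groupby(genes_of_present).sum()
        L = np.log2((g_h + pc) / (ref_h + pc)) - np.log2((g_c + pc) / (ref_c + pc))
    elif method == "median":
        per_guide = np.log2((hpi[present] + pc) / (ref_h + pc)) - np.log2(
            (ctrl[present] + pc) / (ref_c + pc)
        )
        L = per_guide.groupby(genes_of_present).median()
    else:
        raise ConfigError(f"unknown integration method {method!r}")
    n_guides = genes_of_present.groupby(genes_of_present).size()
    out = pd.DataFrame({"log2fc": L, "n_guides": n_guides})
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# Empirical null and p-values


@dataclass
class NullDistribution:
    """Pseudo-gene statistics drawn from control guides under the same L."""

    stats: np.ndarray = field(repr=False)
    set_size: int
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.stats) != self.n_draws:
            raise StatisticalError("null stats length != n_draws")
        if not np.all(np.isfinite(self.stats)):
            raise StatisticalError("null distribution contains non-finite values")

    @property
    def median(self) -> float:
        return float(np.median(self.stats))


def build_empirical_null(
    table: GuideCountTable,
    library: LibraryDesign,
    set_size: int = 4,
    n_draws: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> NullDistribution:
    """Null distribution of L from control-guide pseudo-genes.

    Each draw samples ``set_size`` control guides without replacement,
    treats them as a gene, and computes L against the *remaining* control
    guides as the NT reference — mirroring exactly how a real gene is
    scored against the NT pool.  Deterministic for fixed ``seed``.
    """
    if n_draws < 100:
        raise ConfigError("n_draws must be >= 100 for a usable null")
    controls = library.control_ids.intersection(table.counts.index)
    if len(controls) <= set_size:
        raise StatisticalError(
            f"need more than set_size={set_size} control guides in the table "
            f"(have {len(controls)}); the NT remainder would be empty"
        )
    hpi, ctrl = _pooled(table)
    h = hpi[controls].to_numpy(dtype=float)
    c = ctrl[controls].to_numpy(dtype=float)
    tot_h, tot_c = h.sum(), c.sum()
    pc = float(pseudocount)
    rng = np.random.default_rng(seed)
    stats = np.empty(n_draws)
    n_ctrl = len(controls)
    for i in range(n_draws):
        idx = rng.choice(n_ctrl, size=set_size, replace=False)
        g_h, g_c = h[idx].sum(), c[idx].sum()
        stats[i] = np.log2((g_h + pc) / (tot_h - g_h + pc)) - np.log2(
            (g_c + pc) / (tot_c - g_c + pc)
        )
    return NullDistribution(stats=stats, set_size=set_size, n_draws=n_draws, seed=seed)


def gene_pvalue(
    log2fc: float | np.ndarray,
    null: NullDistribution,
    alternative: str = "two-sided",
) -> float | np.ndarray:
    """Empirical p-value of L against the null, with add-one correction.

    Two-sided (default): p = (#{|null_i - m| >= |L - m|} + 1) / (n + 1)
    with m the null median, so a statistic at the null's center gets p = 1
    and one beyond every null draw gets 1/(n+1).  ``alternative`` may also
    be ``greater`` (enrichment only) or ``less``.
    """
    m = null.median
    dev = null.stats - m
    n = null.n_draws
    L = np.asarray(log2fc, dtype=float)
    if alternative == "two-sided":
        sorted_abs = np.sort(np.abs(dev))
        n_ge = n - np.searchsorted(sorted_abs, np.abs(L - m), side="left")
    elif alternative == "greater":
        sorted_dev = np.sort(dev)
        n_ge = n - np.searchsorted(sorted_dev, L - m, side="left")
    elif alternative == "less":
        sorted_dev = np.sort(dev)
        n_ge = np.searchsorted(sorted_dev, L - m, side="right")
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    p = (n_ge + 1) / (n + 1)
    return float(p) if np.isscalar(log2fc) or p.ndim == 0 else p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise StatisticalError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Per-guide negative-binomial model (replicate-level "full model")


@dataclass
class GuideModelFit:
    """NB regression of one guide's counts on condition across mice.

    ``beta0`` is the baseline natural-log mean (control arm, unit size
    factor); ``beta_cond`` is the hPi condition effect on the log2 scale;
    ``alpha`` the moment-estimated NB dispersion; ``fitted`` the predicted
    mean count per sample.  Non-converged fits carry NaN estimates and
    must be excluded from downstream use.
    """

    guide_id: str
    beta0: float
    beta_cond: float
    alpha: float
    fitted: pd.Series = field(repr=False)
    converged: bool = True


def fit_guide_nb(
    table: GuideCountTable,
    size_factors: pd.Series,
    guide_id: str,
) -> GuideModelFit:
    """Fit counts ~ condition for one guide, NB with log link and offset.

    The offset is log(size factor), so estimates are on the normalized
    scale.  Dispersion alpha is estimated by method of moments from the
    Pearson chi-square of an initial Poisson fit, floored at 1e-6, then a
    negative-binomial GLM is refit at that alpha.
    """
    if guide_id not in table.counts.index:
        raise DataValidationError(f"guide {guide_id!r} not in count table")
    n_h = len(table.samples_for("hPi"))
    n_c = len(table.samples_for("control"))
    if n_h < 2 or n_c < 2:
        raise StatisticalError("need >= 2 samples per condition for the guide model")
    y = table.counts.loc[guide_id].to_numpy(dtype=float)
    cond = (table.samples["condition"] == "hPi").to_numpy(dtype=float)
    X = sm.add_constant(cond)
    offset = np.log(size_factors.loc[table.sample_ids].to_numpy(dtype=float))
    failed = GuideModelFit(
        guide_id=guide_id,
        beta0=np.nan,
        beta_cond=np.nan,
        alpha=np.nan,
        fitted=pd.Series(np.nan, index=table.sample_ids),
        converged=False,
    )
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = pois.mu
        df_resid = max(1, len(y) - 2)
        chi2 = float(np.sum((y - mu) ** 2 / np.maximum(mu, 1e-12)))
        alpha = max(1e-6, (chi2 - df_resid) / float(np.sum(mu)))
        nb = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        ).fit()
    except Exception:  # noqa: BLE001 - any numerical failure flags the fit
        return failed
    if not np.all(np.isfinite(nb.params)):
        return failed
    return GuideModelFit(
        guide_id=guide_id,
        beta0=float(nb.params[0]),
        beta_cond=float(nb.params[1] / _LN2),
        alpha=float(alpha),
        fitted=pd.Series(nb.mu, index=table.sample_ids),
        converged=bool(getattr(nb, "converged", True)),
    )


# ---------------------------------------------------------------------------
# Ranking and the full analysis pass


def rank_genes(
    results: pd.DataFrame,
    expressed_genes=None,
) -> pd.DataFrame:
    """Rank genes by descending L (ties broken by gene name, ascending).

    ``results`` must carry columns ``gene`` and ``log2fc``.  When an
    expressed-gene list is given, genes outside it are excluded *before*
    ranking, matching a screen restricted to genes expressed in the graft.
    """
    if not {"gene", "log2fc"} <= set(results.columns):
        raise DataValidationError("results need columns gene and log2fc")
    out = results.copy()
    if expressed_genes is not None:
        expressed = set(expressed_genes)
        out = out[out["gene"].isin(expressed)]
    if out.empty:
        raise StatisticalError("no genes left to rank")
    out = out.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def drop_silent_guides(table: GuideCountTable) -> GuideCountTable:
    """Remove guides with zero counts in every sample (logged)."""
    silent = table.counts.index[(table.counts == 0).all(axis=1)]
    if len(silent):
        logger.info("dropping %d all-zero guides: %s%s", len(silent),
                    list(silent[:10]), "..." if len(silent) > 10 else "")
        return GuideCountTable(table.counts.drop(index=silent), table.samples)
    return table


def analyze_screen(
    table: GuideCountTable,
    library: LibraryDesign,
    pseudocount: float = 1.0,
    set_size: int = 4,
    n_draws: int = 1000,
    seed: int = 0,
    expressed_genes=None,
    method: str = "sum",
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, NullDistribution]:
    """The full gene-level inference pass.

    Validates the table against the library, drops all-zero guides,
    computes L_g for every (expressed) gene, builds the control-guide
    empirical null, assigns empirical p-values and BH q-values, and ranks.
    Returns the ranked result table (gene, n_guides, log2fc, p, q, rank)
    and the null distribution.
    """
    unknown = table.counts.index.difference(library.guide_ids)
    if len(unknown):
        raise DataValidationError(
            f"count table contains guides not in library: {list(unknown[:5])}"
        )
    table.check_library(library)
    table = drop_silent_guides(table)
    per_gene = gene_log2fc_all(
        table, library, pseudocount=pseudocount, method=method
    ).reset_index()
    if expressed_genes is not None:
        expressed = set(expressed_genes)
        per_gene = per_gene[per_gene["gene"].isin(expressed)]
        if per_gene.empty:
            raise StatisticalError("expressed-gene filter removed every gene")
    null = build_empirical_null(
        table, library, set_size=set_size, n_draws=n_draws, seed=seed,
        pseudocount=pseudocount,
    )
    per_gene = per_gene.copy()
    per_gene["p"] = gene_pvalue(
        per_gene["log2fc"].to_numpy(), null, alternative=alternative
    )
    per_gene["q"] = bh_adjust(per_gene["p"].to_numpy())
    ranked = rank_genes(per_gene)
    return ranked[["gene", "n_guides", "log2fc", "p", "q", "rank"]], null
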