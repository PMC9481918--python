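"""Synthetic pooled-screen generator with ground truth.

Emulates the statistical structure of an in vivo knockout screen in
post-mitotic grafts: lentiviral transduction at low multiplicity of
infection (Poisson integrations, multi-integration cells discarded), an
engraftment bottleneck per mouse (multinomial founder sampling), a single
epoch of condition-dependent selection (global allo-rejection ``r`` times a
per-gene knockout survival multiplier ``theta``), and overdispersed
amplicon sequencing (gamma-Poisson, i.e. negative binomial).  No clonal
growth is simulated: grafted islet cells do not divide, so selection acts
exactly once between engraftment and sequencing.

Randomness is split from one master seed with
``numpy.random.SeedSequence(seed, spawn_key=...)``: key ``(0,)`` builds the
library, ``(1,)`` the transduction, and ``(2, c, m)`` drives everything for
mouse ``m`` of condition index ``c`` — so adding mice or conditions never
reshuffles earlier mice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataValidationError
from .io import CONDITIONS, GuideCountTable, write_counts, write_effects, write_library, write_sample_sheet
from .library import LibraryDesign, build_library

RngLike = int | np.random.SeedSequence | np.random.Generator


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Configuration and ground truth


@dataclass
class SimulationConfig:
    """Study-scale defaults for a Brunello-like in vivo screen.

    ``moi`` is the mean lentiviral integrations per cell (kept < 1 so that
    transduced cells carry a single guide); ``bottleneck`` is the founder
    population represented in each graft; ``rejection_survival`` is the
    global fraction of graft cells surviving allogeneic attack in the
    PBMC-injected (hPi) arm; ``depth`` is the expected total reads for a
    full-sized graft; ``dispersion`` is the negative-binomial dispersion
    alpha (variance mu + alpha*mu^2; 0 = Poisson).
    """

    n_genes: int = 19114
    guides_per_gene: int = 4
    n_nt: int = 941
    n_intergenic: int = 59
    n_cells: int = 20_000_000
    moi: float = 0.5
    bottleneck: int = 500_000
    n_mice_per_condition: int = 6
    rejection_survival: float = 0.5
    depth: float = 10_000_000.0
    dispersion: float = 0.25
    equal_depth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "guides_per_gene", "n_cells", "bottleneck", "n_mice_per_condition"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_nt < 0 or self.n_intergenic < 0:
            raise ConfigError("control guide counts must be >= 0")
        if not self.moi > 0:
            raise ConfigError("moi must be > 0")
        if not 0 < self.rejection_survival <= 1:
            raise ConfigError("rejection_survival must be in (0, 1]")
        if not self.depth > 0:
            raise ConfigError("depth must be > 0")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigError(f"unknown simulation config keys: {sorted(extra)}")
        return cls(**dict(d))


@dataclass
class TrueEffects:
    """Per-gene knockout survival multipliers.

    ``theta[g] > 1`` means knocking out ``g`` protects graft cells from
    rejection (the knockout is enriched in hPi mice), ``theta[g] < 1``
    sensitizes.  Genes absent from the map, and all control guides, are
    neutral (theta = 1).  At use the survival probability is clipped:
    ``min(1, rejection_survival * theta)``.
    """

    theta: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g, t in self.theta.items():
            if not t > 0:
                raise ConfigError(f"theta must be > 0 (gene {g!r}: {t})")

    def survival_probs(self, library: LibraryDesign, rejection_survival: float) -> np.ndarray:
        """Per-guide hPi survival probability min(1, r * theta_gene)."""
        gene = library.table["gene"]
        theta = gene.map(self.theta).fillna(1.0).to_numpy(dtype=float)
        return np.minimum(1.0, rejection_survival * theta)


def spiked_effects(
    library: LibraryDesign,
    n_protective: int,
    n_sensitizing: int,
    theta_protective: float = 4.0,
    theta_sensitizing: float = 0.25,
    seed: RngLike = 0,
) -> TrueEffects:
    """Assign non-neutral theta to random disjoint gene subsets."""
    genes = library.genes
    if n_protective + n_sensitizing > len(genes):
        raise ConfigError("more spiked genes requested than genes in library")
    rng = _rng(seed)
    pick = rng.choice(len(genes), size=n_protective + n_sensitizing, replace=False)
    theta = {genes[i]: theta_protective for i in pick[:n_protective]}
    theta.update({genes[i]: theta_sensitizing for i in pick[n_protective:]})
    return TrueEffects(theta)


# ---------------------------------------------------------------------------
# Simulation stages


def transduce(
    library: LibraryDesign,
    n_cells: int,
    moi: float,
    seed: RngLike,
    full_output: bool = False,
):
    """Transduce ``n_cells`` cells at Poisson MOI and keep single-guide cells.

    Integrations per cell are Poisson(``moi``); cells with zero integrations
    carry no guide and cells with two or more are discarded (the screen
    assumes one perturbation per cell).  Each retained cell receives one
    guide uniformly at random.  Returns the integer abundance vector
    (cells per guide, in library order); with ``full_output`` also a dict
    of ``n_infected`` (>=1 integration), ``n_multi`` and ``n_single``.
    """
    if not moi > 0:
        raise ConfigError("moi must be > 0")
    rng = _rng(seed)
    integrations = rng.poisson(moi, size=n_cells)
    n_infected = int((integrations >= 1).sum())
    n_single = int((integrations == 1).sum())
    n_guides = len(library)
    abundance = rng.multinomial(n_single, np.full(n_guides, 1.0 / n_guides))
    if full_output:
        return abundance, {
            "n_infected": n_infected,
            "n_single": n_single,
            "n_multi": n_infected - n_single,
        }
    return abundance


def sample_graft(abundance: np.ndarray, bottleneck: int, seed: RngLike) -> np.ndarray:
    """Draw one mouse's founder population from the transduced pool.

    Multinomial sampling of ``bottleneck`` founders with probabilities
    proportional to pool abundance (sampling with replacement, so the
    bottleneck may exceed the pool size).
    """
    total = int(np.sum(abundance))
    if total <= 0:
        raise DataValidationError("cannot sample a graft from zero total abundance")
    if bottleneck < 1:
        raise ConfigError("bottleneck must be >= 1")
    rng = _rng(seed)
    p = np.asarray(abundance, dtype=float) / total
    return rng.multinomial(bottleneck, p)


def apply_selection(
    founders: np.ndarray,
    library: LibraryDesign,
    effects: TrueEffects,
    rejection_survival: float,
    condition: str,
    seed: RngLike,
) -> np.ndarray:
    """One epoch of immune selection on a mouse's founders.

    Control mice are untouched.  In hPi mice each founder survives
    independently with probability ``min(1, r * theta_gene)`` (theta = 1
    for control guides), i.e. binomial thinning per guide.
    """
    if condition not in CONDITIONS:
        raise DataValidationError(f"unknown condition {condition!r}")
    if not 0 < rejection_survival <= 1:
        raise ConfigError("rejection_survival must be in (0, 1]")
    founders = np.asarray(founders)
    if condition == "control":
        return founders.copy()
    probs = effects.survival_probs(library, rejection_survival)
    if len(probs) != len(founders):
        raise DataValidationError("founder vector length does not match library")
    rng = _rng(seed)
    return rng.binomial(founders, probs)


def sequence_counts(
    abundance: np.ndarray,
    depth: float,
    dispersion: float,
    seed: RngLike,
) -> np.ndarray:
    """Negative-binomial read counts for one sample.

    Guide ``i`` gets mean ``depth * abundance_i / sum(abundance)`` and
    variance ``mu + dispersion * mu^2`` via a gamma-Poisson mixture;
    ``dispersion = 0`` degenerates to pure Poisson.
    """
    if not depth > 0:
        raise ConfigError("depth must be > 0")
    if dispersion < 0:
        raise ConfigError("dispersion must be >= 0")
    abundance = np.asarray(abundance, dtype=float)
    total = abundance.sum()
    if total <= 0:
        raise DataValidationError("cannot sequence an all-zero abundance vector")
    rng = _rng(seed)
    mu = depth * abundance / total
    if dispersion == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mu)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Full screen


@dataclass
class ScreenDataset:
    """A simulated screen: counts, the library, ground truth and config."""

    counts: GuideCountTable
    library: LibraryDesign
    effects: TrueEffects
    config: SimulationConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write counts/library/sample sheet/effects/config TSV+YAML files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / "counts.tsv",
            "library": outdir / "library.tsv",
            "sample_sheet": outdir / "sample_sheet.tsv",
            "effects": outdir / "effects.tsv",
            "config": outdir / "sim_config.yaml",
        }
        write_counts(self.counts, paths["counts"])
        write_library(self.library, paths["library"])
        write_sample_sheet(self.counts.samples, paths["sample_sheet"])
        write_effects(self.effects.theta, paths["effects"])
        with open(paths["config"], "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=True)
        return paths


def _child_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master, spawn_key=tuple(key))


def simulate_screen(
    config: SimulationConfig,
    effects: TrueEffects | None = None,
    library: LibraryDesign | None = None,
) -> ScreenDataset:
    """Run the full generative model for one two-arm mouse cohort.

    Builds (or reuses) the library, transduces one cell pool, then for each
    mouse independently samples founders through the engraftment
    bottleneck, applies selection (hPi arm only) and sequences.  Unless
    ``config.equal_depth``, each sample's expected depth scales with its
    surviving fraction ``survivors / bottleneck``, so global rejection
    lowers absolute hPi counts just as graft shrinkage lowers recovered
    gDNA.  Fully reproducible from ``config.seed``.
    """
    if effects is None:
        effects = TrueEffects()
    if library is None:
        library = build_library(
            config.n_genes,
            config.guides_per_gene,
            config.n_nt,
            config.n_intergenic,
            seed=_child_seed(config.seed, 0),
        )
    unknown = set(effects.theta) - set(library.genes)
    if unknown:
        raise ConfigError(f"effects reference genes not in library: {sorted(unknown)[:5]}")

    pool = transduce(library, config.n_cells, config.moi, _child_seed(config.seed, 1))

    cols: dict[str, np.ndarray] = {}
    sample_rows: list[dict] = []
    for ci, condition in enumerate(CONDITIONS):
        for m in range(1, config.n_mice_per_condition + 1):
            rng = np.random.default_rng(_child_seed(config.seed, 2, ci, m))
            founders = sample_graft(pool, config.bottleneck, rng)
            survivors = apply_selection(
                founders, library, effects, config.rejection_survival, condition, rng
            )
            if config.equal_depth:
                depth = config.depth
            else:
                depth = config.depth * survivors.sum() / config.bottleneck
            reads = sequence_counts(survivors, depth, config.dispersion, rng)
            sample_id = f"{condition}_m{m}"
            cols[sample_id] = reads
            sample_rows.append(
                {"sample_id": sample_id, "condition": condition, "mouse_id": f"{condition[0]}{m}"}
            )

    counts = pd.DataFrame(cols, index=library.guide_ids)
    table = GuideCountTable(counts, pd.DataFrame(sample_rows))
    return ScreenDataset(counts=table, library=library, effects=effects, config=config)
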