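# Methods

## The screen being modelled

A pooled knockout library is transduced into stem cell-derived islet
(SC-islet) cells at low multiplicity of infection, the cells are
transplanted under the kidney capsule of immunodeficient, MHC-null mice,
and half of the cohort receives allogeneic human PBMCs ("hPi" arm). The
grafted cells are post-mitotic, so there is no growth-based amplification:
selection is a single episode of immune killing between engraftment and
graft recovery, after which guide abundance is read out by amplicon
sequencing of genomic DNA. A knockout that protects cells from rejection is
over-represented in hPi grafts relative to its representation in control
grafts; one that sensitizes is under-represented. Because rejection removes
cells of *all* genotypes, absolute hPi counts drop globally and all
inference must be relative to the non-targeting (NT) controls carried in
the library.

## Gene-level inference

**Statistic.** For gene *g*, raw counts are pooled (summed) across the mice
of each arm and integrated across the gene's guides (typically 4) by
summing before ratios are formed:

L_g = log2[(G_hPi + pc)/(N_hPi + pc)] − log2[(G_ctrl + pc)/(N_ctrl + pc)],

where G is the gene's guide-count sum, N the NT-guide sum, and pc a
pseudocount (default 1). The pseudocount guards against ±∞ when
rejection-driven zeros appear in hPi samples. Summing raw counts weights
guides by their abundance; a robust alternative (`method="median"`, median
of per-guide log2 fold changes) is available for sensitivity analysis.
Pooling across mice is the default; the per-guide replicate-level model
below is the complementary view that keeps mice separate.

**Empirical null and FDR.** The screen's only model-free null is its
control guides: guide sets drawn from controls experience transduction,
engraftment, global rejection and sequencing, but no gene effect. For each
of `n_draws` draws (default 1,000; at least 100 enforced), `set_size`
control guides (default 4, matching the modal guides-per-gene) are sampled
without replacement and scored by L against the *remaining* controls, so a
pseudo-gene is treated exactly like a real gene. Two-sided empirical
p-values use the add-one correction around the null median m:

p = (#{|null_i − m| ≥ |L_g − m|} + 1)/(n_draws + 1),

so p ∈ [1/(n+1), 1] and the smallest achievable p — hence the q-value
resolution — is set by `n_draws`; genome-scale analyses should raise it
(each draw is O(set_size)). One-sided alternatives are available.
Multiplicity is handled by textbook Benjamini–Hochberg step-up over the
evaluated (optionally expression-filtered) genes. When an expressed-gene
list is supplied, filtering happens *before* p-values and BH, so the FDR is
controlled over the genes actually evaluated. The expressed list is an
input, never computed: the expression threshold that defines it belongs to
the scRNA-seq side of a study, not to this package.

**Size factors and per-guide model.** Sample size factors are
median-of-ratios computed over control guides only (geometric-mean
reference per guide, median ratio per sample, rescaled to geometric mean
1). If every control guide has a zero in some sample the estimator falls
back to total-control-count ratios with a logged warning; an all-zero
control total is an error. Each guide's counts across the 12 mice are then
modelled as a negative-binomial GLM, `counts ~ condition`, log link, offset
log(size factor). Dispersion α is method-of-moments from the Pearson
chi-square of an initial Poisson fit, (χ² − df)/Σμ, floored at 1e-6 — with
6 + 6 samples a mean–dispersion trend fit would be underdetermined, so no
shrinkage toward a trend is attempted. Fits that fail numerically are
flagged `converged=False` and excluded, never imputed. The reported
condition effect is on the log2 scale (natural-log coefficient / ln 2).

**Ranking.** Genes are ranked by descending L_g, ties broken
lexicographically by gene symbol (deterministic output ordering). Guides
with zero counts in every sample are dropped with a logged list; a gene
reduced to 3 guides is computed with `n_guides = 3`, not erred.

## Hit intersection

Differential-expression tables (gene, log2fc, padj) are thresholded with
*strict* inequalities — log2FC > 1 and adjusted p < 0.05 — and the screen
circle is "positively enriched": L_g > 1, with an optional q cutoff that is
off by default since positive enrichment alone defines membership. Venn
regions over 2–4 sets are computed exactly (every membership pattern with
its gene list; regions partition the union). When separate per-cell-type DE
tables must become one circle, both merge modes are exposed: `union` (pass
anywhere; most significant row kept) and `intersection` (present and
passing everywhere; least significant row kept).

## The synthetic generator

`simulate_screen` composes the generative process the analysis assumes:

1. **Transduction** — integrations per cell ~ Poisson(MOI); cells with 0
   integrations carry no guide, cells with ≥ 2 are discarded rather than
   modelled (the screen's single-perturbation assumption; at the default
   MOI 0.5, ~23% of infected cells are discarded). Survivors draw one
   guide uniformly.
2. **Engraftment bottleneck** — each mouse's founders are a multinomial
   draw of `bottleneck` cells with probabilities proportional to pool
   abundance (with replacement, so the bottleneck may exceed the pool).
   This is the dominant noise source of in vivo screens.
3. **Selection** — one epoch of binomial thinning in the hPi arm with
   survival min(1, r·θ_g); θ = 1 for control guides and unlisted genes.
   Control mice are untouched. The clipping means protective effects
   saturate at 1/r-fold enrichment (θ = 4 at r = 0.5 yields L ≈ +1, while
   θ = 0.25 yields L ≈ −2): protective and sensitizing effects of equal
   θ-magnitude are *not* symmetric in L, as in any screen where survival
   cannot exceed 100%.
4. **Sequencing** — gamma-Poisson counts with mean depth·aᵢ/Σa and
   variance μ + αμ²; α = 0 degenerates to Poisson. Per-sample expected
   depth scales with graft survival (`depth · survivors/bottleneck`), so
   global rejection lowers absolute hPi counts as graft shrinkage lowers
   recovered gDNA; `equal_depth=True` disables this for pure-composition
   simulations.

**Seeding.** One master seed; children are derived as
`SeedSequence(seed, spawn_key=k)` with k = (0) library, (1) transduction,
(2, condition_index, mouse_number) per mouse — adding mice or conditions
never reshuffles earlier mice, and the whole dataset is byte-reproducible.

**Defaults.** Library scale follows the real pool: 19,114 genes × 4
guides, 941 NT + 59 intergenic controls, MOI 0.5 (< 1), 6 mice per arm,
rejection survival r = 0.5 (hPi grafts lose roughly half their cells,
matching the observed across-the-board reduction in NT reads and endocrine
mass). The founder population per graft and the sequencing depth are not
reported quantities; the defaults (5×10⁵ founders, 10⁷ expected reads,
2×10⁷ transduced cells) are chosen to give the tens-to-hundreds of
founders and hundreds of reads per guide typical of genome-wide in vivo
screens, and are explicit config fields, not constants. NB dispersion
defaults to α = 0.25, in the range commonly estimated for guide-level
counts in pooled screens.

**What the generator does not emulate.** No clonal growth, no guide
efficacy differences, no essential-gene dropout before transplantation, no
xeno-GVHD or immune-population dynamics, no spatial graft structure, no
PCR jackpotting beyond the NB overdispersion, and a uniform
guides-per-gene count (the real library is slightly non-uniform: 76,441
targeting guides vs the uniform 76,456). Passing calibration and recovery
tests therefore demonstrates that the inference machinery is correct and
calibrated *under the assumed generative model*, not that real screens
meet those assumptions.

## Evaluation studies

All desk-scale studies (`isletscreen.evaluate`) run on a screen scaled to
1,000 genes × 4 guides with 100 NT controls, keeping the study's mouse
numbers (6 + 6), MOI (0.5) and rejection survival (0.5), with founders and
depth scaled proportionally (10⁵ founders, ~2×10⁶ reads per sample: ~24
founders and ~500 reads per guide). One simulation plus full inference
takes well under a second, so a 20-replicate calibration and a
10-replicate recovery study complete in seconds:

- **FDR calibration** — on neutral screens (θ ≡ 1) every discovery at
  q < 0.10 is false; mean false discovery proportion over 20 replicates
  must not exceed 0.10 beyond 3 standard errors.
- **Effect recovery** — 25 genes at θ = 4 and 25 at θ = 0.25 among 1,000;
  ranking by |L_g| must reach mean AUROC ≥ 0.90 over 10 replicates, with
  positive mean L for protective and negative for sensitizing genes.
- **Global depletion** — per-mouse mean raw NT counts, hPi vs control,
  one-sided t-test.
- **Moment checks** — infected fraction vs 1 − e^(−MOI), multinomial
  founder variance N·p·(1−p), NB count variance μ + αμ².

## Numerical and design choices

- Exact-match spacer counting only, on the given strand (optional
  reverse-complement scan): deterministic and auditable; amplicon
  structure varies by protocol, so the search window is a required
  user parameter and mismatch-tolerant matching is out of scope.
- Reads matching spacers of two or more guides are unassigned, never
  double-counted; counting is order-independent.
- Strict readers: malformed spacers, unknown classes, duplicate ids,
  negative or non-integer counts, unknown conditions and library/count
  mismatches are errors naming the offending row — no coercion.
- Empirical p-values are never 0 by construction; BH input is validated to
  (0, 1].
- Ties in ranking are broken by gene symbol; all sorts are stable
  (mergesort) so outputs are reproducible across runs and platforms.
- Gene symbols in intersections are compared case-sensitively after
  whitespace stripping; symbol aliasing is an external concern.

## Known limitations

- The empirical null assumes control guides share the targeting guides'
  technical noise; control-specific artifacts (e.g. different cloning
  representation) would mis-calibrate it.
- With pooled counting, one dominant mouse can drive a gene's L_g; the
  per-guide NB fits are the cross-check, but no formal mixed model is
  fitted.
- q-value resolution is bounded by `n_draws`; very small FDRs require
  proportionally many null draws.
- The per-guide NB model conditions on a moment-estimated dispersion
  rather than profiling it; with 12 samples the difference is well below
  the biological noise floor.
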