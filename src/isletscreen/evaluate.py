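"""Calibration and recovery studies run entirely on synthetic screens.

The real screen's gene hits depend on the deposited in vivo sequencing
data; what can be verified at desk scale is that the inference machinery
behaves: false discovery control holds on neutral screens, known spiked-in
survival effects are recovered with the right sign, and the simulator's
global-rejection signature (lower absolute NT counts in hPi grafts)
reproduces.  These studies run the full pipeline on screens scaled to
1,000 genes so a complete calibration fits in minutes; mouse numbers,
guides per gene, MOI and the rejection fraction keep their study values.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .simulate import SimulationConfig, TrueEffects, simulate_screen, spiked_effects
from .stats import analyze_screen

#: Scaled-down study conditions used by every desk-scale evaluation:
#: 1,000 genes x 4 guides with 100 NT controls, 6 mice per arm, MOI 0.5,
#: 50% global rejection survival, founder and depth budgets scaled to the
#: reduced library (~24 founders and ~500 expected reads per guide).
STUDY_SCALE = dict(
    n_genes=1000,
    guides_per_gene=4,
    n_nt=100,
    n_intergenic=0,
    n_cells=400_000,
    moi=0.5,
    bottleneck=100_000,
    n_mice_per_condition=6,
    rejection_survival=0.5,
    depth=2_050_000.0,
    dispersion=0.25,
)


def study_config(seed: int, **overrides) -> SimulationConfig:
    """A :data:`STUDY_SCALE` simulation config with the given seed."""
    params = dict(STUDY_SCALE)
    params.update(overrides)
    return SimulationConfig(seed=seed, **params)


def auroc(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """Area under the ROC curve by the rank-sum identity (ties count half)."""
    pos = np.asarray(scores_pos, dtype=float)
    neg = np.asarray(scores_neg, dtype=float)
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def _library_for(config: SimulationConfig):
    """The library a given config's screen will use (same seed split)."""
    from .library import build_library
    from .simulate import _child_seed

    return build_library(
        config.n_genes, config.guides_per_gene, config.n_nt, config.n_intergenic,
        seed=_child_seed(config.seed, 0),
    )


def null_fdp_study(
    seed: int,
    n_sims: int = 20,
    q_threshold: float = 0.10,
    n_draws: int = 1000,
) -> dict:
    """False discovery proportions over neutral (theta = 1) screens.

    Every gene is null, so every q < threshold call is a false discovery:
    per simulation FDP = 1 if anything is called, else 0, and the mean
    FDP estimates the achieved FDR.  Returns per-sim FDPs, their mean and
    standard error.
    """
    fdps = []
    for i in range(n_sims):
        config = study_config(seed=seed + i)
        dataset = simulate_screen(config)
        ranked, _ = analyze_screen(
            dataset.counts, dataset.library, n_draws=n_draws, seed=seed + i
        )
        n_disc = int((ranked["q"] < q_threshold).sum())
        fdps.append(1.0 if n_disc > 0 else 0.0)
    fdps = np.array(fdps)
    se = float(fdps.std(ddof=1) / np.sqrt(len(fdps))) if len(fdps) > 1 else 0.0
    return {"fdp": fdps, "mean_fdp": float(fdps.mean()), "se": se,
            "q_threshold": q_threshold}


def effect_recovery_study(
    seed: int,
    n_reps: int = 10,
    n_protective: int = 25,
    n_sensitizing: int = 25,
    theta_protective: float = 4.0,
    theta_sensitizing: float = 0.25,
    n_draws: int = 1000,
) -> dict:
    """Recovery of spiked survival effects among neutral genes.

    Each replicate spikes ``n_protective`` genes at ``theta_protective``
    and ``n_sensitizing`` at ``theta_sensitizing`` into a
    :data:`STUDY_SCALE` screen, runs the full inference, and scores
    ranking by |L_g| with true non-neutral genes as positives (AUROC).
    Also reports the mean statistic of each spiked class, whose signs
    check the convention that protective knockouts are positively
    enriched under immune attack.
    """
    aurocs, mean_prot, mean_sens = [], [], []
    for i in range(n_reps):
        rep_seed = seed + 1000 + i
        config = study_config(seed=rep_seed)
        effects = spiked_effects(
            _library_for(config),
            n_protective,
            n_sensitizing,
            theta_protective,
            theta_sensitizing,
            seed=rep_seed,
        )
        dataset = simulate_screen(config, effects)
        ranked, _ = analyze_screen(
            dataset.counts, dataset.library, n_draws=n_draws, seed=rep_seed
        )
        L = ranked.set_index("gene")["log2fc"]
        prot = [g for g, t in effects.theta.items() if t > 1]
        sens = [g for g, t in effects.theta.items() if t < 1]
        spiked = set(prot) | set(sens)
        nulls = [g for g in L.index if g not in spiked]
        aurocs.append(auroc(L[list(spiked)].abs(), L[nulls].abs()))
        mean_prot.append(float(L[prot].mean()))
        mean_sens.append(float(L[sens].mean()))
    return {
        "auroc": np.array(aurocs),
        "mean_auroc": float(np.mean(aurocs)),
        "mean_log2fc_protective": float(np.mean(mean_prot)),
        "mean_log2fc_sensitizing": float(np.mean(mean_sens)),
    }


def nt_depletion_study(seed: int) -> dict:
    """Global-rejection signature: raw NT counts per hPi mouse vs control.

    Simulates one :data:`STUDY_SCALE` screen (r = 0.5, depth tracking graft
    survival) and one-sided t-tests whether per-mouse mean NT guide counts
    are lower in hPi grafts.
    """
    dataset = simulate_screen(study_config(seed=seed))
    nt = dataset.counts.counts.loc[dataset.library.nt_ids]
    per_mouse_ctrl = nt[dataset.counts.samples_for("control")].mean(axis=0)
    per_mouse_hpi = nt[dataset.counts.samples_for("hPi")].mean(axis=0)
    t, p = sps.ttest_ind(per_mouse_hpi, per_mouse_ctrl, alternative="less")
    return {
        "mean_nt_control": float(per_mouse_ctrl.mean()),
        "mean_nt_hpi": float(per_mouse_hpi.mean()),
        "log2_ratio": float(np.log2(per_mouse_hpi.mean() / per_mouse_ctrl.mean())),
        "t": float(t),
        "p": float(p),
    }
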