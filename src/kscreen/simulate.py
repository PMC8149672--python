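"""Synthetic genotype/phenotype generation and simulation experiment designs.

The genotype generator emulates LD-block-structured unphased dosages with
a realistic allele-frequency spectrum: variants are grouped into blocks, a
latent AR(1) Gaussian copula induces within-block LD, and two independent
haplotypes are thresholded at each variant's target allele frequency and
summed to a dosage in {0,1,2}.  The frequency spectrum mixes common,
low-frequency, rare (MAF < 0.01, MAC >= 5) and ultra-rare (MAC < 5)
variants, the regime in which sequencing studies operate.

Phenotype recipes:

* quantitative:  Y = X1 + sum_j beta_j g_j + eps,  X1 ~ N(0,1), eps ~ N(0,3)
* dichotomous:   logit(mu) = beta0 + X1 + sum_j beta_j g_j, with beta0
  solved numerically so the population prevalence hits its target
  (default 10%).

Two effect-size laws are supported: beta_j = a / sqrt(2 m_j (1 - m_j))
with ``a`` calibrated so the realized genetic variance
sum_j beta_j^2 var(g_j) equals a target exactly, and
beta_j = a |log10 m_j| with ``a`` fixed.

``run_design`` reproduces the study designs used to characterize the
method (single-region FDR/power, genome-wide multi-locus discovery,
causal-variant prioritization, the shadow effect of common variants on
rare-variant analysis, population stratification, and the stability of
the selection under knockoff resampling), each at a configurable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import association as assoc
from .knockoff_filter import feature_stats, filter_windows
from .knockoffs import cluster_tight_ld, generate_knockoffs
from .panel import GenotypePanel, categorize_variants, tile_windows
from .screen import ScanConfig, evaluate, scan

__all__ = [
    "HaplotypePanelSpec",
    "SimConfig",
    "simulate_genotypes",
    "simulate_phenotype",
    "calibrate_effects",
    "representative_variants",
    "run_design",
]


@dataclass
class HaplotypePanelSpec:
    """Parameters of the synthetic haplotype panel.

    The MAF spectrum is a categorical mixture over frequency strata; the
    defaults put 40% mass on rare and 15% on ultra-rare variants so that
    the realized spectrum comfortably contains both.
    """

    n: int = 2000
    p: int = 300
    span_bp: int = 200_000
    block_min: int = 4
    block_max: int = 12
    rho_min: float = 0.5
    rho_max: float = 0.95
    freq_weights: tuple = (0.30, 0.15, 0.40, 0.15)  # common, lowfreq, rare, ultra
    seed: int = 0


@dataclass
class SimConfig:
    """Phenotype-generation recipe."""

    family: str = "gaussian"
    causal_fraction: float = 0.005
    signal_window_bp: int = 10_000
    effect_law: str = "maf_variance"  # or "log_maf"
    variance_target: float = 0.05
    effect_a: float = 1.4  # used by the log_maf law
    prevalence: float = 0.10
    eps_var: float = 3.0
    causal_maf_range: tuple = (0.0, 0.5)
    seed: int = 0


def _target_frequencies(spec: HaplotypePanelSpec, rng) -> np.ndarray:
    """Draw per-variant target allele frequencies from the mixture."""
    n2 = 2 * spec.n
    strata = rng.choice(4, size=spec.p, p=np.asarray(spec.freq_weights))
    f = np.empty(spec.p)
    f[strata == 0] = rng.uniform(0.05, 0.5, (strata == 0).sum())
    f[strata == 1] = rng.uniform(0.01, 0.05, (strata == 1).sum())
    rare_lo = min(max(6.0 / n2, 0.0005), 0.009)  # keep MAC >= 5 plausible
    f[strata == 2] = rng.uniform(rare_lo, 0.01, (strata == 2).sum())
    f[strata == 3] = rng.uniform(1.0 / n2, 4.0 / n2, (strata == 3).sum())
    return f


def simulate_genotypes(spec: HaplotypePanelSpec) -> GenotypePanel:
    """Generate a block-LD dosage panel; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    freqs = _target_frequencies(spec, rng)
    thresholds = stats.norm.ppf(freqs)

    # block partition and per-block AR(1) copula correlation
    sizes = []
    while sum(sizes) < spec.p:
        sizes.append(int(rng.integers(spec.block_min, spec.block_max + 1)))
    sizes[-1] -= sum(sizes) - spec.p
    rhos = rng.uniform(spec.rho_min, spec.rho_max, len(sizes))

    def draw_haplotypes():
        H = np.empty((spec.n, spec.p))
        j0 = 0
        for b, rho in zip(sizes, rhos):
            Z = np.empty((spec.n, b))
            Z[:, 0] = rng.standard_normal(spec.n)
            for k in range(1, b):
                Z[:, k] = rho * Z[:, k - 1] + np.sqrt(1 - rho * rho) * rng.standard_normal(spec.n)
            H[:, j0 : j0 + b] = Z
            j0 += b
        return (H < thresholds[None, :]).astype(float)

    dos = draw_haplotypes() + draw_haplotypes()
    positions = np.sort(
        rng.choice(np.arange(1, spec.span_bp + 1), size=spec.p, replace=False)
    )
    panel = GenotypePanel(
        dosages=dos,
        positions=positions,
        chrom=np.repeat("chr1", spec.p),
        variant_ids=np.array([f"v{j}" for j in range(spec.p)], dtype=object),
    )
    keep = panel.mac > 0
    return panel.subset_variants(np.flatnonzero(keep)) if not keep.all() else panel


def representative_variants(panel: GenotypePanel, seed: int = 0) -> np.ndarray:
    """One randomly chosen representative per tight-LD (|r| > 0.75) cluster."""
    rng = np.random.default_rng(seed)
    clusters = cluster_tight_ld(panel)
    keep = []
    for cid in np.unique(clusters.assignment):
        members = clusters.members(cid)
        keep.append(rng.choice(members))
    return np.sort(np.asarray(keep))


def calibrate_effects(
    maf: np.ndarray,
    g_var: np.ndarray,
    law: str,
    variance_target: float = 0.05,
    a: float = 1.4,
) -> tuple[np.ndarray, float]:
    """Per-variant effect sizes under the configured law.

    For ``maf_variance`` the scale ``a`` is solved so that
    sum_j beta_j^2 var(g_j) equals ``variance_target`` exactly on the
    realized genotype variances.  For ``log_maf``, beta_j = a |log10 m_j|.
    Returns (beta, realized genetic variance).
    """
    maf = np.asarray(maf, float)
    g_var = np.asarray(g_var, float)
    if law == "maf_variance":
        base = 1.0 / np.sqrt(2 * maf * (1 - maf))
        denom = float(np.sum(base ** 2 * g_var))
        if denom <= 0:
            raise ValueError("causal variants carry no genotype variance")
        a_cal = np.sqrt(variance_target / denom)
        beta = a_cal * base
    elif law == "log_maf":
        beta = a * np.abs(np.log10(maf))
    else:
        raise ValueError(f"unknown effect law {law!r}")
    return beta, float(np.sum(beta ** 2 * g_var))


def _solve_intercept(eta: np.ndarray, prevalence: float) -> float:
    """beta0 with E[expit(beta0 + eta)] = prevalence on the sampled eta."""

    def gap(b0):
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))) - prevalence)

    return optimize.brentq(gap, -40, 40, xtol=1e-10)


def simulate_phenotype(panel: GenotypePanel, cfg: SimConfig):
    """Simulate a phenotype with causal variants in one signal window.

    Returns ``(Y, X, truth)`` where ``X`` is the n x 1 covariate matrix
    and ``truth`` records the causal indices, effects, realized genetic
    variance, the signal window bounds and (binary only) the solved
    intercept.
    """
    rng = np.random.default_rng(cfg.seed)
    n = panel.n
    X1 = rng.standard_normal(n)

    s = max(1, round(cfg.causal_fraction * panel.p)) if cfg.causal_fraction > 0 else 0
    causal = np.array([], dtype=int)
    wstart = wend = None
    beta = np.array([])
    gvar = 0.0
    if s > 0:
        lo, hi = cfg.causal_maf_range
        eligible = (panel.maf > lo) & (panel.maf <= hi) & (panel.mac > 0)
        pos = panel.positions
        # pick a signal window that contains enough eligible variants
        starts = np.arange(pos.min(), max(pos.max() - cfg.signal_window_bp, pos.min()) + 1, 1000)
        rng.shuffle(starts)
        for ws in starts:
            inwin = eligible & (pos >= ws) & (pos <= ws + cfg.signal_window_bp - 1)
            if inwin.sum() >= s:
                wstart, wend = int(ws), int(ws + cfg.signal_window_bp - 1)
                causal = rng.choice(np.flatnonzero(inwin), size=s, replace=False)
                break
        else:
            raise ValueError("no signal window holds enough eligible causal variants")
        causal = np.sort(causal)
        g = panel.dosages[:, causal]
        beta, gvar = calibrate_effects(
            panel.maf[causal], g.var(axis=0), cfg.effect_law,
            cfg.variance_target, cfg.effect_a,
        )
        eta_g = g @ beta
    else:
        eta_g = np.zeros(n)

    eta = X1 + eta_g
    if cfg.family == "gaussian":
        Y = eta + rng.normal(0.0, np.sqrt(cfg.eps_var), n)
        beta0 = 0.0
    elif cfg.family == "binomial":
        beta0 = _solve_intercept(eta, cfg.prevalence)
        mu = 1.0 / (1.0 + np.exp(-(beta0 + eta)))
        Y = rng.binomial(1, mu).astype(float)
    else:
        raise ValueError(f"unknown family {cfg.family!r}")

    truth = {
        "causal_idx": causal,
        "beta": beta,
        "genetic_variance": gvar,
        "signal_window": (wstart, wend),
        "beta0": beta0,
    }
    return Y, X1[:, None], truth


def _causal_windows_from_truth(panel, truth, windows=None):
    """(chrom, start, end) for every tiled window holding a causal variant."""
    cid = set(truth["causal_idx"].tolist())
    if windows is None:
        windows = tile_windows(panel)
    return [
        (w.chrom, w.start, w.end)
        for w in windows
        if cid & set(w.members)
    ]


# ---------------------------------------------------------------------------
# conventional comparator


def conventional_selection(
    panel, Y, X, config: ScanConfig, method: str = "bonferroni"
):
    """Per-window ensemble p-values with Bonferroni or BH selection.

    The comparator shares the exact test ensemble with the knockoff scan;
    only the multiple-testing correction differs.
    """
    categories = categorize_variants(panel)
    windows = tile_windows(panel, config.sizes, categories)
    null = assoc.fit_null_model(Y, X, family=config.family)
    pv = []
    kept = []
    for w in windows:
        try:
            pv.append(
                assoc.window_pvalue(
                    null, panel.dosages, w, categories, panel.maf,
                    use_spa=config.use_spa,
                )
            )
            kept.append(w)
        except ValueError:
            continue
    pv = np.asarray(pv)
    m = pv.size
    if method == "bonferroni":
        selected = pv <= 0.05 / m
    elif method == "bh":
        order = np.argsort(pv)
        thresh = config.q * (np.arange(1, m + 1)) / m
        passing = np.flatnonzero(pv[order] <= thresh)
        selected = np.zeros(m, dtype=bool)
        if passing.size:
            selected[order[: passing.max() + 1]] = True
    else:
        raise ValueError(f"unknown correction {method!r}")
    return kept, pv, selected


# ---------------------------------------------------------------------------
# experiment designs


def _fdr_power_reps(
    reps, q, M, n, p, family, law, variance_target, maf_range, seed,
    prefilter=True,
):
    fdps, powers = [], []
    for r in range(reps):
        rng_seed = seed + 7919 * r
        panel = simulate_genotypes(HaplotypePanelSpec(n=n, p=p, seed=rng_seed))
        if prefilter:
            panel = panel.subset_variants(
                representative_variants(panel, seed=rng_seed)
            )
        cfg = SimConfig(
            family=family, effect_law=law, variance_target=variance_target,
            causal_maf_range=maf_range, seed=rng_seed + 1,
        )
        Y, X, truth = simulate_phenotype(panel, cfg)
        res = scan(panel, Y, X, ScanConfig(M=M, q=q, seed=rng_seed + 2, family=family))
        causal = _causal_windows_from_truth(panel, truth, res.windows)
        ev = evaluate(res.table, causal)
        fdps.append(ev["fdp"])
        powers.append(ev["power"])
    fdps, powers = np.asarray(fdps), np.asarray(powers)
    return {
        "replicates": reps,
        "fdr": float(fdps.mean()),
        "fdr_se": float(fdps.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
        "power": float(powers.mean()),
    }


def run_single_region(
    reps=50, q=0.1, M=5, n=2000, p=300, family="gaussian",
    scenario="common", seed=0,
):
    """Single-region FDR/power design: 0.5% causal in a 10 kb window.

    A representative variant is kept from each tight-LD cluster before the
    phenotype is simulated, so that the false discovery proportion is well
    defined.  Scenarios: 'common' (causal MAF > 0.01, genetic variance
    0.05) and 'rare' (causal MAF < 0.01, genetic variance 0.1).
    """
    if scenario == "common":
        maf_range, v = (0.01, 0.5), 0.05
    elif scenario == "rare":
        maf_range, v = (0.0, 0.01), 0.10
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return _fdr_power_reps(
        reps, q, M, n, p, family, "maf_variance", v, maf_range, seed,
    )


def run_genome_wide(
    reps=20, q=0.1, M=5, n=1500, n_causal_loci=10, n_noise_loci=50,
    variants_per_locus=60, locus_span=200_000, causal_window_bp=10_000,
    buffers=(50_000, 75_000, 100_000), seed=0, locus_variance=1.0,
):
    """Multi-locus genome-wide design with locus-level FDR at buffers.

    Each locus is an independent LD region on its own chromosome; causal
    loci hold a 10 kb window in which 10% of variants are causal, with the
    per-locus genetic variance calibrated to ``locus_variance``.
    """
    n_loci = n_causal_loci + n_noise_loci
    out = {f"fdr_{b // 1000}kb": [] for b in buffers}
    out["locus_power"] = []
    for r in range(reps):
        rng = np.random.default_rng(seed + 104729 * r)
        panels, causal_windows, parts = [], [], []
        for li in range(n_loci):
            sp = HaplotypePanelSpec(
                n=n, p=variants_per_locus, span_bp=locus_span,
                seed=int(rng.integers(2 ** 31)),
            )
            pl = simulate_genotypes(sp)
            pl.chrom[:] = f"chr{li + 1}"
            panels.append(pl)
        eta_g = np.zeros(n)
        for li in range(n_causal_loci):
            pl = panels[li]
            pos = pl.positions
            ws = int(rng.integers(pos.min(), max(pos.max() - causal_window_bp, pos.min()) + 1))
            inwin = np.flatnonzero((pos >= ws) & (pos <= ws + causal_window_bp - 1) & (pl.mac > 0))
            if inwin.size == 0:
                continue
            s = max(1, round(0.10 * inwin.size))
            causal = rng.choice(inwin, size=s, replace=False)
            g = pl.dosages[:, causal]
            beta, _ = calibrate_effects(
                pl.maf[causal], g.var(axis=0), "maf_variance", locus_variance
            )
            eta_g += g @ beta
            causal_windows.append(
                (f"chr{li + 1}", ws, ws + causal_window_bp - 1)
            )
        X1 = rng.standard_normal(n)
        Y = X1 + eta_g + rng.normal(0, np.sqrt(3.0), n)
        merged = GenotypePanel(
            dosages=np.hstack([pl.dosages for pl in panels]),
            positions=np.concatenate([pl.positions for pl in panels]),
            chrom=np.concatenate([pl.chrom for pl in panels]),
            variant_ids=np.concatenate(
                [[f"l{li}_{v}" for v in pl.variant_ids] for li, pl in enumerate(panels)]
            ),
        )
        res = scan(
            merged, Y, X1[:, None],
            ScanConfig(M=M, q=q, seed=int(rng.integers(2 ** 31))),
        )
        for b in buffers:
            ev = evaluate(res.table, causal_windows, buffer_bp=b)
            out[f"fdr_{b // 1000}kb"].append(ev["fdp"])
        out["locus_power"].append(
            evaluate(res.table, causal_windows, buffer_bp=0)["locus_power"]
        )
    summary = {k: float(np.mean(v)) for k, v in out.items()}
    summary["replicates"] = reps
    for b in buffers:
        vals = np.asarray(out[f"fdr_{b // 1000}kb"])
        summary[f"fdr_{b // 1000}kb_se"] = (
            float(vals.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
        )
    return summary


def run_prioritization(reps=20, q=0.1, M=5, n=2000, p=300, seed=0):
    """Causal-variant prioritization: overlap and distance of selections.

    Binary trait, 5 kb causal window, effect law beta = 1.4 |log10 m|.
    Reports the mean fraction of selected windows overlapping the causal
    window and the mean maximum distance of a selection from it.
    """
    overlaps, maxdist = [], []
    for r in range(reps):
        sd = seed + 7919 * r
        panel = simulate_genotypes(HaplotypePanelSpec(n=n, p=p, seed=sd))
        cfg = SimConfig(
            family="binomial", causal_fraction=0.0025, signal_window_bp=5000,
            effect_law="log_maf", effect_a=1.4, seed=sd + 1,
        )
        Y, X, truth = simulate_phenotype(panel, cfg)
        res = scan(panel, Y, X, ScanConfig(M=M, q=q, seed=sd + 2, family="binomial"))
        sel = res.selected
        if not len(sel):
            continue
        ws, we = truth["signal_window"]
        ov = (sel["start"] <= we) & (sel["end"] >= ws)
        overlaps.append(float(ov.mean()))
        d = np.maximum(ws - sel["end"].to_numpy(), sel["start"].to_numpy() - we)
        maxdist.append(float(np.maximum(d, 0).max()))
    return {
        "replicates": reps,
        "reps_with_selection": len(overlaps),
        "overlap_fraction": float(np.mean(overlaps)) if overlaps else 0.0,
        "max_distance_bp": float(np.mean(maxdist)) if maxdist else 0.0,
    }


def run_shadow(reps=25, q=0.1, M=5, n=2000, p=300, variance_target=1.0, seed=0):
    """Shadow-effect design: common causals, rare-only analysis.

    All causal variants are common but the scan sees only rare variants,
    so every selection is a false positive driven by LD shadow.  Knockoffs
    are generated on the *full* panel and then subset: the knockoff of a
    rare variant thereby preserves its correlation with the causal common
    variants, so knockoff importance scores rise with the originals and
    the contrast statistic stays near zero.  Returns paired
    false-positive counts for the knockoff scan and for the conventional
    comparator (Bonferroni on the same ensemble p-values).
    """
    from .knockoffs import KnockoffSet

    fp_ko, fp_conv = [], []
    for r in range(reps):
        sd = seed + 7919 * r
        panel = simulate_genotypes(HaplotypePanelSpec(n=n, p=p, seed=sd))
        cfg = SimConfig(
            family="gaussian", causal_fraction=0.01,
            causal_maf_range=(0.05, 0.5), variance_target=variance_target,
            seed=sd + 1,
        )
        Y, X, _ = simulate_phenotype(panel, cfg)
        rare = np.flatnonzero(panel.maf < 0.01)
        if rare.size < 5:
            continue
        sub = panel.subset_variants(rare)
        ko_full = generate_knockoffs(panel, M=M, seed=sd + 2)
        ko_sub = KnockoffSet(
            copies=[c[:, rare] for c in ko_full.copies], M=M, seed=sd + 2
        )
        sc = ScanConfig(M=M, q=q, seed=sd + 2, sizes=(1000, 5000, 10000))
        res = scan(sub, Y, X, sc, knockoffs=ko_sub)
        fp_ko.append(int(res.table["selected"].sum()))
        _, _, conv_sel = conventional_selection(sub, Y, X, sc, method="bonferroni")
        fp_conv.append(int(conv_sel.sum()))
    return {
        "replicates": len(fp_ko),
        "fp_knockoff_mean": float(np.mean(fp_ko)),
        "fp_conventional_mean": float(np.mean(fp_conv)),
        "fp_knockoff_total": int(np.sum(fp_ko)),
        "fp_conventional_total": int(np.sum(fp_conv)),
    }


def run_stratification(reps=25, q=0.1, M=5, n=1800, p=200, gamma=1.0, seed=0):
    """Population-stratification design with three groups.

    Group membership shifts both the trait mean (scaled by ``gamma``) and
    the latent allele frequencies, so any selection on the target region
    reflects unadjusted confounding.  Returns the fraction of replicates
    with any (false) selection for the knockoff scan and the conventional
    comparator, without PC adjustment.
    """
    any_ko, any_conv = [], []
    for r in range(reps):
        sd = seed + 7919 * r
        rng = np.random.default_rng(sd)
        spec = HaplotypePanelSpec(n=n, p=p, seed=sd)
        panel = simulate_genotypes(spec)
        groups = rng.integers(0, 3, n)
        # group-specific allele-frequency shift: members of groups 1 and 2
        # gain extra minor alleles at a random 30% of variants, creating
        # genotype-ancestry correlation
        strat_vars = rng.choice(
            panel.p, size=max(1, int(0.3 * panel.p)), replace=False
        )
        for g_lab in (1, 2):
            rows = np.flatnonzero(groups == g_lab)
            bump = rng.binomial(1, 0.04 * g_lab, size=(rows.size, strat_vars.size))
            panel.dosages[np.ix_(rows, strat_vars)] = np.minimum(
                2.0, panel.dosages[np.ix_(rows, strat_vars)] + bump
            )
        panel._recompute_frequencies()
        X1 = rng.standard_normal(n)
        Y = X1 + gamma * groups + rng.normal(0, np.sqrt(3.0), n)
        sc = ScanConfig(M=M, q=q, seed=sd + 2, sizes=(1000, 5000, 10000))
        res = scan(panel, Y, X1[:, None], sc)
        any_ko.append(int(res.table["selected"].sum() > 0))
        _, _, conv_sel = conventional_selection(panel, Y, X1[:, None], sc, method="bh")
        any_conv.append(int(conv_sel.sum() > 0))
    return {
        "replicates": reps,
        "fdr_knockoff": float(np.mean(any_ko)),
        "fdr_conventional": float(np.mean(any_conv)),
    }


def run_stability(n_draws=20, M=5, n=1500, p=150, seed=0):
    """Stability under knockoff resampling: median- vs max-based statistic.

    On fixed genotypes and phenotype, knockoff sets are re-drawn
    ``n_draws`` times and the variance of each window's tau statistic is
    compared between the median-based and the max-based multiple-knockoff
    statistic.  Reports the fraction of signal-bearing windows where the
    median-based statistic is at least as stable.
    """
    panel = simulate_genotypes(HaplotypePanelSpec(n=n, p=p, seed=seed))
    cfg = SimConfig(family="gaussian", variance_target=0.1, seed=seed + 1,
                    causal_fraction=0.01)
    Y, X, truth = simulate_phenotype(panel, cfg)
    categories = categorize_variants(panel)
    windows = tile_windows(panel, (1000, 5000, 10000), categories)
    null = assoc.fit_null_model(Y, X)
    p0 = np.array([
        assoc.window_pvalue(null, panel.dosages, w, categories, panel.maf)
        for w in windows
    ])
    taus_med, taus_max = [], []
    clusters = cluster_tight_ld(panel)
    for d in range(n_draws):
        ko = generate_knockoffs(panel, M=M, seed=seed + 31 * d, clusters=clusters)
        pk = np.column_stack([
            np.array([
                assoc.window_pvalue(null, ko[m], w, categories, panel.maf)
                for w in windows
            ])
            for m in range(M)
        ])
        taus_med.append([feature_stats(p0[i], pk[i], "median").tau for i in range(len(windows))])
        taus_max.append([feature_stats(p0[i], pk[i], "max").tau for i in range(len(windows))])
    vmed = np.var(np.asarray(taus_med), axis=0)
    vmax = np.var(np.asarray(taus_max), axis=0)
    cid = set(truth["causal_idx"].tolist())
    signal = np.array([bool(cid & set(w.members)) for w in windows])
    frac = float(np.mean(vmed[signal] <= vmax[signal])) if signal.any() else np.nan
    return {
        "n_draws": n_draws,
        "signal_windows": int(signal.sum()),
        "median_more_stable_fraction": frac,
        "mean_var_median": float(vmed[signal].mean()) if signal.any() else np.nan,
        "mean_var_max": float(vmax[signal].mean()) if signal.any() else np.nan,
    }


_DESIGNS = {
    "single_region": run_single_region,
    "genome_wide": run_genome_wide,
    "prioritization": run_prioritization,
    "shadow": run_shadow,
    "stratification": run_stratification,
    "stability": run_stability,
}


def run_design(design: str, **kwargs) -> dict:
    """Dispatch to one of the named simulation designs."""
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(_DESIGNS)}")
    return _DESIGNS[design](**kwargs)
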