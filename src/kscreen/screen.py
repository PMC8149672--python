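"""End-to-end genome scan: knockoffs -> window p-values -> knockoff filter.

``scan`` ties the pipeline together and is deterministic given a seed;
``evaluate`` scores a selection against known simulation truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import association as assoc
from .knockoff_filter import filter_windows
from .knockoffs import KnockoffSet, cluster_tight_ld, generate_knockoffs
from .panel import GenotypePanel, Window, categorize_variants, tile_windows

logger = logging.getLogger("kscreen")

__all__ = ["ScanConfig", "ScanResult", "scan", "evaluate"]


@dataclass
class ScanConfig:
    """Knobs for a genome scan."""

    sizes: tuple = (1, 1000, 5000, 10000)
    M: int = 5
    q: float = 0.1
    seed: int = 0
    family: str = "gaussian"
    use_spa: bool = True

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0,1)")
        if len(self.sizes) == 0:
            raise ValueError("sizes must be nonempty")


@dataclass
class ScanResult:
    table: pd.DataFrame
    tau_hat: float
    config: ScanConfig
    windows: list = field(repr=False, default_factory=list)

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"] == 1]

    def summary(self) -> dict:
        by_size = (
            self.table.groupby("size_class")["selected"].agg(["count", "sum"])
            .rename(columns={"count": "tested", "sum": "selected"})
        )
        return {
            "windows_tested": int(len(self.table)),
            "windows_selected": int(self.table["selected"].sum()),
            "per_size_class": {
                str(k): {"tested": int(v["tested"]), "selected": int(v["selected"])}
                for k, v in by_size.iterrows()
            },
            "tau_hat": None if np.isinf(self.tau_hat) else float(self.tau_hat),
            "config": asdict(self.config),
        }


def _window_pvalues(
    null, dosages, windows, categories, maf, annotations, use_spa
) -> np.ndarray:
    cache = assoc.ScoreCache(null, dosages)
    out = np.ones(len(windows))
    for i, w in enumerate(windows):
        try:
            out[i] = assoc.window_pvalue(
                null, dosages, w, categories, maf,
                annotations=annotations, use_spa=use_spa, cache=cache,
            )
        except ValueError:
            out[i] = np.nan  # no testable component; dropped below
    return out


def scan(
    panel: GenotypePanel,
    Y: np.ndarray,
    X: np.ndarray | None = None,
    config: ScanConfig | None = None,
    annotations: np.ndarray | None = None,
    knockoffs: KnockoffSet | None = None,
) -> ScanResult:
    """Scan all windows of a panel and select at the configured target FDR.

    All window size classes are pooled into a single genome-wide filter
    pass.  ``knockoffs`` may be supplied to reuse a cached set; otherwise
    M copies are generated from ``config.seed``.  Knockoff window
    p-values are computed by exactly the same routine as the originals.
    """
    config = config or ScanConfig()
    if len(Y) != panel.n:
        raise ValueError("phenotype length does not match panel samples")
    categories = categorize_variants(panel)
    windows = tile_windows(panel, config.sizes, categories)
    if not windows:
        raise ValueError("no candidate windows")
    clusters = cluster_tight_ld(panel)
    if knockoffs is None:
        knockoffs = generate_knockoffs(
            panel, M=config.M, seed=config.seed, clusters=clusters
        )
    null = assoc.fit_null_model(Y, X, family=config.family)

    logger.info("scanning %d windows (%d variants, n=%d, M=%d)",
                len(windows), panel.p, panel.n, knockoffs.M)
    p0 = _window_pvalues(
        null, panel.dosages, windows, categories, panel.maf,
        annotations, config.use_spa,
    )
    pk = np.column_stack([
        _window_pvalues(
            null, knockoffs[m], windows, categories, panel.maf,
            annotations, config.use_spa,
        )
        for m in range(knockoffs.M)
    ])
    ok = ~np.isnan(p0) & ~np.isnan(pk).any(axis=1)
    windows = [w for w, k in zip(windows, ok) if k]
    p0, pk = p0[ok], pk[ok]

    stats, tau_hat, selected = filter_windows(p0, pk, q=config.q)
    table = pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "size_class": [w.size_class for w in windows],
            "p_original": p0,
            **{f"p_knockoff_{m + 1}": pk[:, m] for m in range(knockoffs.M)},
            "W": [s.W for s in stats],
            "kappa": [s.kappa for s in stats],
            "tau": [s.tau for s in stats],
            "qvalue": [s.qvalue for s in stats],
            "selected": selected.astype(int),
        }
    )
    return ScanResult(table, tau_hat, config, windows)


def evaluate(
    result_table: pd.DataFrame,
    causal_windows: list[tuple],
    buffer_bp: int = 0,
) -> dict:
    """Window-level power and FDP of a selection against known truth.

    ``causal_windows`` holds (chrom, start, end) triples of true signal
    windows.  A selected window is a true positive if it overlaps any
    causal window extended by ``buffer_bp`` on each side; a causal window
    is detected if any selected window overlaps it.  FDP on an empty
    selection is defined as 0.
    """
    sel = result_table[result_table["selected"] == 1]
    tab = result_table
    causal_mask = np.zeros(len(tab), dtype=bool)
    hit = np.zeros(len(causal_windows), dtype=bool)
    for ci, (c, s, e) in enumerate(causal_windows):
        ov = (
            (tab["chrom"].to_numpy() == c)
            & (tab["start"].to_numpy() <= e + buffer_bp)
            & (tab["end"].to_numpy() >= s - buffer_bp)
        )
        causal_mask |= ov
        hit[ci] = bool((ov & (tab["selected"].to_numpy() == 1)).any())
    n_sel = len(sel)
    n_true_sel = int((causal_mask & (tab["selected"].to_numpy() == 1)).sum())
    # window-level power: detected causal windows / causal windows
    causal_sel = tab.loc[causal_mask, "selected"]
    power = float(causal_sel.mean()) if causal_mask.any() else 0.0
    fdp = float((n_sel - n_true_sel) / n_sel) if n_sel else 0.0
    return {
        "n_selected": n_sel,
        "power": power,
        "locus_power": float(hit.mean()) if len(causal_windows) else 0.0,
        "fdp": fdp,
    }


def write_outputs(result: ScanResult, out_prefix: str) -> None:
    """Write the per-window TSV, selection TSV and run summary JSON."""
    result.table.to_csv(f"{out_prefix}.windows.tsv", sep="\t", index=False)
    result.selected.to_csv(f"{out_prefix}.selected.tsv", sep="\t", index=False)
    with open(f"{out_prefix}.summary.json", "w") as fh:
        json.dump(result.summary(), fh, indent=2)
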