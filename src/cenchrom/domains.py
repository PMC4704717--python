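"""Window enrichment, island calling, centromere assembly and the
CENH3-depleted-subdomain test.

The centromere-finding side works SICER-style: small (1-kb) windows are
scored against a Poisson background, runs of significant windows separated
by at most a fixed gap are merged into islands, and islands surviving a
multiple-testing filter are reported.  Merging nearby islands and dropping
small remnants then yields one interval per centromere.

The subdomain side works at 10-kb resolution inside called centromeres:
each mappable window's ChIP count is tested against an input-scaled Poisson
expectation with a *lower-tail* test — significantly too few ChIP reads
means the window is occupied by canonical H3 rather than CENH3 nucleosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .fragments import FragmentSet
from .intervals import as_intervals, merge_intervals, sort_intervals


@dataclass
class IslandParams:
    """SICER-style island-calling parameters."""

    window: int = 1000
    gap: int = 3000
    effective_genome_fraction: float = 0.7
    fdr: float = 0.05
    fragment_size: int = 150  # interface parity; fragments here carry true spans
    eligible_p: float = 1e-3  # per-window Poisson p making a window island-eligible

    def __post_init__(self):
        if self.gap % self.window != 0:
            raise ValueError("gap must be an integer multiple of window")


@dataclass
class DepletedParams:
    """Depleted-subdomain test parameters (10-kb windows)."""

    window: int = 10_000
    p_threshold: float = 1e-5
    edge_exclusion: int = 200_000
    merge_gap: int = 100_000
    min_domain: int = 30_000

    def __post_init__(self):
        for name in ("window", "p_threshold", "edge_exclusion", "merge_gap", "min_domain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def count_midpoints(fs: FragmentSet, chrom_sizes: dict, window: int) -> dict:
    """Per-chromosome window counts; fragments are assigned by midpoint."""
    out = {}
    mids = fs.midpoints
    chroms = fs.df["chrom"].to_numpy()
    for chrom, size in chrom_sizes.items():
        nwin = -(-size // window)
        m = chroms == chrom
        w = np.clip(mids[m] // window, 0, nwin - 1)
        out[chrom] = np.bincount(w, minlength=nwin).astype(np.int64)
    return out


def window_enrichment(
    chip: FragmentSet,
    input_: FragmentSet,
    chrom_sizes: dict,
    window: int = 10_000,
    eps: float = 0.5,
) -> pd.DataFrame:
    """Library-size-normalized fold enrichment per fixed-width window.

    enrichment_w = (chip_w / N_chip) / ((input_w + eps) / N_input); the
    pseudocount ``eps`` guards zero-input windows (set eps=0 for the exact
    ratio where inputs are known nonzero).
    """
    if window <= 0:
        raise ValueError("window size must be positive")
    if len(chip) == 0 or len(input_) == 0:
        raise ValueError("both libraries must be non-empty")
    cc = count_midpoints(chip, chrom_sizes, window)
    ic = count_midpoints(input_, chrom_sizes, window)
    n_chip, n_input = len(chip), len(input_)
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, window)
        ends = np.minimum(starts + window, size)
        c = cc[chrom]
        i = ic[chrom]
        enr = (c / n_chip) / ((i + eps) / n_input) if eps > 0 else np.where(
            i > 0, (c / n_chip) / np.maximum(i, 1e-300) * n_input, np.nan
        )
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                                  "chip_count": c, "input_count": i, "enrichment": enr}))
    return pd.concat(rows, ignore_index=True)


def call_islands(
    chip: FragmentSet,
    input_: FragmentSet,
    chrom_sizes: dict,
    params: IslandParams | None = None,
) -> pd.DataFrame:
    """Call broad ChIP-enriched islands against an input-informed background.

    Per window, the expected count is the larger of the input-scaled count
    and the effective-genome-wide average ChIP rate; windows with an upper
    Poisson tail below ``eligible_p`` are eligible, eligible windows
    separated by at most ``gap`` bp merge into islands, and each island's
    Poisson p over its whole span is Bonferroni-scaled by the number of
    analyzed windows before a Benjamini-Hochberg filter at ``fdr``.
    """
    params = params or IslandParams()
    if len(chip) < 1000:
        warnings.warn("chip library has <1000 fragments; island calls may be unstable")
    w = params.window
    cc = count_midpoints(chip, chrom_sizes, w)
    ic = count_midpoints(input_, chrom_sizes, w)
    n_chip, n_input = len(chip), max(len(input_), 1)
    genome = sum(chrom_sizes.values())
    lam_bg = n_chip * w / (params.effective_genome_fraction * genome)
    scale = n_chip / n_input
    n_windows_total = sum(len(v) for v in cc.values())
    gap_windows = params.gap // w

    islands = []
    for chrom in chrom_sizes:
        c = cc[chrom]
        lam = np.maximum(ic[chrom] * scale, lam_bg)
        pvals = poisson.sf(c - 1, lam)  # P(X >= c)
        eligible = np.nonzero((pvals < params.eligible_p) & (c > 0))[0]
        if len(eligible) == 0:
            continue
        # group eligible windows separated by <= gap_windows ineligible windows
        breaks = np.nonzero(np.diff(eligible) > gap_windows + 1)[0]
        groups = np.split(eligible, breaks + 1)
        for g in groups:
            lo, hi = int(g[0]), int(g[-1])  # inclusive window span
            # island statistic over the eligible windows only (SICER-style):
            # ineligible gap windows would dilute genuinely enriched islands
            C = int(c[g].sum())
            lam_span = float(lam[g].sum())
            p_raw = float(poisson.sf(C - 1, lam_span))
            score = float(-np.log10(np.clip(pvals[g], 1e-300, None)).sum())
            islands.append((chrom, lo * w, min((hi + 1) * w, chrom_sizes[chrom]), score, p_raw))
    if not islands:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "p_raw", "p_adj"])
    df = as_intervals(islands, extra_cols={"score": float, "p_raw": float})
    # Bonferroni over windows (any window could seed an island), then BH over islands
    p_bonf = np.minimum(1.0, df["p_raw"].to_numpy() * n_windows_total)
    from statsmodels.stats.multitest import multipletests

    _, p_adj, _, _ = multipletests(p_bonf, method="fdr_bh")
    df["p_adj"] = p_adj
    df = df.loc[df["p_adj"] <= params.fdr].reset_index(drop=True)
    return sort_intervals(df)


def assemble_centromeres(islands: pd.DataFrame, params: DepletedParams | None = None) -> pd.DataFrame:
    """Merge islands separated by < merge_gap, then drop remnants < min_domain.

    Gap closing first bridges the coverage holes that highly repetitive
    (unmappable) stretches punch through a centromere; the size filter then
    removes isolated small islands that are unlikely to be centromeric.
    """
    params = params or DepletedParams()
    if len(islands) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "length"])
    merged = merge_intervals(islands, lt_gap=params.merge_gap)
    keep = (merged["end"] - merged["start"]) >= params.min_domain
    out = merged.loc[keep].reset_index(drop=True)
    out["length"] = out["end"] - out["start"]
    return out


def depletion_pvalues(chip_counts: np.ndarray, input_counts: np.ndarray, ratio: float) -> np.ndarray:
    """Lower-tail Poisson p-values for CENH3 depletion: P(X <= chip | input*ratio)."""
    lam = np.asarray(input_counts, dtype=float) * ratio
    return poisson.cdf(np.asarray(chip_counts), lam)


def call_depleted(
    chip: FragmentSet,
    input_: FragmentSet,
    centromeres: pd.DataFrame,
    window_table: pd.DataFrame,
    params: DepletedParams | None = None,
    scope: str = "centromere",
) -> pd.DataFrame:
    """Identify CENH3-depleted subdomains inside called centromeres.

    For every mappable ``window``-sized centromeric window the ChIP count is
    tested against lambda = input_count * r with a lower-tail Poisson test,
    where r is the ChIP/input library ratio over mappable centromeric windows
    (``scope='centromere'``, default) or over the whole genome
    (``scope='global'``).  Candidate windows (p < p_threshold) are merged when
    adjacent; subdomains closer than ``edge_exclusion`` to a centromere end
    are discarded, as terminal coverage decay there may mimic depletion.
    """
    params = params or DepletedParams()
    w = params.window
    wt = window_table.loc[window_table["end"] - window_table["start"] <= w]
    chrom_sizes = dict(window_table.groupby("chrom")["end"].max())
    cc = count_midpoints(chip, chrom_sizes, w)
    ic = count_midpoints(input_, chrom_sizes, w)

    # index mappable windows by (chrom, start)
    mappable = {(r.chrom, r.start) for r in window_table.itertuples(index=False) if r.mappable}

    out = []
    # centromere-local or global scaling ratio over mappable windows
    def _totals(rows):
        tc = ti = 0
        for chrom, start in rows:
            tc += cc[chrom][start // w]
            ti += ic[chrom][start // w]
        return tc, ti

    if scope == "global":
        g_tc, g_ti = len(chip), len(input_)

    for cen in centromeres.itertuples(index=False):
        # centromeric windows: those whose midpoint lies inside the centromere
        starts = np.arange(cen.start // w * w, cen.end, w)
        mids = starts + w // 2
        starts = starts[(mids >= cen.start) & (mids < cen.end)]
        cen_windows = [(cen.chrom, int(s)) for s in starts]
        cen_mappable = [x for x in cen_windows if x in mappable]
        if not cen_mappable:
            warnings.warn(f"centromere {cen.chrom}:{cen.start}-{cen.end} has no mappable windows; skipped")
            continue
        if scope == "global":
            tc, ti = g_tc, g_ti
        else:
            tc, ti = _totals(cen_mappable)
        if ti == 0:
            warnings.warn(f"centromere {cen.chrom}:{cen.start}-{cen.end} has no input coverage; skipped")
            continue
        ratio = tc / ti
        chip_w = np.array([cc[c][s // w] for c, s in cen_mappable])
        input_w = np.array([ic[c][s // w] for c, s in cen_mappable])
        pvals = depletion_pvalues(chip_w, input_w, ratio)
        cand = [cen_mappable[i] for i in np.nonzero(pvals < params.p_threshold)[0]]
        if not cand:
            continue
        cand_df = as_intervals([(c, s, min(s + w, cen.end)) for c, s in cand])
        sub = merge_intervals(cand_df, lt_gap=1)
        # clip to the centromere and apply the edge filter
        sub["start"] = sub["start"].clip(lower=cen.start)
        sub["end"] = sub["end"].clip(upper=cen.end)
        near_edge = (sub["start"] - cen.start < params.edge_exclusion) | (
            cen.end - sub["end"] < params.edge_exclusion
        )
        sub = sub.loc[~near_edge]
        for r in sub.itertuples(index=False):
            out.append((r.chrom, r.start, r.end))
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return sort_intervals(as_intervals(out))


def summarize_subdomains(
    depleted: pd.DataFrame,
    centromeres: pd.DataFrame,
    window_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-centromere depleted kb and share of mappable sequence, plus totals.

    Depleted and enriched classifications of mappable sequence are mutually
    exclusive and exhaustive: enriched_pct = 100 - depleted_pct.
    """
    w_map = window_table.loc[window_table["mappable"]]
    rows = []
    for cen in centromeres.itertuples(index=False):
        name = getattr(cen, "name", f"{cen.chrom}:{cen.start}-{cen.end}")
        inw = w_map.loc[
            (w_map["chrom"] == cen.chrom)
            & ((w_map["start"] + w_map["end"]) // 2 >= cen.start)
            & ((w_map["start"] + w_map["end"]) // 2 < cen.end)
        ]
        mappable_bp = int((inw["end"].clip(upper=cen.end) - inw["start"].clip(lower=cen.start)).sum())
        dep = depleted.loc[
            (depleted["chrom"] == cen.chrom)
            & (depleted["end"] > cen.start)
            & (depleted["start"] < cen.end)
        ]
        dep_bp = int((dep["end"].clip(upper=cen.end) - dep["start"].clip(lower=cen.start)).sum())
        pct = 100.0 * dep_bp / mappable_bp if mappable_bp else 0.0
        rows.append((name, cen.chrom, int(cen.start), int(cen.end),
                     (cen.end - cen.start) / 1e3, mappable_bp / 1e3, dep_bp / 1e3, pct, 100.0 - pct))
    df = pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "length_kb",
                                     "mappable_kb", "depleted_kb", "depleted_pct", "enriched_pct"])
    tot_map = df["mappable_kb"].sum()
    tot_dep = df["depleted_kb"].sum()
    tot_pct = 100.0 * tot_dep / tot_map if tot_map else 0.0
    total = pd.DataFrame(
        [("total", "*", 0, 0, df["length_kb"].sum(), tot_map, tot_dep, tot_pct, 100.0 - tot_pct)],
        columns=df.columns,
    )
    return pd.concat([df, total], ignore_index=True)
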