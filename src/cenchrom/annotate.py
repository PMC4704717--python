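"""Gene, histone-mark and centromere-expansion integration.

Centromeric genes are classified by which chromatin subdomain most of the
gene body sits in (CENH3-depleted vs CENH3-enriched) and by transcriptional
activity from an expression table; histone-mark islands are intersected with
depleted subdomains; expansion vs matched non-expansion flank read densities
are compared by bootstrap resampling.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .intervals import as_intervals, intersect_length


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records from a GFF3 file, converted to 0-based half-open."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("ID") or attrs.get("Name") or f"{f[0]}:{f[3]}"
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def classify_genes(
    genes: pd.DataFrame,
    depleted: pd.DataFrame,
    centromeres: pd.DataFrame,
    expression: pd.DataFrame,
    active_fpkm: float = 1.0,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Classify centromeric genes by subdomain membership and activity.

    A gene is 'depleted' if >= ``min_overlap`` of its body overlaps a
    depleted subdomain, 'enriched' if >= that fraction overlaps the
    (non-depleted) centromere, else 'boundary'.  A gene is active iff its
    FPKM in any tissue reaches ``active_fpkm``; genes absent from the
    expression table count as inactive with a warning.  Only genes
    overlapping a centromere are reported.
    """
    cen_genes = genes.loc[intersect_length(genes, centromeres) > 0].reset_index(drop=True)
    gl = (cen_genes["end"] - cen_genes["start"]).to_numpy()
    dep_ov = intersect_length(cen_genes, depleted)
    cen_ov = intersect_length(cen_genes, centromeres)
    enr_ov = cen_ov - dep_ov
    cls = np.where(
        dep_ov >= min_overlap * gl, "depleted", np.where(enr_ov >= min_overlap * gl, "enriched", "boundary")
    )
    expr_cols = [c for c in expression.columns if c != "gene"]
    expr_max = expression.set_index("gene")[expr_cols].max(axis=1)
    missing = [n for n in cen_genes["name"] if n not in expr_max.index]
    if missing:
        warnings.warn(f"{len(missing)} genes absent from the expression table; treated as inactive")
    fpkm = cen_genes["name"].map(expr_max).fillna(0.0)
    out = cen_genes.copy()
    out["subdomain"] = cls
    out["max_fpkm"] = fpkm.to_numpy()
    out["active"] = out["max_fpkm"] >= active_fpkm
    return out


def gene_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts per subdomain class x activity; classes partition all genes."""
    tab = (
        classified.groupby(["subdomain", "active"]).size().unstack(fill_value=0).reindex(
            ["depleted", "enriched", "boundary"], fill_value=0
        )
    )
    tab.columns = ["inactive" if not c else "active" for c in tab.columns]
    for c in ("active", "inactive"):
        if c not in tab.columns:
            tab[c] = 0
    tab["total"] = tab["active"] + tab["inactive"]
    return tab.reset_index()


def mark_overlap(
    mark_islands: dict,
    depleted: pd.DataFrame,
    centromeres: pd.DataFrame,
) -> pd.DataFrame:
    """Per-mark island lengths in centromeres and their depleted share.

    ``mark_islands`` maps mark name -> island interval table (as returned by
    the island caller on that mark's ChIP vs input).
    """
    rows = []
    for mark, islands in mark_islands.items():
        if len(islands) == 0:
            rows.append((mark, 0.0, 0.0, float("nan")))
            continue
        in_cen = intersect_length(islands, centromeres)
        keep = islands.loc[in_cen > 0].reset_index(drop=True)
        cen_kb = intersect_length(keep, centromeres).sum() / 1e3
        # clip islands to centromeres before intersecting with depleted
        dep_kb = 0.0
        for isl in keep.itertuples(index=False):
            probe = as_intervals([(isl.chrom, isl.start, isl.end)])
            dep_kb += min(intersect_length(probe, depleted)[0], intersect_length(probe, centromeres)[0]) / 1e3
        pct = 100.0 * dep_kb / cen_kb if cen_kb else float("nan")
        rows.append((mark, float(cen_kb), float(dep_kb), pct))
    return pd.DataFrame(rows, columns=["mark", "centromeric_kb", "depleted_kb", "depleted_pct"])


def window_density(
    fs: FragmentSet,
    region: tuple,
    window: int = 1000,
    mappability: np.ndarray | None = None,
) -> np.ndarray:
    """Fragment midpoints per window over [start, end), optionally divided by
    per-window mappability fractions ("read density normalized by
    mappability"); windows with zero mappability yield NaN."""
    chrom, start, end = region
    sub = fs.subset(chrom, start, end)
    nwin = (end - start) // window
    w = np.clip((sub.midpoints - start) // window, 0, nwin - 1)
    counts = np.bincount(w, minlength=nwin).astype(float)
    if mappability is not None:
        mappability = np.asarray(mappability, dtype=float)
        counts = np.where(mappability > 0, counts / np.maximum(mappability, 1e-12), np.nan)
    return counts


def expansion_bootstrap(
    density_expanded: np.ndarray,
    density_nonexpanded: np.ndarray,
    B: int = 10_000,
    seed=None,
) -> tuple:
    """Bootstrap comparison of per-window read densities.

    Observed effect = mean(expanded) - mean(nonexpanded).  Each vector is
    resampled with replacement B times; the two-tailed p-value is
    2 * min(P(boot diff <= 0), P(boot diff >= 0)) floored at 1/B and capped
    at 1.  Returns (p_value, effect).
    """
    x = np.asarray(density_expanded, dtype=float)
    y = np.asarray(density_nonexpanded, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 30 or len(y) < 30:
        raise ValueError("need at least 30 windows per side for a stable bootstrap")
    rng = np.random.default_rng(seed)
    effect = float(x.mean() - y.mean())
    bx = x[rng.integers(0, len(x), size=(B, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), size=(B, len(y)))].mean(axis=1)
    diffs = bx - by
    frac_le = float((diffs <= 0).mean())
    frac_ge = float((diffs >= 0).mean())
    p = max(1.0 / B, 2.0 * min(frac_le, frac_ge))
    return min(1.0, p), effect
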