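"""Synthetic centromeric-chromatin generator with planted ground truth.

The generator builds a genome in which every quantity the downstream
analyses estimate is *planted* and recorded in a truth table: tandem
satellite arrays carrying one phased CENH3 nucleosome per monomer,
non-satellite centromeric chromatin with ~190-bp nucleosome spacing,
CENH3-depleted subdomains at a stated ChIP depletion fold, repeat-induced
unmappable windows (created by exact sequence duplication, matching the
exact-uniqueness mappability model), genes of known activity with
histone-mark peaks, and centromere-expansion flank regions.  Sequencing
libraries (ChIP / input / naked MNase / histone marks) are emitted as
fragment coordinates directly; read simulation and alignment are out of
scope, so the real-data entry point of the pipeline is pre-aligned BED/BAM.

The maize-like preset plants the published geometry: seven centromeres of
1.82/1.00/0.93/1.88/1.88/1.26/1.65 Mb, depleted subdomains of
110/128/79/125/184/69/151 kb (846 kb total), a 53% unique fraction of
centromeric sequence, 21 depleted-subdomain genes of which 11 are active,
and 13 inactive genes in enriched regions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentSet
from .intervals import as_intervals, intersect_length, total_length
from .satellite import SYNTHETIC_CENTC_MONOMER

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_DUP_BLOCK = 10_000  # duplication blocks are whole 10-kb analysis windows

DEFAULT_FRAGMENT_MODEL = ((147, 0.7, 4.0), (133, 0.2, 4.0), (123, 0.1, 4.0))


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults follow the study conditions."""

    n_chromosomes: int
    chrom_length: int | list
    centromere_intervals: list  # [(chrom, start, end), ...]
    chrom_names: list | None = None
    satellite_monomer: str = SYNTHETIC_CENTC_MONOMER
    satellite_arrays: list = field(default_factory=list)  # [(chrom, start, n_copies)]
    unique_fraction_centromere: float = 0.53
    depleted_subdomains: list = field(default_factory=list)  # [(chrom, start, end)]
    chip_enrichment_fold: float = 30.0
    depletion_fold: float = 0.1
    nucleosome_spacing_mean: float = 190.0
    spacing_jitter_sd: float = 20.0
    phasing_jitter_sd: float = 5.0
    phasing_offset: int = 78  # nucleosome midpoint within a monomer (center of 156)
    fragment_length_model: tuple = DEFAULT_FRAGMENT_MODEL
    at_cut_bias: float = 12.0
    midpoint_jitter_sd: float = 3.0
    background_fraction: float = 0.02
    underdigested_shift: int = 11
    mark_fold: float = 20.0
    n_fragments_chip: int = 200_000
    n_fragments_input: int = 200_000
    n_fragments_naked: int = 200_000
    genes: list = field(default_factory=list)  # [(chrom, start, end, name, active)]
    mark_peaks: list = field(default_factory=list)  # [(chrom, start, end, mark)]
    expansion_regions: list = field(default_factory=list)  # [(name, chrom, es, ee, ns, ne)]
    seed: int = 0

    # -- derived geometry ------------------------------------------------
    @property
    def names(self) -> list:
        if self.chrom_names is not None:
            return list(self.chrom_names)
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def lengths(self) -> dict:
        ls = self.chrom_length
        if isinstance(ls, (int, np.integer)):
            ls = [int(ls)] * self.n_chromosomes
        return dict(zip(self.names, (int(x) for x in ls)))

    def array_intervals(self) -> list:
        L = len(self.satellite_monomer)
        return [(c, s, s + n * L) for c, s, n in self.satellite_arrays]

    def validate(self) -> None:
        lengths = self.lengths
        if len(lengths) != self.n_chromosomes:
            raise ValueError("chrom_length list does not match n_chromosomes")

        def _check_within(tag, triples):
            for c, s, e in triples:
                if c not in lengths:
                    raise ValueError(f"{tag} interval on unknown chromosome {c!r}")
                if not (0 <= s < e <= lengths[c]):
                    raise ValueError(f"{tag} interval {c}:{s}-{e} outside chromosome bounds")

        cens = [(c, s, e) for c, s, e in self.centromere_intervals]
        _check_within("centromere", cens)
        arrays = self.array_intervals()
        _check_within("satellite array", arrays)
        _check_within("depleted subdomain", self.depleted_subdomains)
        _check_within("gene", [(c, s, e) for c, s, e, *_ in self.genes])
        cen_df = as_intervals(cens)
        for tag, triples in (("satellite array", arrays), ("depleted subdomain", self.depleted_subdomains)):
            for c, s, e in triples:
                probe = as_intervals([(c, s, e)])
                if intersect_length(probe, cen_df)[0] != e - s:
                    raise ValueError(f"{tag} {c}:{s}-{e} is not fully inside a centromere")
        planted = as_intervals(arrays + [tuple(x) for x in self.depleted_subdomains])
        planted = planted.sort_values(["chrom", "start"])
        prev = None
        for row in planted.itertuples(index=False):
            if prev is not None and row.chrom == prev[0] and row.start < prev[1]:
                raise ValueError(
                    f"planted intervals overlap on {row.chrom}: "
                    f"[...{prev[1]}) and [{row.start}...) — arrays and depleted "
                    "subdomains must be disjoint"
                )
            prev = (row.chrom, row.end)
        if not 0 <= self.unique_fraction_centromere <= 1:
            raise ValueError("unique_fraction_centromere must be in [0, 1]")
        if self.chip_enrichment_fold < 1:
            raise ValueError("chip_enrichment_fold must be >= 1")
        if not 0 <= self.depletion_fold <= 1:
            raise ValueError("depletion_fold must be in [0, 1]")


@dataclass
class GenomeModel:
    """A generated genome: sequences, planted features, nucleosomes, truth."""

    sequences: dict  # chrom -> np.uint8 ASCII array (includes the duplication dump)
    chrom_sizes: dict
    features: dict  # name -> DataFrame
    config: GeneratorConfig
    nucleosomes: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    truth: dict = field(default_factory=dict)

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode()

    def monomer_annotation(self) -> pd.DataFrame:
        """One row per satellite monomer copy (all plus strand, tandem)."""
        L = len(self.config.satellite_monomer)
        rows = []
        for arr in self.features["arrays"].itertuples(index=False):
            for i in range(arr.n_copies):
                rows.append((arr.chrom, arr.start + i * L, arr.start + (i + 1) * L, "+"))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def _window_cover_unmappable(features: dict, cen: pd.DataFrame, window: int = _DUP_BLOCK) -> tuple:
    """(mappable windows, total windows) over centromeres, a window counting as
    unmappable when >=50% covered by arrays or duplicated blocks."""
    rep = pd.concat(
        [features["arrays"].loc[:, ["chrom", "start", "end"]],
         features["duplications"].loc[:, ["chrom", "start", "end"]]],
        ignore_index=True,
    )
    n_total = n_map = 0
    for c in cen.itertuples(index=False):
        starts = np.arange(c.start // window * window, c.end, window)
        mids = starts + window // 2
        starts = starts[(mids >= c.start) & (mids < c.end)]
        wins = as_intervals([(c.chrom, int(s), int(s) + window) for s in starts])
        cov = intersect_length(wins, rep)
        n_total += len(wins)
        n_map += int((cov < window // 2).sum())
    return n_map, n_total


def generate_genome(config: GeneratorConfig) -> GenomeModel:
    """Generate sequences and planted features (without nucleosomes).

    Outside-centromere sequence is i.i.d. random; satellite arrays are exact
    tandem copies of the monomer; a fraction of centromeric non-array
    sequence is duplicated into a dump segment appended to the chromosome so
    that whole 10-kb windows become unmappable under exact k-mer uniqueness,
    bringing the unique fraction of each centromere down to the configured
    value (tandem arrays count toward the non-unique share).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = config.lengths
    seqs = {}
    for name, L in lengths.items():
        seqs[name] = _ASCII[rng.integers(0, 4, size=L)]
    monomer = np.frombuffer(config.satellite_monomer.upper().encode(), dtype=np.uint8)
    Lm = len(monomer)
    arrays_rows = []
    for chrom, start, n_copies in config.satellite_arrays:
        tile = np.tile(monomer, n_copies)
        seqs[chrom][start : start + len(tile)] = tile
        arrays_rows.append((chrom, start, start + n_copies * Lm, n_copies))
    arrays = pd.DataFrame(arrays_rows, columns=["chrom", "start", "end", "n_copies"])

    cen = as_intervals(
        [(c, s, e) for c, s, e in config.centromere_intervals],
        extra_cols={"name": str},
    ) if config.centromere_intervals and len(config.centromere_intervals[0]) > 3 else as_intervals(
        [(c, s, e) for c, s, e, *_ in config.centromere_intervals]
    )
    if "name" not in cen.columns:
        cen["name"] = [f"cen_{c.chrom}" for c in cen.itertuples(index=False)]

    depleted = as_intervals(config.depleted_subdomains) if config.depleted_subdomains else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    genes = pd.DataFrame(config.genes, columns=["chrom", "start", "end", "name", "active"]) if config.genes else pd.DataFrame(
        columns=["chrom", "start", "end", "name", "active"]
    )
    marks = pd.DataFrame(config.mark_peaks, columns=["chrom", "start", "end", "mark"]) if config.mark_peaks else pd.DataFrame(
        columns=["chrom", "start", "end", "mark"]
    )
    expansion = pd.DataFrame(
        [(n, c, es, ee, "expanded") for n, c, es, ee, _, _ in config.expansion_regions]
        + [(n, c, ns, ne, "nonexpanded") for n, c, _, _, ns, ne in config.expansion_regions],
        columns=["name", "chrom", "start", "end", "kind"],
    )

    # --- duplication blocks to reach the target unique fraction ---------
    avoid = pd.concat(
        [arrays.loc[:, ["chrom", "start", "end"]], depleted,
         genes.loc[:, ["chrom", "start", "end"]], marks.loc[:, ["chrom", "start", "end"]]],
        ignore_index=True,
    )
    dup_rows = []
    for c in cen.itertuples(index=False):
        cen_len = c.end - c.start
        target_unmap = round((1.0 - config.unique_fraction_centromere) * cen_len)
        arr_bp = int(
            intersect_length(as_intervals([(c.chrom, c.start, c.end)]), arrays)[0]
        )
        n_blocks = max(0, round((target_unmap - arr_bp) / _DUP_BLOCK))
        if n_blocks == 0:
            continue
        starts = np.arange(-(-c.start // _DUP_BLOCK) * _DUP_BLOCK, c.end - _DUP_BLOCK + 1, _DUP_BLOCK)
        wins = as_intervals([(c.chrom, int(s), int(s) + _DUP_BLOCK) for s in starts])
        free = wins.loc[intersect_length(wins, avoid) == 0]
        if len(free) < n_blocks:
            raise ValueError(
                f"centromere {c.chrom}:{c.start}-{c.end} has only {len(free)} free 10-kb "
                f"windows but needs {n_blocks} duplication blocks for "
                f"unique_fraction={config.unique_fraction_centromere}"
            )
        pick = rng.choice(len(free), size=n_blocks, replace=False)
        for i in np.sort(pick):
            row = free.iloc[int(i)]
            dup_rows.append((row["chrom"], int(row["start"]), int(row["end"])))
    # copy picked blocks into a dump segment appended to their chromosome
    dump_parts: dict = {n: [] for n in lengths}
    dup_feature = []
    for chrom, s, e in dup_rows:
        dump_parts[chrom].append(seqs[chrom][s:e].copy())
        dup_feature.append((chrom, s, e, "origin"))
    chrom_sizes = {}
    for name in lengths:
        if dump_parts[name]:
            dump_start = lengths[name]
            dump = np.concatenate(dump_parts[name])
            pos = dump_start
            for part in dump_parts[name]:
                dup_feature.append((name, pos, pos + len(part), "copy"))
                pos += len(part)
            seqs[name] = np.concatenate([seqs[name], dump])
        chrom_sizes[name] = len(seqs[name])
    duplications = pd.DataFrame(dup_feature, columns=["chrom", "start", "end", "role"])

    features = {
        "centromeres": cen,
        "arrays": arrays,
        "depleted": depleted,
        "duplications": duplications,
        "genes": genes,
        "mark_peaks": marks,
        "expansion": expansion,
    }

    # --- expression table ------------------------------------------------
    if len(genes):
        fpkm_root = np.where(genes["active"], np.round(rng.uniform(1.1, 25.0, len(genes)), 1), 0.0)
        fpkm_shoot = np.where(genes["active"], np.round(rng.uniform(1.1, 25.0, len(genes)), 1), 0.0)
        expression = pd.DataFrame({"gene": genes["name"], "root": fpkm_root, "shoot": fpkm_shoot})
    else:
        expression = pd.DataFrame(columns=["gene", "root", "shoot"])

    n_map, n_total = _window_cover_unmappable(features, cen)
    truth = {
        "depleted_total_kb": total_length(depleted) / 1e3,
        "mappable_pct_centromere": 100.0 * n_map / n_total if n_total else float("nan"),
        "depleted_pct_mappable": (100.0 * total_length(depleted) / (n_map * _DUP_BLOCK)) if n_map else 0.0,
        "spacing_mean": config.nucleosome_spacing_mean,
        "satellite_period": Lm,
        "centromere_lengths_mb": [round((c.end - c.start) / 1e6, 2) for c in cen.itertuples(index=False)],
    }
    return GenomeModel(
        sequences=seqs,
        chrom_sizes=chrom_sizes,
        features=features,
        config=config,
        expression=expression,
        truth=truth,
    )


def plant_nucleosomes(model: GenomeModel) -> GenomeModel:
    """Fill the nucleosome map.

    Inside satellite arrays: one nucleosome per monomer, midpoint at
    monomer_start + phasing_offset + N(0, phasing_jitter_sd) — the phased
    configuration.  Everywhere else: sequential midpoints with gaps drawn
    from N(spacing_mean, spacing_jitter_sd) truncated at 147 bp (nucleosomes
    cannot overlap more DNA than a core particle protects).
    """
    cfg = model.config
    rng = np.random.default_rng([cfg.seed, 7])
    Lm = len(cfg.satellite_monomer)
    rows_chrom, rows_mid = [], []
    arr_by_chrom = {c: g for c, g in model.features["arrays"].groupby("chrom")}
    for chrom, size in model.chrom_sizes.items():
        arrs = arr_by_chrom.get(chrom)
        cuts = []
        if arrs is not None:
            for a in arrs.itertuples(index=False):
                offs = np.arange(a.n_copies) * Lm + a.start + cfg.phasing_offset
                jit = np.rint(rng.normal(0, cfg.phasing_jitter_sd, a.n_copies)).astype(np.int64)
                mids = np.clip(offs + jit, a.start, a.end - 1)
                rows_chrom.append(np.full(len(mids), chrom, dtype=object))
                rows_mid.append(mids)
                cuts.append((a.start, a.end))
        # non-array segments
        cuts.sort()
        segs = []
        cursor = 0
        for s, e in cuts:
            if s > cursor:
                segs.append((cursor, s))
            cursor = e
        if cursor < size:
            segs.append((cursor, size))
        for s, e in segs:
            seg_len = e - s
            if seg_len < 147:
                continue
            n_est = int(seg_len / cfg.nucleosome_spacing_mean * 1.3) + 10
            gaps = rng.normal(cfg.nucleosome_spacing_mean, cfg.spacing_jitter_sd, n_est)
            gaps = np.maximum(gaps, 147.0)
            first = s + rng.uniform(0, cfg.nucleosome_spacing_mean)
            mids = np.rint(first + np.concatenate([[0.0], np.cumsum(gaps)])).astype(np.int64)
            mids = mids[mids < e]
            if len(mids):
                rows_chrom.append(np.full(len(mids), chrom, dtype=object))
                rows_mid.append(mids)
    nuc = pd.DataFrame({
        "chrom": np.concatenate(rows_chrom) if rows_chrom else np.array([], dtype=object),
        "mid": np.concatenate(rows_mid) if rows_mid else np.array([], dtype=np.int64),
    })
    nuc["in_array"] = _flag_in(nuc, model.features["arrays"])
    nuc["in_centromere"] = _flag_in(nuc, model.features["centromeres"])
    nuc["in_depleted"] = _flag_in(nuc, model.features["depleted"])
    nuc["is_cenh3"] = nuc["in_centromere"] & ~nuc["in_depleted"]
    model.nucleosomes = nuc
    return model


def _flag_in(nuc: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    out = np.zeros(len(nuc), dtype=bool)
    if len(intervals) == 0 or len(nuc) == 0:
        return out
    for chrom, grp in intervals.groupby("chrom"):
        m = (nuc["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        mids = nuc.loc[m, "mid"].to_numpy()
        grp = grp.sort_values("start")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, mids, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(mids), dtype=bool)
        hit[ok] = mids[ok] < ends[idx[ok]]
        out[m] = hit
    return out


def _draw_lengths(rng, model_modes, n: int) -> np.ndarray:
    modes = np.array([m[0] for m in model_modes], dtype=float)
    weights = np.array([m[1] for m in model_modes], dtype=float)
    sds = np.array([m[2] for m in model_modes], dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(modes), size=n, p=weights)
    return np.maximum(50, np.rint(rng.normal(modes[comp], sds[comp]))).astype(np.int64)


def simulate_library(
    model: GenomeModel,
    kind: str,
    n: int,
    seed=None,
    underdigested: bool = False,
) -> FragmentSet:
    """Draw a fragment library from the planted chromatin.

    kind 'chip': fragments drawn around nucleosome midpoints weighted by
    chip_enrichment_fold for centromeric CENH3 nucleosomes (down-weighted by
    depletion_fold inside depleted subdomains) plus a uniform positional
    background.  kind 'input': all nucleosomes weighted equally.  kind
    'naked': a cut-site process with per-position cut odds at_cut_bias : 1
    for A/T vs G/C (both fragment boundaries biased).  kind 'mark:<name>':
    nucleosomes inside that mark's planted peaks weighted by mark_fold.
    The 'underdigested' flag adds a linker-length shift to all fragments,
    emulating the partially digested (0.2 U) libraries.
    """
    cfg = model.config
    if n <= 0:
        return FragmentSet(pd.DataFrame(columns=["chrom", "start", "end"]), library=kind)
    if seed is None:
        import zlib

        kind_code = {"chip": 1, "input": 2, "naked": 3}.get(kind.split(":")[0], 4)
        seed = [cfg.seed, 11, kind_code, int(underdigested), zlib.crc32(kind.encode())]
    rng = np.random.default_rng(seed)
    lengths = _draw_lengths(rng, cfg.fragment_length_model, n)
    if underdigested:
        lengths = lengths + cfg.underdigested_shift
    if kind == "naked":
        chroms, starts, ends = _draw_naked_cuts(model, rng, lengths)
    else:
        if model.nucleosomes is None:
            raise ValueError("plant_nucleosomes must run before simulating chromatin libraries")
        nuc = model.nucleosomes
        w = np.ones(len(nuc))
        if kind == "chip":
            w[nuc["in_centromere"].to_numpy()] = cfg.chip_enrichment_fold
            w[(nuc["in_centromere"] & nuc["in_depleted"]).to_numpy()] = (
                cfg.chip_enrichment_fold * cfg.depletion_fold
            )
        elif kind.startswith("mark:"):
            mark = kind.split(":", 1)[1]
            peaks = model.features["mark_peaks"]
            peaks = peaks.loc[peaks["mark"] == mark]
            w[_flag_in(nuc, peaks)] = cfg.mark_fold
        elif kind != "input":
            raise ValueError(f"unknown library kind {kind!r}")
        n_bg = rng.binomial(n, cfg.background_fraction) if kind == "chip" else 0
        n_sig = n - n_bg
        idx = rng.choice(len(nuc), size=n_sig, p=w / w.sum())
        mids = nuc["mid"].to_numpy()[idx]
        chroms_sig = nuc["chrom"].to_numpy()[idx]
        if cfg.midpoint_jitter_sd > 0:
            mids = mids + np.rint(rng.normal(0, cfg.midpoint_jitter_sd, n_sig)).astype(np.int64)
        if n_bg:
            names = list(model.chrom_sizes)
            sizes = np.array([model.chrom_sizes[c] for c in names], dtype=float)
            ci = rng.choice(len(names), size=n_bg, p=sizes / sizes.sum())
            bg_mids = (rng.random(n_bg) * sizes[ci]).astype(np.int64)
            chroms = np.concatenate([chroms_sig, np.array(names, dtype=object)[ci]])
            mids = np.concatenate([mids, bg_mids])
        else:
            chroms = chroms_sig
        starts = mids - lengths // 2
        ends = starts + lengths
    # clip fragments into their chromosome
    size_arr = np.array([model.chrom_sizes[c] for c in chroms])
    shift = np.clip(-starts, 0, None) - np.clip(ends - size_arr, 0, None)
    starts = starts + shift
    ends = ends + shift
    return FragmentSet.from_arrays(chroms, starts, ends, library=kind)


def _draw_naked_cuts(model: GenomeModel, rng, lengths: np.ndarray):
    """5' cut positions with A/T bias; 3' ends biased within a small window."""
    cfg = model.config
    n = len(lengths)
    names = list(model.chrom_sizes)
    weights_by_chrom = {}
    sums = []
    for c in names:
        seq = model.sequences[c]
        is_at = (seq == 65) | (seq == 84)
        if np.isinf(cfg.at_cut_bias):
            w = is_at.astype(float)
        else:
            w = np.where(is_at, cfg.at_cut_bias, 1.0)
        weights_by_chrom[c] = w
        sums.append(w.sum())
    sums = np.array(sums)
    n_per = rng.multinomial(n, sums / sums.sum())
    chroms_out, starts_out, ends_out = [], [], []
    taken = 0
    for c, nc in zip(names, n_per):
        if nc == 0:
            continue
        w = weights_by_chrom[c]
        p1 = rng.choice(len(w), size=nc, p=w / w.sum())
        Lf = lengths[taken : taken + nc]
        taken += nc
        # bias the 3' boundary too: candidates p1+L+d, d in [-5, 5]
        d = np.arange(-5, 6)
        kernel = np.exp(-0.5 * (d / 2.0) ** 2)
        cand = p1[:, None] + Lf[:, None] + d[None, :]
        cand = np.clip(cand, 0, len(w) - 1)
        cw = w[cand] * kernel[None, :]
        row_sums = cw.sum(axis=1, keepdims=True)
        flat = row_sums[:, 0] == 0
        if flat.any():
            cw[flat] = kernel[None, :]
            row_sums = cw.sum(axis=1, keepdims=True)
        cdf = np.cumsum(cw / row_sums, axis=1)
        pick = (cdf < rng.random((nc, 1))).sum(axis=1)
        p2 = cand[np.arange(nc), np.clip(pick, 0, len(d) - 1)]
        lo = np.minimum(p1, p2)
        hi = np.maximum(p1, p2)
        ok = hi > lo  # degenerate zero-length fragments (clipped ends) are dropped
        chroms_out.append(np.full(int(ok.sum()), c, dtype=object))
        starts_out.append(lo[ok])
        ends_out.append(hi[ok])
    chroms = np.concatenate(chroms_out)
    starts = np.concatenate(starts_out)
    ends = np.concatenate(ends_out)
    return chroms, starts, ends


def write_truth(model: GenomeModel, outdir) -> dict:
    """Write FASTA + truth annotation files; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in model.sequences.items():
            fh.write(f">{name}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")
    paths["fasta"] = fasta

    feat = model.features
    for key, cols in (
        ("centromeres", ["chrom", "start", "end", "name"]),
        ("arrays", ["chrom", "start", "end", "n_copies"]),
        ("depleted", ["chrom", "start", "end"]),
        ("duplications", ["chrom", "start", "end", "role"]),
        ("mark_peaks", ["chrom", "start", "end", "mark"]),
    ):
        p = outdir / f"{key}.bed"
        feat[key].loc[:, [c for c in cols if c in feat[key].columns]].to_csv(
            p, sep="\t", header=False, index=False
        )
        paths[key] = p
    exp = outdir / "expansion.bed"
    feat["expansion"].loc[:, ["chrom", "start", "end", "name", "kind"]].to_csv(
        exp, sep="\t", header=False, index=False
    )
    paths["expansion"] = exp
    mono = outdir / "monomers.bed"
    ann = model.monomer_annotation()
    ann["name"] = "monomer"
    ann["score"] = 0
    ann.loc[:, ["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        mono, sep="\t", header=False, index=False
    )
    paths["monomers"] = mono

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in feat["genes"].itertuples(index=False):
            fh.write(
                f"{g.chrom}\tcenchrom\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.name}\n"
            )
    paths["genes"] = gff

    expr = outdir / "expression.tsv"
    model.expression.to_csv(expr, sep="\t", index=False)
    paths["expression"] = expr

    truth = outdir / "truth.json"
    with open(truth, "w") as fh:
        json.dump(model.truth, fh, indent=2)
    paths["truth"] = truth

    cfgp = outdir / "config.json"
    with open(cfgp, "w") as fh:
        d = asdict(model.config)
        json.dump(d, fh, indent=2, default=str)
    paths["config"] = cfgp
    return paths


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: centromere lengths (Mb) of the seven well-assembled maize centromeres
MAIZE_CEN_LENGTHS_MB = [1.82, 1.00, 0.93, 1.88, 1.88, 1.26, 1.65]
#: planted depleted-subdomain totals (kb) per centromere, 846 kb overall,
#: planted as two alternating subdomains per centromere (each < 100 kb, the
#: island merge gap, so depleted stretches do not split the assembled
#: centromere — mirroring the alternating enriched/depleted organization)
MAIZE_DEPLETED_KB = [110, 128, 79, 125, 184, 69, 151]
MAIZE_DEPLETED_SPLIT_KB = [(60, 50), (60, 68), (40, 39), (60, 65), (90, 94), (40, 29), (80, 71)]
MAIZE_CHROMS = ["chr2", "chr3", "chr4", "chr5", "chr8", "chr9", "chr10"]
_FLANK = 500_000
_CEN_START = 500_000
_DEP_OFFSET = 300_000  # first depleted subdomain starts this far inside the centromere
_DEP_SPACER = 150_000  # enriched stretch between the two depleted subdomains
_ARRAY_OFFSET = 100_000
_ARRAY_COPIES = 256


def maize_preset(
    n_fragments_chip: int = 2_000_000,
    n_fragments_input: int = 2_000_000,
    n_fragments_naked: int = 500_000,
    seed: int = 0,
) -> GeneratorConfig:
    """The maize-like preset: seven centromeres with the published geometry.

    Depleted subdomains are planted >=200 kb from centromere boundaries so the
    edge filter cannot erase planted truth, and start on 10-kb window
    boundaries (subdomain resolution matches the analysis window).
    """
    names = MAIZE_CHROMS
    cen_lengths = [int(mb * 1e6) for mb in MAIZE_CEN_LENGTHS_MB]
    chrom_lengths = [c + 2 * _FLANK for c in cen_lengths]
    cens = [(n, _CEN_START, _CEN_START + c) for n, c in zip(names, cen_lengths)]
    depleted = []
    dep_chunks = {}  # chrom -> [(start, end), (start, end)]
    for n, (kb1, kb2) in zip(names, MAIZE_DEPLETED_SPLIT_KB):
        s1 = _CEN_START + _DEP_OFFSET
        e1 = s1 + kb1 * 1000
        s2 = e1 + _DEP_SPACER
        e2 = s2 + kb2 * 1000
        depleted += [(n, s1, e1), (n, s2, e2)]
        dep_chunks[n] = [(s1, e1), (s2, e2)]
    arrays = [(n, _CEN_START + _ARRAY_OFFSET, _ARRAY_COPIES) for n in names]

    genes, marks = [], []
    n_active_dep = [2, 2, 2, 2, 1, 1, 1]  # 11 of the 21 depleted-subdomain genes are active
    n_enriched = [2, 2, 2, 2, 2, 2, 1]  # 13 inactive genes in enriched regions
    gid = 0
    for i, (name, cen_len) in enumerate(zip(names, cen_lengths)):
        (s1, _), (s2, _) = dep_chunks[name]
        gene_starts = [s1 + 5_000, s1 + 25_000, s2 + 5_000]  # two in chunk 1, one in chunk 2
        for j, s in enumerate(gene_starts):
            active = j < n_active_dep[i]
            gid += 1
            genes.append((name, s, s + 3_000, f"cengene{gid:03d}", active))
            if active:
                marks += _gene_marks(name, s, s + 3_000)
        cen_end = _CEN_START + cen_len
        enr_pos = [_CEN_START + 160_000, cen_end - 153_000][: n_enriched[i]]
        for s in enr_pos:
            gid += 1
            genes.append((name, s, s + 3_000, f"cengene{gid:03d}", False))
    # one repressive-mark peak on an inactive depleted-subdomain gene
    chr5_dep_gene = next(g for g in genes if g[0] == "chr5" and not g[4] and g[1] < _CEN_START + 1_000_000)
    marks.append(("chr5", chr5_dep_gene[1], chr5_dep_gene[2], "H3K27me3"))

    expansion = []
    for name, cen_len in zip(names, cen_lengths):
        if name not in ("chr2", "chr5", "chr9", "chr10"):
            continue
        cen_end = _CEN_START + cen_len
        expansion.append((f"cen_{name}", name, 60_000, 460_000, cen_end + 60_000, cen_end + 460_000))
        # gene-rich nonexpanded flank vs gene-poor expanded flank
        for j in range(8):
            s = cen_end + 80_000 + j * 40_000
            gid += 1
            genes.append((name, s, s + 3_000, f"flankgene{gid:03d}", True))
            marks += _gene_marks(name, s, s + 3_000)
        gid += 1
        s = 200_000
        genes.append((name, s, s + 3_000, f"flankgene{gid:03d}", True))
        marks += _gene_marks(name, s, s + 3_000)

    return GeneratorConfig(
        n_chromosomes=len(names),
        chrom_length=chrom_lengths,
        chrom_names=names,
        centromere_intervals=cens,
        satellite_arrays=arrays,
        depleted_subdomains=depleted,
        genes=genes,
        mark_peaks=marks,
        expansion_regions=expansion,
        n_fragments_chip=n_fragments_chip,
        n_fragments_input=n_fragments_input,
        n_fragments_naked=n_fragments_naked,
        seed=seed,
    )


def _gene_marks(chrom, s, e):
    return [
        (chrom, s - 500, s + 1_000, "H3K4me3"),
        (chrom, s, e, "H3K36me3"),
        (chrom, s - 500, s + 500, "H3K9ac"),
    ]


def minimal_preset(seed: int = 0, n_fragments: int = 50_000) -> GeneratorConfig:
    """A small single-chromosome configuration for quick runs and examples."""
    return GeneratorConfig(
        n_chromosomes=1,
        chrom_length=5_000_000,
        chrom_names=["chr1"],
        centromere_intervals=[("chr1", 1_800_000, 3_200_000)],
        satellite_arrays=[("chr1", 2_000_000, 200)],
        # two alternating depleted subdomains (each < the 100-kb island merge gap)
        depleted_subdomains=[("chr1", 2_300_000, 2_350_000), ("chr1", 2_450_000, 2_500_000)],
        genes=[("chr1", 2_310_000, 2_313_000, "cengene001", True),
               ("chr1", 2_460_000, 2_463_000, "cengene002", False),
               ("chr1", 2_800_000, 2_803_000, "cengene003", False)],
        mark_peaks=_gene_marks("chr1", 2_310_000, 2_313_000),
        n_fragments_chip=n_fragments,
        n_fragments_input=n_fragments,
        n_fragments_naked=n_fragments,
        seed=seed,
    )
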